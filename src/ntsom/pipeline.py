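"""End-to-end workflow: screen -> select -> split -> model -> project -> compare.

``run_pipeline`` executes the six-step analysis on either a simulated
campaign or a three-file CSV dataset plus blanks, writes every
intermediate table as plain CSV/JSON (so any stage can be inspected or
re-entered), and returns a machine-readable :class:`RunReport` with the
dimension chain, filter bookkeeping, map quality table and the outlier
sets of both models together with their agreement (Jaccard index).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pca as pca_mod
from . import som as som_mod
from .data_io import (
    FeatureTable,
    ValidationError,
    read_feature_table,
    serialize_model,
    write_feature_table,
)
from .screening import (
    blank_filter,
    combine_reports,
    correctness_filter,
    dilution_ttest_filter,
    zscore_apply,
    zscore_fit,
)
from .selection import hca, ordered_heatmap, select_unknown_common, split_subsets
from .synthetic import SyntheticConfig, generate

log = logging.getLogger("ntsom")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    # data: either simulate=True or the 2x three-file layout
    simulate: bool = True
    areas: str | None = None
    samples: str | None = None
    compounds: str | None = None
    blank_areas: str | None = None
    blank_samples: str | None = None
    blank_compounds: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # screening
    blank_factor: float = 5.0
    ttest_alpha: float = 0.05
    ttest_method: str = "paired"
    ttest_scale: str = "log10"
    # selection
    k: int = 5
    delta: float = 2.0
    manual_discard: list[str] | None = None
    # SOM
    som_mode: str = "explicit"
    som_dims: tuple[int, int] = (4, 3)
    rough_epochs: int = 50
    finetune_epochs: int = 100
    qe_threshold_multiplier: float = 1.0
    extra_candidate_dims: tuple[tuple[int, int], ...] = ((5, 3), (4, 3))
    # PCA
    pca_ncomp: int | str = "auto"
    pca_alpha: float = 0.05
    pca_gamma: float = 0.05
    # misc
    out_dir: str = "ntsom_out"
    seed: int = 0
    verbose: bool = False

    def validate(self) -> None:
        if not self.simulate:
            needed = (
                self.areas,
                self.samples,
                self.compounds,
                self.blank_areas,
                self.blank_samples,
                self.blank_compounds,
            )
            if any(p is None for p in needed):
                raise ValidationError(
                    "file mode requires areas/samples/compounds paths for both "
                    "the sample table and the blank table"
                )
        if self.som_mode not in ("regular", "small", "explicit"):
            raise ValidationError(f"unknown som_mode {self.som_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        # run location is not analysis configuration; keeping it out makes
        # reports of identical runs byte-identical wherever they are written
        d.pop("out_dir", None)
        return d


@dataclass
class RunReport:
    config: dict
    stages: list[dict]
    filter_report: dict
    eigen_ratio: float
    quality_table: list[dict]
    som_outliers: list[str]
    pca_outliers: list[str]
    jaccard: float
    disagreements: list[str]
    per_sample: list[dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def _stage(stages: list[dict], name: str, **info) -> None:
    stages.append({"stage": name, **info})
    log.info("stage %-14s %s", name, info)


def compare_models(
    som_projection: som_mod.ProjectionResult,
    pca_records: list[pca_mod.DistanceRecord],
) -> dict:
    """Per-sample comparison of the two outlier detectors.

    Returns the Jaccard index of the two outlier sample sets (1.0 when
    both are empty), the disagreement list, and a per-sample table with
    QE, SD, OD and both flags.
    """
    som_ids = list(som_projection.sample_ids)
    pca_ids = [r.sample_id for r in pca_records]
    if sorted(som_ids) != sorted(pca_ids):
        raise ValidationError("SOM and PCA results cover different sample sets")
    pca_by_id = {r.sample_id: r for r in pca_records}
    som_flags = dict(zip(som_ids, som_projection.is_outlier))
    qes = dict(zip(som_ids, som_projection.qe))

    som_set = {s for s, f in som_flags.items() if f}
    pca_set = {r.sample_id for r in pca_records if r.category == "outlier"}
    union = som_set | pca_set
    jaccard = 1.0 if not union else len(som_set & pca_set) / len(union)
    table = [
        {
            "sample_id": sid,
            "qe": float(qes[sid]),
            "sd": pca_by_id[sid].sd,
            "od": pca_by_id[sid].od,
            "som_outlier": bool(som_flags[sid]),
            "pca_outlier": pca_by_id[sid].category == "outlier",
        }
        for sid in som_ids
    ]
    return {
        "jaccard": jaccard,
        "som_outliers": sorted(som_set),
        "pca_outliers": sorted(pca_set),
        "disagreements": sorted(som_set ^ pca_set),
        "per_sample": table,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages in order; see the module docstring."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    # ---- 0. data ---------------------------------------------------------
    try:
        if config.simulate:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            table, blanks, truth = generate(syn)
            (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
            write_feature_table(table, out / "input")
            write_feature_table(blanks, out / "blanks")
        else:
            table = read_feature_table(config.areas, config.samples, config.compounds)
            blanks = read_feature_table(
                config.blank_areas, config.blank_samples, config.blank_compounds
            )
    except Exception as e:
        raise StageError("data", e) from e
    _stage(stages, "data", n_samples=table.n_samples, n_compounds=table.n_compounds)

    # ---- 1. screening ----------------------------------------------------
    try:
        t1, rep_blank = blank_filter(table, blanks, factor=config.blank_factor)
        t2, rep_ttest = dilution_ttest_filter(
            t1,
            alpha=config.ttest_alpha,
            method=config.ttest_method,
            scale=config.ttest_scale,
        )
        t3, rep_corr = correctness_filter(t2)
        report = combine_reports(rep_blank, rep_ttest, rep_corr)
    except Exception as e:
        raise StageError("screening", e) from e
    _stage(stages, "screening", n_in=table.n_compounds, n_out=t3.n_compounds)
    if config.verbose:
        log.info("  blank=%d ttest=%d correctness=%d",
                 report.n_discarded_blank, report.n_discarded_ttest,
                 report.n_discarded_correctness)
    write_feature_table(t3, out / "screened")
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    # ---- 2. unknown-common selection ------------------------------------
    try:
        full_scaler = zscore_fit(t3)
        z_full = zscore_apply(t3, full_scaler)
        comp_dend = hca(z_full.areas, axis="compounds", items=z_full.compound_ids)
        samp_dend = hca(z_full.areas, axis="samples", items=z_full.sample_ids)
        selection = select_unknown_common(
            z_full,
            comp_dend,
            k=config.k,
            delta=config.delta,
            manual_discard_ids=config.manual_discard,
        )
        if not selection.unknown_common_ids:
            raise ValidationError("no unknown-common compounds selected")
    except StageError:
        raise
    except Exception as e:
        raise StageError("selection", e) from e
    _stage(
        stages,
        "selection",
        n_in=t3.n_compounds,
        n_out=len(selection.unknown_common_ids),
        discarded_clusters=len(selection.discarded_clusters),
    )
    ordered_heatmap(z_full, samp_dend, comp_dend).to_csv(out / "heatmap.csv")
    pd.DataFrame(
        {
            "compound_id": selection.unknown_common_ids,
            "confidence_level": [
                c.confidence_level
                for c in t3.compounds
                if c.compound_id in set(selection.unknown_common_ids)
            ],
        }
    ).to_csv(out / "unknown_common.csv", index=False)

    # ---- 3. split --------------------------------------------------------
    try:
        common = t3.select_compounds(selection.unknown_common_ids)
        urban, industrial = split_subsets(common)
        if industrial is None:
            raise ValidationError("no industrial samples to project")
    except StageError:
        raise
    except Exception as e:
        raise StageError("split", e) from e
    _stage(stages, "split", urban=urban.n_samples, industrial=industrial.n_samples)
    write_feature_table(urban, out / "urban")
    write_feature_table(industrial, out / "industrial")

    # ---- 4. model building ----------------------------------------------
    try:
        scaler = zscore_fit(urban)
        z_urban = zscore_apply(urban, scaler)
        z_industrial = zscore_apply(industrial, scaler)
        serialize_model(scaler, out / "scaler.json")

        ratio = som_mod.eigen_ratio(z_urban.areas)
        tcfg = som_mod.SOMTrainingConfig(
            rough_epochs=config.rough_epochs,
            finetune_epochs=config.finetune_epochs,
        )
        candidates: list[tuple[str, som_mod.SOMGrid]] = [
            ("regular", som_mod.map_size(z_urban.n_samples, ratio, "regular")),
            ("small", som_mod.map_size(z_urban.n_samples, ratio, "small")),
        ]
        for dims in config.extra_candidate_dims:
            candidates.append(
                (f"{dims[0]}x{dims[1]}",
                 som_mod.map_size(0, 1.0, "explicit", dims=dims))
            )
        quality_rows = []
        for label, grid in candidates:
            m = som_mod.train(z_urban.areas, grid, tcfg,
                              scaling=scaler, variable_ids=z_urban.compound_ids)
            q = m.quality
            quality_rows.append(
                {
                    "map": label,
                    "xdim": grid.xdim,
                    "ydim": grid.ydim,
                    "ratio": round(grid.ratio, 1),
                    "dead_nodes": q.dead_nodes,
                    "dead_node_fraction": round(q.dead_node_fraction, 2),
                    "dme": q.dme,
                    "qe": q.qe,
                    "te": q.te,
                }
            )
        if config.som_mode == "explicit":
            final_grid = som_mod.map_size(0, 1.0, "explicit", dims=config.som_dims)
        else:
            final_grid = som_mod.map_size(z_urban.n_samples, ratio, config.som_mode)
        som_model = som_mod.train(
            z_urban.areas, final_grid, tcfg,
            scaling=scaler, variable_ids=z_urban.compound_ids
        )
        serialize_model(som_model, out / "som.json")

        pca_model = pca_mod.pca_fit(z_urban, config.pca_ncomp, scaling=scaler)
        train_dist = pca_mod.distances(pca_model, z_urban)
        sd_lim, od_lim = pca_mod.critical_limits(
            pca_model, train_dist, alpha=config.pca_alpha, gamma=config.pca_gamma
        )
        serialize_model(pca_model, out / "pca.json")
    except StageError:
        raise
    except Exception as e:
        raise StageError("modeling", e) from e
    _stage(
        stages,
        "modeling",
        som_nodes=som_model.grid.n_nodes,
        eigen_ratio=ratio,
        pca_components=pca_model.n_components,
    )
    pd.DataFrame(quality_rows).to_csv(out / "quality_table.csv", index=False)

    # ---- 5. projection ---------------------------------------------------
    try:
        proj_urban = som_mod.project(
            som_model, z_urban, threshold_multiplier=config.qe_threshold_multiplier
        )
        proj_industrial = som_mod.project(
            som_model, z_industrial,
            threshold_multiplier=config.qe_threshold_multiplier,
        )
        pca_train = pca_mod.classify(train_dist, sd_lim, od_lim)
        pca_new = pca_mod.classify(
            pca_mod.distances(pca_model, z_industrial), sd_lim, od_lim
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError("projection", e) from e
    _stage(
        stages,
        "projection",
        som_flagged=int(proj_industrial.is_outlier.sum()),
        pca_flagged=sum(r.category == "outlier" for r in pca_new),
    )
    proj_all = som_mod.ProjectionResult(
        sample_ids=proj_urban.sample_ids + proj_industrial.sample_ids,
        bmu=np.concatenate([proj_urban.bmu, proj_industrial.bmu]),
        qe=np.concatenate([proj_urban.qe, proj_industrial.qe]),
        is_outlier=np.concatenate(
            [proj_urban.is_outlier, proj_industrial.is_outlier]
        ),
        threshold=proj_urban.threshold,
    )
    proj_all.to_frame().to_csv(out / "projection.csv", index=False,
                               float_format="%.17g")
    for node in range(1, som_model.grid.n_nodes + 1):
        som_mod.node_signature(som_model, node, urban.compounds).to_csv(
            out / f"node_{node}_signature.csv", index=False
        )
    all_records = pca_train + pca_new
    pd.DataFrame(
        [dataclasses.asdict(r) for r in all_records]
    ).to_csv(out / "distances.csv", index=False)
    pca_mod.dd_plot_data(
        all_records, sd_lim, od_lim, samples=urban.samples + industrial.samples
    ).to_csv(out / "ddplot.csv", index=False)

    # ---- 6. comparison ---------------------------------------------------
    try:
        comparison = compare_models(proj_all, all_records)
    except Exception as e:
        raise StageError("comparison", e) from e
    _stage(stages, "comparison", jaccard=comparison["jaccard"])

    report_obj = RunReport(
        config=config.to_dict(),
        stages=stages,
        filter_report=report.to_dict(),
        eigen_ratio=float(ratio),
        quality_table=quality_rows,
        som_outliers=comparison["som_outliers"],
        pca_outliers=comparison["pca_outliers"],
        jaccard=comparison["jaccard"],
        disagreements=comparison["disagreements"],
        per_sample=comparison["per_sample"],
    )
    (out / "report.json").write_text(report_obj.to_json())
    return report_obj
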