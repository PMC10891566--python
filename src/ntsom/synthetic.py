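"""Synthetic feature-table generator for the wastewater study design.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage can be exercised and validated without the
(unreleased) instrument data:

* 6 urban + 4 industrial sites, 2 replicates, 2 dilution levels
  (concentrated and 1:10 diluted) -> 40 samples; 2 sequence blanks per
  site in a separate table;
* four compound classes with known ground truth:

  - ``common``       present at every site; half of them additionally
                     carry a shared industrial load -- the same compounds
                     are elevated (by a per-compound log10 offset of
                     about one order of magnitude, plus a small
                     site-idiosyncratic term) at every industrial site.
                     This is the industrial fingerprint the outlier
                     models are expected to detect, strong enough that
                     even 1:10-diluted industrial samples deviate beyond
                     urban replicate scatter, yet, being shared by both
                     site types, weak enough in the pooled z-score
                     geometry that the compounds still cluster as
                     commons rather than as industrial-peculiar blocks;
  - ``industrial_exclusive``  near-zero everywhere except a single
                     assigned industrial site (by default the exclusives
                     are partitioned among 3 of the 4 industrial sites);
  - ``background``   blank-dominated: the sequence blanks carry at least
                     1/5 of the sample area, so the 5x blank rule must
                     remove them;
  - ``artifact``     dilution-ignoring features whose diluted replicates
                     are *higher* than the concentrated ones, which the
                     dilution filters must remove.

Peak areas are log-normal: a per-compound log10 baseline plus class and
site effects, times multiplicative replicate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    CompoundRecord,
    FeatureTable,
    SampleRecord,
    ValidationError,
    build_sample_name,
)

CLASSES = ("common", "industrial_exclusive", "background", "artifact")

#: probabilities of annotation confidence levels 1..5, roughly the
#: proportions seen in real non-target annotation work
_CONFIDENCE_P = (0.003, 0.030, 0.022, 0.883, 0.062)


@dataclass
class SyntheticConfig:
    """Study-design constants and effect sizes of the generator."""

    n_urban_sites: int = 6
    n_industrial_sites: int = 4
    n_replicates: int = 2
    dilution_factor: float = 0.1
    n_common_compounds: int = 300
    n_industrial_exclusive: int = 60
    n_background: int = 40
    n_artifact: int = 30
    baseline_log10_mean: float = 6.0
    baseline_log10_sd: float = 0.5
    #: per-site deviation of each common compound from its shared
    #: baseline (log10 units): every plant has its own fingerprint
    site_log10_sd: float = 0.0
    replicate_cv: float = 0.15
    #: sd of the site-idiosyncratic industrial offset, in units of the
    #: baseline log10 spread (i.e. z-units on the log scale)
    industrial_shift_sd: float = 0.2
    #: mean log10 elevation of the shared industrial load carried by the
    #: shifted commons: the same compounds are raised at every industrial
    #: site, the signature the outlier models are expected to detect
    industrial_elevation_log10: float = 0.9
    #: per-compound spread of that shared elevation (log10)
    industrial_elevation_sd: float = 0.1
    #: fraction of common compounds that carry industrial offsets
    shifted_common_fraction: float = 0.5
    #: blank area as a fraction of the sample area, background compounds
    blank_level_fraction: float = 0.5
    #: log10 level of exclusives outside their assigned site ("near-zero")
    exclusive_low_log10: float = 2.0
    #: diluted/concentrated area ratio of artifact features (> 1)
    artifact_dilution_bias: float = 1.25
    #: number of industrial sites that host exclusive compounds
    n_exclusive_sites: int = 3
    n_blanks_per_site: int = 2
    seed: int = 0

    def validate(self) -> None:
        if min(
            self.n_urban_sites,
            self.n_industrial_sites,
            self.n_replicates,
        ) < 1:
            raise ValidationError("site and replicate counts must be >= 1")
        if min(
            self.n_common_compounds,
            self.n_industrial_exclusive,
            self.n_background,
            self.n_artifact,
        ) < 0:
            raise ValidationError("compound counts must be >= 0")
        if self.n_common_compounds < 2:
            raise ValidationError(
                "n_common_compounds must be >= 2 (clustering undefined otherwise)"
            )
        if not 0 < self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be in (0, 1)")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be >= 0")
        if self.artifact_dilution_bias <= 1:
            raise ValidationError("artifact_dilution_bias must be > 1")


@dataclass
class GroundTruth:
    """Latent structure of a generated table, used as a test oracle."""

    compound_class: dict[str, str]
    #: per-site log10 concentrated-sample levels, sites x compounds
    site_profiles: pd.DataFrame
    #: common compounds that carry industrial offsets
    shifted_common: list[str]
    config: SyntheticConfig

    def ids_of(self, cls: str) -> list[str]:
        return [cid for cid, c in self.compound_class.items() if c == cls]

    def to_dict(self) -> dict:
        return {
            "schema": "ntsom/ground-truth",
            "version": 1,
            "compound_class": self.compound_class,
            "shifted_common": list(self.shifted_common),
        }


@dataclass
class ExpectedOutcome:
    """What screening and common-compound selection should produce."""

    screened: set[str]
    unknown_common: set[str]
    blank_failures: set[str]
    dilution_failures: set[str]


def _site_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    urban = [f"U{i + 1}" for i in range(config.n_urban_sites)]
    industrial = [f"I{i + 1}" for i in range(config.n_industrial_sites)]
    return urban, industrial


def generate(
    config: SyntheticConfig | None = None,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Generate ``(samples, blanks, truth)`` for one simulated campaign.

    Deterministic in ``config.seed``: the same configuration always
    produces bit-identical tables.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    urban_sites, industrial_sites = _site_names(config)
    sites = urban_sites + industrial_sites
    n_sites = len(sites)

    # ---- compound inventory ---------------------------------------------
    classes = (
        ["common"] * config.n_common_compounds
        + ["industrial_exclusive"] * config.n_industrial_exclusive
        + ["background"] * config.n_background
        + ["artifact"] * config.n_artifact
    )
    n_compounds = len(classes)
    ids = [f"F{i + 1:04d}" for i in range(n_compounds)]
    compounds = [
        CompoundRecord(
            compound_id=cid,
            mz=float(mz),
            rt=float(rt),
            name=None,
            confidence_level=int(level),
        )
        for cid, mz, rt, level in zip(
            ids,
            rng.uniform(60.0, 1000.0, n_compounds),
            rng.uniform(0.5, 26.0, n_compounds),
            rng.choice([1, 2, 3, 4, 5], size=n_compounds, p=_CONFIDENCE_P),
        )
    ]

    # ---- latent per-site log10 levels (concentrated samples) ------------
    levels = np.zeros((n_sites, n_compounds))
    is_class = {c: np.array([cls == c for cls in classes]) for c in CLASSES}
    shift_sd_log10 = config.industrial_shift_sd * config.baseline_log10_sd

    common_idx = np.flatnonzero(is_class["common"])
    mu_common = rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, common_idx.size
    )
    # every site (urban and industrial) draws its own fingerprint around
    # the shared baseline of each common compound
    levels[:, common_idx] = mu_common[None, :] + rng.normal(
        0.0, config.site_log10_sd, (n_sites, common_idx.size)
    )
    n_shifted = int(round(config.shifted_common_fraction * common_idx.size))
    shifted_local = rng.choice(common_idx.size, size=n_shifted, replace=False)
    shifted_local.sort()
    shifted_idx = common_idx[shifted_local]
    # shared industrial load: the same commons are elevated at every
    # industrial site (per-compound magnitude), plus a site-idiosyncratic
    # zero-mean offset on top
    elevation = rng.normal(
        config.industrial_elevation_log10,
        config.industrial_elevation_sd,
        shifted_idx.size,
    )
    for k, s in enumerate(industrial_sites):
        row = len(urban_sites) + k
        levels[row, shifted_idx] += elevation + rng.normal(
            0.0, shift_sd_log10, shifted_idx.size
        )

    excl_idx = np.flatnonzero(is_class["industrial_exclusive"])
    host_sites = industrial_sites[: max(1, min(config.n_exclusive_sites,
                                               len(industrial_sites)))]
    levels[:, excl_idx] = config.exclusive_low_log10
    assigned = [host_sites[i % len(host_sites)] for i in range(excl_idx.size)]
    mu_excl = rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, excl_idx.size
    )
    for j, site, mu in zip(excl_idx, assigned, mu_excl):
        levels[sites.index(site), j] = mu

    bg_idx = np.flatnonzero(is_class["background"])
    levels[:, bg_idx] = rng.normal(
        config.baseline_log10_mean - 1.0, 0.3, bg_idx.size
    )[None, :]

    art_idx = np.flatnonzero(is_class["artifact"])
    levels[:, art_idx] = rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, art_idx.size
    )[None, :]

    # ---- samples ---------------------------------------------------------
    samples: list[SampleRecord] = []
    for site in sites:
        site_type = "urban" if site in urban_sites else "industrial"
        for dilution in ("concentrated", "diluted"):
            for rep in range(1, config.n_replicates + 1):
                samples.append(
                    SampleRecord(
                        sample_id=build_sample_name(site, site_type, dilution, rep),
                        site=site,
                        site_type=site_type,
                        dilution=dilution,
                        replicate=rep,
                    )
                )

    sigma_ln = float(np.sqrt(np.log1p(config.replicate_cv**2)))
    log10_dil = np.log10(config.dilution_factor)
    log10_bias = np.log10(config.artifact_dilution_bias)
    dil_responsive = is_class["common"] | is_class["industrial_exclusive"]

    areas = np.zeros((len(samples), n_compounds))
    for i, rec in enumerate(samples):
        log10_level = levels[sites.index(rec.site)].copy()
        if rec.dilution == "diluted":
            log10_level[dil_responsive] += log10_dil
            log10_level[is_class["artifact"]] += log10_bias
        noise = rng.normal(0.0, sigma_ln, n_compounds) if sigma_ln > 0 else 0.0
        areas[i] = 10.0**log10_level * np.exp(noise)

    # guarantee the artifact signature: every site's diluted mean exceeds
    # its concentrated mean, so the dilution filters must discard them
    rows_of_site = {
        site: {
            d: [i for i, r in enumerate(samples) if r.site == site and r.dilution == d]
            for d in ("concentrated", "diluted")
        }
        for site in sites
    }
    for j in art_idx:
        for site in sites:
            conc = rows_of_site[site]["concentrated"]
            dil = rows_of_site[site]["diluted"]
            cm = areas[conc, j].mean()
            dm = areas[dil, j].mean()
            if dm <= cm:
                areas[dil, j] *= (cm / dm) * config.artifact_dilution_bias

    # ---- blanks ----------------------------------------------------------
    blank_samples: list[SampleRecord] = []
    blank_rows: list[np.ndarray] = []
    for site in sites:
        for rep in range(1, config.n_blanks_per_site + 1):
            blank_samples.append(
                SampleRecord(
                    sample_id=build_sample_name(site, "blank", "concentrated", rep),
                    site=site,
                    site_type="blank",
                    dilution="concentrated",
                    replicate=rep,
                )
            )
            row = np.zeros(n_compounds)
            noise = (
                rng.normal(0.0, sigma_ln, bg_idx.size) if sigma_ln > 0 else 0.0
            )
            row[bg_idx] = (
                config.blank_level_fraction
                * 10.0 ** levels[sites.index(site), bg_idx]
                * np.exp(noise)
            )
            blank_rows.append(row)

    table = FeatureTable(areas=areas, samples=samples, compounds=compounds)
    blanks = FeatureTable(
        areas=np.vstack(blank_rows) if blank_rows else np.zeros((0, n_compounds)),
        samples=blank_samples,
        compounds=compounds,
    )
    truth = GroundTruth(
        compound_class=dict(zip(ids, classes)),
        site_profiles=pd.DataFrame(levels, index=sites, columns=ids),
        shifted_common=[ids[j] for j in shifted_idx],
        config=config,
    )
    return table, blanks, truth


def truth_filter_outcome(truth: GroundTruth) -> ExpectedOutcome:
    """Expected screening/selection outcome implied by the ground truth.

    Background features must fall to the blank filter and artifacts to
    the dilution filters, so the screened set is the commons plus the
    industrial exclusives; the exclusives are then removed as peculiar
    clusters, leaving exactly the common class as "unknown commons".
    """
    common = set(truth.ids_of("common"))
    exclusive = set(truth.ids_of("industrial_exclusive"))
    return ExpectedOutcome(
        screened=common | exclusive,
        unknown_common=common,
        blank_failures=set(truth.ids_of("background")),
        dilution_failures=set(truth.ids_of("artifact")),
    )
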