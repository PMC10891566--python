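"""Shared fixtures: small hand-built tables and one full seeded campaign."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from ntsom import (
    CompoundRecord,
    FeatureTable,
    SampleRecord,
    SyntheticConfig,
    blank_filter,
    correctness_filter,
    dilution_ttest_filter,
    generate,
    hca,
    select_unknown_common,
    split_subsets,
    truth_filter_outcome,
    zscore_apply,
    zscore_fit,
)
from ntsom import pca as pca_mod
from ntsom import som as som_mod


def make_table(
    areas,
    sites,
    site_types=None,
    n_replicates=2,
    dilutions=("concentrated", "diluted"),
    compound_ids=None,
):
    """Build a FeatureTable with one row per (site, dilution, replicate).

    ``areas`` must have len(sites) * len(dilutions) * n_replicates rows,
    ordered site-major, then dilution, then replicate.
    """
    areas = np.asarray(areas, dtype=float)
    site_types = site_types or {
        s: ("industrial" if s.startswith("I") else "urban") for s in sites
    }
    samples = []
    for site in sites:
        for dil in dilutions:
            for rep in range(1, n_replicates + 1):
                letter = "c" if dil == "concentrated" else "d"
                samples.append(
                    SampleRecord(
                        sample_id=f"{site}{letter}{rep}",
                        site=site,
                        site_type=site_types[site],
                        dilution=dil,
                        replicate=rep,
                    )
                )
    n_compounds = areas.shape[1]
    compound_ids = compound_ids or [f"C{j + 1}" for j in range(n_compounds)]
    compounds = [
        CompoundRecord(compound_id=cid, mz=100.0 + j, rt=1.0 + 0.1 * j)
        for j, cid in enumerate(compound_ids)
    ]
    return FeatureTable(areas=areas, samples=samples, compounds=compounds)


def make_blanks(table: FeatureTable, blank_areas_by_site: dict):
    """Blank table (2 blanks per site) matching a table's compound set."""
    samples, rows = [], []
    for site in table.sites():
        for rep in (1, 2):
            samples.append(
                SampleRecord(
                    sample_id=f"{site}b{rep}",
                    site=site,
                    site_type="blank",
                    dilution="concentrated",
                    replicate=rep,
                )
            )
            rows.append(np.asarray(blank_areas_by_site[site], dtype=float))
    return FeatureTable(
        areas=np.vstack(rows), samples=samples, compounds=list(table.compounds)
    )


def ward_oracle_heights(X: np.ndarray) -> list[float]:
    """Brute-force Ward agglomeration via the Lance-Williams recurrence.

    Returns merge heights (distance scale, Ward.D2 convention) in merge
    order.  O(n^3); serves as an independent oracle for hca().
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    size = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())
    heights = []
    next_id = n
    while len(size) > 1:
        (a, b), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(float(np.sqrt(best)))
        na, nb = size[a], size[b]
        new = next_id
        next_id += 1
        updates = {}
        for c in size:
            if c in (a, b):
                continue
            nc = size[c]
            dac = d2[(min(a, c), max(a, c))]
            dbc = d2[(min(b, c), max(b, c))]
            updates[(min(new, c), max(new, c))] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * best
            ) / (na + nb + nc)
        d2 = {
            k: v for k, v in d2.items() if a not in k and b not in k
        }
        d2.update(updates)
        del size[a], size[b]
        size[new] = na + nb
    return heights


@dataclass
class Campaign:
    """All intermediate products of one seeded default analysis."""

    config: SyntheticConfig
    table: FeatureTable
    blanks: FeatureTable
    truth: object
    expected: object
    screened: FeatureTable
    reports: tuple
    z_full: FeatureTable
    dend: object
    selection: object
    urban: FeatureTable
    industrial: FeatureTable
    scaler: object
    z_urban: FeatureTable
    z_industrial: FeatureTable
    som: object
    projection: object
    pca: object
    train_distances: list
    new_distances: list
    sd_limits: object
    od_limits: object


@pytest.fixture(scope="session")
def campaign() -> Campaign:
    """Default generator at seed 1, run through every pipeline stage."""
    cfg = SyntheticConfig(seed=1)
    table, blanks, truth = generate(cfg)
    t1, r1 = blank_filter(table, blanks)
    t2, r2 = dilution_ttest_filter(t1)
    t3, r3 = correctness_filter(t2)
    scaler_full = zscore_fit(t3)
    z_full = zscore_apply(t3, scaler_full)
    dend = hca(z_full.areas, axis="compounds", items=z_full.compound_ids)
    selection = select_unknown_common(z_full, dend)
    common = t3.select_compounds(selection.unknown_common_ids)
    urban, industrial = split_subsets(common)
    scaler = zscore_fit(urban)
    z_urban = zscore_apply(urban, scaler)
    z_industrial = zscore_apply(industrial, scaler)
    grid = som_mod.map_size(0, 1.0, "explicit", dims=(4, 3))
    som = som_mod.train(
        z_urban.areas, grid, scaling=scaler, variable_ids=z_urban.compound_ids
    )
    projection = som_mod.project(som, z_industrial)
    pca = pca_mod.pca_fit(z_urban, "auto", scaling=scaler)
    train_distances = pca_mod.distances(pca, z_urban)
    sd_limits, od_limits = pca_mod.critical_limits(pca, train_distances)
    pca_mod.classify(train_distances, sd_limits, od_limits)
    new_distances = pca_mod.classify(
        pca_mod.distances(pca, z_industrial), sd_limits, od_limits
    )
    return Campaign(
        config=cfg,
        table=table,
        blanks=blanks,
        truth=truth,
        expected=truth_filter_outcome(truth),
        screened=t3,
        reports=(r1, r2, r3),
        z_full=z_full,
        dend=dend,
        selection=selection,
        urban=urban,
        industrial=industrial,
        scaler=scaler,
        z_urban=z_urban,
        z_industrial=z_industrial,
        som=som,
        projection=projection,
        pca=pca,
        train_distances=train_distances,
        new_distances=new_distances,
        sd_limits=sd_limits,
        od_limits=od_limits,
    )
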