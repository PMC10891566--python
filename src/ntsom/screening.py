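"""Compound-level screening filters and the z-score transform.

Three filters remove undesired features from a raw peak-area table,
applied in this order:

1. **blank filter** -- a compound whose area in *any* sample is less than
   ``factor`` (default 5) times the mean area in that site's sequence
   blanks is background and is discarded;
2. **dilution t-test filter** -- a compound whose concentrated and 1:10
   diluted areas are not statistically different (p > alpha) shows no
   area/concentration relationship and is discarded;
3. **"Correctness" filter** -- per site, a 0/1 dummy records whether the
   diluted replicate mean is strictly lower than the concentrated one; a
   compound is discarded when the median of the dummies over sites is
   below 1.

The t-test defaults to a paired test on log10 areas: replicates pair
with their same-site diluted counterparts, and the log scale turns the
1:10 dilution into a constant additive offset, so the test's power does
not depend on between-site intensity differences.  The pooled Welch
variant on either scale is available through ``method``/``scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import FeatureTable, ScalingModel, ValidationError

FILTER_BLANK = "blank"
FILTER_TTEST = "ttest"
FILTER_CORRECTNESS = "correctness"


@dataclass
class FilterReport:
    """Bookkeeping of one filter pass (or a whole screening pipeline)."""

    n_input: int
    n_discarded_blank: int = 0
    n_discarded_ttest: int = 0
    n_discarded_correctness: int = 0
    n_retained: int = 0
    per_compound_flags: dict[str, set[str]] = field(default_factory=dict)

    def check(self) -> None:
        discarded = (
            self.n_discarded_blank
            + self.n_discarded_ttest
            + self.n_discarded_correctness
        )
        if self.n_input - discarded != self.n_retained:
            raise ValidationError("filter report counts are inconsistent")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_discarded_blank": self.n_discarded_blank,
            "n_discarded_ttest": self.n_discarded_ttest,
            "n_discarded_correctness": self.n_discarded_correctness,
            "n_retained": self.n_retained,
            "per_compound_flags": {
                k: sorted(v) for k, v in sorted(self.per_compound_flags.items())
            },
        }


def combine_reports(*reports: FilterReport) -> FilterReport:
    """Chain single-filter reports applied in pipeline order."""
    if not reports:
        raise ValidationError("no reports to combine")
    flags: dict[str, set[str]] = {}
    for r in reports:
        for cid, fs in r.per_compound_flags.items():
            flags.setdefault(cid, set()).update(fs)
    combined = FilterReport(
        n_input=reports[0].n_input,
        n_discarded_blank=sum(r.n_discarded_blank for r in reports),
        n_discarded_ttest=sum(r.n_discarded_ttest for r in reports),
        n_discarded_correctness=sum(r.n_discarded_correctness for r in reports),
        n_retained=reports[-1].n_retained,
        per_compound_flags=flags,
    )
    combined.check()
    return combined


def _retained_table(table: FeatureTable, keep: np.ndarray) -> FeatureTable:
    kept_ids = [c.compound_id for c, k in zip(table.compounds, keep) if k]
    if not kept_ids:
        raise ValidationError("filter discarded every compound")
    return table.select_compounds(kept_ids)


# ---------------------------------------------------------------------------
# 1. blank filter
# ---------------------------------------------------------------------------


def blank_filter(
    table: FeatureTable, blanks: FeatureTable, factor: float = 5.0
) -> tuple[FeatureTable, FilterReport]:
    """Discard compounds not sufficiently above their sequence blanks.

    The comparison is strict: a compound survives when every sample area
    is >= ``factor`` times the mean blank area of that sample's site.  A
    compound absent from all blanks (zero blank mean) is always retained.
    """
    if factor <= 0:
        raise ValidationError("blank factor must be > 0")
    if blanks.compound_ids != table.compound_ids:
        raise ValidationError("blank table must share the compound set of the table")

    blank_mean: dict[str, np.ndarray] = {}
    blank_sites = np.array([s.site for s in blanks.samples])
    for site in {s.site for s in table.samples}:
        rows = np.flatnonzero(blank_sites == site)
        if rows.size == 0:
            raise ValidationError(f"no blanks for site {site!r}")
        blank_mean[site] = blanks.areas[rows].mean(axis=0)

    thresholds = np.vstack(
        [factor * blank_mean[s.site] for s in table.samples]
    )
    discard = (table.areas < thresholds).any(axis=0)

    flags = {
        table.compound_ids[j]: {FILTER_BLANK} for j in np.flatnonzero(discard)
    }
    report = FilterReport(
        n_input=table.n_compounds,
        n_discarded_blank=int(discard.sum()),
        n_retained=int((~discard).sum()),
        per_compound_flags=flags,
    )
    report.check()
    return _retained_table(table, ~discard), report


# ---------------------------------------------------------------------------
# 2. dilution t-test filter
# ---------------------------------------------------------------------------


def _paired_rows(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of (concentrated, diluted) pairs matched by site+replicate."""
    conc = {
        (s.site, s.replicate): i
        for i, s in enumerate(table.samples)
        if s.dilution == "concentrated"
    }
    dil = {
        (s.site, s.replicate): i
        for i, s in enumerate(table.samples)
        if s.dilution == "diluted"
    }
    unmatched = set(conc) ^ set(dil)
    if unmatched:
        raise ValidationError(
            f"unpaired (site, replicate) combinations: {sorted(unmatched)}"
        )
    keys = sorted(conc)
    return (
        np.array([conc[k] for k in keys]),
        np.array([dil[k] for k in keys]),
    )


def dilution_ttest_filter(
    table: FeatureTable,
    alpha: float = 0.05,
    method: str = "paired",
    scale: str = "log10",
) -> tuple[FeatureTable, FilterReport]:
    """Discard compounds whose areas do not respond to the 1:10 dilution.

    Per compound, concentrated areas are tested against diluted areas and
    the compound is discarded iff p > ``alpha``.  ``method='paired'``
    (default) pairs each concentrated replicate with the diluted replicate
    of the same site; ``method='welch'`` pools both groups across sites
    and applies the unequal-variance two-sample test.  ``scale`` is
    ``'log10'`` (default, log10(area + 1)) or ``'raw'``.  Degenerate
    columns with zero variance and equal group means are treated as p = 1
    and discarded.
    """
    if method not in ("paired", "welch"):
        raise ValidationError(f"unknown t-test method {method!r}")
    if scale not in ("log10", "raw"):
        raise ValidationError(f"unknown t-test scale {scale!r}")

    conc_rows = np.flatnonzero(table.sample_mask(dilution="concentrated"))
    dil_rows = np.flatnonzero(table.sample_mask(dilution="diluted"))
    if conc_rows.size < 2 or dil_rows.size < 2:
        raise ValidationError("each dilution group needs at least 2 samples")

    values = np.log10(table.areas + 1.0) if scale == "log10" else table.areas

    if method == "paired":
        ci, di = _paired_rows(table)
        diffs = values[ci] - values[di]  # pairs x compounds
        mean = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_1samp(diffs, 0.0, axis=0)
            pvals = np.asarray(res.pvalue, dtype=float)
        degenerate = sd == 0
        pvals[degenerate & (mean == 0)] = 1.0
        pvals[degenerate & (mean != 0)] = 0.0
    else:
        a, b = values[conc_rows], values[dil_rows]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a, b, axis=0, equal_var=False)
            pvals = np.asarray(res.pvalue, dtype=float)
        degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
        equal = a.mean(axis=0) == b.mean(axis=0)
        pvals[degenerate & equal] = 1.0
        pvals[degenerate & ~equal] = 0.0
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    discard = pvals > alpha
    flags = {
        table.compound_ids[j]: {FILTER_TTEST} for j in np.flatnonzero(discard)
    }
    report = FilterReport(
        n_input=table.n_compounds,
        n_discarded_ttest=int(discard.sum()),
        n_retained=int((~discard).sum()),
        per_compound_flags=flags,
    )
    report.check()
    return _retained_table(table, ~discard), report


# ---------------------------------------------------------------------------
# 3. "Correctness" dummy-variable filter
# ---------------------------------------------------------------------------


def correctness_filter(table: FeatureTable) -> tuple[FeatureTable, FilterReport]:
    """Discard compounds whose site-median dilution dummy is below 1.

    Per compound and site the dummy is 1 iff the diluted replicate mean is
    strictly lower than the concentrated replicate mean.  A compound is
    retained iff the median of the dummies across sites equals 1.  The
    rule only compares within-site means, so it is invariant to any
    per-compound strictly increasing affine rescaling (raw vs z-scored
    input gives identical results).
    """
    sites = table.sites()
    dummies = np.zeros((len(sites), table.n_compounds))
    for r, site in enumerate(sites):
        conc = table.sample_mask(site=site, dilution="concentrated")
        dil = table.sample_mask(site=site, dilution="diluted")
        if not conc.any() or not dil.any():
            raise ValidationError(f"site {site!r} is missing a dilution level")
        dummies[r] = (
            table.areas[dil].mean(axis=0) < table.areas[conc].mean(axis=0)
        ).astype(float)

    medians = np.median(dummies, axis=0)
    discard = medians < 1.0
    flags = {
        table.compound_ids[j]: {FILTER_CORRECTNESS}
        for j in np.flatnonzero(discard)
    }
    report = FilterReport(
        n_input=table.n_compounds,
        n_discarded_correctness=int(discard.sum()),
        n_retained=int((~discard).sum()),
        per_compound_flags=flags,
    )
    report.check()
    return _retained_table(table, ~discard), report


# ---------------------------------------------------------------------------
# z-score transform
# ---------------------------------------------------------------------------


def zscore_fit(table: FeatureTable) -> ScalingModel:
    """Per-compound mean and sample sd (n-1 denominator) of the table.

    Compounds that are constant (sd = 0) cannot be scaled; they are
    recorded as dropped and removed when the model is applied.
    """
    if table.n_samples < 2:
        raise ValidationError("z-score fit needs at least 2 samples")
    means = table.areas.mean(axis=0)
    sds = table.areas.std(axis=0, ddof=1)
    keep = sds > 0
    return ScalingModel(
        compound_ids=[c for c, k in zip(table.compound_ids, keep) if k],
        means=means[keep],
        sds=sds[keep],
        dropped=[c for c, k in zip(table.compound_ids, keep) if not k],
        fitted_on=table.sample_ids,
    )


def zscore_apply(table: FeatureTable, model: ScalingModel) -> FeatureTable:
    """Apply a fitted z-score model; returns a table of z values.

    The output carries ``scaling_id`` so downstream models can verify
    that projection data were scaled with the same model.
    """
    missing = set(model.compound_ids) - set(table.compound_ids)
    if missing:
        raise ValidationError(
            f"table lacks compounds required by the scaling model: {sorted(missing)}"
        )
    sub = table.select_compounds(model.compound_ids)
    # align column order with the model
    order = [sub.compound_ids.index(c) for c in model.compound_ids]
    z = (sub.areas[:, order] - model.means) / model.sds
    return FeatureTable(
        areas=z,
        samples=list(sub.samples),
        compounds=[sub.compounds[i] for i in order],
        scaling_id=model.model_id,
    )
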