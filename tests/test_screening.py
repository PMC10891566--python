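"""Blank / dilution-t-test / Correctness filters and the z-score transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ntsom import (
    ValidationError,
    blank_filter,
    combine_reports,
    correctness_filter,
    dilution_ttest_filter,
    zscore_apply,
    zscore_fit,
)

from conftest import make_blanks, make_table


# -- blank filter ----------------------------------------------------------


def _one_site_table(area_value):
    return make_table(np.full((4, 1), float(area_value)), sites=["U1"])


@pytest.mark.parametrize(
    "area, blank_mean, survives",
    [
        (100.0, 25.0, False),  # 100 < 5*25 -> background
        (125.0, 25.0, True),   # exactly 5x: not strictly less -> retained
        (1.0, 0.0, True),      # zero blanks: always retained
    ],
)
def test_blank_filter_boundary_behavior(area, blank_mean, survives):
    t = _one_site_table(area)
    blanks = make_blanks(t, {"U1": [blank_mean]})
    if survives:
        out, rep = blank_filter(t, blanks)
        assert out.compound_ids == ["C1"]
        assert rep.n_discarded_blank == 0
    else:
        with pytest.raises(ValidationError, match="every compound"):
            blank_filter(t, blanks)


def test_blank_filter_uses_each_samples_site_blanks():
    # compound passes at U1 (clean blanks) but fails at I1 (dirty blanks)
    t = make_table(np.full((8, 1), 100.0), sites=["U1", "I1"])
    blanks = make_blanks(t, {"U1": [0.0], "I1": [30.0]})
    with pytest.raises(ValidationError, match="every compound"):
        blank_filter(t, blanks)
    clean = make_blanks(t, {"U1": [0.0], "I1": [10.0]})
    out, rep = blank_filter(t, clean)  # 100 >= 5*10 everywhere
    assert rep.n_retained == 1


def test_blank_filter_input_errors():
    t = _one_site_table(10.0)
    blanks = make_blanks(t, {"U1": [1.0]})
    with pytest.raises(ValidationError, match="factor"):
        blank_filter(t, blanks, factor=0.0)
    other = make_table(np.full((4, 2), 5.0), sites=["U1"])
    with pytest.raises(ValidationError, match="compound set"):
        blank_filter(other, blanks)
    lonely = make_table(np.full((4, 1), 10.0), sites=["U2"])
    with pytest.raises(ValidationError, match="U2"):
        blank_filter(lonely, blanks)


# -- dilution t-test -------------------------------------------------------


def _dilution_table(conc_values, dil_values, n_sites=3):
    """Sites x 2 reps; column 0 takes the given group values in order."""
    n = 2 * 2 * n_sites
    areas = np.empty((n, 1))
    t = make_table(np.ones((n, 1)), sites=[f"U{i+1}" for i in range(n_sites)])
    ci = di = 0
    for row, s in enumerate(t.samples):
        if s.dilution == "concentrated":
            areas[row, 0] = conc_values[ci]
            ci += 1
        else:
            areas[row, 0] = dil_values[di]
            di += 1
    t.areas = areas
    return t


def test_identical_groups_are_discarded_by_both_methods():
    t = _dilution_table([50.0] * 6, [50.0] * 6)
    for method in ("paired", "welch"):
        with pytest.raises(ValidationError, match="every compound"):
            dilution_ttest_filter(t, method=method, scale="raw")


def test_welch_example_matches_closed_form_oracle():
    """Clear 10x dilution response: Welch t from first principles agrees."""
    conc = [100.0, 102.0, 98.0, 101.0, 99.0, 100.0]
    dil = [10.0, 10.2, 9.8, 10.1, 9.9, 10.0]
    a, b = np.array(conc), np.array(dil)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p_oracle = 2.0 * stats.t.sf(abs(t_stat), dof)
    assert p_oracle < 0.05

    table = _dilution_table(conc, dil)
    out, rep = dilution_ttest_filter(table, method="welch", scale="raw")
    assert rep.n_discarded_ttest == 0 and out.compound_ids == ["C1"]


def test_paired_test_pairs_within_site():
    # exact 10x response with heavy between-site spread: the paired test
    # retains it on the log scale regardless of site differences
    conc = [100, 101, 1e6, 1.1e6, 5e3, 5.1e3]
    dil = [10, 10.1, 1e5, 1.1e5, 5e2, 5.1e2]
    t = _dilution_table(conc, dil)
    out, rep = dilution_ttest_filter(t, method="paired", scale="log10")
    assert rep.n_discarded_ttest == 0


def test_alpha_zero_discards_everything():
    t = _dilution_table([100.0, 102, 98, 101, 99, 100],
                        [10.0, 10.2, 9.8, 10.1, 9.9, 10.0])
    with pytest.raises(ValidationError, match="every compound"):
        dilution_ttest_filter(t, alpha=0.0)


def test_small_group_and_bad_options_rejected():
    t = _dilution_table([1.0, 2.0], [1.0, 2.0], n_sites=1)
    t_single = t.select_samples([0, 2])  # one conc, one dil sample
    with pytest.raises(ValidationError, match="at least 2"):
        dilution_ttest_filter(t_single)
    with pytest.raises(ValidationError, match="method"):
        dilution_ttest_filter(t, method="bayes")
    with pytest.raises(ValidationError, match="scale"):
        dilution_ttest_filter(t, scale="ln")


# -- Correctness filter ----------------------------------------------------


def _correctness_table(site_dummies):
    """10 sites, 1 compound; dummy d=1 -> diluted mean below concentrated."""
    sites = [f"S{i+1}" for i in range(len(site_dummies))]
    rows = []
    for d in site_dummies:
        conc = [100.0, 100.0]
        dil = [50.0, 50.0] if d else [200.0, 200.0]
        rows.extend(conc + dil)
    areas = np.array(rows).reshape(-1, 1)
    return make_table(areas, sites=sites,
                      site_types={s: "urban" for s in sites})


@pytest.mark.parametrize(
    "dummies, retained",
    [
        ([1] * 10, True),            # median 1
        ([1] * 5 + [0] * 5, False),  # even split -> median 0.5 < 1
        ([1] * 6 + [0] * 4, True),   # median over sorted 0/1 vector = 1
        ([1] * 4 + [0] * 6, False),
    ],
)
def test_correctness_median_rule(dummies, retained):
    # brute-force oracle: the median of the 0/1 site dummies
    assert (np.median(dummies) >= 1.0) == retained
    t = _correctness_table(dummies)
    if retained:
        out, rep = correctness_filter(t)
        assert rep.n_discarded_correctness == 0
    else:
        with pytest.raises(ValidationError, match="every compound"):
            correctness_filter(t)


def test_correctness_requires_both_dilutions_per_site():
    t = _correctness_table([1] * 4)
    broken = t.select_samples([i for i, s in enumerate(t.samples)
                               if not (s.site == "S2" and s.dilution == "diluted")])
    with pytest.raises(ValidationError, match="S2"):
        correctness_filter(broken)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.1, 50.0),
    offset=st.floats(0.0, 1e4),
)
def test_correctness_invariant_to_increasing_affine_maps(seed, scale, offset):
    """Running the filter on a*x + b (a > 0) changes nothing: z-scored
    and raw inputs give the same retained set."""
    rng = np.random.default_rng(seed)
    t = make_table(10.0 ** rng.uniform(2, 6, size=(8, 4)), sites=["U1", "U2"])
    t2 = make_table(t.areas * scale + offset, sites=["U1", "U2"])

    def outcome(table):
        try:
            out, _ = correctness_filter(table)
            return tuple(out.compound_ids)
        except ValidationError:
            return ()

    assert outcome(t) == outcome(t2)


# -- z-score ---------------------------------------------------------------


def test_zscore_column_example():
    # column [1, 2, 3]: mean 2, sample sd 1 -> z = [-1, 0, 1]
    t = make_table(np.array([[1.0], [2.0], [3.0]]), sites=["U1"],
                   n_replicates=3, dilutions=("concentrated",))
    model = zscore_fit(t)
    assert model.means[0] == 2.0 and model.sds[0] == 1.0
    z = zscore_apply(t, model)
    assert np.allclose(z.areas[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_zscore_drops_and_records_constant_columns():
    areas = np.column_stack([np.arange(4.0) + 1, np.full(4, 7.0)])
    t = make_table(areas, sites=["U1"])
    model = zscore_fit(t)
    assert model.dropped == ["C2"]
    z = zscore_apply(t, model)
    assert z.compound_ids == ["C1"]
    assert z.scaling_id == model.model_id


def test_zscore_apply_is_standardizing():
    rng = np.random.default_rng(4)
    t = make_table(10.0 ** rng.uniform(3, 7, (12, 6)), sites=["U1", "U2", "U3"])
    z = zscore_apply(t, zscore_fit(t))
    assert np.allclose(z.areas.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.areas.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_zscore_apply_requires_model_compounds():
    t = make_table(np.arange(8.0).reshape(4, 2) + 1, sites=["U1"])
    model = zscore_fit(t)
    with pytest.raises(ValidationError, match="C2"):
        zscore_apply(t.select_compounds(["C1"]), model)
    with pytest.raises(ValidationError, match="2 samples"):
        zscore_fit(t.select_samples([0]))


# -- report bookkeeping ----------------------------------------------------


def test_combined_report_counts_chain(campaign):
    report = combine_reports(*campaign.reports)
    assert report.n_input == campaign.table.n_compounds
    assert report.n_retained == campaign.screened.n_compounds
    total_discarded = (
        report.n_discarded_blank
        + report.n_discarded_ttest
        + report.n_discarded_correctness
    )
    assert report.n_input - total_discarded == report.n_retained
    assert len(report.per_compound_flags) == total_discarded


def test_filters_hit_their_designed_classes(campaign):
    """Background falls to the blank rule, artifacts to the dilution rules."""
    r1, r2, r3 = campaign.reports
    exp = campaign.expected
    assert set(r1.per_compound_flags) == exp.blank_failures
    dilution_discards = set(r2.per_compound_flags) | set(r3.per_compound_flags)
    assert dilution_discards == exp.dilution_failures
    assert set(campaign.screened.compound_ids) == exp.screened
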