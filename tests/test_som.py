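"""Hexagonal batch SOM: sizing, training, quality, projection, signatures."""

import numpy as np
import pytest

from ntsom import (
    CompoundRecord,
    SOMGrid,
    SOMTrainingConfig,
    ValidationError,
    bmu,
    eigen_ratio,
    map_size,
    node_signature,
    project,
    quality,
    train,
    zscore_apply,
    zscore_fit,
)

from conftest import make_table


# -- grid and sizing -------------------------------------------------------


def test_hex_grid_geometry():
    grid = SOMGrid(xdim=4, ydim=3)
    assert grid.n_nodes == 12
    pts = grid.coords()
    d = np.linalg.norm(pts[None] - pts[:, None], axis=-1)
    nonzero = d[d > 0]
    # hex lattice: every nearest neighbor at planar distance exactly 1
    assert nonzero.min() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValidationError):
        SOMGrid(xdim=2, ydim=3)


@pytest.mark.parametrize(
    "n, ratio, mode, expected",
    [
        (24, 1.4, "regular", (6, 4)),  # published heuristic outcome
        (24, 1.4, "small", (4, 2)),    # munits=7, round-half-away -> 4x2
        (100, 1.0, "regular", (7, 7)),  # munits=50, ydim=round(sqrt(50))=7
    ],
)
def test_map_size_heuristics(n, ratio, mode, expected):
    grid = map_size(n, ratio, mode)
    assert (grid.xdim, grid.ydim) == expected


def test_map_size_explicit_and_errors():
    assert (map_size(0, 0, "explicit", dims=(5, 3)).xdim) == 5
    with pytest.raises(ValidationError, match="dims"):
        map_size(24, 1.4, "explicit")
    with pytest.raises(ValidationError):
        map_size(1, 1.4, "regular")
    with pytest.raises(ValidationError):
        map_size(24, 0.5, "regular")
    with pytest.raises(ValidationError, match="mode"):
        map_size(24, 1.4, "tiny")


def test_eigen_ratio_on_constructed_spectra():
    rng = np.random.default_rng(0)
    # isotropic two-variable data: lambda1 == lambda2 -> ratio 1.0
    q, _ = np.linalg.qr(rng.normal(size=(40, 2)))
    iso = q * np.sqrt(39)
    assert eigen_ratio(iso) == pytest.approx(1.0)
    # constructed spectrum lambda = (4, 1) -> sqrt(4/1) = 2.0
    aniso = iso * np.array([2.0, 1.0])
    assert eigen_ratio(aniso) == pytest.approx(2.0)
    # rank-1 data: second eigenvalue zero
    rank1 = np.outer(rng.normal(size=10), [1.0, 2.0])
    with pytest.raises(ValidationError, match="eigenvalue"):
        eigen_ratio(rank1)


# -- training --------------------------------------------------------------


def test_single_node_codebook_is_the_column_mean():
    """Batch update with one node is a plain mean: closed form."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(17, 5))
    model = train(X, SOMGrid(1, 1))
    assert np.allclose(model.codebook[0], X.mean(axis=0), atol=1e-12)


def test_memorization_limit_with_annealed_radius():
    """Distinct well-separated points and enough nodes: QE -> 0 once the
    neighborhood is annealed away."""
    X = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
    cfg = SOMTrainingConfig(rough_epochs=20, finetune_epochs=60,
                            rough_radius=(1.0, 0.3),
                            finetune_radius=(0.3, 0.01))
    model = train(X, SOMGrid(2, 2), cfg)
    _, qe = zip(*(bmu(model, x) for x in X))
    assert max(qe) <= 1e-6
    assert model.quality.dead_nodes == 0


def test_training_is_deterministic_and_order_free():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(20, 8))
    m1 = train(X, SOMGrid(3, 2))
    m2 = train(X, SOMGrid(3, 2))
    assert np.array_equal(m1.codebook, m2.codebook)  # bitwise
    perm = rng.permutation(20)
    m3 = train(X[perm], SOMGrid(3, 2))
    assert np.allclose(m3.codebook, m1.codebook, atol=1e-10)


def test_codebook_stays_in_data_bounding_box(campaign):
    """Batch updates are convex combinations of samples."""
    cb = campaign.som.codebook
    lo = campaign.z_urban.areas.min(axis=0)
    hi = campaign.z_urban.areas.max(axis=0)
    assert (cb >= lo - 1e-9).all() and (cb <= hi + 1e-9).all()


def test_training_qe_non_increasing_at_fixed_radius(campaign):
    """With the final radius held fixed, extra fine-tune epochs never
    increase the mean training QE (batch SOM descends its energy)."""
    X = campaign.z_urban.areas
    qes = []
    for extra in (90, 95, 100):
        cfg = SOMTrainingConfig(rough_epochs=50, finetune_epochs=extra,
                                finetune_radius=(1.0, 1.0))
        m = train(X, SOMGrid(4, 3), cfg)
        qes.append(m.quality.qe)
    assert qes[1] <= qes[0] + 1e-9
    assert qes[2] <= qes[1] + 1e-9


def test_train_input_validation():
    with pytest.raises(ValidationError):
        train(np.empty((0, 3)), SOMGrid(2, 1))
    with pytest.raises(ValidationError, match="non-finite"):
        train(np.array([[1.0, np.nan]]), SOMGrid(2, 1))


# -- BMU -------------------------------------------------------------------


def test_bmu_examples(campaign):
    model = campaign.som
    node = 7
    idx, qe = bmu(model, model.codebook[node - 1])
    assert idx == node and qe == 0.0


def test_bmu_three_four_five_triangle():
    m = train(np.array([[3.0, 4.0], [6.0, 8.0]]), SOMGrid(1, 1))
    m.codebook = np.array([[3.0, 4.0], [6.0, 8.0]])
    m.grid = SOMGrid(2, 1)
    idx, qe = bmu(m, np.array([0.0, 0.0]))
    assert idx == 1 and qe == pytest.approx(5.0)
    # equidistant nodes: the lower index wins
    m.codebook = np.array([[1.0, 0.0], [-1.0, 0.0]])
    idx, _ = bmu(m, np.array([0.0, 0.0]))
    assert idx == 1
    with pytest.raises(ValidationError, match="variables"):
        bmu(m, np.array([1.0, 2.0, 3.0]))


# -- quality ---------------------------------------------------------------


def test_quality_bounds_and_dead_nodes(campaign):
    q = campaign.som.quality
    assert 0.0 <= q.te <= 1.0
    assert 0.0 <= q.dme <= 1.0
    assert 0 <= q.dead_nodes <= campaign.som.grid.n_nodes
    assert q.qe > 0.0
    assert q.dead_nodes == int((campaign.som.hit_counts == 0).sum())


def test_te_zero_when_first_and_second_bmus_are_adjacent():
    """Samples sitting between two adjacent nodes give zero topographic
    error; a model that memorizes k points on a big grid counts dead
    nodes as n_nodes - k."""
    X = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
    cfg = SOMTrainingConfig(rough_epochs=20, finetune_epochs=60,
                            rough_radius=(1.0, 0.3),
                            finetune_radius=(0.3, 0.01))
    model = train(X, SOMGrid(3, 3), cfg)
    q = quality(model, X)
    assert q.dead_nodes == 9 - 4
    assert q.qe == pytest.approx(0.0, abs=1e-6)


def test_dme_zero_for_matching_distributions():
    """A codebook whose hit-weighted columns reproduce the data
    distribution flags no variables."""
    X = np.tile(np.array([[1.0, 5.0], [3.0, 7.0]]), (6, 1))
    cfg = SOMTrainingConfig(rough_epochs=10, finetune_epochs=40,
                            rough_radius=(1.0, 0.2),
                            finetune_radius=(0.2, 0.01))
    model = train(X, SOMGrid(2, 1), cfg)
    assert quality(model, X).dme == 0.0


# -- projection ------------------------------------------------------------


def test_projection_flags_industrial_not_training(campaign):
    proj = campaign.projection
    assert proj.is_outlier.all()          # all 16 industrial samples
    assert len(proj.sample_ids) == 16
    train_proj = project(campaign.som, campaign.z_urban)
    assert not train_proj.is_outlier.any()  # threshold = max training QE
    assert proj.qe.min() > train_proj.qe.max()


def test_projection_of_codebook_vector_has_zero_qe(campaign):
    model = campaign.som
    res = project(model, model.codebook[:1], sample_ids=["fake"])
    assert res.qe[0] == 0.0 and not res.is_outlier[0]


def test_projection_requires_matching_scaler(campaign):
    wrong_scaler = zscore_fit(campaign.industrial)
    z_wrong = zscore_apply(campaign.industrial, wrong_scaler)
    with pytest.raises(ValidationError, match="scaled"):
        project(campaign.som, z_wrong)
    with pytest.raises(ValidationError, match="variables"):
        project(campaign.som, np.ones((2, 3)))


def test_projection_frame_has_log_qe(campaign):
    frame = campaign.projection.to_frame()
    assert list(frame.columns) == ["sample_id", "bmu", "qe", "log10_qe",
                                   "is_outlier"]
    assert np.allclose(10.0 ** frame["log10_qe"], frame["qe"])


# -- node signatures -------------------------------------------------------


def test_node_signature_inverts_the_scaler(campaign):
    model = campaign.som
    sig = node_signature(model, 1, campaign.urban.compounds)
    # a zero z-value reconstructs the training mean for that compound
    scaler = model.scaling
    by_id = dict(zip(sig["compound_id"], sig["area"]))
    for cid, z_val, mean, sd in zip(
        model.variable_ids, model.codebook[0], scaler.means, scaler.sds
    ):
        assert by_id[cid] == pytest.approx(max(z_val * sd + mean, 0.0))
    assert (sig["rt"].diff().dropna() >= 0).all()
    assert (sig["area"] >= 0).all()


def test_node_signature_clips_at_zero():
    t = make_table(np.array([[1.0, 10.0]] * 3 + [[3.0, 30.0]]), sites=["U1"])
    scaler = zscore_fit(t)
    z = zscore_apply(t, scaler)
    model = train(z.areas, SOMGrid(1, 1), scaling=scaler,
                  variable_ids=z.compound_ids)
    model.codebook[0] = -scaler.means / scaler.sds  # z of a zero area
    sig = node_signature(model, 1, t.compounds)
    assert np.allclose(sig["area"], 0.0, atol=1e-12)


def test_node_signature_range_and_alignment_errors(campaign):
    with pytest.raises(ValidationError, match="out of range"):
        node_signature(campaign.som, 13, campaign.urban.compounds)
    bad = [CompoundRecord("X1", 100.0, 1.0)] * len(campaign.urban.compounds)
    with pytest.raises(ValidationError, match="align"):
        node_signature(campaign.som, 1, bad)
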