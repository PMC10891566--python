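"""Batch Self-Organizing Map on a hexagonal lattice.

The SOM compresses the urban-sample z-score matrix into a small 2-D grid
of nodes; each node's codebook vector is a recurrent multivariate
signature (reconstructable as a pseudo-chromatogram).  New samples are
assigned to their best matching unit (BMU, the Euclidean-nearest node);
the distance to the BMU is the quantization error (QE), and a projected
sample whose QE exceeds every training sample's QE is flagged as an
outlier.

Training is the deterministic batch algorithm: the codebook is
initialized linearly on the plane of the first two principal components,
then updated in two phases (coarse then fine-tuning) with a Gaussian
neighborhood shrinking linearly per epoch.  Each update sets every node
to the neighborhood-weighted mean of the data, so results are exactly
reproducible and independent of sample order.

Map sizing follows the usual heuristics: the node count is
``ceil(5*sqrt(n))`` ("regular") or ``ceil(5/4*sqrt(n))`` ("small"), and
the side ratio approximates the square root of the ratio of the two
leading eigenvalues of the training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats

from .data_io import (
    FeatureTable,
    ScalingModel,
    ValidationError,
    register_model_schema,
)

_ROW_PITCH = math.sqrt(3.0) / 2.0

#: asymptotic two-sample Kolmogorov-Smirnov coefficient at alpha = 0.05
_KS_COEFF_05 = 1.3581


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SOMGrid:
    """Hexagonal sheet lattice, ``xdim`` columns x ``ydim`` rows.

    Node coordinates are planar: odd rows are offset by +0.5 and the row
    pitch is sqrt(3)/2, so every nearest-neighbor distance is exactly 1.
    Nodes are indexed row-major; public node ids are 1-based.
    """

    xdim: int
    ydim: int

    def __post_init__(self) -> None:
        if not (self.xdim >= self.ydim >= 1):
            raise ValidationError("grid requires xdim >= ydim >= 1")

    @property
    def n_nodes(self) -> int:
        return self.xdim * self.ydim

    @property
    def ratio(self) -> float:
        return self.xdim / self.ydim

    def coords(self) -> np.ndarray:
        """(n_nodes, 2) planar hex coordinates, row-major order."""
        pts = np.empty((self.n_nodes, 2))
        k = 0
        for r in range(self.ydim):
            for c in range(self.xdim):
                pts[k] = (c + 0.5 * (r % 2), r * _ROW_PITCH)
                k += 1
        return pts

    def distances(self) -> np.ndarray:
        pts = self.coords()
        return cdist(pts, pts)


def map_size(
    n_samples: int,
    eigen_ratio: float,
    mode: str = "regular",
    dims: tuple[int, int] | None = None,
) -> SOMGrid:
    """Choose grid dimensions by the sizing heuristics.

    ``regular`` targets ``ceil(5*sqrt(n))`` nodes, ``small`` targets
    ``ceil(5/4*sqrt(n))``; the short side is ``round(sqrt(m/ratio))`` and
    the long side ``round(m/ydim)``, rounding half away from zero.
    ``explicit`` returns ``dims`` unchanged.
    """
    if mode == "explicit":
        if dims is None:
            raise ValidationError("explicit mode requires dims")
        return SOMGrid(xdim=int(dims[0]), ydim=int(dims[1]))
    if n_samples < 2:
        raise ValidationError("map sizing needs at least 2 samples")
    if eigen_ratio < 1:
        raise ValidationError("eigen_ratio must be >= 1")
    if mode == "regular":
        munits = math.ceil(5.0 * math.sqrt(n_samples))
    elif mode == "small":
        munits = math.ceil(5.0 / 4.0 * math.sqrt(n_samples))
    else:
        raise ValidationError(f"unknown map sizing mode {mode!r}")
    ydim = max(1, _round_half_away(math.sqrt(munits / eigen_ratio)))
    xdim = max(1, _round_half_away(munits / ydim))
    if xdim < ydim:
        xdim, ydim = ydim, xdim
    return SOMGrid(xdim=xdim, ydim=ydim)


def eigen_ratio(data: np.ndarray) -> float:
    """sqrt(lambda1 / lambda2) of the data covariance, one decimal.

    The sizing heuristic uses the ratio of the two leading eigenvalues of
    the (already z-scored) training matrix.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValidationError("eigen_ratio needs >= 2 samples and >= 2 variables")
    cov = np.cov(data, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eig[1] <= 0:
        raise ValidationError("second eigenvalue is zero; ratio undefined")
    return round(float(math.sqrt(eig[0] / eig[1])), 1)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class SOMTrainingConfig:
    rough_epochs: int = 50
    finetune_epochs: int = 100
    #: starting/ending neighborhood radii; None -> derived from the grid
    #: as max(1, xdim/2) -> max(1, xdim/8) (rough), then -> 1 (finetune)
    rough_radius: tuple[float, float] | None = None
    finetune_radius: tuple[float, float] | None = None

    def radii(self, grid: SOMGrid) -> tuple[tuple[float, float], tuple[float, float]]:
        rough = self.rough_radius or (max(1.0, grid.xdim / 2.0),
                                      max(1.0, grid.xdim / 8.0))
        fine = self.finetune_radius or (rough[1], 1.0)
        return rough, fine

    def to_dict(self) -> dict:
        return {
            "rough_epochs": self.rough_epochs,
            "finetune_epochs": self.finetune_epochs,
            "rough_radius": list(self.rough_radius) if self.rough_radius else None,
            "finetune_radius": (
                list(self.finetune_radius) if self.finetune_radius else None
            ),
        }


@dataclass
class SOMQuality:
    """Map-level quality metrics.

    qe: mean training quantization error (z-units); te: fraction of
    samples whose first and second BMUs are not grid-adjacent; dme:
    fraction of variables whose codebook distribution (hit-weighted)
    mismatches the data distribution by a two-sample KS test at alpha
    0.05; dead_nodes: nodes that are BMU of no training sample.
    """

    qe: float
    te: float
    dme: float
    dead_nodes: int
    dead_node_fraction: float

    def to_dict(self) -> dict:
        return {
            "qe": self.qe,
            "te": self.te,
            "dme": self.dme,
            "dead_nodes": self.dead_nodes,
            "dead_node_fraction": self.dead_node_fraction,
        }


@dataclass
class SOMModel:
    grid: SOMGrid
    codebook: np.ndarray  # n_nodes x n_variables
    variable_ids: list[str]
    scaling: ScalingModel | None
    training_config: SOMTrainingConfig
    hit_counts: np.ndarray
    training_qe: np.ndarray  # per training sample
    quality: SOMQuality | None = None

    @property
    def n_variables(self) -> int:
        return self.codebook.shape[1]

    def to_dict(self) -> dict:
        return {
            "schema": "ntsom/som-model",
            "version": 1,
            "xdim": self.grid.xdim,
            "ydim": self.grid.ydim,
            "codebook": self.codebook.tolist(),
            "variable_ids": list(self.variable_ids),
            "scaling": self.scaling.to_dict() if self.scaling else None,
            "training_config": self.training_config.to_dict(),
            "hit_counts": self.hit_counts.tolist(),
            "training_qe": self.training_qe.tolist(),
            "quality": self.quality.to_dict() if self.quality else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SOMModel":
        tc = d["training_config"]
        quality = d.get("quality")
        return cls(
            grid=SOMGrid(xdim=d["xdim"], ydim=d["ydim"]),
            codebook=np.asarray(d["codebook"], dtype=float),
            variable_ids=list(d["variable_ids"]),
            scaling=(
                ScalingModel.from_dict(d["scaling"]) if d.get("scaling") else None
            ),
            training_config=SOMTrainingConfig(
                rough_epochs=tc["rough_epochs"],
                finetune_epochs=tc["finetune_epochs"],
                rough_radius=tuple(tc["rough_radius"]) if tc["rough_radius"] else None,
                finetune_radius=(
                    tuple(tc["finetune_radius"]) if tc["finetune_radius"] else None
                ),
            ),
            hit_counts=np.asarray(d["hit_counts"], dtype=int),
            training_qe=np.asarray(d["training_qe"], dtype=float),
            quality=SOMQuality(**quality) if quality else None,
        )


register_model_schema("ntsom/som-model", SOMModel)


@dataclass
class ProjectionResult:
    """Per-sample BMU assignment, QE and outlier flag."""

    sample_ids: list[str]
    bmu: np.ndarray  # 1-based node ids
    qe: np.ndarray
    is_outlier: np.ndarray
    threshold: float

    def outlier_ids(self) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.is_outlier) if f]

    def to_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            log10_qe = np.log10(self.qe)
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "bmu": self.bmu,
                "qe": self.qe,
                "log10_qe": log10_qe,
                "is_outlier": self.is_outlier,
            }
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _linear_init(data: np.ndarray, grid: SOMGrid) -> np.ndarray:
    """Spread the codebook over the plane of the first two PCs."""
    mean = data.mean(axis=0)
    centered = data - mean
    codebook = np.tile(mean, (grid.n_nodes, 1))
    if grid.n_nodes == 1:
        return codebook
    # principal directions; fall back to axis-aligned spread for
    # degenerate (constant) data
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # fix the sign ambiguity of each principal direction from the vector
    # itself, so initialization does not depend on sample order
    for r in range(min(2, vt.shape[0])):
        j = int(np.abs(vt[r]).argmax())
        if vt[r, j] < 0:
            vt[r] = -vt[r]
    n = data.shape[0]
    sdevs = s / math.sqrt(max(n - 1, 1))
    coords = grid.coords()
    for axis in range(2):
        span = coords[:, axis].max() - coords[:, axis].min()
        if span == 0 or axis >= vt.shape[0] or sdevs[axis] == 0:
            continue
        unit = 2.0 * (coords[:, axis] - coords[:, axis].mean()) / span  # [-1, 1]
        codebook += np.outer(unit * sdevs[axis], vt[axis])
    return codebook


def _bmu_indices(data: np.ndarray, codebook: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(data, codebook)
    idx = d.argmin(axis=1)  # argmin takes the lowest index on ties
    return idx, d[np.arange(len(data)), idx]


def train(
    data: np.ndarray | FeatureTable,
    grid: SOMGrid,
    config: SOMTrainingConfig | None = None,
    scaling: ScalingModel | None = None,
    variable_ids: list[str] | None = None,
) -> SOMModel:
    """Train a batch SOM; fully deterministic for a fixed input.

    Two phases of batch updates: every epoch assigns all samples to their
    BMUs and replaces each codebook vector by the Gaussian-neighborhood-
    weighted mean of the data (nodes with numerically zero weight keep
    their previous value).  The neighborhood radius decays linearly per
    epoch within each phase.
    """
    if isinstance(data, FeatureTable):
        variable_ids = data.compound_ids
        if scaling is None and data.scaling_id is not None:
            pass  # caller may attach the model separately
        data = data.areas
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValidationError("training data must be a non-empty 2-D matrix")
    if not np.isfinite(data).all():
        raise ValidationError("training data contains non-finite values")
    config = config or SOMTrainingConfig()
    if variable_ids is None:
        variable_ids = [f"v{j}" for j in range(data.shape[1])]

    codebook = _linear_init(data, grid)
    grid_d2 = grid.distances() ** 2

    def run_phase(radius_from: float, radius_to: float, epochs: int) -> None:
        nonlocal codebook
        for e in range(epochs):
            frac = e / (epochs - 1) if epochs > 1 else 1.0
            sigma = radius_from + (radius_to - radius_from) * frac
            sigma = max(sigma, 1e-9)
            bmu_idx, _ = _bmu_indices(data, codebook)
            h = np.exp(-grid_d2 / (2.0 * sigma**2))
            w = h[bmu_idx]  # n_samples x n_nodes
            den = w.sum(axis=0)
            num = w.T @ data
            update = den > 1e-12
            codebook = codebook.copy()
            codebook[update] = num[update] / den[update, None]

    (r0, r1), (f0, f1) = config.radii(grid)
    run_phase(r0, r1, config.rough_epochs)
    run_phase(f0, f1, config.finetune_epochs)

    bmu_idx, qe = _bmu_indices(data, codebook)
    hits = np.bincount(bmu_idx, minlength=grid.n_nodes)
    model = SOMModel(
        grid=grid,
        codebook=codebook,
        variable_ids=list(variable_ids),
        scaling=scaling,
        training_config=config,
        hit_counts=hits,
        training_qe=qe,
    )
    model.quality = quality(model, data)
    return model


# ---------------------------------------------------------------------------
# evaluation and projection
# ---------------------------------------------------------------------------


def bmu(model: SOMModel, x: np.ndarray) -> tuple[int, float]:
    """Best matching unit (1-based) and its distance; ties -> lowest id."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_variables,):
        raise ValidationError(
            f"sample has {x.size} variables, model expects {model.n_variables}"
        )
    d = np.linalg.norm(model.codebook - x, axis=1)
    idx = int(d.argmin())
    return idx + 1, float(d[idx])


def quality(model: SOMModel, data: np.ndarray) -> SOMQuality:
    """Compute QE / TE / DME / dead-node metrics on a dataset."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValidationError("quality needs non-empty data")
    d = cdist(data, model.codebook)
    order = np.argsort(d, axis=1, kind="stable")
    first = order[:, 0]
    second = order[:, 1] if d.shape[1] > 1 else order[:, 0]
    qe = float(d[np.arange(len(data)), first].mean())

    coords = model.grid.coords()
    planar = np.linalg.norm(coords[first] - coords[second], axis=1)
    te = float((planar > 1.01).mean()) if model.grid.n_nodes > 1 else 0.0

    hits = np.bincount(first, minlength=model.grid.n_nodes)
    weighted = np.repeat(model.codebook, hits, axis=0)
    n, m = data.shape[0], weighted.shape[0]
    if m == 0:
        dme = 1.0
    else:
        crit = _KS_COEFF_05 * math.sqrt((n + m) / (n * m))
        flagged = 0
        for j in range(data.shape[1]):
            stat = stats.ks_2samp(data[:, j], weighted[:, j]).statistic
            if stat > crit:
                flagged += 1
        dme = flagged / data.shape[1]

    dead = int((hits == 0).sum())
    return SOMQuality(
        qe=qe,
        te=te,
        dme=float(dme),
        dead_nodes=dead,
        dead_node_fraction=dead / model.grid.n_nodes,
    )


def project(
    model: SOMModel,
    new_data: FeatureTable | np.ndarray,
    sample_ids: list[str] | None = None,
    threshold_multiplier: float = 1.0,
) -> ProjectionResult:
    """Project samples onto a trained map and flag QE outliers.

    The outlier threshold is the maximum training-sample QE (times an
    optional multiplier); a projected sample is an outlier iff its QE
    strictly exceeds the threshold.  FeatureTable input must carry the
    ``scaling_id`` of the model's own scaling model.
    """
    if isinstance(new_data, FeatureTable):
        if model.scaling is not None:
            if new_data.scaling_id != model.scaling.model_id:
                raise ValidationError(
                    "projection data were not scaled with the model's scaler"
                )
            if new_data.compound_ids != model.variable_ids:
                raise ValidationError("projection data variables do not match model")
        sample_ids = new_data.sample_ids
        X = new_data.areas
    else:
        X = np.asarray(new_data, dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(X.shape[0])]
    if X.shape[1] != model.n_variables:
        raise ValidationError(
            f"data has {X.shape[1]} variables, model expects {model.n_variables}"
        )
    idx, qe = _bmu_indices(X, model.codebook)
    threshold = float(model.training_qe.max() * threshold_multiplier)
    return ProjectionResult(
        sample_ids=list(sample_ids),
        bmu=idx + 1,
        qe=qe,
        is_outlier=qe > threshold,
        threshold=threshold,
    )


def node_signature(model: SOMModel, node: int, compounds) -> pd.DataFrame:
    """Reconstruct one node's signature as a stick chromatogram.

    Inverts the z-score transform per compound (area = z*sd + mean,
    clipped at zero) and returns (rt, mz, area) rows sorted by retention
    time, ready for stick plotting.
    """
    if not 1 <= node <= model.grid.n_nodes:
        raise ValidationError(
            f"node {node} out of range 1..{model.grid.n_nodes}"
        )
    if model.scaling is None:
        raise ValidationError("model carries no scaling model; cannot invert z-scores")
    compounds = list(compounds)
    if [c.compound_id for c in compounds] != model.variable_ids:
        raise ValidationError("compound list does not align with model variables")
    z = model.codebook[node - 1]
    area = np.clip(z * model.scaling.sds + model.scaling.means, 0.0, None)
    frame = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "rt": [c.rt for c in compounds],
            "mz": [c.mz for c in compounds],
            "area": area,
        }
    )
    return frame.sort_values("rt", kind="stable").reset_index(drop=True)
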