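"""PCA baseline: score/orthogonal distances and critical-limit outliers.

The comparison baseline fits a PCA model to the z-scored urban block and
classifies samples by two complementary distances:

* **score distance (SD)** -- Mahalanobis distance within the retained
  component subspace, ``SD = sum_k t_k^2 / lambda_k``;
* **orthogonal distance (OD)** -- squared residual off the subspace,
  ``OD = ||x - P P' x||^2``.

Both are sums of squares, so their null distributions are approximated
by moment-matched scaled chi-square laws estimated from the training
distances (the "data-driven degrees of freedom" approach used by
SIMCA-style chemometrics software).  Two critical limits are drawn per
axis: an *extreme* limit at significance ``alpha`` and an *outlier*
limit at significance ``gamma`` with a per-object correction
``(1-gamma)^(1/n)`` for the size of the training set.  A sample is an
outlier when either axis exceeds its outlier limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    FeatureTable,
    ScalingModel,
    ValidationError,
    register_model_schema,
)

CATEGORIES = ("regular", "extreme", "outlier")


@dataclass
class AxisLimits:
    """Critical limits for one distance axis (SD or OD)."""

    extreme: float
    outlier: float
    alpha: float
    gamma: float
    dof: int
    u0: float
    n_train: int

    def to_dict(self) -> dict:
        return {
            "extreme": self.extreme,
            "outlier": self.outlier,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "dof": self.dof,
            "u0": self.u0,
            "n_train": self.n_train,
        }


@dataclass
class DistanceRecord:
    sample_id: str
    sd: float
    od: float
    category: str | None = None


@dataclass
class PCAModel:
    loadings: np.ndarray  # n_variables x A, orthonormal columns
    eigenvalues: np.ndarray  # lambda_1..lambda_A, non-increasing
    n_components: int
    explained_variance_ratio: np.ndarray
    variable_ids: list[str]
    scaling: ScalingModel | None = None
    sd_limits: AxisLimits | None = None
    od_limits: AxisLimits | None = None

    def __post_init__(self) -> None:
        P = self.loadings
        if not np.allclose(P.T @ P, np.eye(self.n_components), atol=1e-9):
            raise ValidationError("loadings are not orthonormal")
        if (np.diff(self.eigenvalues) > 1e-12).any():
            raise ValidationError("eigenvalues must be non-increasing")
        if (self.eigenvalues <= 0).any():
            raise ValidationError("retained eigenvalues must be > 0")

    def to_dict(self) -> dict:
        return {
            "schema": "ntsom/pca-model",
            "version": 1,
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_components": self.n_components,
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "variable_ids": list(self.variable_ids),
            "scaling": self.scaling.to_dict() if self.scaling else None,
            "sd_limits": self.sd_limits.to_dict() if self.sd_limits else None,
            "od_limits": self.od_limits.to_dict() if self.od_limits else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            n_components=int(d["n_components"]),
            explained_variance_ratio=np.asarray(
                d["explained_variance_ratio"], dtype=float
            ),
            variable_ids=list(d["variable_ids"]),
            scaling=ScalingModel.from_dict(d["scaling"]) if d.get("scaling") else None,
            sd_limits=AxisLimits(**d["sd_limits"]) if d.get("sd_limits") else None,
            od_limits=AxisLimits(**d["od_limits"]) if d.get("od_limits") else None,
        )


register_model_schema("ntsom/pca-model", PCAModel)


def _as_matrix(data, model: PCAModel | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, FeatureTable):
        if model is not None and model.scaling is not None:
            if data.scaling_id != model.scaling.model_id:
                raise ValidationError(
                    "data were not scaled with the model's scaling model"
                )
            if data.compound_ids != model.variable_ids:
                raise ValidationError("data variables do not match the PCA model")
        return data.areas, data.sample_ids
    X = np.asarray(data, dtype=float)
    return X, [f"s{i}" for i in range(X.shape[0])]


def pca_fit(
    data: FeatureTable | np.ndarray,
    n_components: int | str = "auto",
    scaling: ScalingModel | None = None,
) -> PCAModel:
    """SVD-based PCA of an already centered/scaled matrix.

    ``n_components='auto'`` applies Kaiser's rule: retain the components
    whose eigenvalue exceeds the mean of the positive eigenvalues.
    """
    if isinstance(data, FeatureTable):
        X = data.areas
        variable_ids = data.compound_ids
    else:
        X = np.asarray(data, dtype=float)
        variable_ids = [f"v{j}" for j in range(X.shape[1])]
    n = X.shape[0]
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    lam = s**2 / (n - 1)
    positive = lam[lam > max(lam[0], 1.0) * 1e-12]
    rank = positive.size
    if n_components == "auto":
        A = int((positive > positive.mean()).sum())
        A = max(A, 1)
    else:
        A = int(n_components)
        if not 1 <= A <= rank:
            raise ValidationError(
                f"n_components {A} outside the data rank 1..{rank}"
            )
    return PCAModel(
        loadings=vt[:A].T.copy(),
        eigenvalues=lam[:A].copy(),
        n_components=A,
        explained_variance_ratio=lam[:A] / positive.sum(),
        variable_ids=list(variable_ids),
        scaling=scaling,
    )


def distances(
    model: PCAModel, data: FeatureTable | np.ndarray
) -> list[DistanceRecord]:
    """Score and orthogonal distances of each sample under the model.

    The decomposition is Pythagorean: ``OD + ||P t||^2 = ||x||^2`` for
    every sample.
    """
    X, sample_ids = _as_matrix(data, model)
    if X.shape[1] != model.loadings.shape[0]:
        raise ValidationError(
            f"data has {X.shape[1]} variables, model expects "
            f"{model.loadings.shape[0]}"
        )
    T = X @ model.loadings
    sd = (T**2 / model.eigenvalues).sum(axis=1)
    resid = X - T @ model.loadings.T
    od = (resid**2).sum(axis=1)
    return [
        DistanceRecord(sample_id=sid, sd=float(a), od=float(b))
        for sid, a, b in zip(sample_ids, sd, od)
    ]


def _axis_limits(
    values: np.ndarray, alpha: float, gamma: float
) -> AxisLimits:
    mean = float(values.mean())
    var = float(values.var(ddof=1))
    if var <= 0 or mean <= 0:
        raise ValidationError("training distances have zero variance")
    dof = max(1, _round_half_away(2.0 * mean**2 / var))
    n = values.size
    extreme = mean * stats.chi2.ppf(1.0 - alpha, dof) / dof
    outlier = mean * stats.chi2.ppf((1.0 - gamma) ** (1.0 / n), dof) / dof
    return AxisLimits(
        extreme=float(extreme),
        outlier=float(outlier),
        alpha=alpha,
        gamma=gamma,
        dof=dof,
        u0=mean,
        n_train=n,
    )


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def critical_limits(
    model: PCAModel,
    train_distances: list[DistanceRecord],
    alpha: float = 0.05,
    gamma: float = 0.05,
) -> tuple[AxisLimits, AxisLimits]:
    """Moment-matched chi-square limits from the training distances.

    Per axis, the distance distribution is modeled as ``u0 * chi2_N / N``
    with ``N = round(2 mean^2 / var)`` and ``u0`` the training mean; the
    extreme limit is its ``1-alpha`` quantile and the outlier limit the
    ``(1-gamma)^(1/n)`` quantile.  The limits are stored on the model.
    """
    if not train_distances:
        raise ValidationError("no training distances")
    sd = np.array([r.sd for r in train_distances])
    od = np.array([r.od for r in train_distances])
    model.sd_limits = _axis_limits(sd, alpha, gamma)
    model.od_limits = _axis_limits(od, alpha, gamma)
    return model.sd_limits, model.od_limits


def classify(
    records: list[DistanceRecord],
    sd_limits: AxisLimits,
    od_limits: AxisLimits,
) -> list[DistanceRecord]:
    """Assign regular/extreme/outlier categories in place (and return)."""
    for r in records:
        if r.sd > sd_limits.outlier or r.od > od_limits.outlier:
            r.category = "outlier"
        elif r.sd > sd_limits.extreme or r.od > od_limits.extreme:
            r.category = "extreme"
        else:
            r.category = "regular"
    return records


def dd_plot_data(
    records: list[DistanceRecord],
    sd_limits: AxisLimits,
    od_limits: AxisLimits,
    samples=None,
) -> pd.DataFrame:
    """Distance-distance plot table, log-scaled relative to the limits.

    Coordinates are each distance divided by its extreme limit (so a
    sample *at* the limit sits at 1.0), then log10-converted for display.
    ``samples`` is an optional list of SampleRecord used to attach a
    group label (urban/industrial x concentrated/diluted).
    """
    if not records:
        raise ValidationError("no distance records")
    meta = {s.sample_id: s for s in samples} if samples else {}
    rows = []
    for r in records:
        sd_norm = r.sd / sd_limits.extreme
        od_norm = r.od / od_limits.extreme
        rec = meta.get(r.sample_id)
        group = f"{rec.site_type}-{rec.dilution}" if rec else ""
        rows.append(
            {
                "sample_id": r.sample_id,
                "sd": r.sd,
                "od": r.od,
                "sd_norm": sd_norm,
                "od_norm": od_norm,
                "log10_sd_norm": float(np.log10(max(sd_norm, 1e-12))),
                "log10_od_norm": float(np.log10(max(od_norm, 1e-12))),
                "category": r.category or "",
                "group": group,
            }
        )
    return pd.DataFrame(rows)
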