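"""Typed containers and CSV/JSON persistence for LC-HRMS feature tables.

A non-target-screening experiment is represented as three aligned objects:

* a peak-area matrix, rows = samples, columns = compounds;
* per-sample metadata (site, site type, dilution level, replicate);
* per-compound metadata (m/z, retention time, annotation and its
  confidence level on the usual 1-5 scale).

On disk this is a three-file CSV layout -- ``areas.csv`` (first column
``sample_id``, remaining columns one per compound), ``samples.csv`` and
``compounds.csv`` -- which keeps the area matrix purely numeric.  Fitted
models (scaling, SOM, PCA) are stored as versioned JSON documents.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

SITE_TYPES = ("urban", "industrial", "blank")
DILUTIONS = ("concentrated", "diluted")

#: single-letter dilution codes used in sample names (``U1c1`` etc.)
_DILUTION_LETTER = {"concentrated": "c", "diluted": "d"}
_LETTER_DILUTION = {v: k for k, v in _DILUTION_LETTER.items()}

_NAME_RE = re.compile(r"^([A-Za-z]+\d*)([cdb])(\d+)$")


class ValidationError(ValueError):
    """Raised when an input table or model fails structural validation."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One detected feature: mass-to-charge, retention time, annotation."""

    compound_id: str
    mz: float
    rt: float
    name: str | None = None
    confidence_level: int = 5

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not self.mz > 0:
            raise ValidationError(f"compound {self.compound_id}: mz must be > 0")
        if self.rt < 0:
            raise ValidationError(f"compound {self.compound_id}: rt must be >= 0")
        if self.confidence_level not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"compound {self.compound_id}: confidence_level must be in 1..5"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One analyzed sample (or blank) in the sequence."""

    sample_id: str
    site: str
    site_type: str
    dilution: str
    replicate: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValidationError(
                f"sample {self.sample_id}: site_type {self.site_type!r} "
                f"not one of {SITE_TYPES}"
            )
        if self.dilution not in DILUTIONS:
            raise ValidationError(
                f"sample {self.sample_id}: dilution {self.dilution!r} "
                f"not one of {DILUTIONS}"
            )
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id}: replicate must be >= 1")


def build_sample_name(
    site: str, site_type: str, dilution: str, replicate: int
) -> str:
    """Build the conventional sample name, e.g. ``U1c1``.

    Site name, then a dilution letter (``c`` concentrated, ``d`` diluted,
    ``b`` for blanks of that site's sequence), then the replicate number.
    Blanks are undiluted by definition, so ``site_type='blank'`` is only
    valid with ``dilution='concentrated'``.
    """
    if site_type == "blank":
        if dilution != "concentrated":
            raise ValidationError("blanks are undiluted; use dilution='concentrated'")
        letter = "b"
    else:
        letter = _DILUTION_LETTER[dilution]
    return f"{site}{letter}{replicate}"


def parse_sample_name(name: str) -> dict:
    """Invert :func:`build_sample_name`.

    Returns a dict with ``site``, ``dilution``, ``replicate`` and, when the
    letter is ``b``, ``site_type='blank'`` (otherwise ``site_type`` is None:
    urban vs industrial is metadata, not encoded in the name).
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValidationError(f"sample name {name!r} does not match <site><c|d|b><rep>")
    site, letter, rep = m.groups()
    if letter == "b":
        return {
            "site": site,
            "site_type": "blank",
            "dilution": "concentrated",
            "replicate": int(rep),
        }
    return {
        "site": site,
        "site_type": None,
        "dilution": _LETTER_DILUTION[letter],
        "replicate": int(rep),
    }


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Samples x compounds peak-area matrix with aligned metadata.

    ``scaling_id`` is set on tables produced by a z-score transform and
    names the :class:`ScalingModel` that produced them; such tables may
    contain negative values, raw area tables may not.
    """

    areas: np.ndarray
    samples: list[SampleRecord]
    compounds: list[CompoundRecord]
    scaling_id: str | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if len(self.compounds) == 0:
            raise ValidationError("no compounds")
        if len(self.samples) == 0:
            raise ValidationError("no samples")
        if self.areas.ndim != 2 or self.areas.shape != (
            len(self.samples),
            len(self.compounds),
        ):
            raise ValidationError(
                f"area matrix shape {self.areas.shape} does not match "
                f"{len(self.samples)} samples x {len(self.compounds)} compounds"
            )
        bad = np.argwhere(~np.isfinite(self.areas))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"non-finite area at sample {self.samples[r].sample_id!r}, "
                f"compound {self.compounds[c].compound_id!r}"
            )
        if self.scaling_id is None and (self.areas < 0).any():
            r, c = np.argwhere(self.areas < 0)[0]
            raise ValidationError(
                f"negative area at sample {self.samples[r].sample_id!r}, "
                f"compound {self.compounds[c].compound_id!r}"
            )
        ids = [s.sample_id for s in self.samples]
        dup = _duplicates(ids)
        if dup:
            raise ValidationError(f"duplicate sample ids: {sorted(dup)}")
        cids = [c.compound_id for c in self.compounds]
        dup = _duplicates(cids)
        if dup:
            raise ValidationError(f"duplicate compound ids: {sorted(dup)}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    def sites(self) -> list[str]:
        """Unique site names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.site, None)
        return list(seen)

    def sample_mask(self, **conditions) -> np.ndarray:
        """Boolean row mask, e.g. ``sample_mask(site_type='urban')``."""
        mask = np.ones(self.n_samples, dtype=bool)
        for key, value in conditions.items():
            mask &= np.array([getattr(s, key) == value for s in self.samples])
        return mask

    def select_samples(self, index: np.ndarray | Sequence[int]) -> "FeatureTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return FeatureTable(
            areas=self.areas[index].copy(),
            samples=[self.samples[i] for i in index],
            compounds=list(self.compounds),
            scaling_id=self.scaling_id,
        )

    def select_compounds(self, ids: Iterable[str]) -> "FeatureTable":
        """Column subset; keeps this table's column order."""
        wanted = set(ids)
        missing = wanted - set(self.compound_ids)
        if missing:
            raise ValidationError(f"unknown compound ids: {sorted(missing)}")
        keep = [i for i, c in enumerate(self.compounds) if c.compound_id in wanted]
        return FeatureTable(
            areas=self.areas[:, keep].copy(),
            samples=list(self.samples),
            compounds=[self.compounds[i] for i in keep],
            scaling_id=self.scaling_id,
        )

    def column(self, compound_id: str) -> np.ndarray:
        try:
            j = self.compound_ids.index(compound_id)
        except ValueError:
            raise ValidationError(f"unknown compound id: {compound_id}") from None
        return self.areas[:, j]

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.samples == other.samples
            and self.compounds == other.compounds
            and self.scaling_id == other.scaling_id
            and np.array_equal(self.areas, other.areas)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.areas, index=self.sample_ids, columns=self.compound_ids
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# scaling model
# ---------------------------------------------------------------------------


@dataclass
class ScalingModel:
    """Per-compound mean/sd of a z-score transform, with its provenance.

    ``dropped`` lists compounds that were constant in the fitting data
    (sd = 0); these are removed, not scaled, when the model is applied.
    """

    compound_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str]
    fitted_on: list[str]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.compound_ids) == self.means.size == self.sds.size):
            raise ValidationError("scaling model arrays misaligned")
        if not (self.sds > 0).all():
            raise ValidationError("retained compounds must have sd > 0")

    @property
    def model_id(self) -> str:
        h = hashlib.sha1()
        h.update(",".join(self.compound_ids).encode())
        h.update(self.means.tobytes())
        h.update(self.sds.tobytes())
        h.update(",".join(self.fitted_on).encode())
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "schema": "ntsom/scaling-model",
            "version": SCHEMA_VERSION,
            "compound_ids": list(self.compound_ids),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "dropped": list(self.dropped),
            "fitted_on": list(self.fitted_on),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingModel":
        return cls(
            compound_ids=list(d["compound_ids"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            dropped=list(d["dropped"]),
            fitted_on=list(d["fitted_on"]),
        )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def read_feature_table(
    areas_path: str | Path,
    samples_path: str | Path,
    compounds_path: str | Path,
) -> FeatureTable:
    """Read the three-file layout and return a validated table.

    Row and column order is preserved exactly as found in the files; the
    ids in ``areas.csv`` must match the metadata files one-to-one and in
    the same order.
    """
    areas_df = pd.read_csv(areas_path, dtype={0: str}, float_precision="round_trip")
    samples_df = pd.read_csv(
        samples_path, dtype={"sample_id": str, "site": str}, keep_default_na=False
    )
    compounds_df = pd.read_csv(
        compounds_path,
        dtype={"compound_id": str, "name": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    if compounds_df.shape[0] == 0:
        raise ValidationError("no compounds")
    if samples_df.shape[0] == 0:
        raise ValidationError("no samples")

    if areas_df.columns[0] != "sample_id":
        raise ValidationError("areas.csv must start with a 'sample_id' column")
    matrix_samples = areas_df["sample_id"].tolist()
    matrix_compounds = list(areas_df.columns[1:])
    meta_samples = samples_df["sample_id"].tolist()
    meta_compounds = compounds_df["compound_id"].tolist()
    if matrix_samples != meta_samples:
        offenders = sorted(set(matrix_samples) ^ set(meta_samples)) or ["(order)"]
        raise ValidationError(
            f"sample ids in areas.csv do not match samples.csv: {offenders}"
        )
    if matrix_compounds != meta_compounds:
        offenders = sorted(set(matrix_compounds) ^ set(meta_compounds)) or ["(order)"]
        raise ValidationError(
            f"compound ids in areas.csv do not match compounds.csv: {offenders}"
        )

    values = areas_df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"missing or non-numeric area at sample {matrix_samples[r]!r}, "
            f"compound {matrix_compounds[c]!r}"
        )

    samples = [
        SampleRecord(
            sample_id=row.sample_id,
            site=row.site,
            site_type=row.site_type,
            dilution=row.dilution,
            replicate=int(row.replicate),
        )
        for row in samples_df.itertuples()
    ]
    compounds = [
        CompoundRecord(
            compound_id=str(row["compound_id"]),
            mz=float(row["mz"]),
            rt=float(row["rt"]),
            name=str(row["name"]) or None,
            confidence_level=int(row["confidence_level"]),
        )
        for _, row in compounds_df.iterrows()
    ]
    return FeatureTable(areas=values, samples=samples, compounds=compounds)


def write_feature_table(table: FeatureTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the three-file layout; returns the written paths.

    Output is byte-stable: the same table always produces the same files,
    and reading them back reproduces the table exactly (floats are written
    with full round-trip precision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.validate()

    # 17 significant digits round-trip any double exactly; pandas'
    # default 16-digit formatting does not
    exact = "%.17g"

    areas_df = pd.DataFrame(table.areas, columns=table.compound_ids)
    areas_df.insert(0, "sample_id", table.sample_ids)
    areas_path = out / "areas.csv"
    areas_df.to_csv(areas_path, index=False, float_format=exact)

    samples_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in table.samples],
        columns=["sample_id", "site", "site_type", "dilution", "replicate"],
    )
    samples_path = out / "samples.csv"
    samples_df.to_csv(samples_path, index=False)

    compounds_df = pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "mz": c.mz,
                "rt": c.rt,
                "name": c.name or "",
                "confidence_level": c.confidence_level,
            }
            for c in table.compounds
        ],
        columns=["compound_id", "mz", "rt", "name", "confidence_level"],
    )
    compounds_path = out / "compounds.csv"
    compounds_df.to_csv(compounds_path, index=False, float_format=exact)

    return {"areas": areas_path, "samples": samples_path, "compounds": compounds_path}


# ---------------------------------------------------------------------------
# model JSON persistence
# ---------------------------------------------------------------------------

#: schema string -> loader; SOM/PCA models register themselves on import.
_MODEL_SCHEMAS: dict[str, type] = {"ntsom/scaling-model": ScalingModel}


def register_model_schema(schema: str, cls: type) -> None:
    _MODEL_SCHEMAS[schema] = cls


def serialize_model(model, path: str | Path) -> Path:
    """Write any fitted model (scaling / SOM / PCA) as versioned JSON."""
    if not hasattr(model, "to_dict"):
        raise ValidationError(f"cannot serialize object of type {type(model).__name__}")
    d = model.to_dict()
    if "schema" not in d:
        raise ValidationError("model to_dict() must include a 'schema' key")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(d, indent=1), encoding="utf-8")
    return path


def deserialize_model(path: str | Path):
    """Load a model JSON; a truncated/corrupt file raises a parse error."""
    text = Path(path).read_text(encoding="utf-8")
    d = json.loads(text)  # raises json.JSONDecodeError on truncation
    schema = d.get("schema")
    if schema not in _MODEL_SCHEMAS:
        # lazy-import the modules that register the remaining schemas
        from . import pca, som  # noqa: F401

    if d.get("schema") not in _MODEL_SCHEMAS:
        raise ValidationError(f"unknown model schema: {schema!r}")
    return _MODEL_SCHEMAS[d["schema"]].from_dict(d)
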