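"""Volume and table data model, NIfTI/TSV/YAML/JSON I/O, and run provenance.

All volumes of one subject live on a single grid; orientation metadata
beyond voxel spacing is deliberately ignored.  Missing values are NaN
internally and the string ``NA`` in text tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("venalamina")

MISSING = float("nan")

GROUPS = ("young", "old")
COMPARTMENTS = ("SF", "OM", "IM", "DP")
METRICS = ("qT1", "pQSM", "nQSM")

#: columns of a condition table, in canonical order
TABLE_COLUMNS = (
    "participant_id",
    "group",
    "risk",
    "area",
    "compartment",
    "distance_bin",
    "metric",
    "value",
    "n_voxels",
)

_KEY_COLUMNS = ["participant_id", "area", "compartment", "distance_bin", "metric"]


class VolumeError(ValueError):
    """Raised for malformed volumes or incompatible grids."""


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with per-axis spacing in mm.

    Parameters
    ----------
    data:
        3D array; metric units (ms, ppm, mm), probabilities, or labels.
    spacing:
        (sx, sy, sz) voxel edge lengths in mm, strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"Volume data must be 3D, got shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
            raise VolumeError(f"spacing must be 3 positive numbers, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid with different data."""
        return Volume(np.asarray(data), self.spacing)

    def assert_same_grid(self, other: "Volume", what: str = "operation") -> None:
        if self.shape != other.shape:
            raise VolumeError(
                f"{what}: shape mismatch {self.shape} vs {other.shape}"
            )
        if not np.allclose(self.spacing, other.spacing):
            raise VolumeError(
                f"{what}: spacing mismatch {self.spacing} vs {other.spacing}"
            )


def read_volume(path) -> Volume:
    """Read a 3D NIfTI volume; spacing comes from the header.

    A trailing singleton 4th dimension is squeezed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        warnings.warn(f"{path.name}: squeezing singleton 4th dimension")
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"{path.name}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeError(f"{path.name}: non-positive voxel spacing {zooms}")
    return Volume(data, tuple(float(z) for z in zooms))


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as NIfTI-1 with a diagonal RAS affine from spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# condition tables


def validate_condition_table(table: pd.DataFrame, min_voxels_per_bin: int | None = None) -> None:
    """Check the condition-table invariants; raise ValueError on breach."""
    missing_cols = set(TABLE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"condition table lacks columns: {sorted(missing_cols)}")
    if len(table):
        dup = table.duplicated(subset=_KEY_COLUMNS)
        if dup.any():
            rows = table.loc[dup, _KEY_COLUMNS].head().to_dict("records")
            raise ValueError(f"duplicate condition rows, e.g. {rows}")
        if min_voxels_per_bin is not None:
            low = table["n_voxels"] < min_voxels_per_bin
            bad = low != table["value"].isna()
            if bad.any():
                raise ValueError(
                    "value must be missing exactly when n_voxels < "
                    f"{min_voxels_per_bin} ({int(bad.sum())} rows violate this)"
                )


def write_condition_table(table: pd.DataFrame, path) -> None:
    """Write a condition table as TSV; missing values become ``NA``."""
    validate_condition_table(table)
    out = table.loc[:, list(TABLE_COLUMNS)].copy()
    out["value"] = out["value"].map(
        lambda v: "NA" if pd.isna(v) else format(float(v), ".12g")
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_condition_table(path) -> pd.DataFrame:
    """Read a TSV condition table written by :func:`write_condition_table`."""
    table = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        dtype={
            "participant_id": str,
            "group": str,
            "area": str,
            "compartment": str,
            "distance_bin": str,
            "metric": str,
        },
    )
    table["value"] = pd.to_numeric(table["value"], errors="raise")
    table["n_voxels"] = table["n_voxels"].astype(int)
    table["risk"] = table["risk"].astype(int)
    validate_condition_table(table)
    return table


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Study-wide parameters: binning, compartments, statistics, seeds."""

    bin_edges: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    min_voxels_per_bin: int = 4
    n_depths: int = 21
    excluded_superficial: int = 3
    excluded_deep: int = 2
    depth_mode: str = "equivolume"
    vesselness_scales_mm: tuple[float, ...] = (0.5, 1.0)
    otsu_bins: int = 256
    # statistics options
    B_perm: int = 100_000
    B_boot: int = 2000
    m_imputations: int = 5
    seed: int = 0
    output_dir: str = "out"
    phantom: dict = field(default_factory=dict)

    def __post_init__(self):
        edges = tuple(float(e) for e in self.bin_edges)
        if len(edges) < 2 or edges[0] != 0.0 or any(
            b <= a for a, b in zip(edges, edges[1:])
        ):
            raise ValueError(f"bin_edges must be strictly increasing from 0, got {edges}")
        self.bin_edges = edges
        if self.min_voxels_per_bin < 1:
            raise ValueError("min_voxels_per_bin must be >= 1")
        if self.seed is None:
            raise ValueError("every random procedure needs an explicit seed")

    @property
    def bin_labels(self) -> list[str]:
        e = self.bin_edges
        return [f"{_fmt(a)}-{_fmt(b)}" for a, b in zip(e, e[1:])]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bin_edges", "vesselness_scales_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["bin_edges"] = list(self.bin_edges)
        payload["vesselness_scales_mm"] = list(self.vesselness_scales_mm)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


# ---------------------------------------------------------------------------
# provenance


def write_run_report(path, **payload) -> None:
    """Write a JSON provenance report (seeds, counts, manifests...)."""

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)


def empty_condition_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "group": pd.Series(dtype=str),
            "risk": pd.Series(dtype=int),
            "area": pd.Series(dtype=str),
            "compartment": pd.Series(dtype=str),
            "distance_bin": pd.Series(dtype=str),
            "metric": pd.Series(dtype=str),
            "value": pd.Series(dtype=float),
            "n_voxels": pd.Series(dtype=int),
        }
    )
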