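"""Cortical depth assignment: equidistant and equi-volume laminar fractions,
21 depth bins, and the four analysis compartments.

Depth convention: 0 = superficial boundary (CSF side), 1 = deep boundary
(WM side).  The equi-volume correction uses the local outer/inner area
ratio estimated from the mean curvature of the outer boundary under a
linear wedge model; voxels where the wedge degenerates fall back to the
equidistant fraction (counted and reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Volume

__all__ = [
    "LABEL_CODES",
    "DepthField",
    "CompartmentAssignment",
    "equidistant_depth",
    "equivolume_fraction",
    "equivolume_fraction_inverse",
    "compute_depth_field",
    "assign_compartments",
]

#: compartment label codes in the labels volume (NaN outside the cortex)
LABEL_CODES = {"EXCLUDED": 0, "SF": 1, "OM": 2, "IM": 3, "DP": 4}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

N_DEPTHS = 21
EXCLUDED_SUPERFICIAL = (1, 2, 3)
EXCLUDED_DEEP = (20, 21)
COMPARTMENT_DEPTHS = {
    "SF": (4, 5, 6, 7),
    "OM": (8, 9, 10, 11),
    "IM": (12, 13, 14, 15),
    "DP": (16, 17, 18, 19),
}


@dataclass
class DepthField:
    """Per-voxel depth fraction plus the local area-ratio record."""

    depth: Volume
    mode: str
    area_inner: Volume | None = None
    area_outer: Volume | None = None
    n_fallback: int = 0


@dataclass
class CompartmentAssignment:
    labels: Volume  # codes per LABEL_CODES, NaN outside cortex
    depth_index: Volume  # 1..21, NaN outside cortex


def equidistant_depth(d_outer, d_inner):
    """Euclidean depth fraction d_outer / (d_outer + d_inner)."""
    d_outer = np.asarray(d_outer, dtype=float)
    d_inner = np.asarray(d_inner, dtype=float)
    if np.any(d_outer < 0) or np.any(d_inner < 0):
        raise ValueError("distances must be nonnegative")
    total = d_outer + d_inner
    if np.any(total == 0):
        raise ValueError("degenerate voxel: both boundary distances are 0")
    return d_outer / total


def equivolume_fraction(alpha, A_i, A_o):
    """Euclidean fraction at volume fraction ``alpha``, traversing from the
    boundary with local area ``A_i`` toward the boundary with area ``A_o``
    (area varies linearly in between).

    rho = (-A_i + sqrt(alpha A_o^2 + (1 - alpha) A_i^2)) / (A_o - A_i),
    continuously extended to rho = alpha when A_o = A_i.
    """
    alpha = np.asarray(alpha, dtype=float)
    A_i = np.asarray(A_i, dtype=float)
    A_o = np.asarray(A_o, dtype=float)
    if not (np.all(np.isfinite(A_i)) and np.all(np.isfinite(A_o))):
        raise ValueError("non-finite local areas")
    if np.any(A_i <= 0) or np.any(A_o <= 0):
        raise ValueError("local areas must be positive")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must be in [0, 1]")
    diff = A_o - A_i
    root = np.sqrt(alpha * A_o**2 + (1.0 - alpha) * A_i**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(np.abs(diff) > 1e-12, (root - A_i) / diff, alpha)
    return rho if rho.ndim else float(rho)


def equivolume_fraction_inverse(rho, A_i, A_o):
    """Volume fraction whose :func:`equivolume_fraction` equals ``rho``."""
    rho = np.asarray(rho, dtype=float)
    A_i = np.asarray(A_i, dtype=float)
    A_o = np.asarray(A_o, dtype=float)
    diff = A_o - A_i
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            np.abs(diff) > 1e-12,
            ((rho * diff + A_i) ** 2 - A_i**2) / (A_o**2 - A_i**2),
            rho,
        )
    return alpha if alpha.ndim else float(alpha)


def _mean_curvature(outer_sd: Volume) -> np.ndarray:
    """Curvature estimate -div(grad phi / |grad phi|) of the outer boundary.

    Positive where the outer surface is convex toward the outside (gyral
    crowns), negative in sulcal troughs.  For the cylindrically folded
    geometry this is the full principal-curvature sum, which is what the
    linear wedge area model needs.
    """
    phi = outer_sd.data
    sp = outer_sd.spacing
    gx, gy, gz = np.gradient(phi, *sp)
    norm = np.sqrt(gx**2 + gy**2 + gz**2)
    norm = np.where(norm > 1e-9, norm, 1.0)
    nx, ny, nz = gx / norm, gy / norm, gz / norm
    div = (
        np.gradient(nx, sp[0], axis=0)
        + np.gradient(ny, sp[1], axis=1)
        + np.gradient(nz, sp[2], axis=2)
    )
    return -div


def compute_depth_field(
    inner_sd: Volume, outer_sd: Volume, mode: str = "equivolume"
) -> DepthField:
    """Depth fraction per cortex voxel (NaN outside the ribbon).

    ``equidistant``: d_outer / (d_outer + d_inner).  ``equivolume``: the
    voxel's cumulative laminar volume fraction measured from the outer
    boundary, from the inverse of the linear-wedge equi-volume mapping
    with local areas A_o = 1 + H t, A_i = 1 - H (T - t) (t = distance to
    the outer boundary, T = local thickness, H = outer mean curvature).
    Voxels with |H| T >= 1 fall back to equidistant and are counted.
    """
    if mode not in ("equidistant", "equivolume"):
        raise ValueError(f"unknown depth mode: {mode}")
    inner_sd.assert_same_grid(outer_sd, "compute_depth_field")
    ribbon = (inner_sd.data > 0) & (outer_sd.data > 0)
    if not ribbon.any():
        raise ValueError("empty cortex ribbon")

    d_out = np.abs(outer_sd.data[ribbon])
    d_in = np.abs(inner_sd.data[ribbon])
    delta_eq = equidistant_depth(d_out, d_in)

    depth = np.full(inner_sd.shape, np.nan)
    if mode == "equidistant":
        depth[ribbon] = delta_eq
        return DepthField(inner_sd.with_data(depth), mode)

    H = _mean_curvature(outer_sd)[ribbon]
    T = d_out + d_in
    A_o = 1.0 + H * d_out
    A_i = 1.0 - H * (T - d_out)
    bad = (np.abs(H) * T >= 1.0) | (A_o <= 0) | (A_i <= 0)

    # the wedge mapping traverses from the inner (A_i) boundary; mirror
    # the Euclidean fraction, invert, and mirror back so that 0 stays the
    # superficial boundary and laminar volume is conserved
    rho_from_inner = 1.0 - delta_eq
    alpha_from_inner = equivolume_fraction_inverse(rho_from_inner, A_i, A_o)
    delta_ev = 1.0 - alpha_from_inner
    delta_ev = np.where(bad, delta_eq, np.clip(delta_ev, 0.0, 1.0))

    depth[ribbon] = delta_ev
    ai_vol = np.full(inner_sd.shape, np.nan)
    ao_vol = np.full(inner_sd.shape, np.nan)
    ai_vol[ribbon] = A_i
    ao_vol[ribbon] = A_o
    return DepthField(
        inner_sd.with_data(depth),
        mode,
        area_inner=inner_sd.with_data(ai_vol),
        area_outer=inner_sd.with_data(ao_vol),
        n_fallback=int(bad.sum()),
    )


def depth_bin_index(delta: np.ndarray, n_depths: int = N_DEPTHS) -> np.ndarray:
    """Uniform depth bin 1..n_depths (1 = most superficial)."""
    return np.minimum(1 + np.floor(delta * n_depths).astype(int), n_depths)


def assign_compartments(field: DepthField) -> CompartmentAssignment:
    """Map depth fractions to 21 depth bins and SF/OM/IM/DP compartments.

    Depths 1-3 (most superficial) and 20-21 (deepest) are EXCLUDED; the
    remaining 16 depths form four compartments of four consecutive depths.
    """
    delta = field.depth.data
    valid = np.isfinite(delta)
    idx = np.full(delta.shape, np.nan)
    labels = np.full(delta.shape, np.nan)

    j = depth_bin_index(delta[valid])
    idx[valid] = j

    codes = np.zeros(j.shape, dtype=float)  # EXCLUDED by default
    for name, depths in COMPARTMENT_DEPTHS.items():
        sel = (j >= depths[0]) & (j <= depths[-1])
        codes[sel] = LABEL_CODES[name]
    labels[valid] = codes
    return CompartmentAssignment(
        labels=field.depth.with_data(labels),
        depth_index=field.depth.with_data(idx),
    )
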