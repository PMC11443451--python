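"""Synthetic two-group cohort of folded cortical ribbons pierced by veins.

The phantom replaces unavailable in-vivo data: each subject is a folded
slab of "cortex" (between an inner and an outer boundary surface) crossed
by tubular veins, with metric fields (qT1-like in ms, QSM-like in ppm)
that carry programmed depth gradients, distance-to-vein effects, group
offsets, a group x distance interaction, between-subject variance and
voxel noise.  Because the generating model is known, downstream stages are
validated by parameter recovery instead of reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_io import Volume

__all__ = [
    "MetricParams",
    "QsmParams",
    "PhantomSpec",
    "SubjectPhantom",
    "make_surfaces",
    "carve_veins",
    "synthesize_metric_field",
    "generate_cohort",
]


@dataclass
class MetricParams:
    """Generating model for one scalar field on the cortex ribbon.

    value(v) = baseline[area] + depth_gradient * (delta(v) - 0.5)
             + slope_group * (D(v) - 5) + curvature * (D(v) - 5)^2
             + group_offset_old * [old] + u_subject + eps(v)

    with delta the depth fraction (0 = superficial), D the truth distance
    to the nearest vein in mm clipped to [0, 10], u_subject ~ N(0,
    subject_sd^2) and eps ~ N(0, voxel_sd^2).
    """

    baselines: tuple[float, ...]
    depth_gradient: float = 0.0
    slope_young: float = 0.0
    slope_old: float = 0.0
    curvature: float = 0.0
    group_offset_old: float = 0.0
    subject_sd: float = 0.0
    voxel_sd: float = 0.0

    def __post_init__(self):
        vals = [self.depth_gradient, self.slope_young, self.slope_old,
                self.curvature, self.group_offset_old, self.subject_sd,
                self.voxel_sd, *self.baselines]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite metric parameter")
        if self.subject_sd < 0 or self.voxel_sd < 0:
            raise ValueError("sd parameters must be >= 0")


@dataclass
class QsmParams:
    """Bernoulli sign-mixture model for the QSM-like field.

    With probability ``p_pos`` a voxel is positive with magnitude drawn
    from ``pos``; otherwise negative with magnitude from ``neg`` (the
    mirrored construction).  Magnitudes are floored at ``floor``.
    """

    pos: MetricParams
    neg: MetricParams
    p_pos: float = 0.6
    floor: float = 1e-4

    def __post_init__(self):
        if not 0.0 < self.p_pos < 1.0:
            raise ValueError("p_pos must be in (0, 1)")


def _default_qt1() -> MetricParams:
    # calibrated to the target cell-mean / SEM structure: M1 lower than S1,
    # strong superficial-to-deep decrease, opposing group distance slopes
    return MetricParams(
        baselines=(1692.0, 1736.0),
        depth_gradient=-374.0,
        slope_young=-14.4,
        slope_old=1.8,
        curvature=0.0,
        group_offset_old=-24.0,
        subject_sd=66.0,
        voxel_sd=120.0,
    )


def _default_qsm() -> QsmParams:
    pos = MetricParams(
        baselines=(0.0130, 0.0100),
        depth_gradient=-0.0040,
        slope_young=0.0,
        slope_old=0.0,
        curvature=1.5e-4,
        group_offset_old=0.0047,
        subject_sd=0.0020,
        voxel_sd=0.0040,
    )
    neg = MetricParams(
        baselines=(0.0090, 0.0110),
        depth_gradient=0.0020,
        slope_young=0.0,
        slope_old=0.0,
        curvature=1.0e-4,
        group_offset_old=0.0030,
        subject_sd=0.0018,
        voxel_sd=0.0035,
    )
    return QsmParams(pos=pos, neg=neg)


@dataclass
class PhantomSpec:
    """Cohort, geometry, vein, and effect parameters of the phantom."""

    n_young: int = 18
    n_old: int = 17
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    fold_amplitude_mm: float = 3.0
    fold_wavelength_mm: float = 24.0
    thickness_mm: float = 3.0
    n_areas: int = 2
    n_veins: int = 3
    vein_radius_mm: float = 0.75
    vein_tilt: float = 0.15
    vein_min_separation_mm: float = 10.0
    qt1: MetricParams = field(default_factory=_default_qt1)
    qsm: QsmParams = field(default_factory=_default_qsm)
    vein_qsm_ppm: float = 0.30
    background_qsm_sd: float = 0.002
    risk_prevalence: float = 9.0 / 17.0
    max_distance_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        sp = min(self.spacing)
        if self.thickness_mm < 4 * sp:
            raise ValueError(
                f"cortical thickness {self.thickness_mm} mm must be >= 4 x "
                f"spacing ({sp} mm) so depth bins are resolvable"
            )
        if self.vein_radius_mm < sp:
            raise ValueError("vein radius must be >= voxel spacing")
        if self.n_areas < 1:
            raise ValueError("need at least one area")


@dataclass
class SubjectPhantom:
    """One simulated participant with truth volumes and labels."""

    participant_id: str
    group: str
    risk: int
    qT1_volume: Volume
    qsm_volume: Volume
    inner_signed_distance: Volume
    outer_signed_distance: Volume
    vein_mask_truth: Volume
    vein_distance_truth: Volume
    area_labels: Volume
    depth_truth: Volume
    subject_effects: dict


# ---------------------------------------------------------------------------
# geometry


def _grid_coords(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    return x, y, z


def make_surfaces(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Build signed-distance volumes for the inner and outer boundaries.

    The outer boundary is z_out(x) = Z0 + A sin(2 pi x / lambda); the
    inner boundary is offset inward by the cortical thickness along the
    outer surface normal.  Both signed distances are positive toward the
    cortex interior, so the ribbon is {inner > 0 and outer > 0}.
    """
    x, y, z = _grid_coords(spec)
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    extent_z = (nz - 1) * sz
    A = spec.fold_amplitude_mm
    lam = spec.fold_wavelength_mm
    T = spec.thickness_mm
    z0 = 0.60 * extent_z  # outer boundary sits in the upper part of the grid

    margin = 2 * min(spec.spacing)
    if z0 + A + margin > extent_z or z0 - A - T - margin < 0:
        raise ValueError("ribbon does not fit in the grid with a 2-voxel margin")

    if A == 0.0:
        # flat slab: planes, signed distances exact
        zz1 = z[None, :]
        outer_sd2d = np.broadcast_to(z0 - zz1, (nx, nz)).copy()
        inner_sd2d = np.broadcast_to(zz1 - (z0 - T), (nx, nz)).copy()
        outer_sd = np.broadcast_to(outer_sd2d[:, None, :], (nx, ny, nz)).copy()
        inner_sd = np.broadcast_to(inner_sd2d[:, None, :], (nx, ny, nz)).copy()
        return Volume(inner_sd, spec.spacing), Volume(outer_sd, spec.spacing)

    # dense 2D sampling of the outer curve in the (x, z) plane, extended
    # beyond the grid so edge voxels see the true nearest point
    pad = 2 * lam
    u = np.linspace(-pad, x[-1] + pad, 8192)
    f = z0 + A * np.sin(2 * np.pi * u / lam)
    fp = A * (2 * np.pi / lam) * np.cos(2 * np.pi * u / lam)
    w = np.sqrt(1.0 + fp**2)
    outer_pts = np.column_stack([u, f])
    # inward offset along the unit normal (-f', 1)/w pointing to +z outside
    inner_pts = np.column_stack([u + T * fp / w, f - T / w])

    xx, zz = np.meshgrid(x, z, indexing="ij")
    q = np.column_stack([xx.ravel(), zz.ravel()])

    d_out = cKDTree(outer_pts).query(q, workers=-1)[0].reshape(nx, nz)
    d_in = cKDTree(inner_pts).query(q, workers=-1)[0].reshape(nx, nz)

    f_at_x = z0 + A * np.sin(2 * np.pi * xx / lam)
    outer_sd2d = np.where(zz <= f_at_x, d_out, -d_out)

    # the offset curve stays a graph over x while |f''| * T < 1
    order = np.argsort(inner_pts[:, 0])
    zin_at_x = np.interp(xx, inner_pts[order, 0], inner_pts[order, 1])
    inner_sd2d = np.where(zz >= zin_at_x, d_in, -d_in)

    outer_sd = np.broadcast_to(outer_sd2d[:, None, :], (nx, ny, nz)).copy()
    inner_sd = np.broadcast_to(inner_sd2d[:, None, :], (nx, ny, nz)).copy()
    return Volume(inner_sd, spec.spacing), Volume(outer_sd, spec.spacing)


def cortex_mask(inner_sd: Volume, outer_sd: Volume) -> np.ndarray:
    return (inner_sd.data > 0) & (outer_sd.data > 0)


def make_area_labels(spec: PhantomSpec, inner_sd: Volume, outer_sd: Volume) -> Volume:
    """Split the ribbon into ``n_areas`` contiguous slabs along y."""
    nx, ny, nz = spec.grid_shape
    ribbon = cortex_mask(inner_sd, outer_sd)
    ylab = 1 + (np.arange(ny) * spec.n_areas) // ny
    labels = np.broadcast_to(ylab[None, :, None], (nx, ny, nz)).copy()
    labels[~ribbon] = 0
    return Volume(labels.astype(float), spec.spacing)


# ---------------------------------------------------------------------------
# veins


def carve_veins(
    spec: PhantomSpec,
    surfaces: tuple[Volume, Volume],
    rng: np.random.Generator,
) -> tuple[Volume, Volume]:
    """Place jittered near-vertical cylinders through the slab.

    Returns ``(vein_mask_truth, vein_distance_truth)`` where the distance
    volume is the analytic distance to the nearest vein *surface* in mm
    (0 inside a vein).
    """
    if spec.n_veins < 1:
        raise ValueError("vein count must be >= 1")
    inner_sd, outer_sd = surfaces
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    x, y, z = _grid_coords(spec)
    zmid = z[-1] / 2.0

    anchors: list[np.ndarray] = []
    dirs: list[np.ndarray] = []
    margin = 2 * spec.vein_radius_mm
    attempts = 0
    while len(anchors) < spec.n_veins:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                f"could not place {spec.n_veins} veins with separation "
                f"{spec.vein_min_separation_mm} mm; achieved {len(anchors)}"
            )
        a = np.array(
            [
                rng.uniform(margin, x[-1] - margin),
                rng.uniform(margin, y[-1] - margin),
                zmid,
            ]
        )
        d = np.array(
            [
                rng.uniform(-spec.vein_tilt, spec.vein_tilt),
                rng.uniform(-spec.vein_tilt, spec.vein_tilt),
                1.0,
            ]
        )
        d /= np.linalg.norm(d)
        ok = all(
            np.linalg.norm(a[:2] - b[:2]) >= spec.vein_min_separation_mm
            for b in anchors
        )
        if ok:
            anchors.append(a)
            dirs.append(d)

    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)

    dist_axis = np.full(spec.grid_shape, np.inf)
    for a, d in zip(anchors, dirs):
        rel = pts - a
        proj = rel @ d
        perp = rel - proj[..., None] * d
        dist_axis = np.minimum(dist_axis, np.linalg.norm(perp, axis=-1))

    mask = dist_axis <= spec.vein_radius_mm
    ribbon = cortex_mask(inner_sd, outer_sd)
    if not (mask & ribbon).any():
        raise RuntimeError("veins do not intersect the cortex ribbon")

    dist_surface = np.clip(dist_axis - spec.vein_radius_mm, 0.0, None)
    dist_surface[mask] = 0.0
    return (
        Volume(mask.astype(float), spec.spacing),
        Volume(dist_surface, spec.spacing),
    )


# ---------------------------------------------------------------------------
# metric synthesis


def _field_values(
    params: MetricParams,
    area_idx: np.ndarray,
    depth: np.ndarray,
    dist: np.ndarray,
    group: str,
    u_subject: float,
    rng: np.random.Generator | None,
    max_distance: float = 10.0,
) -> np.ndarray:
    baselines = np.asarray(params.baselines, dtype=float)
    slope = params.slope_old if group == "old" else params.slope_young
    offset = params.group_offset_old if group == "old" else 0.0
    D = np.clip(dist, 0.0, max_distance) - max_distance / 2.0
    vals = (
        baselines[area_idx]
        + params.depth_gradient * (depth - 0.5)
        + slope * D
        + params.curvature * D**2
        + offset
        + u_subject
    )
    if rng is not None and params.voxel_sd > 0:
        vals = vals + rng.normal(0.0, params.voxel_sd, size=vals.shape)
    return vals


def expected_metric_value(
    params: MetricParams,
    area_idx,
    depth,
    dist,
    group: str,
    max_distance: float = 10.0,
) -> np.ndarray:
    """Noise-free generator expectation (the analytic oracle for tests)."""
    return _field_values(
        params, np.asarray(area_idx), np.asarray(depth), np.asarray(dist),
        group, 0.0, None, max_distance,
    )


def synthesize_metric_field(
    spec: PhantomSpec,
    group: str,
    depth_truth: Volume,
    vein_distance_truth: Volume,
    area_labels: Volume,
    rng: np.random.Generator,
) -> tuple[Volume, Volume, dict]:
    """Draw the qT1-like and QSM-like volumes for one subject.

    The qT1 volume is defined on the cortex ribbon only (NaN elsewhere);
    the QSM volume is dense: tissue values on the ribbon, bright vein
    signal at vein voxels (so vessel segmentation has a target), and weak
    background noise elsewhere.  Returns the two metric volumes plus the
    record of drawn subject-level random intercepts.
    """
    ribbon = np.isfinite(depth_truth.data)
    area_idx = np.clip(area_labels.data[ribbon].astype(int) - 1, 0, None)
    depth = depth_truth.data[ribbon]
    dist = vein_distance_truth.data[ribbon]

    effects = {
        "u_qt1": rng.normal(0.0, spec.qt1.subject_sd) if spec.qt1.subject_sd else 0.0,
        "u_qsm_pos": rng.normal(0.0, spec.qsm.pos.subject_sd)
        if spec.qsm.pos.subject_sd
        else 0.0,
        "u_qsm_neg": rng.normal(0.0, spec.qsm.neg.subject_sd)
        if spec.qsm.neg.subject_sd
        else 0.0,
    }

    qt1_vals = _field_values(
        spec.qt1, area_idx, depth, dist, group, effects["u_qt1"], rng,
        spec.max_distance_mm,
    )

    pos_mag = _field_values(
        spec.qsm.pos, area_idx, depth, dist, group, effects["u_qsm_pos"], rng,
        spec.max_distance_mm,
    )
    neg_mag = _field_values(
        spec.qsm.neg, area_idx, depth, dist, group, effects["u_qsm_neg"], rng,
        spec.max_distance_mm,
    )
    is_pos = rng.random(qt1_vals.shape) < spec.qsm.p_pos
    qsm_vals = np.where(
        is_pos,
        np.maximum(pos_mag, spec.qsm.floor),
        -np.maximum(neg_mag, spec.qsm.floor),
    )

    qt1 = np.full(spec.grid_shape, np.nan)
    qt1[ribbon] = qt1_vals
    # dense QSM: background noise, tissue values on the ribbon, bright veins
    qsm = rng.normal(0.0, spec.background_qsm_sd, size=spec.grid_shape)
    qsm[ribbon] = qsm_vals
    vein = vein_distance_truth.data == 0
    qsm[vein] = spec.vein_qsm_ppm + rng.normal(
        0.0, spec.background_qsm_sd, size=int(vein.sum())
    )
    return (
        Volume(qt1, spec.spacing),
        Volume(qsm, spec.spacing),
        effects,
    )


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(spec: PhantomSpec) -> list[SubjectPhantom]:
    """Generate the full two-group cohort, deterministically from the seed.

    Geometry (surfaces, areas, truth depth) is shared; veins, risk flags
    and noise are per subject with sub-seeds derived from the master seed.
    """
    inner_sd, outer_sd = make_surfaces(spec)
    area_labels = make_area_labels(spec, inner_sd, outer_sd)
    ribbon = cortex_mask(inner_sd, outer_sd)

    depth = np.full(spec.grid_shape, np.nan)
    di = inner_sd.data[ribbon]
    do = outer_sd.data[ribbon]
    depth[ribbon] = do / (do + di)
    depth_truth = Volume(depth, spec.spacing)

    risk_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9999]))
    risk_old = (risk_rng.random(spec.n_old) < spec.risk_prevalence).astype(int)

    subjects = []
    groups = ["young"] * spec.n_young + ["old"] * spec.n_old
    for idx, group in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        if spec.n_veins == 0:
            # no veins: empty mask, everything maximally distant; the
            # downstream distance transform is what reports the failure
            vein_mask = Volume(np.zeros(spec.grid_shape), spec.spacing)
            vein_dist = Volume(np.full(spec.grid_shape, np.inf), spec.spacing)
        else:
            vein_mask, vein_dist = carve_veins(spec, (inner_sd, outer_sd), rng)
        qt1_vol, qsm_vol, effects = synthesize_metric_field(
            spec, group, depth_truth, vein_dist, area_labels, rng
        )
        risk = int(risk_old[idx - spec.n_young]) if group == "old" else 0
        subjects.append(
            SubjectPhantom(
                participant_id=f"sub-{idx + 1:02d}",
                group=group,
                risk=risk,
                qT1_volume=qt1_vol,
                qsm_volume=qsm_vol,
                inner_signed_distance=inner_sd,
                outer_signed_distance=outer_sd,
                vein_mask_truth=vein_mask,
                vein_distance_truth=vein_dist,
                area_labels=area_labels,
                depth_truth=depth_truth,
                subject_effects=effects,
            )
        )
    return subjects
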