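"""Distance binning and extraction of the long-format condition table.

Vessel distances are discretized into half-open 2-mm bins (0, 2], (2, 4],
..., (8, 10]; vein voxels (distance 0) and voxels beyond the last edge are
excluded.  QSM values are split by sign into pQSM (> 0) and nQSM (< 0)
samples with their own voxel counts.  A cell value is reported only when
it aggregates at least ``min_voxels_per_bin`` voxels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import COMPARTMENTS, StudyConfig, Volume, empty_condition_table
from .laminar import CODE_LABELS, LABEL_CODES, CompartmentAssignment

__all__ = ["bin_distance", "split_qsm", "extract_condition_values"]


def bin_distance(d, edges=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0)):
    """Bin label index for distance(s) ``d`` in mm, or -1 when excluded.

    d = 0 (vein voxel) and d > last edge are excluded; bins are half-open
    (prev, next], so d = 2.0 belongs to bin 0-2 and d = 2.01 to bin 2-4.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance: vessel distance map is corrupt")
    edges = np.asarray(edges, dtype=float)
    # side='left': index i such that edges[i-1] < d <= edges[i]
    idx = np.searchsorted(edges, d, side="left") - 1
    idx = np.where((d <= edges[0]) | (d > edges[-1]), -1, idx)
    return idx if idx.ndim else int(idx)


def split_qsm(values):
    """Split QSM voxel values into (pQSM, nQSM); zeros are discarded."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    return values[values > 0], values[values < 0]


def _cell_row(values: np.ndarray, min_voxels: int) -> tuple[float, int]:
    n = int(values.size)
    value = float(np.mean(values)) if n >= min_voxels else np.nan
    return value, n


def extract_condition_values(
    qt1: Volume,
    qsm: Volume,
    vdm: Volume,
    compartments: CompartmentAssignment,
    areas: Volume,
    vein_mask: Volume,
    config: StudyConfig,
    participant_id: str = "sub-01",
    group: str = "young",
    risk: int = 0,
    area_names: dict | None = None,
) -> pd.DataFrame:
    """Aggregate metric values per (area, compartment, distance bin).

    qT1 cell values are means over all in-cell non-vein voxels; pQSM and
    nQSM are means over the sign-split subsets with their own counts, each
    subject to the minimum-voxel rule independently.
    """
    for vol, name in ((qsm, "qsm"), (vdm, "vdm"), (areas, "areas"),
                      (vein_mask, "vein_mask")):
        qt1.assert_same_grid(vol, f"extract_condition_values[{name}]")

    labels = compartments.labels.data
    area_data = areas.data
    vein = vein_mask.data > 0
    dist = vdm.data
    edges = np.asarray(config.bin_edges)
    bin_labels = config.bin_labels

    area_ids = sorted(int(a) for a in np.unique(area_data[np.isfinite(area_data)]) if a > 0)
    if not area_ids:
        raise ValueError("area label volume contains no areas")
    if area_names is None:
        area_names = {a: f"area{a}" for a in area_ids}

    rows = []
    for aid in area_ids:
        a_mask = area_data == aid
        if not a_mask.any():
            raise ValueError(f"empty area mask: {aid}")
        for comp in COMPARTMENTS:
            if not (a_mask & (labels == LABEL_CODES[comp])).any():
                raise ValueError(
                    f"empty compartment mask: area {area_names[aid]}, {comp}"
                )
            c_mask = a_mask & (labels == LABEL_CODES[comp]) & ~vein
            bins = bin_distance(dist[c_mask], edges) if c_mask.any() else np.array([], int)
            qt1_vals = qt1.data[c_mask]
            qsm_vals = qsm.data[c_mask]
            for b, lbl in enumerate(bin_labels):
                sel = bins == b
                qv = qt1_vals[sel]
                qv = qv[np.isfinite(qv)]
                value, n = _cell_row(qv, config.min_voxels_per_bin)
                rows.append((participant_id, group, risk, area_names[aid],
                             comp, lbl, "qT1", value, n))
                pos, neg = split_qsm(qsm_vals[sel])
                pv, pn = _cell_row(pos, config.min_voxels_per_bin)
                rows.append((participant_id, group, risk, area_names[aid],
                             comp, lbl, "pQSM", pv, pn))
                nv, nn = _cell_row(neg, config.min_voxels_per_bin)
                rows.append((participant_id, group, risk, area_names[aid],
                             comp, lbl, "nQSM", nv, nn))

    table = pd.DataFrame(rows, columns=list(empty_condition_table().columns))
    return table
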