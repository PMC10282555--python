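"""Tract-level aggregation: fixel weight maps, microstructure maps, means,
along-streamline profiles and scan-rescan summary statistics.

Each in-voxel subsegment distributes its length over the voxel's fixels
according to a contribution strategy; accumulating those length-weighted
contributions yields per-fixel weight maps whose fixel-wise sum — the total
segment length map — depends only on the tractography. Normalizing the
weight-weighted fixel metrics produces a tract-specific microstructure map,
which is then summarized as a tract-wide mean under total-segment-length
(tsl) or region-of-interest (roi) voxel weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import FixelField, relative_contribution, segment_metric
from .geometry import Subsegment, Tract, VoxelGrid, split_tract

__all__ = [
    "WeightMaps",
    "MicrostructureMap",
    "TractSummary",
    "compute_weight_maps",
    "compute_microstructure_map",
    "segment_level_map",
    "tract_mean",
    "streamline_profile",
    "scan_rescan_stats",
]


@dataclass
class WeightMaps:
    """Per-fixel weight volumes and the total segment length volume of a tract.

    ``fixel_weights[v, k]`` is the summed, contribution-weighted subsegment
    length (mm) attributed to fixel ``k`` in voxel ``v``; ``total_length[v]``
    is the plain summed subsegment length, independent of the strategy.
    """

    fixel_weights: np.ndarray
    total_length: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        if self.fixel_weights.shape[:3] != self.total_length.shape:
            raise ValueError("fixel_weights and total_length grids differ")


@dataclass
class MicrostructureMap:
    """Voxel-wise tract-specific metric; NaN marks undefined voxels."""

    values: np.ndarray
    metric_name: str

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class TractSummary:
    """Tract-wide mean of a microstructure map under one voxel weighting."""

    mean: float
    weighting: str
    n_voxels: int
    total_length_mm: float


def _grid_of(field: FixelField) -> VoxelGrid:
    return VoxelGrid(field.shape, field.affine)


def compute_weight_maps(
    subsegments: Iterable[Subsegment],
    fixel_field: FixelField,
    strategy: str,
) -> WeightMaps:
    """Accumulate subsegment lengths into per-fixel weight maps.

    For each subsegment, the voxel's present fixels split the subsegment
    length by the chosen contribution strategy; fixel-free voxels accumulate
    only total length. Accumulation is sequential in subsegment order, so the
    maps are bit-reproducible.
    """
    shape = fixel_field.shape
    weights = np.zeros(shape + (fixel_field.k_max,))
    total = np.zeros(shape)
    for sub in subsegments:
        if not sub.in_volume:
            continue
        v = sub.voxel
        total[v] += sub.length
        slots, ori, frac = fixel_field.voxel_fixels(v)
        if slots.size == 0:
            continue
        rc = relative_contribution(strategy, sub.direction, ori, frac)
        weights[v][slots] += rc.alphas * sub.length
    return WeightMaps(fixel_weights=weights, total_length=total, strategy=strategy)


def compute_microstructure_map(
    weight_maps: WeightMaps,
    fixel_field: FixelField,
    metric_name: str,
) -> MicrostructureMap:
    """Fixel-weighted average metric per voxel (NaN where no fixel weight)."""
    if metric_name not in fixel_field.metrics:
        raise KeyError(
            f"unknown metric {metric_name!r}; available: {sorted(fixel_field.metrics)}"
        )
    w = weight_maps.fixel_weights
    m = np.where(fixel_field.present_mask, fixel_field.metrics[metric_name], 0.0)
    denom = w.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        values = np.where(denom > 0, (w * m).sum(axis=-1) / np.where(denom > 0, denom, 1.0), np.nan)
    return MicrostructureMap(values=values, metric_name=metric_name)


def segment_level_map(
    subsegments: Iterable[Subsegment],
    fixel_field: FixelField,
    strategy: str,
    metric_name: str,
) -> MicrostructureMap:
    """Microstructure map built directly from per-segment metrics.

    Each subsegment contributes its own segment metric weighted by its
    intra-voxel length; the result is algebraically identical to
    :func:`compute_microstructure_map` and serves as an independent
    cross-check of the fixel-aggregated route.
    """
    if metric_name not in fixel_field.metrics:
        raise KeyError(
            f"unknown metric {metric_name!r}; available: {sorted(fixel_field.metrics)}"
        )
    shape = fixel_field.shape
    num = np.zeros(shape)
    den = np.zeros(shape)
    for sub in subsegments:
        if not sub.in_volume:
            continue
        v = sub.voxel
        slots, ori, frac = fixel_field.voxel_fixels(v)
        if slots.size == 0:
            continue
        rc = relative_contribution(strategy, sub.direction, ori, frac)
        m_vs = segment_metric(rc, fixel_field.metrics[metric_name][v][slots])
        num[v] += sub.length * m_vs
        den[v] += sub.length
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return MicrostructureMap(values=values, metric_name=metric_name)


def tract_mean(
    micro_map: MicrostructureMap,
    weight_maps: WeightMaps,
    weighting: str = "tsl",
    min_length: float = 0.0,
) -> TractSummary:
    """Tract-wide mean of a microstructure map.

    ``tsl`` weights each voxel by its total segment length, so voxels the
    tract occupies densely dominate; ``roi`` weights every tract-occupied
    voxel equally. Voxels with an undefined map value (no fixels, or total
    length at or below ``min_length``) are excluded from numerator and
    denominator alike.
    """
    if weighting not in ("tsl", "roi"):
        raise ValueError(f"weighting must be 'tsl' or 'roi', got {weighting!r}")
    if micro_map.values.shape != weight_maps.total_length.shape:
        raise ValueError("map and weight maps live on different grids")
    w = weight_maps.total_length
    valid = micro_map.defined & (w > min_length)
    if not np.any(valid):
        raise ValueError("no defined voxels: the tract does not cover any fixel")
    gamma = np.where(valid, w if weighting == "tsl" else 1.0, 0.0)
    mean = float((gamma * np.where(valid, micro_map.values, 0.0)).sum() / gamma.sum())
    return TractSummary(
        mean=mean,
        weighting=weighting,
        n_voxels=int(valid.sum()),
        total_length_mm=float(w.sum()),
    )


def streamline_profile(
    streamline: np.ndarray,
    fixel_field: FixelField,
    strategy: str,
    metric_name: str,
) -> pd.DataFrame:
    """Along-streamline profile of contributions and segment metrics.

    One row per in-volume subsegment, in traversal order, with columns
    ``segment``, ``voxel_i/j/k``, ``alpha_0..alpha_{K_max-1}`` (NaN for absent
    fixel slots), ``length_mm`` and the segment metric ``metric``. The metric
    is NaN in fixel-free voxels. Lets a streamline exhibit non-constant
    microstructure along its course.
    """
    if metric_name not in fixel_field.metrics:
        raise KeyError(
            f"unknown metric {metric_name!r}; available: {sorted(fixel_field.metrics)}"
        )
    tract = Tract(streamlines=[np.asarray(streamline, dtype=float)])
    if len(tract) == 0:
        raise ValueError("streamline has fewer than 2 distinct points")
    grid = _grid_of(fixel_field)
    try:
        subs = split_tract(tract, grid)
    except ValueError:
        subs = []
    rows = []
    k_max = fixel_field.k_max
    for idx, sub in enumerate(subs):
        slots, ori, frac = fixel_field.voxel_fixels(sub.voxel)
        alphas = np.full(k_max, np.nan)
        if slots.size:
            rc = relative_contribution(strategy, sub.direction, ori, frac)
            alphas[slots] = rc.alphas
            m_vs = segment_metric(rc, fixel_field.metrics[metric_name][sub.voxel][slots])
        else:
            m_vs = float("nan")
        row = {
            "segment": idx,
            "voxel_i": sub.voxel[0],
            "voxel_j": sub.voxel[1],
            "voxel_k": sub.voxel[2],
        }
        row.update({f"alpha_{k}": alphas[k] for k in range(k_max)})
        row["length_mm"] = sub.length
        row[metric_name] = m_vs
        rows.append(row)
    cols = (
        ["segment", "voxel_i", "voxel_j", "voxel_k"]
        + [f"alpha_{k}" for k in range(k_max)]
        + ["length_mm", metric_name]
    )
    return pd.DataFrame(rows, columns=cols)


def scan_rescan_stats(
    means_scan1: Sequence[float],
    means_scan2: Sequence[float],
) -> Tuple[np.ndarray, float, float]:
    """Symmetric percentage change between paired scan/rescan tract means.

    Per tract: ``100 * (m2 - m1) / ((m1 + m2) / 2)`` — the Bland-Altman
    convention, antisymmetric under swapping the scans. Returns the per-tract
    changes, their mean, and their sample standard deviation (NaN for a
    single pair).
    """
    m1 = np.asarray(means_scan1, dtype=float)
    m2 = np.asarray(means_scan2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("scan and rescan value lists must be equal-length 1-D sequences")
    if np.any(m1 <= 0) or np.any(m2 <= 0):
        raise ValueError("tract means must be positive")
    changes = 100.0 * (m2 - m1) / ((m1 + m2) / 2.0)
    sd = float(np.std(changes, ddof=1)) if changes.size > 1 else float("nan")
    return changes, float(np.mean(changes)), sd
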