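"""Synthetic crossing-tract phantom with fixel-level ground truth.

The phantom emulates a 2D slice holding two horizontal tracts (high, known
FVF/FA) crossed by two vertical tracts whose FVF and FA increase linearly
from top to bottom, surrounded by CSF voxels that carry no fixels. Crossing
voxels hold both tracts' fixels at orthogonal orientations; every fixel
carries its own tract's ground-truth metric values, so every map, mean and
profile computed on the phantom can be checked against known truth. An
optional corruption operator emulates a multi-fixel model erroneously
splitting one true fiber population into two tilted fixels with biased
metrics.

The phantom is generated directly at the fixel level: the framework consumes
fixels, so fixel-level ground truth exercises the whole pipeline at desk
scale without diffusion-signal simulation or model fitting.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .core import FixelField
from .geometry import Tract

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom", "corrupt_fixels"]

# simulation parameters of the signal-level phantom the geometry mirrors;
# recorded in the manifest as provenance, unused by any computation
_PROVENANCE = {
    "intra_axonal_diffusivity_um2_per_ms": 2.0,
    "extracellular_diffusivity_um2_per_ms": 1.0,
    "axon_diameter_gamma_mean_um": 1.0,
    "axon_diameter_gamma_variance_um": 0.6,
}


@dataclass
class PhantomSpec:
    """Parameters of the crossing-tract phantom.

    Bands are half-open voxel-index ranges ``(start, stop)``. Horizontal
    tracts run along +x occupying rows of the grid; vertical tracts run along
    +y spanning the full grid height. ``v_fvf_range``/``v_fa_range`` give the
    vertical tracts' metric values at the top and bottom grid rows, between
    which each row interpolates linearly.
    """

    shape: Tuple[int, int, int] = (32, 32, 1)
    voxel_size: float = 2.0
    h_bands: Tuple[Tuple[int, int], Tuple[int, int]] = ((20, 24), (8, 12))
    h_fvf: Tuple[float, float] = (0.70, 0.66)
    h_fa: Tuple[float, float] = (0.80, 0.75)
    v_bands: Tuple[Tuple[int, int], Tuple[int, int]] = ((8, 12), (20, 24))
    v_fvf_range: Tuple[float, float] = (0.40, 0.70)  # (top row, bottom row)
    v_fa_range: Tuple[float, float] = (0.45, 0.65)
    crossing_fractions: Tuple[float, float] = (0.5, 0.5)
    single_fixel_fraction: float = 0.7
    n_streamlines: int = 50
    step_size: float = 1.0
    jitter_sd_deg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        nx, ny, nz = self.shape
        for name, bands, n in (("h_bands", self.h_bands, ny), ("v_bands", self.v_bands, nx)):
            for lo, hi in bands:
                if not (0 <= lo < hi <= n):
                    problems.append(f"{name} band ({lo}, {hi}) outside grid extent {n}")
        for name, vals in (
            ("h_fvf", self.h_fvf),
            ("h_fa", self.h_fa),
            ("v_fvf_range", self.v_fvf_range),
            ("v_fa_range", self.v_fa_range),
        ):
            if any(not (0.0 <= v <= 1.0) for v in vals):
                problems.append(f"{name} values must lie in [0, 1]: {vals}")
        if self.n_streamlines <= 0:
            problems.append("n_streamlines must be positive")
        if self.voxel_size <= 0 or self.step_size <= 0:
            problems.append("voxel_size and step_size must be positive")
        if self.jitter_sd_deg < 0:
            problems.append("jitter_sd_deg must be >= 0")
        if not (0 < self.single_fixel_fraction <= 1):
            problems.append("single_fixel_fraction must lie in (0, 1]")
        if sum(self.crossing_fractions) > 1 + 1e-6 or any(f <= 0 for f in self.crossing_fractions):
            problems.append("crossing_fractions must be positive and sum to at most 1")
        if problems:
            raise ValueError("invalid phantom spec:\n  " + "\n  ".join(problems))


@dataclass
class PhantomBundle:
    """Generated fixel field, named tracts and ground-truth manifest.

    ``manifest["tracts"]`` maps tract names (T1/T2 horizontal, T3/T4
    vertical) to their axis, member voxels and per-voxel ground-truth FVF/FA.
    """

    fixel_field: FixelField
    tracts: Dict[str, Tract]
    manifest: Dict = field(default_factory=dict)

    def ground_truth(self, tract: str, metric: str, voxel: Tuple[int, int, int]) -> float:
        """Ground-truth metric value of one tract in one voxel."""
        key = f"{int(voxel[0])},{int(voxel[1])},{int(voxel[2])}"
        return self.manifest["tracts"][tract]["truth"][metric][key]


def _jitter(rng: np.random.Generator, u: np.ndarray, sd_deg: float) -> np.ndarray:
    """Rotate u by a random small-angle perturbation (isotropic axis)."""
    if sd_deg == 0:
        return u
    axis = rng.normal(size=3)
    axis -= axis.dot(u) * u
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return u
    axis /= n
    ang = np.radians(rng.normal(0.0, sd_deg))
    return u * np.cos(ang) + axis * np.sin(ang)


def _band_offsets(lo: int, hi: int, voxel_size: float, n: int) -> np.ndarray:
    """Evenly spaced world offsets across a band's cross-section.

    Inset by a quarter voxel from the band edges so streamlines never ride a
    voxel boundary exactly.
    """
    w_lo = (lo - 0.5 + 0.25) * voxel_size
    w_hi = (hi - 0.5 - 0.25) * voxel_size
    return np.linspace(w_lo, w_hi, n)


def generate_phantom(spec: Optional[PhantomSpec] = None) -> PhantomBundle:
    """Build the crossing-tract phantom for a given spec (default spec if None).

    Fixel orientations are the tract axes (+x for horizontal, +y for vertical
    tracts) with optional seeded angular jitter; streamlines are straight
    polylines spanning the grid along each tract's axis, offset to cover the
    band cross-section. Deterministic for a fixed seed.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    k_max = 2
    affine = np.diag([spec.voxel_size] * 3 + [1.0])

    orientations = np.zeros((nx, ny, nz, k_max, 3))
    fractions = np.zeros((nx, ny, nz, k_max))
    fvf = np.zeros((nx, ny, nz, k_max))
    fa = np.zeros((nx, ny, nz, k_max))

    x_axis = np.array([1.0, 0.0, 0.0])
    y_axis = np.array([0.0, 1.0, 0.0])

    def v_value(rng_pair: Tuple[float, float], j: int) -> float:
        # linear top (j = ny-1) -> bottom (j = 0)
        top, bottom = rng_pair
        t = j / (ny - 1) if ny > 1 else 0.0
        return bottom + (top - bottom) * t

    tract_info: Dict[str, Dict] = {}
    h_names = ("T1", "T2")
    v_names = ("T3", "T4")
    kz = 0  # single slice

    for name, (lo, hi), t_fvf, t_fa in zip(h_names, spec.h_bands, spec.h_fvf, spec.h_fa):
        tract_info[name] = {"axis": "x", "band": (lo, hi), "voxels": [], "truth": {"FVF": {}, "FA": {}}}
        for i in range(nx):
            for j in range(lo, hi):
                tract_info[name]["voxels"].append((i, j, kz))
                tract_info[name]["truth"]["FVF"][f"{i},{j},{kz}"] = t_fvf
                tract_info[name]["truth"]["FA"][f"{i},{j},{kz}"] = t_fa
    for name, (lo, hi) in zip(v_names, spec.v_bands):
        tract_info[name] = {"axis": "y", "band": (lo, hi), "voxels": [], "truth": {"FVF": {}, "FA": {}}}
        for i in range(lo, hi):
            for j in range(ny):
                tract_info[name]["voxels"].append((i, j, kz))
                tract_info[name]["truth"]["FVF"][f"{i},{j},{kz}"] = v_value(spec.v_fvf_range, j)
                tract_info[name]["truth"]["FA"][f"{i},{j},{kz}"] = v_value(spec.v_fa_range, j)

    # populate fixels voxel by voxel
    h_rows = {j: n for n, (lo, hi) in zip(h_names, spec.h_bands) for j in range(lo, hi)}
    v_cols = {i: n for n, (lo, hi) in zip(v_names, spec.v_bands) for i in range(lo, hi)}
    for i in range(nx):
        for j in range(ny):
            members = []
            if j in h_rows:
                members.append((h_rows[j], x_axis))
            if i in v_cols:
                members.append((v_cols[i], y_axis))
            if not members:
                continue  # CSF: no fixels
            if len(members) == 1:
                fracs = (spec.single_fixel_fraction,)
            else:
                fracs = spec.crossing_fractions
            for slot, ((tname, axis), f) in enumerate(zip(members, fracs)):
                orientations[i, j, kz, slot] = _jitter(rng, axis, spec.jitter_sd_deg)
                fractions[i, j, kz, slot] = f
                fvf[i, j, kz, slot] = tract_info[tname]["truth"]["FVF"][f"{i},{j},{kz}"]
                fa[i, j, kz, slot] = tract_info[tname]["truth"]["FA"][f"{i},{j},{kz}"]

    fixel_field = FixelField(
        affine=affine,
        orientations=orientations,
        fractions=fractions,
        metrics={"FVF": fvf, "FA": fa},
    )

    # straight streamlines spanning the grid along each tract axis
    tracts: Dict[str, Tract] = {}
    z_world = 0.0
    for name, info in tract_info.items():
        lo, hi = info["band"]
        offsets = _band_offsets(lo, hi, spec.voxel_size, spec.n_streamlines)
        if info["axis"] == "x":
            span = (nx - 1) * spec.voxel_size
            n_pts = int(np.floor(span / spec.step_size)) + 1
            xs = np.arange(n_pts) * spec.step_size
            sls = [np.column_stack([xs, np.full(n_pts, off), np.full(n_pts, z_world)]) for off in offsets]
        else:
            span = (ny - 1) * spec.voxel_size
            n_pts = int(np.floor(span / spec.step_size)) + 1
            ys = np.arange(n_pts) * spec.step_size
            sls = [np.column_stack([np.full(n_pts, off), ys, np.full(n_pts, z_world)]) for off in offsets]
        tracts[name] = Tract(streamlines=sls, step_size=spec.step_size)

    manifest = {
        "spec": {
            "shape": list(spec.shape),
            "voxel_size_mm": spec.voxel_size,
            "h_bands": [list(b) for b in spec.h_bands],
            "h_fvf": list(spec.h_fvf),
            "h_fa": list(spec.h_fa),
            "v_bands": [list(b) for b in spec.v_bands],
            "v_fvf_range": list(spec.v_fvf_range),
            "v_fa_range": list(spec.v_fa_range),
            "crossing_fractions": list(spec.crossing_fractions),
            "single_fixel_fraction": spec.single_fixel_fraction,
            "n_streamlines": spec.n_streamlines,
            "step_size_mm": spec.step_size,
            "jitter_sd_deg": spec.jitter_sd_deg,
            "seed": spec.seed,
        },
        "tracts": tract_info,
        "signal_simulation_provenance": dict(_PROVENANCE),
        "corruption": None,
    }
    return PhantomBundle(fixel_field=fixel_field, tracts=tracts, manifest=manifest)


def corrupt_fixels(
    bundle: PhantomBundle,
    region: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]],
    split_angle_deg: float = 30.0,
    metric_offsets: Optional[Dict[str, float]] = None,
) -> PhantomBundle:
    """Emulate a multi-fixel model splitting one true fixel into two.

    In every single-fixel voxel of ``region`` (half-open index ranges per
    axis), the true fixel is replaced by two fixels tilted by
    ``±split_angle_deg/2`` about an axis perpendicular to the true
    orientation. Each metric named in ``metric_offsets`` is offset by +δ on
    the first (lowest-index) replacement fixel and −δ on the second; the
    fraction splits in half. The manifest's ground truth is unchanged — the
    corruption models an estimation error, not a change of the tissue.

    Returns a new bundle; the input is not modified.
    """
    metric_offsets = metric_offsets or {}
    out = PhantomBundle(
        fixel_field=FixelField(
            affine=bundle.fixel_field.affine.copy(),
            orientations=bundle.fixel_field.orientations.copy(),
            fractions=bundle.fixel_field.fractions.copy(),
            metrics={k: v.copy() for k, v in bundle.fixel_field.metrics.items()},
        ),
        tracts=bundle.tracts,
        manifest=copy.deepcopy(bundle.manifest),
    )
    for name in metric_offsets:
        if name not in out.fixel_field.metrics:
            raise KeyError(f"unknown metric {name!r}; available: {sorted(out.fixel_field.metrics)}")
    (i0, i1), (j0, j1), (k0, k1) = region
    ff = out.fixel_field
    counts = ff.fixel_count
    n_hit = 0
    half = np.radians(split_angle_deg / 2.0)
    for i in range(i0, i1):
        for j in range(j0, j1):
            for k in range(k0, k1):
                if counts[i, j, k] != 1:
                    continue
                slots, ori, frac = ff.voxel_fixels((i, j, k))
                u = ori[0]
                # tilt axis: perpendicular to u, preferring the slice normal
                axis = np.array([0.0, 0.0, 1.0])
                if abs(np.dot(axis, u)) > 0.9:
                    axis = np.array([1.0, 0.0, 0.0])
                axis -= axis.dot(u) * u
                axis /= np.linalg.norm(axis)
                u_plus = u * np.cos(half) + axis * np.sin(half)
                u_minus = u * np.cos(half) - axis * np.sin(half)
                ff.orientations[i, j, k, 0] = u_plus
                ff.orientations[i, j, k, 1] = u_minus
                f = frac[0]
                ff.fractions[i, j, k, 0] = f / 2.0
                ff.fractions[i, j, k, 1] = f / 2.0
                for mname, marr in ff.metrics.items():
                    true_val = marr[i, j, k, slots[0]]
                    delta = metric_offsets.get(mname, 0.0)
                    marr[i, j, k, 0] = true_val + delta
                    marr[i, j, k, 1] = true_val - delta
                n_hit += 1
    if n_hit == 0:
        raise ValueError("corruption region contains no single-fixel voxels")
    out.manifest["corruption"] = {
        "region": [list(r) for r in region],
        "split_angle_deg": split_angle_deg,
        "metric_offsets": dict(metric_offsets),
        "n_voxels": n_hit,
    }
    return out
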