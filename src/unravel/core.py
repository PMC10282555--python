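"""Fixel field data model and streamline-segment contribution strategies.

A *fixel* is a specific fiber population within a voxel, carrying a principal
orientation (a sign-ambiguous unit vector), a volume fraction and one or more
scalar microstructural metrics. The functions here decide how much each fixel
of a voxel contributes to a streamline segment traversing that voxel:

``vol``
    relative volume weighting — fractions only, orientation-agnostic;
``cfo``
    closest-fixel-only — the angularly nearest fixel takes everything;
``ang``
    angular weighting — all fixels share the contribution according to their
    angular proximity to the segment.

Every strategy returns contributions in [0, 1] that sum to one over the
voxel's present fixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "ORIENTATION_NORM_TOL",
    "ABSENT_NORM_EPS",
    "FixelField",
    "RelativeContribution",
    "axial_angle",
    "alpha_vol",
    "alpha_cfo",
    "alpha_ang",
    "relative_contribution",
    "segment_metric",
]

#: tolerance on the Euclidean norm of a present fixel orientation
ORIENTATION_NORM_TOL = 1e-6
#: below this norm an orientation marks an absent fixel slot
ABSENT_NORM_EPS = 1e-8

STRATEGIES = ("vol", "cfo", "ang")


def axial_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two sign-ambiguous orientations, in [0, 90].

    Fixel orientations and streamline segment directions are axial: ``u`` and
    ``-u`` describe the same physical orientation, so the angle is computed on
    the absolute dot product.

    Parameters
    ----------
    u, v : (3,) array_like
        Orientation vectors; they need not be normalized but must have norm
        greater than ``ABSENT_NORM_EPS``.

    Returns
    -------
    float
        ``arccos(|u·v| / (|u||v|))`` in degrees.

    Raises
    ------
    ValueError
        If either vector is degenerate (near-zero norm).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu <= ABSENT_NORM_EPS or nv <= ABSENT_NORM_EPS:
        raise ValueError(
            f"degenerate orientation vector (norms {nu:.3e}, {nv:.3e}); "
            "orientations must be non-zero"
        )
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return float(np.degrees(np.arccos(min(c, 1.0))))


@dataclass(frozen=True)
class RelativeContribution:
    """Per-fixel relative contributions of one segment in one voxel.

    ``alphas`` has one entry per *present* fixel of the voxel, each in [0, 1];
    the entries sum to 1 when at least one fixel is present and the vector is
    empty for fixel-free (e.g. CSF) voxels.
    """

    alphas: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        object.__setattr__(self, "alphas", a)
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if a.size:
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValueError(f"contributions outside [0, 1]: {a}")
            s = float(a.sum())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"contributions sum to {s}, not 1")

    @property
    def n_fixels(self) -> int:
        return int(self.alphas.size)


def alpha_vol(fractions: np.ndarray) -> RelativeContribution:
    """Relative volume weighting: contribution proportional to volume fraction.

    ``alpha_k = f_k / sum(f)``, independent of the segment orientation. An
    isotropic compartment (fractions summing below 1) drops out of the
    normalization.
    """
    f = np.atleast_1d(np.asarray(fractions, dtype=float))
    if f.size == 0:
        return RelativeContribution(np.empty(0), "vol")
    if np.any(f <= 0):
        raise ValueError("present fixels must have positive volume fractions")
    return RelativeContribution(f / f.sum(), "vol")


def alpha_cfo(segment_dir: np.ndarray, orientations: np.ndarray) -> RelativeContribution:
    """Closest-fixel-only: the angularly nearest fixel takes the whole weight.

    Ties on the axial angle are broken toward the lowest fixel index, keeping
    the maps deterministic.
    """
    ori = np.atleast_2d(np.asarray(orientations, dtype=float))
    if ori.size == 0:
        return RelativeContribution(np.empty(0), "cfo")
    angles = [axial_angle(segment_dir, o) for o in ori]
    a = np.zeros(len(angles))
    a[int(np.argmin(angles))] = 1.0  # argmin returns the first minimum: lowest index wins ties
    return RelativeContribution(a, "cfo")


def alpha_ang(segment_dir: np.ndarray, orientations: np.ndarray) -> RelativeContribution:
    """Angular weighting: every fixel contributes by angular proximity.

    With ``theta_k`` the axial angle between the segment and fixel ``k`` and
    ``phi = min(90, sum(theta))``::

        alpha_k = (phi - theta_k) / (phi * K - sum(theta))     (K > 1)
        alpha   = 1                                            (K = 1)

    The fixel aligned with the segment gets a contribution near 1; a fixel at
    ``phi`` degrees (at most 90) contributes nothing. When the denominator
    vanishes — all angles equal, including the all-aligned case — the limit is
    the uniform split ``1/K``.
    """
    ori = np.atleast_2d(np.asarray(orientations, dtype=float))
    k = ori.shape[0]
    if ori.size == 0:
        return RelativeContribution(np.empty(0), "ang")
    if k == 1:
        # still validates the inputs
        axial_angle(segment_dir, ori[0])
        return RelativeContribution(np.ones(1), "ang")
    theta = np.array([axial_angle(segment_dir, o) for o in ori])
    phi = min(90.0, float(theta.sum()))
    denom = phi * k - float(theta.sum())
    if denom < 1e-12:
        return RelativeContribution(np.full(k, 1.0 / k), "ang")
    return RelativeContribution((phi - theta) / denom, "ang")


def relative_contribution(
    strategy: str,
    segment_dir: np.ndarray,
    orientations: np.ndarray,
    fractions: np.ndarray,
) -> RelativeContribution:
    """Dispatch to one of the three contribution strategies by name."""
    if strategy == "vol":
        return alpha_vol(fractions)
    if strategy == "cfo":
        return alpha_cfo(segment_dir, orientations)
    if strategy == "ang":
        return alpha_ang(segment_dir, orientations)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def segment_metric(alphas: RelativeContribution, metrics: np.ndarray) -> float:
    """Segment-specific microstructural metric: the contribution-weighted sum.

    Returns NaN for a fixel-free voxel; the value always lies within the range
    of the per-fixel metric values.
    """
    m = np.atleast_1d(np.asarray(metrics, dtype=float))
    if alphas.n_fixels == 0:
        return float("nan")
    if m.size != alphas.n_fixels:
        raise ValueError(f"{m.size} metric values for {alphas.n_fixels} contributions")
    return float(np.dot(alphas.alphas, m))


@dataclass
class FixelField:
    """Per-voxel fixel orientations, volume fractions and scalar metrics.

    Parameters
    ----------
    affine : (4, 4) ndarray
        Voxel-to-world (RAS mm) transform shared by all volumes.
    orientations : (X, Y, Z, K_max, 3) ndarray
        Unit orientation vectors in world coordinates, sign-ambiguous. An
        all-zero vector marks an absent fixel slot.
    fractions : (X, Y, Z, K_max) ndarray
        Per-fixel volume fractions in [0, 1]; per-voxel sums may stay below 1
        when an isotropic compartment occupies the remainder. A fraction <= 0
        marks an absent fixel.
    metrics : mapping of str -> (X, Y, Z, K_max) ndarray
        Named per-fixel scalar metrics, e.g. ``"FA"`` or ``"FVF"``.
    """

    affine: np.ndarray
    orientations: np.ndarray
    fractions: np.ndarray
    metrics: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.metrics = {k: np.asarray(v, dtype=float) for k, v in self.metrics.items()}
        self._validate()

    def _validate(self) -> None:
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if self.orientations.ndim != 5 or self.orientations.shape[-1] != 3:
            raise ValueError(
                f"orientations must have shape (X, Y, Z, K_max, 3), got {self.orientations.shape}"
            )
        if self.fractions.shape != self.orientations.shape[:4]:
            raise ValueError(
                f"fractions shape {self.fractions.shape} does not match "
                f"orientations layout {self.orientations.shape[:4]}"
            )
        for name, m in self.metrics.items():
            if m.shape != self.fractions.shape:
                raise ValueError(
                    f"metric {name!r} shape {m.shape} does not match {self.fractions.shape}"
                )
        if np.any(self.fractions > 1 + 1e-6) or np.any(self.fractions < -1e-6):
            raise ValueError("fractions must lie in [0, 1]")
        present = self.present_mask
        sums = np.where(present, self.fractions, 0.0).sum(axis=-1)
        if np.any(sums > 1 + 1e-6):
            raise ValueError("per-voxel fixel fractions must sum to at most 1")
        norms = np.linalg.norm(self.orientations, axis=-1)
        bad = present & (np.abs(norms - 1.0) > ORIENTATION_NORM_TOL)
        if np.any(bad):
            raise ValueError(f"{int(bad.sum())} present fixel orientations are not unit vectors")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.orientations.shape[:3]

    @property
    def k_max(self) -> int:
        return self.orientations.shape[3]

    @property
    def present_mask(self) -> np.ndarray:
        """(X, Y, Z, K_max) boolean mask of present fixels."""
        norms = np.linalg.norm(self.orientations, axis=-1)
        return (norms >= ABSENT_NORM_EPS) & (self.fractions > 0)

    @property
    def fixel_count(self) -> np.ndarray:
        """Effective fixel count per voxel, in [0, K_max]."""
        return self.present_mask.sum(axis=-1).astype(int)

    def voxel_fixels(self, voxel: Tuple[int, int, int]):
        """Present-fixel data of one voxel.

        Returns
        -------
        slots : (K_v,) int ndarray of slot indices into the K_max axis
        orientations : (K_v, 3) ndarray
        fractions : (K_v,) ndarray
        """
        i, j, k = voxel
        mask = self.present_mask[i, j, k]
        slots = np.flatnonzero(mask)
        return slots, self.orientations[i, j, k, slots], self.fractions[i, j, k, slots]

    def voxel_metric(self, voxel: Tuple[int, int, int], name: str) -> np.ndarray:
        """Metric values of the present fixels of one voxel."""
        if name not in self.metrics:
            raise KeyError(
                f"unknown metric {name!r}; available: {sorted(self.metrics)}"
            )
        i, j, k = voxel
        slots = np.flatnonzero(self.present_mask[i, j, k])
        return self.metrics[name][i, j, k, slots]
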