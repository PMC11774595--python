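"""Complexity indices: the three axes of complexity space.

A system's configurational complexity is scored on three decoupled
axes computed from its scatter of parts in a shared morphospace:

1. **Part number** — a count of parts (rows).  More parts, more complex.
2. **Degree of differentiation** — the sum of variances (SoV) of the
   system's part coordinates over all morphospace axes, a standard
   disparity index; rotation- and translation-invariant.  Reported
   alongside a bootstrapped median (resampling parts with replacement
   to the system's own part count).
3. **(Ir)regularity of differentiation** — the coefficient of
   variation (CV = sample SD / mean) of a distance multiset; 0 means
   perfectly regular spacing.  When the morphospace has enough
   dimensions for all parts to be mutually equidistant
   (``n_axes >= n_parts - 1``) the CV of *all* pairwise distances is
   used; otherwise equidistance is geometrically impossible and the CV
   of pooled first- and second-order nearest-neighbour distances (NNDs)
   is used instead.

All variances and standard deviations use the n-1 (sample) convention.
Undefined values (e.g. CV of an all-coincident system, 0/0) are
reported as NaN, never as 0.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .morphospace import Morphospace

__all__ = [
    "ComplexityProfile",
    "ComplexitySpace",
    "part_count",
    "sum_of_variances",
    "sum_of_ranges",
    "mean_pairwise_distance",
    "bootstrap_sov",
    "pairwise_distance_cv",
    "nnd_cv",
    "regularity_index",
    "complexity_profile",
    "build_complexity_space",
]

METHOD_ALL_PAIRWISE = "all_pairwise"
METHOD_NND_1_2 = "nnd_1_2"


@dataclass(frozen=True)
class ComplexityProfile:
    """One system's coordinates on the three complexity axes."""

    system_id: str
    n_parts: int
    sov: float
    sov_boot_median: float
    regularity_cv: float  # NaN when undefined
    regularity_method: str
    boot_reps: int
    seed: int

    @property
    def regularity_defined(self) -> bool:
        return bool(np.isfinite(self.regularity_cv))


@dataclass(frozen=True)
class ComplexitySpace:
    """One profile per system plus the shared method settings."""

    profiles: tuple[ComplexityProfile, ...]
    boot_reps: int
    seed: int

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, system_id: str) -> ComplexityProfile:
        for p in self.profiles:
            if p.system_id == system_id:
                return p
        raise KeyError(f"unknown system {system_id!r}")


def part_count(space: Morphospace, system_id: str) -> int:
    """Number of parts of one system; coincident points each count."""
    return int(space.system_points(system_id).shape[0])


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need a non-empty (n, k) point array")
    return pts


def sum_of_variances(points: np.ndarray) -> float:
    """Sum over axes of the sample variance of the coordinates.

    Invariant to rotation and translation of the cloud; scaling
    coordinates by c multiplies the result by c**2.  A single point has
    SoV 0 by convention (degenerate).
    """
    pts = _as_points(points)
    if pts.shape[0] < 2:
        return 0.0
    return float(np.var(pts, axis=0, ddof=1).sum())


def sum_of_ranges(points: np.ndarray) -> float:
    """Sum over axes of coordinate ranges (optional variant).

    Unlike SoV this depends on axis orientation and sample size; it is
    provided for comparison only and is not part of the default profile.
    """
    pts = _as_points(points)
    return float((pts.max(axis=0) - pts.min(axis=0)).sum())


def mean_pairwise_distance(points: np.ndarray) -> float:
    """Mean of all pairwise Euclidean distances (optional variant)."""
    pts = _as_points(points)
    if pts.shape[0] < 2:
        return 0.0
    return float(pdist(pts).mean())


def bootstrap_sov(
    points: np.ndarray,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Bootstrapped SoV: median over ``reps`` pseudoreplicates.

    Each pseudoreplicate draws n parts with replacement (n = the
    system's own part count, via ``rng.integers(0, n, size=n)``) and
    computes the SoV of the resample.  Returns the median and the full
    replicate vector.  Bit-reproducible for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pts = _as_points(points)
    n = pts.shape[0]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    values = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        values[r] = sum_of_variances(pts[idx])
    return float(np.median(values)), values


def _cv(distances: np.ndarray) -> float:
    """Sample-SD / mean of a distance multiset; NaN for mean 0."""
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        # a single distance exhibits no variation: defined as 0 (degenerate)
        return 0.0
    m = d.mean()
    if m == 0.0:
        return float("nan")
    return float(d.std(ddof=1) / m)


def pairwise_distance_cv(points: np.ndarray) -> float:
    """CV of all n(n-1)/2 pairwise Euclidean distances.

    0 exactly when all parts are mutually equidistant (regular simplex);
    NaN (undefined) when all points coincide or there is a single point.
    Scale-invariant: a ratio of SD to mean.
    """
    pts = _as_points(points)
    if pts.shape[0] < 2:
        return float("nan")
    return _cv(pdist(pts))


def nnd_cv(points: np.ndarray, orders: tuple[int, ...] = (1, 2)) -> float:
    """CV of pooled k-th order nearest-neighbour distances.

    For each point, its distances to the other points are sorted and the
    requested ranks pooled across points (ties share ranks by sorted
    order; coincident points contribute zero distances, which are
    legitimate).  Default orders (1, 2) follow the regular-lattice
    rationale: on a square lattice the 1st- and 2nd-order NNDs are all
    identical, so the CV is 0 there, while the CV of *all* pairwise
    distances is not.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < max(orders) + 1:
        raise ValueError(
            f"need at least {max(orders) + 1} points for order-{max(orders)} "
            f"neighbours, got {n}"
        )
    dmat = squareform(pdist(pts))
    pooled = []
    for i in range(n):
        others = np.sort(np.delete(dmat[i], i))
        for k in orders:
            pooled.append(others[k - 1])
    return _cv(np.array(pooled))


def regularity_index(points: np.ndarray, n_axes: int | None = None) -> tuple[float, str]:
    """Dispatch between the two regularity CVs.

    If ``n_axes >= n_parts - 1`` all parts *could* be mutually
    equidistant, so regularity is indexed by the CV of all pairwise
    distances; otherwise by the CV of pooled 1st/2nd-order NNDs.
    Returns ``(value, method)``; value is NaN when undefined.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 2:
        return float("nan"), METHOD_ALL_PAIRWISE
    k = pts.shape[1] if n_axes is None else int(n_axes)
    if k >= n - 1:
        return pairwise_distance_cv(pts), METHOD_ALL_PAIRWISE
    return nnd_cv(pts), METHOD_NND_1_2


def _system_rng(master_seed: int, system_id: str) -> np.random.Generator:
    """Per-system RNG stream derived by hashing the system id.

    Hashing makes the stream a function of (seed, system_id) only, so
    adding, removing or reordering other systems cannot change any
    system's bootstrap result.
    """
    digest = hashlib.sha256(str(system_id).encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *words]))


def complexity_profile(
    space: Morphospace,
    system_id: str,
    reps: int = 100,
    seed: int = 0,
    axes: list[int] | None = None,
) -> ComplexityProfile:
    """Assemble one system's full complexity profile.

    ``axes`` optionally restricts the index computation to a subset of
    morphospace axes (e.g. the first two PCs); default is the full
    space.  Indices are computed on the pooled-space coordinates — the
    normalization/ordination that produced them is global, which is what
    makes profiles comparable across systems.
    """
    sub = space if axes is None else space.subset_axes(axes)
    pts = sub.system_points(system_id)
    n = pts.shape[0]
    sov = sum_of_variances(pts)
    boot_median, _ = bootstrap_sov(pts, reps=reps, seed=_system_rng(seed, system_id))
    if n >= 2:
        reg, method = regularity_index(pts, n_axes=sub.n_axes)
    else:
        reg, method = float("nan"), METHOD_ALL_PAIRWISE
    return ComplexityProfile(
        system_id=str(system_id),
        n_parts=n,
        sov=sov,
        sov_boot_median=boot_median,
        regularity_cv=reg,
        regularity_method=method,
        boot_reps=reps,
        seed=int(seed),
    )


def build_complexity_space(
    space: Morphospace,
    reps: int = 100,
    seed: int = 0,
    axes: list[int] | None = None,
) -> ComplexitySpace:
    """One profile per system, ordered by system id."""
    systems = space.system_list
    if not systems:
        raise ValueError("morphospace has no systems")
    profiles = tuple(
        complexity_profile(space, s, reps=reps, seed=seed, axes=axes)
        for s in systems
    )
    return ComplexitySpace(profiles=profiles, boot_reps=reps, seed=int(seed))
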