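"""Synthetic fixtures with known complexity properties.

Two kinds of generator live here:

* **analytic configurations** — regular simplices, square lattices and
  isotropic Gaussian clouds whose index values are known in closed
  form; these are the bedrock the indices are validated against;
* **parameterized systems** — trilobite-like segmented bodies (two
  linear measurements per segment) and ant-colony-like sets of head
  outlines, with explicit differentiation / irregularity / shape
  separation dials for parameter-recovery experiments.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphospace import PartTable
from .outlines import Outline

__all__ = [
    "simplex_points",
    "square_lattice",
    "gaussian_system",
    "synthetic_body",
    "synthetic_colony",
    "CASTE_STRUCTURES",
]


def simplex_points(n: int, edge: float = 1.0) -> np.ndarray:
    """Vertices of a regular (n-1)-simplex with the given edge length.

    n mutually equidistant points in n-1 dimensions: the n standard
    basis vectors of R^n projected onto their (n-1)-dimensional affine
    span and scaled so every pairwise distance equals ``edge``.
    """
    if n < 2:
        raise ValueError("a simplex needs n >= 2 vertices")
    if edge <= 0:
        raise ValueError("edge must be positive")
    basis = np.eye(n)
    centered = basis - basis.mean(axis=0)
    # orthonormal basis of the affine span via SVD
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt[: n - 1].T  # (n, n-1)
    # basis vectors are sqrt(2) apart; rescale to the requested edge
    return coords * (edge / np.sqrt(2.0))


def square_lattice(rows: int, cols: int, spacing: float = 1.0) -> np.ndarray:
    """Points of a regular rows x cols square lattice in 2D."""
    if rows < 2 or cols < 2:
        raise ValueError("lattice needs rows >= 2 and cols >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([c.ravel(), r.ravel()]).astype(float) * spacing


def gaussian_system(
    n: int, n_axes: int, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """i.i.d. isotropic normal cloud; E[SoV] = n_axes * sigma**2."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.normal(0.0, sigma, size=(n, n_axes))


def synthetic_body(
    n_segments: int,
    differentiation: float = 1.0,
    irregularity: float = 0.0,
    seed: int = 0,
    system_id: str = "body",
) -> PartTable:
    """Segmented trilobite-like body: axial and pleural lobe widths.

    Segments sit along a smooth anteroposterior gradient whose total
    span scales with ``differentiation`` (0 = identical segments).
    Segment positions on the gradient are a convex mixture of perfectly
    equal spacing and i.i.d. uniform-random placement, weighted by
    ``irregularity`` in [0, 1]: 0 gives equally spaced segments, 1
    fully random placement.  Both measurements are positive and have
    per-system mean ~1 before normalization, emulating mediolateral
    lobe widths after size correction.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if not 0.0 <= irregularity <= 1.0:
        raise ValueError("irregularity must lie in [0, 1]")
    if differentiation < 0:
        raise ValueError("differentiation must be >= 0")
    rng = np.random.default_rng(seed)
    if n_segments == 1:
        t = np.array([0.5])
    else:
        equal = np.linspace(0.0, 1.0, n_segments)
        random = np.sort(rng.uniform(0.0, 1.0, n_segments))
        t = (1.0 - irregularity) * equal + irregularity * random
    # anteroposterior taper: axial lobes widen, pleural lobes narrow,
    # at different rates so the two variables are not redundant
    span = 0.4 * differentiation
    axial = 1.0 + span * (t - t.mean())
    pleural = 1.0 - 0.6 * span * (t - t.mean())
    axial = np.clip(axial, 0.05, None)
    pleural = np.clip(pleural, 0.05, None)
    df = pd.DataFrame(
        {
            "system_id": system_id,
            "part_id": [f"seg{i + 1}" for i in range(n_segments)],
            "position_rank": np.arange(1, n_segments + 1),
            "axial": axial,
            "pleural": pleural,
        }
    )
    return PartTable(df)


#: polyphenism labels per caste structure (male and queen always present)
CASTE_STRUCTURES: dict[str, tuple[str, ...]] = {
    "monomorphic": ("male", "queen", "worker"),
    "dimorphic": ("male", "queen", "minor", "major"),
    "trimorphic": ("male", "queen", "minor", "major", "supermajor"),
}

#: per-polyphenism (aspect-ratio offset, squareness offset) units,
#: scaled by shape_sep; queens/males deviate most from the worker base
_CASTE_OFFSETS: dict[str, tuple[float, float]] = {
    "male": (-0.30, -0.40),
    "queen": (0.35, 0.50),
    "worker": (0.00, 0.00),
    "minor": (-0.10, 0.10),
    "major": (0.15, 0.30),
    "supermajor": (0.30, 0.60),
}


def _superellipse(a: float, b: float, p: float, n_points: int = 256) -> np.ndarray:
    """Egg-tapered superellipse |x/a|^p + |y/b|^p = 1, sampled CCW.

    A mild radial taper (wider vertex, narrower base) breaks the
    up-down symmetry, as in a real head in frontal view; it also gives
    every outline a unique farthest-from-centroid point, which keeps
    downstream alignment well-posed.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    cos, sin = np.cos(theta), np.sin(theta)
    x = a * np.sign(cos) * np.abs(cos) ** (2.0 / p)
    y = b * np.sign(sin) * np.abs(sin) ** (2.0 / p)
    taper = 1.0 + 0.15 * sin
    return np.column_stack([x * taper, y * taper])


def synthetic_colony(
    caste_structure: str,
    shape_sep: float = 1.0,
    seed: int = 0,
    n_points: int = 256,
) -> list[tuple[Outline, str]]:
    """Superellipse 'head' outlines for one synthetic ant colony.

    Returns one (outline, polyphenism-label) pair per part: 3 for a
    monomorphic species (male, queen, worker), 4 for dimorphic, 5 for
    trimorphic.  Each polyphenism's head differs from the base shape in
    aspect ratio and squareness by caste-specific offsets scaled by
    ``shape_sep``; small seeded jitter (also scaled by ``shape_sep``)
    makes colonies non-identical across seeds.  ``shape_sep = 0`` gives
    identical outlines for every polyphenism.
    """
    if caste_structure not in CASTE_STRUCTURES:
        raise ValueError(
            f"unknown caste structure {caste_structure!r}; "
            f"choose from {sorted(CASTE_STRUCTURES)}"
        )
    if shape_sep < 0:
        raise ValueError("shape_sep must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for label in CASTE_STRUCTURES[caste_structure]:
        d_aspect, d_square = _CASTE_OFFSETS[label]
        jitter = rng.normal(0.0, 0.03, size=2) * shape_sep
        aspect = 1.2 + 0.25 * shape_sep * d_aspect + jitter[0]
        squareness = 2.5 + 1.2 * shape_sep * d_square + jitter[1]
        pts = _superellipse(1.0, max(aspect, 0.2), max(squareness, 0.5), n_points)
        out.append((Outline(pts, source_id=label), label))
    return out
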