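"""Closed 2D outlines: extraction, resampling, Procrustes, EFA.

Pipeline for silhouette data (e.g. ant head masks): trace the boundary
of a binary mask, resample it to evenly spaced vertices, superimpose
all outlines by generalized Procrustes analysis (removing position,
size and orientation), and quantify each aligned shape with elliptic
Fourier analysis (EFA).  The resulting coefficient vectors feed the
morphospace module as ordinary part variables.

Conventions (fixed to avoid mirror-image artefacts):

* mask pixel (row r, col c) maps to Cartesian (x = c + 0.5, y = -(r + 0.5));
* outlines are stored counterclockwise in that Cartesian frame;
* reflections are never permitted during alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .morphospace import PartTable

import pandas as pd

__all__ = [
    "Outline",
    "EFACoefficients",
    "extract_outline",
    "resample_outline",
    "procrustes_align",
    "efa_coefficients",
    "efa_reconstruct",
    "harmonic_power",
    "choose_harmonics",
    "flatten_to_morphospace",
]


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


@dataclass(frozen=True)
class Outline:
    """Ordered closed polygon (implicitly closed, stored CCW)."""

    points: np.ndarray  # (n, 2)
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("outline points must be an (n, 2) array")
        # drop an explicit closing vertex if present
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("outline needs at least 3 distinct points")
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(gaps == 0):
            raise ValueError("outline has identical consecutive points")
        area = _signed_area(pts)
        if area == 0:
            raise ValueError("outline encloses zero area")
        if area < 0:  # enforce counterclockwise
            pts = pts[::-1]
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def area(self) -> float:
        return abs(_signed_area(self.points))


@dataclass(frozen=True)
class EFACoefficients:
    """Elliptic Fourier coefficients: H harmonics of (a, b, c, d)."""

    harmonics: np.ndarray  # (H, 4)
    dc: tuple[float, float]  # (A0, C0)
    source_id: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (H, 4) array with H >= 1")
        if not np.all(np.isfinite(h)) or not np.all(np.isfinite(self.dc)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "harmonics", h)

    @property
    def H(self) -> int:
        return self.harmonics.shape[0]


def extract_outline(mask: np.ndarray, source_id: str = "") -> Outline:
    """Trace the outer boundary of the largest foreground component.

    The mask is binarized at > 0; interior holes are filled before
    tracing, so only the outer boundary is returned.  Pixel (r, c)
    centres map to Cartesian (c + 0.5, -(r + 0.5)).

    Raises
    ------
    ValueError
        Empty mask; largest component smaller than 9 pixels; or two
        components tied for largest (ambiguous).
    """
    fg = np.asarray(mask) > 0
    if not fg.any():
        raise ValueError("mask has no foreground pixels")
    labels, n_comp = ndimage.label(fg)
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_comp + 1))
    order = np.argsort(sizes)[::-1]
    if n_comp > 1 and sizes[order[0]] == sizes[order[1]]:
        raise ValueError(
            f"ambiguous mask: {int((sizes == sizes[order[0]]).sum())} "
            f"components tied for largest ({int(sizes[order[0]])} px)"
        )
    if sizes[order[0]] < 9:
        raise ValueError(
            f"largest component has only {int(sizes[order[0]])} pixels (< 9)"
        )
    comp = ndimage.binary_fill_holes(labels == order[0] + 1)
    # pad so the contour is closed even when the shape touches the border
    padded = np.pad(comp, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    boundary = max(contours, key=len)  # (row, col) in padded frame
    r = boundary[:, 0] - 1.0
    c = boundary[:, 1] - 1.0
    pts = np.column_stack([c + 0.5, -(r + 0.5)])
    return Outline(pts, source_id=source_id)


def resample_outline(o: Outline, n_points: int = 200) -> Outline:
    """Resample to ``n_points`` vertices equally spaced by arc length."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    closed = np.vstack([o.points, o.points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        raise ValueError("degenerate zero-length outline")
    targets = np.arange(n_points) * total / n_points
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return Outline(np.column_stack([x, y]), source_id=o.source_id)


def _canonical_start(points: np.ndarray) -> np.ndarray:
    """Rotate vertex indexing so the start vertex is deterministic.

    Start = vertex of maximal x after centering, ties broken by maximal
    y.  Gives all outlines a comparable vertex correspondence without
    landmarks.
    """
    centered = points - points.mean(axis=0)
    order = np.lexsort((centered[:, 1], centered[:, 0]))
    start = order[-1]
    return np.roll(points, -start, axis=0)


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation (no reflection) of shape onto target."""
    u, _, vt = np.linalg.svd(shape.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


def _rotation_fit(shape: np.ndarray, target: np.ndarray) -> float:
    """Max of trace(R^T shape^T target) over proper rotations R.

    Higher is better; equals the inner-product term of the Procrustes
    residual, so comparing fits compares residuals for unit-size shapes.
    """
    m = shape.T @ target
    s = np.linalg.svd(m, compute_uv=False)
    return float(s[0] + np.sign(np.linalg.det(m)) * s[1])


def _best_cyclic_shift(shape: np.ndarray, target: np.ndarray) -> int:
    """Cyclic vertex shift of ``shape`` best superimposing onto target.

    Outline vertices have no landmarks, so the start-vertex
    correspondence is only heuristic; this exact search over integer
    shifts (with the optimal rotation at each) repairs it.
    """
    n = len(shape)
    fits = [_rotation_fit(np.roll(shape, -k, axis=0), target) for k in range(n)]
    return int(np.argmax(fits))


def procrustes_align(
    outlines: list[Outline],
    n_points: int = 200,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes superimposition of closed outlines.

    Each outline is resampled to ``n_points`` vertices, given a
    deterministic start vertex, translated to centroid 0 and scaled to
    unit centroid size, then rotated to the iteratively re-estimated
    mean shape until the mean changes by less than ``tol``.  Reflections
    are not permitted.  Returns the aligned (n_points, 2) arrays in
    input order, plus the mean shape.

    The final configuration is put in a canonical orientation (the mean
    shape's first vertex on the positive x-axis), so the result does
    not depend on input order.
    """
    if len(outlines) < 2:
        raise ValueError("need at least 2 outlines to align")
    shapes = []
    for o in outlines:
        pts = _canonical_start(resample_outline(o, n_points).points)
        pts = pts - pts.mean(axis=0)
        size = np.linalg.norm(pts)
        if size == 0:
            raise ValueError(f"outline {o.source_id!r} has zero centroid size")
        shapes.append(pts / size)
    # initial vertex correspondence: exact cyclic-shift match onto the
    # first shape, repairing the start-vertex heuristic's phase errors
    shapes = [
        np.roll(s, -_best_cyclic_shift(s, shapes[0]), axis=0) for s in shapes
    ]
    mean = shapes[0].copy()
    converged = False
    it_total = 0
    for _outer in range(5):
        converged = False
        while it_total < max_iter:
            it_total += 1
            aligned = [s @ _optimal_rotation(s, mean) for s in shapes]
            new_mean = np.mean(aligned, axis=0)
            new_mean = new_mean - new_mean.mean(axis=0)
            norm = np.linalg.norm(new_mean)
            if norm == 0:
                raise ValueError("degenerate mean shape during alignment")
            new_mean /= norm
            change = np.linalg.norm(new_mean - mean)
            mean = new_mean
            if change < tol:
                converged = True
                break
        # the start-vertex heuristic can misalign vertex correspondence
        # by a cyclic shift; repair it exactly and re-fit if needed
        shifts = [_best_cyclic_shift(s, mean) for s in shapes]
        if all(k == 0 for k in shifts) or it_total >= max_iter:
            break
        shapes = [np.roll(s, -k, axis=0) for s, k in zip(shapes, shifts)]
    if not converged:
        warnings.warn(
            f"Procrustes alignment did not converge in {it_total} iterations",
            RuntimeWarning,
        )
    aligned = [s @ _optimal_rotation(s, mean) for s in shapes]
    # canonical pose, intrinsic to the mean's point set so the result is
    # independent of input order: the mean's farthest-from-centroid
    # vertex goes on the positive x-axis and becomes vertex 0
    idx = int(np.argmax(np.linalg.norm(mean, axis=1)))
    angle = np.arctan2(mean[idx, 1], mean[idx, 0])
    c, s_ = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, s_], [-s_, c]])
    aligned = [np.roll(a @ rot, -idx, axis=0) for a in aligned]
    mean = np.roll(mean @ rot, -idx, axis=0)
    return aligned, mean


def efa_coefficients(
    o: Outline, H: int, parameterization: str = "arclength"
) -> EFACoefficients:
    """Elliptic Fourier coefficients of a closed polygon.

    The outline is parameterized by arc length (the standard choice)
    and each coordinate expanded in a truncated Fourier series of ``H``
    harmonics; harmonic h contributes the quadruple (a_h, b_h, c_h,
    d_h).  ``parameterization="uniform"`` instead assigns every vertex
    an equal parameter step; the two coincide when vertices are already
    equally spaced by arc length (as after :func:`resample_outline`),
    but uniform makes a curve sampled in its natural angle exactly
    band-limited (an ellipse sampled at equal angles is exactly one
    harmonic).  No size or orientation normalization is applied here —
    Procrustes alignment, when wanted, happens upstream.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    if H > o.n_points // 2 - 1:
        raise ValueError(
            f"H={H} exceeds n_points/2 - 1 = {o.n_points // 2 - 1}; "
            "resample the outline more densely"
        )
    if parameterization not in ("arclength", "uniform"):
        raise ValueError("parameterization must be 'arclength' or 'uniform'")
    closed = np.vstack([o.points, o.points[:1]])
    d = np.diff(closed, axis=0)
    dt = np.linalg.norm(d, axis=1)
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    if parameterization == "uniform":
        dt = np.ones_like(dt)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    harmonics = np.empty((H, 4))
    for h in range(1, H + 1):
        const = T / (2.0 * h**2 * np.pi**2)
        d_cos = np.cos(h * phi[1:]) - np.cos(h * phi[:-1])
        d_sin = np.sin(h * phi[1:]) - np.sin(h * phi[:-1])
        harmonics[h - 1] = const * np.array(
            [
                np.sum(d[:, 0] / dt * d_cos),
                np.sum(d[:, 0] / dt * d_sin),
                np.sum(d[:, 1] / dt * d_cos),
                np.sum(d[:, 1] / dt * d_sin),
            ]
        )
    # DC component: mean position of the arc-length parameterized curve
    xi = np.cumsum(d[:, 0]) - d[:, 0] / dt * t[1:]
    delta = np.cumsum(d[:, 1]) - d[:, 1] / dt * t[1:]
    dt2 = np.diff(t**2)
    a0 = closed[0, 0] + np.sum(d[:, 0] / (2.0 * dt) * dt2 + xi * dt) / T
    c0 = closed[0, 1] + np.sum(d[:, 1] / (2.0 * dt) * dt2 + delta * dt) / T
    return EFACoefficients(harmonics, (float(a0), float(c0)), source_id=o.source_id)


def efa_reconstruct(c: EFACoefficients, n_points: int = 200) -> Outline:
    """Sample the truncated Fourier series back into a closed outline."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    s = np.linspace(0.0, 1.0, n_points, endpoint=False)
    x = np.full(n_points, c.dc[0])
    y = np.full(n_points, c.dc[1])
    for h in range(1, c.H + 1):
        a, b, cc, d = c.harmonics[h - 1]
        x += a * np.cos(2 * np.pi * h * s) + b * np.sin(2 * np.pi * h * s)
        y += cc * np.cos(2 * np.pi * h * s) + d * np.sin(2 * np.pi * h * s)
    pts = np.column_stack([x, y])
    if np.allclose(pts, pts[0]):
        raise ValueError(
            "all harmonic coefficients are zero: reconstruction degenerates "
            f"to the single point {c.dc}"
        )
    return Outline(pts, source_id=c.source_id)


def harmonic_power(c: EFACoefficients) -> np.ndarray:
    """Per-harmonic power (a^2 + b^2 + c^2 + d^2) / 2."""
    return (c.harmonics**2).sum(axis=1) / 2.0


def choose_harmonics(
    outlines: list[Outline], threshold: float = 0.99, max_h: int = 20
) -> int:
    """Smallest H whose cumulative harmonic power reaches ``threshold``.

    Evaluated per outline at ``max_h`` harmonics and the maximum
    required H across the set is returned, so every outline in the
    training set meets the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    needed = 1
    for o in outlines:
        hmax = min(max_h, o.n_points // 2 - 1)
        power = harmonic_power(efa_coefficients(o, hmax))
        cum = np.cumsum(power) / power.sum()
        h = int(np.searchsorted(cum, threshold - 1e-12) + 1)
        needed = max(needed, min(h, hmax))
    return needed


def flatten_to_morphospace(
    coeffs: list[EFACoefficients],
    system_ids: list[str],
    part_ids: list[str] | None = None,
) -> PartTable:
    """Turn EFA coefficient sets into a part table (4H variables).

    Each outline becomes one row with variables a1, b1, c1, d1, ...,
    aH, bH, cH, dH; the DC terms (position) are dropped.  All
    coefficient sets must share the same H.
    """
    if not coeffs:
        raise ValueError("no coefficients given")
    if len(system_ids) != len(coeffs):
        raise ValueError("system_ids must match coefficients one-to-one")
    H = coeffs[0].H
    if any(c.H != H for c in coeffs):
        raise ValueError("mixed harmonic counts; recompute with a shared H")
    if part_ids is None:
        part_ids = [c.source_id or f"part{i}" for i, c in enumerate(coeffs)]
    cols = [f"{letter}{h}" for h in range(1, H + 1) for letter in "abcd"]
    rows = [c.harmonics.reshape(-1) for c in coeffs]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "part_id", [str(p) for p in part_ids])
    df.insert(0, "system_id", [str(s) for s in system_ids])
    return PartTable(df)
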