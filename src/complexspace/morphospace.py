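"""Part-level morphospaces.

A morphospace here is a space in which the *parts* of systems — body
segments, worker castes, serial homologues in general — are the points,
not the systems or species themselves.  Each system then occupies the
space as a scatter of points, and complexity indices summarize each
scatter (see :mod:`complexspace.indices`).

This module holds the two tabular containers (:class:`PartTable`,
:class:`Morphospace`) and the three operations that turn raw per-part
measurements into an embedded point set: per-system mean normalization,
morphospace assembly, and PCA ordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "PartTable",
    "AxisMeta",
    "Morphospace",
    "normalize_by_system_mean",
    "build_morphospace",
    "pca_ordinate",
]

#: Reserved (non-variable) column names in a part table.
RESERVED_COLUMNS = ("system_id", "part_id", "position_rank")


@dataclass(frozen=True)
class PartTable:
    """Long-format table of parts: one row per part, tagged with its system.

    Parameters
    ----------
    data
        DataFrame with columns ``system_id``, ``part_id``, an optional
        ``position_rank``, and one or more numeric measurement columns.
        ``position_rank`` is carried through as metadata only; no index
        consumes it.
    normalized
        Names of variables that have been normalized to per-system
        mean 1 (set by :func:`normalize_by_system_mean`).
    """

    data: pd.DataFrame
    normalized: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("system_id", "part_id"):
            if col not in df.columns:
                raise ValueError(f"part table missing required column {col!r}")
        if len(df) == 0:
            raise ValueError("part table is empty")
        dup = df.duplicated(subset=["system_id", "part_id"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValueError(
                f"duplicate (system_id, part_id) pairs at rows {rows}"
            )
        if not self.variables:
            raise ValueError("part table has no measurement variables")
        for v in self.variables:
            col = pd.to_numeric(df[v], errors="coerce")
            bad = col.index[~np.isfinite(col.to_numpy(dtype=float))].tolist()
            if bad:
                raise ValueError(
                    f"variable {v!r} has non-finite or non-numeric values "
                    f"at rows {bad}"
                )

    @property
    def variables(self) -> list[str]:
        """Names of the numeric measurement columns, in table order."""
        out = []
        for c in self.data.columns:
            if c in RESERVED_COLUMNS:
                continue
            if pd.api.types.is_numeric_dtype(self.data[c]):
                out.append(c)
        return out

    @property
    def systems(self) -> list[str]:
        """Distinct system identifiers, sorted."""
        return sorted(self.data["system_id"].astype(str).unique())

    def n_parts(self, system_id: str) -> int:
        mask = self.data["system_id"].astype(str) == str(system_id)
        n = int(mask.sum())
        if n == 0:
            raise KeyError(f"unknown system {system_id!r}")
        return n


@dataclass(frozen=True)
class AxisMeta:
    """Provenance of one morphospace axis."""

    label: str
    provenance: str  # "raw" | "normalized" | "PC"
    variance_fraction: float | None = None


@dataclass(frozen=True)
class Morphospace:
    """Parts embedded as points in a k-axis space.

    ``points`` is an (n_parts, n_axes) array; ``systems`` and
    ``part_ids`` label each row.  Coincident points are legal and
    retained — superimposed parts still count as distinct parts.
    """

    points: np.ndarray
    systems: np.ndarray  # str per row
    part_ids: np.ndarray  # str per row
    axis_meta: tuple[AxisMeta, ...]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] < 1:
            raise ValueError("points must be a 2-D array with >= 1 axis")
        if not np.all(np.isfinite(pts)):
            raise ValueError("morphospace contains non-finite coordinates")
        if len(self.systems) != len(pts) or len(self.part_ids) != len(pts):
            raise ValueError("row labels do not cover every point")
        if len(self.axis_meta) != pts.shape[1]:
            raise ValueError("axis_meta length does not match n_axes")
        fracs = [m.variance_fraction for m in self.axis_meta]
        if all(m.provenance == "PC" for m in self.axis_meta) and all(
            f is not None for f in fracs
        ):
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError("PC variance fractions must sum to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "systems", np.asarray(self.systems, dtype=str))
        object.__setattr__(self, "part_ids", np.asarray(self.part_ids, dtype=str))

    @property
    def n_parts(self) -> int:
        return self.points.shape[0]

    @property
    def n_axes(self) -> int:
        return self.points.shape[1]

    @property
    def system_list(self) -> list[str]:
        return sorted(set(self.systems.tolist()))

    def system_points(self, system_id: str) -> np.ndarray:
        """Rows belonging to one system, in stored order."""
        mask = self.systems == str(system_id)
        if not mask.any():
            raise KeyError(f"unknown system {system_id!r}")
        return self.points[mask]

    def subset_axes(self, axes: "list[int]") -> "Morphospace":
        """Restrict to a subset of axes (e.g. the first two PCs)."""
        idx = list(axes)
        if not idx:
            raise ValueError("axis subset must be non-empty")
        meta = tuple(self.axis_meta[i] for i in idx)
        return Morphospace(self.points[:, idx], self.systems, self.part_ids, meta)


def normalize_by_system_mean(
    table: PartTable, variables: list[str] | None = None
) -> PartTable:
    """Divide each value by the per-system mean of that variable.

    Removes overall size differences between systems: after this, the
    mean of every (system, variable) group is exactly 1, so a system
    measured in millimetres and an identical one measured in inches
    normalize to the same table.  Idempotent.

    Raises
    ------
    ValueError
        If any (system, variable) group has a zero or non-finite mean,
        naming the offending system and variable.
    """
    variables = list(variables) if variables is not None else table.variables
    unknown = [v for v in variables if v not in table.variables]
    if unknown:
        raise KeyError(f"unknown variables {unknown}")
    df = table.data.copy()
    for v in variables:
        means = df.groupby("system_id", sort=False)[v].transform("mean")
        bad = df.loc[(means == 0) | ~np.isfinite(means), "system_id"].unique()
        if len(bad):
            raise ValueError(
                f"zero or non-finite group mean for variable {v!r} "
                f"in system(s) {sorted(map(str, bad))}"
            )
        df[v] = df[v] / means
    return PartTable(df, normalized=table.normalized | frozenset(variables))


def build_morphospace(table: PartTable, variables: list[str] | None = None) -> Morphospace:
    """Assemble a morphospace: one point per part, one axis per variable.

    Axis order follows the requested variable order; provenance is
    "normalized" for variables that went through
    :func:`normalize_by_system_mean`, else "raw".
    """
    variables = list(variables) if variables is not None else table.variables
    unknown = [v for v in variables if v not in table.variables]
    if unknown:
        raise KeyError(f"unknown variables {unknown}")
    if not variables:
        raise ValueError("no variables requested")
    pts = table.data[variables].to_numpy(dtype=float)
    meta = tuple(
        AxisMeta(v, "normalized" if v in table.normalized else "raw")
        for v in variables
    )
    return Morphospace(
        pts,
        table.data["system_id"].astype(str).to_numpy(),
        table.data["part_id"].astype(str).to_numpy(),
        meta,
    )


def pca_ordinate(
    space: Morphospace, center: bool = True, scale: bool = False
) -> Morphospace:
    """Rotate the pooled point cloud onto principal component axes.

    PCA is computed on all parts of all systems together — the shared
    space is what makes per-system indices comparable.  Centering is on
    by default; unit-scaling of input axes is off by default because
    normalized measurements and Fourier coefficients are already
    commensurate.

    The transform is an isometry of the (centered, optionally scaled)
    input: pairwise distances and total variance are preserved.
    """
    if space.n_parts < 2:
        raise ValueError("PCA needs at least 2 parts")
    X = space.points.astype(float)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [space.axis_meta[i].label for i in np.nonzero(sd == 0)[0]]
            raise ValueError(f"cannot unit-scale zero-variance axes {zero}")
        X = X / sd
    if not center:
        # PCA always centers internally; emulate "no centering" by adding
        # the mean back after projection onto the same components.
        pass
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    # Guard: with fewer samples than axes the trailing ratio mass is
    # still assigned to the kept components, so the sum is 1.
    ratios = ratios / ratios.sum()
    meta = tuple(
        AxisMeta(f"PC{i + 1}", "PC", float(ratios[i])) for i in range(n_comp)
    )
    if not center:
        scores = scores + pca.mean_ @ pca.components_.T
    return Morphospace(scores, space.systems, space.part_ids, meta)
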