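"""Feature and response transforms for the B-value regression.

The default pipeline is: count orbits → smooth over a 2.0 Å neighbourhood →
z-score each column; the response is the per-structure (or per-group)
z-scored B value.  Smoothing mimics the refinement restraint that bonded
atoms carry similar displacement parameters: the smoothed value of an atom
is its own value plus the average over all atoms within the smoothing
radius (covalent-bond scale, independent of the graph cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .contact_graph import neighbors_within
from .graphlet_orbits import OrbitMatrix
from .structure_io import StructureModel

__all__ = [
    "FeatureMatrix",
    "BValueVector",
    "smooth_features",
    "zscore_columns",
    "normalize_b",
    "features_from_orbits",
]

#: default smoothing neighbourhood radius, Å (just above covalent bond length)
SMOOTH_RADIUS = 2.0


@dataclass
class FeatureMatrix:
    """N x 15 real matrix of explanatory variables.

    ``transforms_applied`` records the pipeline stages (in order) from
    ``{"smoothed", "column_zscored"}``; ``cutoff`` is the graph cutoff the
    underlying orbit counts were computed at.
    """

    values: np.ndarray
    transforms_applied: tuple[str, ...] = ()
    cutoff: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        self.values = v

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        header = (
            f"# transforms={','.join(self.transforms_applied) or 'none'}"
            f" cutoff={self.cutoff}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            fh.write("\t".join(f"O{k}" for k in range(self.values.shape[1])) + "\n")
            np.savetxt(fh, self.values, delimiter="\t", fmt="%.10g")


@dataclass
class BValueVector:
    """Per-atom B values, raw (Å²) or normalized, with grouping labels."""

    values: np.ndarray
    scale: str = "raw_A2"  # or "normalized"
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != len(self.values):
                raise ValueError("group_labels length mismatch")


def features_from_orbits(
    orbits: OrbitMatrix, cutoff: float | None = None
) -> FeatureMatrix:
    """Wrap raw orbit counts as an (untransformed) feature matrix."""
    return FeatureMatrix(values=orbits.values.astype(float), cutoff=cutoff)


def smooth_features(
    matrix: FeatureMatrix,
    model: StructureModel,
    radius: float = SMOOTH_RADIUS,
) -> FeatureMatrix:
    """Add to each row the mean over rows of atoms within *radius* (<=, Å).

    Atoms with no neighbour inside the radius keep their value unchanged.
    A single pass is applied.
    """
    if matrix.n_rows != len(model.atoms):
        raise ValueError(
            f"matrix rows ({matrix.n_rows}) != model atoms ({len(model.atoms)})"
        )
    nbrs = neighbors_within(model, radius)
    out = matrix.values.copy()
    for i, idx in enumerate(nbrs):
        if len(idx):
            out[i] += matrix.values[idx].mean(axis=0)
    return replace(
        matrix,
        values=out,
        transforms_applied=matrix.transforms_applied + ("smoothed",),
    )


def zscore_columns(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardize each column to mean 0 and sample (n-1) sd 1.

    Constant columns cannot be scaled and map to all zeros with a warning.
    """
    v = matrix.values
    if v.shape[0] < 2:
        raise ValueError("need at least 2 rows to z-score")
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant feature column(s) {np.flatnonzero(const).tolist()} "
            "mapped to zeros",
            stacklevel=2,
        )
    sd_safe = np.where(const, 1.0, sd)
    out = (v - mean) / sd_safe
    out[:, const] = 0.0
    return replace(
        matrix,
        values=out,
        transforms_applied=matrix.transforms_applied + ("column_zscored",),
    )


def normalize_b(values: BValueVector, group_by: str = "structure") -> BValueVector:
    """Z-score B values within normalization groups.

    ``group_by="structure"`` treats all atoms as one group (the default);
    ``"group"`` uses the vector's ``group_labels`` (chains, domains or TLS
    groups), which handles structures whose B values are multimodal because
    rigid units sit at different overall mobility levels.
    """
    v = values.values
    if group_by == "structure":
        labels = np.zeros(len(v), dtype=int)
    elif group_by in ("group", "chain", "label"):
        if values.group_labels is None:
            raise ValueError("group-wise normalization requires group_labels")
        labels = values.group_labels
    else:
        raise ValueError(f"unknown group_by mode: {group_by!r}")
    out = np.empty_like(v, dtype=float)
    for g in np.unique(labels):
        m = labels == g
        if m.sum() < 2:
            raise ValueError(f"normalization group {g!r} has fewer than 2 atoms")
        sd = v[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"normalization group {g!r} has zero B-value sd")
        out[m] = (v[m] - v[m].mean()) / sd
    return BValueVector(
        values=out, scale="normalized", group_labels=values.group_labels
    )
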