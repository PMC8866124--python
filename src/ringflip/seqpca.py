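"""Proteome-wide SH3 design procedure: size scores, PCA, two groups.

SH3 family sequences aligned to the JIP1-SH3 reference are filtered to
those carrying a phenyl-based residue (Tyr/Phe) at the position of
Y526, side chains at the positions of residues 493, 517 and 541 are
scored by their heavy-atom count, and a PCA of the resulting
domains-by-3 score matrix separates eclipsed-ring (group 1, containing
JIP1) from staggered-ring (group 2) domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DataError

__all__ = [
    "SIZE_SCORES",
    "AlignedFamily",
    "PcaResult",
    "size_score",
    "filter_by_anchor",
    "build_score_matrix",
    "run_pca",
    "assign_groups",
]

#: Heavy-atom count of each amino-acid side chain (one-letter code).
SIZE_SCORES: dict[str, int] = {
    "A": 1, "C": 2, "D": 4, "E": 5, "F": 7, "G": 0, "H": 6, "I": 4,
    "K": 5, "L": 4, "M": 4, "N": 4, "P": 3, "Q": 5, "R": 7, "S": 2,
    "T": 3, "V": 3, "Y": 8, "W": 10,
}

#: JIP1-SH3 reference positions tracked by the analysis.
REFERENCE_POSITIONS = (493, 517, 520, 526, 541)
ANCHOR_POSITION = 526
SCORED_POSITIONS = (493, 517, 541)


def size_score(residue: str) -> int:
    """Heavy-atom size score of a canonical one-letter residue code."""
    code = str(residue).upper()
    try:
        return SIZE_SCORES[code]
    except KeyError:
        raise DataError(
            f"non-canonical residue code {residue!r}; no size score defined"
        ) from None


@dataclass
class AlignedFamily:
    """Named, gapped aligned sequences with a reference column map.

    ``column_map`` maps JIP1-SH3 reference positions (e.g. 526) to
    0-based alignment column indices.
    """

    names: list[str]
    sequences: list[str]
    column_map: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise DataError("names and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise DataError("aligned sequences must share the gapped length")
        self.sequences = [s.upper() for s in self.sequences]
        if self.sequences:  # an empty (filtered-out) family keeps its map
            width = lengths.pop()
            for pos, col in self.column_map.items():
                if not 0 <= col < width:
                    raise DataError(
                        f"column {col} for reference position {pos} out of range"
                    )

    def __len__(self) -> int:
        return len(self.sequences)

    def column(self, position: int) -> list[str]:
        """Residues at the column mapped to a reference position."""
        try:
            col = self.column_map[position]
        except KeyError:
            raise DataError(f"reference position {position} is not mapped") from None
        return [s[col] for s in self.sequences]

    @classmethod
    def from_reference(
        cls,
        names: Sequence[str],
        sequences: Sequence[str],
        reference_name: str,
        reference_start: int,
        positions: Sequence[int] = REFERENCE_POSITIONS,
    ) -> "AlignedFamily":
        """Derive the column map from a reference sequence in the alignment.

        ``reference_start`` is the residue number of the reference's
        first non-gap character.
        """
        names = list(names)
        sequences = [s.upper() for s in sequences]
        try:
            ref = sequences[names.index(reference_name)]
        except ValueError:
            raise DataError(f"reference {reference_name!r} not in alignment") from None
        colmap: dict[int, int] = {}
        res = reference_start - 1
        for col, ch in enumerate(ref):
            if ch != "-":
                res += 1
                if res in positions:
                    colmap[res] = col
        missing = set(positions) - set(colmap)
        if missing:
            raise DataError(f"reference does not cover positions {sorted(missing)}")
        return cls(names, sequences, colmap)


def filter_by_anchor(
    family: AlignedFamily,
    anchor: int = ANCHOR_POSITION,
    allowed: frozenset[str] = frozenset({"Y", "F"}),
) -> AlignedFamily:
    """Retain sequences carrying an allowed residue at the anchor column."""
    residues = family.column(anchor)
    keep = [i for i, r in enumerate(residues) if r in allowed]
    return AlignedFamily(
        [family.names[i] for i in keep],
        [family.sequences[i] for i in keep],
        dict(family.column_map),
    )


def build_score_matrix(
    family: AlignedFamily,
    positions: Sequence[int] = SCORED_POSITIONS,
) -> pd.DataFrame:
    """Domains-by-positions integer size-score matrix.

    Sequences with a gap at a scored column are excluded (flagged with a
    logged reason in the returned frame's ``attrs['excluded']``).
    """
    cols = {p: family.column(p) for p in positions}
    rows, index, excluded = [], [], {}
    for i, name in enumerate(family.names):
        residues = [cols[p][i] for p in positions]
        if any(r == "-" for r in residues):
            excluded[name] = "gap at scored column"
            continue
        try:
            rows.append([size_score(r) for r in residues])
        except DataError:
            excluded[name] = "non-canonical residue at scored column"
            continue
        index.append(name)
    matrix = pd.DataFrame(rows, index=index, columns=[str(p) for p in positions],
                          dtype=int)
    matrix.attrs["excluded"] = excluded
    return matrix


@dataclass
class PcaResult:
    """Component scores, loadings, explained variance and group labels."""

    scores: pd.DataFrame  # domains x components
    loadings: np.ndarray  # components x features (orthonormal rows)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str]
    degenerate: bool = False
    groups: pd.Series | None = None

    def reconstruct(self) -> np.ndarray:
        """Invert scaling and projection (all components kept)."""
        return (self.scores.to_numpy() @ self.loadings) * self.scale + self.mean


def run_pca(matrix: pd.DataFrame, scale: bool = True) -> PcaResult:
    """Centered (optionally unit-variance) PCA of the score matrix.

    Deterministic up to component sign, fixed by making the
    largest-|loading| entry of each component positive.  Columns with
    zero variance after scaling are dropped with a warning attribute;
    identical rows give a named degenerate result.
    """
    if matrix.shape[0] < 3:
        raise DataError("need at least 3 domains for a PCA")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    std = x.std(axis=0, ddof=1)
    keep = std > 0
    if not np.any(keep):
        # identical rows: no variance beyond the mean
        return PcaResult(
            scores=pd.DataFrame(np.zeros((len(matrix), 0)), index=matrix.index),
            loadings=np.zeros((0, x.shape[1])),
            explained_variance_ratio=np.zeros(0),
            mean=mean, scale=np.ones(x.shape[1]),
            feature_names=list(matrix.columns), degenerate=True,
        )
    scale_vec = np.where(keep, std, 1.0) if scale else np.ones(x.shape[1])
    xs = xc / scale_vec
    xs = xs[:, keep] if not np.all(keep) else xs
    n_comp = min(xs.shape)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    # sign convention: largest-|loading| entry positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u * s
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    loadings_full = np.zeros((n_comp, x.shape[1]))
    loadings_full[:, keep] = vt
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        ),
        loadings=loadings_full,
        explained_variance_ratio=evr,
        mean=mean,
        scale=scale_vec,
        feature_names=list(matrix.columns),
        degenerate=bool(np.all(~keep)),
    )


def assign_groups(
    pca: PcaResult,
    k: int = 2,
    reference: str | None = None,
    seed: int = 0,
    n_restarts: int = 20,
) -> pd.Series:
    """k-means partition of the first two component scores.

    Group indices are 1-based and ordered so that group 1 contains the
    reference row (when present); without a reference, group 1 is the
    cluster containing the first row.
    """
    n = len(pca.scores)
    if n == 1:
        # a lone domain is its own (reference) group
        return pd.Series([1], index=pca.scores.index, name="group")
    if k > n:
        raise DataError(f"cannot form {k} groups from {n} rows")
    x = pca.scores.to_numpy()[:, : min(2, pca.scores.shape[1])]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)
    index = list(pca.scores.index)
    if reference is not None and reference in index:
        ref_cluster = raw[index.index(reference)]
    else:
        ref_cluster = raw[0]
    order = [ref_cluster] + [c for c in range(k) if c != ref_cluster]
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=pca.scores.index,
                       name="group")
    pca.groups = labels
    return labels
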