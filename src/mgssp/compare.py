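"""Quantitative comparison of substitution profiles.

Profiles are compared position by position with the Jensen-Shannon
divergence (in bits) between their substitution-bias vectors, averaged
with each position weighted by the mean substitution frequency of the two
profiles there. The resulting distance matrix is embedded with classical
(Torgerson) multidimensional scaling for visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mgssp.profile import GSSP, RarityTable

logger = logging.getLogger(__name__)


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log2(0) = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("not a probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits: symmetric, bounded by [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    j = shannon_entropy((p + q) / 2.0) - (shannon_entropy(p) + shannon_entropy(q)) / 2.0
    return float(min(max(j, 0.0), 1.0))


def _qualifying_positions(a: GSSP, b: GSSP) -> list[int]:
    """Shared homologous positions where both profiles observed substitutions.

    Positions where one profile has no substitutions have no bias vector on
    that side and are excluded from both numerator and denominator.
    """
    bya, byb = a.by_position, b.by_position
    return sorted(
        pos
        for pos in set(bya) & set(byb)
        if bya[pos].n_mutated > 0 and byb[pos].n_mutated > 0
    )


def weighted_profile_distance(a: GSSP, b: GSSP) -> float:
    """Weighted average Jensen-Shannon divergence between two profiles.

    <J> = sum_i w_i J(f_A,i, f_B,i) / sum_i w_i with w_i = (m_A,i + m_B,i)/2
    over qualifying shared positions. Cross-gene comparison requires IMGT
    numbering on both sides (homologous positions share labels).
    """
    if a.gene != b.gene and not (
        a.numbering_dialect == b.numbering_dialect == "imgt"
    ):
        raise ValueError(
            "cross-gene comparison requires IMGT numbering on both profiles"
        )
    positions = _qualifying_positions(a, b)
    if not positions:
        raise ValueError(f"no qualifying shared positions between {a.gene} and {b.gene}")
    bya, byb = a.by_position, b.by_position
    num = 0.0
    den = 0.0
    for pos in positions:
        pa, pb = bya[pos], byb[pos]
        w = (pa.m + pb.m) / 2.0
        num += w * js_divergence(pa.f, pb.f)
        den += w
    if den == 0.0:
        raise ValueError("all qualifying positions carry zero weight")
    return num / den


@dataclass
class ProfileDistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    profiles: list[GSSP], labels: list[str] | None = None
) -> ProfileDistanceMatrix:
    """All pairwise weighted profile divergences (symmetric, zero diagonal)."""
    n = len(profiles)
    if labels is None:
        labels = []
        for i, g in enumerate(profiles):
            labels.append(f"{g.gene}#{i}")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = weighted_profile_distance(profiles[i], profiles[j])
            values[i, j] = values[j, i] = d
    return ProfileDistanceMatrix(labels=list(labels), values=values)


@dataclass
class MdsEmbedding:
    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def to_frame(self):
        import pandas as pd

        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def classical_mds(matrix: ProfileDistanceMatrix, dims: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers -1/2 D^2, eigendecomposes, and returns the top ``dims``
    coordinates scaled by the square root of the eigenvalues. Negative
    eigenvalues (non-Euclidean distances) are truncated to zero with a
    logged warning. Orientation is fixed by making the largest-magnitude
    coordinate on each axis positive.
    """
    d = np.asarray(matrix.values, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ (d**2) @ centering
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.any(eigval[:dims] < -1e-9):
        logger.warning("negative eigenvalues truncated to 0 (non-Euclidean distances)")
    lam = np.clip(eigval[:dims], 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(lam)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if np.any(col != 0) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return MdsEmbedding(labels=list(matrix.labels), coordinates=coords, eigenvalues=eigval)


def rarity_correlation(a: RarityTable, b: RarityTable) -> float:
    """Pearson correlation of rarity over shared defined substitutions."""
    keys = a.shared_keys(b)
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} shared defined entries; need >= 3")
    xa = a.values_for(keys)
    xb = b.values_for(keys)
    if np.std(xa) == 0.0 and np.std(xb) == 0.0:
        return 1.0 if np.allclose(xa, xb) else 0.0
    if np.std(xa) == 0.0 or np.std(xb) == 0.0:
        return 0.0
    return float(stats.pearsonr(xa, xb).statistic)
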