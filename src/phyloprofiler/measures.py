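"""Co-occurrence measures on binary phylogenetic profiles.

Four classic pairwise measures quantify how similarly two proteins are
distributed across organisms: Jaccard similarity on joint presences, Pearson
correlation of the 0/1 vectors, mutual information of the joint symbol
distribution (in bits), and the Lp-norm distance (p=1 Hamming, p=2 Euclidean).
Similarities rise and distances fall when two proteins co-occur.

Pearson is undefined when either vector is constant; that case is flagged with
NaN, which every downstream consumer treats as "not positively correlated".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import BinaryProfile

__all__ = [
    "MeasureMatrix",
    "jaccard",
    "pearson",
    "mutual_information",
    "lp_norm",
    "pairwise_matrix",
]

MEASURES = ("jaccard", "pearson", "mi", "lp")


@dataclass
class MeasureMatrix:
    """Symmetric all-against-all score matrix for one measure.

    ``orientation`` records whether larger values mean stronger linkage
    ("similarity") or weaker ("distance"); evaluation code negates distances
    before ranking so a single convention applies everywhere.
    """

    proteins: tuple[str, ...]
    values: np.ndarray
    measure_name: str
    orientation: str  # "similarity" | "distance"

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.proteins)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match protein list")
        if self.orientation not in ("similarity", "distance"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        finite = np.isfinite(self.values)
        sym = np.where(finite & finite.T,
                       np.abs(self.values - self.values.T), 0.0)
        if sym.size and sym.max() > 1e-12:
            raise ValueError("matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        i = self.proteins.index(a)
        j = self.proteins.index(b)
        return float(self.values[i, j])

    def pair_scores(self) -> dict[frozenset, float]:
        """All unordered off-diagonal pairs as ``{frozenset({a, b}): score}``."""
        out = {}
        for i, a in enumerate(self.proteins):
            for j in range(i + 1, len(self.proteins)):
                out[frozenset((a, self.proteins[j]))] = float(self.values[i, j])
        return out


def _check_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("vectors must have length >= 1")
    return x, y


def jaccard(x, y) -> float:
    """Jaccard similarity |x AND y| / |x OR y|, in [0, 1].

    Two all-zero vectors share no evidence of co-evolution, so the 0/0 case
    is defined as 0.
    """
    x, y = _check_pair(x, y)
    union = np.count_nonzero((x == 1) | (y == 1))
    if union == 0:
        return 0.0
    inter = np.count_nonzero((x == 1) & (y == 1))
    return inter / union


def pearson(x, y, on_constant: str = "nan") -> float:
    """Sample Pearson correlation of two equal-length vectors.

    Uses the (n-1) denominator with sample standard deviations.  When either
    vector is constant the correlation is undefined: returns NaN by default,
    or raises if ``on_constant="raise"``.
    """
    x, y = _check_pair(x, y)
    if x.size < 2:
        raise ValueError("pearson requires length >= 2")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        if on_constant == "raise":
            raise ValueError("correlation undefined for a constant vector")
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (x.size - 1)
    return float(cov / (sx * sy))


def mutual_information(x, y) -> float:
    """Mutual information of the empirical joint symbol distribution, in bits.

    Probabilities are symbol frequencies over positions; empty cells follow
    the convention 0*log(.) = 0.  I(x, x) equals the empirical entropy of x.
    """
    x, y = _check_pair(x, y)
    n = x.size
    mi = 0.0
    for xs in (0, 1):
        px = np.count_nonzero(x == xs) / n
        if px == 0:
            continue
        for ys in (0, 1):
            py = np.count_nonzero(y == ys) / n
            pxy = np.count_nonzero((x == xs) & (y == ys)) / n
            if pxy > 0:
                mi += pxy * np.log2(pxy / (px * py))
    return max(mi, 0.0)


def lp_norm(x, y, p: float = 1.0) -> float:
    """Lp-norm distance (sum |x_i - y_i|^p)^(1/p); p=1 is Hamming, p=2 Euclidean."""
    if p < 1:
        raise ValueError("p must be >= 1")
    x, y = _check_pair(x, y)
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


# ---------------------------------------------------------------------------
# Pairwise matrices
#
# All four measures on 0/1 vectors reduce to the four joint counts
# (n11, n10, n01, n00), so each block of rows needs one matrix product
# against the full profile; memory stays bounded by block_size * m.

def _joint_counts(block: np.ndarray, full: np.ndarray):
    n11 = block @ full.T
    rs_b = block.sum(axis=1)[:, None]
    rs_f = full.sum(axis=1)[None, :]
    n10 = rs_b - n11
    n01 = rs_f - n11
    n00 = full.shape[1] - n11 - n10 - n01
    return n11.astype(float), n10.astype(float), n01.astype(float), n00.astype(float)


def _block_jaccard(block, full):
    n11, n10, n01, _ = _joint_counts(block, full)
    union = n11 + n10 + n01
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, n11 / np.maximum(union, 1), 0.0)
    return out


def _block_pearson(block, full):
    m = full.shape[1]
    n11, n10, n01, n00 = _joint_counts(block, full)
    sx = n11 + n10  # presences in block rows
    sy = n11 + n01
    # covariance numerator: m*n11 - sx*sy, scaled consistently with sample SDs
    num = m * n11 - sx * sy
    varx = sx * (m - sx)
    vary = sy * (m - sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / np.sqrt(varx * vary)
    out[(varx == 0) | (vary == 0)] = np.nan
    return out


def _block_mi(block, full):
    m = full.shape[1]
    counts = _joint_counts(block, full)
    sx = counts[0] + counts[1]
    sy = counts[0] + counts[2]
    margx = (sx, sx, m - sx, m - sx)  # matches (n11, n10, n01, n00) order below
    margy = (sy, m - sy, sy, m - sy)
    mi = np.zeros_like(counts[0])
    for nxy, mx, my in zip((counts[0], counts[1], counts[2], counts[3]),
                           margx, margy):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = (nxy / m) * np.log2(np.where(nxy > 0, nxy * m, 1.0)
                                       / np.where(nxy > 0, mx * my, 1.0))
        mi += np.where(nxy > 0, term, 0.0)
    return np.maximum(mi, 0.0)


def _block_lp(block, full, p):
    n11, n10, n01, _ = _joint_counts(block, full)
    mismatches = n10 + n01  # |x-y|^p == |x-y| on 0/1 entries
    return mismatches ** (1.0 / p)


def pairwise_matrix(profile: BinaryProfile, measure: str,
                    p: float = 1.0, block_size: int = 512) -> MeasureMatrix:
    """All-against-all measure matrix over a binary profile, computed in
    row blocks so peak memory scales with ``block_size * n`` rather than n^2
    intermediates per measure term.

    Parameters
    ----------
    measure : {"jaccard", "pearson", "mi", "lp"}
    p : float
        Order of the Lp-norm; only used for ``measure="lp"``.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if len(profile.proteins) < 2:
        raise ValueError("pairwise matrix needs >= 2 proteins")
    if measure == "lp" and p < 1:
        raise ValueError("p must be >= 1")
    full = np.asarray(profile.values, dtype=np.int64)
    n = full.shape[0]
    out = np.empty((n, n), dtype=float)
    for start in range(0, n, block_size):
        block = full[start:start + block_size]
        if measure == "jaccard":
            vals = _block_jaccard(block, full)
        elif measure == "pearson":
            vals = _block_pearson(block, full)
        elif measure == "mi":
            vals = _block_mi(block, full)
        else:
            vals = _block_lp(block, full, p)
        out[start:start + block.shape[0]] = vals
    name = f"lp({p:g})" if measure == "lp" else measure
    orientation = "distance" if measure == "lp" else "similarity"
    return MeasureMatrix(profile.proteins, out, name, orientation)
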