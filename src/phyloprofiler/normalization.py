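"""Bit-score profile normalizations and their paired scorers.

Two normalizations turn raw best-hit bit scores into profiles whose pairwise
comparison is less dominated by overall conservation level:

* **NPP** (normalized phylogenetic profile): floor weak scores to 1, drop
  poorly conserved proteins, take the per-protein log2 ratio to the row
  maximum, then z-score each species column.  Scored by Pearson correlation.
* **SVD**: floor weak scores to 0, scale rows by their maximum, factor the
  matrix by singular value decomposition, retain the leading singular
  dimensions of the left factor, drop poorly conserved proteins, and scale
  each retained row to unit Euclidean norm.  Scored by Euclidean distance,
  which on unit-norm rows lies in [0, 2].
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .measures import MeasureMatrix
from .profiles import BitScoreProfile

__all__ = ["NormalizedProfile", "npp_transform", "svd_transform",
           "npp_score", "svd_score"]


@dataclass
class NormalizedProfile:
    """Real-valued profile after NPP or SVD normalization.

    ``dimensions`` are species identifiers for NPP (columns are preserved) and
    singular-dimension indices ("sv0", "sv1", ...) for SVD.  Proteins removed
    by the conservation filter (or as all-zero rows under SVD) are listed in
    ``dropped_proteins`` with a reason.
    """

    proteins: tuple[str, ...]
    dimensions: tuple[str, ...]
    values: np.ndarray
    method: str  # "npp" | "svd"
    dropped_proteins: list[tuple[str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        self.dimensions = tuple(self.dimensions)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.proteins), len(self.dimensions)):
            raise ValueError("matrix shape does not match identifier lists")
        if self.method not in ("npp", "svd"):
            raise ValueError(f"unknown method {self.method!r}")
        dropped = {p for p, _ in self.dropped_proteins}
        if dropped & set(self.proteins):
            raise ValueError("dropped proteins must not appear in rows")

    def write(self, path, sidecar=None) -> None:
        """Write the matrix as TSV; parameters and drops to a sidecar JSON."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein_id\t" + "\t".join(self.dimensions) + "\n")
            for name, row in zip(self.proteins, self.values):
                fh.write(name + "\t"
                         + "\t".join(format(v, ".10g") for v in row) + "\n")
        if sidecar is not None:
            with open(sidecar, "w", encoding="utf-8") as fh:
                json.dump({"method": self.method, "params": self.params,
                           "dropped_proteins": self.dropped_proteins}, fh,
                          indent=2)


def _conservation_mask(raw: np.ndarray, floor: float, min_homologs: int):
    """Rows to keep: count of species with raw bit score >= floor is enough.

    Counting is on raw scores, before any floor replacement, so the sentinel
    values introduced by flooring can never masquerade as homologs.
    """
    counts = (raw >= floor).sum(axis=1)
    return counts >= min_homologs


def npp_transform(bits: BitScoreProfile, score_floor: float = 70.0,
                  min_homologs: int = 12) -> NormalizedProfile:
    """NPP normalization of a bit-score profile.

    Steps: (1) every entry strictly below ``score_floor`` becomes 1;
    (2) proteins with fewer than ``min_homologs`` species at or above the
    floor are dropped as poorly conserved; (3) each entry becomes
    log2(p_ij / p_max_i) against its row maximum; (4) each species column is
    z-scored with the sample standard deviation.  Columns with zero spread
    are set to 0 and flagged with a warning.
    """
    raw = np.asarray(bits.values, dtype=float)
    n, m = raw.shape
    if n < 2 or m < 2:
        raise ValueError("NPP needs at least 2 proteins and 2 species")
    keep = _conservation_mask(raw, score_floor, min_homologs)
    dropped = [(p, "poor conservation")
               for p, k in zip(bits.proteins, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"all proteins dropped by the conservation filter "
            f"(score_floor={score_floor}, min_homologs={min_homologs})"
        )
    floored = np.where(raw < score_floor, 1.0, raw)[keep]
    row_max = floored.max(axis=1, keepdims=True)
    logratio = np.log2(floored / row_max)
    mu = logratio.mean(axis=0)
    sd = logratio.std(axis=0, ddof=1)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} column(s) have zero spread; set to 0",
            stacklevel=2,
        )
    z = np.where(zero_sd, 0.0, (logratio - mu) / np.where(zero_sd, 1.0, sd))
    return NormalizedProfile(
        proteins=tuple(p for p, k in zip(bits.proteins, keep) if k),
        dimensions=bits.species,
        values=z,
        method="npp",
        dropped_proteins=dropped,
        params={"score_floor": score_floor, "min_homologs": min_homologs,
                "zero_sd_columns": [s for s, f in zip(bits.species, zero_sd) if f]},
    )


def svd_transform(bits: BitScoreProfile, score_floor: float = 60.0,
                  trim_fraction: float = 0.3,
                  min_homologs: int = 12) -> NormalizedProfile:
    """SVD normalization of a bit-score profile.

    Steps: (1) entries strictly below ``score_floor`` become 0; (2) rows are
    scaled by their maximum (all-zero rows are dropped); (3) the matrix is
    factored P = U S V'; (4) the first ceil(trim_fraction * m) columns of U
    are retained; (5) poorly conserved proteins are dropped by the same
    counting rule as NPP, against this floor; (6) every retained row is
    scaled to unit Euclidean norm.
    """
    if not 0 < trim_fraction <= 1:
        raise ValueError("trim_fraction must be in (0, 1]")
    raw = np.asarray(bits.values, dtype=float)
    n, m = raw.shape
    if n < 2 or m < 2:
        raise ValueError("SVD needs at least 2 proteins and 2 species")
    floored = np.where(raw < score_floor, 0.0, raw)
    nonzero = floored.any(axis=1)
    if not nonzero.any():
        raise ValueError("profile is all zero after flooring")
    dropped = [(p, "no score above floor")
               for p, nz in zip(bits.proteins, nonzero) if not nz]
    scaled = floored[nonzero] / floored[nonzero].max(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    # columns beyond the numerical rank span an arbitrary null-space basis
    # and carry no signal, so trimming never reaches past the rank
    rank = int(np.sum(s > max(scaled.shape) * np.finfo(float).eps * s[0]))
    n_keep = min(math.ceil(trim_fraction * m), u.shape[1], max(rank, 1))
    trimmed = u[:, :n_keep]
    # conservation filter applies after factorization, on the raw scores of
    # the surviving rows, so the factor basis itself is unaffected
    keep = _conservation_mask(raw[nonzero], score_floor, min_homologs)
    dropped += [
        (p, "poor conservation")
        for p, k in zip(
            (q for q, nz in zip(bits.proteins, nonzero) if nz), keep)
        if not k
    ]
    if not keep.any():
        raise ValueError(
            f"all proteins dropped by the conservation filter "
            f"(score_floor={score_floor}, min_homologs={min_homologs})"
        )
    retained = trimmed[keep]
    norms = np.linalg.norm(retained, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("degenerate zero row in the trimmed factor")
    unit = retained / norms
    kept_names = tuple(
        p for p, k in zip(
            (q for q, nz in zip(bits.proteins, nonzero) if nz), keep)
        if k
    )
    return NormalizedProfile(
        proteins=kept_names,
        dimensions=tuple(f"sv{i}" for i in range(n_keep)),
        values=unit,
        method="svd",
        dropped_proteins=dropped,
        params={"score_floor": score_floor, "trim_fraction": trim_fraction,
                "min_homologs": min_homologs,
                "singular_values": s.tolist()},
    )


def npp_score(norm: NormalizedProfile) -> MeasureMatrix:
    """Pairwise Pearson correlation on NPP rows (similarity orientation)."""
    if norm.method != "npp":
        raise ValueError(f"npp_score expects an NPP profile, got {norm.method!r}")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(norm.values)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2  # shave float asymmetry
    return MeasureMatrix(norm.proteins, corr, "npp", "similarity")


def svd_score(norm: NormalizedProfile) -> MeasureMatrix:
    """Pairwise Euclidean distance on unit-norm SVD rows (distance orientation)."""
    if norm.method != "svd":
        raise ValueError(f"svd_score expects an SVD profile, got {norm.method!r}")
    dm = squareform(pdist(norm.values, metric="euclidean"))
    return MeasureMatrix(norm.proteins, dm, "svd", "distance")
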