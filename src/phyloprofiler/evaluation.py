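"""Benchmarking predicted linkages against complex-derived reference sets.

Positives are all pairs of proteins sharing an annotated complex; negatives
are sampled pairs whose proteins share no complex and whose complexes share
no subcellular localization label.  Score matrices (or the top-rank sweep)
are swept over thresholds to produce ROC and precision/recall curves with a
trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .measures import MeasureMatrix
from .toprank import LinkageSet, pair_rank_table
from .profiles import BinaryProfile

__all__ = [
    "ComplexTable",
    "ReferenceSet",
    "CurveResult",
    "build_reference",
    "score_curve",
    "toprank_curve",
    "mmm_hit_rate",
    "geneset_coverage",
]


@dataclass
class ComplexTable:
    """Complex membership records (complex_id, protein_id, localization)."""

    records: list[tuple[str, str, str | None]]

    def __post_init__(self) -> None:
        seen = set()
        for cid, pid, _ in self.records:
            if (cid, pid) in seen:
                raise ValueError(f"duplicate membership ({cid}, {pid})")
            seen.add((cid, pid))

    @classmethod
    def read(cls, path) -> "ComplexTable":
        records = []
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cells = line.split("\t")
                if len(cells) < 2:
                    raise ValueError(f"{path}: expected >= 2 columns")
                records.append((cells[0], cells[1],
                                cells[2] if len(cells) > 2 and cells[2] else None))
        return cls(records)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for cid, pid, loc in self.records:
                fh.write(f"{cid}\t{pid}\t{loc or ''}\n")

    def members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cid, pid, _ in self.records:
            out.setdefault(cid, set()).add(pid)
        return out

    def localizations(self) -> dict[str, set[str]]:
        """Localization labels per complex (empty set when unannotated)."""
        out: dict[str, set[str]] = {}
        for cid, _, loc in self.records:
            out.setdefault(cid, set())
            if loc:
                out[cid].add(loc)
        return out


@dataclass
class ReferenceSet:
    """Labelled evaluation pairs: intra-complex positives, sampled negatives."""

    positives: set[frozenset]
    negatives: set[frozenset]
    seed: int
    ratio: float

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        for pair in list(self.positives) + list(self.negatives):
            if len(pair) != 2:
                raise ValueError(f"self-pair in reference: {set(pair)}")


def build_reference(complexes: ComplexTable, ratio: float = 10.0,
                    seed: int = 0, max_subunits: int | None = None) -> ReferenceSet:
    """Build a labelled reference set from a complex table.

    Positives are every unordered pair within a complex, pooled over all
    complexes (complexes with more than ``max_subunits`` members are dropped
    first when that cap is set, to stop huge complexes dominating the pool).
    ``round(ratio * n_positives)`` negatives are sampled uniformly without
    replacement from pairs whose proteins share no complex and whose
    complexes share no localization label; too few eligible candidates is an
    error, never a silent cap.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    members = complexes.members()
    locs = complexes.localizations()
    if max_subunits is not None:
        members = {c: m for c, m in members.items() if len(m) <= max_subunits}
    if len(members) < 2:
        raise ValueError("need at least 2 complexes")
    positives: set[frozenset] = set()
    for m in members.values():
        positives.update(frozenset(p) for p in combinations(sorted(m), 2))
    prot_complexes: dict[str, set[str]] = {}
    for cid, m in members.items():
        for pid in m:
            prot_complexes.setdefault(pid, set()).add(cid)
    prot_locs = {
        pid: set().union(*(locs[c] for c in cids))
        for pid, cids in prot_complexes.items()
    }
    proteins = sorted(prot_complexes)
    candidates = []
    for a, b in combinations(proteins, 2):
        if prot_complexes[a] & prot_complexes[b]:
            continue
        if prot_locs[a] & prot_locs[b]:
            continue
        pair = frozenset((a, b))
        if pair not in positives:
            candidates.append(pair)
    n_neg = int(round(ratio * len(positives)))
    if len(candidates) < n_neg:
        raise ValueError(
            f"only {len(candidates)} eligible negative pairs for the "
            f"requested {n_neg} (ratio={ratio}, positives={len(positives)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_neg, replace=False)
    negatives = {candidates[i] for i in sorted(idx)}
    return ReferenceSet(positives=positives, negatives=negatives,
                        seed=seed, ratio=ratio)


@dataclass
class CurveResult:
    """Threshold-swept confusion counts with ROC/PR coordinates and AUC.

    ``precision`` is NaN where no pair is predicted positive (TP+FP=0); PR
    plots skip those points.  ``auc`` is the trapezoidal area under the ROC
    curve anchored at (0,0) and (1,1).
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    sweep: str = "score"
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "threshold": self.thresholds, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn, "fpr": self.fpr, "tpr": self.tpr,
            "precision": self.precision, "recall": self.recall,
        })


def _confusion_curve(thresholds, tp, fp, n_pos, n_neg, sweep, meta):
    tp = np.asarray(tp, dtype=int)
    fp = np.asarray(fp, dtype=int)
    fn = n_pos - tp
    tn = n_neg - fp
    fpr = 1.0 - tn / n_neg
    tpr = tp / n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
    recall = tpr.copy()
    xs = np.concatenate(([0.0], fpr, [1.0]))
    ys = np.concatenate(([0.0], tpr, [1.0]))
    auc = float(np.trapezoid(ys, xs))
    return CurveResult(np.asarray(thresholds, dtype=float), tp, fp, tn, fn,
                       fpr, tpr, precision, recall, auc, sweep, meta)


def _pair_scores(scores, reference: ReferenceSet):
    """Similarity-oriented score per reference pair; missing = worst."""
    if isinstance(scores, MeasureMatrix):
        lookup = scores.pair_scores()
        sign = -1.0 if scores.orientation == "distance" else 1.0
        return {
            pair: (sign * lookup[pair] if pair in lookup else -np.inf)
            for pair in reference.positives | reference.negatives
        }
    # mapping pair -> score, assumed similarity-oriented
    return {
        pair: scores.get(pair, -np.inf)
        for pair in reference.positives | reference.negatives
    }


def score_curve(scores, reference: ReferenceSet) -> CurveResult:
    """ROC/PR sweep of a score matrix (or pair->score map) over a reference.

    Thresholds are the distinct scores achieved by reference pairs, swept
    from strict to relaxed; a pair is predicted linked when its score is at
    or above the threshold, so tied pairs flip together.  Distance-oriented
    matrices are negated before the sweep.  Reference pairs the scorer
    cannot score count as unlinked at every threshold.
    """
    if not reference.positives or not reference.negatives:
        raise ValueError("reference must contain positives and negatives")
    pair_scores = _pair_scores(scores, reference)
    labels = np.array([pair in reference.positives for pair in pair_scores])
    values = np.array([pair_scores[pair] for pair in pair_scores])
    order = np.argsort(-values, kind="stable")
    labels = labels[order]
    values = values[order]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    # cumulative counts at each distinct threshold (ties flip together);
    # mark the last index of every tied run
    last_of_run = np.empty(values.size, dtype=bool)
    last_of_run[:-1] = values[:-1] != values[1:]
    last_of_run[-1] = True
    distinct = np.nonzero(last_of_run)[0]
    cum_tp = np.cumsum(labels)[distinct]
    cum_fp = np.cumsum(~labels)[distinct]
    return _confusion_curve(values[distinct], cum_tp, cum_fp, n_pos, n_neg,
                            "score", {})


def toprank_curve(profile: BinaryProfile, reference: ReferenceSet,
                  t_values=None) -> CurveResult:
    """ROC/PR sweep of top-rank prediction over thresholds T = 1 .. n-1.

    The sweep variable is the per-protein rank threshold; the pair ranking is
    computed once and thresholded per T.  Fallback (no-solo) links are
    present at every T.
    """
    if not reference.positives or not reference.negatives:
        raise ValueError("reference must contain positives and negatives")
    n = len(profile.proteins)
    if t_values is None:
        t_values = range(1, n)
    ranks, fallbacks = pair_rank_table(profile)
    ref_pairs = reference.positives | reference.negatives
    n_pos = len(reference.positives)
    n_neg = len(reference.negatives)
    tp, fp = [], []
    for t in t_values:
        predicted = {p for p in ref_pairs
                     if p in fallbacks or ranks.get(p, np.inf) <= t}
        tp.append(len(predicted & reference.positives))
        fp.append(len(predicted) - tp[-1])
    return _confusion_curve(list(t_values), tp, fp, n_pos, n_neg,
                            "toprank", {"n_proteins": n})


def linkage_confusion(predicted: LinkageSet, reference: ReferenceSet):
    """Precision and recall of one fixed linkage set against a reference.

    Only reference pairs count: TP = predicted positives, FP = predicted
    negatives.  Returns ``(precision, recall)``; precision is NaN when the
    prediction touches no reference pair.
    """
    pairs = predicted.pairs()
    tp = len(pairs & reference.positives)
    fp = len(pairs & reference.negatives)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / len(reference.positives)
    return precision, recall


def mmm_hit_rate(predicted: LinkageSet, mmm_pairs) -> float:
    """Fraction of an external co-evolving pair list recovered: N_top / N_MMM."""
    mmm = {frozenset(p) for p in mmm_pairs}
    if not mmm:
        raise ValueError("the external pair list is empty")
    return len(predicted.pairs() & mmm) / len(mmm)


def geneset_coverage(predicted: LinkageSet, geneset_edges: dict[str, set]):
    """Predicted fraction of each named gene-set edge list, plus pooled overall.

    Returns ``(per_set, overall)`` where ``per_set[name]`` is the fraction of
    that set's edges present among the predicted links and ``overall`` pools
    every edge (an edge in several sets counts once per set, once overall).
    """
    if not geneset_edges:
        raise ValueError("no gene sets given")
    pairs = predicted.pairs()
    per_set: dict[str, float] = {}
    pooled: set[frozenset] = set()
    for name, edges in geneset_edges.items():
        edges = {frozenset(e) for e in edges}
        if not edges:
            raise ValueError(f"gene set {name!r} is empty")
        per_set[name] = len(pairs & edges) / len(edges)
        pooled |= edges
    overall = len(pairs & pooled) / len(pooled)
    return per_set, overall
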