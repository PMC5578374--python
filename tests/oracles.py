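"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the defining formulas with plain
Python loops, deliberately sharing no code with the package, so agreement is
evidence and not tautology.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, product


# ---------------------------------------------------------------------------
# literal-formula co-occurrence measures

def jaccard_oracle(x, y):
    inter = sum(1 for a, b in zip(x, y) if a == 1 and b == 1)
    union = sum(1 for a, b in zip(x, y) if a == 1 or b == 1)
    return inter / union if union else 0.0


def pearson_oracle(x, y):
    """Sample correlation; None when undefined (constant vector)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / (n - 1))
    if sx == 0 or sy == 0:
        return None
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return num / ((n - 1) * sx * sy)


def mi_oracle(x, y):
    n = len(x)
    total = 0.0
    for xs in (0, 1):
        for ys in (0, 1):
            pxy = sum(1 for a, b in zip(x, y) if a == xs and b == ys) / n
            px = sum(1 for a in x if a == xs) / n
            py = sum(1 for b in y if b == ys) / n
            if pxy > 0:
                total += pxy * math.log2(pxy / (px * py))
    return total


def lp_oracle(x, y, p):
    return sum(abs(a - b) ** p for a, b in zip(x, y)) ** (1.0 / p)


# ---------------------------------------------------------------------------
# rooted binary labelled trees as nested tuples, with exhaustive Dollo search

def all_rooted_binary_trees(labels):
    """Every rooted binary labelled tree shape over ``labels`` (nested tuples)."""
    labels = list(labels)
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]
    trees = []
    for k in range(len(rest) + 1):
        for left_rest in combinations(rest, k):
            right = [l for l in rest if l not in left_rest]
            if not right:
                continue
            for lt in all_rooted_binary_trees([first, *left_rest]):
                for rt in all_rooted_binary_trees(right):
                    trees.append((lt, rt))
    return trees


def nested_to_newick(tree) -> str:
    if isinstance(tree, tuple):
        return "(" + ",".join(nested_to_newick(c) for c in tree) + ")"
    return str(tree)


def _flatten(tree, parent, nodes, parents, leaf_of):
    idx = len(nodes)
    nodes.append(tree)
    parents.append(parent)
    if isinstance(tree, tuple):
        for child in tree:
            _flatten(child, idx, nodes, parents, leaf_of)
    else:
        leaf_of[tree] = idx
    return nodes, parents, leaf_of


def dollo_brute_force(tree, leaf_states):
    """Exhaustive minimum-loss single-gain search on a nested-tuple tree.

    Enumerates every 0/1 assignment to internal nodes, keeps the Dollo-valid
    ones (the present nodes form one connected subtree, i.e. at most one
    branch or the root switches 0 -> 1), and returns
    ``(min_losses, argmin_states)`` where each argmin is a tuple of node
    states in the same preorder as the flattening.
    """
    nodes, parents, leaf_of = _flatten(tree, -1, [], [], {})
    internal = [i for i, nd in enumerate(nodes) if isinstance(nd, tuple)]
    best = None
    argmin = []
    for bits in product((0, 1), repeat=len(internal)):
        state = [0] * len(nodes)
        for i, b in zip(internal, bits):
            state[i] = b
        for label, idx in leaf_of.items():
            state[idx] = leaf_states[label]
        gains = sum(
            1 for i, s in enumerate(state)
            if s == 1 and (parents[i] == -1 or state[parents[i]] == 0)
        )
        if gains > 1:
            continue
        losses = sum(
            1 for i in range(1, len(nodes))
            if state[parents[i]] == 1 and state[i] == 0
        )
        if best is None or losses < best:
            best = losses
            argmin = [tuple(state)]
        elif losses == best:
            argmin.append(tuple(state))
    return best, argmin


def dollo_branch_changes(tree, state):
    """anc - desc per branch of a flattened nested-tuple tree assignment."""
    nodes, parents, _ = _flatten(tree, -1, [], [], {})
    return [state[parents[i]] - state[i] for i in range(1, len(nodes))]


# ---------------------------------------------------------------------------
# literal top-rank prediction: filter by cor > 0, sort by Jaccard, truncate,
# union, with the best-Jaccard fallback for proteins with no candidate.
# Ordering keys are exact rationals so ties cannot be broken by float
# round-off: the Jaccard key is inter/union, and the correlation key
# sign(num) * num^2 / (varx * vary) is strictly monotone in the correlation
# (both share the positive factor 1/sqrt(varx * vary)); positivity of the
# correlation is the positivity of its integer numerator.

def _exact_keys(x, y):
    x = [int(v) for v in x]  # guard against narrow integer dtypes
    y = [int(v) for v in y]
    n = len(x)
    n11 = sum(1 for a, b in zip(x, y) if a == 1 and b == 1)
    sx, sy = sum(x), sum(y)
    union = sx + sy - n11
    jac = Fraction(n11, union) if union else Fraction(0)
    num = n * n11 - sx * sy
    varx, vary = sx * (n - sx), sy * (n - sy)
    defined = varx > 0 and vary > 0
    cor_key = (Fraction(num * abs(num), varx * vary)
               if defined else None)
    return jac, cor_key, defined and num > 0


def toprank_oracle(names, rows, T, strict=False):
    """Predicted pair set (and pure-fallback pairs) by literal
    filter/sort/truncate/union."""

    def sort_key(i, j):
        jac, cor_key, _ = _exact_keys(rows[i], rows[j])
        # undefined correlation sorts below every defined value
        return (-jac, 0 if cor_key is not None else 1,
                -(cor_key if cor_key is not None else 0), names[j])

    regular, fallbacks = set(), set()
    cutoff = T - 1 if strict else T
    for i in range(len(names)):
        others = sorted((j for j in range(len(names)) if j != i),
                        key=lambda j: sort_key(i, j))
        kept = [j for j in others if _exact_keys(rows[i], rows[j])[2]]
        if kept and cutoff >= 1:
            for j in kept[:cutoff]:
                regular.add(frozenset((names[i], names[j])))
        else:
            j = kept[0] if kept else others[0]
            fallbacks.add(frozenset((names[i], names[j])))
    # a pair selected normally in either direction is not a pure fallback
    return regular | fallbacks, fallbacks - regular
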