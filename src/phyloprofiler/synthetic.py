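"""Seeded synthetic fixtures with planted co-evolving modules.

The generator emulates the inputs of the whole pipeline without any external
downloads: a binary profile whose rows fall into "evolutionary modules"
(groups of proteins sharing one clade-structured presence pattern, like the
subunits of a conserved complex), bit scores conditional on presence, a
random rooted species tree whose clades match the profile's block structure,
and a complex table derived from the planted modules for reference-set
construction.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .dollo import RootedTree, parse_newick
from .evaluation import ComplexTable, build_reference
from .profiles import BinaryProfile, BitScoreProfile, SpeciesCatalog

__all__ = ["SyntheticTruth", "simulate_profiles", "simulate_bitscores",
           "simulate_tree", "truth_to_reference"]

# presence probability inside a clade the module occupies vs. outside it:
# high-but-imperfect occupancy keeps patterns clade-structured while leaving
# the species columns non-constant, which NPP's z-scores need
ON_PROB = 0.95
OFF_PROB = 0.02


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated profile.

    ``module_assignment`` maps every protein to its module id, or ``None``
    for background proteins; ``base_pattern`` holds each module's shared
    presence vector before per-protein flip noise.
    """

    module_assignment: dict[str, str | None]
    base_pattern: dict[str, np.ndarray]
    flip_noise: float
    seed: int
    clade_block_sizes: tuple[int, ...] = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes: dict[str, int] = {}
        for mod in self.module_assignment.values():
            if mod is not None:
                sizes[mod] = sizes.get(mod, 0) + 1
        if any(s < 2 for s in sizes.values()):
            raise ValueError("module sizes must be >= 2")
        patterns = [tuple(v) for v in self.base_pattern.values()]
        if len(set(patterns)) != len(patterns):
            raise ValueError("base patterns must be distinct")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must be in [0, 0.5)")

    def module_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for prot, mod in self.module_assignment.items():
            if mod is not None:
                out.setdefault(mod, []).append(prot)
        return out

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "flip_noise": self.flip_noise,
            "clade_block_sizes": list(self.clade_block_sizes),
            "modules": {m: sorted(ps) for m, ps in self.module_members().items()},
            **self.params,
        }


def _draw_pattern(rng, clade_sizes, clade_probs) -> np.ndarray:
    parts = [rng.random(sz) < p for sz, p in zip(clade_sizes, clade_probs)]
    return np.concatenate(parts).astype(np.int8)


def simulate_profiles(n_modules: int = 3, module_size: int = 6,
                      n_background: int = 12, m_species: int = 60,
                      clade_block_sizes=None, presence_prob_per_clade=None,
                      flip_noise: float = 0.05, seed: int = 0):
    """Simulate a binary profile with planted co-evolving modules.

    Species are partitioned into clade blocks (default: 6 equal blocks).
    Each module draws one base pattern — every clade is independently
    occupied with probability 1/2 (at least one occupied), then species in
    occupied clades are present with probability 0.95 and others with 0.02 —
    and each member copies that pattern with independent per-entry flips at
    rate ``flip_noise``.  Background proteins draw their own patterns the
    same way.  Base patterns are redrawn until distinct and non-constant.

    ``presence_prob_per_clade`` overrides the clade occupancy draw: either a
    sequence of per-clade presence probabilities shared by all modules, or a
    matrix of shape (n_modules, n_clades).

    Returns ``(BinaryProfile, SyntheticTruth)``; fully determined by ``seed``.
    """
    if min(n_modules, module_size, m_species) < 1 or n_background < 0:
        raise ValueError("counts must be positive (background may be 0)")
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    if not 0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    if clade_block_sizes is None:
        n_blocks = min(6, m_species)
        base, extra = divmod(m_species, n_blocks)
        clade_block_sizes = [base + (1 if i < extra else 0)
                             for i in range(n_blocks)]
    clade_block_sizes = [int(s) for s in clade_block_sizes]
    if sum(clade_block_sizes) != m_species or min(clade_block_sizes) < 1:
        raise ValueError("clade_block_sizes must be positive and sum to m_species")
    n_clades = len(clade_block_sizes)
    rng = np.random.default_rng(seed)

    probs = None
    if presence_prob_per_clade is not None:
        probs = np.asarray(presence_prob_per_clade, dtype=float)
        if probs.ndim == 1:
            probs = np.tile(probs, (n_modules, 1))
        if probs.shape != (n_modules, n_clades):
            raise ValueError("presence_prob_per_clade has the wrong shape")

    def module_probs(k: int) -> np.ndarray:
        if probs is not None:
            return probs[k]
        on = rng.random(n_clades) < 0.5
        if not on.any():
            on[rng.integers(n_clades)] = True
        return np.where(on, ON_PROB, OFF_PROB)

    base_patterns: list[np.ndarray] = []
    for k in range(n_modules):
        for _ in range(1000):
            pat = _draw_pattern(rng, clade_block_sizes, module_probs(k))
            if 0 < pat.sum() < m_species and not any(
                    np.array_equal(pat, q) for q in base_patterns):
                base_patterns.append(pat)
                break
        else:
            raise ValueError("could not draw distinct non-constant base patterns")

    species = tuple(f"sp{j:03d}" for j in range(m_species))
    proteins: list[str] = []
    rows: list[np.ndarray] = []
    assignment: dict[str, str | None] = {}
    for k, pat in enumerate(base_patterns):
        mod = f"mod{k}"
        for i in range(module_size):
            name = f"{mod}_p{i}"
            flips = rng.random(m_species) < flip_noise
            proteins.append(name)
            rows.append(np.where(flips, 1 - pat, pat).astype(np.int8))
            assignment[name] = mod
    for i in range(n_background):
        name = f"bg_p{i}"
        on = rng.random(n_clades) < 0.5
        pat = _draw_pattern(rng, clade_block_sizes,
                            np.where(on, ON_PROB, OFF_PROB))
        proteins.append(name)
        rows.append(pat)
        assignment[name] = None
    profile = BinaryProfile(proteins, SpeciesCatalog(species), np.vstack(rows))
    truth = SyntheticTruth(
        module_assignment=assignment,
        base_pattern={f"mod{k}": p for k, p in enumerate(base_patterns)},
        flip_noise=flip_noise,
        seed=seed,
        clade_block_sizes=tuple(clade_block_sizes),
        params={"n_modules": n_modules, "module_size": module_size,
                "n_background": n_background, "m_species": m_species},
    )
    return profile, truth


def simulate_bitscores(profile: BinaryProfile, present_mean: float = 150.0,
                       present_sd: float = 30.0, seed: int = 0,
                       floor: float = 25.0) -> BitScoreProfile:
    """Bit scores conditional on presence: zero where absent, where present a
    normal draw truncated below at ``floor`` so the normalization floors
    (60/70) are genuinely exercised by the tail of the distribution."""
    if present_mean <= 0:
        raise ValueError("present_mean must be positive")
    if present_sd <= 0:
        raise ValueError("present_sd must be positive")
    rng = np.random.default_rng(seed)
    present = np.asarray(profile.values) == 1
    a = (floor - present_mean) / present_sd
    draws = truncnorm.rvs(a, np.inf, loc=present_mean, scale=present_sd,
                          size=int(present.sum()), random_state=rng)
    values = np.zeros(profile.shape, dtype=float)
    values[present] = draws
    return BitScoreProfile(profile.proteins, profile.catalog, values)


def _join_random(rng, fragments: list[str]) -> str:
    """Random sequential pairwise joins of newick fragments (bifurcating)."""
    frags = list(fragments)
    while len(frags) > 1:
        i, j = rng.choice(len(frags), size=2, replace=False)
        a, b = frags[int(i)], frags[int(j)]
        frags = [f for k, f in enumerate(frags) if k not in (int(i), int(j))]
        frags.append(f"({a},{b})")
    return frags[0]


def simulate_tree(species, seed: int = 0, clade_block_sizes=None) -> RootedTree:
    """Random rooted bifurcating tree over ``species``.

    When ``clade_block_sizes`` is given (matching the order of ``species``),
    each block is built as a monophyletic subtree before the blocks are
    joined, so tree-aware scoring sees the same clade structure the profile
    generator planted.  Same seed, same Newick.
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    if len(set(species)) != len(species):
        raise ValueError("species must be unique")
    rng = np.random.default_rng(seed)
    if clade_block_sizes is None:
        blocks = [species]
    else:
        sizes = [int(s) for s in clade_block_sizes]
        if sum(sizes) != len(species):
            raise ValueError("clade_block_sizes must sum to the species count")
        blocks, at = [], 0
        for sz in sizes:
            blocks.append(species[at:at + sz])
            at += sz
    subtrees = [_join_random(rng, blk) for blk in blocks]
    return parse_newick(_join_random(rng, subtrees) + ";")


def truth_to_reference(truth: SyntheticTruth, ratio: float = 1.0,
                       seed: int | None = None,
                       max_subunits: int | None = None):
    """Map planted modules to complexes and build a labelled reference set.

    Each module becomes one complex whose localization label is the module id
    itself, so the different-localization rule keeps negatives strictly
    between modules.  Background proteins belong to no complex and are not
    part of the reference.  Returns ``(ReferenceSet, ComplexTable)``.
    """
    if seed is None:
        seed = truth.seed
    records = [(f"cplx_{mod}", prot, mod)
               for prot, mod in sorted(truth.module_assignment.items())
               if mod is not None]
    table = ComplexTable(records)
    reference = build_reference(table, ratio=ratio, seed=seed,
                                max_subunits=max_subunits)
    return reference, table
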