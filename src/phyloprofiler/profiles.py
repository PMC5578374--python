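"""Phylogenetic profile construction and I/O.

A phylogenetic profile records, for each query protein, whether (binary
profile) or how strongly (bit-score profile) a homolog is found in each of a
panel of fully sequenced organisms.  Profiles are built from tabular homology
search results (BLAST outfmt 6) plus a subject-to-species map, or read back
from TSV files written by this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HomologyHit",
    "SpeciesCatalog",
    "BinaryProfile",
    "BitScoreProfile",
    "ProfileFormatError",
    "parse_blast_tab",
    "build_binary_profile",
    "build_bitscore_profile",
    "read_profile",
    "write_profile",
]

#: leading cell of the header row in every profile TSV
HEADER_KEY = "protein_id"

TAXON_GROUPS = ("Animals", "Plants", "Fungi", "Protists", "Bacteria", "Archaea")


class ProfileFormatError(ValueError):
    """Raised when an on-disk profile or homology table violates its format."""


@dataclass(frozen=True)
class HomologyHit:
    """One homology search hit, already resolved to a species.

    Parameters
    ----------
    query_protein : str
        Identifier of the query protein (profile row).
    subject_species : str
        Species the subject sequence belongs to (profile column).
    e_value : float
        BLAST expectation value, >= 0.
    bit_score : float
        BLAST bit score, >= 0.
    """

    query_protein: str
    subject_species: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not self.query_protein or not self.subject_species:
            raise ValueError("hit identifiers must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value!r}")
        if self.bit_score < 0:
            raise ValueError(f"negative bit score {self.bit_score!r}")


@dataclass(frozen=True)
class SpeciesCatalog:
    """Ordered panel of reference organisms; the canonical column order.

    ``taxon_group`` optionally labels each species with one of the six major
    taxa (Animals, Plants, Fungi, Protists, Bacteria, Archaea).
    """

    species: tuple[str, ...]
    taxon_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if len(set(self.species)) != len(self.species):
            raise ValueError("species identifiers must be unique")
        unknown = {g for g in self.taxon_group.values() if g not in TAXON_GROUPS}
        if unknown:
            raise ValueError(f"unknown taxon group(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.species)

    def index_of(self, species_id: str) -> int:
        return self.species.index(species_id)


class _Profile:
    """Shared shape contract of binary and bit-score profiles."""

    def __init__(self, proteins, catalog: SpeciesCatalog, values) -> None:
        proteins = tuple(proteins)
        if len(set(proteins)) != len(proteins):
            raise ValueError("protein identifiers must be unique")
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("profile values must be a 2-D matrix")
        if values.shape != (len(proteins), len(catalog)):
            raise ValueError(
                f"value matrix {values.shape} does not match "
                f"{len(proteins)} proteins x {len(catalog)} species"
            )
        self.proteins = proteins
        self.catalog = catalog
        self.values = values
        self._index = {p: i for i, p in enumerate(proteins)}

    @property
    def species(self) -> tuple[str, ...]:
        return self.catalog.species

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, protein: str) -> np.ndarray:
        try:
            return self.values[self._index[protein]]
        except KeyError:
            raise KeyError(f"protein {protein!r} not in profile") from None

    def index_of(self, protein: str) -> int:
        try:
            return self._index[protein]
        except KeyError:
            raise KeyError(f"protein {protein!r} not in profile") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.proteins),
                            columns=list(self.species))

    def all_zero_rows(self) -> list[str]:
        """Proteins with no qualifying hit in any species (kept, but flagged)."""
        mask = ~self.values.any(axis=1)
        return [p for p, z in zip(self.proteins, mask) if z]

    def __eq__(self, other) -> bool:
        return (
            type(self) is type(other)
            and self.proteins == other.proteins
            and self.species == other.species
            and np.array_equal(self.values, other.values)
        )


class BinaryProfile(_Profile):
    """Presence/absence matrix over {0,1}: rows are proteins, columns species."""

    def __init__(self, proteins, catalog, values) -> None:
        super().__init__(proteins, catalog, values)
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"binary profile entry ({self.proteins[i]}, {self.species[j]}) "
                f"= {self.values[i, j]!r} is not 0/1"
            )
        self.values = self.values.astype(np.int8)


class BitScoreProfile(_Profile):
    """Best BLAST bit score per (protein, species); 0 means no hit."""

    def __init__(self, proteins, catalog, values) -> None:
        super().__init__(proteins, catalog, values)
        if (self.values < 0).any():
            raise ValueError("bit scores must be non-negative")

    def binarize(self) -> BinaryProfile:
        """Presence = any hit at all (equivalent to an infinite E-value cutoff)."""
        return BinaryProfile(self.proteins, self.catalog,
                             (self.values > 0).astype(np.int8))


# ---------------------------------------------------------------------------
# BLAST tabular parsing

def parse_blast_tab(stream, species_map: dict[str, str]):
    """Parse BLAST tabular (outfmt 6) lines into :class:`HomologyHit` records.

    Columns follow the standard outfmt-6 layout (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).  Subjects are
    resolved to species via ``species_map`` — by exact subject id, else by the
    longest map key that prefixes the subject id.  Hits whose subject cannot
    be resolved are dropped and counted.

    Returns
    -------
    (hits, n_unresolved) : (list of HomologyHit, int)
    """
    hits: list[HomologyHit] = []
    unresolved = 0
    prefixes = sorted(species_map, key=len, reverse=True)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ProfileFormatError(
                f"line {lineno}: expected >= 12 tab-separated fields, "
                f"got {len(fields)}"
            )
        query, subject = fields[0], fields[1]
        try:
            e_value = float(fields[10])
            bit_score = float(fields[11])
        except ValueError as exc:
            raise ProfileFormatError(f"line {lineno}: {exc}") from None
        species = species_map.get(subject)
        if species is None:
            species = next(
                (species_map[p] for p in prefixes if subject.startswith(p)), None
            )
        if species is None:
            unresolved += 1
            continue
        hits.append(HomologyHit(query, species, e_value, bit_score))
    return hits, unresolved


def _prepare(proteins, catalog: SpeciesCatalog):
    proteins = tuple(proteins)
    if not proteins:
        raise ValueError("protein list is empty")
    if len(set(proteins)) != len(proteins):
        raise ValueError("duplicate protein identifiers")
    prow = {p: i for i, p in enumerate(proteins)}
    scol = {s: j for j, s in enumerate(catalog.species)}
    return proteins, prow, scol


def build_binary_profile(hits, catalog: SpeciesCatalog, proteins,
                         e_threshold: float = 0.001) -> BinaryProfile:
    """Presence/absence profile: 1 iff some hit has ``e_value <= e_threshold``.

    The comparison is inclusive.  Proteins with no qualifying hit anywhere keep
    an all-zero row (query :meth:`BinaryProfile.all_zero_rows` to flag them).
    Hits for proteins outside ``proteins`` or species outside the catalog are
    ignored.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    proteins, prow, scol = _prepare(proteins, catalog)
    values = np.zeros((len(proteins), len(catalog)), dtype=np.int8)
    for h in hits:
        if h.e_value <= e_threshold:
            i, j = prow.get(h.query_protein), scol.get(h.subject_species)
            if i is not None and j is not None:
                values[i, j] = 1
    return BinaryProfile(proteins, catalog, values)


def build_bitscore_profile(hits, catalog: SpeciesCatalog,
                           proteins) -> BitScoreProfile:
    """Best-hit bit-score profile: the maximum bit score per (protein, species)."""
    proteins, prow, scol = _prepare(proteins, catalog)
    values = np.zeros((len(proteins), len(catalog)), dtype=float)
    for h in hits:
        i, j = prow.get(h.query_protein), scol.get(h.subject_species)
        if i is not None and j is not None and h.bit_score > values[i, j]:
            values[i, j] = h.bit_score
    return BitScoreProfile(proteins, catalog, values)


# ---------------------------------------------------------------------------
# TSV round-trip
#
# Dialect: UTF-8, tab-separated, no quoting, "." decimal; header row is
# "protein_id<TAB>species...", one protein per following row.

def write_profile(profile: _Profile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER_KEY + "\t" + "\t".join(profile.species) + "\n")
        is_binary = isinstance(profile, BinaryProfile)
        for name, row in zip(profile.proteins, profile.values):
            cells = (str(int(v)) if is_binary else format(float(v), "g")
                     for v in row)
            fh.write(name + "\t" + "\t".join(cells) + "\n")


def read_profile(path, kind: str = "auto"):
    """Read a profile TSV written by :func:`write_profile`.

    Parameters
    ----------
    kind : {"auto", "binary", "bitscore"}
        ``auto`` returns a :class:`BinaryProfile` when every cell is 0/1,
        else a :class:`BitScoreProfile`.  ``binary`` insists on 0/1 cells and
        raises :class:`ProfileFormatError` naming the offending cell.
    """
    if kind not in ("auto", "binary", "bitscore"):
        raise ValueError(f"unknown profile kind {kind!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ProfileFormatError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != HEADER_KEY:
            raise ProfileFormatError(
                f"{path}: first header cell must be {HEADER_KEY!r}, got {cols[0]!r}"
            )
        species = cols[1:]
        proteins: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(cols):
                raise ProfileFormatError(
                    f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                    f"expected {len(cols)})"
                )
            proteins.append(cells[0])
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise ProfileFormatError(f"{path}:{lineno}: {exc}") from None
    catalog = SpeciesCatalog(tuple(species))
    if not proteins:
        warnings.warn(f"{path}: profile has zero proteins", stacklevel=2)
        values = np.empty((0, len(species)))
    else:
        values = np.array(rows, dtype=float)
    if kind == "bitscore":
        return BitScoreProfile(proteins, catalog, values)
    is_binary = values.size == 0 or bool(np.isin(values, (0.0, 1.0)).all())
    if kind == "binary" and not is_binary:
        bad = np.argwhere(~np.isin(values, (0.0, 1.0)))[0]
        raise ProfileFormatError(
            f"{path}: cell ({proteins[bad[0]]}, {species[bad[1]]}) = "
            f"{values[bad[0], bad[1]]!r} is not binary"
        )
    if is_binary:
        return BinaryProfile(proteins, catalog, values)
    return BitScoreProfile(proteins, catalog, values)


def read_species_map(path):
    """Read a species-map TSV (subject_prefix_or_id, species_id[, taxon_group]).

    Returns ``(mapping, catalog)`` where the catalog lists species in first-seen
    order with any taxon-group labels attached.
    """
    mapping: dict[str, str] = {}
    order: list[str] = []
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ProfileFormatError(
                    f"{path}:{lineno}: expected >= 2 columns"
                )
            subject, species = cells[0], cells[1]
            mapping[subject] = species
            if species not in groups:
                order.append(species)
                groups[species] = ""
            if len(cells) > 2 and cells[2]:
                groups[species] = cells[2]
    catalog = SpeciesCatalog(
        tuple(order), {s: g for s, g in groups.items() if g}
    )
    return mapping, catalog
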