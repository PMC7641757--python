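"""Per-gene codon-usage-bias metrics.

Six metric families are computed from a single coding sequence:

* **codon frequency** — a 64-entry count vector (:func:`count_codons`);
* **codon aversion** — the set of codons never used in the gene
  (:func:`averted_codons`);
* **identical codon pairing** — recurrences of the same codon within one
  ribosomal footprint of nine codons (:func:`identical_pairing`);
* **co-tRNA codon pairing** — recurrences of synonymous but non-identical
  codons within the footprint (:func:`cotrna_pairing`);
* **RSCU** — relative synonymous codon usage, the observed count of a codon
  divided by its expected count under uniform usage within its synonym
  family (:func:`rscu`);
* **nucleotide composition** — per-base counts and GC fraction
  (:func:`composition`).

Pairing semantics
-----------------
The ribosome footprint spans ``window`` consecutive codons (default 9), so
two codons can pair iff their position difference is at most ``window - 1``.
Each position contributes at most one pairing event: position *j* is counted
as paired when at least one qualifying partner occurs among the previous
``window - 1`` positions.  This keeps every count bounded by the number of
occurrences of the codon (a run of *k* identical codons yields *k − 1*
pairing events, not a quadratic count).  Stop codons never pair; they are,
however, legitimate members of the aversion universe when ``include_stops``
is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .genetic_code import CODONS, GeneticCode, standard_code
from .sequences import CodingSequence, is_valid_codon

#: Default ribosomal footprint, in codons.
DEFAULT_WINDOW = 9


@dataclass(frozen=True)
class CodonCountTable:
    """Counts over all 64 codons for one coding sequence."""

    counts: Mapping[str, int]
    total_codons: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(CODONS):
            raise ValueError("counts must be keyed by all 64 codons")

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    def as_vector(self) -> np.ndarray:
        """Counts in fixed lexicographic codon order."""
        return np.array([self.counts[c] for c in CODONS], dtype=np.int64)


@dataclass(frozen=True)
class RscuTable:
    """Relative synonymous codon usage per sense codon.

    Codons of amino-acid families with zero observations carry ``nan``
    (RSCU is undefined there, not zero).
    """

    rscu: Mapping[str, float]

    def __getitem__(self, codon: str) -> float:
        return self.rscu[codon]


@dataclass(frozen=True)
class PairingProfile:
    """Identical and co-tRNA pairing counts for one coding sequence."""

    window: int
    identical: Mapping[str, int] = field(default_factory=dict)
    cotrna: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CompositionTable:
    """Nucleotide counts and GC fraction for one coding sequence."""

    counts: Mapping[str, int]  # keys A, C, G, T
    gc_content: float


def count_codons(seq: CodingSequence) -> CodonCountTable:
    """Tally each of the 64 codons in *seq*.

    Codons containing ambiguity characters are excluded (and logged by the
    validity mask); the total covers counted codons only.
    """
    counts = dict.fromkeys(CODONS, 0)
    total = 0
    for codon, ok in zip(seq.codons, seq.valid_codon_mask()):
        if ok:
            counts[codon] += 1
            total += 1
    return CodonCountTable(counts=counts, total_codons=total)


def averted_codons(
    table: CodonCountTable,
    include_stops: bool = True,
    code: GeneticCode | None = None,
) -> frozenset[str]:
    """Codons with zero occurrences in *table* (the gene's averted set).

    With ``include_stops`` the universe is all 64 codons; otherwise the 61
    sense codons.
    """
    code = code or standard_code()
    universe: Iterable[str] = CODONS if include_stops else code.sense_codons
    return frozenset(c for c in universe if table[c] == 0)


def identical_pairing(
    seq: CodingSequence,
    window: int = DEFAULT_WINDOW,
    code: GeneticCode | None = None,
) -> PairingProfile:
    """Count identical-codon pairing events within the ribosome footprint.

    For each sense codon ``c``, ``identical[c]`` is the number of positions
    *j* carrying ``c`` such that ``c`` also occurs at some earlier position
    within ``window - 1`` codons.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    code = code or standard_code()
    counts = {c: 0 for c in code.sense_codons}
    last_seen: dict[str, int] = {}
    mask = seq.valid_codon_mask()
    for j, codon in enumerate(seq.codons):
        if not mask[j] or code.is_stop(codon):
            continue
        i = last_seen.get(codon)
        if i is not None and j - i <= window - 1:
            counts[codon] += 1
        last_seen[codon] = j
    return PairingProfile(window=window, identical=counts, cotrna={})


def cotrna_pairing(
    seq: CodingSequence,
    window: int = DEFAULT_WINDOW,
    code: GeneticCode | None = None,
) -> PairingProfile:
    """Count co-tRNA pairing events (synonymous, non-identical) per amino acid.

    ``cotrna[aa]`` is the number of positions *j* whose codon is preceded,
    within ``window - 1`` codons, by a different codon of the same synonym
    family.  Single-codon families (Met, Trp) can never pair this way.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    code = code or standard_code()
    counts = {aa: 0 for aa in code.amino_acids}
    last_seen: dict[str, int] = {}
    mask = seq.valid_codon_mask()
    for j, codon in enumerate(seq.codons):
        if not mask[j] or code.is_stop(codon):
            continue
        aa = code.codon_to_aa[codon]
        for other in code.synonym_families[aa]:
            if other == codon:
                continue
            i = last_seen.get(other)
            if i is not None and j - i <= window - 1:
                counts[aa] += 1
                break
        last_seen[codon] = j
    return PairingProfile(window=window, identical={}, cotrna=counts)


def pairing_profile(
    seq: CodingSequence,
    window: int = DEFAULT_WINDOW,
    code: GeneticCode | None = None,
) -> PairingProfile:
    """Both pairing metrics in one profile."""
    ident = identical_pairing(seq, window, code)
    co = cotrna_pairing(seq, window, code)
    return PairingProfile(window=window, identical=ident.identical, cotrna=co.cotrna)


def rscu(table: CodonCountTable, code: GeneticCode | None = None) -> RscuTable:
    """Relative synonymous codon usage from a codon count table.

    ``RSCU_c = k * X_c / sum_{c' in family}(X_c')`` for a family of size
    *k*; within every observed family the values sum to *k* (mean 1).
    Families with zero total observations yield ``nan`` for each member.
    """
    code = code or standard_code()
    values: dict[str, float] = {}
    for family in code.synonym_families.values():
        total = sum(table[c] for c in family)
        k = len(family)
        for c in family:
            values[c] = k * table[c] / total if total > 0 else float("nan")
    return RscuTable(rscu=values)


def composition(seq: CodingSequence) -> CompositionTable:
    """Nucleotide counts and GC fraction over the coding sequence.

    Non-ACGT characters are excluded from both counts and the GC
    denominator.
    """
    counts = {b: 0 for b in "ACGT"}
    for ch in seq.nucleotides:
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    gc = (counts["G"] + counts["C"]) / total if total else float("nan")
    return CompositionTable(counts=counts, gc_content=gc)
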