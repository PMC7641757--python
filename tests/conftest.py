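"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by the most naive route
available (full pair enumeration, character tallies, explicit sums of
squares) so they stay independent of the library implementations they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from codonpop import CodingSequence, standard_code
from codonpop.sequences import is_valid_codon


@pytest.fixture(scope="session")
def code():
    return standard_code()


def make_seq(codons, sample="s", gene="g") -> CodingSequence:
    return CodingSequence(sample_id=sample, gene_id=gene, codons=tuple(codons))


def brute_force_identical(codons, window, code) -> dict[str, int]:
    """Pair enumeration oracle: position j pairs if any earlier identical
    sense codon lies within window - 1 positions."""
    counts = {c: 0 for c in code.sense_codons}
    for j, cj in enumerate(codons):
        if not is_valid_codon(cj) or code.is_stop(cj):
            continue
        for i in range(max(0, j - window + 1), j):
            if codons[i] == cj:
                counts[cj] += 1
                break
    return counts


def brute_force_cotrna(codons, window, code) -> dict[str, int]:
    """Pair enumeration oracle restricted to synonymous, non-identical
    sense codons."""
    counts = {aa: 0 for aa in code.amino_acids}
    for j, cj in enumerate(codons):
        if not is_valid_codon(cj) or code.is_stop(cj):
            continue
        aa = code.codon_to_aa[cj]
        for i in range(max(0, j - window + 1), j):
            ci = codons[i]
            if (
                is_valid_codon(ci)
                and not code.is_stop(ci)
                and ci != cj
                and code.codon_to_aa[ci] == aa
            ):
                counts[aa] += 1
                break
    return counts


def brute_force_tally(nucleotides: str) -> dict[str, int]:
    """Codon tally by scanning the nucleotide string three at a time."""
    counts: dict[str, int] = {}
    for i in range(0, len(nucleotides), 3):
        codon = nucleotides[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    return counts


def anova_f_by_hand(groups: dict[str, list[float]]) -> float:
    """One-way ANOVA F from an explicit sum-of-squares decomposition."""
    all_values = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    grand = all_values.mean()
    ss_between = sum(
        len(v) * (np.mean(v) - grand) ** 2 for v in groups.values()
    )
    ss_within = sum(
        float(np.sum((np.asarray(v, dtype=float) - np.mean(v)) ** 2))
        for v in groups.values()
    )
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def random_codon_seq(rng, alphabet, length) -> CodingSequence:
    """Random sequence over a restricted codon alphabet."""
    return make_seq([alphabet[k] for k in rng.integers(len(alphabet), size=length)])
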