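"""Standard genetic code tables.

The translation machinery reads 61 sense codons into 20 amino acids; three
stop codons terminate translation.  Synonymous codons — different codons for
the same amino acid — are the raw material of every codon-usage-bias metric
in this package, so the code table and its synonym families are exposed as a
small immutable object rather than scattered dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: All 64 codons in lexicographic order (the fixed column order of every
#: per-codon output table).
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)

#: Symbol used for stop codons in ``codon_to_aa`` maps.
STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid map plus derived synonym families.

    Parameters
    ----------
    codon_to_aa
        Map from each of the 64 uppercase DNA codons to a one-letter amino
        acid, with ``"*"`` for stop codons.
    """

    codon_to_aa: Mapping[str, str]
    synonym_families: Mapping[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            missing = set(CODONS) - set(self.codon_to_aa)
            extra = set(self.codon_to_aa) - set(CODONS)
            raise ValueError(
                f"code table must cover exactly the 64 codons "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        families: dict[str, list[str]] = {}
        for codon in CODONS:  # lexicographic order within each family
            aa = self.codon_to_aa[codon]
            if aa != STOP:
                families.setdefault(aa, []).append(codon)
        object.__setattr__(
            self,
            "synonym_families",
            MappingProxyType({aa: tuple(cs) for aa, cs in families.items()}),
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] == STOP)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.synonym_families))

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonym family (codon tuple) containing *codon*; stops → ()."""
        aa = self.codon_to_aa[codon]
        return () if aa == STOP else self.synonym_families[aa]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI translation table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(MappingProxyType(mapping))
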