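"""Codon-resolved coding sequences.

A :class:`CodingSequence` represents one (sample, gene, isoform, allele)
coding sequence split into codons.  Validation enforces the reading frame
(length a multiple of three); codons containing ambiguity characters are
retained in the sequence but skipped by the metric functions, which log a
warning when they do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGT")


class SequenceValidationError(ValueError):
    """Raised for coding sequences that cannot enter the codon frame."""


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(ch in _VALID_CHARS for ch in codon)


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence for one allele of one sample's gene isoform."""

    sample_id: str
    gene_id: str
    isoform_id: str = "1"
    allele: int = 1
    codons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for codon in self.codons:
            if len(codon) != 3:
                raise SequenceValidationError(
                    f"{self.label}: codon {codon!r} is not a trinucleotide"
                )

    @classmethod
    def from_nucleotides(
        cls,
        nucleotides: str,
        sample_id: str = "",
        gene_id: str = "",
        isoform_id: str = "1",
        allele: int = 1,
    ) -> "CodingSequence":
        """Split a nucleotide string into codons, enforcing the frame."""
        seq = nucleotides.strip().upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise SequenceValidationError(
                f"{sample_id}|{gene_id}|{isoform_id}|{allele}: "
                f"length {len(seq)} is not a multiple of 3"
            )
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        return cls(sample_id, gene_id, isoform_id, allele, codons)

    @property
    def nucleotides(self) -> str:
        return "".join(self.codons)

    @property
    def label(self) -> str:
        return f"{self.sample_id}|{self.gene_id}|{self.isoform_id}|{self.allele}"

    def __len__(self) -> int:
        return len(self.codons)

    def valid_codon_mask(self) -> list[bool]:
        """Per-position flag: True where the codon is unambiguous A/C/G/T."""
        mask = [is_valid_codon(c) for c in self.codons]
        n_bad = len(mask) - sum(mask)
        if n_bad:
            logger.warning(
                "%s: %d codon(s) contain non-ACGT characters and are "
                "excluded from counts",
                self.label,
                n_bad,
            )
        return mask
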