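"""Readers, writers and haplotype materialization.

FASTA records use the header convention ``sample|gene|isoform|allele``
(delimiter configurable).  All metric tables are written as CSV with a
mandatory header row and the identifier columns first; per-codon columns
appear in fixed lexicographic codon order so files from different runs line
up column-for-column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import CODONS, GeneticCode, standard_code
from .metrics import (
    DEFAULT_WINDOW,
    averted_codons,
    composition,
    count_codons,
    pairing_profile,
)
from .popstats import PopulationAssignment
from .ramp import RampResult
from .sequences import CodingSequence, SequenceValidationError

logger = logging.getLogger(__name__)

ID_COLUMNS = ["sample", "gene", "isoform", "allele"]


def parse_header(header: str, delimiter: str = "|") -> tuple[str, str, str, int]:
    """Split ``sample|gene|isoform|allele`` into its fields."""
    parts = header.split(delimiter)
    if len(parts) != 4:
        raise SequenceValidationError(
            f"header {header!r} does not match sample{delimiter}gene"
            f"{delimiter}isoform{delimiter}allele"
        )
    sample, gene, isoform, allele = parts
    try:
        allele_n = int(allele)
    except ValueError as exc:
        raise SequenceValidationError(
            f"header {header!r}: allele {allele!r} is not an integer"
        ) from exc
    return sample, gene, isoform, allele_n


def read_fasta(
    path: str | Path, delimiter: str = "|", strict: bool = False
) -> list[CodingSequence]:
    """Read coding sequences from FASTA.

    Records that fail validation (frame, header) are skipped with a logged
    warning unless ``strict``; the skip count is logged at the end,
    mirroring the exclusion of partial genes and annotation errors from the
    source data.
    """
    sequences: list[CodingSequence] = []
    n_skipped = 0
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            sample, gene, isoform, allele = parse_header(record.id, delimiter)
            seq = CodingSequence.from_nucleotides(
                str(record.seq), sample, gene, isoform, allele
            )
        except SequenceValidationError as exc:
            if strict:
                raise
            logger.warning("skipping record %s: %s", record.id, exc)
            n_skipped += 1
            continue
        sequences.append(seq)
    logger.info("read %d sequences (%d skipped)", len(sequences), n_skipped)
    return sequences


def write_fasta(
    sequences: Iterable[CodingSequence], path: str | Path, delimiter: str = "|"
) -> int:
    """Write coding sequences to FASTA with the header convention."""
    records = [
        SeqRecord(
            Seq(seq.nucleotides),
            id=delimiter.join(
                [seq.sample_id, seq.gene_id, seq.isoform_id, str(seq.allele)]
            ),
            description="",
        )
        for seq in sequences
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_assignment(path: str | Path) -> PopulationAssignment:
    """Read a sample→population TSV (sample, subpopulation, superpopulation)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return PopulationAssignment.from_frame(frame)


def write_assignment(assignment: PopulationAssignment, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "sample": assignment.samples,
            "subpopulation": [assignment.subpopulation[s] for s in assignment.samples],
            "superpopulation": [
                assignment.superpopulation[s] for s in assignment.samples
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def _id_row(seq: CodingSequence) -> dict[str, object]:
    return {
        "sample": seq.sample_id,
        "gene": seq.gene_id,
        "isoform": seq.isoform_id,
        "allele": seq.allele,
    }


def frequency_table(sequences: Iterable[CodingSequence]) -> pd.DataFrame:
    """One row per sequence: identifiers then 64 codon-count columns."""
    rows = []
    for seq in sequences:
        table = count_codons(seq)
        row = _id_row(seq)
        row.update({c: table[c] for c in CODONS})
        rows.append(row)
    return pd.DataFrame(rows, columns=ID_COLUMNS + list(CODONS))


def aversion_table(
    sequences: Iterable[CodingSequence], include_stops: bool = True
) -> pd.DataFrame:
    """One row per sequence: identifiers, averted-codon count and list."""
    rows = []
    for seq in sequences:
        averted = sorted(averted_codons(count_codons(seq), include_stops))
        row = _id_row(seq)
        row["n_averted"] = len(averted)
        row["averted_codons"] = " ".join(averted)
        rows.append(row)
    return pd.DataFrame(rows, columns=ID_COLUMNS + ["n_averted", "averted_codons"])


def pairing_tables(
    sequences: Iterable[CodingSequence],
    window: int = DEFAULT_WINDOW,
    code: GeneticCode | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(identical, co-tRNA) pairing tables: 61 codon / 20 amino-acid columns."""
    code = code or standard_code()
    sense = list(code.sense_codons)
    aas = list(code.amino_acids)
    ident_rows, co_rows = [], []
    for seq in sequences:
        profile = pairing_profile(seq, window=window, code=code)
        row = _id_row(seq)
        ident_rows.append({**row, **{c: profile.identical[c] for c in sense}})
        co_rows.append({**row, **{a: profile.cotrna[a] for a in aas}})
    return (
        pd.DataFrame(ident_rows, columns=ID_COLUMNS + sense),
        pd.DataFrame(co_rows, columns=ID_COLUMNS + aas),
    )


def composition_table(sequences: Iterable[CodingSequence]) -> pd.DataFrame:
    """One row per sequence: A/C/G/T counts and GC fraction."""
    rows = []
    for seq in sequences:
        comp = composition(seq)
        row = _id_row(seq)
        row.update({b: comp.counts[b] for b in "ACGT"})
        row["gc_content"] = comp.gc_content
        rows.append(row)
    return pd.DataFrame(rows, columns=ID_COLUMNS + list("ACGT") + ["gc_content"])


def ramp_table(results: Iterable[tuple[CodingSequence, RampResult | None]]) -> pd.DataFrame:
    """One row per (sequence, ramp result); skipped genes yield no row."""
    rows = []
    for seq, result in results:
        if result is None:
            continue
        row = _id_row(seq)
        row.update(
            {
                "has_ramp": result.has_ramp,
                "ramp_length_nt": (
                    3 * result.ramp_end_codon if result.ramp_end_codon else 0
                ),
                "hmean_ramp": result.hmean_ramp,
                "hmean_gene": result.hmean_gene,
            }
        )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=ID_COLUMNS + ["has_ramp", "ramp_length_nt", "hmean_ramp", "hmean_gene"],
    )


@dataclass(frozen=True)
class VariantRecord:
    """One phased single-nucleotide variant in CDS coordinates (1-based)."""

    gene_id: str
    cds_position: int  # 1-based nucleotide position within the CDS
    ref: str
    alt: str
    genotypes: Mapping[str, tuple[int, int]]  # sample -> (allele1, allele2); 0=ref 1=alt

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise ValueError(f"{self.gene_id}: cds_position is 1-based, got {self.cds_position}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.gene_id}@{self.cds_position}: SNVs only")
        for sample, gt in self.genotypes.items():
            if len(gt) != 2 or any(a not in (0, 1) for a in gt):
                raise ValueError(
                    f"{self.gene_id}@{self.cds_position}: sample {sample} "
                    f"genotype {gt!r} is not a phased biallelic pair"
                )


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a long-format phased SNV CSV.

    Columns: gene, cds_position, ref, alt, sample, allele1, allele2.
    Unphased entries (e.g. missing allele columns) are rejected.
    """
    frame = pd.read_csv(path)
    required = {"gene", "cds_position", "ref", "alt", "sample", "allele1", "allele2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(
            f"variant table is missing columns {sorted(missing)}; phased "
            "allele1/allele2 columns are required (unphased input is not supported)"
        )
    if frame[["allele1", "allele2"]].isna().any().any():
        raise ValueError("variant table contains unphased/missing genotypes")
    records = []
    for (gene, pos, ref, alt), sub in frame.groupby(
        ["gene", "cds_position", "ref", "alt"], sort=True
    ):
        genotypes = {
            row["sample"]: (int(row["allele1"]), int(row["allele2"]))
            for _, row in sub.iterrows()
        }
        records.append(
            VariantRecord(
                gene_id=str(gene), cds_position=int(pos), ref=str(ref),
                alt=str(alt), genotypes=genotypes,
            )
        )
    return records


def materialize_haplotypes(
    reference: CodingSequence, variants: Sequence[VariantRecord]
) -> list[CodingSequence]:
    """Substitute each sample's phased alternate bases into the reference CDS.

    Returns two allele sequences per sample appearing in any variant.
    Variants whose reference base does not match the CDS raise an error
    naming the gene and position.
    """
    ref_nt = reference.nucleotides
    samples: set[str] = set()
    for v in variants:
        if v.gene_id != reference.gene_id:
            raise ValueError(
                f"variant gene {v.gene_id} does not match reference "
                f"{reference.gene_id}"
            )
        if v.cds_position > len(ref_nt):
            raise ValueError(
                f"{v.gene_id}@{v.cds_position}: position beyond CDS of "
                f"length {len(ref_nt)}"
            )
        found = ref_nt[v.cds_position - 1]
        if found != v.ref:
            raise ValueError(
                f"{v.gene_id}@{v.cds_position}: reference base is {found}, "
                f"variant claims {v.ref}"
            )
        samples.update(v.genotypes)

    out = []
    for sample in sorted(samples):
        for allele_idx in (0, 1):
            nt = list(ref_nt)
            for v in variants:
                gt = v.genotypes.get(sample, (0, 0))
                if gt[allele_idx] == 1:
                    nt[v.cds_position - 1] = v.alt
            out.append(
                CodingSequence.from_nucleotides(
                    "".join(nt),
                    sample_id=sample,
                    gene_id=reference.gene_id,
                    isoform_id=reference.isoform_id,
                    allele=allele_idx + 1,
                )
            )
    return out
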