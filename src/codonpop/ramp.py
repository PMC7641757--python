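"""Ramp-sequence detection from per-codon translational-speed proxies.

A ramp sequence is a stretch of slowly translated codons at the beginning of
a gene that spaces out initiating ribosomes and prevents collisions further
downstream.  Translational speed is proxied per codon by its relative
synonymous codon usage (RSCU) computed from a reference sequence set: common
synonyms are translated quickly, rare ones slowly.

Detection slides a ribosomal window (default nine codons) along the gene,
takes the harmonic mean speed in each window — the harmonic mean is the
natural average for ratios such as RSCU and is dominated by slow codons —
and flags a ramp when an outlier-slow window (below ``mean - outlier_z *
sd`` of all window means) starts within the leading fraction of the gene.
The reported ramp runs from the first codon through the end of the
contiguous outlier region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genetic_code import CODONS, GeneticCode, standard_code
from .metrics import DEFAULT_WINDOW, CodonCountTable, RscuTable, count_codons, rscu
from .sequences import CodingSequence

logger = logging.getLogger(__name__)

#: Leading fraction of the gene within which an outlier window must start.
DEFAULT_LEADING_FRACTION = 0.01

#: Number of standard deviations below the mean window speed that marks an
#: outlier-slow window.
DEFAULT_OUTLIER_Z = 2.0


@dataclass(frozen=True)
class SpeedProfile:
    """Per-codon translational speeds (positive reals) for one gene."""

    gene_id: str
    speeds: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.speeds):
            raise ValueError(f"{self.gene_id}: speeds must be strictly positive")

    def __len__(self) -> int:
        return len(self.speeds)


@dataclass(frozen=True)
class RampResult:
    """Outcome of ramp detection for one gene."""

    gene_id: str
    has_ramp: bool
    ramp_end_codon: int | None  # number of codons in the ramp
    ramp_nucleotides: str | None
    hmean_ramp: float | None
    hmean_gene: float


def harmonic_mean(values) -> float:
    """``n / sum(1/x_i)`` for strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("harmonic mean of an empty sequence is undefined")
    if np.any(arr <= 0):
        raise ValueError("harmonic mean requires strictly positive values")
    return arr.size / np.sum(1.0 / arr)


def reference_rscu(
    sequences, code: GeneticCode | None = None
) -> RscuTable:
    """Pooled RSCU table from a reference CDS collection.

    Mirrors the convention of computing reference codon usage from the
    longest isoform of every gene: counts are pooled across all supplied
    sequences before the RSCU formula is applied.
    """
    code = code or standard_code()
    pooled = dict.fromkeys(CODONS, 0)
    total = 0
    for seq in sequences:
        table = count_codons(seq)
        for codon, n in table.counts.items():
            pooled[codon] += n
        total += table.total_codons
    return rscu(CodonCountTable(counts=pooled, total_codons=total), code)


def speed_profile(
    seq: CodingSequence,
    reference: RscuTable,
    code: GeneticCode | None = None,
) -> SpeedProfile:
    """Per-codon speeds for *seq* from a reference RSCU table.

    Stop codons and codons with undefined reference RSCU are dropped from
    the profile (they carry no speed information).
    """
    code = code or standard_code()
    speeds = []
    for codon in seq.codons:
        if codon not in reference.rscu or code.is_stop(codon):
            continue
        value = reference.rscu[codon]
        if np.isfinite(value) and value > 0:
            speeds.append(float(value))
    return SpeedProfile(gene_id=seq.gene_id, speeds=tuple(speeds))


def window_speeds(profile: SpeedProfile, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Harmonic-mean speed of every contiguous *window*-codon stretch.

    Returns an array of length ``len(profile) - window + 1``.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    speeds = np.asarray(profile.speeds, dtype=float)
    if speeds.size < window:
        raise ValueError(
            f"{profile.gene_id}: gene of {speeds.size} codons is shorter "
            f"than the {window}-codon window"
        )
    # rolling sum of reciprocals -> harmonic mean per window
    recip = np.concatenate([[0.0], np.cumsum(1.0 / speeds)])
    window_recip_sums = recip[window:] - recip[:-window]
    return window / window_recip_sums


def detect_ramp(
    profile: SpeedProfile,
    window: int = DEFAULT_WINDOW,
    leading_fraction: float = DEFAULT_LEADING_FRACTION,
    outlier_z: float = DEFAULT_OUTLIER_Z,
    nucleotides: str | None = None,
) -> RampResult | None:
    """Detect a ramp sequence in a per-codon speed profile.

    A ramp is called when at least one window's harmonic-mean speed falls
    below ``mean - outlier_z * sd`` of all window means *and* that window
    starts within ``leading_fraction`` of the gene.  The ramp then spans the
    gene start through the end of the contiguous run of outlier windows
    containing the first qualifying window.

    Returns ``None`` (with a logged warning) for genes shorter than the
    window; such genes are skipped rather than failed.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if not 0 < leading_fraction <= 1:
        raise ValueError(
            f"leading_fraction must be in (0, 1], got {leading_fraction}"
        )
    if outlier_z <= 0:
        raise ValueError(f"outlier_z must be positive, got {outlier_z}")

    n = len(profile)
    if n < window:
        logger.warning(
            "%s: skipped, %d codons is shorter than the %d-codon window",
            profile.gene_id,
            n,
            window,
        )
        return None

    means = window_speeds(profile, window)
    hmean_gene = harmonic_mean(profile.speeds)
    threshold = means.mean() - outlier_z * means.std()
    outlier = means < threshold

    # window start indices qualifying as "the beginning of the gene"
    lead_limit = max(1, int(np.ceil(leading_fraction * n)))
    qualifying = np.flatnonzero(outlier[:lead_limit])
    if qualifying.size == 0:
        return RampResult(
            gene_id=profile.gene_id,
            has_ramp=False,
            ramp_end_codon=None,
            ramp_nucleotides=None,
            hmean_ramp=None,
            hmean_gene=hmean_gene,
        )

    # extend through the contiguous outlier run containing the first
    # qualifying window
    end = int(qualifying[0])
    while end + 1 < outlier.size and outlier[end + 1]:
        end += 1
    ramp_codons = end + window  # last codon covered by the final outlier window
    hmean_ramp = harmonic_mean(profile.speeds[:ramp_codons])
    ramp_nt = nucleotides[: 3 * ramp_codons] if nucleotides is not None else None
    return RampResult(
        gene_id=profile.gene_id,
        has_ramp=True,
        ramp_end_codon=ramp_codons,
        ramp_nucleotides=ramp_nt,
        hmean_ramp=hmean_ramp,
        hmean_gene=hmean_gene,
    )
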