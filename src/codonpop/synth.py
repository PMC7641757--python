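"""Synthetic cohorts of coding sequences with divergent codon preferences.

The generator emulates the object of study — populations that differ only
in *synonymous* codon choice — without any real genotype data:

* every gene has one amino-acid sequence shared by the whole cohort, so all
  variation between individuals is synonymous by construction;
* each population carries its own synonymous-codon probability vector per
  amino-acid family, drawn from a Dirichlet distribution centred on a
  shared base profile.  A single concentration knob (``divergence``)
  controls how far population profiles scatter from the base: large values
  collapse all populations onto the base profile, small values make them
  strongly distinct;
* every population has a *consensus* codon sequence per gene, drawn from
  its profile through common random numbers (one shared uniform per codon
  position, mapped through each profile's inverse CDF).  Populations with
  identical profiles therefore have byte-identical consensus sequences —
  shared ancestry — and consensus sequences diverge exactly where the
  profiles do;
* individuals carry their population's consensus with sparse synonymous
  mutations: each codon is independently resampled from the population
  profile with probability ``mutation_rate``, emulating the low per-site
  polymorphism of real cohorts.

Between-population differences are thus population-wide and systematic
while within-population differences are sparse and private, which is the
regime in which motif-set clustering operates on real genomes.

Ramp planting rewrites a leading block of codons to rare (low-RSCU)
synonyms so ramp detection can be exercised, and a small genotype simulator
draws diploid allele counts with population-specific allele frequencies for
the minor-allele-frequency / Tukey workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, standard_code
from .metrics import RscuTable
from .popstats import PopulationAssignment
from .sequences import CodingSequence


@dataclass(frozen=True)
class PopulationProfile:
    """Synonymous-codon probabilities for one population.

    ``probabilities`` maps each amino acid to a vector over its synonym
    family (codon order as in the genetic code table); each vector sums
    to 1.
    """

    name: str
    probabilities: Mapping[str, np.ndarray]

    def validate(self, code: GeneticCode) -> None:
        for aa, family in code.synonym_families.items():
            p = self.probabilities[aa]
            if len(p) != len(family):
                raise ValueError(f"{self.name}/{aa}: wrong family size")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{self.name}/{aa}: probabilities must sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults produce three strongly divergent populations of 40 haploid
    genomes with 50 genes of 300 codons each — large enough for the
    clustering pipeline to resolve populations, small enough to run in
    seconds.
    """

    n_populations: int = 3
    n_individuals: int = 40
    n_genes: int = 50
    n_codons: int = 300
    #: Dirichlet concentration around the base profile; 1.0 is a flat
    #: Dirichlet on every synonym family — strongly divergent populations.
    divergence: float = 1.0
    #: per-codon probability that an individual's codon is resampled from
    #: its population profile (sparse synonymous polymorphism).
    mutation_rate: float = 0.005
    #: number of leading codons rewritten to slow synonyms by plant_ramp
    ramp_prefix: int = 9
    #: slowdown multiplier for plant_ramp (1 = no slowdown)
    ramp_speed_factor: float = 1.0
    terminal_stop: bool = True
    seed: int = 0
    population_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("n_populations", "n_individuals", "n_genes", "n_codons"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.divergence <= 0:
            raise ValueError("divergence must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not self.population_names:
            object.__setattr__(
                self,
                "population_names",
                tuple(f"POP{i + 1}" for i in range(self.n_populations)),
            )
        if len(self.population_names) != self.n_populations:
            raise ValueError("population_names must match n_populations")


def base_profile(code: GeneticCode | None = None) -> PopulationProfile:
    """Uniform synonymous usage: every codon equally likely in its family."""
    code = code or standard_code()
    return PopulationProfile(
        name="base",
        probabilities={
            aa: np.full(len(family), 1.0 / len(family))
            for aa, family in code.synonym_families.items()
        },
    )


def sample_profiles(
    config: SimulationConfig,
    code: GeneticCode | None = None,
    rng: np.random.Generator | None = None,
) -> list[PopulationProfile]:
    """Draw one synonymous-usage profile per population.

    Family probabilities are Dirichlet-distributed around the (uniform)
    base profile with concentration ``divergence * family_size * base``;
    ``divergence = inf`` returns the base profile for every population.
    """
    code = code or standard_code()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    base = base_profile(code)
    profiles = []
    for name in config.population_names:
        probs: dict[str, np.ndarray] = {}
        for aa, family in code.synonym_families.items():
            b = base.probabilities[aa]
            if len(family) == 1:
                probs[aa] = np.array([1.0])
            elif np.isinf(config.divergence):
                probs[aa] = b.copy()
            else:
                probs[aa] = rng.dirichlet(config.divergence * len(family) * b)
        profile = PopulationProfile(name=name, probabilities=probs)
        profile.validate(code)
        profiles.append(profile)
    return profiles


def _consensus_codons(
    aa_idx: np.ndarray,
    u: np.ndarray,
    profile: PopulationProfile,
    amino_acids: Sequence[str],
    code: GeneticCode,
) -> np.ndarray:
    """Map shared uniforms through the profile's per-family inverse CDF.

    The same ``u`` vector fed through two identical profiles yields the
    same codons, so consensus sequences of equal-profile populations
    coincide exactly (common-random-number coupling).
    """
    codons = np.empty(aa_idx.size, dtype=object)
    for k in np.unique(aa_idx):
        aa = amino_acids[k]
        family = np.asarray(code.synonym_families[aa], dtype=object)
        cdf = np.cumsum(profile.probabilities[aa])
        idx = np.flatnonzero(aa_idx == k)
        codons[idx] = family[np.searchsorted(cdf, u[idx], side="right").clip(max=len(family) - 1)]
    return codons


def generate_cohort(
    config: SimulationConfig,
    profiles: Sequence[PopulationProfile] | None = None,
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], PopulationAssignment]:
    """Simulate the full cohort: sequences plus population assignment.

    One amino-acid sequence per gene is shared by every individual (drawn
    uniformly over the 20 amino acids), so all codon differences between
    individuals are synonymous.  Each population's per-gene consensus is
    drawn from its profile via common random numbers (identical profiles →
    identical consensus); each individual then resamples each codon from
    the population profile with probability ``mutation_rate``.  Individuals
    are haploid (allele 1); a terminal stop codon, shared per gene, is
    appended when configured.
    """
    code = code or standard_code()
    rng = np.random.default_rng(config.seed)
    if profiles is None:
        profiles = sample_profiles(config, code=code, rng=rng)
    amino_acids = code.amino_acids
    n_aa = config.n_codons - (1 if config.terminal_stop else 0)
    stops = code.stop_codons

    genes = []
    for g in range(config.n_genes):
        aa_idx = rng.integers(len(amino_acids), size=n_aa)
        u = rng.random(n_aa)
        stop = stops[rng.integers(len(stops))]
        consensus = {
            profile.name: _consensus_codons(aa_idx, u, profile, amino_acids, code)
            for profile in profiles
        }
        genes.append((aa_idx, stop, consensus))

    sequences: list[CodingSequence] = []
    sub: dict[str, str] = {}
    sup: dict[str, str] = {}
    for profile in profiles:
        for i in range(config.n_individuals):
            sample = f"{profile.name}_{i:03d}"
            sub[sample] = profile.name
            sup[sample] = profile.name
            for g, (aa_idx, stop, consensus) in enumerate(genes):
                codons = consensus[profile.name].copy()
                if config.mutation_rate > 0:
                    mutated = np.flatnonzero(rng.random(n_aa) < config.mutation_rate)
                    for pos in mutated:
                        aa = amino_acids[aa_idx[pos]]
                        family = code.synonym_families[aa]
                        codons[pos] = family[
                            rng.choice(len(family), p=profile.probabilities[aa])
                        ]
                codon_tuple = tuple(codons)
                if config.terminal_stop:
                    codon_tuple = codon_tuple + (stop,)
                sequences.append(
                    CodingSequence(
                        sample_id=sample,
                        gene_id=f"gene{g:03d}",
                        isoform_id="1",
                        allele=1,
                        codons=codon_tuple,
                    )
                )
    return sequences, PopulationAssignment(subpopulation=sub, superpopulation=sup)


def plant_ramp(
    codons: Sequence[str],
    reference: RscuTable,
    slow_prefix: int = 9,
    speed_factor: float = 4.0,
    code: GeneticCode | None = None,
) -> tuple[str, ...]:
    """Rewrite the first ``slow_prefix`` codons toward slow synonyms.

    Each prefix codon is replaced by the synonym whose reference RSCU is
    closest to ``rscu(codon) / speed_factor``; ``speed_factor = 1`` leaves
    the gene unchanged and large factors select the rarest synonym observed
    in the reference (codons never observed there carry no defined speed
    and are not used).  Stop codons and codons without a defined reference
    RSCU are left alone.
    """
    if slow_prefix >= len(codons):
        raise ValueError("slow_prefix must be smaller than the gene length")
    if speed_factor < 1:
        raise ValueError("speed_factor must be >= 1")
    code = code or standard_code()
    out = list(codons)
    for i in range(slow_prefix):
        codon = out[i]
        family = code.family_of(codon)
        if not family:
            continue
        current = reference.rscu.get(codon, float("nan"))
        if not np.isfinite(current) or current <= 0:
            continue
        target = current / speed_factor
        candidates = [
            c for c in family
            if np.isfinite(reference.rscu.get(c, float("nan")))
            and reference.rscu[c] > 0
        ]
        if candidates:
            out[i] = min(
                candidates, key=lambda c: (abs(reference.rscu[c] - target), c)
            )
    return tuple(out)


def generate_genotypes(
    allele_freqs: Mapping[str, float],
    n_per_group: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Diploid genotype table with group-specific alternate-allele frequencies.

    Each sample's alternate-allele count is Binomial(2, p_group).  Returns a
    DataFrame with columns sample, group, genotype.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(allele_freqs):
        p = allele_freqs[group]
        if not 0 <= p <= 1:
            raise ValueError(f"{group}: allele frequency {p} outside [0, 1]")
        counts = rng.binomial(2, p, size=n_per_group)
        for i, c in enumerate(counts):
            rows.append(
                {"sample": f"{group}_{i:03d}", "group": group, "genotype": int(c)}
            )
    return pd.DataFrame(rows)
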