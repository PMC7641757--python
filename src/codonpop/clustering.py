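"""Alignment-free population identification from codon motif sets.

Each gene contributes a *motif*: the sorted tuple of codons that either pair
at least once within the ribosomal window (pairing mode) or are entirely
absent from the gene (aversion mode).  A genome is summarised as the *set*
of its gene motifs — gene identity is deliberately discarded, so two genes
with identical motifs collapse to one element.  Genomes are compared by the
Jaccard distance between their motif sets, a neighbor-joining tree is built
from the distance matrix, and each population is scored by how few clades
its individuals fragment into:

    percent predictive accuracy = 100 * (1 - (n_clusters - 1) / n_individuals)

where a cluster is a maximal clade containing individuals of only that
population.  A population forming a single clade scores 100%.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .genetic_code import GeneticCode, standard_code
from .metrics import DEFAULT_WINDOW, averted_codons, count_codons, identical_pairing
from .popstats import PopulationAssignment
from .sequences import CodingSequence

logger = logging.getLogger(__name__)

MotifMode = Literal["pairing", "aversion"]

#: A gene motif: sorted, duplicate-free codon tuple.
GeneMotif = tuple[str, ...]


@dataclass(frozen=True)
class GenomeMotifSet:
    """All gene motifs of one genome, as a set (gene names discarded)."""

    sample_id: str
    motifs: frozenset[GeneMotif]


def gene_motif(
    seq: CodingSequence,
    mode: MotifMode = "pairing",
    window: int = DEFAULT_WINDOW,
    code: GeneticCode | None = None,
) -> GeneMotif:
    """Motif of one gene: paired codons (pairing) or absent codons (aversion).

    Pairing-mode motifs contain only sense codons; aversion-mode motifs draw
    on all 64 codons, stop codons included.
    """
    code = code or standard_code()
    if mode == "pairing":
        profile = identical_pairing(seq, window=window, code=code)
        return tuple(sorted(c for c, n in profile.identical.items() if n >= 1))
    if mode == "aversion":
        return tuple(sorted(averted_codons(count_codons(seq), include_stops=True)))
    raise ValueError(f"unknown motif mode {mode!r}")


def genome_motif_sets(
    sequences: Iterable[CodingSequence],
    mode: MotifMode = "pairing",
    window: int = DEFAULT_WINDOW,
    code: GeneticCode | None = None,
) -> list[GenomeMotifSet]:
    """Group sequences by sample and collect each sample's motif set."""
    code = code or standard_code()
    by_sample: dict[str, set[GeneMotif]] = {}
    for seq in sequences:
        by_sample.setdefault(seq.sample_id, set()).add(
            gene_motif(seq, mode=mode, window=window, code=code)
        )
    return [
        GenomeMotifSet(sample_id=s, motifs=frozenset(m))
        for s, m in sorted(by_sample.items())
    ]


def motif_distance(a: GenomeMotifSet, b: GenomeMotifSet) -> float:
    """Jaccard distance ``1 - |A ∩ B| / |A ∪ B|`` between motif sets."""
    union = a.motifs | b.motifs
    if not union:
        raise ValueError(
            f"distance between {a.sample_id} and {b.sample_id} is undefined: "
            "both motif sets are empty"
        )
    return 1.0 - len(a.motifs & b.motifs) / len(union)


def distance_matrix(
    motif_sets: Sequence[GenomeMotifSet],
    distance: Callable[[GenomeMotifSet, GenomeMotifSet], float] = motif_distance,
) -> DistanceMatrix:
    """Pairwise distances between all genomes, in sample-id order given."""
    ids = [m.sample_id for m in motif_sets]
    n = len(motif_sets)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = distance(motif_sets[i], motif_sets[j])
    return DistanceMatrix(mat, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining tree from a distance matrix.

    Negative branch lengths produced by the agglomeration are clamped to
    zero (with a log note); the skbio ``DistanceMatrix`` input already
    guarantees symmetry and a zero diagonal.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor-joining needs at least 3 samples")
    tree = nj(dm)
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative branch length(s) to zero", n_clamped)
    return tree


def count_population_clusters(
    tree: TreeNode,
    assignment: PopulationAssignment,
    level: str = "superpopulation",
    root: Literal["midpoint", "asis"] = "midpoint",
) -> dict[str, tuple[int, int]]:
    """Per population: (n individuals, n clusters) on the tree.

    A cluster is a maximal clade whose leaves all belong to one population —
    the largest discrete grouping uninterrupted by any other population.
    The unrooted neighbor-joining tree is rooted at the midpoint of its
    longest leaf-to-leaf path before counting (configurable via ``root``).
    """
    labels = {
        s: assignment.group_of(s, level) for s in assignment.samples
    }
    tips = [t.name for t in tree.tips()]
    unknown = [t for t in tips if t not in labels]
    if unknown:
        raise ValueError(f"tree leaves without population assignment: {unknown[:5]}")

    if root == "midpoint":
        tree = tree.root_at_midpoint()

    # post-order sweep: a node is "pure" when all its leaves share one
    # population; clusters are pure nodes whose parent is not pure
    pure: dict[int, str | None] = {}
    n_individuals: dict[str, int] = {}
    n_clusters: dict[str, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            label = labels[node.name]
            pure[id(node)] = label
            n_individuals[label] = n_individuals.get(label, 0) + 1
        else:
            child_labels = {pure[id(c)] for c in node.children}
            label = child_labels.pop() if len(child_labels) == 1 else None
            pure[id(node)] = label
            if label is None:
                for child in node.children:
                    child_label = pure[id(child)]
                    if child_label is not None:
                        n_clusters[child_label] = n_clusters.get(child_label, 0) + 1
    root_label = pure[id(tree)]
    if root_label is not None:  # whole tree is one population
        n_clusters[root_label] = 1
    return {
        pop: (n_individuals[pop], n_clusters.get(pop, 0))
        for pop in sorted(n_individuals)
    }


def percent_predictive_accuracy(n_clusters: int, n_individuals: int) -> float:
    """``100 * (1 - (n_clusters - 1) / n_individuals)``.

    Scores how completely a population forms a single clade: one cluster
    scores 100%, and every additional cluster costs ``100/n`` points.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    if not 1 <= n_clusters <= n_individuals:
        raise ValueError(
            f"n_clusters must be in [1, {n_individuals}], got {n_clusters}"
        )
    return 100.0 * (1.0 - (n_clusters - 1) / n_individuals)


def cluster_report(
    tree: TreeNode,
    assignment: PopulationAssignment,
    level: str = "superpopulation",
) -> pd.DataFrame:
    """Population / n individuals / n clusters / percent accuracy table."""
    counts = count_population_clusters(tree, assignment, level=level)
    rows = [
        {
            "population": pop,
            "n_individuals": n_ind,
            "n_clusters": n_clu,
            "percent_accuracy": percent_predictive_accuracy(n_clu, n_ind),
        }
        for pop, (n_ind, n_clu) in counts.items()
    ]
    return pd.DataFrame(rows)


def cluster_pipeline(
    sequences: Iterable[CodingSequence],
    assignment: PopulationAssignment,
    mode: MotifMode = "pairing",
    window: int = DEFAULT_WINDOW,
    level: str = "superpopulation",
    code: GeneticCode | None = None,
) -> tuple[TreeNode, pd.DataFrame]:
    """Sequences → motif sets → distances → NJ tree → cluster report."""
    motif_sets = genome_motif_sets(sequences, mode=mode, window=window, code=code)
    dm = distance_matrix(motif_sets)
    tree = neighbor_joining(dm)
    report = cluster_report(tree, assignment, level=level)
    return tree, report
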