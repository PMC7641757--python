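"""End-to-end pipeline: metrics → population statistics → clustering."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import clustering, io, popstats, ramp, synth
from .genetic_code import standard_code
from .metrics import DEFAULT_WINDOW

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``fasta`` (with ``assignment``) or ``simulate`` drives
    the run; all outputs land under ``outdir``.
    """

    outdir: str
    fasta: str | None = None
    assignment: str | None = None
    simulate: bool = False
    window: int = DEFAULT_WINDOW
    motif_mode: clustering.MotifMode = "pairing"
    alpha: float = 0.05
    leading_fraction: float = ramp.DEFAULT_LEADING_FRACTION
    outlier_z: float = ramp.DEFAULT_OUTLIER_Z
    seed: int = 0
    n_populations: int = 3
    n_individuals: int = 40
    n_genes: int = 50
    n_codons: int = 300
    divergence: float = 1.0


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = synth.SimulationConfig(
            n_populations=config.n_populations,
            n_individuals=config.n_individuals,
            n_genes=config.n_genes,
            n_codons=config.n_codons,
            divergence=config.divergence,
            seed=config.seed,
        )
        sequences, assignment = synth.generate_cohort(sim)
        return sequences, assignment
    if not config.fasta or not config.assignment:
        raise ValueError("either simulate=True or both fasta and assignment paths")
    sequences = io.read_fasta(config.fasta)
    assignment = io.read_assignment(config.assignment)
    return sequences, assignment


def compute_metrics(sequences, window: int = DEFAULT_WINDOW) -> dict[str, pd.DataFrame]:
    """All six per-gene metric tables for a sequence collection."""
    code = standard_code()
    ident, co = io.pairing_tables(sequences, window=window, code=code)
    reference = ramp.reference_rscu(sequences, code)
    ramp_results = []
    for seq in sequences:
        profile = ramp.speed_profile(seq, reference, code)
        result = (
            ramp.detect_ramp(profile, window=window, nucleotides=seq.nucleotides)
            if len(profile) >= window
            else None
        )
        ramp_results.append((seq, result))
    return {
        "frequency": io.frequency_table(sequences),
        "aversion": io.aversion_table(sequences),
        "pairing_identical": ident,
        "pairing_cotrna": co,
        "composition": io.composition_table(sequences),
        "ramp": io.ramp_table(ramp_results),
    }


def population_anova(
    metric_table: pd.DataFrame,
    assignment: popstats.PopulationAssignment,
    value_columns: list[str],
    alpha: float = 0.05,
    level: str = "superpopulation",
) -> pd.DataFrame:
    """Per-(gene, column) one-way ANOVA across populations.

    The Bonferroni threshold is computed from the number of tests actually
    run within this metric family.
    """
    labels = metric_table["sample"].map(
        lambda s: assignment.group_of(s, level)
    )
    cells = []
    for gene, sub in metric_table.groupby("gene", sort=True):
        sub_labels = labels.loc[sub.index]
        for col in value_columns:
            grouped = {
                g: sub.loc[sub_labels == g, col].to_numpy(dtype=float)
                for g in sorted(sub_labels.unique())
            }
            grouped = {g: v for g, v in grouped.items() if v.size >= 2}
            if len(grouped) < 2:
                continue
            cells.append((gene, col, grouped))
    if not cells:
        return pd.DataFrame(
            columns=["gene", "unit", "statistic", "p_value", "threshold", "significant"]
        )
    threshold = popstats.bonferroni_threshold(alpha, len(cells))
    rows = []
    for gene, col, grouped in cells:
        result = popstats.one_way_anova(
            popstats.GroupedValues.from_lists(grouped, gene=gene, codon=col),
            threshold=threshold,
        )
        rows.append(
            {
                "gene": gene,
                "unit": col,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "threshold": threshold,
                "significant": result.significant,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute metrics → stats → clustering and write all outputs.

    Returns a name → path map of everything written.  Output files: six
    metric CSVs, an ANOVA CSV per tested metric, the distance matrix CSV,
    the Newick tree and the cluster-report CSV, plus a JSON echo of the
    configuration for provenance.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    sequences, assignment = _load_inputs(config)
    logger.info("pipeline: %d sequences", len(sequences))
    if config.simulate:
        fasta_path = outdir / "cohort.fasta"
        io.write_fasta(sequences, fasta_path)
        outputs["cohort_fasta"] = fasta_path
        assign_path = outdir / "assignment.tsv"
        io.write_assignment(assignment, assign_path)
        outputs["assignment"] = assign_path

    tables = compute_metrics(sequences, window=config.window)
    for name, table in tables.items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        outputs[name] = path
        logger.info("wrote %s (%d rows)", path, len(table))

    code = standard_code()
    anova = population_anova(
        tables["frequency"], assignment, list(code.sense_codons), alpha=config.alpha
    )
    anova_path = outdir / "anova_frequency.csv"
    anova.to_csv(anova_path, index=False)
    outputs["anova_frequency"] = anova_path

    motif_sets = clustering.genome_motif_sets(
        sequences, mode=config.motif_mode, window=config.window
    )
    dm = clustering.distance_matrix(motif_sets)
    dm_path = outdir / "distances.csv"
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(dm_path)
    outputs["distances"] = dm_path

    tree = clustering.neighbor_joining(dm)
    tree_path = outdir / "tree.nwk"
    tree.write(str(tree_path))
    outputs["tree"] = tree_path

    report = clustering.cluster_report(tree, assignment)
    report_path = outdir / "cluster_report.csv"
    report.to_csv(report_path, index=False)
    outputs["cluster_report"] = report_path

    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(asdict(config), indent=2) + "\n")
    outputs["config"] = config_path
    return outputs
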