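"""End-to-end orchestration: reads -> genotypes -> dominance -> prediction
-> seed-set association.

The pipeline can run from a simulation scenario (generating reads or, for
panel-scale Monte-Carlo work, idealized depth profiles directly) or from
existing FASTQ files listed in a sample sheet.  Every stage's tables are
written as TSV when an output directory is given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alleles import AlleleDB
from .expression import (
    DominanceGraph,
    ExpressionProfile,
    infer_hierarchy,
    pairwise_dominance_calls,
    relative_scr_expression,
)
from .genotyping import (
    DepthProfile,
    GenotypeCall,
    assign_reads,
    build_kmer_index,
    call_genotype,
    filter_reads,
)
from .io import Read, read_fastq, write_tsv
from .prediction import (
    DEFAULT_FOCAL,
    DEFAULT_RULE2_THRESHOLD,
    CongruenceResult,
    PredictionRecord,
    congruence_table,
    predict_panel,
)
from .simulate import (
    SimScenario,
    TruthLedger,
    build_truth,
    hybrid_panel,
    make_allele_db,
    simulate_depth_profile,
    simulate_reads,
    true_phenotype,
)
from .stats import AssociationReport, association_report

logger = logging.getLogger("sdom")


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one pipeline run."""

    genotypes: dict[str, GenotypeCall]
    expression: dict[str, ExpressionProfile]
    hierarchy: DominanceGraph
    predictions: list[PredictionRecord]
    congruence: CongruenceResult
    association: AssociationReport | None
    truth: TruthLedger | None = None
    srk_profiles: dict[str, DepthProfile] = field(default_factory=dict)
    scr_profiles: dict[str, DepthProfile] = field(default_factory=dict)


def type_individual(
    reads: Sequence[Read],
    db: AlleleDB,
    gene: str,
    individual: str,
    k: int | None = None,
    use_filter: bool = True,
    **assign_kwargs,
) -> DepthProfile:
    """k-mer filter + local-alignment assignment for one read set."""
    n_filtered = 0
    index = build_kmer_index(db, gene, k)
    if use_filter:
        reads, n_filtered = filter_reads(reads, index)
    return assign_reads(
        reads, db, gene, individual=individual, n_filtered=n_filtered,
        index=index, **assign_kwargs
    )


def _profiles_for_panel(
    scenario: SimScenario, db: AlleleDB, read_level: bool
) -> tuple[dict[str, DepthProfile], dict[str, DepthProfile]]:
    srk_profiles: dict[str, DepthProfile] = {}
    scr_profiles: dict[str, DepthProfile] = {}
    for ind in scenario.individuals:
        for gene, store in (("SRK", srk_profiles), ("SCR", scr_profiles)):
            if read_level:
                reads, _ = simulate_reads(ind, db, scenario, gene)
                store[ind.id] = type_individual(reads, db, gene, ind.id)
            else:
                store[ind.id] = simulate_depth_profile(ind, db, scenario, gene)
    return srk_profiles, scr_profiles


def analyze_profiles(
    srk_profiles: Mapping[str, DepthProfile],
    scr_profiles: Mapping[str, DepthProfile],
    ploidies: Mapping[str, int],
    seed_counts: Mapping[str, int] | None = None,
    focal: str = DEFAULT_FOCAL,
    threshold: float = DEFAULT_RULE2_THRESHOLD,
    hierarchy: DominanceGraph | None = None,
) -> PipelineResult:
    """Genotype, expression, dominance, prediction and association stages,
    starting from depth profiles.

    When ``hierarchy`` is not given it is reconstructed from the panel's own
    pairwise expression asymmetries.
    """
    if not srk_profiles:
        raise ValueError("empty panel")
    genotypes: dict[str, GenotypeCall] = {}
    expression: dict[str, ExpressionProfile] = {}
    panel = []
    for ind_id, srk_profile in srk_profiles.items():
        genotype = call_genotype(srk_profile, ploidies[ind_id])
        genotypes[ind_id] = genotype
        if not genotype.alleles_present:
            continue
        expr = relative_scr_expression(scr_profiles[ind_id], genotype)
        expression[ind_id] = expr
        panel.append((genotype, expr))
    if hierarchy is None:
        calls = pairwise_dominance_calls(panel)
        hierarchy = infer_hierarchy(calls)
    predictions = predict_panel(panel, hierarchy, focal, threshold)
    congruence = congruence_table(predictions)
    association = None
    if seed_counts is not None:
        preds, seeds, shares = [], [], []
        for rec in predictions:
            if rec.individual not in seed_counts:
                continue
            preds.append(rec.rule1_call)
            seeds.append(seed_counts[rec.individual])
            shares.append(rec.rule2_statistic)
        association = association_report(preds, seeds, shares)
    return PipelineResult(
        genotypes=genotypes,
        expression=expression,
        hierarchy=hierarchy,
        predictions=predictions,
        congruence=congruence,
        association=association,
        srk_profiles=dict(srk_profiles),
        scr_profiles=dict(scr_profiles),
    )


def run_simulated_pipeline(
    scenario: SimScenario,
    db: AlleleDB | None = None,
    read_level: bool = True,
    out_dir: str | Path | None = None,
    focal: str = DEFAULT_FOCAL,
    threshold: float = DEFAULT_RULE2_THRESHOLD,
) -> PipelineResult:
    """Simulate a panel and run every downstream stage on it.

    ``read_level=True`` synthesizes FASTQ-level reads and pushes them through
    k-mer filtering and alignment; ``read_level=False`` converts multinomial
    read counts directly into depth profiles (fast path for replicated
    Monte-Carlo runs).
    """
    if not scenario.individuals:
        raise ValueError("scenario has no individuals")
    if db is None:
        db = make_allele_db(seed=scenario.seed)
    truth = build_truth(scenario)
    srk_profiles, scr_profiles = _profiles_for_panel(scenario, db, read_level)
    ploidies = {ind.id: ind.ploidy for ind in scenario.individuals}
    seed_counts = {e.individual: e.seed_count for e in truth}
    result = analyze_profiles(
        srk_profiles, scr_profiles, ploidies, seed_counts, focal, threshold
    )
    result.truth = truth
    if out_dir is not None:
        write_outputs(result, out_dir, scenario=scenario)
    return result


def default_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The default study-sized scenario: 27 diploid + 26 tetraploid hybrids."""
    individuals = hybrid_panel(seed=seed)
    return SimScenario(individuals=individuals, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# file-based entry point


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None):
    """Run the pipeline from a YAML config (or an equivalent mapping).

    Two modes:

    * ``mode: simulate`` — keys under ``scenario`` override
      :class:`SimScenario` defaults (panel sizes via ``n_diploid`` /
      ``n_tetraploid``); reads are simulated.
    * ``mode: files`` — requires ``srk_fasta``, ``scr_fasta`` and
      ``sample_sheet`` (TSV with columns individual, ploidy, seed_count,
      exclude, srk_fastq, scr_fastq); rows with a truthy ``exclude`` flag
      are dropped before analysis.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    out_dir = out_dir or config.get("out_dir")
    focal = config.get("focal", DEFAULT_FOCAL)
    threshold = float(config.get("threshold", DEFAULT_RULE2_THRESHOLD))
    mode = config.get("mode", "simulate")
    if mode == "simulate":
        params = dict(config.get("scenario", {}))
        seed = int(params.pop("seed", 0))
        n_diploid = int(params.pop("n_diploid", 27))
        n_tetraploid = int(params.pop("n_tetraploid", 26))
        individuals = hybrid_panel(
            seed=seed, n_diploid=n_diploid, n_tetraploid=n_tetraploid, focal=focal
        )
        scenario = SimScenario(individuals=individuals, seed=seed, **params)
        read_level = bool(config.get("read_level", True))
        return run_simulated_pipeline(
            scenario, read_level=read_level, out_dir=out_dir,
            focal=focal, threshold=threshold,
        )
    if mode != "files":
        raise ValueError(f"unknown pipeline mode {mode!r}")
    for key in ("srk_fasta", "scr_fasta", "sample_sheet"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    db = AlleleDB.from_fasta(config["srk_fasta"], config["scr_fasta"])
    sheet = pd.read_csv(config["sample_sheet"], sep="\t")
    required = {"individual", "ploidy", "seed_count", "srk_fastq", "scr_fastq"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    if "exclude" in sheet.columns:
        sheet = sheet[~sheet["exclude"].astype(bool)]
    if sheet.empty:
        raise ValueError("sample sheet has no usable rows")
    srk_profiles, scr_profiles, ploidies, seed_counts = {}, {}, {}, {}
    for row in sheet.itertuples(index=False):
        ind = str(row.individual)
        ploidies[ind] = int(row.ploidy)
        seed_counts[ind] = int(row.seed_count)
        srk_profiles[ind] = type_individual(
            read_fastq(row.srk_fastq), db, "SRK", ind
        )
        scr_profiles[ind] = type_individual(
            read_fastq(row.scr_fastq), db, "SCR", ind
        )
    result = analyze_profiles(
        srk_profiles, scr_profiles, ploidies, seed_counts, focal, threshold
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# output writers


def profiles_frame(profiles: Mapping[str, DepthProfile]) -> pd.DataFrame:
    rows = []
    for ind, prof in profiles.items():
        for allele, depth in sorted(prof.mean_depth.items()):
            rows.append(
                {
                    "individual": ind,
                    "gene": prof.gene,
                    "allele": allele,
                    "mean_depth": depth,
                    "n_reads_assigned": prof.n_reads_assigned,
                    "n_reads_filtered_out": prof.n_reads_filtered_out,
                }
            )
    return pd.DataFrame(rows)


def genotypes_frame(genotypes: Mapping[str, GenotypeCall]) -> pd.DataFrame:
    rows = []
    for ind, g in genotypes.items():
        copies = ";".join(
            f"{a}={'UNKNOWN' if g.copy_numbers.get(a) is None else g.copy_numbers[a]}"
            for a in sorted(g.alleles_present)
        )
        rows.append(
            {
                "individual": ind,
                "ploidy": g.ploidy,
                "alleles_present": ";".join(sorted(g.alleles_present)),
                "copy_numbers": copies,
                "confident": g.confident,
                "status": g.status,
            }
        )
    return pd.DataFrame(rows)


def expression_frame(expression: Mapping[str, ExpressionProfile]) -> pd.DataFrame:
    rows = []
    for ind, e in expression.items():
        for allele, share in sorted(e.relative_depth.items()):
            rows.append(
                {
                    "individual": ind,
                    "allele": allele,
                    "relative_depth": share,
                    "dominant": int(allele in e.co_dominant),
                }
            )
    return pd.DataFrame(rows)


def edges_frame(hierarchy: DominanceGraph) -> pd.DataFrame:
    rows = [
        {
            "winner": w,
            "loser": l,
            "support": d.get("support", 0),
            "conflict": d.get("conflict", 0),
        }
        for w, l, d in hierarchy.graph.edges(data=True)
    ]
    return pd.DataFrame(rows)


def predictions_frame(predictions: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual": r.individual,
                "rule1": r.rule1_call,
                "rule2": r.rule2_call,
                "rule2_statistic": r.rule2_statistic,
                "congruent": r.congruent,
            }
            for r in predictions
        ]
    )


def write_outputs(
    result: PipelineResult, out_dir: str | Path, scenario: SimScenario | None = None
) -> None:
    """Write every stage's tables, the hierarchy and a JSON run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.srk_profiles:
        write_tsv(profiles_frame(result.srk_profiles), out / "srk_profiles.tsv")
    if result.scr_profiles:
        write_tsv(profiles_frame(result.scr_profiles), out / "scr_profiles.tsv")
    write_tsv(genotypes_frame(result.genotypes), out / "genotypes.tsv")
    write_tsv(expression_frame(result.expression), out / "expression.tsv")
    write_tsv(edges_frame(result.hierarchy), out / "dominance_edges.tsv")
    with open(out / "hierarchy.txt", "w") as fh:
        if result.hierarchy.linear_order:
            fh.write("\n".join(result.hierarchy.linear_order) + "\n")
    write_tsv(predictions_frame(result.predictions), out / "predictions.tsv")
    if result.truth is not None:
        result.truth.to_tsv(out / "truth.tsv")
    report = {
        "n_individuals": len(result.genotypes),
        "hierarchy_acyclic": result.hierarchy.acyclic,
        "linear_order": result.hierarchy.linear_order,
        "rule_agreement": result.congruence.agreement,
        "congruence_counts": {
            f"{a}/{b}": n for (a, b), n in result.congruence.counts.items()
        },
    }
    if scenario is not None:
        report["scenario"] = {
            "n_individuals": len(scenario.individuals),
            "silencing_epsilon": scenario.silencing_epsilon,
            "target_depth": scenario.target_depth,
            "read_length": scenario.read_length,
            "error_rate": scenario.error_rate,
            "seed": scenario.seed,
        }
    if result.association is not None:
        report["fisher_p_2x3"] = result.association.fisher_p_2x3
        report["fisher_p_2x2"] = result.association.fisher_p_2x2
        if result.association.kruskal is not None:
            report["kruskal_H"] = result.association.kruskal.H_statistic
            report["kruskal_p"] = result.association.kruskal.p_value
        report["seed_table"] = result.association.table.to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline outputs written to %s", out)


# ---------------------------------------------------------------------------
# null calibration


def null_fisher_pvalues(
    n_replicates: int,
    seed: int = 0,
    n_diploid: int = 27,
    n_tetraploid: int = 26,
    sc_prob: float = 0.5,
) -> np.ndarray:
    """Fisher p-values under prediction-independent seed counts.

    Each replicate draws a fresh hybrid panel, predicts SC/SI from the true
    genotypes under the generating hierarchy, then assigns seed counts from
    an independent coin flip (probability ``sc_prob`` of drawing from the
    high-count distribution) so the null of no association holds exactly.
    Returns the 2x3 exact-test p-value per replicate.
    """
    from .simulate import _sub_rng, simulate_seed_set
    from .stats import categorize_seed_set, contingency_table, fisher_exact

    scenario = SimScenario(seed=seed)
    pvals = np.empty(n_replicates)
    for rep in range(n_replicates):
        individuals = hybrid_panel(
            seed=seed * 1_000_003 + rep, n_diploid=n_diploid, n_tetraploid=n_tetraploid
        )
        rng = _sub_rng(seed, "null", rep)
        preds, cats = [], []
        for ind in individuals:
            preds.append(true_phenotype(ind.genotype, scenario.hierarchy))
            coin = "SC" if rng.random() < sc_prob else "SI"
            cats.append(categorize_seed_set(simulate_seed_set(coin, scenario, rng)))
        pvals[rep] = fisher_exact(contingency_table(preds, cats).to_numpy())
    return pvals
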