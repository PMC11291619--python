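"""Allele-specific SCR expression and dominance-hierarchy reconstruction.

Small non-coding RNAs produced by dominant S-haplotypes transcriptionally
silence the *SCR* gene of recessive haplotypes, so in most heterozygotes a
single allele contributes the overwhelming majority of SCR transcripts.  The
identity of that predominantly expressed allele is therefore a direct
read-out of phenotypic dominance in pollen.

This module (1) converts per-allele SCR read depths into relative expression
shares over the alleles an individual actually carries, (2) turns each
individual's dominant allele into pairwise "winner beats loser" observations,
and (3) aggregates those observations across a panel into a directed
dominance graph, reporting the implied linear hierarchy when the relation is
acyclic and total, and flagging cycles, unresolved pairs and edges that
contradict the a-priori dominance classes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .alleles import parse_allele_name
from .genotyping import DepthProfile, GenotypeCall


@dataclass
class ExpressionProfile:
    """Relative SCR expression over the alleles present in one individual.

    ``relative_depth`` holds each present allele's share of the summed mean
    read depth; shares sum to 1.  ``co_dominant`` lists all alleles whose
    share ties the maximum (within tolerance); it has one element in the
    usual, fully silenced case.  ``status`` is ``"no_expression"`` when the
    summed depth is zero (shares undefined).
    """

    individual: str
    relative_depth: dict[str, float]
    dominant_allele: str | None
    dominant_share: float
    co_dominant: tuple[str, ...] = ()
    status: str = "ok"

    @property
    def is_tie(self) -> bool:
        return len(self.co_dominant) > 1


def relative_scr_expression(
    profile: DepthProfile,
    genotype: GenotypeCall,
    tie_tol: float = 1e-6,
) -> ExpressionProfile:
    """Compute each present allele's share of total SCR read depth.

    Only alleles in ``genotype.alleles_present`` enter the denominator;
    depth observed for alleles outside the called genotype is ignored as
    cross-mapping noise.  The dominant allele is the arg-max share; shares
    within ``tie_tol`` of the maximum are reported as co-dominant.
    """
    present = sorted(genotype.alleles_present)
    if not present:
        raise ValueError(f"{genotype.individual}: genotype has no alleles present")
    depths = {a: max(profile.mean_depth.get(a, 0.0), 0.0) for a in present}
    total = sum(depths.values())
    if total <= 0.0:
        return ExpressionProfile(
            individual=genotype.individual,
            relative_depth={a: 0.0 for a in present},
            dominant_allele=None,
            dominant_share=0.0,
            status="no_expression",
        )
    shares = {a: d / total for a, d in depths.items()}
    top = max(shares.values())
    co = tuple(sorted(a for a, s in shares.items() if top - s <= tie_tol))
    return ExpressionProfile(
        individual=genotype.individual,
        relative_depth=shares,
        dominant_allele=co[0] if len(co) == 1 else None,
        dominant_share=top,
        co_dominant=co,
    )


def focal_vs_others_ratio(expr: ExpressionProfile, focal: str) -> float:
    """Depth of the focal allele over the summed depth of the *other* alleles.

    A companion statistic to the share-of-total ``relative_depth`` (which
    includes the focal allele in its denominator); infinite when the focal
    allele is the only one expressed.
    """
    focal_share = expr.relative_depth.get(focal, 0.0)
    rest = sum(s for a, s in expr.relative_depth.items() if a != focal)
    if rest <= 0.0:
        return float("inf") if focal_share > 0 else 0.0
    return focal_share / rest


@dataclass(frozen=True)
class PairwiseCall:
    """Aggregated dominance observations for one allele pair.

    ``n_support`` observations agree with the majority direction
    (``winner`` over ``loser``); ``n_conflict`` disagree.  ``resolved`` is
    False on an exact tie, in which case the direction is arbitrary
    (lexicographic) and must not be used.
    """

    winner: str
    loser: str
    n_support: int
    n_conflict: int
    resolved: bool


def pairwise_dominance_calls(
    panel: Sequence[tuple[GenotypeCall, ExpressionProfile]],
    majority_threshold: float = 0.5,
) -> list[PairwiseCall]:
    """Collect per-pair dominance observations across a panel.

    For each individual, the dominant allele *d* is observed to beat every
    other distinct allele present; co-dominant maxima each beat the
    non-maximal alleles but contribute no observation between themselves.
    Per unordered pair, the direction supported by a strict majority
    (fraction > ``majority_threshold``) wins; exact ties are unresolved.
    Pairs never observed together are absent from the output.
    """
    if not panel:
        return []
    direction_counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for genotype, expr in panel:
        if expr.status != "ok":
            continue
        winners = expr.co_dominant if expr.co_dominant else ()
        if not winners:
            continue
        losers = [a for a in genotype.alleles_present if a not in winners]
        for w in winners:
            for o in losers:
                key = (min(w, o), max(w, o))
                direction_counts[key][(w, o)] += 1
    calls = []
    for (a, b), counts in sorted(direction_counts.items()):
        n_ab = counts.get((a, b), 0)
        n_ba = counts.get((b, a), 0)
        total = n_ab + n_ba
        if n_ab == n_ba:
            calls.append(PairwiseCall(a, b, n_ab, n_ba, resolved=False))
            continue
        winner, loser = (a, b) if n_ab > n_ba else (b, a)
        support = max(n_ab, n_ba)
        conflict = min(n_ab, n_ba)
        resolved = support / total > majority_threshold
        calls.append(PairwiseCall(winner, loser, support, conflict, resolved))
    return calls


@dataclass
class DominanceGraph:
    """Directed pairwise dominance relation over a panel's alleles.

    ``linear_order`` (most dominant first) is present only when the majority
    relation is acyclic and every node pair is connected by a directed path;
    otherwise it is ``None``.  ``class_violations`` lists resolved edges in
    which a lower-class allele dominates a higher-class one.
    """

    graph: nx.DiGraph
    acyclic: bool
    linear_order: list[str] | None
    cycles: list[list[str]] = field(default_factory=list)
    unresolved: list[tuple[str, str]] = field(default_factory=list)
    class_violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def dominates(self, a: str, b: str) -> bool:
        """True when a directed path of majority edges leads from a to b."""
        return (
            a in self.graph
            and b in self.graph
            and nx.has_path(self.graph, a, b)
        )

    def comparable(self, a: str, b: str) -> bool:
        return self.dominates(a, b) or self.dominates(b, a)


def linear_hierarchy(order: Sequence[str]) -> DominanceGraph:
    """Dominance graph for a known linear order (most dominant first)."""
    graph = nx.DiGraph()
    graph.add_nodes_from(order)
    graph.add_edges_from(zip(order, order[1:]))
    return DominanceGraph(graph=graph, acyclic=True, linear_order=list(order))


def infer_hierarchy(
    calls: Iterable[PairwiseCall],
    classes: Mapping[str, int] | None = None,
) -> DominanceGraph:
    """Aggregate pairwise majority calls into a dominance graph.

    Only resolved calls contribute edges.  If the graph is acyclic and the
    transitive closure makes every node pair comparable, the unique
    topological order is emitted as the linear hierarchy.  Cycles are
    reported, never silently broken, and dominance classes (derived from the
    allele names when not given) are used only to report inconsistencies,
    never to force an edge direction.
    """
    calls = list(calls)
    graph = nx.DiGraph()
    unresolved = []
    for c in calls:
        graph.add_node(c.winner)
        graph.add_node(c.loser)
        if not c.resolved:
            unresolved.append((c.winner, c.loser))
            continue
        graph.add_edge(c.winner, c.loser, support=c.n_support, conflict=c.n_conflict)
    acyclic = nx.is_directed_acyclic_graph(graph)
    cycles: list[list[str]] = []
    linear_order = None
    if not acyclic:
        cycles = [list(c) for c in nx.simple_cycles(graph)]
    else:
        closure = nx.transitive_closure_dag(graph)
        order = list(nx.topological_sort(graph))
        total = all(
            closure.has_edge(order[i], order[j])
            for i in range(len(order))
            for j in range(i + 1, len(order))
        )
        if total and order:
            linear_order = order
    violations = []
    if classes is None:
        classes = {}
        for node in graph.nodes:
            try:
                classes[node] = parse_allele_name(node)[0]
            except ValueError:
                pass
    for w, l in graph.edges:
        if w in classes and l in classes and classes[w] < classes[l]:
            violations.append((w, l))
    return DominanceGraph(
        graph=graph,
        acyclic=acyclic,
        linear_order=linear_order,
        cycles=cycles,
        unresolved=unresolved,
        class_violations=sorted(violations),
    )
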