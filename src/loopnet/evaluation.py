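"""Edge-sign annotation and network evaluation statistics.

Covers: Pearson-correlation sign inference at a strict |r| threshold,
per-node F1 against a reference interaction catalog, global precision,
prior-recovery enrichment odds ratios (per probability bin, binding
topology or prior type), DRE–PRE loop geometry summaries, and the Jaccard
consistency between two networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionData, GeneNetwork, PriorTable, RegulatoryLandscape

__all__ = [
    "NodeConfusion",
    "EnrichmentResult",
    "infer_edge_signs",
    "node_f1",
    "network_precision",
    "prior_recovery_enrichment",
    "dre_pre_geometry_summary",
    "network_consistency",
]


def infer_edge_signs(
    network: GeneNetwork, expr: ExpressionData, threshold: float = 0.1
) -> GeneNetwork:
    """Sign each edge from the regulator–target Pearson correlation.

    An edge is activation (+1) when r > ``threshold``, inhibition (−1)
    when r < −``threshold``, and unsigned (0) otherwise — the inequality
    is strict, so |r| exactly at the threshold stays unsigned.  The signed
    copy records per-edge r values and the activation:inhibition ratio in
    its metadata.
    """
    signed = network.copy()
    edge_r: dict[tuple[str, str], float] = {}
    n_act = n_inh = 0
    for u, v in sorted(network.edges):
        x, y = expr.row(u), expr.row(v)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"zero-variance gene on edge ({u}, {v}); left unsigned")
            signed.signs[(u, v)] = 0
            edge_r[(u, v)] = float("nan")
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        edge_r[(u, v)] = r
        if r > threshold:
            signed.signs[(u, v)] = 1
            n_act += 1
        elif r < -threshold:
            signed.signs[(u, v)] = -1
            n_inh += 1
        else:
            signed.signs[(u, v)] = 0
    signed.metadata["edge_r"] = edge_r
    signed.metadata["n_activation"] = n_act
    signed.metadata["n_inhibition"] = n_inh
    signed.metadata["activation_inhibition_ratio"] = (n_act / n_inh) if n_inh else math.inf
    return signed


@dataclass(frozen=True)
class NodeConfusion:
    """Outgoing-link confusion counts and F1 for one node."""

    node: str
    tp: int
    fp: int
    fn: int

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")


def _reference_lookup(reference, directed: bool):
    if directed:
        ref = {tuple(p) for p in reference}
        return ref, lambda u, v: (u, v) in ref
    ref = {frozenset(p) for p in reference}
    return ref, lambda u, v: frozenset((u, v)) in ref


def node_f1(
    network: GeneNetwork,
    reference,
    directed: bool = False,
) -> list[NodeConfusion]:
    """Per-node F1 = 2·TP/(2·TP+FP+FN) over outgoing links.

    TP/FP count the node's outgoing network links present/absent in the
    reference catalog; FN counts reference links from the node missing in
    the network.  Reference pairs are treated as undirected by default
    (functional-interaction catalogs); set ``directed=True`` for TF-target
    catalogs.  Nodes with no outgoing links and no reference links are
    excluded; an empty reference yields an empty result.
    """
    reference = list(reference)
    if not reference:
        return []
    _, in_ref = _reference_lookup(reference, directed)
    out_links: dict[str, set[str]] = {n: set() for n in network.nodes}
    for u, v in network.edges:
        out_links[u].add(v)
    ref_from: dict[str, set[str]] = {}
    for pair in reference:
        if directed:
            u, v = pair
            ref_from.setdefault(u, set()).add(v)
        else:
            u, v = tuple(pair)
            ref_from.setdefault(u, set()).add(v)
            ref_from.setdefault(v, set()).add(u)
    results = []
    for node in network.nodes:
        outs = out_links[node]
        refs = ref_from.get(node, set())
        if not outs and not refs:
            continue
        tp = sum(1 for v in outs if in_ref(node, v))
        fp = len(outs) - tp
        fn = sum(
            1
            for v in refs
            if v not in outs and not (not directed and node in out_links.get(v, set()))
        )
        results.append(NodeConfusion(node, tp, fp, fn))
    return results


def network_precision(network: GeneNetwork, reference, directed: bool = False) -> float:
    """Global precision TP/(TP+FP) over all edges; NaN when edgeless."""
    if not network.edges:
        warnings.warn("network has no edges; precision undefined")
        return float("nan")
    _, in_ref = _reference_lookup(list(reference), directed)
    tp = sum(1 for u, v in network.edges if in_ref(u, v))
    return tp / len(network.edges)


@dataclass(frozen=True)
class EnrichmentResult:
    """Recovery enrichment for one class of prior relationships."""

    label: str
    n_prior: int
    recovered_fraction: float
    expected_fraction: float

    @property
    def odds_ratio(self) -> float:
        if self.expected_fraction == 0:
            return float("inf") if self.recovered_fraction > 0 else float("nan")
        return self.recovered_fraction / self.expected_fraction


DEFAULT_PROBABILITY_BINS = (0.0, 0.25, 0.5, 0.75, 1.0 + 1e-12)


def prior_recovery_enrichment(
    prior: PriorTable,
    functional: GeneNetwork,
    bins: tuple[float, ...] = DEFAULT_PROBABILITY_BINS,
    group_by: str = "probability_bin",
) -> list[EnrichmentResult]:
    """Enrichment odds ratio of prior recovery in the functional network.

    Per class: recovered_fraction = |prior pairs retained as functional
    edges| / |prior pairs in class|; expected_fraction = |functional
    edges| / |all ordered gene pairs| over the functional network's gene
    universe; odds_ratio = recovered / expected.  ``group_by`` selects the
    class structure: ``probability_bin`` (half-open bins over the prior
    probability, last bin closed), ``topology`` or ``prior_type``
    (tf vs eqtl).  Empty classes are omitted.
    """
    n = len(functional.nodes)
    if n < 2:
        raise ValueError("functional network needs at least 2 nodes")
    expected = len(functional.edges) / (n * (n - 1))
    edges = functional.edges

    groups: dict[str, list] = {}
    for e in prior:
        if group_by == "probability_bin":
            j = np.searchsorted(bins, e.probability, side="right") - 1
            j = min(max(j, 0), len(bins) - 2)
            label = f"[{bins[j]:g},{min(bins[j + 1], 1.0):g})"
        elif group_by == "topology":
            label = "eqtl" if isinstance(e.cls, str) else e.cls[2]
        elif group_by == "prior_type":
            label = e.cls if isinstance(e.cls, str) else "tf"
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        groups.setdefault(label, []).append(e)

    out = []
    for label in sorted(groups):
        members = groups[label]
        rec = sum(1 for e in members if (e.regulator, e.target) in edges) / len(members)
        out.append(EnrichmentResult(label, len(members), rec, expected))
    return out


DISTANCE_BANDS = (0, 50_000, 100_000, 200_000, 500_000, 1_000_000)


def _distance_band(d: float) -> str:
    for lo, hi in zip(DISTANCE_BANDS, DISTANCE_BANDS[1:]):
        if lo <= d < hi:
            return f"{lo // 1000}-{hi // 1000}kb"
    return ">=1Mb"


def dre_pre_geometry_summary(
    landscape: RegulatoryLandscape,
    prior_pairs: set | None = None,
    functional_pairs: set | None = None,
    gene_body_span: int = 30_000,
) -> pd.DataFrame:
    """Positioning and distance of every DRE–PRE loop in the landscape.

    Each loop with a DRE anchor and a PRE anchor yields one row with the
    anchor midpoint distance (NaN for inter-chromosomal loops), a
    positioning category (``intragenic`` when the DRE midpoint lies within
    ``gene_body_span`` downstream of any TSS, distance band otherwise,
    ``inter_chromosomal`` across chromosomes) and, when regulator→target
    pair sets are supplied, whether the loop supports a prior and/or
    functional pair (TF bound at the DRE, target = the looped PRE's gene).
    """
    tfs_on: dict[str, set[str]] = {}
    for ev in landscape.binding_events:
        tfs_on.setdefault(ev.element, set()).add(ev.tf)
    genes_by_chrom: dict[str, list] = {}
    for g in landscape.genes.values():
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for a, b in landscape.loops:
        ea, eb = landscape.elements[a], landscape.elements[b]
        if {ea.kind, eb.kind} != {"DRE", "PRE"}:
            continue
        dre, pre = (ea, eb) if ea.kind == "DRE" else (eb, ea)
        target = landscape.gene_of_pre(pre.name)
        if dre.chrom != pre.chrom:
            dist, category = float("nan"), "inter_chromosomal"
        else:
            dist = abs(dre.midpoint - pre.midpoint)
            intragenic = any(
                (g.tss <= dre.midpoint < g.tss + gene_body_span)
                if g.strand == "+"
                else (g.tss - gene_body_span < dre.midpoint <= g.tss)
                for g in genes_by_chrom.get(dre.chrom, [])
            )
            category = "intragenic" if intragenic else _distance_band(dist)
        bound = sorted(tfs_on.get(dre.name, ()))
        in_prior = in_functional = False
        if target is not None:
            if prior_pairs is not None:
                in_prior = any((tf, target) in prior_pairs for tf in bound)
            if functional_pairs is not None:
                in_functional = any((tf, target) in functional_pairs for tf in bound)
        rows.append(
            dict(
                dre=dre.name,
                pre=pre.name,
                target_gene=target,
                distance=dist,
                category=category,
                in_prior=in_prior,
                in_functional=in_functional,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dre",
            "pre",
            "target_gene",
            "distance",
            "category",
            "in_prior",
            "in_functional",
        ],
    )


def network_consistency(a: GeneNetwork, b: GeneNetwork) -> float:
    """Jaccard similarity of the two edge sets; 1.0 when both are empty."""
    union = a.edges | b.edges
    if not union:
        return 1.0
    return len(a.edges & b.edges) / len(union)
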