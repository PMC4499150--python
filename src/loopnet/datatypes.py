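"""Core data containers shared across the loopnet pipeline.

The pipeline moves through a small set of in-memory objects:

* :class:`RegulatoryLandscape` — genes/TSSs, proximal (PRE) and distal (DRE)
  regulatory elements, chromatin loops between elements, and TF binding
  events with their evidence (ChIP peak vs motif-in-DHS) and cell-context
  (same cell type vs other cell type) labels.
* :class:`PriorTable` — regulator→target pairs with a prior probability and
  the evidence class that produced it.
* :class:`ExpressionData` / :class:`DiscreteExpression` — continuous and
  k-level discretized gene-by-sample matrices.
* :class:`GeneNetwork` — a directed graph over gene symbols, optionally
  signed (activation / inhibition) and carrying per-edge support counts.
* :class:`TrueNetwork`, :class:`CohortData`, :class:`DrugResponseSet` —
  synthetic ground truth and downstream clinical-style inputs.

Genomic coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "TOPOLOGIES",
    "BindingEvent",
    "Gene",
    "Element",
    "RegulatoryLandscape",
    "ProbabilityAssignment",
    "PriorEdge",
    "PriorTable",
    "GeneNetwork",
    "ExpressionData",
    "DiscreteExpression",
    "TrueNetwork",
    "Mutation",
    "CohortData",
    "DrugResponseSet",
]

#: Binding topologies, ordered from the most direct (a TF sitting on the
#: target's own promoter-proximal element) to the longest tether (a distal
#: element looped to a promoter that is itself looped to the target's
#: promoter).  The order is also the tie-break order when one pair is
#: supported by several classes with equal prior probability.
TOPOLOGIES = (
    "PRE_direct",
    "DRE_loop_PRE",
    "PRE_loop_PRE",
    "DRE_loop_PRE_loop_PRE",
)

EVIDENCE_KINDS = ("chip", "motif")
CELL_CONTEXTS = ("same_cell", "cross_cell")


@dataclass(frozen=True)
class BindingEvent:
    """One TF binding observation on a regulatory element.

    ``evidence`` is ``"chip"`` for a ChIP-seq peak and ``"motif"`` for a
    cognate motif inside a DNase hypersensitive site.  ``cell_context``
    records whether the observation comes from the modeled cell type or was
    transferred from another cell type; transferred (cross-cell) evidence
    only counts when the element lies in accessible chromatin in the
    modeled cells (``accessible``).
    """

    tf: str
    element: str
    evidence: str
    cell_context: str
    accessible: bool = True

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.evidence!r}")
        if self.cell_context not in CELL_CONTEXTS:
            raise ValueError(f"unknown cell context {self.cell_context!r}")


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    strand: str
    tss: int


@dataclass(frozen=True)
class Element:
    """A regulatory element interval; ``kind`` is ``"PRE"`` or ``"DRE"``."""

    name: str
    kind: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("PRE", "DRE"):
            raise ValueError(f"element kind must be PRE or DRE, got {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"element {self.name}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class RegulatoryLandscape:
    """Genes, regulatory elements, chromatin loops and TF binding events."""

    def __init__(
        self,
        genes: Iterable[Gene],
        elements: Iterable[Element],
        pre_gene: Mapping[str, str],
        loops: Iterable[tuple[str, str]],
        binding_events: Iterable[BindingEvent],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.genes: dict[str, Gene] = {g.name: g for g in genes}
        self.elements: dict[str, Element] = {e.name: e for e in elements}
        #: PRE element id -> the single gene it is assigned to.
        self.pre_gene: dict[str, str] = dict(pre_gene)
        #: unordered anchor pairs, stored sorted for determinism.
        self.loops: list[tuple[str, str]] = [tuple(sorted(l)) for l in loops]
        self.binding_events: list[BindingEvent] = list(binding_events)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes or {})
        self._partners: dict[str, list[str]] | None = None
        self.validate()

    def validate(self) -> None:
        for pre, gene in self.pre_gene.items():
            if pre not in self.elements:
                raise ValueError(f"PRE link references unknown element {pre!r}")
            if self.elements[pre].kind != "PRE":
                raise ValueError(f"element {pre!r} linked to a gene but is not a PRE")
            if gene not in self.genes:
                raise ValueError(f"PRE {pre!r} links to unknown gene {gene!r}")
        for e in self.elements.values():
            if e.kind == "PRE" and e.name not in self.pre_gene:
                raise ValueError(f"PRE {e.name!r} is not linked to any gene")
        for a, b in self.loops:
            for anchor in (a, b):
                if anchor not in self.elements:
                    raise ValueError(f"loop anchor {anchor!r} is not a known element")
        for ev in self.binding_events:
            if ev.element not in self.elements:
                raise ValueError(f"binding event on unknown element {ev.element!r}")

    def loop_partners(self, element: str) -> list[str]:
        """Elements connected to ``element`` by at least one loop."""
        if self._partners is None:
            partners: dict[str, list[str]] = {}
            for a, b in self.loops:
                partners.setdefault(a, []).append(b)
                partners.setdefault(b, []).append(a)
            self._partners = {k: sorted(set(v)) for k, v in partners.items()}
        return self._partners.get(element, [])

    def gene_of_pre(self, element: str) -> str | None:
        return self.pre_gene.get(element)

    def pres_of_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pre, gene in self.pre_gene.items():
            out.setdefault(gene, []).append(pre)
        return {g: sorted(v) for g, v in out.items()}

    def invalidate_caches(self) -> None:
        self._partners = None


class ProbabilityAssignment:
    """Map from (evidence, cell_context, topology) to a prior probability.

    The default table encodes the qualitative hierarchy of the binding
    scenarios: same-cell evidence beats cross-cell, ChIP peaks beat motif
    calls, and shorter tethers beat longer ones.  All values live in
    (0, 1]; a floor keeps the weakest class strictly positive.  The table
    is fully configurable — these defaults are this package's own
    calibration, not measured constants.
    """

    FLOOR = 0.05

    def __init__(self, table: Mapping[tuple[str, str, str], float]):
        self.table = dict(table)
        for cls, p in self.table.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"probability for class {cls} must be in (0,1], got {p}")

    @classmethod
    def default(cls) -> "ProbabilityAssignment":
        base = {
            "PRE_direct": 0.9,
            "DRE_loop_PRE": 0.8,
            "PRE_loop_PRE": 0.6,
            "DRE_loop_PRE_loop_PRE": 0.5,
        }
        table = {}
        for topo, p in base.items():
            for evidence in EVIDENCE_KINDS:
                for context in CELL_CONTEXTS:
                    q = p
                    if context == "cross_cell":
                        q -= 0.15
                    if evidence == "motif":
                        q -= 0.25
                    table[(evidence, context, topo)] = max(q, cls.FLOOR)
        return cls(table)

    def __getitem__(self, cls_key: tuple[str, str, str]) -> float:
        try:
            return self.table[cls_key]
        except KeyError:
            raise KeyError(
                f"no prior probability configured for class "
                f"(evidence={cls_key[0]!r}, cell_context={cls_key[1]!r}, "
                f"topology={cls_key[2]!r})"
            ) from None

    def __contains__(self, cls_key: tuple[str, str, str]) -> bool:
        return cls_key in self.table


@dataclass(frozen=True)
class PriorEdge:
    """One regulator→target prior with its probability and evidence class.

    ``cls`` is either an (evidence, cell_context, topology) triple for TF
    binding priors or the string ``"eqtl"`` for genetic-association priors.
    """

    regulator: str
    target: str
    probability: float
    cls: tuple[str, str, str] | str

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValueError(
                f"prior probability must be in (0,1], got {self.probability}"
            )
        if self.regulator == self.target:
            raise ValueError(f"self-loop prior {self.regulator!r} rejected")


def _class_rank(cls: tuple[str, str, str] | str) -> tuple:
    # chip > motif, same > cross, shorter tether first; non-TF classes
    # (eqtl and other string markers) rank after all TF binding classes.
    if isinstance(cls, str):
        return (1, 0, 0, 0)
    evidence, context, topo = cls
    return (
        0,
        EVIDENCE_KINDS.index(evidence),
        CELL_CONTEXTS.index(context),
        TOPOLOGIES.index(topo),
    )


class PriorTable:
    """A set of regulator→target priors keyed by the ordered pair.

    Duplicate pairs keep the maximum probability; among equal maxima the
    class with the stronger evidence rank wins (ChIP before motif,
    same-cell before cross-cell, shorter tether first, eQTL last).
    """

    def __init__(self, entries: Iterable[PriorEdge] = ()):
        self.entries: dict[tuple[str, str], PriorEdge] = {}
        for e in entries:
            self.add(e)

    def add(self, edge: PriorEdge) -> None:
        key = (edge.regulator, edge.target)
        old = self.entries.get(key)
        if old is None:
            self.entries[key] = edge
            return
        if (edge.probability, [-x for x in _class_rank(edge.cls)]) > (
            old.probability,
            [-x for x in _class_rank(old.cls)],
        ):
            self.entries[key] = edge

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.entries)

    def probability(self, regulator: str, target: str) -> float | None:
        e = self.entries.get((regulator, target))
        return None if e is None else e.probability

    def regulators(self) -> set[str]:
        return {r for r, _ in self.entries}

    def genes(self) -> set[str]:
        out = set()
        for r, t in self.entries:
            out.add(r)
            out.add(t)
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PriorTable):
            return NotImplemented
        return self.entries == other.entries


class GeneNetwork:
    """A directed network over gene symbols.

    ``signs`` maps edges to +1 (activation), −1 (inhibition) or 0
    (unsigned); ``support`` carries consensus support counts; ``metadata``
    is free-form (e.g. a cyclicity flag on consensus summaries).
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        signs: Mapping[tuple[str, str], int] | None = None,
        support: Mapping[tuple[str, str], int] | None = None,
        metadata: dict | None = None,
    ) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        node_set = set(self.nodes)
        self.edges: set[tuple[str, str]] = set()
        for u, v in edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if u == v:
                raise ValueError(f"self-loop on {u!r} rejected")
            self.edges.add((u, v))
        self.signs: dict[tuple[str, str], int] = dict(signs or {})
        self.support: dict[tuple[str, str], int] = dict(support or {})
        self.metadata: dict = dict(metadata or {})

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(
            self.nodes, set(self.edges), dict(self.signs), dict(self.support), dict(self.metadata)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.edges == other.edges
            and self.signs == other.signs
            and self.support == other.support
        )

    def __repr__(self) -> str:
        return f"GeneNetwork({len(self.nodes)} nodes, {len(self.edges)} edges)"


class ExpressionData:
    """Continuous gene-by-sample expression matrix (log-scale values)."""

    def __init__(self, genes: Iterable[str], samples: Iterable[str], values: np.ndarray):
        self.genes: tuple[str, ...] = tuple(genes)
        self.samples: tuple[str, ...] = tuple(samples)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionData":
        samples = list(samples)
        idx = [self.samples.index(s) for s in samples]
        return ExpressionData(self.genes, samples, self.values[:, idx])

    def discretize(self, k: int = 3, z_cut: float = 1.0) -> "DiscreteExpression":
        """Discretize each gene into ``k`` levels.

        Default (k=3): z-score each gene across samples and cut at
        ``±z_cut`` → levels {0: low, 1: mid, 2: high}.  For other k,
        equal-probability quantile bins per gene are used.
        """
        if k < 2:
            raise ValueError("need at least 2 levels")
        n_genes, _ = self.values.shape
        levels = np.zeros(self.values.shape, dtype=np.int8)
        if k == 3:
            mu = self.values.mean(axis=1, keepdims=True)
            sd = self.values.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            z = (self.values - mu) / sd
            levels = (np.int8(1) + (z > z_cut).astype(np.int8) - (z < -z_cut).astype(np.int8))
        else:
            qs = np.quantile(self.values, np.linspace(0, 1, k + 1)[1:-1], axis=1).T
            for i in range(n_genes):
                levels[i] = np.searchsorted(qs[i], self.values[i], side="right")
        return DiscreteExpression(self.genes, self.samples, levels, k)


class DiscreteExpression:
    """k-level discretized expression matrix used for Bayesian scoring."""

    def __init__(self, genes: Iterable[str], samples: Iterable[str], levels: np.ndarray, k: int):
        self.genes: tuple[str, ...] = tuple(genes)
        self.samples: tuple[str, ...] = tuple(samples)
        self.levels = np.ascontiguousarray(levels, dtype=np.int8)
        self.k = int(k)
        if self.levels.shape != (len(self.genes), len(self.samples)):
            raise ValueError("levels shape mismatch")
        if self.levels.min(initial=0) < 0 or self.levels.max(initial=0) >= self.k:
            raise ValueError(f"levels must lie in [0, {self.k})")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


class TrueNetwork:
    """Ground-truth signed DAG used by the synthetic-data generators.

    Edges originate only from designated regulator nodes.  Each edge
    carries a sign (±1) and an effect size; each node a noise level used by
    the linear-Gaussian expression simulator.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        regulators: Iterable[str],
        edges: Iterable[tuple[str, str]],
        edge_sign: Mapping[tuple[str, str], int],
        edge_effect: Mapping[tuple[str, str], float],
        topo_order: Iterable[str],
    ) -> None:
        self.nodes = tuple(nodes)
        self.regulators = tuple(regulators)
        self.edges = sorted(edges)
        self.edge_sign = dict(edge_sign)
        self.edge_effect = dict(edge_effect)
        self.topo_order = tuple(topo_order)
        reg_set = set(self.regulators)
        order_pos = {n: i for i, n in enumerate(self.topo_order)}
        for u, v in self.edges:
            if u not in reg_set:
                raise ValueError(f"edge source {u!r} is not a regulator")
            if order_pos[u] >= order_pos[v]:
                raise ValueError("edges must respect the topological order")
            if self.edge_sign[(u, v)] not in (-1, 1):
                raise ValueError("edge signs must be ±1")

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def parents(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in self.edges:
            out[v].append(u)
        return out

    def to_network(self) -> GeneNetwork:
        return GeneNetwork(self.nodes, self.edges, signs=self.edge_sign)


@dataclass(frozen=True)
class Mutation:
    """A non-coding somatic mutation that breaks one TF's binding site."""

    patient: str
    chrom: str
    position: int
    broken_tf: str


@dataclass
class CohortData:
    """Paired tumor/normal cohort with mutations, genotypes and risk links.

    ``tumor`` and ``normal`` share the patient id as sample id, so every
    tumor column has a matched normal column.  Genotypes are risk-allele
    dosages in {0, 1, 2}.
    """

    patients: tuple[str, ...]
    tumor: ExpressionData
    normal: ExpressionData
    subclass: dict[str, str]
    coding_mutations: set = field(default_factory=set)
    noncoding_mutations: list = field(default_factory=list)
    genotypes: dict = field(default_factory=dict)  # (patient, snp) -> dosage
    risk_links: dict = field(default_factory=dict)  # snp -> gene
    snp_positions: dict = field(default_factory=dict)  # snp -> (chrom, pos)

    def __post_init__(self) -> None:
        if tuple(self.tumor.samples) != tuple(self.patients):
            raise ValueError("tumor samples must match patient ids")
        if tuple(self.normal.samples) != tuple(self.patients):
            raise ValueError("every tumor sample needs a matched normal")
        for (_, _), dosage in self.genotypes.items():
            if dosage not in (0, 1, 2):
                raise ValueError("genotype dosages must be 0, 1 or 2")

    def dosage(self, patient: str, snp: str) -> int:
        return self.genotypes.get((patient, snp), 0)


@dataclass
class DrugResponseSet:
    """Per-drug gene-level expression-change magnitudes (signed).

    ``changes[drug]`` maps gene → change; ``true_targets`` records, for
    synthetic data only, which TFs the drug actually perturbs.
    """

    changes: dict[str, dict[str, float]]
    true_targets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def drugs(self) -> list[str]:
        return sorted(self.changes)

    def __post_init__(self) -> None:
        for drug, table in self.changes.items():
            for gene, val in table.items():
                if not np.isfinite(val):
                    raise ValueError(f"non-finite change for {gene} under {drug}")
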