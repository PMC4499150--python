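"""Synthetic regulatory systems with known ground truth.

Every downstream capability of loopnet — prior construction from binding
topology, Bayesian structure learning, evaluation statistics, driver and
risk-gene tests — is exercisable against data produced here, where the true
causal network is known by construction.

The generative model, briefly:

* :func:`generate_true_network` draws a DAG whose edges leave only from a
  designated set of regulator (TF) nodes, with ±1 signs and per-edge effect
  sizes.
* :func:`generate_landscape` materializes a physical regulatory landscape
  that *supports* every true edge through one of the four binding
  topologies (TF on the target's PRE; TF on a DRE looped to the PRE; TF on
  another gene's PRE looped to the target's PRE; TF on a DRE looped to a
  PRE looped to the target's PRE).  Support gadgets use dedicated elements
  so that, with no decoys, the implied prior pair set equals the truth edge
  set exactly.  Decoy binding events add false pairs at a configurable
  rate.
* :func:`simulate_expression` samples a linear-Gaussian system over the
  DAG's topological order.
* :func:`simulate_cohort` builds matched tumor/normal patients with driver
  mutations (expression shifts in carriers), risk-allele genotypes that
  amplify a risk gene's responsiveness to its regulators, and
  subclass-specific expression shifts.
* :func:`simulate_drug_responses` builds drug signatures whose strongly
  responsive genes are downstream of each drug's true target TFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    BindingEvent,
    CohortData,
    DrugResponseSet,
    Element,
    ExpressionData,
    Gene,
    Mutation,
    RegulatoryLandscape,
    TrueNetwork,
)

__all__ = [
    "LoopDistanceConfig",
    "EffectConfig",
    "generate_true_network",
    "generate_landscape",
    "simulate_expression",
    "simulate_cohort",
    "simulate_noncoding_mutations",
    "simulate_drug_responses",
]


@dataclass(frozen=True)
class LoopDistanceConfig:
    """Log-normal DRE–PRE loop span distribution.

    Defaults give a median span of 100 kb, capped at 1 Mb (loops stay
    intra-chromosomal and short-range), with a 5 kb floor so DREs remain
    distal to the promoter window.
    """

    median: float = 100_000.0
    sigma: float = 0.8
    cap: float = 1_000_000.0
    floor: float = 5_000.0

    def sample(self, rng: np.random.Generator) -> int:
        d = rng.lognormal(mean=math.log(self.median), sigma=self.sigma)
        return int(min(self.cap, max(self.floor, d)))


@dataclass(frozen=True)
class EffectConfig:
    """Perturbation strengths for the synthetic tumor cohort.

    All expression is on a log2-like scale, so additive shifts correspond
    to fold changes.  ``driver_shift`` is added to a driver gene's value in
    tumor samples of mutation carriers (and propagates downstream through
    the structural equations).  The risk allele acts as a constitutive
    modulator of the risk gene's regulatory input (a germline change in
    binding affinity, present in both tissues): carriers transmit upstream
    signal with gain ``risk_amplification``, non-carriers with the
    attenuated gain ``risk_baseline``, so the risk gene is selectively
    responsive to driver perturbation in the risk group.
    """

    driver_shift: float = 2.5
    driver_noise_inflation: float = 1.5
    carrier_fraction: float = 0.4
    risk_amplification: float = 2.0
    risk_baseline: float = 0.3
    risk_allele_freq: float = 0.3
    subclass_effect: float = 2.0
    subclass_genes_per_class: int = 5
    noise_sd: float = 0.5

    @classmethod
    def null(cls) -> "EffectConfig":
        """All effects off: tumor and normal come from the same model."""
        return cls(
            driver_shift=0.0,
            driver_noise_inflation=1.0,
            risk_amplification=1.0,
            risk_baseline=1.0,
            subclass_effect=0.0,
        )


SUBCLASSES = ("luminalA", "luminalB", "HER2", "basal")


def generate_true_network(
    n_genes: int,
    n_regulators: int,
    mean_out_degree: float,
    seed: int,
    negative_sign_fraction: float = 0.4,
    effect_range: tuple[float, float] = (0.8, 1.2),
) -> TrueNetwork:
    """Draw a ground-truth signed DAG with edges leaving regulators only.

    A random topological order is drawn with regulators placed in the
    upstream half (TFs act as sources of regulation); each regulator then
    receives a Poisson(``mean_out_degree``) number of targets sampled from
    the nodes after it in the order, which guarantees acyclicity.  Signs
    are −1 with probability ``negative_sign_fraction`` (activation is more
    common than repression); effect sizes are uniform on ``effect_range``.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not 1 <= n_regulators <= n_genes:
        raise ValueError("n_regulators must be in [1, n_genes]")
    if mean_out_degree <= 0:
        raise ValueError("mean_out_degree must be positive")
    rng = np.random.default_rng(seed)

    regulators = [f"TF{i + 1:02d}" for i in range(n_regulators)]
    targets = [f"G{i + 1:03d}" for i in range(n_genes - n_regulators)]
    nodes = regulators + targets

    # Topological order: regulators shuffled into the first half, targets fill
    # the remaining slots.
    n_head = max(n_regulators, (n_genes + 1) // 2)
    head_slots = rng.choice(n_head, size=n_regulators, replace=False)
    order: list[str | None] = [None] * n_genes
    for slot, tf in zip(sorted(head_slots), rng.permutation(regulators)):
        order[slot] = tf
    rest = iter(rng.permutation(targets))
    for i in range(n_genes):
        if order[i] is None:
            order[i] = next(rest)
    order = [n for n in order if n is not None]
    pos = {n: i for i, n in enumerate(order)}

    edges: list[tuple[str, str]] = []
    edge_sign: dict[tuple[str, str], int] = {}
    edge_effect: dict[tuple[str, str], float] = {}
    for tf in regulators:
        downstream = order[pos[tf] + 1 :]
        if not downstream:
            continue
        k = min(len(downstream), rng.poisson(mean_out_degree))
        if k == 0:
            continue
        chosen = rng.choice(len(downstream), size=k, replace=False)
        for j in sorted(chosen):
            v = downstream[j]
            edges.append((tf, v))
            edge_sign[(tf, v)] = -1 if rng.random() < negative_sign_fraction else 1
            edge_effect[(tf, v)] = float(rng.uniform(*effect_range))
    return TrueNetwork(nodes, regulators, edges, edge_sign, edge_effect, order)


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

_TOPOLOGY_WEIGHTS = {
    "PRE_direct": 0.40,
    "DRE_loop_PRE": 0.30,
    "PRE_loop_PRE": 0.15,
    "DRE_loop_PRE_loop_PRE": 0.15,
}


class _LandscapeBuilder:
    """Incremental builder that keeps support gadgets leak-free.

    Each true edge is supported by a dedicated gadget whose elements are
    private to it (fresh DREs; fresh auxiliary PREs for the loop-mediated
    topologies), so classification of the finished landscape yields exactly
    the intended regulator→target pairs and nothing else.
    """

    GENE_SPACING = 1_000_000
    DRE_WIDTH = 600

    def __init__(self, truth: TrueNetwork, pre_halfwidth: int, rng: np.random.Generator):
        self.rng = rng
        self.pre_halfwidth = pre_halfwidth
        n = len(truth.nodes)
        n_chrom = max(2, min(23, n // 8 + 1))
        per_chrom = math.ceil(n / n_chrom)
        self.genes: list[Gene] = []
        self.gene_by_name: dict[str, Gene] = {}
        self.elements: list[Element] = []
        self.pre_gene: dict[str, str] = {}
        self.loops: list[tuple[str, str]] = []
        self.events: list[BindingEvent] = []
        self.chrom_sizes: dict[str, int] = {}
        self._aux_count: dict[str, int] = {}
        self._dre_count = 0

        shuffled = list(rng.permutation(truth.nodes))
        for i, name in enumerate(shuffled):
            chrom = f"chr{i // per_chrom + 1}"
            slot = i % per_chrom
            tss = (slot + 1) * self.GENE_SPACING + int(rng.integers(0, 200_000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = Gene(name, chrom, strand, tss)
            self.genes.append(g)
            self.gene_by_name[name] = g
            self.primary_pre(g)
        for chrom in {g.chrom for g in self.genes}:
            top = max(g.tss for g in self.genes if g.chrom == chrom)
            self.chrom_sizes[chrom] = top + 2 * self.GENE_SPACING

    # -- element factories ---------------------------------------------------

    def primary_pre(self, g: Gene) -> str:
        name = f"PRE_{g.name}"
        if name not in self.pre_gene:
            el = Element(
                name, "PRE", g.chrom, max(0, g.tss - self.pre_halfwidth), g.tss + self.pre_halfwidth
            )
            self.elements.append(el)
            self.pre_gene[name] = g.name
        return name

    def aux_pre(self, gene: str) -> str:
        """A fresh loop-free promoter-region element assigned to ``gene``."""
        k = self._aux_count.get(gene, 0)
        self._aux_count[gene] = k + 1
        g = self.gene_by_name[gene]
        start = g.tss + self.pre_halfwidth + 500 + k * 1200
        el = Element(f"PRE_{gene}_aux{k + 1}", "PRE", g.chrom, start, start + 1000)
        self.elements.append(el)
        self.pre_gene[el.name] = gene
        return el.name

    def fresh_dre(self, near_gene: str, dist_cfg: LoopDistanceConfig) -> str:
        self._dre_count += 1
        g = self.gene_by_name[near_gene]
        d = dist_cfg.sample(self.rng)
        side = -1 if self.rng.random() < 0.5 else 1
        start = g.tss + side * d
        start = max(0, min(start, self.chrom_sizes[g.chrom] - self.DRE_WIDTH))
        el = Element(f"DRE{self._dre_count:05d}", "DRE", g.chrom, start, start + self.DRE_WIDTH)
        self.elements.append(el)
        return el.name

    # -- gadgets: each supports one (tf, target) pair -------------------------

    def support(
        self,
        tf: str,
        target: str,
        topology: str,
        sibling: str | None,
        dist_cfg: LoopDistanceConfig,
        evidence: str,
        context: str,
        accessible: bool,
    ) -> None:
        ev = dict(evidence=evidence, cell_context=context, accessible=accessible)
        if topology == "PRE_direct":
            self.events.append(BindingEvent(tf, self.primary_pre(self.gene_by_name[target]), **ev))
        elif topology == "DRE_loop_PRE":
            dre = self.fresh_dre(target, dist_cfg)
            self.loops.append((dre, self.primary_pre(self.gene_by_name[target])))
            self.events.append(BindingEvent(tf, dre, **ev))
        elif topology == "PRE_loop_PRE":
            # Event on an aux PRE of a sibling target; side pair tf->sibling is
            # a true edge by choice of sibling.
            anchor = self.aux_pre(sibling)
            other = self.aux_pre(target)
            self.loops.append((anchor, other))
            self.events.append(BindingEvent(tf, anchor, **ev))
        elif topology == "DRE_loop_PRE_loop_PRE":
            dre = self.fresh_dre(sibling, dist_cfg)
            mid = self.aux_pre(sibling)
            far = self.aux_pre(target)
            self.loops.append((dre, mid))
            self.loops.append((mid, far))
            self.events.append(BindingEvent(tf, dre, **ev))
        else:  # pragma: no cover - guarded by caller
            raise ValueError(f"unknown topology {topology}")

    def build(self) -> RegulatoryLandscape:
        return RegulatoryLandscape(
            self.genes, self.elements, self.pre_gene, self.loops, self.events, self.chrom_sizes
        )


def _draw_class(
    rng: np.random.Generator, p_chip: float, p_same: float, p_accessible: float
) -> tuple[str, str, bool]:
    evidence = "chip" if rng.random() < p_chip else "motif"
    context = "same_cell" if rng.random() < p_same else "cross_cell"
    accessible = bool(rng.random() < p_accessible)
    return evidence, context, accessible


def generate_landscape(
    truth: TrueNetwork,
    decoy_binding_rate: float,
    loop_distance_distribution: LoopDistanceConfig | None = None,
    seed: int = 0,
    pre_halfwidth: int = 2500,
    topology_weights: dict[str, float] | None = None,
) -> RegulatoryLandscape:
    """Materialize a physical landscape supporting every true edge.

    Each true edge gets one binding-support gadget, with its topology drawn
    from ``topology_weights``; loop-mediated gadgets need a second ("sibling")
    target of the same TF and fall back to direct/DRE support when the TF
    has only one target.  True-edge evidence is biased toward strong
    classes (ChIP, same cell, accessible); decoy events — supporting pairs
    that are *not* true edges — are added per true edge with probability
    ``decoy_binding_rate`` and biased toward weak classes.
    """
    if not 0.0 <= decoy_binding_rate <= 1.0:
        raise ValueError("decoy_binding_rate must be in [0, 1]")
    dist_cfg = loop_distance_distribution or LoopDistanceConfig()
    weights = dict(_TOPOLOGY_WEIGHTS if topology_weights is None else topology_weights)
    rng = np.random.default_rng(seed)
    builder = _LandscapeBuilder(truth, pre_halfwidth, rng)
    truth_edges = truth.edge_set()

    targets_of: dict[str, list[str]] = {}
    for u, v in truth.edges:
        targets_of.setdefault(u, []).append(v)

    topo_names = list(weights)
    topo_p = np.array([weights[t] for t in topo_names], dtype=float)
    topo_p = topo_p / topo_p.sum()

    for tf in truth.regulators:
        tgts = targets_of.get(tf, [])
        for target in tgts:
            topology = topo_names[rng.choice(len(topo_names), p=topo_p)]
            sibling = None
            if topology in ("PRE_loop_PRE", "DRE_loop_PRE_loop_PRE"):
                others = [t for t in tgts if t != target]
                if others:
                    sibling = others[int(rng.integers(len(others)))]
                else:
                    topology = "DRE_loop_PRE"  # no sibling available
            evidence, context, _ = _draw_class(rng, p_chip=0.8, p_same=0.85, p_accessible=1.0)
            # True support always counts: cross-cell true events sit in
            # accessible chromatin so the pair is never silently dropped.
            builder.support(tf, target, topology, sibling, dist_cfg, evidence, context, True)

    # Decoys: false regulator->target pairs with weak-leaning evidence.
    all_nodes = list(truth.nodes)
    n_decoys = int(rng.binomial(len(truth.edges), decoy_binding_rate)) if truth.edges else 0
    made = 0
    guard = 0
    while made < n_decoys and guard < 50 * (n_decoys + 1):
        guard += 1
        tf = truth.regulators[int(rng.integers(len(truth.regulators)))]
        target = all_nodes[int(rng.integers(len(all_nodes)))]
        if target == tf or (tf, target) in truth_edges:
            continue
        topology = "PRE_direct" if rng.random() < 0.5 else "DRE_loop_PRE"
        evidence, context, accessible = _draw_class(rng, p_chip=0.3, p_same=0.3, p_accessible=0.7)
        builder.support(tf, target, topology, None, dist_cfg, evidence, context, accessible)
        made += 1

    return builder.build()


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def _structural_sample(
    truth: TrueNetwork,
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
    shift: dict[str, np.ndarray] | None = None,
    noise_scale: dict[str, np.ndarray] | None = None,
    incoming_gain: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Forward-sample the linear-Gaussian system in topological order.

    Optional per-gene, per-sample modifiers implement interventions:
    ``shift`` adds to the gene's value (propagates downstream),
    ``noise_scale`` multiplies its noise, ``incoming_gain`` multiplies the
    summed parental input (risk-allele responsiveness amplification).
    """
    parents = truth.parents()
    idx = {g: i for i, g in enumerate(truth.nodes)}
    x = np.empty((len(truth.nodes), n_samples))
    for gene in truth.topo_order:
        i = idx[gene]
        pa = parents[gene]
        eps = rng.normal(0.0, 1.0, size=n_samples)
        if noise_scale and gene in noise_scale:
            eps = eps * noise_scale[gene]
        if not pa:
            x[i] = eps  # roots are standard normal (noise_sd applies to children)
        else:
            drive = np.zeros(n_samples)
            for p in pa:
                e = truth.edge_effect[(p, gene)] * truth.edge_sign[(p, gene)]
                drive += e * x[idx[p]]
            if incoming_gain and gene in incoming_gain:
                drive = drive * incoming_gain[gene]
            x[i] = drive + noise_sd * eps
        if shift and gene in shift:
            x[i] = x[i] + shift[gene]
    return x


def simulate_expression(
    truth: TrueNetwork, n_samples: int, noise_sd: float, seed: int
) -> ExpressionData:
    """Sample a continuous expression matrix from the true DAG.

    Root genes are standard normal; every other gene is the signed,
    effect-weighted sum of its parents plus N(0, ``noise_sd``) noise,
    evaluated in topological order.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    values = _structural_sample(truth, n_samples, noise_sd, rng)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    return ExpressionData(truth.nodes, samples, values)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    truth: TrueNetwork,
    n_patients: int,
    driver_genes: list[str],
    risk_gene_links: dict[str, str],
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> CohortData:
    """Matched tumor/normal cohort with driver and risk-allele effects.

    Normal samples come from the structural model without somatic effects;
    tumor samples add, per patient, a ``driver_shift`` to each mutated
    driver (carriers drawn at ``carrier_fraction``) with inflated driver
    noise.  Risk alleles are germline: in both tissues, the linked risk
    gene's parental input is scaled by ``risk_amplification`` for carriers
    (dosage ≥ 1 under ``risk_allele_freq``; heterozygotes count as
    carriers) and by ``risk_baseline`` for non-carriers.  Subclass labels
    are assigned uniformly and a handful of genes per subclass get a
    tumor-only additive shift so subclass-specific expression exists.
    """
    cfg = effect_config or EffectConfig()
    node_set = set(truth.nodes)
    for g in driver_genes:
        if g not in node_set:
            raise ValueError(f"unknown driver gene {g!r}")
    for snp, g in risk_gene_links.items():
        if g not in node_set:
            raise ValueError(f"risk link {snp!r} points to unknown gene {g!r}")
    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    subclass = {p: SUBCLASSES[int(rng.integers(len(SUBCLASSES)))] for p in patients}

    coding_mutations: set[tuple[str, str]] = set()
    for d in driver_genes:
        for p in patients:
            if rng.random() < cfg.carrier_fraction:
                coding_mutations.add((p, d))

    genotypes: dict[tuple[str, str], int] = {}
    for snp in risk_gene_links:
        for p in patients:
            genotypes[(p, snp)] = int(rng.binomial(2, cfg.risk_allele_freq))

    gain: dict[str, np.ndarray] = {}
    for snp, gene in risk_gene_links.items():
        carrier = np.array([1.0 if genotypes[(p, snp)] >= 1 else 0.0 for p in patients])
        g = cfg.risk_baseline + (cfg.risk_amplification - cfg.risk_baseline) * carrier
        gain[gene] = np.maximum(gain.get(gene, np.full(n_patients, -np.inf)), g)

    normal_vals = _structural_sample(truth, n_patients, cfg.noise_sd, rng, incoming_gain=gain)

    shift = {
        d: np.array([cfg.driver_shift if (p, d) in coding_mutations else 0.0 for p in patients])
        for d in driver_genes
    }
    noise_scale = {
        d: np.array(
            [cfg.driver_noise_inflation if (p, d) in coding_mutations else 1.0 for p in patients]
        )
        for d in driver_genes
    }
    tumor_vals = _structural_sample(
        truth, n_patients, cfg.noise_sd, rng, shift=shift, noise_scale=noise_scale, incoming_gain=gain
    )

    # Subclass-specific tumor shifts on a few non-driver genes per subclass.
    if cfg.subclass_effect != 0.0 and cfg.subclass_genes_per_class > 0:
        pool = [g for g in truth.nodes if g not in driver_genes]
        idx = {g: i for i, g in enumerate(truth.nodes)}
        for sc in SUBCLASSES:
            n_pick = min(cfg.subclass_genes_per_class, len(pool))
            picked = [pool[j] for j in rng.choice(len(pool), size=n_pick, replace=False)]
            members = np.array([subclass[p] == sc for p in patients])
            for g in picked:
                sign = -1.0 if rng.random() < 0.5 else 1.0
                tumor_vals[idx[g], members] += sign * cfg.subclass_effect

    tumor = ExpressionData(truth.nodes, patients, tumor_vals)
    normal = ExpressionData(truth.nodes, patients, normal_vals)
    return CohortData(
        patients=tuple(patients),
        tumor=tumor,
        normal=normal,
        subclass=subclass,
        coding_mutations=coding_mutations,
        genotypes=genotypes,
        risk_links=dict(risk_gene_links),
    )


def simulate_noncoding_mutations(
    landscape: RegulatoryLandscape,
    patients: list[str],
    driver_tfs: list[str],
    mutations_per_patient: int = 30,
    driver_hit_fraction: float = 0.0,
    seed: int = 0,
    positions: str = "elements",
) -> list[Mutation]:
    """Non-coding mutations over the landscape.

    With ``positions='elements'``, background mutations fall on uniformly
    chosen element positions; with ``positions='uniform'`` they fall
    uniformly along the chromosomes (most land outside any element).  In
    both cases the broken TF is drawn from the TFs bound at the hit
    element ("none" when unbound).  With ``driver_hit_fraction`` > 0, that
    fraction of each patient's mutations is concentrated on elements bound
    by one of ``driver_tfs``, creating a recurrence signal for the
    driver-discovery test.
    """
    if positions not in ("elements", "uniform"):
        raise ValueError("positions must be 'elements' or 'uniform'")
    rng = np.random.default_rng(seed)
    elems = sorted(landscape.elements.values(), key=lambda e: e.name)
    tf_on_element: dict[str, list[str]] = {}
    for ev in landscape.binding_events:
        tf_on_element.setdefault(ev.element, []).append(ev.tf)
    driver_elems = [
        e for e in elems if any(tf in driver_tfs for tf in tf_on_element.get(e.name, []))
    ]
    by_chrom: dict[str, list[Element]] = {}
    for e in elems:
        by_chrom.setdefault(e.chrom, []).append(e)
    chroms = sorted(landscape.chrom_sizes) or sorted(by_chrom)
    out: list[Mutation] = []
    for p in patients:
        for _ in range(mutations_per_patient):
            if driver_elems and rng.random() < driver_hit_fraction:
                e = driver_elems[int(rng.integers(len(driver_elems)))]
                tfs = sorted({t for t in tf_on_element.get(e.name, []) if t in driver_tfs})
                pos = int(rng.integers(e.start, e.end))
                chrom = e.chrom
            elif positions == "elements":
                e = elems[int(rng.integers(len(elems)))]
                tfs = sorted(set(tf_on_element.get(e.name, [])))
                pos = int(rng.integers(e.start, e.end))
                chrom = e.chrom
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                size = landscape.chrom_sizes.get(chrom, 1_000_000)
                pos = int(rng.integers(0, size))
                hits = [
                    e for e in by_chrom.get(chrom, []) if e.start <= pos < e.end
                ]
                tfs = sorted({t for e in hits for t in tf_on_element.get(e.name, [])})
            broken = tfs[int(rng.integers(len(tfs)))] if tfs else "none"
            out.append(Mutation(p, chrom, pos, broken))
    return out


# ---------------------------------------------------------------------------
# Drug responses
# ---------------------------------------------------------------------------


def simulate_drug_responses(
    truth: TrueNetwork,
    n_drugs: int,
    targets_per_drug: int,
    seed: int,
    effect_size: float = 3.0,
    noise_sd: float = 0.3,
) -> DrugResponseSet:
    """Drug signatures: large changes downstream of each drug's target TFs.

    Genes reachable from a drug's true target TFs (including the TFs
    themselves) receive a signed change of magnitude ≈ ``effect_size``;
    all other genes receive N(0, ``noise_sd``) noise.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    if targets_per_drug < 1:
        raise ValueError("targets_per_drug must be >= 1")
    rng = np.random.default_rng(seed)
    children: dict[str, list[str]] = {}
    for u, v in truth.edges:
        children.setdefault(u, []).append(v)

    def reachable(roots: tuple[str, ...]) -> set[str]:
        seen = set(roots)
        stack = list(roots)
        while stack:
            u = stack.pop()
            for v in children.get(u, []):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    changes: dict[str, dict[str, float]] = {}
    true_targets: dict[str, tuple[str, ...]] = {}
    n_reg = len(truth.regulators)
    for i in range(n_drugs):
        drug = f"drug{i + 1:03d}"
        k = min(targets_per_drug, n_reg)
        tfs = tuple(sorted(truth.regulators[j] for j in rng.choice(n_reg, size=k, replace=False)))
        true_targets[drug] = tfs
        down = reachable(tfs)
        table: dict[str, float] = {}
        for g in truth.nodes:
            if g in down:
                sign = -1.0 if rng.random() < 0.5 else 1.0
                table[g] = sign * effect_size + float(rng.normal(0.0, noise_sd))
            else:
                table[g] = float(rng.normal(0.0, noise_sd))
        changes[drug] = table
    return DrugResponseSet(changes=changes, true_targets=true_targets)
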