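"""Bayesian structure priors from physical TF binding and genetic association.

A TF binding event reaches a target gene through one of four regulatory
topologies:

* ``PRE_direct`` — the bound element is the target's own proximal element;
* ``DRE_loop_PRE`` — a distal element looped to the target's proximal
  element;
* ``PRE_loop_PRE`` — another gene's proximal element looped to the
  target's;
* ``DRE_loop_PRE_loop_PRE`` — a distal element looped to a proximal
  element that is itself looped to the target's (two loop hops at most).

Each (evidence, cell context, topology) class carries a configurable prior
probability; a regulator→target pair supported by several classes keeps the
maximum.  Cross-cell evidence (binding observed in other cell types) only
counts when the element lies in accessible chromatin in the modeled cells.

An independent eQTL-style prior links gene A to gene B when a SNP is
cis-associated with A and trans-associated with B, with a probability that
grows monotonically with the trans-association strength.  TF and eQTL
tables merge by the maximum-probability rule for duplicate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import (
    BindingEvent,
    CohortData,
    ExpressionData,
    PriorEdge,
    PriorTable,
    ProbabilityAssignment,
    RegulatoryLandscape,
)

__all__ = [
    "classify_topologies",
    "build_tf_priors",
    "EqtlConfig",
    "build_eqtl_priors",
    "merge_priors",
    "subset_priors",
]


def classify_topologies(
    landscape: RegulatoryLandscape,
) -> list[tuple[BindingEvent, str, str]]:
    """Enumerate (binding event, target gene, topology) triples.

    Loop traversal depth is at most two anchors; events on elements with no
    reachable PRE simply yield no pairs.  Output order is deterministic
    (event order, then gene name).
    """
    out: list[tuple[BindingEvent, str, str]] = []
    for ev in landscape.binding_events:
        el = landscape.elements[ev.element]
        found: list[tuple[str, str]] = []
        if el.kind == "PRE":
            own = landscape.gene_of_pre(el.name)
            if own is not None:
                found.append((own, "PRE_direct"))
            for partner in landscape.loop_partners(el.name):
                pel = landscape.elements[partner]
                if pel.kind == "PRE":
                    g = landscape.gene_of_pre(partner)
                    if g is not None and g != own:
                        found.append((g, "PRE_loop_PRE"))
        else:  # DRE
            for partner in landscape.loop_partners(el.name):
                pel = landscape.elements[partner]
                if pel.kind != "PRE":
                    continue
                g = landscape.gene_of_pre(partner)
                if g is not None:
                    found.append((g, "DRE_loop_PRE"))
                for second in landscape.loop_partners(partner):
                    if second == el.name:
                        continue
                    sel = landscape.elements[second]
                    if sel.kind != "PRE":
                        continue
                    g2 = landscape.gene_of_pre(second)
                    if g2 is not None and g2 != g:
                        found.append((g2, "DRE_loop_PRE_loop_PRE"))
        # deduplicate (gene, topology) pairs per event, keep sorted order
        for gene, topo in sorted(set(found)):
            out.append((ev, gene, topo))
    return out


def build_tf_priors(
    landscape: RegulatoryLandscape,
    assignment: ProbabilityAssignment | None = None,
) -> PriorTable:
    """Build the TF binding prior table from a classified landscape.

    Each supported (regulator, target) pair receives the maximum
    probability over its supporting classes.  Cross-cell evidence is
    dropped unless the element is flagged accessible; self-pairs are
    skipped.  A class missing from ``assignment`` raises ``KeyError``
    naming the class.
    """
    assignment = assignment or ProbabilityAssignment.default()
    table = PriorTable()
    for ev, gene, topo in classify_topologies(landscape):
        if ev.tf == gene:
            continue
        if ev.cell_context == "cross_cell" and not ev.accessible:
            continue
        cls = (ev.evidence, ev.cell_context, topo)
        table.add(PriorEdge(ev.tf, gene, assignment[cls], cls))
    return table


@dataclass(frozen=True)
class EqtlConfig:
    """Settings for the cis/trans association scan.

    ``cis_window`` (bp) bounds the SNP–TSS distance for a cis pair;
    associations use the Pearson correlation of allele dosage with
    expression at nominal p-value thresholds.  Trans probabilities are a
    normalized-rank map of the trans-association strength scaled into
    [``prob_floor``, ``prob_ceiling``].
    """

    cis_window: int = 1_000_000
    cis_p: float = 1e-3
    trans_p: float = 1e-3
    prob_floor: float = 0.05
    prob_ceiling: float = 0.95


def _dosage_correlation(dosage: np.ndarray, expr: np.ndarray) -> tuple[float, float]:
    if np.std(dosage) == 0 or np.std(expr) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(dosage, expr)
    return float(r), float(p)


def build_eqtl_priors(
    cohort: CohortData,
    expression: ExpressionData,
    landscape: RegulatoryLandscape,
    config: EqtlConfig | None = None,
) -> PriorTable:
    """Genetic-association priors: cis gene → trans gene per SNP.

    For each SNP cis-associated (within ``cis_window`` of the TSS, p <
    ``cis_p``) with gene A and trans-associated (p < ``trans_p``, outside
    the cis window or on another chromosome) with gene B, the pair A→B is
    emitted with a probability that increases with the rank of the trans
    |r| among all candidate trans associations.
    """
    cfg = config or EqtlConfig()
    samples = [s for s in expression.samples if s in set(cohort.patients)]
    if not samples:
        raise ValueError("no overlap between genotyped patients and expression samples")
    expr = expression.subset_samples(samples)

    snps = sorted({snp for (_, snp) in cohort.genotypes})
    dosages = {
        snp: np.array([cohort.dosage(p, snp) for p in samples], dtype=float) for snp in snps
    }

    candidates: list[tuple[str, str, float]] = []  # (cis gene, trans gene, |r|)
    for snp in snps:
        if snp not in cohort.snp_positions:
            raise ValueError(f"SNP {snp!r} has no genomic position")
        chrom, pos = cohort.snp_positions[snp]
        dose = dosages[snp]
        cis_genes = []
        for gname in expr.genes:
            g = landscape.genes.get(gname)
            if g is None:
                continue
            if g.chrom == chrom and abs(g.tss - pos) <= cfg.cis_window:
                r, p = _dosage_correlation(dose, expr.row(gname))
                if p < cfg.cis_p:
                    cis_genes.append(gname)
        if not cis_genes:
            continue
        for gname in expr.genes:
            g = landscape.genes.get(gname)
            if g is None or gname in cis_genes:
                continue
            if g.chrom == chrom and abs(g.tss - pos) <= cfg.cis_window:
                continue  # still cis territory, just not associated
            r, p = _dosage_correlation(dose, expr.row(gname))
            if p < cfg.trans_p:
                for a in cis_genes:
                    if a != gname:
                        candidates.append((a, gname, abs(r)))

    table = PriorTable()
    if not candidates:
        return table
    strengths = np.array([c[2] for c in candidates])
    ranks = stats.rankdata(strengths, method="average")
    lo, hi = cfg.prob_floor, cfg.prob_ceiling
    probs = lo + (hi - lo) * (ranks - 0.5) / len(ranks)
    for (a, b, _), p in zip(candidates, probs):
        table.add(PriorEdge(a, b, float(p), "eqtl"))
    return table


def merge_priors(a: PriorTable, b: PriorTable) -> PriorTable:
    """Union of pairs; duplicates keep the maximum probability.

    Commutative, associative and idempotent: the surviving entry for a
    duplicate pair is the one with the highest probability, ties broken by
    evidence-class rank.
    """
    merged = PriorTable()
    for edge in a:
        merged.add(edge)
    for edge in b:
        merged.add(edge)
    return merged


def subset_priors(
    table: PriorTable,
    mode: str,
    null_rate: float = 3.0,
    seed: int = 0,
) -> PriorTable:
    """The four prior subsets used for evaluation.

    ``complete_tf`` keeps every TF binding entry (all topologies);
    ``proximal_tf`` keeps only direct-PRE entries; ``eqtl`` keeps genetic
    entries; ``null_poisson`` ignores the table's pairs and draws, for each
    regulator, Poisson(``null_rate``) random targets from the table's gene
    universe with a neutral probability of 0.5.
    """
    if mode == "complete_tf":
        return PriorTable(e for e in table if e.cls != "eqtl")
    if mode == "proximal_tf":
        return PriorTable(
            e for e in table if e.cls != "eqtl" and e.cls[2] == "PRE_direct"
        )
    if mode == "eqtl":
        return PriorTable(e for e in table if e.cls == "eqtl")
    if mode == "null_poisson":
        rng = np.random.default_rng(seed)
        genes = sorted(table.genes())
        regulators = sorted(table.regulators())
        out = PriorTable()
        for reg in regulators:
            k = int(rng.poisson(null_rate))
            pool = [g for g in genes if g != reg]
            k = min(k, len(pool))
            if k == 0:
                continue
            for j in rng.choice(len(pool), size=k, replace=False):
                out.add(PriorEdge(reg, pool[int(j)], 0.5, ("chip", "same_cell", "PRE_direct")))
        return out
    raise ValueError(f"unknown prior subset mode {mode!r}")
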