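"""Network-interpretation statistics for tumor cohorts.

Implements the clinical/downstream layer on top of a learned network:
subclass-specific gene mapping, drug–TF connectivity matrices,
group-wise expression perturbation, regulatory-driver discovery by
mutation-randomization, driver↔risk permutation tests, misregulation
concordance, and risk-allele susceptibility analysis.

Conventions used throughout:

* Expression is on a log2-like scale, so the 2-fold differential
  threshold corresponds to |tumor − normal| ≥ 1 per matched patient.
* Empirical p-values use the add-one estimator p = (1 + k) / (N + 1),
  where k counts null statistics at least as extreme as the observed one;
  ties between the observed and null statistics are broken uniformly at
  random (seeded), which makes the p-value exactly uniform under the null
  even for discrete statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .datatypes import CohortData, DrugResponseSet, ExpressionData, GeneNetwork, Mutation, RegulatoryLandscape

__all__ = [
    "combine_driver_sets",
    "subclass_specific_genes",
    "descendant_pathway_fraction",
    "network_distance",
    "ConnectivityMatrix",
    "drug_connectivity",
    "expression_perturbation",
    "differential_expression_vector",
    "misregulation_concordance",
    "AnnotatedMutation",
    "annotate_mutations",
    "identify_regulatory_drivers",
    "DriverRiskTestResult",
    "driver_risk_connectivity_test",
    "risk_allele_susceptibility",
]


def combine_driver_sets(coding: set[str], regulatory: set[str]) -> set[str]:
    """Union of coding and regulatory driver factors (overlap counted once)."""
    return set(coding) | set(regulatory)


def _empirical_p(observed: float, null: np.ndarray, rng: np.random.Generator) -> float:
    """Add-one empirical p with randomized tie-breaking (exactly uniform
    under exchangeability of observed and null draws)."""
    greater = int(np.sum(null > observed))
    ties = int(np.sum(null == observed))
    # The observed value takes a uniformly random rank among its ties, the
    # discrete analogue of adding continuous jitter before ranking.
    k = greater + (int(rng.integers(0, ties + 1)) if ties else 0)
    return (1 + k) / (len(null) + 1)


# ---------------------------------------------------------------------------
# Subclass mapping and pathway statistics
# ---------------------------------------------------------------------------


def subclass_specific_genes(
    cohort: CohortData,
    fold: float = 2.0,
    patient_fraction: float = 0.20,
) -> dict[str, set[str]]:
    """Genes differentially expressed ≥ ``fold`` in > ``patient_fraction``
    of a subclass's patients (tumor vs matched normal, either direction).

    The fraction threshold is strict: a gene changed in exactly 20% of
    patients is excluded.
    """
    cut = math.log2(fold)
    diff = cohort.tumor.values - cohort.normal.values  # log-scale
    subclasses = sorted(set(cohort.subclass.values()))
    out: dict[str, set[str]] = {}
    patients = list(cohort.patients)
    for sc in subclasses:
        members = [i for i, p in enumerate(patients) if cohort.subclass[p] == sc]
        if not members:
            warnings.warn(f"subclass {sc!r} has no patients")
            out[sc] = set()
            continue
        changed = np.abs(diff[:, members]) >= cut
        frac = changed.mean(axis=1)
        out[sc] = {g for g, f in zip(cohort.tumor.genes, frac) if f > patient_fraction}
    return out


def descendant_pathway_fraction(network: GeneNetwork, regulator: str, gene_set) -> float:
    """Fraction of ``gene_set`` reachable from ``regulator`` by directed paths."""
    if regulator not in set(network.nodes):
        raise ValueError(f"regulator {regulator!r} not in network")
    gene_set = set(gene_set)
    if not gene_set:
        return float("nan")
    reach = nx.descendants(network.to_networkx(), regulator)
    return len(gene_set & reach) / len(gene_set)


def network_distance(network: GeneNetwork, source: str, targets) -> dict[str, float]:
    """Intervening-node counts (shortest directed path length − 1) from
    ``source`` to each target; unreachable targets map to ``inf``."""
    if source not in set(network.nodes):
        raise ValueError(f"source {source!r} not in network")
    lengths = nx.single_source_shortest_path_length(network.to_networkx(), source)
    return {
        t: (lengths[t] - 1 if t in lengths and t != source else math.inf) for t in targets
    }


# ---------------------------------------------------------------------------
# Drug connectivity
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """TF × drug connection scores with normalization and clustering.

    ``raw`` holds fractions in [0, 1] (per drug they sum to ≤ 1, with
    equality when every responsive gene has an upstream TF).  ``normalized``
    is the column-then-row z-scored matrix restricted to TFs whose
    normalized score escapes (−``filter_band``, ``filter_band``) for at
    least one drug.  Leaf orders come from Spearman-distance
    complete-linkage clustering of the filtered matrix.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    tf_order: list[str] = field(default_factory=list)
    drug_order: list[str] = field(default_factory=list)
    filter_band: float = 0.2


def _closest_upstream_tfs(
    graph: nx.DiGraph, gene: str, tfs: set[str], direct_only: bool
) -> list[str]:
    """All TFs at the minimal upstream distance from ``gene`` (ties kept)."""
    preds = [t for t in graph.predecessors(gene) if t in tfs] if gene in graph else []
    if direct_only or preds:
        return sorted(preds)
    rev = graph.reverse(copy=False)
    lengths = nx.single_source_shortest_path_length(rev, gene) if gene in graph else {}
    best: list[str] = []
    best_d = math.inf
    for t in tfs:
        d = lengths.get(t, math.inf)
        if t == gene or d == math.inf:
            continue
        if d < best_d:
            best_d, best = d, [t]
        elif d == best_d:
            best.append(t)
    return sorted(best)


def drug_connectivity(
    network: GeneNetwork,
    responses: DrugResponseSet,
    top_n: int = 200,
    tfs: set[str] | None = None,
    direct_only: bool = False,
    filter_band: float = 0.2,
) -> ConnectivityMatrix:
    """Connectivity scores between TFs and drugs.

    Per drug: take the ``top_n`` genes by absolute expression change, find
    each gene's closest upstream TF in the network (minimal intervening
    nodes; ties split the gene's weight equally), and score each TF by the
    fraction of the responsive genes attributed to it.  The score matrix
    is z-normalized column-wise then row-wise, TFs whose normalized score
    stays within (−0.2, 0.2) for every drug are dropped, and both axes are
    ordered by Spearman-correlation-distance complete-linkage clustering.
    """
    graph = network.to_networkx()
    node_set = set(network.nodes)
    if tfs is None:
        tfs = {u for u, _ in network.edges}
    tf_list = sorted(tfs)
    drugs = responses.drugs()
    raw = pd.DataFrame(0.0, index=tf_list, columns=drugs)
    for drug in drugs:
        table = responses.changes[drug]
        measured = [(g, abs(c)) for g, c in table.items() if g in node_set]
        if len(measured) < top_n:
            warnings.warn(f"drug {drug!r}: only {len(measured)} measured genes (< {top_n})")
        measured.sort(key=lambda t: (-t[1], t[0]))
        top = [g for g, _ in measured[:top_n]]
        if not top:
            continue
        for g in top:
            closest = _closest_upstream_tfs(graph, g, tfs, direct_only)
            if not closest:
                continue
            w = 1.0 / (len(closest) * len(top))
            for t in closest:
                raw.loc[t, drug] += w

    norm = raw.copy()
    col_sd = norm.std(axis=0, ddof=0).replace(0.0, 1.0)
    norm = (norm - norm.mean(axis=0)) / col_sd
    row_sd = norm.std(axis=1, ddof=0).replace(0.0, 1.0)
    norm = norm.sub(norm.mean(axis=1), axis=0).div(row_sd, axis=0)
    keep = norm.index[(norm.abs() >= filter_band).any(axis=1)]
    norm = norm.loc[keep]

    tf_order = list(norm.index)
    drug_order = list(norm.columns)
    if norm.shape[0] > 2:
        rho = stats.spearmanr(norm.values, axis=1).statistic
        rho = np.atleast_2d(rho)
        d = np.clip(1.0 - rho, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        tf_order = [norm.index[i] for i in leaves_list(linkage(squareform(d, checks=False), "complete"))]
    if norm.shape[1] > 2 and norm.shape[0] > 1:
        rho = stats.spearmanr(norm.values, axis=0).statistic
        rho = np.atleast_2d(rho)
        d = np.clip(1.0 - rho, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        d = np.nan_to_num(d, nan=1.0)
        drug_order = [norm.columns[i] for i in leaves_list(linkage(squareform(d, checks=False), "complete"))]
    return ConnectivityMatrix(raw, norm, tf_order, drug_order, filter_band)


# ---------------------------------------------------------------------------
# Expression perturbation and misregulation concordance
# ---------------------------------------------------------------------------


def expression_perturbation(
    expr: ExpressionData,
    gene_set,
    groups: tuple[list[str], list[str]],
) -> tuple[pd.DataFrame, float]:
    """Mean absolute deviation from the pooled expectation, per group.

    For each gene, E is its mean across *all* samples in both groups
    pooled; each group's score is mean(|X_i − E|).  Returns the per-gene
    table and the fraction of genes where group 1's score exceeds
    group 2's (ties count one half).
    """
    g1, g2 = groups
    if not g1 or not g2:
        raise ValueError("both patient groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("patient groups must be disjoint")
    i1 = [expr.samples.index(s) for s in g1]
    i2 = [expr.samples.index(s) for s in g2]
    rows = []
    wins = 0.0
    genes = [g for g in gene_set if g in set(expr.genes)]
    for g in genes:
        x = expr.row(g)
        e = x[i1 + i2].mean()
        s1 = float(np.abs(x[i1] - e).mean())
        s2 = float(np.abs(x[i2] - e).mean())
        rows.append(dict(gene=g, group1=s1, group2=s2))
        wins += 1.0 if s1 > s2 else (0.5 if s1 == s2 else 0.0)
    frac = wins / len(genes) if genes else float("nan")
    return pd.DataFrame(rows, columns=["gene", "group1", "group2"]), frac


def differential_expression_vector(
    cohort: CohortData, gene: str, fold: float = 2.0
) -> np.ndarray:
    """Per-patient −1/0/+1 tumor-vs-normal status at a fold threshold.

    Expression is log-scale, so a 2-fold change is |tumor − normal| ≥ 1.
    """
    cut = math.log2(fold)
    d = cohort.tumor.row(gene) - cohort.normal.row(gene)
    return np.sign(d) * (np.abs(d) >= cut)


def misregulation_concordance(vec_a: np.ndarray, vec_b: np.ndarray) -> tuple[float, float]:
    """|Pearson r| between two −1/0/+1 differential vectors, with p-value.

    Symmetric in its arguments and invariant to jointly flipping both
    signs.  Degenerate (constant) vectors give (nan, nan).
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 patients")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return abs(float(r)), float(p)


# ---------------------------------------------------------------------------
# Regulatory driver discovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatedMutation:
    """A non-coding mutation mapped to the regulator–target pairs it hits."""

    patient: str
    chrom: str
    position: int
    tf: str
    targets: tuple[str, ...]


def annotate_mutations(
    mutations: list[Mutation],
    landscape: RegulatoryLandscape,
    network: GeneNetwork | None = None,
) -> list[AnnotatedMutation]:
    """Map each mutation to the target genes its broken TF site controls.

    A mutation's position is intersected with the landscape's elements;
    targets are the genes reachable from the hit element through the
    binding topologies (direct PRE, loops, two-hop chains).  With a
    ``network`` given, targets are restricted to actual network edges of
    the broken TF.
    """
    from .priors import classify_topologies  # local import to avoid cycle

    element_targets: dict[str, set[str]] = {}
    for ev, gene, _ in classify_topologies(landscape):
        element_targets.setdefault(ev.element, set()).add(gene)
    # Elements without any binding event still reach genes through loops;
    # compute their target sets directly from the loop structure.
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for el in landscape.elements.values():
        by_chrom.setdefault(el.chrom, []).append((el.start, el.end, el.name))
    for v in by_chrom.values():
        v.sort()

    net_edges = network.edges if network is not None else None
    out = []
    for m in mutations:
        hits = [
            name
            for start, end, name in by_chrom.get(m.chrom, [])
            if start <= m.position < end
        ]
        targets: set[str] = set()
        for el in hits:
            targets |= element_targets.get(el, set())
            el_obj = landscape.elements[el]
            if el_obj.kind == "PRE":
                g = landscape.gene_of_pre(el)
                if g:
                    targets.add(g)
            else:
                for partner in landscape.loop_partners(el):
                    g = landscape.gene_of_pre(partner)
                    if g:
                        targets.add(g)
        if net_edges is not None:
            targets = {t for t in targets if (m.broken_tf, t) in net_edges}
        out.append(AnnotatedMutation(m.patient, m.chrom, m.position, m.broken_tf, tuple(sorted(targets))))
    return out


def _recurrence_counts(annotated: list[AnnotatedMutation]) -> dict[str, int]:
    """Per TF: number of its target genes mutated in ≥ 2 distinct patients."""
    patients_per: dict[tuple[str, str], set[str]] = {}
    for m in annotated:
        for t in m.targets:
            patients_per.setdefault((m.tf, t), set()).add(m.patient)
    counts: dict[str, int] = {}
    for (tf, _), pats in patients_per.items():
        if len(pats) >= 2:
            counts[tf] = counts.get(tf, 0) + 1
    return counts


def identify_regulatory_drivers(
    network: GeneNetwork | None,
    noncoding_mutations: list[Mutation],
    landscape: RegulatoryLandscape,
    n_sim: int = 1000,
    mode: str = "insilico",
    seed: int = 0,
    alpha: float = 0.05,
    mutation_pool: list[Mutation] | None = None,
) -> pd.DataFrame:
    """Regulatory driver factors by mutation-randomization.

    The observed statistic per TF is the number of its target genes
    recurrently affected (mutations from ≥ 2 distinct patients).  The null
    redistributes mutations while preserving each patient's per-chromosome
    mutation counts: ``clinical`` mode draws positions (with their broken
    TFs) from a supplied mutation pool on the same chromosome;
    ``insilico`` mode draws positions uniformly along the chromosome and
    assigns the broken TF from the binding events at the hit element.
    Drivers are TFs with empirical p < ``alpha``.
    """
    if n_sim < 19:
        raise ValueError("n_sim must be >= 19 to resolve p < 0.05")
    if mode not in ("clinical", "insilico"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    annotated = annotate_mutations(noncoding_mutations, landscape, network)
    observed = _recurrence_counts(annotated)
    # Test every TF bound somewhere in the landscape, not only those hit by
    # an observed mutation (unhit TFs have observed statistic 0).
    tf_universe = sorted(
        {ev.tf for ev in landscape.binding_events}
        | {m.broken_tf for m in noncoding_mutations if m.broken_tf != "none"}
    )

    # Per-patient, per-chromosome mutation counts to preserve.
    counts: dict[tuple[str, str], int] = {}
    for m in noncoding_mutations:
        counts[(m.patient, m.chrom)] = counts.get((m.patient, m.chrom), 0) + 1

    pool = mutation_pool if mutation_pool is not None else noncoding_mutations
    pool_by_chrom: dict[str, list[Mutation]] = {}
    for m in pool:
        pool_by_chrom.setdefault(m.chrom, []).append(m)

    tf_on_element: dict[str, list[str]] = {}
    for ev in landscape.binding_events:
        tf_on_element.setdefault(ev.element, []).append(ev.tf)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for el in landscape.elements.values():
        by_chrom.setdefault(el.chrom, []).append((el.start, el.end, el.name))
    for v in by_chrom.values():
        v.sort()
    chrom_sizes = landscape.chrom_sizes or {
        c: max(e for _, e, _ in v) + 10_000 for c, v in by_chrom.items()
    }

    # Per-chromosome totals let clinical mode draw pool entries without
    # replacement (exact-position duplicates across virtual patients are an
    # artifact of a finite pool, not a feature of real mutation data).
    chrom_totals: dict[str, int] = {}
    for (_, chrom), k in counts.items():
        chrom_totals[chrom] = chrom_totals.get(chrom, 0) + k

    null_stats = {tf: np.zeros(n_sim) for tf in tf_universe}
    for s in range(n_sim):
        sim: list[Mutation] = []
        if mode == "clinical":
            drawn: dict[str, list[Mutation]] = {}
            for chrom, total in sorted(chrom_totals.items()):
                cands = pool_by_chrom.get(chrom, [])
                if not cands:
                    drawn[chrom] = []
                elif len(cands) >= total:
                    idx = rng.choice(len(cands), size=total, replace=False)
                    drawn[chrom] = [cands[int(j)] for j in idx]
                else:
                    idx = rng.integers(len(cands), size=total)
                    drawn[chrom] = [cands[int(j)] for j in idx]
        for (patient, chrom), k in sorted(counts.items()):
            if mode == "clinical":
                cands = drawn.get(chrom, [])
                take, drawn[chrom] = cands[:k], cands[k:]
                for src in take:
                    sim.append(Mutation(patient, chrom, src.position, src.broken_tf))
            else:
                size = chrom_sizes.get(chrom, 1_000_000)
                for pos in rng.integers(0, size, size=k):
                    pos = int(pos)
                    hits = [
                        name
                        for start, end, name in by_chrom.get(chrom, [])
                        if start <= pos < end
                    ]
                    tf = "none"
                    cand_tfs = sorted({t for el in hits for t in tf_on_element.get(el, [])})
                    if cand_tfs:
                        tf = cand_tfs[int(rng.integers(len(cand_tfs)))]
                    sim.append(Mutation(patient, chrom, pos, tf))
        sim_counts = _recurrence_counts(annotate_mutations(sim, landscape, network))
        for tf in tf_universe:
            null_stats[tf][s] = sim_counts.get(tf, 0)

    rows = []
    for tf in tf_universe:
        obs = observed.get(tf, 0)
        p = _empirical_p(obs, null_stats[tf], rng)
        rows.append(dict(tf=tf, observed=obs, p_value=p, is_driver=p < alpha))
    return pd.DataFrame(rows, columns=["tf", "observed", "p_value", "is_driver"])


# ---------------------------------------------------------------------------
# Driver-risk connectivity and susceptibility
# ---------------------------------------------------------------------------


@dataclass
class DriverRiskTestResult:
    """Observed driver↔risk connectivity statistics with permutation p-values.

    ``observed`` / ``p_values`` are keyed by statistic name:
    ``driver_to_risk_edges``, ``risk_with_incoming_pct`` (direct edges,
    the headline statistic), ``risk_with_incoming_path_pct`` (any directed
    path), and the reverse-direction counterparts.
    """

    observed: dict[str, float]
    p_values: dict[str, float]
    null_means: dict[str, float]
    n_perm: int


def _connectivity_stats(
    adj: np.ndarray, reach: np.ndarray, src: np.ndarray, dst: np.ndarray
) -> tuple[float, float, float]:
    sub = adj[np.ix_(src, dst)]
    edges = float(sub.sum())
    incoming = float(sub.any(axis=0).mean() * 100.0) if len(dst) else 0.0
    path_incoming = (
        float(reach[np.ix_(src, dst)].any(axis=0).mean() * 100.0) if len(dst) else 0.0
    )
    return edges, incoming, path_incoming


def driver_risk_connectivity_test(
    network: GeneNetwork,
    drivers: set[str],
    risk_genes: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> DriverRiskTestResult:
    """Permutation test of driver→risk (and risk→driver) connectivity.

    Observed statistics: the number of directed driver→risk edges, the
    percentage of risk genes with an incoming driver edge (direct, and a
    directed-path variant), plus the reverse-direction counterparts.  The
    null resamples gene sets of the same size as the risk set from the
    network's nodes excluding the drivers.
    """
    nodes = list(network.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    for g in drivers | risk_genes:
        if g not in index:
            raise ValueError(f"gene {g!r} not in network")
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in network.edges:
        adj[index[u], index[v]] = True
    graph = network.to_networkx()
    reach = np.zeros((n, n), dtype=bool)
    for g in nodes:
        for d in nx.descendants(graph, g):
            reach[index[g], index[d]] = True

    d_idx = np.array(sorted(index[g] for g in drivers), dtype=int)
    r_idx = np.array(sorted(index[g] for g in risk_genes), dtype=int)
    universe = np.array([i for i in range(n) if nodes[i] not in drivers], dtype=int)
    if len(r_idx) > len(universe):
        raise ValueError("risk set larger than the sampling universe")

    names = [
        "driver_to_risk_edges",
        "risk_with_incoming_pct",
        "risk_with_incoming_path_pct",
        "risk_to_driver_edges",
        "driver_with_incoming_pct",
        "driver_with_incoming_path_pct",
    ]
    fwd = _connectivity_stats(adj, reach, d_idx, r_idx)
    rev = _connectivity_stats(adj, reach, r_idx, d_idx)
    observed = dict(zip(names, fwd + rev))

    rng = np.random.default_rng(seed)
    null = {k: np.zeros(n_perm) for k in names}
    for s in range(n_perm):
        samp = universe[rng.choice(len(universe), size=len(r_idx), replace=False)]
        f = _connectivity_stats(adj, reach, d_idx, samp)
        r = _connectivity_stats(adj, reach, samp, d_idx)
        for k, v in zip(names, f + r):
            null[k][s] = v

    p_values = {k: _empirical_p(observed[k], null[k], rng) for k in names}
    null_means = {k: float(null[k].mean()) for k in names}
    return DriverRiskTestResult(observed, p_values, null_means, n_perm)


def risk_allele_susceptibility(
    cohort: CohortData,
    pairs: list[tuple[str, str, str]],
    min_group: int = 10,
    p_threshold: float = 0.01,
    fold: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Group-wise misregulation concordance by risk-allele status.

    ``pairs`` holds (driver, risk gene, snp) triples.  Patients split by
    dosage at the SNP: ≥ 1 (heterozygotes included) forms the risk group,
    0 the non-risk group; a pair is evaluated only when both groups have
    strictly more than ``min_group`` patients.  "Identified cases" are
    pairs whose driver–risk concordance is significant (p < ``p_threshold``)
    in either group; the returned fraction is the share of identified
    cases where the risk group's |r| exceeds the non-risk group's.
    """
    rows = []
    identified = 0
    risk_higher = 0
    genotyped_snps = {snp for (_, snp) in cohort.genotypes}
    for driver, risk_gene, snp in pairs:
        if snp not in genotyped_snps:
            raise ValueError(f"SNP {snp!r} absent from genotypes")
        risk_pat = [p for p in cohort.patients if cohort.dosage(p, snp) >= 1]
        nonrisk_pat = [p for p in cohort.patients if cohort.dosage(p, snp) == 0]
        if len(risk_pat) <= min_group or len(nonrisk_pat) <= min_group:
            rows.append(
                dict(driver=driver, risk_gene=risk_gene, snp=snp, evaluated=False,
                     risk_r=float("nan"), risk_p=float("nan"),
                     nonrisk_r=float("nan"), nonrisk_p=float("nan"), identified=False)
            )
            continue
        dv = differential_expression_vector(cohort, driver, fold)
        rv = differential_expression_vector(cohort, risk_gene, fold)
        pidx = {p: i for i, p in enumerate(cohort.patients)}
        ri = [pidx[p] for p in risk_pat]
        ni = [pidx[p] for p in nonrisk_pat]
        r_r, r_p = misregulation_concordance(dv[ri], rv[ri])
        n_r, n_p = misregulation_concordance(dv[ni], rv[ni])
        is_ident = bool(
            (np.isfinite(r_p) and r_p < p_threshold) or (np.isfinite(n_p) and n_p < p_threshold)
        )
        if is_ident:
            identified += 1
            if np.isfinite(r_r) and (not np.isfinite(n_r) or r_r > n_r):
                risk_higher += 1
        rows.append(
            dict(driver=driver, risk_gene=risk_gene, snp=snp, evaluated=True,
                 risk_r=r_r, risk_p=r_p, nonrisk_r=n_r, nonrisk_p=n_p, identified=is_ident)
        )
    frac = risk_higher / identified if identified else float("nan")
    cols = ["driver", "risk_gene", "snp", "evaluated", "risk_r", "risk_p",
            "nonrisk_r", "nonrisk_p", "identified"]
    return pd.DataFrame(rows, columns=cols), frac
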