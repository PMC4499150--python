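# Methods

This note documents the models, defaults and design choices behind
loopnet, and what the synthetic benchmarks do and do not demonstrate.

## Prior model

A binding event is a (TF, element, evidence, cell-context, accessibility)
record.  Evidence is `chip` (a ChIP-seq peak) or `motif` (a cognate motif
inside a DNase-hypersensitive site); cell context is `same_cell` for the
modeled cell type and `cross_cell` for evidence transferred from other
cell types, which only counts when the element is flagged accessible in
the modeled cells.  Classification routes each event to target genes by
four topologies, traversing at most two loop anchors: `PRE_direct`,
`DRE_loop_PRE`, `PRE_loop_PRE`, `DRE_loop_PRE_loop_PRE`.

The probability assigned to each (evidence, context, topology) class is a
configuration table, not a measured constant.  The default table encodes
three orderings that the class hierarchy implies — same-cell > cross-cell,
ChIP > motif, shorter tether > longer tether — anchored at 0.9 for
chip/same-cell/PRE-direct, decreasing by 0.1–0.2 per topology step, by
0.15 for cross-cell, by 0.25 for motif evidence, floored at 0.05.  The
top same-cell ChIP classes deliberately sit in the highest probability bin
(≥ 0.75) so that the enrichment analysis can resolve them.  Pairs
supported by several classes keep the maximum probability; ties keep the
stronger class (ChIP before motif, same before cross, shorter tether
first).  Self-pairs are dropped.

The eQTL prior is a cis–trans mediation heuristic: a SNP within 1 Mb of a
gene's TSS (default) and nominally associated with it (dosage–expression
Pearson correlation, p < 1e−3) marks that gene as the cis mediator; genes
associated in trans get an edge from the mediator, with a probability that
is a normalized-rank map of the trans |r| into [0.05, 0.95].  This is a
deliberately simple monotone map — only the ordering of trans strengths
matters downstream, because the merged table is used through log Pr in a
score that is compared across structures, not calibrated probabilities.

## Score

Networks are scored on k-level discretized expression (default k = 3 by
per-gene z-score cuts at ±1) with the BDeu marginal likelihood (equivalent
sample size 1) plus a per-edge structure prior: log Pr(u→v) for prior
pairs, log κ with κ = 0.01 otherwise, and a parent cap of 5.  κ controls
sparsity: a non-prior edge must improve the data likelihood by
−log κ ≈ 4.6 nats to enter the network.  The score is decomposable, so
single-edge moves re-score only the affected family; family scores are
memoized on (child, parent set) and shared across all GA runs and MCMC
chains on the same data.

## Search

**GA.**  Each chromosome is a DAG.  Initialization includes every prior
pair with probability equal to its prior probability, then adds
Poisson(1)-many random out-links per regulator; cycle-closing or
cap-exceeding links are rejected.  Each generation sorts the population
into four fitness quartiles.  The next generation is bred by group
identity: the top group's slots are filled by uniform edge crossover of
top×top parent pairs, the second group by top×second, the third by
second×third, and the bottom group is replaced by fresh prior-sampled
chromosomes.  Uniform crossover keeps edges present in both parents and
inherits each disagreeing edge with probability 1/2, inserting edges in
random order with cycle rejection.  Mutation applies Poisson(rate)-many
random add/remove/reverse moves with group-wise rates (0.5, 1, 2, 4
by default) increasing from best to worst group; the incumbent best
chromosome survives unmutated (elitism).  The loop stops when the best
fitness improves by less than a relative 1e−6 over 200 consecutive
generations, or at the generation cap.  The group-wise crossover and
mutation operators are this package's concrete instantiation of a
four-group scheme; the selective pressure they encode (better groups
recombine, worse groups are refreshed and mutate more) is the design
intent.

**MCMC.**  Metropolis–Hastings over DAGs: a proposal picks an unordered
node pair uniformly and moves its state within {no edge, u→v, v→u} to one
of the other two states uniformly.  This proposal is symmetric, so the
acceptance probability is min(1, exp(Δscore/T)); cycle-creating or
cap-exceeding proposals are rejected.  Edge visit frequencies are
accumulated after a 25% burn-in via occupancy segments; the best network
visited anywhere in the chain is also returned.  On 3-node instances the
chain's edge frequencies reproduce exhaustively enumerated Boltzmann
weights to well under 0.05, which is the correctness check for the
proposal/acceptance pair.

**Hybrid pipeline.**  `build_global_network` runs `n_runs` independent
GA searches (seeds derived up front from one seed, so results are
identical for any thread count), refines each best chromosome by MCMC,
and keeps edges present in at least `min_support` refined networks
(default: half the runs).  The consensus is a summary and may in
principle be cyclic; a flag in the metadata records whether it is a DAG.
Whether consensus should precede or follow MCMC refinement is ambiguous
in principle; here each GA network is refined first and the consensus is
taken last, which lets the refinement correct individual GA runs before
voting.

**Default scales.**  Full-scale defaults are population 128, up to
20 000 generations and 1000 runs.  The test suite and the acceptance
script use the scaled configuration (population 32, ≤ 500 generations,
10 runs), which this package treats as its standard desk-scale setting;
on 20–30-gene systems with a few hundred samples it converges well before
the generation cap.

## Evaluation statistics

Edge signs use Pearson correlation on the continuous (pre-discretization)
matrix with a strict threshold: activation iff r > 0.1, inhibition iff
r < −0.1, unsigned otherwise; zero-variance genes yield an unsigned edge
and a warning.  Node-wise F1 is 2·TP/(2·TP+FP+FN) over outgoing links
against a reference catalog, undirected by default (functional-interaction
catalogs carry no direction) with a directed mode for TF-target catalogs;
nodes with neither outgoing nor reference links are excluded.  Global
precision is TP/(TP+FP).  Prior-recovery enrichment compares, per class
(probability bin, topology, or prior type), the fraction of prior pairs
retained in a functional network with the all-pairs edge density of that
network; the ratio is the enrichment odds ratio.  Network consistency is
the Jaccard index of edge sets (1.0 when both are empty); the underlying
overlap formula is a package choice where alternatives (one-sided overlap)
exist.

## Downstream statistics

* **Subclass-specific genes:** |tumor − normal| ≥ log2(fold) per matched
  patient (expression is log2-scale throughout, so 2-fold means a
  difference of 1), counted per subclass; a gene qualifies when changed in
  strictly more than 20% of the subclass's patients.
* **Drug connectivity:** per drug, the top-200 genes by |change| (fewer,
  with a warning, when fewer are measured) are each attributed to their
  closest upstream TF — minimal intervening-node directed distance, ties
  splitting the gene's weight equally; "upstream" means any directed path,
  with a direct-edge-only mode available.  The TF×drug score matrix is
  z-normalized column-wise then row-wise; TFs whose normalized scores stay
  inside (−0.2, 0.2) for every drug are dropped; both axes are ordered by
  complete-linkage clustering of Spearman-correlation distances.
* **Expression perturbation:** Σ|Xᵢ − E|/n per gene per patient group,
  with E the mean over all samples of both groups pooled.  The statistic
  is translation-invariant and scales linearly, which the tests assert.
* **Misregulation concordance:** |Pearson r| between two patients-long
  −1/0/+1 differential vectors, with the correlation-test p-value;
  constant vectors are returned as undefined.
* **Regulatory drivers:** the statistic per TF is the number of its
  target genes hit by non-coding mutations in ≥ 2 distinct patients
  (mutations are mapped position → element → topology-reachable targets,
  restricted to the TF's network edges).  The null redistributes
  mutations preserving each patient's per-chromosome counts: `clinical`
  mode draws (position, broken TF) entries from an independent mutation
  pool on the same chromosome, without replacement when the pool allows
  (exact-position duplicates across patients are a finite-pool artifact);
  `insilico` mode draws positions uniformly along each chromosome and
  assigns the broken TF from the binding events at the hit element.  The
  recurrence threshold of ≥ 2 distinct patients is a package choice.
* **Driver→risk connectivity:** observed statistics are the direct
  driver→risk edge count and the percentage of risk genes with an
  incoming driver edge — reported both for direct edges (the headline
  variant) and for any directed path — plus the same statistics in the
  reverse direction.  The null resamples gene sets of the risk set's size
  from the network's nodes excluding the drivers.
* **Risk-allele susceptibility:** patients split by risk-allele dosage
  (≥ 1 → risk group; heterozygotes are carriers), pairs evaluated only
  when both groups exceed 10 patients; "identified cases" have
  concordance p < 0.01 in either group, and the reported fraction is the
  share of identified cases with higher risk-group |r|.

**Empirical p-values** use the add-one estimator (1+k)/(N+1), so no
p-value is ever 0 and the smallest attainable value is 1/(N+1).  Because
the statistics are discrete, k counts null values above the observed one
plus a uniformly random share of the ties — the discrete analogue of
jittering before ranking.  This makes the p-value exactly uniform under
the null (the plain ≥-count is conservative under heavy ties, which would
silently deflate type-I error); the randomization is seeded and
reproducible.

## Synthetic data

The generator is the package's test bed and defines its study conditions.

* **Truth networks:** a random topological order with the TFs placed in
  the upstream half; each TF draws Poisson(mean out-degree) targets from
  the nodes after it, guaranteeing acyclicity with edges leaving TFs only.
  Signs are −1 with probability 0.4 (activation is more common than
  repression, matching the roughly 1.5:1 ratio the sign-inference example
  prints); effect sizes are uniform on [0.8, 1.2].
* **Expression:** linear-Gaussian structural equations in topological
  order — root genes standard normal, children the signed effect-weighted
  sum of parents plus N(0, σ) noise (σ = 0.5 in the standard conditions).
  The real data this emulates is a normalized log-intensity matrix; the
  generator makes no attempt to mimic microarray batch structure, count
  noise, or hidden confounding, so recovery results bound what the method
  can do when its likelihood family is correct, not its robustness to
  model misspecification.
* **Landscape:** genes are laid out at ~1 Mb spacing across up to 23
  chromosomes; each gene's PRE is a ±2.5 kb window around the TSS (the
  PRE extent is a simulation default, not a measured quantity).  Every
  true edge is supported by one binding gadget whose topology is drawn at
  0.40/0.30/0.15/0.15 over the four classes; loop-mediated gadgets use
  dedicated auxiliary elements so that classification of the finished
  landscape implies exactly the true pairs — with zero decoys, prior
  recall and precision are both 1 by construction, which the tests
  assert.  Loop-mediated topologies need a second target of the same TF
  and fall back to DRE-loop support otherwise.  DRE–PRE spans are
  log-normal with median 100 kb (σ = 0.8), floored at 5 kb and capped at
  1 Mb, keeping loops intra-chromosomal and short-range.  True-edge
  evidence is biased strong (80% ChIP, 85% same-cell, always accessible);
  decoys — added per true edge with the configured probability — are
  biased weak (30% ChIP, 30% same-cell, 70% accessible), so prior
  probability correlates with truth, the gradient that the enrichment
  analysis measures.
* **Cohorts:** matched tumor/normal pairs per patient.  Driver mutations
  (carrier fraction 0.4) add a +2.5 shift to the driver's tumor value with
  1.5× noise inflation, propagating downstream through the structural
  equations.  Risk alleles (frequency 0.3) are germline modulators of the
  risk gene's regulatory input in both tissues: carriers transmit
  upstream signal with gain 2.0, non-carriers with gain 0.3 — i.e. the
  allele strengthens the binding site through which upstream drivers act,
  which is what makes the risk gene selectively responsive in carriers.
  Subclass labels are uniform over four classes with five genes per class
  shifted by ±2 in tumor samples only.
* **Drug responses:** genes reachable from a drug's target TFs change by
  ±effect (default 3) plus N(0, 0.3) noise; all other genes are pure
  noise, and a zero-effect drug is noise-only.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open throughout.  Distance bands for loop
geometry are half-open ([100, 200) kb contains a 150 kb loop).  Readers
reject malformed input (duplicate genes, missing values, negative or
inverted intervals, self-loops) rather than coercing; writers sort rows
so outputs are diffable.  All stochastic operations take explicit seeds;
the hybrid pipeline derives per-run seeds ahead of execution so thread
count cannot change results.  Division-by-zero cases are defined
explicitly: precision of an edgeless network and concordance of constant
vectors are NaN with a warning or flag; consistency of two empty networks
is 1; F1 of a node with TP = 0 and FP+FN > 0 is 0.

## Problem sizes

The standard benchmark conditions are 30 genes / 5 TFs / 300 samples with
a 0.3 decoy rate for recovery experiments, 20 genes / 600 samples for the
hybrid-vs-pure-MCMC comparison, 3–4 node instances for exhaustive-oracle
checks (25 and 543 DAGs), 21 virtual patients with 5 mutations each over
200 replicates for permutation-test calibration, and 170-patient cohorts
for the clinical statistics.  These sizes are the package's chosen
desk-scale study conditions; the full-scale configuration (128 / 20 000 /
1000) remains available through `GAConfig`.

## Known limitations

Pure structure MCMC on these instances mixes poorly — chains freeze in
local optima that single-edge moves cannot escape — which is precisely
the motivation for GA seeding; the hybrid-vs-pure consistency number
should be read with that in mind.  Sign inference from marginal
correlation can mislabel edges whose direct effect is opposed by stronger
indirect paths, so the printed activation:inhibition ratio runs slightly
below the generator's 1.5:1 sign odds.  The eQTL prior assumes the cis
gene mediates the trans association; genuine pleiotropy violates this and
is not modeled.  The driver statistic saturates at a TF's target count,
limiting power on small landscapes (calibration, not power, is what the
test suite certifies).  Consensus networks are not guaranteed acyclic.
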