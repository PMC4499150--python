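"""Tests for the downstream clinical/driver/risk statistics."""

import math

import numpy as np
import pytest

from loopnet import analysis, synthetic
from loopnet.datatypes import (
    CohortData,
    DrugResponseSet,
    ExpressionData,
    GeneNetwork,
    Mutation,
    TrueNetwork,
)


def _cohort_from_arrays(genes, tumor, normal, subclass=None, **kw):
    patients = tuple(f"P{i}" for i in range(tumor.shape[1]))
    t = ExpressionData(genes, patients, tumor)
    n = ExpressionData(genes, patients, normal)
    sc = subclass or {p: "basal" for p in patients}
    return CohortData(patients, t, n, sc, **kw)


class TestDriverUnion:
    def test_union_counts_overlap_once(self):
        coding = {f"C{i}" for i in range(27)} | {"X1", "X2"}  # 29 factors
        regulatory = {f"R{i}" for i in range(15)} | {"X1", "X2"}  # 17 factors
        union = analysis.combine_driver_sets(coding, regulatory)
        assert (len(coding), len(regulatory)) == (29, 17)
        assert len(coding & regulatory) == 2
        assert len(union) == 44


class TestSubclassSpecificGenes:
    def test_strong_change_included_and_constant_excluded(self):
        normal = np.zeros((2, 10))
        tumor = np.zeros((2, 10))
        tumor[0, :] = math.log2(3)  # 3-fold up in all patients
        cohort = _cohort_from_arrays(["up", "flat"], tumor, normal)
        sets = analysis.subclass_specific_genes(cohort)
        assert "up" in sets["basal"] and "flat" not in sets["basal"]

    def test_exactly_twenty_percent_excluded(self):
        normal = np.zeros((1, 10))
        tumor = np.zeros((1, 10))
        tumor[0, :2] = 1.0  # 2-fold in exactly 20% of patients
        cohort = _cohort_from_arrays(["g"], tumor, normal)
        assert "g" not in analysis.subclass_specific_genes(cohort)["basal"]
        tumor[0, 2] = 1.0  # now 30% -> included
        cohort = _cohort_from_arrays(["g"], tumor, normal)
        assert "g" in analysis.subclass_specific_genes(cohort)["basal"]


class TestPathwayStats:
    def _chain(self):
        return GeneNetwork(tuple("abcd"), [("a", "b"), ("b", "c")])

    def test_star_reaches_everything(self):
        nodes = ("r", "x", "y", "z")
        star = GeneNetwork(nodes, [("r", n) for n in nodes[1:]])
        assert analysis.descendant_pathway_fraction(star, "r", {"x", "y", "z"}) == 1.0

    def test_chain_fraction_and_unreachable(self):
        net = self._chain()
        assert analysis.descendant_pathway_fraction(net, "a", {"b", "c", "d"}) == pytest.approx(2 / 3)
        assert analysis.descendant_pathway_fraction(net, "c", {"a"}) == 0.0

    def test_network_distance_intervening_nodes(self):
        net = self._chain()
        d = analysis.network_distance(net, "a", ["b", "c", "d"])
        assert d["b"] == 0 and d["c"] == 1 and d["d"] == math.inf

    def test_unknown_regulator_rejected(self):
        with pytest.raises(ValueError):
            analysis.descendant_pathway_fraction(self._chain(), "nope", {"a"})


def _bipartite_truth(n_tfs=3, targets_per_tf=5):
    """TFs regulate disjoint target sets; no TF->TF edges."""
    tfs = [f"TF{i}" for i in range(n_tfs)]
    targets = [f"G{i}" for i in range(n_tfs * targets_per_tf)]
    edges, sign, eff = [], {}, {}
    for i, tf in enumerate(tfs):
        for j in range(targets_per_tf):
            v = targets[i * targets_per_tf + j]
            edges.append((tf, v))
            sign[(tf, v)] = 1
            eff[(tf, v)] = 1.0
    return TrueNetwork(tfs + targets, tfs, edges, sign, eff, tfs + targets)


class TestDrugConnectivity:
    def test_single_tf_star_scores_fraction_of_its_targets(self):
        nodes = ("TF0", "x", "y", "z", "w")
        net = GeneNetwork(nodes, [("TF0", "x"), ("TF0", "y")])
        resp = DrugResponseSet({"d": {"x": 5.0, "y": 4.0, "z": 3.0, "w": 0.1}})
        cm = analysis.drug_connectivity(net, resp, top_n=3)
        assert cm.raw.loc["TF0", "d"] == pytest.approx(2 / 3)

    def test_true_target_attains_max_raw_score(self):
        truth = _bipartite_truth()
        net = truth.to_network()
        resp = synthetic.simulate_drug_responses(truth, 6, 1, seed=4)
        for drug in resp.drugs():
            tf = resp.true_targets[drug][0]
            col = cm_col = analysis.drug_connectivity(net, resp, top_n=6).raw[drug]
            assert col.idxmax() == tf

    def test_raw_scores_per_drug_sum_to_at_most_one(self, truth30):
        net = truth30.to_network()
        resp = synthetic.simulate_drug_responses(truth30, 5, 2, seed=5)
        cm = analysis.drug_connectivity(net, resp, top_n=12)
        assert (cm.raw.sum(axis=0) <= 1 + 1e-9).all()

    def test_label_permutation_destroys_attribution(self):
        truth = _bipartite_truth(4, 5)
        net = truth.to_network()
        resp = synthetic.simulate_drug_responses(truth, 8, 1, seed=6)
        cm = analysis.drug_connectivity(net, resp, top_n=6)
        matched = np.mean(
            [cm.raw.loc[resp.true_targets[d][0], d] for d in resp.drugs()]
        )
        rng = np.random.default_rng(7)
        genes = sorted(next(iter(resp.changes.values())))
        perm = dict(zip(genes, rng.permutation(genes)))
        shuffled = DrugResponseSet(
            {d: {perm[g]: c for g, c in tab.items()} for d, tab in resp.changes.items()},
            resp.true_targets,
        )
        cm2 = analysis.drug_connectivity(net, shuffled, top_n=6)
        perm_matched = np.mean(
            [cm2.raw.loc[resp.true_targets[d][0], d] for d in resp.drugs()]
        )
        assert perm_matched < matched - 0.3

    def test_filter_removes_flat_tfs(self):
        truth = _bipartite_truth(4, 4)
        net = truth.to_network()
        resp = synthetic.simulate_drug_responses(truth, 8, 1, seed=8)
        cm = analysis.drug_connectivity(net, resp, top_n=5)
        assert set(cm.normalized.index) <= set(cm.raw.index)
        flat = cm.normalized.abs().max(axis=1)
        assert (flat >= cm.filter_band).all()


class TestExpressionPerturbation:
    def test_hand_arithmetic(self):
        vals = np.array([[1.0, 3.0, 2.0, 2.0]])
        expr = ExpressionData(["g"], ["a", "b", "c", "d"], vals)
        # E over all four samples = 2; group1 = {1,3} -> (1+1)/2 = 1.0
        table, _ = analysis.expression_perturbation(expr, ["g"], (["a", "b"], ["c", "d"]))
        assert table.loc[0, "group1"] == pytest.approx(1.0)
        assert table.loc[0, "group2"] == pytest.approx(0.0)

    def test_translation_invariance_and_scaling(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(1, 20))
        samples = [f"s{i}" for i in range(20)]
        groups = (samples[:10], samples[10:])
        base, _ = analysis.expression_perturbation(
            ExpressionData(["g"], samples, vals), ["g"], groups
        )
        shifted, _ = analysis.expression_perturbation(
            ExpressionData(["g"], samples, vals + 7.0), ["g"], groups
        )
        scaled, _ = analysis.expression_perturbation(
            ExpressionData(["g"], samples, vals * 3.0), ["g"], groups
        )
        assert shifted["group1"][0] == pytest.approx(base["group1"][0])
        assert scaled["group1"][0] == pytest.approx(3 * base["group1"][0])

    def test_exchangeable_groups_fraction_near_half(self):
        rng = np.random.default_rng(10)
        n_genes = 400
        vals = rng.normal(size=(n_genes, 60))
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(60)]
        expr = ExpressionData(genes, samples, vals)
        _, frac = analysis.expression_perturbation(expr, genes, (samples[:30], samples[30:]))
        assert 0.40 < frac < 0.60

    def test_group_errors(self):
        expr = ExpressionData(["g"], ["a", "b"], np.zeros((1, 2)))
        with pytest.raises(ValueError):
            analysis.expression_perturbation(expr, ["g"], ([], ["a"]))
        with pytest.raises(ValueError):
            analysis.expression_perturbation(expr, ["g"], (["a"], ["a"]))


class TestMisregulationConcordance:
    def test_identical_vectors(self):
        v = np.array([1, -1, 0, 1])
        r, p = analysis.misregulation_concordance(v, v)
        assert r == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        a = np.array([1, 1, -1, -1])
        b = np.array([1, -1, 1, -1])
        r, _ = analysis.misregulation_concordance(a, b)
        assert r == pytest.approx(0.0)

    def test_hand_computed_case(self):
        a = np.array([1, 1, 0, -1], dtype=float)
        b = np.array([1, 0, 0, -1], dtype=float)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        r, _ = analysis.misregulation_concordance(a, b)
        assert r == pytest.approx(abs(num / den))

    def test_symmetry_and_joint_flip_invariance(self):
        a = np.array([1, 0, -1, 1, 0], dtype=float)
        b = np.array([0, 1, -1, 1, -1], dtype=float)
        assert analysis.misregulation_concordance(a, b) == analysis.misregulation_concordance(b, a)
        assert analysis.misregulation_concordance(-a, -b)[0] == pytest.approx(
            analysis.misregulation_concordance(a, b)[0]
        )

    def test_degenerate_and_short_inputs(self):
        const = np.zeros(5)
        var = np.array([1, -1, 0, 1, 0], dtype=float)
        r, p = analysis.misregulation_concordance(const, var)
        assert math.isnan(r) and math.isnan(p)
        with pytest.raises(ValueError):
            analysis.misregulation_concordance(np.array([1, 0]), np.array([0, 1]))

    def test_two_fold_threshold_on_log_scale(self, truth30):
        cohort = synthetic.simulate_cohort(truth30, 20, [], {}, seed=11)
        vec = analysis.differential_expression_vector(cohort, truth30.nodes[0])
        diff = cohort.tumor.row(truth30.nodes[0]) - cohort.normal.row(truth30.nodes[0])
        assert set(np.unique(vec)) <= {-1.0, 0.0, 1.0}
        assert np.all((np.abs(diff) >= 1) == (vec != 0))


class TestRegulatoryDrivers:
    def test_concentrated_signal_minimal_p(self, truth30, landscape30):
        patients = [f"P{i:02d}" for i in range(21)]
        driver = truth30.regulators[0]
        muts = synthetic.simulate_noncoding_mutations(
            landscape30, patients, [driver], mutations_per_patient=5,
            driver_hit_fraction=0.8, seed=1,
        )
        df = analysis.identify_regulatory_drivers(
            truth30.to_network(), muts, landscape30, n_sim=199, mode="insilico", seed=2
        )
        row = df[df.tf == driver].iloc[0]
        assert row.p_value <= 3 / 200 and bool(row.is_driver)

    def test_recurrence_requires_two_distinct_patients(self, landscape30, truth30):
        # two mutations in the same patient's same element do not recur
        el = next(
            e for e in landscape30.elements.values()
            if any(ev.element == e.name for ev in landscape30.binding_events)
        )
        tf = next(ev.tf for ev in landscape30.binding_events if ev.element == el.name)
        muts = [
            Mutation("P1", el.chrom, el.start + 1, tf),
            Mutation("P1", el.chrom, el.start + 2, tf),
        ]
        annotated = analysis.annotate_mutations(muts, landscape30)
        counts = analysis._recurrence_counts(annotated)
        assert counts.get(tf, 0) == 0
        muts.append(Mutation("P2", el.chrom, el.start + 3, tf))
        counts = analysis._recurrence_counts(analysis.annotate_mutations(muts, landscape30))
        assert counts.get(tf, 0) >= 1

    def test_too_few_simulations_rejected(self, truth30, landscape30):
        with pytest.raises(ValueError):
            analysis.identify_regulatory_drivers(
                truth30.to_network(), [], landscape30, n_sim=10
            )


class TestDriverRiskTest:
    def test_out_neighbors_give_full_incoming_and_minimal_p(self, truth30):
        net = truth30.to_network()
        driver = truth30.regulators[0]
        risk = {v for u, v in truth30.edges if u == driver}
        res = analysis.driver_risk_connectivity_test(net, {driver}, risk, n_perm=199, seed=3)
        assert res.observed["risk_with_incoming_pct"] == 100.0
        assert res.p_values["risk_with_incoming_pct"] <= 3 / 200

    def test_p_value_lower_bound(self, truth30):
        net = truth30.to_network()
        risk = set(list(truth30.nodes)[-4:]) - set(truth30.regulators)
        res = analysis.driver_risk_connectivity_test(
            net, set(truth30.regulators[:2]), risk, n_perm=49, seed=4
        )
        assert all(p >= 1 / 50 for p in res.p_values.values())

    def test_oversized_risk_set_rejected(self):
        net = GeneNetwork(("a", "b", "c"), [("a", "b")])
        with pytest.raises(ValueError, match="larger"):
            # universe excludes the two drivers, leaving one candidate node
            analysis.driver_risk_connectivity_test(net, {"a", "b"}, {"b", "c"}, n_perm=19)


class TestRiskAlleleSusceptibility:
    def test_small_groups_skipped(self, truth30):
        cohort = synthetic.simulate_cohort(truth30, 15, [], {"rs1": truth30.nodes[-1]}, seed=5)
        # with 15 patients, one group is necessarily <= 10
        table, frac = analysis.risk_allele_susceptibility(
            cohort, [(truth30.regulators[0], truth30.nodes[-1], "rs1")], min_group=10
        )
        assert not table.evaluated.iloc[0]
        assert math.isnan(frac)

    def test_amplified_pair_identified_with_risk_group_higher(self, truth30):
        driver = truth30.regulators[0]
        risk_gene = next(v for u, v in truth30.edges if u == driver)
        cohort = synthetic.simulate_cohort(
            truth30, 150, [driver], {"rs1": risk_gene}, seed=6
        )
        table, frac = analysis.risk_allele_susceptibility(
            cohort, [(driver, risk_gene, "rs1")]
        )
        assert table.identified.iloc[0]
        assert frac == 1.0

    def test_unknown_snp_rejected(self, truth30):
        cohort = synthetic.simulate_cohort(truth30, 30, [], {}, seed=7)
        with pytest.raises(ValueError, match="rs9"):
            analysis.risk_allele_susceptibility(
                cohort, [(truth30.regulators[0], truth30.nodes[-1], "rs9")]
            )
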