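import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phylocontrast.phylo_io import parse_newick, tip_labels
from phylocontrast.pic import (
    IndependentContrasts,
    ancestral_states,
    classify_node_changes,
    compute_contrasts,
    standardization_diagnostic,
)
from phylocontrast.synthetic_data import SimSpec, simulate_bm, simulate_tree
from phylocontrast.traitmodels import bm_covariance


class TestComputeContrasts:
    def test_hand_worked_example(self, three_taxon):
        tree, traits = three_taxon
        cs = compute_contrasts(tree, traits)
        std = sorted(cs.table["contrast"].abs())
        assert std == pytest.approx([1.0690, 1.4142], abs=1e-4)
        ab = cs.table.set_index("node").loc["nd1"]
        assert ab["nodal_value"] == pytest.approx(3.0)
        assert ab["branch_to_parent"] == pytest.approx(1.5)
        assert cs.root_value == pytest.approx(2.1429, abs=1e-4)

    def test_equal_tip_values_give_zero_contrasts(self, random_trees):
        tree = random_trees[0]
        traits = {l: 3.14 for l in tip_labels(tree)}
        cs = compute_contrasts(tree, traits)
        assert np.allclose(cs.table["contrast"], 0.0)

    def test_cherry_closed_form(self):
        tree = parse_newick("(A:1,B:1);")
        cs = compute_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert abs(cs.table["contrast"].iloc[0]) == pytest.approx(
            np.sqrt(2.0), abs=1e-9
        )

    def test_count_is_n_minus_one(self, random_trees):
        for tree in random_trees:
            n = len(tip_labels(tree))
            traits = dict(
                zip(tip_labels(tree), np.arange(n, dtype=float))
            )
            assert len(compute_contrasts(tree, traits)) == n - 1

    def test_zero_variance_cherry_errors(self):
        tree = parse_newick("((A:0,B:0):1,C:2);")
        with pytest.raises(ValueError, match="zero contrast variance"):
            compute_contrasts(tree, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_missing_tip_errors(self, three_taxon):
        tree, traits = three_taxon
        del traits["B"]
        with pytest.raises(ValueError, match="B"):
            compute_contrasts(tree, traits)


class TestStandardizationDiagnostic:
    def _fake(self, contrast, sd):
        return compute_contrasts.__wrapped__ if False else None

    def test_flat_relation_passes(self):
        from phylocontrast.pic import ContrastSet

        table = pd.DataFrame(
            {
                "node": [f"n{i}" for i in range(6)],
                "raw": np.ones(6),
                "contrast": [2.0, -2.0, 2.0, -2.0, 2.0, -2.0],
                "sd": [0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
                "nodal_value": np.zeros(6),
                "branch_to_parent": np.ones(6),
            }
        )
        cs = ContrastSet(table, 0.0, 1.0, 7)
        out = standardization_diagnostic(cs)
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)
        assert out["verdict"] == "pass"

    def test_perfect_trend_fails(self):
        from phylocontrast.pic import ContrastSet

        sd = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        table = pd.DataFrame(
            {
                "node": [f"n{i}" for i in range(6)],
                "raw": np.ones(6),
                "contrast": 2.0 * sd,
                "sd": sd,
                "nodal_value": np.zeros(6),
                "branch_to_parent": np.ones(6),
            }
        )
        out = standardization_diagnostic(ContrastSet(table, 0.0, 1.0, 7))
        assert out["r"] == pytest.approx(1.0)
        assert out["p"] < 0.05
        assert out["verdict"] == "fail"

    def test_identical_sds_degenerate_pass(self):
        from phylocontrast.pic import ContrastSet

        table = pd.DataFrame(
            {
                "node": ["a", "b", "c"],
                "raw": [1.0, 2.0, 3.0],
                "contrast": [1.0, 2.0, 3.0],
                "sd": [1.0, 1.0, 1.0],
                "nodal_value": np.zeros(3),
                "branch_to_parent": np.ones(3),
            }
        )
        out = standardization_diagnostic(ContrastSet(table, 0.0, 1.0, 4))
        assert out["degenerate"] and out["verdict"] == "pass"

    def test_null_simulation_mostly_passes(self):
        """Under Brownian motion the diagnostic should rarely reject."""
        tree = simulate_tree(SimSpec(n_tips=50, seed=11))
        rng = np.random.default_rng(12)
        passes = 0
        n_rep = 200
        for _ in range(n_rep):
            traits = simulate_bm(tree, SimSpec(n_tips=50, sigma2=1.0), rng=rng)
            cs = compute_contrasts(tree, traits)
            if standardization_diagnostic(cs)["verdict"] == "pass":
                passes += 1
        assert passes / n_rep >= 0.90


class TestContrastDistribution:
    def test_contrasts_normal_under_bm(self):
        tree = simulate_tree(SimSpec(n_tips=30, seed=5))
        rng = np.random.default_rng(6)
        nonreject = 0
        n_rep = 200
        for _ in range(n_rep):
            traits = simulate_bm(tree, SimSpec(n_tips=30, sigma2=2.0), rng=rng)
            c = compute_contrasts(tree, traits).table["contrast"]
            if sps.shapiro(c).pvalue >= 0.05:
                nonreject += 1
        assert nonreject / n_rep >= 0.90

    def test_contrast_variance_matches_rate(self):
        sigma2 = 3.0
        tree = simulate_tree(SimSpec(n_tips=200, seed=21))
        rng = np.random.default_rng(22)
        # average the contrast variance over replicates to beat noise
        ratios = []
        for _ in range(30):
            traits = simulate_bm(
                tree, SimSpec(n_tips=200, sigma2=sigma2), rng=rng
            )
            c = compute_contrasts(tree, traits).table["contrast"].to_numpy()
            ratios.append(np.mean(c * c) / sigma2)
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.10)


class TestAncestralStates:
    def test_root_estimate_hand_worked(self, three_taxon):
        tree, traits = three_taxon
        est = ancestral_states(tree, traits)
        root = est.set_index("node").loc["nd0"]
        assert root["estimate"] == pytest.approx(2.1429, abs=1e-4)

    def test_star_tree_root_is_mean(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        traits = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0}
        est = ancestral_states(tree, traits)
        root = est.set_index("node").loc["nd0"]
        assert root["estimate"] == pytest.approx(3.0)

    def test_root_matches_gls_phylogenetic_mean(self, random_trees):
        """Root state equals (1'C^-1 x)/(1'C^-1 1) from the dense matrix."""
        rng = np.random.default_rng(99)
        for tree in random_trees:
            labels = sorted(tip_labels(tree))
            x = rng.normal(size=len(labels))
            traits = dict(zip(labels, x))
            cs = compute_contrasts(tree, traits)
            C = bm_covariance(tree).loc[labels, labels].to_numpy()
            Cinv = np.linalg.inv(C)
            one = np.ones(len(labels))
            gls = (one @ Cinv @ x) / (one @ Cinv @ one)
            assert cs.root_value == pytest.approx(gls, abs=1e-8)
            # and the root variance is the GLS variance factor
            assert cs.root_variance == pytest.approx(
                1.0 / (one @ Cinv @ one), abs=1e-8
            )


class TestClassifyNodeChanges:
    def _estimates(self, tree, traits, overrides=None):
        est = ancestral_states(tree, traits)
        if overrides:
            for node, (mu, se) in overrides.items():
                est.loc[est["node"] == node, ["estimate", "se"]] = (mu, se)
        return est

    def test_small_increase_within_interval(self, three_taxon):
        """A child just above the parent's estimate but inside +/- SE."""
        tree, traits = three_taxon
        est = self._estimates(tree, traits, {"nd0": (0.67, 0.48)})
        traits = {"A": 0.684, "B": 2.0, "C": 1.0}
        changes = classify_node_changes(tree, est, traits)
        # C hangs off the root (nd0): 1.0 vs 0.67 +/- 0.48 -> up, ns
        row = changes.set_index("node").loc["C"]
        assert row["direction"] == "up" and not row["significant"]

    def test_suberosa_case(self):
        tree = parse_newick("(suberosa:0.3,other:0.3);")
        est = pd.DataFrame(
            [{"node": "nd0", "estimate": 0.67, "se": 0.48}]
        )
        changes = classify_node_changes(
            tree, est, {"suberosa": 0.684, "other": 0.5}
        )
        row = changes.set_index("node").loc["suberosa"]
        assert row["direction"] == "up"
        assert not row["significant"]

    def test_exact_equality_is_equal(self):
        tree = parse_newick("(A:1,B:1);")
        est = pd.DataFrame([{"node": "nd0", "estimate": 1.0, "se": 0.5}])
        changes = classify_node_changes(tree, est, {"A": 1.0, "B": 2.0})
        assert changes.set_index("node").loc["A", "direction"] == "equal"
        assert not changes.set_index("node").loc["A", "significant"]

    def test_outside_interval_is_significant(self):
        tree = parse_newick("(A:1,B:1);")
        est = pd.DataFrame([{"node": "nd0", "estimate": 0.5, "se": 0.2}])
        changes = classify_node_changes(tree, est, {"A": 2.0, "B": 0.1})
        a = changes.set_index("node").loc["A"]
        b = changes.set_index("node").loc["B"]
        assert a["direction"] == "up" and a["significant"]
        assert b["direction"] == "down" and b["significant"]

    def test_zero_se_marks_everything_significant(self, three_taxon):
        tree, traits = three_taxon
        est = ancestral_states(tree, traits)
        est["se"] = 0.0
        changes = classify_node_changes(tree, est, traits)
        nonzero = changes[changes["direction"] != "equal"]
        assert nonzero["significant"].all()

    def test_boundary_value_not_significant(self):
        tree = parse_newick("(A:1,B:1);")
        est = pd.DataFrame([{"node": "nd0", "estimate": 1.0, "se": 0.5}])
        changes = classify_node_changes(tree, est, {"A": 1.5, "B": 0.5})
        a = changes.set_index("node").loc["A"]
        assert a["direction"] == "up" and not a["significant"]


class TestEstimator:
    def test_fit_sets_attributes(self, three_taxon):
        tree, traits = three_taxon
        est = IndependentContrasts(compute_ancestral=True).fit(tree, traits)
        assert est.root_value_ == pytest.approx(2.1429, abs=1e-4)
        assert len(est.contrasts_) == 2
        assert set(est.node_changes_["node"]) >= {"A", "B", "C"}

    def test_get_params_roundtrip(self):
        est = IndependentContrasts(trait="gs_pg")
        assert est.get_params()["trait"] == "gs_pg"
        est.set_params(trait="fd_cm")
        assert est.trait == "fd_cm"
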