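import numpy as np
import pytest

from phylocontrast.phylo_io import parse_newick, tip_labels
from phylocontrast.synthetic_data import SimSpec, simulate_bm, simulate_tree
from phylocontrast.traitmodels import (
    BMFit,
    PagelBrownian,
    TransformParams,
    apply_transforms,
    bm_covariance,
    bm_loglik,
    bm_loglik_pruning,
    fit_ml,
)


class TestCovariance:
    def test_three_taxon_matrix(self, three_taxon):
        tree, _ = three_taxon
        C = bm_covariance(tree)
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        assert np.allclose(C.loc[["A", "B", "C"], ["A", "B", "C"]], expected)

    def test_star_tree_diagonal(self):
        tree = parse_newick("(A:2,B:2,C:2,D:2);")
        C = bm_covariance(tree).to_numpy()
        # zero-length polytomy resolution keeps the covariance diagonal
        assert np.allclose(C, 2.0 * np.eye(4))

    def test_symmetric_psd_diag_dominant(self, random_trees):
        for tree in random_trees[:10]:
            C = bm_covariance(tree).to_numpy()
            assert np.allclose(C, C.T)
            assert np.all(np.diag(C)[:, None] >= C - 1e-12)
            w = np.linalg.eigvalsh(C)
            assert w.min() > -1e-9


class TestTransforms:
    def test_identity_is_noop(self, random_trees):
        tree = random_trees[0]
        C = bm_covariance(tree)
        out = apply_transforms(tree, TransformParams())
        assert np.allclose(C.to_numpy(), out.to_numpy(), atol=1e-12)

    def test_kappa_zero_unit_branches(self, three_taxon):
        tree, _ = three_taxon
        out = apply_transforms(tree, TransformParams(kappa=0.0))
        # every branch -> 1: A,B share one unit branch (depth 2); C depth 1
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(out.loc[["A", "B", "C"], ["A", "B", "C"]], expected)

    def test_lambda_zero_kills_offdiagonal(self, three_taxon):
        tree, _ = three_taxon
        out = apply_transforms(tree, TransformParams(lambda_=0.0)).to_numpy()
        assert np.allclose(out - np.diag(np.diag(out)), 0.0)
        assert np.allclose(np.diag(out), [2.0, 2.0, 2.0])

    def test_delta_elementwise(self, three_taxon):
        tree, _ = three_taxon
        out = apply_transforms(tree, TransformParams(delta=2.0))
        assert out.loc["A", "B"] == pytest.approx(1.0)
        assert out.loc["A", "A"] == pytest.approx(4.0)

    def test_kappa_on_matrix_rejected(self, three_taxon):
        tree, _ = three_taxon
        C = bm_covariance(tree)
        with pytest.raises(ValueError, match="kappa"):
            apply_transforms(C, TransformParams(kappa=0.5))

    @pytest.mark.parametrize(
        "kwargs", [{"kappa": -0.1}, {"lambda_": 1.5}, {"lambda_": -0.1}, {"delta": 0.0}]
    )
    def test_out_of_range_params(self, kwargs):
        with pytest.raises(ValueError):
            TransformParams(**kwargs)


class TestLoglik:
    def test_single_tip_standard_normal(self):
        C = np.array([[1.0]])
        fit = BMFit(sigma2=1.0, root_state=0.5, trend_beta=0.0,
                    transform=TransformParams(), loglik=0.0, model="A")
        assert bm_loglik(np.array([0.5]), C, fit) == pytest.approx(
            -0.9189385, abs=1e-6
        )

    def test_two_independent_tips(self):
        C = np.eye(2)
        fit = BMFit(sigma2=1.0, root_state=2.0, trend_beta=0.0,
                    transform=TransformParams(), loglik=0.0, model="A")
        assert bm_loglik(np.array([3.0, 1.0]), C, fit) == pytest.approx(
            -2.837877, abs=1e-5
        )

    def test_dense_equals_pruning_oracle(self, random_trees):
        """Two independent routes to the BM likelihood agree to 1e-8."""
        rng = np.random.default_rng(7)
        for tree in random_trees[:20]:
            labels = sorted(tip_labels(tree))
            x = rng.normal(size=len(labels)) * 2.0 + 1.0
            traits = dict(zip(labels, x))
            sigma2, alpha = 1.7, 0.9
            C = bm_covariance(tree).loc[labels, labels]
            fit = BMFit(sigma2=sigma2, root_state=alpha, trend_beta=0.0,
                        transform=TransformParams(), loglik=0.0, model="A")
            dense = bm_loglik(traits, C, fit)
            pruned = bm_loglik_pruning(tree, traits, sigma2, alpha)
            assert dense == pytest.approx(pruned, abs=1e-8)

    def test_model_b_with_zero_trend_equals_model_a(self, random_trees):
        tree = random_trees[1]
        labels = sorted(tip_labels(tree))
        x = np.linspace(-1, 2, len(labels))
        C = bm_covariance(tree).loc[labels, labels]
        fa = BMFit(sigma2=1.0, root_state=0.3, trend_beta=0.0,
                   transform=TransformParams(), loglik=0.0, model="A")
        fb = BMFit(sigma2=1.0, root_state=0.3, trend_beta=0.0,
                   transform=TransformParams(), loglik=0.0, model="B")
        assert bm_loglik(x, C, fa) == pytest.approx(bm_loglik(x, C, fb))


class TestFitML:
    def test_two_tip_star_matches_brute_force(self):
        """Profiled ML equals a brute-force grid search over (alpha, s2)."""
        tree = parse_newick("(A:1,B:1);")
        traits = {"A": 3.0, "B": 1.0}
        with pytest.raises(ValueError):
            fit_ml(traits, tree, model="A")  # guards n >= 3
        tree3 = parse_newick("(A:1,B:1,C:1);")
        traits3 = {"A": 3.0, "B": 1.0, "C": 2.0}
        fit = fit_ml(traits3, tree3, model="A")
        # brute force on the star tree (C = I)
        alphas = np.linspace(0, 4, 401)
        s2s = np.linspace(0.05, 5, 496)
        x = np.array([3.0, 1.0, 2.0])
        best = -np.inf
        for a in alphas:
            r = x - a
            q = r @ r
            ll = -0.5 * (3 * np.log(2 * np.pi * s2s) + q / s2s)
            i = np.argmax(ll)
            if ll[i] > best:
                best, best_a, best_s2 = ll[i], a, s2s[i]
        assert fit.root_state == pytest.approx(best_a, abs=0.02)
        assert fit.sigma2 == pytest.approx(best_s2, abs=0.02)
        assert fit.loglik == pytest.approx(best, abs=1e-3)

    def test_identity_transform_reproduces_plain_bm(self, random_trees):
        tree = random_trees[2]
        labels = sorted(tip_labels(tree))
        rng = np.random.default_rng(3)
        traits = dict(zip(labels, rng.normal(size=len(labels))))
        plain = fit_ml(traits, tree, model="A")
        fixed = fit_ml(
            traits, tree, model="A",
            fixed_values={"kappa": 1.0, "lambda": 1.0, "delta": 1.0},
        )
        assert plain.loglik == pytest.approx(fixed.loglik, abs=1e-12)

    def test_free_lambda_never_worse_than_fixed(self, random_trees):
        tree = random_trees[3]
        labels = sorted(tip_labels(tree))
        rng = np.random.default_rng(4)
        traits = dict(zip(labels, rng.normal(size=len(labels))))
        free = fit_ml(traits, tree, model="A", free_transforms=("lambda",))
        for lam in (0.0, 0.3, 0.7, 1.0):
            fixed = fit_ml(
                traits, tree, model="A", fixed_values={"lambda": lam}
            )
            assert free.loglik >= fixed.loglik - 1e-6

    def test_branch_rescaling_invariance(self, random_trees):
        """logL is unchanged when branches x c and sigma2 / c jointly."""
        tree = random_trees[4]
        labels = sorted(tip_labels(tree))
        rng = np.random.default_rng(5)
        x = rng.normal(size=len(labels))
        traits = dict(zip(labels, x))
        fit = fit_ml(traits, tree, model="A")
        scaled = tree.clone(depth=1)
        for node in scaled.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.edge.length * 4.0
        fit_scaled = fit_ml(traits, scaled, model="A")
        assert fit_scaled.sigma2 == pytest.approx(fit.sigma2 / 4.0, rel=1e-8)
        assert fit_scaled.loglik == pytest.approx(fit.loglik, abs=1e-8)

    def test_ultrametric_refuses_trend(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        traits = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        with pytest.raises(ValueError, match="ultrametric"):
            fit_ml(traits, tree, model="B")

    def test_directional_trend_recovered(self):
        # rate-jittered branches make the tree non-ultrametric, so the
        # per-tip path lengths vary and the trend is identifiable
        from phylocontrast.synthetic_data import jitter_branch_lengths

        base = simulate_tree(SimSpec(n_tips=80, seed=31))
        tree = jitter_branch_lengths(
            base, np.random.default_rng(33), sd_log=0.4
        )
        spec = SimSpec(n_tips=80, sigma2=0.05, root_state=0.0,
                       trend_beta=2.0, seed=32)
        traits = simulate_bm(tree, spec)
        fit = fit_ml(traits, tree, model="B")
        assert fit.model == "B"
        assert fit.trend_beta == pytest.approx(2.0, rel=0.25)

    def test_constant_traits_degenerate(self, random_trees):
        tree = random_trees[5]
        traits = {l: 1.0 for l in tip_labels(tree)}
        fit = fit_ml(traits, tree, model="A")
        assert fit.degenerate
        assert fit.sigma2 == 0.0

    def test_lambda_recovery_smoke(self):
        """lambda fitted on lambda=1 data should stay near the top."""
        hits = 0
        for seed in range(10):
            tree = simulate_tree(SimSpec(n_tips=150, seed=100 + seed))
            traits = simulate_bm(
                tree, SimSpec(n_tips=150, sigma2=1.0, seed=200 + seed)
            )
            fit = fit_ml(traits, tree, model="A", free_transforms=("lambda",))
            if 0.85 <= fit.transform.lambda_ <= 1.0:
                hits += 1
        assert hits >= 7


class TestEstimator:
    def test_fit_and_score(self, random_trees):
        tree = random_trees[6]
        labels = sorted(tip_labels(tree))
        rng = np.random.default_rng(8)
        traits = dict(zip(labels, rng.normal(size=len(labels))))
        est = PagelBrownian(model="A", free_transforms=("lambda",))
        est.fit(tree, traits)
        assert 0.0 <= est.transform_.lambda_ <= 1.0
        assert est.score(tree, traits) == pytest.approx(est.loglik_, abs=1e-9)

    def test_sklearn_param_interface(self):
        est = PagelBrownian(model="B")
        params = est.get_params()
        assert params["model"] == "B"
        est.set_params(model="A")
        assert est.model == "A"
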