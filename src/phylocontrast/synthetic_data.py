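"""Simulated trees and traits with the structure the analysis assumes.

Provides a Yule (pure-birth) tree simulator, Brownian trait simulation
(single- and correlated two-trait) with Pagel transforms, and a
"passiflora-like" preset: a 50-tip tree with two sister clades of 36 and
13 tips plus an outgroup, whose clades differ in trait mean and
dispersion the way the packaged genome-size/flower-diameter table does,
together with a jittered tree set standing in for a posterior sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .phylo_io import TraitTable, TreeSet, parse_newick, write_newick
from .traitmodels import TransformParams, apply_transforms

import pandas as pd

__all__ = [
    "SimSpec",
    "yule_depth_expectation",
    "simulate_tree",
    "simulate_bm",
    "simulate_bm_correlated",
    "jitter_branch_lengths",
    "make_passiflora_like",
    "PassifloraLike",
]


@dataclass
class SimSpec:
    """Parameters of one simulation run (the seed is always recorded)."""

    n_tips: int
    birth_rate: float = 1.0
    sigma2: float = 1.0
    root_state: float = 0.0
    transform: TransformParams = field(default_factory=TransformParams)
    trend_beta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")


def yule_depth_expectation(n_tips: int, birth_rate: float = 1.0) -> float:
    """Expected root-to-tip depth of the simulated Yule tree.

    The simulator starts at the root split (2 lineages) and extends all
    tips by one final inter-event time, so the depth is a sum of
    exponential segments with rates k*birth for k = 2..n.
    """
    return sum(1.0 / (k * birth_rate) for k in range(2, n_tips + 1))


def simulate_tree(spec: SimSpec, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Simulate a Yule tree with ``spec.n_tips`` tips.

    Branch lengths are in time units (1 / birth_rate per expected
    waiting time per lineage).  Tips are labelled t1..tn in order of
    creation.  Reproducible: the same spec/seed gives the same Newick.
    """
    rng = rng or np.random.default_rng(spec.seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    birth_time = {c1: 0.0, c2: 0.0}
    active = [c1, c2]
    now = 0.0
    while len(active) < spec.n_tips:
        k = len(active)
        now += rng.exponential(1.0 / (k * spec.birth_rate))
        idx = rng.integers(k)
        node = active.pop(idx)
        node.edge.length = now - birth_time[node]
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        birth_time[a] = birth_time[b] = now
        active.extend([a, b])
    # one trailing segment so the youngest cherries keep positive lengths
    now += rng.exponential(1.0 / (len(active) * spec.birth_rate))
    ns = tree.taxon_namespace
    for i, node in enumerate(active, start=1):
        node.edge.length = now - birth_time[node]
        node.taxon = ns.new_taxon(label=f"t{i}")
    return tree


def _branch_walk(tree, rng, sigma, root_state, beta, kappa):
    values = {tree.seed_node: np.asarray(root_state, dtype=float)}
    out = {}
    k = np.atleast_1d(sigma).shape[0]
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        b = float(node.edge.length or 0.0) ** kappa
        step = rng.normal(size=k) * np.sqrt(b)
        incr = sigma @ step if k > 1 else float(sigma[0, 0]) * step[0]
        values[node] = values[node.parent_node] + beta * b + incr
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


def simulate_bm(
    tree: dendropy.Tree,
    spec: SimSpec,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Simulate one Brownian trait on a tree.

    With identity (or kappa-only) transforms the walk runs branch by
    branch in preorder: child = parent + beta*b + N(0, sigma2*b).  With
    lambda or delta active the tip vector is drawn in one shot from the
    multivariate normal implied by the transformed covariance, which is
    the same distribution.
    """
    rng = rng or np.random.default_rng(spec.seed)
    tp = spec.transform
    if tp.lambda_ == 1.0 and tp.delta == 1.0:
        sig = np.array([[np.sqrt(spec.sigma2)]])
        vals = _branch_walk(
            tree, rng, sig, spec.root_state, spec.trend_beta, tp.kappa
        )
        return {k: float(v) for k, v in vals.items()}
    C = apply_transforms(tree, tp)
    labels = list(C.index)
    Cm = C.to_numpy()
    mean = spec.root_state + spec.trend_beta * np.diag(Cm)
    L = np.linalg.cholesky(Cm + 1e-12 * np.eye(len(labels)))
    x = mean + np.sqrt(spec.sigma2) * (L @ rng.normal(size=len(labels)))
    return dict(zip(labels, map(float, x)))


def simulate_bm_correlated(
    tree: dendropy.Tree,
    sigma2: tuple[float, float],
    correlation: float,
    root_state: tuple[float, float],
    rng: np.random.Generator,
    kappa: float = 1.0,
) -> dict[str, np.ndarray]:
    """Two traits under correlated Brownian motion (shared increments).

    The 2x2 per-unit-time trait covariance is built from the two rates
    and the cross-trait correlation and applied to independent Gaussian
    increments through its Cholesky factor.
    """
    s1, s2 = np.sqrt(sigma2[0]), np.sqrt(sigma2[1])
    Sigma = np.array(
        [
            [sigma2[0], correlation * s1 * s2],
            [correlation * s1 * s2, sigma2[1]],
        ]
    )
    Lc = np.linalg.cholesky(Sigma)
    return _branch_walk(
        tree, rng, Lc, np.asarray(root_state, float), 0.0, kappa
    )


def jitter_branch_lengths(
    tree: dendropy.Tree, rng: np.random.Generator, sd_log: float = 0.1
) -> dendropy.Tree:
    """Copy of tree with each branch scaled by lognormal(0, sd_log) noise."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is not None:
            node.edge.length = float(
                node.edge.length * rng.lognormal(0.0, sd_log)
            )
    return clone


def _scale_to_depth(tree: dendropy.Tree, target_mean_depth: float) -> None:
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    factor = target_mean_depth / float(np.mean(depths))
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is not None:
            node.edge.length = float(node.edge.length * factor)


@dataclass
class PassifloraLike:
    """Bundle of the passiflora-like preset outputs."""

    tree: dendropy.Tree
    trees: TreeSet
    traits: TraitTable
    seed: int
    params: dict


# Study-condition targets for the two-clade preset: clade trait means and
# sample SDs of the packaged table (GS in pg, FD in cm).
_CLADE_TARGETS = {
    "Passiflora": {"n": 36, "gs": (1.311, 0.431), "fd": (7.28, 2.23)},
    "Decaloba": {"n": 13, "gs": (0.413, 0.239), "fd": (2.92, 0.75)},
}
_CLADE_HEIGHT = 0.75  # mean root-to-tip depth within each clade
_STEM_LENGTH = 0.25
_OUTGROUP_DEPTH = 1.2
_CROSS_TRAIT_R = 0.6
#: effective fraction of root-to-tip Brownian variance that spreads tips
#: around the clade mean (the complement is shared ancestry); ~0.65 for a
#: Yule clade, used to convert a target tip SD into a Brownian rate
_INDEP_FRACTION = 0.65
_GS_FLOOR, _FD_FLOOR = 0.05, 0.1
#: lognormal sd of per-branch rate variation in the base tree
_RATE_JITTER = 0.3


def make_passiflora_like(
    seed: int, n_posterior_trees: int = 100, correlation: float = _CROSS_TRAIT_R
) -> PassifloraLike:
    """Simulate a dataset shaped like the packaged Passiflora study.

    A 50-tip tree: sister clades of 36 and 13 tips (clade height 0.75,
    stems 0.25, time units) plus an outgroup at depth 1.  Genome size
    and flower diameter evolve as correlated Brownian motion
    (cross-trait correlation 0.6) within each clade, started at the
    clade's target mean, with per-clade rates calibrated so tip SDs land
    near the packaged table's clade SDs.  A set of ``n_posterior_trees``
    branch-length-jittered copies (lognormal noise, sd 0.1 on the log
    scale) emulates a posterior tree sample.
    """
    rng = np.random.default_rng(seed)
    clades = {}
    for name, tgt in _CLADE_TARGETS.items():
        sub = simulate_tree(SimSpec(n_tips=tgt["n"], seed=0), rng=rng)
        _scale_to_depth(sub, _CLADE_HEIGHT)
        # molecular branch lengths: lognormal rate variation breaks the
        # ultrametricity of the pure-birth clock
        sub = jitter_branch_lengths(sub, rng, sd_log=_RATE_JITTER)
        clades[name] = sub

    prefix = {"Passiflora": "P", "Decaloba": "D"}
    rows = []
    for name, tgt in _CLADE_TARGETS.items():
        sub = clades[name]
        for i, leaf in enumerate(sub.leaf_node_iter(), start=1):
            leaf.taxon = sub.taxon_namespace.new_taxon(
                label=f"{prefix[name]}{i:02d}"
            )
        # convert a target tip SD into a per-unit-time rate: only part of
        # the root-to-tip variance is independent across tips (the rest is
        # shared ancestry and does not spread tips around the clade mean)
        rate_gs = tgt["gs"][1] ** 2 / (_CLADE_HEIGHT * _INDEP_FRACTION)
        rate_fd = tgt["fd"][1] ** 2 / (_CLADE_HEIGHT * _INDEP_FRACTION)
        vals = simulate_bm_correlated(
            sub,
            sigma2=(rate_gs, rate_fd),
            correlation=correlation,
            root_state=(tgt["gs"][0], tgt["fd"][0]),
            rng=rng,
        )
        for sp, (gs, fd) in vals.items():
            rows.append(
                {
                    "species": sp,
                    "clade": name,
                    "gs_pg": max(float(gs), _GS_FLOOR),
                    "fd_cm": max(float(fd), _FD_FLOOR),
                }
            )

    tree = dendropy.Tree()
    root = tree.seed_node
    ingroup = dendropy.Node()
    root.add_child(ingroup)
    ingroup.edge.length = _OUTGROUP_DEPTH - _CLADE_HEIGHT - _STEM_LENGTH
    out_tip = dendropy.Node()
    root.add_child(out_tip)
    out_tip.edge.length = _OUTGROUP_DEPTH
    out_tip.taxon = tree.taxon_namespace.new_taxon(label="OUT")
    for name, sub in clades.items():
        attach = sub.seed_node
        ingroup.add_child(attach)
        attach.edge.length = _STEM_LENGTH
    tree.update_taxon_namespace()
    rows.append(
        {
            "species": "OUT",
            "clade": "outgroup",
            "gs_pg": max(float(rng.normal(0.815, 0.05)), _GS_FLOOR),
            "fd_cm": max(float(rng.normal(4.69, 0.3)), _FD_FLOOR),
        }
    )
    traits = TraitTable(pd.DataFrame(rows))

    posterior = [
        jitter_branch_lengths(tree, rng) for _ in range(n_posterior_trees)
    ]
    params = {
        "seed": seed,
        "clade_targets": _CLADE_TARGETS,
        "correlation": correlation,
        "clade_height": _CLADE_HEIGHT,
        "stem_length": _STEM_LENGTH,
        "n_posterior_trees": n_posterior_trees,
    }
    return PassifloraLike(
        tree=tree, trees=TreeSet(posterior), traits=traits, seed=seed,
        params=params,
    )
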