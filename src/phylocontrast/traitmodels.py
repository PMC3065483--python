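"""Brownian-motion trait models with Pagel branch-length transforms.

A continuous trait evolving by Brownian motion on a rooted tree is
multivariate normal across the tips: mean alpha (the root state) and
covariance sigma^2 * C, where C[i,j] is the branch length shared by the
root-to-tip paths of i and j.  Three one-parameter deformations of C
probe the tempo and mode of evolution:

* kappa — each branch length b is replaced by b**kappa before C is
  rebuilt.  kappa = 1 is gradual change proportional to branch length;
  kappa = 0 makes every branch count equally ("punctuational" change at
  nodes).
* delta — every element of C is raised to the power delta.  delta > 1
  inflates recent shared history (late change dominates); delta < 1
  inflates early history.
* lambda — off-diagonal elements of C are multiplied by lambda in
  [0, 1].  lambda = 1 keeps the full phylogenetic covariance; lambda = 0
  is a star phylogeny (no signal).

Two mean structures are supported: a drift-free random walk ("A", mean
alpha everywhere) and a directional model ("B", mean alpha + beta times
the root-to-tip path length, identifiable only on non-ultrametric
trees).  alpha (and beta) are profiled out by GLS and sigma^2
analytically, leaving a low-dimensional numerical search over the free
transform parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

from . import pic
from .phylo_io import TraitTable

__all__ = [
    "TransformParams",
    "BMFit",
    "tree_design",
    "bm_covariance",
    "apply_transforms",
    "bm_loglik",
    "bm_loglik_pruning",
    "fit_ml",
    "PagelBrownian",
]

_KAPPA_BOUNDS = (0.0, 3.0)
_LAMBDA_BOUNDS = (0.0, 1.0)
_DELTA_BOUNDS = (1e-4, 3.0)
#: documented multi-start grid for the transform search
_STARTS = {
    "kappa": (0.5, 1.0, 2.0),
    "lambda": (0.2, 0.6, 1.0),
    "delta": (0.5, 1.0, 2.0),
}


@dataclass(frozen=True)
class TransformParams:
    """Pagel transform parameters; (1, 1, 1) is the identity."""

    kappa: float = 1.0
    lambda_: float = 1.0
    delta: float = 1.0

    def __post_init__(self):
        if self.kappa < _KAPPA_BOUNDS[0]:
            raise ValueError("kappa must be >= 0")
        if not (_LAMBDA_BOUNDS[0] <= self.lambda_ <= _LAMBDA_BOUNDS[1]):
            raise ValueError("lambda must lie in [0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")

    def is_identity(self) -> bool:
        return self.kappa == 1.0 and self.lambda_ == 1.0 and self.delta == 1.0


@dataclass
class BMFit:
    """A fitted Brownian model."""

    sigma2: float
    root_state: float
    trend_beta: float
    transform: TransformParams
    loglik: float
    model: str
    n_tips: int = 0
    degenerate: bool = False
    reml: bool = False

    def __post_init__(self):
        if self.model not in ("A", "B"):
            raise ValueError("model must be 'A' or 'B'")
        if self.model == "A" and self.trend_beta != 0.0:
            raise ValueError("Model A has no trend")


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

def tree_design(tree: dendropy.Tree):
    """Root-path incidence decomposition of a tree.

    Returns ``(labels, A, b)`` with tip labels sorted, ``A`` the
    (tips x edges) 0/1 incidence matrix of root-to-tip paths and ``b``
    the edge-length vector, so that ``C = A @ diag(b) @ A.T``.  Branch
    transforms then act on ``b`` without touching the topology.
    """
    edges = []
    edge_index = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        edge_index[node] = len(edges)
        edges.append(float(node.edge.length or 0.0))
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in leaves]
    A = np.zeros((len(leaves), len(edges)))
    for i, leaf in enumerate(leaves):
        node = leaf
        while node.parent_node is not None:
            A[i, edge_index[node]] = 1.0
            node = node.parent_node
    return labels, A, np.asarray(edges, dtype=float)


def bm_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian covariance structure of the tips (shared path lengths).

    ``C[i, j]`` is the length of the root-to-MRCA(i, j) path; the
    diagonal holds root-to-tip distances.  Rows/columns are labelled by
    tip name, sorted.
    """
    labels, A, b = tree_design(tree)
    C = (A * b) @ A.T
    return pd.DataFrame(C, index=labels, columns=labels)


def apply_transforms(obj, params: TransformParams) -> pd.DataFrame | np.ndarray:
    """Apply kappa -> delta -> lambda to a tree or covariance matrix.

    kappa needs the branch lengths, so passing a plain matrix with
    kappa != 1 is an error; delta acts element-wise on C and lambda
    scales the off-diagonal only.
    """
    if isinstance(obj, dendropy.Tree):
        labels, A, b = tree_design(obj)
        C = (A * b**params.kappa) @ A.T
        out = pd.DataFrame(
            _transform_cov(C, params), index=labels, columns=labels
        )
        return out
    C = np.asarray(obj, dtype=float)
    if params.kappa != 1.0:
        raise ValueError(
            "kappa transforms branch lengths; pass the tree, not the matrix"
        )
    res = _transform_cov(C.copy(), params)
    if isinstance(obj, pd.DataFrame):
        return pd.DataFrame(res, index=obj.index, columns=obj.columns)
    return res


def _transform_cov(C: np.ndarray, params: TransformParams) -> np.ndarray:
    if params.delta != 1.0:
        C = np.sign(C) * np.abs(C) ** params.delta
    if params.lambda_ != 1.0:
        d = np.diag(C).copy()
        C = C * params.lambda_
        np.fill_diagonal(C, d)
    return C


def _chol_with_ridge(C: np.ndarray):
    """Cholesky factor of C, adding one small ridge if needed."""
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        n = C.shape[0]
        ridge = 1e-10 * np.trace(C) / n
        try:
            return linalg.cholesky(C + ridge * np.eye(n), lower=True)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "covariance singular even after ridge; collapse zero-length "
                "branches or drop duplicate tips"
            ) from exc


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _mvn_loglik(x, mean, cov_factor, sigma2):
    """MVN log density given the Cholesky factor of C (cov = sigma2*C)."""
    n = x.shape[0]
    L = cov_factor
    resid = x - mean
    z = linalg.solve_triangular(L, resid, lower=True)
    logdet_C = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (
        n * np.log(2.0 * np.pi * sigma2)
        + logdet_C
        + z @ z / sigma2
    )


def _align(traits, labels):
    if isinstance(traits, Mapping):
        missing = [l for l in labels if l not in traits]
        if missing:
            raise ValueError(f"no trait value for tips {missing}")
        return np.array([float(traits[l]) for l in labels])
    x = np.asarray(traits, dtype=float)
    if x.shape[0] != len(labels):
        raise ValueError("trait vector length does not match tip count")
    return x


def bm_loglik(traits, C, fit: BMFit) -> float:
    """Log-likelihood (nats) of tip data under a fitted Brownian model.

    ``C`` is the (already transformed) covariance structure aligned with
    ``traits``; the mean is the root state, plus trend * root-to-tip
    path length (diagonal of C) under the directional model.
    """
    if isinstance(C, pd.DataFrame):
        labels = list(C.index)
        x = _align(traits, labels)
        Cm = C.to_numpy(dtype=float)
    else:
        Cm = np.asarray(C, dtype=float)
        x = np.asarray(traits, dtype=float)
    mean = np.full(x.shape[0], fit.root_state)
    if fit.model == "B":
        mean = mean + fit.trend_beta * np.diag(Cm)
    L = _chol_with_ridge(Cm)
    return float(_mvn_loglik(x, mean, L, fit.sigma2))


def bm_loglik_pruning(
    tree: dendropy.Tree, traits: Mapping[str, float], sigma2: float, alpha: float
) -> float:
    """Random-walk BM log-likelihood via the contrasts recursion.

    Independent route to the same quantity as the dense multivariate
    normal: the joint density factors into the n-1 standardized-contrast
    densities times the density of the GLS root estimate (unit Jacobian),
    so no covariance matrix is ever formed.  Random-walk mean only.
    """
    cs = pic.compute_contrasts(tree, traits)
    t = cs.table
    ll = 0.0
    for raw, sd in zip(t["raw"], t["sd"]):
        var = sigma2 * sd * sd
        ll += -0.5 * (np.log(2.0 * np.pi * var) + raw * raw / var)
    var_root = sigma2 * cs.root_variance
    ll += -0.5 * (
        np.log(2.0 * np.pi * var_root)
        + (cs.root_value - alpha) ** 2 / var_root
    )
    return float(ll)


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

def _profile_loglik(x, C, model, reml=False):
    """GLS-profile alpha (and beta), then sigma2, on a fixed C.

    Returns (loglik, alpha, beta, sigma2, degenerate).
    """
    n = x.shape[0]
    L = _chol_with_ridge(C)
    d = np.diag(C)
    if model == "B":
        X = np.column_stack([np.ones(n), d])
        if np.ptp(d) <= 1e-10 * max(np.max(np.abs(d)), 1.0):
            raise ValueError(
                "tree is ultrametric (all root-to-tip paths equal): the "
                "directional trend is unidentifiable; fit model 'A' instead"
            )
    else:
        X = np.ones((n, 1))
    Xs = linalg.solve_triangular(L, X, lower=True)
    xs = linalg.solve_triangular(L, x, lower=True)
    coef, *_ = np.linalg.lstsq(Xs, xs, rcond=None)
    resid = xs - Xs @ coef
    q = float(resid @ resid)
    logdet_C = 2.0 * np.sum(np.log(np.diag(L)))
    p = X.shape[1]
    dof = n - p if reml else n
    if q <= 1e-12 * max(float(x @ x), 1.0):
        # constant trait (after mean removal): boundary sigma2 -> 0
        return np.inf, float(coef[0]), float(coef[1]) if p == 2 else 0.0, 0.0, True
    sigma2 = q / dof
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet_C + q / sigma2)
    alpha = float(coef[0])
    beta = float(coef[1]) if p == 2 else 0.0
    return float(ll), alpha, beta, sigma2, False


def fit_ml(
    traits,
    tree: dendropy.Tree,
    model: str = "A",
    free_transforms: Sequence[str] = (),
    fixed_values: Mapping[str, float] | None = None,
    reml: bool = False,
) -> BMFit:
    """Maximum-likelihood Brownian fit with optional free transforms.

    alpha (and the trend beta under model "B") are profiled by GLS and
    sigma2 analytically; the remaining search over the free transform
    parameters runs bounded L-BFGS-B from a fixed grid of starts, so the
    result is deterministic without a seed.

    ``fixed_values`` pins non-free transforms (default 1.0 each).
    """
    if model not in ("A", "B"):
        raise ValueError("model must be 'A' or 'B'")
    free = list(free_transforms)
    for name in free:
        if name not in ("kappa", "lambda", "delta"):
            raise ValueError(f"unknown transform {name!r}")
    fixed = {"kappa": 1.0, "lambda": 1.0, "delta": 1.0}
    fixed.update(fixed_values or {})
    labels, A, b = tree_design(tree)
    x = _align(traits, labels)
    n = len(labels)
    if n < (4 if model == "B" else 3):
        raise ValueError(f"too few tips ({n}) for model {model}")

    def build_C(theta: Mapping[str, float]) -> np.ndarray:
        params = TransformParams(
            kappa=theta["kappa"], lambda_=theta["lambda"], delta=theta["delta"]
        )
        C = (A * b ** params.kappa) @ A.T
        return _transform_cov(C, params)

    def objective(vec):
        theta = dict(fixed)
        theta.update(dict(zip(free, vec)))
        try:
            C = build_C(theta)
            ll, *_ = _profile_loglik(x, C, model, reml=reml)
        except (linalg.LinAlgError, ValueError):
            return 1e10
        if not np.isfinite(ll):
            return -1e10  # degenerate: sigma2 -> 0, likelihood unbounded
        return -ll

    bounds_map = {
        "kappa": _KAPPA_BOUNDS,
        "lambda": _LAMBDA_BOUNDS,
        "delta": _DELTA_BOUNDS,
    }
    if free:
        bounds = [bounds_map[name] for name in free]
        best = None
        for start in itertools.product(*(_STARTS[name] for name in free)):
            res = optimize.minimize(
                objective,
                np.asarray(start, dtype=float),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = dict(fixed)
        theta.update(dict(zip(free, best.x)))
    else:
        theta = dict(fixed)

    C = build_C(theta)
    ll, alpha, beta, sigma2, degenerate = _profile_loglik(x, C, model, reml=reml)
    return BMFit(
        sigma2=sigma2,
        root_state=alpha,
        trend_beta=beta if model == "B" else 0.0,
        transform=TransformParams(
            kappa=theta["kappa"], lambda_=theta["lambda"], delta=theta["delta"]
        ),
        loglik=ll,
        model=model,
        n_tips=n,
        degenerate=degenerate,
        reml=reml,
    )


class PagelBrownian(BaseEstimator):
    """Estimator interface to the transformed Brownian models.

    Parameters mirror :func:`fit_ml`; after ``fit`` the usual
    trailing-underscore attributes hold the estimates.

    Example
    -------
    >>> est = PagelBrownian(model="A", free_transforms=("lambda",))
    >>> est.fit(tree, {"A": 0.1, "B": 0.3, "C": 1.2})   # doctest: +SKIP
    >>> est.transform_.lambda_                           # doctest: +SKIP
    """

    def __init__(
        self,
        model: str = "A",
        free_transforms: Sequence[str] = (),
        fixed_values: Mapping[str, float] | None = None,
        trait: str | None = None,
        reml: bool = False,
    ):
        self.model = model
        self.free_transforms = free_transforms
        self.fixed_values = fixed_values
        self.trait = trait
        self.reml = reml

    def fit(self, tree: dendropy.Tree, traits) -> "PagelBrownian":
        if isinstance(traits, TraitTable):
            if self.trait is None:
                raise ValueError("set trait= to fit from a TraitTable")
            traits = traits.values_for(self.trait)
        result = fit_ml(
            traits,
            tree,
            model=self.model,
            free_transforms=self.free_transforms,
            fixed_values=self.fixed_values,
            reml=self.reml,
        )
        self.fit_ = result
        self.sigma2_ = result.sigma2
        self.root_state_ = result.root_state
        self.trend_beta_ = result.trend_beta
        self.transform_ = result.transform
        self.loglik_ = result.loglik
        self.n_tips_ = result.n_tips
        self.degenerate_ = result.degenerate
        return self

    def score(self, tree: dendropy.Tree, traits) -> float:
        """Log-likelihood of data under the already-fitted parameters."""
        if isinstance(traits, TraitTable):
            traits = traits.values_for(self.trait)
        C = apply_transforms(tree, self.transform_)
        return bm_loglik(traits, C, self.fit_)
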