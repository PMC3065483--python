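"""MCMC over Brownian model parameters, averaged across a tree set.

A Metropolis-Hastings sampler explores (sigma2, alpha, optional trend
beta, and any free Pagel transforms) under independent uniform priors,
while the tree itself is resampled uniformly from a posterior tree set
with a small per-generation probability, so the chain integrates over
phylogenetic uncertainty.  Marginal likelihoods are estimated by the
harmonic mean of the sampled likelihoods (high-variance, but fully in
log space; a stepping-stone estimator is available as a cross-check)
and models are compared on the 2 * delta-log-marginal Bayes-factor
scale: > 2 positive, > 5 strong, > 10 very strong evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

from .phylo_io import TraitTable, TreeSet
from .traitmodels import TransformParams, _transform_cov, tree_design

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "McmcTrace",
    "BayesFactorResult",
    "default_priors",
    "mcmc_run",
    "log_marginal_harmonic",
    "log_marginal_steppingstone",
    "bayes_factor",
    "run_model_battery",
]

_TRANSFORM_BOUNDS = {"kappa": (0.0, 3.0), "lambda": (0.0, 1.0), "delta": (1e-4, 3.0)}


@dataclass(frozen=True)
class ModelSpec:
    """Which mean structure and which transforms the chain samples.

    ``free`` lists transform parameters sampled under their priors;
    everything else is pinned at ``fixed`` (default 1.0).  Model "B"
    additionally samples the directional trend beta.
    """

    model: str = "A"
    free: tuple[str, ...] = ()
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ("A", "B"):
            raise ValueError("model must be 'A' or 'B'")
        for name in self.free:
            if name not in _TRANSFORM_BOUNDS:
                raise ValueError(f"unknown transform {name!r}")

    def fixed_value(self, name: str) -> float:
        return float(self.fixed.get(name, 1.0))


@dataclass
class McmcTrace:
    """Retained post-burn-in samples plus chain metadata."""

    samples: pd.DataFrame  # parameter columns + tree_index + loglik
    generations: int
    burnin: int
    thinning: int
    seed: int
    acceptance_rate: float
    proposal_widths: dict

    @property
    def loglik(self) -> np.ndarray:
        return self.samples["loglik"].to_numpy()

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class BayesFactorResult:
    bf: float
    favored: str
    category: str  # none | positive | strong | very strong


def default_priors(x: np.ndarray, mean_depth: float) -> dict[str, tuple[float, float]]:
    """Uniform prior bounds scaled to the data.

    sigma2 ~ U(0, 100 * var(x)); alpha ~ U over the observed range
    widened by 3 SD; beta ~ U(-10, 10) in units of trait SD per unit
    branch length; lambda ~ U(0, 1); kappa, delta ~ U(0, 3).
    """
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else max(abs(float(x[0])), 1.0)
    sd = sd if sd > 0 else 1.0
    var = sd * sd
    beta_scale = 10.0 * sd / max(mean_depth, 1e-12)
    return {
        "sigma2": (1e-12, 100.0 * var),
        "alpha": (float(np.min(x)) - 3.0 * sd, float(np.max(x)) + 3.0 * sd),
        "beta": (-beta_scale, beta_scale),
        "kappa": _TRANSFORM_BOUNDS["kappa"],
        "lambda": _TRANSFORM_BOUNDS["lambda"],
        "delta": _TRANSFORM_BOUNDS["delta"],
    }


class _Likelihood:
    """Dense BM likelihood over a tree set with covariance caching.

    The Cholesky factor only depends on (tree index, kappa, delta,
    lambda); proposals touching sigma2/alpha/beta reuse it, which is
    what makes long chains affordable.
    """

    def __init__(self, trees: TreeSet, traits: Mapping[str, float]):
        self.designs = []
        labels0 = None
        for tree in trees:
            labels, A, b = tree_design(tree)
            if labels0 is None:
                labels0 = labels
            elif labels != labels0:
                raise ValueError("trees in the set disagree on tip labels")
            self.designs.append((A, b))
        missing = [l for l in labels0 if l not in traits]
        if missing:
            raise ValueError(f"no trait value for tips {missing}")
        self.x = np.array([float(traits[l]) for l in labels0])
        self.n = len(labels0)
        self.labels = labels0
        self._key = None
        self._chol = None
        self._logdet = None
        self._diag = None

    def _factor(self, tree_idx: int, kappa: float, delta: float, lam: float):
        key = (tree_idx, kappa, delta, lam)
        if key != self._key:
            A, b = self.designs[tree_idx]
            C = (A * b**kappa) @ A.T
            C = _transform_cov(
                C, TransformParams(kappa=1.0, lambda_=lam, delta=delta)
            )
            L = linalg.cholesky(C + 1e-10 * np.eye(self.n) * np.trace(C) / self.n,
                                lower=True)
            self._key = key
            self._chol = L
            self._logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            self._diag = np.diag(C).copy()
        return self._chol, self._logdet, self._diag

    def loglik(self, tree_idx: int, params: Mapping[str, float], model: str) -> float:
        L, logdet, diag = self._factor(
            tree_idx, params["kappa"], params["delta"], params["lambda"]
        )
        mean = params["alpha"] + (
            params["beta"] * diag if model == "B" else 0.0
        )
        resid = self.x - mean
        z = linalg.solve_triangular(L, resid, lower=True)
        s2 = params["sigma2"]
        return float(
            -0.5 * (self.n * np.log(2.0 * np.pi * s2) + logdet + z @ z / s2)
        )


def _as_values(traits, trait: str | None) -> Mapping[str, float]:
    if isinstance(traits, TraitTable):
        if trait is None:
            raise KeyError("a trait name is required with a TraitTable")
        return traits.values_for(trait)
    return traits


def mcmc_run(
    traits,
    trees: TreeSet,
    model_spec: ModelSpec,
    priors: Mapping[str, tuple[float, float]] | None = None,
    generations: int = 1_000_000,
    burnin: int = 100_000,
    thinning: int = 100,
    seed: int = 0,
    trait: str | None = None,
    tree_move_prob: float = 0.1,
    likelihood_power: float = 1.0,
) -> McmcTrace:
    """Sample the posterior of a Brownian model over a tree set.

    One parameter is updated per generation with a sliding-window
    proposal (reflected rejection at the uniform prior bounds); with
    probability ``tree_move_prob`` the generation instead proposes a
    uniformly drawn tree from the set.  Proposal widths are tuned
    towards 20-40% acceptance during burn-in and frozen afterwards.
    Point priors (zero-width bounds) pin a parameter.  The chain is
    reproducible given the seed.  ``likelihood_power`` tempers the
    likelihood (used by the stepping-stone estimator).
    """
    if generations <= burnin:
        raise ValueError("generations must exceed burnin")
    values = _as_values(traits, trait)
    like = _Likelihood(trees, values)
    mean_depth = float(
        np.mean([np.diag((A * b) @ A.T).mean() for A, b in like.designs[:1]])
    )
    pri = default_priors(like.x, mean_depth)
    pri.update(priors or {})
    for name, (lo, hi) in pri.items():
        if lo > hi:
            raise ValueError(f"empty prior support for {name}")

    model = model_spec.model
    sampled = ["sigma2", "alpha"]
    if model == "B":
        sampled.append("beta")
    sampled += [t for t in model_spec.free]
    # point priors pin parameters
    sampled = [p for p in sampled if pri[p][0] < pri[p][1]]

    init_var = float(np.var(like.x, ddof=1)) if like.n > 1 else 1.0
    if not np.isfinite(init_var) or init_var <= 0:
        init_var = 1.0
    params = {
        "sigma2": float(np.clip(init_var, *pri["sigma2"])),
        "alpha": float(np.clip(np.mean(like.x), *pri["alpha"])),
        "beta": 0.0,
        "kappa": model_spec.fixed_value("kappa"),
        "lambda": model_spec.fixed_value("lambda"),
        "delta": model_spec.fixed_value("delta"),
    }
    for name in ("sigma2", "alpha", "beta"):
        lo, hi = pri[name]
        params[name] = float(np.clip(params[name], lo, hi))
    for name in model_spec.free:
        lo, hi = pri[name]
        params[name] = float(np.clip(params[name], lo, hi))

    rng = np.random.default_rng(seed)
    widths = {p: (pri[p][1] - pri[p][0]) / 10.0 for p in sampled}
    tree_idx = 0
    ll = like.loglik(tree_idx, params, model)

    n_prop = {p: 0 for p in sampled}
    n_acc = {p: 0 for p in sampled}
    total_prop = 0
    total_acc = 0
    consecutive_rejects = 0
    warned = False
    records = []
    tune_interval = max(200, burnin // 50) if burnin else 0

    for gen in range(1, generations + 1):
        moved = False
        if len(trees) > 1 and rng.random() < tree_move_prob:
            new_idx = int(rng.integers(len(trees)))
            new_ll = like.loglik(new_idx, params, model)
            total_prop += 1
            if np.log(rng.random()) < likelihood_power * (new_ll - ll):
                tree_idx, ll, moved = new_idx, new_ll, True
                total_acc += 1
            else:
                # restore cache to current state lazily on next eval
                pass
        elif sampled:
            p = sampled[int(rng.integers(len(sampled)))]
            lo, hi = pri[p]
            prop = params[p] + widths[p] * (rng.random() - 0.5)
            n_prop[p] += 1
            total_prop += 1
            if lo <= prop <= hi:
                old = params[p]
                params[p] = prop
                try:
                    new_ll = like.loglik(tree_idx, params, model)
                except linalg.LinAlgError:
                    new_ll = -np.inf
                if np.log(rng.random()) < likelihood_power * (new_ll - ll):
                    ll, moved = new_ll, True
                    n_acc[p] += 1
                    total_acc += 1
                else:
                    params[p] = old
        if moved:
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
            if consecutive_rejects > 10_000 and not warned:
                logger.warning(
                    "over 10000 consecutive rejected proposals; consider "
                    "narrower proposal widths or wider priors"
                )
                warned = True
        if gen <= burnin and tune_interval and gen % tune_interval == 0:
            for p in sampled:
                if n_prop[p] >= 10:
                    rate = n_acc[p] / n_prop[p]
                    if rate > 0.4:
                        widths[p] *= 1.3
                    elif rate < 0.2:
                        widths[p] /= 1.3
                    n_prop[p] = n_acc[p] = 0
        if gen > burnin and (gen - burnin) % thinning == 0:
            rec = {k: params[k] for k in ("sigma2", "alpha", "beta",
                                          "kappa", "lambda", "delta")}
            rec["tree_index"] = tree_idx
            rec["loglik"] = ll
            records.append(rec)

    acc_rate = total_acc / total_prop if total_prop else np.nan
    return McmcTrace(
        samples=pd.DataFrame(records),
        generations=generations,
        burnin=burnin,
        thinning=thinning,
        seed=seed,
        acceptance_rate=float(acc_rate) if total_prop else np.nan,
        proposal_widths=dict(widths),
    )


def log_marginal_harmonic(trace: McmcTrace | np.ndarray) -> float:
    """Harmonic-mean estimate of the log marginal likelihood (nats).

    Computed entirely in log space as -(logsumexp(-l) - log N) over the
    retained log-likelihoods, so it is stable for |l| up to ~1e5.
    """
    ll = trace.loglik if isinstance(trace, McmcTrace) else np.asarray(trace, float)
    if ll.size == 0:
        raise ValueError("empty trace")
    return float(-(logsumexp(-ll) - np.log(ll.size)))


def log_marginal_steppingstone(
    traits,
    trees: TreeSet,
    model_spec: ModelSpec,
    priors=None,
    generations: int = 20_000,
    burnin: int = 4_000,
    thinning: int = 10,
    seed: int = 0,
    n_rungs: int = 8,
    trait: str | None = None,
) -> float:
    """Stepping-stone marginal-likelihood estimate (opt-in cross-check).

    Runs one tempered chain per rung with likelihood power beta_k =
    (k / K)^(1/0.3) (the usual beta-distribution-quantile ladder) and
    accumulates log mean exp((b_{k+1} - b_k) * l) along the path from
    prior to posterior.
    """
    betas = (np.arange(n_rungs + 1) / n_rungs) ** (1.0 / 0.3)
    seeds = np.random.SeedSequence(seed).generate_state(n_rungs) % (2**31)
    total = 0.0
    for k in range(n_rungs):
        trace = mcmc_run(
            traits, trees, model_spec, priors=priors,
            generations=generations, burnin=burnin, thinning=thinning,
            seed=int(seeds[k]), trait=trait,
            likelihood_power=float(betas[k]),
        )
        ll = trace.loglik
        total += float(
            logsumexp((betas[k + 1] - betas[k]) * ll) - np.log(ll.size)
        )
    return total


def bayes_factor(logml_alt: float, logml_null: float) -> BayesFactorResult:
    """Twice the log marginal-likelihood difference, with the verdict.

    Positive values favour the alternative; > 2 is positive evidence,
    > 5 strong, > 10 very strong (on the magnitude, either direction).
    """
    if not (np.isfinite(logml_alt) and np.isfinite(logml_null)):
        raise ValueError("marginal likelihoods must be finite")
    bf = 2.0 * (logml_alt - logml_null)
    mag = abs(bf)
    if mag > 10:
        category = "very strong"
    elif mag > 5:
        category = "strong"
    elif mag > 2:
        category = "positive"
    else:
        category = "none"
    return BayesFactorResult(
        bf=float(bf), favored="alt" if bf > 0 else "null", category=category
    )


def run_model_battery(
    traits,
    trees: TreeSet,
    trait: str | None = None,
    priors=None,
    generations: int = 1_000_000,
    burnin: int = 100_000,
    thinning: int = 100,
    seed: int = 0,
    include_zero: bool = True,
    tree_move_prob: float = 0.1,
) -> dict:
    """Bayes-factor battery over tempo-and-mode hypotheses for one trait.

    Chains: a null random walk with all transforms at 1; one chain per
    transform left free under its prior; optionally chains with lambda
    and kappa pinned at 0; and a directional (trend) chain.  Each free
    transform is compared against its pinned values, and the directional
    model against the random walk, by harmonic-mean Bayes factors.

    Returns ``{"table": DataFrame, "logml": {chain: value}, "traces": {...}}``.
    """
    values = _as_values(traits, trait)
    chains: dict[str, ModelSpec] = {
        "null": ModelSpec(model="A"),
        "free_lambda": ModelSpec(model="A", free=("lambda",)),
        "free_delta": ModelSpec(model="A", free=("delta",)),
        "free_kappa": ModelSpec(model="A", free=("kappa",)),
        "model_b": ModelSpec(model="B"),
    }
    if include_zero:
        chains["lambda_0"] = ModelSpec(model="A", fixed={"lambda": 0.0})
        chains["kappa_0"] = ModelSpec(model="A", fixed={"kappa": 0.0})
    seeds = np.random.SeedSequence(seed).generate_state(len(chains)) % (2**31)
    traces = {}
    logml = {}
    for (name, spec), s in zip(chains.items(), seeds):
        traces[name] = mcmc_run(
            values, trees, spec, priors=priors,
            generations=generations, burnin=burnin, thinning=thinning,
            seed=int(s), tree_move_prob=tree_move_prob,
        )
        logml[name] = log_marginal_harmonic(traces[name])

    rows = []

    def add(parameter, fixed_value, alt, null):
        res = bayes_factor(logml[alt], logml[null])
        rows.append(
            {
                "parameter": parameter,
                "comparison": f"ML vs {fixed_value}",
                "alt_chain": alt,
                "null_chain": null,
                "bf": res.bf,
                "favored": res.favored,
                "category": res.category,
            }
        )

    add("lambda", "1.0", "free_lambda", "null")
    add("delta", "1.0", "free_delta", "null")
    add("kappa", "1.0", "free_kappa", "null")
    if include_zero:
        add("lambda", "0.0", "free_lambda", "lambda_0")
        add("kappa", "0.0", "free_kappa", "kappa_0")
    add("trend", "model B vs A", "model_b", "null")
    return {"table": pd.DataFrame(rows), "logml": logml, "traces": traces}
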