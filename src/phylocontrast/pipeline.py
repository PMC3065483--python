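"""End-to-end analysis: summaries, correlations, contrasts, fits, BFs.

``run_full_analysis`` chains the whole comparative workflow for a trait
table and a rooted tree (plus, optionally, a posterior tree set for the
MCMC battery) and returns a JSON-serialisable report; every number in
the report is produced by one of the module-level operations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import bayes, pic, stats, traitmodels
from .phylo_io import (
    TraitTable,
    TreeSet,
    parse_newick,
    parse_nexus_trees,
    read_trait_table,
    tip_labels,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "traits": ["gs_pg", "fd_cm"],
    "ingroup_clades": ["Passiflora", "Decaloba"],
    "run_mcmc": False,
    "mcmc": {
        "generations": 1_000_000,
        "burnin": 100_000,
        "thinning": 100,
        "tree_move_prob": 0.1,
        "include_zero": True,
    },
    "ml_free_transforms": [["lambda"], ["kappa"], ["delta"]],
    "seed": 0,
}

__all__ = ["run_full_analysis", "write_report", "DEFAULT_CONFIG"]


def _digest(path) -> str | None:
    try:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()
    except (OSError, TypeError):
        return None


def _merge_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _prune_to(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    tips = set(tip_labels(tree))
    missing = sorted(set(species) - tips)
    if missing:
        raise ValueError(
            f"species absent from the tree: {missing}"
        )
    if tips - set(species):
        clone = tree.extract_tree_with_taxa_labels(species)
        return clone
    return tree.clone(depth=1)


def _corr_dict(res: stats.CorrelationResult) -> dict:
    return {"r": res.r, "n": res.n, "p": res.p, "mode": res.mode}


def run_full_analysis(
    traits,
    tree,
    treeset=None,
    config: dict | None = None,
) -> dict:
    """Run the full comparative analysis and return the report dict.

    Parameters accept in-memory objects (TraitTable / dendropy.Tree /
    TreeSet) or file paths (CSV-TSV / Newick / NEXUS).
    """
    cfg = _merge_config(config)
    digests = {}
    if not isinstance(traits, TraitTable):
        digests["traits"] = _digest(traits)
        traits = read_trait_table(traits)
    if not isinstance(tree, dendropy.Tree):
        digests["tree"] = _digest(tree)
        tree = parse_newick(tree)
    if treeset is not None and not isinstance(treeset, TreeSet):
        digests["treeset"] = _digest(treeset)
        treeset = parse_nexus_trees(treeset)

    ingroup = cfg["ingroup_clades"]
    trait_names = [t for t in cfg["traits"] if t in traits.trait_names]
    report = {
        "schema_version": SCHEMA_VERSION,
        "inputs": {
            "digests": digests,
            "n_species": len(traits),
            "n_tree_tips": len(tip_labels(tree)),
            "seed": cfg["seed"],
            "config": cfg,
        },
    }

    # --- group summaries and raw correlations -------------------------------
    summary = stats.group_summary(traits, ingroup=ingroup)
    report["group_summary"] = summary.reset_index().to_dict(orient="records")

    ing = traits.subset(ingroup)
    raw = {}
    if len(trait_names) >= 2:
        t1, t2 = trait_names[:2]
        raw["all_ingroup"] = _corr_dict(
            stats.pearson(ing.data[t1], ing.data[t2])
        )
        for clade in ingroup:
            sub = traits.subset([clade])
            if len(sub) >= 3:
                raw[clade] = _corr_dict(
                    stats.pearson(sub.data[t1], sub.data[t2])
                )
        # sensitivity: outgroup pooled with the larger subgenus, the
        # variant that reproduces the published within-Passiflora value
        pooled = traits.subset([ingroup[0], "outgroup"])
        if len(pooled) > len(traits.subset([ingroup[0]])):
            raw[f"{ingroup[0]}_plus_outgroup"] = _corr_dict(
                stats.pearson(pooled.data[t1], pooled.data[t2])
            )
        report["raw_correlations"] = raw
        report["group_compare"] = {
            trait: stats.group_compare(traits, trait, groups=tuple(ingroup))
            for trait in (t1, t2)
        }

    # --- contrasts ----------------------------------------------------------
    # Ancestral states and node changes use the full tree (all species);
    # the "whole set" contrast correlations and the standardization
    # diagnostic use the ingroup only, mirroring the pooled statistics.
    species = traits.species
    work_tree = _prune_to(tree, species)
    ing_tree = _prune_to(tree, ing.species)
    contrasts = {}
    diagnostics = {}
    ancestral = {}
    changes = {}
    for trait in trait_names:
        est = pic.IndependentContrasts(trait=trait, compute_ancestral=True)
        est.fit(work_tree, traits)
        diagnostics[trait] = est.diagnostic()
        ancestral[trait] = est.ancestral_states_
        changes[trait] = est.node_changes_
        contrasts[trait] = pic.compute_contrasts(
            ing_tree, ing.values_for(trait)
        )
    report["standardization_diagnostics"] = diagnostics
    report["n_contrasts"] = {t: len(cs) for t, cs in contrasts.items()}
    report["ancestral_states"] = {
        t: df.to_dict(orient="records") for t, df in ancestral.items()
    }
    report["node_changes"] = {
        t: df.to_dict(orient="records") for t, df in changes.items()
    }

    if len(trait_names) >= 2:
        t1, t2 = trait_names[:2]
        cx = contrasts[t1].table["contrast"].to_numpy()
        cy = contrasts[t2].table["contrast"].to_numpy()
        ox, oy = stats.orient_contrasts(cx, cy)
        contrast_corr = {
            "all": {
                "through_origin": _corr_dict(
                    stats.correlation_through_origin(ox, oy)
                ),
                "ordinary": _corr_dict(stats.pearson(ox, oy)),
            }
        }
        for clade in ingroup:
            sub = traits.subset([clade])
            if len(sub) < 4:
                continue
            subtree = _prune_to(tree, sub.species)
            c1 = pic.compute_contrasts(subtree, sub.values_for(t1))
            c2 = pic.compute_contrasts(subtree, sub.values_for(t2))
            ox, oy = stats.orient_contrasts(
                c1.table["contrast"], c2.table["contrast"]
            )
            contrast_corr[clade] = {
                "through_origin": _corr_dict(
                    stats.correlation_through_origin(ox, oy)
                ),
                "ordinary": _corr_dict(stats.pearson(ox, oy)),
            }
        report["contrast_correlations"] = contrast_corr

    # --- ML fits ------------------------------------------------------------
    fits = {}
    for trait in trait_names:
        per_trait = {}
        values = traits.values_for(trait)
        per_trait["modelA"] = _fit_dict(
            traitmodels.fit_ml(values, work_tree, model="A")
        )
        try:
            per_trait["modelB"] = _fit_dict(
                traitmodels.fit_ml(values, work_tree, model="B")
            )
        except ValueError as exc:
            per_trait["modelB"] = {"error": str(exc)}
        for free in cfg["ml_free_transforms"]:
            key = "free_" + "_".join(free)
            per_trait[key] = _fit_dict(
                traitmodels.fit_ml(
                    values, work_tree, model="A", free_transforms=free
                )
            )
        fits[trait] = per_trait
    report["ml_fits"] = fits

    # --- optional MCMC battery ---------------------------------------------
    if cfg["run_mcmc"] and treeset is not None:
        mc = cfg["mcmc"]
        battery = {}
        for trait in trait_names:
            res = bayes.run_model_battery(
                traits,
                treeset,
                trait=trait,
                generations=mc["generations"],
                burnin=mc["burnin"],
                thinning=mc["thinning"],
                seed=cfg["seed"],
                include_zero=mc["include_zero"],
                tree_move_prob=mc["tree_move_prob"],
            )
            battery[trait] = {
                "table": res["table"].to_dict(orient="records"),
                "logml": res["logml"],
            }
        report["bayes_factor_battery"] = battery

    return report


def _fit_dict(fit: traitmodels.BMFit) -> dict:
    return {
        "model": fit.model,
        "sigma2": fit.sigma2,
        "root_state": fit.root_state,
        "trend_beta": fit.trend_beta,
        "kappa": fit.transform.kappa,
        "lambda": fit.transform.lambda_,
        "delta": fit.transform.delta,
        "loglik": fit.loglik if np.isfinite(fit.loglik) else None,
        "degenerate": fit.degenerate,
    }


def write_report(report: dict, out_dir) -> Path:
    """Write the report bundle (JSON plus TSV extracts) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    for key in ("ancestral_states", "node_changes"):
        for trait, records in report.get(key, {}).items():
            pd.DataFrame(records).to_csv(
                out / f"{key}_{trait}.tsv", sep="\t", index=False
            )
    pd.DataFrame(report.get("group_summary", [])).to_csv(
        out / "group_summary.tsv", sep="\t", index=False
    )
    return out / "report.json"


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
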