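"""Rooted-tree and trait-table input/output.

Trees are :class:`dendropy.Tree` objects throughout the package.  Parsing
enforces the conventions the comparative machinery needs: a single root,
non-negative branch lengths, unique tip labels, and strictly bifurcating
internal nodes (polytomies are resolved deterministically into zero-length
bifurcations at parse time).  Trait tables are thin, validated wrappers
around a pandas DataFrame with one row per species.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NewickParseError",
    "TraitTable",
    "TreeSet",
    "parse_newick",
    "write_newick",
    "parse_nexus_trees",
    "reroot",
    "read_trait_table",
    "write_trait_table",
    "tip_labels",
    "path_length_matrix",
    "resolve_polytomies",
    "label_internal_nodes",
]

TRAIT_COLUMNS = ("species", "clade", "gs_pg", "fd_cm")


class NewickParseError(ValueError):
    """Malformed Newick/NEXUS input; carries a character offset when known."""


# ---------------------------------------------------------------------------
# Newick / NEXUS parsing
# ---------------------------------------------------------------------------

def _check_newick_syntax(text: str) -> None:
    """Cheap structural validation so errors can name a character offset."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {i}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of input "
            f"(length {len(text.rstrip())})"
        )
    stripped = text.rstrip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"missing terminating ';' at character offset {len(stripped)}"
        )


def resolve_polytomies(tree: dendropy.Tree) -> int:
    """Resolve every polytomy into zero-length bifurcations, in place.

    Children are taken in input order and folded from the left: the first
    two children are joined under a new zero-length node, that node is
    joined with the third child, and so on.  This is deterministic and
    leaves every tip-to-tip path length unchanged, so the Brownian-motion
    covariance matrix of the tips is exactly preserved.

    Returns the number of polytomies resolved.
    """
    n_resolved = 0
    for node in list(tree.preorder_node_iter()):
        children = list(node.child_nodes())
        while len(children) > 2:
            left, right = children[0], children[1]
            node.remove_child(left)
            node.remove_child(right)
            joint = dendropy.Node()
            joint.add_child(left)
            joint.add_child(right)
            joint.edge.length = 0.0
            node.insert_child(0, joint)
            children = list(node.child_nodes())
            n_resolved += 1
    return n_resolved


def _validate_branch_lengths(
    tree: dendropy.Tree, assume_unit_branches: bool
) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            if assume_unit_branches:
                node.edge.length = 1.0
            else:
                label = node.taxon.label if node.taxon else node.label
                raise NewickParseError(
                    f"missing branch length on edge above node {label!r}; "
                    "pass assume_unit_branches=True to default them to 1.0"
                )
        elif node.edge.length < 0:
            raise NewickParseError(
                f"negative branch length {node.edge.length} not allowed"
            )


def _check_unique_tips(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate tip labels: {dupes}")


def _as_text(source) -> str:
    if isinstance(source, (str,)):
        return source
    if isinstance(source, Path):
        return source.read_text()
    return source.read()


def parse_newick(
    text,
    *,
    assume_unit_branches: bool = False,
    resolve: bool = True,
) -> dendropy.Tree:
    """Parse a single rooted Newick tree.

    Parameters
    ----------
    text:
        Newick string, file path, or open text stream.
    assume_unit_branches:
        If True, edges without a stated length get length 1.0 (the
        convention under which a branch-length exponent of zero operates);
        otherwise a missing length is an error.
    resolve:
        Resolve polytomies into zero-length bifurcations (logged).
    """
    raw = _as_text(text)
    if isinstance(text, (Path,)) or (
        isinstance(text, str) and "\n" not in text and Path(text).is_file()
    ):
        raw = Path(text).read_text() if isinstance(text, str) else raw
    _check_newick_syntax(raw)
    try:
        tree = dendropy.Tree.get(
            data=raw,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    _check_unique_tips(tree)
    _validate_branch_lengths(tree, assume_unit_branches)
    if len(tree.leaf_nodes()) == 1:
        logger.warning("single-tip tree parsed; most analyses need >= 3 tips")
    if resolve:
        n = resolve_polytomies(tree)
        if n:
            logger.warning(
                "resolved %d polytomies into zero-length bifurcations", n
            )
    return tree


def write_newick(tree: dendropy.Tree, dest=None) -> str:
    """Serialise a tree to Newick; writes to *dest* (path/stream) if given."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip() + "\n"
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(s)
        else:
            dest.write(s)
    return s


@dataclass
class TreeSet:
    """An ordered collection of rooted trees over one tip-label universe.

    Carrier for a posterior sample of trees (e.g. the last trees retained
    by a Bayesian phylogenetic run) to be averaged over during MCMC.
    """

    trees: list = field(default_factory=list)

    def __post_init__(self):
        if not self.trees:
            raise ValueError("TreeSet must contain at least one tree")
        ref = set(tip_labels(self.trees[0]))
        for i, t in enumerate(self.trees[1:], start=1):
            labels = set(tip_labels(t))
            if labels != ref:
                diff = sorted(labels.symmetric_difference(ref))
                raise ValueError(
                    f"tree {i} has a different tip set; "
                    f"symmetric difference: {diff}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[dendropy.Tree]:
        return iter(self.trees)

    def __getitem__(self, i) -> dendropy.Tree:
        return self.trees[i]

    @property
    def taxon_labels(self) -> list[str]:
        return sorted(tip_labels(self.trees[0]))


def parse_nexus_trees(
    text, *, assume_unit_branches: bool = False, resolve: bool = True
) -> TreeSet:
    """Parse the TREES block of a NEXUS file into a :class:`TreeSet`.

    TRANSLATE tables are applied, so every returned tree carries full tip
    labels.  Order of appearance is preserved.  All trees must share one
    tip set; a mismatch is an error listing the offending labels.
    """
    raw = _as_text(text)
    if isinstance(text, (str, Path)) and "\n" not in str(text) and Path(str(text)).is_file():
        raw = Path(str(text)).read_text()
    try:
        tl = dendropy.TreeList.get(
            data=raw,
            schema="nexus",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"NEXUS parse failed: {exc}") from exc
    if len(tl) == 0:
        raise NewickParseError("NEXUS TREES block contains no trees")
    trees = []
    for t in tl:
        _check_unique_tips(t)
        _validate_branch_lengths(t, assume_unit_branches)
        if resolve:
            resolve_polytomies(t)
        trees.append(t)
    return TreeSet(trees)


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "nd") -> None:
    """Assign stable labels nd0, nd1, ... to unlabelled internal nodes.

    Labels are assigned in preorder so they are reproducible for a given
    topology; existing labels are kept.
    """
    i = 0
    for node in tree.preorder_internal_node_iter():
        if not node.label:
            node.label = f"{prefix}{i}"
        i += 1


def _find_node(tree: dendropy.Tree, node_ref) -> dendropy.Node:
    if isinstance(node_ref, dendropy.Node):
        if node_ref not in set(tree.preorder_node_iter()):
            raise ValueError("node is not part of this tree")
        return node_ref
    for node in tree.preorder_node_iter():
        if node.label == node_ref or (
            node.taxon is not None and node.taxon.label == node_ref
        ):
            return node
    raise ValueError(f"no node labelled {node_ref!r} in tree")


def reroot(tree: dendropy.Tree, node_ref) -> dendropy.Tree:
    """Return a copy of *tree* rooted at the given node (label or Node).

    The tip-to-tip path-length matrix is preserved exactly; the input tree
    is not modified.  Rerooting at the current root returns an unchanged
    copy.  The old root, if left with a single child, is suppressed (its
    two incident branches are merged), which may leave the new root with
    three children; downstream code treats that as a zero-length polytomy.
    """
    # clone, then find the matching node in the clone
    target = _find_node(tree, node_ref)  # validate against the original
    clone = tree.clone(depth=1)
    if target.parent_node is None:
        return clone
    # locate the corresponding node in the clone by position in preorder
    orig_nodes = list(tree.preorder_node_iter())
    clone_nodes = list(clone.preorder_node_iter())
    target_clone = clone_nodes[orig_nodes.index(target)]
    clone.reroot_at_node(target_clone, update_bipartitions=False)
    clone.suppress_unifurcations()
    return clone


def path_length_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix as a labelled DataFrame."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = np.array(
        [[pdm.patristic_distance(a, b) for b in taxa] for a in taxa]
    )
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species-level trait data: one row per species.

    Columns: ``species`` (unique), ``clade`` (subgenus or "outgroup"),
    plus numeric trait columns (by default genome size ``gs_pg`` in
    picograms, 1C, and flower diameter ``fd_cm`` in centimetres).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in ("species", "clade") if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        if df["species"].duplicated().any():
            dupes = sorted(df.loc[df["species"].duplicated(), "species"])
            raise ValueError(f"duplicate species: {dupes}")
        for col in self.trait_names:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), "species"].tolist()
                raise ValueError(f"non-numeric {col} for species {bad}")
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite values in {col}")
            self.data[col] = vals.astype(float)
        for col in ("gs_pg", "fd_cm"):
            if col in df.columns and (df[col] <= 0).any():
                bad = df.loc[df[col] <= 0, "species"].tolist()
                raise ValueError(f"{col} must be > 0; offending: {bad}")
        self.data = self.data.reset_index(drop=True)

    @property
    def trait_names(self) -> list[str]:
        return [
            c for c in self.data.columns if c not in ("species", "clade")
        ]

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    def values_for(self, trait: str) -> dict[str, float]:
        """Mapping species -> trait value."""
        if trait not in self.trait_names:
            raise KeyError(
                f"unknown trait {trait!r}; have {self.trait_names}"
            )
        return dict(zip(self.data["species"], self.data[trait]))

    def subset(self, clades: Iterable[str]) -> "TraitTable":
        clades = set(clades)
        return TraitTable(
            self.data[self.data["clade"].isin(clades)].reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.data)


def read_trait_table(source) -> TraitTable:
    """Read a CSV/TSV trait table with header species, clade, gs_pg, fd_cm."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    if not text.strip():
        raise ValueError("empty trait table")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"trait table missing required columns {missing}; "
            f"expected header {','.join(TRAIT_COLUMNS)}"
        )
    df["species"] = df["species"].astype(str).str.strip()
    df["clade"] = df["clade"].astype(str).str.strip()
    return TraitTable(df)


def write_trait_table(table: TraitTable, dest, sep: str = ",") -> None:
    if isinstance(dest, (str, Path)):
        table.data.to_csv(dest, sep=sep, index=False)
    else:
        table.data.to_csv(dest, sep=sep, index=False)
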