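"""Tree handling: support-annotated newick, node collapsing, Robinson-Foulds
concordance, a bootstrap-null test, and a neighbor-joining fallback.

Gene trees from ML bootstrap engines arrive with nodal supports in square
brackets after branch lengths (``(..):0.12[87]``); these are rewritten into
the internal-node-label position so standard newick readers and coalescent
tools accept them.  Nodes with support strictly below a threshold (default
10%) are collapsed into polytomies before coalescent summary methods.

Topological concordance between inference methods is measured with the
normalized Robinson-Foulds distance: the number of bipartitions unique to
either tree divided by the total number of nontrivial bipartitions in both
trees (a convention that stays well defined for polytomous trees).  Whether
an observed inter-method distance exceeds phylogenetic noise is judged
against the null distribution of distances between a best tree and its
bootstrap replicates.  A standard neighbor-joining builder (scikit-bio) is
included so the package remains runnable without external inference engines.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError

_BRACKET = re.compile(r"(:[0-9.eE+\-]+)\[([0-9.eE+\-]+)\]")


def reformat_support_newick(text: str) -> str:
    """Rewrite ``):length[support]`` into ``)support:length``.

    Input without bracketed supports is returned unchanged.  Unbalanced
    parentheses or brackets raise a parse error with the offset.
    """
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced ')' at offset {i}")
    if depth != 0:
        raise ParseError("unbalanced '(' in newick")
    if text.count("[") != text.count("]"):
        raise ParseError("unbalanced square brackets in newick")
    return _BRACKET.sub(lambda m: m.group(2) + m.group(1), text)


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string (supports as internal node labels)."""
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"cannot parse newick: {exc}") from exc


def write_tree(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()


def _support_percent(label: str | None, scale_hint: float | None = None) -> float | None:
    if label is None or label == "":
        return None
    try:
        v = float(label)
    except ValueError:
        return None
    if scale_hint is not None:
        return v * 100.0 if scale_hint <= 1.0 else v
    return v


def _detect_scale(tree: dendropy.Tree) -> float | None:
    vals = []
    for nd in tree.preorder_internal_node_iter():
        if nd.label:
            try:
                vals.append(float(nd.label))
            except ValueError:
                pass
    if not vals:
        return None
    return max(vals)


def collapse_low_support(tree: dendropy.Tree, threshold_percent: float = 10.0) -> dendropy.Tree:
    """Collapse internal edges with support strictly below the threshold.

    Support scale is auto-detected (all values <= 1 are read as proportions).
    Internal nodes lacking a support label are never collapsed.  Idempotent;
    the leaf set is unchanged.
    """
    t = tree.clone(depth=1)
    scale = _detect_scale(t)
    to_collapse = []
    for nd in t.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        sup = _support_percent(nd.label, scale)
        if sup is not None and sup < threshold_percent:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return t


# ------------------------------------------------------------------ RF


@dataclass
class RFResult:
    raw: int
    normalized: float
    n_bipartitions_a: int
    n_bipartitions_b: int
    shared: int


def _nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions as frozensets of leaf labels, each normalised
    to the side not containing the alphabetically first leaf."""
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(leaves)
    bips: set[frozenset] = set()
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = {l.taxon.label for l in nd.leaf_iter()}
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            bips.add(frozenset(side))
    return bips


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> RFResult:
    """Robinson-Foulds distance on the same leaf set.

    raw = bipartitions unique to either tree; normalized = raw divided by the
    total number of nontrivial bipartitions in both trees, in [0, 1].
    """
    la = {l.taxon.label for l in tree_a.leaf_node_iter()}
    lb = {l.taxon.label for l in tree_b.leaf_node_iter()}
    if la != lb:
        diff = sorted(la ^ lb)
        raise ConfigError(f"leaf sets differ; symmetric difference: {diff[:10]}")
    ba = _nontrivial_bipartitions(tree_a)
    bb = _nontrivial_bipartitions(tree_b)
    raw = len(ba ^ bb)
    denom = len(ba) + len(bb)
    return RFResult(
        raw=raw,
        normalized=(raw / denom) if denom else 0.0,
        n_bipartitions_a=len(ba),
        n_bipartitions_b=len(bb),
        shared=len(ba & bb),
    )


@dataclass
class RFNullReport:
    null_min: float
    null_max: float
    null_mean: float
    null_sd: float
    observed: dict[str, float]
    exceeds: dict[str, bool]
    percentile: dict[str, float]


def rf_null_test(
    best_tree: dendropy.Tree,
    replicate_trees: Sequence[dendropy.Tree],
    observed: Mapping[str, float | dendropy.Tree],
) -> RFNullReport:
    """Compare observed inter-method RF distances against the bootstrap null.

    The null is the distribution of normalized RF between the best tree and
    each replicate.  Each observed distance (a number, or a tree to compare
    against the best tree) is flagged as exceeding when it is greater than
    the null maximum, and located by its empirical percentile (fraction of
    null values strictly below it).
    """
    if len(replicate_trees) < 2:
        raise ConfigError("need at least 2 replicate trees for the null distribution")
    null = np.array([rf_distance(best_tree, rep).normalized for rep in replicate_trees])
    obs: dict[str, float] = {}
    for name, val in observed.items():
        if isinstance(val, dendropy.Tree):
            obs[name] = rf_distance(best_tree, val).normalized
        else:
            obs[name] = float(val)
    return RFNullReport(
        null_min=float(null.min()),
        null_max=float(null.max()),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        observed=obs,
        exceeds={k: v > float(null.max()) for k, v in obs.items()},
        percentile={k: float((null < v).mean()) for k, v in obs.items()},
    )


# ------------------------------------------------------------------ NJ


def nj_tree(distance: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining topology from a symmetric distance matrix with zero
    diagonal (scikit-bio implementation)."""
    import skbio

    arr = distance.to_numpy(dtype=float)
    if distance.shape[0] != distance.shape[1] or not np.allclose(arr, arr.T):
        raise ConfigError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ConfigError("distance matrix must have a zero diagonal")
    dm = skbio.DistanceMatrix(arr, ids=list(distance.index))
    sk = skbio.tree.nj(dm)
    buf = io.StringIO()
    sk.write(buf)
    return read_tree(buf.getvalue())


def random_nni(tree: dendropy.Tree, n_moves: int = 1, seed: int = 0) -> dendropy.Tree:
    """Apply ``n_moves`` random nearest-neighbour interchanges (test utility
    for constructing perturbed topologies)."""
    rng = np.random.default_rng(seed)
    t = tree.clone(depth=1)
    for _ in range(n_moves):
        internal = [
            e
            for e in t.preorder_edge_iter()
            if e.head_node.parent_node is not None and not e.head_node.is_leaf() and e.tail_node is not None and e.tail_node.parent_node is not None
        ]
        if not internal:
            break
        edge = internal[int(rng.integers(0, len(internal)))]
        child = edge.head_node
        parent = edge.tail_node
        kids = child.child_nodes()
        sibs = [c for c in parent.child_nodes() if c is not child]
        if not kids or not sibs:
            continue
        a = kids[int(rng.integers(0, len(kids)))]
        b = sibs[int(rng.integers(0, len(sibs)))]
        child.remove_child(a)
        parent.remove_child(b)
        child.add_child(b)
        parent.add_child(a)
    t.update_bipartitions(suppress_unifurcations=True)
    return read_tree(write_tree(t))


# ------------------------------------------------------------------ export


def write_multiphylo(trees: Sequence[dendropy.Tree], path) -> None:
    """One newick per line (the multi-tree input coalescent tools expect)."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_tree(t) + "\n")


def export_nexus_with_taxa_blocks(supermatrix, species_of_genome: Mapping[str, str], path) -> None:
    """NEXUS export of a supermatrix with a taxon-partition block mapping
    genomes to species, as quartet-based species-tree tools consume."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(supermatrix.genome_ids)} NCHAR={supermatrix.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        for gid in supermatrix.genome_ids:
            fh.write(f"    {gid}  {supermatrix.sequences[gid]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        by_species: dict[str, list[str]] = {}
        for gid in supermatrix.genome_ids:
            by_species.setdefault(species_of_genome.get(gid, gid), []).append(gid)
        parts = []
        for sp, members in by_species.items():
            parts.append(f"    {sp} : {' '.join(members)}")
        fh.write("  TAXPARTITION SPECIES =\n" + ",\n".join(parts) + ";\nEND;\n")
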