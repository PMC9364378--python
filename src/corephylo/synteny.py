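"""Core-genome architecture: links, the synteny index, and reference-guided
scaffold reordering of draft genomes.

A *link* is an unordered pair of core genes that are immediate neighbours on
a chromosome or scaffold.  On a complete circular chromosome carrying g core
genes every gene has two neighbours, so the genome carries exactly g distinct
links.  The synteny index between two genomes is the proportion of links they
share, SI = |A ∩ B| / max(|A|, |B|), ranging from 0 (no link conserved) to 1
(identical architecture); the max-denominator keeps SI(x, x) = 1 while
preventing missing data in drafts from inflating similarity.

Draft genomes are unordered, arbitrarily oriented scaffolds, so their core
gene order must be inferred.  Against each reference genome with a known
circular order: (i) each scaffold is scored by the circular mean position of
its core genes on the reference circle and scaffolds are sorted by that
score; (ii) scaffold orientations are chosen to maximise the number of
junction adjacencies (edge-gene pairs between consecutive scaffolds,
including the circular closure) present in the reference, by an exact
two-state dynamic program; (iii) the implied circular core-gene order yields
a link set and an SI against the reference.  The configuration with the
highest SI over all references is kept, and its implied order joins the
reference pool so that progressively more fragmented drafts see more
references (drafts are processed in decreasing completeness: descending N50,
ties by fewer scaffolds).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

Link = frozenset


@dataclass
class LinkSet:
    genome_id: str
    links: set[frozenset]

    @property
    def n_links(self) -> int:
        return len(self.links)


@dataclass
class SyntenyConfiguration:
    """An ordered, oriented scaffold arrangement for a draft genome."""

    genome_id: str
    scaffold_order: list[tuple[str, str]]  # (scaffold_id, "forward" | "reverse")
    gene_order: list[str]  # implied circular core-gene order
    best_reference: str = ""
    si: float = 0.0
    dropped_scaffolds: list[str] = field(default_factory=list)


def order_links(order: Sequence[str], circular: bool = True) -> set[frozenset]:
    """Adjacency links of a gene order (circular closure optional)."""
    links = {frozenset((a, b)) for a, b in zip(order, order[1:])}
    if circular and len(order) >= 2:
        links.add(frozenset((order[-1], order[0])))
    return {l for l in links if len(l) == 2}


def extract_links(scaffold_orders: Sequence[Sequence[str]], circular: bool = False, genome_id: str = "") -> LinkSet:
    """Links from per-scaffold core-gene orders.

    Within-scaffold neighbours are always paired.  With ``circular`` the
    scaffolds are read as one circular sequence in the given order: junctions
    between consecutive scaffolds and the closing edge-gene pair are added
    (single-scaffold complete genomes thus yield g links for g >= 3 genes).
    """
    flat = [g for sc in scaffold_orders for g in sc]
    if len(flat) != len(set(flat)):
        dup = sorted({g for g in flat if flat.count(g) > 1})
        raise ConfigError(f"duplicate core gene(s) in one genome: {dup[:5]}")
    if len(flat) < 2:
        raise ConfigError("need at least 2 core genes to extract links")
    if circular:
        links = order_links(flat, circular=True)
    else:
        links = set()
        for sc in scaffold_orders:
            links |= order_links(sc, circular=False)
    return LinkSet(genome_id=genome_id, links=links)


def synteny_index(links_a: LinkSet | set, links_b: LinkSet | set) -> float:
    """SI = |A ∩ B| / max(|A|, |B|); symmetric, in [0, 1], SI(x, x) = 1."""
    a = links_a.links if isinstance(links_a, LinkSet) else links_a
    b = links_b.links if isinstance(links_b, LinkSet) else links_b
    if not a or not b:
        raise ConfigError("synteny index undefined for an empty link set")
    return len(a & b) / max(len(a), len(b))


# -------------------------------------------------------- scaffold reordering


def score_scaffolds(
    scaffold_genes: Mapping[str, Sequence[str]],
    reference_order: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Order draft scaffolds by the circular mean position of their core genes
    on the reference circle.

    The reference chromosome is circular, so gene positions are mapped to
    angles and each scaffold scored by its mean direction; this makes the
    score independent of where the reference's linear representation starts.
    Scaffolds sharing no gene with the reference are dropped from the order
    (returned separately).  Ties break by scaffold id.
    """
    g = len(reference_order)
    rank = {gene: i for i, gene in enumerate(reference_order)}
    scored: list[tuple[float, str]] = []
    dropped: list[str] = []
    for sid in sorted(scaffold_genes):
        angles = [2.0 * np.pi * rank[x] / g for x in scaffold_genes[sid] if x in rank]
        if not angles:
            dropped.append(sid)
            continue
        mean_dir = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
        score = (mean_dir % (2.0 * np.pi)) * g / (2.0 * np.pi)
        scored.append((score, sid))
    ordered = [sid for _, sid in sorted(scored)]
    return ordered, dropped


def orient_scaffolds(
    ordered_scaffolds: Sequence[str],
    scaffold_genes: Mapping[str, Sequence[str]],
    reference_links: set,
    genome_id: str = "",
) -> SyntenyConfiguration:
    """Choose per-scaffold orientations maximising reference junction links.

    The objective (number of junction adjacencies, including the circular
    closure, present in the reference link set) decomposes over consecutive
    scaffold pairs, so a two-state dynamic program over forward/reverse per
    scaffold — run once per orientation of the first scaffold to close the
    circle — finds the exact optimum.  Ties resolve to forward.
    """
    sids = [s for s in ordered_scaffolds if scaffold_genes[s]]
    genes = {s: list(scaffold_genes[s]) for s in sids}
    if not sids:
        raise ConfigError("no scaffolds with core genes to orient")
    k = len(sids)

    def ends(sid: str, orient: int) -> tuple[str, str]:
        gl = genes[sid] if orient == 0 else genes[sid][::-1]
        return gl[0], gl[-1]

    def junction(prev_sid: str, po: int, sid: str, o: int) -> int:
        return int(frozenset((ends(prev_sid, po)[1], ends(sid, o)[0])) in reference_links)

    if k == 1:
        best = [(sids[0], "forward")]
    else:
        best_total, best_orients = -1, None
        for first in (0, 1):
            # dp[o] = (score, path) best over scaffolds[1..i] with scaffold i in orientation o
            dp = {o: (junction(sids[0], first, sids[1], o), [first, o]) for o in (0, 1)}
            for i in range(2, k):
                ndp = {}
                for o in (0, 1):
                    cands = [(dp[po][0] + junction(sids[i - 1], po, sids[i], o), dp[po][1] + [o]) for po in (0, 1)]
                    ndp[o] = max(cands, key=lambda t: (t[0], -sum(t[1])))
                dp = ndp
            closed = {o: (dp[o][0] + junction(sids[-1], o, sids[0], first), dp[o][1]) for o in (0, 1)}
            score, path = max(closed.values(), key=lambda t: (t[0], -sum(t[1])))
            if score > best_total:
                best_total, best_orients = score, path
        best = [(sid, "forward" if o == 0 else "reverse") for sid, o in zip(sids, best_orients)]

    gene_order: list[str] = []
    for sid, orient in best:
        gl = genes[sid] if orient == "forward" else genes[sid][::-1]
        gene_order.extend(gl)
    return SyntenyConfiguration(genome_id=genome_id, scaffold_order=best, gene_order=gene_order)


def reorder_draft(
    genome_id: str,
    scaffold_genes: Mapping[str, Sequence[str]],
    reference_orders: Mapping[str, Sequence[str]],
) -> SyntenyConfiguration:
    """Best ordered/oriented configuration of a draft over a reference pool.

    One candidate configuration per reference (order by circular mean
    position, then orientation DP); the configuration with the highest SI
    against its reference wins, ties broken by reference id.
    """
    if not reference_orders:
        raise ConfigError("reference pool is empty")
    if not any(scaffold_genes.values()):
        raise ConfigError(f"draft {genome_id} carries no core genes")
    best: SyntenyConfiguration | None = None
    for ref_id in sorted(reference_orders):
        ref_order = list(reference_orders[ref_id])
        ref_links = order_links(ref_order, circular=True)
        ordered, dropped = score_scaffolds(scaffold_genes, ref_order)
        if not ordered:
            continue
        cfg = orient_scaffolds(ordered, scaffold_genes, ref_links, genome_id=genome_id)
        cfg.best_reference = ref_id
        cfg.dropped_scaffolds = dropped
        links = order_links(cfg.gene_order, circular=True)
        cfg.si = synteny_index(links, ref_links)
        if best is None or cfg.si > best.si:
            best = cfg
    if best is None:
        raise ConfigError(f"draft {genome_id} shares no core genes with any reference")
    return best


def reorder_all(
    drafts: Sequence[tuple[str, Mapping[str, Sequence[str]], float, int]],
    reference_orders: Mapping[str, Sequence[str]],
) -> dict[str, SyntenyConfiguration]:
    """Reorder every draft, in decreasing completeness, growing the pool.

    ``drafts`` holds (genome_id, scaffold->core-gene-order, n50, n_scaffolds).
    Completeness ranks by descending N50, ties by fewer scaffolds, then id.
    Each accepted configuration's implied order joins the reference pool
    before the next draft is processed.
    """
    if not reference_orders:
        raise ConfigError("at least one complete genome is required as reference")
    pool: dict[str, list[str]] = {k: list(v) for k, v in reference_orders.items()}
    out: dict[str, SyntenyConfiguration] = {}
    for gid, scaffold_genes, n50, n_sc in sorted(drafts, key=lambda d: (-d[2], d[3], d[0])):
        cfg = reorder_draft(gid, scaffold_genes, pool)
        out[gid] = cfg
        pool[gid] = list(cfg.gene_order)
    return out


# -------------------------------------------------------- occurrence & maps


def link_label(link: frozenset) -> str:
    a, b = sorted(link)
    return f"{a}|{b}"


def link_occurrence_matrix(linksets: Sequence[LinkSet]) -> pd.DataFrame:
    """Genome x link 0/1 occurrence matrix (columns sorted by label)."""
    all_links = sorted({l for ls in linksets for l in ls.links}, key=link_label)
    data = [[int(l in ls.links) for l in all_links] for ls in linksets]
    return pd.DataFrame(data, index=[ls.genome_id for ls in linksets], columns=[link_label(l) for l in all_links], dtype=int)


def species_link_presence(occurrence: pd.DataFrame, genome_to_species: Mapping[str, str]) -> pd.DataFrame:
    """Species x link presence: a link is present in a species if present in
    at least one member genome."""
    return (occurrence.groupby([genome_to_species[g] for g in occurrence.index]).max() >= 1).astype(int)


def consensus_network(
    species_presence: pd.DataFrame,
    group_of_species: Mapping[str, str],
    majority: float = 0.50,
) -> pd.DataFrame:
    """Majority-rule consensus architecture: links kept iff their
    species-frequency strictly exceeds ``majority`` in at least one group.

    Returns one row per link with per-group frequencies and the kept flag.
    """
    groups = sorted(set(group_of_species.values()))
    rows = []
    freq_by_group = {}
    for grp in groups:
        members = [s for s in species_presence.index if group_of_species.get(s) == grp]
        freq_by_group[grp] = species_presence.loc[members].mean(axis=0) if members else pd.Series(0.0, index=species_presence.columns)
    for link in species_presence.columns:
        freqs = {grp: float(freq_by_group[grp][link]) for grp in groups}
        kept = any(f > majority for f in freqs.values())
        row = {"link": link, "kept": kept}
        row.update({f"freq_{g}": freqs[g] for g in groups})
        row["dominant_group"] = max(groups, key=lambda g: (freqs[g], g)) if kept else ""
        rows.append(row)
    return pd.DataFrame(rows)


def to_networkx(consensus: pd.DataFrame):
    """Kept consensus links as a networkx graph (genes as nodes)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in consensus[consensus["kept"]].iterrows():
        a, b = row["link"].split("|")
        attrs = {k.replace("freq_", ""): v for k, v in row.items() if k.startswith("freq_")}
        g.add_edge(a, b, dominant_group=row["dominant_group"], **attrs)
    return g


def write_sif(consensus: pd.DataFrame, path) -> None:
    """Kept consensus links in SIF format (``gene1 link gene2`` per line)."""
    with open(path, "w") as fh:
        for _, row in consensus[consensus["kept"]].iterrows():
            a, b = row["link"].split("|")
            fh.write(f"{a}\tlink\t{b}\n")


def write_graphml(consensus: pd.DataFrame, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(consensus), path)


def dotplot_coordinates(order_a: Sequence[str], order_b: Sequence[str]) -> pd.DataFrame:
    """Relative positions of shared core genes in two circular orders, for
    pairwise synteny dot plots (one row per shared gene)."""
    pos_a = {g: i / len(order_a) for i, g in enumerate(order_a)}
    pos_b = {g: i / len(order_b) for i, g in enumerate(order_b)}
    shared = [g for g in order_a if g in pos_b]
    return pd.DataFrame(
        {"gene": shared, "relative_position_a": [pos_a[g] for g in shared], "relative_position_b": [pos_b[g] for g in shared]}
    )


def choose_reference_genome(si_matrix: pd.DataFrame) -> str:
    """Genome with the highest mean SI to all other genomes (ties: smallest id)."""
    ids = list(si_matrix.index)
    if len(ids) == 1:
        return ids[0]
    means = {g: (si_matrix.loc[g].sum() - si_matrix.loc[g, g]) / (len(ids) - 1) for g in ids}
    best = max(sorted(ids), key=lambda g: means[g])
    # max over sorted ids returns the first (smallest) id among ties
    return best


def conserved_link_profile(
    reference_id: str,
    reference_order: Sequence[str],
    species_presence: pd.DataFrame,
    group_of_species: Mapping[str, str],
) -> pd.DataFrame:
    """Conservation of the reference genome's links across species.

    Rows are the reference's links in chromosomal order; columns give each
    species' presence plus the per-group frequency of the link.
    """
    groups = sorted(set(group_of_species.values()))
    ref_links = []
    order = list(reference_order)
    for i, a in enumerate(order):
        b = order[(i + 1) % len(order)]
        ref_links.append(frozenset((a, b)))
    rows = []
    for pos, link in enumerate(ref_links):
        lbl = link_label(link)
        present = species_presence[lbl] if lbl in species_presence.columns else pd.Series(0, index=species_presence.index)
        row = {"position": pos, "link": lbl}
        for grp in groups:
            members = [s for s in species_presence.index if group_of_species.get(s) == grp]
            row[f"freq_{grp}"] = float(present.loc[members].mean()) if members else 0.0
        for s in species_presence.index:
            row[f"species_{s}"] = int(present.loc[s])
        rows.append(row)
    return pd.DataFrame(rows)


def si_matrix(linksets: Sequence[LinkSet]) -> pd.DataFrame:
    """Symmetric SI matrix over genomes (diagonal 1)."""
    ids = [ls.genome_id for ls in linksets]
    out = pd.DataFrame(1.0, index=ids, columns=ids)
    for (i, a), (j, b) in itertools.combinations(enumerate(linksets), 2):
        v = synteny_index(a, b)
        out.iat[i, j] = out.iat[j, i] = v
    return out


def grouped_si_summary(si: pd.DataFrame, genome_to_species: Mapping[str, str], group_of_species: Mapping[str, str]) -> pd.DataFrame:
    """Mean +/- sd SI within species, among species within groups, and among
    groups (upper-triangle pairs only)."""
    rows = []
    pairs: dict[str, list[float]] = {}
    ids = list(si.index)
    for a, b in itertools.combinations(ids, 2):
        sa, sb = genome_to_species[a], genome_to_species[b]
        ga, gb = group_of_species[sa], group_of_species[sb]
        if sa == sb:
            key = f"within_species:{ga}"
        elif ga == gb:
            key = f"within_group:{ga}"
        else:
            key = f"between_groups:{min(ga, gb)}-{max(ga, gb)}"
        pairs.setdefault(key, []).append(float(si.loc[a, b]))
    for key in sorted(pairs):
        arr = np.asarray(pairs[key])
        rows.append({"comparison": key, "mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0, "n_pairs": arr.size})
    return pd.DataFrame(rows)
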