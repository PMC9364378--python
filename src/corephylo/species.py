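"""Species delimitation from core-genome nucleotide similarity (PNS).

PNS (percentage nucleotide similarity, analogous to ANI) between two rows of
the concatenated core alignment is the percentage of identical positions among
positions where both rows carry an unambiguous base (gaps, Ns and other
ambiguity codes excluded from the denominator).  Genomes are clustered into
species as the connected components of the graph whose edges join pairs with
PNS >= 97% (single linkage: the pairwise criterion is transitive by closure).
Clusters containing a type strain take its published species name; the rest
become numbered candidate species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import Supermatrix
from .errors import ConfigError

logger = logging.getLogger(__name__)

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SpeciesInfo:
    species_id: str
    name: str
    status: str  # "described" | "candidate"
    members: list[str]
    group: str = ""
    type_strain_names: list[str] = field(default_factory=list)


@dataclass
class SpeciesAssignment:
    """A partition of genomes into species."""

    genome_to_species: dict[str, str]
    species: dict[str, SpeciesInfo]

    def members(self, species_id: str) -> list[str]:
        return self.species[species_id].members

    def n_species(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, sid in self.genome_to_species.items():
            info = self.species[sid]
            rows.append({"genome_id": gid, "species": sid, "name": info.name, "status": info.status, "group": info.group})
        return pd.DataFrame(rows)


def compute_pns(seq_a: str, seq_b: str) -> tuple[float, int]:
    """PNS between two equal-length aligned sequences.

    Returns (percent, n_compared).  Positions where either sequence carries
    anything other than A/C/G/T are excluded from the denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ConfigError(f"sequences differ in length: {len(seq_a)} vs {len(seq_b)}")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    ok = np.isin(a, _VALID) & np.isin(b, _VALID)
    n = int(ok.sum())
    if n == 0:
        raise ConfigError("no comparable positions (all gaps/Ns)")
    matches = int((a[ok] == b[ok]).sum())
    return 100.0 * matches / n, n


def pns_matrix(sm: Supermatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric PNS matrix and compared-position counts over a supermatrix."""
    ids = sm.genome_ids
    arrs = {g: np.frombuffer(sm.sequences[g].upper().encode(), dtype=np.uint8) for g in ids}
    valid = {g: np.isin(arrs[g], _VALID) for g in ids}
    pns = pd.DataFrame(100.0, index=ids, columns=ids)
    counts = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for g in ids:
        counts.loc[g, g] = int(valid[g].sum())
    for ga, gb in itertools.combinations(ids, 2):
        ok = valid[ga] & valid[gb]
        n = int(ok.sum())
        if n == 0:
            raise ConfigError(f"no comparable positions between {ga} and {gb}")
        p = 100.0 * int((arrs[ga][ok] == arrs[gb][ok]).sum()) / n
        pns.loc[ga, gb] = pns.loc[gb, ga] = p
        counts.loc[ga, gb] = counts.loc[gb, ga] = n
    return pns, counts


def delimit_species(pns: pd.DataFrame, threshold: float = 97.0) -> SpeciesAssignment:
    """Partition genomes into species: connected components of the graph with
    edges where PNS >= threshold.  Species ids are assigned in order of each
    component's smallest genome id."""
    ids = list(pns.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        if pns.loc[a, b] >= threshold:
            g.add_edge(a, b)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    genome_to_species: dict[str, str] = {}
    species: dict[str, SpeciesInfo] = {}
    for i, comp in enumerate(comps, start=1):
        sid = f"SP{i:03d}"
        species[sid] = SpeciesInfo(species_id=sid, name=sid, status="candidate", members=comp)
        for gid in comp:
            genome_to_species[gid] = sid
    return SpeciesAssignment(genome_to_species=genome_to_species, species=species)


def label_species(
    assignment: SpeciesAssignment,
    type_strain_table: Mapping[str, str] | None = None,
    group_of_genome: Mapping[str, str] | None = None,
    group_order: Sequence[str] | None = None,
    species_order: Sequence[str] | None = None,
    candidate_prefix: str = "Methylobacterium sp.",
) -> SpeciesAssignment:
    """Name described species after their type strains and number candidates.

    Clusters containing at least one type strain take the alphabetically first
    published name (all names recorded; a merge of several type strains is
    logged).  Candidate clusters are numbered sequentially, blocked by group:
    groups in ``group_order`` (default: alphabetical), species within a group
    in ``species_order`` (default: by smallest member genome id, a stand-in
    for tree order).
    """
    type_strain_table = dict(type_strain_table or {})
    group_of_genome = dict(group_of_genome or {})
    for sid, info in assignment.species.items():
        groups = [group_of_genome[g] for g in info.members if g in group_of_genome]
        if groups:
            # majority group of members; ties by name
            vals, cnts = np.unique(groups, return_counts=True)
            info.group = sorted(zip(-cnts, vals))[0][1]
        names = sorted({type_strain_table[g] for g in info.members if g in type_strain_table})
        if names:
            info.status = "described"
            info.type_strain_names = names
            info.name = names[0]
            if len(names) > 1:
                logger.warning("species %s merges type strains %s; named %s by priority", sid, names, names[0])
        else:
            info.status = "candidate"
    # number candidates, blocked by group
    all_groups = sorted({info.group for info in assignment.species.values()})
    if group_order is None:
        group_order = all_groups
    else:
        group_order = list(group_order) + [g for g in all_groups if g not in set(group_order)]
    candidates = [sid for sid, info in assignment.species.items() if info.status == "candidate"]
    if species_order is not None:
        rank = {s: i for i, s in enumerate(species_order)}
        key = lambda sid: (group_order.index(assignment.species[sid].group), rank.get(sid, len(rank)), assignment.species[sid].members[0])
    else:
        key = lambda sid: (group_order.index(assignment.species[sid].group), assignment.species[sid].members[0])
    for num, sid in enumerate(sorted(candidates, key=key), start=1):
        assignment.species[sid].name = f"{candidate_prefix} {num:03d}"
    return assignment
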