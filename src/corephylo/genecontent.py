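"""Gene-content comparison: species profiles, Bray-Curtis dissimilarity,
pan/core rarefaction and Venn overlaps.

Species-level occurrence profiles average the copy count of each annotation
over member genomes and round to 0 (< 0.5), 1 (0.5 <= n < 1.5) or 2 (>= 1.5)
copies.  Pairwise genome or species dissimilarity is the Bray-Curtis index on
Hellinger-normalized abundances (square root of per-row relative abundance),
which damps the inflated copy counts that fragmented assemblies produce.

Pan-genome (any gene present at least once in at least one sampled genome)
and core-genome (genes in exactly one copy in every sampled genome) sizes per
group are rarefied by sampling 1..N species per group, one random genome per
species, with nested accumulation within a replicate so per-replicate curves
are monotone.  A fixed-depth variant (default 15 species per group) feeds the
pan/core Venn-diagram overlap between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .errors import ConfigError
from .species import SpeciesAssignment

logger = logging.getLogger(__name__)


def round_occurrence(n: float) -> int:
    """Round an average occurrence to 0, 1 or 2 copies."""
    if n < 0.5:
        return 0
    if n < 1.5:
        return 1
    return 2


def species_occurrence_profile(matrix: pd.DataFrame, assignment: SpeciesAssignment) -> pd.DataFrame:
    """Species x gene profile of rounded mean copy counts over member genomes."""
    unassigned = [g for g in matrix.index if g not in assignment.genome_to_species]
    if unassigned:
        raise ConfigError(f"genomes not assigned to any species: {unassigned[:5]}")
    groups = matrix.groupby([assignment.genome_to_species[g] for g in matrix.index]).mean()
    out = groups.map(round_occurrence).astype(int)
    out.index.name = "species"
    return out


def hellinger(profile: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Per-row Hellinger transformation: sqrt of relative abundance.

    Transformed rows are unit vectors under the squared-sum norm.
    """
    if isinstance(profile, pd.Series):
        total = profile.sum()
        if total == 0:
            raise ConfigError("all-zero profile cannot be Hellinger-transformed")
        return np.sqrt(profile / total)
    totals = profile.sum(axis=1)
    if (totals == 0).any():
        raise ConfigError("all-zero row(s) cannot be Hellinger-transformed")
    return np.sqrt(profile.div(totals, axis=0))


def bray_curtis(profile_a: Sequence[float], profile_b: Sequence[float], hellinger_transform: bool = True) -> float:
    """Bray-Curtis dissimilarity between two abundance profiles over the same
    gene universe, optionally on Hellinger-transformed values.  In [0, 1]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("profiles cover different gene universes")
    if a.sum() == 0 and b.sum() == 0:
        raise ConfigError("both profiles are all-zero")
    if hellinger_transform:
        if a.sum() == 0 or b.sum() == 0:
            raise ConfigError("all-zero profile cannot be Hellinger-transformed")
        a = np.sqrt(a / a.sum())
        b = np.sqrt(b / b.sum())
    return float(braycurtis(a, b))


def bray_curtis_matrix(matrix: pd.DataFrame, hellinger_transform: bool = True) -> pd.DataFrame:
    """Symmetric Bray-Curtis matrix over the rows of an abundance matrix."""
    ids = list(matrix.index)
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    vals = matrix.to_numpy(dtype=float)
    if hellinger_transform:
        totals = vals.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ConfigError("all-zero row(s) cannot be Hellinger-transformed")
        vals = np.sqrt(vals / totals)
    for i, j in combinations(range(len(ids)), 2):
        d = float(braycurtis(vals[i], vals[j]))
        out.iat[i, j] = out.iat[j, i] = d
    return out


@dataclass
class RarefactionResult:
    """Mean +/- sd pan and core sizes per group and sample size."""

    table: pd.DataFrame  # columns: group, n_species, pan_mean, pan_sd, core_mean, core_sd

    def for_group(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)


def _pan_core(counts: np.ndarray) -> tuple[int, int]:
    """Pan and core gene counts of a stack of genome count rows."""
    pan = int((counts.max(axis=0) >= 1).sum())
    core = int(((counts == 1).all(axis=0)).sum())
    return pan, core


def rarefy_pan_core(
    matrix: pd.DataFrame,
    assignment: SpeciesAssignment,
    group_of_species: Mapping[str, str],
    n_max: int,
    replicates: int = 100,
    seed: int = 0,
) -> RarefactionResult:
    """Rarefaction of pan/core genome size per group.

    Per replicate: a fresh random species order for the group and one random
    genome per species; sizes accumulated over nested subsets 1..N, so pan is
    non-decreasing and core non-increasing within the replicate.
    """
    rng = np.random.default_rng(seed)
    species_by_group: dict[str, list[str]] = {}
    for sid, grp in group_of_species.items():
        species_by_group.setdefault(grp, []).append(sid)
    rows = []
    vals = matrix.to_numpy(dtype=int)
    row_of = {g: i for i, g in enumerate(matrix.index)}
    for grp in sorted(species_by_group):
        species = sorted(species_by_group[grp])
        n_here = min(n_max, len(species))
        if n_here < n_max:
            logger.warning("group %s has only %d species; rarefaction truncated from %d", grp, len(species), n_max)
        pan = np.zeros((replicates, n_here), dtype=int)
        core = np.zeros((replicates, n_here), dtype=int)
        for r in range(replicates):
            order = list(rng.permutation(species))
            picked = []
            for k, sid in enumerate(order[:n_here]):
                members = assignment.members(sid)
                gid = members[int(rng.integers(0, len(members)))]
                picked.append(row_of[gid])
                p, c = _pan_core(vals[picked])
                pan[r, k] = p
                core[r, k] = c
        for k in range(n_here):
            rows.append(
                {
                    "group": grp,
                    "n_species": k + 1,
                    "pan_mean": float(pan[:, k].mean()),
                    "pan_sd": float(pan[:, k].std(ddof=1)) if replicates > 1 else 0.0,
                    "core_mean": float(core[:, k].mean()),
                    "core_sd": float(core[:, k].std(ddof=1)) if replicates > 1 else 0.0,
                }
            )
    return RarefactionResult(table=pd.DataFrame(rows))


def venn_overlap(
    matrix: pd.DataFrame,
    assignment: SpeciesAssignment,
    group_of_species: Mapping[str, str],
    species_per_group: int = 15,
    replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Exclusive Venn-region sizes of group pan and core gene sets at a fixed
    species depth.

    Per replicate, ``species_per_group`` species are drawn per group (the full
    set, with a warning, if a group is smaller); the group's pan set is every
    gene with rounded occurrence >= 1 in >= 1 sampled species, its core set
    every gene with rounded occurrence exactly 1 in all sampled species.  The
    returned frame has one row per non-empty group subset (region) with mean
    and sd counts over replicates, for pan and core variants.
    """
    groups = sorted(set(group_of_species.values()))
    if len(groups) < 2:
        raise ConfigError(f"venn_overlap needs >= 2 groups, got {groups}")
    rng = np.random.default_rng(seed)
    profile = species_occurrence_profile(matrix, assignment)
    species_by_group: dict[str, list[str]] = {g: [] for g in groups}
    for sid, grp in group_of_species.items():
        if sid in profile.index:
            species_by_group[grp].append(sid)
    for grp, sps in species_by_group.items():
        if len(sps) < species_per_group:
            logger.warning("group %s has only %d species (< %d); using all", grp, len(sps), species_per_group)
    regions = [subset for r in range(1, len(groups) + 1) for subset in combinations(groups, r)]
    acc: dict[tuple[str, tuple[str, ...]], list[int]] = {("pan", s): [] for s in regions}
    acc.update({("core", s): [] for s in regions})
    prof_vals = profile.to_numpy()
    sp_row = {s: i for i, s in enumerate(profile.index)}
    for _ in range(replicates):
        pan_sets: dict[str, set[int]] = {}
        core_sets: dict[str, set[int]] = {}
        for grp in groups:
            sps = sorted(species_by_group[grp])
            k = min(species_per_group, len(sps))
            chosen = [sps[i] for i in rng.choice(len(sps), size=k, replace=False)]
            sub = prof_vals[[sp_row[s] for s in chosen]]
            pan_sets[grp] = set(np.flatnonzero(sub.max(axis=0) >= 1))
            core_sets[grp] = set(np.flatnonzero((sub == 1).all(axis=0)))
        for variant, sets in (("pan", pan_sets), ("core", core_sets)):
            for subset in regions:
                inside = set.intersection(*(sets[g] for g in subset))
                for g in groups:
                    if g not in subset:
                        inside -= sets[g]
                acc[(variant, subset)].append(len(inside))
    rows = []
    for (variant, subset), vals in acc.items():
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "variant": variant,
                "region": "&".join(subset),
                "n_groups": len(subset),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def export_binary_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a 0/1 presence matrix as a pseudo-FASTA (one record per row) with
    a sidecar ``<path>.columns.tsv`` recording the fixed column order.

    Suitable input for an external binary-model (presence/absence) tree
    search.  Returns the sidecar path.
    """
    path = Path(path)
    binary = (matrix.to_numpy() >= 1).astype(int)
    with open(path, "w") as fh:
        for i, rid in enumerate(matrix.index):
            fh.write(f">{rid}\n")
            fh.write("".join(map(str, binary[i])) + "\n")
    sidecar = path.with_suffix(path.suffix + ".columns.tsv")
    pd.Series(list(matrix.columns), name="column").to_csv(sidecar, sep="\t", index_label="index")
    return sidecar


def read_binary_matrix(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`export_binary_matrix`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".columns.tsv")
    cols = pd.read_csv(sidecar, sep="\t", index_col=0)["column"].tolist()
    rows: dict[str, list[int]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:]
            elif line and name is not None:
                rows[name] = [int(c) for c in line]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
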