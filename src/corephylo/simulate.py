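"""Synthetic Methylobacteriaceae-like clade generator.

Produces a clade of several groups of species with known ground truth so that
every downstream stage (annotation parsing, core-panel filtering, alignment,
species delimitation, gene content, synteny, tree comparison) can be exercised
and checked without external data.  The generator emulates the features of the
real collection that matter to those stages:

* a shared single-copy core gene set evolving by independent-site substitution
  (Jukes-Cantor-like: each site mutates with a configured probability, new
  base uniform over the other three), with divergence structured hierarchically
  (genomes within species < species within groups < groups);
* accessory gene content varying by gain/loss events along the hierarchy;
* circular chromosomes whose gene order differs by inversions and block
  translocations;
* draft assemblies as unordered, arbitrarily oriented scaffolds, optionally
  with one gene split across a scaffold breakpoint;
* annotation noise rows (hypothetical proteins, mobile element proteins,
  repeat regions) that the abundance matrix later excludes.

It does not simulate reads, assembly graphs, or intergenic sequence: genes
abut directly on the chromosome.  Accessory and noise gene sequences are held
fixed across the clade (only their presence varies); core gene sequences are
the ones that evolve, because they alone feed the alignment and similarity
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import GeneCall, GenomeRecord, write_fasta, write_rast_table
from .errors import ConfigError

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Literal noise annotation strings, as RAST writes them.
NOISE_FUNCTIONS = {
    "hypothetical": "hypothetical protein",
    "mobile": "Mobile element protein",
    "repeat": "repeat region",
}

_ISOLATION_SOURCES = (
    "phyllosphere",
    "rhizosphere",
    "soil",
    "water",
    "sediment",
    "anthropogenic",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic clade.

    Divergences are expected pairwise substitutions per site between units at
    that level (e.g. two genomes of different species in the same group differ
    at about ``between_species_divergence`` of their core sites).  Rates are
    Poisson means per branch of the group/species/genome hierarchy.
    """

    n_groups: int = 4
    species_per_group: int = 5
    genomes_per_species: int = 2
    core_panel_size: int = 300
    accessory_pool_size: int = 600
    within_species_divergence: float = 0.005
    between_species_divergence: float = 0.05
    between_group_divergence: float = 0.15
    gene_gain_rate: float = 8.0
    gene_loss_rate: float = 8.0
    rearrangement_rate: float = 2.0
    mean_gene_length_codons: int = 300
    draft_fraction: float = 0.5
    scaffolds_per_draft: tuple[int, int] = (4, 12)
    gene_split_probability: float = 0.05
    noise_annotation_rates: dict = field(
        default_factory=lambda: {"hypothetical": 0.08, "mobile": 0.01, "repeat": 0.005}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_groups",
            "species_per_group",
            "genomes_per_species",
            "accessory_pool_size",
            "mean_gene_length_codons",
        ):
            if getattr(self, name) < 1 and name != "accessory_pool_size":
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.core_panel_size < 3:
            raise ConfigError(f"core_panel_size must be >= 3, got {self.core_panel_size}")
        for name in (
            "within_species_divergence",
            "between_species_divergence",
            "between_group_divergence",
            "gene_gain_rate",
            "gene_loss_rate",
            "rearrangement_rate",
            "gene_split_probability",
            "draft_fraction",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (
            self.within_species_divergence
            <= self.between_species_divergence
            <= self.between_group_divergence
        ):
            raise ConfigError(
                "divergences must satisfy within_species_divergence <= "
                "between_species_divergence <= between_group_divergence"
            )
        if not (0.0 <= self.draft_fraction <= 1.0):
            raise ConfigError(f"draft_fraction must be in [0, 1], got {self.draft_fraction}")
        lo, hi = self.scaffolds_per_draft
        if lo < 1 or hi < lo:
            raise ConfigError(f"scaffolds_per_draft must be a range (lo>=1, hi>=lo), got {self.scaffolds_per_draft}")
        for k, v in self.noise_annotation_rates.items():
            if k not in NOISE_FUNCTIONS:
                raise ConfigError(f"noise_annotation_rates: unknown class {k!r}")
            if v < 0:
                raise ConfigError(f"noise_annotation_rates[{k!r}] must be >= 0, got {v}")


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a simulated dataset."""

    species_assignment: dict[str, str]
    group_assignment: dict[str, str]
    true_gene_orders: dict[str, list[str]]
    true_tree: str
    core_sequences: dict[str, dict[str, str]]
    gene_content: "object" = None  # pandas DataFrame genome x gene copy counts
    type_strains: dict[str, str] = field(default_factory=dict)
    core_gene_functions: list[str] = field(default_factory=list)
    core_gene_lengths: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------- sequences


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence: n_codons non-stop codons plus a terminal stop."""
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "".join(_CODONS[i] for i in idx) + "TAA"


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Independent-site substitution on a coding sequence.

    Each site flips with probability ``divergence`` to one of the three other
    bases, uniformly — except that a substitution which would create an
    internal stop codon is redirected to another base (purifying selection
    against nonsense mutations, which real core genes are under; without it
    almost every gene acquires premature stops at realistic divergences).
    The terminal codon is free to vary.
    """
    if divergence <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    n = int(hit.sum())
    if not n:
        return seq
    cur_idx = np.searchsorted(_BASES, arr[hit])
    new_idx = (cur_idx + rng.integers(1, 4, size=n)) % 4
    arr[hit] = _BASES[new_idx]
    n_codons = arr.size // 3
    if n_codons > 1:
        usable = 3 * n_codons
        codons = arr[:usable].reshape(-1, 3)
        hitc = hit[:usable].reshape(-1, 3)
        candidates = np.flatnonzero(hitc.any(axis=1))
        for ci in candidates:
            if ci == n_codons - 1 and arr.size % 3 == 0:
                continue  # the gene's own stop codon may drift
            while codons[ci].tobytes().decode() in _STOPS:
                for pos in np.flatnonzero(hitc[ci]):
                    alternates = [b for b in "ACGT" if b != seq[3 * ci + pos]]
                    codons[ci, pos] = ord(alternates[int(rng.integers(0, 3))])
    return arr.tobytes().decode()


# ---------------------------------------------------------------- gene order


def _apply_rearrangements(order: list[str], strands: dict[str, str], n_events: int, rng: np.random.Generator) -> list[str]:
    """Random inversions and block translocations on a circular gene order."""
    order = list(order)
    g = len(order)
    for _ in range(n_events):
        if g < 3:
            break
        i = int(rng.integers(0, g))
        span = int(rng.integers(1, max(2, g // 4)))
        seg = [order[(i + k) % g] for k in range(span)]
        rest = [x for x in order if x not in set(seg)]
        if rng.random() < 0.5:  # inversion in place
            seg = seg[::-1]
            for gene in seg:
                strands[gene] = "-" if strands[gene] == "+" else "+"
            j = i % (len(rest) + 1)
        else:  # translocation to a random position
            j = int(rng.integers(0, len(rest) + 1))
        order = rest[:j] + seg + rest[j:]
    return order


# ---------------------------------------------------------------- simulation


def _core_id(i: int) -> str:
    return f"Core protein CP{i:04d}"


def _acc_id(i: int) -> str:
    return f"Accessory protein AP{i:04d}"


def simulate_dataset(config: SimConfig):
    """Simulate one clade.

    Returns
    -------
    (genomes, genecalls, truth)
        ``genomes``: genome_id -> :class:`GenomeRecord`;
        ``genecalls``: flat list of :class:`GeneCall` over all genomes;
        ``truth``: :class:`SyntheticTruth`.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)

    core = [_core_id(i) for i in range(config.core_panel_size)]
    pool = [_acc_id(i) for i in range(config.accessory_pool_size)]
    lengths = {g: max(50, int(rng.poisson(config.mean_gene_length_codons))) for g in core + pool}
    root_seq = {g: random_cds(rng, lengths[g]) for g in core + pool}

    # root content: core plus a random half of the accessory pool
    n_root_acc = config.accessory_pool_size // 2
    root_acc = list(rng.choice(pool, size=n_root_acc, replace=False)) if n_root_acc else []
    root_order = core + root_acc
    rng.shuffle(root_order)
    root_strands = {g: ("+" if rng.random() < 0.5 else "-") for g in core + pool}

    dw = config.within_species_divergence / 2.0
    ds = config.between_species_divergence / 2.0
    dg = config.between_group_divergence / 2.0

    def branch(node, div, rng):
        """Evolve (sequences, order, strands) along one branch.

        Every pool gene's sequence evolves whether or not it is currently
        present, so a gene regained later carries lineage-specific divergence.
        """
        seqs, order, strands = node
        seqs = {g: mutate(s, div, rng) for g, s in seqs.items()}
        order = list(order)
        strands = dict(strands)
        present_acc = [g for g in order if g not in set(core)]
        n_loss = int(rng.poisson(config.gene_loss_rate))
        for _ in range(min(n_loss, len(present_acc))):
            victim = present_acc.pop(int(rng.integers(0, len(present_acc))))
            order.remove(victim)
        absent = [g for g in pool if g not in set(order)]
        n_gain = int(rng.poisson(config.gene_gain_rate))
        for _ in range(min(n_gain, len(absent))):
            gained = absent.pop(int(rng.integers(0, len(absent))))
            order.insert(int(rng.integers(0, len(order) + 1)), gained)
        order = _apply_rearrangements(order, strands, int(rng.poisson(config.rearrangement_rate)), rng)
        return seqs, order, strands

    root = (dict(root_seq), root_order, root_strands)
    # the sequence dict at a node covers the whole gene pool

    genomes: dict[str, GenomeRecord] = {}
    genecalls: list[GeneCall] = []
    species_assignment: dict[str, str] = {}
    group_assignment: dict[str, str] = {}
    true_orders: dict[str, list[str]] = {}
    core_sequences: dict[str, dict[str, str]] = {g: {} for g in core}
    content_rows: dict[str, dict[str, int]] = {}
    type_strains: dict[str, str] = {}
    tree_groups = []

    group_names = [chr(ord("A") + i) for i in range(config.n_groups)]
    genome_counter = 0
    n_genomes_total = config.n_groups * config.species_per_group * config.genomes_per_species
    draft_flags = rng.random(n_genomes_total) < config.draft_fraction

    for gi, gname in enumerate(group_names):
        gnode = branch(root, dg, rng)
        tree_species = []
        for si in range(config.species_per_group):
            sname = f"sp{gname}{si + 1:02d}"
            group_assignment[sname] = gname
            snode = branch(gnode, ds, rng)
            tree_tips = []
            for ki in range(config.genomes_per_species):
                genome_counter += 1
                gid = f"G{genome_counter:04d}"
                seqs, order, strands = branch(snode, dw, rng)
                species_assignment[gid] = sname
                true_orders[gid] = [g for g in order if g in set(core)]
                for g in core:
                    core_sequences[g][gid] = seqs[g]
                # annotation noise rows, inserted into the layout
                layout = [(g, seqs[g], strands[g]) for g in order]
                for cls, rate in config.noise_annotation_rates.items():
                    n_noise = int(rng.poisson(rate * len(order)))
                    for _ in range(n_noise):
                        nseq = random_cds(rng, max(30, int(rng.poisson(120))))
                        pos = int(rng.integers(0, len(layout) + 1))
                        layout.insert(pos, (NOISE_FUNCTIONS[cls], nseq, "+" if rng.random() < 0.5 else "-"))
                # random origin on the circle
                rot = int(rng.integers(0, len(layout)))
                layout = layout[rot:] + layout[:rot]
                record, calls = _assemble(gid, layout)
                if draft_flags[genome_counter - 1]:
                    lo, hi = config.scaffolds_per_draft
                    n_sc = int(rng.integers(lo, hi + 1))
                    n_sc = min(n_sc, len(layout))
                    record, calls = fragment_assembly(
                        record,
                        calls,
                        n_sc,
                        split_genes=rng.random() < config.gene_split_probability,
                        rng=rng,
                    )
                record.metadata.update(
                    {
                        "group": gname,
                        "species": sname,
                        "isolation_source": _ISOLATION_SOURCES[int(rng.integers(0, len(_ISOLATION_SOURCES)))],
                    }
                )
                genomes[gid] = record
                genecalls.extend(calls)
                row: dict[str, int] = {}
                for g in order:
                    row[g] = row.get(g, 0) + 1
                content_rows[gid] = row
                tree_tips.append(f"{gid}:{dw:.6f}")
            # described species: first half of each group's species carry a type strain
            if si < config.species_per_group // 2:
                first = sorted(g for g, s in species_assignment.items() if s == sname)[0]
                type_strains[first] = f"Methylobacterium synthesis{gi * config.species_per_group + si + 1:03d}"
            tree_species.append("(" + ",".join(tree_tips) + f"):{ds:.6f}")
        tree_groups.append("(" + ",".join(tree_species) + f"):{dg:.6f}")
    newick = "(" + ",".join(tree_groups) + ");"

    all_genes = core + pool
    content = pd.DataFrame(
        [[content_rows[gid].get(g, 0) for g in all_genes] for gid in genomes],
        index=list(genomes),
        columns=all_genes,
        dtype=int,
    )
    content.index.name = "genome_id"

    truth = SyntheticTruth(
        species_assignment=species_assignment,
        group_assignment=group_assignment,
        true_gene_orders=true_orders,
        true_tree=newick,
        core_sequences=core_sequences,
        gene_content=content,
        type_strains=type_strains,
        core_gene_functions=core,
        core_gene_lengths={g: 3 * lengths[g] + 3 for g in core},
    )
    return genomes, genecalls, truth


def _assemble(genome_id: str, layout: list[tuple[str, str, str]], scaffold_prefix: str = "SC") -> tuple[GenomeRecord, list[GeneCall]]:
    """Lay genes end-to-end on one scaffold and emit record + calls."""
    from .annotation import reverse_complement

    seq_parts = []
    calls = []
    pos = 0
    for func, gseq, strand in layout:
        placed = gseq if strand == "+" else reverse_complement(gseq)
        start, stop = pos + 1, pos + len(gseq)
        calls.append(
            GeneCall(
                genome_id=genome_id,
                scaffold_id=f"{scaffold_prefix}001",
                start=start,
                stop=stop,
                strand=strand,
                function=func,
                sequence=gseq,
                feature_id=f"{genome_id}.f{len(calls) + 1:05d}",
            )
        )
        seq_parts.append(placed)
        pos = stop
    record = GenomeRecord(genome_id=genome_id, scaffolds={f"{scaffold_prefix}001": "".join(seq_parts)}, is_draft=False)
    return record, calls


def fragment_assembly(
    genome: GenomeRecord,
    genecalls: list[GeneCall],
    n_scaffolds: int,
    split_genes: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeRecord, list[GeneCall]]:
    """Break a complete (single-scaffold, circular) genome into a draft.

    The circular gene order is cut at ``n_scaffolds`` boundaries; each
    resulting scaffold keeps its internal gene order but scaffold order and
    orientation are randomised.  With ``split_genes``, one cut lands inside a
    gene, which is then emitted as two partial calls whose lengths sum to the
    full gene length.
    """
    if genome.is_draft or len(genome.scaffolds) != 1:
        raise ConfigError(f"fragment_assembly requires a complete single-scaffold genome, got {genome.genome_id}")
    calls = sorted((c for c in genecalls if c.genome_id == genome.genome_id), key=lambda c: c.start)
    g = len(calls)
    if n_scaffolds > g:
        raise ConfigError(f"n_scaffolds={n_scaffolds} exceeds gene count {g}")
    if rng is None:
        rng = np.random.default_rng(seed)

    items: list[tuple[str, str, str]] = [(c.function, c.sequence, c.strand) for c in calls]
    cuts = sorted(int(x) for x in rng.choice(g, size=n_scaffolds, replace=False))
    arcs: list[list[tuple[str, str, str]]] = []
    for a, b in zip(cuts, cuts[1:] + [cuts[0] + g]):
        arcs.append([items[k % g] for k in range(a, b)])

    if split_genes and n_scaffolds >= 1:
        # cut inside the first gene of one arc: its head stays with the
        # previous arc's tail, keeping both partials' sizes summing to 1.
        ai = int(rng.integers(0, len(arcs)))
        func, seq, strand = arcs[ai][0]
        if len(seq) >= 60:
            p = int(rng.integers(int(0.1 * len(seq)), int(0.9 * len(seq))))
            head, tail = seq[:p], seq[p:]
            prev = arcs[(ai - 1) % len(arcs)]
            if strand == "+":
                prev.append((func, head, "+"))
                arcs[ai][0] = (func, tail, "+")
            else:
                # minus strand: the scaffold carries the reverse complement, so
                # the left-hand scaffold piece holds the 3' (tail) of the CDS
                prev.append((func, tail, "-"))
                arcs[ai][0] = (func, head, "-")

    order = list(rng.permutation(len(arcs)))
    flips = rng.random(len(arcs)) < 0.5
    from .annotation import reverse_complement

    scaffolds: dict[str, str] = {}
    new_calls: list[GeneCall] = []
    for rank, ai in enumerate(order):
        arc = arcs[ai]
        if flips[ai]:
            arc = [(f, s, "-" if st == "+" else "+") for f, s, st in arc[::-1]]
        sid = f"SC{rank + 1:03d}"
        pos = 0
        parts = []
        for func, gseq, strand in arc:
            placed = gseq if strand == "+" else reverse_complement(gseq)
            start, stop = pos + 1, pos + len(gseq)
            new_calls.append(
                GeneCall(
                    genome_id=genome.genome_id,
                    scaffold_id=sid,
                    start=start,
                    stop=stop,
                    strand=strand,
                    function=func,
                    sequence=gseq,
                    feature_id=f"{genome.genome_id}.f{len(new_calls) + 1:05d}",
                )
            )
            parts.append(placed)
            pos = stop
        scaffolds[sid] = "".join(parts)
    record = GenomeRecord(
        genome_id=genome.genome_id,
        scaffolds=scaffolds,
        is_draft=True,
        metadata=dict(genome.metadata),
    )
    return record, new_calls


# ---------------------------------------------------------------- output


def write_dataset(
    genomes: dict[str, GenomeRecord],
    genecalls: list[GeneCall],
    truth: SyntheticTruth,
    directory: str | Path,
) -> list[Path]:
    """Write the dataset to disk: one RAST-dialect TSV and one FASTA per
    genome, a metadata table, and the truth tables.  Returns the manifest
    (list of written paths).  Empty genome set -> empty manifest, no files."""
    import pandas as pd

    manifest: list[Path] = []
    if not genomes:
        return manifest
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[GeneCall]] = {}
    for c in genecalls:
        by_genome.setdefault(c.genome_id, []).append(c)
    meta_rows = []
    for gid, rec in genomes.items():
        tsv = directory / f"{gid}.tsv"
        write_rast_table(by_genome.get(gid, []), tsv)
        fna = directory / f"{gid}.fna"
        write_fasta(rec.scaffolds, fna)
        manifest += [tsv, fna]
        meta_rows.append(
            {
                "genome_id": gid,
                "group": rec.metadata.get("group", ""),
                "species": rec.metadata.get("species", ""),
                "type_strain_name": truth.type_strains.get(gid, ""),
                "n50": rec.n50,
                "n_scaffolds": len(rec.scaffolds),
                "is_draft": int(rec.is_draft),
                "isolation_source": rec.metadata.get("isolation_source", ""),
            }
        )
    meta = directory / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(meta, sep="\t", index=False)
    manifest.append(meta)

    tdir = directory / "truth"
    tdir.mkdir(exist_ok=True)
    sa = tdir / "species_assignment.tsv"
    pd.DataFrame(
        [(g, s, truth.group_assignment[s]) for g, s in truth.species_assignment.items()],
        columns=["genome_id", "species", "group"],
    ).to_csv(sa, sep="\t", index=False)
    go = tdir / "gene_orders.tsv"
    pd.DataFrame(
        [(g, ";".join(order)) for g, order in truth.true_gene_orders.items()],
        columns=["genome_id", "core_gene_order"],
    ).to_csv(go, sep="\t", index=False)
    nwk = tdir / "true_tree.nwk"
    nwk.write_text(truth.true_tree + "\n")
    gc = tdir / "gene_content.tsv"
    truth.gene_content.to_csv(gc, sep="\t")
    manifest += [sa, go, nwk, gc]
    return manifest
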