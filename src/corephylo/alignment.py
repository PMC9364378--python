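"""Per-gene codon alignments and the concatenated supermatrix.

Core-gene nucleotide sequences are aligned via their amino-acid translation
(translate, align the proteins, back-thread the codons), terminal stop codons
excluded.  The aligner is an external contract: any callable mapping a
``{genome_id: protein}`` dict to the same dict with gap characters inserted
can be plugged in.  Two implementations ship with the package:

* :class:`CenterStarAligner` — a deterministic center-star progressive
  aligner built on Biopython's pairwise aligner, sufficient for the
  substitution-dominated synthetic data and for fixtures;
* :class:`MafftAligner` — a thin adapter around an external ``mafft``
  executable for real datasets.

Alignment ends whose terminal codon column is missing (gap or N) in more than
90% of rows are trimmed, and per-gene alignments are concatenated into a
supermatrix in panel order, genes missing from a genome filled with N runs
spanning exactly their partition.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from Bio import Align
from Bio.Seq import Seq

from .errors import ConfigError, ParseError

_MISSING = set("-Nn?")


@dataclass
class GeneAlignment:
    """Codon-respecting nucleotide alignment of one gene (gaps in triplets)."""

    gene_id: str
    sequences: dict[str, str]
    missing_genomes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


@dataclass
class Supermatrix:
    """Concatenated core-gene alignment with per-gene partitions.

    ``partitions`` holds (gene_id, start, end) half-open column ranges.
    """

    genome_ids: list[str]
    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def slice_gene(self, gene_id: str) -> dict[str, str]:
        for g, a, b in self.partitions:
            if g == gene_id:
                return {gid: s[a:b] for gid, s in self.sequences.items()}
        raise KeyError(gene_id)


# ------------------------------------------------------------------ aligners


class CenterStarAligner:
    """Deterministic center-star multiple alignment of protein sequences.

    The longest sequence (ties by key order) is the center; every other
    sequence is globally aligned against it and the pairwise alignments are
    merged by propagating center gaps.  Exact for the no-indel and
    single-indel cases used in tests; adequate plumbing for synthetic data
    where substitutions dominate.
    """

    def __init__(self) -> None:
        self._pw = Align.PairwiseAligner()
        self._pw.mode = "global"
        self._pw.match_score = 2.0
        self._pw.mismatch_score = -1.0
        self._pw.open_gap_score = -5.0
        self._pw.extend_gap_score = -0.5

    def __call__(self, proteins: Mapping[str, str]) -> dict[str, str]:
        keys = list(proteins)
        if len(keys) == 1:
            return {keys[0]: proteins[keys[0]]}
        if len(set(len(p) for p in proteins.values())) == 1:
            # equal-length inputs: gap-free alignment is optimal under
            # affine gap costs dominated by the open penalty
            return dict(proteins)
        center = max(keys, key=lambda k: (len(proteins[k]), -keys.index(k)))
        center_seq = proteins[center]
        # pairwise alignments against the center
        pair: dict[str, tuple[str, str]] = {}
        for k in keys:
            if k == center:
                continue
            aln = self._pw.align(center_seq, proteins[k])[0]
            a, b = str(aln[0]), str(aln[1])
            pair[k] = (a, b)
        # merged center coordinates: for each center residue, the maximum gap
        # run preceding it over all pairwise alignments
        gaps_before = [0] * (len(center_seq) + 1)
        for a, _ in pair.values():
            i = 0
            run = 0
            for ch in a:
                if ch == "-":
                    run += 1
                else:
                    gaps_before[i] = max(gaps_before[i], run)
                    run = 0
                    i += 1
            gaps_before[len(center_seq)] = max(gaps_before[len(center_seq)], run)
        out: dict[str, str] = {}
        out[center] = self._thread(center_seq, "-" * 0, gaps_before, center=True)
        for k in keys:
            if k == center:
                continue
            a, b = pair[k]
            out[k] = self._merge(a, b, gaps_before)
        # preserve input row order
        return {k: out[k] for k in keys}

    @staticmethod
    def _thread(seq: str, _unused: str, gaps_before: list[int], center: bool) -> str:
        parts = []
        for i, ch in enumerate(seq):
            parts.append("-" * gaps_before[i])
            parts.append(ch)
        parts.append("-" * gaps_before[len(seq)])
        return "".join(parts)

    @staticmethod
    def _merge(center_aln: str, other_aln: str, gaps_before: list[int]) -> str:
        out = []
        i = 0  # center residue index
        run = []
        for ca, ob in zip(center_aln, other_aln):
            if ca == "-":
                run.append(ob)
            else:
                pad = gaps_before[i] - len(run)
                out.append("-" * pad)
                out.extend(run)
                run = []
                out.append(ob)
                i += 1
        pad = gaps_before[len(gaps_before) - 1] - len(run)
        out.append("-" * pad)
        out.extend(run)
        return "".join(out)


class MafftAligner:
    """Adapter for an external MAFFT executable (default parameters)."""

    def __init__(self, executable: str = "mafft") -> None:
        if shutil.which(executable) is None:
            raise ConfigError(f"aligner executable {executable!r} not found on PATH")
        self.executable = executable

    def __call__(self, proteins: Mapping[str, str]) -> dict[str, str]:
        with tempfile.TemporaryDirectory() as td:
            inp = Path(td) / "in.faa"
            with open(inp, "w") as fh:
                for k, s in proteins.items():
                    fh.write(f">{k}\n{s}\n")
            proc = subprocess.run(
                [self.executable, "--quiet", "--auto", str(inp)],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise ParseError(f"mafft failed: {proc.stderr.strip()}")
            out: dict[str, str] = {}
            name = None
            for line in proc.stdout.splitlines():
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    out[name] = ""
                elif name:
                    out[name] += line.strip()
        return {k: out[k].upper() for k in proteins}


Aligner = Callable[[Mapping[str, str]], dict[str, str]]


# ------------------------------------------------------------------ operations


def align_gene(
    sequences: Mapping[str, str],
    gene_id: str = "",
    aligner: Aligner | None = None,
) -> GeneAlignment:
    """Translate-align-back-translate one gene.

    Terminal stop codons are removed before translation and never reappear in
    the output.  A sequence with an internal stop codon, or whose length is
    not a codon multiple, is flagged and its genome listed missing.
    """
    if aligner is None:
        aligner = CenterStarAligner()
    proteins: dict[str, str] = {}
    codons: dict[str, str] = {}
    missing: list[str] = []
    for gid, nt in sequences.items():
        nt = nt.upper()
        if nt[-3:] in ("TAA", "TAG", "TGA"):
            nt = nt[:-3]
        if not nt or len(nt) % 3:
            missing.append(gid)
            continue
        aa = str(Seq(nt).translate())
        if "*" in aa:
            missing.append(gid)
            continue
        proteins[gid] = aa
        codons[gid] = nt
    if not proteins:
        return GeneAlignment(gene_id=gene_id, sequences={}, missing_genomes=missing)
    aligned_aa = aligner(proteins)
    lengths = {len(a) for a in aligned_aa.values()}
    if len(lengths) != 1:
        raise ParseError(f"aligner returned ragged rows for gene {gene_id!r}")
    out: dict[str, str] = {}
    for gid, aa in aligned_aa.items():
        nt = codons[gid]
        parts = []
        i = 0
        for ch in aa:
            if ch == "-":
                parts.append("---")
            else:
                parts.append(nt[i : i + 3])
                i += 3
        if i != len(nt):
            raise ParseError(f"aligner dropped residues for genome {gid} in gene {gene_id!r}")
        out[gid] = "".join(parts)
    return GeneAlignment(gene_id=gene_id, sequences=out, missing_genomes=missing)


def _codon_missing_fraction(aln: GeneAlignment, codon_index: int) -> float:
    n = 0
    miss = 0
    for s in aln.sequences.values():
        cod = s[3 * codon_index : 3 * codon_index + 3]
        n += 1
        if all(ch in _MISSING for ch in cod):
            miss += 1
    return miss / n if n else 0.0


def trim_alignment_ends(aln: GeneAlignment, max_missing: float = 0.90) -> GeneAlignment:
    """Trim terminal codon columns whose missing-data fraction (gap or N,
    over rows) strictly exceeds ``max_missing``; interior columns are never
    touched.  Idempotent."""
    if not aln.sequences:
        return aln
    n_codons = aln.length // 3
    lo, hi = 0, n_codons
    while lo < hi and _codon_missing_fraction(aln, lo) > max_missing:
        lo += 1
    while hi > lo and _codon_missing_fraction(aln, hi - 1) > max_missing:
        hi -= 1
    if lo >= hi:
        raise ParseError(f"trimming would empty the alignment of gene {aln.gene_id!r}")
    if lo == 0 and hi == n_codons:
        return aln
    return GeneAlignment(
        gene_id=aln.gene_id,
        sequences={g: s[3 * lo : 3 * hi] for g, s in aln.sequences.items()},
        missing_genomes=list(aln.missing_genomes),
    )


def concatenate(alignments: Sequence[GeneAlignment], genome_ids: Sequence[str]) -> Supermatrix:
    """Concatenate trimmed gene alignments in the given order; genomes missing
    a gene carry an N run spanning exactly that gene's partition."""
    genome_ids = list(genome_ids)
    parts: dict[str, list[str]] = {g: [] for g in genome_ids}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for aln in alignments:
        seen = set()
        for gid in aln.sequences:
            if gid in seen:
                raise ParseError(f"duplicate genome {gid} in gene {aln.gene_id!r}")
            seen.add(gid)
        L = aln.length
        for gid in genome_ids:
            parts[gid].append(aln.sequences.get(gid, "N" * L))
        partitions.append((aln.gene_id, pos, pos + L))
        pos += L
    return Supermatrix(
        genome_ids=genome_ids,
        sequences={g: "".join(p) for g, p in parts.items()},
        partitions=partitions,
    )


# ------------------------------------------------------------------ export


def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sm.genome_ids:
            fh.write(f">{gid}\n{sm.sequences[gid]}\n")


def write_supermatrix_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: name, space, sequence."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.genome_ids)} {sm.length}\n")
        for gid in sm.genome_ids:
            fh.write(f"{gid}  {sm.sequences[gid]}\n")


def write_partition_file(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file: ``DNA, gene = start-end`` (1-based)."""
    with open(path, "w") as fh:
        for gene, a, b in sm.partitions:
            fh.write(f"DNA, {gene} = {a + 1}-{b}\n")
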