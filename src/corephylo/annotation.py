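"""Annotation-table parsing and per-genome summaries.

The package consumes per-genome gene-call tables in the tab-separated
"Spreadsheet" dialect exported by the RAST annotation server: one row per
feature with the contig, coordinates, strand, the free-text ``function``
string, and the called nucleotide sequence.  Gene identity across genomes is
equated with identity of the function string, so the genome x function
copy-count matrix (after excluding uninformative annotations: hypothetical
proteins, repeat regions and mobile element proteins) is the basic object
every downstream stage works from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ParseError

logger = logging.getLogger(__name__)

#: Function strings removed before any gene-content computation
#: (matched case-insensitively, exact after casefold).
DEFAULT_EXCLUSIONS: tuple[str, ...] = (
    "hypothetical protein",
    "repeat region",
    "mobile element protein",
)

#: Columns a RAST-dialect table must provide.
RAST_COLUMNS: tuple[str, ...] = (
    "contig_id",
    "feature_id",
    "type",
    "location",
    "start",
    "stop",
    "strand",
    "function",
    "nucleotide_sequence",
)


@dataclass
class GeneCall:
    """One annotated feature.

    Coordinates are 1-based inclusive with ``start <= stop``; RAST writes
    minus-strand features with start > stop, which is normalised on read and
    recorded in ``strand``.  ``sequence`` is the coding-strand nucleotide
    sequence (already reverse-complemented for minus-strand features by RAST).
    """

    genome_id: str
    scaffold_id: str
    start: int
    stop: int
    strand: str
    function: str
    sequence: str
    feature_id: str = ""
    partial: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeStats:
    """Coding-sequence summary statistics for one genome."""

    genome_id: str
    coding_size: int
    n_annotations: int
    n_unique_annotations: int
    mean_copy_number: float
    n_mobile_elements: int
    gc_content: float


@dataclass
class GenomeRecord:
    """One assembly: scaffold sequences plus assembly-level metadata."""

    genome_id: str
    scaffolds: dict[str, str]
    is_draft: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n50(self) -> int:
        return n50(len(s) for s in self.scaffolds.values())

    @property
    def total_size(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


def n50(lengths: Iterable[int]) -> int:
    """Assembly N50: length at which half the total assembly is in longer pieces."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        return 0
    half = sum(ls) / 2.0
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    return ls[-1]


def _norm_function(function: str) -> str:
    return " ".join(function.casefold().split())


def is_excluded(function: str, exclusions: Sequence[str] = DEFAULT_EXCLUSIONS) -> bool:
    """Case-insensitive exact match of a function string against the exclusion list."""
    f = _norm_function(function)
    return any(f == _norm_function(e) for e in exclusions)


def read_rast_table(path: str | Path, genome_id: str | None = None) -> list[GeneCall]:
    """Parse one RAST-dialect tab-separated table into gene calls.

    Rows lacking a nucleotide sequence are kept with an empty sequence and
    flagged ``partial``.  Minus-strand rows with start > stop are normalised
    to (min, max).

    Raises
    ------
    ParseError
        If a mandatory column is absent, or a coordinate cannot be parsed
        (the message carries the 1-based data line number).
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - I/O failure path
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in ("contig_id", "start", "stop", "strand", "function") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    seq_col = "nucleotide_sequence" if "nucleotide_sequence" in df.columns else None
    calls: list[GeneCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        try:
            a, b = int(r["start"]), int(r["stop"])
        except ValueError as exc:
            raise ParseError(f"{path}: malformed coordinate on data line {i}: {exc}") from exc
        strand = r["strand"].strip() or ("+" if a <= b else "-")
        seq = (r[seq_col] if seq_col else "").strip().upper()
        calls.append(
            GeneCall(
                genome_id=genome_id,
                scaffold_id=r["contig_id"],
                start=min(a, b),
                stop=max(a, b),
                strand="-" if strand in ("-", "-1") else "+",
                function=r["function"].strip(),
                sequence=seq,
                feature_id=r.get("feature_id", ""),
                partial=not seq,
            )
        )
    if not calls:
        logger.warning("%s: table contains a header but no feature rows", path)
    return calls


def write_rast_table(calls: Sequence[GeneCall], path: str | Path) -> None:
    """Write gene calls back to the RAST-dialect TSV (minus strand as start>stop)."""
    rows = []
    for c in calls:
        start, stop = (c.stop, c.start) if c.strand == "-" else (c.start, c.stop)
        rows.append(
            {
                "contig_id": c.scaffold_id,
                "feature_id": c.feature_id,
                "type": "CDS",
                "location": f"{c.scaffold_id}_{start}_{stop}",
                "start": start,
                "stop": stop,
                "strand": c.strand,
                "function": c.function,
                "nucleotide_sequence": c.sequence,
            }
        )
    pd.DataFrame(rows, columns=list(RAST_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read an assembly FASTA into a scaffold-id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_annotation_matrix(
    genecalls: Iterable[GeneCall],
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
) -> pd.DataFrame:
    """Genome x function copy-count matrix with the exclusion rules applied.

    Cell (g, f) is the number of calls with function f in genome g.  Excluded
    functions never appear as columns; the operation is idempotent.  Partial
    calls (no sequence) still count: the annotation exists in the genome.
    """
    counts: dict[tuple[str, str], int] = {}
    genomes: dict[str, None] = {}
    functions: dict[str, None] = {}
    for c in genecalls:
        genomes.setdefault(c.genome_id, None)
        if is_excluded(c.function, exclusions):
            continue
        functions.setdefault(c.function, None)
        counts[(c.genome_id, c.function)] = counts.get((c.genome_id, c.function), 0) + 1
    mat = pd.DataFrame(0, index=list(genomes), columns=list(functions), dtype=int)
    for (g, f), n in counts.items():
        mat.loc[g, f] = n
    mat.index.name = "genome_id"
    return mat


def genome_summary(
    genecalls: Sequence[GeneCall],
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
) -> GenomeStats:
    """Coding-sequence statistics for the calls of a single genome.

    ``mean_copy_number`` and ``n_unique_annotations`` are computed after
    exclusions; ``coding_size``, ``gc_content`` and ``n_annotations`` cover
    every call with a sequence.
    """
    calls = [c for c in genecalls if c.sequence]
    if not calls:
        raise ParseError("genome_summary: no call carries a nucleotide sequence")
    genome_ids = {c.genome_id for c in genecalls}
    if len(genome_ids) != 1:
        raise ParseError(f"genome_summary expects one genome, got {sorted(genome_ids)}")
    coding = "".join(c.sequence for c in calls)
    gc = 100.0 * sum(1 for b in coding if b in "GCgc") / len(coding)
    kept = [c for c in genecalls if not is_excluded(c.function, exclusions)]
    uniq = {c.function for c in kept}
    n_mobile = sum(1 for c in genecalls if _norm_function(c.function) == "mobile element protein")
    return GenomeStats(
        genome_id=next(iter(genome_ids)),
        coding_size=len(coding),
        n_annotations=len(genecalls),
        n_unique_annotations=len(uniq),
        mean_copy_number=(len(kept) / len(uniq)) if uniq else 0.0,
        n_mobile_elements=n_mobile,
        gc_content=gc,
    )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
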