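"""Core-gene panel definition: occupancy and normalized-size filters.

Candidate core genes are annotations present in exactly one copy in at least
90% of genomes.  Because draft assemblies fragment genes across scaffolds
(inflating apparent copy number) and truncate them, raw copy counts cannot
distinguish real duplications from assembly artefacts.  The filters therefore
work on *normalized size*: each copy's nucleotide length divided by the mean
length of that gene among complete (well-assembled) genomes.

Per gene and genome:

* >= 2 copies each with normalized size > 0.75 mark a true duplication and
  remove the gene from the panel entirely;
* copies with normalized size < 0.7 are fragments and are discarded;
* a surviving single copy with normalized size > 1.3 is scored missing
  (suspect call), as is a genome with no surviving copy;
* two surviving copies both in (0.7, 0.75] are ambiguous and scored missing
  (conservative).

Genes scored missing in at least ``max_missing_genomes`` genomes are dropped;
what remains is the final core-gene panel with one full-length sequence per
(genome, gene) where present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneCall
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class CoreGenePanel:
    """The filtered single-copy core gene set.

    ``presence`` is a boolean genome x gene frame; ``sequences`` maps
    (genome_id, gene) -> the retained full-length nucleotide sequence.
    ``provenance`` records per-gene filter decisions ('kept',
    'true_duplicate', 'too_missing', 'unsizeable').
    """

    gene_ids: list[str]
    expected_size: dict[str, float]
    presence: pd.DataFrame
    sequences: dict[tuple[str, str], str]
    provenance: dict[str, str] = field(default_factory=dict)

    def missing_counts(self) -> pd.Series:
        return (~self.presence[self.gene_ids]).sum(axis=0)


def select_candidates(matrix: pd.DataFrame, occupancy_threshold: float = 0.90) -> list[str]:
    """Genes present in exactly one copy in at least ``occupancy_threshold``
    of genomes (column order of the matrix preserved)."""
    if not (0.0 < occupancy_threshold <= 1.0):
        raise ConfigError(f"occupancy_threshold must be in (0, 1], got {occupancy_threshold}")
    if matrix.empty:
        raise ConfigError("annotation matrix is empty")
    frac_single = (matrix == 1).mean(axis=0)
    return [g for g in matrix.columns if frac_single[g] >= occupancy_threshold]


def expected_gene_sizes(
    genecalls: Iterable[GeneCall],
    complete_genome_ids: Sequence[str],
    candidates: Sequence[str] | None = None,
) -> dict[str, float]:
    """Mean nucleotide length per gene over its single-copy occurrences in
    complete genomes.  Genes absent (or never single-copy) in every complete
    genome are flagged unsizeable and omitted, with a warning."""
    complete = set(complete_genome_ids)
    per_gene: dict[str, dict[str, list[int]]] = {}
    for c in genecalls:
        if c.genome_id not in complete or not c.sequence:
            continue
        if candidates is not None and c.function not in set(candidates):
            continue
        per_gene.setdefault(c.function, {}).setdefault(c.genome_id, []).append(c.length)
    sizes: dict[str, float] = {}
    universe = list(candidates) if candidates is not None else list(per_gene)
    for gene in universe:
        lengths = [ls[0] for ls in per_gene.get(gene, {}).values() if len(ls) == 1]
        if lengths:
            sizes[gene] = sum(lengths) / len(lengths)
        else:
            logger.warning("gene %r is unsizeable: no single-copy occurrence in complete genomes", gene)
    return sizes


def apply_size_filters(
    candidates: Sequence[str],
    genecalls: Iterable[GeneCall],
    expected_sizes: Mapping[str, float],
    dup_threshold: float = 0.75,
    upper: float = 1.3,
    lower: float = 0.7,
    max_missing_genomes: int = 4,
    genome_ids: Sequence[str] | None = None,
) -> CoreGenePanel:
    """Apply the duplicate / fragment / oversize filters and the missing-data
    cutoff; see the module docstring for the rules."""
    if not (0.0 < lower < dup_threshold < upper):
        raise ConfigError(
            f"size thresholds must satisfy 0 < lower < dup_threshold < upper, "
            f"got lower={lower}, dup_threshold={dup_threshold}, upper={upper}"
        )
    genecalls = list(genecalls)
    if genome_ids is None:
        genome_ids = sorted({c.genome_id for c in genecalls})
    genome_ids = list(genome_ids)
    cand = [g for g in candidates if g in expected_sizes]
    provenance: dict[str, str] = {}
    for g in candidates:
        if g not in expected_sizes:
            provenance[g] = "unsizeable"

    copies: dict[str, dict[str, list[str]]] = {g: {} for g in cand}
    for c in genecalls:
        if c.function in copies and c.sequence:
            copies[c.function].setdefault(c.genome_id, []).append(c.sequence)

    kept_genes: list[str] = []
    presence = pd.DataFrame(False, index=genome_ids, columns=cand)
    sequences: dict[tuple[str, str], str] = {}
    for gene in cand:
        exp = expected_sizes[gene]
        dup = False
        for gid, seqs in copies[gene].items():
            big = [s for s in seqs if len(s) / exp > dup_threshold]
            if len(big) >= 2:
                dup = True
                break
        if dup:
            provenance[gene] = "true_duplicate"
            continue
        for gid in genome_ids:
            surviving = [s for s in copies[gene].get(gid, []) if len(s) / exp >= lower]
            if len(surviving) == 1 and len(surviving[0]) / exp <= upper:
                presence.loc[gid, gene] = True
                sequences[(gid, gene)] = surviving[0]
            elif len(surviving) > 1:
                logger.debug("gene %r genome %s: ambiguous multi-copy in (%.2f, %.2f]; scored missing", gene, gid, lower, dup_threshold)
        kept_genes.append(gene)

    final: list[str] = []
    for gene in kept_genes:
        n_missing = int((~presence[gene]).sum())
        if n_missing >= max_missing_genomes:
            provenance[gene] = "too_missing"
        else:
            provenance[gene] = "kept"
            final.append(gene)
    presence = presence[final]
    sequences = {k: v for k, v in sequences.items() if k[1] in set(final)}
    return CoreGenePanel(
        gene_ids=final,
        expected_size={g: expected_sizes[g] for g in final},
        presence=presence,
        sequences=sequences,
        provenance=provenance,
    )


def panel_report(panel: CoreGenePanel) -> pd.DataFrame:
    """Per-gene report: expected size, decision, number of missing genomes."""
    rows = []
    missing = panel.missing_counts()
    for g in panel.gene_ids:
        rows.append(
            {
                "gene": g,
                "expected_size": panel.expected_size[g],
                "decision": panel.provenance.get(g, "kept"),
                "n_missing": int(missing[g]),
            }
        )
    for g, decision in panel.provenance.items():
        if decision != "kept":
            rows.append({"gene": g, "expected_size": float("nan"), "decision": decision, "n_missing": -1})
    return pd.DataFrame(rows, columns=["gene", "expected_size", "decision", "n_missing"])
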