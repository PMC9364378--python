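"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: simulate (or load) -> annotation matrix ->
core panel -> alignments/supermatrix -> PNS/species -> gene content and
synteny -> tree building and concordance.  Every output file is recorded in
a manifest with its stage, parameters, and SHA-256 checksum; a single top
seed fans out to per-stage seeds by stable hashing so toggling one stage
never perturbs another's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import alignment as aln_mod
from . import annotation as ann_mod
from . import corepanel as core_mod
from . import genecontent as gc_mod
from . import simulate as sim_mod
from . import species as sp_mod
from . import synteny as syn_mod
from . import trees as tree_mod
from .errors import ConfigError, PipelineError

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis with their standard defaults."""

    output_dir: str = "corephylo_out"
    seed: int = 0
    simulate: dict | None = None  # SimConfig fields; None -> load from input_dir
    input_dir: str | None = None
    occupancy_threshold: float = 0.90
    dup_threshold: float = 0.75
    size_lower: float = 0.7
    size_upper: float = 1.3
    max_missing_genomes: int = 4
    trim_max_missing: float = 0.90
    pns_threshold: float = 97.0
    collapse_support: float = 10.0
    consensus_majority: float = 0.50
    venn_species_per_group: int = 15
    replicates: int = 100
    rarefaction_n_max: int = 15
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "annotate", "core", "align", "species", "content", "synteny", "trees"]
    )

    def validate(self) -> None:
        if not (0.0 < self.occupancy_threshold <= 1.0):
            raise ConfigError(f"occupancy_threshold must be in (0, 1], got {self.occupancy_threshold}")
        if not (0.0 < self.size_lower < self.dup_threshold < self.size_upper):
            raise ConfigError("size thresholds must satisfy 0 < lower < dup < upper")
        if not (0.0 <= self.pns_threshold <= 100.0):
            raise ConfigError(f"pns_threshold must be in [0, 100], got {self.pns_threshold}")
        if not (0.0 <= self.trim_max_missing <= 1.0):
            raise ConfigError(f"trim_max_missing must be in [0, 1], got {self.trim_max_missing}")
        if not (0.0 <= self.consensus_majority < 1.0):
            raise ConfigError(f"consensus_majority must be in [0, 1), got {self.consensus_majority}")
        if self.max_missing_genomes < 1:
            raise ConfigError(f"max_missing_genomes must be >= 1, got {self.max_missing_genomes}")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if self.simulate is None and self.input_dir is None:
            raise ConfigError("either a simulate block or input_dir is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class Manifest:
    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, path: Path, **params) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries.append({"stage": stage, "path": str(path), "sha256": digest, "params": params})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.entries, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Run all configured stages; returns the output manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()
    st = set(config.stages)

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: simulate / load -------------------------------------------
    truth = None
    try:
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
            sim_cfg = sim_mod.SimConfig(**sim_kwargs)
            genomes, genecalls, truth = sim_mod.simulate_dataset(sim_cfg)
            if "simulate" in st:
                data_dir = out / "data"
                for p in sim_mod.write_dataset(genomes, genecalls, truth, data_dir):
                    manifest.add("simulate", p, seed=sim_cfg.seed)
            meta = pd.DataFrame(
                [
                    {
                        "genome_id": gid,
                        "group": rec.metadata.get("group", ""),
                        "species": rec.metadata.get("species", ""),
                        "is_draft": rec.is_draft,
                        "n50": rec.n50,
                        "n_scaffolds": len(rec.scaffolds),
                        "type_strain_name": truth.type_strains.get(gid, ""),
                    }
                    for gid, rec in genomes.items()
                ]
            ).set_index("genome_id")
        else:
            data_dir = Path(config.input_dir)
            meta = pd.read_csv(data_dir / "metadata.tsv", sep="\t", dtype={"genome_id": str}).set_index("genome_id")
            genecalls = []
            for gid in meta.index:
                genecalls.extend(ann_mod.read_rast_table(data_dir / f"{gid}.tsv", genome_id=gid))
            genomes = {}
    except PipelineError:
        raise
    except Exception as exc:
        fail("simulate", exc)

    genome_ids = list(meta.index)
    complete_ids = [g for g in genome_ids if not bool(meta.loc[g, "is_draft"])]
    group_of_genome = {g: meta.loc[g, "group"] for g in genome_ids}

    # ---- stage: annotate ---------------------------------------------------
    try:
        matrix = ann_mod.build_annotation_matrix(genecalls)
        stats = []
        by_genome: dict[str, list] = {}
        for c in genecalls:
            by_genome.setdefault(c.genome_id, []).append(c)
        for gid in genome_ids:
            s = ann_mod.genome_summary(by_genome[gid])
            stats.append(vars(s))
        if "annotate" in st:
            p = out / "annotation_matrix.tsv"
            matrix.to_csv(p, sep="\t")
            manifest.add("annotate", p, exclusions=list(ann_mod.DEFAULT_EXCLUSIONS))
            p = out / "genome_stats.tsv"
            pd.DataFrame(stats).to_csv(p, sep="\t", index=False)
            manifest.add("annotate", p)
    except PipelineError:
        raise
    except Exception as exc:
        fail("annotate", exc)

    # ---- stage: core panel -------------------------------------------------
    try:
        candidates = core_mod.select_candidates(matrix, config.occupancy_threshold)
        sizes = core_mod.expected_gene_sizes(genecalls, complete_ids, candidates)
        panel = core_mod.apply_size_filters(
            candidates,
            genecalls,
            sizes,
            dup_threshold=config.dup_threshold,
            upper=config.size_upper,
            lower=config.size_lower,
            max_missing_genomes=config.max_missing_genomes,
            genome_ids=genome_ids,
        )
        logger.info(
            "core panel: %d candidates -> %d genes (%d true duplicates, %d too missing)",
            len(candidates),
            len(panel.gene_ids),
            sum(1 for v in panel.provenance.values() if v == "true_duplicate"),
            sum(1 for v in panel.provenance.values() if v == "too_missing"),
        )
        if "core" in st:
            p = out / "core_panel.tsv"
            core_mod.panel_report(panel).to_csv(p, sep="\t", index=False)
            manifest.add(
                "core",
                p,
                occupancy=config.occupancy_threshold,
                dup=config.dup_threshold,
                lower=config.size_lower,
                upper=config.size_upper,
                max_missing=config.max_missing_genomes,
            )
    except PipelineError:
        raise
    except Exception as exc:
        fail("core", exc)

    # ---- stage: align ------------------------------------------------------
    try:
        aligner = aln_mod.CenterStarAligner()
        gene_alignments = []
        for gene in panel.gene_ids:
            seqs = {gid: panel.sequences[(gid, gene)] for gid in genome_ids if (gid, gene) in panel.sequences}
            ga = aln_mod.align_gene(seqs, gene_id=gene, aligner=aligner)
            ga = aln_mod.trim_alignment_ends(ga, config.trim_max_missing)
            gene_alignments.append(ga)
        supermatrix = aln_mod.concatenate(gene_alignments, genome_ids)
        if "align" in st:
            p = out / "supermatrix.fasta"
            aln_mod.write_supermatrix_fasta(supermatrix, p)
            manifest.add("align", p, trim=config.trim_max_missing)
            p = out / "partitions.txt"
            aln_mod.write_partition_file(supermatrix, p)
            manifest.add("align", p)
    except PipelineError:
        raise
    except Exception as exc:
        fail("align", exc)

    # ---- stage: species ----------------------------------------------------
    try:
        pns, _counts = sp_mod.pns_matrix(supermatrix)
        assignment = sp_mod.delimit_species(pns, config.pns_threshold)
        type_strains = {}
        if "type_strain_name" in meta.columns:
            type_strains = {g: n for g, n in meta["type_strain_name"].items() if isinstance(n, str) and n}
        assignment = sp_mod.label_species(assignment, type_strains, group_of_genome)
        group_of_species = {sid: info.group for sid, info in assignment.species.items()}
        if "species" in st:
            p = out / "pns_matrix.tsv"
            pns.to_csv(p, sep="\t")
            manifest.add("species", p)
            p = out / "species_table.tsv"
            assignment.to_frame().to_csv(p, sep="\t", index=False)
            manifest.add("species", p, threshold=config.pns_threshold)
    except PipelineError:
        raise
    except Exception as exc:
        fail("species", exc)

    # ---- stage: gene content ----------------------------------------------
    try:
        if "content" in st:
            profile = gc_mod.species_occurrence_profile(matrix, assignment)
            p = out / "species_occurrence.tsv"
            profile.to_csv(p, sep="\t")
            manifest.add("content", p)
            bc = gc_mod.bray_curtis_matrix(matrix)
            p = out / "bray_curtis.tsv"
            bc.to_csv(p, sep="\t")
            manifest.add("content", p, hellinger=True)
            rar = gc_mod.rarefy_pan_core(
                matrix,
                assignment,
                group_of_species,
                n_max=config.rarefaction_n_max,
                replicates=config.replicates,
                seed=stage_seed(config.seed, "content"),
            )
            p = out / "rarefaction.tsv"
            rar.table.to_csv(p, sep="\t", index=False)
            manifest.add("content", p, replicates=config.replicates)
            if len(set(group_of_species.values())) >= 2:
                venn = gc_mod.venn_overlap(
                    matrix,
                    assignment,
                    group_of_species,
                    species_per_group=config.venn_species_per_group,
                    replicates=config.replicates,
                    seed=stage_seed(config.seed, "venn"),
                )
                p = out / "venn_regions.tsv"
                venn.to_csv(p, sep="\t", index=False)
                manifest.add("content", p, species_per_group=config.venn_species_per_group)
            p = out / "gene_presence.fasta"
            gc_mod.export_binary_matrix(matrix, p)
            manifest.add("content", p)
            manifest.add("content", p.with_suffix(p.suffix + ".columns.tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        fail("content", exc)

    # ---- stage: synteny ----------------------------------------------------
    try:
        core_set = set(panel.gene_ids)
        scaffold_orders: dict[str, dict[str, list[str]]] = {}
        for gid in genome_ids:
            per_scaffold: dict[str, list] = {}
            for c in by_genome[gid]:
                if c.function in core_set and panel.presence.loc[gid, c.function]:
                    per_scaffold.setdefault(c.scaffold_id, []).append(c)
            ordered = {}
            for sid, calls in per_scaffold.items():
                calls = sorted(calls, key=lambda c: c.start)
                seen = set()
                genes = []
                for c in calls:
                    if c.function not in seen and panel.sequences.get((gid, c.function)) == c.sequence:
                        genes.append(c.function)
                        seen.add(c.function)
                if genes:
                    ordered[sid] = genes
            scaffold_orders[gid] = ordered
        reference_orders = {}
        for gid in complete_ids:
            scs = scaffold_orders[gid]
            if len(scs) == 1:
                reference_orders[gid] = next(iter(scs.values()))
        draft_inputs = []
        for gid in genome_ids:
            if gid in reference_orders:
                continue
            rec_n50 = int(meta.loc[gid, "n50"]) if "n50" in meta.columns else 0
            n_sc = int(meta.loc[gid, "n_scaffolds"]) if "n_scaffolds" in meta.columns else len(scaffold_orders[gid])
            draft_inputs.append((gid, scaffold_orders[gid], rec_n50, n_sc))
        configs = syn_mod.reorder_all(draft_inputs, reference_orders) if draft_inputs else {}
        orders = dict(reference_orders)
        orders.update({gid: cfg.gene_order for gid, cfg in configs.items()})
        linksets = [syn_mod.extract_links([orders[gid]], circular=True, genome_id=gid) for gid in genome_ids]
        si = syn_mod.si_matrix(linksets)
        occurrence = syn_mod.link_occurrence_matrix(linksets)
        sp_presence = syn_mod.species_link_presence(occurrence, assignment.genome_to_species)
        consensus = syn_mod.consensus_network(sp_presence, group_of_species, config.consensus_majority)
        ref_genome = syn_mod.choose_reference_genome(si)
        profile_links = syn_mod.conserved_link_profile(ref_genome, orders[ref_genome], sp_presence, group_of_species)
        if "synteny" in st:
            p = out / "si_matrix.tsv"
            si.to_csv(p, sep="\t")
            manifest.add("synteny", p)
            p = out / "si_summary.tsv"
            syn_mod.grouped_si_summary(si, assignment.genome_to_species, group_of_species).to_csv(p, sep="\t", index=False)
            manifest.add("synteny", p)
            p = out / "link_occurrence.fasta"
            gc_mod.export_binary_matrix(occurrence, p)
            manifest.add("synteny", p)
            manifest.add("synteny", p.with_suffix(p.suffix + ".columns.tsv"))
            p = out / "consensus_network.tsv"
            consensus.to_csv(p, sep="\t", index=False)
            manifest.add("synteny", p, majority=config.consensus_majority)
            p = out / "conserved_link_profile.tsv"
            profile_links.to_csv(p, sep="\t", index=False)
            manifest.add("synteny", p, reference=ref_genome)
            p = out / "configurations.tsv"
            pd.DataFrame(
                [
                    {
                        "genome_id": gid,
                        "best_reference": cfg.best_reference,
                        "si_vs_reference": cfg.si,
                        "n_scaffolds_used": len(cfg.scaffold_order),
                        "scaffold_order": ";".join(f"{s}{'+' if o == 'forward' else '-'}" for s, o in cfg.scaffold_order),
                    }
                    for gid, cfg in configs.items()
                ]
            ).to_csv(p, sep="\t", index=False)
            manifest.add("synteny", p)
    except PipelineError:
        raise
    except Exception as exc:
        fail("synteny", exc)

    # ---- stage: trees ------------------------------------------------------
    try:
        if "trees" in st:
            dist_pns = (100.0 - pns) / 100.0
            lineage = tree_mod.nj_tree(dist_pns)
            bc_m = gc_mod.bray_curtis_matrix(matrix)
            content_tree = tree_mod.nj_tree(bc_m)
            synteny_tree = tree_mod.nj_tree(1.0 - si)
            trees = {"lineage_nj": lineage, "gene_content_nj": content_tree, "synteny_nj": synteny_tree}
            for name, t in trees.items():
                p = out / f"{name}.nwk"
                p.write_text(tree_mod.write_tree(t) + "\n")
                manifest.add("trees", p)
            rows = []
            for (na, ta), (nb, tb) in [
                (("lineage_nj", lineage), ("gene_content_nj", content_tree)),
                (("lineage_nj", lineage), ("synteny_nj", synteny_tree)),
                (("gene_content_nj", content_tree), ("synteny_nj", synteny_tree)),
            ]:
                r = tree_mod.rf_distance(ta, tb)
                rows.append({"tree_a": na, "tree_b": nb, "raw_rf": r.raw, "normalized_rf": r.normalized})
            p = out / "rf_distances.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            manifest.add("trees", p)
    except PipelineError:
        raise
    except Exception as exc:
        fail("trees", exc)

    mpath = out / "manifest.json"
    manifest.write(mpath)
    return manifest
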