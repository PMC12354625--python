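"""End-to-end orchestration: simulate -> preprocess -> assign -> dietstats.

Every run is fully determined by (inputs, config, seed). A machine-readable
run manifest records parameter values, the seed, and per-stage record counts
so that records in = records out + records removed can be audited per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import dietstats as ds
from . import preprocess as pp
from . import taxassign as ta
from .errors import ConfigError
from .synthetic import (
    ReferenceDatabase,
    SimConfig,
    generate_reference_db,
    iter_sample_reads,
)
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for a full run; parameters default to the published
    values (minimum cluster size 3, bit-score window 2%, coverage 90%,
    identity 98%, agreement 80%, noise threshold 0.1%, minimum reads 100)."""

    # simulation (used when simulate=True)
    simulate: bool = True
    n_species: int = 26
    sim: SimConfig = field(default_factory=SimConfig)
    # inputs (used when simulate=False)
    reads_dir: Optional[str] = None
    reference_fasta: Optional[str] = None
    lineage_table: Optional[str] = None
    manifest_path: Optional[str] = None
    hits_dir: Optional[str] = None  # start from precomputed hit tables
    # stage parameters
    min_cluster_size: int = 3
    denoise: pp.DenoiseParams = field(default_factory=pp.DenoiseParams)
    chimera: pp.ChimeraParams = field(default_factory=pp.ChimeraParams)
    assignment: ta.AssignmentParams = field(default_factory=ta.AssignmentParams)
    filters: ds.FilterParams = field(default_factory=ds.FilterParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config key: {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            else:
                setattr(cfg, key, value)
        cfg.sim.seed = cfg.seed
        return cfg

    def snapshot(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class PipelineResult:
    clusters: list[pp.SeqCluster]
    assignments: pd.DataFrame
    profiles: list[ds.SampleProfile]
    summary: ds.DietSummary
    stage_counts: dict
    truth: Optional[pd.DataFrame] = None


def write_centroids(clusters, path) -> None:
    """Centroid FASTA with ';size=N' abundance annotations."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f">{c.cluster_id};size={c.size}\n{c.centroid}\n")


def read_sample_fastas(reads_dir) -> dict[str, list[str]]:
    reads = {}
    for path in sorted(Path(reads_dir).glob("*.fasta")):
        reads[path.stem] = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return reads


def preprocess_reads(
    reads_by_sample, config: PipelineConfig, stage_counts: dict
) -> list[pp.SeqCluster]:
    clusters = pp.dereplicate(reads_by_sample)
    stage_counts["dereplicate_clusters"] = len(clusters)
    stage_counts["dereplicate_reads"] = sum(c.size for c in clusters)
    clusters = pp.filter_small_clusters(clusters, config.min_cluster_size)
    stage_counts["after_min_size"] = len(clusters)
    clusters = pp.denoise(clusters, config.denoise)
    stage_counts["after_denoise"] = len(clusters)
    clusters = pp.remove_chimeras(clusters, config.chimera)
    stage_counts["after_chimera"] = len(clusters)
    return clusters


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute all stages in canonical order; optionally write the result
    bundle (CSV outputs, centroid FASTA, run manifest, resolved config)."""
    stage_counts: dict = {}
    truth = None

    if config.simulate:
        db = generate_reference_db(config.n_species, config.sim.seed)
        taxonomy = db.taxonomy()
        truth_rows: list[dict] = []
        manifest_rows: list[dict] = []

        def stream():
            for sample_id, reads, t_rows, m_row in iter_sample_reads(db, config.sim):
                truth_rows.extend(t_rows)
                manifest_rows.append(m_row)
                yield sample_id, reads

        clusters = preprocess_reads(stream(), config, stage_counts)
        truth = pd.DataFrame(
            truth_rows,
            columns=["sample_id", "true_host", "field_label", "taxon_id", "kind", "reads"],
        )
        manifest = pd.DataFrame(
            manifest_rows, columns=["sample_id", "field_label", "season", "habitat"]
        )
        # manifests carry taxon_ids; diet tables use species labels
        manifest = manifest.assign(
            field_label=[taxonomy.species_label(t) for t in manifest["field_label"]]
        )
    else:
        if not (config.reference_fasta and config.lineage_table and config.manifest_path):
            raise ConfigError("non-simulated runs need reference_fasta, lineage_table and manifest_path")
        db = ReferenceDatabase.read(config.reference_fasta, config.lineage_table)
        taxonomy = db.taxonomy()
        manifest = pd.read_csv(config.manifest_path, sep="\t", dtype=str)
        if config.reads_dir:
            reads = read_sample_fastas(config.reads_dir)
            clusters = preprocess_reads(reads, config, stage_counts)
        elif config.hits_dir:
            clusters = []
        else:
            raise ConfigError("provide reads_dir or hits_dir")

    if config.hits_dir and not config.simulate:
        hits = []
        query_counts: dict[str, dict[str, int]] = {}
        for path in sorted(Path(config.hits_dir).glob("*.tsv")):
            hits.extend(ta.parse_hits(path, taxonomy))
        qfile = Path(config.hits_dir) / "queries.csv"
        if not qfile.exists():
            raise ConfigError("hits_dir must contain queries.csv (query_id,sample_id,reads)")
        queries = pd.read_csv(qfile)
        for row in queries.itertuples(index=False):
            query_counts.setdefault(row.query_id, {})[row.sample_id] = int(row.reads)
        assignments_map = ta.assign_queries(hits, query_counts, config.assignment)
        assign_df = ta.assign_counts(assignments_map, query_counts)
    else:
        hits = ta.align_clusters(clusters, db)
        assignments_map = ta.assign_queries(
            hits, [c.cluster_id for c in clusters], config.assignment
        )
        assign_df = ta.assign_counts(assignments_map, clusters)
    stage_counts["assigned_queries"] = sum(1 for v in assignments_map.values() if v is not None)
    stage_counts["unassigned_queries"] = sum(1 for v in assignments_map.values() if v is None)

    params = config.filters
    profiles, profile_counts = ds.build_profiles(assign_df, manifest, params, taxonomy)
    stage_counts.update(profile_counts)
    summary = ds.summarize(profiles, taxonomy)

    result = PipelineResult(
        clusters=clusters,
        assignments=assign_df,
        profiles=profiles,
        summary=summary,
        stage_counts=stage_counts,
        truth=truth,
    )
    if outdir is not None:
        _write_bundle(result, config, db, manifest, Path(outdir))
    return result


def _write_bundle(result, config, db, manifest, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_centroids(result.clusters, outdir / "centroids.fasta")
    cluster_rows = [
        dict(cluster_id=c.cluster_id, sample_id=s, reads=n)
        for c in result.clusters
        for s, n in sorted(c.sample_counts.items())
    ]
    pd.DataFrame(cluster_rows, columns=["cluster_id", "sample_id", "reads"]).to_csv(
        outdir / "cluster_counts.csv", index=False
    )
    result.assignments.to_csv(outdir / "assignments.csv", index=False)
    s = result.summary
    s.foo_taxa.rename_axis("taxon").to_csv(outdir / "foo.csv")
    s.foo_groups.rename_axis("group").to_csv(outdir / "foo_groups.csv")
    s.rra_taxa.rename_axis("taxon").to_csv(outdir / "rra.csv")
    s.confusion_matrix.to_csv(outdir / "confusion.csv")
    s.richness_per_sample.rename_axis("sample_id").to_csv(outdir / "richness.csv")
    s.habitat_ratio.rename_axis("group").to_csv(outdir / "habitat_ratio.csv")
    manifest.to_csv(outdir / "manifest_resolved.tsv", sep="\t", index=False)
    if result.truth is not None:
        result.truth.to_csv(outdir / "truth.csv", index=False)
    db.write(outdir / "reference.fasta", outdir / "lineage_table.tsv")
    run_manifest = dict(
        seed=config.seed,
        config=config.snapshot(),
        stage_counts=result.stage_counts,
        misid_pct={k: float(v) for k, v in s.misid_pct.items()},
    )
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
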