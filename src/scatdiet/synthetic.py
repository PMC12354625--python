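"""Synthetic scat-metabarcoding data with known ground truth.

Real scat surveys of this kind yield, per scat sample, a pool of short 12S
amplicon reads dominated by the depositing predator (the host), mixed with
highly skewed read counts from prey taxa, human contamination, positive
control spikes, sequencing substitution errors and PCR bimeras. No public
read archive exists for the study system this package models, so this module
is the test substrate for the whole pipeline: it emits a reference database,
per-sample reads, a sample manifest with (possibly wrong) field labels, and
a ground-truth table recording every count it drew.

All randomness flows from a single integer seed; each sample uses a
deterministic substream so outputs are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError
from .taxonomy import RANKS, Lineage, Taxonomy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: Sentinel taxon id used in truth tables for bimeric (chimeric) reads.
CHIMERA_ID = "(chimera)"

# Curated core of UK vertebrates (plus contamination/control taxa) giving the
# lineage tree realistic structure: congeneric pairs for nontrivial MLCA votes,
# rodents + shrews for the small-mammal group, passerines, ducks for the
# ambiguous roll-up, and a wader (woodcock). Habitat classes drive the
# woodland:open diet ratio. Fields: taxon_id, class, order, family, genus,
# species, habitat. Domain/phylum are constant (Eukaryota/Chordata).
_CORE_SPECIES: tuple[tuple[str, str, str, str, str, str, str], ...] = (
    ("Vulpes_vulpes", "Mammalia", "Carnivora", "Canidae", "Vulpes", "Vulpes vulpes", "none"),
    ("Martes_martes", "Mammalia", "Carnivora", "Mustelidae", "Martes", "Martes martes", "none"),
    ("Homo_sapiens", "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens", "none"),
    ("Maylandia_zebra", "Actinopteri", "Cichliformes", "Cichlidae", "Maylandia", "Maylandia zebra", "none"),
    ("Microtus_agrestis", "Mammalia", "Rodentia", "Cricetidae", "Microtus", "Microtus agrestis", "open"),
    ("Apodemus_sylvaticus", "Mammalia", "Rodentia", "Muridae", "Apodemus", "Apodemus sylvaticus", "woodland"),
    ("Apodemus_flavicollis", "Mammalia", "Rodentia", "Muridae", "Apodemus", "Apodemus flavicollis", "woodland"),
    ("Sorex_araneus", "Mammalia", "Eulipotyphla", "Soricidae", "Sorex", "Sorex araneus", "open"),
    ("Sorex_minutus", "Mammalia", "Eulipotyphla", "Soricidae", "Sorex", "Sorex minutus", "open"),
    ("Rana_temporaria", "Amphibia", "Anura", "Ranidae", "Rana", "Rana temporaria", "aquatic"),
    ("Cervus_elaphus", "Mammalia", "Artiodactyla", "Cervidae", "Cervus", "Cervus elaphus", "open"),
    ("Oryctolagus_cuniculus", "Mammalia", "Lagomorpha", "Leporidae", "Oryctolagus", "Oryctolagus cuniculus", "open"),
    ("Zootoca_vivipara", "Reptilia", "Squamata", "Lacertidae", "Zootoca", "Zootoca vivipara", "open"),
    ("Scolopax_rusticola", "Aves", "Charadriiformes", "Scolopacidae", "Scolopax", "Scolopax rusticola", "woodland"),
    ("Phasianus_colchicus", "Aves", "Galliformes", "Phasianidae", "Phasianus", "Phasianus colchicus", "woodland"),
    ("Lagopus_lagopus", "Aves", "Galliformes", "Phasianidae", "Lagopus", "Lagopus lagopus", "open"),
    ("Fringilla_coelebs", "Aves", "Passeriformes", "Fringillidae", "Fringilla", "Fringilla coelebs", "woodland"),
    ("Carduelis_carduelis", "Aves", "Passeriformes", "Fringillidae", "Carduelis", "Carduelis carduelis", "woodland"),
    ("Emberiza_citrinella", "Aves", "Passeriformes", "Emberizidae", "Emberiza", "Emberiza citrinella", "open"),
    ("Erithacus_rubecula", "Aves", "Passeriformes", "Muscicapidae", "Erithacus", "Erithacus rubecula", "woodland"),
    ("Anthus_pratensis", "Aves", "Passeriformes", "Motacillidae", "Anthus", "Anthus pratensis", "open"),
    ("Turdus_philomelos", "Aves", "Passeriformes", "Turdidae", "Turdus", "Turdus philomelos", "woodland"),
    ("Anas_platyrhynchos", "Aves", "Anseriformes", "Anatidae", "Anas", "Anas platyrhynchos", "aquatic"),
    ("Anas_crecca", "Aves", "Anseriformes", "Anatidae", "Anas", "Anas crecca", "aquatic"),
    ("Columba_palumbus", "Aves", "Columbiformes", "Columbidae", "Columba", "Columba palumbus", "woodland"),
    ("Canis_familiaris", "Mammalia", "Carnivora", "Canidae", "Canis", "Canis lupus familiaris", "none"),
)


@dataclass(frozen=True)
class RefTaxon:
    """One reference-database entry: species-level lineage plus its amplicon."""

    taxon_id: str
    lineage: Lineage
    sequence: str
    habitat_class: str


class ReferenceDatabase:
    """An ordered set of RefTaxon records with FASTA + lineage-table I/O."""

    def __init__(self, taxa: Sequence[RefTaxon]):
        self.taxa: dict[str, RefTaxon] = {}
        for t in taxa:
            if t.taxon_id in self.taxa:
                raise ConfigError(f"duplicate taxon_id: {t.taxon_id}")
            self.taxa[t.taxon_id] = t

    def __len__(self) -> int:
        return len(self.taxa)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.taxa

    def __getitem__(self, taxon_id: str) -> RefTaxon:
        return self.taxa[taxon_id]

    @property
    def ids(self) -> list[str]:
        return list(self.taxa)

    def sequence(self, taxon_id: str) -> str:
        return self.taxa[taxon_id].sequence

    def taxonomy(self) -> Taxonomy:
        rows = {
            tid: dict(zip(RANKS, t.lineage.names), habitat_class=t.habitat_class)
            for tid, t in self.taxa.items()
        }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "taxon_id"
        return Taxonomy(frame)

    def write(self, fasta_path, lineage_path) -> None:
        records = [
            SeqRecord(Seq(t.sequence), id=t.taxon_id, description="")
            for t in self.taxa.values()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        self.taxonomy().to_tsv(lineage_path)

    @classmethod
    def read(cls, fasta_path, lineage_path) -> "ReferenceDatabase":
        tax = Taxonomy.from_tsv(lineage_path)
        taxa = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            taxa.append(
                RefTaxon(rec.id, tax.lineage(rec.id), str(rec.seq), tax.habitat(rec.id))
            )
        return cls(taxa)


def generate_reference_db(
    n_species: int,
    seed: int,
    *,
    seq_length: int = 97,
    identity_threshold: float = 98.0,
    identity_margin: float = 2.0,
) -> ReferenceDatabase:
    """Generate a reference database of ``n_species`` distinct amplicons.

    Lineages come from a curated core of UK vertebrates (several genera hold
    multiple species, so consensus votes downstream are nontrivial); beyond
    the core, extra congeners are synthesized into existing genera. Pairwise
    sequence identity between species is forced below
    ``identity_threshold - identity_margin`` percent so that no reference
    sequence can be mistaken for another at the species-assignment threshold.
    """
    if n_species < 2:
        raise ConfigError(f"n_species must be >= 2, got {n_species}")
    rows: list[tuple[str, str, str, str, str, str, str]] = list(
        _CORE_SPECIES[: min(n_species, len(_CORE_SPECIES))]
    )
    extra = n_species - len(rows)
    if extra > 0:
        # cycle through core genera, minting new congeners
        base = [r for r in _CORE_SPECIES if r[1] != "Actinopteri"]
        for k in range(extra):
            src = base[k % len(base)]
            genus = src[4]
            epithet = f"{genus.lower()}ensis{k + 1}"
            rows.append(
                (f"{genus}_{epithet}", src[1], src[2], src[3], genus,
                 f"{genus} {epithet}", src[6])
            )

    min_dist = max(1, math.ceil(seq_length * (1.0 - (identity_threshold - identity_margin) / 100.0)))
    rng = np.random.default_rng(seed)
    seqs = np.empty((len(rows), seq_length), dtype=np.uint8)
    for i in range(len(rows)):
        while True:
            cand = rng.integers(0, 4, size=seq_length).astype(np.uint8)
            if i == 0 or (seqs[:i] != cand).sum(axis=1).min() >= min_dist:
                seqs[i] = cand
                break

    taxa = []
    for i, (tid, cls_, order, fam, genus, species, habitat) in enumerate(rows):
        lineage = Lineage(("Eukaryota", "Chordata", cls_, order, fam, genus, species))
        seq = _BASES[seqs[i]].tobytes().decode("ascii")
        taxa.append(RefTaxon(tid, lineage, seq, habitat))
    return ReferenceDatabase(taxa)


@dataclass(frozen=True)
class PreyItem:
    """Per-taxon diet parameters for one host: probability a scat contains the
    taxon at all, and the relative read weight it takes when present."""

    inclusion_prob: float
    weight: float


def _default_prey_profiles() -> dict[str, dict[str, PreyItem]]:
    """Study-like diets: per-host inclusion probabilities follow the reported
    per-predator occurrence frequencies, weights the reported read-abundance
    structure (wood mice and birds heavy for pine marten; frogs, carrion and
    the other predator's DNA heavy for fox)."""
    pm = {
        "Microtus_agrestis": PreyItem(0.64, 0.10),
        "Apodemus_sylvaticus": PreyItem(0.50, 0.30),
        "Sorex_araneus": PreyItem(0.15, 0.04),
        "Rana_temporaria": PreyItem(0.35, 0.16),
        "Emberiza_citrinella": PreyItem(0.12, 0.20),
        "Fringilla_coelebs": PreyItem(0.15, 0.08),
        "Erithacus_rubecula": PreyItem(0.10, 0.05),
        "Turdus_philomelos": PreyItem(0.08, 0.04),
        "Cervus_elaphus": PreyItem(0.08, 0.03),
        "Vulpes_vulpes": PreyItem(0.16, 0.05),
        "Lagopus_lagopus": PreyItem(0.05, 0.02),
    }
    fox = {
        "Microtus_agrestis": PreyItem(0.21, 0.05),
        "Apodemus_sylvaticus": PreyItem(0.13, 0.04),
        "Rana_temporaria": PreyItem(0.27, 0.24),
        "Martes_martes": PreyItem(0.50, 0.23),
        "Cervus_elaphus": PreyItem(0.46, 0.21),
        "Phasianus_colchicus": PreyItem(0.06, 0.03),
        "Anas_platyrhynchos": PreyItem(0.04, 0.02),
        "Oryctolagus_cuniculus": PreyItem(0.06, 0.04),
        "Anthus_pratensis": PreyItem(0.05, 0.02),
        "Canis_familiaris": PreyItem(0.02, 0.02),
    }
    return {"Martes_martes": pm, "Vulpes_vulpes": fox}


@dataclass
class SimConfig:
    """Parameters of the scat-dataset generator.

    Depth defaults (log-normal, median 20,000 reads/sample) and the host
    read-fraction range emulate typical Illumina metabarcoding output; the
    host always dominates any single prey taxon in expectation.
    """

    n_samples: int = 50
    candidate_hosts: tuple[str, ...] = ("Vulpes_vulpes", "Martes_martes")
    host_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Vulpes_vulpes": 0.5, "Martes_martes": 0.5}
    )
    balanced_hosts: bool = False  # deterministic alternation instead of draws
    misid_rate: float = 14.0 / 48.0
    prey_profiles: Mapping[str, Mapping[str, PreyItem]] = field(
        default_factory=_default_prey_profiles
    )
    reads_per_sample_mu: float = math.log(20_000.0)
    reads_per_sample_sigma: float = 0.5
    host_fraction_range: tuple[float, float] = (0.55, 0.85)
    dirichlet_concentration: float = 50.0
    substitution_error_rate: float = 0.002
    chimera_rate: float = 0.005
    contamination_fraction: float = 0.01
    control_fraction: float = 0.005
    contaminant_taxon: str = "Homo_sapiens"
    control_taxon: str = "Maylandia_zebra"
    seed: int = 0

    def validate(self, db: Optional[ReferenceDatabase] = None) -> None:
        for name in ("misid_rate", "substitution_error_rate", "chimera_rate",
                     "contamination_fraction", "control_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.reads_per_sample_sigma < 0 or not math.isfinite(self.reads_per_sample_mu):
            raise ConfigError("reads_per_sample parameters must be positive/finite")
        if len(self.candidate_hosts) != 2:
            raise ConfigError("exactly two candidate hosts are supported")
        if abs(sum(self.host_mix.get(h, 0.0) for h in self.candidate_hosts) - 1.0) > 1e-9:
            raise ConfigError("host_mix must sum to 1 over the candidate hosts")
        for host, profile in self.prey_profiles.items():
            for taxon, item in profile.items():
                if not 0.0 <= item.inclusion_prob <= 1.0 or item.weight <= 0:
                    raise ConfigError(f"bad prey item for {host}/{taxon}")
        if db is not None:
            wanted = set(self.candidate_hosts) | {self.contaminant_taxon, self.control_taxon}
            for profile in self.prey_profiles.values():
                wanted |= set(profile)
            missing = sorted(t for t in wanted if t not in db)
            if missing:
                raise ConfigError(f"config references taxa absent from the database: {missing}")


@dataclass
class ScatDataset:
    """Generated reads plus manifest and ground truth.

    ``truth`` is long-form with columns sample_id, true_host, field_label,
    taxon_id, kind (host/prey/contamination/control/chimera) and reads; the
    per-sample sum over all kinds equals the number of reads emitted.
    """

    reads: dict[str, list[str]]
    manifest: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        reads_dir = outdir / "reads"
        reads_dir.mkdir(parents=True, exist_ok=True)
        for sample_id, seqs in self.reads.items():
            records = [
                SeqRecord(Seq(s), id=f"{sample_id}.r{j}", description="")
                for j, s in enumerate(seqs)
            ]
            SeqIO.write(records, str(reads_dir / f"{sample_id}.fasta"), "fasta")
        self.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), index])


def draw_sample_counts(
    rng: np.random.Generator, cfg: SimConfig, true_host: str
) -> dict[str, int]:
    """Draw the per-taxon template read counts for one scat (no sequences).

    This defines the configured count distribution; the read emitter and any
    Monte-Carlo check of recovered summaries both consume it.
    """
    depth = max(1, int(round(rng.lognormal(cfg.reads_per_sample_mu, cfg.reads_per_sample_sigma))))
    n_contam = rng.binomial(depth, cfg.contamination_fraction) if cfg.contamination_fraction else 0
    n_control = rng.binomial(depth, cfg.control_fraction) if cfg.control_fraction else 0
    n_main = max(0, depth - n_contam - n_control)
    f_host = rng.uniform(*cfg.host_fraction_range)
    n_host = int(round(f_host * n_main))
    n_prey = n_main - n_host

    counts: dict[str, int] = {}
    profile = cfg.prey_profiles.get(true_host, {})
    taxa = list(profile)
    included = [t for t in taxa if rng.random() < profile[t].inclusion_prob]
    if included and n_prey > 0:
        conc = np.array([cfg.dirichlet_concentration * profile[t].weight for t in included])
        shares = rng.gamma(conc)
        total = shares.sum()
        if total <= 0:
            shares = np.full(len(included), 1.0 / len(included))
        else:
            shares = shares / total
        prey_counts = rng.multinomial(n_prey, shares)
        for t, c in zip(included, prey_counts):
            if c > 0:
                counts[t] = int(c)
    else:
        n_host += n_prey

    counts[true_host] = counts.get(true_host, 0) + n_host
    if n_contam > 0:
        counts[cfg.contaminant_taxon] = counts.get(cfg.contaminant_taxon, 0) + n_contam
    if n_control > 0:
        counts[cfg.control_taxon] = counts.get(cfg.control_taxon, 0) + n_control
    return counts


def _emit_reads(
    rng: np.random.Generator,
    db: ReferenceDatabase,
    counts: Mapping[str, int],
    cfg: SimConfig,
) -> tuple[list[str], int]:
    """Emit reads for one sample: template copies with i.i.d. substitutions,
    plus bimeric reads (single-crossover two-parent concatenations of
    templates present in the sample). Returns (reads, n_chimera)."""
    taxa = [t for t, c in counts.items() if c > 0]
    template_mats = []
    for t in taxa:
        codes = _CODE[np.frombuffer(db.sequence(t).encode("ascii"), dtype=np.uint8)]
        template_mats.append(np.tile(codes, (counts[t], 1)))

    n_templates = sum(counts[t] for t in taxa)
    n_chimera = 0
    chim_rows = []
    if cfg.chimera_rate > 0 and len(taxa) >= 2 and n_templates > 0:
        n_chimera = int(rng.binomial(n_templates, cfg.chimera_rate))
        weights = np.array([counts[t] for t in taxa], dtype=float)
        weights = weights / weights.sum()
        for _ in range(n_chimera):
            i1, i2 = rng.choice(len(taxa), size=2, replace=False, p=weights)
            s1 = _CODE[np.frombuffer(db.sequence(taxa[i1]).encode("ascii"), dtype=np.uint8)]
            s2 = _CODE[np.frombuffer(db.sequence(taxa[i2]).encode("ascii"), dtype=np.uint8)]
            length = min(len(s1), len(s2))
            k = int(rng.integers(1, length))
            chim_rows.append(np.concatenate([s1[:k], s2[k:]]))

    if not template_mats and not chim_rows:
        return [], 0
    # all sequences share a length in practice; pad is unnecessary here because
    # templates come from one database with a fixed amplicon length.
    mat = np.vstack(template_mats + ([np.vstack(chim_rows)] if chim_rows else []))
    if cfg.substitution_error_rate > 0:
        mask = rng.random(mat.shape) < cfg.substitution_error_rate
        n_err = int(mask.sum())
        if n_err:
            # shift by 1..3 mod 4 so every hit is a real substitution
            mat[mask] = (mat[mask] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    order = rng.permutation(mat.shape[0])
    blob = _BASES[mat[order]].tobytes().decode("ascii")
    width = mat.shape[1]
    reads = [blob[i * width : (i + 1) * width] for i in range(mat.shape[0])]
    return reads, n_chimera


_HABITATS = ("peatland_road", "open_peatland", "forestry_road", "forestry")


def iter_sample_reads(
    db: ReferenceDatabase, cfg: SimConfig
) -> Iterator[tuple[str, list[str], list[dict], dict]]:
    """Yield (sample_id, reads, truth_rows, manifest_row) one sample at a time.

    Streaming form of :func:`generate_scat_dataset`; lets a caller dereplicate
    incrementally without holding every sample's reads in memory.
    """
    cfg.validate(db)
    hosts = list(cfg.candidate_hosts)
    mix = np.array([cfg.host_mix[h] for h in hosts], dtype=float)
    mix = mix / mix.sum()
    for i in range(cfg.n_samples):
        rng = _sample_rng(cfg.seed, i)
        sample_id = f"S{i:03d}"
        if cfg.balanced_hosts:
            true_host = hosts[i % len(hosts)]
        else:
            true_host = hosts[int(rng.choice(len(hosts), p=mix))]
        other = hosts[1 - hosts.index(true_host)]
        field_label = other if rng.random() < cfg.misid_rate else true_host
        counts = draw_sample_counts(rng, cfg, true_host)
        reads, n_chimera = _emit_reads(rng, db, counts, cfg)

        truth_rows = []
        for taxon, c in counts.items():
            if taxon == true_host:
                kind = "host"
            elif taxon == cfg.contaminant_taxon:
                kind = "contamination"
            elif taxon == cfg.control_taxon:
                kind = "control"
            else:
                kind = "prey"
            truth_rows.append(
                dict(sample_id=sample_id, true_host=true_host, field_label=field_label,
                     taxon_id=taxon, kind=kind, reads=c)
            )
        if n_chimera:
            truth_rows.append(
                dict(sample_id=sample_id, true_host=true_host, field_label=field_label,
                     taxon_id=CHIMERA_ID, kind="chimera", reads=n_chimera)
            )
        manifest_row = dict(
            sample_id=sample_id,
            field_label=field_label,
            season="breeding",
            habitat=_HABITATS[int(rng.integers(0, len(_HABITATS)))],
        )
        yield sample_id, reads, truth_rows, manifest_row


def generate_scat_dataset(db: ReferenceDatabase, cfg: SimConfig) -> ScatDataset:
    """Generate the full dataset eagerly (reads for every sample in memory)."""
    reads: dict[str, list[str]] = {}
    truth_rows: list[dict] = []
    manifest_rows: list[dict] = []
    for sample_id, sample_reads, t_rows, m_row in iter_sample_reads(db, cfg):
        reads[sample_id] = sample_reads
        truth_rows.extend(t_rows)
        manifest_rows.append(m_row)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "true_host", "field_label", "taxon_id", "kind", "reads"],
    )
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "field_label", "season", "habitat"]
    )
    return ScatDataset(reads=reads, manifest=manifest, truth=truth, config=cfg)


#: Column order of the documented BLAST-tabular dialect: standard outfmt-6
#: twelve columns plus an appended percent-query-coverage column.
HIT_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovs",
)


def simulate_hit_tables(
    db: ReferenceDatabase,
    truth: pd.DataFrame,
    *,
    identity_noise: float = 0.3,
    seed: int = 0,
    ambiguous_taxa: Iterable[str] = (),
    decoys_per_query: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shortcut substrate for the assignment stage: fabricate per-query hit
    tables directly from truth, skipping read emission and alignment.

    Every true source taxon gets a top self-hit (identity >= 98, coverage
    >= 90) plus decoy hits to lineage relatives at strictly lower bit-scores.
    Decoys sit below the top-2% bit-score window unless the taxon is listed in
    ``ambiguous_taxa``, in which case congeners score inside the window (with
    passing identity/coverage) to force genus-level consensus outcomes.

    Returns ``(hits, queries)``: hits in the documented tabular dialect and a
    query table (query_id, sample_id, taxon_id, reads) standing in for cluster
    sizes.
    """
    rng = np.random.default_rng(seed % (2**31))
    ambiguous = set(ambiguous_taxa)
    tax_ids = db.ids
    hit_rows: list[tuple] = []
    query_rows: list[dict] = []
    template = truth[truth["kind"] != "chimera"]
    length = len(db.sequence(tax_ids[0]))
    for j, (_, row) in enumerate(template.iterrows()):
        qid = f"{row['sample_id']}.q{j}"
        taxon = row["taxon_id"]
        query_rows.append(
            dict(query_id=qid, sample_id=row["sample_id"], taxon_id=taxon,
                 reads=int(row["reads"]))
        )
        self_ident = float(np.clip(100.0 - abs(rng.normal(0.0, identity_noise)), 98.0, 100.0))
        hit_rows.append(_hit_row(qid, taxon, round(self_ident, 3), length, 180.0))
        lin = db[taxon].lineage
        relatives = sorted(
            (t for t in tax_ids if t != taxon),
            key=lambda t: -_shared_depth(lin, db[t].lineage),
        )
        in_window = taxon in ambiguous
        for d, rel in enumerate(relatives[:decoys_per_query]):
            if in_window and _shared_depth(lin, db[rel].lineage) >= 6:
                score = 178.0 - d  # inside the 2% window of 180
                ident = 98.2
            else:
                score = 170.0 - 2 * d  # below 176.4, outside the window
                ident = 96.5
            hit_rows.append(_hit_row(qid, rel, ident, length, score))

    hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)
    queries = pd.DataFrame(query_rows, columns=["query_id", "sample_id", "taxon_id", "reads"])
    return hits, queries


def _shared_depth(a: Lineage, b: Lineage) -> int:
    d = 0
    for x, y in zip(a.names, b.names):
        if x != y or x == "":
            break
        d += 1
    return d


def _hit_row(qid: str, sid: str, pident: float, length: int, bitscore: float) -> tuple:
    mismatch = int(round(length * (100.0 - pident) / 100.0))
    return (qid, sid, pident, length, mismatch, 0, 1, length, 1, length,
            1e-40, bitscore, 100.0)


def write_hit_tables(hits: pd.DataFrame, outdir) -> None:
    """Write one tab-separated hit file per sample (sample inferred from the
    query-id prefix before the first '.')."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = hits["qseqid"].str.split(".").str[0]
    for sample_id, chunk in hits.groupby(samples, sort=True):
        chunk.to_csv(outdir / f"{sample_id}.tsv", sep="\t", header=False, index=False)
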