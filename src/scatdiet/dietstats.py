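"""Post-assignment filtering, host confirmation and diet summaries.

The canonical filter order, applied by :func:`build_profiles`:

1. remove positive-control taxa and the unassigned bucket; drop samples left
   with no assignable reads;
2. per-sample noise threshold — taxa below 0.1% of the sample's total reads
   (at that stage) are removed; at-threshold counts are retained;
3. roll-up of configured ambiguous species groups (e.g. ducks) to a named
   higher taxon;
4. molecular host identification — the candidate predator with the most reads,
   subject to a minimum host-read floor; samples with no confident host are
   dropped;
5. subtraction of the host taxon and contaminant taxa (the OTHER predator's
   DNA is kept: it is a reported diet/contact item);
6. per-sample per-taxon minimum read threshold (default 100, inclusive).

Summaries are percent frequency of occurrence (%FOO), relative read abundance
(RRA, pooled reads per predator group by default), per-sample and per-group
prey richness, woodland:open habitat ratios over distinct prey species, and
the field-label vs DNA-host confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .taxassign import UNASSIGNED
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

COMBINED = "combined"

#: Default prey-group definitions: a sample counts once for a group if ANY
#: member taxon occurs. Membership is by (rank, name) pairs tested against
#: each prey taxon's lineage.
DEFAULT_TAXON_GROUPS: dict[str, tuple[tuple[str, str], ...]] = {
    "small mammals": (("order", "Rodentia"), ("family", "Soricidae")),
    "birds": (("class", "Aves"),),
    "passerines": (("order", "Passeriformes"),),
}


@dataclass
class SampleProfile:
    """Per-sample taxon -> read-count table with field and DNA host labels."""

    sample_id: str
    field_label: str
    counts: dict[str, int]
    dna_host: Optional[str] = None

    def total(self) -> int:
        return sum(self.counts.values())

    def copy(self) -> "SampleProfile":
        return replace(self, counts=dict(self.counts))


@dataclass
class FilterParams:
    noise_fraction: float = 0.001
    min_reads: int = 100
    contaminant_taxa: tuple[str, ...] = ("Homo sapiens",)
    control_taxa: tuple[str, ...] = ("Maylandia zebra",)
    ambiguous_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    candidate_hosts: tuple[str, ...] = ("Vulpes vulpes", "Martes martes")
    min_host_reads: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.noise_fraction < 1.0:
            raise ConfigError("noise_fraction must be in (0,1)")
        if self.min_reads < 1:
            raise ConfigError("min_reads must be >= 1")


def profiles_from_assignments(
    assignments: pd.DataFrame, manifest: pd.DataFrame
) -> list[SampleProfile]:
    """Join the long assignment table (sample_id, taxon, rank, reads) with the
    sample manifest's field labels."""
    labels = dict(zip(manifest["sample_id"], manifest["field_label"]))
    profiles = []
    for sample_id, chunk in assignments.groupby("sample_id", sort=True):
        counts = dict(zip(chunk["taxon"], chunk["reads"].astype(int)))
        profiles.append(SampleProfile(str(sample_id), labels.get(str(sample_id), ""), counts))
    return profiles


def remove_nontarget(
    profiles: Sequence[SampleProfile], params: FilterParams
) -> list[SampleProfile]:
    """Delete control taxa and the unassigned bucket; drop samples with no
    assignable reads left."""
    drop = set(params.control_taxa) | {UNASSIGNED}
    out = []
    for p in profiles:
        counts = {t: n for t, n in p.counts.items() if t not in drop and n > 0}
        if not counts:
            logger.info("remove_nontarget: dropping %s (no assignable reads)", p.sample_id)
            continue
        out.append(replace(p, counts=counts))
    return out


def apply_noise_threshold(profile: SampleProfile, noise_fraction: float = 0.001) -> SampleProfile:
    """Remove taxa strictly below noise_fraction x (sample total before this
    filter); at-threshold taxa are retained."""
    total = profile.total()
    if total == 0:
        return profile.copy()
    cut = noise_fraction * total
    counts = {t: n for t, n in profile.counts.items() if n >= cut}
    return replace(profile, counts=counts)


def rollup_ambiguous(
    profile: SampleProfile,
    ambiguous_groups: Mapping[str, tuple[str, ...]],
    taxonomy: Optional[Taxonomy] = None,
) -> SampleProfile:
    """Re-label reads of species the marker cannot separate to a configured
    higher taxon (e.g. both ducks -> Anatidae) and sum them."""
    if not ambiguous_groups:
        return profile.copy()
    mapping: dict[str, str] = {}
    for target, members in ambiguous_groups.items():
        for m in members:
            if taxonomy is not None and taxonomy.lineage_for_label(m) is None:
                raise ConfigError(f"ambiguous-group member not in lineage table: {m!r}")
            mapping[m] = target
    counts: dict[str, int] = {}
    for t, n in profile.counts.items():
        label = mapping.get(t, t)
        counts[label] = counts.get(label, 0) + n
    return replace(profile, counts=counts)


def identify_host(
    profile: SampleProfile,
    candidate_hosts: Sequence[str],
    min_host_reads: int = 10,
) -> Optional[str]:
    """The depositing predator, identified molecularly.

    The candidate host with the largest read count is accepted when that count
    clears the host-read floor; the exception policy is that the host need not
    beat every single prey taxon, only dominate among candidates (hosts are
    'generally' the top taxon, and the floor guards the degenerate cases).
    Returns None (indeterminate) when no candidate qualifies.
    """
    if not candidate_hosts:
        raise ConfigError("candidate_hosts must be nonempty")
    best, best_n = None, 0
    for h in candidate_hosts:
        n = profile.counts.get(h, 0)
        if n > best_n:
            best, best_n = h, n
    if best is None or best_n < min_host_reads:
        return None
    return best


def subtract_host_and_contaminants(
    profile: SampleProfile, contaminant_taxa: Iterable[str] = ("Homo sapiens",)
) -> SampleProfile:
    """Remove the confirmed host taxon and contaminant taxa, leaving the prey
    profile. The other predator's DNA is retained as a diet/contact item."""
    if profile.dna_host is None:
        raise ConfigError(f"{profile.sample_id}: dna_host not determined")
    drop = set(contaminant_taxa) | {profile.dna_host}
    counts = {t: n for t, n in profile.counts.items() if t not in drop}
    return replace(profile, counts=counts)


def apply_min_reads(profile: SampleProfile, min_reads: int = 100) -> SampleProfile:
    """Remove per-sample per-taxon counts strictly below min_reads
    (at-threshold counts are retained)."""
    counts = {t: n for t, n in profile.counts.items() if n >= min_reads}
    return replace(profile, counts=counts)


def build_profiles(
    assignments: pd.DataFrame,
    manifest: pd.DataFrame,
    params: FilterParams,
    taxonomy: Optional[Taxonomy] = None,
) -> tuple[list[SampleProfile], dict[str, int]]:
    """Run the canonical filter order; returns (prey profiles, stage counts)."""
    profiles = profiles_from_assignments(assignments, manifest)
    stage = {"input_samples": len(profiles)}
    profiles = remove_nontarget(profiles, params)
    stage["after_remove_nontarget"] = len(profiles)
    profiles = [apply_noise_threshold(p, params.noise_fraction) for p in profiles]
    profiles = [rollup_ambiguous(p, params.ambiguous_groups, taxonomy) for p in profiles]
    kept = []
    for p in profiles:
        host = identify_host(p, params.candidate_hosts, params.min_host_reads)
        if host is None:
            logger.info("identify_host: %s indeterminate, dropped", p.sample_id)
            continue
        p = replace(p, dna_host=host)
        kept.append(p)
    stage["after_host_id"] = len(kept)
    prey = [
        apply_min_reads(
            subtract_host_and_contaminants(p, params.contaminant_taxa), params.min_reads
        )
        for p in kept
    ]
    stage["retained_samples"] = len(prey)
    return prey, stage


# ---------------------------------------------------------------------------
# summaries


def _groups_of(profiles: Sequence[SampleProfile]) -> dict[str, list[SampleProfile]]:
    groups: dict[str, list[SampleProfile]] = {COMBINED: list(profiles)}
    for p in profiles:
        if p.dna_host is not None:
            groups.setdefault(p.dna_host, []).append(p)
    return groups


def _group_members(
    taxa: Iterable[str],
    taxon_groups: Mapping[str, tuple[tuple[str, str], ...]],
    taxonomy: Taxonomy,
) -> dict[str, set[str]]:
    members: dict[str, set[str]] = {g: set() for g in taxon_groups}
    for t in taxa:
        lin = taxonomy.lineage_for_label(t)
        if lin is None:
            continue
        for g, pairs in taxon_groups.items():
            if any(lin.name_at(rank) == name for rank, name in pairs):
                members[g].add(t)
    return members


def foo(
    profiles: Sequence[SampleProfile],
    taxonomy: Optional[Taxonomy] = None,
    taxon_groups: Mapping[str, tuple[tuple[str, str], ...]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent frequency of occurrence per taxon (and per taxon group).

    Returns (taxa table, group-aggregate table), each indexed by taxon with
    one column per predator group plus 'combined'. A group aggregate counts a
    sample once if any member taxon occurs. Empty predator groups yield NaN.
    """
    taxon_groups = DEFAULT_TAXON_GROUPS if taxon_groups is None else taxon_groups
    groups = _groups_of(profiles)
    all_taxa = sorted({t for p in profiles for t in p.counts})
    taxa_tbl = pd.DataFrame(index=all_taxa, columns=list(groups), dtype=float)
    for gname, members in groups.items():
        n = len(members)
        for t in all_taxa:
            taxa_tbl.loc[t, gname] = (
                np.nan if n == 0 else 100.0 * sum(t in p.counts for p in members) / n
            )
    agg_members = (
        _group_members(all_taxa, taxon_groups, taxonomy) if taxonomy is not None else {}
    )
    agg_tbl = pd.DataFrame(index=sorted(agg_members), columns=list(groups), dtype=float)
    for agg, mem in agg_members.items():
        for gname, members in groups.items():
            n = len(members)
            agg_tbl.loc[agg, gname] = (
                np.nan if n == 0
                else 100.0 * sum(bool(mem & set(p.counts)) for p in members) / n
            )
    return taxa_tbl, agg_tbl


def rra(
    profiles: Sequence[SampleProfile],
    *,
    per_sample_mean: bool = False,
) -> pd.DataFrame:
    """Relative read abundance per taxon and predator group.

    Default is the pooled-reads definition: reads of a taxon summed over the
    group's samples divided by all prey reads in the group, so each column
    sums to 1. With ``per_sample_mean=True`` the per-sample proportions are
    averaged instead. Groups with zero prey reads yield NaN.
    """
    groups = _groups_of(profiles)
    all_taxa = sorted({t for p in profiles for t in p.counts})
    tbl = pd.DataFrame(index=all_taxa, columns=list(groups), dtype=float)
    for gname, members in groups.items():
        if per_sample_mean:
            shares = []
            for p in members:
                tot = p.total()
                if tot > 0:
                    shares.append({t: n / tot for t, n in p.counts.items()})
            if not shares:
                tbl[gname] = np.nan
                continue
            for t in all_taxa:
                tbl.loc[t, gname] = sum(s.get(t, 0.0) for s in shares) / len(shares)
        else:
            total = sum(p.total() for p in members)
            if total == 0:
                tbl[gname] = np.nan
                continue
            for t in all_taxa:
                tbl.loc[t, gname] = sum(p.counts.get(t, 0) for p in members) / total
    return tbl


def confusion(profiles: Sequence[SampleProfile]) -> tuple[pd.DataFrame, pd.Series]:
    """Field-label vs DNA-host cross-tabulation and per-species
    misidentification percentages.

    misid%(s) = 100 x #(dna_host = s, field_label != s) / #(dna_host = s).
    """
    rows = [(p.field_label, p.dna_host) for p in profiles if p.dna_host is not None]
    frame = pd.DataFrame(rows, columns=["field_label", "dna_host"])
    matrix = pd.crosstab(frame["field_label"], frame["dna_host"])
    species = sorted(frame["dna_host"].unique())
    misid = {}
    for s in species:
        sub = frame[frame["dna_host"] == s]
        misid[s] = 100.0 * (sub["field_label"] != s).sum() / len(sub)
    return matrix, pd.Series(misid, name="misid_pct")


def richness_and_habitat(
    profiles: Sequence[SampleProfile], taxonomy: Taxonomy
) -> tuple[pd.Series, dict[str, int], pd.DataFrame]:
    """Per-sample prey richness, per-group total richness, and the
    woodland:open ratio over distinct prey species (other habitats excluded),
    normalized to percentages."""
    per_sample = pd.Series(
        {p.sample_id: len(p.counts) for p in profiles}, name="richness", dtype=int
    )
    groups = _groups_of(profiles)
    group_richness = {
        g: len({t for p in members for t in p.counts}) for g, members in groups.items()
    }
    ratio = pd.DataFrame(index=list(groups), columns=["woodland", "open"], dtype=float)
    for g, members in groups.items():
        taxa = {t for p in members for t in p.counts}
        habs = [taxonomy.habitat_for_label(t) for t in sorted(taxa)]
        n_wood = sum(h == "woodland" for h in habs)
        n_open = sum(h == "open" for h in habs)
        denom = n_wood + n_open
        if denom == 0:
            ratio.loc[g] = np.nan
        else:
            ratio.loc[g, "woodland"] = 100.0 * n_wood / denom
            ratio.loc[g, "open"] = 100.0 * n_open / denom
    return per_sample, group_richness, ratio


@dataclass
class DietSummary:
    """All §-style diet outputs for one analysed dataset."""

    foo_taxa: pd.DataFrame
    foo_groups: pd.DataFrame
    rra_taxa: pd.DataFrame
    richness_per_sample: pd.Series
    group_richness: dict[str, int]
    habitat_ratio: pd.DataFrame
    confusion_matrix: pd.DataFrame
    misid_pct: pd.Series
    n_samples: dict[str, int]


def summarize(
    profiles: Sequence[SampleProfile],
    taxonomy: Taxonomy,
    taxon_groups: Mapping[str, tuple[tuple[str, str], ...]] | None = None,
    *,
    rra_per_sample_mean: bool = False,
) -> DietSummary:
    """Compute every diet summary from filtered prey profiles."""
    foo_taxa, foo_groups = foo(profiles, taxonomy, taxon_groups)
    rra_taxa = rra(profiles, per_sample_mean=rra_per_sample_mean)
    richness, group_richness, habitat = richness_and_habitat(profiles, taxonomy)
    matrix, misid = confusion(profiles)
    n_samples = {g: len(m) for g, m in _groups_of(profiles).items()}
    return DietSummary(
        foo_taxa=foo_taxa,
        foo_groups=foo_groups,
        rra_taxa=rra_taxa,
        richness_per_sample=richness,
        group_richness=group_richness,
        habitat_ratio=habitat,
        confusion_matrix=matrix,
        misid_pct=misid,
        n_samples=n_samples,
    )
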