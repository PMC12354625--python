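"""Post-assignment filters, host confirmation and diet summaries."""

import numpy as np
import pytest

from scatdiet.dietstats import (
    FilterParams,
    SampleProfile,
    apply_min_reads,
    apply_noise_threshold,
    confusion,
    foo,
    identify_host,
    remove_nontarget,
    richness_and_habitat,
    rollup_ambiguous,
    rra,
    subtract_host_and_contaminants,
)
from scatdiet.errors import ConfigError

FOX = "Vulpes vulpes"
PM = "Martes martes"
HOSTS = (FOX, PM)


def prof(sample_id, counts, field=FOX, dna=None):
    return SampleProfile(sample_id, field, dict(counts), dna)


class TestRemoveNontarget:
    def test_sample_with_only_control_and_unassigned_dropped(self):
        params = FilterParams(control_taxa=("Maylandia zebra",))
        out = remove_nontarget(
            [prof("s1", {"Maylandia zebra": 500, "unassigned": 50})], params
        )
        assert out == []

    def test_clean_sample_is_identity(self):
        params = FilterParams()
        p = prof("s1", {FOX: 100, "Rana temporaria": 50})
        assert remove_nontarget([p], params)[0].counts == p.counts


class TestNoiseThreshold:
    def test_strictly_below_removed_at_threshold_retained(self):
        # 0.1% of 50,000 = 50 reads
        p = prof("s1", {"a": 49_000, "b": 901, "c": 49, "d": 50})
        out = apply_noise_threshold(p, 0.001)
        assert set(out.counts) == {"a", "b", "d"}

    def test_single_taxon_sample_retained(self):
        p = prof("s1", {"a": 7})
        assert apply_noise_threshold(p).counts == {"a": 7}

    def test_all_above_is_identity(self):
        p = prof("s1", {"a": 600, "b": 400})
        assert apply_noise_threshold(p).counts == p.counts


class TestRollup:
    def test_duck_species_merge_to_family(self, taxonomy26):
        groups = {"Anatidae": ("Anas platyrhynchos", "Anas crecca")}
        p = prof("s1", {"Anas platyrhynchos": 30, "Anas crecca": 20, FOX: 100})
        out = rollup_ambiguous(p, groups, taxonomy26)
        assert out.counts == {"Anatidae": 50, FOX: 100}

    def test_empty_mapping_is_identity(self):
        p = prof("s1", {"a": 1})
        assert rollup_ambiguous(p, {}).counts == {"a": 1}

    def test_unknown_member_is_config_error(self, taxonomy26):
        with pytest.raises(ConfigError):
            rollup_ambiguous(prof("s1", {"a": 1}), {"X": ("Not a species",)}, taxonomy26)


class TestIdentifyHost:
    def test_candidate_with_most_reads_wins(self):
        p = prof("s1", {FOX: 12_000, "Microtus agrestis": 900, "Homo sapiens": 40})
        assert identify_host(p, HOSTS) == FOX

    def test_no_candidate_present_is_indeterminate(self):
        p = prof("s1", {"Microtus agrestis": 300})
        assert identify_host(p, HOSTS) is None

    def test_below_floor_is_indeterminate(self):
        p = prof("s1", {FOX: 4})
        assert identify_host(p, HOSTS, min_host_reads=10) is None


class TestSubtractHostAndContaminants:
    def test_host_and_human_removed(self):
        p = prof("s1", {FOX: 12_000, "Rana temporaria": 600, "Homo sapiens": 40}, dna=FOX)
        out = subtract_host_and_contaminants(p)
        assert out.counts == {"Rana temporaria": 600}

    def test_other_predator_kept_as_diet_item(self):
        p = prof("s1", {FOX: 12_000, PM: 700}, dna=FOX)
        assert subtract_host_and_contaminants(p).counts == {PM: 700}

    def test_empty_after_subtraction(self):
        p = prof("s1", {FOX: 12_000}, dna=FOX)
        assert subtract_host_and_contaminants(p).counts == {}


class TestMinReads:
    def test_woodcock_92_reads_removed(self):
        p = prof("s1", {"Scolopax rusticola": 92, "Rana temporaria": 500})
        assert set(apply_min_reads(p).counts) == {"Rana temporaria"}

    def test_exactly_100_retained(self):
        p = prof("s1", {"Scolopax rusticola": 100})
        assert apply_min_reads(p).counts == {"Scolopax rusticola": 100}


class TestFoo:
    def test_half_of_samples(self, taxonomy26):
        profiles = [
            prof(f"s{i}", {"Rana temporaria": 200} if i < 12 else {"Cervus elaphus": 150}, dna=FOX)
            for i in range(24)
        ]
        taxa, _ = foo(profiles, taxonomy26)
        assert taxa.loc["Rana temporaria", "combined"] == pytest.approx(50.0)
        assert taxa.loc["Rana temporaria", FOX] == pytest.approx(50.0)

    def test_absent_taxon_absent_or_zero(self, taxonomy26):
        profiles = [prof("s1", {"Rana temporaria": 200}, dna=FOX)]
        taxa, _ = foo(profiles, taxonomy26)
        assert "Cervus elaphus" not in taxa.index

    def test_group_aggregates_count_sample_once(self, taxonomy26):
        # rodent + shrew in one sample: small-mammal group counts it once
        profiles = [
            prof("s1", {"Microtus agrestis": 200, "Sorex araneus": 150}, dna=FOX),
            prof("s2", {"Rana temporaria": 150}, dna=FOX),
        ]
        _, groups = foo(profiles, taxonomy26)
        assert groups.loc["small mammals", "combined"] == pytest.approx(50.0)
        assert groups.loc["birds", "combined"] == pytest.approx(0.0)

    def test_passerine_group_membership(self, taxonomy26):
        profiles = [
            prof("s1", {"Fringilla coelebs": 200}, dna=PM),
            prof("s2", {"Anas platyrhynchos": 150}, dna=PM),
        ]
        _, groups = foo(profiles, taxonomy26)
        assert groups.loc["birds", "combined"] == pytest.approx(100.0)
        assert groups.loc["passerines", "combined"] == pytest.approx(50.0)


class TestRra:
    def test_pooled_proportions(self):
        profiles = [prof("s1", {"a": 750, "b": 250}, dna=FOX)]
        tbl = rra(profiles)
        assert tbl.loc["a", "combined"] == pytest.approx(0.75)
        assert tbl.loc["b", "combined"] == pytest.approx(0.25)

    def test_single_taxon_is_one(self):
        tbl = rra([prof("s1", {"a": 42}, dna=FOX)])
        assert tbl.loc["a", "combined"] == pytest.approx(1.0)

    def test_columns_sum_to_one(self):
        profiles = [
            prof("s1", {"a": 300, "b": 100}, dna=FOX),
            prof("s2", {"b": 500, "c": 100}, dna=PM),
        ]
        tbl = rra(profiles)
        assert np.allclose(tbl.sum(axis=0), 1.0, atol=1e-9)

    def test_per_sample_mean_variant(self):
        profiles = [
            prof("s1", {"a": 900, "b": 100}, dna=FOX),
            prof("s2", {"a": 100, "b": 900}, dna=FOX),
        ]
        tbl = rra(profiles, per_sample_mean=True)
        assert tbl.loc["a", "combined"] == pytest.approx(0.5)


class TestConfusion:
    def test_study_arithmetic(self):
        # 24 DNA pine marten of which 8 field-labelled fox; 24 DNA fox of
        # which 6 field-labelled pine marten
        profiles = (
            [prof(f"p{i}", {}, field=FOX if i < 8 else PM, dna=PM) for i in range(24)]
            + [prof(f"f{i}", {}, field=PM if i < 6 else FOX, dna=FOX) for i in range(24)]
        )
        matrix, misid = confusion(profiles)
        assert misid[PM] == pytest.approx(100 * 8 / 24)
        assert misid[FOX] == pytest.approx(25.0)
        assert matrix.sum().sum() == 48
        assert matrix.sum(axis=0).to_dict() == {FOX: 24, PM: 24}

    def test_perfect_labels(self):
        profiles = [prof("s1", {}, field=FOX, dna=FOX), prof("s2", {}, field=PM, dna=PM)]
        matrix, misid = confusion(profiles)
        assert (misid == 0).all()
        assert matrix.values.diagonal().sum() == 2


class TestRichnessAndHabitat:
    def test_per_sample_richness(self, taxonomy26):
        profiles = [
            prof("s1", {"Rana temporaria": 500, "Microtus agrestis": 300,
                        "Cervus elaphus": 100}, dna=FOX),
            prof("s2", {}, dna=FOX),
        ]
        per_sample, group_rich, _ = richness_and_habitat(profiles, taxonomy26)
        assert per_sample["s1"] == 3
        assert per_sample["s2"] == 0
        assert group_rich["combined"] == 3

    def test_woodland_open_ratio(self, taxonomy26):
        # 7 woodland vs 3 open species; aquatic/none excluded
        woodland = ["Apodemus sylvaticus", "Fringilla coelebs", "Erithacus rubecula",
                    "Turdus philomelos", "Columba palumbus", "Phasianus colchicus",
                    "Scolopax rusticola"]
        open_ = ["Microtus agrestis", "Cervus elaphus", "Lagopus lagopus"]
        counts = {t: 200 for t in woodland + open_ + ["Rana temporaria"]}
        profiles = [prof("s1", counts, dna=PM)]
        _, _, ratio = richness_and_habitat(profiles, taxonomy26)
        assert ratio.loc["combined", "woodland"] == pytest.approx(70.0)
        assert ratio.loc["combined", "open"] == pytest.approx(30.0)
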