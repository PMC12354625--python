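"""Hit parsing/filtering, the majority-LCA consensus, and count propagation."""

import numpy as np
import pytest

from scatdiet import Lineage
from scatdiet.errors import ConsistencyError, HitParseError
from scatdiet.preprocess import SeqCluster
from scatdiet.taxassign import (
    AlignmentHit,
    AssignmentParams,
    align_clusters,
    assign_counts,
    filter_hits,
    mlca,
    parse_hits,
)

from conftest import oracle_mlca, random_lineages


def lin(*names):
    return Lineage.from_names(names)


def hit(lineage, bitscore=200.0, ident=99.0, cov=95.0, qid="q1", taxon="t"):
    return AlignmentHit(qid, taxon, lineage, bitscore, ident, cov)


MOUSE = lin("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Muridae", "Apodemus", "Apodemus sylvaticus")
VOLE = lin("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Cricetidae", "Microtus", "Microtus agrestis")


class TestParseHits:
    def _write(self, path, rows):
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))

    def _row(self, qid, sid, pident=99.0, bitscore=180.0, qcovs=100.0):
        return (qid, sid, pident, 97, 1, 0, 1, 97, 1, 97, 1e-40, bitscore, qcovs)

    def test_empty_file(self, tmp_path, taxonomy26):
        f = tmp_path / "hits.tsv"
        f.write_text("")
        assert parse_hits(f, taxonomy26) == []

    def test_well_formed_rows(self, tmp_path, taxonomy26):
        f = tmp_path / "hits.tsv"
        self._write(f, [self._row("q1", "Vulpes_vulpes"),
                        self._row("q1", "Martes_martes"),
                        self._row("q2", "Rana_temporaria")])
        hits = parse_hits(f, taxonomy26)
        assert len(hits) == 3
        assert hits[0].lineage.deepest_name == "Vulpes vulpes"

    def test_unknown_taxon_rejected_with_log(self, tmp_path, taxonomy26, caplog):
        f = tmp_path / "hits.tsv"
        self._write(f, [self._row("q1", "Vulpes_vulpes"), self._row("q1", "No_such_taxon")])
        with caplog.at_level("WARNING"):
            hits = parse_hits(f, taxonomy26)
        assert len(hits) == 1
        assert any("rejected 1" in m for m in caplog.messages)

    def test_malformed_row_names_line(self, tmp_path, taxonomy26):
        f = tmp_path / "hits.tsv"
        f.write_text("\t".join(map(str, self._row("q1", "Vulpes_vulpes"))) + "\nbad\trow\n")
        with pytest.raises(HitParseError, match="line 2"):
            parse_hits(f, taxonomy26)


class TestFilterHits:
    def test_top_two_percent_bitscore_window(self):
        hits = [hit(MOUSE, bitscore=b) for b in (200.0, 197.0, 195.0)]
        kept = filter_hits(hits)
        assert [h.bit_score for h in kept] == [200.0, 197.0]  # cutoff 196

    def test_identity_below_98_excluded(self):
        hits = [hit(MOUSE, ident=97.9), hit(VOLE, ident=98.0)]
        kept = filter_hits(hits)
        assert [h.percent_identity for h in kept] == [98.0]

    def test_coverage_exactly_90_retained(self):
        assert len(filter_hits([hit(MOUSE, cov=90.0)])) == 1
        assert len(filter_hits([hit(MOUSE, cov=89.9)])) == 0

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_invariant_to_bitscore_rescaling(self):
        hits = [hit(MOUSE, bitscore=b) for b in (200.0, 197.0, 195.0)]
        scaled = [hit(MOUSE, bitscore=3.5 * b) for b in (200.0, 197.0, 195.0)]
        assert [h.bit_score / 1.0 for h in filter_hits(hits)] == [
            h.bit_score / 3.5 for h in filter_hits(scaled)
        ]


class TestMlca:
    def test_genus_level_consensus(self):
        # five unique lineages, all Muridae; four share the genus (4/5 = 0.8
        # passes), species votes are singletons (tie) -> genus Apodemus
        lineages = [
            lin("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Muridae", "Apodemus", sp)
            for sp in ("Apodemus sylvaticus", "Apodemus flavicollis",
                       "Apodemus agrarius", "Apodemus alpicola")
        ] + [lin("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Muridae", "Mus", "Mus musculus")]
        result = mlca([hit(l) for l in lineages])
        assert result is not None
        assert result.deepest_rank == "genus"
        assert result.deepest_name == "Apodemus"

    def test_single_hit_assigned_to_species(self):
        result = mlca([hit(VOLE)])
        assert result == VOLE

    def test_agreement_only_at_class_is_unassigned(self):
        lineages = [
            lin("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Muridae", "Apodemus", "Apodemus sylvaticus"),
            lin("Eukaryota", "Chordata", "Mammalia", "Carnivora", "Canidae", "Vulpes", "Vulpes vulpes"),
        ]
        assert mlca([hit(l) for l in lineages]) is None

    def test_empty_hits_unassigned(self):
        assert mlca([]) is None

    def test_duplicate_lineages_do_not_overweight(self):
        # ten hits to one reference species vs one hit to a congener: unique
        # lineages are 1:1, so the species vote is a tie -> genus level
        a = lin("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Muridae", "Apodemus", "Apodemus sylvaticus")
        b = lin("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Muridae", "Apodemus", "Apodemus flavicollis")
        hits = [hit(a) for _ in range(10)] + [hit(b)]
        result = mlca(hits)
        assert result.deepest_rank == "genus"

    @pytest.mark.parametrize("nested", [True, False])
    def test_matches_bruteforce_oracle_on_fuzzed_pools(self, nested):
        rng = np.random.default_rng(42 if nested else 43)
        for _ in range(200):
            pool = random_lineages(rng, int(rng.integers(1, 9)), nested_names=nested)
            agreement = float(rng.choice([0.5, 0.66, 0.8, 0.9, 1.0]))
            got = mlca([hit(l) for l in pool], AssignmentParams(agreement=agreement))
            want = oracle_mlca(pool, agreement)
            assert got == want, (pool, agreement)

    def test_raising_agreement_never_deepens_assignment(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pool = random_lineages(rng, int(rng.integers(2, 9)))
            hits = [hit(l) for l in pool]
            depths = []
            for agreement in (0.5, 0.7, 0.9):
                r = mlca(hits, AssignmentParams(agreement=agreement))
                depths.append(0 if r is None else r.depth)
            assert depths == sorted(depths, reverse=True)


class TestAssignCounts:
    def test_counts_sum_per_taxon(self):
        frog = lin("Eukaryota", "Chordata", "Amphibia", "Anura", "Ranidae", "Rana", "Rana temporaria")
        assignments = {"q1": frog, "q2": frog}
        counts = {"q1": {"s1": 60}, "q2": {"s1": 50}}
        table = assign_counts(assignments, counts)
        row = table[(table["sample_id"] == "s1") & (table["taxon"] == "Rana temporaria")]
        assert row["reads"].tolist() == [110]

    def test_all_unassigned_bucket(self):
        table = assign_counts({"q1": None, "q2": None}, {"q1": {"s1": 5}, "q2": {"s1": 7}})
        assert table["taxon"].unique().tolist() == ["unassigned"]
        assert table["reads"].sum() == 12

    def test_conservation_over_samples(self):
        assignments = {"q1": MOUSE, "q2": None, "q3": VOLE}
        counts = {"q1": {"s1": 10, "s2": 4}, "q2": {"s1": 3}, "q3": {"s2": 8}}
        table = assign_counts(assignments, counts)
        got = table.groupby("sample_id")["reads"].sum().to_dict()
        assert got == {"s1": 13, "s2": 12}

    def test_missing_cluster_record_is_error(self):
        with pytest.raises(ConsistencyError):
            assign_counts({"q1": MOUSE}, {})


class TestAlignClusters:
    def test_exact_centroid_yields_top_self_hit(self, db26):
        tid = db26.ids[0]
        cluster = SeqCluster("c0", db26.sequence(tid), 10, {"s1": 10})
        hits = align_clusters([cluster], db26)
        best = max(hits, key=lambda h: h.bit_score)
        assert best.taxon_id == tid
        assert best.percent_identity == 100.0
        # and the consensus assigns the correct species
        kept = filter_hits(hits)
        assert mlca(kept).deepest_name == db26[tid].lineage.deepest_name
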