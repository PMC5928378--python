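import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdhc_miner.clustering import (
    classify_rdhc,
    cooccurrence_filter,
    family_report,
    greedy_cluster,
    pairwise_identity,
)
from rdhc_miner.motifs import BUILTIN_MOTIFS, scan_sequence
from rdhc_miner.seqio import GenomeAnnotation, ProteinRecord, RdhcError
from rdhc_miner.topology import assign_topology

from .oracles import gotoh_identity, greedy_cluster_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_seq(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = random_seq(rng, 100)
        assert pairwise_identity(s, s) == 1.0

    def test_ten_substitutions_in_hundred(self, rng):
        s = list(random_seq(rng, 100))
        t = s.copy()
        for pos in rng.choice(100, size=10, replace=False):
            t[pos] = AA[(AA.index(t[pos]) + 1) % 20]
        assert pairwise_identity("".join(s), "".join(t)) == pytest.approx(0.90)

    def test_truncation_scores_one_with_shorter_denominator(self, rng):
        s = random_seq(rng, 80)
        assert pairwise_identity(s, s[:50]) == 1.0
        assert pairwise_identity(s, s[:50], denominator="columns") < 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(RdhcError):
            pairwise_identity("", "ACD")

    @given(st.integers(0, 10**6))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, int(rng.integers(5, 40)))
        b = random_seq(rng, int(rng.integers(5, 40)))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    @given(st.integers(0, 10**6))
    def test_matches_exhaustive_dp_oracle_on_short_pairs(self, seed):
        """Alignment identity equals an independent affine-gap DP oracle."""
        rng = np.random.default_rng(seed)
        a = random_seq(rng, int(rng.integers(3, 13)))
        b = random_seq(rng, int(rng.integers(3, 13)))
        _, identities = gotoh_identity(a, b)
        assert pairwise_identity(a, b) == pytest.approx(identities / min(len(a), len(b)))


def family_records(rng, n_families=4, variants_per=3, length=60):
    """Small mixture of mutation families plus singletons for clustering tests."""
    records = []
    for f in range(n_families):
        seed_seq = random_seq(rng, length + f)
        records.append(ProteinRecord(id=f"f{f}_seed", sequence=seed_seq))
        for v in range(variants_per):
            chars = list(seed_seq)
            for pos in rng.choice(len(chars), size=2, replace=False):
                chars[pos] = AA[int(rng.integers(20))]
            records.append(ProteinRecord(id=f"f{f}_v{v}", sequence="".join(chars)))
    for s in range(4):
        records.append(ProteinRecord(id=f"solo{s}", sequence=random_seq(rng, 50 + s)))
    return records


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        records = [ProteinRecord(id=f"p{i}", sequence="ACDEFGHIK" * 5) for i in range(3)]
        clusters = greedy_cluster(records, threshold=0.95)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["p0", "p1", "p2"]

    def test_threshold_splits_borderline_pair(self, rng):
        s = random_seq(rng, 100)
        t = list(s)
        for pos in rng.choice(100, size=6, replace=False):  # identity 0.94
            t[pos] = AA[(AA.index(t[pos]) + 3) % 20]
        records = [ProteinRecord(id="a", sequence=s), ProteinRecord(id="b", sequence="".join(t))]
        assert len(greedy_cluster(records, threshold=0.95)) == 2
        assert len(greedy_cluster(records, threshold=0.90)) == 1

    def test_partition_property(self, rng):
        records = family_records(rng)
        clusters = greedy_cluster(records, threshold=0.95)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(r.id for r in records)

    def test_matches_direct_oracle_on_twenty_records(self, rng):
        """Greedy partition equals a replay from the exhaustive identity matrix."""
        records = family_records(rng)[:20]
        clusters = greedy_cluster(records, threshold=0.95)
        oracle = greedy_cluster_oracle(records, 0.95, pairwise_identity)
        assert [c.member_ids for c in clusters] == oracle

    def test_deterministic(self, rng):
        records = family_records(rng)
        a = greedy_cluster(records, threshold=0.95)
        b = greedy_cluster(list(reversed(records)), threshold=0.95)
        assert [c.member_ids for c in a] == [c.member_ids for c in b]

    def test_threshold_monotonicity(self, rng):
        records = family_records(rng)
        previous = 0
        for threshold in (0.5, 0.8, 0.95, 1.0):
            n = len(greedy_cluster(records, threshold=threshold))
            assert n >= previous
            previous = n

    def test_member_identities_meet_threshold(self, rng):
        records = family_records(rng)
        for cluster in greedy_cluster(records, threshold=0.9):
            for member, ident in cluster.identities.items():
                assert ident >= 0.9

    def test_bad_threshold_rejected(self):
        with pytest.raises(RdhcError):
            greedy_cluster([], threshold=0.0)


class TestCooccurrenceFilter:
    GENOMES = {
        "gpos": GenomeAnnotation("gpos", True, "OHRB"),
        "gneg": GenomeAnnotation("gneg", False, "non-OHRB"),
    }

    def _cluster(self, members, rep=None):
        from rdhc_miner.clustering import Cluster

        return Cluster(
            representative_id=rep or members[0],
            member_ids=list(members),
            threshold=0.95,
            identities={m: 1.0 for m in members},
        )

    def test_single_member_rdha_positive_retained(self):
        clusters = [self._cluster(["a"])]
        retained = cooccurrence_filter(clusters, {"a": "gpos"}, self.GENOMES)
        assert len(retained) == 1

    def test_all_rdha_less_cluster_dropped(self):
        clusters = [self._cluster(["a", "b"])]
        retained = cooccurrence_filter(
            clusters, {"a": "gneg", "b": "gneg"}, self.GENOMES
        )
        assert retained == []

    def test_mixed_cluster_retained_with_flags(self):
        clusters = [self._cluster(["a", "b"])]
        retained = cooccurrence_filter(
            clusters, {"a": "gpos", "b": "gneg"}, self.GENOMES
        )
        assert len(retained) == 1
        assert retained[0].rdha_flags == {"a": True, "b": False}

    def test_unknown_genome_is_hard_error(self):
        clusters = [self._cluster(["a"])]
        with pytest.raises(RdhcError, match="mystery"):
            cooccurrence_filter(clusters, {"a": "mystery"}, self.GENOMES)


class TestClassifyRdhc:
    def test_planted_rdhc_protein_accepted(self, rdhc_protein):
        from rdhc_miner.config import PipelineConfig
        from rdhc_miner.pipeline import protein_topology

        record, _ = rdhc_protein
        cand = classify_rdhc(
            record,
            scan_sequence(record, BUILTIN_MOTIFS["FMN_CONSENSUS"]),
            scan_sequence(record, BUILTIN_MOTIFS["CX3CP"]),
            protein_topology(record, PipelineConfig()),
        )
        assert cand.accepted
        assert cand.reasons == ()
        assert cand.fbd_side == "O"

    def test_missing_cx3cp_reason_code(self, rdhc_protein):
        from rdhc_miner.config import PipelineConfig
        from rdhc_miner.pipeline import protein_topology

        record, _ = rdhc_protein
        cand = classify_rdhc(
            record,
            scan_sequence(record, BUILTIN_MOTIFS["FMN_CONSENSUS"]),
            [],
            protein_topology(record, PipelineConfig()),
        )
        assert not cand.accepted
        assert "cx3cp<2" in cand.reasons

    def test_soluble_protein_with_motif_rejected(self):
        record = ProteinRecord(id="sol", sequence="QQQQQTGSTVSQQQQQQQQQ")
        topo = assign_topology([], len(record.sequence), "I")
        cand = classify_rdhc(
            record,
            scan_sequence(record, BUILTIN_MOTIFS["FMN_CONSENSUS"]),
            [],
            topo,
        )
        assert not cand.accepted
        assert "tm<min" in cand.reasons


class TestFamilyReport:
    def _cluster(self, members):
        from rdhc_miner.clustering import Cluster

        return Cluster(
            representative_id=members[0],
            member_ids=list(members),
            threshold=0.95,
            identities={m: 1.0 for m in members},
        )

    def test_counts_and_histogram(self):
        report = family_report([self._cluster(["a"]), self._cluster(["b", "c", "d"])])
        assert report.n_clusters == 2
        assert report.n_sequences == 4
        assert report.size_histogram == {1: 1, 3: 1}

    def test_empty_input(self):
        report = family_report([])
        assert report.n_clusters == 0
        assert report.n_sequences == 0
        assert report.size_histogram == {}

    def test_per_genome_breakdown(self):
        genomes = {"g1": GenomeAnnotation("g1", True, "taxA")}
        report = family_report(
            [self._cluster(["a", "b"])], {"a": "g1", "b": "g1"}, genomes
        )
        assert report.per_genome.iloc[0]["n_members"] == 2
        assert report.per_genome.iloc[0]["taxon_label"] == "taxA"
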