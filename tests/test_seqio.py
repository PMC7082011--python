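import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitopop import (
    collapse_haplotypes,
    group_distances,
    make_alignment,
    pairwise_differences,
    read_alignment,
    strip_segment,
    write_alignment,
)
from mitopop.errors import (
    AlignmentError,
    AlphabetError,
    CoordinateError,
    MetadataError,
    UndefinedDistanceError,
)

from conftest import brute_force_differences


class TestAlignmentConstruction:
    def test_valid_rectangular(self, toy_alignment):
        assert toy_alignment.n == 3
        assert toy_alignment.length == 4

    def test_ragged_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            make_alignment([("a", "x", "ACGT"), ("b", "x", "ACGTA")])

    def test_illegal_character_rejected(self):
        with pytest.raises(AlphabetError):
            make_alignment([("a", "x", "ACGX")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError):
            make_alignment([("a", "x", "ACGT"), ("a", "y", "ACGT")])

    def test_lowercase_normalized(self):
        aln = make_alignment([("a", "x", "acgt")])
        assert aln.sequences[0] == "ACGT"


class TestRoundTrip:
    def test_write_read_identity(self, toy_alignment, tmp_path):
        fasta = tmp_path / "aln.fasta"
        meta = tmp_path / "meta.tsv"
        coords = {"north": (42.0, -8.0), "south": (16.0, -23.0)}
        write_alignment(toy_alignment, fasta, meta, coords)
        aln2, sites = read_alignment(fasta, meta)
        assert aln2.specimen_ids == toy_alignment.specimen_ids
        assert aln2.sequences == toy_alignment.sequences
        assert aln2.site_labels == toy_alignment.site_labels
        assert set(sites.index) == {"north", "south"}
        assert sites.loc["north", "n"] == 2

    def test_unknown_specimen_rejected(self, toy_alignment, tmp_path):
        fasta = tmp_path / "aln.fasta"
        meta = tmp_path / "meta.tsv"
        write_alignment(toy_alignment, fasta, meta)
        meta.write_text(
            "specimen_id\tsite\tlatitude\tlongitude\nsp1\tnorth\t42\t-8\n"
        )
        with pytest.raises(MetadataError):
            read_alignment(fasta, meta)

    def test_bad_coordinates_rejected(self, toy_alignment, tmp_path):
        fasta = tmp_path / "aln.fasta"
        meta = tmp_path / "meta.tsv"
        write_alignment(toy_alignment, fasta, meta)
        rows = ["specimen_id\tsite\tlatitude\tlongitude"]
        rows += [f"{s}\tx\t95.0\t0.0" for s in toy_alignment.specimen_ids]
        meta.write_text("\n".join(rows) + "\n")
        with pytest.raises(CoordinateError):
            read_alignment(fasta, meta)


class TestStripSegment:
    def test_zero_length_is_identity(self, toy_alignment):
        assert strip_segment(toy_alignment, 2, 0) is toy_alignment

    def test_removes_block(self):
        aln = make_alignment([("a", "x", "AACCGGTT")])
        out = strip_segment(aln, 3, 2)  # drop the CC block (1-based)
        assert out.sequences[0] == "AAGGTT"

    def test_duplication_removal_restores_target_length(self):
        # 700-column alignment with a 63-column insert at position 144
        seq = "A" * 700
        aln = make_alignment([("a", "x", seq), ("b", "x", seq)])
        out = strip_segment(aln, 144, 63)
        assert out.length == 637

    def test_out_of_range_rejected(self, toy_alignment):
        with pytest.raises(CoordinateError):
            strip_segment(toy_alignment, 5, 1)
        with pytest.raises(CoordinateError):
            strip_segment(toy_alignment, 2, 99)


class TestCollapseHaplotypes:
    def test_counts_by_inspection(self):
        aln = make_alignment(
            [("a", "x", "ACGT"), ("b", "x", "ACGT"), ("c", "x", "ACGA")]
        )
        ht = collapse_haplotypes(aln)
        assert ht.k == 2
        assert sorted(ht.counts.sum(axis=1)) == [1, 2]
        assert ht.total_n == 3

    def test_all_identical_single_haplotype(self):
        aln = make_alignment([(f"s{i}", "x", "ACGT") for i in range(5)])
        assert collapse_haplotypes(aln).k == 1

    def test_missing_tolerant_vs_strict(self):
        aln = make_alignment([("a", "x", "ACGT"), ("b", "x", "ACGN")])
        assert collapse_haplotypes(aln, "ignore_missing_sites").k == 1
        assert collapse_haplotypes(aln, "strict_identity").k == 2

    def test_marginals_match_site_sizes(self, small_dataset, small_haplotypes):
        ht = small_haplotypes
        per_site = {
            s: sum(1 for lab in small_dataset.alignment.site_labels if lab == s)
            for s in ht.site_labels
        }
        for j, s in enumerate(ht.site_labels):
            assert ht.counts[:, j].sum() == per_site[s]


class TestPairwiseDifferences:
    @pytest.mark.parametrize(
        "seqs,expected",
        [ (["ACGT", "ACGA"], 1), (["ACGT", "ACGT"], 0), (["AAAA", "TTTT"], 4) ],
    )
    def test_simple_counts(self, seqs, expected):
        dm = pairwise_differences(seqs)
        assert dm.values[0, 1] == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT-N", min_size=12, max_size=12),
            min_size=2,
            max_size=8,
        )
    )
    def test_matches_brute_force_oracle(self, seqs):
        oracle = brute_force_differences(seqs)
        # pairs with no jointly-called site are undefined by contract
        try:
            dm = pairwise_differences(seqs)
        except UndefinedDistanceError:
            mat = np.array([[c in "-N" for c in s] for s in seqs])
            overlap = (~mat[:, None] & ~mat[None, :]).sum(axis=2)
            assert (overlap[np.triu_indices(len(seqs), 1)] == 0).any()
            return
        assert np.array_equal(dm.values, oracle)

    def test_strict_rule_counts_missing_as_state(self):
        dm = pairwise_differences(["ACGT", "ACGN"], missing_rule="strict_identity")
        assert dm.values[0, 1] == 1

    def test_p_distance_range(self):
        dm = pairwise_differences(["AAAA", "TTAA"], metric="p_distance")
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_no_overlap_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            pairwise_differences(["AC--", "--GT"])


class TestGroupDistances:
    def test_group_against_itself_has_zero_net(self):
        seqs = ["AAAA", "AATT", "ATTT"]
        labels = ["a1", "a2", "a3"]
        dm = pairwise_differences(seqs, labels=labels)
        within, between, net = group_distances(dm, {"X": labels, "Y": list(labels)})
        assert net == pytest.approx(0.0)
        assert between == pytest.approx(within["X"])

    def test_symmetric_in_group_order(self):
        seqs = ["AAAA", "AATT", "TTTT", "TTAA", "ATAT", "TATA"]
        labels = [f"s{i}" for i in range(6)]
        dm = pairwise_differences(seqs, labels=labels)
        part = {"X": labels[:3], "Y": labels[3:]}
        _, _, net1 = group_distances(dm, part)
        _, _, net2 = group_distances(dm, {"Y": labels[3:], "X": labels[:3]})
        assert net1 == pytest.approx(net2)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(6)]
        labels = [f"s{i}" for i in range(6)]
        dm = pairwise_differences(seqs, labels=labels)
        part = {"X": labels[:2], "Y": labels[2:]}
        within, between, net = group_distances(dm, part)
        # independent hand enumeration
        d = brute_force_differences(seqs)
        wX = d[0, 1]
        pairs_Y = [(i, j) for i in range(2, 6) for j in range(i + 1, 6)]
        wY = np.mean([d[i, j] for i, j in pairs_Y])
        bt = np.mean([d[i, j] for i in range(2) for j in range(2, 6)])
        assert within["X"] == pytest.approx(wX)
        assert within["Y"] == pytest.approx(wY)
        assert between == pytest.approx(bt)
        assert net == pytest.approx(bt - (wX + wY) / 2)

    def test_singleton_group_flagged(self):
        seqs = ["AAAA", "AATT", "TTTT"]
        dm = pairwise_differences(seqs, labels=["a", "b", "c"])
        with pytest.warns(UserWarning):
            within, _, net = group_distances(dm, {"X": ["a"], "Y": ["b", "c"]})
        assert np.isnan(within["X"])
        assert np.isnan(net)
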