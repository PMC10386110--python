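"""Alignment, substitution calling, V-region mapping, TN93 and neighbor joining."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from oxymet.mutscan import (
    AlignmentResult,
    SaturationError,
    SequenceRecord,
    call_substitutions,
    global_align,
    load_region_map,
    map_to_regions,
    neighbor_joining,
    position_map,
    scan_series,
    tn93_distance,
    tn93_matrix,
)
from oxymet.synthdata import SimConfig, gen_16s_series, sequence_preset

from conftest import gotoh_free_end_score, random_additive_matrix

REGIONS = load_region_map()


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _phylo_distances(newick, labels):
    tree = Phylo.read(io.StringIO(newick), "newick")
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            out[frozenset((a, b))] = tree.distance(a, b)
    return out


class TestGlobalAlign:
    def test_identical_sequences_score_two_per_base(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.score == 16
        assert aln.query_aligned == aln.ref_aligned

    def test_single_mismatch(self):
        aln = global_align("ACGT", "AGGT")
        assert aln.score == 5  # 3 matches x2 - 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_score_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(30):
            q = _random_seq(rng, int(rng.integers(5, 31)))
            r = _random_seq(rng, int(rng.integers(5, 31)))
            assert global_align(q, r).score == pytest.approx(
                gotoh_free_end_score(q, r)
            ), (q, r)


class TestCallSubstitutions:
    def test_identical_sequences_call_nothing(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert call_substitutions(aln) == []

    def test_planted_substitution_with_exact_coordinates(self):
        ref = "ACGTACGTACGT"
        query = ref[:5] + "G" + ref[6:]  # position 6: C -> G
        (call,) = call_substitutions(global_align(query, ref))
        assert (call.query_position, call.ref_position) == (6, 6)
        assert (call.ref_base, call.alt_base) == ("C", "G")

    def test_gap_and_ambiguity_columns_are_never_called(self, rng):
        for _ in range(20):
            ref = _random_seq(rng, 60)
            # delete a block and sprinkle Ns into the query
            query = list(ref[:20] + ref[30:])
            for pos in rng.choice(len(query), size=5, replace=False):
                query[pos] = "N"
            aln = global_align("".join(query), ref)
            for call in call_substitutions(aln):
                assert call.ref_base in "ACGT" and call.alt_base in "ACGT"
            cols = list(zip(aln.query_aligned, aln.ref_aligned))
            called = {(c.query_position, c.ref_position) for c in call_substitutions(aln)}
            qpos = rpos = 0
            for qc, rc in cols:
                qpos += qc != "-"
                rpos += rc != "-"
                if (qpos, rpos) in called and (qc == "-" or rc == "-" or "N" in (qc, rc)):
                    pytest.fail("called a gap or ambiguity column")

    def test_untrusted_positions_are_masked_out(self):
        ref = "ACGTACGT"
        query = "AGGTACGT"  # substitution at position 2
        aln = global_align(query, ref)
        mask = tuple(i != 1 for i in range(len(query)))
        assert call_substitutions(aln, query_mask=mask) == []
        assert len(call_substitutions(aln)) == 1

    def test_self_comparison_is_empty_for_any_mask(self, rng):
        seq = _random_seq(rng, 40)
        mask = tuple(bool(b) for b in rng.integers(0, 2, size=40))
        aln = global_align(seq, seq)
        assert call_substitutions(aln, query_mask=mask, ref_mask=mask) == []


class TestRegions:
    @pytest.mark.parametrize("pos,label", [(1, "conserved"), (180, "V2"), (1350, "V9"),
                                           (100, "conserved"), (69, "V1"), (1435, "V9")])
    def test_coordinate_labelling(self, pos, label):
        assert map_to_regions(pos, REGIONS) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            map_to_regions(0, REGIONS)
        with pytest.raises(ValueError):
            map_to_regions(2000, REGIONS, ref_length=1542)

    def test_position_map_shifts_across_deletions(self):
        ref = "AAAACCCCGGGGTTTT"
        query = ref[:4] + ref[8:]  # query lacks the CCCC block
        mapping = position_map(query, ref)
        assert mapping[4] == 4
        assert mapping[5] == 9  # first G in the query is ref position 9


class TestScanSeries:
    def test_planted_series_recovers_week_and_region(self):
        reference, series, truth = sequence_preset("rhodococcus_o3", seed=0)
        calls = scan_series(series, coord_reference=reference)
        assert len(calls) == 2
        by_week = {c.sample_id: c for c in calls}
        first, second = sorted(by_week)
        assert (by_week[first].ref_base, by_week[first].alt_base) == ("T", "G")
        assert by_week[first].region_label == "V2"
        assert (by_week[second].ref_base, by_week[second].alt_base) == ("C", "T")
        assert by_week[second].region_label == "V9"
        assert {(c.ref_position) for c in calls} == {t.position for t in truth}

    def test_clean_series_calls_nothing(self):
        reference, series, truth = sequence_preset("streptomyces", seed=0)
        assert truth == []
        assert scan_series(series, coord_reference=reference) == []

    def test_planted_substitutions_recovered_exactly(self, rng):
        """q <= 5 isolated substitutions in a 1 kb series: exact recovery."""
        for seed in range(10):
            local = np.random.default_rng(seed)
            q = int(local.integers(1, 6))
            positions = sorted(local.choice(np.arange(10, 990), size=q, replace=False))
            config = SimConfig(seed=seed, seq_length=1000, strain_divergence=0.0)
            scenarios = []
            for pos in positions:
                ref, alt = local.choice(list("ACGT"), size=2, replace=False)
                scenarios.append((2, int(pos), str(ref), str(alt)))
            reference, series, truth = gen_16s_series(
                config, scenarios, weeks=(1, 2)
            )
            calls = scan_series(series, coord_reference=reference)
            assert sorted(c.ref_position for c in calls) == [t.position for t in truth]
            assert {(c.ref_position, c.ref_base, c.alt_base) for c in calls} == {
                (t.position, t.ref, t.alt) for t in truth
            }


class TestTn93:
    def test_identical_sequences_have_zero_distance(self, rng):
        seq = _random_seq(rng, 200)
        assert tn93_distance(seq, seq) == 0.0

    def test_symmetry(self, rng):
        a, b = _random_seq(rng, 500), None
        b = list(a)
        for pos in rng.choice(500, size=30, replace=False):
            b[pos] = rng.choice([c for c in "ACGT" if c != a[pos]])
        b = "".join(b)
        assert tn93_distance(a, b) == pytest.approx(tn93_distance(b, a), rel=1e-12)

    def test_reduces_to_jukes_cantor_in_the_equal_rate_limit(self):
        """Uniform base composition + equal counts of all 12 substitution
        types makes TN93 collapse onto the Jukes-Cantor closed form."""
        a, b = [], []
        for base in "ACGT":
            a += [base] * 30
            b += [base] * 30
        for x in "ACGT":
            for y in "ACGT":
                if x != y:
                    a.append(x)
                    b.append(y)
        a, b = "".join(a), "".join(b)
        p = 12 / len(a)
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert tn93_distance(a, b) == pytest.approx(jc, abs=1e-9)

    def test_recovers_the_simulated_branch_length(self):
        """Distance estimated from a pair simulated under the model itself."""
        from scipy.linalg import expm

        rng = np.random.default_rng(12)
        pi = np.array([0.3, 0.2, 0.3, 0.2])  # A C G T
        alpha1, alpha2, beta = 4.0, 2.0, 1.0  # A<->G, C<->T, transversions
        rates = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                purine = {0, 2}
                if {i, j} == purine:
                    r = alpha1
                elif {i, j} == {1, 3}:
                    r = alpha2
                else:
                    r = beta
                rates[i, j] = r * pi[j]
        np.fill_diagonal(rates, -rates.sum(axis=1))
        mu = -np.sum(pi * np.diag(rates))
        t_true = 0.1
        P = expm(rates / mu * t_true)
        n = 10_000
        anc = rng.choice(4, size=n, p=pi)
        child = np.array([rng.choice(4, p=P[x]) for x in anc])
        bases = np.array(list("ACGT"))
        d = tn93_distance("".join(bases[anc]), "".join(bases[child]))
        assert abs(d - t_true) < 0.015  # ~3 standard errors at this length

    def test_gapped_and_ambiguous_columns_are_dropped(self):
        assert tn93_distance("AC-GN", "ACCGT") == 0.0

    def test_saturation_is_an_explicit_error(self):
        with pytest.raises(SaturationError):
            tn93_distance("A" * 100, "G" * 100)


class TestNeighborJoining:
    def test_three_taxa_solve_the_closed_form(self):
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        newick = neighbor_joining(D)
        got = _phylo_distances(newick, list("ABC"))
        assert got[frozenset("AB")] == pytest.approx(3.0)
        assert got[frozenset("AC")] == pytest.approx(4.0)
        assert got[frozenset("BC")] == pytest.approx(5.0)

    def test_four_point_matrix_recovers_split_and_lengths(self):
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        newick = neighbor_joining(D)
        got = _phylo_distances(newick, list("ABCD"))
        for pair, expected in (("AB", 3), ("AC", 5), ("AD", 6), ("BC", 6), ("BD", 7), ("CD", 7)):
            assert got[frozenset(pair)] == pytest.approx(float(expected))

    def test_additive_matrices_are_reproduced_exactly(self, rng):
        for seed in range(20):
            local = np.random.default_rng(seed)
            n = int(local.integers(4, 9))
            labels, mat = random_additive_matrix(local, n)
            newick = neighbor_joining(mat, labels=labels)
            got = _phylo_distances(newick, labels)
            for a in range(n):
                for b in range(a + 1, n):
                    assert got[frozenset((labels[a], labels[b]))] == pytest.approx(
                        mat[a, b], abs=1e-8
                    )

    def test_agrees_with_the_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj

        for seed in range(5):
            local = np.random.default_rng(100 + seed)
            labels, mat = random_additive_matrix(local, 6)
            ours = _phylo_distances(neighbor_joining(mat, labels=labels), labels)
            theirs_tree = nj(DistanceMatrix(mat, labels))
            for a in range(6):
                for b in range(a + 1, 6):
                    theirs = theirs_tree.find(labels[a]).distance(theirs_tree.find(labels[b]))
                    assert ours[frozenset((labels[a], labels[b]))] == pytest.approx(
                        theirs, abs=1e-8
                    )

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0.0, 1.0], [1.0, 0.0]]))
        bad = np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(bad)


def test_tn93_matrix_is_symmetric_with_zero_diagonal(rng):
    seqs = []
    base = _random_seq(rng, 300)
    for i in range(4):
        s = list(base)
        for pos in rng.choice(300, size=10 + 5 * i, replace=False):
            s[pos] = rng.choice([c for c in "ACGT" if c != base[pos]])
        seqs.append(SequenceRecord(id=f"s{i}", bases="".join(s)))
    mat = tn93_matrix(seqs)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 0)


def test_sequence_record_validation():
    with pytest.raises(ValueError):
        SequenceRecord(id="x", bases="ACGZ")
    with pytest.raises(ValueError):
        SequenceRecord(id="x", bases="ACG", quality_mask=(True,))
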