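"""Distance models: counts, K2P/TrN+G corrections, summaries, histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodedelim.distances import (
    DistanceModelConfig,
    distance_histogram,
    distance_matrix,
    estimate_base_frequencies,
    evolutionary_distance,
    group_summary,
    pairwise_counts,
    PairwiseCounts,
    saturation_profile,
)
from barcodedelim.errors import AssignmentError, ConfigurationError, DegeneratePairError
from conftest import make_alignment


class TestPairwiseCounts:
    def test_direct_count_example(self):
        a = make_alignment([("i", "ACGTACGTAC"), ("j", "GCGTACGTAT")])
        c = pairwise_counts(a, "i", "j")
        assert c.n_valid == 10
        assert c.n_transitions_purine == 1  # A<->G at column 1
        assert c.n_transitions_pyrimidine == 1  # C<->T at column 10
        assert c.n_transversions == 0
        assert c.P == pytest.approx(0.2) and c.Q == 0.0

    def test_identical_sequences(self):
        a = make_alignment([("i", "ACGT"), ("j", "ACGT")])
        c = pairwise_counts(a, "i", "j")
        assert c.P == 0.0 and c.Q == 0.0

    def test_ambiguous_column_dropped_pairwise(self):
        a = make_alignment([("i", "ACGTN"), ("j", "ACGTA")])
        assert pairwise_counts(a, "i", "j").n_valid == 4

    def test_no_shared_columns_is_degenerate(self):
        a = make_alignment([("i", "NNAA"), ("j", "AANN")])
        with pytest.raises(DegeneratePairError):
            pairwise_counts(a, "i", "j")


class TestEvolutionaryDistance:
    def test_p_distance_is_p_plus_q(self):
        c = PairwiseCounts(10, 1, 1, 0)
        assert evolutionary_distance(c, DistanceModelConfig(model="p")) == pytest.approx(0.2)

    def test_k2p_closed_form_spot_value(self):
        # P=0.1, Q=0.05: -0.5*ln(0.75) - 0.25*ln(0.9) = 0.17018
        c = PairwiseCounts(100, 5, 5, 5)
        d = evolutionary_distance(c, DistanceModelConfig(model="K2P"))
        assert d == pytest.approx(-0.5 * math.log(0.75) - 0.25 * math.log(0.9))
        assert d == pytest.approx(0.17018, abs=5e-6)

    def test_trn_reduces_to_k2p_at_equal_frequencies(self):
        # equal base frequencies, P1 = P2, alpha -> infinity
        c = PairwiseCounts(200, 10, 10, 10)
        k2p = evolutionary_distance(c, DistanceModelConfig(model="K2P"))
        trn = evolutionary_distance(
            c,
            DistanceModelConfig(
                model="TrN+G", alpha=1e7, base_frequencies=(0.25, 0.25, 0.25, 0.25)
            ),
        )
        assert trn == pytest.approx(k2p, abs=1e-6)

    def test_saturated_pair_flagged_not_raised(self):
        c = PairwiseCounts(10, 3, 3, 3)  # 2P + Q = 1.5 > 1
        assert math.isnan(evolutionary_distance(c, DistanceModelConfig(model="K2P")))

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            DistanceModelConfig(model="JC+wrong")


class TestDistanceMatrix:
    def test_two_sample_p_distance(self):
        a = make_alignment([("i", "ACGTACGTAC"), ("j", "ACGAACGAAC")])
        m = distance_matrix(a, DistanceModelConfig(model="p"))
        assert m.d[0, 1] == pytest.approx(0.2)

    def test_identical_sequences_zero_matrix(self):
        a = make_alignment([(s, "ACGTACGT") for s in "xyz"])
        m = distance_matrix(a, DistanceModelConfig(model="K2P"))
        assert np.allclose(m.d, 0.0)

    def test_symmetry_zero_diagonal_and_p_below_k2p(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 60)]) for _ in range(8)]
        a = make_alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
        for model in ("p", "K2P"):
            m = distance_matrix(a, DistanceModelConfig(model=model))
            assert np.allclose(m.d, m.d.T, equal_nan=True)
            assert np.all(np.diag(m.d) == 0)
        mp = distance_matrix(a, DistanceModelConfig(model="p"))
        mk = distance_matrix(a, DistanceModelConfig(model="K2P"))
        defined = ~np.isnan(mk.d)
        assert np.all(mp.d[defined] <= mk.d[defined] + 1e-12)
        # equality iff identical pair
        off = np.triu_indices(mp.n, 1)
        for i, j in zip(*off):
            if defined[i, j] and mp.d[i, j] > 0:
                assert mk.d[i, j] > mp.d[i, j]

    def test_trn_uses_alignment_frequencies_by_default(self):
        a = make_alignment([("i", "AAACCCGGGTTT"), ("j", "AAACCCGGGTTA")])
        m = distance_matrix(a, DistanceModelConfig(model="TrN+G", alpha=1.0))
        assert m.model.base_frequencies == pytest.approx(
            estimate_base_frequencies(a), abs=1e-12
        )
        assert np.isfinite(m.d[0, 1])


class TestGroupSummary:
    def _matrix(self):
        a = make_alignment(
            [
                ("a1", "AAAAAAAAAA"),
                ("a2", "AAAAAAAAAG"),
                ("b1", "GGGGGGGGGG"),
                ("b2", "GGGGGGGGGA"),
            ]
        )
        return distance_matrix(a, DistanceModelConfig(model="p"))

    def test_per_group_averages(self):
        m = self._matrix()
        part = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        s = group_summary(m, part)
        assert s.per_group_intra == pytest.approx({"A": 0.1, "B": 0.1})
        assert s.intra.mean == pytest.approx(0.1)
        assert s.inter.mean == pytest.approx((0.9 + 1.0 + 1.0 + 0.9) / 4)
        assert s.clean_gap

    def test_single_group_has_empty_inter(self):
        m = self._matrix()
        s = group_summary(m, {i: "X" for i in m.ids})
        assert s.inter is None
        assert s.intra.mean == pytest.approx(s.overall.mean)

    def test_singleton_groups_contribute_no_intra(self):
        m = self._matrix()
        s = group_summary(m, {"a1": "A", "a2": "A", "b1": "B", "b2": "C"})
        assert set(s.per_group_intra) == {"A"}

    def test_missing_assignment_is_error(self):
        m = self._matrix()
        with pytest.raises(AssignmentError):
            group_summary(m, {"a1": "A"})

    def test_all_pairs_semantics_differ_when_groups_uneven(self):
        m = self._matrix()
        part = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        s_all = group_summary(m, part, semantics="all-pairs")
        assert s_all.intra.n == 2  # raw pair values, not per-group averages


class TestHistogramAndSaturation:
    def test_bin_counts_conserve_pairs(self, easy_k2p):
        h = distance_histogram(easy_k2p, 0.02)
        n = easy_k2p.n
        assert h["count"].sum() == n * (n - 1) // 2 - len(easy_k2p.undefined_pairs)

    def test_half_open_bins(self):
        a = make_alignment(
            [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAG"), ("c", "GGGGAAAAAA")]
        )
        m = distance_matrix(a, DistanceModelConfig(model="p"))
        h = distance_histogram(m, 0.1).set_index("bin_left")["count"]
        assert h.loc[0.1] == 1  # d(a,b)=0.1 falls in [0.1, 0.2)
        assert h.loc[0.4] == 1  # d(a,c)=0.4

    def test_gap_region_empty_for_clustered_data(self, easy_dataset, easy_k2p):
        max_intra, min_inter = easy_dataset.realized_gap
        vals = easy_k2p.offdiag_values()
        assert not np.any((vals > max_intra) & (vals < min_inter))

    def test_codon_position_subset(self):
        a = make_alignment([("i", "ACGTACGTA"), ("j", "ACGTACGTA")])
        prof = saturation_profile(a, codon_positions={1, 2})
        # 9 columns, positions {1,2} -> 6 columns used
        assert prof.iloc[0]["transitions"] + prof.iloc[0]["transversions"] == 0

    def test_transitions_plateau_transversions_grow(self):
        # evolve pairs at increasing divergence under the simulator's TrN
        from barcodedelim.simulate import SimulationParams, simulate_alignment
        from barcodedelim.trees import parse_newick

        p = SimulationParams(seq_length=20000, alpha=1e6, duplicate_fraction=0.0)
        rows = []
        for t in (0.05, 0.4, 1.2):
            tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
            aln = simulate_alignment(tree, p, seed=42)
            c = pairwise_counts(aln, "A", "B")
            rows.append((c.P, c.Q))
        # transversions keep growing; transition share saturates
        assert rows[0][1] < rows[1][1] < rows[2][1]
        assert rows[2][0] - rows[1][0] < rows[1][0] - rows[0][0]
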