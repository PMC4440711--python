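"""Splits, confusion metrics, grid-search CV, ROC/KS and position refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwmcleave import (
    CVConfig,
    InputError,
    ProteinSubstrate,
    SubstrateRecord,
    build_pwm,
    compute_frequencies,
    compute_metrics,
    evaluate_peptides,
    grid_search_cv,
    kfold_partition,
    ks_separation,
    refine_cleavage_positions,
    roc_auc,
    sample_protein_negatives,
    split_train_test,
    uniform_motif,
)
from pwmcleave.selection import score_labeled_bonds
from pwmcleave.simulate import MotifSpec, generate_background, generate_substrates


def _records(n, seed=0):
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return [
        SubstrateRecord(enzyme="E", sequence="".join(rng.choice(alphabet, size=17)),
                        cleavage_index=7)
        for _ in range(n)
    ]


class TestSplits:
    def test_two_to_one_split_sizes(self):
        train, test = split_train_test(_records(300), fraction=2 / 3, seed=1)
        assert len(train) == 200 and len(test) == 100

    def test_split_is_disjoint_exhaustive_and_reproducible(self):
        records = _records(50)
        a = split_train_test(records, seed=9)
        b = split_train_test(records, seed=9)
        assert a == b
        train, test = a
        joined = {id(r) for r in train} | {id(r) for r in test}
        assert len(joined) == 50 and not ({id(r) for r in train} & {id(r) for r in test})

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_fractions_rejected(self, fraction):
        with pytest.raises(InputError):
            split_train_test(_records(10), fraction=fraction)

    def test_leave_one_out_partition(self):
        folds = kfold_partition(_records(10), k=10, seed=0)
        assert [len(f) for f in folds] == [1] * 10

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = kfold_partition(_records(23), k=10, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 7 + [3] * 3

    def test_partition_law(self):
        records = _records(23)
        folds = kfold_partition(records, k=5, seed=3)
        ids = [id(r) for fold in folds for r in fold]
        assert sorted(ids) == sorted(id(r) for r in records)

    def test_too_few_substrates_rejected(self):
        with pytest.raises(InputError):
            kfold_partition(_records(5), k=10)


class TestComputeMetrics:
    def test_hand_computed_confusion_table(self):
        m = compute_metrics(tp=9, fp=1, tn=89, fn=1)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.fpr == pytest.approx(1 / 90)
        assert m.precision == pytest.approx(0.9)
        assert m.accuracy == pytest.approx(0.98)
        assert m.specificity == pytest.approx(89 / 90)
        assert m.mcc == pytest.approx(800 / 900)
        assert m.f1 == pytest.approx(0.9)
        assert not m.flagged

    def test_perfect_classifier(self):
        m = compute_metrics(tp=10, fp=0, tn=90, fn=0)
        assert (m.sensitivity, m.specificity, m.precision, m.mcc, m.f1) == (1, 1, 1, 1, 1)

    def test_no_predicted_positives_is_flagged(self):
        m = compute_metrics(tp=0, fp=0, tn=10, fn=5)
        assert "precision" in m.flagged and "mcc" in m.flagged
        assert m.precision == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            compute_metrics(tp=-1, fp=0, tn=0, fn=0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, derandomize=True)
    def test_rate_invariants(self, tp, fp, tn, fn):
        m = compute_metrics(tp, fp, tn, fn)
        for rate in (m.sensitivity, m.specificity, m.accuracy, m.precision, m.fpr, m.f1):
            assert 0.0 <= rate <= 1.0
        assert -1.0 <= m.mcc <= 1.0
        if "fpr" not in m.flagged:
            assert m.fpr == pytest.approx(1.0 - m.specificity)


def _auc_oracle(pos, neg):
    """Brute-force Mann-Whitney pair counting with ties at 1/2."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 10.0, 11.0])
        labels = np.array([False, False, True, True])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)

    def test_tied_pair_counts_half(self):
        scores = np.array([2.0, 3.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.875)

    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_pair_counting_oracle(self, pos, neg):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([True] * len(pos) + [False] * len(neg))
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(_auc_oracle(pos, neg), abs=1e-12)

    def test_shuffled_labels_are_uninformative(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_one_class_input_rejected(self):
        with pytest.raises(InputError):
            roc_auc(np.array([1.0, 2.0]), np.array([True, True]))


def _ks_oracle(a, b):
    grid = sorted(set(a) | set(b))
    a, b = np.asarray(a, float), np.asarray(b, float)
    return max(abs((a <= x).mean() - (b <= x).mean()) for x in grid)


class TestKsSeparation:
    def test_identical_samples(self):
        assert ks_separation([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_disjoint_supports(self):
        assert ks_separation([1, 2], [3, 4]) == pytest.approx(1.0)

    def test_interleaved_samples(self):
        assert ks_separation([1, 3], [2, 4]) == pytest.approx(0.5)

    @given(
        a=st.lists(st.integers(-6, 6), min_size=1, max_size=10),
        b=st.lists(st.integers(-6, 6), min_size=1, max_size=10),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_ecdf_oracle(self, a, b):
        assert ks_separation(a, b) == pytest.approx(_ks_oracle(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            ks_separation([], [1.0])


class TestGridSearchCV:
    def test_single_cell_grid_returns_that_cell(self, planted_substrates, planted_background):
        config = CVConfig(k_folds=5, grid_offsets=(-5.0,), grid_thresholds=(1.0,), seed=2)
        result = grid_search_cv(planted_substrates, planted_background, config)
        assert result.best_offset == -5.0 and result.best_threshold == 1.0
        assert result.f1_grid.shape == (1, 1)

    def test_deterministic_under_seed(self, planted_substrates, planted_background):
        config = CVConfig(k_folds=5, seed=4)
        a = grid_search_cv(planted_substrates, planted_background, config)
        b = grid_search_cv(planted_substrates, planted_background, config)
        assert a.best_offset == b.best_offset and a.best_threshold == b.best_threshold
        assert a.f1_grid.equals(b.f1_grid)

    def test_strong_motif_reaches_high_f1(self, planted_substrates, planted_background):
        result = grid_search_cv(planted_substrates, planted_background, CVConfig(seed=2))
        assert result.best_mean_f1 >= 0.95

    def test_null_motif_f1_collapses_to_prevalence_bound(self):
        # background = foreground: fully uniform peptides with no constant
        # scaffold, so no window position is distinguishable from any other
        spec = MotifSpec(columns=uniform_motif(), flank_n="", flank_c="",
                         hexamer_len=17, bond_offset=7,
                         n_substrates=100, n_background=300, seed=5)
        substrates = generate_substrates(spec)
        background = generate_background(spec)
        result = grid_search_cv(substrates, background, CVConfig(k_folds=5, seed=5))
        # prevalence 1/13; an uninformative score cannot beat the
        # all-positive bound 2p/(1+p) ~ 0.14 by much
        assert result.f1_grid.values.max() <= 0.3

    def test_summary_uses_sample_sd(self, planted_substrates, planted_background):
        result = grid_search_cv(planted_substrates, planted_background, CVConfig(seed=2))
        f1s = [m.f1 for m in result.fold_metrics]
        assert result.summary.loc["f1", "mean"] == pytest.approx(np.mean(f1s))
        assert result.summary.loc["f1", "sd"] == pytest.approx(np.std(f1s, ddof=1))


class TestEvaluatePeptides:
    def test_self_evaluation_of_planted_motif_is_strong(self, planted_substrates,
                                                        planted_background):
        pwm = build_pwm(
            compute_frequencies(planted_substrates, planted_background),
            offset=-5.0, threshold=1.0,
        )
        metrics = evaluate_peptides(pwm, planted_substrates)
        assert metrics.f1 >= 0.95

    def test_all_positive_labels_rejected(self, toy_pwm):
        rec = SubstrateRecord(enzyme="E", sequence="ACDEF", cleavage_index=3)
        with pytest.raises(InputError):
            evaluate_peptides(toy_pwm, [rec])


class TestProteinSampling:
    def _proteins(self, seed=0):
        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(alphabet, size=700))
        return [ProteinSubstrate("p1", seq, (10, 100, 200, 300, 400))]

    def test_ratio_controls_negative_count(self):
        bonds = sample_protein_negatives(self._proteins(), ratio=100, seed=0)
        labels = [b.label for b in bonds]
        assert sum(labels) == 5
        assert len(labels) - sum(labels) == 500

    def test_sampling_is_reproducible_and_without_replacement(self):
        a = sample_protein_negatives(self._proteins(), ratio=50, seed=3)
        b = sample_protein_negatives(self._proteins(), ratio=50, seed=3)
        assert a == b
        negs = [(x.protein_index, x.p1_position) for x in a if not x.label]
        assert len(negs) == len(set(negs))

    def test_insufficient_pool_uses_all_negatives(self):
        prot = ProteinSubstrate("p", "ACDEFGHIKLMNPQRSTVWY", (5, 10))
        bonds = sample_protein_negatives([prot], ratio=100, seed=0)
        # 16 full-window bonds, 2 annotated -> only 14 negatives available
        assert sum(not b.label for b in bonds) == 14

    def test_fully_annotated_protein_contributes_no_negatives(self):
        prot = ProteinSubstrate("p", "ACDEFGHI", tuple(range(3, 7)))
        bonds = sample_protein_negatives([prot], ratio=100, seed=0)
        assert all(b.label for b in bonds)

    def test_scoring_skips_unscorable_windows(self, toy_pwm):
        prot = ProteinSubstrate("p", "ACDEFXGHIKLMNP", (9,))
        bonds = sample_protein_negatives([prot], ratio=100, seed=0)
        scores, labels = score_labeled_bonds(toy_pwm, [prot], bonds)
        assert len(scores) == len(labels) < len(bonds)


class TestRefineCleavagePositions:
    def _pwm_for(self, sequence, good_p1):
        """PWM scoring +5 for the window at good_p1 in sequence, -5 elsewhere."""
        from pwmcleave.alphabet import AA_INDEX

        matrix = np.full((20, 5), -1.0)
        window = sequence[good_p1 - 3 : good_p1 + 2]
        for j, aa in enumerate(window):
            matrix[AA_INDEX[aa], j] = 1.0
        from pwmcleave import PWM

        return PWM(enzyme="R", matrix=matrix, offset=-5.0, threshold=5.0)

    def test_reported_bond_above_threshold_is_kept(self):
        seq = "GGSGPSALDATASGAET"
        pwm = self._pwm_for(seq, 7)
        rec = SubstrateRecord(enzyme="E", sequence=seq, cleavage_index=7)
        corrected, n = refine_cleavage_positions(pwm, [rec])
        assert n == 0 and corrected[0].cleavage_index == 7

    def test_below_threshold_bond_moves_to_nearby_winner(self):
        seq = "GGSGPSALDATASGAET"
        pwm = self._pwm_for(seq, 9)  # true site two bonds downstream
        rec = SubstrateRecord(enzyme="E", sequence=seq, cleavage_index=7)
        corrected, n = refine_cleavage_positions(pwm, [rec], max_shift=4)
        assert n == 1 and corrected[0].cleavage_index == 9

    def test_no_winner_within_range_keeps_report(self):
        seq = "GGSGPSALDATASGAET"
        pwm = self._pwm_for(seq, 14)  # seven bonds away: out of reach
        rec = SubstrateRecord(enzyme="E", sequence=seq, cleavage_index=7)
        corrected, n = refine_cleavage_positions(pwm, [rec], max_shift=4)
        assert n == 0 and corrected[0].cleavage_index == 7

    def test_refinement_never_moves_far_and_never_lowers_score(self, toy_pwm):
        from pwmcleave import score_window

        rng = np.random.default_rng(17)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        records = [
            SubstrateRecord(enzyme="E", sequence="".join(rng.choice(alphabet, size=30)),
                            cleavage_index=int(rng.integers(3, 28)))
            for _ in range(40)
        ]
        corrected, _ = refine_cleavage_positions(toy_pwm, records, max_shift=4)
        for before, after in zip(records, corrected):
            shift = abs(after.cleavage_index - before.cleavage_index)
            assert shift <= 4
            if shift > 0:
                old = score_window(toy_pwm, before.window)
                new = score_window(toy_pwm, after.window)
                assert new >= old
                assert new >= toy_pwm.threshold
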