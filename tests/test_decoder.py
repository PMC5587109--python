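import itertools
import warnings

import numpy as np
import pytest

from p300composer import decoder as dec
from p300composer import session_runner as sr
from p300composer.matrix_engine import make_schedule
from p300composer.signal_sim import RecordingParams, bandpass, extract_epochs, synthesize_recording


def simulate_epochs(attended=(2, 3), n_seq=3, noise_sd=0.0, amplitude=5.0, seed=0):
    sched = make_schedule(6, 6, n_seq, seed=seed)
    p = RecordingParams(noise_sd=noise_sd, p300_amplitude=amplitude, seed=seed + 1)
    rec = bandpass(synthesize_recording(sched, attended, p))
    return extract_epochs(rec, attended)


class TestFeatures:
    def test_decimation_one_is_identity(self):
        eps = simulate_epochs(n_seq=1)
        feats = dec.build_features(eps, decimation=1)
        assert np.allclose(feats, eps.epochs.reshape(len(eps), -1))

    def test_feature_length_arithmetic(self):
        data = np.zeros((4, 6, 200))
        assert dec.build_features(data, decimation=10).shape == (4, 120)
        assert dec.build_features(data, decimation=12).shape == (4, 6 * 17)

    def test_constant_epoch_averages_to_constant(self):
        data = np.full((2, 3, 50), 2.5)
        assert np.allclose(dec.build_features(data, decimation=7), 2.5)

    def test_invalid_decimation(self):
        data = np.zeros((1, 2, 10))
        with pytest.raises(ValueError):
            dec.build_features(data, decimation=0)
        with pytest.raises(ValueError):
            dec.build_features(data, decimation=11)


class TestTraining:
    def test_separable_clouds_are_fully_separated(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(5, 0.1, (40, 8)), rng.normal(-5, 0.1, (40, 8))])
        y = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        clf = dec.train(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_permuted_labels_give_chance_level(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 10))
        y = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        accs = []
        for _ in range(100):
            perm = rng.permutation(200)
            clf = dec.train(X[perm[:150]], y[perm[:150]])
            accs.append((clf.predict(X[perm[150:]]) == y[perm[150:]]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 12))
        y = rng.random(60) > 0.5
        y[:2] = [True, False]
        c1, c2 = dec.train(X, y), dec.train(X, y)
        assert np.array_equal(c1.weights, c2.weights) and c1.bias == c2.bias

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dec.train(np.zeros((5, 3)), np.ones(5, bool))


class TestElementScoring:
    def test_noiseless_sequence_decodes_attended_element(self):
        eps = simulate_epochs(attended=(2, 3), n_seq=3)
        clf = dec.train(dec.build_features(eps), eps.labels)
        d = dec.score_elements(clf, eps.sequence(0), 6, 6)
        assert d.argmax == (2, 3)

    def test_tie_breaks_to_lowest_row_major_index(self):
        clf = dec.ErpClassifier(np.zeros(102), 0.0)  # every epoch scores 0
        eps = simulate_epochs(n_seq=1)
        d = dec.score_elements(clf, eps.sequence(0), 6, 6)
        assert d.argmax == (0, 0)

    def test_accumulated_scores_equal_sum_of_per_sequence_scores(self):
        eps = simulate_epochs(attended=(1, 4), n_seq=4, noise_sd=2.0)
        clf = dec.train(dec.build_features(eps), eps.labels)
        acc = None
        per_seq = []
        for s in range(4):
            single = dec.score_elements(clf, eps.sequence(s), 6, 6)
            per_seq.append(single.scores)
            acc = dec.score_elements(clf, eps.sequence(s), 6, 6, acc)
        assert np.allclose(acc.scores, np.sum(per_seq, axis=0))

    def test_missing_group_is_an_integrity_error(self):
        eps = simulate_epochs(n_seq=1)
        clf = dec.train(dec.build_features(simulate_epochs(n_seq=2)),
                        simulate_epochs(n_seq=2).labels)
        broken = eps.sequence(0)
        broken.epochs = broken.epochs[:-1]
        broken.group_kinds = broken.group_kinds[:-1]
        broken.group_indices = broken.group_indices[:-1]
        with pytest.raises(ValueError, match="missing"):
            dec.score_elements(clf, broken, 6, 6)


def brute_force_outcome(decisions, max_sequences):
    """Reference implementation of the stopping rule on a decision string:
    walk the string, check the three-in-a-row rule, reset at max_sequences."""
    window = []
    for i, d in enumerate(decisions):
        window.append(d)
        if len(window) >= 3 and window[-1] == window[-2] == window[-3]:
            return ("select", d, i + 1)
        if len(window) >= max_sequences:
            return ("reset", None, i + 1)
    return ("pending", None, len(decisions))


class TestDynamicStopping:
    @pytest.mark.parametrize(
        "decisions, expect",
        [
            ("AAA", ("select", "A", 3)),
            ("ABAAA", ("select", "A", 5)),
            ("ABABABABABABABA", ("reset", None, 15)),
        ],
    )
    def test_printed_stopping_examples(self, decisions, expect):
        outcome = brute_force_outcome(list(decisions), 15)
        assert outcome == expect
        # the controller-facing rule agrees
        history = []
        for i, d in enumerate(decisions):
            history.append(d)
            status = dec.dynamic_stop(history, 15)
            if status != dec.PENDING:
                break
        assert (status, i + 1) == (expect[0], expect[2])

    def test_exhaustive_equivalence_with_brute_force(self):
        """All decision strings of length <= 8 over a 3-symbol alphabet."""
        for length in range(1, 9):
            for s in itertools.product("ABC", repeat=length):
                ref_status, _, ref_n = brute_force_outcome(list(s), 8)
                history = []
                status = dec.PENDING
                for i, d in enumerate(s):
                    history.append(d)
                    status = dec.dynamic_stop(history, 8)
                    if status != dec.PENDING:
                        break
                n = i + 1 if status != dec.PENDING else length
                assert (status, n) == (ref_status, ref_n), s

    def test_minimum_sequences_is_three(self):
        assert dec.dynamic_stop(["A", "A"], 15) == dec.PENDING
        assert dec.dynamic_stop(["A", "A", "A"], 15) == dec.SELECT

    def test_max_sequences_below_three_rejected(self):
        with pytest.raises(ValueError):
            dec.dynamic_stop(["A"], 2)

    def test_no_selection_across_reset_boundary(self):
        """After a reset the controller needs three fresh agreements."""
        eps = simulate_epochs(attended=(0, 0), n_seq=1)
        clf = dec.train(dec.build_features(simulate_epochs(n_seq=3)),
                        simulate_epochs(n_seq=3).labels)
        ctrl = dec.SelectionController(clf, 6, 6, max_sequences=3, max_resets=5)
        # noiseless target (0,0): selects after exactly 3 sequences, not before
        res = None
        fed = 0
        while res is None:
            res = ctrl.feed_sequence(simulate_epochs(attended=(0, 0), n_seq=1,
                                                     seed=fed).sequence(0))
            fed += 1
        assert res.n_sequences_used == 3
        assert res.history[-3:] == [(0, 0)] * 3


class TestCalibration:
    def test_noiseless_calibration_is_perfect_at_all_sequence_counts(self, noiseless_system):
        user, system = noiseless_system
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            blocks, targets = sr.simulate_calibration(user, system, seed=11)
        rep = dec.calibrate_loo(blocks, targets, 6, 6)
        assert np.all(rep.accuracy == 100.0)
        assert rep.passed

    def test_report_matches_brute_force_re_decode(self, default_system):
        """Oracle equivalence: re-decode every held-out letter independently."""
        user, system = default_system
        blocks, targets = sr.simulate_calibration(user, system, seed=12)
        rep = dec.calibrate_loo(blocks, targets, 6, 6)

        ref = np.zeros(15)
        for held in range(6):
            train_set = None
            for i, b in enumerate(blocks):
                if i == held:
                    continue
                train_set = b if train_set is None else train_set.concat(b)
            clf = dec.train(dec.build_features(train_set), train_set.labels)
            for n in range(1, 16):
                total = None
                for s in range(n):
                    seq = blocks[held].sequence(s)
                    feats = dec.build_features(seq, clf.decimation)
                    scores = clf.decision_scores(feats)
                    rows, cols = np.zeros(6), np.zeros(6)
                    for kind, gi, sc in zip(seq.group_kinds, seq.group_indices, scores):
                        (rows if kind == "row" else cols)[gi] += sc
                    grid = rows[:, None] + cols[None, :]
                    total = grid if total is None else total + grid
                if divmod(int(np.argmax(total)), 6) == targets[held]:
                    ref[n - 1] += 1
        assert np.allclose(rep.accuracy, 100.0 * ref / 6)

    def test_fewer_than_two_blocks_rejected(self):
        with pytest.raises(ValueError):
            dec.calibrate_loo([simulate_epochs()], [(0, 0)], 6, 6)
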