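"""HMM machinery: bleach screening, EM fitting, decoding, rates, classification.

Forward likelihood and Viterbi decoding are checked against brute-force
enumeration over all state paths; the forward recursion is additionally
cross-checked against an independent HMM library.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from sti1dyn import hmm, studies, synthetic
from sti1dyn.hmm import HMMFit
from sti1dyn.synthetic import SimConfig, StateModel


def make_trace(donor, acceptor, frame_time=0.03):
    n = len(donor)
    return synthetic.FRETTrace(
        time=np.arange(n) * frame_time,
        donor=np.asarray(donor, float),
        acceptor=np.asarray(acceptor, float),
        frame_time=frame_time,
    )


def brute_force_loglik(fit: HMMFit, seq):
    """Exhaustive sum over all K^T state paths (oracle for the forward pass)."""
    k, t_len = fit.n_states, len(seq)
    total = 0.0
    for path in itertools.product(range(k), repeat=t_len):
        p = fit.start[path[0]] * stats.norm.pdf(seq[0], fit.means[path[0]], fit.sds[path[0]])
        for t in range(1, t_len):
            p *= fit.trans[path[t - 1], path[t]] * stats.norm.pdf(
                seq[t], fit.means[path[t]], fit.sds[path[t]]
            )
        total += p
    return np.log(total)


def brute_force_viterbi(fit: HMMFit, seq):
    k, t_len = fit.n_states, len(seq)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(k), repeat=t_len):
        lp = np.log(fit.start[path[0]]) + stats.norm.logpdf(
            seq[0], fit.means[path[0]], fit.sds[path[0]]
        )
        for t in range(1, t_len):
            lp += np.log(fit.trans[path[t - 1], path[t]]) + stats.norm.logpdf(
                seq[t], fit.means[path[t]], fit.sds[path[t]]
            )
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


def reference_fit(k=3):
    """A hand-specified fit object for decoding tests."""
    means = np.array([0.16, 0.52, 0.84])[:k]
    sds = np.full(k, 0.08)
    trans = np.full((k, k), 0.05)
    np.fill_diagonal(trans, 1.0 - 0.05 * (k - 1))
    start = np.full(k, 1.0 / k)
    return HMMFit(
        n_states=k, means=means, sds=sds, trans=trans, start=start,
        log_lik=0.0, n_iter=0,
    )


class TestBleachDetection:
    def test_constant_trace_has_no_steps(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.poisson(500, 200), rng.poisson(500, 200))
        assert hmm.detect_bleach_steps(tr) == []

    def test_single_donor_bleach_located(self):
        rng = np.random.default_rng(1)
        b = 70
        donor = np.concatenate([rng.poisson(500, b), rng.poisson(15, 130)])
        acceptor = np.concatenate([rng.poisson(500, b), rng.poisson(15, 130)])
        steps = hmm.detect_bleach_steps(make_trace(donor, acceptor))
        assert len(steps) == 1
        assert steps[0].channel == "donor"
        assert abs(steps[0].frame - b) <= 2

    def test_acceptor_bleach_reroutes_to_donor(self):
        rng = np.random.default_rng(2)
        b = 60
        donor = np.concatenate([rng.poisson(500, b), rng.poisson(1000, 140)])
        acceptor = np.concatenate([rng.poisson(500, b), rng.poisson(15, 140)])
        steps = hmm.detect_bleach_steps(make_trace(donor, acceptor))
        assert len(steps) == 1
        assert steps[0].channel == "acceptor"
        assert abs(steps[0].frame - b) <= 2

    def test_double_bleach_yields_two_steps_for_discard(self):
        rng = np.random.default_rng(3)
        ba, bd = 60, 140
        donor = np.concatenate(
            [rng.poisson(500, ba), rng.poisson(1000, bd - ba), rng.poisson(15, 200 - bd)]
        )
        acceptor = np.concatenate([rng.poisson(500, ba), rng.poisson(15, 200 - ba)])
        steps = hmm.detect_bleach_steps(make_trace(donor, acceptor))
        assert len(steps) == 2  # more than one step -> trace discarded upstream

    def test_generator_bleach_frame_recovered(self):
        m = StateModel(np.array([0.5]), np.array([0.02]), np.zeros((1, 1)))
        cfg = SimConfig(n_frames=300, brightness=2000.0, bleach_rate_d=0.25,
                        background_d=10.0, background_a=10.0)
        p = synthetic.simulate_state_path(m, 9.0, seed=0)
        for seed in range(30):
            tr = synthetic.simulate_tirf_trace(p, m, cfg, seed=seed)
            b = tr.meta["bleach_frame_d"]
            if b is not None and 30 < b < 270:
                break
        steps = hmm.detect_bleach_steps(tr)
        assert len(steps) == 1
        assert abs(steps[0].frame - b) <= 2


class TestPrepareTrace:
    def test_balanced_channels_give_constant_half(self):
        tr = make_trace(np.full(100, 400.0), np.full(100, 400.0))
        e = hmm.prepare_trace(tr, steps=[])
        np.testing.assert_allclose(e, 0.5)

    def test_truncates_at_first_bleach_even_if_acceptor(self):
        rng = np.random.default_rng(4)
        ba, bd = 60, 140
        donor = np.concatenate(
            [rng.poisson(500, ba), rng.poisson(1000, bd - ba), rng.poisson(15, 200 - bd)]
        )
        acceptor = np.concatenate([rng.poisson(500, ba), rng.poisson(15, 200 - ba)])
        e = hmm.prepare_trace(make_trace(donor, acceptor))
        assert len(e) == pytest.approx(ba, abs=2)

    def test_early_bleach_rejected(self):
        tr = make_trace(np.full(100, 400.0), np.full(100, 400.0))
        with pytest.raises(ValueError):
            hmm.prepare_trace(tr, steps=[hmm.BleachStep(frame=5, channel="donor")])

    def test_state_grouped_means_match_model(self):
        m = studies.sti1_hsp70_state_model()
        cfg = SimConfig(n_frames=2000, brightness=5000.0, background_d=20.0, background_a=20.0)
        path = synthetic.simulate_framewise_path(m, 2000, 0.03, seed=5)
        tr = synthetic.simulate_tirf_trace(path, m, cfg, seed=6)
        e = hmm.prepare_trace(tr, steps=[])
        occ = path.occupancy(0.03, 2000)
        true_state = occ.argmax(axis=1)
        for s in range(3):
            assert e[true_state == s].mean() == pytest.approx(m.efficiencies[s], abs=0.02)


class TestFitHmmGlobal:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(7)
        seqs = [rng.normal(0.4, 0.07, 120), rng.normal(0.4, 0.07, 80)]
        fit = hmm.fit_hmm_global(seqs, n_states=1, n_restarts=1)
        pooled = np.concatenate(seqs)
        assert fit.means[0] == pytest.approx(pooled.mean(), abs=1e-9)
        assert fit.sds[0] == pytest.approx(pooled.std(), abs=1e-9)

    def test_transition_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        seqs = [np.concatenate([rng.normal(0.2, 0.05, 50), rng.normal(0.8, 0.05, 50)])]
        fit = hmm.fit_hmm_global(seqs, n_states=2, n_restarts=3)
        np.testing.assert_allclose(fit.trans.sum(axis=1), 1.0, atol=1e-9)
        assert fit.start.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.means) > 0)  # label switching resolved by sorting

    def test_repeated_fits_are_identical(self):
        rng = np.random.default_rng(9)
        seqs = [np.concatenate([rng.normal(0.2, 0.05, 60), rng.normal(0.8, 0.05, 60)])]
        f1 = hmm.fit_hmm_global(seqs, n_states=2, n_restarts=4, seed=3)
        f2 = hmm.fit_hmm_global(seqs, n_states=2, n_restarts=4, seed=3)
        np.testing.assert_array_equal(f1.means, f2.means)
        np.testing.assert_array_equal(f1.trans, f2.trans)
        assert f1.log_lik == f2.log_lik

    def test_nan_input_rejected(self):
        with pytest.raises(ValueError):
            hmm.fit_hmm_global([np.array([0.1, np.nan] * 10)], n_states=2)

    def test_degenerate_states_warn_with_sd_floor(self):
        seqs = [np.full(60, 0.5)]
        with pytest.warns(RuntimeWarning):
            fit = hmm.fit_hmm_global(seqs, n_states=2, n_restarts=1, max_iter=10)
        assert np.all(fit.sds >= 1e-3)

    def test_forward_equals_path_enumeration(self):
        # likelihood oracle: exhaustive sum over all paths, T <= 8, K <= 3
        rng = np.random.default_rng(10)
        for k, t_len in [(2, 6), (3, 6), (2, 8), (3, 8)]:
            fit = reference_fit(k)
            seq = rng.uniform(0.0, 1.0, t_len)
            ll = hmm.loglik_sequence(fit, seq)
            assert ll == pytest.approx(brute_force_loglik(fit, seq), rel=1e-8)

    def test_forward_matches_independent_library(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        fit = reference_fit(3)
        rng = np.random.default_rng(11)
        seq = rng.uniform(0.0, 1.0, 200)
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        model.startprob_ = fit.start
        model.transmat_ = fit.trans
        model.means_ = fit.means[:, None]
        model.covars_ = (fit.sds**2)[:, None]
        assert hmm.loglik_sequence(fit, seq) == pytest.approx(
            model.score(seq[:, None]), rel=1e-8
        )

    def test_em_loglik_monotone_on_noisy_data(self):
        # the fitter raises AssertionError internally if EM ever decreases
        rng = np.random.default_rng(12)
        seqs = [
            np.concatenate([rng.normal(0.3, 0.1, 40), rng.normal(0.6, 0.1, 40)])
            for _ in range(5)
        ]
        fit = hmm.fit_hmm_global(seqs, n_states=2, n_restarts=5, max_iter=200)
        assert np.isfinite(fit.log_lik)

    def test_parameter_recovery_three_state(self):
        r = studies.hmm_recovery_study(seed=3, n_traces=30, n_frames=200, n_restarts=4)
        np.testing.assert_allclose(r["means"], r["truth"]["means"], atol=0.03)


class TestViterbi:
    def test_single_state_constant_path(self):
        fit = reference_fit(1)
        vr = hmm.viterbi_path(fit, np.random.default_rng(0).normal(0.16, 0.08, 50))
        assert np.all(vr.path == 0)

    def test_noiseless_well_separated_states_decoded_exactly(self):
        fit = reference_fit(3)
        true = np.array([0, 0, 0, 2, 2, 1, 1, 1, 0, 0])
        seq = fit.means[true]
        vr = hmm.viterbi_path(fit, seq)
        np.testing.assert_array_equal(vr.path, true)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(13)
        for k, t_len in [(2, 6), (3, 6)]:
            fit = reference_fit(k)
            seq = rng.uniform(0.0, 1.0, t_len)
            vr = hmm.viterbi_path(fit, seq)
            oracle_path, oracle_lp = brute_force_viterbi(fit, seq)
            np.testing.assert_array_equal(vr.path, oracle_path)
            assert vr.path_log_lik == pytest.approx(oracle_lp, rel=1e-8)

    def test_path_loglik_never_exceeds_forward_loglik(self):
        rng = np.random.default_rng(14)
        fit = reference_fit(3)
        for _ in range(5):
            seq = rng.uniform(0.0, 1.0, 30)
            vr = hmm.viterbi_path(fit, seq)
            assert vr.path_log_lik <= hmm.loglik_sequence(fit, seq) + 1e-12


class TestTransitionDensityAndRates:
    def test_static_paths_give_empty_density(self):
        fit = reference_fit(3)
        paths = [hmm.ViterbiResult(np.full(50, s), 0.0) for s in range(3)]
        td = hmm.transition_density(paths, fit)
        assert td.n_transitions == 0

    def test_three_state_data_populates_six_classes(self):
        r = studies.hmm_recovery_study(seed=4, n_traces=30, n_frames=200, n_restarts=3)
        td = hmm.transition_density(r["paths"], r["fit"])
        off = td.counts[~np.eye(3, dtype=bool)]
        assert np.all(off > 0)  # all K(K-1) = 6 transition classes observed
        assert np.all(np.diag(td.counts) == 0)
        assert td.n_transitions == r["rates"].counts.sum()

    def test_rate_conversion_first_order(self):
        fit = reference_fit(2)
        fit.trans = np.array([[0.865, 0.135], [0.1, 0.9]])
        rt = hmm.rates_from_fit(fit, [], frame_time=0.03)
        assert rt.rates[0, 1] == pytest.approx(4.5)
        assert np.all(np.diag(rt.rates) == 0)

    def test_diagonal_matrix_gives_zero_rates(self):
        fit = reference_fit(2)
        fit.trans = np.eye(2)
        rt = hmm.rates_from_fit(fit, [], frame_time=0.03)
        np.testing.assert_array_equal(rt.rates, 0.0)

    def test_matrix_log_inverts_exact_discretization(self):
        from scipy.linalg import expm

        q = np.array([[-6.0, 1.5, 4.5], [1.5, -2.4, 0.9], [1.0, 1.5, -2.5]])
        fit = reference_fit(3)
        fit.trans = expm(q * 0.03)
        rt = hmm.rates_from_fit(fit, [], frame_time=0.03, method="matrix_log")
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(rt.rates[off], q[off], rtol=1e-8)


class TestDynamicClassification:
    @staticmethod
    def _static_and_dynamic_sequences(n_static, n_dynamic, seed):
        rng = np.random.default_rng(seed)
        m = studies.sti1_hsp70_state_model()
        frozen = StateModel(m.efficiencies, m.widths, np.zeros((3, 3)))
        seqs = []
        for _ in range(n_static):
            s = int(rng.choice(3))
            seqs.append(np.clip(rng.normal(m.efficiencies[s], 0.08, 150), 0, 1))
        for _ in range(n_dynamic):
            p = synthetic.simulate_framewise_path(m, 150, 0.03, seed=rng)
            occ = p.occupancy(0.03, 150)
            states = occ.argmax(axis=1)
            seqs.append(np.clip(rng.normal(m.efficiencies[states], 0.08), 0, 1))
        return seqs

    def test_known_dynamic_fraction_recovered(self):
        seqs = self._static_and_dynamic_sequences(70, 30, seed=15)
        fit = hmm.fit_hmm_global(seqs, n_states=3, n_restarts=4, seed=1)
        paths = [hmm.viterbi_path(fit, s) for s in seqs]
        frac = hmm.fraction_dynamic(paths, fit=fit)
        assert frac == pytest.approx(30.0, abs=5.0)

    def test_static_false_positive_rate_low(self):
        seqs = self._static_and_dynamic_sequences(100, 0, seed=16)
        fit = reference_fit(3)  # decode against the well-separated state model
        paths = [hmm.viterbi_path(fit, s) for s in seqs]
        assert hmm.fraction_dynamic(paths, fit=fit) < 5.0

    def test_all_static_paths_zero_percent(self):
        paths = [hmm.ViterbiResult(np.full(40, 1), 0.0) for _ in range(10)]
        assert hmm.fraction_dynamic(paths) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hmm.fraction_dynamic([])
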