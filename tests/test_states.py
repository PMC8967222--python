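"""Diffusive-state mixture: likelihood, EM, selection, filtering, MSD, fractions."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smtkit import (
    AcquisitionProtocol,
    MotionState,
    SimulationModel,
    StateModel,
    filter_states,
    fit_pem,
    select_model,
    simulate_switching_tracks,
    state_msd,
    summarize_fractions,
)
from smtkit.states import _state_loglik, track_displacements

PROTO = AcquisitionProtocol(0.012, 0.010, n_frames=21, label="fast")


def toy_tracks(positions_by_track, protocol=PROTO):
    rows = []
    for tid, pos in positions_by_track.items():
        for f, (x, y) in enumerate(pos):
            rows.append((tid, f, x, y))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]), protocol


class TestDisplacements:
    def test_stationary_track_gives_zero_displacements(self):
        df, proto = toy_tracks({0: [(1.0, 2.0)] * 5})
        from smtkit.core import TrackSet

        disp = track_displacements(TrackSet(df, proto))
        (idx, X, Y) = disp.by_len[4]
        assert np.all(X == 0) and np.all(Y == 0)

    def test_displacement_arithmetic(self):
        df, proto = toy_tracks({0: [(0, 0), (1, 0), (1, 1)]})
        from smtkit.core import TrackSet

        disp = track_displacements(TrackSet(df, proto))
        (_, X, Y) = disp.by_len[2]
        assert X.tolist() == [[1.0, 0.0]]
        assert Y.tolist() == [[0.0, 1.0]]

    def test_counts_conserved_and_order_invariant(self):
        model = SimulationModel(
            states=(MotionState("free", 0.2),), initial_weights=(1.0,), seed=2
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=20)
        disp = track_displacements(tracks)
        assert disp.total_displacements == len(tracks.df) - tracks.n_tracks
        # shuffling whole tracks leaves per-track displacements identical
        order = np.random.default_rng(0).permutation(tracks.n_tracks)
        shuffled = pd.concat(
            [tracks.df[tracks.df.track_id == tid] for tid in np.asarray(tracks.track_ids)[order]],
            ignore_index=True,
        )
        from smtkit.core import TrackSet

        disp2 = track_displacements(TrackSet(shuffled, PROTO))
        for tid in tracks.track_ids:
            i = int(np.flatnonzero(disp.track_ids == tid)[0])
            j = int(np.flatnonzero(disp2.track_ids == tid)[0])
            assert disp.ssq[i] == disp2.ssq[j]


class TestLikelihood:
    def test_tridiagonal_matches_dense_mvn(self):
        rng = np.random.default_rng(0)
        df, proto = toy_tracks(
            {t: [(rng.normal(0, 0.1), rng.normal(0, 0.1)) for _ in range(4)] for t in range(6)}
        )
        from smtkit.core import TrackSet

        disp = track_displacements(TrackSet(df, proto))
        dt = proto.frame_interval_s
        for D, eps2 in [(0.3, 5e-4), (0.5, -7.7e-4), (0.01, 8.5e-4)]:
            ll = _state_loglik(disp, D, eps2)
            var = 2 * D * dt + 2 * eps2
            cov = np.diag([var] * 3) + np.diag([-eps2] * 2, 1) + np.diag([-eps2] * 2, -1)
            mvn = sps.multivariate_normal(np.zeros(3), cov)
            (idx, X, Y) = disp.by_len[3]
            dense = mvn.logpdf(X) + mvn.logpdf(Y)
            assert np.max(np.abs(ll[idx] - dense) / np.abs(dense)) < 1e-10


class TestFitPem:
    def test_single_state_matches_moment_oracle(self):
        model = SimulationModel(
            states=(MotionState("free", 0.5),),
            initial_weights=(1.0,),
            localization_sigma_um=0.03,
            seed=17,
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=1000)
        disp = track_displacements(tracks)
        # brute-force covariance-based oracle from the same displacements
        d_oracle = (
            disp.ssq.sum() / disp.n0.sum() + 2 * disp.scross.sum() / disp.n1.sum()
        ) / (2 * disp.dt)
        fit = fit_pem(tracks, K=1, n_restarts=1, n_perturbations=2, seed=17)
        assert abs(fit.diffusivities[0] - d_oracle) / d_oracle < 0.05

    def test_two_state_assignment_accuracy(self):
        model = SimulationModel(
            states=(MotionState("bound", 0.02), MotionState("free", 0.5)),
            initial_weights=(0.3, 0.7),
            localization_sigma_um=0.03,
            seed=18,
        )
        tracks, gt = simulate_switching_tracks(model, PROTO, n_tracks=800)
        fit = fit_pem(tracks, K=2, n_restarts=2, n_perturbations=2, seed=18)
        truth = gt.step_labels.groupby("track_id")["state"].first()
        truth = truth.reindex(fit.track_ids).to_numpy()
        acc = np.mean((fit.posteriors.argmax(1) == 0) == (truth == "bound"))
        assert acc >= 0.95

    def test_all_zero_displacements_degenerate_limit(self):
        df, proto = toy_tracks({t: [(1.0, 1.0)] * 5 for t in range(12)})
        from smtkit.core import TrackSet

        fit = fit_pem(TrackSet(df, proto), K=1, n_restarts=1, n_perturbations=0)
        assert fit.diffusivities[0] == 0.0
        assert fit.epsilon_sq[0] == 0.0

    def test_requires_enough_tracks(self):
        df, proto = toy_tracks({t: [(0, 0), (1, 1)] for t in range(15)})
        from smtkit.core import TrackSet

        with pytest.raises(ValueError, match="at least"):
            fit_pem(TrackSet(df, proto), K=2)

    def test_em_runs_are_monotone(self):
        model = SimulationModel(
            states=(MotionState("bound", 0.02), MotionState("free", 0.5)),
            initial_weights=(0.3, 0.7),
            localization_sigma_um=0.03,
            seed=19,
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=500)
        fit = fit_pem(tracks, K=3, n_restarts=2, n_perturbations=3, seed=19)
        for h in fit.em_histories:
            d = np.diff(h)
            assert np.all(d >= -1e-9 * np.abs(h[:-1]))

    def test_states_sorted_ascending_and_valid(self):
        model = SimulationModel(
            states=(MotionState("free", 0.4), MotionState("bound", 0.01)),
            initial_weights=(0.6, 0.4),
            localization_sigma_um=0.03,
            seed=20,
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=400)
        fit = fit_pem(tracks, K=2, n_restarts=2, n_perturbations=1, seed=20)
        fit.validate()
        assert np.all(np.diff(fit.diffusivities) >= 0)
        assert abs(fit.posteriors.sum(1) - 1).max() < 1e-9


class TestSelectModel:
    def test_k_range_of_one_returns_that_fit(self):
        model = SimulationModel(
            states=(MotionState("free", 0.3),), initial_weights=(1.0,), seed=21
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=200)
        sel = select_model(tracks, [1], n_restarts=1, n_perturbations=1, seed=1)
        assert sel.K == 1
        assert len(sel.bic_table) == 1

    def test_bic_table_reports_all_k(self):
        model = SimulationModel(
            states=(MotionState("free", 0.3),), initial_weights=(1.0,), seed=22
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=200)
        sel = select_model(tracks, range(1, 4), n_restarts=1, n_perturbations=1, seed=1)
        assert sel.bic_table["K"].tolist() == [1, 2, 3]


def planted_model(populations, diffusivities, M=1000):
    """Construct a StateModel with near-hard posteriors in given proportions."""
    K = len(populations)
    counts = (np.asarray(populations) * M).astype(int)
    counts[0] += M - counts.sum()
    gamma = np.full((M, K), 0.02 / (K - 1))
    start = 0
    for k, c in enumerate(counts):
        gamma[start : start + c, k] = 0.98
        start += c
    gamma /= gamma.sum(1, keepdims=True)
    w = gamma.mean(0)
    logf = np.log(gamma) - np.log(w)  # E-step with these weights reproduces gamma
    m = StateModel(
        K=K,
        weights=w,
        diffusivities=np.asarray(diffusivities, float),
        epsilon_sq=np.full(K, 8e-4),
        shared_noise=False,
        posteriors=gamma,
        log_densities=logf,
        log_likelihood=0.0,
        bic=0.0,
        n_disp=20 * M,
        protocol=PROTO,
        track_ids=np.arange(M),
    )
    return m


class TestFilterStates:
    def test_minor_state_removed_and_weights_renormalized(self):
        m = planted_model([0.50, 0.47, 0.03], [0.01, 0.05, 0.6])
        out = filter_states(m, min_population=0.05, posterior_threshold=0.6)
        assert out.K == 2
        assert abs(out.weights.sum() - 1.0) < 1e-9
        assert abs(out.posteriors.sum(1) - 1).max() < 1e-9

    def test_all_majority_states_unchanged(self):
        m = planted_model([0.5, 0.5], [0.01, 0.6])
        assert filter_states(m) is m

    def test_threshold_count_governs_not_soft_weight(self):
        """A state can hold soft weight while no track crosses the posterior
        threshold; the count rule must remove it."""
        M, K = 200, 2
        gamma = np.column_stack([np.full(M, 0.65), np.full(M, 0.35)])
        w = gamma.mean(0)
        m = StateModel(
            K=K, weights=w, diffusivities=np.array([0.01, 0.5]),
            epsilon_sq=np.full(K, 8e-4), shared_noise=False, posteriors=gamma,
            log_densities=np.log(gamma) - np.log(w), log_likelihood=0.0, bic=0.0,
            n_disp=100, protocol=PROTO, track_ids=np.arange(M),
        )
        # brute-force recount: state 1 has zero tracks above 0.6 -> removed
        assert (gamma[:, 1] > 0.6).mean() == 0.0
        out = filter_states(m)
        assert out.K == 1

    def test_refuses_to_remove_every_state(self):
        M = 100
        gamma = np.full((M, 2), 0.5)
        w = gamma.mean(0)
        m = StateModel(
            K=2, weights=w, diffusivities=np.array([0.01, 0.5]),
            epsilon_sq=np.full(2, 8e-4), shared_noise=False, posteriors=gamma,
            log_densities=np.log(gamma) - np.log(w), log_likelihood=0.0, bic=0.0,
            n_disp=100, protocol=PROTO, track_ids=np.arange(M),
        )
        with pytest.raises(ValueError, match="every state"):
            filter_states(m)


@pytest.fixture(scope="module")
def two_state_fit():
    model = SimulationModel(
        states=(MotionState("bound", 0.02), MotionState("free", 0.5)),
        initial_weights=(0.3, 0.7),
        localization_sigma_um=0.03,
        seed=23,
    )
    tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=600)
    fit = fit_pem(tracks, K=2, n_restarts=2, n_perturbations=1, seed=23)
    return tracks, fit


class TestStateMSD:
    def test_k1_equals_plain_ensemble_msd(self):
        model = SimulationModel(
            states=(MotionState("free", 0.4),), initial_weights=(1.0,), seed=24,
            localization_sigma_um=0.03,
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=300)
        fit = fit_pem(tracks, K=1, n_restarts=1, n_perturbations=0, seed=24)
        [curve] = state_msd(fit, tracks, max_lag=5)
        disp = track_displacements(tracks)
        for lag in range(1, 6):
            vals = []
            for _, X, Y in disp.by_len.values():
                px = np.concatenate([np.zeros((len(X), 1)), np.cumsum(X, 1)], axis=1)
                py = np.concatenate([np.zeros((len(Y), 1)), np.cumsum(Y, 1)], axis=1)
                vals.append(((px[:, lag:] - px[:, :-lag]) ** 2
                             + (py[:, lag:] - py[:, :-lag]) ** 2).mean(1))
            plain = np.concatenate(vals).mean()
            assert np.isclose(curve.msd_um2[lag - 1], plain, rtol=1e-12)

    def test_slow_state_curve_below_fast_state(self, two_state_fit):
        tracks, fit = two_state_fit
        slow, fast = state_msd(fit, tracks, max_lag=5)
        assert np.all(slow.msd_um2 < fast.msd_um2)

    def test_free_state_slope_matches_4d(self, two_state_fit):
        tracks, fit = two_state_fit
        _, fast = state_msd(fit, tracks, max_lag=5)
        slope = np.polyfit(fast.lag_s, fast.msd_um2, 1)[0]
        # 3-SE-scale tolerance on the fitted slope for this track count
        assert abs(slope - 4 * 0.5) / (4 * 0.5) < 0.05

    def test_max_lag_validated(self, two_state_fit):
        tracks, fit = two_state_fit
        with pytest.raises(ValueError, match="max_lag"):
            state_msd(fit, tracks, max_lag=21)


class TestFractions:
    def test_formatting_example(self):
        m = planted_model([0.36, 0.29, 0.35], [0.005, 0.02, 0.6])
        m.weights = np.array([0.36, 0.29, 0.35])
        s = summarize_fractions(m, bound_D_max_um2_s=0.03)
        assert np.allclose(
            [s.fraction_bound, s.fraction_confined, s.fraction_free], [0.36, 0.29, 0.35]
        )

    def test_single_free_state(self):
        m = planted_model([1.0 - 1e-9, 1e-9], [0.5, 0.9], M=100)
        m.weights = np.array([1.0, 0.0])
        s = summarize_fractions(m, bound_D_max_um2_s=0.03)
        assert (s.fraction_bound, s.fraction_confined, s.fraction_free) == (0.0, 0.0, 1.0)
        assert s.warnings

    def test_bound_fraction_recovered(self):
        model = SimulationModel(
            states=(MotionState("bound", 0.02), MotionState("free", 0.5)),
            initial_weights=(0.3, 0.7),
            localization_sigma_um=0.03,
            seed=25,
        )
        tracks, _ = simulate_switching_tracks(model, PROTO, n_tracks=2000)
        fit = fit_pem(tracks, K=2, n_restarts=2, n_perturbations=1, seed=25)
        s = summarize_fractions(fit, bound_D_max_um2_s=0.03)
        assert abs(s.fraction_bound - 0.3) <= 0.03
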