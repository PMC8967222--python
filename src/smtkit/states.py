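"""Diffusive-state mixture estimation for whole trajectories.

Trajectories are classified into K diffusive states by perturbation
expectation-maximization (pEM) with BIC model selection. Under state k, a
track's per-axis displacement sequence is modelled as a zero-mean Gaussian
with tridiagonal covariance

    Var(d_i)          = 2 D_k dt + 2 eps2_k
    Cov(d_i, d_{i+1}) = -eps2_k
    Cov beyond lag 1  = 0

where ``eps2 = sigma^2 - D t_E / 3`` is the *effective* localization noise:
static localization error minus the motion-blur contribution of the camera
exposure. These are the standard moments of blurred single-particle
trajectories; the package's simulator doubles as the empirical oracle for
them. Because blur couples ``eps2`` to ``D``, the effective noise is
state-dependent by default (it can legitimately be negative for fast
states, where blur exceeds the static noise); a shared-noise variant is
available via ``shared_noise=True``.

The M-step uses posterior-weighted lag-0/lag-1 displacement covariances:
``D_k = (Var + 2 Cov) / (2 dt)`` — the covariance-based estimator, in which
noise and blur cancel exactly — and ``eps2_k = -Cov``. A monotone guard
(step-halving toward the previous parameters, stopping if the likelihood
would still decrease) keeps the recorded log-likelihood sequence
non-decreasing, since moment updates are not the exact M-step of the
structured covariance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve_banded, cholesky_banded
from scipy.special import logsumexp

from ._rng import stage_seed_sequence
from .core import AcquisitionProtocol, TrackSet

__all__ = [
    "Displacements",
    "StateModel",
    "MSDCurve",
    "FractionSummary",
    "StateCollapseError",
    "track_displacements",
    "fit_pem",
    "select_model",
    "filter_states",
    "state_msd",
    "summarize_fractions",
]

_LOG2PI = np.log(2.0 * np.pi)


class StateCollapseError(RuntimeError):
    """Raised when a state loses all responsibility mass (K too large)."""


# ---------------------------------------------------------------------------
# displacements
# ---------------------------------------------------------------------------

@dataclass
class Displacements:
    """Per-track displacement sequences, grouped by length for vectorization.

    ``by_len`` maps a displacement count ``n`` to ``(track_index, X, Y)``
    where ``X``/``Y`` are ``(m, n)`` per-axis displacement arrays (um).
    ``ssq``/``scross`` are per-track sums over both axes of squared
    displacements and adjacent-lag products; ``n0``/``n1`` the matching
    term counts.
    """

    track_ids: np.ndarray
    lengths: np.ndarray
    by_len: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ssq: np.ndarray
    scross: np.ndarray
    n0: np.ndarray
    n1: np.ndarray
    dt: float
    protocol: AcquisitionProtocol

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)

    @property
    def total_displacements(self) -> int:
        return int(self.lengths.sum())


def track_displacements(tracks: TrackSet) -> Displacements:
    """Per-axis displacement sequences (um) of every track.

    Counts are conserved: a track of N positions yields N-1 displacements.
    Tracks with frame gaps are rejected (they violate the track invariant).
    """
    df = tracks.df
    ids = df["track_id"].to_numpy()
    frames = df["frame"].to_numpy()
    xy = df[["x_um", "y_um"]].to_numpy(float)
    # boundaries of tracks in the (already frame-ordered) table
    change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(ids)]))
    same = ids[1:] == ids[:-1]
    if np.any(same & (np.diff(frames) != 1)):
        raise ValueError("tracks with frame gaps cannot be analysed")

    track_ids = ids[starts]
    lengths = ends - starts - 1
    d_all = np.diff(xy, axis=0)  # rows crossing track boundaries removed below

    by_len: dict[int, list[int]] = {}
    for i, n in enumerate(lengths):
        by_len.setdefault(int(n), []).append(i)

    grouped: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    ssq = np.zeros(len(track_ids))
    scross = np.zeros(len(track_ids))
    for n, idx_list in by_len.items():
        idx = np.asarray(idx_list)
        X = np.empty((len(idx), n))
        Y = np.empty((len(idx), n))
        for row, i in enumerate(idx):
            d = d_all[starts[i] : starts[i] + n]
            X[row] = d[:, 0]
            Y[row] = d[:, 1]
        grouped[n] = (idx, X, Y)
        ssq[idx] = (X**2).sum(axis=1) + (Y**2).sum(axis=1)
        if n > 1:
            scross[idx] = (X[:, 1:] * X[:, :-1]).sum(axis=1) + (Y[:, 1:] * Y[:, :-1]).sum(axis=1)
    return Displacements(
        track_ids=track_ids,
        lengths=lengths,
        by_len=grouped,
        ssq=ssq,
        scross=scross,
        n0=2 * lengths,
        n1=2 * np.maximum(lengths - 1, 0),
        dt=tracks.protocol.frame_interval_s,
        protocol=tracks.protocol,
    )


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """A fitted K-state diffusive mixture.

    States are always sorted by ascending diffusivity. ``log_densities``
    caches per-track per-state log densities (independent of the weights),
    which lets :func:`filter_states` recompute posteriors without the data.
    """

    K: int
    weights: np.ndarray
    diffusivities: np.ndarray  # um^2/s, ascending
    epsilon_sq: np.ndarray  # um^2, per state (constant array in shared mode)
    shared_noise: bool
    posteriors: np.ndarray  # (M, K)
    log_densities: np.ndarray  # (M, K)
    log_likelihood: float
    bic: float
    n_disp: int
    protocol: AcquisitionProtocol
    track_ids: np.ndarray
    converged: bool = True
    n_iter: int = 0
    em_histories: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    bic_table: pd.DataFrame | None = None

    @property
    def n_params(self) -> int:
        return 2 * self.K if self.shared_noise else 3 * self.K - 1

    def validate(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise AssertionError("state weights must sum to 1")
        if self.posteriors.size:
            rs = self.posteriors.sum(axis=1)
            if np.any(np.abs(rs - 1.0) > 1e-9):
                raise AssertionError("posterior rows must sum to 1")
        if np.any(np.diff(self.diffusivities) < -1e-15):
            raise AssertionError("diffusivities must be sorted ascending")
        if not np.isfinite(self.bic):
            raise AssertionError("BIC must be finite")

    def populations(self, posterior_threshold: float = 0.6) -> np.ndarray:
        """Fraction of tracks whose posterior for each state exceeds the threshold."""
        return (self.posteriors > posterior_threshold).mean(axis=0)


@dataclass
class MSDCurve:
    """Posterior-weighted MSD of one diffusive state (both axes summed)."""

    state: int
    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_effective: np.ndarray


@dataclass
class FractionSummary:
    """Bound / confined / free population split of a fitted model."""

    fraction_bound: float
    fraction_confined: float
    fraction_free: float
    bound_D_max_um2_s: float
    rule: str
    n_bound_states: int
    warnings: list = field(default_factory=list)

    @property
    def fraction_unbound(self) -> float:
        """The simple bound-vs-unbound split's unbound side."""
        return 1.0 - self.fraction_bound - self.fraction_confined


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _banded_cov(n: int, var: float, cov: float) -> np.ndarray:
    """Upper banded form of the tridiagonal displacement covariance."""
    ab = np.zeros((2, n))
    ab[1, :] = var
    ab[0, 1:] = cov
    return ab


def _safe_params(D: float, eps2: float, dt: float) -> tuple[float, float]:
    """Clamp (D, eps2) so the tridiagonal covariance stays positive definite."""
    D = max(D, 0.0)
    if D == 0.0:
        eps2 = max(eps2, 0.0)
    elif eps2 < 0.0:
        eps2 = max(eps2, -0.49 * D * dt)
    var = 2.0 * D * dt + 2.0 * eps2
    if var < 1e-14:  # fully degenerate (e.g. all-zero displacements)
        var = 1e-14
    return var, -eps2


def _state_loglik(disp: Displacements, D: float, eps2: float) -> np.ndarray:
    """Log density of every track's displacement sequence under one state."""
    var, off = _safe_params(D, eps2, disp.dt)
    out = np.empty(disp.n_tracks)
    for n, (idx, X, Y) in disp.by_len.items():
        ab = _banded_cov(n, var, off)
        try:
            c = cholesky_banded(ab, lower=False)
        except np.linalg.LinAlgError:
            # fall back to a diagonal-dominant clamp
            ab = _banded_cov(n, var, 0.0)
            c = cholesky_banded(ab, lower=False)
        logdet = 2.0 * np.log(c[1]).sum()
        B = np.concatenate([X, Y], axis=0).T  # (n, 2m)
        sol = cho_solve_banded((c, False), B)
        quad = (B * sol).sum(axis=0)
        m = len(idx)
        qx, qy = quad[:m], quad[m:]
        out[idx] = -0.5 * (2 * n * _LOG2PI + 2 * logdet + qx + qy)
    return out


def _log_density_matrix(disp: Displacements, D: np.ndarray, eps2: np.ndarray) -> np.ndarray:
    return np.column_stack([_state_loglik(disp, D[k], eps2[k]) for k in range(len(D))])


def _total_loglik(logf: np.ndarray, weights: np.ndarray) -> float:
    return float(logsumexp(logf + np.log(np.maximum(weights, 1e-300)), axis=1).sum())


def _posteriors(logf: np.ndarray, weights: np.ndarray) -> np.ndarray:
    a = logf + np.log(np.maximum(weights, 1e-300))
    a -= a.max(axis=1, keepdims=True)
    g = np.exp(a)
    g /= g.sum(axis=1, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _m_step(
    disp: Displacements, gamma: np.ndarray, shared_noise: bool, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    K = gamma.shape[1]
    Nk = gamma.sum(axis=0)
    if np.any(Nk < 1e-12 * max(gamma.shape[0], 1)):
        k_bad = int(np.argmin(Nk))
        raise StateCollapseError(
            f"state {k_bad} collapsed (responsibility mass {Nk[k_bad]:.3g}); "
            f"K={K} exceeds the distinguishable support of the data"
        )
    warns: list[str] = []
    weights = Nk / Nk.sum()
    V = (gamma * disp.ssq[:, None]).sum(axis=0) / (gamma * disp.n0[:, None]).sum(axis=0)
    n1w = (gamma * disp.n1[:, None]).sum(axis=0)
    C = np.where(n1w > 0, (gamma * disp.scross[:, None]).sum(axis=0) / np.maximum(n1w, 1e-300), 0.0)
    if shared_noise:
        tot1 = disp.n1.sum()
        eps_shared = -disp.scross.sum() / tot1 if tot1 > 0 else 0.0
        if eps_shared < 0:
            warns.append("shared eps^2 floored at 0")
            eps_shared = 0.0
        eps2 = np.full(K, eps_shared)
        D = np.maximum((V - 2.0 * eps_shared) / (2.0 * dt), 0.0)
    else:
        D = np.maximum((V + 2.0 * C) / (2.0 * dt), 0.0)
        eps2 = -C
        lo = np.where(D > 0, -0.49 * D * dt, 0.0)
        clamped = eps2 < lo
        if np.any(clamped):
            warns.append("eps^2 clamped to keep the covariance positive definite")
        eps2 = np.maximum(eps2, lo)
    return weights, D, eps2, warns


def _run_em(
    disp: Displacements,
    weights: np.ndarray,
    D: np.ndarray,
    eps2: np.ndarray,
    shared_noise: bool,
    max_iter: int,
    tol: float,
) -> dict:
    """One EM run from the given start, with a monotone likelihood guard."""
    dt = disp.dt
    logf = _log_density_matrix(disp, D, eps2)
    ll = _total_loglik(logf, weights)
    history = [ll]
    warns: list[str] = []
    converged = False
    for it in range(max_iter):
        gamma = _posteriors(logf, weights)
        new_w, new_D, new_e, w_warn = _m_step(disp, gamma, shared_noise, dt)
        warns.extend(w_warn)
        # monotone guard: halve the step toward the old parameters if needed
        accepted = False
        frac = 1.0
        for _ in range(6):
            cand_w = (1 - frac) * weights + frac * new_w
            cand_w /= cand_w.sum()
            cand_D = (1 - frac) * D + frac * new_D
            cand_e = (1 - frac) * eps2 + frac * new_e
            cand_logf = _log_density_matrix(disp, cand_D, cand_e)
            cand_ll = _total_loglik(cand_logf, cand_w)
            if cand_ll >= ll - 1e-9 * abs(ll):
                accepted = True
                break
            frac *= 0.5
        if not accepted:
            converged = True
            break
        rel = abs(cand_ll - ll) / max(abs(ll), 1.0)
        weights, D, eps2, logf = cand_w, cand_D, cand_e, cand_logf
        ll = max(cand_ll, ll)  # guard numerical jitter below assertion tolerance
        history.append(ll)
        if rel < tol:
            converged = True
            break
    gamma = _posteriors(logf, weights)
    return {
        "weights": weights,
        "D": D,
        "eps2": eps2,
        "loglik": ll,
        "posteriors": gamma,
        "log_densities": logf,
        "history": np.asarray(history),
        "converged": converged,
        "n_iter": len(history) - 1,
        "warnings": warns,
    }


def _initial_params(
    disp: Displacements, K: int, rng: np.random.Generator, jitter: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d_naive = (disp.ssq / np.maximum(disp.n0, 1) + 2.0 * disp.scross / np.maximum(disp.n1, 1)) / (
        2.0 * disp.dt
    )
    d_naive = np.maximum(d_naive, 0.0)
    qs = (np.arange(K) + 0.5) / K
    D0 = np.quantile(d_naive, qs)
    floor = max(np.median(d_naive) * 1e-3, 1e-6)
    D0 = np.maximum(D0, floor)
    if jitter:
        D0 = D0 * rng.lognormal(0.0, 0.5, size=K)
    e_glob = -disp.scross.sum() / max(disp.n1.sum(), 1)
    eps0 = np.full(K, max(e_glob, 1e-6))
    w0 = np.full(K, 1.0 / K)
    return w0, np.sort(D0), eps0


def fit_pem(
    tracks: TrackSet | Displacements,
    K: int,
    n_restarts: int = 5,
    n_perturbations: int = 10,
    seed: int = 0,
    shared_noise: bool = False,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> StateModel:
    """Fit a K-state diffusive mixture by perturbation EM.

    Each of ``n_restarts`` independent initializations is run to
    convergence (relative log-likelihood change < ``tol`` or ``max_iter``
    iterations); the converged diffusivities are then perturbed
    ``n_perturbations`` times by a log-normal factor (s.d. 0.3 in log
    space) and EM re-run, keeping the best likelihood seen. Deterministic
    under ``seed``.
    """
    disp = tracks if isinstance(tracks, Displacements) else track_displacements(tracks)
    if K < 1:
        raise ValueError("K must be >= 1")
    if disp.n_tracks < 10 * K:
        raise ValueError(f"need at least {10 * K} tracks to fit K={K} states, got {disp.n_tracks}")

    rng = np.random.default_rng(stage_seed_sequence(seed, f"fit_pem_K{K}"))
    best: dict | None = None
    histories: list[np.ndarray] = []
    all_warns: list[str] = []
    err: Exception | None = None
    for r in range(max(n_restarts, 1)):
        try:
            w0, D0, e0 = _initial_params(disp, K, rng, jitter=r > 0)
            run = _run_em(disp, w0, D0, e0, shared_noise, max_iter, tol)
            histories.append(run["history"])
            all_warns.extend(run["warnings"])
            if best is None or run["loglik"] > best["loglik"]:
                best = run
            for _ in range(n_perturbations):
                D_p = run["D"] * rng.lognormal(0.0, 0.3, size=K)
                trial = _run_em(
                    disp, run["weights"], D_p, run["eps2"], shared_noise, max_iter, tol
                )
                histories.append(trial["history"])
                all_warns.extend(trial["warnings"])
                if trial["loglik"] > best["loglik"]:
                    best = trial
        except StateCollapseError as e:
            err = e
            continue
    if best is None:
        raise err if err is not None else RuntimeError("no EM run succeeded")

    order = np.argsort(best["D"], kind="stable")
    n_disp = disp.total_displacements
    n_params = 2 * K if shared_noise else 3 * K - 1
    bic = -2.0 * best["loglik"] + n_params * np.log(max(n_disp, 1))
    model = StateModel(
        K=K,
        weights=best["weights"][order],
        diffusivities=best["D"][order],
        epsilon_sq=best["eps2"][order],
        shared_noise=shared_noise,
        posteriors=best["posteriors"][:, order],
        log_densities=best["log_densities"][:, order],
        log_likelihood=best["loglik"],
        bic=bic,
        n_disp=n_disp,
        protocol=disp.protocol,
        track_ids=disp.track_ids,
        converged=best["converged"],
        n_iter=best["n_iter"],
        em_histories=histories,
        warnings=sorted(set(all_warns)),
    )
    model.validate()
    return model


def select_model(
    tracks: TrackSet | Displacements,
    K_range=range(1, 5),
    keep_models: bool = False,
    **fit_kwargs,
) -> StateModel:
    """Fit every K in ``K_range`` and return the model minimizing BIC.

    ``BIC = -2 lnL + p ln(n_displacements)``; displacements are the
    likelihood's observation unit. Per-K failures are recorded in the BIC
    table; at least one K must succeed.
    """
    K_list = list(K_range)
    if not K_list:
        raise ValueError("K_range must be non-empty")
    disp = tracks if isinstance(tracks, Displacements) else track_displacements(tracks)
    rows = []
    models: dict[int, StateModel] = {}
    for K in K_list:
        try:
            m = fit_pem(disp, K, **fit_kwargs)
            models[K] = m
            rows.append(
                {"K": K, "loglik": m.log_likelihood, "bic": m.bic, "converged": m.converged,
                 "error": ""}
            )
        except (StateCollapseError, ValueError) as e:
            rows.append({"K": K, "loglik": np.nan, "bic": np.nan, "converged": False,
                         "error": str(e)})
    table = pd.DataFrame(rows)
    if not models:
        raise RuntimeError(f"no K in {K_list} could be fitted:\n{table}")
    best_K = min(models, key=lambda k: models[k].bic)
    best = models[best_K]
    best.bic_table = table
    if keep_models:
        best.all_models = models  # type: ignore[attr-defined]
    return best


# ---------------------------------------------------------------------------
# post-fit operations
# ---------------------------------------------------------------------------

def filter_states(
    model: StateModel,
    min_population: float = 0.05,
    posterior_threshold: float = 0.6,
    refit: bool = False,
    tracks: TrackSet | Displacements | None = None,
    **fit_kwargs,
) -> StateModel:
    """Discard minor states and renormalize.

    A state's population is the fraction of tracks whose posterior for it
    exceeds ``posterior_threshold``; states below ``min_population`` are
    removed, remaining weights renormalized and posteriors recomputed under
    the reduced model (from the cached log densities). With ``refit=True``
    (requires ``tracks``), the reduced model is refitted instead.
    """
    pops = model.populations(posterior_threshold)
    keep = pops >= min_population
    if not np.any(keep):
        raise ValueError("the population filter would remove every state")
    if np.all(keep):
        return model
    if refit:
        if tracks is None:
            raise ValueError("refit=True requires the tracks")
        return fit_pem(tracks, K=int(keep.sum()), shared_noise=model.shared_noise, **fit_kwargs)
    w = model.weights[keep]
    w = w / w.sum()
    logf = model.log_densities[:, keep]
    gamma = _posteriors(logf, w)
    ll = _total_loglik(logf, w)
    K = int(keep.sum())
    n_params = 2 * K if model.shared_noise else 3 * K - 1
    out = StateModel(
        K=K,
        weights=w,
        diffusivities=model.diffusivities[keep],
        epsilon_sq=model.epsilon_sq[keep],
        shared_noise=model.shared_noise,
        posteriors=gamma,
        log_densities=logf,
        log_likelihood=ll,
        bic=-2.0 * ll + n_params * np.log(max(model.n_disp, 1)),
        n_disp=model.n_disp,
        protocol=model.protocol,
        track_ids=model.track_ids,
        converged=model.converged,
        n_iter=model.n_iter,
        warnings=model.warnings + [f"filtered {int((~keep).sum())} state(s) below "
                                   f"{min_population:.0%}/{posterior_threshold} rule"],
    )
    out.validate()
    return out


def state_msd(
    model: StateModel, tracks: TrackSet | Displacements, max_lag: int
) -> list[MSDCurve]:
    """Posterior-probability-weighted MSD per diffusive state.

    ``MSD_k(n dt) = sum_m gamma_mk msd_m(n) / sum_m gamma_mk`` with
    ``msd_m(n)`` the time-averaged squared displacement (both axes summed)
    of track m at lag n.
    """
    disp = tracks if isinstance(tracks, Displacements) else track_displacements(tracks)
    min_len = int(disp.lengths.min())
    if max_lag >= min_len + 1:
        raise ValueError(
            f"max_lag must be < shortest track length ({min_len + 1} positions)"
        )
    M = disp.n_tracks
    msd = np.zeros((M, max_lag))
    for n, (idx, X, Y) in disp.by_len.items():
        cx = np.cumsum(np.concatenate([np.zeros((len(idx), 1)), X], axis=1), axis=1)
        cy = np.cumsum(np.concatenate([np.zeros((len(idx), 1)), Y], axis=1), axis=1)
        for lag in range(1, max_lag + 1):
            dx = cx[:, lag:] - cx[:, :-lag]
            dy = cy[:, lag:] - cy[:, :-lag]
            msd[idx, lag - 1] = (dx**2 + dy**2).mean(axis=1)
    dt = disp.dt
    curves = []
    for k in range(model.K):
        g = model.posteriors[:, k]
        tot = g.sum()
        lags = dt * np.arange(1, max_lag + 1)
        pairs = np.array([g @ (disp.lengths - lag + 1).clip(min=0) for lag in range(1, max_lag + 1)])
        vals = (g @ msd) / tot if tot > 0 else np.full(max_lag, np.nan)
        ok = pairs > 0
        if not np.all(ok):
            warnings.warn(f"state {k}: dropping {int((~ok).sum())} lag(s) with zero weight")
        curves.append(MSDCurve(state=k, lag_s=lags[ok], msd_um2=vals[ok], n_effective=pairs[ok]))
    return curves


def summarize_fractions(model: StateModel, bound_D_max_um2_s: float = 0.03) -> FractionSummary:
    """Bound / confined / free population split.

    States with ``D <= bound_D_max`` form the bound class; the slowest of
    them is chromatin-bound, the remaining bound-class states pool into the
    confined fraction, and everything faster is free. With no bound-class
    state the split is (0, 0, 1) with a warning.
    """
    bound_class = model.diffusivities <= bound_D_max_um2_s
    warns: list[str] = []
    if not np.any(bound_class):
        warns.append(f"no state with D <= {bound_D_max_um2_s} um^2/s; all mass labelled free")
        fb, fc = 0.0, 0.0
    else:
        idx = np.flatnonzero(bound_class)
        fb = float(model.weights[idx[0]])  # diffusivities are ascending: first is slowest
        fc = float(model.weights[idx[1:]].sum())
    ff = float(1.0 - fb - fc)
    out = FractionSummary(
        fraction_bound=fb,
        fraction_confined=fc,
        fraction_free=ff,
        bound_D_max_um2_s=bound_D_max_um2_s,
        rule=(
            f"states with D <= {bound_D_max_um2_s} um^2/s are bound-class; slowest = "
            "chromatin-bound, rest of bound-class = confined, remainder = free"
        ),
        n_bound_states=int(bound_class.sum()),
        warnings=warns,
    )
    total = out.fraction_bound + out.fraction_confined + out.fraction_free
    assert abs(total - 1.0) <= 1e-9
    return out
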