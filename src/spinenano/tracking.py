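"""Single-molecule trajectory analysis.

Pools single-step displacements from short 2D trajectories recorded at a
fixed frame interval (default 0.022 s) and fits a hidden Markov model over
diffusive states.  The emission model is the standard one for
displacement-based state inference: in state ``k`` a single-step
displacement vector is zero-mean bivariate Gaussian with per-coordinate
variance ``2 * D_k * dt``, so the jump magnitude is Rayleigh with
``<r^2> = 4 * D_k * dt``.  Models with K = 1..3 states are fit by
expectation-maximization with per-track forward-backward passes and the
number of states is chosen by BIC; the 3-state cap guards against
over-fitting on photobleaching-limited track lengths.

States are always reported sorted by ascending diffusion coefficient, so
state 1 is the bound/immobile state.  Stationary occupancies are those of
the fitted per-step transition matrix, and per-state mean dwell times are
``dt / (1 - A_kk)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "Track",
    "TrackSet",
    "JumpSet",
    "JumpStats",
    "DiffusionHMM",
    "compute_jumps",
    "jump_stats",
    "mixture_cdf",
    "fit_diffusion_hmm",
    "dwell_times",
    "stationary_distribution",
]

DEFAULT_DT = 0.022  # s per frame


@dataclass(frozen=True)
class Track:
    """One gapless trajectory: strictly increasing frames, positions in um."""

    id: str
    frames: np.ndarray
    positions: np.ndarray
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(frames) != len(pos):
            raise ValueError("frames and positions length mismatch")
        if len(pos) < 2:
            raise ValueError("a track needs >= 2 positions")
        d = np.diff(frames)
        if np.any(d <= 0):
            raise ValueError("frames must be strictly increasing")
        if np.any(d != 1):
            raise ValueError("gapped track; split it at load")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", pos)

    def jumps(self) -> np.ndarray:
        """Magnitudes of consecutive-frame displacements, um."""
        d = np.diff(self.positions, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class TrackSet:
    tracks: tuple[Track, ...]
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        object.__setattr__(self, "tracks", tuple(self.tracks))

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass(frozen=True)
class JumpSet:
    """Pooled single-step displacement magnitudes across tracks."""

    magnitudes: np.ndarray
    dt: float
    n_tracks: int

    @property
    def n_jumps(self) -> int:
        return len(self.magnitudes)


@dataclass(frozen=True)
class JumpStats:
    median: float
    p25: float
    p75: float
    frac_short: float  # fraction of jumps < short threshold (default 0.1 um)
    frac_long: float   # fraction of jumps >= long threshold (default 0.2 um)
    n_jumps: int


@dataclass(frozen=True)
class DiffusionHMM:
    """Fitted <=3-state diffusion HMM, states sorted by ascending D."""

    K: int
    D: np.ndarray            # um^2/s, ascending
    A: np.ndarray            # per-step transition matrix
    pi: np.ndarray           # stationary occupancies of A
    dwell: np.ndarray        # s; dt / (1 - A_kk)
    loglik: float
    bic: float
    dt: float
    n_jumps: int
    n_restarts: int
    seed: int | None
    converged: bool
    loglik_trace: tuple[float, ...] = ()


def compute_jumps(tracks: TrackSet | Iterable[Track]) -> JumpSet:
    """Pool Euclidean single-step displacement magnitudes across tracks."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks")
    dt = tracks[0].dt
    mags = np.concatenate([t.jumps() for t in tracks])
    return JumpSet(mags, dt, len(tracks))


def jump_stats(
    jumps: JumpSet, short: float = 0.1, long: float = 0.2
) -> JumpStats:
    """Empirical quantiles (linear interpolation) and threshold fractions."""
    r = jumps.magnitudes
    if r.size == 0:
        raise ValueError("empty jump set")
    p25, med, p75 = (float(q) for q in np.percentile(r, [25, 50, 75]))
    return JumpStats(
        median=med,
        p25=p25,
        p75=p75,
        frac_short=float(np.mean(r < short)),
        frac_long=float(np.mean(r >= long)),
        n_jumps=int(r.size),
    )


def mixture_cdf(
    r: float | np.ndarray,
    D: Sequence[float],
    pi: Sequence[float],
    dt: float = DEFAULT_DT,
    loc_error: float = 0.0,
) -> float | np.ndarray:
    """Closed-form CDF of jump magnitudes under a state mixture.

    ``P(R <= r) = sum_k pi_k * (1 - exp(-r^2 / (4 D_k dt + 4 loc_error^2)))``
    — a mixture of Rayleigh distributions, one per diffusive state, with
    optional static localization error added in quadrature.
    """
    D = np.asarray(D, dtype=float)
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    scale = 4.0 * D * dt + 4.0 * loc_error**2  # = <r^2> per state
    r2 = np.atleast_1d(np.asarray(r, dtype=float)) ** 2
    terms = np.empty((len(D), len(r2)))
    for k, s in enumerate(scale):
        if s <= 0:
            terms[k] = (r2 > 0).astype(float)  # point mass at zero
        else:
            terms[k] = 1.0 - np.exp(-r2 / s)
    out = pi @ terms
    return float(out[0]) if np.isscalar(r) else out


def mixture_quantile(
    q: float,
    D: Sequence[float],
    pi: Sequence[float],
    dt: float = DEFAULT_DT,
    loc_error: float = 0.0,
) -> float:
    """Invert the mixture CDF by bisection."""
    from scipy.optimize import brentq

    hi = 10.0 * math.sqrt(max(4 * max(D) * dt + 4 * loc_error**2, 1e-12))
    return float(
        brentq(lambda r: mixture_cdf(r, D, pi, dt, loc_error) - q, 0.0, hi)
    )


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic, irreducible matrix."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("A is not row-stochastic")
    if A.shape[0] == 1:
        return np.ones(1)
    n_comp, _ = connected_components(csr_matrix(A > 0), connection="strong")
    if n_comp != 1:
        raise ValueError("reducible chain has no unique stationary distribution")
    vals, vecs = np.linalg.eig(A.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def dwell_times(A: np.ndarray, dt: float = DEFAULT_DT) -> np.ndarray:
    """Mean dwell time per state, ``dt / (1 - A_kk)``; inf for absorbing."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("A is not row-stochastic")
    stay = np.clip(np.diag(A), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        return np.where(stay < 1.0, dt / (1.0 - stay), np.inf)


# ---------------------------------------------------------------------------
# EM fitting


def _pad_tracks(tracks: Sequence[Track]) -> tuple[np.ndarray, np.ndarray]:
    """Squared jump magnitudes padded to (n_tracks, max_len) + lengths."""
    sq = [t.jumps() ** 2 for t in tracks]
    lengths = np.array([len(s) for s in sq])
    out = np.zeros((len(sq), lengths.max()))
    for i, s in enumerate(sq):
        out[i, : len(s)] = s
    return out, lengths


def _log_emissions(r2: np.ndarray, D: np.ndarray, dt: float) -> np.ndarray:
    """log density of 2D displacement vectors given per-state D.

    ``r2`` is (T, L); returns (T, L, K).  Per-coordinate variance is
    ``2 D dt`` so the 2D density is ``exp(-r^2 / (4 D dt)) / (4 pi D dt)``.
    """
    var = np.maximum(4.0 * D * dt, 1e-30)  # = 2 sigma^2
    return -r2[..., None] / var - np.log(np.pi * var)


def _em_once(
    r2: np.ndarray,
    lengths: np.ndarray,
    D0: np.ndarray,
    A0: np.ndarray,
    rho0: np.ndarray,
    dt: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, list[float]]:
    """Batched Baum-Welch over padded tracks."""
    T, L = r2.shape
    K = len(D0)
    D, A, rho = D0.copy(), A0.copy(), rho0.copy()
    mask = np.arange(L)[None, :] < lengths[:, None]  # (T, L)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logB = _log_emissions(r2, D, dt)
        B = np.exp(logB - logB.max(axis=2, keepdims=True))
        Bscale = logB.max(axis=2)  # (T, L)
        # forward, scaled
        alpha = np.zeros((T, L, K))
        c = np.ones((T, L))
        a = rho[None, :] * B[:, 0, :]
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / c[:, 0, None]
        for t in range(1, L):
            act = mask[:, t]
            a = (alpha[:, t - 1] @ A) * B[:, t, :]
            s = a.sum(axis=1)
            s = np.where(act & (s > 0), s, 1.0)
            alpha[:, t] = np.where(act[:, None], a / s[:, None], alpha[:, t - 1])
            c[:, t] = np.where(act, s, 1.0)
        # log-likelihood includes the emission scaling pulled out of B
        ll = float(np.sum(np.log(c) * mask) + np.sum(Bscale * mask))
        trace.append(ll)
        # backward, scaled
        beta = np.zeros((T, L, K))
        beta[np.arange(T), lengths - 1] = 1.0
        for t in range(L - 2, -1, -1):
            act = lengths - 1 > t
            b = (beta[:, t + 1] * B[:, t + 1, :]) @ A.T
            b = b / c[:, t + 1, None]
            beta[:, t] = np.where(act[:, None], b, beta[:, t])
        gamma = alpha * beta
        gamma = gamma / np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
        gamma = gamma * mask[..., None]
        # pairwise expectations
        xi_sum = np.zeros((K, K))
        for t in range(1, L):
            act = mask[:, t]
            if not act.any():
                break
            x = (
                alpha[act, t - 1][:, :, None]
                * A[None, :, :]
                * (B[act, t, :] * beta[act, t])[:, None, :]
                / c[act, t][:, None, None]
            )
            xi_sum += x.sum(axis=0)
        # M-step
        gsum = gamma.sum(axis=(0, 1))
        D = (gamma * r2[..., None]).sum(axis=(0, 1)) / np.maximum(
            4.0 * dt * gsum, 1e-300
        )
        D = np.maximum(D, 1e-12)
        if K > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300), A)
            A = A / A.sum(axis=1, keepdims=True)
            rho = gamma[:, 0, :].sum(axis=0)
            rho = rho / rho.sum()
        if prev > -np.inf and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
    return D, A, rho, trace[-1], converged, trace


def fit_diffusion_hmm(
    tracks: TrackSet | Sequence[Track],
    k_max: int = 3,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> DiffusionHMM:
    """Fit diffusion HMMs with 1..k_max states and select K by BIC.

    Each restart perturbs log-spaced initial diffusion coefficients spanning
    the empirical displacement range; transition matrices start at 0.8 on
    the diagonal.  The best restart per K is kept and the K minimizing BIC
    is returned with states relabeled by ascending D.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks")
    if k_max not in (1, 2, 3):
        raise ValueError("k_max must be 1, 2, or 3")
    dt = tracks[0].dt
    r2, lengths = _pad_tracks(tracks)
    n_jumps = int(lengths.sum())
    if n_jumps < 100:
        raise ValueError("insufficient data: need >= 100 pooled jumps")
    rng = np.random.default_rng(seed)
    msd = float((r2.sum() / n_jumps))
    D_emp = msd / (4.0 * dt)
    lo, hi = 0.05 * D_emp, 5.0 * D_emp

    best: DiffusionHMM | None = None
    for K in range(1, k_max + 1):
        best_k: tuple | None = None
        n_tries = 1 if K == 1 else n_restarts
        for rep in range(n_tries):
            if K == 1:
                D0 = np.array([D_emp])
            else:
                base = np.exp(np.linspace(np.log(lo), np.log(hi), K))
                D0 = base * np.exp(rng.normal(0, 0.4, K))
            if K == 1:
                A0 = np.ones((1, 1))
            else:
                A0 = np.full((K, K), 0.2 / (K - 1))
                np.fill_diagonal(A0, 0.8)
            rho0 = np.full(K, 1.0 / K)
            D, A, rho, ll, conv, trace = _em_once(
                r2, lengths, D0, A0, rho0, dt, tol, max_iter
            )
            if best_k is None or ll > best_k[3]:
                best_k = (D, A, rho, ll, conv, trace)
        D, A, rho, ll, conv, trace = best_k
        n_params = K + K * (K - 1) + (K - 1)  # D, off-diagonals, initial dist
        bic = -2.0 * ll + n_params * math.log(n_jumps)
        order = np.argsort(D)
        D, A = D[order], A[np.ix_(order, order)]
        try:
            pi = stationary_distribution(A)
        except ValueError:
            pi = rho[order]
        model = DiffusionHMM(
            K=K,
            D=D,
            A=A,
            pi=pi,
            dwell=dwell_times(A, dt),
            loglik=ll,
            bic=bic,
            dt=dt,
            n_jumps=n_jumps,
            n_restarts=n_tries,
            seed=seed,
            converged=conv,
            loglik_trace=tuple(trace),
        )
        if best is None or model.bic < best.bic:
            best = model
    return best
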