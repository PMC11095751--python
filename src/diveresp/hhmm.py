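"""Semi-supervised hierarchical hidden Markov model over dive tracks.

Structure: a coarse Markov chain over track behaviours (resting,
travelling, foraging); conditional on a track's behaviour, a fine Markov
chain over dive types (shallow, medium, deep, logging) generates that
track's dives.  Each dive emits three observables — max depth, dive
duration and surface-interval duration — modelled as conditionally
independent gamma variables given the dive type.  Emission parameters are
shared across behaviours; behaviours differ only through their fine-chain
dynamics.

Partial labels (video behaviours on some tracks, rule-derived dive types
on some dives) are incorporated by zeroing the disallowed state weights
inside every forward/backward/Viterbi recursion, at both hierarchy
levels.  All recursions run in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, polygamma

__all__ = [
    "BEHAVIOURS",
    "DIVE_TYPES",
    "HHMMParams",
    "TrackObs",
    "WhaleObs",
    "DecodedStates",
    "emission_logdensity",
    "fine_track_likelihood",
    "coarse_log_likelihood",
    "fit_em",
    "viterbi_decode",
    "posterior_state_probs",
]

log = logging.getLogger(__name__)

BEHAVIOURS = ("resting", "travelling", "foraging")
DIVE_TYPES = ("shallow", "medium", "deep", "logging")
OBS_CHANNELS = ("max_depth", "dive_duration", "surface_interval")

LOG_FLOOR = -700.0  # exp(-700) ~ 1e-304, the probability floor
_ROW_TOL = 1e-10


@dataclass
class HHMMParams:
    """Full parameter set of the hierarchical model.

    ``emissions[d, c]`` holds the gamma ``(shape, scale)`` pair of dive
    type ``d``'s channel ``c`` (depth, duration, surface interval).
    """

    pi_coarse: np.ndarray            # (B,)
    gamma_coarse: np.ndarray         # (B, B)
    pi_fine: np.ndarray              # (B, D)
    gamma_fine: np.ndarray           # (B, D, D)
    emissions: np.ndarray            # (D, 3, 2)
    behaviours: tuple[str, ...] = BEHAVIOURS
    dive_types: tuple[str, ...] = DIVE_TYPES

    def __post_init__(self) -> None:
        self.pi_coarse = np.asarray(self.pi_coarse, dtype=float)
        self.gamma_coarse = np.asarray(self.gamma_coarse, dtype=float)
        self.pi_fine = np.asarray(self.pi_fine, dtype=float)
        self.gamma_fine = np.asarray(self.gamma_fine, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)

    @property
    def n_behaviours(self) -> int:
        return len(self.behaviours)

    @property
    def n_dive_types(self) -> int:
        return len(self.dive_types)

    def validate(self) -> None:
        B, D = self.n_behaviours, self.n_dive_types
        if self.pi_coarse.shape != (B,) or self.gamma_coarse.shape != (B, B):
            raise ValueError("coarse parameter shapes inconsistent with behaviours")
        if self.pi_fine.shape != (B, D) or self.gamma_fine.shape != (B, D, D):
            raise ValueError("fine parameter shapes inconsistent with dive types")
        if self.emissions.shape != (D, len(OBS_CHANNELS), 2):
            raise ValueError("emissions must have shape (D, 3, 2)")
        for name, arr in (("pi_coarse", self.pi_coarse[None, :]),
                          ("gamma_coarse", self.gamma_coarse),
                          ("pi_fine", self.pi_fine),
                          ("gamma_fine", self.gamma_fine.reshape(-1, D))):
            sums = arr.sum(axis=-1)
            if np.any(np.abs(sums - 1.0) > _ROW_TOL) or np.any(arr < 0):
                raise ValueError(f"{name} rows must be non-negative and sum to 1")
        if np.any(self.emissions <= 0):
            raise ValueError("emission parameters must be strictly positive")

    def copy(self) -> "HHMMParams":
        return HHMMParams(
            self.pi_coarse.copy(), self.gamma_coarse.copy(),
            self.pi_fine.copy(), self.gamma_fine.copy(), self.emissions.copy(),
            self.behaviours, self.dive_types,
        )


@dataclass
class TrackObs:
    """One track's dive observables and optional labels for the model.

    ``obs`` is ``(n_dives, 3)``; ``dive_constraints`` holds dive-type
    indices with -1 for unconstrained; ``video_behaviour`` and
    ``rule_behaviour`` are behaviour indices or -1.
    """

    obs: np.ndarray
    dive_constraints: np.ndarray = None  # type: ignore[assignment]
    video_behaviour: int = -1
    rule_behaviour: int = -1

    def __post_init__(self) -> None:
        self.obs = np.atleast_2d(np.asarray(self.obs, dtype=float))
        if self.dive_constraints is None:
            self.dive_constraints = np.full(self.obs.shape[0], -1, dtype=int)
        else:
            self.dive_constraints = np.asarray(self.dive_constraints, dtype=int)
        if self.obs.shape[0] != self.dive_constraints.shape[0]:
            raise ValueError("dive_constraints length must match obs")

    @property
    def n_dives(self) -> int:
        return self.obs.shape[0]

    def behaviour_constraint(self, use_video: bool = True) -> int:
        if use_video and self.video_behaviour >= 0:
            return self.video_behaviour
        return self.rule_behaviour


@dataclass
class WhaleObs:
    whale_id: str
    age_class: str
    tracks: list[TrackObs]


@dataclass
class DecodedStates:
    behaviours: np.ndarray           # (T,) behaviour index per track
    dive_types: list[np.ndarray]     # per track, (n_dives,) dive-type index
    posteriors: np.ndarray           # (T, B) track behaviour posteriors


# ---------------------------------------------------------------------------
# emissions and constraint masks

def emission_logdensity(params: HHMMParams, obs: np.ndarray) -> np.ndarray:
    """Per-dive, per-dive-type emission log density, shape (n, D)."""
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    n = obs.shape[0]
    D = params.n_dive_types
    logb = np.zeros((n, D))
    for d in range(D):
        for c in range(len(OBS_CHANNELS)):
            a, scale = params.emissions[d, c]
            x = obs[:, c]
            logb[:, d] += (a - 1.0) * np.log(x) - x / scale - gammaln(a) - a * np.log(scale)
    return np.maximum(logb, LOG_FLOOR * 3)


def _dive_mask(constraints: np.ndarray, D: int) -> np.ndarray:
    """(n, D) additive log mask: 0 allowed, -inf disallowed."""
    mask = np.zeros((constraints.shape[0], D))
    lab = constraints >= 0
    mask[lab] = -np.inf
    mask[lab, constraints[lab]] = 0.0
    return mask


def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


# ---------------------------------------------------------------------------
# fine level (dive types within one track)

def _fine_forward(log_pi: np.ndarray, log_gamma: np.ndarray,
                  logb: np.ndarray) -> tuple[float, np.ndarray]:
    n, D = logb.shape
    alpha = np.empty((n, D))
    alpha[0] = log_pi + logb[0]
    for t in range(1, n):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + log_gamma, axis=0) + logb[t]
    return float(logsumexp(alpha[-1])), alpha


def _fine_backward(log_gamma: np.ndarray, logb: np.ndarray) -> np.ndarray:
    n, D = logb.shape
    beta = np.zeros((n, D))
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(log_gamma + (logb[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def fine_track_likelihood(
    params: HHMMParams,
    behaviour: int | str,
    obs: np.ndarray,
    dive_constraints: Optional[np.ndarray] = None,
    logb: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of one track's dive sequence under a behaviour.

    ``-inf`` is a legitimate value (the behaviour assigns zero probability
    to the constrained path set); an all-impossible emission raises.
    """
    if isinstance(behaviour, str):
        behaviour = params.behaviours.index(behaviour)
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[0] == 0:
        raise ValueError("track must contain at least one dive")
    if logb is None:
        logb = emission_logdensity(params, obs)
    if dive_constraints is not None:
        mask = _dive_mask(np.asarray(dive_constraints, dtype=int), params.n_dive_types)
        if np.any(np.all(np.isinf(logb + mask), axis=1) & np.all(np.isinf(mask), axis=1)):
            raise ValueError("a dive constraint admits no state")
        logb = logb + mask
    ll, _ = _fine_forward(_safe_log(params.pi_fine[behaviour]),
                          _safe_log(params.gamma_fine[behaviour]), logb)
    return ll


# ---------------------------------------------------------------------------
# coarse level (behaviours over a whale's tracks)

def _track_emission_matrix(params: HHMMParams, whale: WhaleObs,
                           use_video: bool = True) -> np.ndarray:
    """(T, B) log fine-likelihood of each track under each behaviour,
    with behaviour constraints applied as -inf masks."""
    B = params.n_behaviours
    T = len(whale.tracks)
    E = np.empty((T, B))
    for t, track in enumerate(whale.tracks):
        logb = emission_logdensity(params, track.obs)
        logb = logb + _dive_mask(track.dive_constraints, params.n_dive_types)
        for b in range(B):
            E[t, b] = _fine_forward(_safe_log(params.pi_fine[b]),
                                    _safe_log(params.gamma_fine[b]), logb)[0]
        c = track.behaviour_constraint(use_video)
        if c >= 0:
            keep = E[t, c]
            E[t, :] = -np.inf
            E[t, c] = keep
    return E


def coarse_log_likelihood(params: HHMMParams, whale: WhaleObs,
                          use_video: bool = True) -> float:
    """Total log-likelihood of one whale's track sequence."""
    if not whale.tracks:
        raise ValueError("whale has no tracks")
    E = _track_emission_matrix(params, whale, use_video)
    log_pi = _safe_log(params.pi_coarse)
    log_gamma = _safe_log(params.gamma_coarse)
    alpha = log_pi + E[0]
    if np.all(np.isinf(alpha)):
        raise ValueError("impossible constraint set: zero-probability first track")
    for t in range(1, E.shape[0]):
        alpha = logsumexp(alpha[:, None] + log_gamma, axis=0) + E[t]
        if np.all(np.isinf(alpha)):
            raise ValueError(f"impossible constraint set at track {t}")
    return float(logsumexp(alpha))


def posterior_state_probs(params: HHMMParams, whale: WhaleObs,
                          use_video: bool = True) -> np.ndarray:
    """Per-track behaviour posteriors, rows summing to 1."""
    E = _track_emission_matrix(params, whale, use_video)
    log_pi = _safe_log(params.pi_coarse)
    log_gamma = _safe_log(params.gamma_coarse)
    _, alpha = _fine_forward(log_pi, log_gamma, E)
    beta = _fine_backward(log_gamma, E)
    post = alpha + beta
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post)


def viterbi_decode(params: HHMMParams, whale: WhaleObs,
                   use_video: bool = True) -> DecodedStates:
    """Joint maximum-probability decoding, coarse then fine.

    Ties break deterministically toward the lower state index.
    """
    E = _track_emission_matrix(params, whale, use_video)
    T, B = E.shape
    log_pi = _safe_log(params.pi_coarse)
    log_gamma = _safe_log(params.gamma_coarse)
    delta = np.empty((T, B))
    back = np.zeros((T, B), dtype=int)
    delta[0] = log_pi + E[0]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + log_gamma
        back[t] = np.argmax(scores, axis=0)  # first max -> lower index
        delta[t] = scores[back[t], np.arange(B)] + E[t]
    if np.all(np.isinf(delta[-1])):
        raise ValueError("impossible constraint set: no feasible behaviour path")
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]

    dive_paths: list[np.ndarray] = []
    for t, track in enumerate(whale.tracks):
        b = path[t]
        logb = emission_logdensity(params, track.obs)
        logb = logb + _dive_mask(track.dive_constraints, params.n_dive_types)
        dive_paths.append(_fine_viterbi(_safe_log(params.pi_fine[b]),
                                        _safe_log(params.gamma_fine[b]), logb))
    return DecodedStates(
        behaviours=path,
        dive_types=dive_paths,
        posteriors=posterior_state_probs(params, whale, use_video),
    )


def _fine_viterbi(log_pi: np.ndarray, log_gamma: np.ndarray,
                  logb: np.ndarray) -> np.ndarray:
    n, D = logb.shape
    delta = np.empty((n, D))
    back = np.zeros((n, D), dtype=int)
    delta[0] = log_pi + logb[0]
    for t in range(1, n):
        scores = delta[t - 1][:, None] + log_gamma
        back[t] = np.argmax(scores, axis=0)
        delta[t] = scores[back[t], np.arange(D)] + logb[t]
    if np.all(np.isinf(delta[-1])):
        raise ValueError("impossible dive constraint set")
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# EM fitting

def _weighted_gamma_mle(w_sum: float, wx_sum: float, wlogx_sum: float,
                        prev: tuple[float, float],
                        max_shape: float = 1e6) -> tuple[float, float]:
    """Weighted maximum-likelihood gamma (shape, scale) fit.

    Newton iteration on the shape equation ``log a - digamma(a) = s`` with
    ``s = log(mean) - mean(log)``; degenerate fits (s -> 0) are capped.
    """
    if w_sum <= 1e-10:
        return prev
    m = wx_sum / w_sum
    s = np.log(m) - wlogx_sum / w_sum
    if not np.isfinite(s) or s <= 1e-12:
        a = max_shape
    else:
        a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        for _ in range(40):
            f = np.log(a) - digamma(a) - s
            fp = 1.0 / a - polygamma(1, a)
            step = f / fp
            a_new = a - step
            if a_new <= 0:
                a_new = a / 2.0
            if abs(a_new - a) < 1e-12 * a:
                a = a_new
                break
            a = a_new
        a = min(max(a, 1e-3), max_shape)
    return float(a), float(max(m / a, 1e-12))


def _normalize_rows(num: np.ndarray, prev: np.ndarray) -> np.ndarray:
    out = prev.copy()
    sums = num.sum(axis=-1)
    ok = sums > 1e-300
    out[ok] = num[ok] / sums[ok][..., None]
    return out


def _em_e_step(params: HHMMParams, whales: Sequence[WhaleObs],
               use_video: bool = True) -> tuple[float, dict]:
    """One constrained forward-backward sweep; returns (loglik, stats)."""
    B, D, C = params.n_behaviours, params.n_dive_types, len(OBS_CHANNELS)
    stats = {
        "pi_coarse": np.zeros(B),
        "gamma_coarse": np.zeros((B, B)),
        "pi_fine": np.zeros((B, D)),
        "gamma_fine": np.zeros((B, D, D)),
        "w_sum": np.zeros((D, C)),
        "wx_sum": np.zeros((D, C)),
        "wlogx_sum": np.zeros((D, C)),
    }
    log_pi_c = _safe_log(params.pi_coarse)
    log_gamma_c = _safe_log(params.gamma_coarse)
    log_pi_f = _safe_log(params.pi_fine)
    log_gamma_f = _safe_log(params.gamma_fine)
    total_ll = 0.0

    for whale in whales:
        T = len(whale.tracks)
        E = np.empty((T, B))
        fine_post = []   # per track: (n, D) marginal posteriors per behaviour b
        fine_xi = []     # per track: (B, D, D)
        fine_first = []  # per track: (B, D)
        for t, track in enumerate(whale.tracks):
            logb = emission_logdensity(params, track.obs)
            logb = logb + _dive_mask(track.dive_constraints, D)
            n = track.n_dives
            post_b = np.zeros((B, n, D))
            xi_b = np.zeros((B, D, D))
            first_b = np.zeros((B, D))
            for b in range(B):
                ll, alpha = _fine_forward(log_pi_f[b], log_gamma_f[b], logb)
                E[t, b] = ll
                if not np.isfinite(ll):
                    continue
                beta = _fine_backward(log_gamma_f[b], logb)
                g = alpha + beta - ll
                post_b[b] = np.exp(np.maximum(g, LOG_FLOOR))
                first_b[b] = post_b[b][0]
                if n > 1:
                    # xi[t] summed over transitions, in log space pairwise
                    for u in range(n - 1):
                        pair = (alpha[u][:, None] + log_gamma_f[b]
                                + (logb[u + 1] + beta[u + 1])[None, :] - ll)
                        xi_b[b] += np.exp(np.maximum(pair, LOG_FLOOR))
            fine_post.append(post_b)
            fine_xi.append(xi_b)
            fine_first.append(first_b)
            c = track.behaviour_constraint(use_video)
            if c >= 0:
                keep = E[t, c]
                E[t, :] = -np.inf
                E[t, c] = keep

        ll_whale, alpha_c = _fine_forward(log_pi_c, log_gamma_c, E)
        if not np.isfinite(ll_whale):
            raise ValueError(f"impossible constraint set for whale {whale.whale_id}")
        beta_c = _fine_backward(log_gamma_c, E)
        w = np.exp(np.maximum(alpha_c + beta_c - ll_whale, LOG_FLOOR))  # (T, B)
        total_ll += ll_whale

        stats["pi_coarse"] += w[0]
        for t in range(T - 1):
            pair = (alpha_c[t][:, None] + log_gamma_c
                    + (E[t + 1] + beta_c[t + 1])[None, :] - ll_whale)
            stats["gamma_coarse"] += np.exp(np.maximum(pair, LOG_FLOOR))
        for t, track in enumerate(whale.tracks):
            for b in range(B):
                if w[t, b] <= 0:
                    continue
                stats["pi_fine"][b] += w[t, b] * fine_first[t][b]
                stats["gamma_fine"][b] += w[t, b] * fine_xi[t][b]
            u = np.einsum("b,bnd->nd", w[t], fine_post[t])  # (n, D)
            x = track.obs  # (n, C)
            stats["w_sum"] += u.sum(axis=0)[:, None]
            stats["wx_sum"] += u.T @ x
            stats["wlogx_sum"] += u.T @ np.log(x)
    return total_ll, stats


def _em_m_step(params: HHMMParams, stats: dict,
               smoothing: float = 0.0) -> HHMMParams:
    B, D, C = params.n_behaviours, params.n_dive_types, len(OBS_CHANNELS)
    new = params.copy()
    s = smoothing
    pc = stats["pi_coarse"] + s
    if pc.sum() > 0:
        new.pi_coarse = pc / pc.sum()
    new.gamma_coarse = _normalize_rows(stats["gamma_coarse"] + s, params.gamma_coarse)
    new.pi_fine = _normalize_rows(stats["pi_fine"] + s, params.pi_fine)
    new.gamma_fine = _normalize_rows(stats["gamma_fine"] + s, params.gamma_fine)
    for d in range(D):
        if stats["w_sum"][d, 0] <= 1e-8:
            log.warning("dive type %s has no effective data; emissions unchanged",
                        params.dive_types[d])
            continue
        for c in range(C):
            new.emissions[d, c] = _weighted_gamma_mle(
                stats["w_sum"][d, c], stats["wx_sum"][d, c],
                stats["wlogx_sum"][d, c], tuple(params.emissions[d, c]),
            )
    return new


def _perturb(params: HHMMParams, rng: np.random.Generator,
             conc: float = 50.0, emis_jitter: float = 0.15) -> HHMMParams:
    """Randomized restart: Dirichlet jitter on rows, lognormal on emissions."""
    new = params.copy()
    new.pi_coarse = rng.dirichlet(conc * params.pi_coarse + 1.0)
    new.gamma_coarse = np.stack(
        [rng.dirichlet(conc * row + 1.0) for row in params.gamma_coarse])
    new.pi_fine = np.stack([rng.dirichlet(conc * row + 1.0) for row in params.pi_fine])
    new.gamma_fine = np.stack(
        [np.stack([rng.dirichlet(conc * row + 1.0) for row in m])
         for m in params.gamma_fine])
    new.emissions = params.emissions * np.exp(
        rng.normal(0.0, emis_jitter, size=params.emissions.shape))
    return new


def fit_em(
    initial: HHMMParams,
    whales: Sequence[WhaleObs],
    tol: float = 1e-6,
    max_iter: int = 200,
    n_restarts: int = 1,
    seed: Optional[int] = None,
    use_video: bool = True,
    smoothing: float = 0.0,
) -> tuple[HHMMParams, list[float]]:
    """Constrained EM over all whales (independent sequences, shared params).

    Returns the best-scoring fit over ``n_restarts`` randomized initials
    (the first restart starts exactly at ``initial``) and its per-iteration
    log-likelihood trace.  With ``smoothing == 0`` this is pure EM and the
    trace is asserted non-decreasing up to a small numerical tolerance;
    ``smoothing > 0`` adds a Dirichlet pseudocount to the transition and
    initial-distribution counts (MAP-style), which keeps small-sample
    estimates away from exact zeros at the price of the raw-likelihood
    monotonicity guarantee.
    """
    initial.validate()
    if not whales:
        raise ValueError("dataset is empty")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, HHMMParams, list[float]] | None = None
    for r in range(n_restarts):
        params = initial.copy() if r == 0 else _perturb(initial, rng)
        trace: list[float] = []
        for it in range(max_iter):
            ll, stats = _em_e_step(params, whales, use_video)
            if trace and smoothing == 0.0:
                assert ll >= trace[-1] - 1e-7 * max(1.0, abs(trace[-1])), (
                    f"EM log-likelihood decreased: {trace[-1]} -> {ll}")
            improved = not trace or (ll - trace[-1]) > tol * max(1.0, abs(ll))
            trace.append(ll)
            params = _em_m_step(params, stats, smoothing)
            if not improved and it > 0:
                break
        final_ll = sum(coarse_log_likelihood(params, w, use_video) for w in whales)
        trace.append(final_ll)
        if best is None or final_ll > best[0]:
            best = (final_ll, params, trace)
    assert best is not None
    return best[1], best[2]
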