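"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own recursions: the
segmentation oracle is a linear threshold scan, and the likelihood
oracles enumerate every latent path, computing emission densities with
``scipy.stats.gamma`` rather than the package's hand-rolled log density.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from diveresp.hhmm import HHMMParams, TrackObs, WhaleObs
from diveresp.segmentation import DepthRecord


# ---------------------------------------------------------------------------
# segmentation oracle

def scan_segment_oracle(depth, fs, threshold):
    """Brute-force linear scan; returns [(start_idx, n, max_depth, si_s), ...]
    of complete dives under the same boundary conventions as the package:
    drop a dive truncated by the record end; trailing surface belongs to
    the final dive when the record ends at the surface."""
    runs = []
    in_dive = False
    for i, d in enumerate(depth):
        if d > threshold and not in_dive:
            runs.append([i, i + 1])
            in_dive = True
        elif d > threshold:
            runs[-1][1] = i + 1
        else:
            in_dive = False
    if runs and runs[-1][1] == len(depth):
        runs.pop()
    out = []
    for j, (a, b) in enumerate(runs):
        nxt = runs[j + 1][0] if j + 1 < len(runs) else len(depth)
        out.append((a, b - a, max(depth[a:b]), (nxt - b) / fs))
    return out


# ---------------------------------------------------------------------------
# likelihood enumeration oracles

def emission_ll_oracle(params: HHMMParams, obs: np.ndarray) -> np.ndarray:
    """(n, D) log emission density via scipy.stats.gamma."""
    obs = np.atleast_2d(obs)
    n, D = obs.shape[0], params.n_dive_types
    out = np.zeros((n, D))
    for d in range(D):
        for c in range(obs.shape[1]):
            a, scale = params.emissions[d, c]
            out[:, d] += gamma_dist.logpdf(obs[:, c], a, scale=scale)
    return out


def fine_ll_enumeration(params, b, obs, constraints=None):
    """Log-likelihood of one track under behaviour b by summing over all
    dive-type paths."""
    logb = emission_ll_oracle(params, obs)
    n, D = logb.shape
    total = -np.inf
    for path in itertools.product(range(D), repeat=n):
        if constraints is not None and any(
                c >= 0 and p != c for p, c in zip(path, constraints)):
            continue
        lp = np.log(params.pi_fine[b, path[0]]) if params.pi_fine[b, path[0]] > 0 else -np.inf
        for t in range(1, n):
            g = params.gamma_fine[b, path[t - 1], path[t]]
            lp += np.log(g) if g > 0 else -np.inf
        lp += sum(logb[t, path[t]] for t in range(n))
        total = np.logaddexp(total, lp)
    return total


def coarse_ll_enumeration(params, whale: WhaleObs, use_video=True):
    """Total log-likelihood by summing over all behaviour paths."""
    T, B = len(whale.tracks), params.n_behaviours
    fine = np.empty((T, B))
    for t, track in enumerate(whale.tracks):
        for b in range(B):
            fine[t, b] = fine_ll_enumeration(params, b, track.obs,
                                             track.dive_constraints)
    total = -np.inf
    for path in itertools.product(range(B), repeat=T):
        ok = all(
            whale.tracks[t].behaviour_constraint(use_video) < 0
            or path[t] == whale.tracks[t].behaviour_constraint(use_video)
            for t in range(T))
        if not ok:
            continue
        lp = np.log(params.pi_coarse[path[0]]) if params.pi_coarse[path[0]] > 0 else -np.inf
        for t in range(1, T):
            g = params.gamma_coarse[path[t - 1], path[t]]
            lp += np.log(g) if g > 0 else -np.inf
        lp += sum(fine[t, path[t]] for t in range(T))
        total = np.logaddexp(total, lp)
    return total


# ---------------------------------------------------------------------------
# random model / data builders

def random_params(rng, B=3, D=4) -> HHMMParams:
    behaviours = tuple(f"b{i}" for i in range(B)) if B != 3 else \
        ("resting", "travelling", "foraging")
    dive_types = tuple(f"d{i}" for i in range(D)) if D != 4 else \
        ("shallow", "medium", "deep", "logging")
    emissions = np.stack([
        np.column_stack([rng.uniform(1.0, 8.0, 3), rng.uniform(0.5, 10.0, 3)])
        for _ in range(D)
    ])
    return HHMMParams(
        pi_coarse=rng.dirichlet(np.ones(B)),
        gamma_coarse=np.stack([rng.dirichlet(np.ones(B)) for _ in range(B)]),
        pi_fine=np.stack([rng.dirichlet(np.ones(D)) for _ in range(B)]),
        gamma_fine=np.stack([np.stack([rng.dirichlet(np.ones(D)) for _ in range(D)])
                             for _ in range(B)]),
        emissions=emissions,
        behaviours=behaviours,
        dive_types=dive_types,
    )


def random_whale(params, rng, n_tracks, n_dives, label_frac=0.0,
                 constrain_frac=0.0, whale_id="w0", age_class="juvenile"):
    """Draw a whale's observations from the model itself."""
    B, D = params.n_behaviours, params.n_dive_types
    tracks = []
    b = rng.choice(B, p=params.pi_coarse)
    for t in range(n_tracks):
        if t > 0:
            b = rng.choice(B, p=params.gamma_coarse[b])
        obs = np.empty((n_dives, 3))
        cons = np.full(n_dives, -1)
        d = rng.choice(D, p=params.pi_fine[b])
        for i in range(n_dives):
            if i > 0:
                d = rng.choice(D, p=params.gamma_fine[b, d])
            for c in range(3):
                a, scale = params.emissions[d, c]
                obs[i, c] = rng.gamma(a, scale)
            if rng.random() < constrain_frac:
                cons[i] = d
        video = b if rng.random() < label_frac else -1
        tracks.append(TrackObs(obs, cons, video_behaviour=video))
    return WhaleObs(whale_id, age_class, tracks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
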