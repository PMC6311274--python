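"""Discrete-observation hidden Markov model over tissue-state ray series.

The model phi = (M, N, pi, A, B) has M=4 hidden tissue states (lumen, intima,
pathology, adventitia) and N=10 observation symbols. Because decoding starts
at the axis point, which lies inside the lumen, the initial distribution is
pinned at pi = (1, 0, 0, 0) and is not re-estimated. A is row-stochastic
(transitions), B is an N x M matrix whose columns are the per-state emission
distributions. Training is Baum-Welch (EM) with per-position scaling;
posterior state marginals ("similarity maps") come from the scaled
forward-backward recursions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .rays import STATE_NAMES

__all__ = [
    "HmmModel",
    "SimilarityMap",
    "init_hmm",
    "supervised_init",
    "forward_backward",
    "forward_backward_batch",
    "forward_loglik",
    "baum_welch",
    "map_decode",
    "training_precision",
    "match_states",
]

FORMAT_VERSION = 1


@dataclass
class HmmModel:
    """phi = (M, N, pi, A, B) with column-stochastic emissions B (N x M)."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    state_names: tuple[str, ...] = STATE_NAMES

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        M = len(self.pi)
        if self.A.shape != (M, M):
            raise ValueError(f"A must be {M}x{M}, got {self.A.shape}")
        if self.B.shape[1] != M:
            raise ValueError(f"B must have {M} columns, got {self.B.shape}")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of A must sum to 1")
        if not np.allclose(self.B.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("columns of B must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.pi)

    @property
    def n_symbols(self) -> int:
        return self.B.shape[0]

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "state_names": list(self.state_names),
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')}")
        return cls(np.asarray(d["pi"]), np.asarray(d["A"]), np.asarray(d["B"]),
                   tuple(d["state_names"]))

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "HmmModel":
        path = str(path)
        with open(path) as fh:
            d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_dict(d)


@dataclass
class SimilarityMap:
    """Posterior state marginals P(state | model, series), one row per sample."""

    posteriors: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.posteriors.ndim != 2:
            raise ValueError("posteriors must be an n x M matrix")
        if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("posterior rows must sum to 1")


def init_hmm(M: int = 4, N_obs: int = 10) -> HmmModel:
    """Uniform A and B; pi concentrated on the first (lumen) state."""
    if M < 1 or N_obs < 1:
        raise ValueError("state and symbol counts must be positive")
    pi = np.zeros(M)
    pi[0] = 1.0
    A = np.full((M, M), 1.0 / M)
    B = np.full((N_obs, M), 1.0 / N_obs)
    names = STATE_NAMES if M == len(STATE_NAMES) else tuple(f"s{i}" for i in range(M))
    return HmmModel(pi, A, B, names)


def supervised_init(
    observations: np.ndarray,
    states: np.ndarray,
    M: int = 4,
    N_obs: int = 10,
    pseudocount: float = 1.0,
) -> HmmModel:
    """A and B from labeled transition/emission counts; pi stays (1, 0, ..., 0).

    Fixes the semantic identity of the states (state m *is* tissue m), which
    uniform initialization cannot guarantee, and speeds up convergence.
    """
    obs = np.atleast_2d(np.asarray(observations))
    st = np.atleast_2d(np.asarray(states))
    if obs.shape != st.shape:
        raise ValueError("observations and states must align")
    A = np.full((M, M), pseudocount)
    np.add.at(A, (st[:, :-1].ravel(), st[:, 1:].ravel()), 1.0)
    A /= A.sum(axis=1, keepdims=True)
    B = np.full((N_obs, M), pseudocount)
    np.add.at(B, (obs.ravel(), st.ravel()), 1.0)
    B /= B.sum(axis=0, keepdims=True)
    pi = np.zeros(M)
    pi[0] = 1.0
    names = STATE_NAMES if M == len(STATE_NAMES) else tuple(f"s{i}" for i in range(M))
    return HmmModel(pi, A, B, names)


def _check_symbols(model: HmmModel, obs: np.ndarray) -> None:
    if obs.size and (obs.min() < 0 or obs.max() >= model.n_symbols):
        raise ValueError(
            f"symbols must lie in 0..{model.n_symbols - 1}, "
            f"got range [{obs.min()}, {obs.max()}]"
        )


def _forward_backward_arrays(model: HmmModel, obs2d: np.ndarray):
    """Scaled alpha/beta over a batch of equal-length sequences.

    Returns (alpha_hat (R,n,M), beta_hat (R,n,M), c (R,n)) with
    log-likelihood per sequence = sum(log c).
    """
    pi, A, B = model.pi, model.A, model.B
    R, n = obs2d.shape
    M = model.n_states
    alpha = np.empty((R, n, M))
    beta = np.empty((R, n, M))
    c = np.empty((R, n))

    a = pi[None, :] * B[obs2d[:, 0]]
    c[:, 0] = a.sum(axis=1)
    _raise_if_impossible(c[:, 0], 0)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, n):
        a = (alpha[:, t - 1] @ A) * B[obs2d[:, t]]
        c[:, t] = a.sum(axis=1)
        _raise_if_impossible(c[:, t], t)
        alpha[:, t] = a / c[:, t, None]

    beta[:, n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        b = (beta[:, t + 1] * B[obs2d[:, t + 1]]) @ A.T
        beta[:, t] = b / c[:, t + 1, None]
    return alpha, beta, c


def _raise_if_impossible(scale: np.ndarray, t: int) -> None:
    if np.any(scale <= 0):
        raise ValueError(
            f"observation sequence impossible under the model at position {t}"
        )


def forward_backward_batch(model: HmmModel, obs2d: np.ndarray):
    """Posteriors (R, n, M) and log-likelihoods (R,) for equal-length series."""
    obs2d = np.atleast_2d(np.asarray(obs2d))
    _check_symbols(model, obs2d)
    alpha, beta, c = _forward_backward_arrays(model, obs2d)
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post, np.log(c).sum(axis=1)


def forward_backward(model: HmmModel, obs) -> SimilarityMap:
    """Exact posterior state marginals for one observation series."""
    obs = np.asarray(obs)
    post, ll = forward_backward_batch(model, obs[None, :])
    return SimilarityMap(post[0], float(ll[0]))


def forward_loglik(model: HmmModel, obs) -> float:
    """Sequence log-likelihood from the forward recursion alone."""
    obs2d = np.atleast_2d(np.asarray(obs))
    _check_symbols(model, obs2d)
    _, _, c = _forward_backward_arrays(model, obs2d)
    return float(np.log(c).sum())


def baum_welch(
    model: HmmModel,
    training,
    tol: float = 1e-6,
    max_iter: int = 500,
    fix_pi: bool = True,
    floor: float = 1e-6,
) -> tuple[HmmModel, dict]:
    """EM re-estimation of (A, B) from observation series.

    ``training`` is a list of 1-D symbol arrays or an (R, n) array of
    equal-length series. pi is held at (1, 0, ..., 0) unless ``fix_pi`` is
    False. After each M-step, entries are floored at ``floor`` and rows of A /
    columns of B renormalized so no probability locks at exactly zero.
    Stops when the relative total log-likelihood improvement drops below
    ``tol``. Returns the trained model and an info dict with the per-iteration
    log-likelihood history.
    """
    batches = _as_batches(training)
    if not batches:
        raise ValueError("empty training set")
    M, N = model.n_states, model.n_symbols
    for b in batches:
        _check_symbols(model, b)

    pi, A, B = model.pi.copy(), model.A.copy(), model.B.copy()
    history = []
    for it in range(max_iter):
        cur = HmmModel(pi, A, B, model.state_names)
        A_num = np.zeros((M, M))
        B_num = np.zeros((N, M))
        gamma_from = np.zeros(M)   # expected visits excluding the last position
        gamma_all = np.zeros(M)
        pi_num = np.zeros(M)
        ll = 0.0
        for obs2d in batches:
            alpha, beta, c = _forward_backward_arrays(cur, obs2d)
            ll += float(np.log(c).sum())
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            pi_num += gamma[:, 0].sum(axis=0)
            gamma_all += gamma.sum(axis=(0, 1))
            gamma_from += gamma[:, :-1].sum(axis=(0, 1))
            n = obs2d.shape[1]
            for t in range(n - 1):
                xi = (
                    alpha[:, t, :, None]
                    * A[None, :, :]
                    * (B[obs2d[:, t + 1]] * beta[:, t + 1])[:, None, :]
                )
                xi /= xi.sum(axis=(1, 2), keepdims=True)
                A_num += xi.sum(axis=0)
            np.add.at(B_num, obs2d.ravel(), gamma.reshape(-1, M))
        history.append(ll)

        A = A_num / np.where(gamma_from > 0, gamma_from, 1.0)[:, None]
        A[gamma_from == 0] = 1.0 / M
        B = B_num / np.where(gamma_all > 0, gamma_all, 1.0)[None, :]
        B[:, gamma_all == 0] = 1.0 / N
        A = np.maximum(A, floor)
        A /= A.sum(axis=1, keepdims=True)
        B = np.maximum(B, floor)
        B /= B.sum(axis=0, keepdims=True)
        if not fix_pi:
            pi = pi_num / pi_num.sum()

        if len(history) > 1:
            prev = history[-2]
            if ll + 1e-8 < prev:
                warnings.warn(f"log-likelihood decreased at iteration {it}")
            if abs(ll - prev) < tol * max(1.0, abs(prev)):
                break

    trained = HmmModel(pi, A, B, model.state_names)
    final_ll = sum(
        float(np.log(_forward_backward_arrays(trained, b)[2]).sum()) for b in batches
    )
    history.append(final_ll)
    return trained, {"log_likelihood": history, "n_iter": len(history) - 1}


def _as_batches(training) -> list[np.ndarray]:
    """Group series by length into 2-D batches for vectorized E-steps."""
    if isinstance(training, np.ndarray) and training.ndim == 2:
        return [training.astype(int)] if training.size else []
    groups: dict[int, list] = {}
    for seq in training:
        seq = np.asarray(seq, dtype=int)
        groups.setdefault(len(seq), []).append(seq)
    return [np.stack(v) for v in groups.values()]


def map_decode(similarity: SimilarityMap | np.ndarray) -> np.ndarray:
    """Per-position argmax of the posterior rows; ties go to the lower state."""
    post = similarity.posteriors if isinstance(similarity, SimilarityMap) else similarity
    return np.argmax(post, axis=-1)


def training_precision(model: HmmModel, labeled, positive_states=(0, 1)) -> float:
    """Per-voxel precision TP / (TP + FP) of decoded vessel calls.

    ``labeled`` is an iterable of (observation series, state-label series);
    a call is positive when the decoded state is lumen or intima, a truth
    when the label is. Returns 0 (with a warning) when nothing is called
    positive.
    """
    tp = fp = 0
    positive = set(positive_states)
    for obs, states in labeled:
        obs = np.asarray(obs)
        states = np.asarray(states)
        if len(obs) != len(states):
            raise ValueError("observation/label length mismatch")
        decoded = map_decode(forward_backward(model, obs))
        called = np.isin(decoded, list(positive))
        truth = np.isin(states, list(positive))
        tp += int(np.sum(called & truth))
        fp += int(np.sum(called & ~truth))
    if tp + fp == 0:
        warnings.warn("no positive calls; precision defined as 0")
        return 0.0
    return tp / (tp + fp)


def match_states(model: HmmModel, labeled) -> tuple[HmmModel, np.ndarray]:
    """Permute states to best agree with labels (for uniform-init training).

    Builds the decoded-vs-true contingency table over ``labeled`` and solves
    the maximum-agreement assignment; returns the permuted model (columns of
    B, rows/cols of A, entries of pi reordered) and the permutation, where
    ``perm[new_state] = old_state``.
    """
    from scipy.optimize import linear_sum_assignment

    M = model.n_states
    agree = np.zeros((M, M))
    for obs, states in labeled:
        decoded = map_decode(forward_backward(model, np.asarray(obs)))
        np.add.at(agree, (np.asarray(states), decoded), 1.0)
    true_idx, old_idx = linear_sum_assignment(-agree)
    perm = np.empty(M, dtype=int)
    perm[true_idx] = old_idx
    permuted = HmmModel(
        model.pi[perm], model.A[np.ix_(perm, perm)], model.B[:, perm],
        model.state_names,
    )
    return permuted, perm
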