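"""Constrained hidden Markov model of migratory behaviour.

Three latent states — resident (1), outward migration (2), inward
migration (3) — drive the signed daily displacement from the GAB
reference, d_t.  Each state emits d_t ~ Normal(mu_i, sigma_i); resident has
mu near 0, outward a positive mean, inward a negative mean (its magnitude
is what gets reported).  The transition matrix carries *structural zeros*:
a fish cannot switch directly between outward and inward migration, it
must pass through the resident state (possibly for a single day), so
pi_{2,3} = pi_{3,2} = 0 exactly and only four transition parameters are
free.  One-way migrants (track censored before any return) are handled by
a nested two-state model using only the resident and one migratory state.

Inference is classical Baum-Welch EM with scaled forward-backward
recursions (monotone in likelihood, safe for tracks of 10^4+ steps) and
Viterbi decoding for the most-likely state path.  Zero transition entries
are invariant under the EM update, so the structural constraint is
preserved exactly through fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "RESIDENT", "OUTWARD", "INWARD",
    "HmmParams", "Decoding", "FitResult",
    "validate_transition_matrix", "stationary_distribution",
    "forward_loglik", "posterior_probs", "viterbi_decode", "decode_tracks",
    "default_init", "fit_em", "fit_two_state",
    "save_params", "load_params",
]

RESIDENT, OUTWARD, INWARD = 0, 1, 2
STATE_LABELS_3 = ("resident", "outward", "inward")
STATE_LABELS_2 = ("resident", "migratory")
# direct outward <-> inward switches are forbidden by model design
STRUCTURAL_ZEROS_3 = ((OUTWARD, INWARD), (INWARD, OUTWARD))

_ROW_SUM_TOL = 1e-10


def validate_transition_matrix(P: np.ndarray, structural_zeros=()) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if np.max(np.abs(P.sum(axis=1) - 1.0)) > _ROW_SUM_TOL:
        raise ValueError("transition matrix rows must sum to 1")
    for i, j in structural_zeros:
        if P[i, j] != 0.0:
            raise ValueError(f"structural zero at ({i},{j}) violated: {P[i, j]}")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left eigenvector of P for eigenvalue 1, normalized to a distribution.

    Raises for reducible chains (some state unreachable from another along
    allowed transitions), for which long-run occupancy is ill-defined.
    """
    P = validate_transition_matrix(P)
    n = P.shape[0]
    reach = np.linalg.matrix_power(np.eye(n) + (P > 0), n)
    if np.any(reach == 0):
        raise ValueError("transition matrix is reducible; no unique stationary distribution")
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    # one refinement step squeezes eigen-solver noise well below 1e-12
    pi = pi @ P
    return pi / pi.sum()


@dataclass
class HmmParams:
    """Transition matrix, per-state normal emissions and initial weights."""

    transition: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    initial: np.ndarray | None = None
    state_labels: tuple[str, ...] = STATE_LABELS_3
    structural_zeros: tuple[tuple[int, int], ...] = STRUCTURAL_ZEROS_3

    def __post_init__(self) -> None:
        self.transition = validate_transition_matrix(self.transition, self.structural_zeros)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n = self.transition.shape[0]
        if not (len(self.means) == len(self.sds) == len(self.state_labels) == n):
            raise ValueError("inconsistent state count across parameters")
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be positive")
        if self.initial is None:
            self.initial = stationary_distribution(self.transition)
        self.initial = np.asarray(self.initial, dtype=float)
        if abs(self.initial.sum() - 1.0) > 1e-8 or np.any(self.initial < 0):
            raise ValueError("initial distribution must be a probability vector")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def to_dict(self) -> dict:
        return {
            "transition": self.transition.tolist(),
            "emission_means": self.means.tolist(),
            "emission_sds": self.sds.tolist(),
            "initial": self.initial.tolist(),
            "state_labels": list(self.state_labels),
            "structural_zeros": [list(ij) for ij in self.structural_zeros],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        return cls(
            transition=np.array(d["transition"], dtype=float),
            means=np.array(d["emission_means"], dtype=float),
            sds=np.array(d["emission_sds"], dtype=float),
            initial=np.array(d["initial"], dtype=float),
            state_labels=tuple(d["state_labels"]),
            structural_zeros=tuple(tuple(ij) for ij in d.get("structural_zeros", [])),
        )


def save_params(params: HmmParams, path) -> None:
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(params.to_dict(), fh, indent=2)
        else:
            yaml.safe_dump(params.to_dict(), fh)


def load_params(path) -> HmmParams:
    path = str(path)
    with open(path) as fh:
        d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return HmmParams.from_dict(d)


@dataclass
class Decoding:
    """Viterbi path, posterior state probabilities and track log-likelihood."""

    states: np.ndarray          # (T,) int Viterbi path
    posteriors: np.ndarray      # (T, S) forward-backward marginals
    loglik: float
    state_labels: tuple[str, ...] = STATE_LABELS_3


def _check_obs(obs: np.ndarray) -> np.ndarray:
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    bad = ~np.isfinite(obs)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise ValueError(f"non-finite observation at index {tuple(int(i) for i in idx)}")
    return obs


def _emission_pdf(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """Normal emission densities, shape (N, T, S) for batched obs (N, T)."""
    z = (obs[..., None] - params.means) / params.sds
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * params.sds)


def _forward(B: np.ndarray, params: HmmParams):
    """Scaled forward pass.  B: (N, T, S).  Returns alpha, scales, logliks."""
    N, T, S = B.shape
    alpha = np.empty((N, T, S))
    scales = np.empty((N, T))
    a = params.initial[None, :] * B[:, 0]
    c = a.sum(axis=1)
    if np.any(c <= 0):
        raise FloatingPointError("zero forward mass at t=0 (observation impossible under model)")
    alpha[:, 0] = a / c[:, None]
    scales[:, 0] = c
    P = params.transition
    for t in range(1, T):
        a = (alpha[:, t - 1] @ P) * B[:, t]
        c = a.sum(axis=1)
        if np.any(c <= 0):
            raise FloatingPointError(f"zero forward mass at t={t}")
        alpha[:, t] = a / c[:, None]
        scales[:, t] = c
    return alpha, scales, np.log(scales).sum(axis=1)


def _backward(B: np.ndarray, scales: np.ndarray, params: HmmParams) -> np.ndarray:
    N, T, S = B.shape
    beta = np.empty((N, T, S))
    beta[:, T - 1] = 1.0
    P = params.transition
    for t in range(T - 2, -1, -1):
        beta[:, t] = ((B[:, t + 1] * beta[:, t + 1]) @ P.T) / scales[:, t + 1][:, None]
    return beta


def forward_loglik(obs: np.ndarray, params: HmmParams) -> float:
    """Log-likelihood of one observation series under the model."""
    obs = _check_obs(obs)
    B = _emission_pdf(obs, params)
    _, _, ll = _forward(B, params)
    return float(ll[0])


def posterior_probs(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """Forward-backward smoothed state marginals, rows summing to 1."""
    obs = _check_obs(obs)
    B = _emission_pdf(obs, params)
    alpha, scales, _ = _forward(B, params)
    beta = _backward(B, scales, params)
    gamma = alpha * beta
    return (gamma / gamma.sum(axis=2, keepdims=True))[0]


def viterbi_decode(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """Globally most probable state path (log-domain dynamic programme).

    Structurally forbidden transitions have probability 0 hence log -inf
    and can never enter the optimal path.
    """
    obs = _check_obs(obs)[0]
    T, S = len(obs), params.n_states
    with np.errstate(divide="ignore"):
        logP = np.log(params.transition)
        logB = np.log(_emission_pdf(obs[None, :], params)[0])
        logdelta = np.log(params.initial)
    score = logdelta + logB[0]
    back = np.zeros((T, S), dtype=np.intp)
    for t in range(1, T):
        cand = score[:, None] + logP
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(S)] + logB[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_tracks(obs_list, params: HmmParams) -> list[Decoding]:
    """Viterbi path + posteriors + loglik for each observation series."""
    out = []
    for obs in obs_list:
        obs = np.asarray(obs, dtype=float)
        out.append(Decoding(
            states=viterbi_decode(obs, params),
            posteriors=posterior_probs(obs, params),
            loglik=forward_loglik(obs, params),
            state_labels=params.state_labels,
        ))
    return out


@dataclass
class FitResult:
    params: HmmParams
    loglik: float
    loglik_history: np.ndarray
    converged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)


def default_init(obs_list, n_states: int = 3, self_transition: float = 0.9) -> HmmParams:
    """Neutral, data-driven starting point for EM.

    Means from the pooled (10%, 50%, 90%) displacement quantiles mapped to
    (inward, resident, outward); common SD from the pooled spread;
    persistent self-transitions.  For two states, (50%, 90%) quantiles map
    to (resident, migratory).
    """
    pooled = np.concatenate([np.asarray(o, dtype=float) for o in obs_list])
    sd = max(float(np.std(pooled)), 1.0)
    if n_states == 3:
        q10, q50, q90 = np.quantile(pooled, [0.10, 0.50, 0.90])
        means = np.array([q50, q90, q10])  # resident, outward, inward
        labels, zeros = STATE_LABELS_3, STRUCTURAL_ZEROS_3
    elif n_states == 2:
        q50, q90 = np.quantile(pooled, [0.50, 0.90])
        means = np.array([q50, q90])
        labels, zeros = STATE_LABELS_2, ()
    else:
        raise ValueError("only 2- or 3-state models are supported")
    if np.ptp(means) < 1e-6:  # degenerate data; separate arbitrarily
        means = means + np.linspace(-sd, sd, n_states)[np.argsort(np.argsort(means))]
    P = np.full((n_states, n_states), (1.0 - self_transition) / (n_states - 1))
    np.fill_diagonal(P, self_transition)
    for i, j in zeros:
        P[i, i] += P[i, j]
        P[i, j] = 0.0
    return HmmParams(P, means, np.full(n_states, sd), state_labels=labels, structural_zeros=zeros)


def _relabel(params: HmmParams) -> HmmParams:
    """Resolve label switching: sort by emission mean.

    Three states: most negative mean -> inward, middle -> resident, most
    positive -> outward.  Two states: smaller |mean| -> resident.
    """
    if params.n_states == 3:
        order_sorted = np.argsort(params.means)       # [inward, resident, outward]
        perm = order_sorted[[1, 2, 0]]                # -> (resident, outward, inward)
    else:
        perm = np.argsort(np.abs(params.means))
    if np.array_equal(perm, np.arange(params.n_states)):
        return params
    P = params.transition[np.ix_(perm, perm)]
    for i, j in params.structural_zeros:
        P[i, j] = 0.0
        P[i] = P[i] / P[i].sum()
    return HmmParams(P, params.means[perm], params.sds[perm], params.initial[perm] / params.initial[perm].sum(),
                     params.state_labels, params.structural_zeros)


def _em_single(groups, init: HmmParams, tol: float, max_iter: int, sigma_floor: float):
    params = init
    history = []
    prev = -np.inf
    converged = False
    n_done = 0
    for it in range(max_iter):
        ll_total = 0.0
        S = params.n_states
        g0_sum = np.zeros(S)
        n_seq = 0
        xi_sum = np.zeros((S, S))
        w_sum = np.zeros(S)
        wx_sum = np.zeros(S)
        wxx_sum = np.zeros(S)
        P = params.transition
        for obs in groups:  # obs: (N, T) equal-length batch
            B = _emission_pdf(obs, params)
            alpha, scales, ll = _forward(B, params)
            beta = _backward(B, scales, params)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            ll_total += float(ll.sum())
            g0_sum += gamma[:, 0].sum(axis=0)
            n_seq += obs.shape[0]
            # xi_t(i,j) = alpha_t(i) P(i,j) B_{t+1}(j) beta_{t+1}(j) / c_{t+1}
            bb = B[:, 1:] * beta[:, 1:] / scales[:, 1:, None]
            xi_sum += np.einsum("nti,ij,ntj->ij", alpha[:, :-1], P, bb)
            w = gamma.reshape(-1, S)
            x = obs.reshape(-1)
            w_sum += w.sum(axis=0)
            wx_sum += w.T @ x
            wxx_sum += w.T @ (x * x)
        history.append(ll_total)
        n_done = it + 1
        if ll_total - prev <= tol * (abs(prev) + 1.0) and it > 0:
            converged = True
            break
        prev = ll_total
        # M-step (pooled across tracks)
        newP = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        for i, j in params.structural_zeros:
            newP[i, j] = 0.0
        newP /= newP.sum(axis=1, keepdims=True)
        means = wx_sum / w_sum
        var = wxx_sum / w_sum - means ** 2
        if np.any(var < (1e-3) ** 2):
            raise ValueError(
                "emission variance collapsed during EM; supply more data or raise the variance floor")
        sds = np.maximum(np.sqrt(var), sigma_floor)
        params = HmmParams(newP, means, sds, g0_sum / n_seq,
                           params.state_labels, params.structural_zeros)
    return params, np.asarray(history), converged, n_done


def _group_by_length(obs_list):
    """Stack equal-length series so forward-backward vectorizes across tracks."""
    by_len: dict[int, list] = {}
    for obs in obs_list:
        obs = np.asarray(obs, dtype=float)
        if obs.ndim != 1 or len(obs) < 2:
            raise ValueError("each observation series must be 1-D with length >= 2")
        _check_obs(obs)
        by_len.setdefault(len(obs), []).append(obs)
    return [np.vstack(v) for v in by_len.values()]


def fit_em(obs_list, init: HmmParams | None = None, *, n_states: int = 3,
           tol: float = 1e-8, max_iter: int = 500, n_restarts: int = 5,
           sigma_floor: float = 0.1, random_state: int | None = 0) -> FitResult:
    """Pooled Baum-Welch fit across all tracks.

    One parameter set is estimated for the whole population (per-track
    decoding happens afterwards with :func:`decode_tracks`).  Multiple
    restarts perturb the starting emissions; the best final likelihood
    wins.  States are relabeled post hoc so that the most negative fitted
    mean is inward, the most positive outward, the middle resident.
    """
    if not obs_list:
        raise ValueError("need at least one observation series")
    groups = _group_by_length(obs_list)
    base = init if init is not None else default_init(obs_list, n_states=n_states)
    rng = np.random.default_rng(random_state)
    spread = max(float(np.ptp(base.means)), 1.0)

    best = None
    warn_msgs: list[str] = []
    for r in range(max(1, n_restarts)):
        if r == 0:
            start = base
        else:
            means = base.means + rng.normal(0.0, 0.15 * spread, size=base.n_states)
            sds = base.sds * np.exp(rng.normal(0.0, 0.2, size=base.n_states))
            start = replace(base, means=means, sds=np.maximum(sds, sigma_floor))
        params, history, converged, n_iter = _em_single(groups, start, tol, max_iter, sigma_floor)
        if best is None or history[-1] > best[1][-1]:
            best = (params, history, converged, n_iter)
    params, history, converged, n_iter = best
    if not converged:
        msg = f"EM did not converge in {n_iter} iterations (returning best parameters)"
        warn_msgs.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return FitResult(_relabel(params), float(history[-1]), history, converged, n_iter, warn_msgs)


def fit_two_state(obs_list, init: HmmParams | None = None, **kwargs) -> FitResult:
    """Two-state (resident / migratory) fit for one-way migrant tracks.

    The transition matrix is the upper-left 2x2 block of the 3-state
    structure; the migratory emission mean is unconstrained in sign, so the
    same reduced model serves outward-only and inward-only migrants.
    """
    return fit_em(obs_list, init=init, n_states=2, **kwargs)
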