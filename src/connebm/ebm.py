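"""Event-based model core: sequencing, MCMC uncertainty, bootstrap, staging.

The event-based model assumes every subject sits at an unknown stage k of a
single cascade: the first k events of a sequence S have occurred, the rest
have not. With a uniform prior over the N+1 stages the likelihood of one
subject's measurements x is

    P(x | S) = 1/(N+1) * sum_k  prod_{i<=k} P(x_i | event) * prod_{i>k} P(x_i | no event)

where the conditional densities come from the per-biomarker KDE mixtures.
The maximum-likelihood sequence is found by greedy pairwise-swap ascent with
random restarts; positional uncertainty by a Metropolis chain over
permutations with transposition proposals; cross-validation by refitting the
sequence to bootstrap resamples of subjects (mixture fits held fixed); and
patients are staged by the posterior over k given the ML sequence.

All arithmetic is in the log domain with per-subject scaling so cohorts with
~40 events do not underflow. Transposing two positions only changes the
staged terms between them, which gives an O(subjects) update per candidate
swap / MCMC proposal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import NumericalError

__all__ = [
    "EBMData",
    "EventSequence",
    "MCMCSamples",
    "sequence_loglik",
    "greedy_ascent",
    "mcmc_sample",
    "positional_variance",
    "bootstrap_sequences",
    "stage_subjects",
]

_LOG_FLOOR = -745.0  # log of the smallest positive double


@dataclass
class EBMData:
    """Per subject x event log-densities under the event / no-event components."""

    log_p_event: np.ndarray = field(repr=False)  # (n_subjects, n_events)
    log_p_noevent: np.ndarray = field(repr=False)
    event_names: list[str] = field(default_factory=list)

    @classmethod
    def from_densities(
        cls,
        p_event: np.ndarray,
        p_noevent: np.ndarray,
        event_names: list[str] | None = None,
    ) -> "EBMData":
        p_event = np.asarray(p_event, float)
        p_noevent = np.asarray(p_noevent, float)
        if p_event.shape != p_noevent.shape or p_event.ndim != 2:
            raise ValueError("density matrices must share a (subjects, events) shape")
        if np.any(~np.isfinite(p_event)) or np.any(~np.isfinite(p_noevent)):
            raise ValueError("densities must be finite")
        if np.any(p_event < 0) or np.any(p_noevent < 0):
            raise ValueError("densities must be nonnegative")
        names = event_names or [f"event{j}" for j in range(p_event.shape[1])]
        if len(names) != p_event.shape[1]:
            raise ValueError("one name per event required")
        with np.errstate(divide="ignore"):
            return cls(
                np.maximum(np.log(p_event), _LOG_FLOOR),
                np.maximum(np.log(p_noevent), _LOG_FLOOR),
                list(names),
            )

    @property
    def n_subjects(self) -> int:
        return self.log_p_event.shape[0]

    @property
    def n_events(self) -> int:
        return self.log_p_event.shape[1]

    def subset(self, idx: np.ndarray) -> "EBMData":
        return EBMData(self.log_p_event[idx], self.log_p_noevent[idx], self.event_names)


@dataclass
class EventSequence:
    """A permutation of event indices (position -> event) with its log-likelihood."""

    order: np.ndarray
    loglik: float = np.nan

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if sorted(self.order.tolist()) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of 0..N-1")

    def event_labels(self, data: EBMData) -> list[str]:
        return [data.event_names[i] for i in self.order]


@dataclass
class MCMCSamples:
    sequences: np.ndarray = field(repr=False)  # (n_samples, n_events)
    logliks: np.ndarray = field(repr=False)
    acceptance_rate: float = np.nan
    seed: int = 0


def _stage_logmatrix(data: EBMData, order: np.ndarray) -> np.ndarray:
    """T[s, k] = log prod_{i<=k} p_event + log prod_{i>k} p_noevent, k = 0..N."""
    A = data.log_p_event[:, order]
    B = data.log_p_noevent[:, order]
    S = A.shape[0]
    zeros = np.zeros((S, 1))
    ca = np.concatenate([zeros, np.cumsum(A, axis=1)], axis=1)
    cb = np.concatenate([zeros, np.cumsum(B, axis=1)], axis=1)
    total_b = cb[:, -1:]
    return ca + (total_b - cb)


def _check_nonzero(T: np.ndarray, n_events: int) -> None:
    """Raise when a subject's likelihood is zero at every stage.

    Densities of exactly 0 are floored at the smallest positive double when
    the data matrix is built, so a subject whose every stage product sits at
    the floor has no usable likelihood under any stage.
    """
    bad = T.max(axis=1) <= _LOG_FLOOR * max(1, n_events) + 1.0
    if bad.any():
        raise NumericalError(
            f"zero total likelihood for subject(s) {np.nonzero(bad)[0].tolist()}"
        )


def sequence_loglik(data: EBMData, s: EventSequence | np.ndarray) -> float:
    """Total log-likelihood of a sequence under the uniform-stage EBM."""
    order = s.order if isinstance(s, EventSequence) else np.asarray(s, int)
    T = _stage_logmatrix(data, order)
    _check_nonzero(T, data.n_events)
    per_subject = logsumexp(T, axis=1)
    return float(per_subject.sum() - data.n_subjects * np.log(data.n_events + 1))


def _swap_scan(T: np.ndarray, A: np.ndarray, B: np.ndarray):
    """Log-likelihood of every pairwise transposition of the current order.

    ``T`` is the staged log matrix for the current order, ``A``/``B`` the
    event/no-event log densities already arranged in that order. Swapping
    positions p < q flips the contribution of those two events for exactly the
    stages k in {p+1..q}, shifting them by a per-subject constant; range sums
    of exp(T) give each candidate in O(subjects).
    Returns (pair index arrays p, q, per-pair total log-likelihood).
    """
    S, N = A.shape
    m = T.max(axis=1, keepdims=True)
    E = np.exp(T - m)
    P = np.concatenate([np.zeros((S, 1)), np.cumsum(E, axis=1)], axis=1)
    total = P[:, -1]
    pi, qi = np.triu_indices(N, k=1)
    inner = P[:, qi + 1] - P[:, pi + 1]  # stages p+1..q
    outer = np.maximum(total[:, None] - inner, 0.0)
    delta = (A[:, qi] - A[:, pi]) + (B[:, pi] - B[:, qi])
    with np.errstate(divide="ignore"):
        cand = np.logaddexp(np.log(outer), np.log(inner) + delta) + m
    return pi, qi, cand.sum(axis=0)


def _ascend(data: EBMData, order: np.ndarray) -> tuple[np.ndarray, float]:
    """Best-improvement pairwise-swap hill climb from one starting permutation."""
    order = order.copy()
    n_prior = np.log(data.n_events + 1) * data.n_subjects
    while True:
        A = data.log_p_event[:, order]
        B = data.log_p_noevent[:, order]
        T = _stage_logmatrix(data, order)
        cur = logsumexp(T, axis=1).sum()
        pi, qi, cand = _swap_scan(T, A, B)
        best = int(np.argmax(cand))
        if cand[best] <= cur + 1e-10:
            return order, float(cur - n_prior)
        p, q = pi[best], qi[best]
        order[p], order[q] = order[q], order[p]


def greedy_ascent(data: EBMData, seed: int = 0, n_restarts: int = 10) -> EventSequence:
    """Maximum-likelihood sequence by seeded multi-restart greedy swap ascent.

    One restart starts from the events ordered by decreasing prevalence
    (mean of p_event / (p_event + p_noevent) across subjects) — under the
    model, earlier events are abnormal in more subjects, so this start
    usually sits in the basin of the optimum; the remaining restarts are
    random permutations.
    """
    if data.n_events < 2:
        raise ValueError("sequencing needs >= 2 events")
    rng = np.random.default_rng(seed)
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + np.exp(data.log_p_noevent - data.log_p_event))
    informed = np.argsort(-frac.mean(axis=0), kind="stable").astype(int)
    starts = [informed] + [rng.permutation(data.n_events) for _ in range(max(0, n_restarts - 1))]
    best_order, best_ll = None, -np.inf
    for start in starts:
        order, ll = _ascend(data, start)
        if ll > best_ll:
            best_order, best_ll = order, ll
    return EventSequence(order=best_order, loglik=best_ll)


def mcmc_sample(
    data: EBMData,
    init: EventSequence,
    n_samples: int = 50_000,
    seed: int = 0,
    burn_in: float = 0.5,
) -> MCMCSamples:
    """Metropolis chain over sequences with uniform transposition proposals.

    ``n_samples`` post-burn-in states are recorded (every state, including
    repeats after rejection); the burn-in fraction of the total chain is
    discarded, so the chain runs n_samples / (1 - burn_in) proposals in all.
    Acceptance probability is min(1, exp(delta log-likelihood)).
    """
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    N = data.n_events
    n_burn = int(round(burn_in / (1.0 - burn_in) * n_samples))
    total = n_burn + n_samples
    order = init.order.copy()
    A = data.log_p_event
    B = data.log_p_noevent
    T = _stage_logmatrix(data, order)
    cur = logsumexp(T, axis=1)  # per-subject, prior constant omitted
    # pre-draw proposals
    p_idx = rng.integers(0, N, size=total)
    q_idx = rng.integers(0, N - 1, size=total)
    q_idx = np.where(q_idx >= p_idx, q_idx + 1, q_idx)
    log_u = np.log(rng.random(total))
    seqs = np.empty((n_samples, N), dtype=np.int16)
    lls = np.empty(n_samples)
    accepted = 0
    log_prior = data.n_subjects * np.log(N + 1)
    for t in range(total):
        p, q = int(p_idx[t]), int(q_idx[t])
        if p > q:
            p, q = q, p
        ep, eq = order[p], order[q]
        delta = (A[:, eq] - A[:, ep]) + (B[:, ep] - B[:, eq])
        m = T.max(axis=1)
        E = np.exp(T - m[:, None])
        inner = E[:, p + 1 : q + 1].sum(axis=1)
        outer = np.maximum(E.sum(axis=1) - inner, 0.0)
        with np.errstate(divide="ignore"):
            new = np.logaddexp(np.log(outer), np.log(inner) + delta) + m
        gain = float((new - cur).sum())
        if log_u[t] < gain:
            accepted += 1
            order[p], order[q] = order[q], order[p]
            T[:, p + 1 : q + 1] += delta[:, None]
            cur = new
        if t >= n_burn:
            i = t - n_burn
            seqs[i] = order
            lls[i] = float(cur.sum()) - log_prior
    return MCMCSamples(
        sequences=seqs, logliks=lls, acceptance_rate=accepted / total, seed=seed
    )


def positional_variance(
    samples: MCMCSamples | np.ndarray | list, ml: EventSequence
) -> np.ndarray:
    """Fraction of samples placing each event (rows, ML order) at each position.

    Rows follow the maximum-likelihood ordering, columns are positions; the
    matrix is doubly stochastic because each sample is a permutation. A
    perfectly certain sequence gives the identity matrix.
    """
    seqs = samples.sequences if isinstance(samples, MCMCSamples) else np.asarray(samples)
    seqs = np.atleast_2d(np.asarray(seqs, int))
    n_samples, N = seqs.shape
    counts = np.zeros((N, N))
    for pos in range(N):
        counts[:, pos] = np.bincount(seqs[:, pos], minlength=N)
    counts /= n_samples
    return counts[ml.order]


def bootstrap_sequences(
    data: EBMData,
    B: int = 100,
    seed: int = 0,
    *,
    n_restarts: int = 10,
    ml: EventSequence | None = None,
) -> tuple[list[EventSequence], np.ndarray | None]:
    """Refit the ML sequence to B bootstrap resamples of subjects.

    The event measures (mixture fits, i.e. the densities in ``data``) stay
    fixed; only the sequence is refit per resample. Returns the B sequences
    and their positional-variance summary relative to ``ml`` (or to the
    full-data ML fit when not supplied); the summary is None when B == 0.
    """
    if data.n_subjects < 2:
        raise ValueError("bootstrap needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    out: list[EventSequence] = []
    for b in range(B):
        idx = rng.integers(0, data.n_subjects, size=data.n_subjects)
        sub = data.subset(idx)
        out.append(greedy_ascent(sub, seed=int(rng.integers(2**31)), n_restarts=n_restarts))
    if B == 0:
        return out, None
    if ml is None:
        ml = greedy_ascent(data, seed=seed, n_restarts=n_restarts)
    pv = positional_variance(np.stack([s.order for s in out]), ml)
    return out, pv


def stage_subjects(data: EBMData, s: EventSequence) -> np.ndarray:
    """Posterior over stages 0..N per subject given the sequence (uniform prior)."""
    T = _stage_logmatrix(data, s.order)
    _check_nonzero(T, data.n_events)
    norm = logsumexp(T, axis=1)
    return np.exp(T - norm[:, None])
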