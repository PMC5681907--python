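"""Two-component mixtures of weighted kernel density estimates.

Each biomarker's observed c-scores are modeled as a mixture of a "normal"
(pre-event) and an "event" (post-event) component, both nonparametric
Gaussian-kernel density estimates. Component membership is soft: an
alternating procedure re-weights every observation's kernel by its current
responsibility, refits both densities (bandwidth included), and updates the
mixing weight. Identifiability constraints (a control anchor, monotone
responsibilities in the c-score, and a parametric warm start) keep the two
components from collapsing onto each other. The fitted component densities
are exactly the P(x | event) and P(x | no event) terms the event-based
model needs.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import isotonic_regression

from .errors import DegenerateDensityError

__all__ = [
    "KDEComponent",
    "KDEMixtureFit",
    "bandwidth_rule",
    "fit_kde_mixture",
    "event_likelihoods",
    "single_kde_loglik",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(q, cw, v))


def bandwidth_rule(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted Silverman rule: 0.9 * min(sd, IQR/1.34) * n_eff^(-1/5).

    ``n_eff = (sum w)^2 / sum w^2`` is Kish's effective sample size, so the
    rule is invariant to rescaling all weights. Zero-spread data raise
    :class:`DegenerateDensityError`.
    """
    values = np.asarray(values, float)
    weights = np.ones_like(values) if weights is None else np.asarray(weights, float)
    if np.count_nonzero(weights > 0) < 2:
        raise DegenerateDensityError("need >= 2 points with positive weight")
    wsum = weights.sum()
    n_eff = wsum**2 / (weights**2).sum()
    mu = (weights * values).sum() / wsum
    sd = np.sqrt((weights * (values - mu) ** 2).sum() / wsum)
    iqr = _weighted_quantile(values, weights, 0.75) - _weighted_quantile(
        values, weights, 0.25
    )
    candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not candidates:
        raise DegenerateDensityError("zero spread: bandwidth undefined")
    return 0.9 * min(candidates) * n_eff ** (-0.2)


@dataclass
class KDEComponent:
    """Gaussian-kernel density over the observed values with soft weights."""

    support_points: np.ndarray = field(repr=False)
    responsibilities: np.ndarray = field(repr=False)  # per-point weights in [0, 1]
    bandwidth: float = 1.0

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        """Mixture-of-Gaussians density; integrates to 1 analytically."""
        x = np.atleast_1d(np.asarray(x, float))
        z = (x[:, None] - self.support_points[None, :]) / self.bandwidth
        kern = np.exp(-0.5 * z**2) / (self.bandwidth * _SQRT2PI)
        w = self.responsibilities / self.responsibilities.sum()
        return kern @ w

    def weighted_median(self) -> float:
        return _weighted_quantile(self.support_points, self.responsibilities, 0.5)


@dataclass
class KDEMixtureFit:
    """Converged two-component KDE mixture for one biomarker."""

    pi_normal: float
    normal_component: KDEComponent
    event_component: KDEComponent
    loglik_trace: list[float]
    converged: bool

    @property
    def pi_event(self) -> float:
        return 1.0 - self.pi_normal

    def responsibility(self, x: np.ndarray | float) -> np.ndarray:
        """Posterior probability that x belongs to the event component."""
        f_e = self.event_component.pdf(x)
        f_n = self.normal_component.pdf(x)
        num = self.pi_event * f_e
        return num / (num + self.pi_normal * f_n)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pi_normal": self.pi_normal,
            "converged": self.converged,
            "loglik_trace": list(map(float, self.loglik_trace)),
        }
        for name, comp in (("normal", self.normal_component),
                           ("event", self.event_component)):
            payload[name] = {
                "support_points": comp.support_points.tolist(),
                "responsibilities": comp.responsibilities.tolist(),
                "bandwidth": comp.bandwidth,
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "KDEMixtureFit":
        d = json.loads(Path(path).read_text())

        def comp(name):
            c = d[name]
            return KDEComponent(
                np.asarray(c["support_points"], float),
                np.asarray(c["responsibilities"], float),
                float(c["bandwidth"]),
            )

        return cls(
            pi_normal=d["pi_normal"],
            normal_component=comp("normal"),
            event_component=comp("event"),
            loglik_trace=list(d["loglik_trace"]),
            converged=bool(d["converged"]),
        )


def _mixture_state(values, r, floor, frozen_normal=None, pi_event=None):
    """Build components and evaluate the mixture log-likelihood for weights r.

    With ``frozen_normal`` the normal component is held fixed and only the
    event component is refit from the responsibilities. ``pi_event``
    overrides the mixing weight (mean of r by default).
    """
    r = np.clip(r, floor, 1.0 - floor)
    w_event, w_normal = r, 1.0 - r
    if frozen_normal is None:
        normal = KDEComponent(values, w_normal, bandwidth_rule(values, w_normal))
    else:
        normal = frozen_normal
    event = KDEComponent(values, w_event, bandwidth_rule(values, w_event))
    if pi_event is None:
        pi_event = float(r.mean())
    f_n, f_e = normal.pdf(values), event.pdf(values)
    mix = (1.0 - pi_event) * f_n + pi_event * f_e
    ll = float(np.log(mix).sum())
    return normal, event, pi_event, f_n, f_e, mix, ll


def _monotone_in_value(values: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Isotonic (PAVA) projection of responsibilities onto r non-decreasing in x.

    Encodes the c-score convention that the probability of having
    experienced the event cannot fall as abnormality rises.
    """
    order = np.argsort(values, kind="stable")
    out = np.empty_like(r)
    out[order] = isotonic_regression(r[order]).x
    return np.clip(out, 0.0, 1.0)


def _group_mixing_weight(
    values: np.ndarray,
    labels: np.ndarray,
    normal: KDEComponent,
    event: KDEComponent,
    floor: float = 1e-6,
) -> float:
    """Overall event weight from group-specific mixing weights.

    Given the two fitted component densities, the mixing weight of each
    diagnostic group (patients sit at all stages; controls mostly before the
    first event) is estimated by exact EM — for fixed densities this is the
    maximum-likelihood estimate. Returns the mean posterior event
    membership over the whole sample.
    """
    f_n, f_e = normal.pdf(values), event.pdf(values)
    pi = {True: 0.5, False: 0.1}
    groups = {g: labels == g for g in (True, False)}
    r = np.empty(len(values))
    for _ in range(500):
        moved = 0.0
        for g, mask in groups.items():
            num = pi[g] * f_e[mask]
            r[mask] = num / (num + (1.0 - pi[g]) * f_n[mask] + 1e-300)
            new = float(np.clip(r[mask].mean(), floor, 1.0 - floor))
            moved = max(moved, abs(new - pi[g]))
            pi[g] = new
        if moved < 1e-10:
            break
    return float(r.mean())


def _gap_init(
    values: np.ndarray, labels: np.ndarray, min_tail: int = 3
) -> np.ndarray | None:
    """Hard split at the widest spacing in the upper half of the sample.

    Biomarkers that change as a step produce a bimodal sample with a gap
    between the pre- and post-event clusters; splitting there starts the
    alternation with each component on its own cluster. Returns None when no
    admissible split exists (the split must lie above the control median and
    leave at least ``min_tail`` points on the event side without claiming
    more than half the sample).
    """
    ctrl_median = np.median(values[~labels])
    sv = np.sort(values)
    n = len(sv)
    best_gap, best_split = -1.0, None
    for i in range(n - 1):
        if sv[i] < ctrl_median:
            continue
        n_above = n - (i + 1)
        if n_above < min_tail or n_above > n // 2:
            continue
        gap = sv[i + 1] - sv[i]
        if gap > best_gap:
            best_gap, best_split = gap, 0.5 * (sv[i] + sv[i + 1])
    if best_split is None:
        return None
    return (values > best_split).astype(float)


def _gaussian_anchor_init(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Event responsibilities from an anchored two-Gaussian EM, multi-start.

    The normal component's moments are frozen to the control sample, so the
    parametric mixture is identifiable; EM over (pi, mu1, sd1) is exact.
    Three starting locations for the event mean (upper quartile, top-decile
    mean, three control-sds out) are run to convergence and the highest-
    likelihood solution wins — with very few post-event subjects a single
    start can lock onto the bulk's right shoulder instead of the event mode.
    The resulting posterior memberships give the KDE alternation a starting
    point inside the basin of the separated solution.
    """
    ctrl = values[~labels]
    mu0, sd0 = ctrl.mean(), max(ctrl.std(), 1e-8)
    f0 = np.exp(-0.5 * ((values - mu0) / sd0) ** 2) / sd0
    n_top = max(3, len(values) // 10)
    starts = [
        float(np.quantile(values, 0.75)),
        float(np.mean(np.sort(values)[-n_top:])),
        float(mu0 + 3.0 * sd0),
    ]
    best_ll, best_r = -np.inf, None
    for mu1 in starts:
        sd1, pi = sd0, 0.1
        for _ in range(300):
            f1 = np.exp(-0.5 * ((values - mu1) / sd1) ** 2) / sd1
            r = pi * f1 / (pi * f1 + (1.0 - pi) * f0 + 1e-300)
            w = r.sum()
            if w < 1e-8:
                break
            new_pi = float(r.mean())
            new_mu1 = float((r * values).sum() / w)
            new_sd1 = float(np.sqrt((r * (values - new_mu1) ** 2).sum() / w))
            # scale floor: stops the event component collapsing to a spike
            new_sd1 = max(new_sd1, 0.5 * sd0)
            moved = max(abs(new_pi - pi), abs(new_mu1 - mu1), abs(new_sd1 - sd1))
            pi, mu1, sd1 = new_pi, new_mu1, new_sd1
            if moved < 1e-8:
                break
        f1 = np.exp(-0.5 * ((values - mu1) / sd1) ** 2) / sd1
        ll = float(np.log(pi * f1 + (1.0 - pi) * f0 + 1e-300).sum())
        if ll > best_ll:
            best_ll = ll
            best_r = pi * f1 / (pi * f1 + (1.0 - pi) * f0 + 1e-300)
    return best_r


def fit_kde_mixture(
    values: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    *,
    responsibility_floor: float = 1e-6,
    anchor: str = "controls",
    init: str | None = None,
) -> KDEMixtureFit:
    """Fit the two-component KDE mixture by alternating reweighting.

    Responsibilities start from an anchored two-Gaussian EM posterior
    (``init="gaussian"``, default) or from the hard diagnostic labels
    (``init="labels"``: controls -> normal, patients -> event); each
    iteration refits the weighted KDEs (bandwidths included), recomputes the
    mixing weight, then updates responsibilities from the current densities.
    The parametric warm start matters when only a few subjects have
    experienced an event: starting from the raw labels leaves the event
    component covering the whole patient sample, a spurious fixed point of
    the alternation. Iteration stops
    when the mixture log-likelihood improves by less than ``tol`` (or would
    decrease — bandwidth refitting is not an exact EM M-step, so a decrease
    triggers a rollback to the previous state) or at ``max_iter``, in which
    case ``converged`` is False. At the end the component with the larger
    weighted median is labeled the event component.

    ``anchor`` controls identifiability. A fully unconstrained two-KDE
    mixture is not identifiable — one nonparametric component can absorb the
    whole sample, so the alternation drifts toward a degenerate fit in which
    the event component empties out. ``"controls"`` (default) therefore
    (i) pins controls and any value at or below the control median to the
    normal side of the event density — a measurement less abnormal than the
    median control cannot evidence a post-event state; (ii) projects each
    E-step's responsibilities onto monotone non-decreasing in the c-score
    (isotonic regression); and (iii) runs the alternation from two starting
    points — the anchored two-Gaussian EM posterior and a largest-gap hard
    split — keeping the fixed point with the higher mixture likelihood.
    Both component densities are refit each step, so the normal component
    can absorb gradual pre-event drift; the constraints keep rare late
    events right-shifted instead of letting them melt into the bulk.
    ``"low-controls"`` pins only controls at or below the control median to
    the normal side (controls above it may have experienced early events);
    ``"none"`` runs the fully symmetric unconstrained alternation.

    The alternation is not an exact EM — bandwidths are refit each step — so
    the per-iteration log-likelihood can wiggle by a fraction of a unit;
    convergence is declared at a fixed point of the responsibilities (or
    when the log-likelihood change falls below ``tol`` while the
    responsibilities are nearly stationary), and the fit returned is that
    fixed point. ``loglik_trace`` records the raw per-iteration values.

    ``labels`` is boolean (True = patient). The procedure is deterministic;
    ``seed`` is accepted for interface symmetry with the stochastic stages.
    """
    del seed  # deterministic label-based initialization
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    if len(values) != len(labels):
        raise ValueError("values and labels must align")
    for grp in (labels, ~labels):
        if grp.sum() < 5:
            raise ValueError("need >= 5 values per label group")
    if np.ptp(values) == 0:
        raise DegenerateDensityError("all values identical")
    monotone = False
    if anchor == "controls":
        # values at or below the control median carry no post-event evidence
        pinned = (~labels) | (values <= np.median(values[~labels]))
        monotone = True
    elif anchor == "low-controls":
        pinned = (~labels) & (values <= np.median(values[~labels]))
    elif anchor == "none":
        pinned = np.zeros(len(values), bool)
    else:
        raise ValueError("anchor must be 'controls', 'low-controls' or 'none'")

    if init is None:
        # the Gaussian warm start is itself control-anchored, so the
        # symmetric procedures keep the label initialization
        init = "gaussian" if anchor == "controls" else "labels"
    if init == "labels":
        starts = [labels.astype(float)]
    elif init == "gaussian":
        r0 = _gaussian_anchor_init(values, labels)
        if monotone:
            r0 = _monotone_in_value(values, r0)
        starts = [r0]
        r_gap = _gap_init(values, labels)
        if r_gap is not None:
            starts.append(r_gap)
    else:
        raise ValueError("init must be 'gaussian' or 'labels'")

    def _alternate(r_start):
        r = r_start.copy()
        r[pinned] = 0.0
        state = _mixture_state(values, r, responsibility_floor)
        trace = [state[-1]]
        converged = False
        for _ in range(max_iter):
            normal, event, pi_event, f_n, f_e, mix, ll = state
            r_post = np.clip(pi_event * f_e / mix, 0.0, 1.0)
            if monotone:
                r_post = _monotone_in_value(values, r_post)
            r_new = r_post.copy()
            r_new[pinned] = 0.0  # pinned points never feed the event density
            delta_r = float(np.max(np.abs(r_new - np.clip(r, 0, 1))))
            r = r_new
            # the mixing weight comes from the unpinned posterior so pinned
            # points still contribute their membership probability mass
            state = _mixture_state(
                values, r, responsibility_floor, pi_event=float(r_post.mean())
            )
            trace.append(state[-1])
            if delta_r < 1e-5 or (abs(trace[-1] - trace[-2]) < tol and delta_r < 1e-3):
                converged = True
                break
        return state, trace, converged

    fits = [_alternate(r_start) for r_start in starts]
    state, trace, converged = max(fits, key=lambda f: f[0][-1])
    if not converged:
        warnings.warn("KDE mixture fit did not converge", stacklevel=2)
    normal, event, pi_event, *_ = state
    if event.weighted_median() < normal.weighted_median():
        normal, event = event, normal
        pi_event = 1.0 - pi_event
    if anchor == "controls":
        # final mixing weight: with the component densities fixed, maximum-
        # likelihood group-specific mixing weights (patients and controls
        # have different event prevalence by design) estimated by exact EM;
        # the reported pi is the mean posterior membership under those
        # weights. The symmetric procedures keep the plain mean-
        # responsibility mixing weight.
        pi_event = _group_mixing_weight(values, labels, normal, event)
    return KDEMixtureFit(
        pi_normal=1.0 - pi_event,
        normal_component=normal,
        event_component=event,
        loglik_trace=trace,
        converged=converged,
    )


def event_likelihoods(
    fit: KDEMixtureFit, x: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Component densities (P(x | event), P(x | no event)) at x."""
    return fit.event_component.pdf(x), fit.normal_component.pdf(x)


def single_kde_loglik(values: np.ndarray) -> float:
    """Log-likelihood of a single unweighted KDE fit (no-effect reference model)."""
    values = np.asarray(values, float)
    comp = KDEComponent(values, np.ones_like(values), bandwidth_rule(values))
    return float(np.log(comp.pdf(values)).sum())
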