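"""Synthetic cohorts with a planted event cascade.

Generates the statistical structure the downstream analysis assumes: a
ground-truth ordering of biomarker events, per-event pre/post-event value
distributions, subjects staged along the cascade (patients uniformly, controls
at stage 0 with a small leak into stage 1), and connectomes whose connectivity
degrades node by node with disease stage. This is the test substrate standing
in for an imaging cohort; it plants a known answer so that sequence recovery
can be measured.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import WeightedConnectome, normalize_weights, write_connectome_csv
from .errors import InvalidTruthError

__all__ = [
    "SyntheticTruth",
    "SyntheticConnectomeConfig",
    "generate_ebm_cohort",
    "generate_connectome_cohort",
    "sample_base_connectome",
    "sample_stages",
    "simulate_study",
    "default_truth",
]


@dataclass
class SyntheticTruth:
    """Planted event ordering and per-event value distributions.

    ``pre_params``/``post_params`` map each event id to a (location, scale)
    pair on the abnormality-increasing scale; a subject at stage k draws the
    first k events of ``planted_sequence`` from their post-event distribution
    and the rest from the pre-event one. ``control_leak`` is the probability
    that a control has already progressed past the first event.
    """

    planted_sequence: list[str]
    pre_params: dict[str, tuple[float, float]]
    post_params: dict[str, tuple[float, float]]
    control_leak: float = 0.1
    distribution: str = "normal"  # "normal" or "skewnorm"
    skew: float = 0.0

    def __post_init__(self) -> None:
        events = list(self.planted_sequence)
        if len(set(events)) != len(events):
            raise InvalidTruthError("planted_sequence has repeated event ids")
        for params, name in ((self.pre_params, "pre"), (self.post_params, "post")):
            if set(params) != set(events):
                raise InvalidTruthError(f"{name}_params keys do not match the sequence")
        for e in events:
            if self.post_params[e][0] < self.pre_params[e][0]:
                raise InvalidTruthError(
                    f"event {e}: post-event location below pre-event location"
                )
            if self.pre_params[e][1] <= 0 or self.post_params[e][1] <= 0:
                raise InvalidTruthError(f"event {e}: nonpositive scale")
        if not 0 <= self.control_leak < 1:
            raise InvalidTruthError("control_leak must be in [0, 1)")
        if self.distribution not in ("normal", "skewnorm"):
            raise InvalidTruthError(f"unknown distribution {self.distribution!r}")

    @property
    def n_events(self) -> int:
        return len(self.planted_sequence)

    def _draw(self, rng: np.random.Generator, loc: float, scale: float, size: int):
        if self.distribution == "normal":
            return rng.normal(loc, scale, size)
        return stats.skewnorm.rvs(self.skew, loc=loc, scale=scale, size=size, random_state=rng)


def default_truth(
    n_events: int = 10,
    *,
    pre: tuple[float, float] = (0.0, 1.0),
    post: tuple[float, float] = (3.0, 1.0),
    control_leak: float = 0.1,
    prefix: str = "E",
) -> SyntheticTruth:
    """Homogeneous truth: identical pre/post distributions for every event."""
    events = [f"{prefix}{i:02d}" for i in range(1, n_events + 1)]
    return SyntheticTruth(
        planted_sequence=events,
        pre_params={e: pre for e in events},
        post_params={e: post for e in events},
        control_leak=control_leak,
    )


def sample_stages(
    n_controls: int,
    n_patients: int,
    n_stages: int,
    control_leak: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Control stages (0 or leaked 1) and patient stages (uniform on 0..N)."""
    ctrl = (rng.random(n_controls) < control_leak).astype(int)
    pat = rng.integers(0, n_stages + 1, size=n_patients)
    return ctrl, pat


def generate_ebm_cohort(
    n_controls: int,
    n_patients: int,
    truth: SyntheticTruth,
    seed: int = 0,
    *,
    include_covariates: bool = True,
    suvr_cutoff: float = 1.10,
) -> pd.DataFrame:
    """Cross-sectional cohort with per-subject stage and planted event values.

    Patients ("AD") are staged uniformly on {0..N}; controls ("CN") sit at
    stage 0 except a ``control_leak`` fraction promoted to stage 1. A subject
    at stage k draws events 1..k of the planted sequence from their
    post-event distribution and the rest from the pre-event one. Optional
    covariates (age, education, sex) and an amyloid SUVR consistent with the
    diagnosis are attached so the cohort-filter and adjustment steps can run.
    """
    if n_controls < 1 or n_patients < 1:
        raise ValueError("need at least one control and one patient")
    rng = np.random.default_rng(seed)
    N = truth.n_events
    ctrl_stages, pat_stages = sample_stages(
        n_controls, n_patients, N, truth.control_leak, rng
    )
    stages = np.concatenate([ctrl_stages, pat_stages])
    n = n_controls + n_patients
    diagnosis = np.array(["CN"] * n_controls + ["AD"] * n_patients)

    values = np.empty((n, N))
    for j, e in enumerate(truth.planted_sequence):
        past = stages > j  # event j (0-indexed) occurred iff stage >= j+1
        pre_loc, pre_sc = truth.pre_params[e]
        post_loc, post_sc = truth.post_params[e]
        v = truth._draw(rng, pre_loc, pre_sc, n)
        v_post = truth._draw(rng, post_loc, post_sc, n)
        values[:, j] = np.where(past, v_post, v)

    table = pd.DataFrame(
        {"subject_id": [f"S{i:04d}" for i in range(n)], "diagnosis": diagnosis,
         "stage": stages}
    )
    if include_covariates:
        table["age"] = np.round(rng.normal(73, 7, n), 1)
        table["education"] = rng.integers(10, 21, n)
        table["sex"] = rng.integers(0, 2, n)
        is_ctrl = diagnosis == "CN"
        suvr = np.where(
            is_ctrl,
            rng.uniform(0.85, suvr_cutoff - 0.01, n),
            rng.uniform(suvr_cutoff + 0.01, 1.6, n),
        )
        table["amyloid_suvr"] = np.round(suvr, 3)
    for j, e in enumerate(truth.planted_sequence):
        table[e] = values[:, j]
    return table


@dataclass
class SyntheticConnectomeConfig:
    """Stochastic-block-model base connectome plus stage-wise degradation.

    A single base graph is drawn (seeded); a subject at stage k has every edge
    incident to the first k nodes of ``node_ordering`` multiplied by
    ``degradation_factor`` before renormalization to [0, 1].
    """

    n_nodes: int = 60
    n_modules: int = 4
    within_module_density: float = 0.6
    between_module_density: float = 0.15
    base_weight_scale: float = 1.0
    node_ordering: list[int] | None = None
    degradation_factor: float = 0.5
    seed: int = 0
    #: sigma of multiplicative log-normal per-subject edge noise; 0 makes a
    #: subject's connectome a deterministic function of its stage.
    edge_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.within_module_density, self.between_module_density):
            if not 0 <= d <= 1:
                raise ValueError("densities must lie in [0, 1]")
        if not 0 < self.degradation_factor < 1:
            raise ValueError("degradation_factor must be strictly between 0 and 1")
        if self.base_weight_scale <= 0:
            raise ValueError("base_weight_scale must be positive")
        if self.node_ordering is None:
            self.node_ordering = list(range(self.n_nodes))
        order = list(self.node_ordering)
        if sorted(order) != list(range(self.n_nodes)):
            raise ValueError("node_ordering must be a permutation of the nodes")


def sample_base_connectome(cfg: SyntheticConnectomeConfig) -> WeightedConnectome:
    """Modular random base graph: SBM edges with log-normal weights, normalized."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    module = np.arange(n) % cfg.n_modules
    same = module[:, None] == module[None, :]
    p_edge = np.where(same, cfg.within_module_density, cfg.between_module_density)
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < p_edge[iu]
    w = rng.lognormal(mean=0.0, sigma=0.5, size=len(iu[0])) * cfg.base_weight_scale
    W = np.zeros((n, n))
    W[iu] = np.where(present, w, 0.0)
    W = W + W.T
    labels = [f"R{i:03d}" for i in range(n)]
    return normalize_weights(WeightedConnectome(labels, W))


def generate_connectome_cohort(
    n_subjects: int,
    stages: np.ndarray,
    cfg: SyntheticConnectomeConfig,
) -> list[WeightedConnectome]:
    """Per-subject connectomes with stage-dependent nodal degradation.

    All subjects share one base graph; at stage k the edges incident to the
    first k nodes of ``cfg.node_ordering`` are attenuated by
    ``degradation_factor`` and the matrix is renormalized into [0, 1].
    Degradation only lowers weights, so renormalization is only needed when
    per-subject edge noise pushes weights above 1; in that case the whole
    cohort is divided by one common maximum. Normalizing each subject by its
    own maximum would couple every node's strength to whichever single edge
    happens to be that subject's maximum, injecting common-mode noise and
    making strength non-monotone in stage, which destroys the planted
    cascade.
    """
    stages = np.asarray(stages, dtype=int)
    if len(stages) != n_subjects:
        raise ValueError("one stage per subject required")
    if stages.min(initial=0) < 0 or stages.max(initial=0) > cfg.n_nodes:
        raise ValueError("stages must lie in [0, n_nodes]")
    base = sample_base_connectome(cfg)
    order = np.asarray(cfg.node_ordering)
    noise_rng = np.random.default_rng([cfg.seed, 1])
    iu = np.triu_indices(cfg.n_nodes, k=1)
    out = []
    for k in stages:
        W = base.weights.copy()
        if k > 0:
            hit = np.zeros(cfg.n_nodes, dtype=bool)
            hit[order[:k]] = True
            mask = hit[:, None] | hit[None, :]
            W[mask] *= cfg.degradation_factor
        if cfg.edge_noise_sigma > 0:
            noise = np.zeros_like(W)
            noise[iu] = noise_rng.lognormal(0.0, cfg.edge_noise_sigma, len(iu[0]))
            W *= noise + noise.T
        out.append(W)
    scale = max(max(W.max(initial=0.0) for W in out), 1.0)
    conns = []
    for W in out:
        conn = WeightedConnectome(list(base.node_labels), W / scale)
        conn.validate(normalized=True)
        conns.append(conn)
    return conns


def simulate_study(
    n_controls: int,
    n_patients: int,
    cfg: SyntheticConnectomeConfig,
    *,
    nonnet_truth: SyntheticTruth | None = None,
    control_leak: float = 0.1,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[WeightedConnectome], dict]:
    """Full synthetic study: cohort table + connectomes + ground-truth record.

    Subjects are staged on {0..n_nodes}; connectomes degrade along
    ``cfg.node_ordering``. Optional non-network biomarkers become abnormal at
    planted cut-points spread evenly across the stage axis, so they interleave
    with the network events in the global cascade. When ``out_dir`` is given,
    the cohort CSV, one connectome CSV per subject, and a JSON truth sidecar
    are written there.
    """
    rng = np.random.default_rng(seed)
    ctrl_stages, pat_stages = sample_stages(
        n_controls, n_patients, cfg.n_nodes, control_leak, rng
    )
    stages = np.concatenate([ctrl_stages, pat_stages])
    n = n_controls + n_patients
    diagnosis = np.array(["CN"] * n_controls + ["AD"] * n_patients)
    connectomes = generate_connectome_cohort(n, stages, cfg)

    table = pd.DataFrame(
        {"subject_id": [f"S{i:04d}" for i in range(n)], "diagnosis": diagnosis,
         "stage": stages}
    )
    table["age"] = np.round(rng.normal(73, 7, n), 1)
    table["education"] = rng.integers(10, 21, n)
    table["sex"] = rng.integers(0, 2, n)
    table["amyloid_suvr"] = np.round(
        np.where(diagnosis == "CN", rng.uniform(0.85, 1.09, n), rng.uniform(1.11, 1.6, n)), 3
    )

    truth_record: dict = {
        "node_ordering": [int(x) for x in cfg.node_ordering],
        "node_labels": list(connectomes[0].node_labels),
        "degradation_factor": cfg.degradation_factor,
        "control_leak": control_leak,
        "stages": [int(s) for s in stages],
        "nonnetwork_cutpoints": {},
    }
    if nonnet_truth is not None:
        K = nonnet_truth.n_events
        cutpoints = np.linspace(1, cfg.n_nodes, K).round().astype(int)
        for e, cp in zip(nonnet_truth.planted_sequence, cutpoints):
            pre_loc, pre_sc = nonnet_truth.pre_params[e]
            post_loc, post_sc = nonnet_truth.post_params[e]
            past = stages >= cp
            v = np.where(
                past,
                nonnet_truth._draw(rng, post_loc, post_sc, n),
                nonnet_truth._draw(rng, pre_loc, pre_sc, n),
            )
            table[e] = v
            truth_record["nonnetwork_cutpoints"][e] = int(cp)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "connectomes").mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort.csv", index=False)
        for sid, conn in zip(table["subject_id"], connectomes):
            write_connectome_csv(conn, out / "connectomes" / f"{sid}.csv")
        (out / "truth.json").write_text(json.dumps(truth_record, indent=2))
    return table, connectomes, truth_record
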