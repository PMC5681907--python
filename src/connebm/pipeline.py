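"""End-to-end orchestration of the connectome sequencing pipeline.

Stages: cohort filter -> per-subject graph metrics -> covariate adjustment and
c-scores -> disease-signal screen -> per-biomarker KDE mixtures -> event-based
model (greedy ML fit, MCMC positional variance, bootstrap cross-validation,
patient staging) -> figures. Model variants combine the fixed non-network
biomarker set with network biomarker categories:

* EBM0 — non-network biomarkers only,
* EBM1 — EBM0 plus hub metrics (degree, strength, degree z-score),
* EBM2 — EBM0 plus importance metrics (efficiency, path length,
  participation, betweenness, eigenvector/PageRank centrality),
* EBM3 — EBM0 plus segregation/integration metrics (clustering,
  eccentricity),
* EBM4 — everything.

A variant whose network category has no disease-signal survivors is skipped
with an explanatory log entry rather than fitted on nothing.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import read_connectome_csv
from .ebm import (
    EBMData,
    bootstrap_sequences,
    greedy_ascent,
    mcmc_sample,
    positional_variance,
    stage_subjects,
)
from .errors import NoEventsError
from .graph_metrics import NODE_METRICS, global_metrics, node_metric_table
from .kde import KDEMixtureFit, event_likelihoods, fit_kde_mixture
from .plotting import positional_variance_diagram
from .prep import (
    adjust_covariates,
    compare_global_metrics,
    disease_signal_filter,
    select_cohort,
    to_cscores,
)

__all__ = [
    "PipelineConfig",
    "HUB_METRICS",
    "IMPORTANCE_METRICS",
    "SEGREGATION_METRICS",
    "EBM0_DEFAULT_MARKERS",
    "assemble_ebm_inputs",
    "run_pipeline",
    "metric_category",
]

log = logging.getLogger(__name__)

HUB_METRICS = frozenset({"degree", "strength", "degree_zscore"})
IMPORTANCE_METRICS = frozenset(
    {
        "local_efficiency",
        "char_path_length",
        "participation_coef",
        "node_betweenness",
        "edge_betweenness_nodal",
        "eigenvector_centrality",
        "pagerank_centrality",
    }
)
SEGREGATION_METRICS = frozenset({"clustering_coef", "eccentricity"})

#: Standard non-network biomarker columns (all optional in synthetic mode).
EBM0_DEFAULT_MARKERS = (
    "av45_suvr_mean",
    "fdg",
    "mmse",
    "hippocampus",
    "entorhinal",
    "ventricles",
    "whole_brain",
)

_VARIANT_CATEGORIES: dict[str, tuple[frozenset[str], ...]] = {
    "EBM0": (),
    "EBM1": (HUB_METRICS,),
    "EBM2": (IMPORTANCE_METRICS,),
    "EBM3": (SEGREGATION_METRICS,),
    "EBM4": (HUB_METRICS, IMPORTANCE_METRICS, SEGREGATION_METRICS),
}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; round-trips through YAML."""

    cohort_csv: str = "cohort.csv"
    connectome_dir: str = "connectomes"
    out_dir: str = "results"
    suvr_cutoff: float = 1.10
    alpha: float = 0.05
    n_metrics_per_region: int = 12
    bootstrap: int = 100
    mcmc_samples: int = 50_000
    mcmc_burn_in: float = 0.5
    n_restarts: int = 10
    seed: int = 0
    variants: list[str] = field(
        default_factory=lambda: ["EBM0", "EBM1", "EBM2", "EBM3", "EBM4"]
    )
    ebm0_markers: list[str] = field(default_factory=lambda: list(EBM0_DEFAULT_MARKERS))
    covariates: list[str] = field(default_factory=lambda: ["age", "education", "sex"])
    volume_biomarkers: list[str] = field(
        default_factory=lambda: ["hippocampus", "entorhinal", "ventricles", "whole_brain"]
    )
    fit_cohort: str = "controls+patients"  # or "all" to include every scored subject

    def __post_init__(self) -> None:
        for name in ("suvr_cutoff", "alpha", "n_metrics_per_region", "n_restarts",
                     "mcmc_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bootstrap < 0:
            raise ValueError("bootstrap count must be >= 0")
        unknown = set(self.variants) - set(_VARIANT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown EBM variants: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def metric_category(biomarker: str) -> str:
    """Classify a biomarker name: metric prefix for network markers, else non-network."""
    for metric in NODE_METRICS:
        if biomarker.startswith(metric + "_"):
            return metric
    return "non-network"


def assemble_ebm_inputs(
    retained: list[str],
    variant: str,
    ebm0_markers: list[str] | tuple[str, ...] = EBM0_DEFAULT_MARKERS,
) -> list[str] | None:
    """Event list for a variant: EBM0 set plus its network categories, survivors only.

    Returns None (with a log entry) when the variant requests a network
    category with no disease-signal survivors; raises when the resulting
    event list would be empty altogether.
    """
    if variant not in _VARIANT_CATEGORIES:
        raise ValueError(f"unknown variant {variant!r}")
    nonnet = [b for b in retained if metric_category(b) == "non-network" and b in ebm0_markers]
    events = list(nonnet)
    for category in _VARIANT_CATEGORIES[variant]:
        members = [b for b in retained if metric_category(b) in category]
        if not members and variant != "EBM4":
            log.info(
                "variant %s skipped: no disease signal in category %s",
                variant, sorted(category),
            )
            return None
        events.extend(members)
    if variant == "EBM4" and len(events) == len(nonnet):
        net = [b for b in retained if metric_category(b) != "non-network"]
        if not net:
            log.info("variant EBM4 skipped: no network biomarker survived the screen")
            return None
    if not events:
        raise NoEventsError(f"variant {variant}: empty event list")
    return events


def _provenance_header(cfg: PipelineConfig) -> str:
    return f"# connebm {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg))
        df.to_csv(fh, **kw)


def _fit_variant(
    name: str,
    events: list[str],
    cscores: pd.DataFrame,
    fits: dict[str, KDEMixtureFit],
    fit_mask: np.ndarray,
    cfg: PipelineConfig,
    out: Path,
) -> dict:
    """Fit one EBM variant end to end and write its artifacts."""
    x = cscores.loc[:, events].to_numpy(float)
    p_event = np.column_stack([event_likelihoods(fits[e], x[:, j])[0] for j, e in enumerate(events)])
    p_noevent = np.column_stack([event_likelihoods(fits[e], x[:, j])[1] for j, e in enumerate(events)])
    data_all = EBMData.from_densities(p_event, p_noevent, events)
    data_fit = data_all.subset(np.nonzero(fit_mask)[0])

    ml = greedy_ascent(data_fit, seed=cfg.seed, n_restarts=cfg.n_restarts)
    chain = mcmc_sample(
        data_fit, ml, n_samples=cfg.mcmc_samples, seed=cfg.seed, burn_in=cfg.mcmc_burn_in
    )
    pv = positional_variance(chain, ml)
    boots, boot_pv = bootstrap_sequences(
        data_fit, B=cfg.bootstrap, seed=cfg.seed, n_restarts=cfg.n_restarts, ml=ml
    )
    posterior = stage_subjects(data_all, ml)

    vdir = out / name
    vdir.mkdir(parents=True, exist_ok=True)
    labels = ml.event_labels(data_all)
    with open(vdir / "ml_sequence.txt", "w") as fh:
        fh.write(_provenance_header(cfg))
        fh.write(f"# loglik {ml.loglik:.6f}\n")
        fh.write("\n".join(labels) + "\n")
    pv_df = pd.DataFrame(pv, index=labels, columns=[str(i) for i in range(len(labels))])
    _write_csv(pv_df, vdir / "positional_variance.csv", cfg)
    if boot_pv is not None:
        _write_csv(
            pd.DataFrame(boot_pv, index=labels, columns=pv_df.columns),
            vdir / "bootstrap_pv.csv", cfg,
        )
    stage_df = pd.DataFrame(
        posterior, index=cscores["subject_id"],
        columns=[f"stage_{k}" for k in range(posterior.shape[1])],
    )
    stage_df.insert(0, "expected_stage", posterior @ np.arange(posterior.shape[1]))
    _write_csv(stage_df, vdir / "stages.csv", cfg)
    positional_variance_diagram(
        pv, labels, title=f"{name}: MCMC positional variance", path=vdir / "pv_mcmc.png"
    )
    if boot_pv is not None:
        positional_variance_diagram(
            boot_pv, labels, title=f"{name}: bootstrap cross-validation",
            path=vdir / "pv_bootstrap.png",
        )
    return {
        "events": events,
        "ml_sequence": ml,
        "mcmc": chain,
        "positional_variance": pv,
        "bootstrap_sequences": boots,
        "bootstrap_pv": boot_pv,
        "stage_posterior": posterior,
    }


def compute_metric_tables(
    cohort: pd.DataFrame, connectome_dir: str | Path, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-subject nodal metrics (wide), long format, and global metrics.

    Subjects listed in the cohort without a connectome CSV are dropped with a
    warning. Wide columns are named ``<metric>_<region>``.
    """
    cdir = Path(connectome_dir)
    wide_rows, long_rows, global_rows, kept = [], [], [], []
    for sid in cohort["subject_id"]:
        path = cdir / f"{sid}.csv"
        if not path.exists():
            log.warning("subject %s: connectome %s missing, subject dropped", sid, path)
            continue
        conn = read_connectome_csv(path)
        conn.validate(normalized=True)
        tbl = node_metric_table(conn, seed=seed)
        flat = {
            f"{metric}_{region}": tbl.at[region, metric]
            for region in tbl.index for metric in tbl.columns
        }
        wide_rows.append({"subject_id": sid, **flat})
        for region in tbl.index:
            for metric in tbl.columns:
                long_rows.append(
                    {"subject_id": sid, "region": region, "metric": metric,
                     "value": tbl.at[region, metric]}
                )
        global_rows.append({"subject_id": sid, **global_metrics(conn).as_dict()})
        kept.append(sid)
    wide = pd.DataFrame(wide_rows)
    return wide, pd.DataFrame(long_rows), pd.DataFrame(global_rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    cohort = pd.read_csv(cfg.cohort_csv, comment="#")
    t0 = time.perf_counter()

    def _tick(stage):
        nonlocal t0
        log.info("stage %-14s done in %.2fs", stage, time.perf_counter() - t0)
        t0 = time.perf_counter()

    wide, long_metrics, gm = compute_metric_tables(cohort, cfg.connectome_dir, seed=cfg.seed)
    cohort = cohort[cohort["subject_id"].isin(wide["subject_id"])].reset_index(drop=True)
    table = cohort.merge(wide, on="subject_id")
    _write_csv(long_metrics, out / "metrics.csv", cfg, index=False)
    _tick("metrics")

    controls, patients = select_cohort(table, cfg.suvr_cutoff)
    ctrl, pat = controls.to_numpy(), patients.to_numpy()
    log.info("cohort: %d controls, %d patients, %d scored subjects",
             ctrl.sum(), pat.sum(), len(table))

    gm = gm.set_index("subject_id").loc[table["subject_id"]].reset_index()
    global_cmp = compare_global_metrics(
        gm.loc[ctrl, gm.columns[1:]], gm.loc[pat, gm.columns[1:]], alpha=cfg.alpha
    )
    _write_csv(global_cmp, out / "global_comparison.csv", cfg, index=False)

    network_markers = [c for c in wide.columns if c != "subject_id"]
    nonnet_markers = [m for m in cfg.ebm0_markers if m in table.columns]
    biomarkers = nonnet_markers + network_markers

    # biomarkers with (numerically) no spread in controls cannot be
    # standardized or screened; checked again after adjustment because
    # residualizing an almost-constant column can zero it out exactly
    def _drop_degenerate(frame):
        nonlocal biomarkers, network_markers, nonnet_markers
        ctrl_vals = frame.loc[ctrl, biomarkers].astype(float)
        scale = ctrl_vals.abs().mean().clip(lower=1.0)
        bad = set(ctrl_vals.columns[ctrl_vals.std(ddof=1) <= 1e-10 * scale])
        if bad:
            log.warning("dropping %d biomarkers with zero control variance", len(bad))
            biomarkers = [b for b in biomarkers if b not in bad]
            network_markers = [b for b in network_markers if b not in bad]
            nonnet_markers = [b for b in nonnet_markers if b not in bad]

    _drop_degenerate(table)
    covs = [c for c in cfg.covariates if c in table.columns]
    if covs:
        table = adjust_covariates(
            table, biomarkers, covs, controls,
            volume_biomarkers=tuple(m for m in cfg.volume_biomarkers if m in table.columns),
        )
        _drop_degenerate(table)
    cscores, _signs = to_cscores(table, biomarkers, controls, patients)
    _write_csv(cscores[["subject_id", *biomarkers]], out / "cscores.csv", cfg, index=False)
    _tick("prep")

    retained_net, report_net = disease_signal_filter(
        cscores, network_markers, controls, patients,
        alpha=cfg.alpha, n_tests_per_region=cfg.n_metrics_per_region,
    )
    retained_nonnet, report_nonnet = disease_signal_filter(
        cscores, nonnet_markers, controls, patients, alpha=cfg.alpha, n_tests_per_region=1
    )
    retained = retained_nonnet + retained_net
    report = pd.concat([report_nonnet, report_net], ignore_index=True)
    _write_csv(report, out / "disease_signal.csv", cfg, index=False)
    with open(out / "retained.txt", "w") as fh:
        fh.write(_provenance_header(cfg))
        fh.write("\n".join(retained) + "\n")

    fits: dict[str, KDEMixtureFit] = {}
    mdir = out / "mixtures"
    mdir.mkdir(exist_ok=True)
    fit_mask = ctrl | pat if cfg.fit_cohort == "controls+patients" else np.ones(len(table), bool)
    for b in retained:
        vals = cscores.loc[fit_mask, b].to_numpy(float)
        labs = pat[fit_mask]
        fits[b] = fit_kde_mixture(vals, labs, seed=cfg.seed)
        fits[b].to_json(mdir / f"{b}.json")
    _tick("mixtures")

    results: dict = {
        "config": cfg, "retained": retained, "disease_signal": report,
        "global_comparison": global_cmp, "variants": {},
    }
    for variant in cfg.variants:
        try:
            events = assemble_ebm_inputs(retained, variant, cfg.ebm0_markers)
        except NoEventsError as exc:
            log.warning("variant %s skipped: %s", variant, exc)
            events = None
        if events is not None and len(events) < 2:
            log.warning("variant %s skipped: a sequence needs >= 2 events "
                        "(got %d)", variant, len(events))
            events = None
        if events is None:
            results["variants"][variant] = None
            continue
        # EBM fits on the modeling cohort; staging covers all scored subjects
        results["variants"][variant] = _fit_variant(
            variant, events, cscores, fits, fit_mask, cfg, out
        )
        _tick(f"ebm[{variant}]")
    summary = {
        "version": __version__, "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "n_controls": int(ctrl.sum()), "n_patients": int(pat.sum()),
        "retained": retained,
        "variants_fit": [v for v, r in results["variants"].items() if r is not None],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return results
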