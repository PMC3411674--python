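"""End-to-end orchestration: simulate/ingest -> classify -> survival -> markers
-> cognate ranking -> signature -> summary.

Every run is driven by a single :class:`PipelineConfig` (loadable from YAML);
all stage outputs are TSV, and the JSON summary carries the seed and a hash of
the config so results are traceable to their exact settings.
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

from . import classify as _classify
from . import io as _io
from . import markers as _markers
from . import ranking as _ranking
from . import signature as _signature
from . import simulate as _simulate
from . import survival as _survival
from .errors import StageError

log = logging.getLogger("vakgbm")


@dataclass
class PipelineConfig:
    # input: either a simulation preset or paths to the three tables
    preset: str | None = "paper-like"
    clinical_path: str | None = None
    expression_path: str | None = None
    binding_path: str | None = None
    expression_linear: bool = False
    outdir: str = "vak_out"
    seed: int = 0
    # classification
    cutoffs: _classify.VakCutoffs = field(default_factory=_classify.VakCutoffs)
    # marker selection
    permutations: int = 999
    top_n: int = 100
    alpha: float = 0.05
    stat: str = "snr"
    # ranking / signature
    size_A: int = 12
    size_B: int = 13
    strength_mode: str = "mean"
    signature_scale: str = "linear"
    # survival
    ties: str = "efron"
    cox_covariates: bool = True   # fit dichotomized volume/age/KPS Cox model

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cut = raw.pop("cutoffs", None)
        cfg = cls(**raw)
        if cut:
            cfg.cutoffs = _classify.VakCutoffs(**cut)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("ingest")
def _load_inputs(cfg: PipelineConfig):
    if cfg.preset:
        params = _simulate.with_overrides(_simulate.scenario_preset(cfg.preset), seed=cfg.seed)
        cohort, truth, expr, binding, feature_truth = _simulate.generate_scenario(params)
        return cohort, expr, binding, truth, feature_truth
    for label, p in (
        ("clinical", cfg.clinical_path),
        ("expression", cfg.expression_path),
        ("binding", cfg.binding_path),
    ):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{label} input path missing or nonexistent: {p}")
    cohort = _io.read_clinical_table(cfg.clinical_path)
    expr = _io.read_expression_matrix(cfg.expression_path, linear=cfg.expression_linear)
    binding = _io.read_binding_table(cfg.binding_path)
    return cohort, expr, binding, None, None


@_stage("survive")
def _survival_stage(cohort, vak: pd.DataFrame, cfg: PipelineConfig) -> dict:
    clin = cohort.to_frame().merge(vak, on="patient_id")
    out: dict = {"groups": {}}
    masks = {cls: clin["vak_class"] == cls for cls in (_classify.VAK_A, _classify.VAK_B)}
    for cls, m in masks.items():
        curve = _survival.km_curve(clin.loc[m, "os_months"], clin.loc[m, "event"])
        med = _survival.km_median(curve)
        out["groups"][cls] = {
            "n": int(m.sum()),
            "median_months": med if med is not None else "NR",
        }
    lr = _survival.logrank(
        clin.loc[masks[_classify.VAK_A], "os_months"],
        clin.loc[masks[_classify.VAK_A], "event"],
        clin.loc[masks[_classify.VAK_B], "os_months"],
        clin.loc[masks[_classify.VAK_B], "event"],
    )
    out["logrank_chi2"] = lr.chi2
    out["logrank_p"] = lr.p
    if cfg.cox_covariates:
        X = np.column_stack(
            [vak["size_point"].to_numpy(), vak["age_point"].to_numpy(), vak["kps_point"].to_numpy()]
        )
        fit = _survival.cox_fit(X, clin["os_months"], clin["event"], ties=cfg.ties)
        out["cox"] = {
            "covariates": ["size_point", "age_point", "kps_point"],
            "coefficients": [float(c) for c in fit.coefficients],
            "hazard_ratios": [float(h) for h in fit.hazard_ratios],
            "lr_stat": fit.lr_stat,
            "lr_p": fit.lr_p,
        }
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages, write per-stage TSVs and a JSON summary; return the summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, expr, binding, truth, feature_truth = _load_inputs(cfg)
    _io.write_clinical_table(cohort, str(outdir / "clinical.tsv"))
    _io.write_expression_matrix(expr, str(outdir / "expr.tsv"))
    _io.write_binding_table(binding, str(outdir / "binding.tsv"))
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        feature_truth.to_csv(outdir / "feature_truth.tsv", sep="\t", index=False)

    vak = _stage("classify")(_classify.classify_cohort)(cohort, cfg.cutoffs)
    vak.to_csv(outdir / "vak.tsv", sep="\t", index=False)

    surv = _survival_stage(cohort, vak, cfg)

    classes = pd.Series(vak["vak_class"].to_numpy(), index=vak["patient_id"])
    mk = _stage("markers")(_markers.run_marker_selection)(
        expr, classes, B=cfg.permutations, seed=cfg.seed, top_n=cfg.top_n,
        alpha=cfg.alpha, stat=cfg.stat,
    )
    mk.table.to_csv(outdir / "markers.tsv", sep="\t", index=False)

    build = _stage("rank")(_ranking.build_cognate_network)
    net_A = build(mk, binding, _classify.VAK_A, strength_mode=cfg.strength_mode)
    net_B = build(mk, binding, _classify.VAK_B, strength_mode=cfg.strength_mode)
    pd.concat([net_A.to_frame(), net_B.to_frame()]).to_csv(
        outdir / "network.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(m, g, n, net.vak_class) for net in (net_A, net_B) for m, g, n in net.edges],
        columns=["mirna_id", "gene_id", "n_algorithms", "vak_class"],
    ).to_csv(outdir / "edges.tsv", sep="\t", index=False)
    set_A, set_B = _stage("rank")(_ranking.select_signature)(net_A, net_B, cfg.size_A, cfg.size_B)

    scores = _stage("signature")(_signature.score_cohort)(expr, set_A, set_B, cfg.signature_scale)
    groups = _signature.stratify_median(scores)
    sig = pd.DataFrame({"signature_score": scores, "signature_group": groups})
    sig.index.name = "patient_id"
    sig.to_csv(outdir / "signature.tsv", sep="\t")

    clin = cohort.to_frame().set_index("patient_id").join(sig)
    hi = clin["signature_group"] == _signature.GROUP_HIGH
    sig_surv = {}
    for label, m in (("high", hi), ("low", ~hi)):
        curve = _survival.km_curve(clin.loc[m, "os_months"], clin.loc[m, "event"])
        med = _survival.km_median(curve)
        sig_surv[label] = {"n": int(m.sum()), "median_months": med if med is not None else "NR"}
    lr = _survival.logrank(
        clin.loc[hi, "os_months"], clin.loc[hi, "event"],
        clin.loc[~hi, "os_months"], clin.loc[~hi, "event"],
    )

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_patients": len(cohort),
        "vak": {
            cls: int((vak["vak_class"] == cls).sum())
            for cls in (_classify.VAK_A, _classify.VAK_B)
        },
        "survival": surv,
        "signature": {
            "set_A": set_A,
            "set_B": set_B,
            "n_molecules": len(set_A) + len(set_B),
            "groups": sig_surv,
            "logrank_chi2": lr.chi2,
            "logrank_p": lr.p,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
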