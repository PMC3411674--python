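"""Synthetic radiogenomic GBM cohort generator with known ground truth.

Emulates the statistical structure the VAK analysis assumes: log-normal tumor
volumes (median 30,000 mm^3) with a sphere-equivalent noisy diameter surrogate
(diameter-volume R^2 around 0.8), ages centered at 60, KPS concentrated at
100, class-conditional exponential survival (VAK-A-like median 20 months vs
VAK-B-like 12 by default) with uniform administrative censoring, a bimodal
MGMT beta mixture, and planted inversely expressed miRNA-gene modules
(3 miRNAs x 9 genes for the A class, 5 x 8 for B) on top of i.i.d. Gaussian
noise features. The latent prognostic class of a patient is the VAK class
computed from their generated covariates, so classification, survival and
expression are coupled the way the analysis expects.

A single master seed spawns independent sub-streams for the clinical,
expression and binding stages, so each stage is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import VAK_A, VakCutoffs, vak_points
from .io import BindingTable, ClinicalCohort, ClinicalRecord, ExpressionMatrix


@dataclass(frozen=True)
class ScenarioParams:
    """Generator knobs; defaults are the 'paper-like' study conditions."""

    n_patients: int = 142
    seed: int = 0
    # clinical marginals
    volume_median_mm3: float = 30_000.0
    volume_sigma_log: float = 0.8          # sd of ln(volume)
    diameter_noise_sd: float = 0.08        # multiplicative log-scale noise on the surrogate
    age_mean: float = 60.0
    age_sd: float = 12.0
    kps_p100: float = 0.5                  # only the =100 dichotomy matters
    kps_values: tuple[int, ...] = (60, 70, 80, 90, 100)
    # survival
    median_survival_A: float = 20.0        # months
    median_survival_B: float = 12.0
    censor_horizon: float = 60.0           # uniform administrative censoring on [0, horizon]
    # MGMT; optional hazard multipliers for methylated patients (1.0 = betas
    # independent of survival, keeping class medians exactly on target)
    mgmt_methylated_frac: float = 0.5
    mgmt_hazard_ratio_A: float = 1.0
    mgmt_hazard_ratio_B: float = 1.0
    # expression / modules
    n_noise_genes: int = 400
    n_noise_mirnas: int = 100
    module_A_shape: tuple[int, int] = (3, 9)   # (miRNAs, genes)
    module_B_shape: tuple[int, int] = (5, 8)
    delta_log2: float = 2.0                # planted shift, log2 units
    sigma_log2: float = 1.0                # within-class sd
    baseline_log2: float = 8.0
    # binding
    n_decoy_pairs: int = 500
    planted_alg_range: tuple[int, int] = (3, 10)
    decoy_alg_range: tuple[int, int] = (1, 10)

    def validate(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive (0 would censor everyone at 0)")
        if min(self.median_survival_A, self.median_survival_B) <= 0:
            raise ValueError("median survivals must be positive")
        if min(self.volume_median_mm3, self.volume_sigma_log, self.age_mean, self.age_sd) <= 0:
            raise ValueError("clinical scale parameters must be positive")
        if not 0 <= self.kps_p100 <= 1 or not 0 <= self.mgmt_methylated_frac <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.delta_log2 < 0 or self.sigma_log2 <= 0:
            raise ValueError("delta_log2 must be >= 0 and sigma_log2 > 0")

    @property
    def hazard_ratio(self) -> float:
        """Planted hazard ratio of B-like vs A-like patients."""
        return self.median_survival_A / self.median_survival_B


PRESETS = ("paper-like", "null", "strong-effect")


def scenario_preset(name: str) -> ScenarioParams:
    """Named parameter bundles: 'paper-like', 'null', 'strong-effect'."""
    if name == "paper-like":
        return ScenarioParams()
    if name == "null":
        return ScenarioParams(median_survival_A=16.0, median_survival_B=16.0, delta_log2=0.0)
    if name == "strong-effect":
        return ScenarioParams(median_survival_A=20.0, median_survival_B=10.0, delta_log2=3.0)
    raise ValueError(f"unknown preset '{name}'; available: {PRESETS}")


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    clin, expr, bind = np.random.SeedSequence(seed).spawn(3)
    return (np.random.default_rng(clin), np.random.default_rng(expr), np.random.default_rng(bind))


def _sphere_diameter_mm(volume_mm3: np.ndarray) -> np.ndarray:
    return 2.0 * (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def generate_clinical(params: ScenarioParams) -> tuple[ClinicalCohort, pd.DataFrame]:
    """Generate a clinical cohort plus its ground-truth table.

    The truth table records, per patient, the latent prognostic class (the VAK
    class of the generated covariates), the true hazard, the uncensored event
    time, and the true MGMT state.
    """
    params.validate()
    rng, _, _ = _streams(params.seed)
    n = params.n_patients

    volume = np.exp(rng.normal(math.log(params.volume_median_mm3), params.volume_sigma_log, n))
    diameter = _sphere_diameter_mm(volume) * np.exp(rng.normal(0.0, params.diameter_noise_sd, n))
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18.0, 95.0)
    p_other = (1.0 - params.kps_p100) / (len(params.kps_values) - 1)
    probs = [p_other] * (len(params.kps_values) - 1) + [params.kps_p100]
    kps = rng.choice(params.kps_values, size=n, p=probs)
    methylated = rng.random(n) < params.mgmt_methylated_frac
    # bimodal beta mixture, two probes per patient
    a_par = np.where(methylated, 8.0, 2.0)
    b_par = np.where(methylated, 3.0, 8.0)
    betas = rng.beta(a_par[:, None], b_par[:, None], size=(n, 2))

    cutoffs = VakCutoffs()
    records, latent, hazards = [], [], []
    for i in range(n):
        rec = ClinicalRecord(
            patient_id=f"P{i + 1:04d}",
            volume_mm3=float(volume[i]),
            diameter_mm=float(diameter[i]),
            age_years=float(age[i]),
            kps=int(kps[i]),
            os_months=0.0,
            event=0,
            mgmt_betas=[float(b) for b in betas[i]],
            tmz=int(rng.random() < 0.8),
            rt=int(rng.random() < 0.9),
        )
        cls = vak_points(rec, cutoffs).vak_class
        median = params.median_survival_A if cls == VAK_A else params.median_survival_B
        lam = math.log(2.0) / median
        lam *= (
            params.mgmt_hazard_ratio_A if cls == VAK_A else params.mgmt_hazard_ratio_B
        ) if methylated[i] else 1.0
        latent.append(cls)
        hazards.append(lam)
        records.append(rec)

    true_t = rng.exponential(1.0 / np.asarray(hazards))
    censor_t = rng.uniform(0.0, params.censor_horizon, n)
    os_months = np.minimum(true_t, censor_t)
    event = (true_t <= censor_t).astype(int)
    for i, rec in enumerate(records):
        rec.os_months = float(round(os_months[i], 2))
        rec.event = int(event[i])

    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "latent_class": latent,
            "true_hazard": hazards,
            "true_time": true_t,
            "censor_time": censor_t,
            "mgmt_methylated": methylated.astype(int),
        }
    )
    return ClinicalCohort(records=records), truth


def _module_ids(prefix: str, shape: tuple[int, int]) -> tuple[list[str], list[str]]:
    n_mir, n_gene = shape
    return (
        [f"miR-{prefix}{i + 1}" for i in range(n_mir)],
        [f"GENE-{prefix}{i + 1}" for i in range(n_gene)],
    )


def generate_expression_and_binding(
    truth: pd.DataFrame, params: ScenarioParams
) -> tuple[ExpressionMatrix, BindingTable, pd.DataFrame]:
    """Expression matrix + binding table with planted inverse modules.

    In A-class samples the A-module genes are shifted up by delta and the
    A-module miRNAs down by delta (mirrored for B), on top of i.i.d. Gaussian
    noise. The binding table contains every planted miRNA->gene pair within a
    module plus random decoy pairs. Returns a feature truth table marking the
    planted molecules and their module.
    """
    params.validate()
    _, rng, rng_bind = _streams(params.seed)
    samples = list(truth["patient_id"])
    is_A = (truth["latent_class"] == VAK_A).to_numpy()

    mir_A, gene_A = _module_ids("A", params.module_A_shape)
    mir_B, gene_B = _module_ids("B", params.module_B_shape)
    noise_genes = [f"GENE{i + 1:04d}" for i in range(params.n_noise_genes)]
    noise_mirs = [f"miR-{i + 1:04d}" for i in range(params.n_noise_mirnas)]
    if len(set(mir_A + gene_A + mir_B + gene_B) & set(noise_genes + noise_mirs)):
        raise ValueError("planted ids collide with noise ids")

    gene_ids = gene_A + gene_B + noise_genes
    mir_ids = mir_A + mir_B + noise_mirs
    feature_ids = gene_ids + mir_ids
    kinds = ["gene"] * len(gene_ids) + ["microRNA"] * len(mir_ids)

    X = rng.normal(params.baseline_log2, params.sigma_log2, (len(feature_ids), len(samples)))
    idx = {f: i for i, f in enumerate(feature_ids)}
    d = params.delta_log2
    X[[idx[g] for g in gene_A]] += np.where(is_A, d, 0.0)
    X[[idx[m] for m in mir_A]] -= np.where(is_A, d, 0.0)
    X[[idx[g] for g in gene_B]] += np.where(is_A, 0.0, d)
    X[[idx[m] for m in mir_B]] -= np.where(is_A, 0.0, d)

    expr = ExpressionMatrix(
        values=pd.DataFrame(X, index=feature_ids, columns=samples),
        feature_kind=pd.Series(kinds, index=feature_ids),
    )

    lo, hi = params.planted_alg_range
    rows = [
        (m, g, int(rng_bind.integers(lo, hi + 1)))
        for mirs, genes in ((mir_A, gene_A), (mir_B, gene_B))
        for m in mirs
        for g in genes
    ]
    seen = {(m, g) for m, g, _ in rows}
    lo_d, hi_d = params.decoy_alg_range
    attempts = 0
    target = len(seen) + params.n_decoy_pairs
    while len(rows) < target and attempts < 50 * params.n_decoy_pairs:
        attempts += 1
        m = mir_ids[int(rng_bind.integers(len(mir_ids)))]
        g = gene_ids[int(rng_bind.integers(len(gene_ids)))]
        if (m, g) not in seen:
            seen.add((m, g))
            rows.append((m, g, int(rng_bind.integers(lo_d, hi_d + 1))))
    binding = BindingTable(pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n_algorithms"]))

    feature_truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "kind": kinds,
            "planted_module": [
                "A" if f in set(mir_A + gene_A) else "B" if f in set(mir_B + gene_B) else ""
                for f in feature_ids
            ],
        }
    )
    return expr, binding, feature_truth


def generate_scenario(
    params: ScenarioParams,
) -> tuple[ClinicalCohort, pd.DataFrame, ExpressionMatrix, BindingTable, pd.DataFrame]:
    """Convenience: clinical + truth + expression + binding in one call."""
    cohort, truth = generate_clinical(params)
    expr, binding, feature_truth = generate_expression_and_binding(truth, params)
    return cohort, truth, expr, binding, feature_truth


def with_overrides(params: ScenarioParams, **kwargs) -> ScenarioParams:
    """Functional update of a frozen ScenarioParams."""
    return replace(params, **kwargs)
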