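import numpy as np
import pandas as pd
import pytest

from vakgbm import ClinicalCohort, ClinicalRecord, ExpressionMatrix


@pytest.fixture
def small_cohort() -> ClinicalCohort:
    """Ten patients with all-distinct MGMT betas and a spread of VAK profiles."""
    records = []
    specs = [
        # (volume, diameter, age, kps, os, event, betas)
        (10_000, 25.0, 45, 100, 24.0, 1, [0.05, 0.07]),
        (31_000, 41.0, 65, 80, 8.0, 1, [0.15, 0.17]),
        (28_000, 39.0, 59, 100, 30.0, 0, [0.25, 0.27]),
        (45_000, 48.0, 70, 90, 6.5, 1, [0.35, 0.37]),
        (12_000, 28.0, 61, 100, 18.0, 1, [0.45, 0.47]),
        (50_000, 52.0, 55, 70, 9.0, 1, [0.55, 0.57]),
        (8_000, 22.0, 40, 100, 40.0, 0, [0.65, 0.67]),
        (33_000, 44.0, 66, 60, 5.0, 1, [0.75, 0.77]),
        (29_999, 39.9, 59.9, 100, 22.0, 1, [0.85, 0.87]),
        (30_000, 40.0, 60, 90, 11.0, 1, [0.95, 0.97]),
    ]
    for i, (vol, diam, age, kps, os_m, ev, betas) in enumerate(specs):
        records.append(
            ClinicalRecord(
                patient_id=f"T{i + 1:02d}",
                volume_mm3=float(vol),
                diameter_mm=diam,
                age_years=float(age),
                kps=kps,
                os_months=os_m,
                event=ev,
                mgmt_betas=betas,
            )
        )
    return ClinicalCohort(records=records)


def make_expression(X: np.ndarray, kinds: list[str], prefix: str = "F") -> ExpressionMatrix:
    ids = [f"{prefix}{i + 1:03d}" for i in range(X.shape[0])]
    samples = [f"S{i + 1:03d}" for i in range(X.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(X, index=ids, columns=samples),
        feature_kind=pd.Series(kinds, index=ids),
    )


@pytest.fixture
def planted_expression():
    """20 features x 12 samples, first 3 genes shifted up by 2 sigma in class A."""
    rng = np.random.default_rng(123)
    X = rng.normal(8.0, 1.0, (20, 12))
    X[:3, :6] += 2.0
    expr = make_expression(X, ["gene"] * 20)
    classes = pd.Series(["VAK-A"] * 6 + ["VAK-B"] * 6, index=expr.sample_ids)
    return expr, classes
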