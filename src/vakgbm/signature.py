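"""The 25-molecule signature score, median stratification, and a simplified
regulator activation z-score.

The signature score of a sample is the ratio of the mean expression of the
VAK-A module molecules to the mean expression of the VAK-B module molecules,
computed on the linear (anti-logged) scale so it is strictly positive and
invariant to per-sample multiplicative rescaling. Scores above the cohort
median mark a patient as VAK-A-like (favorable); at or below, VAK-B-like.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

GROUP_HIGH = "signature-high/VAK-A-like"
GROUP_LOW = "signature-low/VAK-B-like"


@dataclass
class Regulon:
    """A transcriptional regulator and the signed directions it imposes on targets."""

    regulator_id: str
    targets: list[tuple[str, int]]  # (feature_id, expected direction +1/-1)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("regulon needs at least one target")
        bad = [t for t in self.targets if t[1] not in (+1, -1)]
        if bad:
            raise ValueError(f"expected directions must be +1/-1: {bad}")


def signature_score(
    expr: ExpressionMatrix,
    set_A: list[str],
    set_B: list[str],
    sample_id: str,
    scale: str = "linear",
) -> float:
    """mean(set_A expression) / mean(set_B expression) for one sample.

    ``scale='linear'`` (default) anti-logs the log2 values before averaging;
    ``scale='log2'`` averages the log2 values and returns 2^(difference of
    means), an alternative reading of the same ratio.
    """
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    missing = [f for f in [*set_A, *set_B] if f not in expr.values.index]
    if missing:
        raise ValueError(f"signature molecule(s) absent from expression matrix: {missing}")
    if sample_id not in expr.values.columns:
        raise ValueError(f"unknown sample '{sample_id}'")
    col = expr.values[sample_id]
    if scale == "linear":
        a = float(np.mean(2.0 ** col.loc[set_A]))
        b = float(np.mean(2.0 ** col.loc[set_B]))
        return a / b
    return float(2.0 ** (col.loc[set_A].mean() - col.loc[set_B].mean()))


def score_cohort(
    expr: ExpressionMatrix,
    set_A: list[str],
    set_B: list[str],
    scale: str = "linear",
) -> pd.Series:
    """Signature score for every sample of the matrix."""
    return pd.Series(
        {s: signature_score(expr, set_A, set_B, s, scale) for s in expr.sample_ids},
        name="signature_score",
    )


def stratify_median(scores: pd.Series) -> pd.Series:
    """Median-cutoff stratification: score > cohort median -> VAK-A-like.

    Scores exactly at the median fall to the low (VAK-B-like) group. If all
    scores are equal the whole cohort lands in the low group, with a warning.
    """
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to stratify")
    med = float(scores.median())
    if (scores == scores.iloc[0]).all():
        warnings.warn("all signature scores identical; entire cohort assigned to the low group")
    return pd.Series(
        np.where(scores > med, GROUP_HIGH, GROUP_LOW), index=scores.index, name="signature_group"
    )


def regulator_z(regulon: Regulon, observed: dict[str, int]) -> float | None:
    """Activation z-score of a regulator given observed target directions.

    z = sum(expected_i * observed_i) / sqrt(#targets with non-zero observation);
    |z| >= 2 is conventionally flagged significant. Returns None when no target
    has a non-zero observed direction. Observed directions are +1 (up), -1
    (down) or 0 (unchanged/unobserved); unit edge weights are used throughout.
    """
    terms = [
        exp_dir * observed.get(fid, 0)
        for fid, exp_dir in regulon.targets
        if observed.get(fid, 0) != 0
    ]
    if not terms:
        return None
    return float(sum(terms) / math.sqrt(len(terms)))
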