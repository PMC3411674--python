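"""Two-class differential marker selection across VAK-A / VAK-B.

Per feature: a signal-to-noise ratio (or Welch t) statistic, a two-sided
permutation p-value, and a signed linear-scale fold regulation. Genes and
microRNAs are ranked in separate pools, and the class-specific top lists feed
the cognate-network ranking stage.

Conventions: expression is log2 scale; a positive statistic / fold means up in
VAK-A. Fold regulation is 2^|mean difference| carrying the sign of the
difference, so +2 is two-fold up in VAK-A and -2 two-fold up in VAK-B.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .classify import VAK_A, VAK_B
from .io import ExpressionMatrix

_EPS = 1e-8
MIN_PERMUTATIONS = 100


def _group_stats(x: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=ddof))


def _floored_sigma(sigma, mu):
    """Noise floor of the marker-selection SNR: sigma >= max(0.2|mu|, eps)."""
    return np.maximum(sigma, np.maximum(0.2 * np.abs(mu), _EPS))


def snr_stat(xA, xB) -> float:
    """Signal-to-noise ratio (muA - muB) / (sigmaA' + sigmaB') with floored sigmas.

    Positive means up in VAK-A. Each group needs >= 2 samples.
    """
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    if xA.size < 2 or xB.size < 2:
        raise ValueError("each group needs at least 2 samples")
    muA, sA = _group_stats(xA)
    muB, sB = _group_stats(xB)
    return (muA - muB) / (_floored_sigma(sA, muA) + _floored_sigma(sB, muB))


def t_stat(xA, xB) -> float:
    """Welch t statistic, selectable alternative to the SNR."""
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    if xA.size < 2 or xB.size < 2:
        raise ValueError("each group needs at least 2 samples")
    vA = np.var(xA, ddof=1) / xA.size
    vB = np.var(xB, ddof=1) / xB.size
    return float((np.mean(xA) - np.mean(xB)) / math.sqrt(max(vA + vB, _EPS**2)))


def fold_regulation(xA, xB) -> float:
    """Signed linear fold: 2^|muA - muB| with the sign of (muA - muB); +1 if equal."""
    d = float(np.mean(xA) - np.mean(xB))
    return math.copysign(2.0 ** abs(d), d) if d != 0 else 1.0


def _stat_matrix(X: np.ndarray, maskA: np.ndarray, stat: str) -> np.ndarray:
    """Statistic for every row of X (features x samples) under a boolean A-mask."""
    nA = int(maskA.sum())
    nB = X.shape[1] - nA
    xA, xB = X[:, maskA], X[:, ~maskA]
    muA, muB = xA.mean(axis=1), xB.mean(axis=1)
    if stat == "snr":
        sA = _floored_sigma(xA.std(axis=1, ddof=1), muA)
        sB = _floored_sigma(xB.std(axis=1, ddof=1), muB)
        return (muA - muB) / (sA + sB)
    vA = xA.var(axis=1, ddof=1) / nA
    vB = xB.var(axis=1, ddof=1) / nB
    return (muA - muB) / np.sqrt(np.maximum(vA + vB, _EPS**2))


def _perm_stats(X: np.ndarray, nA: int, B: int, rng: np.random.Generator, stat: str) -> np.ndarray:
    """(features x B) matrix of statistics under random label permutations.

    Vectorized via indicator matrix products: group sums and sums of squares
    for all permutations come from two matmuls. Callers consume |stat| only
    (|stat| is symmetric in the two groups), so passing min(nA, nB) makes the
    null invariant to which class is called A.
    """
    f, n = X.shape
    ind = np.zeros((n, B))
    for b in range(B):
        ind[rng.permutation(n)[:nA], b] = 1.0
    s1_tot = X.sum(axis=1, keepdims=True)
    s2_tot = (X**2).sum(axis=1, keepdims=True)
    s1A = X @ ind
    s2A = (X**2) @ ind
    nB = n - nA
    muA = s1A / nA
    muB = (s1_tot - s1A) / nB
    varA = np.maximum(s2A - nA * muA**2, 0.0) / (nA - 1)
    varB = np.maximum((s2_tot - s2A) - nB * muB**2, 0.0) / (nB - 1)
    if stat == "snr":
        sA = _floored_sigma(np.sqrt(varA), muA)
        sB = _floored_sigma(np.sqrt(varB), muB)
        return (muA - muB) / (sA + sB)
    return (muA - muB) / np.sqrt(np.maximum(varA / nA + varB / nB, _EPS**2))


def permutation_p(
    x,
    labels,
    B: int = 999,
    seed: int = 0,
    stat: str = "snr",
    exhaustive: bool = False,
) -> float:
    """Two-sided permutation p-value for one feature row.

    Monte-Carlo: p = (1 + #{|stat_perm| >= |stat_obs|}) / (B + 1), permutations
    drawn with ``seed``. With ``exhaustive=True`` all label assignments
    preserving group sizes are enumerated and p is the exact fraction with
    |stat_perm| >= |stat_obs| (the observed assignment is one of them).
    """
    x = np.asarray(x, dtype=float)[None, :]
    labels = np.asarray(labels)
    maskA = labels == VAK_A
    nA, nB = int(maskA.sum()), int((~maskA).sum())
    if nA < 2 or nB < 2:
        raise ValueError("both classes need at least 2 samples")
    obs = abs(float(_stat_matrix(x, maskA, stat)[0]))
    if obs == 0.0:
        return 1.0
    n = labels.size
    if exhaustive:
        count = total = 0
        for combo in itertools.combinations(range(n), nA):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            total += 1
            if abs(float(_stat_matrix(x, mask, stat)[0])) >= obs - 1e-12:
                count += 1
        return count / total
    if B < MIN_PERMUTATIONS:
        raise ValueError(f"B must be >= {MIN_PERMUTATIONS} for a stable p-value")
    rng = np.random.default_rng(seed)
    perm = np.abs(_perm_stats(x, min(nA, nB), B, rng, stat)[0])
    return (1 + int((perm >= obs - 1e-12).sum())) / (B + 1)


@dataclass
class MarkerResult:
    """Full per-feature statistics plus class-specific top lists.

    ``top[(cls, kind)]`` holds feature ids associated with class ``cls``:
    genes are assigned to the class they are up-regulated in, microRNAs to the
    class they are *down*-regulated in — the inverse-expression convention of
    the cognate networks (down-regulated miRNAs pair with up-regulated targets
    within a class).
    """

    table: pd.DataFrame
    top: dict[tuple[str, str], list[str]] = field(default_factory=dict)


def run_marker_selection(
    expr: ExpressionMatrix,
    classes: pd.Series,
    B: int = 999,
    seed: int = 0,
    top_n: int = 100,
    alpha: float = 0.05,
    stat: str = "snr",
) -> MarkerResult:
    """Differential marker selection of genes and microRNAs across VAK classes.

    ``classes`` maps sample id -> VAK-A/VAK-B; every sample of ``expr`` must be
    labeled and each class must have >= 2 samples. Permutation p-values use a
    single set of B label permutations shared across features (seeded).
    Returns the full statistics table (with a Benjamini-Hochberg ``q`` column,
    reporting only) and, per class and kind, the ``top_n`` features ranked by
    |stat| among those with p <= alpha.
    """
    if stat not in ("snr", "t"):
        raise ValueError("stat must be 'snr' or 't'")
    if B < MIN_PERMUTATIONS:
        raise ValueError(f"B must be >= {MIN_PERMUTATIONS}")
    classes = pd.Series(classes)
    unlabeled = [s for s in expr.sample_ids if s not in classes.index]
    if unlabeled:
        raise ValueError(f"unlabeled sample(s): {unlabeled}")
    labels = classes.reindex(expr.sample_ids)
    maskA = (labels == VAK_A).to_numpy()
    maskB = (labels == VAK_B).to_numpy()
    if not (maskA | maskB).all():
        bad = [s for s, keep in zip(expr.sample_ids, maskA | maskB) if not keep]
        raise ValueError(f"sample(s) with non-VAK label: {bad}")
    if maskA.sum() < 2 or maskB.sum() < 2:
        raise ValueError("each VAK class needs at least 2 samples")

    for kind in ("gene", "microRNA"):
        n_kind = int((expr.feature_kind == kind).sum())
        if n_kind and top_n > n_kind:
            raise ValueError(f"top_n={top_n} exceeds number of {kind} features ({n_kind})")

    X = expr.values.to_numpy(dtype=float)
    obs = _stat_matrix(X, maskA, stat)
    muA = X[:, maskA].mean(axis=1)
    muB = X[:, maskB].mean(axis=1)
    d = muA - muB
    fold = np.where(d == 0, 1.0, np.sign(d) * 2.0 ** np.abs(d))

    rng = np.random.default_rng(seed)
    k = min(int(maskA.sum()), int(maskB.sum()))
    perm = np.abs(_perm_stats(X, k, B, rng, stat))
    p = (1 + (perm >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)) / (B + 1)
    p = np.where(np.abs(obs) == 0, 1.0, p)

    table = pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "kind": expr.feature_kind.to_numpy(),
            "stat": obs,
            "p": p,
            "q": multipletests(p, method="fdr_bh")[1],
            "fold_regulation": fold,
            "up_in": np.where(obs >= 0, VAK_A, VAK_B),
        }
    )

    top: dict[tuple[str, str], list[str]] = {}
    for cls in (VAK_A, VAK_B):
        for kind in ("gene", "microRNA"):
            sub = table[(table["kind"] == kind) & (table["p"] <= alpha)]
            if kind == "gene":
                sub = sub[sub["up_in"] == cls]
            else:  # miRNAs belong to the class they are down-regulated in
                sub = sub[sub["up_in"] != cls]
            sub = sub.reindex(
                sub["stat"].abs().sort_values(ascending=False, kind="stable").index
            )
            top[(cls, kind)] = list(sub["feature_id"].head(top_n))
    return MarkerResult(table=table, top=top)
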