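"""Between-region comparisons and richness-predictor decomposition.

One-way ANOVA (with Tukey HSD pairwise follow-up when significant) compares a
clade-level parameter across regions.  Hierarchical partitioning decomposes
the R-squared of log species richness regressed on clade-level predictors
(crown age, netDiv0, netDiv_crown, alpha) into per-predictor independent
contributions: the Chevan-Sutherland average, over all predictor orderings,
of the R-squared increase when the predictor enters the model.  All 2^p
subsets (including the intercept-only model) are fitted and ranked by AICc.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaResult", "HPResult", "anova_tukey", "hierarchical_partitioning"]


@dataclass
class AnovaResult:
    F: float
    p: float
    tukey: pd.DataFrame | None
    reason: str | None = None   # why Tukey was omitted


def anova_tukey(values_by_group: dict[str, np.ndarray],
                alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across groups; Tukey HSD only when ANOVA p < alpha."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.allclose(v, v[0]) for v in groups.values()):
        raise ValueError("zero within-group variance in every group")
    F, p = scipy.stats.f_oneway(*groups.values())
    if p < alpha:
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        vals = np.concatenate(list(groups.values()))
        tk = pairwise_tukeyhsd(vals, labels, alpha=alpha)
        table = pd.DataFrame(tk.summary().data[1:],
                             columns=tk.summary().data[0])
        return AnovaResult(F=float(F), p=float(p), tukey=table)
    return AnovaResult(F=float(F), p=float(p), tukey=None,
                       reason=f"ANOVA p={p:.4g} >= {alpha}")


# ---------------------------------------------------------------------------
# Hierarchical partitioning
# ---------------------------------------------------------------------------

@dataclass
class HPResult:
    """All-subsets regression with hierarchical partitioning of R-squared.

    Identities: sum(independent) = full-model R-squared;
    independent[k] + joint[k] = univariate R-squared of predictor k.
    """

    predictors: tuple[str, ...]
    independent: dict[str, float]
    joint: dict[str, float]
    r2_full: float
    subsets: pd.DataFrame       # columns: subset, k, r2, aicc
    best_subset: tuple[str, ...]

    def percent_independent(self, base: str = "sum_I") -> dict[str, float]:
        """Per-predictor share of explained variance, in percent.

        ``base="sum_I"`` divides by the summed independent contributions
        (= full-model R-squared); ``base="r2_full"`` is identical up to the
        decomposition identity and kept for explicitness.
        """
        denom = (sum(self.independent.values()) if base == "sum_I"
                 else self.r2_full)
        return {k: 100.0 * v / denom for k, v in self.independent.items()}


def _r2(y: np.ndarray, X: np.ndarray | None) -> tuple[float, float]:
    """R-squared and RSS of an OLS fit with intercept (X=None: null model)."""
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    if X is None or X.shape[1] == 0:
        return 0.0, sst
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ beta) ** 2))
    return (1.0 - rss / sst if sst > 0 else 0.0), rss


def _aicc(n: int, rss: float, n_coef: int) -> float:
    k = n_coef + 1  # + residual variance
    if n - k - 1 <= 0:
        return math.inf
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def hierarchical_partitioning(y, X: pd.DataFrame,
                              log_response: bool = False) -> HPResult:
    """Chevan-Sutherland decomposition of regression R-squared.

    ``y`` is the response (optionally log-transformed here), ``X`` a frame of
    predictors.  Every subset of predictors is fitted by OLS; the independent
    contribution of predictor k averages, over all orderings, the R-squared
    gain from adding k, which equals the Shapley value of k in the R-squared
    game.  Collinear predictors are permitted (lstsq handles rank deficiency);
    the decomposition identities still hold.
    """
    y = np.asarray(y, dtype=float)
    if log_response:
        if np.any(y <= 0):
            raise ValueError("log response requires positive values")
        y = np.log(y)
    names = tuple(X.columns)
    p = len(names)
    n = len(y)
    if n < p + 2:
        raise ValueError(f"need >= {p + 2} observations for {p} predictors")
    Xm = X.to_numpy(dtype=float)

    r2 = {}
    rows = []
    for size in range(p + 1):
        for sub in itertools.combinations(range(p), size):
            r2v, rss = _r2(y, Xm[:, list(sub)] if sub else None)
            r2[sub] = r2v
            rows.append({"subset": "+".join(names[i] for i in sub) or "(null)",
                         "k": size, "r2": r2v,
                         "aicc": _aicc(n, rss, size + 1)})
    subsets = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)

    fact = [math.factorial(i) for i in range(p + 1)]
    independent = {}
    for k in range(p):
        acc = 0.0
        for sub in r2:
            if k in sub:
                continue
            w = fact[len(sub)] * fact[p - len(sub) - 1] / fact[p]
            acc += w * (r2[tuple(sorted(sub + (k,)))] - r2[sub])
        independent[names[k]] = acc
    joint = {names[k]: r2[(k,)] - independent[names[k]] for k in range(p)}
    best_label = subsets.iloc[0]["subset"]
    best = tuple(best_label.split("+")) if best_label != "(null)" else ()
    return HPResult(predictors=names, independent=independent, joint=joint,
                    r2_full=r2[tuple(range(p))], subsets=subsets,
                    best_subset=best)
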