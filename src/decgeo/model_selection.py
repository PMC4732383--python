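"""Model comparison: LRT, AICc, evidence ratios, relative probabilities.

The comparison follows the convention of reporting, per model, the evidence
ratio exp(-(AICc_i - AICc_best) / 2) normalized so the best model scores 1,
alongside relative model probabilities (the same ratios normalized to sum to
one, rendered as rounded percentages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InvalidConfigurationError
from .inference import FitResult

_LNL_TOL = 1e-6


def aic(lnl: float, k: int) -> float:
    return -2.0 * lnl + 2.0 * k


def aicc(lnl: float, k: int, n: int) -> float:
    """AIC with the small-sample correction 2k(k+1)/(n-k-1).

    ``n`` is the sample size — here the number of tree tips.
    """
    if n <= k + 1:
        raise InvalidConfigurationError(
            f"AICc needs n > k + 1 (got n={n}, k={k})"
        )
    return aic(lnl, k) + 2.0 * k * (k + 1) / (n - k - 1)


def lrt(nested: FitResult, full: FitResult, df: int | None = None):
    """Likelihood-ratio test of a nested model against a fuller one.

    Returns ``(statistic, p_value)`` with the statistic clipped at zero; a
    full-model likelihood materially below the nested one indicates an
    optimizer failure and triggers a warning.
    """
    if nested.k >= full.k:
        raise InvalidConfigurationError("nested model must have fewer parameters")
    if df is None:
        df = full.k - nested.k
    stat = 2.0 * (full.lnl - nested.lnl)
    if stat < -_LNL_TOL:
        warnings.warn(
            f"full model lnL {full.lnl} below nested lnL {nested.lnl}; "
            "likely optimizer failure — statistic clipped to 0",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    return stat, float(scipy.stats.chi2.sf(stat, df))


def akaike_weights(aicc_values: Sequence[float]):
    """Evidence ratios (best = 1) and relative model probabilities."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 2:
        raise InvalidConfigurationError("need at least two models to compare")
    ratios = np.exp(-(a - a.min()) / 2.0)
    return ratios, ratios / ratios.sum()


@dataclass(frozen=True)
class ModelComparison:
    """A model-comparison table: one row per fitted model."""

    table: pd.DataFrame
    n: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @property
    def best(self) -> str:
        return str(self.table.loc[self.table["AICc"].idxmin(), "model"])


def comparison_table(fits: Sequence[FitResult], n: int) -> ModelComparison:
    """Assemble the AICc comparison of a set of fits of the same data.

    Columns: model, free_parameters, lnL, AICc, AICc_weight (evidence ratio,
    best model = 1) and relative_probability_percent (simplex-normalized,
    rounded to whole percent).
    """
    names = [f.model for f in fits]
    if len(set(names)) != len(names):
        raise InvalidConfigurationError("duplicate model names in comparison")
    lnls = np.array([f.lnl for f in fits])
    ks = np.array([f.k for f in fits])
    aiccs = np.array([aicc(l, int(k), n) for l, k in zip(lnls, ks)])
    if len(fits) == 1:
        ratios = np.array([1.0])
        probs = np.array([1.0])
    else:
        ratios, probs = akaike_weights(aiccs)
    table = pd.DataFrame(
        {
            "model": names,
            "free_parameters": ks,
            "lnL": lnls,
            "AICc": aiccs,
            "AICc_weight": ratios,
            "relative_probability_percent": np.rint(100 * probs).astype(int),
        }
    )
    return ModelComparison(table, n)
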