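"""Exhaustive combination ranking and sex-bias analysis.

Enumerates the full 3^8 level space, predicts each combination's
%alpha-SMA reduction from a fitted quadratic model (back-transforming
through the model's response transform, with non-real inverses assigned
zero efficacy), ranks all 6561 combinations, extracts top candidates per
drug count and predicted-ineffective negative controls, and differences
male and female predictions to classify sex-biased combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, full_factorial
from .response_surface import QuadraticModel

__all__ = [
    "RankingError",
    "BIAS_DEADBAND",
    "predict_all",
    "top_k_by_drug_count",
    "bottom_controls",
    "sex_bias_table",
    "validate_predictions",
]

#: |male - female| below this (in %reduction units) classifies as neutral.
#: The sign rule alone is unstable under noise for near-zero differences.
BIAS_DEADBAND = 5.0


class RankingError(ValueError):
    pass


def _levels_frame(design: DesignMatrix) -> pd.DataFrame:
    return pd.DataFrame(design.runs, columns=list(design.drugs))


def predict_all(
    model: QuadraticModel, space: DesignMatrix | None = None
) -> pd.DataFrame:
    """Rank every combination of the level space by predicted response.

    Predictions are back-transformed through the model's exponent; negative
    transformed values (imaginary square roots under the square transform)
    map to response 0. Sorting is by predicted response descending, ties
    broken lexicographically by level vector, so the ranking is a
    deterministic permutation of the space.

    Returns a DataFrame with one level column per drug plus ``n_drugs``,
    ``predicted_pct`` and ``rank`` (1 = best).
    """
    if space is None:
        space = full_factorial(len(model.drugs), 3, drugs=model.drugs)
    if tuple(space.drugs) != tuple(model.drugs):
        raise RankingError("space drugs do not match model drugs")
    df = _levels_frame(space)
    df["n_drugs"] = (space.runs > 0).sum(axis=1)
    df["predicted_pct"] = model.predict(space.runs)
    lex_cols = list(space.drugs)
    df = df.sort_values(
        by=["predicted_pct"] + lex_cols,
        ascending=[False] + [True] * len(lex_cols),
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_k_by_drug_count(ranked: pd.DataFrame, k_drugs: int, top_n: int) -> pd.DataFrame:
    """Highest-ranked combinations using exactly ``k_drugs`` drugs.

    Mirrors candidate prioritization: the top entries of the two-, three-
    and four-drug strata become validation candidates. If fewer than
    ``top_n`` such combinations exist, all are returned.
    """
    if top_n < 1:
        raise RankingError("top_n must be >= 1")
    sub = ranked[ranked["n_drugs"] == k_drugs]
    return sub.nsmallest(top_n, "rank").reset_index(drop=True)


def bottom_controls(ranked: pd.DataFrame, n: int, min_drugs: int = 2) -> pd.DataFrame:
    """Lowest-ranked multi-drug combinations: predicted-ineffective controls."""
    if n < 1:
        raise RankingError("n must be >= 1")
    sub = ranked[ranked["n_drugs"] >= min_drugs]
    return sub.nlargest(n, "rank").reset_index(drop=True)


def sex_bias_table(
    male_ranked: pd.DataFrame,
    female_ranked: pd.DataFrame,
    drugs: tuple[str, ...],
    deadband: float = BIAS_DEADBAND,
) -> pd.DataFrame:
    """Male-minus-female prediction differences over the aligned space.

    Combinations are aligned on their level vectors; the female predicted
    %reduction is subtracted from the male one and rows are sorted by the
    difference, descending. Positive differences are male-biased, negative
    female-biased, and differences within ``deadband`` neutral.
    """
    cols = list(drugs)
    m = male_ranked[cols + ["n_drugs", "predicted_pct"]].rename(
        columns={"predicted_pct": "male_pred"}
    )
    f = female_ranked[cols + ["predicted_pct"]].rename(
        columns={"predicted_pct": "female_pred"}
    )
    merged = m.merge(f, on=cols, how="inner", validate="one_to_one")
    if len(merged) != len(male_ranked) or len(merged) != len(female_ranked):
        raise RankingError("male and female rankings cover different level spaces")
    merged["difference"] = merged["male_pred"] - merged["female_pred"]
    merged["bias_class"] = np.select(
        [merged["difference"] >= deadband, merged["difference"] <= -deadband],
        ["male_biased", "female_biased"],
        default="neutral",
    )
    merged = merged.sort_values(
        by=["difference"] + cols, ascending=[False] + [True] * len(cols),
        kind="mergesort",
    ).reset_index(drop=True)
    return merged


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def validate_predictions(predicted, measured) -> CorrelationReport:
    """Pearson correlation between model predictions and measurements.

    The two-sided p-value comes from the t-distribution with n - 2 degrees
    of freedom; the least-squares line (measured on predicted) is reported
    alongside.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise RankingError("predicted and measured must be paired 1-D lists")
    if len(predicted) < 3:
        raise RankingError("at least 3 pairs required")
    res = stats.linregress(predicted, measured)
    return CorrelationReport(
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(predicted),
    )
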