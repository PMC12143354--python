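"""Bliss-independence synergy scoring of checkerboard assays.

Two drugs are tested on an all-pairs dose grid including a zero dose for
each (a 6x6 checkerboard in the screen, giving 25 nonzero dose pairs). For
each nonzero pair, the Bliss independence null predicts a combined effect
fA + fB - fA*fB from the matched monotherapy effect fractions; the synergy
score is 100 times the observed excess over that expectation. Scores above
+10 are synergistic, below -10 antagonistic, and additive in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynergyError",
    "SYNERGY_THRESHOLD",
    "effect_fraction",
    "bliss_score",
    "score_checkerboard",
    "sex_synergy_contrast",
    "SynergyMap",
]

#: Classification thresholds on the Bliss score (percent scale).
SYNERGY_THRESHOLD = 10.0


class SynergyError(ValueError):
    pass


def effect_fraction(pct_reduction) -> np.ndarray | float:
    """Map %reduction onto the [0, 1] effect scale Bliss requires.

    Negative reductions (drug-worsened activation) are treated as no
    effect; values above 100 saturate at full effect.
    """
    return np.clip(np.asarray(pct_reduction, dtype=float) / 100.0, 0.0, 1.0)


def bliss_score(f_a: float, f_b: float, f_ab: float) -> float:
    """100 * (observed - Bliss expectation); symmetric in the two drugs."""
    for name, v in (("f_a", f_a), ("f_b", f_b), ("f_ab", f_ab)):
        if not 0.0 <= v <= 1.0:
            raise SynergyError(f"{name} must be a fraction in [0, 1], got {v}")
    expected = f_a + f_b - f_a * f_b
    return 100.0 * (f_ab - expected)


def classify(score: float, threshold: float = SYNERGY_THRESHOLD) -> str:
    if score > threshold:
        return "synergistic"
    if score < -threshold:
        return "antagonistic"
    return "additive"


@dataclass(frozen=True)
class SynergyMap:
    """Scored checkerboard for one drug pair.

    ``cells`` has one row per nonzero dose pair with columns ``dose_a_uM,
    dose_b_uM, observed, expected, score, p_value, classification``; the
    score is computed from replicate-mean effects, and the p-value is a
    one-sample t-test of the per-replicate scores against zero.
    """

    drug_a: str
    drug_b: str
    cells: pd.DataFrame

    @property
    def grid(self) -> pd.DataFrame:
        """Scores pivoted to a (doses_a x doses_b) matrix."""
        return self.cells.pivot(
            index="dose_a_uM", columns="dose_b_uM", values="score"
        )

    def transpose(self) -> "SynergyMap":
        cells = self.cells.rename(
            columns={"dose_a_uM": "dose_b_uM", "dose_b_uM": "dose_a_uM"}
        )
        cells = cells.sort_values(["dose_a_uM", "dose_b_uM"]).reset_index(drop=True)
        return SynergyMap(self.drug_b, self.drug_a, cells)


def score_checkerboard(
    table: pd.DataFrame,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
    threshold: float = SYNERGY_THRESHOLD,
) -> SynergyMap:
    """Score every nonzero dose pair of a checkerboard table.

    The table needs columns ``dose_a_uM, dose_b_uM, replicate,
    response_pct`` and must contain the zero-dose row and column — the
    monotherapy references the Bliss expectation is built from (taken from
    the checkerboard itself, not from refit curves, keeping the map
    self-contained). Per-cell significance of a positive score is a
    one-sample t-test across replicates where replicate-matched monotherapy
    rows allow it.
    """
    required = {"dose_a_uM", "dose_b_uM", "replicate", "response_pct"}
    missing = required - set(table.columns)
    if missing:
        raise SynergyError(f"checkerboard table missing columns: {sorted(missing)}")
    doses_a = np.sort(table["dose_a_uM"].unique())
    doses_b = np.sort(table["dose_b_uM"].unique())
    if 0.0 not in doses_a or 0.0 not in doses_b:
        raise SynergyError("checkerboard must include the zero-dose row and column")

    def cell(da, db):
        return table[(table["dose_a_uM"] == da) & (table["dose_b_uM"] == db)]

    rows = []
    for da in doses_a[doses_a > 0]:
        mono_a = cell(da, 0.0)
        fa_mean = float(effect_fraction(mono_a["response_pct"]).mean())
        for db in doses_b[doses_b > 0]:
            mono_b = cell(0.0, db)
            combo = cell(da, db)
            if combo.empty or mono_a.empty or mono_b.empty:
                raise SynergyError(f"missing measurements for dose pair ({da},{db})")
            fb_mean = float(effect_fraction(mono_b["response_pct"]).mean())
            fab_mean = float(effect_fraction(combo["response_pct"]).mean())
            score = bliss_score(fa_mean, fb_mean, fab_mean)

            # replicate-matched per-replicate scores for the significance test
            reps = sorted(
                set(combo["replicate"])
                & set(mono_a["replicate"])
                & set(mono_b["replicate"])
            )
            rep_scores = []
            for r in reps:
                fa = float(
                    effect_fraction(
                        mono_a.loc[mono_a["replicate"] == r, "response_pct"]
                    ).mean()
                )
                fb = float(
                    effect_fraction(
                        mono_b.loc[mono_b["replicate"] == r, "response_pct"]
                    ).mean()
                )
                fab = float(
                    effect_fraction(
                        combo.loc[combo["replicate"] == r, "response_pct"]
                    ).mean()
                )
                rep_scores.append(bliss_score(fa, fb, fab))
            if len(rep_scores) >= 2 and np.std(rep_scores) > 0:
                p = float(stats.ttest_1samp(rep_scores, 0.0).pvalue)
            else:
                p = float("nan")
            rows.append(
                (da, db, fab_mean, fa_mean + fb_mean - fa_mean * fb_mean, score, p,
                 classify(score, threshold))
            )
    cells = pd.DataFrame(
        rows,
        columns=[
            "dose_a_uM", "dose_b_uM", "observed", "expected", "score",
            "p_value", "classification",
        ],
    )
    return SynergyMap(drug_a, drug_b, cells)


def sex_synergy_contrast(
    map_m: SynergyMap, map_f: SynergyMap, cells: list[tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Side-by-side male and female Bliss scores for selected dose pairs.

    Used to ask whether a synergy is sex-dependent: a pair can be
    synergistic in one sex and merely additive in the other. ``contrast``
    is the male minus female score; swapping the inputs negates it.
    """
    if (map_m.drug_a, map_m.drug_b) != (map_f.drug_a, map_f.drug_b):
        raise SynergyError("maps must cover the same drug pair")
    keys = ["dose_a_uM", "dose_b_uM"]
    m = map_m.cells[keys + ["score", "classification"]].rename(
        columns={"score": "male_score", "classification": "male_class"}
    )
    f = map_f.cells[keys + ["score", "classification"]].rename(
        columns={"score": "female_score", "classification": "female_class"}
    )
    merged = m.merge(f, on=keys, how="inner", validate="one_to_one")
    if len(merged) != len(map_m.cells):
        raise SynergyError("maps cover different dose grids")
    if cells is not None:
        sel = pd.DataFrame(cells, columns=keys)
        merged = merged.merge(sel, on=keys, how="inner")
    merged["contrast"] = merged["male_score"] - merged["female_score"]
    return merged.reset_index(drop=True)
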