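"""In-silico VIC drug-response datasets.

Stands in for the wet-lab immunofluorescence measurements with data that
carry the statistical structure the analysis pipeline assumes: per-sex 4PL
monotherapy curves, a per-sex ground-truth second-order quadratic
combination surface with sparse bilinear interactions, and additive
Gaussian well-level noise (default SD 10 %alpha-SMA-reduction units, the
value the screen's power analysis assumed).

Level codes {L0, L1, L2} are evaluated on the surface at coded values
{0, 0.5, 1}: the concentration spacing between L1 and L2 is drug-specific
and unknown, so the surface is read as level-indexed, not
concentration-indexed.

All randomness flows through explicit integer seeds; no global RNG state is
touched, and identical seeds reproduce identical tables byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, DoseLadder
from .dose_response import DoseResponseCurve, four_pl

__all__ = [
    "TrueSurface",
    "NoiseModel",
    "SyntheticDataError",
    "LEVEL_CODING",
    "RESPONSE_FLOOR",
    "simulate_monotherapy",
    "simulate_design_responses",
    "simulate_checkerboard",
    "make_sex_pair",
    "make_drug_curves",
]

#: Ordinal coding of level codes for surface evaluation.
LEVEL_CODING = {0: 0.0, 1: 0.5, 2: 1.0}

#: Lower clip for simulated responses: drugs can worsen activation
#: (negative %reduction) but cells cannot exceed ~150% of control activity.
RESPONSE_FLOOR = -50.0


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth second-order quadratic combination surface for one sex.

    The surface value at a coded level vector x is

        intercept + sum_i linear[i] x_i + sum_i quadratic[i] x_i^2
                  + sum_{i<j} bilinear[(i,j)] x_i x_j

    in transformed-response units. ``transform_exponent`` t is a monotone
    warp linking the surface to the observed %reduction scale: observed =
    max(surface, 0)**(1/t) for t != 1, identity for t = 1. Fitting the
    response surface with a power transform of exponent t then inverts the
    warp exactly on noiseless data.
    """

    drugs: tuple[str, ...]
    intercept: float
    linear: tuple[float, ...]
    quadratic: tuple[float, ...]
    bilinear: dict[tuple[int, int], float] = field(default_factory=dict)
    transform_exponent: float = 1.0

    def __post_init__(self) -> None:
        k = len(self.drugs)
        if len(self.linear) != k or len(self.quadratic) != k:
            raise SyntheticDataError("linear/quadratic must have one entry per drug")
        for i, j in self.bilinear:
            if not (0 <= i < j < k):
                raise SyntheticDataError(
                    f"bilinear key ({i},{j}) must be an ordered distinct pair"
                )
        if self.transform_exponent <= 0:
            raise SyntheticDataError("transform_exponent must be positive")

    def evaluate(self, levels) -> float:
        """Surface value (transformed scale) at one level-code vector."""
        x = np.array([LEVEL_CODING[int(c)] for c in levels])
        lin = np.asarray(self.linear)
        quad = np.asarray(self.quadratic)
        val = self.intercept + float(lin @ x) + float(quad @ x**2)
        for (i, j), coef in self.bilinear.items():
            val += coef * x[i] * x[j]
        return val

    def observed(self, levels) -> float:
        """Noiseless observed response: the surface through the warp."""
        u = self.evaluate(levels)
        t = self.transform_exponent
        if t == 1.0:
            return u
        return max(u, 0.0) ** (1.0 / t)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian well-level noise."""

    well_sd: float = 10.0
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.well_sd < 0:
            raise SyntheticDataError("well_sd must be nonnegative")
        if self.replicate_count < 1:
            raise SyntheticDataError("replicate_count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_monotherapy(
    curve: DoseResponseCurve, doses, noise: NoiseModel
) -> pd.DataFrame:
    """Simulate a single-drug dose-response table from a 4PL curve.

    One row per dose x replicate; columns ``drug, sex, dose_uM, replicate,
    response_pct``. The per-dose sample mean converges to the 4PL value as
    the replicate count grows.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise SyntheticDataError("doses must be nonnegative")
    rng = noise.rng()
    rows = []
    for dose in doses:
        mean = float(four_pl(dose, curve.top, curve.ec50, curve.hill))
        for rep in range(1, noise.replicate_count + 1):
            resp = mean + rng.normal(0.0, noise.well_sd) if noise.well_sd else mean
            rows.append((curve.drug, curve.sex, dose, rep, resp))
    return pd.DataFrame(
        rows, columns=["drug", "sex", "dose_uM", "replicate", "response_pct"]
    )


def simulate_design_responses(
    surface: TrueSurface, design: DesignMatrix, noise: NoiseModel
) -> pd.DataFrame:
    """Simulate responses for every run of a level-coded design.

    response = warp(quadratic series at coded levels) + N(0, well_sd),
    clipped below at ``RESPONSE_FLOOR``. Replicates are separate rows.
    Columns: one level column per drug, then ``run_id, replicate,
    response_pct``.
    """
    if design.drugs != surface.drugs:
        raise SyntheticDataError("design columns must match surface drugs")
    rng = noise.rng()
    rows = []
    for run_id, levels in enumerate(design.runs):
        mean = surface.observed(levels)
        for rep in range(1, noise.replicate_count + 1):
            resp = mean + (rng.normal(0.0, noise.well_sd) if noise.well_sd else 0.0)
            rows.append(
                list(int(c) for c in levels) + [run_id, rep, max(resp, RESPONSE_FLOOR)]
            )
    cols = list(design.drugs) + ["run_id", "replicate", "response_pct"]
    return pd.DataFrame(rows, columns=cols)


def simulate_checkerboard(
    curve_a: DoseResponseCurve,
    curve_b: DoseResponseCurve,
    planted_bliss_excess: float,
    ladder_a: DoseLadder,
    ladder_b: DoseLadder,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Simulate a two-drug checkerboard with a planted Bliss excess.

    Monotherapy rows and columns follow the two 4PL curves. At cells where
    both doses are nonzero the mean response is the Bliss expectation of
    the two monotherapy effects plus ``planted_bliss_excess`` (in score
    units, i.e. percentage points). With zero noise and zero excess, every
    computed Bliss score is exactly 0. Columns: ``dose_a_uM, dose_b_uM,
    replicate, response_pct``.
    """
    for lad in (ladder_a, ladder_b):
        if 0.0 not in lad.doses:
            raise SyntheticDataError(
                "ladders must include dose 0 (Bliss reference undefined without it)"
            )
    rng = noise.rng()
    rows = []
    for da in ladder_a.doses:
        fa = float(four_pl(da, curve_a.top, curve_a.ec50, curve_a.hill)) / 100.0
        fa = min(max(fa, 0.0), 1.0)
        for db in ladder_b.doses:
            fb = float(four_pl(db, curve_b.top, curve_b.ec50, curve_b.hill)) / 100.0
            fb = min(max(fb, 0.0), 1.0)
            if da > 0 and db > 0:
                mean = 100.0 * (fa + fb - fa * fb) + planted_bliss_excess
            elif da > 0:
                mean = 100.0 * fa
            elif db > 0:
                mean = 100.0 * fb
            else:
                mean = 0.0
            for rep in range(1, noise.replicate_count + 1):
                resp = mean + (
                    rng.normal(0.0, noise.well_sd) if noise.well_sd else 0.0
                )
                rows.append((da, db, rep, resp))
    return pd.DataFrame(
        rows, columns=["dose_a_uM", "dose_b_uM", "replicate", "response_pct"]
    )


# --------------------------------------------------------------------------
# Sex-specific surface pair
# --------------------------------------------------------------------------

# Index pairs in the default drug panel: losartan/SD-208 carry the
# male-specific interaction, LY294002/H1152 the female-specific one.
_MALE_PAIR = (6, 7)
_FEMALE_PAIR = (1, 2)


def make_sex_pair(
    seed: int,
    drugs: tuple[str, ...] | None = None,
    strong_interaction: float = 40.0,
    weak_interaction: float = 5.0,
) -> tuple[TrueSurface, TrueSurface]:
    """Ground-truth male and female surfaces over the same drug panel.

    Emulates the screen's qualitative findings: monotherapies are broadly
    ineffective (every single-drug L2 response is at most 15 units), each
    sex has one strong planted bilinear synergy — losartan x SD-208 in the
    male surface, LY294002 x H1152 in the female surface — and the
    cross-sex coefficient for each pair is weak, so the planted pairs are
    sex-biased by at least ``strong_interaction - weak_interaction`` units
    at their both-L2 combination. Small per-drug linear and quadratic
    coefficients are drawn from the seeded RNG.
    """
    from .design import DEFAULT_DRUGS

    if drugs is None:
        drugs = DEFAULT_DRUGS
    k = len(drugs)
    rng = np.random.default_rng(seed)

    # Shared base monotherapy profile with small per-sex perturbations:
    # linear + quadratic <= 12 keeps every L2 monotherapy response <= 15,
    # and bounding the sex perturbation at +/-1.5 per drug keeps the planted
    # pair's both-L2 sex difference above strong - weak - 6 units.
    lin_base = rng.uniform(2.0, 7.0, size=k)
    quad = rng.uniform(-2.0, np.minimum(12.0 - lin_base - 1.5, 2.0), size=k)
    lin_m = tuple(lin_base + rng.uniform(-1.5, 1.5, size=k))
    lin_f = tuple(lin_base + rng.uniform(-1.5, 1.5, size=k))
    quad_m = quad_f = tuple(quad)

    shared = rng.uniform(-weak_interaction, weak_interaction, size=2)
    shared_pairs = [(0, 3), (4, 5)]  # mild, identical in both sexes
    bil_m = {p: float(c) for p, c in zip(shared_pairs, shared)}
    bil_f = dict(bil_m)
    bil_m[_MALE_PAIR] = strong_interaction
    bil_f[_MALE_PAIR] = weak_interaction
    bil_f[_FEMALE_PAIR] = strong_interaction
    bil_m[_FEMALE_PAIR] = weak_interaction

    male = TrueSurface(tuple(drugs), 0.0, lin_m, quad_m, bil_m)
    female = TrueSurface(tuple(drugs), 0.0, lin_f, quad_f, bil_f)
    return male, female


def make_drug_curves(
    seed: int, drugs: tuple[str, ...], sex: str
) -> dict[str, tuple[DoseResponseCurve, DoseResponseCurve]]:
    """Ground-truth efficacy and cytotoxicity 4PL curves per drug.

    Efficacy tops are partial (60-95%), EC50s log-uniform over a realistic
    micromolar window, Hill slopes near 1; cytotoxicity sets in one to two
    orders of magnitude above the efficacy EC50, so the selected L1/L2
    doses usually bind on the EC or Cmax rule rather than toxicity.
    Returns ``{drug: (efficacy_curve, cytotoxicity_curve)}``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[DoseResponseCurve, DoseResponseCurve]] = {}
    for drug in drugs:
        top = float(rng.uniform(60.0, 95.0))
        ec50 = float(10 ** rng.uniform(-1.3, 0.7))  # ~0.05 to 5 uM
        hill = float(rng.uniform(0.8, 2.0))
        eff = DoseResponseCurve(drug, sex, "asma_reduction", top, ec50, hill)
        cc50 = ec50 * float(10 ** rng.uniform(1.3, 2.0))
        tox = DoseResponseCurve(
            drug, sex, "cytotoxicity", 100.0, cc50, float(rng.uniform(1.5, 3.0))
        )
        out[drug] = (eff, tox)
    return out
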