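"""Constrained four-parameter logistic dose-response analysis.

Fits 4PL curves to %alpha-SMA-reduction (efficacy) and %cytotoxicity
readouts, with the constraints used throughout the screen: bottom fixed at
0, top at most 100 (maximum possible effect), Hill slope at most 5. From
the fitted curves it computes *absolute* EC/CC values — the concentration
producing a stated absolute response f, not a fraction of the fitted top —
and selects the clinically bounded L1/L2 screening doses as

    L1 = min(EC1, CC1, 0.05 * Cmax)
    L2 = min(EC2, CC2, 0.10 * Cmax)

where Cmax is the drug's maximum clinical serum concentration.

The 4PL parameterization is ``response(x) = top / (1 + (ec50 / x)**hill)``
with ``response(0) = 0`` by continuity, so zero doses need no log handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseCurve",
    "DoseLevels",
    "DrugInfo",
    "DoseResponseError",
    "UnreachableEffectError",
    "percent_reduction",
    "four_pl",
    "fit_4pl",
    "absolute_ec",
    "ec_sex_ratio",
    "percent_cytotoxicity",
    "select_levels",
    "power_n",
]

HILL_MAX = 5.0
TOP_MAX = 100.0


class DoseResponseError(ValueError):
    pass


class UnreachableEffectError(DoseResponseError):
    """The fitted curve never attains the requested absolute effect."""


@dataclass(frozen=True)
class DoseResponseCurve:
    """Constrained 4PL parameters for one drug/sex/readout.

    ``ec50`` holds the EC50 for the efficacy readout and the CC50 for the
    cytotoxicity readout. ``is_flat`` marks the all-zero-response sentinel,
    for which no EC is defined.
    """

    drug: str
    sex: str
    readout: str
    top: float
    ec50: float
    hill: float
    bottom: float = 0.0
    sse: float = float("nan")
    is_flat: bool = False

    def __post_init__(self) -> None:
        if self.is_flat:
            return
        if not 0 < self.top <= TOP_MAX:
            raise DoseResponseError(f"top must be in (0, 100], got {self.top}")
        if not 0 < self.hill <= HILL_MAX:
            raise DoseResponseError(f"hill must be in (0, 5], got {self.hill}")
        if self.ec50 <= 0:
            raise DoseResponseError(f"ec50 must be positive, got {self.ec50}")
        if self.bottom != 0:
            raise DoseResponseError("bottom is fixed at 0")

    def response(self, dose):
        """Evaluate the curve; accepts scalars or arrays, dose 0 maps to 0."""
        if self.is_flat:
            return np.zeros_like(np.asarray(dose, dtype=float))
        return four_pl(dose, self.top, self.ec50, self.hill)


@dataclass(frozen=True)
class DoseLevels:
    """Selected L1/L2 screening doses with binding-constraint provenance."""

    drug: str
    sex: str
    l1: float
    l2: float
    l1_bound: str
    l2_bound: str

    def __post_init__(self) -> None:
        if not 0 < self.l1 <= self.l2:
            raise DoseResponseError("levels must satisfy 0 < L1 <= L2")


@dataclass(frozen=True)
class DrugInfo:
    """Clinical context for level selection."""

    name: str
    cmax: float
    vehicle: str = "water"

    def __post_init__(self) -> None:
        if self.cmax <= 0:
            raise DoseResponseError("Cmax must be positive")


def percent_reduction(control_mean: float, drug_mean: float) -> float:
    """Percent reduction relative to control: 100 * (control - drug) / control.

    The vehicle control maps to exactly 0 by construction, which is why
    downstream significance tests compare against a thresholded zero.
    """
    if control_mean <= 0:
        raise DoseResponseError("control mean must be positive")
    return 100.0 * (control_mean - drug_mean) / control_mean


def four_pl(dose, top: float, ec50: float, hill: float):
    """4PL with bottom 0; vectorized; response(0) = 0 by the x -> 0 limit."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise DoseResponseError("doses must be nonnegative")
    out = np.zeros_like(dose)
    nz = dose > 0
    out[nz] = top / (1.0 + (ec50 / dose[nz]) ** hill)
    return out if out.ndim else float(out)


# Coarse deterministic multi-start grid over (ec50, hill); the best local
# solution wins.  No randomness, so fits are reproducible.
_HILL_STARTS = (0.5, 1.0, 2.0, 4.0)


def fit_4pl(
    doses,
    responses,
    drug: str = "drug",
    sex: str = "unspecified",
    readout: str = "asma_reduction",
    flat_tol: float = 1.0,
) -> DoseResponseCurve:
    """Least-squares constrained 4PL fit.

    Bottom is fixed at 0; bounds are top in (0, 100], hill in (0, 5], ec50
    positive. Data generated with a steeper slope than 5 fit at the hill
    bound. If every response is within ``flat_tol`` of zero a flat-curve
    sentinel is returned (no EC defined).

    Raises
    ------
    DoseResponseError
        Fewer than 4 distinct doses (under-determined with 3 free
        parameters) or negative doses.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise DoseResponseError("doses and responses must align")
    if np.any(doses < 0):
        raise DoseResponseError("doses must be nonnegative")
    if len(np.unique(doses)) < 4:
        raise DoseResponseError("at least 4 distinct doses required for a 4PL fit")
    if np.all(np.abs(responses) <= flat_tol):
        return DoseResponseCurve(
            drug, sex, readout, top=float("nan"), ec50=float("nan"),
            hill=float("nan"), sse=float(np.sum(responses**2)), is_flat=True,
        )

    pos = doses[doses > 0]
    ec50_starts = np.geomspace(pos.min(), pos.max(), 5)
    top0 = min(max(responses.max(), 1.0), TOP_MAX)
    lb = (1e-9, 1e-12, 1e-9)
    ub = (TOP_MAX, np.inf, HILL_MAX)

    def resid(theta):
        top, ec50, hill = theta
        return four_pl(doses, top, ec50, hill) - responses

    best = None
    for ec50_0 in ec50_starts:
        for hill_0 in _HILL_STARTS:
            sol = optimize.least_squares(
                resid, x0=(top0, ec50_0, hill_0), bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    top, ec50, hill = best.x
    return DoseResponseCurve(
        drug, sex, readout,
        top=float(np.clip(top, 1e-9, TOP_MAX)),
        ec50=float(ec50),
        hill=float(np.clip(hill, 1e-9, HILL_MAX)),
        sse=float(2 * best.cost),
    )


def absolute_ec(curve: DoseResponseCurve, f: float) -> float:
    """Concentration producing the absolute response f under the curve.

    Inverts the 4PL analytically: x = ec50 / (top/f - 1)**(1/hill). The
    round trip ``curve.response(absolute_ec(curve, f)) == f`` holds to
    floating precision for every attainable f in (0, top).
    """
    if curve.is_flat:
        raise UnreachableEffectError(f"{curve.drug}: flat curve, no EC defined")
    if f <= 0:
        raise DoseResponseError("effect level must be positive")
    if f >= curve.top:
        raise UnreachableEffectError(
            f"{curve.drug}: effect {f} not attainable (top = {curve.top})"
        )
    return curve.ec50 / (curve.top / f - 1.0) ** (1.0 / curve.hill)


def ec_sex_ratio(curve_m: DoseResponseCurve, curve_f: DoseResponseCurve, f: float) -> float:
    """log10 of male-to-female absolute EC ratio at effect f.

    Negative values mean the drug is more potent in male cells (a smaller
    concentration achieves the same effect).
    """
    return math.log10(absolute_ec(curve_m, f) / absolute_ec(curve_f, f))


def percent_cytotoxicity(cell_measures, alive_ref, dead_ref) -> float:
    """Fraction of cells classified dead by a control-derived threshold.

    The threshold is the midpoint of the alive-control and dead-control mean
    marker intensities; cells above it count as dead. Returns a percentage.
    """
    cells = np.asarray(cell_measures, dtype=float)
    alive = np.asarray(alive_ref, dtype=float)
    dead = np.asarray(dead_ref, dtype=float)
    if alive.size == 0 or dead.size == 0:
        raise DoseResponseError("both control lists must be nonempty")
    if np.isclose(alive.mean(), dead.mean()):
        raise DoseResponseError("degenerate threshold: control means coincide")
    threshold = 0.5 * (alive.mean() + dead.mean())
    return 100.0 * float(np.mean(cells > threshold))


def select_levels(
    ec1: float, cc1: float, ec2: float, cc2: float, info: DrugInfo,
    sex: str = "unspecified",
) -> DoseLevels:
    """Pick the clinically bounded L1/L2 doses.

    L1 is the smallest of EC1, CC1 and 5% of Cmax; L2 the smallest of EC2,
    CC2 and 10% of Cmax. Provenance records which bound was binding.
    """
    for name, v in (("ec1", ec1), ("cc1", cc1), ("ec2", ec2), ("cc2", cc2)):
        if v <= 0:
            raise DoseResponseError(f"{name} must be positive")
    c1 = {"EC": ec1, "CC": cc1, "Cmax": 0.05 * info.cmax}
    c2 = {"EC": ec2, "CC": cc2, "Cmax": 0.10 * info.cmax}
    b1 = min(c1, key=c1.get)
    b2 = min(c2, key=c2.get)
    return DoseLevels(info.name, sex, c1[b1], c2[b2], b1, b2)


def power_n(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.8,
    two_sample: bool = True,
    n_cap: int = 10_000,
) -> int:
    """Smallest per-group n achieving the target power for a t-test.

    Power is evaluated exactly through the noncentral t distribution for a
    two-sided test. The default two-sample formulation (experimental group
    vs control, equal n, pooled variance) gives n = 3 at the screen's
    planning point (delta 35, SD 10, alpha 0.05, power 0.8); a one-sample
    variant against a thresholded zero is available via ``two_sample=False``.
    """
    if delta <= 0 or sd <= 0:
        raise DoseResponseError("delta and sd must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise DoseResponseError("alpha and power must be in (0, 1)")
    for n in range(2, n_cap + 1):
        if two_sample:
            df = 2 * n - 2
            ncp = delta / (sd * math.sqrt(2.0 / n))
        else:
            df = n - 1
            ncp = delta / (sd / math.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        achieved = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        if achieved >= power:
            return n
    raise DoseResponseError(f"required n exceeds cap {n_cap}")
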