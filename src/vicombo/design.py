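"""Combination screening designs.

Constructs the designs used to interrogate an 8-drug, 3-level (L0/L1/L2)
combination space: a 59-run orthogonal array composite design (OACD)
consisting of a 32-run resolution-IV two-level fractional factorial plus a
27-run strength-2 three-level orthogonal array, L1/L2 monotherapy runs, the
full 3^8 enumeration, and twofold-dilution checkerboard dose ladders.

Level codes are integers: 0 = drug absent, 1 = low dose (L1), 2 = high dose
(L2). The two-level block uses codes {0, 2} (absence vs. the high dose),
following the OACD convention of embedding the factorial block at the
extreme levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesignMatrix",
    "DoseLadder",
    "DesignError",
    "build_oacd",
    "verify_design",
    "monotherapy_runs",
    "full_factorial",
    "checkerboard_ladder",
]

VALID_CODES = (0, 1, 2)

#: Default drug panel: the eight myofibroblast-pathway inhibitors screened
#: (ROCK, PI3K, ROCK2, p38 MAPK, STS, PAI-1, AT1R, TGFbetaRI inhibitors).
DEFAULT_DRUGS = (
    "Y-27632",
    "LY294002",
    "H1152",
    "SB203580",
    "irosustat",
    "TM5441",
    "losartan",
    "SD-208",
)


class DesignError(ValueError):
    """Raised for unsupported or invalid design requests."""


@dataclass(frozen=True)
class DesignMatrix:
    """Runs-by-drugs table of level codes.

    Parameters
    ----------
    drugs
        Ordered drug identifiers, one per column.
    runs
        Level-code matrix of shape (n_runs, n_drugs), codes in {0, 1, 2}.
    block_labels
        Per-run tag: ``two_level``, ``three_level``, ``monotherapy``, or
        ``custom``.
    """

    drugs: tuple[str, ...]
    runs: np.ndarray
    block_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        runs = np.asarray(self.runs, dtype=int)
        object.__setattr__(self, "runs", runs)
        if runs.ndim != 2 or runs.shape[1] != len(self.drugs):
            raise DesignError(
                f"runs must be 2-D with one column per drug "
                f"({runs.shape} vs {len(self.drugs)} drugs)"
            )
        if len(self.block_labels) != runs.shape[0]:
            raise DesignError("one block label required per run")
        if not np.isin(runs, VALID_CODES).all():
            bad = sorted(set(runs.ravel()) - set(VALID_CODES))
            raise DesignError(f"level codes outside {{0,1,2}}: {bad}")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def block(self, label: str) -> np.ndarray:
        """Return the runs carrying the given block label."""
        mask = np.array([b == label for b in self.block_labels])
        return self.runs[mask]

    def concat(self, other: "DesignMatrix") -> "DesignMatrix":
        if self.drugs != other.drugs:
            raise DesignError("cannot concatenate designs over different drugs")
        return DesignMatrix(
            self.drugs,
            np.vstack([self.runs, other.runs]),
            self.block_labels + other.block_labels,
        )


@dataclass(frozen=True)
class DoseLadder:
    """Ascending checkerboard dose ladder, first dose 0, twofold steps."""

    drug: str
    doses: tuple[float, ...]

    def __post_init__(self) -> None:
        d = self.doses
        if d[0] != 0:
            raise DesignError("dose ladder must start at 0")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise DesignError("dose ladder must be strictly ascending")
        nz = d[1:]
        for a, b in zip(nz, nz[1:]):
            if not np.isclose(b / a, 2.0):
                raise DesignError("successive nonzero doses must be twofold")


# --------------------------------------------------------------------------
# OACD construction
# --------------------------------------------------------------------------

# 2^(8-3) fraction of resolution IV: five basic factors A..E in a full 2^5,
# generators F = ABC, G = ABD, H = BCDE.  All words of the defining relation
# (ABCF, ABDG, BCDEH and their products) have length >= 4, so no main effect
# is aliased with any two-factor interaction; verify_design re-checks this
# numerically rather than trusting the algebra.
_TWO_LEVEL_GENERATORS = ((0, 1, 2), (0, 1, 3), (1, 2, 3, 4))


def _two_level_block(n_factors: int = 8) -> np.ndarray:
    """32-run resolution-IV fraction in +/-1 coding, columns = factors."""
    base = np.array(list(itertools.product((-1, 1), repeat=5)))
    cols = [base[:, i] for i in range(5)]
    for gen in _TWO_LEVEL_GENERATORS:
        cols.append(np.prod([base[:, i] for i in gen], axis=0))
    return np.column_stack(cols[:n_factors])


def _three_level_block(n_factors: int = 8) -> np.ndarray:
    """27-run strength-2 orthogonal array over levels {0,1,2}.

    Rows are the points of GF(3)^3; each column is the dot product with a
    fixed direction vector (first nonzero coordinate 1).  Any two
    non-proportional direction vectors give a strength-2 pair, so every
    subset of the 13 columns is a strength-2 OA.
    """
    points = np.array(list(itertools.product(range(3), repeat=3)))
    directions = [
        v
        for v in itertools.product(range(3), repeat=3)
        if any(v) and v[next(i for i, x in enumerate(v) if x)] == 1
    ]
    cols = [(points @ np.array(v)) % 3 for v in directions[:n_factors]]
    return np.column_stack(cols)


def build_oacd(n_factors: int, drugs: tuple[str, ...] | None = None) -> DesignMatrix:
    """Build the 59-run orthogonal array composite design.

    The design is the union of a 32-run resolution-IV two-level fractional
    factorial (levels coded {0, 2}: absence vs. L2) and a 27-run strength-2
    three-level orthogonal array (levels {0, 1, 2}). Both blocks are built
    from fixed generator sets, so repeated calls are identical.

    Parameters
    ----------
    n_factors
        Number of drugs; only 8 is supported (the screening panel size).
    drugs
        Optional drug names; defaults to the 8-inhibitor panel.

    Returns
    -------
    DesignMatrix
        59 runs labelled ``two_level`` (32) and ``three_level`` (27).
    """
    if n_factors != 8:
        raise DesignError(
            f"OACD construction is defined for 8 factors, got {n_factors}"
        )
    if drugs is None:
        drugs = DEFAULT_DRUGS
    if len(drugs) != n_factors:
        raise DesignError("drug list length must equal n_factors")
    two = (_two_level_block(n_factors) + 1)  # {-1,+1} -> {0,2}
    three = _three_level_block(n_factors)
    runs = np.vstack([two, three])
    labels = ("two_level",) * two.shape[0] + ("three_level",) * three.shape[0]
    return DesignMatrix(tuple(drugs), runs, labels)


# --------------------------------------------------------------------------
# Design verification
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only diagnostics for a design block."""

    level_counts: dict[str, dict[int, int]]
    balanced: bool
    orthogonality_violations: list[tuple[str, str]]
    strength2: bool
    aliased_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    resolution_iv: bool | None = None


def _pair_counts(col_i: np.ndarray, col_j: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for a, b in zip(col_i, col_j):
        counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
    return counts


def verify_design(design: DesignMatrix) -> ValidationReport:
    """Check balance, pairwise orthogonality, and two-level aliasing.

    For every column: level counts and balance. For every column pair: a
    strength-2 check (each ordered level pair equally often). For designs
    whose columns take exactly two levels: a resolution-IV check — no main
    effect column may equal plus or minus the elementwise product of two
    other columns (in +/-1 coding). Report-only; nothing is raised.
    """
    runs = design.runs
    n, k = runs.shape
    level_counts: dict[str, dict[int, int]] = {}
    balanced = True
    for j, drug in enumerate(design.drugs):
        levels, counts = np.unique(runs[:, j], return_counts=True)
        level_counts[drug] = dict(zip(levels.tolist(), counts.tolist()))
        if len(set(counts.tolist())) > 1:
            balanced = False

    violations: list[tuple[str, str]] = []
    strength2 = True
    for i, j in itertools.combinations(range(k), 2):
        counts = _pair_counts(runs[:, i], runs[:, j])
        li = len(np.unique(runs[:, i]))
        lj = len(np.unique(runs[:, j]))
        expected = n / (li * lj)
        if len(counts) != li * lj or any(c != expected for c in counts.values()):
            strength2 = False
            violations.append((design.drugs[i], design.drugs[j]))

    report = ValidationReport(level_counts, balanced, violations, strength2)

    # Aliasing only meaningful for a two-level block.
    if all(len(np.unique(runs[:, j])) == 2 for j in range(k)):
        signed = np.empty_like(runs, dtype=float)
        for j in range(k):
            lo, hi = np.unique(runs[:, j])
            signed[:, j] = np.where(runs[:, j] == lo, -1.0, 1.0)
        aliased: list[tuple[str, str, str]] = []
        for c in range(k):
            for a, b in itertools.combinations(range(k), 2):
                if c in (a, b):
                    continue
                prod = signed[:, a] * signed[:, b]
                if np.array_equal(signed[:, c], prod) or np.array_equal(
                    signed[:, c], -prod
                ):
                    aliased.append(
                        (design.drugs[c], design.drugs[a], design.drugs[b])
                    )
        report.aliased_pairs = aliased
        report.resolution_iv = not aliased
    return report


# --------------------------------------------------------------------------
# Auxiliary designs
# --------------------------------------------------------------------------

def monotherapy_runs(
    n_drugs: int, drugs: tuple[str, ...] | None = None
) -> DesignMatrix:
    """L1 and L2 single-drug runs: 2 per drug, one nonzero code each."""
    if n_drugs < 1:
        raise DesignError("n_drugs must be >= 1")
    if drugs is None:
        drugs = (
            DEFAULT_DRUGS[:n_drugs]
            if n_drugs <= len(DEFAULT_DRUGS)
            else tuple(f"drug{i + 1}" for i in range(n_drugs))
        )
    rows = []
    for j in range(n_drugs):
        for code in (1, 2):
            row = np.zeros(n_drugs, dtype=int)
            row[j] = code
            rows.append(row)
    return DesignMatrix(tuple(drugs), np.array(rows), ("monotherapy",) * (2 * n_drugs))


def full_factorial(
    n_drugs: int,
    n_levels: int,
    drugs: tuple[str, ...] | None = None,
    max_runs: int = 100_000,
) -> DesignMatrix:
    """All level combinations, lexicographically ordered.

    For the 8-drug, 3-level screen this is the 6561-run prediction space.
    """
    if n_levels < 2:
        raise DesignError("n_levels must be >= 2")
    if n_levels > 3:
        raise DesignError("level codes above 2 are not defined")
    size = n_levels**n_drugs
    if size > max_runs:
        raise DesignError(f"full factorial would have {size} runs (cap {max_runs})")
    if drugs is None:
        drugs = (
            DEFAULT_DRUGS[:n_drugs]
            if n_drugs <= len(DEFAULT_DRUGS)
            else tuple(f"drug{i + 1}" for i in range(n_drugs))
        )
    runs = np.array(list(itertools.product(range(n_levels), repeat=n_drugs)))
    return DesignMatrix(tuple(drugs), runs, ("custom",) * size)


def checkerboard_ladder(l2_dose: float, drug: str = "drug") -> DoseLadder:
    """Six-dose checkerboard ladder: 0 up to 4x the L2 dose, twofold steps.

    Doses are ``{0, L2/4, L2/2, L2, 2*L2, 4*L2}``, giving 25 nonzero dose
    pairs in a 6x6 two-drug grid.
    """
    if l2_dose <= 0:
        raise DesignError("l2_dose must be positive")
    doses = (0.0, l2_dose / 4, l2_dose / 2, l2_dose, 2 * l2_dose, 4 * l2_dose)
    return DoseLadder(drug, doses)
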