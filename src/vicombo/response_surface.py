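"""Second-order quadratic response-surface modeling.

Relates level-coded drug combinations to measured %alpha-SMA reduction via
the full second-order series — intercept, per-drug linear and squared
terms, and all pairwise bilinear terms (45 terms for 8 drugs) — selected by
bidirectional F-test stepwise regression. A power (Box-Cox family)
transform of the response is chosen by profile likelihood over a candidate
exponent grid before fitting; residual-based outlier screening uses
externally studentized residuals.

The bilinear coefficients are the quantities of pharmacological interest: a
significantly positive bilinear coefficient flags a strong two-drug
interaction worth checkerboard follow-up.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignMatrix
from .synthetic import LEVEL_CODING

__all__ = [
    "Term",
    "QuadraticModel",
    "OutlierReport",
    "ModelError",
    "full_basis",
    "expand_terms",
    "power_transform",
    "inverse_power_transform",
    "boxcox_select",
    "stepwise_fit",
    "adjusted_r2",
    "outlier_scan",
    "DEFAULT_LAMBDA_GRID",
    "P_ENTER",
    "P_REMOVE",
]

#: Classical stepwise thresholds (entry and removal p-values).
P_ENTER = 0.05
P_REMOVE = 0.10

#: Candidate power-transform exponents; 1 = identity, 2 = square, 0 = log.
DEFAULT_LAMBDA_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class Term:
    """One term of the quadratic series."""

    kind: str  # intercept | linear | quadratic | bilinear
    drugs: tuple[int, ...]  # drug indices; () for intercept

    def label(self, names: tuple[str, ...]) -> str:
        if self.kind == "intercept":
            return "intercept"
        if self.kind == "linear":
            return names[self.drugs[0]]
        if self.kind == "quadratic":
            return f"{names[self.drugs[0]]}^2"
        i, j = self.drugs
        return f"{names[i]}*{names[j]}"


def full_basis(n_drugs: int) -> tuple[Term, ...]:
    """The full second-order basis: 1 + k linear + k quadratic + C(k,2) bilinear."""
    terms = [Term("intercept", ())]
    terms += [Term("linear", (i,)) for i in range(n_drugs)]
    terms += [Term("quadratic", (i,)) for i in range(n_drugs)]
    terms += [
        Term("bilinear", (i, j)) for i, j in itertools.combinations(range(n_drugs), 2)
    ]
    return tuple(terms)


def expand_terms(
    design: DesignMatrix | np.ndarray, coding: dict[int, float] | None = None
) -> tuple[np.ndarray, tuple[Term, ...]]:
    """Model matrix of the full quadratic basis for a level-coded design.

    Returns (X, terms) with one column per term in fixed basis order.
    """
    runs = design.runs if isinstance(design, DesignMatrix) else np.asarray(design)
    if coding is None:
        coding = LEVEL_CODING
    x = np.empty(runs.shape, dtype=float)
    for code, val in coding.items():
        x[runs == code] = float(val)
    n, k = x.shape
    terms = full_basis(k)
    cols = [np.ones(n)]
    cols += [x[:, i] for i in range(k)]
    cols += [x[:, i] ** 2 for i in range(k)]
    cols += [x[:, i] * x[:, j] for i, j in itertools.combinations(range(k), 2)]
    return np.column_stack(cols), terms


# --------------------------------------------------------------------------
# Response transform
# --------------------------------------------------------------------------

def power_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """Simple power transform: y**lam, or log(y) for lam = 0.

    Non-integer and nonpositive exponents require strictly positive
    responses (callers shift first); integer exponents tolerate zeros and
    negatives.
    """
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        if np.any(y <= 0):
            raise ModelError("log transform requires positive responses")
        return np.log(y)
    if (lam != int(lam) or lam < 0) and np.any(y <= 0):
        raise ModelError(f"lambda={lam} requires positive responses")
    return y**lam


def inverse_power_transform(z: np.ndarray, lam: float) -> np.ndarray:
    """Invert the power transform, mapping unattainable values to 0.

    For an even exponent (the square transform in particular) a negative
    transformed prediction has no real preimage — the inverse would be
    imaginary — and is assigned a response of 0 (no efficacy). The same
    clamp applies to any lam > 0; for lam = 0 the inverse is exp.
    """
    z = np.asarray(z, dtype=float)
    if lam == 0.0:
        return np.exp(z)
    if lam < 0:
        out = np.zeros_like(z)
        pos = z > 0
        out[pos] = z[pos] ** (1.0 / lam)
        return out
    return np.where(z > 0, np.maximum(z, 0.0) ** (1.0 / lam), 0.0)


def boxcox_select(
    responses: np.ndarray,
    model_matrix: np.ndarray,
    candidate_lambdas=DEFAULT_LAMBDA_GRID,
) -> tuple[float, float]:
    """Choose a response-transform exponent by Box-Cox profile likelihood.

    Each candidate exponent is scored by the profile log-likelihood of the
    least-squares fit of the *full* basis to the transformed response,
    including the Jacobian term that makes likelihoods comparable across
    exponents. Responses are shifted by (1 - min) when any response is
    nonpositive; the shift is returned and recorded in the fitted model.
    Identity (1.0) wins ties within a small likelihood tolerance, and
    constant responses return identity.

    Returns
    -------
    (lambda, shift)
    """
    lams = list(candidate_lambdas)
    if not lams:
        raise ModelError("candidate lambda list is empty")
    y = np.asarray(responses, dtype=float)
    X = np.asarray(model_matrix, dtype=float)
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
    ys = y + shift
    n = len(ys)
    if np.allclose(ys, ys[0]):
        return 1.0, shift

    loglik: dict[float, float] = {}
    logy_sum = float(np.sum(np.log(ys)))
    for lam in lams:
        z = power_transform(ys, lam)
        resid = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        sse = float(resid @ resid)
        # SSE of the normalized Box-Cox form (y^lam - 1)/lam differs from the
        # plain-power SSE by lam^2; fold that in so exponents are comparable.
        if lam != 0.0:
            sse = sse / lam**2
        sse = max(sse, 1e-300)
        loglik[lam] = -0.5 * n * np.log(sse / n) + (lam - 1.0) * logy_sum

    best = max(loglik.values())
    if 1.0 in loglik and loglik[1.0] >= best - 1e-9:
        return 1.0, shift
    # deterministic tie-break: highest likelihood, then smallest |lam - 1|
    return (
        min(loglik, key=lambda l: (-loglik[l], abs(l - 1.0))),
        shift,
    )


# --------------------------------------------------------------------------
# Stepwise regression
# --------------------------------------------------------------------------

@dataclass
class QuadraticModel:
    """A fitted, term-selected quadratic response surface."""

    drugs: tuple[str, ...]
    terms: tuple[Term, ...]  # selected, intercept always first
    coefficients: np.ndarray  # transformed-response units
    transform_lambda: float = 1.0
    shift: float = 0.0
    p_values: np.ndarray = field(default_factory=lambda: np.array([]))
    adj_r2: float = float("nan")
    sse: float = float("nan")
    n_obs: int = 0

    def predict_transformed(self, runs: np.ndarray) -> np.ndarray:
        X_full, all_terms = expand_terms(np.asarray(runs))
        idx = [all_terms.index(t) for t in self.terms]
        return X_full[:, idx] @ self.coefficients

    def predict(self, runs: np.ndarray) -> np.ndarray:
        """Back-transformed predictions on the %reduction scale, clamped at 0."""
        z = self.predict_transformed(runs)
        y = inverse_power_transform(z, self.transform_lambda) - self.shift
        return np.maximum(y, 0.0)

    def coefficient_for(self, kind: str, drugs: tuple[int, ...]) -> float | None:
        for t, c in zip(self.terms, self.coefficients):
            if t.kind == kind and t.drugs == tuple(drugs):
                return float(c)
        return None


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


def adjusted_r2(sse: float, sst: float, n: int, p: int) -> float:
    """1 - (SSE/(n-p)) / (SST/(n-1)); equals 0 for an intercept-only model."""
    if n <= p:
        raise ModelError("adjusted R^2 requires n > number of terms")
    if sst == 0:
        return 1.0 if sse == 0 else float("-inf")
    return 1.0 - (sse / (n - p)) / (sst / (n - 1))


def stepwise_fit(
    model_matrix: np.ndarray,
    responses: np.ndarray,
    terms: tuple[Term, ...],
    drugs: tuple[str, ...],
    p_enter: float = P_ENTER,
    p_remove: float = P_REMOVE,
    transform_lambda: float = 1.0,
    shift: float = 0.0,
    sse_tol: float = 1e-10,
) -> QuadraticModel:
    """Bidirectional sum-of-squares F-test stepwise regression.

    Starting from intercept only, repeatedly add the excluded term with the
    smallest partial-F p-value below ``p_enter``, then drop any included
    term whose p-value exceeds ``p_remove``. SSE decreases monotonically at
    every addition and each model is visited at most once, so the loop
    terminates. When the fit is numerically exact (relative SSE below
    ``sse_tol``) no further terms can demonstrate improvement and selection
    stops.

    ``responses`` must already be on the transformed scale;
    ``transform_lambda``/``shift`` are recorded on the returned model so
    predictions can be back-transformed.
    """
    if p_enter > p_remove:
        raise ModelError("p_enter must be <= p_remove")
    X = np.asarray(model_matrix, dtype=float)
    y = np.asarray(responses, dtype=float)
    n = len(y)
    if n < 3:
        raise ModelError("at least 3 observations required")
    sst = float(np.sum((y - y.mean()) ** 2))
    scale = max(sst, 1.0)

    included = [0]  # intercept
    candidates = set(range(1, X.shape[1]))
    _, sse_cur = _sse(X[:, included], y)

    def partial_f_p(sse_red: float, sse_full: float, df_resid: int) -> float:
        if df_resid <= 0:
            return 1.0
        mse = sse_full / df_resid
        if mse <= 0:
            return 0.0 if sse_red > sse_full else 1.0
        f = (sse_red - sse_full) / mse
        return float(stats.f.sf(max(f, 0.0), 1, df_resid))

    while True:
        changed = False
        # forward: best excluded term
        if sse_cur / scale > sse_tol and candidates:
            best_j, best_p, best_sse = None, None, None
            for j in sorted(candidates):
                cols = included + [j]
                if np.linalg.matrix_rank(X[:, cols]) < len(cols):
                    continue
                _, sse_j = _sse(X[:, cols], y)
                p = partial_f_p(sse_cur, sse_j, n - len(cols))
                if best_p is None or p < best_p or (p == best_p and sse_j < best_sse):
                    best_j, best_p, best_sse = j, p, sse_j
            if best_j is not None and best_p < p_enter:
                included.append(best_j)
                candidates.discard(best_j)
                sse_cur = best_sse
                changed = True
        # backward: drop worst included (never the intercept)
        while len(included) > 1:
            worst_j, worst_p = None, None
            for j in included[1:]:
                reduced = [c for c in included if c != j]
                _, sse_red = _sse(X[:, reduced], y)
                p = partial_f_p(sse_red, sse_cur, n - len(included))
                if worst_p is None or p > worst_p:
                    worst_j, worst_p = j, p
            if worst_p is not None and worst_p > p_remove:
                included.remove(worst_j)
                candidates.add(worst_j)
                _, sse_cur = _sse(X[:, included], y)
                changed = True
            else:
                break
        if not changed:
            break

    if np.linalg.matrix_rank(X[:, included]) < len(included):
        labels = [terms[i].label(drugs) for i in included]
        raise ModelError(f"selected basis is rank deficient: {labels}")

    beta, sse_fin = _sse(X[:, included], y)
    df_resid = n - len(included)
    pvals = np.ones(len(included))
    for pos, j in enumerate(included):
        if j == 0:
            # intercept p-value from its own partial F
            reduced = [c for c in included if c != j]
            if reduced:
                _, sse_red = _sse(X[:, reduced], y)
            else:
                sse_red = float(y @ y)
        else:
            reduced = [c for c in included if c != j]
            _, sse_red = _sse(X[:, reduced], y)
        pvals[pos] = partial_f_p(sse_red, sse_fin, df_resid)

    adj = adjusted_r2(sse_fin, sst, n, len(included)) if n > len(included) else float("nan")
    # exact fits can leave adj barely below 1 from float error
    if sse_fin / scale < sse_tol:
        adj = 1.0
    order = np.argsort(included)
    inc_sorted = [included[i] for i in order]
    return QuadraticModel(
        drugs=tuple(drugs),
        terms=tuple(terms[i] for i in inc_sorted),
        coefficients=beta[order],
        transform_lambda=transform_lambda,
        shift=shift,
        p_values=pvals[order],
        adj_r2=adj,
        sse=sse_fin,
        n_obs=n,
    )


# --------------------------------------------------------------------------
# Outlier screening
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierReport:
    flagged: tuple[int, ...]
    studentized: np.ndarray
    threshold: float


def outlier_scan(
    model_matrix: np.ndarray,
    responses: np.ndarray,
    selected_columns: list[int] | None = None,
    threshold: float = 3.0,
) -> OutlierReport:
    """Flag runs with externally studentized residuals beyond the threshold.

    Each residual is scaled by a leave-one-out error estimate, so a single
    aberrant well does not inflate its own reference variance.
    """
    X = np.asarray(model_matrix, dtype=float)
    if selected_columns is not None:
        X = X[:, selected_columns]
    y = np.asarray(responses, dtype=float)
    n, p = X.shape
    if n - p < 2:
        raise ModelError("outlier scan requires residual df >= 2")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    # hat diagonal via the pseudoinverse (X may be exactly collinear-free here)
    Q, _ = np.linalg.qr(X)
    h = np.sum(Q**2, axis=1)
    sse = float(e @ e)
    denom = np.maximum(1.0 - h, 1e-12)
    s2_i = np.maximum((sse - e**2 / denom) / (n - p - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = e / np.sqrt(s2_i * denom)
    t = np.where(np.isfinite(t), t, 0.0)
    flagged = tuple(int(i) for i in np.nonzero(np.abs(t) > threshold)[0])
    return OutlierReport(flagged, t, threshold)


# --------------------------------------------------------------------------
# One-call surface fit (transform selection + stepwise)
# --------------------------------------------------------------------------

def fit_response_surface(
    design_runs: np.ndarray,
    responses: np.ndarray,
    drugs: tuple[str, ...],
    p_enter: float = P_ENTER,
    p_remove: float = P_REMOVE,
    candidate_lambdas=DEFAULT_LAMBDA_GRID,
    select_transform: bool = True,
) -> QuadraticModel:
    """Box-Cox transform selection followed by stepwise term selection."""
    X, terms = expand_terms(np.asarray(design_runs))
    y = np.asarray(responses, dtype=float)
    if select_transform:
        lam, shift = boxcox_select(y, X, candidate_lambdas)
    else:
        lam, shift = 1.0, 0.0
    z = power_transform(y + shift, lam)
    return stepwise_fit(
        X, z, terms, drugs, p_enter=p_enter, p_remove=p_remove,
        transform_lambda=lam, shift=shift,
    )
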