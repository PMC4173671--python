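"""Linear models of phenology and recruitment, with predictive model selection.

Models are declared as :class:`ModelSpec` objects: a response (optionally
log-transformed), a list of terms (predictor, power, optional interaction
with a low/high dummy), and a dummy definition.  Continuous predictors are
centred by their in-sample mean *before* powers and interactions are
formed, so quadratic terms read as curvature around the sample mean and
the dummy interaction splits a slope into low/high-density variants.

Selection follows the predictive protocol used for the Windermere perch
analysis: backward deletion scored by leave-one-year-out cross-validated
RMSE, cross-checked against small-sample AICc, with residual diagnostics
(autocorrelation, variance homogeneity, normality) on the selected model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Term",
    "ModelSpec",
    "DesignState",
    "FitResult",
    "SelectionStep",
    "SelectionTrace",
    "DiagnosticsReport",
    "build_design",
    "ols_fit",
    "fit_model",
    "loo_cv_rmse",
    "backward_select",
    "aicc",
    "aicc_from_fit",
    "residual_diagnostics",
    "preset_specs",
    "YEAR_RECORD_FIELDS",
]

#: Canonical per-year record schema: spawn-year predictors and responses.
#: S spawners, MS mean spawner size (mm), CA age-3+ fish in the recruits'
#: first year, WT winter temperature in the first year (degC), ST spring
#: temperature, MT May temperature, P disease flag, PM mismatch (days),
#: LS hatching-period duration (days), PS peak spawning day, R recruits
#: at age 2.
YEAR_RECORD_FIELDS = ("year", "S", "MS", "CA", "WT", "ST", "MT", "P", "PM", "LS", "PS", "R")


@dataclass(frozen=True)
class Term:
    """One model term: a predictor, its power, and an optional dummy split."""

    predictor: str
    power: int = 1
    by_dummy: bool = False

    def __post_init__(self) -> None:
        if self.power not in (1, 2):
            raise ValueError("power must be 1 or 2")

    @property
    def order(self) -> int:
        """Complexity rank used for deterministic tie-breaking."""
        return self.power + (2 if self.by_dummy else 0)

    def labels(self) -> list[str]:
        base = self.predictor if self.power == 1 else f"{self.predictor}^2"
        if self.by_dummy:
            return [f"{base}:D_low", f"{base}:D_high"]
        return [base]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative linear-model structure.

    ``dummy_var`` names the record field defining the low/high dummy:
    with ``dummy_rule="median"`` a year is low when the field is at or
    below the in-sample median; with ``"flag"`` low means the field is 0.
    Predictors in ``categorical`` are never centred.
    """

    response: str
    terms: tuple[Term, ...]
    log_response: bool = False
    dummy_var: str | None = None
    dummy_rule: str = "median"
    categorical: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if any(t.by_dummy for t in self.terms) and self.dummy_var is None:
            raise ValueError("dummy interactions require a dummy_var")
        if self.dummy_rule not in ("median", "flag"):
            raise ValueError("dummy_rule must be 'median' or 'flag'")
        if len({t.labels()[0] for t in self.terms}) != len(self.terms):
            raise ValueError("duplicate terms in spec")

    @property
    def n_coefficients(self) -> int:
        """Coefficient count including the intercept."""
        return 1 + sum(len(t.labels()) for t in self.terms)

    def column_names(self) -> list[str]:
        names = ["const"]
        for t in self.terms:
            names.extend(t.labels())
        return names

    def predictors(self) -> set[str]:
        out = {t.predictor for t in self.terms}
        if self.dummy_var is not None:
            out.add(self.dummy_var)
        return out


@dataclass(frozen=True)
class DesignState:
    """In-sample centring means and dummy threshold, for out-of-sample rows."""

    means: dict[str, float]
    dummy_threshold: float | None


class _Compiled:
    """Raw predictor arrays plus fast numpy design construction.

    Centring means and the dummy median are recomputed for whatever row
    subset is passed, which is what makes fold-wise refitting in the
    cross-validation honest about out-of-sample information.
    """

    def __init__(self, records: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        needed = sorted(spec.predictors() | {spec.response})
        missing = [c for c in needed if c not in records.columns]
        if missing:
            raise KeyError(f"records missing field(s): {', '.join(missing)}")
        sub = records[needed]
        if sub.isna().any().any():
            col = sub.columns[sub.isna().any()][0]
            year = records.index[sub[col].isna()][0]
            raise ValueError(f"missing value in field {col} (year {year})")
        self.raw = {c: records[c].to_numpy(dtype=float) for c in needed}
        self.n = len(records)
        y = self.raw[spec.response]
        if spec.log_response:
            if np.any(y <= 0):
                raise ValueError(f"log response requires positive {spec.response}")
            y = np.log(y)
        self.y = y
        for t in spec.terms:
            col = self.raw[t.predictor]
            if np.ptp(col) == 0:
                raise ValueError(f"constant predictor: {t.predictor}")

    def state_for(self, idx: np.ndarray) -> DesignState:
        spec = self.spec
        means = {
            p: float(self.raw[p][idx].mean())
            for p in {t.predictor for t in spec.terms}
            if p not in spec.categorical
        }
        thr = None
        if spec.dummy_var is not None:
            if spec.dummy_rule == "median":
                thr = float(np.median(self.raw[spec.dummy_var][idx]))
            else:
                thr = 0.0
        return DesignState(means=means, dummy_threshold=thr)

    def _columns(self, idx: np.ndarray, state: DesignState) -> np.ndarray:
        spec = self.spec
        cols = [np.ones(len(idx))]
        if spec.dummy_var is not None:
            dv = self.raw[spec.dummy_var][idx]
            low = dv <= state.dummy_threshold if spec.dummy_rule == "median" else dv == 0
        for t in spec.terms:
            x = self.raw[t.predictor][idx]
            if t.predictor not in spec.categorical:
                x = x - state.means[t.predictor]
            if t.power == 2:
                x = x * x
            if t.by_dummy:
                cols.append(np.where(low, x, 0.0))
                cols.append(np.where(low, 0.0, x))
            else:
                cols.append(x)
        return np.column_stack(cols)

    def build(self, idx: np.ndarray | None = None, state: DesignState | None = None):
        if idx is None:
            idx = np.arange(self.n)
        if state is None:
            state = self.state_for(idx)
        return self._columns(idx, state), self.y[idx], state

    def rows(self, idx: np.ndarray, state: DesignState) -> np.ndarray:
        """Design rows for held-out records using a *training* state."""
        return self._columns(idx, state)


def build_design(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Series, DesignState]:
    """Design matrix (with intercept) and response vector for a spec.

    Continuous predictors are centred by their in-sample mean before
    powers and interactions are formed; dummy-interacted terms become one
    column per level (low where the split variable is at or below the
    in-sample median).
    """
    comp = _Compiled(records, spec)
    X, y, state = comp.build()
    idx = records.index
    Xdf = pd.DataFrame(X, columns=spec.column_names(), index=idx)
    name = f"log({spec.response})" if spec.log_response else spec.response
    return Xdf, pd.Series(y, index=idx, name=name), state


@dataclass
class FitResult:
    """OLS estimates with classical inference and leverage diagnostics."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    rss: float
    residuals: np.ndarray
    fitted: np.ndarray
    leverage: np.ndarray
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.k >= self.n:
            raise ValueError("need more observations than coefficients")


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        tol = d.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(d)) if d[i] < tol]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {', '.join(bad)}"
        )


def ols_fit(X: pd.DataFrame | np.ndarray, y) -> FitResult:
    """Ordinary least squares with classical standard errors and leverages."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    _check_rank(Xa, names)
    res = sm.OLS(ya, Xa).fit()
    leverage = (Xa * np.linalg.solve(Xa.T @ Xa, Xa.T).T).sum(axis=1)
    return FitResult(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r_squared=float(res.rsquared),
        rss=float(res.ssr),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        leverage=leverage,
        n=len(ya),
        k=Xa.shape[1],
    )


def fit_model(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Build the design for ``spec`` and fit it by OLS."""
    X, y, _ = build_design(records, spec)
    return ols_fit(X, y)


def loo_cv_rmse(
    records: pd.DataFrame, spec: ModelSpec, refit_centring: bool = True
) -> float:
    """Leave-one-year-out cross-validated prediction RMSE.

    For each year: fit the model to all other years, predict the held-out
    year, record the prediction error, and return the root mean squared
    error over years.  With ``refit_centring=True`` (default) the centring
    means and the dummy median are recomputed inside each training fold —
    a strict out-of-sample contract.  With ``refit_centring=False`` the
    full-sample design is frozen and only the coefficients are refitted,
    which reproduces the closed-form PRESS identity exactly.
    """
    comp = _Compiled(records, spec)
    n = comp.n
    p = spec.n_coefficients
    if n < p + 1:  # every training fold of n-1 rows must support p coefficients
        raise ValueError(f"need at least {p + 1} years for {p} coefficients")
    full_state = comp.state_for(np.arange(n))
    errors = np.empty(n)
    for i in range(n):
        train = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        state = comp.state_for(train) if refit_centring else full_state
        X, y, _ = comp.build(train, state)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient design in fold leaving out row {i}"
            )
        xrow = comp.rows(np.array([i]), state)[0]
        errors[i] = xrow @ beta - comp.y[i]
    return float(np.sqrt(np.mean(errors**2)))


@dataclass(frozen=True)
class SelectionStep:
    spec: ModelSpec
    cv_rmse: float
    dropped: str | None  # label of the simplification applied to reach this spec


@dataclass(frozen=True)
class SelectionTrace:
    steps: tuple[SelectionStep, ...]

    @property
    def final_spec(self) -> ModelSpec:
        return self.steps[-1].spec

    @property
    def final_cv_rmse(self) -> float:
        return self.steps[-1].cv_rmse


def _candidate_moves(spec: ModelSpec) -> list[tuple[str, ModelSpec, int]]:
    """Admissible single simplifications, respecting marginality.

    A dummy interaction collapses to its plain term; a quadratic term may
    be dropped; a plain linear term may be dropped only when no quadratic
    or interaction of the same predictor remains.
    """
    moves = []
    for i, t in enumerate(spec.terms):
        others = spec.terms[:i] + spec.terms[i + 1 :]
        if t.by_dummy:
            new_t = replace(t, by_dummy=False)
            if any(o.labels()[0] == new_t.labels()[0] for o in others):
                continue  # plain twin already present; nothing to collapse to
            new_terms = spec.terms[:i] + (new_t,) + spec.terms[i + 1 :]
            label = f"interaction {t.labels()[0].split(':')[0]} x D"
        else:
            if t.power == 1 and any(o.predictor == t.predictor for o in others):
                continue  # marginality: main effect pinned by higher-order term
            new_terms = others
            label = t.labels()[0]
        moves.append((label, replace(spec, terms=new_terms), t.order))
    return moves


def backward_select(
    records: pd.DataFrame, full_spec: ModelSpec, refit_centring: bool = True
) -> SelectionTrace:
    """Backward deletion scored by leave-one-year-out prediction error.

    Starting from the full model, every admissible single simplification
    is scored by :func:`loo_cv_rmse`; the best one is applied whenever it
    does not increase the current model's CV error, and selection stops
    otherwise.  Ties prefer removing the higher-order term, then resolve
    lexicographically, so the trace is deterministic.
    """
    current = full_spec
    current_cv = loo_cv_rmse(records, current, refit_centring)
    steps = [SelectionStep(current, current_cv, None)]
    while True:
        candidates = []
        for label, cand, order in _candidate_moves(current):
            cv = loo_cv_rmse(records, cand, refit_centring)
            candidates.append((cv, -order, label, cand))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        best_cv, _, best_label, best_spec = candidates[0]
        if best_cv <= current_cv:
            current, current_cv = best_spec, best_cv
            steps.append(SelectionStep(current, current_cv, best_label))
        else:
            break
    return SelectionTrace(steps=tuple(steps))


def aicc(n: int, rss: float, k: int) -> float:
    """Small-sample corrected AIC for a Gaussian linear model.

    ``k`` counts all estimated parameters including the intercept and the
    error variance.  ``AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if rss <= 0:
        raise ValueError("AICc requires positive residual sum of squares")
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def aicc_from_fit(fit: FitResult) -> float:
    """AICc of a fitted model, counting coefficients plus the error variance."""
    return aicc(fit.n, fit.rss, fit.k + 1)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual checks at alpha = 0.05: autocorrelation, homogeneity, normality."""

    lag1_autocorr: float
    autocorr_bound: float
    autocorr_ok: bool
    homogeneity_stat: float
    homogeneity_pvalue: float
    homogeneity_ok: bool
    normality_stat: float
    normality_pvalue: float
    normality_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.autocorr_ok and self.homogeneity_ok and self.normality_ok

    def summary(self) -> str:
        def mark(ok: bool) -> str:
            return "pass" if ok else "FAIL"

        return (
            f"lag-1 autocorrelation {self.lag1_autocorr:+.3f} "
            f"(bound {self.autocorr_bound:.3f}): {mark(self.autocorr_ok)}\n"
            f"variance homogeneity LM {self.homogeneity_stat:.3f} "
            f"(p={self.homogeneity_pvalue:.3f}): {mark(self.homogeneity_ok)}\n"
            f"normality W {self.normality_stat:.3f} "
            f"(p={self.normality_pvalue:.3f}): {mark(self.normality_ok)}"
        )


def residual_diagnostics(fit: FitResult, alpha: float = 0.05) -> DiagnosticsReport:
    """Validate a fitted model's residuals.

    Checks lag-1 autocorrelation against the large-sample 1.96/sqrt(n)
    bound, variance homogeneity by a Breusch-Pagan-type test of squared
    residuals against fitted values, and normality by the Shapiro-Wilk
    statistic.
    """
    e = fit.residuals
    n = len(e)
    if n < 8:
        raise ValueError("need at least 8 residuals for diagnostics")
    if np.ptp(e) == 0:
        raise ValueError("degenerate fit: residuals have zero variance")
    e0 = e - e.mean()
    r1 = float(np.sum(e0[:-1] * e0[1:]) / np.sum(e0**2))
    bound = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n)

    from statsmodels.stats.diagnostic import het_breuschpagan

    exog = np.column_stack([np.ones(n), fit.fitted])
    lm, lm_p, _, _ = het_breuschpagan(e, exog)
    w, w_p = stats.shapiro(e)
    return DiagnosticsReport(
        lag1_autocorr=r1,
        autocorr_bound=float(bound),
        autocorr_ok=bool(abs(r1) <= bound),
        homogeneity_stat=float(lm),
        homogeneity_pvalue=float(lm_p),
        homogeneity_ok=bool(lm_p > alpha),
        normality_stat=float(w),
        normality_pvalue=float(w_p),
        normality_ok=bool(w_p > alpha),
    )


def preset_specs(stage: str = "selected") -> dict[str, ModelSpec]:
    """The three standard model structures of the analysis.

    ``stage="selected"`` returns the final structures: peak spawning
    (PS ~ S + P + ST + ST^2), spawning duration (LS ~ MS + S + MT + MT^2)
    and recruitment (log R ~ LS x D + PM + PM^2 x D + S^2 + CA + WT with D
    split at the median CA).  ``stage="candidate"`` returns the full
    starting models for backward selection, which additionally carry the
    disease-by-temperature interaction in the phenology models and
    quadratic spawner/temperature terms in the recruitment model.
    """
    if stage not in ("selected", "candidate"):
        raise ValueError("stage must be 'selected' or 'candidate'")
    recruitment = ModelSpec(
        name="recruitment",
        response="R",
        log_response=True,
        dummy_var="CA",
        dummy_rule="median",
        terms=(
            Term("LS", 1, by_dummy=True),
            Term("PM", 1),
            Term("PM", 2, by_dummy=True),
            Term("S", 2),
            Term("CA", 1),
            Term("WT", 1),
        ),
    )
    peak = ModelSpec(
        name="peak_spawning",
        response="PS",
        categorical=frozenset({"P"}),
        terms=(Term("S", 1), Term("P", 1), Term("ST", 1), Term("ST", 2)),
    )
    duration = ModelSpec(
        name="spawning_duration",
        response="LS",
        terms=(Term("MS", 1), Term("S", 1), Term("MT", 1), Term("MT", 2)),
    )
    if stage == "candidate":
        peak = replace(
            peak,
            dummy_var="P",
            dummy_rule="flag",
            terms=(Term("S", 1), Term("P", 1), Term("ST", 1, by_dummy=True), Term("ST", 2)),
        )
        duration = replace(
            duration,
            dummy_var="P",
            dummy_rule="flag",
            terms=(Term("MS", 1), Term("S", 1), Term("MT", 1, by_dummy=True), Term("MT", 2)),
        )
        recruitment = replace(
            recruitment,
            terms=recruitment.terms + (Term("S", 1), Term("WT", 2)),
        )
    return {"recruitment": recruitment, "peak_spawning": peak, "duration": duration}
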