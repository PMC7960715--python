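"""Age calibration against the protein-folding ratio.

Four candidate ordinary-least-squares models relate chronological age to
the folding ratio R (sex coded M=1, F=0):

    Model 1:  age ~ 1 + R
    Model 2:  age ~ 1 + R + R^2
    Model 3:  age ~ 1 + R + R^2 + sex
    Model 4:  age ~ 1 + R + sex + R:sex

Model choice uses repeated 10-fold cross-validation (RMSE, then R^2 as a
tie-break), and new-donor age uncertainty is reported as t-based prediction
intervals, point +/- t_{(1+level)/2, df} * s * sqrt(1 + h), with leverage h
from the training design and the lower bound clamped at zero age.

``REFERENCE_MODELS`` carries the calibration coefficients estimated on the
original 132-donor forensic skin cohort; together with
:func:`reference_model` they let prediction tables be regenerated without
the raw cohort (zero-leverage "reproduction" mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io import DonorRecord

__all__ = [
    "MODEL_TERMS",
    "REFERENCE_MODELS",
    "CalibrationModel",
    "CVMetrics",
    "PredictionInterval",
    "CorrelationResult",
    "SexEffect",
    "pearson",
    "fit_model",
    "cross_validate",
    "select_model",
    "predict_age",
    "prediction_interval",
    "prediction_table",
    "compare_sex",
    "reference_model",
]

MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: ("intercept", "rpf"),
    2: ("intercept", "rpf", "rpf2"),
    3: ("intercept", "rpf", "rpf2", "sex"),
    4: ("intercept", "rpf", "sex", "rpf_sex"),
}

#: Calibration coefficients estimated on the original 132-donor autopsy
#: cohort (ages 0-93), in MODEL_TERMS order; the quadratic Model 2 is the
#: calibration deployed for casework (cross-validated RMSE 11.3 years).
REFERENCE_MODELS: dict[int, tuple[float, ...]] = {
    1: (108.4, -133.8),
    2: (130.0, -233.3, 99.4),
    3: (129.3, -237.2, 102.7, 2.4),
    4: (106.8, -132.5, 2.7, -2.5),
}

#: Residual scale (years) and residual degrees of freedom accompanying the
#: reference Model 2 calibration (n=132, 3 fitted terms).
REFERENCE_RESIDUAL_SD = 11.3
REFERENCE_DF = 129


@dataclass
class CalibrationModel:
    """A fitted (or reference) age-regression model.

    ``design_moments`` is the training cross-product matrix X'X, enough to
    compute the leverage h = x'(X'X)^{-1}x of a new point; it is None in
    reproduction mode, where intervals use h = 0.
    """

    model_id: int
    terms: tuple[str, ...]
    coefficients: np.ndarray
    residual_sd: float
    df: int
    design_moments: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != len(self.terms):
            raise ValueError("one coefficient per term required")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    @property
    def uses_sex(self) -> bool:
        return any(t in ("sex", "rpf_sex") for t in self.terms)


@dataclass
class CVMetrics:
    """Repeated k-fold cross-validation summary for one model."""

    model_id: int
    rmse: float
    r2: float
    per_repeat_rmse: list[float]
    per_repeat_r2: list[float]
    k: int
    repeats: int
    seed: int


@dataclass
class PredictionInterval:
    """Point age estimate with bounds at one confidence level."""

    rpf: float
    level: float
    point: float
    lower: float
    upper: float
    leverage_mode: str = "full"


@dataclass
class CorrelationResult:
    """Sample Pearson correlation with its two-sided t-test p-value."""

    r: float
    n: int
    p_value: float
    variables: tuple[str, str] = ("x", "y")


@dataclass
class SexEffect:
    """Wald test of the sex term in Model 3."""

    estimate: float
    se: float
    p_value: float
    significant: bool


def pearson(x, y, variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Sample Pearson correlation between two equal-length variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=int(x.size), p_value=float(res.pvalue),
        variables=variables,
    )


def _design(rpf: np.ndarray, sex: np.ndarray | None, model_id: int) -> np.ndarray:
    if model_id not in MODEL_TERMS:
        raise ValueError(f"model_id must be one of {sorted(MODEL_TERMS)}")
    cols = {"intercept": np.ones_like(rpf), "rpf": rpf, "rpf2": rpf**2}
    if model_id in (3, 4):
        if sex is None:
            raise ValueError(f"model {model_id} requires sex (M=1, F=0)")
        cols["sex"] = sex
        cols["rpf_sex"] = rpf * sex
    return np.column_stack([cols[t] for t in MODEL_TERMS[model_id]])


def _donor_arrays(donors) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    donors = list(donors)
    missing = [d.donor_id for d in donors if d.rpf is None]
    if missing:
        raise ValueError(f"donors without rpf: {missing}")
    rpf = np.array([d.rpf for d in donors])
    age = np.array([d.age for d in donors])
    sex = np.array([d.sex_code for d in donors], dtype=float)
    return rpf, age, sex


def fit_model(donors, model_id: int) -> CalibrationModel:
    """Fit one candidate model by OLS.

    Returns coefficients, residual scale s = sqrt(SSE/df), residual degrees
    of freedom and the design cross-product matrix for later leverage
    computations.
    """
    rpf, age, sex = _donor_arrays(donors)
    terms = MODEL_TERMS[model_id]
    if rpf.size < len(terms) + 1:
        raise ValueError(
            f"model {model_id} needs at least {len(terms) + 1} donors, got {rpf.size}"
        )
    if model_id in (3, 4) and np.ptp(sex) == 0:
        raise ValueError(f"model {model_id} requires both sexes in the cohort")
    X = _design(rpf, sex, model_id)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    fit = sm.OLS(age, X).fit()
    df = int(fit.df_resid)
    return CalibrationModel(
        model_id=model_id,
        terms=terms,
        coefficients=fit.params,
        residual_sd=float(np.sqrt(fit.ssr / df)),
        df=df,
        design_moments=X.T @ X,
        n=int(rpf.size),
    )


def reference_model(
    model_id: int = 2,
    residual_sd: float = REFERENCE_RESIDUAL_SD,
    df: int = REFERENCE_DF,
) -> CalibrationModel:
    """The reference calibration in reproduction mode (no design moments)."""
    return CalibrationModel(
        model_id=model_id,
        terms=MODEL_TERMS[model_id],
        coefficients=np.array(REFERENCE_MODELS[model_id]),
        residual_sd=residual_sd,
        df=df,
        design_moments=None,
    )


def _row(model: CalibrationModel, rpf: float, sex: int | None) -> np.ndarray:
    if model.uses_sex and sex is None:
        raise ValueError(f"model {model.model_id} requires sex (M=1, F=0)")
    vals = {
        "intercept": 1.0,
        "rpf": rpf,
        "rpf2": rpf**2,
        "sex": float(sex) if sex is not None else 0.0,
        "rpf_sex": rpf * float(sex) if sex is not None else 0.0,
    }
    return np.array([vals[t] for t in model.terms])


def linear_predictor(model: CalibrationModel, rpf: float, sex: int | None = None) -> float:
    """Unclamped model evaluation (used internally by CV and intervals)."""
    return float(_row(model, rpf, sex) @ model.coefficients)


def predict_age(model: CalibrationModel, rpf: float, sex: int | None = None) -> float:
    """Point age estimate in years, clamped at 0 for reporting."""
    return max(linear_predictor(model, rpf, sex), 0.0)


def cross_validate(
    donors, model_id: int, k: int = 10, repeats: int = 100, seed: int = 0
) -> CVMetrics:
    """Repeated k-fold cross-validation of one model.

    Per repeat: a seeded uniform shuffle is cut into k contiguous folds
    (sizes differing by at most one); each fold is predicted from a fit on
    the rest; held-out squared errors are pooled into RMSE and
    R^2 = 1 - SSE/SST (SST about the full-sample mean).  Reported rmse/r2
    are means over repeats.  No age clamping enters the error computation.
    """
    rpf, age, sex = _donor_arrays(donors)
    n = rpf.size
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} donors")
    X = _design(rpf, sex, model_id)
    sst = float(np.sum((age - age.mean()) ** 2))
    rng = np.random.default_rng(seed)
    rmses, r2s = [], []
    for _ in range(repeats):
        perm = rng.permutation(n)
        sse = 0.0
        for fold in np.array_split(perm, k):
            train = np.setdiff1d(perm, fold, assume_unique=True)
            beta, *_ = np.linalg.lstsq(X[train], age[train], rcond=None)
            err = age[fold] - X[fold] @ beta
            sse += float(err @ err)
        rmses.append(np.sqrt(sse / n))
        r2s.append(1.0 - sse / sst)
    return CVMetrics(
        model_id=model_id,
        rmse=float(np.mean(rmses)),
        r2=float(np.mean(r2s)),
        per_repeat_rmse=[float(v) for v in rmses],
        per_repeat_r2=[float(v) for v in r2s],
        k=k,
        repeats=repeats,
        seed=seed,
    )


def select_model(metrics) -> int:
    """Pick the model with the lowest mean CV RMSE.

    Ties within 1e-6 years are broken by higher mean R^2, then lower
    model_id.
    """
    metrics = list(metrics)
    if len(metrics) < 2:
        raise ValueError("model selection needs at least two candidates")
    best = min(m.rmse for m in metrics)
    tied = [m for m in metrics if m.rmse - best <= 1e-6]
    tied.sort(key=lambda m: (-m.r2, m.model_id))
    return tied[0].model_id


def prediction_interval(
    model: CalibrationModel,
    rpf: float,
    level: float = 0.95,
    sex: int | None = None,
    leverage_mode: str = "full",
) -> PredictionInterval:
    """t-based prediction interval for a new donor's age.

    ``leverage_mode="full"`` uses h = x'(X'X)^{-1}x from the training
    design; ``"none"`` sets h = 0 (reproduction mode, the only choice when
    the model carries no design moments).  The lower bound (and point) are
    clamped at age 0.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if model.df < 1:
        raise ValueError("df must be >= 1")
    if leverage_mode not in ("full", "none"):
        raise ValueError("leverage_mode must be 'full' or 'none'")
    x = _row(model, rpf, sex)
    point = float(x @ model.coefficients)
    if leverage_mode == "full":
        if model.design_moments is None:
            raise ValueError(
                "model has no design moments; use leverage_mode='none'"
            )
        h = float(x @ np.linalg.solve(model.design_moments, x))
    else:
        h = 0.0
    half = stats.t.ppf((1.0 + level) / 2.0, model.df) * model.residual_sd * np.sqrt(1.0 + h)
    lower = max(point - half, 0.0)
    upper = point + half
    return PredictionInterval(
        rpf=rpf,
        level=level,
        point=max(point, 0.0),
        lower=lower,
        upper=max(upper, 0.0),
        leverage_mode=leverage_mode,
    )


def prediction_table(
    model: CalibrationModel,
    rpf_values,
    levels=(0.50, 0.80, 0.95),
    sex: int | None = None,
    leverage_mode: str = "full",
    decimals: int = 1,
):
    """Prediction intervals on a grid of folding-ratio values.

    Returns a pandas DataFrame with one row per rpf and lower/upper columns
    per level, rounded (reporting only) to ``decimals``.
    """
    import pandas as pd

    rows = []
    for r in rpf_values:
        row = {"rpf": r}
        for level in levels:
            pi = prediction_interval(model, r, level, sex=sex, leverage_mode=leverage_mode)
            pct = int(round(100 * level))
            row[f"lower_{pct}"] = round(pi.lower, decimals)
            row[f"upper_{pct}"] = round(pi.upper, decimals)
        rows.append(row)
    cols = ["rpf"]
    for level in levels:
        pct = int(round(100 * level))
        cols += [f"lower_{pct}", f"upper_{pct}"]
    return pd.DataFrame(rows, columns=cols)


def compare_sex(donors, model_id: int = 3) -> SexEffect:
    """Two-sided Wald test of the sex coefficient at the 5% level."""
    rpf, age, sex = _donor_arrays(donors)
    if np.ptp(sex) == 0:
        raise ValueError("sex comparison requires both sexes in the cohort")
    X = _design(rpf, sex, model_id)
    fit = sm.OLS(age, X).fit()
    idx = MODEL_TERMS[model_id].index("sex")
    p = float(fit.pvalues[idx])
    return SexEffect(
        estimate=float(fit.params[idx]),
        se=float(fit.bse[idx]),
        p_value=p,
        significant=p < 0.05,
    )
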