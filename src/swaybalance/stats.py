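"""Concurrent-validity statistics for the two measurement modalities.

Implements the study-style analysis chain: normality screening
(Shapiro–Wilk, with descriptive skewness/kurtosis/CV), log transform of
non-normal variables, CP-vs-control Mann–Whitney U comparisons, Pearson
correlations between image-derived and force-plate sway parameters with
conventional strength labels, predictor selection (|r| > 0.25 with
significance, pairwise collinearity cutoff 0.80), Enter-method multiple
regression predicting each COP parameter from image parameters, and
Cohen's R² effect-size labels (0.02 small / 0.13 medium / 0.26 large).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .sway import PARAMETER_ORDER

__all__ = [
    "NormalityReport",
    "CorrelationResult",
    "TestResult",
    "RegressionModel",
    "assess_normality",
    "log_transform_if_needed",
    "pearson_correlation",
    "mann_whitney_u",
    "select_predictors",
    "fit_linear_regression_enter",
    "run_validation",
    "correlation_strength_label",
    "effect_size_label",
]

logger = logging.getLogger(__name__)

#: |r| band edges for strength labels, smallest to largest.
STRENGTH_BANDS = (0.2, 0.4, 0.6, 0.8)
STRENGTH_LABELS = ("very weak", "weak", "moderate", "strong", "very strong")

#: Cohen's R² bands.
EFFECT_BANDS = (0.02, 0.13, 0.26)
EFFECT_LABELS = ("negligible", "small", "medium", "large")

#: Canonical image-parameter column order (Table-style names), used for
#: deterministic tie-breaking in predictor selection.
IMAGE_COLUMNS = tuple(
    f"{name.rsplit('_', 1)[0]}_COM{name.rsplit('_', 1)[1]}" for name in PARAMETER_ORDER
)
COP_OUTCOME_COLUMNS = tuple(
    f"{name.rsplit('_', 1)[0]}_COP{name.rsplit('_', 1)[1]}" for name in PARAMETER_ORDER
)


def correlation_strength_label(r: float,
                               bands: tuple[float, ...] = STRENGTH_BANDS) -> str:
    """Map |r| to a conventional strength label (band edges configurable)."""
    a = abs(r)
    for edge, label in zip(bands, STRENGTH_LABELS):
        if a <= edge:  # boundary values belong to the lower band
            return label
    return STRENGTH_LABELS[len(bands)]


def effect_size_label(r_squared: float) -> str:
    """Cohen's R² label: ≥0.26 large, ≥0.13 medium, ≥0.02 small."""
    for edge, label in zip(reversed(EFFECT_BANDS), reversed(EFFECT_LABELS[1:])):
        if r_squared >= edge:
            return label
    return EFFECT_LABELS[0]


@dataclass(frozen=True)
class NormalityReport:
    shapiro_p: float
    skewness: float
    kurtosis: float  # excess kurtosis
    coefficient_of_variation: float
    verdict: str  # "normal" | "non_normal"
    transformed: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    strength_label: str


@dataclass(frozen=True)
class TestResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: float
    iqr2: float
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class RegressionModel:
    outcome: str
    predictors: tuple[str, ...]
    coefficients: pd.DataFrame  # index: const + predictors; columns: coef, std_err, t, p
    r_squared: float
    adjusted_r_squared: float
    f_pvalue: float
    residual_shapiro_p: float
    effect_size_label: str
    n: int


def assess_normality(sample, alpha: float = 0.05) -> NormalityReport:
    """Shapiro–Wilk screen with descriptive skewness, kurtosis, and CV.

    The verdict gates on the Shapiro–Wilk p-value only; the other
    statistics are reported for inspection, not combined into the rule.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 values, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality is undefined")
    shapiro_p = float(sps.shapiro(x).pvalue)
    mean = float(np.mean(x))
    cv = float(np.std(x, ddof=1) / abs(mean)) if mean != 0 else float("inf")
    return NormalityReport(
        shapiro_p=shapiro_p,
        skewness=float(sps.skew(x, bias=False)),
        kurtosis=float(sps.kurtosis(x, bias=False)),
        coefficient_of_variation=cv,
        verdict="normal" if shapiro_p >= alpha else "non_normal",
    )


def log_transform_if_needed(sample, report: NormalityReport):
    """Natural-log transform a sample judged non-normal; else pass through.

    Zero or negative values are handled as log(v + c) with c equal to
    the smallest positive value observed (the offset is logged).
    Returns (values, transformed_flag).
    """
    x = np.asarray(sample, dtype=float)
    if report.verdict != "non_normal":
        return x, False
    if np.min(x) <= 0:
        positive = x[x > 0]
        if len(positive) == 0:
            raise ValueError("cannot log-transform an all-nonpositive sample")
        c = float(np.min(positive))
        logger.info("log transform with offset c=%g for nonpositive values", c)
        return np.log(x + c), True
    return np.log(x), True


def pearson_correlation(x, y,
                        bands: tuple[float, ...] = STRENGTH_BANDS) -> CorrelationResult:
    """Product-moment correlation with two-sided t-test p and strength label."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"lengths differ: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("cannot correlate a constant series")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        r=r, p_value=float(res.pvalue), n=len(x),
        strength_label=correlation_strength_label(r, bands),
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact p by enumeration of the rank distribution when n₁·n₂ ≤ 400
    and there are no ties; otherwise the normal approximation with
    continuity and tie correction.  U is computed from rank sums with
    midranks for ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    exact = len(a) * len(b) <= 400 and not _has_ties(a, b)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return TestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(a), n2=len(b),
        median1=float(np.median(a)), median2=float(np.median(b)),
        iqr1=float(q3a - q1a), iqr2=float(q3b - q1b),
        method="exact" if exact else "asymptotic",
    )


def select_predictors(
    correlations: dict[str, CorrelationResult],
    intercorrelations: pd.DataFrame,
    r_threshold: float = 0.25,
    alpha: float = 0.05,
    collinearity_threshold: float = 0.80,
    column_order: tuple[str, ...] = IMAGE_COLUMNS,
) -> list[str]:
    """Select regression predictors from outcome correlations.

    Keeps parameters with |r| > ``r_threshold`` and p < ``alpha``; among
    any pair with mutual |r| > ``collinearity_threshold`` the one with
    the smaller |r| to the outcome is dropped (ties: the later one in
    the canonical column order).  An empty selection is a valid outcome.
    """
    kept = [
        name for name in column_order
        if name in correlations
        and abs(correlations[name].r) > r_threshold
        and correlations[name].p_value < alpha
    ]
    # also admit candidates outside the canonical order, appended deterministically
    kept += sorted(
        name for name in correlations
        if name not in column_order
        and abs(correlations[name].r) > r_threshold
        and correlations[name].p_value < alpha
    )

    dropped: set[str] = set()
    for i, p1 in enumerate(kept):
        for p2 in kept[i + 1:]:
            if p1 in dropped or p2 in dropped:
                continue
            try:
                rho = abs(float(intercorrelations.loc[p1, p2]))
            except KeyError:
                continue
            if rho > collinearity_threshold:
                r1, r2 = abs(correlations[p1].r), abs(correlations[p2].r)
                victim = p2 if r1 >= r2 else p1  # tie: drop the later one
                dropped.add(victim)
                logger.info(
                    "collinearity |r|=%.3f between %s and %s: dropping %s",
                    rho, p1, p2, victim,
                )
    return [p for p in kept if p not in dropped]


def fit_linear_regression_enter(
    outcome: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    outcome_name: str = "outcome",
) -> RegressionModel:
    """Ordinary least squares with all predictors entered simultaneously.

    Reports the coefficient table, R², adjusted R², overall F p-value, a
    Shapiro–Wilk p for the residuals, and the Cohen effect-size label.
    """
    y = np.asarray(outcome, dtype=float)
    X = predictors.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"n={len(y)} too small for {X.shape[1]} predictors"
        )
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}): "
            f"check predictors {list(X.columns)} for exact collinearity"
        )
    fit = sm.OLS(y, design).fit()
    coef = pd.DataFrame({
        "coef": fit.params,
        "std_err": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    resid_p = float(sps.shapiro(fit.resid).pvalue) if len(y) >= 3 else float("nan")
    return RegressionModel(
        outcome=outcome_name,
        predictors=tuple(X.columns),
        coefficients=coef,
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue),
        residual_shapiro_p=resid_p,
        effect_size_label=effect_size_label(float(fit.rsquared)),
        n=len(y),
    )


KEY_COLUMNS = ("subject_id", "group", "condition")


@dataclass
class ValidationReport:
    """Per-condition group tests, correlation matrix, and regression models."""

    group_tests: pd.DataFrame
    correlations: pd.DataFrame
    models: pd.DataFrame
    model_objects: dict[tuple[str, str], RegressionModel] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Validation summary", "=" * 18]
        for cond, sub in self.correlations.groupby("condition", sort=False):
            lines.append(f"\nCondition: {cond}")
            best = sub.loc[sub["r"].abs().idxmax()]
            lines.append(
                f"  strongest image-COP correlation: {best['image_parameter']}"
                f" vs {best['cop_parameter']}: r={best['r']:.3f}"
                f" ({best['strength']}, p={best['p_value']:.2g})"
            )
            msub = self.models[self.models["condition"] == cond]
            for _, row in msub.iterrows():
                lines.append(
                    f"  model {row['outcome']} ~ {row['predictors']}: "
                    f"R2={row['r_squared']:.3f} ({row['effect_size']}, "
                    f"F p={row['f_pvalue']:.2g})"
                )
        return "\n".join(lines)


def run_validation(
    image_params: pd.DataFrame,
    cop_params: pd.DataFrame,
    outcomes: tuple[str, ...] | None = None,
    scope: str = "pooled",
) -> ValidationReport:
    """Run the full concurrent-validity analysis per condition.

    ``image_params`` and ``cop_params`` are trial tables keyed by
    (subject_id, group, condition) with Table-style parameter columns
    (Vmean_COMx …, Vmean_COPx …).  Per condition this computes
    (1) CP-vs-control Mann–Whitney tests of every image parameter,
    (2) the full image↔COP Pearson correlation matrix,
    (3) predictor selection and an Enter regression per COP outcome.
    ``scope`` restricts correlations/regressions to one group ("cp") or
    pools both groups ("pooled", default).
    """
    for name, df in (("image", image_params), ("cop", cop_params)):
        missing = [k for k in KEY_COLUMNS if k not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing key column(s) {missing}")

    merged = image_params.merge(
        cop_params, on=list(KEY_COLUMNS), how="inner", validate="one_to_one"
    )
    lost = len(image_params) - len(merged)
    if lost:
        keys_img = set(map(tuple, image_params[list(KEY_COLUMNS)].to_numpy()))
        keys_cop = set(map(tuple, cop_params[list(KEY_COLUMNS)].to_numpy()))
        raise ValueError(
            "image/cop key mismatch; unmatched keys: "
            f"{sorted(keys_img ^ keys_cop)[:10]}"
        )

    image_cols = [c for c in IMAGE_COLUMNS if c in merged.columns]
    cop_cols = [c for c in (outcomes or COP_OUTCOME_COLUMNS) if c in merged.columns]
    if not image_cols or not cop_cols:
        raise ValueError("no recognizable image/COP parameter columns found")

    test_rows, corr_rows, model_rows = [], [], []
    model_objects: dict[tuple[str, str], RegressionModel] = {}

    for cond, sub in merged.groupby("condition", sort=False):
        cp = sub[sub["group"] == "cp"]
        ctrl = sub[sub["group"] == "control"]
        if len(cp) and len(ctrl):
            for col in image_cols:
                t = mann_whitney_u(cp[col], ctrl[col])
                test_rows.append({
                    "condition": cond, "parameter": col,
                    "u_statistic": t.u_statistic, "p_value": t.p_value,
                    "median_cp": t.median1, "iqr_cp": t.iqr1,
                    "median_control": t.median2, "iqr_control": t.iqr2,
                    "method": t.method,
                })

        analysis = sub if scope == "pooled" else sub[sub["group"] == scope]
        if len(analysis) < 3:
            logger.warning("condition %s: too few trials for correlations", cond)
            continue

        inter = analysis[image_cols].corr()
        for cop_col in cop_cols:
            correlations: dict[str, CorrelationResult] = {}
            for img_col in image_cols:
                try:
                    cr = pearson_correlation(analysis[img_col], analysis[cop_col])
                except ValueError:
                    continue
                correlations[img_col] = cr
                corr_rows.append({
                    "condition": cond, "image_parameter": img_col,
                    "cop_parameter": cop_col, "r": cr.r,
                    "p_value": cr.p_value, "n": cr.n,
                    "strength": cr.strength_label,
                })
            selected = select_predictors(correlations, inter)
            if not selected:
                logger.info("condition %s, outcome %s: no predictors survive "
                            "selection", cond, cop_col)
                continue
            model = fit_linear_regression_enter(
                analysis[cop_col], analysis[selected], outcome_name=cop_col
            )
            model_objects[(str(cond), cop_col)] = model
            model_rows.append({
                "condition": cond, "outcome": cop_col,
                "predictors": "+".join(model.predictors),
                "n_predictors": len(model.predictors),
                "r_squared": model.r_squared,
                "adjusted_r_squared": model.adjusted_r_squared,
                "f_pvalue": model.f_pvalue,
                "effect_size": model.effect_size_label,
                "n": model.n,
            })

    return ValidationReport(
        group_tests=pd.DataFrame(test_rows),
        correlations=pd.DataFrame(corr_rows),
        models=pd.DataFrame(model_rows),
        model_objects=model_objects,
    )
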