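"""The inference layer: per-read-out multiple regression on age, gender
and tendon type, plus normality diagnostics and a results table.

Continuous read-outs are fitted by ordinary least squares with an
intercept (coefficient t-tests, multiple R^2); the intact/released
outcome by a maximum-likelihood logistic model (Wald tests, McFadden
pseudo-R^2 = 1 - l(model)/l(intercept-only)).  Covariate coding follows
the study's convention: male = 1, semitendinosus = 1, intact = 1.  No
multiple-testing correction is applied (alpha = 0.05 per test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

COVARIATES = ("age", "gender_male", "tendon_semitendinosus")

#: Canonical read-out row order of the results table.
READOUT_ORDER = (
    "intact/released",
    "surface area 48 h (%)",
    "pro-collagen I (ng/ml)",
    "tenomodulin / tubulin (-)",
    "aSMA / tubulin (-)",
    "active MMP2 (A.U.)",
    "MMP2 active fraction (-)",
)


@dataclass
class ModelInput:
    """Per-tendon modelling rows for one read-out.

    ``y`` is the read-out (continuous, or the 0/1 intact indicator with
    intact coded 1); covariates are age in years and 0/1 indicators for
    male and semitendinosus.
    """

    readout: str
    y: np.ndarray
    age: np.ndarray
    gender_male: np.ndarray
    tendon_semitendinosus: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.y, self.age, self.gender_male, self.tendon_semitendinosus)]
        self.y, self.age, self.gender_male, self.tendon_semitendinosus = arrays
        n = len(self.y)
        if any(len(a) != n for a in arrays):
            raise ValueError("all columns must have equal length")
        if any(np.isnan(a).any() for a in arrays):
            raise ValueError("missing values in model input; drop rows first")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, column: str, readout: str | None = None
                   ) -> "ModelInput":
        sub = df[["age_y", "gender", "tendon", column]].dropna()
        return cls(
            readout=readout or column,
            y=sub[column].to_numpy(dtype=float),
            age=sub["age_y"].to_numpy(dtype=float),
            gender_male=(sub["gender"] == "M").to_numpy(dtype=float),
            tendon_semitendinosus=(sub["tendon"] == "ST").to_numpy(dtype=float),
        )

    def design(self) -> np.ndarray:
        return np.column_stack(
            [np.ones_like(self.age), self.age, self.gender_male, self.tendon_semitendinosus]
        )


@dataclass
class RegressionResult:
    readout: str
    model: str                               # 'linear' or 'logistic'
    terms: dict                              # covariate -> (estimate, se, p)
    intercept: tuple                         # (estimate, se, p)
    fit_statistic: float                     # R^2 or McFadden pseudo-R^2
    fit_statistic_name: str                  # 'R2' or 'pseudo-R2'
    n: int
    alpha: float = 0.05
    variant: str = "all"                     # e.g. 'all' / 'excluding-outliers'
    notes: list[str] = field(default_factory=list)

    def stars(self, covariate: str) -> str:
        return "*" if self.terms[covariate][2] < self.alpha else ""


def _check_design(X: np.ndarray) -> None:
    names = ("intercept",) + COVARIATES
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names[1:]}")


def fit_linear(inp: ModelInput, variant: str = "all") -> RegressionResult:
    """Ordinary least squares with intercept; t-test p-values, multiple R^2."""
    X = inp.design()
    if len(inp.y) <= X.shape[1]:
        raise ValueError("need more rows than parameters")
    _check_design(X)
    res = sm.OLS(inp.y, X).fit()
    terms = {
        name: (float(res.params[j + 1]), float(res.bse[j + 1]), float(res.pvalues[j + 1]))
        for j, name in enumerate(COVARIATES)
    }
    return RegressionResult(
        readout=inp.readout,
        model="linear",
        terms=terms,
        intercept=(float(res.params[0]), float(res.bse[0]), float(res.pvalues[0])),
        fit_statistic=float(res.rsquared),
        fit_statistic_name="R2",
        n=int(res.nobs),
        variant=variant,
    )


def fit_logistic(inp: ModelInput, variant: str = "all",
                 maxiter: int = 100, tol: float = 1e-8) -> RegressionResult:
    """Maximum-likelihood logit fit; Wald p-values, McFadden pseudo-R^2."""
    y = inp.y
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binary read-out must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = inp.design()
    _check_design(X)
    model = sm.Logit(y, X)
    model.raise_on_perfect_prediction = False
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")      # convergence is checked explicitly below
        res = model.fit(disp=0, maxiter=maxiter, tol=tol, method="newton")
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 50:
        raise ValueError(
            "logistic fit did not converge (diverging coefficients suggest "
            "perfect separation)"
        )
    terms = {
        name: (float(res.params[j + 1]), float(res.bse[j + 1]), float(res.pvalues[j + 1]))
        for j, name in enumerate(COVARIATES)
    }
    return RegressionResult(
        readout=inp.readout,
        model="logistic",
        terms=terms,
        intercept=(float(res.params[0]), float(res.bse[0]), float(res.pvalues[0])),
        fit_statistic=float(1.0 - res.llf / res.llnull),
        fit_statistic_name="pseudo-R2",
        n=int(res.nobs),
        variant=variant,
        notes=["pseudo-R2 (McFadden), since multiple R2 is not defined for "
               "logistic regression"],
    )


def qq_normality(residuals) -> tuple[np.ndarray, np.ndarray, float]:
    """Quantile-comparison pairs and the probability-plot correlation.

    Returns (theoretical standard-normal quantiles Phi^-1((i - 0.5)/n),
    ordered sample values, Pearson correlation of the pairs).
    """
    from scipy import stats as sps

    x = np.sort(np.asarray(residuals, dtype=float))
    if x.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(x) == 0:
        raise ValueError("constant residuals; quantile comparison undefined")
    theo = sps.norm.ppf((np.arange(1, x.size + 1) - 0.5) / x.size)
    corr = float(np.corrcoef(theo, x)[0, 1])
    return theo, x, corr


def results_table(results: list[RegressionResult]) -> pd.DataFrame:
    """One row per read-out: estimate / std. error / p per covariate, the
    fit statistic (pseudo-R^2 footnoted for logistic rows) and
    significance stars at alpha = 0.05."""
    if not results:
        raise ValueError("need at least one regression result")

    def sort_key(r: RegressionResult):
        try:
            return (READOUT_ORDER.index(r.readout), r.variant)
        except ValueError:
            return (len(READOUT_ORDER), r.variant)

    rows = []
    for r in sorted(results, key=sort_key):
        row: dict = {"readout": r.readout, "model": r.model, "variant": r.variant, "n": r.n}
        for cov in COVARIATES:
            est, se, p = r.terms[cov]
            row[f"{cov}_estimate"] = est
            row[f"{cov}_se"] = se
            row[f"{cov}_p"] = p
            row[f"{cov}_sig"] = r.stars(cov)
        row["fit_statistic"] = r.fit_statistic
        row["fit_statistic_name"] = r.fit_statistic_name
        rows.append(row)
    return pd.DataFrame(rows)


def format_results_text(table: pd.DataFrame) -> str:
    """Plain-text rendering of the results table."""
    lines = ["read-out | age (est, se, p) | gender m=1 (est, se, p) | "
             "tendon st=1 (est, se, p) | fit | n"]
    for _, row in table.iterrows():
        cells = [f"{row['readout']} [{row['variant']}]"]
        for cov in COVARIATES:
            cells.append(
                f"{row[f'{cov}_estimate']:.3g}, {row[f'{cov}_se']:.3g}, "
                f"{row[f'{cov}_p']:.3g}{row[f'{cov}_sig']}"
            )
        fit_name = row["fit_statistic_name"]
        mark = " (a)" if fit_name == "pseudo-R2" else ""
        cells.append(f"{fit_name}={row['fit_statistic']:.3g}{mark}")
        cells.append(str(row["n"]))
        lines.append(" | ".join(cells))
    if (table["fit_statistic_name"] == "pseudo-R2").any():
        lines.append("(a) pseudo-R2, since multiple R2 is not defined for "
                     "logistic regression")
    lines.append("* p < 0.05; no multiple-testing correction applied")
    return "\n".join(lines)
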