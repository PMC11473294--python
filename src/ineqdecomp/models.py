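"""Pooled cross-sectional regressions of health-service utilization.

Two links serve two purposes: the logit fit yields the odds-ratio tables
used for reporting, and the probit fit supplies the average marginal
effects (dy/dx) that weight each covariate in the concentration-index
decomposition.  Both are maximum-likelihood fits on complete cases with
wave dummies entering first (reference wave = first wave).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr

from .cohort import VariableSpec, default_variable_specs, specs_by_role
from .exceptions import ConfigurationError, DataError, ModelFitError

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


@dataclass
class ModelSpec:
    """Specification of one utilization regression.

    ``covariates`` defaults to the study's need + non-need sets with wave
    dummies first; ``include_disability_type`` adds the six-level disability
    factor (reference: physical).
    """

    outcome: str
    link: str = "logit"
    include_disability_type: bool = False
    covariates: list[VariableSpec] | None = None
    marginal_mode: str = "calculus"

    def __post_init__(self):
        if self.link not in {"logit", "probit"}:
            raise ConfigurationError(f"link must be logit or probit, got {self.link!r}")
        if self.marginal_mode not in {"calculus", "discrete"}:
            raise ConfigurationError("marginal_mode must be 'calculus' or 'discrete'")

    def resolved_covariates(self) -> list[VariableSpec]:
        if self.covariates is not None:
            return list(self.covariates)
        roles = specs_by_role(default_variable_specs())
        wave = [s for s in roles.get("control", []) if s.name == "wave"]
        disability = [s for s in roles.get("control", []) if s.name == "disability_type"]
        out = wave + roles.get("need", []) + roles.get("non_need", [])
        if self.include_disability_type:
            out += disability
        return out


@dataclass(frozen=True)
class ColumnInfo:
    """Book-keeping for one design column (used to regroup factor dummies)."""

    column: str
    variable: str
    level: object
    role: str


def build_design(
    df: pd.DataFrame,
    covariates: list[VariableSpec],
) -> tuple[pd.DataFrame, list[ColumnInfo]]:
    """Dummy-encode covariates against their declared references.

    Binary 0/1 variables keep their own name as the column; categorical and
    ordered variables contribute one ``name[level]`` column per
    non-reference level.
    """
    X = pd.DataFrame(index=df.index)
    info: list[ColumnInfo] = []
    for spec in covariates:
        if spec.name not in df.columns:
            raise DataError(f"design variable {spec.name!r} not in records")
        col = df[spec.name]
        if spec.kind == "binary" and list(spec.levels) == [0, 1]:
            X[spec.name] = col.astype(float)
            info.append(ColumnInfo(spec.name, spec.name, 1, spec.role))
        else:
            for lv in spec.dummy_levels:
                name = f"{spec.name}[{lv}]"
                X[name] = (col == lv).astype(float)
                X.loc[col.isna(), name] = np.nan
                info.append(ColumnInfo(name, spec.name, lv, spec.role))
    return X, info


def drop_empty_columns(
    X: pd.DataFrame, info: list[ColumnInfo]
) -> tuple[pd.DataFrame, list[ColumnInfo]]:
    """Drop dummy columns with no variation among complete cases.

    A level unobserved in the estimation sample contributes an all-zero
    (or all-one) column that would make the design singular; such columns
    are removed rather than reported as collinearity.
    """
    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if constant:
        logger.info("dropping constant design columns: %s", constant)
        X = X.drop(columns=constant)
        info = [ci for ci in info if ci.column not in constant]
    return X, info


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(r, X.shape[1])
               if i < len(piv)]
        raise ModelFitError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear columns: {bad}")


class UtilizationModel:
    """Binary-response model for one utilization outcome.

    Construct with :meth:`from_dataframe`, then call :meth:`fit` for a
    :class:`UtilizationResults`.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame,
                 link: str = "logit", column_info: list[ColumnInfo] | None = None,
                 outcome: str = "y", marginal_mode: str = "calculus"):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.link = link
        self.column_info = column_info or []
        self.outcome = outcome
        self.marginal_mode = marginal_mode
        if self.endog.sum() == 0 or self.endog.sum() == len(self.endog):
            raise DataError(
                f"outcome {outcome!r} needs both events and non-events among "
                "complete cases")
        _check_rank(exog.to_numpy(dtype=float), list(exog.columns))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec) -> "UtilizationModel":
        covs = spec.resolved_covariates()
        if spec.outcome not in df.columns:
            raise DataError(f"outcome {spec.outcome!r} not in records")
        X, info = build_design(df, covs)
        keep = df[spec.outcome].notna() & X.notna().all(axis=1)
        X = X[keep].astype(float)
        X, info = drop_empty_columns(X, info)
        X.insert(0, "const", 1.0)
        y = df.loc[keep, spec.outcome].astype(float).to_numpy()
        return cls(y, X, link=spec.link, column_info=info, outcome=spec.outcome,
                   marginal_mode=spec.marginal_mode)

    def fit(self, maxiter: int = 200) -> "UtilizationResults":
        family = sm.Logit if self.link == "logit" else sm.Probit
        model = family(self.endog, self.exog.to_numpy(dtype=float))
        try:
            res = model.fit(disp=0, maxiter=maxiter, method="newton")
        except Exception as exc:  # includes perfect-separation errors
            raise ModelFitError(f"{self.link} fit for {self.outcome!r} failed: {exc}")
        if not res.mle_retvals.get("converged", False) or np.isnan(res.params).any():
            raise ModelFitError(
                f"{self.link} fit for {self.outcome!r} did not converge after "
                f"{maxiter} iterations")
        return UtilizationResults(self, res)


class UtilizationResults:
    """Estimates, uncertainties and effect summaries of one fitted model."""

    def __init__(self, model: UtilizationModel, smres):
        self.model = model
        self._smres = smres
        cols = list(model.exog.columns)
        self.params = pd.Series(smres.params, index=cols)
        self.bse = pd.Series(smres.bse, index=cols)
        self.cov_params = pd.DataFrame(smres.cov_params(), index=cols, columns=cols)
        self.pvalues = pd.Series(smres.pvalues, index=cols)
        self.n_used = int(model.endog.shape[0])
        self.llf = float(smres.llf)

    @property
    def link(self) -> str:
        return self.model.link

    @property
    def pseudo_r2(self) -> float:
        """McFadden pseudo R-squared."""
        return float(self._smres.prsquared)

    def odds_ratios(self) -> pd.DataFrame:
        """exp(beta) with Wald 95% intervals (logit link only)."""
        if self.link != "logit":
            raise ConfigurationError("odds ratios are reported for the logit link")
        lo = self.params - Z95 * self.bse
        hi = self.params + Z95 * self.bse
        return pd.DataFrame({
            "odds_ratio": np.exp(self.params),
            "ci_low": np.exp(lo),
            "ci_high": np.exp(hi),
            "p_value": self.pvalues,
        })

    def _linear_index(self) -> np.ndarray:
        return self.model.exog.to_numpy(dtype=float) @ self.params.to_numpy()

    def marginal_effects(self, mode: str | None = None) -> pd.Series:
        """Average marginal effects dy/dx over the estimation sample.

        ``"calculus"`` (default) uses the density approximation
        mean(pdf(x'b)) * b_j for every column; ``"discrete"`` computes, for
        dummy columns, the average discrete change from the factor's
        reference category.  The constant is excluded.
        """
        mode = mode or self.model.marginal_mode
        X = self.model.exog
        beta = self.params
        xb = self._linear_index()
        dist = stats.norm if self.link == "probit" else stats.logistic
        cols = [c for c in X.columns if c != "const"]
        if mode == "calculus":
            scale = float(dist.pdf(xb).mean())
            return pd.Series({c: scale * beta[c] for c in cols})
        if mode != "discrete":
            raise ConfigurationError("mode must be 'calculus' or 'discrete'")
        # discrete change: switch the factor to the target level vs reference
        by_var: dict[str, list[str]] = {}
        for ci in self.model.column_info:
            by_var.setdefault(ci.variable, []).append(ci.column)
        out = {}
        Xv = X.to_numpy(dtype=float)
        for ci in self.model.column_info:
            siblings = by_var[ci.variable]
            X0 = Xv.copy()
            X1 = Xv.copy()
            for s in siblings:
                j = X.columns.get_loc(s)
                X0[:, j] = 0.0
                X1[:, j] = 1.0 if s == ci.column else 0.0
            b = beta.to_numpy()
            out[ci.column] = float((dist.cdf(X1 @ b) - dist.cdf(X0 @ b)).mean())
        return pd.Series(out).reindex(cols)

    def table(self) -> pd.DataFrame:
        """One row per term: variable, level, estimate and, for logit, OR."""
        rows = []
        info = {ci.column: ci for ci in self.model.column_info}
        orf = self.odds_ratios() if self.link == "logit" else None
        for c in self.params.index:
            ci = info.get(c)
            row = {
                "column": c,
                "variable": ci.variable if ci else c,
                "level": ci.level if ci else "",
                "coef": self.params[c],
                "se": self.bse[c],
                "p_value": self.pvalues[c],
            }
            if orf is not None:
                row.update(odds_ratio=orf.loc[c, "odds_ratio"],
                           ci_low=orf.loc[c, "ci_low"],
                           ci_high=orf.loc[c, "ci_high"])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (f"{self.link} model of {self.model.outcome!r}: n={self.n_used}, "
                f"McFadden R2={self.pseudo_r2:.4f}\n")
        frame = self.table()
        if self.link == "logit":
            frame = frame[["variable", "level", "odds_ratio", "ci_low",
                           "ci_high", "p_value"]]
        else:
            frame = frame[["variable", "level", "coef", "se", "p_value"]]
        return head + frame.to_string(index=False, float_format="%.4f")


def fit(records: pd.DataFrame, spec: ModelSpec) -> UtilizationResults:
    """Convenience wrapper: build the model from records and fit it."""
    return UtilizationModel.from_dataframe(records, spec).fit()


def crude_or(table) -> tuple[float, float, float]:
    """Cross-product odds ratio ad/bc of a 2x2 table with Wald 95% interval.

    Raises on zero cells; whether and how to apply a continuity correction
    is the caller's choice.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DataError("crude_or needs a 2x2 table")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) <= 0:
        raise DataError("zero cell in 2x2 table; apply a continuity correction "
                        "first if desired")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (float(or_), float(np.exp(np.log(or_) - Z95 * se)),
            float(np.exp(np.log(or_) + Z95 * se)))
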