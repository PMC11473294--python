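"""Concentration index, concentration curve, horizontal inequity and the
Wagstaff decomposition.

The concentration index (CI) of a health variable ``h`` over living
standards is

    C = 2 * cov(h, r) / mu,

where ``r`` is the fractional rank of annual per-capita household
expenditure (poorest to richest, weighted midpoint convention) and ``mu``
the mean of ``h``.  C in [-1, 1]; positive values mean utilization is
concentrated among the better-off (pro-rich).

The decomposition writes C for an outcome generated through a regression
model as

    C = sum_j beta_j^m * xbar_j / mu * c_j  +  GC_eps / mu,

one term per regressor: ``beta_j^m`` is the average marginal effect (dy/dx)
from a probit fit, ``xbar_j`` the regressor mean, ``c_j`` the concentration
index of the regressor itself over ``r``, and the generalized concentration
index of the error absorbs whatever the model leaves unexplained (including
the nonlinear-link approximation error).  The horizontal inequity index
subtracts the need-variable terms from C:

    HI = C - sum_{j in need} beta_j^m * xbar_j / mu * c_j,

i.e. the socioeconomic inequality remaining once legitimate differences in
need are standardized away.

Standard errors for C come from the "convenient regression" device: the
OLS slope of 2 * var(r) * h_i / mu on r_i equals C, and its
heteroskedasticity-robust (HC1) standard error is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VariableSpec, specs_by_role
from .exceptions import (ConfigurationError, DataError, ModelFitError,
                         UndefinedIndexError)
from .models import ModelSpec, UtilizationModel

__all__ = [
    "fractional_rank", "RankedOutcome", "CIResults", "concentration_index",
    "concentration_curve_points", "WagstaffDecomposition",
    "DecompositionResults", "decompose", "horizontal_inequity",
    "inequality_by_group",
]


def fractional_rank(expenditure, weights=None) -> np.ndarray:
    """Weighted fractional ranks in (0, 1), poorest to richest.

    Record *i* receives ``(W_below + w_i/2) / W_total`` where ``W_below``
    is the total weight of strictly poorer records; a block of tied
    expenditures shares the midpoint rank of the block.  The weighted mean
    of the ranks is exactly 0.5.
    """
    x = np.asarray(expenditure, dtype=float)
    if np.isnan(x).any():
        raise DataError("missing expenditure: filter records before ranking")
    n = len(x)
    if n == 0:
        raise DataError("cannot rank an empty sample")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise DataError("weights must be non-negative and not all zero")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    W = ws.sum()
    cum = np.concatenate([[0.0], np.cumsum(ws)])
    # midpoint rank per tie block
    r_sorted = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        r_sorted[i:j + 1] = (cum[i] + cum[j + 1]) / 2.0 / W
        i = j + 1
    r = np.empty(n)
    r[order] = r_sorted
    return r


@dataclass(frozen=True)
class RankedOutcome:
    """A binary outcome paired with socioeconomic fractional ranks."""

    h: np.ndarray
    r: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_arrays(cls, h, expenditure=None, ranks=None, weights=None
                    ) -> "RankedOutcome":
        h = np.asarray(h, dtype=float)
        if np.isnan(h).any():
            raise DataError("missing outcome values: filter records first")
        if (ranks is None) == (expenditure is None):
            raise ConfigurationError("pass exactly one of expenditure or ranks")
        w = np.ones(len(h)) if weights is None else np.asarray(weights, float)
        r = (np.asarray(ranks, dtype=float) if ranks is not None
             else fractional_rank(expenditure, w))
        if len(r) != len(h):
            raise DataError("outcome and rank vectors differ in length")
        return cls(h=h, r=r, weights=w)

    @property
    def mu(self) -> float:
        return float(np.average(self.h, weights=self.weights))

    @property
    def n(self) -> int:
        return len(self.h)


def _wcov(a, b, w):
    """Population (divide-by-total-weight) weighted covariance."""
    wa = np.average(a, weights=w)
    wb = np.average(b, weights=w)
    return float(np.average((a - wa) * (b - wb), weights=w))


def _convenient_regression_se(h, r, w, mu) -> float:
    """HC1-robust SE of the convenient-regression slope (which equals C)."""
    var_r = _wcov(r, r, w)
    y = 2.0 * var_r * h / mu
    x = r - np.average(r, weights=w)
    n = len(h)
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y)) / sxx
    inter = np.average(y, weights=w) - slope * 0.0  # x already centred
    e = y - inter - slope * x
    dof = n / max(n - 2, 1)
    return float(np.sqrt(dof * np.sum((w * x * e) ** 2) / sxx ** 2))


@dataclass(frozen=True)
class CIResults:
    """A fitted concentration index with its curve and convenient-regression SE."""

    estimate: float
    se: float
    n: int
    mu: float
    curve: np.ndarray = field(repr=False)
    normalization: str = "none"

    @property
    def p_value(self) -> float:
        if self.se == 0:
            return 1.0 if self.estimate == 0 else 0.0
        return float(2 * stats.norm.sf(abs(self.estimate) / self.se))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.estimate - z * self.se, self.estimate + z * self.se)

    def stars(self) -> str:
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value < cut:
                return mark
        return ""

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return (f"concentration index = {self.estimate:+.4f}{self.stars()} "
                f"(SE {self.se:.4f}, 95% CI [{lo:+.4f}, {hi:+.4f}]), "
                f"n={self.n}, mu={self.mu:.4f}")

    def plot(self, ax=None, label: str | None = None):
        """Draw the concentration curve against the equality diagonal.

        Requires matplotlib (the ``plot`` extra); returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 1], [0, 1], color="grey", linewidth=0.8, linestyle="--")
        ax.plot(self.curve[:, 0], self.curve[:, 1],
                label=label or f"C = {self.estimate:+.3f}")
        ax.set_xlabel("cumulative population share (poorest first)")
        ax.set_ylabel("cumulative outcome share")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.legend()
        return ax


def concentration_curve_points(h, ranks, weights=None) -> np.ndarray:
    """Concentration-curve vertices: cumulative population share vs
    cumulative outcome share in rank order, starting at (0, 0).

    The curve lies below the 45-degree line when the outcome is pro-rich;
    twice the signed area between the diagonal and the curve approximates C.
    """
    h = np.asarray(h, dtype=float)
    r = np.asarray(ranks, dtype=float)
    w = np.ones(len(h)) if weights is None else np.asarray(weights, float)
    total_h = float(np.sum(w * h))
    if total_h <= 0:
        raise UndefinedIndexError("curve undefined for zero-prevalence outcome")
    order = np.argsort(r, kind="stable")
    cw = np.cumsum(w[order]) / np.sum(w)
    ch = np.cumsum((w * h)[order]) / total_h
    return np.column_stack([np.concatenate([[0.0], cw]),
                            np.concatenate([[0.0], ch])])


def concentration_index(
    h,
    expenditure=None,
    ranks=None,
    weights=None,
    normalization: str = "none",
) -> CIResults:
    """Concentration index C = 2 cov(h, r) / mu with curve and robust SE.

    ``normalization`` rescales the binary-outcome index: ``"wagstaff"``
    divides by (1 - mu), ``"erreygers"`` multiplies by 4 mu.  Default is
    the plain index.
    """
    ranked = RankedOutcome.from_arrays(h, expenditure, ranks, weights)
    if ranked.n < 2:
        raise DataError("need at least two records")
    mu = ranked.mu
    if mu == 0:
        raise UndefinedIndexError("concentration index undefined: mean outcome is 0")
    est = 2.0 * _wcov(ranked.h, ranked.r, ranked.weights) / mu
    se = _convenient_regression_se(ranked.h, ranked.r, ranked.weights, mu)
    if normalization == "wagstaff":
        if mu >= 1:
            raise UndefinedIndexError("Wagstaff normalization undefined at mu = 1")
        est, se = est / (1 - mu), se / (1 - mu)
    elif normalization == "erreygers":
        est, se = 4 * mu * est, 4 * mu * se
    elif normalization != "none":
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    curve = concentration_curve_points(ranked.h, ranked.r, ranked.weights)
    return CIResults(estimate=float(est), se=float(se), n=ranked.n, mu=mu,
                     curve=curve, normalization=normalization)


def _decomposition_covariates(covariates=None, include_wave=False):
    if covariates is not None:
        return list(covariates)
    roles = specs_by_role()
    covs = roles.get("need", []) + roles.get("non_need", [])
    if include_wave:
        covs = [s for s in roles.get("control", []) if s.name == "wave"] + covs
    return covs


class WagstaffDecomposition:
    """Regression-based decomposition of the concentration index.

    A probit model of the outcome on the need and non-need covariates
    supplies average marginal effects; each design column's contribution is
    ``AME_j * mean_j / mu * c_j`` where ``c_j`` is the concentration index
    of the column itself over the expenditure ranks.  The residual term
    (the generalized concentration index of the error over mu) is reported,
    never hidden.  Ranks are computed on continuous expenditure of the
    complete-case sample; the expenditure-quintile dummies enter only as
    regressors.
    """

    def __init__(self, df: pd.DataFrame, outcome: str,
                 covariates: list[VariableSpec] | None = None,
                 link: str = "probit", marginal_mode: str = "calculus",
                 rank_scope: str = "pooled", include_wave: bool = False,
                 weights=None):
        if rank_scope not in {"pooled", "within_wave"}:
            raise ConfigurationError("rank_scope must be 'pooled' or 'within_wave'")
        self.outcome = outcome
        self.covariates = _decomposition_covariates(covariates, include_wave)
        self.link = link
        self.marginal_mode = marginal_mode
        self.rank_scope = rank_scope
        from .models import build_design
        X, info = build_design(df, self.covariates)
        exp = pd.to_numeric(df["expenditure"], errors="coerce")
        keep = (df[outcome].notna() & X.notna().all(axis=1) & exp.notna())
        if self.rank_scope == "within_wave":
            keep &= df["wave"].notna()
        self._df = df[keep]
        self._X = X[keep].astype(float)
        self._info = info
        self._y = df.loc[keep, outcome].astype(float).to_numpy()
        self._exp = exp[keep].to_numpy()
        self._weights = (np.ones(keep.sum()) if weights is None
                         else np.asarray(weights, float)[keep.to_numpy()])

    @classmethod
    def from_dataframe(cls, df, outcome, **kwargs) -> "WagstaffDecomposition":
        return cls(df, outcome, **kwargs)

    def _ranks(self) -> np.ndarray:
        if self.rank_scope == "pooled":
            return fractional_rank(self._exp, self._weights)
        r = np.empty(len(self._exp))
        waves = self._df["wave"].to_numpy()
        for wv in pd.unique(waves):
            m = waves == wv
            r[m] = fractional_rank(self._exp[m], self._weights[m])
        return r

    def fit(self) -> "DecompositionResults":
        from .models import drop_empty_columns
        Xd, info = drop_empty_columns(self._X, self._info)
        Xc = Xd.copy()
        Xc.insert(0, "const", 1.0)
        model = UtilizationModel(self._y, Xc, link=self.link,
                                 column_info=info, outcome=self.outcome,
                                 marginal_mode=self.marginal_mode)
        fitres = model.fit()
        ame = fitres.marginal_effects()
        r = self._ranks()
        w = self._weights
        total = concentration_index(self._y, ranks=r, weights=w)
        mu = total.mu
        rows = []
        for ci in info:
            x = Xd[ci.column].to_numpy(dtype=float)
            mean = float(np.average(x, weights=w))
            cov = _wcov(x, r, w)
            c_var = 2.0 * cov / mean if mean > 0 else np.nan
            contribution = 2.0 * float(ame[ci.column]) * cov / mu
            rows.append({
                "column": ci.column, "variable": ci.variable, "level": ci.level,
                "role": ci.role, "coef": float(fitres.params[ci.column]),
                "ame": float(ame[ci.column]), "mean": mean,
                "ci_variable": c_var, "contribution": contribution,
            })
        table = pd.DataFrame(rows)
        explained = float(table["contribution"].sum())
        residual = total.estimate - explained
        if total.estimate == 0:
            warnings.warn("total concentration index is 0: contribution rates "
                          "are undefined", stacklevel=2)
            table["contribution_rate"] = np.nan
        else:
            table["contribution_rate"] = 100 * table["contribution"] / total.estimate
        need = float(table.loc[table["role"] == "need", "contribution"].sum())
        non_need = float(table.loc[table["role"] == "non_need", "contribution"].sum())
        return DecompositionResults(
            outcome=self.outcome, table=table, total=total, residual=residual,
            need_contribution=need, non_need_contribution=non_need,
            n_used=len(self._y), mu=mu, rank_scope=self.rank_scope,
            fit_results=fitres,
        )


@dataclass
class DecompositionResults:
    """Per-variable contributions to the concentration index, plus HI."""

    outcome: str
    table: pd.DataFrame
    total: CIResults
    residual: float
    need_contribution: float
    non_need_contribution: float
    n_used: int
    mu: float
    rank_scope: str
    fit_results: object = field(repr=False, default=None)

    @property
    def total_ci(self) -> float:
        return self.total.estimate

    @property
    def hi(self) -> float:
        """Horizontal inequity: C minus all need-variable contributions."""
        return self.total.estimate - self.need_contribution

    def by_factor(self) -> pd.DataFrame:
        """Contributions aggregated over each factor's dummy columns.

        Multi-level factors (e.g. the expenditure-quintile block) are often
        reported as a single aggregated row; per-dummy rows remain available
        in :attr:`table`.
        """
        g = (self.table.groupby(["variable", "role"], sort=False)["contribution"]
             .sum().reset_index())
        if self.total.estimate != 0:
            g["contribution_rate"] = 100 * g["contribution"] / self.total.estimate
        else:
            g["contribution_rate"] = np.nan
        return g

    def adding_up_error(self) -> float:
        """| sum of contributions + residual - C |; zero up to float error."""
        return abs(float(self.table["contribution"].sum())
                   + self.residual - self.total.estimate)

    def summary(self) -> str:
        lines = [
            f"decomposition of concentration index: outcome={self.outcome!r}, "
            f"n={self.n_used}, mu={self.mu:.4f}, ranks={self.rank_scope}",
            f"C = {self.total.estimate:+.4f}{self.total.stars()} "
            f"(SE {self.total.se:.4f})   HI = {self.hi:+.4f}   "
            f"residual = {self.residual:+.4f}",
        ]
        frame = self.table[["variable", "level", "role", "ame", "mean",
                            "ci_variable", "contribution", "contribution_rate"]]
        lines.append(frame.to_string(index=False, float_format="%.4f"))
        return "\n".join(lines)


def decompose(records: pd.DataFrame, spec: ModelSpec | None = None,
              outcome: str | None = None, **kwargs) -> DecompositionResults:
    """Run the probit-based decomposition on ``records``.

    Accepts either a :class:`ModelSpec` (its link must be probit) or an
    outcome name with keyword options forwarded to
    :class:`WagstaffDecomposition`.
    """
    if spec is not None:
        if spec.link != "probit":
            raise ConfigurationError("decomposition requires the probit link")
        outcome = spec.outcome
        kwargs.setdefault("covariates", spec.covariates)
        kwargs.setdefault("marginal_mode", spec.marginal_mode)
    if outcome is None:
        raise ConfigurationError("an outcome is required")
    return WagstaffDecomposition(records, outcome, **kwargs).fit()


def horizontal_inequity(ranked: RankedOutcome,
                        decomposition: DecompositionResults) -> float:
    """HI = C minus summed need contributions of ``decomposition``.

    With an empty need set nothing is subtracted and HI equals C (a warning
    is emitted since the index then measures total, not inequitable,
    inequality).
    """
    if not (decomposition.table["role"] == "need").any():
        warnings.warn("need set is empty: HI equals the total concentration "
                      "index", stacklevel=2)
    c = concentration_index(ranked.h, ranks=ranked.r, weights=ranked.weights)
    return c.estimate - decomposition.need_contribution


def inequality_by_group(
    df: pd.DataFrame,
    outcome: str,
    by: list[str] | str = "wave",
    min_n: int = 30,
    with_hi: bool = True,
    covariates: list[VariableSpec] | None = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """CI (and HI) per subgroup, with small groups reported as missing.

    Groups with fewer than ``min_n`` complete cases, a degenerate outcome,
    or a failed probit fit yield NaN entries rather than an error, matching
    how sparse subgroup panels are usually reported.
    """
    by = [by] if isinstance(by, str) else list(by)
    frames = []
    combos = [("all", df)] if include_overall else []
    for g in by:
        combos += [(f"{g}={val}", df[df[g] == val])
                   for val in sorted(df[g].dropna().unique().astype(str))]
    for label, sub in combos:
        use = sub[sub[outcome].notna() & sub["expenditure"].notna()]
        row = {"group": label, "outcome": outcome, "n": len(use),
               "mu": np.nan, "ci": np.nan, "se": np.nan, "p_value": np.nan,
               "hi": np.nan}
        if len(use) >= min_n and use[outcome].astype(float).mean() > 0:
            res = concentration_index(use[outcome].astype(float).to_numpy(),
                                      expenditure=use["expenditure"].to_numpy(float))
            row.update(mu=res.mu, ci=res.estimate, se=res.se, p_value=res.p_value)
            if with_hi:
                try:
                    dec = WagstaffDecomposition(use, outcome,
                                                covariates=covariates).fit()
                    if dec.n_used >= min_n:
                        row["hi"] = dec.hi
                except (ModelFitError, DataError):
                    pass  # insufficient data for need standardization
        frames.append(row)
    return pd.DataFrame(frames)
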