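"""Synthetic survey cohorts with a known pro-rich utilization gradient.

This module generates person-wave records shaped like a four-wave ageing
survey of middle-aged and older adults with disabilities: a right-skewed
annual per-capita household expenditure with extreme values injected at
both tails, six mutually exclusive disability types, binary and categorical
need/non-need covariates, and three binary health-service outcomes drawn
from a probit data-generating process whose linear index includes
expenditure-quintile effects.  Because the generating coefficients are
known, the generator doubles as the ground truth for parameter-recovery
and null-calibration tests of the concentration-index machinery.

It also ships, as package data, a set of published contingency tables
(counts and their Pearson chi-squared statistics) used as exact fixtures
for the descriptive statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import _quintile_bins
from .exceptions import ConfigurationError

OUTCOMES = ["outpatient", "inpatient", "self_treatment"]

#: design columns of the generating probit index, in order
DGP_COLUMNS = [
    "const", "wave_2013", "wave_2015", "wave_2018",
    "female", "age_60_74", "age_75plus", "srh_general", "srh_poor",
    "chronic", "adl", "iadl",
    "q2", "q3", "q4", "q5",
    "smoking", "drinking", "married",
    "edu_below_primary", "edu_primary", "edu_junior_plus",
    "social", "child_support", "region_central", "region_eastern", "insured",
]

#: variables eligible for item-level missingness (identifiers, age, wave and
#: disability type always stay complete so the inclusion rules are testable)
MASKABLE = [
    "gender", "self_rated_health", "chronic_disease", "adl_limited",
    "iadl_limited", "smoking", "drinking", "married", "education",
    "social_activity", "child_support", "region", "insured", "expenditure",
    "outpatient", "inpatient", "self_treatment",
]


def default_prevalences() -> dict:
    """Marginal covariate distributions of the default cohort.

    Categorical variables map level -> frequency (summing to 1); binary
    variables map to the probability of the positive level.
    """
    return {
        "gender": {"male": 0.522, "female": 0.478},
        "age_band": {"45-59": 0.391, "60-74": 0.412, "75+": 0.197},
        "disability_type": {
            "physical": 0.150, "intellectual": 0.085, "vision": 0.200,
            "hearing": 0.328, "speech": 0.007, "multiple": 0.230,
        },
        "self_rated_health": {"good": 0.126, "general": 0.387, "poor": 0.487},
        "education": {
            "illiterate": 0.388, "below_primary": 0.219,
            "primary": 0.197, "junior_plus": 0.196,
        },
        "region": {"western": 0.377, "central": 0.341, "eastern": 0.282},
        "chronic_disease": 0.790,
        "adl_limited": 0.165,
        "iadl_limited": 0.334,
        "smoking": 0.350,
        "drinking": 0.318,
        "married": 0.781,
        "social_activity": 0.423,
        "child_support": 0.447,
        "insured": 0.921,
    }


# Default generating coefficients on the probit scale.  Effect patterns are
# chosen to place the synthetic cohort in a realistic utilization regime: a
# monotone pro-rich expenditure-quintile gradient (strongest for inpatient
# care), higher use under poor self-rated health, chronic disease and
# functional limitation, and rising inpatient/self-treatment use across
# waves.  Constants are calibrated so pooled prevalences land near
# outpatient 0.24, inpatient 0.20 and self-treatment 0.62.
def default_probit_coefficients() -> dict:
    return {
        "outpatient": {
            "const": -1.857,
            "wave_2013": 0.223, "wave_2015": 0.027, "wave_2018": -0.105,
            "female": 0.060, "age_60_74": 0.073, "age_75plus": -0.036,
            "srh_general": 0.364, "srh_poor": 0.738,
            "chronic": 0.195, "adl": 0.011, "iadl": 0.003,
            "q2": 0.201, "q3": 0.329, "q4": 0.272, "q5": 0.350,
            "smoking": -0.141, "drinking": -0.115, "married": 0.099,
            "edu_below_primary": -0.147, "edu_primary": -0.251,
            "edu_junior_plus": -0.099,
            "social": 0.193, "child_support": 0.103,
            "region_central": -0.102, "region_eastern": -0.037,
            "insured": 0.178,
        },
        "inpatient": {
            "const": -2.703,
            "wave_2013": 0.394, "wave_2015": 0.357, "wave_2018": 0.547,
            "female": -0.183, "age_60_74": 0.201, "age_75plus": 0.262,
            "srh_general": 0.182, "srh_poor": 0.505,
            "chronic": 0.238, "adl": 0.194, "iadl": 0.344,
            "q2": 0.226, "q3": 0.450, "q4": 0.650, "q5": 0.850,
            "smoking": -0.317, "drinking": -0.188, "married": -0.039,
            "edu_below_primary": 0.192, "edu_primary": 0.123,
            "edu_junior_plus": 0.148,
            "social": 0.009, "child_support": 0.158,
            "region_central": -0.092, "region_eastern": -0.203,
            "insured": 0.468,
        },
        "self_treatment": {
            "const": -1.169,
            "wave_2013": 0.255, "wave_2015": 0.237, "wave_2018": 0.410,
            "female": 0.213, "age_60_74": 0.188, "age_75plus": 0.141,
            "srh_general": 0.269, "srh_poor": 0.458,
            "chronic": 0.387, "adl": 0.133, "iadl": 0.083,
            "q2": 0.014, "q3": 0.113, "q4": 0.136, "q5": 0.128,
            "smoking": 0.008, "drinking": -0.016, "married": 0.049,
            "edu_below_primary": 0.136, "edu_primary": 0.217,
            "edu_junior_plus": 0.386,
            "social": 0.103, "child_support": 0.001,
            "region_central": -0.118, "region_eastern": -0.075,
            "insured": 0.168,
        },
    }


@dataclass
class DGPConfig:
    """Configuration of the synthetic data-generating process.

    Parameters
    ----------
    n_per_wave : mapping of wave label -> positive record count.  Defaults
        to the pre-trimming per-wave sizes of the emulated study design.
    expenditure_log_mean, expenditure_log_sd : parameters of the log-normal
        base expenditure distribution (log currency units per year).
    outlier_fraction : total proportion of records whose expenditure is
        replaced by an extreme draw (half per tail, scaled x10 above and
        x0.1 below), giving the trimming stage something to remove.
    covariate_prevalences : marginal distributions, see
        :func:`default_prevalences`.
    probit_coefficients : per-outcome linear-index coefficients over
        :data:`DGP_COLUMNS`.
    missing_rate : per-variable item-missingness probability (MCAR, applied
        after outcome generation) in [0, 0.2].
    seed : RNG seed; fixing it fixes the cohort bit-for-bit.
    """

    n_per_wave: dict = field(default_factory=lambda: {
        "2011": 3088, "2013": 2388, "2015": 2634, "2018": 2425})
    expenditure_log_mean: float = 9.0
    expenditure_log_sd: float = 0.85
    outlier_fraction: float = 0.02
    covariate_prevalences: dict = field(default_factory=default_prevalences)
    probit_coefficients: dict = field(default_factory=default_probit_coefficients)
    missing_rate: float = 0.02
    seed: int = 20110101

    def __post_init__(self):
        for wave, n in self.n_per_wave.items():
            if int(n) <= 0:
                raise ConfigurationError(f"n_per_wave[{wave!r}] must be positive, got {n}")
        if not 0 <= self.outlier_fraction <= 0.1:
            raise ConfigurationError("outlier_fraction must be in [0, 0.1]")
        if not 0 <= self.missing_rate <= 0.2:
            raise ConfigurationError("missing_rate must be in [0, 0.2]")
        if self.expenditure_log_sd <= 0:
            raise ConfigurationError("expenditure_log_sd must be positive")
        for name, spec in self.covariate_prevalences.items():
            if isinstance(spec, dict):
                probs = np.array(list(spec.values()), dtype=float)
                if (probs < 0).any() or (probs > 1).any():
                    raise ConfigurationError(f"probabilities for {name} outside [0,1]")
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"level frequencies for {name} sum to {probs.sum()}, not 1")
            else:
                if not 0 <= float(spec) <= 1:
                    raise ConfigurationError(f"prevalence for {name} outside [0,1]")
        for outcome, coefs in self.probit_coefficients.items():
            if outcome not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {outcome!r}")
            for key in coefs:
                if key not in DGP_COLUMNS:
                    raise ConfigurationError(
                        f"probit coefficient for unknown design column {key!r} "
                        f"(outcome {outcome})")

    @property
    def waves(self) -> list[str]:
        return list(self.n_per_wave)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_wave.values()))

    def replace(self, **kwargs) -> "DGPConfig":
        return dataclasses.replace(self, **kwargs)

    def with_zero_gradient(self) -> "DGPConfig":
        """Copy with every expenditure-quintile coefficient set to zero."""
        coefs = {o: dict(c) for o, c in self.probit_coefficients.items()}
        for c in coefs.values():
            for q in ("q2", "q3", "q4", "q5"):
                c[q] = 0.0
        return self.replace(probit_coefficients=coefs)

    def scaled_to(self, n_total: int) -> "DGPConfig":
        """Copy with per-wave sizes rescaled to roughly ``n_total`` records."""
        factor = n_total / self.n_total
        n = {w: max(1, round(v * factor)) for w, v in self.n_per_wave.items()}
        return self.replace(n_per_wave=n)

    @classmethod
    def from_dict(cls, d: dict) -> "DGPConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _draw_categorical(rng, spec: dict, n: int) -> np.ndarray:
    levels = list(spec)
    p = np.array([spec[lv] for lv in levels], dtype=float)
    return rng.choice(np.array(levels, dtype=object), size=n, p=p / p.sum())


def _dgp_design(df: pd.DataFrame, quintile: np.ndarray) -> pd.DataFrame:
    """Design matrix of the generating index from drawn covariates."""
    X = pd.DataFrame(index=df.index, dtype=float)
    X["const"] = 1.0
    for w in ("2013", "2015", "2018"):
        X[f"wave_{w}"] = (df["wave"] == w).astype(float)
    X["female"] = (df["gender"] == "female").astype(float)
    X["age_60_74"] = (df["age_band"] == "60-74").astype(float)
    X["age_75plus"] = (df["age_band"] == "75+").astype(float)
    X["srh_general"] = (df["self_rated_health"] == "general").astype(float)
    X["srh_poor"] = (df["self_rated_health"] == "poor").astype(float)
    X["chronic"] = df["chronic_disease"].astype(float)
    X["adl"] = df["adl_limited"].astype(float)
    X["iadl"] = df["iadl_limited"].astype(float)
    for i, q in enumerate(("q2", "q3", "q4", "q5"), start=1):
        X[q] = (quintile == i).astype(float)
    X["smoking"] = df["smoking"].astype(float)
    X["drinking"] = df["drinking"].astype(float)
    X["married"] = df["married"].astype(float)
    X["edu_below_primary"] = (df["education"] == "below_primary").astype(float)
    X["edu_primary"] = (df["education"] == "primary").astype(float)
    X["edu_junior_plus"] = (df["education"] == "junior_plus").astype(float)
    X["social"] = df["social_activity"].astype(float)
    X["child_support"] = df["child_support"].astype(float)
    X["region_central"] = (df["region"] == "central").astype(float)
    X["region_eastern"] = (df["region"] == "eastern").astype(float)
    X["insured"] = (df["insured"] == 1).astype(float)
    return X[DGP_COLUMNS]


_AGE_RANGE = {"45-59": (45, 59), "60-74": (60, 74), "75+": (75, 89)}


def generate_cohort(config: DGPConfig) -> pd.DataFrame:
    """Generate one synthetic cohort (all waves) under ``config``.

    Every record satisfies the inclusion rules by construction (age >= 45,
    a known disability type); outcomes are Bernoulli draws with success
    probability Phi(x'beta) under the configured probit index, where the
    expenditure-quintile dummies are cut within wave on the generated
    (pre-trimming) expenditure.  Item missingness is applied last, so the
    latent complete data always obey the generating process.
    """
    rng = np.random.default_rng(config.seed)
    prev = config.covariate_prevalences
    frames = []
    for wave, n in config.n_per_wave.items():
        n = int(n)
        df = pd.DataFrame({
            "person_id": [f"{wave}-{i:06d}" for i in range(n)],
            "wave": np.repeat(str(wave), n),
        })
        df["age_band"] = _draw_categorical(rng, prev["age_band"], n)
        lo = np.array([_AGE_RANGE[b][0] for b in df["age_band"]])
        hi = np.array([_AGE_RANGE[b][1] for b in df["age_band"]])
        df["age"] = rng.integers(lo, hi + 1)
        df["gender"] = _draw_categorical(rng, prev["gender"], n)
        df["disability_type"] = _draw_categorical(rng, prev["disability_type"], n)
        df["self_rated_health"] = _draw_categorical(rng, prev["self_rated_health"], n)
        df["education"] = _draw_categorical(rng, prev["education"], n)
        df["region"] = _draw_categorical(rng, prev["region"], n)
        for name in ("chronic_disease", "adl_limited", "iadl_limited", "smoking",
                     "drinking", "married", "social_activity", "child_support",
                     "insured"):
            df[name] = (rng.random(n) < float(prev[name])).astype(float)

        exp = rng.lognormal(config.expenditure_log_mean, config.expenditure_log_sd, n)
        k = round(n * config.outlier_fraction / 2)
        if k > 0:
            pick = rng.choice(n, size=2 * k, replace=False)
            base = rng.lognormal(config.expenditure_log_mean,
                                 config.expenditure_log_sd, 2 * k)
            exp[pick[:k]] = base[:k] * 0.1   # extreme lower tail
            exp[pick[k:]] = base[k:] * 10.0  # extreme upper tail
        df["expenditure"] = exp

        quintile = _quintile_bins(exp)
        X = _dgp_design(df, quintile).to_numpy()
        for outcome in OUTCOMES:
            coefs = config.probit_coefficients.get(outcome, {})
            beta = np.array([coefs.get(c, 0.0) for c in DGP_COLUMNS])
            p = norm.cdf(X @ beta)
            df[outcome] = (rng.random(n) < p).astype(float)
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        for col in MASKABLE:
            mask = rng.random(len(out)) < config.missing_rate
            out.loc[mask, col] = np.nan
    return out


def expected_prevalence(config: DGPConfig, outcome: str, n: int = 200_000,
                        seed: int | None = None) -> float:
    """Monte-Carlo mean of Phi(x'beta) over the covariate distribution.

    Independent check that generated outcome prevalences match the probit
    index, without touching the Bernoulli draws.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    cfg = config.scaled_to(n).replace(
        missing_rate=0.0, seed=config.seed if seed is None else seed)
    rng = np.random.default_rng(cfg.seed)
    prev = cfg.covariate_prevalences
    vals = []
    for wave, nw in cfg.n_per_wave.items():
        nw = int(nw)
        df = pd.DataFrame({"wave": np.repeat(str(wave), nw)})
        df["age_band"] = _draw_categorical(rng, prev["age_band"], nw)
        df["gender"] = _draw_categorical(rng, prev["gender"], nw)
        df["self_rated_health"] = _draw_categorical(rng, prev["self_rated_health"], nw)
        df["education"] = _draw_categorical(rng, prev["education"], nw)
        df["region"] = _draw_categorical(rng, prev["region"], nw)
        for name in ("chronic_disease", "adl_limited", "iadl_limited", "smoking",
                     "drinking", "married", "social_activity", "child_support",
                     "insured"):
            df[name] = (rng.random(nw) < float(prev[name])).astype(float)
        exp = rng.lognormal(cfg.expenditure_log_mean, cfg.expenditure_log_sd, nw)
        quintile = _quintile_bins(exp)
        coefs = cfg.probit_coefficients.get(outcome, {})
        beta = np.array([coefs.get(c, 0.0) for c in DGP_COLUMNS])
        X = _dgp_design(df, quintile).to_numpy()
        vals.append(norm.cdf(X @ beta))
    return float(np.concatenate(vals).mean())


def oracle_ci(config: DGPConfig, outcome: str, n_oracle: int = 1_000_000,
              trim_total: float = 0.02) -> float:
    """Pseudo-true concentration index of ``outcome`` under ``config``.

    Runs the full estimation pipeline (trimming, pooled fractional ranks,
    covariance formula) on one very large generated sample, so that
    small-sample estimates can be benchmarked against it.
    """
    from .cohort import trim_expenditure
    from .inequality import concentration_index

    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    if n_oracle < 100_000:
        raise ConfigurationError("n_oracle must be at least 1e5 for a stable oracle")
    cfg = config.scaled_to(n_oracle)
    df = trim_expenditure(generate_cohort(cfg), trim_total)
    use = df[df["expenditure"].notna() & df[outcome].notna()]
    res = concentration_index(use[outcome].to_numpy(float),
                              expenditure=use["expenditure"].to_numpy(float))
    return float(res.estimate)


@dataclass(frozen=True)
class FixtureTable:
    """One published contingency table with its printed test statistic."""

    name: str
    row_variable: str
    col_variable: str
    row_labels: list
    col_labels: list
    counts: np.ndarray
    printed_chi2: float

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ConfigurationError(f"fixture {self.name}: need >= 2x2 counts")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ConfigurationError(f"fixture {self.name}: counts must be "
                                     "non-negative integers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


def load_fixture_tables() -> dict[str, FixtureTable]:
    """Load the published contingency tables shipped as package data."""
    pkg = resources.files("ineqdecomp.data")
    meta = json.loads(pkg.joinpath("printed_tables_meta.json").read_text())
    with resources.as_file(pkg.joinpath("printed_tables.csv")) as path:
        long = pd.read_csv(path, dtype={"row": str, "col": str})
    out = {}
    for name, m in meta.items():
        sub = long[long["table"] == name]
        mat = (sub.pivot(index="row", columns="col", values="count")
               .reindex(index=[str(r) for r in m["row_labels"]],
                        columns=[str(c) for c in m["col_labels"]]))
        out[name] = FixtureTable(
            name=name,
            row_variable=m["row_variable"],
            col_variable=m["col_variable"],
            row_labels=list(m["row_labels"]),
            col_labels=list(m["col_labels"]),
            counts=mat.to_numpy(dtype=np.int64),
            printed_chi2=float(m["printed_chi2"]),
        )
    return out
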