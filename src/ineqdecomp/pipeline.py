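"""End-to-end orchestration: generate/load -> prepare -> describe ->
regress -> concentration index -> decomposition, with a run manifest.

All outputs are plain CSV/JSON so they can be consumed from R or a
spreadsheet directly.  Randomness flows from the single config seed; the
manifest records the config hash, the seed and the record count after each
filtering stage so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import descriptives as desc_mod
from . import inequality as ineq_mod
from . import models as models_mod
from . import synthetic as synth_mod
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

OUTCOMES = synth_mod.OUTCOMES

#: columns written for a cohort snapshot, in stable order
SNAPSHOT_COLUMNS = [
    "person_id", "wave", "age", "age_band", "gender", "disability_type",
    "self_rated_health", "chronic_disease", "adl_limited", "iadl_limited",
    "smoking", "drinking", "married", "education", "social_activity",
    "child_support", "region", "insured", "expenditure",
    "expenditure_quintile", "outpatient", "inpatient", "self_treatment",
]


@dataclass
class PipelineConfig:
    """Configuration of one reproducible pipeline run.

    Exactly one of ``input_csv`` (load a cohort snapshot) or ``generate``
    (simulate under ``dgp``) must be active.
    """

    generate: bool = True
    input_csv: str | None = None
    dgp: dict = field(default_factory=dict)
    trim_total: float = 0.02
    min_age: int = 45
    rank_scope: str = "pooled"
    marginal_mode: str = "calculus"
    outcomes: list = field(default_factory=lambda: list(OUTCOMES))
    decompose_waves: list | None = None
    min_group_n: int = 30
    seed: int | None = None
    out_dir: str = "ineqdecomp_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if bool(self.generate) == (self.input_csv is not None):
            raise ConfigurationError(
                "exactly one of generate=True or input_csv must be specified")
        if not 0 <= self.trim_total < 0.5:
            raise ConfigurationError("trim_total must be in [0, 0.5)")
        if self.rank_scope not in {"pooled", "within_wave"}:
            raise ConfigurationError("rank_scope must be 'pooled' or 'within_wave'")
        if self.marginal_mode not in {"calculus", "discrete"}:
            raise ConfigurationError("marginal_mode must be calculus or discrete")
        for o in self.outcomes:
            if o not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {o!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def analysis_dict(self) -> dict:
        """Config without run-location metadata (used for hashing/manifest),
        so identical analyses written to different directories produce
        byte-identical bundles."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def dgp_config(self) -> synth_mod.DGPConfig:
        cfg = synth_mod.DGPConfig.from_dict(self.dgp) if self.dgp \
            else synth_mod.DGPConfig()
        if self.seed is not None:
            cfg = cfg.replace(seed=int(self.seed))
        return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def load_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"wave": str, "person_id": str})
    if "wave" not in df.columns:
        raise DataError("cohort CSV must contain a 'wave' column")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in SNAPSHOT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def fixture_chi2_report() -> pd.DataFrame:
    """Recompute the chi-squared statistic of every shipped printed table."""
    rows = []
    for name, fx in synth_mod.load_fixture_tables().items():
        table = desc_mod.ContingencyTable(
            fx.row_variable, fx.col_variable, fx.row_labels, fx.col_labels,
            fx.counts)
        test = desc_mod.chi_squared(table)
        rows.append({
            "table": name,
            "printed_chi2": fx.printed_chi2,
            "computed_chi2": round(test.statistic, 3),
            "df": test.df,
            "p_value": test.p_value,
            "match_3dp": bool(abs(round(test.statistic, 3) - fx.printed_chi2) < 5e-4),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Any stage error aborts with the failing stage named; outputs written by
    earlier stages are preserved in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.analysis_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "generate/load"
    try:
        if config.generate:
            raw = synth_mod.generate_cohort(config.dgp_config())
            write_cohort_csv(raw, out / "cohort_raw.csv")
        else:
            raw = load_cohort_csv(config.input_csv)
        manifest["stages"]["input_records"] = len(raw)

        stage = "prepare"
        included = cohort_mod.apply_inclusion(raw, config.min_age)
        manifest["stages"]["after_inclusion"] = len(included)
        trimmed = cohort_mod.trim_expenditure(included, config.trim_total)
        manifest["stages"]["after_trimming"] = len(trimmed)
        prepared = cohort_mod.assign_quintiles(trimmed)
        write_cohort_csv(prepared, out / "cohort_prepared.csv")
        manifest["stages"]["per_wave"] = (
            prepared["wave"].value_counts().sort_index().astype(int).to_dict())

        stage = "describe"
        char_vars = ["disability_type", "gender", "age_band",
                     "self_rated_health", "chronic_disease", "adl_limited",
                     "iadl_limited", "expenditure_quintile", "smoking",
                     "drinking", "married", "education", "social_activity",
                     "child_support", "region", "insured"]
        char = desc_mod.characteristics_tables(prepared, char_vars, "wave")
        rows = []
        for v, (table, test) in char.items():
            pct = table.margin_percentages
            for i, lev in enumerate(table.row_labels):
                for j, wv in enumerate(table.col_labels):
                    rows.append({"variable": v, "level": lev, "wave": wv,
                                 "count": int(table.counts[i, j]),
                                 "percent": round(float(pct[i, j]), 1),
                                 "chi2": round(test.statistic, 3) if test else np.nan,
                                 "df": test.df if test else np.nan,
                                 "p_value": test.p_value if test else np.nan})
        _write(pd.DataFrame(rows), out / "table_characteristics.csv")
        util = desc_mod.utilization_table(prepared, outcomes=config.outcomes)
        _write(desc_mod.utilization_frame(util), out / "table_utilization.csv")

        stage = "regress"
        n_models = 0
        for outcome in config.outcomes:
            for with_dis in (False, True):
                spec = models_mod.ModelSpec(outcome=outcome, link="logit",
                                            include_disability_type=with_dis)
                res = models_mod.fit(prepared, spec)
                tab = res.table()
                tab["n_used"] = res.n_used
                tab["mcfadden_r2"] = res.pseudo_r2
                suffix = "_with_disability" if with_dis else ""
                _write(tab, out / f"regression_{outcome}{suffix}.csv")
                n_models += 1
        manifest["stages"]["regressions_fitted"] = n_models

        stage = "concentration index"
        complete = prepared[prepared["expenditure"].notna()]
        manifest["stages"]["rank_sample"] = len(complete)
        for outcome in config.outcomes:
            groups = ineq_mod.inequality_by_group(
                complete, outcome, by=["wave", "disability_type"],
                min_n=config.min_group_n)
            _write(groups.round(6), out / f"ci_hi_{outcome}.csv")
            use = complete[complete[outcome].notna()]
            res = ineq_mod.concentration_index(
                use[outcome].astype(float).to_numpy(),
                expenditure=use["expenditure"].to_numpy(float))
            _write(pd.DataFrame(res.curve, columns=["population_share",
                                                    "outcome_share"]).round(8),
                   out / f"curve_{outcome}.csv")

        stage = "decompose"
        waves = config.decompose_waves
        if waves is None:
            wv = sorted(prepared["wave"].dropna().unique().astype(str))
            waves = [wv[0], wv[-1]] if len(wv) > 1 else wv
        for outcome in config.outcomes:
            for wave in waves:
                sub = prepared[prepared["wave"] == str(wave)]
                dec = ineq_mod.WagstaffDecomposition(
                    sub, outcome, marginal_mode=config.marginal_mode).fit()
                tab = dec.table.copy().round(6)
                _write(tab, out / f"decomposition_{outcome}_{wave}.csv")
                agg = dec.by_factor().round(6)
                summary = pd.DataFrame([
                    {"variable": "<total CI>", "role": "", "contribution": dec.total.estimate,
                     "contribution_rate": 100.0},
                    {"variable": "<residual>", "role": "", "contribution": dec.residual,
                     "contribution_rate": (100 * dec.residual / dec.total.estimate
                                           if dec.total.estimate else np.nan)},
                    {"variable": "<HI>", "role": "", "contribution": dec.hi,
                     "contribution_rate": np.nan},
                ]).round(6)
                _write(pd.concat([agg, summary], ignore_index=True),
                       out / f"decomposition_{outcome}_{wave}_by_factor.csv")
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs kept in %s",
                     stage, out)
        raise
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True, default=str)
    return manifest
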