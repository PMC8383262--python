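"""Long-format CSV ingestion, study configuration, and the end-to-end driver.

The exchange format for observed data is a long CSV with columns
``unit,group,variable,condition,time,value`` (UTF-8, missing values blank or
``NA``).  ``run_study`` reproduces the shape of a two-window monitoring
analysis: per-variable repeated-measures permutation tests across the two
condition windows, and per-window multivariate + per-variable
independent-groups FANOVA across the station groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import FunctionalSample, RawSeries, make_bspline_basis
from .homogeneity import mfanova_pipeline
from .mfpca import assemble_multivariate
from .repeated import RepeatedMeasuresFANOVA, PairedFunctionalSample

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "StudyConfig",
    "read_long_csv",
    "write_long_csv",
    "run_study",
    "report_to_tsv",
]

REQUIRED_COLUMNS = ("unit", "group", "variable", "condition", "time", "value")

_NA_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A"}


class SchemaError(ValueError):
    """Input table does not match the required long-format schema."""


@dataclass
class StudyConfig:
    """Settings of a two-window, grouped monitoring study."""

    conditions: list[str] | None = None       # order of the two windows
    variables: list[str] | None = None        # subset/order of variables
    group_map: dict | None = None             # unit -> group label override
    n_basis: int = 20
    order: int = 4
    n_perm: int = 2000
    alpha: float = 0.05
    threshold: float = 0.99
    grid_size: int = 1001
    seed: int | None = None
    statistics: tuple[str, ...] = ("cn", "dn", "en")
    test: str = "both"
    daily_average: bool = False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "statistics" in raw:
            raw["statistics"] = tuple(raw["statistics"])
        return cls(**raw)

    def echo(self) -> dict:
        return {
            "conditions": self.conditions,
            "variables": self.variables,
            "n_basis": self.n_basis,
            "order": self.order,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "grid_size": self.grid_size,
            "seed": self.seed,
            "statistics": list(self.statistics),
            "test": self.test,
            "daily_average": self.daily_average,
        }


def read_long_csv(path) -> list[RawSeries]:
    """Parse a long-format CSV into one RawSeries per (unit, variable, condition).

    Times are normalized to [0, 1] per condition window (over the window's
    global time range so all units share a common normalized domain).
    Duplicate timestamps within a series keep the last value, with a warning.
    """
    df = pd.read_csv(path, dtype={c: str for c in ("unit", "group", "variable", "condition")})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    raw_vals = df["value"].astype(str).str.strip()
    is_na = df["value"].isna() | raw_vals.isin(_NA_TOKENS)
    values = pd.to_numeric(df["value"].where(~is_na), errors="coerce")
    bad = (~is_na) & values.isna()
    if bad.any():
        first = df.loc[bad].iloc[0]
        raise SchemaError(
            f"non-numeric value {first['value']!r} "
            f"(unit={first['unit']}, variable={first['variable']})"
        )
    df = df.assign(_value=values, time=pd.to_numeric(df["time"], errors="raise"))

    windows = {
        cond: (float(sub["time"].min()), float(sub["time"].max()))
        for cond, sub in df.groupby("condition")
    }

    out: list[RawSeries] = []
    for (unit, var, cond), sub in df.groupby(["unit", "variable", "condition"], sort=True):
        sub = sub.sort_values("time", kind="stable")
        dup = sub["time"].duplicated(keep="last")
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} duplicate timestamps for "
                f"(unit={unit}, variable={var}, condition={cond}); keeping last",
                RuntimeWarning,
                stacklevel=2,
            )
            sub = sub[~dup]
        lo, hi = windows[cond]
        span = hi - lo if hi > lo else 1.0
        times = sub["time"].to_numpy(dtype=float)
        out.append(
            RawSeries(
                unit_id=str(unit),
                group_label=str(sub["group"].iloc[0]),
                condition_label=str(cond),
                variable_name=str(var),
                times=times,
                values=sub["_value"].to_numpy(dtype=float),
                times_norm=(times - lo) / span,
            )
        )
    return out


def write_long_csv(series: list[RawSeries], path) -> None:
    """Write RawSeries back to the long CSV exchange format."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "unit": s.unit_id,
                    "group": s.group_label,
                    "variable": s.variable_name,
                    "condition": s.condition_label,
                    "time": s.times,
                    "value": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _daily_average(series: RawSeries) -> RawSeries:
    """Aggregate sub-daily samples to daily means (floor of the time stamp)."""
    day = np.floor(series.times)
    days = np.unique(day)
    vals = np.array(
        [np.nanmean(series.values[day == d]) if np.any(np.isfinite(series.values[day == d])) else np.nan
         for d in days]
    )
    lo, hi = series.times_norm.min(), series.times_norm.max()
    span = hi - lo if hi > lo else 1.0
    norm = np.array([series.times_norm[day == d].mean() for d in days])
    return RawSeries(
        unit_id=series.unit_id,
        group_label=series.group_label,
        condition_label=series.condition_label,
        variable_name=series.variable_name,
        times=days,
        values=vals,
        times_norm=(norm - lo) / span,
    )


def _index_series(series: list[RawSeries]):
    idx: dict[tuple[str, str, str], RawSeries] = {}
    for s in series:
        idx[(s.unit_id, s.variable_name, s.condition_label)] = s
    return idx


def run_study(config: StudyConfig, series: list[RawSeries]) -> dict:
    """Two-window grouped study: repeated-measures and group FANOVA reports.

    Returns a JSON-serializable dict with a ``repeated`` table (one row per
    variable, permutation p-values of the chosen statistics across the two
    windows) and a ``groups`` table per window (rows = "all variables" plus
    each variable separately).  Failures are recorded per cell rather than
    aborting the report.
    """
    if config.daily_average:
        series = [_daily_average(s) for s in series]

    conditions = config.conditions or sorted({s.condition_label for s in series})
    if len(conditions) != 2:
        raise ValueError(f"exactly two condition windows required, got {conditions}")
    variables = config.variables or sorted({s.variable_name for s in series})
    units = sorted({s.unit_id for s in series})
    group_map = config.group_map or {
        s.unit_id: s.group_label for s in series
    }

    basis = make_bspline_basis((0.0, 1.0), config.n_basis, config.order)
    idx = _index_series(series)
    root = np.random.SeedSequence(config.seed)
    seeds = iter(root.generate_state(2 * len(variables) + 2 * (len(variables) + 1)))

    report: dict = {
        "config": config.echo(),
        "conditions": conditions,
        "units": units,
        "groups": {u: group_map[u] for u in units},
        "repeated": {},
        "independent": {},
    }

    # (i) per-variable repeated-measures tests across the two windows
    samples: dict[tuple[str, str], FunctionalSample] = {}
    for var in variables:
        cell: dict = {}
        try:
            per_cond = []
            for cond in conditions:
                sl = [idx[(u, var, cond)] for u in units]
                per_cond.append(FunctionalSample.from_series(sl, basis))
            samples[(var, conditions[0])] = per_cond[0]
            samples[(var, conditions[1])] = per_cond[1]
            paired = PairedFunctionalSample.from_samples(
                per_cond[0], per_cond[1], tuple(conditions)
            )
            res = RepeatedMeasuresFANOVA(paired).fit(
                statistics=config.statistics,
                n_perm=config.n_perm,
                seed=int(next(seeds)),
                grid_size=config.grid_size,
            )
            cell = res.to_dict()
        except KeyError as exc:
            cell = {"error": f"missing series {exc}"}
        except Exception as exc:  # per-cell failure flag, not an abort
            cell = {"error": f"{type(exc).__name__}: {exc}"}
        report["repeated"][var] = cell

    # (ii) per-window independent-groups tests (multivariate + univariate)
    for cond in conditions:
        table: dict = {}
        labels = np.array([group_map[u] for u in units])
        per_var = {
            var: samples.get((var, cond)) for var in variables
        }
        try:
            mv_vars = [per_var[v] for v in variables]
            if any(v is None for v in mv_vars):
                raise ValueError("one or more variables failed to smooth")
            mv = assemble_multivariate(mv_vars, group_labels=labels)
            res = mfanova_pipeline(
                mv,
                threshold=config.threshold,
                test=config.test,
                alpha=config.alpha,
                n_perm=config.n_perm,
                seed=int(next(seeds)),
            )
            table["all variables"] = _homogeneity_cell(res)
        except Exception as exc:
            table["all variables"] = {"error": f"{type(exc).__name__}: {exc}"}
        for var in variables:
            try:
                if per_var[var] is None:
                    raise ValueError("smoothing failed for this variable")
                mv = assemble_multivariate([per_var[var]], group_labels=labels)
                res = mfanova_pipeline(
                    mv,
                    threshold=config.threshold,
                    test=config.test,
                    alpha=config.alpha,
                    n_perm=config.n_perm,
                    seed=int(next(seeds)),
                )
                table[var] = _homogeneity_cell(res)
            except Exception as exc:
                table[var] = {"error": f"{type(exc).__name__}: {exc}"}
        report["independent"][cond] = table
    return report


def _homogeneity_cell(res) -> dict:
    return {
        "q": res.q,
        "explained": res.explained,
        "multivariate_p": res.multivariate_p,
        "multivariate_statistic": res.multivariate_statistic,
        "anova_family_p": res.anova_family_p,
        "corrected_alpha": res.corrected_alpha,
        "exhaustive": res.exhaustive,
        "per_component": [
            {
                "component": c.component,
                "F": c.f_statistic,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in res.per_component
        ],
        "group_sizes": {str(k): v for k, v in res.group_sizes.items()},
    }


def report_to_tsv(report: dict) -> dict[str, str]:
    """Flatten a study report into TSV tables (repeated + one per window)."""
    out = {}
    rep_rows = ["variable\tstatistic\tobserved\tp_value\texhaustive"]
    for var, cell in report["repeated"].items():
        if "error" in cell:
            rep_rows.append(f"{var}\tERROR\t{cell['error']}\t\t")
            continue
        for stat, r in cell.items():
            rep_rows.append(
                f"{var}\t{stat}\t{r['observed']:.6g}\t{r['p_value']:.4f}\t{r['exhaustive']}"
            )
    out["repeated"] = "\n".join(rep_rows) + "\n"
    for cond, table in report["independent"].items():
        rows = ["row\tq\tmultivariate_p\tanova_family_p"]
        for name, cell in table.items():
            if "error" in cell:
                rows.append(f"{name}\tERROR\t{cell['error']}\t")
                continue
            mp = cell["multivariate_p"]
            ap = cell["anova_family_p"]
            rows.append(
                f"{name}\t{cell['q']}\t"
                f"{'' if mp is None else format(mp, '.4f')}\t"
                f"{'' if ap is None else format(ap, '.4f')}"
            )
        out[f"independent_{cond}"] = "\n".join(rows) + "\n"
    return out


def save_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
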