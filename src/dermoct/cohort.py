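"""Cohort-level aggregation and statistics for multi-group OCT studies.

Volumes belong to one of three groups — NC (normal culture), UV (irradiated)
and UV+VC (irradiated, vitamin-C-supplemented medium) — observed on days 1-4
(day 1 = before irradiation, one 3 J/cm^2 UVA dose per subsequent cycle).
Per-volume parameters (mean thickness, cuticle thickness, Sa, ASM, COR, mean
scattering coefficient) are summarized as group mean +/- SD, normalized to
the same-day NC mean where applicable, compared across groups with Welch's
heteroscedastic one-way ANOVA (morphology) and Welch t-tests (scattering /
optical density), and related to external covariates with Pearson
correlation.  Significance is two-sided at alpha = 0.05 with no
multiple-testing correction (a Holm option exists but is off by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DermoctError, ValidationError

__all__ = [
    "GROUPS",
    "ManifestEntry",
    "CohortManifest",
    "WelchAnovaResult",
    "percent_change",
    "normalize_to_baseline",
    "welch_anova",
    "welch_t_test",
    "pearson_fit",
    "build_report",
    "write_report",
]

GROUPS = ("NC", "UV", "UV+VC")
BASELINE_GROUP = "NC"
ALPHA = 0.05


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    group: str
    day: int
    replicate: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if self.day not in (1, 2, 3, 4):
            raise ValidationError("day must be in 1..4")


@dataclass
class CohortManifest:
    """List of volumes with group/day/replicate labels.

    ``dose_per_cycle`` is the UVA dose per irradiation cycle in J/cm^2;
    cumulative dose on day ``d`` is ``(d - 1) * dose_per_cycle``.
    """

    entries: list[ManifestEntry] = field(default_factory=list)
    dose_per_cycle: float = 3.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("manifest must contain at least one entry")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        d = json.loads(Path(path).read_text())
        entries = [ManifestEntry(**e) for e in d["entries"]]
        return cls(entries=entries, dose_per_cycle=d.get("dose_per_cycle", 3.0))

    def to_json(self, path: str | Path) -> None:
        d = {
            "dose_per_cycle": self.dose_per_cycle,
            "entries": [vars(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(d, indent=2))


class WelchAnovaResult(NamedTuple):
    F: float
    df1: float
    df2: float
    p: float


class WelchTResult(NamedTuple):
    t: float
    df: float
    p: float


class PearsonFit(NamedTuple):
    r: float
    slope: float
    intercept: float


def percent_change(reference: float, value: float) -> float:
    """``100 * (value - reference) / reference`` (reported to 1 decimal in
    tables; the exact value is returned here)."""
    if reference == 0:
        raise ValidationError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def normalize_to_baseline(
    df: pd.DataFrame,
    value_col: str = "value",
    baseline_group: str = BASELINE_GROUP,
) -> pd.DataFrame:
    """Divide each value by the same-day mean of the baseline group.

    ``df`` needs columns ``group``, ``day`` and ``value_col``.  The baseline
    group's normalized mean is 1 on every day by construction; the operation
    is invariant to any global rescaling of the raw values.
    """
    df = df.copy()
    base = (
        df[df["group"] == baseline_group]
        .groupby("day")[value_col]
        .mean()
    )
    missing = sorted(set(df["day"]) - set(base.index))
    if missing:
        raise DermoctError(f"missing baseline group on day(s) {missing}")
    if (base <= 0).any():
        raise DermoctError("baseline mean must be positive")
    df["normalized"] = df[value_col] / df["day"].map(base)
    return df


def welch_anova(*groups: Sequence[float]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Uses the Welch (1951) statistic: with ``w_j = n_j / s_j^2``,
    ``F* = sum w_j (xbar_j - xtilde)^2 / (k-1)`` over
    ``1 + 2(k-2)/(k^2-1) * sum h_j`` with
    ``h_j = (1 - w_j / sum w)^2 / (n_j - 1)``, compared against an F
    distribution with ``df1 = k-1`` and ``df2 = (k^2-1) / (3 sum h_j)``.
    For two groups this reduces to the squared Welch t statistic.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    for a in arrs:
        if a.size < 2:
            raise ValidationError("each group needs n >= 2")
        if a.var(ddof=1) == 0:
            raise ValidationError("each group needs positive variance")
    k = len(arrs)
    n = np.array([a.size for a in arrs], dtype=np.float64)
    m = np.array([a.mean() for a in arrs])
    v = np.array([a.var(ddof=1) for a in arrs])
    w = n / v
    sw = w.sum()
    grand = (w * m).sum() / sw
    h = (1 - w / sw) ** 2 / (n - 1)
    sh = h.sum()
    num = (w * (m - grand) ** 2).sum() / (k - 1)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * sh
    F = num / den
    df1 = float(k - 1)
    df2 = float((k**2 - 1) / (3 * sh))
    p = float(sps.f.sf(F, df1, df2))
    return WelchAnovaResult(F=float(F), df1=df1, df2=df2, p=p)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchTResult:
    """Two-sided Welch (unpooled-variance) t-test."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return WelchTResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValidationError("degenerate samples with zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchTResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def pearson_fit(x: Sequence[float], y: Sequence[float]) -> PearsonFit:
    """Pearson correlation with the accompanying OLS line."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need n >= 3 paired samples")
    if x.var() == 0 or y.var() == 0:
        raise ValidationError("zero variance: correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    lr = sps.linregress(x, y)
    return PearsonFit(r=r, slope=float(lr.slope), intercept=float(lr.intercept))


def _group_summaries(params: pd.DataFrame) -> pd.DataFrame:
    g = (
        params.groupby(["parameter", "group", "day"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    base = g[g["group"] == BASELINE_GROUP].set_index(["parameter", "day"])["mean"]

    def _norm(row):
        key = (row["parameter"], row["day"])
        if key in base.index and base[key] > 0:
            return row["mean"] / base[key]
        return np.nan

    g["normalized_mean"] = g.apply(_norm, axis=1)
    return g.sort_values(["parameter", "day", "group"]).reset_index(drop=True)


def _vc_inhibition_candidates(summ: pd.DataFrame) -> dict:
    """Candidate definitions of the VC cuticle-thickening inhibition.

    No single formula applied to the group means reproduces a unique
    published figure, so all candidates are reported and none asserted.
    """
    try:
        cut = summ[summ["parameter"] == "mean_cuticle_um"].set_index(["group", "day"])
        nc = cut.loc[("NC", 4), "mean"]
        uv = cut.loc[("UV", 4), "mean"]
        vc = cut.loc[("UV+VC", 4), "mean"]
    except KeyError:
        return {}
    out = {
        "excess_over_nc_reduction_pct": 100.0 * (uv - vc) / (uv - nc) if uv != nc else np.nan,
        "relative_day4_reduction_pct": 100.0 * (uv - vc) / uv,
    }
    base = cut["mean"].get(("NC", 1))
    if base is not None and not np.isnan(base):
        out["growth_reduction_pct"] = 100.0 * ((uv - base) - (vc - base)) / (uv - base)
    return out


def build_report(
    manifest: CohortManifest,
    params: pd.DataFrame,
    anova_parameters: Sequence[str] = (
        "mean_thickness_um",
        "mean_cuticle_um",
        "sa_um",
    ),
    ttest_parameters: Sequence[str] = ("mean_mu_mm1",),
) -> dict:
    """Assemble summary tables from per-volume parameters.

    ``params`` has one row per (volume, parameter): columns ``path``,
    ``group``, ``day``, ``parameter``, ``value``.  Returns a dict with:

    * ``summary`` — group x day x parameter grid (mean, sd, n, normalized);
    * ``percent_change`` — day-4 group means against the day-1 grand mean
      and UV/UV+VC against same-day NC;
    * ``tests`` — Welch ANOVA across groups per day (morphology) and Welch
      t-tests day 4 vs day 1 (scattering-like parameters);
    * ``incomplete`` — manifest entries missing any parameter (never
      silently dropped);
    * ``vc_inhibition_candidates`` — alternative inhibition definitions.
    Ordering is deterministic throughout.
    """
    required = {"path", "group", "day", "parameter", "value"}
    if not required.issubset(params.columns):
        raise ValidationError(f"params needs columns {sorted(required)}")
    expected = {(e.path, e.group, e.day) for e in manifest.entries}
    have = set(zip(params["path"], params["group"], params["day"]))
    incomplete = sorted(str(p) for (p, g, d) in expected - have)

    summary = _group_summaries(params)

    pc_rows = []
    for param in sorted(params["parameter"].unique()):
        sub = summary[summary["parameter"] == param]
        day1 = params[(params["parameter"] == param) & (params["day"] == 1)]
        ref_day1 = day1["value"].mean() if len(day1) else np.nan
        for _, row in sub[sub["day"] == sub["day"].max()].iterrows():
            if np.isfinite(ref_day1) and ref_day1 != 0:
                pc_rows.append(
                    {
                        "parameter": param,
                        "comparison": f"{row['group']}-day{row['day']} vs day1",
                        "percent_change": round(
                            percent_change(ref_day1, row["mean"]), 1
                        ),
                    }
                )
        last = sub[sub["day"] == sub["day"].max()].set_index("group")
        if BASELINE_GROUP in last.index:
            nc_mean = last.loc[BASELINE_GROUP, "mean"]
            for grp in last.index:
                if grp == BASELINE_GROUP or nc_mean == 0:
                    continue
                pc_rows.append(
                    {
                        "parameter": param,
                        "comparison": f"{grp} vs NC (day {int(last.loc[grp, 'day'])})",
                        "percent_change": round(
                            percent_change(nc_mean, last.loc[grp, "mean"]), 1
                        ),
                    }
                )
    percent_changes = pd.DataFrame(pc_rows)

    test_rows = []
    for param in anova_parameters:
        sub = params[params["parameter"] == param]
        for day in sorted(sub["day"].unique()):
            samples = [
                sub[(sub["group"] == g) & (sub["day"] == day)]["value"].to_numpy()
                for g in GROUPS
                if len(sub[(sub["group"] == g) & (sub["day"] == day)]) >= 2
            ]
            if len(samples) < 2:
                continue
            try:
                res = welch_anova(*samples)
            except ValidationError:
                continue
            test_rows.append(
                {
                    "parameter": param,
                    "test": "welch_anova",
                    "day": day,
                    "statistic": res.F,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                    "significant": res.p < ALPHA,
                }
            )
    for param in ttest_parameters:
        sub = params[params["parameter"] == param]
        for grp in GROUPS:
            a = sub[(sub["group"] == grp) & (sub["day"] == 1)]["value"].to_numpy()
            b = sub[(sub["group"] == grp) & (sub["day"] == sub["day"].max())][
                "value"
            ].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            try:
                res = welch_t_test(a, b)
            except ValidationError:
                continue
            test_rows.append(
                {
                    "parameter": param,
                    "test": "welch_t",
                    "day": int(sub["day"].max()),
                    "group": grp,
                    "statistic": res.t,
                    "df1": res.df,
                    "df2": np.nan,
                    "p": res.p,
                    "significant": res.p < ALPHA,
                }
            )
    tests = pd.DataFrame(test_rows)

    return {
        "summary": summary,
        "percent_change": percent_changes,
        "tests": tests,
        "incomplete": incomplete,
        "vc_inhibition_candidates": _vc_inhibition_candidates(summary),
    }


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the report tables as CSV plus a JSON overview."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("summary", "percent_change", "tests"):
        df = report[key]
        if isinstance(df, pd.DataFrame):
            df.to_csv(out_dir / f"{key}.csv", index=False)
    overview = {
        "incomplete": report["incomplete"],
        "vc_inhibition_candidates": report["vc_inhibition_candidates"],
        "percent_change": report["percent_change"].to_dict(orient="records")
        if isinstance(report["percent_change"], pd.DataFrame)
        else [],
    }
    (out_dir / "report.json").write_text(json.dumps(overview, indent=2, default=float))
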