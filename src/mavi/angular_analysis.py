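"""Angle-sensitivity statistics for vegetation indices.

Quantifies how each index responds to the view zenith angle:
nadir-relative change profiles and extreme-angle amplitudes, one-way
ANOVA across VZA groups, Pearson correlation with LAI per angle within
sub-datasets, and the DR angular-stability statistic
``DR = (max − min)/mean`` over a set of correlation coefficients —
smaller DR means the index-LAI relationship is more stable across
angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mavi.errors import DataError, UndefinedStatisticError
from mavi.spectral_core import MultiAngleDataset, SampleRecord

log = logging.getLogger(__name__)

_MEAN_TOL = 1e-12

#: Default sub-dataset filters for the stability report.  Stage slices
#: isolate phenology; the treatment slices isolate one experimental
#: factor by conditioning on the other (nitrogen gradient within the
#: unmulched plots; coverage contrast at the middle nitrogen level).
DEFAULT_SUB_DATASETS: dict[str, Callable[[SampleRecord], bool]] = {
    "budding": lambda rec: rec.stage == "budding",
    "flowering": lambda rec: rec.stage == "flowering",
    "n_rates": lambda rec: rec.coverage == "NM",
    "overlay": lambda rec: rec.nitrogen == "N2",
}


def amplitude_vs_nadir(vi_theta: float, vi_nadir: float, tol: float = 1e-12) -> float:
    """Percent change of an index value at an off-nadir angle relative to
    its nadir value: ``100*(vi_theta − vi_nadir)/vi_nadir``."""
    if abs(vi_nadir) < tol:
        raise UndefinedStatisticError(f"nadir value {vi_nadir!r} within tolerance of zero")
    return 100.0 * (vi_theta - vi_nadir) / vi_nadir


def oneway_f(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA.

    Returns ``(F, df_between, df_within, p)`` with
    ``F = MS_between / MS_within``.  When both between- and within-group
    variance vanish (all values identical) F is defined as 0.
    """
    if len(groups) < 2:
        raise DataError(f"need at least 2 groups; got {len(groups)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise DataError(f"group {i} has {a.size} value(s); need at least 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0.0:
        if ss_between <= 0.0:
            return 0.0, df_between, df_within, 1.0
        raise UndefinedStatisticError("zero within-group variance with unequal means: F undefined")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), df_between, df_within, p


def significance_stars(p: float) -> str:
    """Star coding at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; raises on zero variance in either input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError(f"need equal-length inputs of size >= 3; got {x.size}, {y.size}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def correlation_by_angle(
    vitable: pd.DataFrame,
    metadata: Mapping[str, SampleRecord],
    index: str,
    subset: Callable[[SampleRecord], bool] | None = None,
) -> pd.Series:
    """Pearson r(index value, LAI) per VZA within a metadata-filtered
    sub-dataset.  Signed r is reported (no absolute value)."""
    keep = {sid for sid, rec in metadata.items() if subset is None or subset(rec)}
    sub = vitable[(vitable["index"] == index) & vitable["sample_id"].isin(keep)]
    if sub.empty:
        raise DataError(f"no rows for index {index!r} in the requested subset")
    out = {}
    for vza, group in sub.groupby("vza_deg"):
        group = group.dropna(subset=["value"])
        if len(group) < 3:
            raise DataError(f"fewer than 3 defined samples at VZA {vza} for index {index!r}")
        lai = np.array([metadata[sid].lai for sid in group["sample_id"]])
        out[float(vza)] = pearson_r(group["value"].to_numpy(), lai)
    return pd.Series(out, name=index).sort_index()


def dr_statistic(r_values: Sequence[float], tol: float = _MEAN_TOL) -> float:
    """DR = (max − min)/mean of correlation coefficients; DR >= 0, equal
    to 0 iff all values coincide, and scale-invariant for positive
    scalings."""
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        raise DataError("empty value list")
    mean = r.mean()
    if abs(mean) < tol:
        raise UndefinedStatisticError(f"mean {mean!r} within tolerance of zero")
    return float((r.max() - r.min()) / mean)


def r_profile_summary(r_values: Sequence[float]) -> dict[str, float]:
    """Max / min / mean / DR of a per-angle correlation profile."""
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        raise DataError("empty value list")
    return {
        "r_max": float(r.max()),
        "r_min": float(r.min()),
        "r_mean": float(r.mean()),
        "dr": dr_statistic(r),
    }


@dataclass
class StabilityReport:
    """Assembled angle-sensitivity tables for a set of indices.

    ``amplitudes`` — per index: percent change vs nadir at the extreme
    angles; ``profiles`` — mean normalized difference vs nadir per VZA;
    ``anova`` — F over all VZAs and over the forward subset, with dfs,
    p-values and star codes; ``r_by_angle`` — signed Pearson r(VI, LAI)
    per VZA per sub-dataset; ``dr`` — DR per (index, sub-dataset).
    """

    amplitudes: pd.DataFrame
    profiles: pd.DataFrame
    anova: pd.DataFrame
    r_by_angle: pd.DataFrame
    dr: pd.DataFrame

    def ranking(self, sub_dataset: str) -> pd.DataFrame:
        """Indices ranked by (|DR| ascending, mean |r| descending).

        |DR| = spread relative to the magnitude of the mean; the absolute
        value guards against profiles with a negative mean r, whose raw
        DR is negative and would otherwise spuriously rank first.
        """
        sub = self.dr[self.dr["sub_dataset"] == sub_dataset].copy()
        if sub.empty:
            raise DataError(f"unknown sub-dataset {sub_dataset!r}")
        sub["abs_dr"] = sub["dr"].abs()
        sub["abs_r_mean"] = sub["r_mean"].abs()
        return (
            sub.sort_values(["abs_dr", "abs_r_mean"], ascending=[True, False])
            .drop(columns=["abs_dr", "abs_r_mean"])
            .reset_index(drop=True)
        )

    def to_dir(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.amplitudes.to_csv(out / "amplitudes.csv", index=False)
        self.profiles.to_csv(out / "profiles.csv", index=False)
        self.anova.to_csv(out / "anova.csv", index=False)
        self.r_by_angle.to_csv(out / "r_by_angle.csv", index=False)
        self.dr.to_csv(out / "dr.csv", index=False)


FORWARD_VZAS = (30.0, 45.0, 60.0)


def stability_report(
    vitable: pd.DataFrame,
    metadata: Mapping[str, SampleRecord],
    sub_datasets: Mapping[str, Callable[[SampleRecord], bool]] | None = None,
    nadir_vza: float = 0.0,
    extreme_vzas: tuple[float, float] = (-60.0, 60.0),
) -> StabilityReport:
    """Build the full angle-sensitivity report from an index table.

    Amplitudes and profiles are computed on the per-VZA mean index value
    across samples; ANOVA groups per-sample values by VZA (full set and
    the forward subset); correlations use all samples passing each
    sub-dataset filter.  Requires nadir observations.
    """
    if sub_datasets is None:
        sub_datasets = DEFAULT_SUB_DATASETS
    vzas = sorted(vitable["vza_deg"].unique())
    if nadir_vza not in vzas:
        raise DataError(f"no nadir ({nadir_vza} deg) observations in the index table")
    index_names = sorted(vitable["index"].unique())

    amp_rows, prof_rows, anova_rows, r_rows, dr_rows = [], [], [], [], []
    for name in index_names:
        sub = vitable[vitable["index"] == name].dropna(subset=["value"])
        mean_by_vza = sub.groupby("vza_deg")["value"].mean()
        nadir_mean = mean_by_vza[nadir_vza]
        amp = {}
        for vza in vzas:
            try:
                amp[vza] = amplitude_vs_nadir(mean_by_vza[vza], nadir_mean)
            except UndefinedStatisticError:
                amp[vza] = float("nan")
            prof_rows.append(
                {"index": name, "vza_deg": vza, "normalized_difference": amp[vza] / 100.0}
            )
        amp_rows.append(
            {
                "index": name,
                "amplitude_minus60_pct": amp.get(extreme_vzas[0], float("nan")),
                "amplitude_plus60_pct": amp.get(extreme_vzas[1], float("nan")),
            }
        )

        wide = sub.pivot(index="sample_id", columns="vza_deg", values="value").dropna()
        for label, group_vzas in (("full", vzas), ("forward", [v for v in FORWARD_VZAS if v in vzas])):
            if len(group_vzas) < 2 or len(wide) < 2:
                continue
            groups = [wide[v].to_numpy() for v in group_vzas]
            try:
                f_stat, dfb, dfw, p = oneway_f(groups)
            except UndefinedStatisticError:
                f_stat, dfb, dfw, p = float("nan"), len(group_vzas) - 1, -1, float("nan")
            anova_rows.append(
                {
                    "index": name,
                    "design": label,
                    "f_value": f_stat,
                    "df_between": dfb,
                    "df_within": dfw,
                    "p_value": p,
                    "stars": significance_stars(p) if np.isfinite(p) else "",
                }
            )

        for sub_name, predicate in sub_datasets.items():
            try:
                r = correlation_by_angle(vitable, metadata, name, predicate)
            except (DataError, UndefinedStatisticError) as exc:
                log.warning("r_by_angle skipped for %s / %s: %s", name, sub_name, exc)
                continue
            for vza, value in r.items():
                r_rows.append(
                    {"index": name, "sub_dataset": sub_name, "vza_deg": vza, "r": value}
                )
            summary = r_profile_summary(r.to_numpy())
            dr_rows.append({"index": name, "sub_dataset": sub_name, **summary})

    return StabilityReport(
        amplitudes=pd.DataFrame(amp_rows),
        profiles=pd.DataFrame(prof_rows),
        anova=pd.DataFrame(anova_rows),
        r_by_angle=pd.DataFrame(r_rows),
        dr=pd.DataFrame(dr_rows),
    )
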