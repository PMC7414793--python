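"""Hierarchical aggregation of FLIM parameters and group statistics.

The unit of biological replication is the sample (dish or animal), not
the pixel: per-pixel parameters are averaged to field-of-view (FOV)
means, ~20 FOV means are averaged (unweighted) to one value per sample
and compartment, and hypothesis tests run on the per-sample means only.
Passing pixel- or FOV-level tables to :func:`compare_groups` raises —
the guard against pseudoreplication.

Tests offered: paired and unpaired (Student's) t-tests, one-way ANOVA,
and classical repeated-measures ANOVA (sphericity assumed, no
correction).  No multiple-testing correction is applied: each comparison
is a single planned test at ``alpha`` (default 0.05).

``a1`` is carried in percent throughout these tables (column
``mean_a1_pct``), matching the conventional "a1[%]" reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decay_model import DomainError, GridMismatchError
from .fitting import FlimMaps
from .segmentation import BACKGROUND, MICROGLIA, NON_MICROGLIA, CompartmentMask

__all__ = [
    "FOV_COLUMNS",
    "SAMPLE_COLUMNS",
    "ComparisonResult",
    "UnitOfAnalysisError",
    "DesignError",
    "summarize_fov",
    "summarize_sample",
    "summarize_group",
    "compare_groups",
]

FOV_COLUMNS = [
    "group",
    "sample_id",
    "fov_id",
    "compartment",
    "mean_taum",
    "mean_a1_pct",
    "n_pixels",
]
SAMPLE_COLUMNS = [
    "group",
    "sample_id",
    "compartment",
    "mean_taum",
    "mean_a1_pct",
    "n_fovs",
]

_COMPARTMENT_NAMES = {
    MICROGLIA: "microglia",
    NON_MICROGLIA: "non_microglia",
    BACKGROUND: "background",
}
_PARAM_COLUMNS = {"taum": "mean_taum", "a1": "mean_a1_pct"}
_DESIGNS = ("paired_t", "students_t", "oneway_anova", "rm_anova")


class UnitOfAnalysisError(ValueError):
    """A test was requested on pixel- or FOV-level records."""


class DesignError(ValueError):
    """The comparison design does not match the data layout."""


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one group comparison on per-sample means."""

    test: str
    parameter: str
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    n_per_group: dict[str, int]
    alpha: float = 0.05
    significant: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "significant", bool(self.p_value < self.alpha))


def summarize_fov(
    maps: FlimMaps,
    compartments: CompartmentMask,
    sample_id: str = "s0",
    fov_id: str = "f0",
    group: str = "",
) -> pd.DataFrame:
    """Pixel-mean tau_m and a1 per non-empty compartment of one FOV.

    Means run over pixels that are both in the compartment and in the
    fit's ``valid_mask``; an empty compartment yields no record.
    """
    if maps.shape != compartments.labels.shape:
        raise GridMismatchError(
            f"maps shape {maps.shape} != compartment shape {compartments.labels.shape}"
        )
    records = []
    for code, name in _COMPARTMENT_NAMES.items():
        sel = (compartments.labels == code) & maps.valid_mask
        n = int(sel.sum())
        if n == 0:
            continue
        records.append(
            {
                "group": group,
                "sample_id": sample_id,
                "fov_id": fov_id,
                "compartment": name,
                "mean_taum": float(maps.taum[sel].mean()),
                "mean_a1_pct": float(maps.a1[sel].mean()) * 100.0,
                "n_pixels": n,
            }
        )
    return pd.DataFrame(records, columns=FOV_COLUMNS)


def summarize_sample(fovs: pd.DataFrame, pixel_weighted: bool = False) -> pd.DataFrame:
    """Roll FOV means up to one record per (group, sample, compartment).

    FOV means are averaged unweighted by default; ``pixel_weighted=True``
    weights each FOV by its pixel count instead.
    """
    missing = set(FOV_COLUMNS) - set(fovs.columns)
    if missing:
        raise DomainError(f"FOV table lacks columns {sorted(missing)}")
    if len(fovs) == 0:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)

    def agg(sub: pd.DataFrame) -> pd.Series:
        w = sub["n_pixels"].to_numpy(float) if pixel_weighted else None
        return pd.Series(
            {
                "mean_taum": np.average(sub["mean_taum"], weights=w),
                "mean_a1_pct": np.average(sub["mean_a1_pct"], weights=w),
                "n_fovs": len(sub),
            }
        )

    out = (
        fovs.groupby(["group", "sample_id", "compartment"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n_fovs"] = out["n_fovs"].astype(int)
    return out[SAMPLE_COLUMNS]


def summarize_group(samples: pd.DataFrame) -> pd.DataFrame:
    """Grand mean +/- SD over samples per (group, compartment)."""
    _require_sample_level(samples)
    return (
        samples.groupby(["group", "compartment"], sort=True)
        .agg(
            mean_taum=("mean_taum", "mean"),
            sd_taum=("mean_taum", "std"),
            mean_a1_pct=("mean_a1_pct", "mean"),
            sd_a1_pct=("mean_a1_pct", "std"),
            n_samples=("sample_id", "nunique"),
        )
        .reset_index()
    )


def _require_sample_level(samples: pd.DataFrame) -> None:
    if "fov_id" in samples.columns or "n_pixels" in samples.columns:
        raise UnitOfAnalysisError(
            "records are pixel- or FOV-level; aggregate with summarize_sample "
            "first — tests must run on biological replicates"
        )
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise DomainError(f"sample table lacks columns {sorted(missing)}")


def compare_groups(
    samples: pd.DataFrame,
    design: str,
    parameter: str = "taum",
    alpha: float = 0.05,
    compartment: str = "microglia",
) -> ComparisonResult:
    """Run the named test on per-sample means of one compartment.

    ``design`` is one of ``paired_t``, ``students_t``, ``oneway_anova``,
    ``rm_anova``.  Paired designs require every sample_id to appear in
    every group.  ``n`` in the result counts biological replicates.
    """
    _require_sample_level(samples)
    if design not in _DESIGNS:
        raise DesignError(f"unknown design {design!r}; choose from {_DESIGNS}")
    if parameter not in _PARAM_COLUMNS:
        raise DesignError(f"parameter must be one of {tuple(_PARAM_COLUMNS)}")
    col = _PARAM_COLUMNS[parameter]
    data = samples[samples["compartment"] == compartment]
    groups = sorted(data["group"].unique())
    if len(groups) < 2:
        raise DesignError(f"need >= 2 groups, found {groups}")
    values = {g: data.loc[data["group"] == g, col].to_numpy(float) for g in groups}
    for g, v in values.items():
        if len(v) < 2:
            raise DesignError(f"group {g!r} has fewer than 2 samples")

    if design in ("paired_t", "rm_anova"):
        wide = data.pivot_table(index="sample_id", columns="group", values=col)
        if wide.isna().any().any():
            raise DesignError(
                "paired/repeated designs require matched sample_ids across groups"
            )

    if design == "students_t":
        if len(groups) != 2:
            raise DesignError("students_t requires exactly 2 groups")
        stat, p = stats.ttest_ind(values[groups[0]], values[groups[1]], equal_var=True)
    elif design == "paired_t":
        if len(groups) != 2:
            raise DesignError("paired_t requires exactly 2 groups")
        a = wide[groups[0]].to_numpy(float)
        b = wide[groups[1]].to_numpy(float)
        stat, p = stats.ttest_rel(a, b)
    elif design == "oneway_anova":
        stat, p = stats.f_oneway(*(values[g] for g in groups))
    else:  # rm_anova: classical within-subject F, sphericity assumed
        from statsmodels.stats.anova import AnovaRM

        res = AnovaRM(
            data=data, depvar=col, subject="sample_id", within=["group"]
        ).fit()
        stat = float(res.anova_table["F Value"].iloc[0])
        p = float(res.anova_table["Pr > F"].iloc[0])

    return ComparisonResult(
        test=design,
        parameter=parameter,
        statistic=float(stat),
        p_value=float(p),
        group_means={g: float(v.mean()) for g, v in values.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in values.items()},
        n_per_group={g: int(len(v)) for g, v in values.items()},
        alpha=alpha,
    )
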