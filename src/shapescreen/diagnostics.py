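"""Per-well normalization and plate-artifact diagnostics.

Intensity read-outs in slide-based imaging assays carry background
(additive) and scale (multiplicative) artifacts from dye loading and
illumination, which make per-well means and variances erratic while
leaving the *shape* of the per-well distribution untouched.  This module
provides:

* ``normalize_distribution`` — subtract the mean, divide by the standard
  deviation (population convention), the operation that removes any
  affine artifact;
* ``distribution_moments`` — mean/variance plus the dimensionless shape
  measures skewness and kurtosis;
* ``anova_f`` — one-way ANOVA F comparing between- vs within-group
  variability of a per-well moment across rows, columns or slides (used
  descriptively, no p-value attached);
* ``rescale_convergence_check`` — compares replicate wells after a
  nonlinear pre-transform, which distinguishes affine artifacts (log
  breaks the equivalence when offsets differ) from purely multiplicative
  ones;
* ``partial_normalize`` — rescales a well to the average mean and
  variance of its eight nearest neighbors (the partial-normalization
  comparator for scoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDistributionError
from .ks import ks_statistic


@dataclass(frozen=True)
class MomentSummary:
    """First four moments of a per-well sample.

    ``skewness`` is m3 / m2^(3/2) and ``kurtosis`` is m4 / m2^2 (the
    non-excess Pearson convention; a normal distribution has kurtosis 3).
    Shape moments are ``nan``-flagged when the variance is zero or the
    sample is too small.
    """

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    groups: str = ""
    measure: str = ""


def normalize_distribution(values) -> np.ndarray:
    """Shift and rescale ``values`` to zero mean and unit variance.

    Uses the population standard deviation (ddof=0), which makes the
    operation exactly idempotent.  Raises
    :class:`DegenerateDistributionError` for constant input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateDistributionError(
            f"need at least 2 values to normalize, got {v.size}")
    sd = v.std()
    if sd == 0:
        raise DegenerateDistributionError("constant sample: sd = 0")
    return (v - v.mean()) / sd


def distribution_moments(values) -> MomentSummary:
    v = np.asarray(values, dtype=float)
    n = v.size
    mean = float(v.mean()) if n else float("nan")
    var = float(v.var()) if n else float("nan")
    skew = kurt = float("nan")
    if n >= 3 and var > 0:
        c = v - mean
        m2 = np.mean(c ** 2)
        skew = float(np.mean(c ** 3) / m2 ** 1.5)
        if n >= 4:
            kurt = float(np.mean(c ** 4) / m2 ** 2)
    return MomentSummary(mean=mean, variance=var, skewness=skew,
                         kurtosis=kurt, n=n)


def anova_f(values: Sequence[float], groups: Sequence,
            group_label: str = "", measure: str = "") -> AnovaResult:
    """One-way ANOVA F statistic for per-well summary ``values`` grouped
    by ``groups`` (e.g. slide rows).

    Groups with fewer than two members are dropped with a warning; fewer
    than two usable groups is an error.  When the within-group mean
    square is zero the F statistic is reported as ``nan`` (flagged
    degenerate) rather than infinite.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(groups)})
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(f"dropping {len(small)} group(s) with < 2 members")
        df = df[~df["group"].isin(small)]
    n_groups = df["group"].nunique()
    if n_groups < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    n = len(df)
    grand = df["value"].mean()
    agg = df.groupby("group")["value"].agg(["mean", "count"])
    ss_between = float((agg["count"] * (agg["mean"] - grand) ** 2).sum())
    merged = df.merge(agg["mean"].rename("gmean"), left_on="group",
                      right_index=True)
    ss_within = float(((merged["value"] - merged["gmean"]) ** 2).sum())
    df_b, df_w = n_groups - 1, n - n_groups
    ms_within = ss_within / df_w
    if ms_within == 0:
        f = float("nan")
    else:
        f = (ss_between / df_b) / ms_within
    return AnovaResult(f_statistic=f, df_between=df_b, df_within=df_w,
                       groups=group_label, measure=measure)


_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "log": np.log,
}


def _resolve_transform(transform):
    if callable(transform):
        return transform
    if transform == "log":
        return np.log
    if isinstance(transform, tuple) and transform[0] == "power":
        p = float(transform[1])
        return lambda v: np.power(v, p)
    raise ValueError(f"unknown transform {transform!r}")


def rescale_convergence_check(wells: Mapping[str, np.ndarray],
                              transform="log") -> pd.DataFrame:
    """Pairwise KS distance between normalized wells, with and without a
    nonlinear pre-transform.

    If the wells differ only by affine maps, plain normalization makes
    them identical (D at resampling-noise level) while a log or power
    pre-transform does not — unless the artifact is purely
    multiplicative, in which case log turns it into a shift that
    normalization removes.  The table of before/after D values supports
    exactly this diagnosis.
    """
    fn = _resolve_transform(transform)
    if fn in (np.log,) or (callable(transform) and transform is np.log):
        bad = [w for w, v in wells.items() if np.any(np.asarray(v) <= 0)]
        if transform == "log" and bad:
            raise ValueError(f"log transform requires positive values; "
                             f"offending wells: {bad}")
    names = list(wells)
    plain = {w: normalize_distribution(wells[w]) for w in names}
    trans = {w: normalize_distribution(fn(np.asarray(wells[w], dtype=float)))
             for w in names}
    rows = []
    for i, wa in enumerate(names):
        for wb in names[i + 1:]:
            rows.append({
                "well_a": wa,
                "well_b": wb,
                "d_normalized": ks_statistic(plain[wa], plain[wb]).d,
                "d_transformed": ks_statistic(trans[wa], trans[wb]).d,
            })
    return pd.DataFrame(rows)


def neighbor_wells(position: tuple[int, int],
                   positions: Mapping[str, tuple[int, int]]) -> list[str]:
    """Well ids in the Chebyshev ring of radius 1 around ``position``
    (up to 8; fewer at slide edges and corners)."""
    r0, c0 = position
    return [w for w, (r, c) in positions.items()
            if max(abs(r - r0), abs(c - c0)) == 1]


def partial_normalize(wells: Mapping[str, np.ndarray],
                      positions: Mapping[str, tuple[int, int]],
                      target_well: str) -> np.ndarray:
    """Linearly transform ``target_well`` so its mean and variance equal
    the averages of its 8-neighborhood's means and variances.

    Edge and corner wells use their existing 5 or 3 neighbors.  Raises if
    the target is degenerate or no neighbor has a valid (non-degenerate)
    sample.
    """
    if target_well not in wells:
        raise KeyError(target_well)
    v = np.asarray(wells[target_well], dtype=float)
    sd = v.std()
    if sd == 0:
        raise DegenerateDistributionError(
            f"target well {target_well!r} is constant")
    stats = []
    for w in neighbor_wells(positions[target_well], positions):
        nv = np.asarray(wells[w], dtype=float)
        if nv.size >= 2 and nv.std() > 0:
            stats.append((nv.mean(), nv.var()))
    if not stats:
        raise DegenerateDistributionError(
            f"no valid neighbors for well {target_well!r}")
    mean_t = float(np.mean([m for m, _ in stats]))
    var_t = float(np.mean([s for _, s in stats]))
    return (v - v.mean()) / sd * np.sqrt(var_t) + mean_t


def moment_anova_report(cell_table: pd.DataFrame, layout: pd.DataFrame,
                        features: Sequence[str],
                        groupings: Sequence[str] = ("row", "col"),
                        measures: Sequence[str] = ("mean", "variance",
                                                   "skewness", "kurtosis"),
                        ) -> pd.DataFrame:
    """Per-(slide, grouping, measure, feature) ANOVA F table.

    For each slide, per-well moments are computed for each feature and
    compared between vs within rows (or columns) — the positional
    artifact diagnostic.
    """
    pos = layout.set_index(["slide_id", "well_id"])
    records = []
    for (slide, well), grp in cell_table.groupby(["slide_id", "well_id"]):
        for feat in features:
            m = distribution_moments(grp[feat].to_numpy())
            records.append({"slide_id": slide, "well_id": well,
                            "feature": feat, "mean": m.mean,
                            "variance": m.variance, "skewness": m.skewness,
                            "kurtosis": m.kurtosis,
                            "row": pos.loc[(slide, well), "row"],
                            "col": pos.loc[(slide, well), "col"]})
    moments = pd.DataFrame(records)
    rows = []
    for (slide, feat), grp in moments.groupby(["slide_id", "feature"]):
        for grouping in groupings:
            for measure in measures:
                ok = grp[measure].notna()
                res = anova_f(grp.loc[ok, measure], grp.loc[ok, grouping],
                              group_label=grouping, measure=measure)
                rows.append({"slide_id": slide, "feature": feat,
                             "grouping": grouping, "measure": measure,
                             "f_statistic": res.f_statistic,
                             "df_between": res.df_between,
                             "df_within": res.df_within})
    return pd.DataFrame(rows)
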