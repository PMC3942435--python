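"""Shape-based per-slide scoring.

A well's score quantifies how far the *shape* of its per-cell feature
distribution deviates from the negative controls on the same slide.  The
procedure, per slide and feature:

1. preprocess every well according to the mode —
   ``N`` normalize to zero mean / unit variance (shape only),
   ``P`` partially normalize to the average mean and variance of the
   well's eight nearest neighbors,
   ``U`` leave the raw values untouched;
2. for each designated negative-control well, compute the scaled KS
   distance D* against every well on the slide, giving one row vector
   per negative;
3. standardize each row to zero mean and unit variance;
4. preliminary per-well Z = column mean over all negative rows;
5. hold out the ``n_holdout`` negatives with the highest preliminary Z
   ("worst-scoring" negatives) — they play no further part in scoring
   and serve downstream as an unbiased false-positive set;
6. re-form the matrix from the retained negatives, re-standardize rows,
   and report the final per-well Z as the column mean.

In mode ``N`` the score is invariant under per-well affine maps with
positive scale — the property that makes it robust to background and
gain artifacts.

A mean-based comparator, :func:`traditional_zscore`, scores a well by
the squared standardized deviation of its mean from the slide average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import normalize_distribution, partial_normalize
from .errors import DegenerateDistributionError
from .ks import d_star_matrix
from .simulate import ScreenDataset

MODES = ("N", "P", "U")


@dataclass
class SlideScores:
    """Per-well scores for one (slide, feature, mode).

    ``z`` is indexed by well id; ``held_out`` lists the negative wells
    removed before forming the final matrix; ``matrix`` is the
    row-standardized retained-negatives x wells D* matrix (``None`` for
    the traditional score); ``excluded`` lists degenerate wells dropped
    from scoring.
    """

    slide_id: str
    feature: str
    mode: str
    z: pd.Series
    held_out: list[str] = field(default_factory=list)
    matrix: np.ndarray | None = None
    wells: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def _row_standardize(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (m - mu) / sd


def score_slide(well_values: Mapping[str, np.ndarray],
                negatives: Sequence[str],
                mode: str = "N",
                n_holdout: int = 10,
                positions: Mapping[str, tuple[int, int]] | None = None,
                slide_id: str = "", feature: str = "") -> SlideScores:
    """Score every well of one slide against its negative controls.

    ``well_values`` maps well id to the per-cell values of one feature;
    ``negatives`` names the designated negative-control wells.  Mode
    ``P`` additionally needs ``positions`` (well id -> (row, col)).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    negatives = [w for w in negatives]
    if len(negatives) < n_holdout + 2:
        raise ValueError(
            f"need at least {n_holdout + 2} negatives to hold out "
            f"{n_holdout}; got {len(negatives)}")
    if mode == "P" and positions is None:
        raise ValueError("mode P requires well positions")

    processed: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for w, v in well_values.items():
        v = np.asarray(v, dtype=float)
        try:
            if mode == "N":
                processed[w] = np.sort(normalize_distribution(v))
            elif mode == "P":
                processed[w] = np.sort(
                    partial_normalize(well_values, positions, w))
            else:
                if v.size < 2 or v.std() == 0:
                    raise DegenerateDistributionError(w)
                processed[w] = np.sort(v)
        except DegenerateDistributionError:
            excluded.append(w)
    neg_ok = [w for w in negatives if w in processed]
    if len(neg_ok) < n_holdout + 2:
        raise ValueError("too many degenerate negative wells")
    wells = sorted(processed)
    col_samples = [processed[w] for w in wells]

    def zscores(neg_list):
        m = d_star_matrix([processed[w] for w in neg_list], col_samples)
        m = _row_standardize(m)
        return m, m.mean(axis=0)

    _, z_prelim = zscores(neg_ok)
    prelim = pd.Series(z_prelim, index=wells)
    held_out = list(prelim.loc[neg_ok].sort_values(ascending=False)
                    .index[:n_holdout])
    retained = [w for w in neg_ok if w not in held_out]
    matrix, z_final = zscores(retained)
    z = pd.Series(np.nan, index=sorted(well_values), name="z")
    z.loc[wells] = z_final
    return SlideScores(slide_id=slide_id, feature=feature, mode=mode,
                       z=z, held_out=held_out, matrix=matrix, wells=wells,
                       excluded=excluded)


def traditional_zscore(well_values: Mapping[str, np.ndarray],
                       slide_id: str = "",
                       feature: str = "") -> SlideScores:
    """Mean-based comparator score.

    The signal s_i is the per-well mean; the score is
    (s_i - s_bar)^2 / Var(s) with s_bar and Var (population) taken over
    all wells of the slide.
    """
    wells = sorted(well_values)
    if len(wells) < 2:
        raise ValueError("need at least 2 wells")
    signal = np.array([np.mean(well_values[w]) for w in wells], dtype=float)
    var = signal.var()
    if var == 0:
        raise DegenerateDistributionError(
            "zero variance of per-well means across the slide")
    scores = (signal - signal.mean()) ** 2 / var
    return SlideScores(slide_id=slide_id, feature=feature,
                       mode="traditional",
                       z=pd.Series(scores, index=wells, name="z"))


def score_screen(dataset: ScreenDataset, feature: str, mode: str = "N",
                 n_holdout: int = 10) -> pd.DataFrame:
    """Score every slide of a screen for one feature.

    Returns a long table with columns slide_id, well_id, gene, role,
    replicate, feature, mode, z, held_out.
    """
    frames = []
    for slide_id in dataset.slide_ids():
        wells = dataset.wells(slide_id, feature)
        roles = dataset.roles(slide_id)
        negatives = list(roles[roles == "negative"].index)
        if mode == "traditional":
            ss = traditional_zscore(wells, slide_id=slide_id, feature=feature)
        else:
            ss = score_slide(wells, negatives, mode=mode,
                             n_holdout=n_holdout,
                             positions=dataset.positions(slide_id),
                             slide_id=slide_id, feature=feature)
        sub = dataset.layout[dataset.layout["slide_id"] == slide_id]
        frame = sub[["slide_id", "well_id", "gene", "role",
                     "replicate"]].copy()
        frame["feature"] = feature
        frame["mode"] = mode
        frame["z"] = frame["well_id"].map(ss.z)
        frame["held_out"] = frame["well_id"].isin(ss.held_out)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def gene_score_table(scores: pd.DataFrame, roles: Sequence[str] = ("test",),
                     ) -> pd.DataFrame:
    """Pivot a long score table to one row per gene with the replicate
    Z-scores as columns z1..zK.

    Only genes whose role is in ``roles`` are kept (controls have their
    own reporting paths).  Genes with missing replicates keep NaN
    columns; downstream consumers decide how to treat them.
    """
    sub = scores[scores["role"].isin(roles)]
    wide = sub.pivot_table(index="gene", columns="replicate", values="z")
    wide.columns = [f"z{int(c)}" for c in wide.columns]
    return wide
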