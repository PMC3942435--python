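"""Cell-state (classifier/output) analysis.

Shape changes under perturbation suggest that cells occupy distinct
hidden states that respond differently.  A candidate "classifier" is a
feature that (1) is itself unaffected by the perturbation and (2)
predicts the response of another ("output") feature.  Within each well,
cells are sorted into three classifier percentile windows
(A: 5-15%, B: 45-55%, C: 85-95%) and the mean output in each window
(m_A, m_B, m_C) defines the correlation score

    y = (m_A - m_B) / (m_B - m_C)

The per-pair summary is Delta-y: the median y over positive-control
wells minus the median over negative-control wells.  A near-zero
diagonal entry (feature against itself) marks a valid classifier; a
large off-diagonal |Delta-y| marks a state-dependent output.

``binned_response`` profiles the effect directly: cells are pooled,
split into five classifier percentile bins, and the mean output per bin
is compared between perturbed and unperturbed pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOWS = ((5.0, 15.0), (45.0, 55.0), (85.0, 95.0))


@dataclass(frozen=True)
class CellStateScore:
    m_a: float
    m_b: float
    m_c: float
    y: float
    valid: bool
    n: int


def classifier_score(classifier, output,
                     windows=DEFAULT_WINDOWS, min_cells: int = 30,
                     guard_rel: float = 1e-6) -> CellStateScore:
    """Correlation score y for one well.

    Percentiles are computed within the well.  The score is invalid when
    the well is too small, a window is empty, or the denominator
    |m_B - m_C| falls below ``guard_rel`` times the output sd (ratios of
    noise are meaningless).
    """
    c = np.asarray(classifier, dtype=float)
    o = np.asarray(output, dtype=float)
    if c.shape != o.shape:
        raise ValueError("classifier and output must be the same length")
    n = c.size
    means = []
    ok = n >= min_cells
    for lo, hi in windows:
        if n == 0:
            means.append(np.nan)
            ok = False
            continue
        qlo, qhi = np.percentile(c, [lo, hi])
        sel = (c >= qlo) & (c <= qhi)
        if not sel.any():
            means.append(np.nan)
            ok = False
        else:
            means.append(float(o[sel].mean()))
    m_a, m_b, m_c = means
    guard = guard_rel * (o.std() if n else 0.0)
    y = np.nan
    if ok and abs(m_b - m_c) > guard:
        y = (m_a - m_b) / (m_b - m_c)
    else:
        ok = False
    return CellStateScore(m_a=m_a, m_b=m_b, m_c=m_c, y=float(y),
                          valid=bool(ok), n=n)


def _well_frames(cell_table: pd.DataFrame):
    return {key: frame for key, frame in
            cell_table.groupby(["slide_id", "well_id"], sort=False)}


def _well_y_scores(frames, wells: pd.DataFrame, classifier: str,
                   output: str, min_cells: int = 30) -> np.ndarray:
    ys = []
    for key in zip(wells["slide_id"], wells["well_id"]):
        sub = frames.get(key)
        if sub is None:
            continue
        s = classifier_score(sub[classifier].to_numpy(),
                             sub[output].to_numpy(), min_cells=min_cells)
        if s.valid:
            ys.append(s.y)
    return np.asarray(ys)


@dataclass
class DeltaYMatrix:
    """Delta-y over candidate feature pairs (classifier rows, output
    columns); entries with fewer than ``min_wells`` valid wells on
    either side are NaN-masked."""

    delta: pd.DataFrame
    n_positive: pd.DataFrame
    n_negative: pd.DataFrame


def delta_y_matrix(cell_table: pd.DataFrame, layout: pd.DataFrame,
                   features: Sequence[str], min_wells: int = 3,
                   min_cells: int = 30,
                   positive_role: str = "positive",
                   negative_role: str = "negative") -> DeltaYMatrix:
    """Delta-y for every (classifier, output) pair of ``features``.

    Delta-y_ij = median y(i -> j) over positive-control wells minus the
    median over negative-control wells.  The matrix is not symmetric;
    the (i, j) and (j, i) entries are computed independently.
    """
    pos_wells = layout[layout["role"] == positive_role]
    neg_wells = layout[layout["role"] == negative_role]
    frames = _well_frames(cell_table)
    delta = pd.DataFrame(np.nan, index=list(features), columns=list(features))
    n_pos = pd.DataFrame(0, index=list(features), columns=list(features))
    n_neg = pd.DataFrame(0, index=list(features), columns=list(features))
    for ci in features:
        for oj in features:
            ypos = _well_y_scores(frames, pos_wells, ci, oj, min_cells)
            yneg = _well_y_scores(frames, neg_wells, ci, oj, min_cells)
            n_pos.loc[ci, oj] = ypos.size
            n_neg.loc[ci, oj] = yneg.size
            if ypos.size >= min_wells and yneg.size >= min_wells:
                delta.loc[ci, oj] = np.median(ypos) - np.median(yneg)
    return DeltaYMatrix(delta=delta, n_positive=n_pos, n_negative=n_neg)


def delta_y_with_permutation(cell_table: pd.DataFrame, layout: pd.DataFrame,
                             classifier: str, outputs: Sequence[str],
                             n_perm: int = 200, seed: int | None = None,
                             min_cells: int = 30,
                             ) -> pd.DataFrame:
    """Delta-y for one classifier against several outputs, with the 95th
    percentile of |Delta-y| under random reassignment of the
    positive/negative well labels.

    Per-well y values are computed once and only the labels are
    permuted, so the null preserves the full y distribution.
    """
    pos = layout[layout["role"] == "positive"]
    neg = layout[layout["role"] == "negative"]
    frames = _well_frames(cell_table)
    rng = np.random.default_rng(seed)
    rows = []
    for out in outputs:
        ypos = _well_y_scores(frames, pos, classifier, out, min_cells)
        yneg = _well_y_scores(frames, neg, classifier, out, min_cells)
        observed = float(np.median(ypos) - np.median(yneg))
        pool = np.concatenate([ypos, yneg])
        k = ypos.size
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pool)
            null[i] = np.median(perm[:k]) - np.median(perm[k:])
        rows.append({"classifier": classifier, "output": out,
                     "delta_y": observed,
                     "null_q95": float(np.percentile(np.abs(null), 95)),
                     "n_positive": int(ypos.size),
                     "n_negative": int(yneg.size)})
    return pd.DataFrame(rows)


@dataclass
class BinnedResponse:
    """Mean output per classifier percentile bin for the perturbed and
    unperturbed pools, plus the per-bin difference."""

    table: pd.DataFrame  # bin, lo, hi, mean_unperturbed, mean_perturbed,
    #                      diff, n_unperturbed, n_perturbed


def binned_response(unperturbed: tuple[np.ndarray, np.ndarray],
                    perturbed: tuple[np.ndarray, np.ndarray],
                    n_bins: int = 5) -> BinnedResponse:
    """Per-bin mean output over ``n_bins`` equal-width classifier
    percentile windows.

    Each argument is a (classifier values, output values) pair of pooled
    cells.  Bin edges come from the classifier percentiles of the
    combined pool, so the two pools are profiled on a common axis;
    ``n_bins=1`` reduces to the pooled mean difference.
    """
    cu, ou = (np.asarray(a, dtype=float) for a in unperturbed)
    cp, op = (np.asarray(a, dtype=float) for a in perturbed)
    if cu.size == 0 or cp.size == 0:
        raise ValueError("both pools must be non-empty")
    combined = np.concatenate([cu, cp])
    qs = np.percentile(combined, np.linspace(0, 100, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    rows = []
    for i in range(n_bins):
        in_u = (cu >= qs[i]) & (cu < qs[i + 1]) if i < n_bins - 1 \
            else (cu >= qs[i])
        in_p = (cp >= qs[i]) & (cp < qs[i + 1]) if i < n_bins - 1 \
            else (cp >= qs[i])
        mu = float(ou[in_u].mean()) if in_u.any() else np.nan
        mp = float(op[in_p].mean()) if in_p.any() else np.nan
        rows.append({"bin": i, "percentile_lo": 100 * i / n_bins,
                     "percentile_hi": 100 * (i + 1) / n_bins,
                     "mean_unperturbed": mu, "mean_perturbed": mp,
                     "diff": mp - mu, "n_unperturbed": int(in_u.sum()),
                     "n_perturbed": int(in_p.sum())})
    return BinnedResponse(table=pd.DataFrame(rows))
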