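"""Triplicate hit calling and screen-level reporting.

Each gene is assayed in triplicate, so it carries three Z-scores per
feature.  A gene is called a hit when at least two of its three scores
exceed the threshold (strictly; default threshold 3).  The triplicate
rule suppresses false positives: if each replicate independently
exceeds threshold with probability alpha under the null, the 2/3-rule
false-positive rate is 3*alpha^2*(1-alpha) + alpha^3.

The evidence that a screen contains reproducible hits is the
permutation band: gene labels are shuffled independently within each
replicate (preserving each replicate's Z-score multiset while breaking
triplicate coherence) and hits are re-called over a grid of thresholds;
observed counts rising above the band maximum signal genuine
reproducibility.

False-positive rates are estimated empirically from the held-out
negative wells excluded during scoring, and two reporting helpers
quantify biological signal in hit lists: overlap between hit sets
versus the independence expectation, and one-tailed Fisher enrichment
of annotation terms with a permutation-based family-wise correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_Z_COLS = ("z1", "z2", "z3")


def _score_matrix(scores) -> np.ndarray:
    """Coerce a gene score table (DataFrame with z1..z3 columns, or a
    (G, 3) array) to a float matrix."""
    if isinstance(scores, pd.DataFrame):
        cols = [c for c in scores.columns if c.startswith("z")]
        return scores[cols].to_numpy(dtype=float)
    return np.asarray(scores, dtype=float)


def call_hits(scores, threshold: float = 3.0,
              min_replicates: int = 2) -> pd.DataFrame:
    """Apply the 2/3 rule at ``threshold``.

    Returns a table with times_above, n_available and is_hit per gene.
    Genes with fewer than ``min_replicates`` usable (non-NaN) scores are
    excluded.  The comparison is strict (z > threshold).
    """
    m = _score_matrix(scores)
    index = scores.index if isinstance(scores, pd.DataFrame) \
        else pd.RangeIndex(m.shape[0])
    available = np.sum(~np.isnan(m), axis=1)
    times_above = np.nansum(m > threshold, axis=1).astype(int)
    out = pd.DataFrame({"times_above": times_above,
                        "n_available": available,
                        "is_hit": times_above >= 2,
                        "threshold": threshold}, index=index)
    usable = available >= min_replicates
    return out[usable]


def null_hit_fraction(alpha: float) -> float:
    """Closed-form 2/3-rule hit probability for a null gene whose
    replicates each exceed threshold independently with probability
    ``alpha``: 3*alpha^2*(1-alpha) + alpha^3."""
    return 3 * alpha ** 2 * (1 - alpha) + alpha ** 3


@dataclass
class PermutationBand:
    thresholds: np.ndarray
    observed: np.ndarray   # hit counts at each threshold
    lo: np.ndarray         # min over permutations
    hi: np.ndarray         # max over permutations
    n_permutations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "observed": self.observed,
                             "band_min": self.lo, "band_max": self.hi})


def permutation_band(scores, thresholds: Sequence[float],
                     n_perm: int = 1000, seed: int | None = None,
                     ) -> PermutationBand:
    """Null band of 2/3-rule hit counts from within-replicate label
    shuffles.

    Each permutation independently permutes each replicate's score
    column, then hits are recounted over the threshold grid; the band is
    the per-threshold min/max over ``n_perm`` permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m = _score_matrix(scores)
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 2:
        raise ValueError("need at least 2 complete triplicates")
    t = np.asarray(thresholds, dtype=float)
    rng = np.random.default_rng(seed)
    n_genes = m.shape[0]

    def counts(mat):
        above = mat[:, :, None] > t[None, None, :]
        return (above.sum(axis=1) >= 2).sum(axis=0)

    observed = counts(m)
    lo = np.full(t.size, np.iinfo(np.int64).max)
    hi = np.zeros(t.size, dtype=np.int64)
    for _ in range(n_perm):
        perm = np.column_stack([m[rng.permutation(n_genes), r]
                                for r in range(m.shape[1])])
        c = counts(perm)
        lo = np.minimum(lo, c)
        hi = np.maximum(hi, c)
    return PermutationBand(thresholds=t, observed=observed.astype(int),
                           lo=lo.astype(int), hi=hi.astype(int),
                           n_permutations=n_perm)


def fp_rate_heldout(scores: pd.DataFrame, threshold: float = 3.0) -> float:
    """Fraction of held-out negative-well Z-scores above ``threshold``,
    pooled across slides.

    ``scores`` is a long score table (as from
    :func:`shapescreen.scoring.score_screen`) with a ``held_out``
    column; a plain array of held-out scores is also accepted.
    """
    if isinstance(scores, pd.DataFrame):
        z = scores.loc[scores["held_out"], "z"].to_numpy(dtype=float)
    else:
        z = np.asarray(scores, dtype=float)
    z = z[~np.isnan(z)]
    if z.size == 0:
        raise ValueError("no held-out negative scores available")
    return float(np.mean(z > threshold))


def overlap_expected(set_a, set_b, universe) -> dict[str, float]:
    """Observed overlap of two hit sets and its independence
    expectation |A|*|B|/|U| (the hypergeometric mean)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    return {"observed": len(a & b),
            "expected": len(a) * len(b) / len(universe)}


def enrichment(hits, annotations: Mapping[str, str], universe,
               n_perm: int = 1000, seed: int | None = None,
               family_wise: bool = True) -> pd.DataFrame:
    """One-tailed Fisher enrichment of annotation terms among hits, with
    permutation-corrected p-values.

    ``annotations`` maps gene -> single most-specific term.  The raw
    p-value per term is the upper hypergeometric tail (equivalent to the
    one-tailed Fisher exact test on the 2x2 hit x term table).  The
    correction permutes term labels over the annotated genes ``n_perm``
    times; with ``family_wise=True`` the corrected p is the fraction of
    permutations whose *minimum* raw p over all terms is <= the term's
    observed raw p (add-one convention), otherwise each term is
    calibrated against its own permutation distribution.
    """
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    hits = set(hits) & uset
    genes = [g for g in universe if g in annotations]
    terms = pd.Series({g: annotations[g] for g in genes})
    skipped = sorted(set(annotations) - uset)
    n_universe, n_hits = len(universe), len(hits)

    def raw_pvalues(term_series: pd.Series) -> pd.Series:
        term_sizes = term_series.value_counts()
        in_hit = term_series[term_series.index.isin(hits)].value_counts()
        p = {}
        for term, m in term_sizes.items():
            a = int(in_hit.get(term, 0))
            p[term] = float(stats.hypergeom.sf(a - 1, n_universe, m, n_hits))
        return pd.Series(p)

    observed_p = raw_pvalues(terms)
    rng = np.random.default_rng(seed)
    labels = terms.to_numpy()
    if family_wise:
        min_ps = np.empty(n_perm)
        for i in range(n_perm):
            perm = pd.Series(rng.permutation(labels), index=terms.index)
            min_ps[i] = raw_pvalues(perm).min()
        corrected = {t: (1 + np.sum(min_ps <= p)) / (n_perm + 1)
                     for t, p in observed_p.items()}
    else:
        counts = {t: 0 for t in observed_p.index}
        for i in range(n_perm):
            perm = pd.Series(rng.permutation(labels), index=terms.index)
            pp = raw_pvalues(perm)
            for t in counts:
                if pp.get(t, 1.0) <= observed_p[t]:
                    counts[t] += 1
        corrected = {t: (1 + c) / (n_perm + 1) for t, c in counts.items()}
    out = pd.DataFrame({"p_raw": observed_p,
                        "p_corrected": pd.Series(corrected)})
    out.index.name = "term"
    out.attrs["skipped_genes"] = skipped
    return out.sort_values("p_raw")


def screen_hits(gene_tables: Mapping[str, pd.DataFrame],
                threshold: float = 3.0) -> set[str]:
    """Union hit set over features: a gene is a screen hit if it passes
    the 2/3 rule for at least one feature."""
    out: set[str] = set()
    for feature, table in gene_tables.items():
        calls = call_hits(table, threshold=threshold)
        out |= set(calls.index[calls["is_hit"]])
    return out
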