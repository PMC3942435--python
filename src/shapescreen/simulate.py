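"""Synthetic perturbation-screen generator.

The real screen this package targets measures single-cell features over
slides of 300 wells (10 rows x 30 columns), with 30 negative-control and
8 positive-control wells per slide, 200-500 cells per well, and every
slide assayed in triplicate with a scrambled well-to-gene assignment.
The raw imaging data are not available in machine-readable form, so this
module emulates the study design end-to-end: it produces per-cell
feature tables, slide layouts and a ground-truth table so that every
downstream stage (diagnostics, scoring, hit calling, power inference,
cell-state analysis) can be exercised and validated offline.

Feature families
----------------
* *intensity-like* features are right-skewed and continuous (gamma
  baseline) and are the ones hit by slide-positional artifacts;
* *geometry-like* features are narrow or discrete (Poisson counts or a
  narrow normal) and are left artifact-free, matching the observation
  that positional artifacts arise from dye loading and illumination,
  which do not affect geometric measurements.

Artifacts are affine per well: every cell value v in a well is mapped to
a*v + b, where the scale a (strictly positive, log-normal) and offset b
are sums/products of row, column and slide effects.  This is exactly the
artifact class that per-well mean/variance normalization removes.

Perturbations act on a gene-specific fraction of cells (the penetrance):
responding cells are redrawn from a shape-shifted distribution, the rest
stay at baseline.  Penetrance varies across hit genes (truncated-normal
distribution), which induces the spectrum of per-gene true-positive
rates that the power-inference module is designed to recover.  Positive
controls come in three tiers (strong/medium/weak penetrance), mirroring
control perturbations of differing strength.

Optionally the penetrance can be coupled to an unperturbed "cell state"
feature (``state_classifier``): responding cells are then the cells with
the largest classifier values rather than a uniform random subset, which
gives the cell-state analysis a recoverable classifier -> output
signature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError, FormatError

INTENSITY = "intensity"
GEOMETRY = "geometry"


def _sample_dist(params: Mapping[str, float], n: int,
                 rng: np.random.Generator) -> np.ndarray:
    dist = params["dist"]
    if dist == "gamma":
        return rng.gamma(params["shape"], params["scale"], size=n)
    if dist == "poisson":
        v = rng.poisson(params["lam"], size=n).astype(float)
        jitter = params.get("jitter", 0.0)
        if jitter:
            v += rng.normal(0.0, jitter, size=n)
        return v
    if dist == "normal":
        return rng.normal(params["loc"], params["scale"], size=n)
    if dist == "bimodal":
        side = rng.random(n) < params.get("weight", 0.5)
        loc, spread = params["loc"], params["spread"]
        return rng.normal(np.where(side, loc - spread, loc + spread),
                          params["sd"], size=n)
    if dist == "twopoint":
        v = np.where(rng.random(n) < params.get("weight", 0.5),
                     float(params["lo"]), float(params["hi"]))
        jitter = params.get("jitter", 0.0)
        if jitter:
            v = v + rng.normal(0.0, jitter, size=n)
        return v
    raise ConfigurationError(f"unknown distribution {dist!r}")


_KNOWN_DISTS = ("gamma", "poisson", "normal", "bimodal", "twopoint")


@dataclass(frozen=True)
class FeatureSpec:
    """One single-cell feature: its family, baseline distribution and
    the distribution responding cells are redrawn from.

    ``baseline`` and ``perturbed`` are parameter mappings with a
    ``dist`` key naming the family: ``gamma`` (shape, scale),
    ``poisson`` (lam, optional additive normal ``jitter`` emulating the
    sub-resolution measurement noise that smears integer counts in real
    geometric features), ``normal`` (loc, scale), ``bimodal`` (two
    normal modes at loc +/- spread with sd), or ``twopoint`` (lo/hi
    values, optional jitter).  ``perturbed=None`` marks a feature no
    perturbation touches (e.g. a cell-state classifier).

    The default perturbations are *shape-only*: the responding-cell
    distribution matches the baseline mean and variance but differs in
    skewness/kurtosis, so the normalized-shape distance between a hit
    well and baseline grows essentially linearly with penetrance (a
    location-shift perturbation would make the post-normalization
    distance non-monotone in penetrance).
    """

    name: str
    family: str
    baseline: Mapping[str, float]
    perturbed: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if self.family not in (INTENSITY, GEOMETRY):
            raise ConfigurationError(f"unknown feature family {self.family!r}")
        for params in (self.baseline, self.perturbed):
            if params is not None and params.get("dist") not in _KNOWN_DISTS:
                raise ConfigurationError(
                    f"unknown distribution {params.get('dist')!r}")

    def sample(self, n: int, rng: np.random.Generator,
               perturbed: bool = False) -> np.ndarray:
        params = self.perturbed if (perturbed and self.perturbed is not None) \
            else self.baseline
        return _sample_dist(params, n, rng)


def default_features() -> tuple[FeatureSpec, ...]:
    """Two-feature default: a right-skewed continuous intensity feature
    and a discrete geometry feature.

    Both perturbations preserve the baseline mean and variance (gamma(2)
    has mean 2, variance 2; the bimodal counterpart has modes 2 +/- 1.35
    with sd 0.4, variance ~1.98; Poisson(4) has mean and variance 4; the
    two-point counterpart {2, 6} has mean 4, variance 4) and act only on
    distribution shape.
    """
    return (
        FeatureSpec("I1", INTENSITY,
                    baseline={"dist": "gamma", "shape": 2.0, "scale": 1.0},
                    perturbed={"dist": "bimodal", "loc": 2.0,
                               "spread": 1.35, "sd": 0.4}),
        FeatureSpec("G1", GEOMETRY,
                    baseline={"dist": "poisson", "lam": 4.0, "jitter": 0.3},
                    perturbed={"dist": "twopoint", "lo": 2.0, "hi": 6.0,
                               "jitter": 0.3}),
    )


@dataclass(frozen=True)
class ArtifactSpec:
    """Magnitudes of the affine positional artifacts.

    Offsets are additive effects (raw feature units) drawn per row,
    column and slide; scales are multiplicative, drawn log-normally so
    they are strictly positive.  Artifacts apply to intensity-family
    features only.
    """

    row_offset_sd: float = 0.5
    col_offset_sd: float = 0.3
    slide_offset_sd: float = 0.5
    row_log_scale_sd: float = 0.15
    col_log_scale_sd: float = 0.10
    slide_log_scale_sd: float = 0.15

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    @property
    def enabled(self) -> bool:
        return any(v != 0.0 for v in dataclasses.astuple(self))


DEFAULT_POSITIVE_TIERS: tuple[tuple[str, int, float], ...] = (
    ("pos_strong", 3, 0.95),
    ("pos_medium", 3, 0.60),
    ("pos_weak", 2, 0.30),
)


@dataclass
class SimConfig:
    """Configuration for one synthetic screen.

    ``n_slides`` counts distinct slide *designs*; each design is assayed
    ``n_replicates`` times with an independently scrambled well-to-gene
    assignment, so a default screen of one design yields three physical
    slides sharing 262 test genes.
    """

    n_slides: int = 1
    n_replicates: int = 3
    n_rows: int = 10
    n_cols: int = 30
    n_negative: int = 30
    n_positive: int = 8
    cells_per_well: tuple[int, int] = (200, 500)
    features: tuple[FeatureSpec, ...] = field(default_factory=default_features)
    hit_fraction: float = 0.1
    penetrance_mean: float = 0.5
    penetrance_sd: float = 0.2
    positive_tiers: tuple[tuple[str, int, float], ...] = DEFAULT_POSITIVE_TIERS
    state_classifier: Optional[str] = None
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    rng_seed: int = 0

    @property
    def wells_per_slide(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_test(self) -> int:
        return self.wells_per_slide - self.n_negative - self.n_positive

    def validate(self) -> None:
        if self.n_slides < 1 or self.n_replicates < 1:
            raise ConfigurationError("need >= 1 slide design and replicate")
        if self.n_negative + self.n_positive > self.wells_per_slide:
            raise ConfigurationError(
                "control wells exceed slide capacity: "
                f"{self.n_negative}+{self.n_positive} > {self.wells_per_slide}")
        lo, hi = self.cells_per_well
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad cells_per_well range {lo}..{hi}")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ConfigurationError("hit_fraction must be in [0, 1]")
        if sum(n for _, n, _ in self.positive_tiers) != self.n_positive:
            raise ConfigurationError("positive tier counts must sum to "
                                     f"n_positive={self.n_positive}")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate feature names")
        if self.state_classifier is not None:
            if self.state_classifier not in names:
                raise ConfigurationError(
                    f"state_classifier {self.state_classifier!r} is not a "
                    "feature")


@dataclass
class ScreenDataset:
    """A complete synthetic screen.

    ``cell_table`` has one row per cell (slide_id, well_id, cell_id,
    one column per feature); ``layout`` one row per (slide, well) with
    position, gene, role and replicate; ``truth`` one row per test gene
    with hit status, penetrance and affected features.
    """

    cell_table: pd.DataFrame
    layout: pd.DataFrame
    truth: pd.DataFrame
    config: Optional[SimConfig] = None

    def slide_ids(self) -> list[str]:
        return list(self.layout["slide_id"].unique())

    def wells(self, slide_id: str, feature: str) -> dict[str, np.ndarray]:
        sub = self.cell_table[self.cell_table["slide_id"] == slide_id]
        return {w: g[feature].to_numpy(dtype=float)
                for w, g in sub.groupby("well_id", sort=True)}

    def roles(self, slide_id: str) -> pd.Series:
        sub = self.layout[self.layout["slide_id"] == slide_id]
        return sub.set_index("well_id")["role"]

    def positions(self, slide_id: str) -> dict[str, tuple[int, int]]:
        sub = self.layout[self.layout["slide_id"] == slide_id]
        return {w: (int(r), int(c)) for w, r, c in
                zip(sub["well_id"], sub["row"], sub["col"])}


def apply_affine_artifact(values, scale: float, offset: float) -> np.ndarray:
    """Map each value v to scale*v + offset (order preserved).

    ``scale`` must be strictly positive — the artifact class is
    background plus (positive) gain.
    """
    if scale <= 0:
        raise ValueError(f"artifact scale must be > 0, got {scale}")
    return np.asarray(values, dtype=float) * scale + offset


def _truncnorm(mean: float, sd: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws on [0, 1]."""
    if sd == 0:
        return np.full(size, np.clip(mean, 0.0, 1.0))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_screen(config: SimConfig) -> ScreenDataset:
    """Simulate a full screen from ``config``; deterministic given
    ``config.rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.cells_per_well
    feat_names = [f.name for f in config.features]
    intensity_feats = [f.name for f in config.features
                       if f.family == INTENSITY]
    classifier = config.state_classifier

    layout_rows = []
    truth_rows = []
    slide_frames = []

    for d in range(config.n_slides):
        # per-design gene panel: units of (gene, role, penetrance)
        units: list[tuple[str, str, float]] = []
        units += [(f"neg_{d:02d}_{i:02d}", "negative", 0.0)
                  for i in range(config.n_negative)]
        for tier, count, pen in config.positive_tiers:
            units += [(f"{tier}_{d:02d}_{i}", "positive", pen)
                      for i in range(count)]
        n_test = config.n_test
        test_genes = [f"g{d:02d}_{i:04d}" for i in range(n_test)]
        n_hits = int(round(config.hit_fraction * n_test))
        hit_idx = rng.choice(n_test, size=n_hits, replace=False)
        penetrance = np.zeros(n_test)
        if n_hits:
            penetrance[hit_idx] = _truncnorm(config.penetrance_mean,
                                             config.penetrance_sd,
                                             n_hits, rng)
        is_hit = np.zeros(n_test, dtype=bool)
        is_hit[hit_idx] = True
        affected = [f.name for f in config.features
                    if f.perturbed is not None and f.name != classifier]
        for g, hit, pen in zip(test_genes, is_hit, penetrance):
            units.append((g, "test", float(pen) if hit else 0.0))
            truth_rows.append({
                "gene": g, "is_hit": bool(hit),
                "penetrance": float(pen) if hit else 0.0,
                "affected_features": ";".join(affected) if hit else ""})

        for rep in range(1, config.n_replicates + 1):
            slide_id = f"S{d:02d}R{rep}"
            order = rng.permutation(len(units))
            cols: dict[str, list] = {k: [] for k in
                                     ("slide_id", "well_id", "cell_id")}
            fcols: dict[str, list] = {k: [] for k in feat_names}
            # positional artifact effects for this physical slide; the
            # draws are unconditional so the random stream (and hence
            # every cell value) is identical between artifact-on and
            # artifact-off configs at the same seed
            art = config.artifact
            b_row = rng.normal(0, art.row_offset_sd, config.n_rows)
            b_col = rng.normal(0, art.col_offset_sd, config.n_cols)
            b_slide = rng.normal(0, art.slide_offset_sd)
            l_row = rng.normal(0, art.row_log_scale_sd, config.n_rows)
            l_col = rng.normal(0, art.col_log_scale_sd, config.n_cols)
            l_slide = rng.normal(0, art.slide_log_scale_sd)

            for w, unit_i in enumerate(order):
                gene, role, pen = units[unit_i]
                r, c = divmod(w, config.n_cols)
                well_id = f"r{r + 1:02d}c{c + 1:02d}"
                layout_rows.append({"slide_id": slide_id, "well_id": well_id,
                                    "row": r + 1, "col": c + 1, "gene": gene,
                                    "role": role, "replicate": rep})
                n = int(rng.integers(lo, hi + 1))
                values = {f.name: f.sample(n, rng) for f in config.features}
                if pen > 0:
                    k = int(round(pen * n))
                    if k > 0:
                        if classifier is not None:
                            resp = np.argsort(values[classifier])[-k:]
                        else:
                            resp = rng.choice(n, size=k, replace=False)
                        for f in config.features:
                            if f.perturbed is None or f.name == classifier:
                                continue
                            values[f.name][resp] = f.sample(k, rng,
                                                            perturbed=True)
                if art.enabled:
                    a = float(np.exp(l_row[r] + l_col[c] + l_slide))
                    b = float(b_row[r] + b_col[c] + b_slide)
                    for name in intensity_feats:
                        values[name] = apply_affine_artifact(values[name],
                                                             a, b)
                cols["slide_id"] += [slide_id] * n
                cols["well_id"] += [well_id] * n
                cols["cell_id"] += list(range(n))
                for name in feat_names:
                    fcols[name].append(values[name])
            frame = pd.DataFrame({
                "slide_id": cols["slide_id"],
                "well_id": cols["well_id"],
                "cell_id": np.asarray(cols["cell_id"], dtype=int)})
            for name in feat_names:
                frame[name] = np.concatenate(fcols[name])
            slide_frames.append(frame)

    cell_table = pd.concat(slide_frames, ignore_index=True)
    layout = pd.DataFrame(layout_rows)
    truth = pd.DataFrame(truth_rows)
    return ScreenDataset(cell_table=cell_table, layout=layout, truth=truth,
                         config=config)


# ---------------------------------------------------------------------------
# score-level generator (for power-inference validation)

@dataclass
class TriplicateScoreSim:
    """Score-level synthetic screen: per-gene triplicate Z-scores drawn
    directly from the hit/negative mixture, plus held-out negative-well
    scores for empirical false-positive estimation."""

    scores: np.ndarray          # (n_genes, 3)
    is_hit: np.ndarray          # (n_genes,) bool
    fn_rates: np.ndarray        # per-gene FN rate at `threshold` (0 for negs)
    heldout_scores: np.ndarray  # (n_heldout,)
    threshold: float


def simulate_triplicate_scores(n_genes: int, hit_fraction: float,
                               fp_rate: float, fn_mean: float, fn_sd: float,
                               threshold: float = 3.0, n_heldout: int = 300,
                               seed: int | None = None,
                               ) -> TriplicateScoreSim:
    """Draw triplicate Z-scores from the generative model the
    power-inference module assumes.

    Negative genes score N(0, s^2) with s chosen so that
    P(Z > threshold) = ``fp_rate``.  Each hit gene g draws a
    false-negative rate beta_g from a truncated normal
    (``fn_mean``, ``fn_sd``) on [0, 1] and scores
    N(mu_g, s^2) with mu_g = threshold - s * Phi^-1(beta_g), so that at
    ``threshold`` its per-replicate miss probability is exactly beta_g.
    Held-out negative wells score from the negative distribution.
    """
    if not 0 < fp_rate < 1:
        raise ValueError("fp_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    s = threshold / stats.norm.ppf(1 - fp_rate)
    n_hits = int(round(hit_fraction * n_genes))
    is_hit = np.zeros(n_genes, dtype=bool)
    is_hit[rng.choice(n_genes, size=n_hits, replace=False)] = True
    fn = np.zeros(n_genes)
    fn[is_hit] = _truncnorm(fn_mean, fn_sd, n_hits, rng)
    mu = np.zeros(n_genes)
    with np.errstate(divide="ignore"):
        ppf = stats.norm.ppf(np.clip(fn[is_hit], 1e-12, 1 - 1e-12))
    mu[is_hit] = threshold - s * ppf
    scores = rng.normal(mu[:, None], s, size=(n_genes, 3))
    heldout = rng.normal(0.0, s, size=n_heldout)
    return TriplicateScoreSim(scores=scores, is_hit=is_hit, fn_rates=fn,
                              heldout_scores=heldout, threshold=threshold)


# ---------------------------------------------------------------------------
# on-disk round trip

_CELL_FILE = "cells.csv"
_LAYOUT_FILE = "layout.csv"
_TRUTH_FILE = "truth.csv"
_CONFIG_FILE = "config.yaml"

_ID_COLS = ["slide_id", "well_id", "cell_id"]
# row/col are optional: only partial normalization (mode P) needs them
_LAYOUT_COLS = ["slide_id", "well_id", "gene", "role", "replicate"]


def _config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["features"] = [dataclasses.asdict(f) for f in config.features]
    d["features"] = [{**f, "baseline": dict(f["baseline"]),
                      "perturbed": dict(f["perturbed"])
                      if f["perturbed"] is not None else None}
                     for f in d["features"]]
    d["cells_per_well"] = list(config.cells_per_well)
    d["positive_tiers"] = [list(t) for t in config.positive_tiers]
    return d


def _config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["features"] = tuple(FeatureSpec(**f) for f in d["features"])
    d["cells_per_well"] = tuple(d["cells_per_well"])
    d["positive_tiers"] = tuple(tuple(t) for t in d["positive_tiers"])
    d["artifact"] = ArtifactSpec(**d["artifact"])
    return SimConfig(**d)


def write_screen(dataset: ScreenDataset, path) -> None:
    """Write a screen as plain delimited text (full float precision)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.cell_table.to_csv(path / _CELL_FILE, index=False)
    dataset.layout.to_csv(path / _LAYOUT_FILE, index=False)
    dataset.truth.to_csv(path / _TRUTH_FILE, index=False)
    if dataset.config is not None:
        with open(path / _CONFIG_FILE, "w") as fh:
            yaml.safe_dump(_config_to_dict(dataset.config), fh,
                           sort_keys=False)


def read_screen(path) -> ScreenDataset:
    """Read a screen written by :func:`write_screen`, validating the
    schema (well coverage, uniqueness, numeric feature cells)."""
    path = Path(path)
    cells = pd.read_csv(path / _CELL_FILE)
    layout = pd.read_csv(path / _LAYOUT_FILE)
    truth = pd.read_csv(path / _TRUTH_FILE)
    truth["affected_features"] = truth["affected_features"].fillna("")
    missing = [c for c in _LAYOUT_COLS if c not in layout.columns]
    if missing:
        raise FormatError(f"layout is missing columns {missing}")
    dup = layout.duplicated(subset=["slide_id", "well_id"])
    if dup.any():
        row = layout[dup].iloc[0]
        raise FormatError("duplicate layout row for well "
                          f"{row['slide_id']}/{row['well_id']}")
    feat_cols = [c for c in cells.columns if c not in _ID_COLS]
    for col in feat_cols:
        numeric = pd.to_numeric(cells[col], errors="coerce")
        bad = numeric.isna() & cells[col].notna()
        if bad.any():
            raise FormatError(f"non-numeric value in feature {col!r} at "
                              f"row {int(bad.idxmax())}")
        cells[col] = numeric
    cell_wells = set(map(tuple, cells[["slide_id", "well_id"]]
                         .drop_duplicates().itertuples(index=False)))
    layout_wells = set(map(tuple, layout[["slide_id", "well_id"]]
                           .itertuples(index=False)))
    orphans = sorted(cell_wells - layout_wells)
    if orphans:
        raise FormatError(f"cell table wells missing from layout: "
                          f"{orphans[:5]}")
    config = None
    cfg_path = path / _CONFIG_FILE
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = _config_from_dict(yaml.safe_load(fh))
    return ScreenDataset(cell_table=cells, layout=layout, truth=truth,
                         config=config)
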