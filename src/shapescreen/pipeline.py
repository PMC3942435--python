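"""End-to-end orchestration of a screen analysis run.

A run either simulates a screen or loads one from disk, then executes
diagnostics -> scoring (all requested modes) -> hit calling with the
permutation band -> power inference, and optionally the cell-state
analysis.  Every output is a delimited text table under the run's
output directory, together with a machine-readable manifest recording
the configuration, the derived per-stage seeds and the package version.

One top-level seed deterministically derives independent per-stage
seeds (by hashing the stage name), so a stage can be re-run on its own
and reproduce the full-pipeline result exactly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_state import delta_y_with_permutation
from .diagnostics import moment_anova_report
from .errors import ConfigurationError
from .hits import call_hits, fp_rate_heldout, permutation_band
from .power import bins_from_scores, fit_power_model, tp_fp_curve
from .scoring import gene_score_table, score_screen
from .simulate import (ScreenDataset, SimConfig, _config_from_dict,
                       _config_to_dict, generate_screen, read_screen,
                       write_screen)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``simulate`` holds a :class:`SimConfig` to generate the screen;
    alternatively ``input_dir`` points at an existing screen written by
    :func:`shapescreen.simulate.write_screen`.  ``features`` of None
    means every feature found in the cell table.
    """

    out_dir: str = "shapescreen_run"
    simulate: Optional[SimConfig] = field(default_factory=SimConfig)
    input_dir: Optional[str] = None
    features: Optional[Sequence[str]] = None
    modes: Sequence[str] = ("N",)
    n_holdout: int = 10
    call_threshold: float = 3.0
    thresholds: Sequence[float] = tuple(np.arange(0.5, 6.01, 0.25))
    n_permutations: int = 1000
    run_diagnostics: bool = True
    run_power: bool = True
    cellstate_classifier: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = _config_from_dict(raw["simulate"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = (_config_to_dict(self.simulate)
                         if self.simulate is not None else None)
        d["features"] = list(self.features) if self.features else None
        d["modes"] = list(self.modes)
        d["thresholds"] = [float(t) for t in self.thresholds]
        return d


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the run
    seed and the stage name."""
    return (base_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all requested stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        dataset = read_screen(config.input_dir)
    elif config.simulate is not None:
        sim = dataclasses.replace(
            config.simulate,
            rng_seed=stage_seed(config.seed, "simulate"))
        dataset = generate_screen(sim)
        write_screen(dataset, out / "screen")
    else:
        raise ConfigurationError("either simulate or input_dir is required")

    feat_cols = [c for c in dataset.cell_table.columns
                 if c not in ("slide_id", "well_id", "cell_id")]
    features = list(config.features) if config.features else feat_cols
    unknown = set(features) - set(feat_cols)
    if unknown:
        raise ConfigurationError(f"unknown features requested: "
                                 f"{sorted(unknown)}")
    if any(m == "P" for m in config.modes) and \
            not {"row", "col"} <= set(dataset.layout.columns):
        raise ConfigurationError("mode P requires well positions "
                                 "(row/col) in the layout")

    manifest = {"version": __version__, "seed": config.seed,
                "config": config.to_dict(), "stage_seeds": {}}

    if config.run_diagnostics:
        report = moment_anova_report(dataset.cell_table, dataset.layout,
                                     features)
        report.to_csv(out / "diagnostics_anova.csv", index=False)

    all_scores = []
    gene_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for mode in config.modes:
        for feature in features:
            sc = score_screen(dataset, feature, mode=mode,
                              n_holdout=config.n_holdout)
            all_scores.append(sc)
            gene_tables[(feature, mode)] = gene_score_table(sc)
    scores = pd.concat(all_scores, ignore_index=True)
    scores.to_csv(out / "scores.csv", index=False)

    hit_frames, band_frames, power_frames, curve_frames = [], [], [], []
    for (feature, mode), table in gene_tables.items():
        calls = call_hits(table, threshold=config.call_threshold)
        calls = calls.assign(feature=feature, mode=mode)
        hit_frames.append(calls.reset_index())
        seed_b = stage_seed(config.seed, f"band:{feature}:{mode}")
        manifest["stage_seeds"][f"band:{feature}:{mode}"] = seed_b
        band = permutation_band(table, config.thresholds,
                                n_perm=config.n_permutations, seed=seed_b)
        band_frames.append(band.as_frame().assign(feature=feature,
                                                  mode=mode))
        if config.run_power:
            seed_p = stage_seed(config.seed, f"power:{feature}:{mode}")
            manifest["stage_seeds"][f"power:{feature}:{mode}"] = seed_p
            fit = fit_power_model(bins_from_scores(table,
                                                   config.thresholds),
                                  seed=seed_p)
            sub = scores[(scores["feature"] == feature)
                         & (scores["mode"] == mode)]
            fp_obs = fp_rate_heldout(sub, config.call_threshold)
            tab = fit.table.assign(feature=feature, mode=mode, h=fit.h,
                                   converged=fit.converged,
                                   fp_heldout_at_call=fp_obs)
            power_frames.append(tab)
            curve_frames.append(tp_fp_curve(fit).assign(feature=feature,
                                                        mode=mode))
    pd.concat(hit_frames, ignore_index=True).to_csv(out / "hits.csv",
                                                    index=False)
    pd.concat(band_frames, ignore_index=True).to_csv(
        out / "permutation_band.csv", index=False)
    if power_frames:
        pd.concat(power_frames, ignore_index=True).to_csv(
            out / "power_fit.csv", index=False)
        pd.concat(curve_frames, ignore_index=True).to_csv(
            out / "tp_fp_curve.csv", index=False)

    if config.cellstate_classifier:
        outputs = [f for f in features if f != config.cellstate_classifier]
        seed_c = stage_seed(config.seed, "cellstate")
        manifest["stage_seeds"]["cellstate"] = seed_c
        dy = delta_y_with_permutation(dataset.cell_table, dataset.layout,
                                      config.cellstate_classifier,
                                      outputs + [config.cellstate_classifier],
                                      seed=seed_c)
        dy.to_csv(out / "cellstate_delta_y.csv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
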