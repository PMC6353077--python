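"""End-to-end pipeline driver and report rendering.

``run_full_pipeline`` chains the three analysis stages — observer-error
screen, per-trait dimorphism table, cross-validation table — over a
measurement file and a dual-observer file, writing one CSV per stage plus
a JSON provenance record (seed, configuration hash, package version).
Reports carry both full-precision columns and display columns rounded the
way the field prints them (2 decimals for mm and D, 1 for percents).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .crossval import CrossValConfig, cross_validate
from .dimorphism import DimorphismStats, dimorphism_table
from .io import (
    MeasurementTable,
    ObserverTable,
    read_measurement_table,
    read_observer_table,
)
from .tem import DEFAULT_RTEM_THRESHOLD, screen_traits

__all__ = ["RunConfig", "run_full_pipeline", "render_distribution_plot"]


@dataclass(frozen=True)
class RunConfig:
    measurements: str
    observers: str
    out_dir: str
    seed: int = 0
    rtem_threshold: float = DEFAULT_RTEM_THRESHOLD
    train_fraction: float = 0.70
    reps: int = 1000
    bootstrap_reps: int = 1000

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _round_like_reports(df: pd.DataFrame, mm_cols: list[str], pct_cols: list[str],
                        d_cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in mm_cols + d_cols:
        if c in out:
            out[c + "_2dp"] = out[c].round(2)
    for c in pct_cols:
        if c in out:
            out[c + "_1dp"] = out[c].round(1)
    return out


def run_full_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run screen → dimorphism → cross-validation and write the reports.

    Returns the paths of the four artifacts written under ``out_dir``.
    Any stage failure aborts with a stage-named error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    try:
        table = read_measurement_table(config.measurements)
        observers = read_observer_table(config.observers)
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc

    try:
        screen = screen_traits(observers, config.rtem_threshold)
        screen_df = screen.to_frame()
        screen_df["seed"] = config.seed
        paths["error_screen"] = out_dir / "error_screen.csv"
        _round_like_reports(screen_df, ["mean_mm", "tem_mm"], ["rtem_percent"], []).to_csv(
            paths["error_screen"], index=False
        )
    except Exception as exc:
        raise RuntimeError(f"observer-error stage failed: {exc}") from exc

    try:
        usable = [t for t in screen.retained if t in table.trait_codes]
        dim = dimorphism_table(table, traits=usable,
                               bootstrap_reps=config.bootstrap_reps, seed=config.seed)
        dim_df = dim.to_frame()
        dim_df["seed"] = config.seed
        paths["dimorphism"] = out_dir / "dimorphism.csv"
        _round_like_reports(
            dim_df,
            ["male_mean_mm", "female_mean_mm", "male_sd_mm", "female_sd_mm", "cutoff_mm"],
            [], ["D", "D_sd"],
        ).to_csv(paths["dimorphism"], index=False)
    except Exception as exc:
        raise RuntimeError(f"dimorphism stage failed: {exc}") from exc

    try:
        cv_rows = []
        cv_config = CrossValConfig(
            train_fraction=config.train_fraction, reps=config.reps, seed=config.seed
        )
        for s in dim.stats:
            try:
                cv = cross_validate(table, s.trait, cv_config)
            except Exception:
                continue
            cv_rows.append(
                {
                    "trait": cv.trait,
                    "accuracy_mean": cv.accuracy_mean,
                    "accuracy_sd": cv.accuracy_sd,
                    "precision_male_mean": cv.precision_male_mean,
                    "precision_female_mean": cv.precision_female_mean,
                    "train_n": cv.train_n,
                    "test_n": cv.test_n,
                    "cutoff_mean_mm": cv.cutoff_mean,
                    "cutoff_sd_mm": cv.cutoff_sd,
                    "reps_used": cv.reps_used,
                }
            )
        cv_df = pd.DataFrame(cv_rows)
        cv_df["seed"] = config.seed
        paths["crossval"] = out_dir / "crossval.csv"
        _round_like_reports(
            cv_df, ["cutoff_mean_mm", "cutoff_sd_mm"],
            ["accuracy_mean", "accuracy_sd", "precision_male_mean", "precision_female_mean"],
            [],
        ).to_csv(paths["crossval"], index=False)
    except Exception as exc:
        raise RuntimeError(f"cross-validation stage failed: {exc}") from exc

    provenance = {
        "package": "cremsex",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    paths["provenance"] = out_dir / "provenance.json"
    paths["provenance"].write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return paths


def render_distribution_plot(stats: DimorphismStats, path=None):
    """Two fitted sex-specific normal curves with the cut-off marked.

    Returns the matplotlib figure; writes it to ``path`` when given. The
    vertical marker line is placed at the computed cut-off and labelled
    with D and its SD.
    """
    m, f = stats.male, stats.female
    # degenerate (constant) traits are drawn as a narrow spike rather than failing
    sd_m = max(m.sd, 1e-3)
    sd_f = max(f.sd, 1e-3)
    lo = min(m.mean - 4 * sd_m, f.mean - 4 * sd_f)
    hi = max(m.mean + 4 * sd_m, f.mean + 4 * sd_f)
    x = np.linspace(lo, hi, 512)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, sps.norm.pdf(x, f.mean, sd_f), color="crimson",
            label=f"F (n={f.n}, {f.mean:.2f}±{f.sd:.2f} mm)")
    ax.plot(x, sps.norm.pdf(x, m.mean, sd_m), color="steelblue",
            label=f"M (n={m.n}, {m.mean:.2f}±{m.sd:.2f} mm)")
    if np.isfinite(stats.cutoff):
        ax.axvline(stats.cutoff, color="black", linestyle="--", linewidth=1,
                   label=f"x0 = {stats.cutoff:.2f} mm")
    d_txt = f"D = {stats.D:.3f}" + (f" (sd {stats.D_sd:.2f})" if stats.D_sd is not None else "")
    ax.set_title(f"{stats.trait}: {d_txt}")
    ax.set_xlabel("measurement (mm)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
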