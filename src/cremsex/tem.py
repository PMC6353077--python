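"""Inter-observer technical error of measurement (TEM) and trait screening.

For two observers measuring the same N individuals, the absolute
technical error of measurement is

    TEM = sqrt( sum_i d_i^2 / (2 N) ),   d_i = observer1_i − observer2_i,

in mm, and the relative TEM is RTEM = 100·TEM / MEAN, where MEAN is the
mean of the two observers' means over the same individuals. Traits whose
RTEM reaches the acceptance threshold (default 5%) are excluded from all
downstream dimorphism analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ObserverTable, ValidationError

__all__ = ["ErrorEstimate", "ScreenResult", "tem", "rtem", "screen_traits", "screen_estimates"]

DEFAULT_RTEM_THRESHOLD = 5.0  # percent


@dataclass(frozen=True)
class ErrorEstimate:
    """TEM/RTEM summary for one trait."""

    trait: str
    grand_mean: float  # mean of the two observers' means, mm
    tem: float  # mm
    rtem: float  # percent
    n_pairs: int
    retained: bool


@dataclass(frozen=True)
class ScreenResult:
    retained: list[str]
    excluded: list[str]
    estimates: list[ErrorEstimate]
    failed: dict[str, str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": e.trait,
                    "n_pairs": e.n_pairs,
                    "mean_mm": e.grand_mean,
                    "tem_mm": e.tem,
                    "rtem_percent": e.rtem,
                    "retained": e.retained,
                }
                for e in self.estimates
            ]
        )


def tem(pairs: np.ndarray | pd.DataFrame) -> float:
    """Two-observer TEM (mm) from an (N, 2) array of paired readings."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (N, 2) array with N >= 1")
    if np.isnan(arr).any():
        raise ValidationError("incomplete observer pairs (NaN present)")
    d = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.sum(d**2) / (2 * len(d))))


def rtem(tem_value: float, grand_mean: float) -> float:
    """Relative TEM in percent: 100·TEM/MEAN."""
    if not grand_mean > 0:
        raise ValueError("grand mean must be positive")
    if tem_value < 0:
        raise ValueError("TEM must be nonnegative")
    return 100.0 * tem_value / grand_mean


def _estimate(trait: str, wide: pd.DataFrame, threshold: float) -> ErrorEstimate:
    arr = wide[["obs1", "obs2"]].to_numpy(float)
    grand_mean = float(np.mean(arr.mean(axis=0)))
    t = tem(arr)
    r = rtem(t, grand_mean)
    return ErrorEstimate(
        trait=trait,
        grand_mean=grand_mean,
        tem=t,
        rtem=r,
        n_pairs=len(arr),
        retained=r < threshold,
    )


def screen_traits(
    observer_table: ObserverTable, threshold_percent: float = DEFAULT_RTEM_THRESHOLD
) -> ScreenResult:
    """Estimate TEM/RTEM per trait and screen at the RTEM threshold.

    A trait is excluded iff its RTEM is greater than or equal to
    ``threshold_percent``. Traits whose pairs are malformed are reported
    in ``failed`` and do not abort the screen for the others.
    """
    estimates: list[ErrorEstimate] = []
    failed: dict[str, str] = {}
    for trait in observer_table.trait_codes:
        try:
            wide = observer_table.pairs(trait)
            estimates.append(_estimate(trait, wide, threshold_percent))
        except (ValidationError, ValueError) as exc:
            failed[trait] = str(exc)
    if not estimates and not failed:
        raise ValidationError("observer table contains no traits")
    return ScreenResult(
        retained=[e.trait for e in estimates if e.retained],
        excluded=[e.trait for e in estimates if not e.retained],
        estimates=estimates,
        failed=failed,
        threshold=threshold_percent,
    )


def screen_estimates(
    means_tems: dict[str, tuple[float, float]],
    threshold_percent: float = DEFAULT_RTEM_THRESHOLD,
) -> ScreenResult:
    """Screen traits from already-computed (grand mean, TEM) pairs.

    Useful when only published error statistics are available rather than
    the raw dual-observer readings.
    """
    estimates = []
    for trait, (mean, t) in means_tems.items():
        r = rtem(t, mean)
        estimates.append(
            ErrorEstimate(
                trait=trait, grand_mean=mean, tem=t, rtem=r, n_pairs=0,
                retained=r < threshold_percent,
            )
        )
    return ScreenResult(
        retained=[e.trait for e in estimates if e.retained],
        excluded=[e.trait for e in estimates if not e.retained],
        estimates=estimates,
        failed={},
        threshold=threshold_percent,
    )
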