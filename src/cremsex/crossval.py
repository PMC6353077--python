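"""Cut-off classification, confusion matrices, and stratified cross-validation.

The validation procedure mirrors the study design: per trait, (1) draw a
training set of ~70% of the complete-case individuals, stratified by sex
with per-sex ceiling rounding; (2) fit the density-intersection cut-off
x₀ on the training summaries; (3) classify the held-out test set by the
cut-off; (4) tabulate the 2×2 confusion matrix against the archaeological
gender labels; (5–7) compute accuracy and per-sex precision (per-class
recall); (8) repeat 1000 times and report means and SDs of accuracy,
precisions and cut-offs.

Replicates whose test set happens to lack one sex contribute to all
defined quantities; the undefined precision is excluded from its own
mean/SD rather than imputed. Per-replicate RNG substreams are derived
from the master seed, so results are independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dimorphism import cm_cutoff
from .io import MeasurementTable, ValidationError
from .registry import FEMALE, MALE, ReferenceStandard, TraitStandard

__all__ = [
    "ConfusionMatrix",
    "CrossValConfig",
    "CrossValSummary",
    "classify",
    "confusion",
    "metrics",
    "stratified_split",
    "cross_validate",
    "apply_external_standard",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 sex-classification tally against gender labels.

    CA: females classified female; CB: females classified male;
    CC: males classified female; CD: males classified male.
    """

    CA: int
    CB: int
    CC: int
    CD: int

    @property
    def total(self) -> int:
        return self.CA + self.CB + self.CC + self.CD

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.CA + other.CA, self.CB + other.CB, self.CC + other.CC, self.CD + other.CD
        )


@dataclass(frozen=True)
class CrossValConfig:
    train_fraction: float = 0.70
    reps: int = 1000
    seed: int = 0
    min_per_sex: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class CrossValSummary:
    """Replicate means/SDs of accuracy, per-sex precision and cut-off."""

    trait: str
    accuracy_mean: float
    accuracy_sd: float
    precision_male_mean: float
    precision_male_sd: float
    precision_female_mean: float
    precision_female_sd: float
    cutoff_mean: float
    cutoff_sd: float
    train_n: int
    test_n: int
    reps: int
    reps_used: int


def classify(value: float, cutoff: float, male_side: str = "above") -> str:
    """Classify one measurement by a cut-off.

    ``male_side='above'`` (the usual case: male mean exceeds female mean)
    assigns M to values at or above the cut-off; ties go to the male side.
    """
    if male_side not in ("above", "below"):
        raise ValueError("male_side must be 'above' or 'below'")
    if male_side == "above":
        return MALE if value >= cutoff else FEMALE
    return MALE if value <= cutoff else FEMALE


def _confusion_arrays(
    values_m: np.ndarray, values_f: np.ndarray, cutoff: float, male_side: str = "above"
) -> ConfusionMatrix:
    if male_side == "above":
        cd = int(np.sum(values_m >= cutoff))
        ca = int(np.sum(values_f < cutoff))
    else:
        cd = int(np.sum(values_m <= cutoff))
        ca = int(np.sum(values_f > cutoff))
    return ConfusionMatrix(
        CA=ca, CB=len(values_f) - ca, CC=len(values_m) - cd, CD=cd
    )


def confusion(
    test: MeasurementTable, trait: str, cutoff: float, male_side: str = "above"
) -> ConfusionMatrix:
    """Confusion matrix of cut-off classification on a test table."""
    values_m, values_f = test.sex_values(trait)
    if len(values_m) + len(values_f) == 0:
        raise ValidationError(f"trait {trait!r}: empty test set")
    return _confusion_arrays(values_m, values_f, cutoff, male_side)


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy and per-sex precision (percent) from a confusion matrix.

    accuracy = (CA+CD)/N; precision_female = CA/(CA+CB);
    precision_male = CD/(CC+CD). A precision whose sex is absent from the
    test set is returned as NaN, not 0.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    acc = 100.0 * (cm.CA + cm.CD) / cm.total
    prec_f = 100.0 * cm.CA / (cm.CA + cm.CB) if (cm.CA + cm.CB) > 0 else float("nan")
    prec_m = 100.0 * cm.CD / (cm.CC + cm.CD) if (cm.CC + cm.CD) > 0 else float("nan")
    return {"accuracy": acc, "precision_male": prec_m, "precision_female": prec_f}


def _train_counts(n_m: int, n_f: int, train_fraction: float) -> tuple[int, int]:
    return math.ceil(train_fraction * n_m), math.ceil(train_fraction * n_f)


def stratified_split(
    table: MeasurementTable,
    trait: str,
    train_fraction: float = 0.70,
    seed: int = 0,
    min_per_sex: int = 2,
) -> tuple[MeasurementTable, MeasurementTable]:
    """Per-sex stratified train/test split of the trait's complete cases.

    The training set takes ``ceil(train_fraction × n)`` individuals of each
    sex, sampled uniformly without replacement; the remainder forms the
    test set. Only rows with the trait present are used.
    """
    df = table.df
    present = df[trait].notna()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    train_idx: list[int] = []
    test_idx: list[int] = []
    for sex in (MALE, FEMALE):
        idx = df.index[present & (df["gender"] == sex)].to_numpy()
        if len(idx) < min_per_sex:
            raise ValidationError(
                f"trait {trait!r}: only {len(idx)} {sex} individuals (< {min_per_sex})"
            )
        k = math.ceil(train_fraction * len(idx))
        perm = rng.permutation(idx)
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    return table.restrict(sorted(train_idx)), table.restrict(sorted(test_idx))


def _fit_cutoff(train_m: np.ndarray, train_f: np.ndarray) -> tuple[float, str]:
    mu_m, sd_m = float(np.mean(train_m)), float(np.std(train_m, ddof=1))
    mu_f, sd_f = float(np.mean(train_f)), float(np.std(train_f, ddof=1))
    x0 = cm_cutoff(mu_m, sd_m, mu_f, sd_f)
    return x0, ("above" if mu_m >= mu_f else "below")


def cross_validate(
    table: MeasurementTable, trait: str, config: CrossValConfig = CrossValConfig()
) -> CrossValSummary:
    """The 8-step resampling validation of one trait's cut-off classifier."""
    values_m, values_f = table.sex_values(trait)
    n_m, n_f = len(values_m), len(values_f)
    if min(n_m, n_f) < config.min_per_sex:
        raise ValidationError(
            f"trait {trait!r}: per-sex counts ({n_m} M, {n_f} F) below minimum "
            f"{config.min_per_sex}"
        )
    k_m, k_f = _train_counts(n_m, n_f, config.train_fraction)
    if k_m >= n_m and k_f >= n_f:
        raise ValidationError(f"trait {trait!r}: split leaves an empty test set")

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.reps)
    acc = np.full(config.reps, np.nan)
    pm = np.full(config.reps, np.nan)
    pf = np.full(config.reps, np.nan)
    cut = np.full(config.reps, np.nan)
    for r in range(config.reps):
        rng = np.random.default_rng(streams[r])
        perm_m = rng.permutation(values_m)
        perm_f = rng.permutation(values_f)
        train_m, test_m = perm_m[:k_m], perm_m[k_m:]
        train_f, test_f = perm_f[:k_f], perm_f[k_f:]
        try:
            x0, male_side = _fit_cutoff(train_m, train_f)
        except ValidationError:
            continue  # degenerate training draw; replicate skipped
        cm = _confusion_arrays(test_m, test_f, x0, male_side)
        assert cm.total == len(test_m) + len(test_f)
        mets = metrics(cm)
        acc[r] = mets["accuracy"]
        pm[r] = mets["precision_male"]
        pf[r] = mets["precision_female"]
        cut[r] = x0

    used = int(np.sum(~np.isnan(cut)))
    if used == 0:
        raise ValidationError(f"trait {trait!r}: every replicate was degenerate")

    def _mean_sd(x: np.ndarray) -> tuple[float, float]:
        x = x[~np.isnan(x)]
        if len(x) == 0:
            return float("nan"), float("nan")
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
        return float(np.mean(x)), sd

    a_m, a_s = _mean_sd(acc)
    pm_m, pm_s = _mean_sd(pm)
    pf_m, pf_s = _mean_sd(pf)
    c_m, c_s = _mean_sd(cut)
    return CrossValSummary(
        trait=trait,
        accuracy_mean=a_m, accuracy_sd=a_s,
        precision_male_mean=pm_m, precision_male_sd=pm_s,
        precision_female_mean=pf_m, precision_female_sd=pf_s,
        cutoff_mean=c_m, cutoff_sd=c_s,
        train_n=k_m + k_f, test_n=(n_m - k_m) + (n_f - k_f),
        reps=config.reps, reps_used=used,
    )


def apply_external_standard(
    table: MeasurementTable,
    trait: str,
    standard: ReferenceStandard | TraitStandard,
    use_stored_cutoff: bool = False,
) -> dict:
    """Classify a whole series by a cut-off taken from an external standard.

    By default the cut-off is recomputed from the standard's per-sex
    summaries via the density-intersection rule; ``use_stored_cutoff``
    applies the standard's published cut-off instead, when present.
    Returns the cut-off, the confusion matrix against the table's gender
    labels, and the derived metrics.
    """
    ts = standard[trait] if isinstance(standard, ReferenceStandard) else standard
    if use_stored_cutoff and ts.cutoff is not None:
        x0 = float(ts.cutoff)
    else:
        x0 = cm_cutoff(ts.male.mean, ts.male.sd, ts.female.mean, ts.female.sd)
    male_side = "above" if ts.male.mean >= ts.female.mean else "below"
    cm = confusion(table, trait, x0, male_side)
    return {"cutoff": x0, "male_side": male_side, "confusion": cm, "metrics": metrics(cm)}
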