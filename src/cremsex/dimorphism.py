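"""Per-trait sexual-dimorphism statistics for two-normal trait models.

The central quantity is the Chakraborty–Majumder non-overlap index D: fit
a normal to each sex from its complete-case mean and sample SD, and let D
be the area where the two densities do NOT overlap,

    D = 1 − ∫ min(φ_M(x), φ_F(x)) dx ,

which equals the probability of correct classification (minus chance
overlap) of an equal-prior Bayes classifier on the two fitted normals.
D = 0 for identical distributions and D → 1 under full separation. The
associated cut-off point x₀ is the density crossing in the bulk of the
two distributions — the root of φ_M(x₀) = φ_F(x₀) at which the common
density value is largest. With equal SDs this is the midpoint of the
means; with unequal SDs the crossing quadratic has two roots and the
second lies far in the tails, usually carrying negligible mass, so D
coincides with the misclassification complement of the single threshold
x₀ for all practically dimorphic traits.

Also provided: Welch's unequal-variance t test computed from per-sex
summaries (sign convention female − male, so dimorphic traits with larger
male means give negative t), two-sided variance-ratio and Bartlett tests,
and a parametric-bootstrap standard error for D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MeasurementTable, ValidationError, summarize_trait
from .registry import SexSpecificSummary, load_trait_registry

__all__ = [
    "DimorphismStats",
    "welch_t",
    "variance_tests",
    "cm_cutoff",
    "cm_D",
    "bootstrap_D_sd",
    "dimorphism_table",
]

_DENSITY_TOL = 1e-9


@dataclass(frozen=True)
class DimorphismStats:
    """One trait's row of the dimorphism analysis."""

    trait: str
    male: SexSpecificSummary
    female: SexSpecificSummary
    t: float
    df: float
    p_t: float
    p_f: float | None
    p_bartlett: float | None
    D: float
    D_sd: float | None
    cutoff: float


def welch_t(m: SexSpecificSummary, f: SexSpecificSummary) -> dict[str, float]:
    """Welch's unequal-variance t from per-sex summaries.

    t = (mean_F − mean_M) / sqrt(s_M²/n_M + s_F²/n_F) with
    Welch–Satterthwaite degrees of freedom and a two-sided p-value.
    """
    for s in (m, f):
        if s.n < 2:
            raise ValidationError(f"trait {s.trait!r}, sex {s.sex}: need n >= 2 for a t test")
    vm, vf = m.sd**2 / m.n, f.sd**2 / f.n
    se2 = vm + vf
    if se2 == 0:
        raise ValidationError("both groups have zero variance; t is undefined")
    t = (f.mean - m.mean) / math.sqrt(se2)
    df = se2**2 / (vm**2 / (m.n - 1) + vf**2 / (f.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": t, "df": df, "p_t": p}


def variance_tests(samples_m: np.ndarray, samples_f: np.ndarray) -> dict[str, float]:
    """Two-sided variance-ratio (F) and Bartlett tests of equal variances."""
    xm = np.asarray(samples_m, dtype=float)
    xf = np.asarray(samples_f, dtype=float)
    if len(xm) < 2 or len(xf) < 2:
        raise ValidationError("need at least 2 values per group for variance tests")
    vm, vf = np.var(xm, ddof=1), np.var(xf, ddof=1)
    if vm == 0 or vf == 0:
        raise ValidationError("constant group: variance tests undefined")
    F = vm / vf
    dfm, dff = len(xm) - 1, len(xf) - 1
    cdf = stats.f.cdf(F, dfm, dff)
    p_f = 2.0 * min(cdf, 1.0 - cdf)
    _, p_bartlett = stats.bartlett(xm, xf)
    return {"F": float(F), "p_f": float(min(p_f, 1.0)), "p_bartlett": float(p_bartlett)}


def _crossings(mu1: float, sd1: float, mu2: float, sd2: float) -> np.ndarray:
    """Real solutions of φ₁(x) = φ₂(x), ascending."""
    if np.isclose(sd1, sd2):
        return np.array([(mu1 + mu2) / 2.0])
    a = 1.0 / sd1**2 - 1.0 / sd2**2
    b = -2.0 * (mu1 / sd1**2 - mu2 / sd2**2)
    c = mu1**2 / sd1**2 - mu2**2 / sd2**2 + 2.0 * math.log(sd1 / sd2)
    disc = b * b - 4.0 * a * c
    if disc < 0:  # cannot happen for distinct normal densities
        raise ValidationError("no real density crossing found")
    # numerically stable quadratic roots
    q = -0.5 * (b + math.copysign(math.sqrt(disc), b))
    roots = np.array([q / a, c / q]) if q != 0 else np.array([0.0, -b / a])
    return np.sort(roots)


def _check_nondegenerate(mu_m, sd_m, mu_f, sd_f) -> None:
    for sd in (sd_m, sd_f):
        if not np.isfinite(sd) or sd <= 0:
            raise ValidationError("standard deviations must be positive and finite")
    if not (np.isfinite(mu_m) and np.isfinite(mu_f)):
        raise ValidationError("means must be finite")
    if np.isclose(mu_m, mu_f) and np.isclose(sd_m, sd_f):
        raise ValidationError(
            "identical distributions: no discriminating cut-off exists"
        )


def cm_cutoff(mu_m: float, sd_m: float, mu_f: float, sd_f: float) -> float:
    """Sex-classification cut-off x₀: the bulk crossing of the two densities.

    With equal SDs this is exactly the midpoint of the means. Otherwise
    the density-equality quadratic has two roots; the cut-off is the root
    where the common density value is largest, which coincides with the
    root between the means whenever one exists.
    """
    _check_nondegenerate(mu_m, sd_m, mu_f, sd_f)
    roots = _crossings(mu_m, sd_m, mu_f, sd_f)
    if len(roots) == 1:
        return float(roots[0])
    dens = stats.norm.logpdf(roots, loc=mu_m, scale=sd_m)
    # equal means make both crossings equally dense; break the tie with the
    # lower root so the choice is deterministic and label-symmetric
    if abs(dens[0] - dens[1]) <= 1e-9 * max(1.0, abs(dens[0]), abs(dens[1])):
        return float(roots[0])
    return float(roots[int(np.argmax(dens))])


def cm_D(mu_m: float, sd_m: float, mu_f: float, sd_f: float) -> float:
    """Chakraborty–Majumder non-overlap index of two fitted normals.

    D = 1 − ∫ min(φ_M, φ_F); 0 for identical distributions (returned
    directly rather than raising), approaching 1 under full separation.
    Symmetric in the two labels.
    """
    for sd in (sd_m, sd_f):
        if not np.isfinite(sd) or sd < 0:
            raise ValidationError("standard deviations must be nonnegative and finite")
    if np.isclose(mu_m, mu_f) and np.isclose(sd_m, sd_f):
        return 0.0
    if sd_m == 0 or sd_f == 0:
        # a point mass overlaps a continuous density on a null set
        return 1.0
    roots = _crossings(mu_m, sd_m, mu_f, sd_f)
    edges = np.concatenate(([-np.inf], roots, [np.inf]))
    overlap = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == -np.inf:
            probe = hi - 1.0
        elif hi == np.inf:
            probe = lo + 1.0
        else:
            probe = 0.5 * (lo + hi)
        # log densities: the sign of logφ_m − logφ_f is constant between
        # crossings and immune to tail underflow
        if stats.norm.logpdf(probe, mu_m, sd_m) <= stats.norm.logpdf(probe, mu_f, sd_f):
            overlap += stats.norm.cdf(hi, mu_m, sd_m) - stats.norm.cdf(lo, mu_m, sd_m)
        else:
            overlap += stats.norm.cdf(hi, mu_f, sd_f) - stats.norm.cdf(lo, mu_f, sd_f)
    return float(1.0 - overlap)


def bootstrap_D_sd(
    m: SexSpecificSummary,
    f: SexSpecificSummary,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap SD of D at the observed per-sex (n, mean, sd).

    Each replicate redraws n_M and n_F values from the fitted normals,
    refits means/SDs and recomputes D; the estimate is the sample SD of D
    over replicates. Seed-reproducible.
    """
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    for s in (m, f):
        if s.n < 3:
            raise ValidationError(f"sex {s.sex}: need n >= 3 to bootstrap D")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    xm = rng.normal(m.mean, m.sd, size=(reps, m.n))
    xf = rng.normal(f.mean, f.sd, size=(reps, f.n))
    mum, sdm = xm.mean(axis=1), xm.std(axis=1, ddof=1)
    muf, sdf = xf.mean(axis=1), xf.std(axis=1, ddof=1)
    ds = np.array([cm_D(mum[i], sdm[i], muf[i], sdf[i]) for i in range(reps)])
    return float(np.std(ds, ddof=1))


@dataclass(frozen=True)
class DimorphismResult:
    stats: list[DimorphismStats]
    skipped: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stats:
            rows.append(
                {
                    "trait": s.trait,
                    "male_n": s.male.n,
                    "female_n": s.female.n,
                    "male_mean_mm": s.male.mean,
                    "female_mean_mm": s.female.mean,
                    "male_sd_mm": s.male.sd,
                    "female_sd_mm": s.female.sd,
                    "t": s.t,
                    "p_t": s.p_t,
                    "df": s.df,
                    "p_f": s.p_f,
                    "p_bartlett": s.p_bartlett,
                    "D": s.D,
                    "D_sd": s.D_sd,
                    "cutoff_mm": s.cutoff,
                }
            )
        return pd.DataFrame(rows)


def dimorphism_table(
    table: MeasurementTable,
    traits: list[str] | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> DimorphismResult:
    """Full per-trait dimorphism analysis of a measurement table.

    Complete-case per trait, ordered as the registry. Traits failing
    preconditions (a sex absent, n < 2) are reported in ``skipped``
    rather than aborting the table. Degenerate traits with identical
    constant values in both sexes yield a D = 0 row with an undefined
    cut-off.
    """
    registry = load_trait_registry()
    wanted = traits if traits is not None else [
        c for c in registry.codes if c in table.trait_codes
    ]
    stats_out: list[DimorphismStats] = []
    skipped: dict[str, str] = {}
    for code in wanted:
        try:
            m, f = summarize_trait(table, code)
            if m.n < 2 or f.n < 2:
                raise ValidationError(f"trait {code!r}: need n >= 2 per sex")
            vals_m, vals_f = table.sex_values(code)
            D = cm_D(m.mean, m.sd, f.mean, f.sd)
            if D == 0.0 and np.isclose(m.sd, f.sd) and np.isclose(m.mean, f.mean):
                cutoff = float("nan")
            else:
                cutoff = cm_cutoff(m.mean, m.sd, f.mean, f.sd)
            try:
                w = welch_t(m, f)
            except ValidationError:
                w = {"t": float("nan"), "df": float("nan"), "p_t": float("nan")}
            try:
                v = variance_tests(vals_m, vals_f)
            except ValidationError:
                v = {"p_f": None, "p_bartlett": None}
            try:
                d_sd = bootstrap_D_sd(m, f, reps=bootstrap_reps, seed=seed)
            except (ValidationError, ValueError):
                d_sd = None
            stats_out.append(
                DimorphismStats(
                    trait=code, male=m, female=f,
                    t=w["t"], df=w["df"], p_t=w["p_t"],
                    p_f=v["p_f"], p_bartlett=v["p_bartlett"],
                    D=D, D_sd=d_sd, cutoff=cutoff,
                )
            )
        except (ValidationError, KeyError) as exc:
            skipped[code] = str(exc)
    return DimorphismResult(stats=stats_out, skipped=skipped)
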