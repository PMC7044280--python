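"""Normality checks and fused-vs-unfused comparisons.

Shapiro-Wilk W is computed with Royston's approximation (AS R94,
covering 3 <= n <= 5000) in full double precision: approximate normal
scores m_i = Phi^{-1}((i - 3/8)/(n + 1/4)), polynomial corrections to
the two extreme weights, and Royston's normalising transforms for the
one-sided p-value (small W signals departure from normality).  The n = 3
case uses the exact weight sqrt(1/2) and arcsine p-value.

Welch's two-sample t-test (unequal variances) with Welch-Satterthwaite
degrees of freedom and two-sided p-values is used to compare the
mesh-weighted mean stresses of fused and unfused models per bone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

__all__ = [
    "StatsError",
    "ComparisonReport",
    "shapiro_wilk",
    "welch_t",
    "compare_fused_unfused",
    "make_sample_set",
]


class StatsError(RuntimeError):
    pass


@dataclass(frozen=True)
class ComparisonReport:
    """Normality check plus Welch test for one bone at one load angle."""

    bone: str
    angle_deg: float
    n_fused: int
    n_unfused: int
    mean_fused: float
    mean_unfused: float
    shapiro_W: float
    shapiro_p: float
    t: float
    df: float
    p: float

    @property
    def fused_lower(self) -> bool:
        return self.mean_fused < self.mean_unfused


def _poly(coeffs: Sequence[float], x: float) -> float:
    """Horner evaluation of c0 + c1 x + c2 x^2 + ..."""
    out = 0.0
    for c in reversed(coeffs):
        out = out * x + c
    return out


# Royston (1995) polynomial constants.
_C1 = (0.0, 0.221157, -0.147981, -2.071190, 4.434685, -2.706056)
_C2 = (0.0, 0.042981, -0.293762, -1.752461, 5.682633, -3.582633)
_C3 = (0.5440, -0.39978, 0.025054, -6.714e-4)
_C4 = (1.3822, -0.77857, 0.062767, -0.0020322)
_C5 = (-1.5861, -0.31082, -0.083751, 0.0038915)
_C6 = (-0.4803, -0.082676, 0.0030302)


def shapiro_wilk(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W and one-sided p-value (Royston's AS R94).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 3 or n > 5000:
        raise StatsError("Shapiro-Wilk requires 3 <= n <= 5000")
    ssx = float(np.sum((x - x.mean()) ** 2))
    if ssx == 0:
        raise StatsError("Shapiro-Wilk W is undefined for a constant sample")

    m = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    ssm = float(np.dot(m, m))
    rsn = 1.0 / np.sqrt(n)
    a = np.empty(n)
    if n == 3:
        a[0], a[1], a[2] = -np.sqrt(0.5), 0.0, np.sqrt(0.5)
    else:
        a_n = m[-1] / np.sqrt(ssm) + _poly(_C1, rsn)
        if n > 5:
            a_n1 = m[-2] / np.sqrt(ssm) + _poly(_C2, rsn)
            phi = (ssm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (
                1 - 2 * a_n**2 - 2 * a_n1**2
            )
            a[2:-2] = m[2:-2] / np.sqrt(phi)
            a[-1], a[-2], a[0], a[1] = a_n, a_n1, -a_n, -a_n1
        else:
            phi = (ssm - 2 * m[-1] ** 2) / (1 - 2 * a_n**2)
            a[1:-1] = m[1:-1] / np.sqrt(phi)
            a[-1], a[0] = a_n, -a_n
    W = float(np.dot(a, x) ** 2 / ssx)
    W = min(W, 1.0)

    if n == 3:
        p = 1.90985931710274 * (np.arcsin(np.sqrt(W)) - 1.04719755119660)
        return W, float(np.clip(p, 0.0, 1.0))
    y = np.log(1 - W)
    if n <= 11:
        gamma = _poly((-2.273, 0.459), n)
        mu = _poly(_C3, n)
        sigma = np.exp(_poly(_C4, n))
        y = -np.log(gamma - y)
    else:
        ln = np.log(n)
        mu = _poly(_C5, ln)
        sigma = np.exp(_poly(_C6, ln))
    return W, float(norm.sf((y - mu) / sigma))


def welch_t(
    sample1: Sequence[float], sample2: Sequence[float]
) -> Tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite df, two-sided p."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise StatsError("Welch's t-test requires n >= 2 per group")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if x.mean() == y.mean():
            raise StatsError(
                "Welch's t is undefined: both samples constant and equal"
            )
        return float(np.sign(x.mean() - y.mean()) * np.inf), float(
            min(n1, n2) - 1
        ), 0.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


def make_sample_set(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy MWAM sample table.

    Expected columns: species, bone, variant, angle_deg, mwam — one row
    per (species, bone, variant, angle).
    """
    required = {"species", "bone", "variant", "angle_deg", "mwam"}
    missing = required - set(records.columns)
    if missing:
        raise StatsError(f"sample set missing columns: {sorted(missing)}")
    bad = set(records["variant"]) - {"fused", "unfused"}
    if bad:
        raise StatsError(f"unknown variants: {sorted(bad)}")
    keys = records[["species", "bone", "variant", "angle_deg"]]
    if keys.duplicated().any():
        raise StatsError("duplicate (species, bone, variant, angle) records")
    return records


def compare_fused_unfused(
    samples: pd.DataFrame, bone: str, angle_deg: float = 0.0
) -> ComparisonReport:
    """Shapiro-Wilk on the pooled per-bone sample, then Welch's t-test.

    Normality is assessed on the pooled fused + unfused sample (the two
    groups together), and the t statistic is fused minus unfused, so a
    negative t means lower stress in the fused morphology.
    """
    samples = make_sample_set(samples)
    sub = samples[(samples["bone"] == bone) & (samples["angle_deg"] == angle_deg)]
    fused = sub[sub["variant"] == "fused"]["mwam"].to_numpy()
    unfused = sub[sub["variant"] == "unfused"]["mwam"].to_numpy()
    if len(fused) == 0 or len(unfused) == 0:
        raise StatsError(
            f"bone {bone!r} at {angle_deg} deg is missing a variant group"
        )
    sp_f = set(sub[sub["variant"] == "fused"]["species"])
    sp_u = set(sub[sub["variant"] == "unfused"]["species"])
    if sp_f != sp_u:
        raise StatsError(
            f"unequal species coverage for bone {bone!r}: {sp_f ^ sp_u}"
        )
    W, pW = shapiro_wilk(np.concatenate([fused, unfused]))
    t, df, p = welch_t(fused, unfused)
    return ComparisonReport(
        bone=bone,
        angle_deg=angle_deg,
        n_fused=len(fused),
        n_unfused=len(unfused),
        mean_fused=float(fused.mean()),
        mean_unfused=float(unfused.mean()),
        shapiro_W=W,
        shapiro_p=pW,
        t=t,
        df=df,
        p=p,
    )
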