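"""Shared helpers for the test suite (imported by test modules)."""

import numpy as np

from carpofem.model import (
    LigamentSpec,
    MaterialSet,
    assemble_model,
    default_boundary,
    make_load_case,
)


def zero_load_system(mesh):
    """Fully assembled carpal system with zero applied load (mass = 0)."""
    topo = "direct" if mesh.variant == "fused" else "serial"
    return assemble_model(
        mesh,
        MaterialSet(),
        LigamentSpec(topology=topo),
        default_boundary(mesh),
        make_load_case(0.0),
    )


def brute_force_welch(x, y):
    """Welch's t from first principles: sums only, no library calls."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / se2**0.5
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def brute_force_shapiro_W(x):
    """Shapiro-Wilk W from the published algorithm, coded independently:
    Blom-type normal scores, the two polynomial-corrected extreme
    weights, explicit renormalisation, W = (a . x_sorted)^2 / SS."""
    from scipy.stats import norm

    xs = sorted(float(v) for v in x)
    n = len(xs)
    m = [norm.ppf((i - 0.375) / (n + 0.25)) for i in range(1, n + 1)]
    ssm = sum(v * v for v in m)
    u = n ** (-0.5)
    if n == 3:
        a = [-(0.5**0.5), 0.0, 0.5**0.5]
    else:
        c1 = [0.0, 0.221157, -0.147981, -2.071190, 4.434685, -2.706056]
        c2 = [0.0, 0.042981, -0.293762, -1.752461, 5.682633, -3.582633]
        p1 = sum(c * u**i for i, c in enumerate(c1))
        p2 = sum(c * u**i for i, c in enumerate(c2))
        an = m[-1] / ssm**0.5 + p1
        a = [0.0] * n
        if n > 5:
            an1 = m[-2] / ssm**0.5 + p2
            phi = (ssm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (
                1 - 2 * an**2 - 2 * an1**2
            )
            for i in range(2, n - 2):
                a[i] = m[i] / phi**0.5
            a[-1], a[-2], a[0], a[1] = an, an1, -an, -an1
        else:
            phi = (ssm - 2 * m[-1] ** 2) / (1 - 2 * an**2)
            for i in range(1, n - 1):
                a[i] = m[i] / phi**0.5
            a[-1], a[0] = an, -an
    mean = sum(xs) / n
    ss = sum((v - mean) ** 2 for v in xs)
    num = sum(ai * vi for ai, vi in zip(a, xs)) ** 2
    return min(num / ss, 1.0)


def brute_force_weighted_quantile(values, weights, q):
    """Smallest value with cumulative weight >= q of the total (by scan)."""
    pairs = sorted(zip(values, weights), key=lambda p: p[0])
    total = sum(w for _, w in pairs)
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc >= q * total - 1e-12 * total:
            return v
    return pairs[-1][0]
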