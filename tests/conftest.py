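"""Shared fixtures and independent brute-force oracles.

The oracles here solve the same conservation equations as the library
but with nothing beyond pure interval bisection, so agreement between
the two is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest


def pure_bisection(f, lo: float, hi: float, steps: int = 200) -> float:
    """Plain interval halving; no Newton, no library code."""
    flo = f(lo)
    if flo == 0.0:
        return lo
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        if flo * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
            flo = f(lo)
    return 0.5 * (lo + hi)


def oracle_homodimer_free_monomer(c_P: float, K_D: float) -> float:
    """Free monomer from bisection on [P] + 2[P]^2/K_D = c_P."""
    if c_P == 0:
        return 0.0
    return pure_bisection(lambda P: P + 2 * P * P / K_D - c_P, 0.0, c_P)


def oracle_binding_complex(c_P: float, c_L: float, K_D: float) -> float:
    """[PL] from bisection on the quadratic conservation equation."""
    if c_P == 0 or c_L == 0:
        return 0.0
    hi = min(c_P, c_L)
    return pure_bisection(
        lambda PL: (c_P - PL) * (c_L - PL) - K_D * PL, 0.0, hi
    )


def oracle_competing_ligands_free_P(c_P, c_L, c_Lp, K_D, K_Dp) -> float:
    return pure_bisection(
        lambda P: P * (1 + c_L / (K_D + P) + c_Lp / (K_Dp + P)) - c_P,
        0.0,
        c_P,
    )


def oracle_competing_receptors_free_L(c_P, c_Pp, c_L, K_D, K_Dp) -> float:
    return pure_bisection(
        lambda L: L * (1 + c_P / (K_D + L) + c_Pp / (K_Dp + L)) - c_L,
        0.0,
        c_L,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture
def slider_log_range() -> tuple[float, float]:
    """The interactive slider span used for randomized parameter draws."""
    return (-9.0, -1.0)
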