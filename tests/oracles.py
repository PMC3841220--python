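"""Independent numerical oracles used to cross-check the implementation.

Deliberately avoid the code paths under test: the normal CDF is a Taylor
series for erf, the Student-t tail is numerical quadrature of the density
written from the gamma-function formula.
"""

from __future__ import annotations

import math

from scipy.integrate import quad


def normal_cdf_series(z: float, terms: int = 120) -> float:
    """Phi(z) via the Maclaurin series of erf; accurate to ~1e-12 for |z| <= 6."""
    if z < -8.0:
        return 0.0
    if z > 8.0:
        return 1.0
    x = z / math.sqrt(2.0)
    total = 0.0
    term = x
    for n in range(terms):
        if n > 0:
            term *= -x * x / n
        total += term / (2 * n + 1)
    erf = 2.0 / math.sqrt(math.pi) * total
    return 0.5 * (1.0 + erf)


def _t_density(x: float, df: int) -> float:
    log_c = (
        math.lgamma((df + 1) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )
    return math.exp(log_c - (df + 1) / 2.0 * math.log1p(x * x / df))


def t_sf_quad(t: float, df: int) -> float:
    """P(T >= t) for Student's t with df degrees of freedom, by quadrature."""
    if t >= 0:
        val, _ = quad(_t_density, t, math.inf, args=(df,))
        return val
    val, _ = quad(_t_density, -t, math.inf, args=(df,))
    return 1.0 - val


def population_sd(values) -> float:
    mu = sum(values) / len(values)
    return math.sqrt(sum((v - mu) ** 2 for v in values) / len(values))
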