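"""Repeated-measures ANOVA power for within-subject factors.

Follows the within-factors convention used by G*Power: with n subjects,
m repeated measurements, Cohen's effect size f, correlation rho among
repeated measures, and nonsphericity correction epsilon, the test
statistic under the alternative is noncentral F with

    lambda = f^2 * n * m / (1 - rho),
    df1 = epsilon * (m - 1),    df2 = epsilon * (n - 1) * (m - 1).

Power is P(F' > F_crit(alpha)) under the noncentral distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    n: int
    m: int = 4
    f: float = 0.25
    rho: float = 0.5
    alpha: float = 0.05
    epsilon: float = 1.0

    def __post_init__(self):
        if self.n < 2 or self.m < 2:
            raise ValueError("need n >= 2 subjects and m >= 2 measurements")
        if self.f < 0:
            raise ValueError("effect size f must be nonnegative")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")


def rm_power(spec: PowerSpec) -> float:
    """Power of the within-factors repeated-measures F test."""
    lam = spec.f ** 2 * spec.n * spec.m / (1.0 - spec.rho)
    df1 = spec.epsilon * (spec.m - 1)
    df2 = spec.epsilon * (spec.n - 1) * (spec.m - 1)
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_n(target_power: float, m: int = 4, f: float = 0.25,
               rho: float = 0.5, alpha: float = 0.05,
               epsilon: float = 1.0, n_max: int = 10_000) -> int:
    """Smallest n with rm_power >= target_power, by increasing search."""
    if not alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    for n in range(2, n_max + 1):
        if rm_power(PowerSpec(n=n, m=m, f=f, rho=rho, alpha=alpha,
                              epsilon=epsilon)) >= target_power:
            return n
    raise ValueError(f"target power {target_power} unreachable with n <= {n_max}")
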