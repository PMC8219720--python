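"""Sample size for a chi-square test of association at a given Cohen's w.

Power of the level-alpha chi-square test with df degrees of freedom at
sample size N is the survival function of a noncentral chi-square with
noncentrality N * w**2 at the central critical value; the returned N is the
smallest integer meeting the target power.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerSpec:
    effect_size_w: float
    alpha: float = 0.05
    power: float = 0.80
    df: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise PowerError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise PowerError(f"power must be in (0, 1), got {self.power}")
        if self.df < 1:
            raise PowerError(f"df must be >= 1, got {self.df}")
        if self.effect_size_w < 0:
            raise PowerError(f"effect size must be non-negative, got {self.effect_size_w}")


def chisq_power(n: float, spec: PowerSpec) -> float:
    crit = stats.chi2.ppf(1.0 - spec.alpha, spec.df)
    return float(stats.ncx2.sf(crit, spec.df, n * spec.effect_size_w**2))


def chisq_sample_size(spec: PowerSpec) -> int:
    """Smallest integer N whose noncentral chi-square power meets the target."""
    if spec.effect_size_w == 0:
        raise PowerError("target power is unattainable at zero effect size")
    lo, hi = 1, 2
    while chisq_power(hi, spec) < spec.power:
        hi *= 2
        if hi > 10**9:
            raise PowerError("sample size exceeds 1e9; check the specification")
    while lo < hi:
        mid = (lo + hi) // 2
        if chisq_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return lo
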