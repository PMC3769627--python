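"""Expected clade size under a background birth-death process, and the test
for exceptional species richness.

Model
-----
A clade evolves under a constant-rate linear birth-death process with
speciation rate λ, extinction rate μ, net rate ``r = λ - μ > 0`` and
relative extinction ``ε = μ/λ in [0, 1)``.  Write

    β = (e^{rt} - 1) / (e^{rt} - ε),        α = ε β.

Conditional on leaving at least one extant descendant after time t, the
number of present-day descendants of a single lineage is geometric with
parameter β on {1, 2, ...}.  Observing a *crown* group of age t means both
basal daughter lineages survived to the present, so the crown clade size is
the sum of two independent such geometrics:

    P(N = n) = (n - 1) (1 - β)^2 β^{n-2},        n >= 2,
    P(N <= n) = 1 - β^{n-1} (n (1 - β) + β).

The 95% confidence band on expected clade size at age t is the integer
2.5th/97.5th percentile pair [k_lower, k_upper] of this distribution; a
clade whose standing richness falls strictly outside the band is flagged as
exceptionally species-rich or species-poor relative to the background rate.
ε = 0 recovers the pure-birth (Yule) crown distribution with
β = 1 - e^{-rt}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .rates import CladeRecord

VERDICT_RICH = "exceptionally_rich"
VERDICT_POOR = "exceptionally_poor"
VERDICT_WITHIN = "within_expectation"
VERDICT_NOT_TESTABLE = "not_testable"


class RichnessOverflowError(ValueError):
    """rt so large that β rounds to 1: the interval is unbounded at working
    precision."""


@dataclass(frozen=True)
class BDBackground:
    """Background birth-death parameterisation.

    Parameters
    ----------
    r : float
        Net diversification rate (per lineage per Ma), > 0.
    epsilon : float
        Relative extinction μ/λ, in [0, 1).
    """

    r: float
    epsilon: float = 0.0

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if not 0 <= self.epsilon < 1:
            raise ValueError(f"epsilon must be in [0, 1), got {self.epsilon}")

    @property
    def speciation_rate(self) -> float:
        """λ = r / (1 - ε)."""
        return self.r / (1 - self.epsilon)

    @property
    def extinction_rate(self) -> float:
        """μ = ε λ."""
        return self.epsilon * self.speciation_rate


@dataclass(frozen=True)
class BDAux:
    """Auxiliary birth-death quantities β and α = εβ at a given age."""

    beta: float
    alpha: float


def bd_aux(background: BDBackground, t: float) -> BDAux:
    """β = (e^{rt}-1)/(e^{rt}-ε) and α = εβ, computed via the overflow-safe
    form β = (1 - e^{-rt}) / (1 - ε e^{-rt})."""
    if not t > 0:
        raise ValueError(f"age must be > 0, got {t}")
    x = math.exp(-background.r * t)
    beta = -math.expm1(-background.r * t) / (1.0 - background.epsilon * x)
    if beta >= 1.0:
        raise RichnessOverflowError(
            f"rt = {background.r * t:.3g}: beta rounds to 1 at working "
            "precision, the richness interval is unbounded"
        )
    return BDAux(beta=beta, alpha=background.epsilon * beta)


def crown_size_pmf(n, background: BDBackground, t: float):
    """P(N = n) for the crown clade size, n >= 2 (array-friendly in n)."""
    b = bd_aux(background, t).beta
    n = np.asarray(n)
    if np.any(n < 2):
        raise ValueError("crown clade size support starts at n = 2")
    return (n - 1) * (1 - b) ** 2 * b ** (n - 2)


def crown_size_cdf(n, background: BDBackground, t: float):
    """P(N <= n) = 1 - β^{n-1} (n(1-β) + β), for integer n >= 2."""
    b = bd_aux(background, t).beta
    n = np.asarray(n)
    if np.any(n < 2):
        raise ValueError("crown clade size support starts at n = 2")
    return _cdf_from_beta(n, b)


def _cdf_from_beta(n, b: float):
    # valid for real n >= 1 (the continuous relaxation); F(1) = 0
    n = np.asarray(n, dtype=float)
    out = 1.0 - b ** (n - 1.0) * (n * (1.0 - b) + b)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class RichnessInterval:
    """Confidence band on crown clade size at age t under the background.

    ``k_lower``/``k_upper`` are the integer band edges; the ``_cont``
    fields are the real-valued solutions of the same tail equations, for
    smooth confidence curves on the diversity-vs-age plot.
    """

    t: float
    epsilon: float
    coverage: float
    k_lower: int
    k_upper: int
    k_lower_cont: float
    k_upper_cont: float


def richness_interval(
    background: BDBackground, t: float, coverage: float = 0.95
) -> RichnessInterval:
    """Integer 2.5/97.5 (for coverage 0.95) percentile band of crown size.

    Conventions: ``k_upper = min{n : P(N <= n) >= 1 - (1-coverage)/2}`` and
    ``k_lower = max{n >= 2 : P(N < n) <= (1-coverage)/2}``.  Both integer
    quantiles are conservative, so the band over-covers slightly.
    """
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    b = bd_aux(background, t).beta
    q_lo = (1.0 - coverage) / 2.0
    q_hi = 1.0 - q_lo

    k_upper = _smallest_n_with_cdf_at_least(b, q_hi)
    # largest n >= 2 with P(N < n) = F(n-1) <= q_lo; F(1) = 0 so n = 2 works
    k_lower = _smallest_n_with_cdf_at_least(b, q_lo, strict_above=True)
    # that returns smallest n with F(n) > q_lo; then largest n with
    # F(n-1) <= q_lo is that n itself
    k_lower = max(2, k_lower)

    k_upper_cont = _solve_cdf_cont(b, q_hi)
    k_lower_cont = max(2.0, _solve_cdf_cont(b, q_lo) + 1.0)
    return RichnessInterval(
        t=t,
        epsilon=background.epsilon,
        coverage=coverage,
        k_lower=int(k_lower),
        k_upper=int(k_upper),
        k_lower_cont=k_lower_cont,
        k_upper_cont=k_upper_cont,
    )


def _smallest_n_with_cdf_at_least(b: float, q: float, strict_above: bool = False) -> int:
    """Smallest integer n >= 2 with F(n) >= q (or > q if strict_above)."""
    def ok(n):
        f = _cdf_from_beta(n, b)
        return f > q if strict_above else f >= q

    hi = 2
    while not ok(hi):
        hi *= 2
        if hi > 10 ** 12:  # pragma: no cover - guarded by bd_aux overflow check
            raise RichnessOverflowError("quantile search exceeded 1e12 species")
    lo = hi // 2 if hi > 2 else 2
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return hi


def _solve_cdf_cont(b: float, q: float) -> float:
    """Real x >= 1 with F(x) = q; F is continuous and increasing in x."""
    if q <= 0.0:
        return 1.0
    hi = 2.0
    while _cdf_from_beta(hi, b) < q:
        hi *= 2.0
    return brentq(lambda x: _cdf_from_beta(x, b) - q, 1.0, hi, xtol=1e-10, rtol=1e-12)


@dataclass(frozen=True)
class ExceptionalityResult:
    """Verdict for one clade at one ε."""

    name: str
    epsilon: float
    observed_n: int
    t: float
    interval: Optional[RichnessInterval]
    verdict: str
    reason: str = ""


def classify(observed_n: int, interval: RichnessInterval) -> str:
    """Strict-inequality verdict: outside [k_lower, k_upper] is exceptional."""
    if observed_n > interval.k_upper:
        return VERDICT_RICH
    if observed_n < interval.k_lower:
        return VERDICT_POOR
    return VERDICT_WITHIN


def test_exceptional(
    clades: Iterable[CladeRecord],
    backgrounds: Iterable[BDBackground],
    coverage: float = 0.95,
) -> list:
    """One :class:`ExceptionalityResult` per clade per background ε.

    Each clade is tested at its mean crown age.  Clades with fewer than two
    species cannot form a crown group and are flagged not-testable rather
    than dropped.
    """
    backgrounds = list(backgrounds)
    out = []
    for rec in clades:
        for bg in backgrounds:
            if rec.n_species < 2:
                out.append(
                    ExceptionalityResult(
                        name=rec.name,
                        epsilon=bg.epsilon,
                        observed_n=rec.n_species,
                        t=rec.age_mean,
                        interval=None,
                        verdict=VERDICT_NOT_TESTABLE,
                        reason="fewer than 2 species: no crown group",
                    )
                )
                continue
            iv = richness_interval(bg, rec.age_mean, coverage)
            out.append(
                ExceptionalityResult(
                    name=rec.name,
                    epsilon=bg.epsilon,
                    observed_n=rec.n_species,
                    t=rec.age_mean,
                    interval=iv,
                    verdict=classify(rec.n_species, iv),
                )
            )
    return out


def exceptionality_dataframe(results: Sequence[ExceptionalityResult]) -> pd.DataFrame:
    """Long-format verdict table (clade, epsilon, N, t, k_lower, k_upper, verdict)."""
    return pd.DataFrame(
        {
            "clade": [r.name for r in results],
            "epsilon": [r.epsilon for r in results],
            "n_species": [r.observed_n for r in results],
            "age_mean": [r.t for r in results],
            "k_lower": [r.interval.k_lower if r.interval else pd.NA for r in results],
            "k_upper": [r.interval.k_upper if r.interval else pd.NA for r in results],
            "verdict": [r.verdict for r in results],
            "reason": [r.reason for r in results],
        }
    )


def figure_coordinates(
    clades: Sequence[CladeRecord],
    backgrounds: Iterable[BDBackground],
    coverage: float = 0.95,
    n_grid: int = 200,
    t_min: Optional[float] = None,
    t_max: Optional[float] = None,
) -> pd.DataFrame:
    """Coordinates for the semi-log diversity-vs-age plot (no rendering).

    Returns a long-format frame with columns ``series``, ``t``,
    ``log10_value``.  Observed clades appear as single-point series named
    ``observed:<clade>``; each background ε contributes smooth lower/upper
    confidence curves ``eps=<ε>:lower`` / ``eps=<ε>:upper`` built from the
    continuous relaxation of the band edges.
    """
    ages = [c.age_mean for c in clades]
    lo = t_min if t_min is not None else min(ages) * 0.25
    hi = t_max if t_max is not None else max(ages) * 1.05
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < t_min < t_max, got ({lo}, {hi})")
    grid = np.linspace(lo, hi, n_grid)

    rows = []
    for c in clades:
        rows.append(("observed:" + c.name, c.age_mean, math.log10(c.n_species)))
    for bg in backgrounds:
        for t in grid:
            iv = richness_interval(bg, float(t), coverage)
            rows.append((f"eps={bg.epsilon:g}:lower", float(t), math.log10(iv.k_lower_cont)))
            rows.append((f"eps={bg.epsilon:g}:upper", float(t), math.log10(iv.k_upper_cont)))
    return pd.DataFrame(rows, columns=["series", "t", "log10_value"])
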