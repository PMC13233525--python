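"""The four disproportionality estimators and their signal criteria.

Given a four-grid (a, b, c, d) with N = a+b+c+d:

* **ROR** (reporting odds ratio) = (a/c)/(b/d) = ad/(bc), with a
  lognormal Wald 95% CI from SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d).
* **PRR** (proportional reporting ratio) = (a/(a+b))/(c/(c+d)), with
  SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)) and the uncorrected
  Pearson chi-square of the four-grid (Yates correction by flag).
* **BCPNN** information component IC = log2(aN/((a+b)(a+c))), the base-2
  log of the observed-to-expected co-reporting ratio, with the
  prior-adjusted lower credibility bound IC025 = E(IC) - 2*sqrt(V(IC))
  under Dirichlet priors (default alpha1 = beta1 = gamma11 = 1,
  alpha = beta = 2).
* **MGPS** EBGM = aN/((a+b)(a+c)) — the same observed/expected ratio on
  the plain scale, so IC = log2(EBGM) identically — with the one-sided
  lower 5% bound EBGM05 = exp(ln EBGM - 1.64*SE(ln ROR)).

Signal criteria: ROR and PRR positive when a >= 3 and the CI lower bound
exceeds 1; BCPNN positive when IC025 > 0 (graded low/medium/high at 1.5
and 3 bits); MGPS positive when EBGM05 > 2 and a > 0.  A pair is
*combined positive* only when all four methods flag it.

Zero cells are not continuity-corrected; the affected method is marked
non-evaluable instead (the criteria already require a >= 3).
All functions accept numpy arrays as well as scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from bitewatch.contingency import ContingencyTable

Z_TWO_SIDED = 1.96   # two-sided 95%
Z_ONE_SIDED = 1.64   # one-sided 95% (EBGM05)
LN2 = math.log(2.0)

IC_GRADES = ("none", "low", "medium", "high")


@dataclass(frozen=True)
class BcpnnPriors:
    """Dirichlet prior counts of the BCPNN model.

    ``gamma`` (the joint-cell prior total) is derived, not stored:
    gamma = gamma11 * (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1)),
    which centres the prior IC at zero.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("all prior counts must be strictly positive")


DEFAULT_PRIORS = BcpnnPriors()


@dataclass(frozen=True)
class SignalEstimates:
    """All four estimators, bounds, flags and the IC grade for one pair."""

    a: int
    ror: float = math.nan
    ror_ci: tuple[float, float] = (math.nan, math.nan)
    prr: float = math.nan
    prr_ci: tuple[float, float] = (math.nan, math.nan)
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    ror_pos: bool = False
    prr_pos: bool = False
    bcpnn_pos: bool = False
    mgps_pos: bool = False
    combined_pos: bool = False
    ic_grade: str = "none"
    evaluable: bool = False


def ror_estimate(t: ContingencyTable):
    """ROR point estimate and 95% CI; NaNs when any cell is zero."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - Z_TWO_SIDED * se)
    hi = math.exp(math.log(ror) + Z_TWO_SIDED * se)
    return ror, lo, hi


def prr_estimate(t: ContingencyTable, yates: bool = False):
    """PRR point estimate, 95% CI and Pearson chi-square.

    Chi-square is the uncorrected N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d));
    ``yates=True`` applies the continuity correction.  Returns NaNs for
    the PRR parts when a, c or a margin is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n_total
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins > 0:
        delta = abs(a * d - b * c)
        if yates:
            delta = max(delta - n / 2, 0.0)
        chi2 = n * delta**2 / margins
    else:
        chi2 = math.nan
    if a == 0 or c == 0 or (a + b) == 0 or (c + d) == 0:
        return math.nan, math.nan, math.nan, chi2
    prr = (a / (a + b)) / (c / (c + d))
    se_sq = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(se_sq, 0.0))
    lo = math.exp(math.log(prr) - Z_TWO_SIDED * se)
    hi = math.exp(math.log(prr) + Z_TWO_SIDED * se)
    return prr, lo, hi, chi2


def bcpnn_estimate(t: ContingencyTable, priors: BcpnnPriors = DEFAULT_PRIORS):
    """Information component (bits) and its lower credibility bound.

    The point IC is the simplified log2 observed/expected ratio
    (identical to log2 EBGM); the bound is the prior-adjusted
    IC025 = E(IC) - 2*sqrt(V(IC)).  With a = 0 the point IC is NaN but
    IC025 remains computable from the priors.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n_total
    if a > 0 and (a + b) > 0 and (a + c) > 0:
        ic = math.log2(a * n / ((a + b) * (a + c)))
    else:
        ic = math.nan
    p = priors
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (a + b + p.alpha1) * (a + c + p.beta1)
    )
    e_ic = math.log2(
        (a + p.gamma11)
        * (n + p.alpha)
        * (n + p.beta)
        / ((n + gamma) * (a + b + p.alpha1) * (a + c + p.beta1))
    )
    v_ic = (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - (a + b) + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
        + (n - (a + c) + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
    ) / LN2**2
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return ic, ic025


def mgps_estimate(t: ContingencyTable):
    """EBGM point estimate and one-sided lower 5% bound EBGM05.

    EBGM = aN/((a+b)(a+c)) is defined whenever both margins are positive;
    EBGM05 additionally needs all four cells positive.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n_total
    if (a + b) == 0 or (a + c) == 0 or a == 0:
        return math.nan, math.nan
    ebgm = a * n / ((a + b) * (a + c))
    if min(a, b, c, d) == 0:
        return ebgm, math.nan
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ebgm05 = math.exp(math.log(ebgm) - Z_ONE_SIDED * se)
    return ebgm, ebgm05


def ic_grade(ic025: float) -> str:
    """BCPNN signal grade from IC025 (bits): none (<=0), low (0, 1.5],
    medium (1.5, 3], high (> 3)."""
    if math.isnan(ic025) or ic025 <= 0:
        return "none"
    if ic025 <= 1.5:
        return "low"
    if ic025 <= 3.0:
        return "medium"
    return "high"


def classify_signal(
    t: ContingencyTable, est: SignalEstimates, min_a: int = 3
) -> SignalEstimates:
    """Apply the per-method signal criteria and the combined rule.

    ``min_a`` is the minimum report count for the ROR/PRR criteria
    (conventionally 3).  A non-evaluable method (NaN bound) never flags
    positive.
    """
    ror_pos = t.a >= min_a and not math.isnan(est.ror_ci[0]) and est.ror_ci[0] > 1.0
    prr_pos = t.a >= min_a and not math.isnan(est.prr_ci[0]) and est.prr_ci[0] > 1.0
    bcpnn_pos = not math.isnan(est.ic025) and est.ic025 > 0.0
    mgps_pos = t.a > 0 and not math.isnan(est.ebgm05) and est.ebgm05 > 2.0
    return replace(
        est,
        ror_pos=ror_pos,
        prr_pos=prr_pos,
        bcpnn_pos=bcpnn_pos,
        mgps_pos=mgps_pos,
        combined_pos=ror_pos and prr_pos and bcpnn_pos and mgps_pos,
        ic_grade=ic_grade(est.ic025),
    )


def estimate_signals(
    t: ContingencyTable,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    yates: bool = False,
    min_a: int = 3,
) -> SignalEstimates:
    """Run all four estimators on one table and classify the signal."""
    ror, ror_lo, ror_hi = ror_estimate(t)
    prr, prr_lo, prr_hi, chi2 = prr_estimate(t, yates=yates)
    ic, ic025 = bcpnn_estimate(t, priors)
    ebgm, ebgm05 = mgps_estimate(t)
    est = SignalEstimates(
        a=t.a,
        ror=ror,
        ror_ci=(ror_lo, ror_hi),
        prr=prr,
        prr_ci=(prr_lo, prr_hi),
        chi2=chi2,
        ic=ic,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
        evaluable=min(t.a, t.b, t.c, t.d) > 0,
    )
    return classify_signal(t, est, min_a=min_a)


def ror_interval_arrays(a, b, c, d, z: float = Z_TWO_SIDED):
    """Vectorized ROR point and Wald CI over arrays of four-grid counts.

    Cells must all be positive (use masking upstream); intended for
    simulation studies such as CI-coverage checks.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    ror = a * d / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, np.exp(np.log(ror) - z * se), np.exp(np.log(ror) + z * se)
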