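"""Effect statistics for two-arm comparisons: proportion CIs, risk
difference, risk ratio, and NNT/NNH with proper interval inversion.

The number needed to treat (NNT) or harm (NNH) is the reciprocal of the
absolute risk difference, rounded up to a whole number of patients. Its
confidence region is obtained by inverting the risk-difference interval.
When that interval excludes zero the result is an ordinary finite
integer interval; when it spans zero the inverted region is the disjoint
union of two half-infinite intervals, (-inf, a] U [b, +inf) with
a < 0 < b — reporting a single finite interval in that case is a
well-known error in the NNT literature.

The default risk-difference interval is the hybrid score method
(Newcombe): per-arm Wilson score bounds combined as

    lower = rd - sqrt((p_t - l_t)^2 + (u_c - p_c)^2)
    upper = rd + sqrt((u_t - p_t)^2 + (p_c - l_c)^2)

which has near-nominal coverage even at small event counts, where the
Wald interval is anti-conservative. A Wald variant is provided for
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .trial_data import Direction, TwoArmComparison

__all__ = [
    "ProportionCI",
    "RiskDifferenceResult",
    "NNTKind",
    "NNTResult",
    "RelativeRiskResult",
    "wilson_ci",
    "risk_difference",
    "nnt",
    "relative_risk",
]


def _check_level(level: float) -> None:
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with a confidence interval."""

    estimate: float
    lower: float
    upper: float
    method: str
    level: float


def wilson_ci(events: int, total: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    Bounds lie in [0, 1] by construction; the interval for ``total - events``
    is the mirror image about 0.5 of the interval for ``events``.
    """
    _check_level(level)
    if total < 1 or not 0 <= events <= total:
        raise ValidationError(
            f"need 0 <= events <= total with total >= 1, got {events}/{total}"
        )
    lower, upper = proportion_confint(events, total, alpha=1 - level, method="wilson")
    # boundary cases are exact: x=0 -> lower 0, x=n -> upper 1
    lower = 0.0 if events == 0 else min(max(float(lower), 0.0), 1.0)
    upper = 1.0 if events == total else min(max(float(upper), 0.0), 1.0)
    return ProportionCI(
        estimate=events / total,
        lower=lower,
        upper=upper,
        method="wilson",
        level=level,
    )


@dataclass(frozen=True)
class RiskDifferenceResult:
    """Risk difference (treatment - comparator) with confidence interval."""

    rd: float
    lower: float
    upper: float
    method: str
    level: float

    def contains_zero(self) -> bool:
        return self.lower <= 0.0 <= self.upper

    def to_json_obj(self) -> dict[str, Any]:
        return {
            "rd": self.rd,
            "lower": self.lower,
            "upper": self.upper,
            "method": self.method,
            "level": self.level,
        }


def risk_difference(
    cmp: TwoArmComparison, method: str = "newcombe_hybrid", level: float = 0.95
) -> RiskDifferenceResult:
    """Risk difference p_t - p_c with a Wald or hybrid-score interval."""
    _check_level(level)
    p_t = cmp.treatment.proportion
    p_c = cmp.comparator.proportion
    rd = p_t - p_c
    if method == "newcombe_hybrid":
        t_ci = wilson_ci(cmp.treatment.events, cmp.treatment.total, level)
        c_ci = wilson_ci(cmp.comparator.events, cmp.comparator.total, level)
        lower = rd - math.sqrt((p_t - t_ci.lower) ** 2 + (c_ci.upper - p_c) ** 2)
        upper = rd + math.sqrt((t_ci.upper - p_t) ** 2 + (p_c - c_ci.lower) ** 2)
    elif method == "wald":
        z = norm.ppf(0.5 + level / 2)
        se = math.sqrt(
            p_t * (1 - p_t) / cmp.treatment.total + p_c * (1 - p_c) / cmp.comparator.total
        )
        lower, upper = rd - z * se, rd + z * se
    else:
        raise ValueError(f"unknown method {method!r}; expected 'newcombe_hybrid' or 'wald'")
    return RiskDifferenceResult(
        rd=rd,
        lower=max(lower, -1.0),
        upper=min(upper, 1.0),
        method=method,
        level=level,
    )


class NNTKind(str, Enum):
    NNT = "NNT"
    NNH = "NNH"


def _inv_ceil(x: float) -> float:
    """ceil(1/x) with signed zero handled as an infinite bound."""
    if x == 0.0:
        return math.inf if x > 0 or math.copysign(1.0, x) > 0 else -math.inf
    return math.ceil(1.0 / x)


@dataclass(frozen=True)
class NNTResult:
    """NNT or NNH point estimate with its inverted confidence region.

    ``interval_type`` is "finite" (``interval`` = (low, high) whole
    patients) when the risk-difference CI excludes zero, else
    "disjoint_union" (``interval`` = (a, b) read as (-inf, a] U [b, +inf)
    with a < 0 < b). A zero risk difference leaves the point estimate
    undefined (``point`` is None, ``undefined_point`` True); the region
    is still computed from the interval.
    """

    kind: NNTKind
    point: int | None
    rd_basis: RiskDifferenceResult
    interval_type: str
    interval: tuple[float, float]
    undefined_point: bool = False

    def to_json_obj(self) -> dict[str, Any]:
        def bound(x: float) -> float | str:
            if x == math.inf:
                return "+inf"
            if x == -math.inf:
                return "-inf"
            return x

        return {
            "kind": self.kind.value,
            "point": self.point,
            "undefined_point": self.undefined_point,
            "interval_type": self.interval_type,
            "interval": [bound(self.interval[0]), bound(self.interval[1])],
            "rd_basis": self.rd_basis.to_json_obj(),
        }

    def format(self) -> str:
        """Compact display, e.g. ``NNH 93 (-inf, -67] U [22, +inf)``."""
        label = "undefined" if self.point is None else str(self.point)
        if self.interval_type == "finite":
            lo, hi = self.interval
            return f"{self.kind.value} {label} ({_fmt_bound(lo)}, {_fmt_bound(hi)})"
        a, b = self.interval
        return f"{self.kind.value} {label} (-inf, {_fmt_bound(a)}] U [{_fmt_bound(b)}, +inf)"


def _fmt_bound(x: float) -> str:
    if x == math.inf:
        return "+inf"
    if x == -math.inf:
        return "-inf"
    return str(int(x))


def nnt(
    cmp: TwoArmComparison, method: str = "newcombe_hybrid", level: float = 0.95
) -> NNTResult:
    """Number needed to treat/harm with Altman-style interval inversion.

    The point estimate is ceil(1 / |rd|). The label is NNT when the
    treatment does better (more of a favorable outcome, or fewer of an
    unfavorable one) and NNH when it does worse. Inverted CI bounds are
    rounded with mathematical ceiling.
    """
    rd_res = risk_difference(cmp, method=method, level=level)
    rd = rd_res.rd
    treatment_better = (rd > 0) == (cmp.direction == Direction.favorable) and rd != 0
    if rd == 0.0:
        kind = NNTKind.NNT if cmp.direction == Direction.favorable else NNTKind.NNH
        point, undefined = None, True
    else:
        kind = NNTKind.NNT if treatment_better else NNTKind.NNH
        point, undefined = math.ceil(1.0 / abs(rd)), False

    lower, upper = rd_res.lower, rd_res.upper
    if rd_res.contains_zero():
        # 0 in the RD interval: inversion yields two half-infinite pieces.
        a = _inv_ceil(lower) if lower < 0 else -math.inf
        b = _inv_ceil(upper) if upper > 0 else math.inf
        return NNTResult(
            kind=kind,
            point=point,
            rd_basis=rd_res,
            interval_type="disjoint_union",
            interval=(a, b),
            undefined_point=undefined,
        )
    # Both bounds share a sign; invert magnitudes (order flips under 1/x).
    m_near, m_far = sorted((abs(lower), abs(upper)))
    return NNTResult(
        kind=kind,
        point=point,
        rd_basis=rd_res,
        interval_type="finite",
        interval=(math.ceil(1.0 / m_far), math.ceil(1.0 / m_near)),
        undefined_point=undefined,
    )


@dataclass(frozen=True)
class RelativeRiskResult:
    """Risk ratio p_t / p_c with a log-scale normal-approximation CI."""

    rr: float
    lower: float
    upper: float
    level: float
    continuity_corrected: bool = False

    def to_json_obj(self) -> dict[str, Any]:
        def bound(x: float) -> float | str:
            return "+inf" if x == math.inf else x

        return {
            "rr": bound(self.rr),
            "lower": bound(self.lower),
            "upper": bound(self.upper),
            "level": self.level,
            "continuity_corrected": self.continuity_corrected,
        }


def relative_risk(cmp: TwoArmComparison, level: float = 0.95) -> RelativeRiskResult:
    """Risk ratio with the log-ratio normal method.

    The point estimate always uses the raw counts (0 or inf at the
    boundaries). When any cell of the 2x2 table is zero the CI is
    computed after adding 0.5 to all four cells (Haldane-Anscombe) and
    the result is flagged ``continuity_corrected``.
    """
    _check_level(level)
    x_t, n_t = cmp.treatment.events, cmp.treatment.total
    x_c, n_c = cmp.comparator.events, cmp.comparator.total
    if x_c == 0:
        point = math.inf if x_t > 0 else math.nan
    else:
        point = (x_t / n_t) / (x_c / n_c)
    zero_cell = 0 in (x_t, n_t - x_t, x_c, n_c - x_c)
    if zero_cell:
        x_t_, n_t_, x_c_, n_c_ = x_t + 0.5, n_t + 1.0, x_c + 0.5, n_c + 1.0
    else:
        x_t_, n_t_, x_c_, n_c_ = float(x_t), float(n_t), float(x_c), float(n_c)
    log_rr = math.log((x_t_ / n_t_) / (x_c_ / n_c_))
    se = math.sqrt(1 / x_t_ - 1 / n_t_ + 1 / x_c_ - 1 / n_c_)
    z = norm.ppf(0.5 + level / 2)
    return RelativeRiskResult(
        rr=0.0 if (x_t == 0 and x_c > 0) else point,
        lower=math.exp(log_rr - z * se),
        upper=math.exp(log_rr + z * se),
        level=level,
        continuity_corrected=zero_cell,
    )
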