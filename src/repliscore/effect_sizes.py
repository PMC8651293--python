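"""Effect-size standardization to a common SMD scale.

Heterogeneous experimental outcomes (two-group mean differences, survival
hazard ratios, correlations) are placed on the standardized mean difference
(SMD) scale so that original and replication results can be compared and
meta-analytically pooled with a single set of criteria.  Conversions follow
the standard approximations: hazard ratios scale by sqrt(3)/pi (logistic to
normal standard deviation ratio), and Pearson correlations are expressed as
the mean shift per chosen contrast on the independent variable.

All intervals use normal (z) critical values; the SMD estimates carry
large-sample normal-theory standard errors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Tuple

from scipy import stats

__all__ = [
    "EffectScale",
    "DirectionLabel",
    "EffectEstimate",
    "SMDEstimate",
    "InvalidInputError",
    "DegenerateInputError",
    "cohens_d_from_summary",
    "smd_from_log_hazard_ratio",
    "smd_from_correlation",
    "interval_from_se",
    "se_from_interval",
    "LOG_HR_TO_SMD",
]

#: Conversion factor from log hazard ratio to SMD: sqrt(3)/pi.
LOG_HR_TO_SMD = math.sqrt(3.0) / math.pi


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its domain."""


class DegenerateInputError(ValueError):
    """Raised when inputs are formally valid but carry no information
    (e.g. zero pooled standard deviation)."""


class EffectScale(str, enum.Enum):
    """Native scale on which an effect was reported."""

    COHENS_D = "cohens_d"
    COHENS_DZ = "cohens_dz"
    GLASS_DELTA = "glass_delta"
    LOG_HAZARD_RATIO = "log_hazard_ratio"
    PEARSON_R = "pearson_r"
    CLIFFS_DELTA = "cliffs_delta"
    IMAGE_ONLY = "image_only"


#: Scales that are already (a flavour of) standardized mean difference.
SMD_FAMILY = frozenset(
    {EffectScale.COHENS_D, EffectScale.COHENS_DZ, EffectScale.GLASS_DELTA}
)

#: Scales excluded from SMD-based computations (carried through for the
#: binary direction/significance criteria only).
NON_SMD_PASSTHROUGH = frozenset({EffectScale.CLIFFS_DELTA})


class DirectionLabel(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


@dataclass(frozen=True)
class EffectEstimate:
    """One experimental result on its native effect scale.

    Parameters
    ----------
    scale
        Native effect scale.
    estimate
        Point estimate in native units; ``None`` for image-only results.
    se
        Standard error, if reported.  When absent a confidence interval must
        be supplied (except for image-only results).
    ci_low, ci_high
        Reported confidence-interval bounds (95% unless stated otherwise by
        the data source).
    n1, n2, n_total
        Per-arm and total sample sizes where available.
    p_value
        Reported (native-scale) p-value.
    direction_label
        Direction for image-only results without a numeric estimate.
    """

    scale: EffectScale
    estimate: Optional[float] = None
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n1: Optional[int] = None
    n2: Optional[int] = None
    n_total: Optional[int] = None
    p_value: Optional[float] = None
    direction_label: DirectionLabel = DirectionLabel.NONE

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise InvalidInputError("ci_low must not exceed ci_high")
        if self.se is not None and self.se < 0:
            raise InvalidInputError("se must be nonnegative")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError("p_value must lie in [0, 1]")
        if (
            self.scale == EffectScale.PEARSON_R
            and self.estimate is not None
            and abs(self.estimate) >= 1.0
        ):
            raise InvalidInputError("correlation out of open interval (-1, 1)")
        if (
            self.se is None
            and self.scale != EffectScale.IMAGE_ONLY
            and (self.ci_low is None or self.ci_high is None)
            and self.estimate is not None
        ):
            raise InvalidInputError(
                "se absent: a confidence interval is required for numeric scales"
            )

    @property
    def direction(self) -> int:
        """Sign of the result: +1, -1, or 0 when undetermined."""
        if self.estimate is not None:
            if self.estimate > 0:
                return 1
            if self.estimate < 0:
                return -1
            return 0
        if self.direction_label == DirectionLabel.POSITIVE:
            return 1
        if self.direction_label == DirectionLabel.NEGATIVE:
            return -1
        return 0


@dataclass(frozen=True)
class SMDEstimate:
    """An effect standardized to the SMD scale with its standard error."""

    smd: float
    se: float
    source_scale: EffectScale = EffectScale.COHENS_D

    def __post_init__(self) -> None:
        if not (math.isfinite(self.smd) and math.isfinite(self.se)):
            raise InvalidInputError("SMD estimate must be finite")
        if self.se <= 0:
            raise InvalidInputError("SMD se must be strictly positive")

    def ci(self, level: float = 0.95) -> Tuple[float, float]:
        return interval_from_se(self.smd, self.se, level)

    @property
    def z(self) -> float:
        return self.smd / self.se

    @property
    def p_value(self) -> float:
        """Two-sided normal-theory p-value against SMD = 0."""
        return 2.0 * stats.norm.sf(abs(self.z))


# ---------------------------------------------------------------------------
# Conversions


def cohens_d_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> SMDEstimate:
    """Cohen's d from two-group summary statistics.

    d = (m1 - m2) / s_pooled, with the pooled SD weighted by degrees of
    freedom, and the usual large-sample standard error

        se = sqrt((n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2))).

    No small-sample (Hedges) correction is applied.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("need at least 2 observations per group")
    if s1 <= 0 or s2 <= 0:
        raise InvalidInputError("group SDs must be strictly positive")
    s_pooled = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise DegenerateInputError("pooled SD is zero")
    d = (m1 - m2) / s_pooled
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return SMDEstimate(smd=d, se=se, source_scale=EffectScale.COHENS_D)


def smd_from_log_hazard_ratio(log_hr: float, se_log_hr: float) -> SMDEstimate:
    """Approximate SMD from a log hazard ratio.

    Scales by sqrt(3)/pi, the conversion between the logistic and normal
    standard deviations; the same linear factor applies to the SE.
    """
    if se_log_hr <= 0:
        raise InvalidInputError("se of log hazard ratio must be positive")
    return SMDEstimate(
        smd=log_hr * LOG_HR_TO_SMD,
        se=se_log_hr * LOG_HR_TO_SMD,
        source_scale=EffectScale.LOG_HAZARD_RATIO,
    )


def smd_from_correlation(r: float, n: int, contrast_sd: float = 1.0) -> SMDEstimate:
    """SMD implied by a Pearson correlation for a chosen contrast.

    For a bivariate-normal (X, Y) pair, a shift of ``contrast_sd`` standard
    deviations on X shifts Y by r / sqrt(1 - r^2) residual SDs, giving

        smd = contrast_sd * r / sqrt(1 - r^2).

    The SE follows by the delta method with var(r) = (1 - r^2)^2 / (n - 1):
    d(smd)/dr = contrast_sd * (1 - r^2)^(-3/2), hence

        se = contrast_sd / (sqrt(1 - r^2) * sqrt(n - 1)).
    """
    if abs(r) >= 1.0:
        raise InvalidInputError("correlation out of open interval (-1, 1)")
    if n < 4:
        raise InvalidInputError("need n >= 4 for the correlation conversion")
    if contrast_sd <= 0:
        raise InvalidInputError("contrast_sd must be positive")
    one_minus = 1.0 - r * r
    smd = contrast_sd * r / math.sqrt(one_minus)
    se = contrast_sd / (math.sqrt(one_minus) * math.sqrt(n - 1))
    return SMDEstimate(smd=smd, se=se, source_scale=EffectScale.PEARSON_R)


# ---------------------------------------------------------------------------
# Interval plumbing


def interval_from_se(est: float, se: float, level: float = 0.95) -> Tuple[float, float]:
    """Symmetric normal-theory interval est +/- z_{(1+level)/2} * se."""
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must lie in (0, 1)")
    if se <= 0:
        raise InvalidInputError("se must be positive")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return est - z * se, est + z * se


def se_from_interval(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Back-compute a standard error from a symmetric normal interval."""
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must lie in (0, 1)")
    if ci_high < ci_low:
        raise InvalidInputError("ci_high must be >= ci_low")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return (ci_high - ci_low) / (2.0 * z)


def smd_from_effect(effect: EffectEstimate) -> Optional[SMDEstimate]:
    """Standardize a native-scale effect to SMD where possible.

    Returns ``None`` for image-only results with no numeric estimate and for
    nonparametric scales (Cliff's delta) that are carried through on the
    native scale for the binary criteria but excluded from SMD arithmetic.
    """
    if effect.scale == EffectScale.IMAGE_ONLY and effect.estimate is None:
        return None
    if effect.scale in NON_SMD_PASSTHROUGH:
        return None
    if effect.estimate is None:
        return None

    se = effect.se
    if se is None and effect.ci_low is not None and effect.ci_high is not None:
        se = se_from_interval(effect.ci_low, effect.ci_high)
    if se is None or se <= 0:
        return None

    if effect.scale == EffectScale.LOG_HAZARD_RATIO:
        return smd_from_log_hazard_ratio(effect.estimate, se)
    if effect.scale == EffectScale.PEARSON_R:
        n = effect.n_total if effect.n_total is not None else 0
        if n >= 4:
            return smd_from_correlation(effect.estimate, n)
        return None
    # SMD-family scales and image-derived mean differences pass through.
    return SMDEstimate(smd=effect.estimate, se=se, source_scale=effect.scale)
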