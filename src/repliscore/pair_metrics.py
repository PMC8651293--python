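"""Replication-success criteria for a single original/replication pair.

A pair is scored on seven criteria:

1. same direction — sign agreement of the two estimates;
2. significance agreement — replication significant in the original's
   direction (positive originals) or non-significant (null originals);
3. original estimate inside the replication's 95% CI;
4. replication estimate inside the original's 95% CI;
5. replication estimate inside the original's 95% prediction interval,
   summarized continuously by ``p_orig`` — the p-value for the hypothesis
   that original and replication share one population effect size;
6. effect-size comparison — whether the replication effect is at least as
   large as the original along the claimed direction;
7. fixed-effect meta-analytic pooling of the two estimates.

Criteria 2-5 and 7 form the five-criterion tally applied to both positive
and null originals; criteria 1 and 6 have a 50% floor/ceiling under noise
and are not part of the tally.  An optional within-pair heterogeneity SD
``tau`` (on the SMD scale) widens the prediction interval, p_orig, and the
expected-significance computation; confidence intervals never use tau.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

from scipy import stats

from .effect_sizes import (
    DirectionLabel,
    EffectEstimate,
    InvalidInputError,
    SMDEstimate,
    interval_from_se,
    smd_from_effect,
)

__all__ = [
    "Tristate",
    "Interpretation",
    "Reporting",
    "Moderators",
    "HeterogeneityConfig",
    "PairRecord",
    "PairAssessment",
    "same_direction",
    "significance_agreement",
    "ci_inclusion",
    "p_orig",
    "prediction_interval",
    "expected_significance",
    "es_comparison",
    "pooled_fixed_effect",
    "criteria_vector",
    "FIVE_CRITERIA",
]

ALPHA_DEFAULT = 0.05
CI_LEVEL_DEFAULT = 0.95


class Tristate(str, enum.Enum):
    SUCCESS = "success"
    FAILURE = "failure"
    NOT_APPLICABLE = "not_applicable"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("Tristate is not boolean; compare explicitly")


class Interpretation(str, enum.Enum):
    """Original authors' interpretation of their result.

    The label overrides the original p-value: effects interpreted as
    positive stay positive even with p >= 0.05, and vice versa.
    """

    POSITIVE = "positive"
    NULL = "null"


class Reporting(str, enum.Enum):
    NUMERIC = "numeric"
    IMAGE = "image"


@dataclass(frozen=True)
class Moderators:
    """Candidate moderators of replication success."""

    animal: Optional[bool] = None
    cro_lab: Optional[bool] = None
    core_lab: Optional[bool] = None
    materials_shared: Optional[str] = None  # {"no", "yes", "not_requested"}
    clarification_quality: Optional[int] = None  # 0..5, analyzed continuously

    def __post_init__(self) -> None:
        if self.materials_shared is not None and self.materials_shared not in (
            "no",
            "yes",
            "not_requested",
        ):
            raise InvalidInputError(
                f"unknown materials_shared level: {self.materials_shared!r}"
            )
        if self.clarification_quality is not None and not (
            0 <= self.clarification_quality <= 5
        ):
            raise InvalidInputError("clarification_quality must be in 0..5")


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Within-pair heterogeneity SD on the SMD scale.

    ``tau = 0`` is the main analysis; ``tau = 0.21`` is the sensitivity
    analysis value estimated from multisite replication projects.
    """

    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InvalidInputError("tau must be nonnegative")

    @property
    def tau2(self) -> float:
        return self.tau * self.tau


@dataclass(frozen=True)
class PairRecord:
    """One original/replication outcome pair with hierarchy IDs."""

    paper_id: str
    experiment_id: str
    effect_id: str
    outcome_id: str
    original: EffectEstimate
    replication: EffectEstimate
    original_interpretation: Interpretation = Interpretation.POSITIVE
    reporting: Reporting = Reporting.NUMERIC
    moderators: Moderators = field(default_factory=Moderators)

    @property
    def original_smd(self) -> Optional[SMDEstimate]:
        return smd_from_effect(self.original)

    @property
    def replication_smd(self) -> Optional[SMDEstimate]:
        return smd_from_effect(self.replication)


@dataclass
class PairAssessment:
    """Criterion outcomes for one pair.

    ``n_criteria_success`` / ``n_criteria_evaluable`` count only the five
    tally criteria (significance agreement, both CI inclusions, prediction
    interval, pooled meta-analysis).
    """

    outcome_id: str
    paper_id: str = ""
    experiment_id: str = ""
    effect_id: str = ""
    interpretation: Interpretation = Interpretation.POSITIVE
    reporting: Reporting = Reporting.NUMERIC
    same_direction: Tristate = Tristate.NOT_APPLICABLE
    significance_agreement: Tristate = Tristate.NOT_APPLICABLE
    orig_in_rep_ci: Tristate = Tristate.NOT_APPLICABLE
    rep_in_orig_ci: Tristate = Tristate.NOT_APPLICABLE
    pi_success: Tristate = Tristate.NOT_APPLICABLE
    p_orig: Optional[float] = None
    es_smaller: Tristate = Tristate.NOT_APPLICABLE
    pooled: Optional[SMDEstimate] = None
    pooled_p: Optional[float] = None
    meta_significant: Tristate = Tristate.NOT_APPLICABLE
    expected_sig: Optional[float] = None
    n_criteria_evaluable: int = 0
    n_criteria_success: int = 0


#: Names of the five tally criteria on PairAssessment.
FIVE_CRITERIA = (
    "significance_agreement",
    "orig_in_rep_ci",
    "rep_in_orig_ci",
    "pi_success",
    "meta_significant",
)

#: All seven criteria in presentation order.
SEVEN_CRITERIA = ("same_direction",) + FIVE_CRITERIA[:4] + ("es_smaller", "meta_significant")


# ---------------------------------------------------------------------------
# Individual criteria


def same_direction(pair: PairRecord) -> Tristate:
    """Sign agreement of original and replication effects.

    Not applicable to original null effects: "null" is an interpretation in
    significance testing, and most null estimates still carry an arbitrary
    direction.  A replication estimate of exactly zero does not support the
    claimed direction and counts as failure.
    """
    if pair.original_interpretation == Interpretation.NULL:
        return Tristate.NOT_APPLICABLE
    d_orig = pair.original.direction
    d_rep = pair.replication.direction
    if d_orig == 0:
        return Tristate.NOT_APPLICABLE
    if d_rep == 0:
        # nil replication estimate: direction undefined -> failure
        if pair.replication.estimate is None:
            return Tristate.NOT_APPLICABLE
        return Tristate.FAILURE
    return Tristate.SUCCESS if d_orig == d_rep else Tristate.FAILURE


def _replication_p(pair: PairRecord) -> Optional[float]:
    """Replication p-value: native-scale when recorded, else SMD normal theory."""
    if pair.replication.p_value is not None:
        return pair.replication.p_value
    smd = smd_from_effect(pair.replication)
    if smd is not None:
        return smd.p_value
    return None


def significance_agreement(pair: PairRecord, alpha: float = ALPHA_DEFAULT) -> Tristate:
    """Direction-and-significance criterion.

    Positive originals: success iff the replication is significant
    (strictly p < alpha) *and* in the original's direction.  Null
    originals: success iff the replication is non-significant, regardless
    of direction.
    """
    rep_p = _replication_p(pair)
    if rep_p is None:
        return Tristate.NOT_APPLICABLE
    if pair.original_interpretation == Interpretation.NULL:
        return Tristate.SUCCESS if rep_p >= alpha else Tristate.FAILURE
    if rep_p >= alpha:
        return Tristate.FAILURE
    d_orig = pair.original.direction
    d_rep = pair.replication.direction
    if d_orig == 0:
        return Tristate.NOT_APPLICABLE
    return Tristate.SUCCESS if d_rep == d_orig else Tristate.FAILURE


def ci_inclusion(
    point: float, interval_holder: SMDEstimate, level: float = CI_LEVEL_DEFAULT
) -> Tristate:
    """Whether ``point`` lies in the holder's normal-theory CI (closed)."""
    low, high = interval_from_se(interval_holder.smd, interval_holder.se, level)
    return Tristate.SUCCESS if low <= point <= high else Tristate.FAILURE


def p_orig(
    orig: SMDEstimate,
    rep: SMDEstimate,
    het: HeterogeneityConfig = HeterogeneityConfig(),
) -> float:
    """p-value for equality of the original and replication population effects.

    p = 2 (1 - Phi(|d_o - d_r| / sqrt(tau^2 + se_o^2 + se_r^2))).
    Nondecreasing in tau and in either SE; 1 when the estimates coincide.
    """
    denom = math.sqrt(het.tau2 + orig.se**2 + rep.se**2)
    z = abs(orig.smd - rep.smd) / denom
    return float(2.0 * stats.norm.sf(z))


def prediction_interval(
    orig: SMDEstimate,
    rep_se: float,
    het: HeterogeneityConfig = HeterogeneityConfig(),
    level: float = CI_LEVEL_DEFAULT,
) -> Tuple[float, float]:
    """Prediction interval of the original for a replication with SE rep_se.

    d_o +/- z sqrt(se_o^2 + rep_se^2 + tau^2).  A replication estimate
    falls inside iff p_orig > 1 - level (exact equivalence).
    """
    if rep_se <= 0:
        raise InvalidInputError("rep_se must be positive")
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * math.sqrt(orig.se**2 + rep_se**2 + het.tau2)
    return orig.smd - half, orig.smd + half


def expected_significance(
    orig: SMDEstimate,
    rep_se: float,
    het: HeterogeneityConfig = HeterogeneityConfig(),
    alpha: float = ALPHA_DEFAULT,
) -> float:
    """Probability the replication is significant in the original's direction.

    The replication estimate is modeled as Normal(d_o, se_o^2 + rep_se^2 +
    tau^2); significance requires |d_r| / rep_se to exceed the two-sided
    critical value with the correct sign.  Averaged over pairs this is the
    significance-agreement rate expected if every replication were
    statistically consistent with its original.
    """
    if rep_se <= 0:
        raise InvalidInputError("rep_se must be positive")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    sd = math.sqrt(orig.se**2 + rep_se**2 + het.tau2)
    if orig.smd >= 0:
        return float(stats.norm.sf((z_crit * rep_se - orig.smd) / sd))
    return float(stats.norm.cdf((-z_crit * rep_se - orig.smd) / sd))


def es_comparison(pair: PairRecord) -> Tristate:
    """Whether the replication effect is at least as large as the original.

    Measured along the original claim's direction; ties count as success.
    Not applicable to null originals (comparing magnitudes of noise is not
    meaningful) or when either numeric estimate is missing.
    """
    if pair.original_interpretation == Interpretation.NULL:
        return Tristate.NOT_APPLICABLE
    orig_smd = smd_from_effect(pair.original)
    rep_smd = smd_from_effect(pair.replication)
    if orig_smd is not None and rep_smd is not None:
        o, r = orig_smd.smd, rep_smd.smd
    elif pair.original.estimate is not None and pair.replication.estimate is not None:
        o, r = pair.original.estimate, pair.replication.estimate
    else:
        return Tristate.NOT_APPLICABLE
    sign = 1.0 if o >= 0 else -1.0
    return Tristate.SUCCESS if sign * r >= sign * o else Tristate.FAILURE


def pooled_fixed_effect(
    orig: SMDEstimate, rep: SMDEstimate
) -> Tuple[SMDEstimate, float]:
    """Inverse-variance fixed-effect pool of the two estimates.

    Equivalent to treating the two experiments as equally informative about
    one common effect; returns the pooled estimate and its two-sided
    normal-theory p-value.
    """
    w_o = 1.0 / orig.se**2
    w_r = 1.0 / rep.se**2
    est = (w_o * orig.smd + w_r * rep.smd) / (w_o + w_r)
    se = 1.0 / math.sqrt(w_o + w_r)
    pooled = SMDEstimate(smd=est, se=se, source_scale=orig.source_scale)
    return pooled, pooled.p_value


# ---------------------------------------------------------------------------
# Full assessment


def criteria_vector(
    pair: PairRecord,
    het: HeterogeneityConfig = HeterogeneityConfig(),
    alpha: float = ALPHA_DEFAULT,
    ci_level: float = CI_LEVEL_DEFAULT,
) -> PairAssessment:
    """Score one pair on all seven criteria and tally the five-criterion set.

    Non-evaluable criteria degrade to ``not_applicable`` and are excluded
    from both numerator and denominator of the tally.  The meta-analysis
    criterion is success when the pooled estimate is significant in the
    original's direction (positive originals) or non-significant (null
    originals, "stayed null").
    """
    out = PairAssessment(
        outcome_id=pair.outcome_id,
        paper_id=pair.paper_id,
        experiment_id=pair.experiment_id,
        effect_id=pair.effect_id,
        interpretation=pair.original_interpretation,
        reporting=pair.reporting,
    )
    out.same_direction = same_direction(pair)
    out.significance_agreement = significance_agreement(pair, alpha)
    out.es_smaller = es_comparison(pair)

    orig_smd = smd_from_effect(pair.original)
    rep_smd = smd_from_effect(pair.replication)

    if orig_smd is not None and rep_smd is not None:
        out.orig_in_rep_ci = ci_inclusion(orig_smd.smd, rep_smd, ci_level)
        out.rep_in_orig_ci = ci_inclusion(rep_smd.smd, orig_smd, ci_level)
        out.p_orig = p_orig(orig_smd, rep_smd, het)
        low, high = prediction_interval(orig_smd, rep_smd.se, het, ci_level)
        out.pi_success = (
            Tristate.SUCCESS if low <= rep_smd.smd <= high else Tristate.FAILURE
        )
        pooled, pooled_p = pooled_fixed_effect(orig_smd, rep_smd)
        out.pooled = pooled
        out.pooled_p = pooled_p
        if pair.original_interpretation == Interpretation.NULL:
            out.meta_significant = (
                Tristate.SUCCESS if pooled_p > alpha else Tristate.FAILURE
            )
        else:
            same_sign = (
                pooled.smd > 0
                if pair.original.direction > 0
                else (pooled.smd < 0 if pair.original.direction < 0 else False)
            )
            out.meta_significant = (
                Tristate.SUCCESS
                if (pooled_p < alpha and same_sign)
                else Tristate.FAILURE
            )
        if pair.original_interpretation == Interpretation.POSITIVE:
            out.expected_sig = expected_significance(orig_smd, rep_smd.se, het, alpha)

    evaluable = [
        getattr(out, name)
        for name in FIVE_CRITERIA
        if getattr(out, name) != Tristate.NOT_APPLICABLE
    ]
    out.n_criteria_evaluable = len(evaluable)
    out.n_criteria_success = sum(1 for t in evaluable if t == Tristate.SUCCESS)
    return out
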