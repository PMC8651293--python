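"""Aggregation of pairwise results across the outcome/effect/experiment/paper
hierarchy, and ensemble statistics over a collection of pairs.

Internal replications of one effect are combined by fixed-effect
(inverse-variance) meta-analysis, reflecting the assumption that they test
the same effect size.  Effects are combined into experiments, and
experiments into papers, with random-effects models (REML estimate of the
between-unit variance, DerSimonian-Laird fallback), since effects within an
experiment may be genuinely heterogeneous.  Positive- and null-interpreted
originals are kept in separate strata throughout.

Ensemble statistics: the harmonic-mean p-value for the global null over
p_orig values, Fisher's combined-probability test over replication
p-values, an exact binomial sign test for the share of shrunken effects,
and the Spearman rank correlation of original vs replication effect sizes.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effect_sizes import (
    EffectEstimate,
    EffectScale,
    InvalidInputError,
    SMDEstimate,
)
from .pair_metrics import (
    FIVE_CRITERIA,
    SEVEN_CRITERIA,
    HeterogeneityConfig,
    Interpretation,
    PairAssessment,
    PairRecord,
    Reporting,
    Tristate,
    criteria_vector,
)

logger = logging.getLogger("repliscore")

__all__ = [
    "Level",
    "SummaryTable",
    "CriteriaProfile",
    "combine_internal_replications",
    "random_effects_aggregate",
    "harmonic_mean_p",
    "sign_test_smaller",
    "fisher_combine",
    "rank_correlation",
    "aggregate_pairs",
    "assess_pairs",
    "summarize_criteria",
    "criteria_profile",
    "round_percent",
]


class Level(str, enum.Enum):
    OUTCOME = "outcome"
    EFFECT = "effect"
    EXPERIMENT = "experiment"
    PAPER = "paper"


#: Hierarchy order, finest first.
LEVEL_ORDER = (Level.OUTCOME, Level.EFFECT, Level.EXPERIMENT, Level.PAPER)


def round_percent(x: float) -> int:
    """Round half away from zero to an integer percent (display convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


# ---------------------------------------------------------------------------
# Meta-analytic pooling


def combine_internal_replications(outcomes: Sequence[SMDEstimate]) -> SMDEstimate:
    """Fixed-effect inverse-variance pool; a single outcome is returned as is."""
    if len(outcomes) == 0:
        raise InvalidInputError("need at least one outcome to combine")
    if len(outcomes) == 1:
        return outcomes[0]
    w = np.array([1.0 / o.se**2 for o in outcomes])
    y = np.array([o.smd for o in outcomes])
    est = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return SMDEstimate(smd=est, se=se, source_scale=outcomes[0].source_scale)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> Optional[float]:
    """REML estimate of the between-unit variance tau^2.

    Maximizes the restricted log-likelihood

        l(t) = -1/2 [ sum ln(v_i + t) + ln sum w_i + sum w_i (y_i - mu)^2 ]

    with w_i = 1/(v_i + t) and mu the weighted mean, over t >= 0.
    Returns None on failure (caller falls back to DerSimonian-Laird).
    """

    def neg_restricted_ll(t: float) -> float:
        w = 1.0 / (v + t)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + t))
            + math.log(np.sum(w))
            + np.sum(w * (y - mu) ** 2)
        )

    upper = max(float(np.var(y)) * 4.0, float(np.max(v)) * 4.0, 1e-6)
    try:
        res = optimize.minimize_scalar(
            neg_restricted_ll, bounds=(0.0, upper), method="bounded",
            options={"xatol": 1e-10},
        )
    except Exception:  # pragma: no cover - defensive
        return None
    if not res.success:
        return None
    # the bounded optimum can sit at 0 legitimately (homogeneous data)
    if neg_restricted_ll(0.0) <= res.fun:
        return 0.0
    return float(res.x)


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimate of tau^2 (truncated at 0)."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def random_effects_aggregate(
    estimates: Sequence[SMDEstimate], method: str = "reml"
) -> Tuple[SMDEstimate, float]:
    """Random-effects pool of several estimates; returns (pooled, tau2_hat).

    With a single estimate the input is returned unchanged (tau2 = 0).  With
    exactly two, heterogeneity is barely estimable and the tau^2 estimate
    should be treated with caution (a warning is logged).  REML is the
    default estimator; on failure, or with ``method="dl"``, the
    DerSimonian-Laird moment estimator is used.
    """
    k = len(estimates)
    if k == 0:
        raise InvalidInputError("need at least one estimate to aggregate")
    if k == 1:
        return estimates[0], 0.0
    if k == 2:
        logger.debug(
            "random-effects pool of only two units: tau^2 estimate is unstable"
        )
    y = np.array([e.smd for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    tau2: Optional[float]
    if method == "reml":
        tau2 = _reml_tau2(y, v)
        if tau2 is None:
            logger.warning("REML did not converge; falling back to DerSimonian-Laird")
            tau2 = _dl_tau2(y, v)
    elif method == "dl":
        tau2 = _dl_tau2(y, v)
    else:
        raise InvalidInputError(f"unknown random-effects estimator: {method!r}")
    w = 1.0 / (v + tau2)
    est = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return SMDEstimate(smd=est, se=se, source_scale=estimates[0].source_scale), float(tau2)


# ---------------------------------------------------------------------------
# Ensemble statistics


def harmonic_mean_p(ps: Sequence[float], calibrated: bool = False) -> float:
    """Harmonic mean of p-values: k / sum(1/p_i).

    Robust to dependence among the p-values (nested pairs).  The raw
    harmonic mean is returned by default; with ``calibrated=True`` an
    asymptotically exact tail probability is returned instead, using the
    Landau-distribution approximation for the mean of reciprocal uniform
    p-values (equal weights).
    """
    ps_arr = np.asarray(ps, dtype=float)
    if ps_arr.size == 0:
        raise InvalidInputError("need at least one p-value")
    if np.any(ps_arr <= 0) or np.any(ps_arr > 1):
        raise InvalidInputError("p-values must lie in (0, 1]")
    k = ps_arr.size
    hmp = k / float(np.sum(1.0 / ps_arr))
    if not calibrated:
        return float(hmp)
    # mean reciprocal x = 1/hmp is asymptotically Landau(log k + 0.874, pi/2)
    x = 1.0 / hmp
    loc = math.log(k) + 0.874367040387922
    p_cal = float(stats.landau.sf(x, loc=loc, scale=math.pi / 2.0))
    return min(1.0, max(0.0, p_cal))


def sign_test_smaller(k_smaller: int, n: int) -> float:
    """Two-sided exact binomial test of k 'smaller' outcomes in n at null 1/2.

    p = min(1, 2 min(P(X <= k), P(X >= k))).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not (0 <= k_smaller <= n):
        raise InvalidInputError("k must lie in [0, n]")
    lower = float(stats.binom.cdf(k_smaller, n, 0.5))
    upper = float(stats.binom.sf(k_smaller - 1, n, 0.5))
    return min(1.0, 2.0 * min(lower, upper))


def fisher_combine(ps: Sequence[float]) -> Tuple[float, int, float]:
    """Fisher's combined-probability test: chi^2 = -2 sum ln p_i, df = 2k."""
    ps_arr = np.asarray(ps, dtype=float)
    if ps_arr.size == 0:
        raise InvalidInputError("need at least one p-value")
    if np.any(ps_arr <= 0) or np.any(ps_arr > 1):
        raise InvalidInputError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(ps_arr)))
    df = 2 * int(ps_arr.size)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def rank_correlation(
    orig: Sequence[float], rep: Sequence[float]
) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    if len(orig) != len(rep):
        raise InvalidInputError("vectors must have equal length")
    if len(orig) < 3:
        raise InvalidInputError("need at least 3 pairs")
    res = stats.spearmanr(orig, rep)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Hierarchical aggregation of pair records

#: Grouping keys per level (strata kept separate at every level).
_LEVEL_KEYS = {
    Level.EFFECT: ("paper_id", "experiment_id", "effect_id"),
    Level.EXPERIMENT: ("paper_id", "experiment_id"),
    Level.PAPER: ("paper_id",),
}


def _estimate_from_smd(smd: SMDEstimate) -> EffectEstimate:
    return EffectEstimate(
        scale=EffectScale.COHENS_D, estimate=smd.smd, se=smd.se
    )


def _group_pairs(
    records: Sequence[PairRecord], keys: Tuple[str, ...]
) -> Dict[tuple, List[PairRecord]]:
    groups: Dict[tuple, List[PairRecord]] = {}
    for rec in records:
        key = tuple(getattr(rec, k) for k in keys) + (
            rec.original_interpretation,
            rec.reporting,
        )
        groups.setdefault(key, []).append(rec)
    return groups


def aggregate_pairs(
    records: Sequence[PairRecord], level: Level, re_method: str = "reml"
) -> List[PairRecord]:
    """Aggregate outcome-level pair records up to the requested level.

    Outcomes within an effect (internal replications) are pooled by
    fixed-effect meta-analysis; effects within an experiment, and
    experiments within a paper, by random-effects models.  Aggregation is
    stratified by interpretation (positive/null) and reporting
    (numeric/image), so one experiment can contribute an aggregate pair to
    more than one stratum.  Effects lacking an SMD on either side (image-only
    originals, nonparametric scales) are carried forward unchanged at the
    effect level, where the direction criteria still apply, but cannot enter
    the experiment- and paper-level meta-analytic pools.
    """
    if level == Level.OUTCOME:
        return list(records)

    def pool(recs: List[PairRecord], fixed: bool) -> Optional[PairRecord]:
        smds_o = [r.original_smd for r in recs]
        smds_r = [r.replication_smd for r in recs]
        if any(s is None for s in smds_o) or any(s is None for s in smds_r):
            usable = [
                (o, r, rec)
                for o, r, rec in zip(smds_o, smds_r, recs)
                if o is not None and r is not None
            ]
            if not usable:
                if fixed:
                    # image-only or native-scale effects: carried forward at
                    # the effect level (only the direction criteria apply)
                    if len(recs) > 1:
                        logger.debug(
                            "effect %s: no poolable outcomes; keeping first",
                            recs[0].effect_id,
                        )
                    return recs[0]
                return None
            smds_o = [u[0] for u in usable]
            smds_r = [u[1] for u in usable]
            recs = [u[2] for u in usable]
        if fixed:
            # internal replications share one original: pooling duplicates is
            # harmless (fixed-effect pool of identical estimates is identity
            # in value with an optimistic SE), so deduplicate first
            uniq = {(s.smd, s.se): s for s in smds_o}
            smds_o_u = list(uniq.values())
            agg_o = (
                smds_o_u[0]
                if len(smds_o_u) == 1
                else combine_internal_replications(smds_o_u)
            )
            agg_r = combine_internal_replications(smds_r)
        else:
            agg_o, _ = random_effects_aggregate(smds_o, re_method)
            agg_r, _ = random_effects_aggregate(smds_r, re_method)
        first = recs[0]
        return PairRecord(
            paper_id=first.paper_id,
            experiment_id=first.experiment_id if level != Level.PAPER else "*",
            effect_id=first.effect_id if level == Level.EFFECT else "*",
            outcome_id="*",
            original=_estimate_from_smd(agg_o),
            replication=_estimate_from_smd(agg_r),
            original_interpretation=first.original_interpretation,
            reporting=first.reporting,
            moderators=first.moderators,
        )

    # outcomes -> effects (fixed-effect pooling of internal replications)
    effect_groups = _group_pairs(records, _LEVEL_KEYS[Level.EFFECT])
    effects = [p for g in effect_groups.values() if (p := pool(g, fixed=True))]
    if level == Level.EFFECT:
        return effects

    exp_groups = _group_pairs(effects, _LEVEL_KEYS[Level.EXPERIMENT])
    experiments = [p for g in exp_groups.values() if (p := pool(g, fixed=False))]
    if level == Level.EXPERIMENT:
        return experiments

    paper_groups = _group_pairs(experiments, _LEVEL_KEYS[Level.PAPER])
    papers = [p for g in paper_groups.values() if (p := pool(g, fixed=False))]
    if level == Level.PAPER:
        return papers
    raise InvalidInputError(f"unknown aggregation level: {level!r}")


def assess_pairs(
    records: Sequence[PairRecord],
    level: Level = Level.OUTCOME,
    het: HeterogeneityConfig = HeterogeneityConfig(),
    alpha: float = 0.05,
    ci_level: float = 0.95,
    re_method: str = "reml",
) -> List[PairAssessment]:
    """Aggregate to the requested level and score every aggregated pair."""
    aggregated = aggregate_pairs(records, level, re_method)
    return [criteria_vector(p, het, alpha, ci_level) for p in aggregated]


# ---------------------------------------------------------------------------
# Summary tables


@dataclass
class SummaryTable:
    """Per-criterion success counts at one hierarchy level and stratum."""

    level: Level
    stratum: str  # e.g. "positive_numeric"
    rows: List[Tuple[str, int, int, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rows, columns=["criterion", "n_success", "n_evaluable", "percent"]
        )
        df["level"] = self.level.value
        df["stratum"] = self.stratum
        return df


@dataclass
class CriteriaProfile:
    """Histogram of five-criterion success tallies (Table-6 shape)."""

    level: Level
    counts: Dict[int, int]
    total: int

    @property
    def majority_success_rate(self) -> float:
        """Share of units succeeding on three or more of the five criteria."""
        if self.total == 0:
            return float("nan")
        return sum(v for k, v in self.counts.items() if k >= 3) / self.total


def _stratum_name(interpretation: Interpretation, reporting: Reporting) -> str:
    return f"{interpretation.value}_{reporting.value}"


def summarize_criteria(
    records: Sequence[PairAssessment],
    level: Level = Level.OUTCOME,
    stratum: Optional[str] = None,
) -> SummaryTable:
    """Tabulate success counts per criterion (Table-1 shape).

    ``records`` must already be at the requested level (see
    :func:`assess_pairs`); ``stratum`` filters to one
    interpretation/reporting stratum, e.g. ``"positive_numeric"``.
    """
    if not isinstance(level, Level):
        raise InvalidInputError(f"unknown level: {level!r}")
    selected = [
        a
        for a in records
        if stratum is None or _stratum_name(a.interpretation, a.reporting) == stratum
    ]
    rows: List[Tuple[str, int, int, float]] = []
    for name in SEVEN_CRITERIA:
        vals = [getattr(a, name) for a in selected]
        n_eval = sum(1 for v in vals if v != Tristate.NOT_APPLICABLE)
        n_succ = sum(1 for v in vals if v == Tristate.SUCCESS)
        pct = 100.0 * n_succ / n_eval if n_eval else float("nan")
        rows.append((name, n_succ, n_eval, pct))
    return SummaryTable(level=level, stratum=stratum or "all", rows=rows)


def criteria_profile(
    records: Sequence[PairAssessment], level: Level = Level.OUTCOME
) -> CriteriaProfile:
    """Histogram of the number of five-criterion successes (0..5).

    Only units evaluable on all five criteria enter, matching the
    convention that partial tallies are not comparable to full ones.
    """
    counts = {k: 0 for k in range(6)}
    total = 0
    for a in records:
        if a.n_criteria_evaluable == len(FIVE_CRITERIA):
            counts[a.n_criteria_success] += 1
            total += 1
    return CriteriaProfile(level=level, counts=counts, total=total)
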