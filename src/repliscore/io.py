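"""Master-table I/O, run configuration, and the end-to-end pipeline.

The master table is a flat CSV (UTF-8, comma-separated, "." decimal, header
row, empty fields for missing values): one row per outcome, with internal
replications as separate rows sharing an ``effect_id``.  Reading validates
every row; rows that fail validation are collected into a rejects report
with line numbers and reasons, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .aggregation import (
    Level,
    assess_pairs,
    criteria_profile,
    fisher_combine,
    harmonic_mean_p,
    rank_correlation,
    sign_test_smaller,
    summarize_criteria,
)
from .effect_sizes import (
    DirectionLabel,
    EffectEstimate,
    EffectScale,
    InvalidInputError,
)
from .moderators import fit_moderator_model, moderator_frame
from .pair_metrics import (
    HeterogeneityConfig,
    Interpretation,
    Moderators,
    PairRecord,
    Reporting,
    Tristate,
)

logger = logging.getLogger("repliscore")

__all__ = [
    "MASTER_COLUMNS",
    "RunConfig",
    "read_master_table",
    "write_master_table",
    "run_pipeline",
]

_SIDE_FIELDS = (
    "scale",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "n1",
    "n2",
    "n_total",
    "p_value",
    "direction_label",
)

MASTER_COLUMNS: Tuple[str, ...] = (
    ("paper_id", "experiment_id", "effect_id", "outcome_id")
    + tuple(f"original_{f}" for f in _SIDE_FIELDS)
    + tuple(f"replication_{f}" for f in _SIDE_FIELDS)
    + (
        "original_interpretation",
        "reporting",
        "animal",
        "cro_lab",
        "core_lab",
        "materials_shared",
        "clarification_quality",
    )
)

MANDATORY_COLUMNS = (
    "paper_id",
    "experiment_id",
    "effect_id",
    "outcome_id",
    "original_scale",
    "replication_scale",
    "original_interpretation",
    "reporting",
)


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration shared by the pipeline and the CLI."""

    alpha: float = 0.05
    ci_level: float = 0.95
    tau: float = 0.0
    re_estimator: str = "reml"
    hmp_calibrated: bool = False
    levels: Tuple[str, ...] = ("outcome", "effect", "experiment", "paper")
    sensitivity_tau: Optional[float] = None  # e.g. 0.21 to add a re-run
    moderator_metrics: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError("alpha must lie in (0, 1)")
        if not (0.0 < self.ci_level < 1.0):
            raise InvalidInputError("ci_level must lie in (0, 1)")
        if self.tau < 0:
            raise InvalidInputError("tau must be nonnegative")
        if self.re_estimator not in ("reml", "dl"):
            raise InvalidInputError(f"unknown estimator: {self.re_estimator!r}")
        for lv in self.levels:
            Level(lv)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "levels" in data:
            data["levels"] = tuple(data["levels"])
        if "moderator_metrics" in data:
            data["moderator_metrics"] = tuple(data["moderator_metrics"])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Master-table serialization


def _effect_to_row(side: str, e: EffectEstimate) -> Dict[str, object]:
    row: Dict[str, object] = {}
    for f in _SIDE_FIELDS:
        v = getattr(e, f)
        if f == "scale":
            v = e.scale.value
        elif f == "direction_label":
            v = e.direction_label.value
        row[f"{side}_{f}"] = v
    return row


def write_master_table(records: Sequence[PairRecord], path: str | Path) -> None:
    """Serialize pair records to the master-table CSV dialect."""
    rows = []
    for r in records:
        row: Dict[str, object] = {
            "paper_id": r.paper_id,
            "experiment_id": r.experiment_id,
            "effect_id": r.effect_id,
            "outcome_id": r.outcome_id,
        }
        row.update(_effect_to_row("original", r.original))
        row.update(_effect_to_row("replication", r.replication))
        m = r.moderators
        row.update(
            {
                "original_interpretation": r.original_interpretation.value,
                "reporting": r.reporting.value,
                "animal": None if m.animal is None else int(m.animal),
                "cro_lab": None if m.cro_lab is None else int(m.cro_lab),
                "core_lab": None if m.core_lab is None else int(m.core_lab),
                "materials_shared": m.materials_shared,
                "clarification_quality": m.clarification_quality,
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(MASTER_COLUMNS))
    df.to_csv(path, index=False)


def _parse_optional_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _parse_optional_int(v) -> Optional[int]:
    f = _parse_optional_float(v)
    return None if f is None else int(f)


def _row_to_effect(side: str, row: pd.Series) -> EffectEstimate:
    scale = EffectScale(str(row[f"{side}_scale"]))
    label_raw = row.get(f"{side}_direction_label")
    label = (
        DirectionLabel(str(label_raw))
        if isinstance(label_raw, str) and label_raw
        else DirectionLabel.NONE
    )
    return EffectEstimate(
        scale=scale,
        estimate=_parse_optional_float(row.get(f"{side}_estimate")),
        se=_parse_optional_float(row.get(f"{side}_se")),
        ci_low=_parse_optional_float(row.get(f"{side}_ci_low")),
        ci_high=_parse_optional_float(row.get(f"{side}_ci_high")),
        n1=_parse_optional_int(row.get(f"{side}_n1")),
        n2=_parse_optional_int(row.get(f"{side}_n2")),
        n_total=_parse_optional_int(row.get(f"{side}_n_total")),
        p_value=_parse_optional_float(row.get(f"{side}_p_value")),
        direction_label=label,
    )


def read_master_table(
    path: str | Path,
) -> Tuple[List[PairRecord], pd.DataFrame]:
    """Read and validate a master-table CSV.

    Returns ``(records, rejects)`` where ``rejects`` is a report of rows
    that failed validation, with 1-based data line numbers and reasons.
    Extra columns are ignored with a warning; a missing mandatory column is
    a schema error.
    """
    # keep_default_na so the literal interpretation label "null" survives;
    # only empty fields are missing values
    df = pd.read_csv(
        path, keep_default_na=False, na_values=[""], float_precision="round_trip"
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in MASTER_COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s): %s", ", ".join(extra))

    records: List[PairRecord] = []
    rejects = []
    seen_outcomes = set()
    for i, row in df.iterrows():
        line = int(i) + 1
        try:
            oid = str(row["outcome_id"])
            if not oid or oid == "nan":
                raise InvalidInputError("empty outcome_id")
            if oid in seen_outcomes:
                raise InvalidInputError(f"duplicate outcome_id {oid!r}")
            ms = row.get("materials_shared")
            cq = _parse_optional_int(row.get("clarification_quality"))
            animal = _parse_optional_int(row.get("animal"))
            cro = _parse_optional_int(row.get("cro_lab"))
            core = _parse_optional_int(row.get("core_lab"))
            rec = PairRecord(
                paper_id=str(row["paper_id"]),
                experiment_id=str(row["experiment_id"]),
                effect_id=str(row["effect_id"]),
                outcome_id=oid,
                original=_row_to_effect("original", row),
                replication=_row_to_effect("replication", row),
                original_interpretation=Interpretation(
                    str(row["original_interpretation"])
                ),
                reporting=Reporting(str(row["reporting"])),
                moderators=Moderators(
                    animal=None if animal is None else bool(animal),
                    cro_lab=None if cro is None else bool(cro),
                    core_lab=None if core is None else bool(core),
                    materials_shared=(
                        str(ms) if isinstance(ms, str) and ms else None
                    ),
                    clarification_quality=cq,
                ),
            )
            seen_outcomes.add(oid)
            records.append(rec)
        except (InvalidInputError, ValueError) as exc:
            rejects.append({"line": line, "reason": str(exc)})
            logger.warning("rejected master-table row %d: %s", line, exc)
    return records, pd.DataFrame(rejects, columns=["line", "reason"])


# ---------------------------------------------------------------------------
# Pipeline


def _es_statistics(
    records: Sequence[PairRecord], hmp_calibrated: bool
) -> Dict[str, object]:
    """Effect-size comparison statistics over positive pairs with both SMDs."""
    orig_vals, rep_vals, p_origs, rep_ps = [], [], [], []
    from .pair_metrics import criteria_vector  # deferred: avoid cycle at import

    for rec in records:
        if rec.original_interpretation != Interpretation.POSITIVE:
            continue
        o, r = rec.original_smd, rec.replication_smd
        if o is None or r is None:
            continue
        orig_vals.append(o.smd)
        rep_vals.append(r.smd)
        a = criteria_vector(rec)
        if a.p_orig is not None:
            p_origs.append(max(a.p_orig, 1e-300))
        rep_p = rec.replication.p_value
        if rep_p is not None:
            rep_ps.append(max(rep_p, 1e-300))

    out: Dict[str, object] = {"n_pairs": len(orig_vals)}
    if not orig_vals:
        return out
    orig_arr, rep_arr = np.array(orig_vals), np.array(rep_vals)
    sign = np.where(orig_arr >= 0, 1.0, -1.0)
    k_smaller = int(np.sum(sign * rep_arr < sign * orig_arr))
    out.update(
        {
            "median_original": float(np.median(orig_arr)),
            "iqr_original": [
                float(np.percentile(orig_arr, 25)),
                float(np.percentile(orig_arr, 75)),
            ],
            "median_replication": float(np.median(rep_arr)),
            "iqr_replication": [
                float(np.percentile(rep_arr, 25)),
                float(np.percentile(rep_arr, 75)),
            ],
            "n_smaller": k_smaller,
            "sign_test_p": sign_test_smaller(k_smaller, len(orig_vals)),
        }
    )
    if len(orig_vals) >= 3:
        rho, p = rank_correlation(orig_vals, rep_vals)
        out["spearman_rho"] = rho
        out["spearman_p"] = p
    if p_origs:
        out["median_p_orig"] = float(np.median(p_origs))
        out["hmp_p_orig"] = harmonic_mean_p(p_origs, calibrated=hmp_calibrated)
    if rep_ps:
        chi2, df, p = fisher_combine(rep_ps)
        out["fisher_chi2"] = chi2
        out["fisher_df"] = df
        out["fisher_p"] = p
    return out


def run_pipeline(
    config: RunConfig,
    records: Sequence[PairRecord],
    out_dir: Optional[str | Path] = None,
) -> Dict[str, object]:
    """Score, aggregate and summarize a full pair ensemble.

    Returns a result bundle: per-level assessments, summary tables for each
    interpretation/reporting stratum, five-criterion profiles, effect-size
    comparison statistics, optional moderator fits, and an optional
    sensitivity re-run at another heterogeneity value.  When ``out_dir`` is
    given, tables are written as CSV and the scalar statistics as JSON,
    stamped with the config hash and seed.
    """
    if not records:
        raise InvalidInputError("no records to analyze")
    het = HeterogeneityConfig(tau=config.tau)
    strata = [
        f"{i}_{r}"
        for i in ("positive", "null")
        for r in ("numeric", "image")
    ]

    bundle: Dict[str, object] = {"config_hash": config.digest(), "seed": config.seed}
    assessments_by_level = {}
    tables = []
    profiles = {}
    for lv_name in config.levels:
        lv = Level(lv_name)
        assessments = assess_pairs(
            records, lv, het, config.alpha, config.ci_level, config.re_estimator
        )
        assessments_by_level[lv_name] = assessments
        for stratum in strata:
            tables.append(summarize_criteria(assessments, lv, stratum))
        profiles[lv_name] = criteria_profile(assessments, lv)
    bundle["assessments"] = assessments_by_level
    bundle["summary_tables"] = tables
    bundle["profiles"] = profiles
    bundle["es_statistics"] = _es_statistics(records, config.hmp_calibrated)

    if config.moderator_metrics:
        outcome_assessments = assessments_by_level.get(
            "outcome",
            assess_pairs(records, Level.OUTCOME, het, config.alpha, config.ci_level),
        )
        frame = moderator_frame(list(records), outcome_assessments)
        fits = {}
        for metric in config.moderator_metrics:
            try:
                fits[metric] = fit_moderator_model(frame, metric)
            except InvalidInputError as exc:
                logger.warning("moderator fit for %r skipped: %s", metric, exc)
        bundle["moderator_fits"] = fits

    if config.sensitivity_tau is not None:
        het_s = HeterogeneityConfig(tau=config.sensitivity_tau)
        sens = assess_pairs(
            records, Level.EFFECT, het_s, config.alpha, config.ci_level
        )
        bundle["sensitivity"] = {
            "tau": config.sensitivity_tau,
            "assessments": sens,
            "pi_success_count": sum(
                1 for a in sens if a.pi_success == Tristate.SUCCESS
            ),
        }

    if out_dir is not None:
        _write_bundle(bundle, config, Path(out_dir))
    return bundle


def _write_bundle(bundle: Dict[str, object], config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": bundle["config_hash"], "seed": config.seed}
    tables: List = bundle["summary_tables"]  # type: ignore[assignment]
    frames = [t.to_frame() for t in tables]
    summary = pd.concat(frames, ignore_index=True)
    summary["config_hash"] = stamp["config_hash"]
    summary = summary[
        ["criterion", "n_success", "n_evaluable", "percent", "level", "stratum", "config_hash"]
    ]
    summary.to_csv(out_dir / "summary_tables.csv", index=False)

    profile_rows = []
    for lv, prof in bundle["profiles"].items():  # type: ignore[union-attr]
        for k, v in prof.counts.items():
            profile_rows.append(
                {"level": lv, "n_success": k, "count": v, "total": prof.total}
            )
    pd.DataFrame(profile_rows).to_csv(out_dir / "criteria_profiles.csv", index=False)

    scalars = dict(stamp)
    scalars["es_statistics"] = bundle["es_statistics"]
    with open(out_dir / "statistics.json", "w", encoding="utf-8") as fh:
        json.dump(scalars, fh, indent=2)

    if "moderator_fits" in bundle:
        fits = bundle["moderator_fits"]
        if fits:
            mod = pd.concat([f.to_frame() for f in fits.values()], ignore_index=True)
            mod["config_hash"] = stamp["config_hash"]
            mod.to_csv(out_dir / "moderator_fits.csv", index=False)
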