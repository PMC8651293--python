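"""Moderator meta-regression with clustering-aware inference.

Each replication-success metric (binary criteria as 0/1 linear-probability
outcomes, or continuous metrics such as p_orig and the original-minus-
replication difference) is regressed on five candidate moderators
simultaneously: animal vs in-vitro experiment, CRO replication lab,
academic core-facility lab, materials sharing (three-level factor), and
clarification quality (0-5, continuous).

The working model is a linear mixed model with random intercepts for
experiments nested in papers; metrics that carry known sampling variances
are additionally weighted by inverse variance (a meta-regression).
Variance components are estimated by REML on the profiled likelihood, and
coefficient inference uses CR2 small-sample-adjusted cluster-robust
standard errors at the paper level with t reference distribution on
(clusters - 1) degrees of freedom.  Bonferroni correction multiplies raw
p-values by the number of candidate moderators (five).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effect_sizes import InvalidInputError
from .pair_metrics import PairAssessment, PairRecord, Tristate

logger = logging.getLogger("repliscore")

__all__ = [
    "ModeratorFit",
    "MODERATOR_TERMS",
    "N_MODERATORS",
    "moderator_frame",
    "fit_moderator_model",
    "point_biserial_matrix",
]

#: Number of candidate moderators (Bonferroni multiplier).
N_MODERATORS = 5

#: Design columns generated from the Moderators record.  materials_shared
#: enters as two indicator contrasts against reference level "no".
MODERATOR_TERMS = (
    "animal",
    "cro_lab",
    "core_lab",
    "materials_shared_yes",
    "materials_shared_not_requested",
    "clarification_quality",
)


@dataclass
class ModeratorFit:
    """Result of one moderator regression."""

    metric_name: str
    coefficients: List[Tuple[str, float, float, float, float]] = field(
        default_factory=list
    )  # (name, estimate, robust_se, p_raw, p_bonferroni)
    n_pairs: int = 0
    n_clusters: int = 0
    dropped_terms: List[str] = field(default_factory=list)
    variance_components: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coefficients,
            columns=["term", "estimate", "robust_se", "p_raw", "p_bonferroni"],
        )
        df["metric"] = self.metric_name
        return df


# ---------------------------------------------------------------------------
# Design-matrix construction


def _tristate_to_float(t: Tristate) -> float:
    if t == Tristate.SUCCESS:
        return 1.0
    if t == Tristate.FAILURE:
        return 0.0
    return float("nan")


def moderator_frame(
    records: Sequence[PairRecord], assessments: Sequence[PairAssessment]
) -> pd.DataFrame:
    """Build the analysis frame: metrics, metric variances, moderators, IDs.

    Binary criteria become 0/1 columns; continuous metrics are ``p_orig``,
    ``es_difference`` (replication minus original SMD, with its sampling
    variance) and ``pooled_estimate`` (with variance).  Rows missing a
    metric are dropped per-metric at fit time, not here.
    """
    if len(records) != len(assessments):
        raise InvalidInputError("records and assessments must align")
    rows = []
    for rec, a in zip(records, assessments):
        m = rec.moderators
        orig = rec.original_smd
        rep = rec.replication_smd
        es_diff = es_diff_var = None
        if orig is not None and rep is not None:
            es_diff = rep.smd - orig.smd
            es_diff_var = orig.se**2 + rep.se**2
        rows.append(
            {
                "paper_id": rec.paper_id,
                "experiment_id": rec.experiment_id,
                "effect_id": rec.effect_id,
                "outcome_id": rec.outcome_id,
                "significance_agreement": _tristate_to_float(a.significance_agreement),
                "orig_in_rep_ci": _tristate_to_float(a.orig_in_rep_ci),
                "rep_in_orig_ci": _tristate_to_float(a.rep_in_orig_ci),
                "pi_success": _tristate_to_float(a.pi_success),
                "meta_significant": _tristate_to_float(a.meta_significant),
                "same_direction": _tristate_to_float(a.same_direction),
                "p_orig": a.p_orig,
                "es_difference": es_diff,
                "es_difference_var": es_diff_var,
                "pooled_estimate": a.pooled.smd if a.pooled is not None else None,
                "pooled_estimate_var": a.pooled.se**2 if a.pooled is not None else None,
                "animal": None if m.animal is None else float(m.animal),
                "cro_lab": None if m.cro_lab is None else float(m.cro_lab),
                "core_lab": None if m.core_lab is None else float(m.core_lab),
                "materials_shared_yes": (
                    None if m.materials_shared is None else float(m.materials_shared == "yes")
                ),
                "materials_shared_not_requested": (
                    None
                    if m.materials_shared is None
                    else float(m.materials_shared == "not_requested")
                ),
                "clarification_quality": (
                    None
                    if m.clarification_quality is None
                    else float(m.clarification_quality)
                ),
            }
        )
    return pd.DataFrame(rows)


#: Metrics that carry sampling variances and are fit with inverse-variance
#: weights.
WEIGHTED_METRICS = {"es_difference": "es_difference_var", "pooled_estimate": "pooled_estimate_var"}


# ---------------------------------------------------------------------------
# REML variance components + GLS + CR2


def _build_blocks(
    df: pd.DataFrame, X: np.ndarray, y: np.ndarray, v: Optional[np.ndarray]
) -> List[dict]:
    """Split data into paper-level cluster blocks with experiment sub-blocks."""
    blocks = []
    for _, idx in df.groupby("paper_id", sort=False).indices.items():
        idx = np.asarray(idx)
        exp = df.iloc[idx]["experiment_id"].to_numpy()
        # indicator matrix of experiments within this paper
        _, codes = np.unique(exp, return_inverse=True)
        Zx = np.eye(codes.max() + 1)[codes]
        blocks.append(
            {
                "X": X[idx],
                "y": y[idx],
                "Zx": Zx,
                "v": None if v is None else v[idx],
                "n": len(idx),
            }
        )
    return blocks


def _cluster_cov(block: dict, s2_paper: float, s2_exp: float, s2_res: float) -> np.ndarray:
    n = block["n"]
    V = s2_paper * np.ones((n, n)) + s2_exp * (block["Zx"] @ block["Zx"].T)
    diag = s2_res * np.ones(n)
    if block["v"] is not None:
        diag = diag + block["v"]
    V[np.diag_indices(n)] += diag
    return V


def _pad_blocks(blocks: List[dict], p: int) -> dict:
    """Stack cluster blocks into padded (G, n_max, ...) arrays.

    Padded rows get V = identity, X = 0, y = 0 so they contribute nothing
    to the restricted likelihood; this lets the REML objective evaluate
    all clusters in one batched Cholesky.
    """
    G = len(blocks)
    n_max = max(b["n"] for b in blocks)
    Xp = np.zeros((G, n_max, p))
    yp = np.zeros((G, n_max))
    ones = np.zeros((G, n_max, n_max))  # paper-intercept block JJ'
    zz = np.zeros((G, n_max, n_max))  # experiment-intercept block ZZ'
    diag_v = np.zeros((G, n_max))  # known sampling variances
    mask = np.zeros((G, n_max))
    for g, b in enumerate(blocks):
        n = b["n"]
        Xp[g, :n] = b["X"]
        yp[g, :n] = b["y"]
        ones[g, :n, :n] = 1.0
        zz[g, :n, :n] = b["Zx"] @ b["Zx"].T
        if b["v"] is not None:
            diag_v[g, :n] = b["v"]
        mask[g, :n] = 1.0
    return {"X": Xp, "y": yp, "ones": ones, "zz": zz, "v": diag_v, "mask": mask}


def _reml_nll(log_params: np.ndarray, padded: dict, p: int) -> float:
    s2_paper, s2_exp, s2_res = np.exp(log_params)
    mask = padded["mask"]
    n_max = mask.shape[1]
    V = s2_paper * padded["ones"] + s2_exp * padded["zz"]
    diag = s2_res * mask + padded["v"] + (1.0 - mask)  # identity padding
    V[:, np.arange(n_max), np.arange(n_max)] += diag
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_V = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
    Xy = np.concatenate([padded["X"], padded["y"][:, :, None]], axis=2)
    sol = np.linalg.solve(V, Xy)  # batched V^{-1} [X | y]
    Vinv_X, Vinv_y = sol[:, :, :p], sol[:, :, p]
    XtVX = np.einsum("gni,gnj->ij", padded["X"], Vinv_X)
    XtVy = np.einsum("gni,gn->i", padded["X"], Vinv_y)
    yVy = float(np.einsum("gn,gn->", padded["y"], Vinv_y))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12
    yPy = yVy - float(XtVy @ beta)
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e12
    return 0.5 * (logdet_V + logdet_XtVX + yPy)


def _fit_gls(
    blocks: List[dict], p: int, s2: Tuple[float, float, float]
) -> Tuple[np.ndarray, np.ndarray, List[np.ndarray]]:
    """GLS fixed effects given variance components.

    Returns (beta, bread matrix M = (X'V^-1 X)^-1, whitened per-cluster
    design/residual pairs for the sandwich).
    """
    s2_paper, s2_exp, s2_res = s2
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    whitened = []
    for b in blocks:
        V = _cluster_cov(b, s2_paper, s2_exp, s2_res)
        # symmetric inverse square root of V
        evals, evecs = np.linalg.eigh(V)
        evals = np.clip(evals, 1e-12, None)
        W_half = evecs @ np.diag(evals**-0.5) @ evecs.T
        Xw = W_half @ b["X"]
        yw = W_half @ b["y"]
        XtVX += Xw.T @ Xw
        XtVy += Xw.T @ yw
        whitened.append((Xw, yw))
    M = np.linalg.inv(XtVX)
    beta = M @ XtVy
    return beta, M, whitened


def _cr2_cov(
    beta: np.ndarray, M: np.ndarray, whitened: List[Tuple[np.ndarray, np.ndarray]],
    adjustment: str = "cr2",
) -> np.ndarray:
    """Cluster-robust sandwich on the whitened (GLS) model.

    CR2 rescales each cluster's residuals by the symmetric inverse square
    root of (I - H_gg), removing the first-order downward bias of the plain
    sandwich with few clusters; CR1 applies the scalar G/(G-1) correction.
    """
    G = len(whitened)
    meat = np.zeros_like(M)
    for Xw, yw in whitened:
        e = yw - Xw @ beta
        if adjustment == "cr2":
            H = Xw @ M @ Xw.T
            I_H = np.eye(len(yw)) - H
            evals, evecs = np.linalg.eigh(I_H)
            inv_sqrt = np.where(evals > 1e-10, 1.0 / np.sqrt(np.clip(evals, 1e-10, None)), 0.0)
            A = evecs @ np.diag(inv_sqrt) @ evecs.T
            e = A @ e
        u = Xw.T @ e
        meat += np.outer(u, u)
    if adjustment == "cr1":
        meat *= G / (G - 1.0)
    return M @ meat @ M


def fit_moderator_model(
    frame: pd.DataFrame,
    metric: str,
    weighted: Optional[bool] = None,
    adjustment: str = "cr2",
    bonferroni_m: int = N_MODERATORS,
) -> ModeratorFit:
    """Regress one replication-success metric on the candidate moderators.

    Parameters
    ----------
    frame
        Output of :func:`moderator_frame`.
    metric
        Column name of the metric to model.
    weighted
        Inverse-variance weighting; defaults to True exactly for metrics
        that carry sampling variances (``es_difference``,
        ``pooled_estimate``).
    adjustment
        ``"cr2"`` (default) or the simpler ``"cr1"`` scalar correction
        (its use is logged).
    """
    if metric not in frame.columns:
        raise InvalidInputError(f"unknown metric: {metric!r}")
    if weighted is None:
        weighted = metric in WEIGHTED_METRICS
    if weighted and metric not in WEIGHTED_METRICS:
        raise InvalidInputError(f"metric {metric!r} carries no variance to weight by")
    if adjustment not in ("cr2", "cr1"):
        raise InvalidInputError(f"unknown adjustment: {adjustment!r}")
    if adjustment == "cr1":
        logger.info("using CR1 scalar cluster adjustment instead of CR2")

    cols = list(MODERATOR_TERMS)
    needed = [metric] + cols + ["paper_id", "experiment_id"]
    if weighted:
        needed.append(WEIGHTED_METRICS[metric])
    df = frame[needed].dropna().reset_index(drop=True)
    if df.empty:
        raise InvalidInputError(f"no complete rows for metric {metric!r}")

    n_clusters = df["paper_id"].nunique()
    if n_clusters < 2:
        raise InvalidInputError("cluster-robust inference needs >= 2 paper clusters")

    # drop constant or collinear moderator columns
    dropped: List[str] = []
    kept: List[str] = []
    for c in cols:
        vals = df[c].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            dropped.append(c)
            logger.warning("moderator %r is constant; dropped from the model", c)
        else:
            kept.append(c)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in kept])
    # rank check: drop trailing collinear columns
    while np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(X.shape[1] - 1, 0, -1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                logger.warning(
                    "moderator %r is collinear; dropped from the model", kept[j - 1]
                )
                dropped.append(kept.pop(j - 1))
                X = Xr
                break
        else:  # pragma: no cover - cannot reduce further
            raise InvalidInputError("design matrix is rank deficient")

    y = df[metric].to_numpy(dtype=float)
    v = df[WEIGHTED_METRICS[metric]].to_numpy(dtype=float) if weighted else None
    blocks = _build_blocks(df, X, y, v)
    p = X.shape[1]

    # REML variance components (paper, experiment-in-paper, residual)
    y_var = max(float(np.var(y)), 1e-8)
    padded = _pad_blocks(blocks, p)
    x0 = np.log(np.array([y_var / 4, y_var / 4, y_var / 2]))
    res = optimize.minimize(
        _reml_nll, x0, args=(padded, p), method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 1000},
    )
    s2 = tuple(np.exp(res.x))
    # collapse negligible components to the boundary (degrades to WLS/OLS)
    s2 = tuple(0.0 if c < 1e-10 * y_var else float(c) for c in s2)
    if not weighted and s2[2] == 0.0:
        s2 = (s2[0], s2[1], 1e-8 * y_var)  # keep V positive definite

    beta, M, whitened = _fit_gls(blocks, p, s2)
    cov = _cr2_cov(beta, M, whitened, adjustment)
    se = np.sqrt(np.diag(cov))
    dof = n_clusters - 1
    t_vals = beta / se
    p_raw = 2.0 * stats.t.sf(np.abs(t_vals), dof)

    names = ["intercept"] + kept
    coefs = []
    for name, b, s, pr in zip(names, beta, se, p_raw):
        pb = min(1.0, bonferroni_m * pr) if name != "intercept" else float("nan")
        coefs.append((name, float(b), float(s), float(pr), float(pb)))
    return ModeratorFit(
        metric_name=metric,
        coefficients=coefs,
        n_pairs=len(df),
        n_clusters=n_clusters,
        dropped_terms=dropped,
        variance_components={
            "paper": s2[0], "experiment": s2[1], "residual": s2[2]
        },
    )


# ---------------------------------------------------------------------------
# Moderator correlation matrix


def point_biserial_matrix(columns: Dict[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Pearson correlations among binary (0/1) and continuous columns.

    Point-biserial correlations are Pearson correlations with the binary
    variable coded 0/1.  Zero-variance columns yield NaN entries (flagged
    undefined); the diagonal is 1 and the matrix is symmetric.
    """
    names = list(columns)
    arrs = [np.asarray(columns[n], dtype=float) for n in names]
    n_len = {len(a) for a in arrs}
    if len(n_len) != 1:
        raise InvalidInputError("all columns must have equal length")
    k = len(names)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                out[i, j] = 1.0 if np.std(arrs[i]) > 0 else np.nan
                continue
            if np.std(arrs[i]) == 0 or np.std(arrs[j]) == 0:
                logger.warning(
                    "zero-variance column in correlation matrix: %r / %r",
                    names[i], names[j],
                )
                continue
            r = float(np.corrcoef(arrs[i], arrs[j])[0, 1])
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=names, columns=names)
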