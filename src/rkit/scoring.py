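"""Scalar metrics for reactivity-vs-structure agreement and model accuracy.

Covers the classic Eterna data-fit score, the OpenKnot pseudoknot-likelihood
score, exact-pair F1 and its crossed-pair restriction, clipped mean absolute
error, MCRMSE (mean of per-channel RMSEs), linear eF1 confidence estimates
from mean predicted pair scores, and the power-law data-scaling fit
MAE = a + b * N^-c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .structure import SecondaryStructure, PairScoreMatrix, crossed_pairs

__all__ = [
    "StructureEvalResult",
    "OpenKnotResult",
    "ConfidenceEstimate",
    "ScalingFit",
    "eterna_score_classic",
    "openknot_score",
    "f1_structure",
    "f1_crossed_pair",
    "mae_clipped",
    "mcrmse",
    "estimate_ef1",
    "fit_scaling_law",
    "mean_by_cluster",
    "EF1_SS_COEFFS",
    "EF1_CROSSED_COEFFS",
]

# Linear confidence relations mapping mean predicted pair score to estimated
# F1: eF1 = 2.25 <M>_ss - 1.29 for the whole structure and
# eF1,crossed = 2 <M>_crossed - 1.19 for crossed pairs only.
EF1_SS_COEFFS = (2.25, -1.29)
EF1_CROSSED_COEFFS = (2.0, -1.19)


@dataclass
class StructureEvalResult:
    precision: float
    recall: float
    f1: float
    f1_crossed: float | None
    n_ref_crossed: int
    n_pred_crossed: int


@dataclass
class OpenKnotResult:
    """OpenKnot score in [0, 100] with the best-fit candidate breakdown."""

    score: float
    best_fit: list[int]
    classic_scores: list[float]
    pk_subscores: list[float]


@dataclass
class ConfidenceEstimate:
    mean_pair_score_ss: float
    mean_pair_score_crossed: float | None
    ef1: float
    ef1_crossed: float | None
    ef1_raw: float
    ef1_crossed_raw: float | None


@dataclass
class ScalingFit:
    a: float
    b: float
    c: float
    residual_norm: float
    success: bool


def eterna_score_classic(
    reactivity: np.ndarray,
    structure: SecondaryStructure,
    paired_thresh: float = 0.5,
    unpaired_thresh: float = 0.125,
) -> float:
    """Percentage of nucleotides whose reactivity is consistent with the
    candidate structure: paired positions must have reactivity < 0.5,
    unpaired positions > 0.125 (strict).  Missing positions are excluded
    from both numerator and denominator."""
    r = np.asarray(reactivity, dtype=float)
    if r.shape[0] != structure.length:
        raise ValueError("profile/structure length mismatch")
    paired = np.zeros(structure.length, dtype=bool)
    for i, j in structure.pairs:
        paired[i] = paired[j] = True
    present = ~np.isnan(r)
    if not present.any():
        raise ValueError("no non-missing positions to score")
    ok = np.where(paired, r < paired_thresh, r > unpaired_thresh)
    return 100.0 * float(ok[present].sum()) / float(present.sum())


def _pk_subscore(
    reactivity: np.ndarray, structure: SecondaryStructure, paired_thresh: float
) -> float:
    """Classic-score rule restricted to nucleotides in crossed pairs (all
    such nucleotides are paired, so the test is reactivity < paired_thresh);
    0 when the candidate has no crossed pairs."""
    cp = crossed_pairs(structure)
    if not cp:
        return 0.0
    idx = sorted({k for p in cp for k in p})
    r = np.asarray(reactivity, dtype=float)[idx]
    present = ~np.isnan(r)
    if not present.any():
        return 0.0
    return 100.0 * float((r[present] < paired_thresh).sum()) / float(present.sum())


def openknot_score(
    reactivity: np.ndarray,
    candidates: list[SecondaryStructure],
    window: float = 5.0,
    paired_thresh: float = 0.5,
    unpaired_thresh: float = 0.125,
) -> OpenKnotResult:
    """OpenKnot score: likelihood that the best data-fitting structure is
    pseudoknotted.

    Candidates within ``window`` classic-score units of the best fit are
    averaged; each contributes the mean of its classic score and its
    crossed-pair subscore (0 for crossing-free candidates, penalizing
    pseudoknot-free fits).
    """
    if not candidates:
        raise ValueError("need at least one candidate structure")
    classic = [
        eterna_score_classic(reactivity, c, paired_thresh, unpaired_thresh)
        for c in candidates
    ]
    best = max(classic)
    best_fit = [k for k, s in enumerate(classic) if s >= best - window]
    pk = [_pk_subscore(reactivity, candidates[k], paired_thresh) for k in best_fit]
    values = [(classic[k] + p) / 2.0 for k, p in zip(best_fit, pk)]
    return OpenKnotResult(
        score=float(np.mean(values)),
        best_fit=best_fit,
        classic_scores=classic,
        pk_subscores=pk,
    )


def _f1_from_sets(ref: set, pred: set) -> tuple[float, float, float]:
    if not ref and not pred:
        return 1.0, 1.0, 1.0
    tp = len(ref & pred)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(ref) if ref else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def f1_structure(
    reference: SecondaryStructure, predicted: SecondaryStructure
) -> StructureEvalResult:
    """Exact-pair precision/recall/F1, with crossed-pair F1 attached.

    Conventions: an empty prediction against a nonempty reference scores 0;
    two empty structures score 1.
    """
    if reference.length != predicted.length:
        raise ValueError("reference/predicted length mismatch")
    precision, recall, f1 = _f1_from_sets(set(reference.pairs), set(predicted.pairs))
    ref_cp = crossed_pairs(reference)
    pred_cp = crossed_pairs(predicted)
    return StructureEvalResult(
        precision=precision,
        recall=recall,
        f1=f1,
        f1_crossed=f1_crossed_pair(reference, predicted),
        n_ref_crossed=len(ref_cp),
        n_pred_crossed=len(pred_cp),
    )


def f1_crossed_pair(
    reference: SecondaryStructure, predicted: SecondaryStructure
) -> float | None:
    """F1 after filtering both pair lists to crossed pairs only.

    Returns None (excluded from aggregates) when both structures are
    crossing-free; 0 when only the prediction has crossings (overprediction)
    or only the reference does (miss).
    """
    if reference.length != predicted.length:
        raise ValueError("reference/predicted length mismatch")
    ref_cp = set(crossed_pairs(reference))
    pred_cp = set(crossed_pairs(predicted))
    if not ref_cp and not pred_cp:
        return None
    if not ref_cp or not pred_cp:
        return 0.0
    return _f1_from_sets(ref_cp, pred_cp)[2]


def mae_clipped(
    pred: np.ndarray,
    data: np.ndarray,
    lo: float = 0.0,
    hi: float = 1.0,
    mask: np.ndarray | None = None,
) -> float:
    """Mean absolute error after clipping both vectors to [lo, hi], over
    unmasked, non-missing positions."""
    p = np.asarray(pred, dtype=float)
    d = np.asarray(data, dtype=float)
    if p.shape != d.shape:
        raise ValueError("shape mismatch")
    valid = ~np.isnan(p) & ~np.isnan(d)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any():
        raise ValueError("no valid positions for MAE")
    return float(np.mean(np.abs(np.clip(p[valid], lo, hi) - np.clip(d[valid], lo, hi))))


def mcrmse(pred: np.ndarray, data: np.ndarray) -> float:
    """Mean column RMSE: RMSE per output channel over non-missing positions,
    averaged (unweighted) across channels."""
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    d = np.atleast_2d(np.asarray(data, dtype=float))
    if p.shape != d.shape:
        raise ValueError("shape mismatch")
    rmses = []
    for c in range(p.shape[1]):
        valid = ~np.isnan(p[:, c]) & ~np.isnan(d[:, c])
        if not valid.any():
            raise ValueError(f"channel {c} has no valid positions")
        rmses.append(np.sqrt(np.mean((p[valid, c] - d[valid, c]) ** 2)))
    return float(np.mean(rmses))


def estimate_ef1(
    matrix: PairScoreMatrix, structure: SecondaryStructure
) -> ConfidenceEstimate:
    """Linear confidence estimate of F1 from mean predicted pair scores.

    The whole-structure relation uses the mean score over the structure's
    pairs; the crossed-pair relation uses the mean over crossed pairs only
    and is undefined for crossing-free structures.  Estimates are clipped to
    [0, 1]; raw (unclipped) values are also reported.
    """
    if matrix.length != structure.length:
        raise ValueError("matrix/structure length mismatch")
    if not structure.pairs:
        raise ValueError("cannot estimate confidence for an empty structure")
    mean_ss = float(np.mean([matrix.scores[i, j] for i, j in structure.pairs]))
    a, b = EF1_SS_COEFFS
    raw = a * mean_ss + b
    cp = crossed_pairs(structure)
    if cp:
        mean_cp = float(np.mean([matrix.scores[i, j] for i, j in cp]))
        ac, bc = EF1_CROSSED_COEFFS
        raw_cp = ac * mean_cp + bc
        ef1_cp = float(np.clip(raw_cp, 0.0, 1.0))
    else:
        mean_cp = None
        raw_cp = None
        ef1_cp = None
    return ConfidenceEstimate(
        mean_pair_score_ss=mean_ss,
        mean_pair_score_crossed=mean_cp,
        ef1=float(np.clip(raw, 0.0, 1.0)),
        ef1_crossed=ef1_cp,
        ef1_raw=raw,
        ef1_crossed_raw=raw_cp,
    )


def fit_scaling_law(n_sequences, mae) -> ScalingFit:
    """Fit MAE = a + b * N^-c by nonlinear least squares with c >= 0.

    Degenerate (constant) inputs return a = mean(mae), b = c = 0.  A fit
    that fails to converge is reported with success=False rather than
    raising.
    """
    n = np.asarray(n_sequences, dtype=float)
    y = np.asarray(mae, dtype=float)
    if n.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(n <= 0):
        raise ValueError("sequence counts must be positive")
    if np.ptp(y) < 1e-12:
        return ScalingFit(a=float(y.mean()), b=0.0, c=0.0, residual_norm=0.0, success=True)

    def model(x, a, b, c):
        return a + b * np.power(x, -c)

    try:
        p0 = (max(y.min(), 1e-6), max(y.max() - y.min(), 1e-6), 0.5)
        popt, _ = curve_fit(
            model,
            n,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        resid = float(np.linalg.norm(model(n, *popt) - y))
        return ScalingFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                          residual_norm=resid, success=True)
    except RuntimeError:
        return ScalingFit(a=np.nan, b=np.nan, c=np.nan, residual_norm=np.inf, success=False)


def mean_by_cluster(values, cluster_ids) -> float:
    """Mean of per-cluster means, for test-set summaries where sequences are
    grouped by similarity.  None values are dropped before averaging."""
    groups: dict = {}
    for v, cid in zip(values, cluster_ids, strict=True):
        if v is None:
            continue
        groups.setdefault(cid, []).append(float(v))
    if not groups:
        raise ValueError("no values to aggregate")
    return float(np.mean([np.mean(g) for g in groups.values()]))
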