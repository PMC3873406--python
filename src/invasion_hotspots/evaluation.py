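"""Model accuracy, selection statistics, and the niche-containment check.

Gates used to screen species models: AUC above 0.75 (rank-based,
presence vs background scores) and the fixed-sensitivity omission test
at 90% sensitivity.  The omission gate in the source protocol is stated
as "omission ... < 0.5"; both the omission rate and the exact binomial
p-value are computed and reported, so either reading of the gate can be
applied (the default gate checks both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon


@dataclass
class EvaluationReport:
    auc: float
    threshold: float
    omission_rate: float
    binomial_p: float
    predicted_area_fraction: float
    aicc: float | None
    bic: float
    n_test: int
    passed: bool
    auc_gate: float = 0.75
    omission_gate: float = 0.5


@dataclass
class NicheCheckResult:
    fraction_inside: float
    outside_points: list
    hull_vertices: list


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(presence > background) + 0.5 P(tie).

    Mann-Whitney statistic computed from midranks of the pooled scores.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def fixed_sensitivity_threshold(presence_scores, sensitivity: float = 0.90) -> float:
    """Largest threshold keeping at least the given fraction of presences.

    Suitable habitat is score >= threshold, so the threshold is the
    ceil(sensitivity * n)-th largest presence score; the predicted area
    is minimized subject to the sensitivity floor.
    """
    scores = np.asarray(presence_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("presence scores must be non-empty")
    if not 0.0 < sensitivity <= 1.0:
        raise ValueError("sensitivity must be in (0, 1]")
    k = int(np.ceil(sensitivity * scores.size))
    return float(np.sort(scores)[::-1][k - 1])


def binomial_omission_test(n_test: int, n_omitted: int, predicted_area_fraction: float) -> float:
    """Exact one-sided binomial p-value against a random prediction.

    Probability that a random map covering the given area fraction
    includes at least n_test - n_omitted of n_test presences by chance.
    """
    if not 0 <= n_omitted <= n_test:
        raise ValueError("n_omitted must be between 0 and n_test")
    if not 0.0 < predicted_area_fraction < 1.0:
        raise ValueError("predicted_area_fraction must be strictly inside (0, 1)")
    hits = n_test - n_omitted
    # P(X >= hits), X ~ Binomial(n_test, area)
    return float(stats.binom.sf(hits - 1, n_test, predicted_area_fraction))


def information_criteria(model, presence_raw_scores) -> tuple[float | None, float, float]:
    """(AICc, BIC, AIC) from the normalized likelihood at the presences.

    ``presence_raw_scores`` are the model's relative occurrence rates at
    presence cells, normalized so the distribution sums to 1 over the
    landscape; k counts nonzero weights.  AICc is None (flagged
    undefined) when n <= k + 1.
    """
    q = np.asarray(presence_raw_scores, dtype=float)
    if np.any(q <= 0):
        raise ValueError("presence probabilities must be positive")
    n = q.size
    k = int(np.count_nonzero(model.lambdas))
    lnl = float(np.log(q).sum())
    aic = 2 * k - 2 * lnl
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n > k + 1 else None
    bic = k * np.log(n) - 2 * lnl
    return aicc, float(bic), float(aic)


def niche_containment(target_points, reference_points) -> NicheCheckResult:
    """Fraction of target (AMT, AP) points inside the reference hull.

    Convex hull of the reference cloud; boundary points count as
    inside.  Raises on a degenerate (collinear) reference set.
    """
    ref = np.asarray(reference_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 reference points")
    try:
        hull = ConvexHull(ref)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) reference niche cloud") from exc
    poly = Polygon(ref[hull.vertices])
    outside = [tuple(p) for p in tgt if not poly.covers(Point(p))]
    frac = 1.0 - len(outside) / len(tgt)
    return NicheCheckResult(frac, outside, [tuple(v) for v in ref[hull.vertices]])


def evaluate(
    model,
    presence_scores,
    background_scores,
    sensitivity: float = 0.90,
    auc_gate: float = 0.75,
    omission_gate: float = 0.5,
    presence_raw_scores=None,
) -> EvaluationReport:
    """Full accuracy report for one model on one presence/background split.

    Scores may be any strictly-increasing transform of the model output
    (logistic by default); the threshold, omission rate and area
    fraction are invariant to that choice.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    a = auc(p, b)
    t = fixed_sensitivity_threshold(p, sensitivity)
    omission = float(np.mean(p < t))
    landscape = np.concatenate([p, b])
    area = float(np.mean(landscape >= t))
    area_for_test = min(max(area, 1e-12), 1 - 1e-12)
    pval = binomial_omission_test(p.size, int(np.sum(p < t)), area_for_test)
    aicc = bic = None
    if presence_raw_scores is not None:
        aicc, bic, _ = information_criteria(model, presence_raw_scores)
    passed = (a > auc_gate) and (omission < omission_gate) and (pval < 0.05)
    return EvaluationReport(
        auc=a,
        threshold=t,
        omission_rate=omission,
        binomial_p=pval,
        predicted_area_fraction=area,
        aicc=aicc,
        bic=bic if bic is not None else float("nan"),
        n_test=int(p.size),
        passed=passed,
        auc_gate=auc_gate,
        omission_gate=omission_gate,
    )
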