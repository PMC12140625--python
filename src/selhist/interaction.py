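"""Conditional-independence benchmark for interactions between history
variables.

Two history variables A and B (e.g. the recent color sequence and the
recent location sequence) are conditionally independent given the trial
outcome C when P(A, B | C) = P(A | C) P(B | C). Under that assumption,
Bayes' theorem turns the two separately measured accuracies P(C=1|A) and
P(C=1|B), together with the overall prior P(C=1), into a parameter-free
prediction for the jointly conditioned accuracy:

    P(C=1|A,B) = [ p_a p_b / prior ] /
                 [ p_a p_b / prior + (1 - p_a)(1 - p_b) / (1 - prior) ]

The benchmark enumerates every fully specified joint history sequence at a
given depth, measures the informed-choice (ceiling-window) accuracy for the
joint condition, predicts it from the marginals, and summarizes agreement
by the slope of an ordinary least-squares regression of predicted on
measured accuracy over the reliable points (measured CI span below a
threshold, 15 percentage points by default). A slope near 1 indicates no
functional interaction; a shallower slope means the prediction compresses
the real joint effects — the signature of an interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .history import (HistoryCondition, SequenceKey, enumerate_sequences,
                      label_joint)
from .tachometric import AccuracySummary, CEILING_MIN_MS, agresti_coull
from .trials import TrialTable

logger = logging.getLogger(__name__)

#: Marginal accuracies of exactly 0 or 1 (possible at small n) are clamped
#: into the open interval before entering the prediction formula.
CLAMP_EPS = 1e-9

#: Points whose measured-accuracy CI spans at least this much (probability
#: units) are excluded from the summary regression.
RELIABILITY_MAX_CI_SPAN = 0.15

#: Supported history-variable pairings. The two-variable pairings predict
#: the joint sequence from each variable's own sequence; the
#: outcome-augmented pairing predicts color+location+outcome sequences from
#: the two outcome-augmented single-variable sequences.
PAIRS = {
    ("color", "location"),
    ("color", "outcome"),
    ("location", "outcome"),
    ("color+outcome", "location+outcome"),
}


def predict_joint(p_a: float, p_b: float, prior: float) -> float:
    """No-interaction prediction of a jointly conditioned success
    probability from two singly conditioned probabilities and the prior.

    All inputs are clamped to [CLAMP_EPS, 1 - CLAMP_EPS]; a prior of
    exactly 0 or 1 is an error (the prediction is undefined there).
    """
    if not 0.0 < prior < 1.0:
        raise ValueError(f"degenerate prior {prior}: must be strictly "
                         "inside (0, 1)")
    eps = CLAMP_EPS
    if not (eps <= p_a <= 1 - eps and eps <= p_b <= 1 - eps):
        logger.debug("clamping marginal accuracy into [%g, %g]", eps, 1 - eps)
    p_a = min(max(float(p_a), eps), 1 - eps)
    p_b = min(max(float(p_b), eps), 1 - eps)
    prior = min(max(float(prior), eps), 1 - eps)
    num = p_a * p_b / prior
    den = num + (1 - p_a) * (1 - p_b) / (1 - prior)
    return num / den


def conditional_accuracy(table: TrialTable, mask=None,
                         ceiling_min_ms: float = CEILING_MIN_MS,
                         conf: float = 0.95) -> AccuracySummary:
    """Proportion correct among masked trials in the informed (ceiling)
    window PT > ``ceiling_min_ms``, with Agresti-Coull CI."""
    if mask is None:
        mask = np.ones(len(table), dtype=bool)
    sel = np.asarray(mask, bool) & (table.pt_ms > ceiling_min_ms)
    window = (ceiling_min_ms, np.inf)
    return AccuracySummary.from_counts(int(table.correct[sel].sum()),
                                       int(sel.sum()), window, conf)


@dataclass
class InteractionPoint:
    """Measured vs predicted informed accuracy for one joint sequence."""

    key: str
    H: int
    measured: AccuracySummary
    predicted: float
    predicted_se: float
    marginal_a: AccuracySummary
    marginal_b: AccuracySummary
    reliable: bool

    def to_dict(self) -> dict:
        return {"key": self.key, "H": self.H,
                "measured": self.measured.to_dict(),
                "predicted": self.predicted,
                "predicted_se": self.predicted_se,
                "marginal_a": self.marginal_a.to_dict(),
                "marginal_b": self.marginal_b.to_dict(),
                "reliable": self.reliable}


@dataclass
class InteractionResult:
    """All sequence points at one depth plus the summary regression."""

    variables: tuple
    H: int
    prior: float
    points: list
    slope: float
    slope_ci: tuple
    intercept: float
    n_reliable: int
    reliability_max_span: float = RELIABILITY_MAX_CI_SPAN
    slope_defined: bool = True

    def to_dict(self) -> dict:
        return {"variables": list(self.variables), "H": self.H,
                "prior": self.prior,
                "points": [p.to_dict() for p in self.points],
                "slope": self.slope, "slope_ci": list(self.slope_ci),
                "intercept": self.intercept,
                "n_reliable": self.n_reliable,
                "reliability_max_span": self.reliability_max_span,
                "slope_defined": self.slope_defined}


def _split_variable(v: str) -> list:
    return v.split("+")


def _marginal_conditions(variable: str, key: SequenceKey) -> list:
    """Conditions defining one side's marginal history for a joint key.

    For a plain variable this is its own pattern; for an outcome-augmented
    variable (``color+outcome``) it is the variable's pattern together with
    the outcome pattern.
    """
    out = []
    for v in _split_variable(variable):
        idx = key.variables.index(v)
        out.append(HistoryCondition(v, key.patterns[idx]))
    return out


def _regress(measured: np.ndarray, predicted: np.ndarray,
             conf: float = 0.95, fit_intercept: bool = True):
    """OLS of predicted (response) on measured (predictor); returns
    (slope, (lo, hi), intercept) with a t-based CI on the slope."""
    n = measured.size
    if fit_intercept:
        X = np.column_stack([np.ones(n), measured])
    else:
        X = measured[:, None]
    beta, _, _, _ = np.linalg.lstsq(X, predicted, rcond=None)
    resid = predicted - X @ beta
    dof = n - X.shape[1]
    if dof <= 0:
        return float(beta[-1]), (float("-inf"), float("inf")), \
            (float(beta[0]) if fit_intercept else 0.0)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[-1, -1])
    tq = stats.t.ppf(0.5 * (1 + conf), dof)
    slope = float(beta[-1])
    return slope, (slope - tq * se, slope + tq * se), \
        (float(beta[0]) if fit_intercept else 0.0)


def interaction_scan(table: TrialTable, variables=("color", "location"),
                     H: int = 1, ceiling_min_ms: float = CEILING_MIN_MS,
                     reliability_max_span: float = RELIABILITY_MAX_CI_SPAN,
                     fit_intercept: bool = True,
                     conf: float = 0.95) -> InteractionResult:
    """Measure vs predict informed accuracy for every joint history
    sequence of depth ``H`` over a pair of history variables.

    The prior is the ceiling-window overall accuracy of ``table`` —
    recomputed for each dataset, never assumed. The summary slope is an OLS
    regression of predicted on measured accuracy restricted to reliable
    points (measured CI span < ``reliability_max_span``).
    """
    variables = tuple(variables)
    if tuple(sorted(variables)) not in {tuple(sorted(p)) for p in PAIRS}:
        raise ValueError(f"unsupported variable pair: {variables}")
    atomic = sorted({v for pair in variables for v in _split_variable(pair)})
    keys = enumerate_sequences(atomic, H)

    prior_summary = conditional_accuracy(table, None, ceiling_min_ms, conf)
    if not prior_summary.defined:
        raise ValueError("no trials in the informed window; cannot form a "
                         "prior")
    prior = prior_summary.estimate

    # cache marginal accuracies: several joint keys share each marginal
    marg_cache: dict = {}

    def marginal(variable: str, key: SequenceKey) -> AccuracySummary:
        conds = _marginal_conditions(variable, key)
        tag = tuple((c.variable, c.pattern) for c in conds)
        if tag not in marg_cache:
            marg_cache[tag] = conditional_accuracy(
                table, label_joint(table, conds), ceiling_min_ms, conf)
        return marg_cache[tag]

    points = []
    for key in keys:
        joint_mask = label_joint(table, key.conditions())
        measured = conditional_accuracy(table, joint_mask, ceiling_min_ms,
                                        conf)
        ma = marginal(variables[0], key)
        mb = marginal(variables[1], key)
        if ma.defined and mb.defined:
            pred = predict_joint(ma.estimate, mb.estimate, prior)
            # first-order (delta-method) SE propagated from the marginal
            # CIs; for display only — never used for the reliability split
            z = stats.norm.ppf(0.5 * (1 + conf))
            se_a = ma.ci_span / (2 * z)
            se_b = mb.ci_span / (2 * z)
            h = 1e-6
            dqa = (predict_joint(min(ma.estimate + h, 1 - CLAMP_EPS),
                                 mb.estimate, prior) -
                   predict_joint(max(ma.estimate - h, CLAMP_EPS),
                                 mb.estimate, prior)) / (2 * h)
            dqb = (predict_joint(ma.estimate,
                                 min(mb.estimate + h, 1 - CLAMP_EPS),
                                 prior) -
                   predict_joint(ma.estimate,
                                 max(mb.estimate - h, CLAMP_EPS),
                                 prior)) / (2 * h)
            pred_se = float(np.hypot(dqa * se_a, dqb * se_b))
        else:
            pred, pred_se = float("nan"), float("nan")
        reliable = bool(measured.defined and not np.isnan(pred) and
                        measured.ci_span < reliability_max_span)
        points.append(InteractionPoint(key.name, H, measured, pred, pred_se,
                                       ma, mb, reliable))

    rel = [p for p in points if p.reliable]
    if len(rel) >= 2:
        x = np.array([p.measured.estimate for p in rel])
        y = np.array([p.predicted for p in rel])
        slope, ci, intercept = _regress(x, y, conf, fit_intercept)
        defined = True
    else:
        slope, ci, intercept, defined = float("nan"), \
            (float("nan"), float("nan")), float("nan"), False
        logger.warning("interaction scan H=%d: %d reliable points; slope "
                       "undefined", H, len(rel))
    return InteractionResult(variables, H, prior, points, slope, ci,
                             intercept, len(rel), reliability_max_span,
                             defined)


def conditionally_independent_joint(prior: float, p_a_given_c,
                                    p_b_given_c) -> np.ndarray:
    """Construct a 2x2x2 joint P(A, B, C) satisfying conditional
    independence exactly.

    ``p_a_given_c`` and ``p_b_given_c`` are (P(A=1|C=0), P(A=1|C=1)) pairs.
    Axes of the returned array are (A, B, C).
    """
    pc = np.array([1 - prior, prior], float)
    pa = np.asarray(p_a_given_c, float)
    pb = np.asarray(p_b_given_c, float)
    joint = np.zeros((2, 2, 2))
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                qa = pa[c] if a else 1 - pa[c]
                qb = pb[c] if b else 1 - pb[c]
                joint[a, b, c] = qa * qb * pc[c]
    return joint


def ci_oracle_check(joint: np.ndarray, n_samples: int,
                    seed: int | None = None) -> float:
    """Verify the prediction formula against sampling from an explicit
    three-variable joint distribution.

    Samples (A, B, C) from ``joint`` (axes A, B, C; must sum to 1), computes
    the empirical P(C=1|A=a,B=b) for each of the four (a, b) cells and the
    predictions built from the empirical marginals P(C=1|A=a), P(C=1|B=b)
    and P(C=1), and returns the maximum absolute discrepancy. Under exact
    conditional independence the discrepancy vanishes as n grows; a
    genuinely interacting joint keeps it bounded away from zero.
    """
    joint = np.asarray(joint, float)
    if joint.shape != (2, 2, 2) or np.any(joint < 0) or \
            not np.isclose(joint.sum(), 1.0):
        raise ValueError("joint must be a 2x2x2 probability array summing "
                         "to 1")
    rng = np.random.default_rng(seed)
    flat = joint.ravel()
    counts = rng.multinomial(n_samples, flat).reshape(2, 2, 2)

    n_ab = counts.sum(axis=2)
    c_ab = counts[:, :, 1]
    n_a = counts.sum(axis=(1, 2))
    c_a = counts[:, :, 1].sum(axis=1)
    n_b = counts.sum(axis=(0, 2))
    c_b = counts[:, :, 1].sum(axis=0)
    prior = counts[:, :, 1].sum() / n_samples

    worst = 0.0
    for a in (0, 1):
        for b in (0, 1):
            if n_ab[a, b] == 0 or n_a[a] == 0 or n_b[b] == 0:
                continue
            empirical = c_ab[a, b] / n_ab[a, b]
            predicted = predict_joint(c_a[a] / n_a[a], c_b[b] / n_b[b],
                                      prior)
            worst = max(worst, abs(empirical - predicted))
    return worst


def analytic_discrepancy(joint: np.ndarray) -> float:
    """Population-level (n -> infinity) version of :func:`ci_oracle_check`:
    the maximum |P(C=1|A,B) - prediction| computed directly from the joint.
    Exactly zero when the joint satisfies conditional independence."""
    joint = np.asarray(joint, float)
    p_c1 = joint[:, :, 1].sum()
    worst = 0.0
    for a in (0, 1):
        for b in (0, 1):
            n_ab = joint[a, b].sum()
            if n_ab == 0:
                continue
            emp = joint[a, b, 1] / n_ab
            pa = joint[a, :, 1].sum() / joint[a].sum()
            pb = joint[:, b, 1].sum() / joint[:, b].sum()
            worst = max(worst, abs(emp - predict_joint(pa, pb, p_c1)))
    return worst
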