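"""Cross-subject tachometric-curve alignment for data pooling.

Two subjects performing the same urgent task can differ in the processing
time at which their choices become informed, as well as in their asymptotic
accuracy. Before pooling their trials, one subject's curve is registered
onto the other's with a three-parameter transform

    z(j) = g * (y2(j + delta) + b)

— a gain ``g``, a baseline shift ``b`` (fraction-correct units), and a PT
shift ``delta`` (ms) — chosen to minimize the average absolute deviation
|y1(j) - z(j)| over the PT bins where both curves are defined. Only
``delta`` is consumed downstream: it is subtracted from the second
subject's RTs (and hence PTs) before the trial tables are concatenated.
``g`` and ``b`` are reported but never applied to the data.

``delta`` is searched over an integer-ms grid (the curves live on a 1-ms
grid, and a discrete search keeps results exactly reproducible); at each
``delta`` the inner 2-parameter L1 problem is solved by iteratively
reweighted least squares on the reparameterization z = a*y2 + c (a = g,
c = g*b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tachometric import TachometricCurve
from .trials import TrialTable, concat_tables, shift_rt

#: IRLS constants for the inner least-absolute-deviations fit.
_IRLS_MAX_ITER = 200
_IRLS_TOL = 1e-12
_IRLS_EPS = 1e-10


@dataclass
class AlignmentParams:
    """Result of aligning curve 2 onto curve 1."""

    g: float
    b: float
    delta_ms: int
    #: mean |y1 - z| over the overlap at the optimum
    objective_value: float
    #: the same deviation as a plain sum over overlap bins
    objective_sum: float
    overlap_bins: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"g": self.g, "b": self.b, "delta_ms": self.delta_ms,
                "objective_value": self.objective_value,
                "objective_sum": self.objective_sum,
                "overlap_bins": self.overlap_bins,
                "degenerate": self.degenerate}


def _lad_fit(x: np.ndarray, y: np.ndarray, w0: np.ndarray | None = None):
    """Least-absolute-deviations fit y ~ a*x + c by IRLS.

    Returns (a, c, mean_abs_resid, degenerate). Degenerate means x is
    (numerically) constant, so the gain is unidentifiable.
    """
    if np.ptp(x) < 1e-12:
        resid = y - np.median(y)
        return np.nan, float(np.median(y)), float(np.mean(np.abs(resid))), True
    X = np.column_stack([x, np.ones_like(x)])
    base_w = np.ones_like(y) if w0 is None else np.asarray(w0, float)
    beta, *_ = np.linalg.lstsq(X * base_w[:, None], y * base_w, rcond=None)
    for _ in range(_IRLS_MAX_ITER):
        r = y - X @ beta
        w = base_w / np.maximum(np.abs(r), _IRLS_EPS)
        sw = np.sqrt(w)
        new_beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(new_beta - beta)) < _IRLS_TOL:
            beta = new_beta
            break
        beta = new_beta
    r = y - X @ beta
    return float(beta[0]), float(beta[1]), float(np.mean(np.abs(r))), False


def align_curves(y1: TachometricCurve, y2: TachometricCurve,
                 delta_grid=None, min_overlap: int = 50,
                 weight_by_n: bool = False) -> AlignmentParams:
    """Find (g, b, delta) mapping curve ``y2`` onto curve ``y1``.

    For each candidate delta, the overlap is the set of PT bins j where
    y1(j) and y2(j + delta) are both defined; the inner L1 fit runs on the
    overlap and the normalized objective (mean absolute deviation, so
    different overlap sizes are comparable) selects the winner. Ties are
    broken by smaller |delta|, then smaller delta.

    With ``weight_by_n`` the L1 residuals are weighted by the geometric
    mean of the two bins' trial counts.
    """
    if y1.step_ms != y2.step_ms:
        raise ValueError("curves must share the same PT step")
    step = y1.step_ms
    if delta_grid is None:
        delta_grid = np.arange(-100, 101, max(int(step), 1))
    delta_grid = np.asarray(delta_grid, int)

    c1 = y1.bin_center_ms
    c2 = y2.bin_center_ms
    best = None
    any_overlap = False
    for delta in delta_grid:
        # z(j) samples y2 at j + delta: y2's value at center j+delta is
        # compared against y1's value at center j
        common, i1, i2 = np.intersect1d(c1, c2 - delta, return_indices=True)
        if common.size == 0:
            continue
        ok = (y1.n_trials[i1] > 0) & (y2.n_trials[i2] > 0)
        if int(ok.sum()) < min_overlap:
            continue
        any_overlap = True
        yy1 = y1.frac_correct[i1][ok]
        yy2 = y2.frac_correct[i2][ok]
        w = None
        if weight_by_n:
            w = np.sqrt(y1.n_trials[i1][ok] * y2.n_trials[i2][ok])
            w = w / w.mean()
        a, c, obj, degen = _lad_fit(yy2, yy1, w)
        cand = (obj, abs(int(delta)), int(delta))
        if best is None or cand < best[0]:
            g = a
            b = c / a if not degen and abs(a) > 1e-12 else np.nan
            best = (cand, AlignmentParams(
                g=g, b=b, delta_ms=int(delta), objective_value=obj,
                objective_sum=obj * int(ok.sum()),
                overlap_bins=int(ok.sum()), degenerate=degen))
    if best is None:
        raise ValueError(
            "no delta in the grid reaches the minimum overlap of "
            f"{min_overlap} defined bins" if not any_overlap else
            "alignment failed")
    return best[1]


def pool_tables(table1: TrialTable, table2: TrialTable,
                params: AlignmentParams) -> TrialTable:
    """Pool two subjects' tables after applying the alignment shift.

    ``params.delta_ms`` is subtracted from every RT of ``table2`` (shifting
    its PTs by the same amount), then the tables are concatenated with
    session ids prefixed by subject label. Gain and baseline are not
    applied — they only served to register the curves.
    """
    shifted = shift_rt(table2, float(params.delta_ms))
    pooled = concat_tables([table1, shifted])
    pooled.meta["alignment"] = params.to_dict()
    return pooled
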