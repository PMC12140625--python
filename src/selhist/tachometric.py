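"""Tachometric curves and accuracy/RT summaries.

The tachometric curve plots the probability of a correct choice as a
function of processing time (PT = RT - gap): at short PT choices cannot be
informed by the color cue and accuracy sits at the guessing floor; as PT
grows, accuracy rises to an asymptotic ceiling. The curve is computed in a
rectangular sliding PT window (default width 50 ms, stepping every 1 ms).

Floor and ceiling accuracies are simple proportions over fixed PT windows
(PT < 100 ms and PT > 150 ms by default) and are therefore independent of
the bin width and step used for display. Binomial 95% confidence intervals
use the Agresti-Coull adjusted-Wald method throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trials import TrialTable
from .history import label_lagged_event

#: Default display bin: 50 ms wide, sliding every 1 ms.
DEFAULT_BIN_WIDTH_MS = 50.0
DEFAULT_STEP_MS = 1.0

#: PT windows defining uninformed (floor) and informed (ceiling) choices.
FLOOR_MAX_MS = 100.0
CEILING_MIN_MS = 150.0


def agresti_coull(successes: int, trials: int, conf: float = 0.95):
    """Agresti-Coull adjusted-Wald binomial confidence interval.

    With z the standard-normal quantile at (1+conf)/2, the adjusted count
    is n~ = n + z^2 and center p~ = (x + z^2/2) / n~; the interval is
    p~ +/- z * sqrt(p~ (1 - p~) / n~), clipped to [0, 1].
    """
    x, n = successes, trials
    if n < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("successes must be in [0, trials]")
    z = stats.norm.ppf(0.5 * (1.0 + conf))
    n_adj = n + z * z
    p_adj = (x + 0.5 * z * z) / n_adj
    half = z * np.sqrt(p_adj * (1.0 - p_adj) / n_adj)
    return max(0.0, p_adj - half), min(1.0, p_adj + half)


@dataclass
class AccuracySummary:
    """Proportion correct over a PT window, with Agresti-Coull 95% CI.

    ``defined`` is False (and the numeric fields NaN) when the window holds
    no trials; undefined summaries are never silently treated as zero.
    """

    estimate: float
    ci_low: float
    ci_high: float
    n: int
    window: tuple
    defined: bool = True

    @property
    def ci_span(self) -> float:
        return self.ci_high - self.ci_low

    @classmethod
    def undefined(cls, window) -> "AccuracySummary":
        return cls(float("nan"), float("nan"), float("nan"), 0, window,
                   defined=False)

    @classmethod
    def from_counts(cls, x: int, n: int, window, conf: float = 0.95):
        if n == 0:
            return cls.undefined(window)
        lo, hi = agresti_coull(x, n, conf)
        return cls(x / n, lo, hi, n, window)

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n": self.n,
                "window_ms": list(self.window), "defined": self.defined}


@dataclass
class RTSummary:
    """Mean RT with SD and SEM over all selected trials (correct and
    incorrect alike, at all PTs)."""

    mean_ms: float
    sd_ms: float
    sem_ms: float
    n: int

    @classmethod
    def from_values(cls, rt: np.ndarray) -> "RTSummary":
        rt = np.asarray(rt, float)
        n = rt.size
        if n == 0:
            raise ValueError("empty selection")
        if n == 1:
            return cls(float(rt[0]), float("nan"), float("nan"), 1)
        sd = float(np.std(rt, ddof=1))
        return cls(float(rt.mean()), sd, sd / np.sqrt(n), n)

    def to_dict(self) -> dict:
        return {"mean_ms": self.mean_ms, "sd_ms": self.sd_ms,
                "sem_ms": self.sem_ms, "n": self.n}


@dataclass
class TachometricCurve:
    """Fraction correct vs PT in sliding bins.

    Bins are half-open: a trial with processing time t falls in the bin
    centered at c iff c - w/2 <= t < c + w/2. Centers lie on an integer-ms
    grid spanning the selected trials' PT range. Bins containing no trials
    are undefined (NaN fraction, n = 0), not zero.
    """

    bin_center_ms: np.ndarray
    frac_correct: np.ndarray
    n_trials: np.ndarray
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS
    step_ms: float = DEFAULT_STEP_MS

    @property
    def defined(self) -> np.ndarray:
        return self.n_trials > 0

    @property
    def se(self) -> np.ndarray:
        """Per-bin binomial standard error (NaN where undefined)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_trials > 0,
                            np.sqrt(self.frac_correct *
                                    (1 - self.frac_correct) /
                                    np.maximum(self.n_trials, 1)),
                            np.nan)

    def to_dict(self) -> dict:
        return {"bin_center_ms": self.bin_center_ms.tolist(),
                "frac_correct": self.frac_correct.tolist(),
                "n_trials": self.n_trials.tolist(),
                "bin_width_ms": self.bin_width_ms,
                "step_ms": self.step_ms}


def _select(table: TrialTable, mask) -> tuple:
    if mask is None:
        mask = np.ones(len(table), dtype=bool)
    mask = np.asarray(mask, bool)
    if mask.shape != (len(table),):
        raise ValueError("mask length does not match table")
    return table.pt_ms[mask], table.correct[mask], \
        table.data["rt_ms"].to_numpy(float)[mask]


def tachometric_curve(table: TrialTable, mask=None,
                      bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
                      step_ms: float = DEFAULT_STEP_MS) -> TachometricCurve:
    """Compute the sliding-bin tachometric curve for the masked trials."""
    if bin_width_ms <= 0 or step_ms <= 0:
        raise ValueError("bin_width_ms and step_ms must be positive")
    pt, correct, _ = _select(table, mask)
    if pt.size == 0:
        raise ValueError("empty selection")
    centers = np.arange(np.ceil(pt.min()), np.floor(pt.max()) + step_ms,
                        step_ms)
    order = np.argsort(pt, kind="stable")
    pt_sorted = pt[order]
    corr_cum = np.concatenate(([0], np.cumsum(correct[order])))
    lo = np.searchsorted(pt_sorted, centers - bin_width_ms / 2, side="left")
    hi = np.searchsorted(pt_sorted, centers + bin_width_ms / 2, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, (corr_cum[hi] - corr_cum[lo]) /
                        np.maximum(n, 1), np.nan)
    return TachometricCurve(centers, frac, n, bin_width_ms, step_ms)


def floor_ceiling(table: TrialTable, mask=None,
                  floor_max_ms: float = FLOOR_MAX_MS,
                  ceiling_min_ms: float = CEILING_MIN_MS,
                  conf: float = 0.95):
    """Floor (PT < floor_max) and ceiling (PT > ceiling_min) accuracies.

    Proportions over the raw windows — independent of any binning. Either
    summary is flagged undefined (not an error) if its window is empty.
    """
    pt, correct, _ = _select(table, mask)
    out = []
    for window, sel in ((( -np.inf, floor_max_ms), pt < floor_max_ms),
                        ((ceiling_min_ms, np.inf), pt > ceiling_min_ms)):
        out.append(AccuracySummary.from_counts(int(correct[sel].sum()),
                                               int(sel.sum()), window, conf))
    return tuple(out)


def rt_summary(table: TrialTable, mask=None) -> RTSummary:
    """Mean/SD/SEM of RT over the masked trials (all outcomes, all PTs)."""
    _, _, rt = _select(table, mask)
    return RTSummary.from_values(rt)


def difference_curve(curve_s: TachometricCurve,
                     curve_d: TachometricCurve) -> TachometricCurve:
    """Pointwise difference of two tachometric curves (S minus D) on their
    common grid, with binomial SEs propagated in quadrature.

    The returned object reuses the TachometricCurve container with
    ``frac_correct`` holding the difference; ``n_trials`` is the minimum of
    the two per-bin counts (0 marks bins undefined in either input).
    """
    if curve_s.step_ms != curve_d.step_ms or \
            curve_s.bin_width_ms != curve_d.bin_width_ms:
        raise ValueError("curves must share bin width and step")
    common, ia, ib = np.intersect1d(curve_s.bin_center_ms,
                                    curve_d.bin_center_ms,
                                    return_indices=True)
    if common.size == 0:
        raise ValueError("curves have no common PT grid")
    ns, nd = curve_s.n_trials[ia], curve_d.n_trials[ib]
    n = np.minimum(ns, nd)
    diff = np.where(n > 0, curve_s.frac_correct[ia] - curve_d.frac_correct[ib],
                    np.nan)
    out = TachometricCurve(common, diff, n, curve_s.bin_width_ms,
                           curve_s.step_ms)
    out.se_diff = np.where(n > 0, np.sqrt(curve_s.se[ia] ** 2 +
                                          curve_d.se[ib] ** 2), np.nan)
    return out


def single_event_timecourse(table: TrialTable, variable: str,
                            lags=range(10),
                            floor_max_ms: float = FLOOR_MAX_MS,
                            ceiling_min_ms: float = CEILING_MIN_MS) -> dict:
    """Track how the influence of a single same/different event fades with
    the number of intervening trials.

    For each lag k, trials are conditioned on the event k+1 trials back
    being S or D (intervening trials unconstrained) and floor/ceiling
    accuracies are computed for each. Returns
    ``{relation: [(lag, floor, ceiling), ...]}``.
    """
    out = {}
    for rel in ("S", "D"):
        rows = []
        for k in lags:
            mask = label_lagged_event(table, variable, rel, k)
            fl, ce = floor_ceiling(table, mask, floor_max_ms, ceiling_min_ms)
            rows.append((int(k), fl, ce))
        out[rel] = rows
    return out


def bootstrap_ci(values: np.ndarray, statistic, n_reps: int = 10_000,
                 conf: float = 0.95, seed: int | None = None):
    """Percentile bootstrap CI for an arbitrary statistic of a 1-d sample.

    Provided for significance testing of derived quantities; the percentile
    method with ``n_reps`` resamples (default 10^4) is used throughout.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(values)
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    idx = rng.integers(0, n, size=(n_reps, n))
    boot = np.array([statistic(values[row]) for row in idx])
    alpha = 1.0 - conf
    return (float(np.quantile(boot, alpha / 2)),
            float(np.quantile(boot, 1 - alpha / 2)))
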