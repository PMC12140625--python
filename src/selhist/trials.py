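"""Trial-table data model: validation, I/O, and elementary transforms.

Every stage of the pipeline exchanges a :class:`TrialTable` — an ordered
collection of completed urgent-choice trials grouped by session. Each trial
records the gap (delay from go signal to color cue), the reaction time (go
signal to saccade onset), the derived processing time PT = RT - gap, the
target's color and location, the chosen location, and the outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COLORS = ("red", "green")
LOCATIONS = ("right", "up", "left", "down")

#: Response deadline: a saccade later than this after the go signal aborts
#: the trial, so completed trials always satisfy 0 < rt_ms <= deadline.
RT_DEADLINE_MS = 450.0

#: The cue-onset delay is drawn from this range (ms).
GAP_RANGE_MS = (0, 225)

REQUIRED_COLUMNS = (
    "session_id",
    "trial_index",
    "gap_ms",
    "rt_ms",
    "target_color",
    "target_location",
    "choice_location",
)

DERIVED_COLUMNS = ("pt_ms", "correct")

CANONICAL_COLUMNS = REQUIRED_COLUMNS + DERIVED_COLUMNS


class TrialValidationError(ValueError):
    """A trial table violates the schema; the message names the first bad row."""


@dataclass
class TrialTable:
    """Ordered trials with provenance metadata.

    ``data`` holds one row per completed trial in canonical column order;
    sessions are contiguous blocks with strictly increasing ``trial_index``.
    ``meta`` records where the table came from (generator seed, source file,
    subject label) so downstream artifacts are traceable.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        a = self.data[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        b = other.data[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        for col in CANONICAL_COLUMNS:
            if a[col].dtype.kind == "f" or b[col].dtype.kind == "f":
                if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float),
                                   rtol=0, atol=1e-9):
                    return False
            elif not (a[col].astype(str) == b[col].astype(str)).all() and \
                    not (a[col] == b[col]).all():
                return False
        return True

    @property
    def sessions(self) -> list:
        """Session identifiers in order of first appearance."""
        return list(dict.fromkeys(self.data["session_id"]))

    def session_groups(self):
        """Yield ``(session_id, row-index array)`` preserving table order."""
        sid = self.data["session_id"].to_numpy()
        boundaries = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1], True])
        for start, stop in zip(boundaries[:-1], boundaries[1:]):
            yield sid[start], np.arange(start, stop)

    @property
    def pt_ms(self) -> np.ndarray:
        return self.data["pt_ms"].to_numpy(float)

    @property
    def correct(self) -> np.ndarray:
        return self.data["correct"].to_numpy(bool)


def _fail(row: int, msg: str) -> None:
    raise TrialValidationError(f"row {row}: {msg}")


def validate_trials(
    df: pd.DataFrame,
    *,
    rt_deadline_ms: float = RT_DEADLINE_MS,
    gap_range_ms: tuple = GAP_RANGE_MS,
    drop_invalid: bool = False,
) -> pd.DataFrame:
    """Validate and canonicalize a raw trial DataFrame.

    Derived fields (``pt_ms``, ``correct``) are recomputed; if the input
    supplies them, they are cross-checked against the recomputed values.
    Row numbers in error messages are 0-based positions in ``df``.

    With ``drop_invalid=True``, rows violating the timing constraints are
    removed (count recorded in ``df.attrs['n_dropped']``) instead of raising;
    inconsistent derived fields still raise, because they indicate a
    corrupted file rather than an out-of-window trial.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialValidationError(f"missing required column: {col!r}")
    df = df.copy()

    for col, allowed in (("target_color", COLORS),
                         ("target_location", LOCATIONS),
                         ("choice_location", LOCATIONS)):
        vals = df[col].astype(str).str.lower()
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            _fail(row, f"{col}={df[col].iloc[row]!r} not in {allowed}")
        df[col] = vals

    try:
        df["gap_ms"] = df["gap_ms"].astype(int)
        df["rt_ms"] = df["rt_ms"].astype(float)
        df["trial_index"] = df["trial_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise TrialValidationError(f"unparseable numeric value: {exc}") from exc

    rt = df["rt_ms"].to_numpy()
    gap = df["gap_ms"].to_numpy()
    bad_rt = (rt <= 0) | (rt > rt_deadline_ms)
    bad_gap = (gap < gap_range_ms[0]) | (gap > gap_range_ms[1])
    invalid = bad_rt | bad_gap
    if invalid.any() and not drop_invalid:
        row = int(np.flatnonzero(invalid)[0])
        if bad_rt[np.flatnonzero(invalid)[0]]:
            _fail(row, f"rt_ms={rt[row]} outside (0, {rt_deadline_ms}] "
                       f"(response deadline {rt_deadline_ms} ms)")
        _fail(row, f"gap_ms={gap[row]} outside {list(gap_range_ms)}")

    pt = df["rt_ms"] - df["gap_ms"]
    if "pt_ms" in df.columns and df["pt_ms"].notna().any():
        mismatch = ~np.isclose(df["pt_ms"].astype(float).to_numpy(),
                               pt.to_numpy(), rtol=0, atol=1e-6)
        if mismatch.any():
            row = int(np.flatnonzero(mismatch)[0])
            _fail(row, f"pt_ms={df['pt_ms'].iloc[row]} inconsistent with "
                       f"rt_ms - gap_ms = {pt.iloc[row]}")
    df["pt_ms"] = pt

    corr = (df["choice_location"] == df["target_location"])
    if "correct" in df.columns and df["correct"].notna().any():
        provided = df["correct"].map(
            {True: True, False: False, "true": True, "false": False,
             "True": True, "False": False, 1: True, 0: False, "1": True,
             "0": False})
        mismatch = provided != corr
        if mismatch.any():
            row = int(np.flatnonzero(mismatch.to_numpy())[0])
            _fail(row, "correct column contradicts choice_location vs "
                       "target_location")
    df["correct"] = corr

    n_dropped = 0
    if drop_invalid and invalid.any():
        n_dropped = int(invalid.sum())
        df = df.loc[~invalid]

    df["session_id"] = df["session_id"].astype(str)
    # enforce contiguous sessions with strictly increasing trial_index
    seen: dict = {}
    sid = df["session_id"].to_numpy()
    tix = df["trial_index"].to_numpy()
    prev_sid = None
    for pos in range(len(df)):
        s = sid[pos]
        if s != prev_sid:
            if s in seen:
                _fail(pos, f"session {s!r} not contiguous")
            seen[s] = tix[pos]
            prev_sid = s
        else:
            if tix[pos] <= seen[s]:
                _fail(pos, f"trial_index not strictly increasing in "
                           f"session {s!r}")
            seen[s] = tix[pos]

    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    out = df[list(CANONICAL_COLUMNS) + extra].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def read_trials(
    path,
    *,
    column_map: Mapping[str, str] | None = None,
    drop_invalid: bool = False,
    rt_deadline_ms: float = RT_DEADLINE_MS,
) -> TrialTable:
    """Read a delimited trial table (CSV with header, UTF-8).

    ``column_map`` renames source columns to the canonical names, e.g.
    ``{"trial": "trial_index"}`` — this supports foreign dialects without
    hard-coding any of them.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    data = validate_trials(df, drop_invalid=drop_invalid,
                           rt_deadline_ms=rt_deadline_ms)
    meta = {"source": str(path)}
    if data.attrs.get("n_dropped"):
        meta["n_dropped"] = data.attrs["n_dropped"]
    return TrialTable(data, meta)


def write_trials(table: TrialTable, path) -> Path:
    """Write a trial table as canonical CSV; round-trips field-for-field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data[list(CANONICAL_COLUMNS)].to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    """Serialize a result object (dict of plain types) as indented JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))
    return path


def shift_rt(table: TrialTable, delta_ms: float) -> TrialTable:
    """Subtract ``delta_ms`` from every RT (and hence every PT).

    This is the temporal-alignment step used before pooling subjects whose
    guess-to-informed transitions occur at different processing times: a
    positive delta moves the subject's tachometric curve leftward.
    """
    data = table.data.copy()
    data["rt_ms"] = data["rt_ms"] - delta_ms
    data["pt_ms"] = data["rt_ms"] - data["gap_ms"]
    meta = dict(table.meta)
    meta["rt_shift_ms"] = meta.get("rt_shift_ms", 0.0) + delta_ms
    return TrialTable(data, meta)


def quadrantize(angle_deg) -> np.ndarray | str:
    """Map a target angle (degrees, counterclockwise from +x) to a quadrant
    location label.

    Assignment is half-open counterclockwise: the positive x axis and the
    upper-right quadrant interior map to ``right``; the positive y axis and
    the upper-left interior to ``up``; the negative x axis and lower-left
    interior to ``left``; the negative y axis and lower-right interior to
    ``down``.
    """
    a = np.asarray(angle_deg, dtype=float) % 360.0
    idx = (a // 90).astype(int) % 4
    labels = np.array(LOCATIONS)[idx]
    if np.isscalar(angle_deg) or getattr(angle_deg, "ndim", 0) == 0:
        return str(labels if labels.ndim == 0 else labels[()])
    return labels


def concat_tables(tables: Sequence[TrialTable], relabel: bool = True) -> TrialTable:
    """Concatenate tables; with ``relabel`` session ids are prefixed by the
    table's subject label (from meta) to keep them unique."""
    frames = []
    for i, t in enumerate(tables):
        df = t.data.copy()
        if relabel:
            label = t.meta.get("subject", f"s{i + 1}")
            df["session_id"] = [f"{label}:{s}" for s in df["session_id"]]
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    meta = {"pooled_from": [t.meta for t in tables]}
    return TrialTable(data, meta)
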