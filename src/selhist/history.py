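"""Trial-history (serial-dependence) labeling.

Every trial can be conditioned on what happened on the trials before it,
within the same session:

* **Run conditions** — ``NS`` / ``ND``: the N immediately preceding trials
  all had the same (S) or a different (D) target color or location than the
  *current* trial. Semantics are "at least N", so the 2S set is a subset of
  the 1S set.
* **Outcome runs** — ``NC`` / ``NE``: the N preceding trials were all
  correct (C) or all errors (E). These are absolute, not relative to the
  current trial.
* **Lagged single events** — ``1Skx`` / ``1Dkx``: the trial k+1 positions
  back matches (S) or differs from (D) the current trial, with the k
  intervening trials unconstrained. Used to measure how fast a single
  event's influence fades.
* **Joint conditions** — conjunctions, e.g. ``1SC`` (preceding trial same
  color AND correct) or ``1SSC`` (same color, same location, and correct).
* **Fully specified patterns** — per-step strings such as color ``SD`` with
  location ``DS``; at depth H over a set of variables these partition the
  eligible trials and are what the interaction analysis enumerates.

Histories never cross session boundaries: the first N trials of a session
carry no depth-N label.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from .trials import TrialTable

#: Variables a history condition may constrain, in canonical order.
VARIABLES = ("color", "location", "outcome")

_COLUMN = {"color": "target_color", "location": "target_location",
           "outcome": "correct"}
_ALPHABET = {"color": "SD", "location": "SD", "outcome": "CE"}


@dataclass(frozen=True)
class HistoryCondition:
    """One variable's history constraint: a per-step pattern (most recent
    step first) over {S, D} for color/location or {C, E} for outcome, with
    an optional lag for single-event (depth-1) conditions."""

    variable: str
    pattern: str
    lag: int = 0

    def __post_init__(self):
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown history variable: {self.variable!r}")
        allowed = set(_ALPHABET[self.variable])
        if not self.pattern or set(self.pattern) - allowed:
            raise ValueError(
                f"pattern {self.pattern!r} invalid for {self.variable} "
                f"(alphabet {sorted(allowed)})")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.lag > 0 and len(self.pattern) != 1:
            raise ValueError("lagged conditions require depth 1")

    @property
    def depth(self) -> int:
        return len(self.pattern)

    @property
    def name(self) -> str:
        if self.lag:
            return f"1{self.pattern}{self.lag}x"
        return f"{self.depth}{self.pattern[0]}" if len(set(self.pattern)) == 1 \
            else self.pattern

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}:{self.variable}"


@dataclass(frozen=True)
class SequenceKey:
    """A fully specified joint history sequence at depth H: one per-step
    pattern for each participating variable. Decodes uniquely back to its
    component conditions."""

    variables: tuple
    patterns: tuple  # parallel to variables; each a length-H string
    H: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "H", len(self.patterns[0]))
        if any(len(p) != self.H for p in self.patterns):
            raise ValueError("all patterns must share the same depth")

    @property
    def name(self) -> str:
        return f"{self.H}" + "".join(self.patterns)

    def conditions(self) -> list:
        return [HistoryCondition(v, p)
                for v, p in zip(self.variables, self.patterns)]


def _positions_in_session(table: TrialTable) -> np.ndarray:
    """0-based position of each trial within its session block."""
    pos = np.empty(len(table), dtype=np.int64)
    for _, idx in table.session_groups():
        pos[idx] = np.arange(len(idx))
    return pos


def _step_mask(values: np.ndarray, pos: np.ndarray, step: int,
               variable: str, rel: str) -> np.ndarray:
    """True where the trial ``step`` positions back (same session) satisfies
    ``rel`` with respect to the current trial."""
    n = len(values)
    ok = np.zeros(n, dtype=bool)
    valid = pos >= step
    prev = np.empty_like(values)
    prev[step:] = values[:-step] if step else values
    if variable == "outcome":
        match = prev == (rel == "C")
    else:
        match = (prev == values) if rel == "S" else (prev != values)
    ok[valid] = match[valid]
    return ok


def label_pattern(table: TrialTable, condition: HistoryCondition) -> np.ndarray:
    """Boolean mask for a per-step history pattern (most recent step first).

    For ``lag = k`` the single constrained step sits k+1 trials back and the
    intervening k trials are unconstrained.
    """
    values = table.data[_COLUMN[condition.variable]].to_numpy()
    pos = _positions_in_session(table)
    mask = np.ones(len(table), dtype=bool)
    if condition.lag:
        return _step_mask(values, pos, condition.lag + 1,
                          condition.variable, condition.pattern)
    for j, rel in enumerate(condition.pattern, start=1):
        mask &= _step_mask(values, pos, j, condition.variable, rel)
    return mask


def label_run(table: TrialTable, variable: str, relation: str,
              depth: int) -> np.ndarray:
    """Mask of trials preceded by at least ``depth`` trials that are all
    same (S) / different (D) in ``variable`` relative to the current trial.

    For location, "different" means any of the three other locations.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if variable not in ("color", "location"):
        raise ValueError("label_run applies to color or location; use "
                         "label_outcome_run for outcomes")
    if relation not in ("S", "D"):
        raise ValueError("relation must be 'S' or 'D'")
    return label_pattern(table, HistoryCondition(variable, relation * depth))


def label_outcome_run(table: TrialTable, relation: str,
                      depth: int) -> np.ndarray:
    """Mask of trials preceded by at least ``depth`` correct (C) or error
    (E) trials. Absolute: unlike S/D, does not reference the current trial."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if relation not in ("C", "E"):
        raise ValueError("relation must be 'C' or 'E'")
    return label_pattern(table, HistoryCondition("outcome", relation * depth))


def label_lagged_event(table: TrialTable, variable: str, relation: str,
                       lag: int) -> np.ndarray:
    """Mask for a single S/D event ``lag + 1`` trials back with ``lag``
    unconstrained intervening trials (the ``1Skx`` / ``1Dkx`` conditions).

    ``lag = 0`` reduces exactly to ``label_run(..., depth=1)``.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    return label_pattern(table, HistoryCondition(variable, relation, lag=lag))


def label_joint(table: TrialTable, conditions) -> np.ndarray:
    """Conjunction of history conditions (e.g. 1S color AND 1C outcome).

    All conditions must share the same depth so the joint label describes
    one well-defined stretch of preceding trials.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one condition")
    depths = {c.depth for c in conditions}
    if len(depths) > 1:
        raise ValueError(f"incompatible depths in joint condition: "
                         f"{sorted(depths)}")
    mask = np.ones(len(table), dtype=bool)
    for c in conditions:
        mask &= label_pattern(table, c)
    return mask


def label_sequence(table: TrialTable, key: SequenceKey) -> np.ndarray:
    """Mask for a fully specified joint sequence."""
    return label_joint(table, key.conditions())


def enumerate_sequences(variables, H: int) -> list:
    """All fully specified joint sequences at depth ``H`` over ``variables``.

    Count is ``(2 ** len(variables)) ** H``. Canonical order: most recent
    step varies slowest, and within a step S precedes D and C precedes E,
    with variables in (color, location, outcome) order.
    """
    variables = tuple(variables)
    if not 1 <= H <= 4:
        raise ValueError("H must be in 1..4")
    bad = [v for v in variables if v not in VARIABLES]
    if bad or not variables:
        raise ValueError(f"invalid variables: {bad or variables}")
    variables = tuple(v for v in VARIABLES if v in variables)
    # slots ordered step-major (most recent step first), variable-minor
    slots = [(step, v) for step in range(H) for v in variables]
    keys = []
    for combo in itertools.product(*(_ALPHABET[v] for _, v in slots)):
        patterns = {v: [""] * H for v in variables}
        for (step, v), ch in zip(slots, combo):
            patterns[v][step] = ch
        keys.append(SequenceKey(variables,
                                tuple("".join(patterns[v]) for v in variables)))
    return keys


_CONDITION_RE = re.compile(
    r"^(?P<depth>\d+)(?P<rel>[SD])(?:(?P<lag>\d+)x)?(?P<rel2>[SD])?"
    r"(?P<out>[CE])?$")


def parse_condition(text: str) -> list:
    """Parse a condition label like ``2S:color``, ``1D2x:location``,
    ``3C``, ``2SC:color`` or ``1SSC`` into HistoryConditions.

    A ``variable`` suffix after ``:`` names the S/D variable; two S/D
    letters with no suffix denote (color, location) in that order; a
    trailing C/E adds an outcome run of the same depth.
    """
    text = text.strip()
    if ":" in text:
        label, variable = text.split(":", 1)
        variable = variable.strip()
    else:
        label, variable = text, None
    m = re.match(r"^(\d+)([CE])$", label)
    if m:
        return [HistoryCondition("outcome", m.group(2) * int(m.group(1)))]
    m = _CONDITION_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse history condition: {text!r}")
    depth = int(m.group("depth"))
    conditions = []
    if m.group("rel2"):
        if variable is not None:
            raise ValueError(f"{text!r}: two S/D letters already imply "
                             "(color, location); drop the variable suffix")
        conditions.append(HistoryCondition("color", m.group("rel") * depth))
        conditions.append(HistoryCondition("location",
                                           m.group("rel2") * depth))
    else:
        if variable is None:
            raise ValueError(f"{text!r}: specify a variable, e.g. "
                             f"'{label}:color'")
        if m.group("lag") is not None:
            if depth != 1:
                raise ValueError("lagged conditions require depth 1")
            conditions.append(HistoryCondition(variable, m.group("rel"),
                                               lag=int(m.group("lag"))))
        else:
            conditions.append(HistoryCondition(variable,
                                               m.group("rel") * depth))
    if m.group("out"):
        if m.group("lag") is not None:
            raise ValueError("outcome runs cannot combine with lagged "
                             "conditions")
        conditions.append(HistoryCondition("outcome", m.group("out") * depth))
    return conditions


def condition_name(conditions) -> str:
    """Canonical column name for a (joint) condition."""
    conditions = list(conditions)
    if len(conditions) == 1:
        c = conditions[0]
        return f"{c.name}_{c.variable}" if not c.lag else \
            f"{c.name}_{c.variable}"
    depth = conditions[0].depth
    by_var = {c.variable: c for c in conditions}
    parts = [by_var[v].pattern if v in by_var else "" for v in VARIABLES]
    if all(len(set(p)) <= 1 for p in parts):
        return f"{depth}" + "".join(p[0] if p else "" for p in parts)
    return f"{depth}" + "".join(parts)
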