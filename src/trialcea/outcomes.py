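"""Clinical outcomes: responder status, individual effect sizes, utilities, QALYs.

The clinical endpoint is treatment response, defined as a decrease of at
least 50% on the IDS-SR total score relative to baseline.  Quality of life is
derived indirectly: an individual standardized effect size

    d_i = (IDS_i[TX] - IDS_i[T0]) / SD(IDS[T0])

(negative = improvement) is mapped to a utility change through a conversion
factor expressing the average utility difference associated with one effect
size unit in depression.  Utility changes are then integrated over time to
give quality-adjusted life-years (QALYs) gained relative to the baseline
health state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: 1-based item numbers of the appetite (11/12) and weight (13/14)
#: increase/decrease alternatives: each pair contributes a single score, which
#: is how a 30-item instrument has a 0-84 total range (28 scored items x 3).
DEFAULT_ALTERNATIVE_PAIRS: tuple[tuple[int, int], ...] = ((11, 12), (13, 14))


def ids_total(
    items: Sequence[int],
    alternative_pairs: tuple[tuple[int, int], ...] = DEFAULT_ALTERNATIVE_PAIRS,
) -> int:
    """Total IDS-SR score from the 30 item scores.

    Each item scores 0-3.  Items in an alternative pair (by default the
    appetite and weight increase/decrease pairs) contribute the maximum of the
    pair, so the total ranges over [0, 84].
    """
    if len(items) != 30:
        raise ValueError(f"expected 30 item scores, got {len(items)}")
    arr = np.asarray(items)
    if arr.min() < 0 or arr.max() > 3 or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("item scores must be integers in {0, 1, 2, 3}")
    paired = {i for pair in alternative_pairs for i in pair}
    total = sum(int(arr[i - 1]) for i in range(1, 31) if i not in paired)
    total += sum(max(int(arr[a - 1]), int(arr[b - 1])) for a, b in alternative_pairs)
    return total


def is_responder(baseline: float, followup: float) -> bool:
    """True iff the score decreased by 50% or more from baseline."""
    if baseline <= 0:
        raise ValueError("baseline score must be positive")
    return (baseline - followup) / baseline >= 0.5


@dataclass(frozen=True)
class ResponderFlag:
    participant_id: str
    wave: int
    is_responder: bool


def responder_rate(flags: Iterable, n_randomized: int) -> float:
    """Intent-to-treat responder rate in percent, to one decimal.

    ``flags`` may be booleans or :class:`ResponderFlag` objects; the
    denominator is everyone randomized, not just completers.
    """
    if n_randomized <= 0:
        raise ValueError("n_randomized must be positive")
    count = 0
    for f in flags:
        count += bool(f.is_responder if isinstance(f, ResponderFlag) else f)
    return round(100.0 * count / n_randomized, 1)


def cohen_d_individual(ids_t0: float, ids_tx: float, sd_t0: float) -> float:
    """Individual standardized change; negative values mean improvement."""
    if sd_t0 <= 0:
        raise ValueError("sd_t0 must be positive")
    return (ids_tx - ids_t0) / sd_t0


def utility_change(
    d: float, factor: float, baseline_utility: float | None = None
) -> float:
    """Map an individual effect size to a utility change.

    A symptom improvement (d < 0) becomes a utility gain of ``factor`` per
    effect size unit.  When a baseline utility anchor is given, the change is
    clamped so the resulting utility stays on the [0, 1] scale; the change
    itself is always clamped to [-1, 1].
    """
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    delta = -factor * d
    if baseline_utility is not None:
        if not 0.0 <= baseline_utility <= 1.0:
            raise ValueError("baseline_utility must lie in [0, 1]")
        delta = min(max(delta, -baseline_utility), 1.0 - baseline_utility)
    return float(np.clip(delta, -1.0, 1.0))


def qaly_gained(
    utility_changes: Sequence[float],
    wave_times: Sequence[float],
    method: str = "auc",
) -> float:
    """QALYs gained relative to the baseline health state.

    ``wave_times`` are in years, strictly increasing and starting at 0, with
    the baseline utility change defined as 0.  ``method="auc"`` (default)
    integrates the linearly interpolated utility-change curve; ``"rectangle"``
    applies each wave's utility change to the whole preceding interval (the
    time spent in that health state).
    """
    t = np.asarray(wave_times, dtype=float)
    u = np.asarray(utility_changes, dtype=float)
    if t.shape != u.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("need matching 1-d arrays with at least two waves")
    if t[0] != 0:
        raise ValueError("wave times must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("wave times must be strictly increasing")
    if u[0] != 0:
        raise ValueError("baseline utility change must be 0")
    if method == "auc":
        return float(np.trapezoid(u, t))
    if method == "rectangle":
        return float(np.sum(u[1:] * np.diff(t)))
    raise ValueError(f"unknown method: {method}")


__all__ = [
    "DEFAULT_ALTERNATIVE_PAIRS",
    "ResponderFlag",
    "ids_total",
    "is_responder",
    "responder_rate",
    "cohen_d_individual",
    "utility_change",
    "qaly_gained",
]
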