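"""DNA fiber combing: tract lengths to fork speeds and fork-behavior classes.

Fibers carry two sequential pulse labels (IdU then CldU, 20 min each by
default). Measured tract lengths in micrometers convert to kilobases at
2.59 kb/µm. A fiber with both labels is an ongoing fork whose speed is the
total tract length divided by the total pulse time; first-label-only fibers
are stalled forks; second-label-only fibers are new origins. Stalled and
new-origin fibers carry no speed and are excluded from cohort mean speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

KB_PER_UM = 2.59  # DNA compaction on combed fibers
DEFAULT_PULSE_MIN = 20.0

ONGOING, STALLED, NEW_ORIGIN = "ongoing", "stalled", "new_origin"
CLASSES = (ONGOING, STALLED, NEW_ORIGIN)


@dataclass(frozen=True)
class FiberTract:
    """One measured fiber with per-label tract lengths in micrometers."""

    fiber_id: str
    idu_um: float
    cldu_um: float
    idu_pulse_min: float = DEFAULT_PULSE_MIN
    cldu_pulse_min: float = DEFAULT_PULSE_MIN
    condition: str = ""

    def __post_init__(self):
        if self.idu_um < 0 or self.cldu_um < 0:
            raise ValueError("tract lengths must be >= 0")
        if self.idu_um == 0 and self.cldu_um == 0:
            raise ValueError("a fiber must carry at least one label")
        if self.idu_pulse_min <= 0 or self.cldu_pulse_min <= 0:
            raise ValueError("pulse durations must be > 0")


@dataclass(frozen=True)
class ForkCall:
    fiber_id: str
    fork_class: str
    speed_kb_per_min: Optional[float]  # present only for ongoing forks


def tract_kb(length_um: float, kb_per_um: float = KB_PER_UM) -> float:
    """Convert a tract length in micrometers to kilobases."""
    if length_um < 0:
        raise ValueError("tract length must be >= 0")
    return length_um * kb_per_um


def fork_speed(tract: FiberTract, kb_per_um: float = KB_PER_UM,
               per_label: bool = False,
               stall_threshold_um: float = 0.0) -> ForkCall:
    """Classify one fiber and compute its speed when both labels are present.

    Default speed = total tract length (kb) / total pulse time (min). With
    ``per_label`` the speed is instead the mean of the two per-label speeds.
    A label counts as present when its tract exceeds ``stall_threshold_um``.
    """
    has_idu = tract.idu_um > stall_threshold_um
    has_cldu = tract.cldu_um > stall_threshold_um
    if has_idu and has_cldu:
        if per_label:
            speed = 0.5 * (tract_kb(tract.idu_um, kb_per_um) / tract.idu_pulse_min
                           + tract_kb(tract.cldu_um, kb_per_um) / tract.cldu_pulse_min)
        else:
            speed = (tract_kb(tract.idu_um + tract.cldu_um, kb_per_um)
                     / (tract.idu_pulse_min + tract.cldu_pulse_min))
        return ForkCall(tract.fiber_id, ONGOING, speed)
    if has_idu:
        return ForkCall(tract.fiber_id, STALLED, None)
    # only the second label (or neither above threshold, where the first
    # pulse left no measurable tract either): scored as a new origin
    return ForkCall(tract.fiber_id, NEW_ORIGIN, None)


def summarize_forks(calls: Sequence[ForkCall]) -> Dict[str, float]:
    """Cohort summary: class fractions plus mean ± SEM of ongoing speeds."""
    if not calls:
        raise ValueError("empty cohort")
    n = len(calls)
    speeds = np.array([c.speed_kb_per_min for c in calls
                       if c.fork_class == ONGOING], dtype=float)
    out: Dict[str, float] = {"n_fibers": float(n)}
    for cls in CLASSES:
        out[f"fraction_{cls}"] = sum(c.fork_class == cls for c in calls) / n
    out["n_ongoing"] = float(speeds.size)
    out["mean_speed_kb_per_min"] = float(speeds.mean()) if speeds.size else float("nan")
    out["sem_speed_kb_per_min"] = (
        float(speeds.std(ddof=1) / math.sqrt(speeds.size))
        if speeds.size > 1 else 0.0)
    return out


def read_tracts(path: Path | str) -> List[FiberTract]:
    """Read a tract table (TSV: fiber_id, condition, idu_um, cldu_um,
    optional idu_pulse_min / cldu_pulse_min overrides)."""
    df = pd.read_csv(path, sep="\t")
    tracts = []
    for _, row in df.iterrows():
        tracts.append(FiberTract(
            fiber_id=str(row["fiber_id"]),
            idu_um=float(row["idu_um"]),
            cldu_um=float(row["cldu_um"]),
            idu_pulse_min=float(row.get("idu_pulse_min", DEFAULT_PULSE_MIN)),
            cldu_pulse_min=float(row.get("cldu_pulse_min", DEFAULT_PULSE_MIN)),
            condition=str(row.get("condition", "")),
        ))
    return tracts


def forks_table(tracts: Sequence[FiberTract], **kwargs) -> pd.DataFrame:
    calls = [fork_speed(t, **kwargs) for t in tracts]
    return pd.DataFrame({
        "fiber_id": [c.fiber_id for c in calls],
        "condition": [t.condition for t in tracts],
        "fork_class": [c.fork_class for c in calls],
        "speed_kb_per_min": [c.speed_kb_per_min for c in calls],
    })
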