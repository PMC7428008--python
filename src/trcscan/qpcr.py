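"""qPCR quantification: DRIP relative abundance, RNase H sensitivity, ΔΔCt.

DRIP-qPCR signal is expressed relative to the non-immunoprecipitated input:
with amplification efficiency E per cycle (default 2, perfect doubling),

    relative abundance = E ** (adjusted_input_Ct − IP_Ct),

where the input Ct is first adjusted by log_E(input_fraction) so that an
input well representing only a fraction of the template pool stands in for
the whole of it. RNase H sensitivity is the ratio of treated to untreated
relative abundance — values near zero indicate hybrid-specific signal.
Relative mRNA expression uses the comparative-Ct (ΔΔCt) method against an
explicit reference gene.

Undetermined Ct values are treated as signal-absent (relative abundance 0,
flagged), never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DEFAULT_EFFICIENCY = 2.0


@dataclass(frozen=True)
class QpcrWell:
    """One qPCR measurement."""

    sample_id: str
    amplicon: str
    ct: Optional[float]  # None = undetermined
    role: str  # 'IP', 'input', or 'cDNA'
    condition: str = ""
    rnaseh_pretreated: bool = False
    input_fraction: float = 1.0
    replicate: int = 1

    def __post_init__(self):
        if self.ct is not None and self.ct <= 0:
            raise ValueError("Ct must be > 0 when present")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must be in (0, 1]")


@dataclass(frozen=True)
class RelativeAbundance:
    amplicon: str
    condition: str
    value: float
    n_replicates: int
    sem: float
    any_undetermined: bool = False

    def __post_init__(self):
        if self.value < 0 or self.sem < 0:
            raise ValueError("value and sem must be >= 0")


def _mean_sem(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, sem


def drip_relative_abundance(
    ip: Sequence[QpcrWell],
    input_wells: Sequence[QpcrWell],
    efficiency: float = DEFAULT_EFFICIENCY,
) -> RelativeAbundance:
    """Relative abundance of hybrids, IP normalized to input template.

    Per replicate: adjusted input Ct = input Ct + log_E(input_fraction);
    value = E ** (adjusted input Ct − IP Ct). Replicates are paired by
    replicate number (falling back to the mean input Ct); the result is the
    replicate mean with SEM. Undetermined IP Ct contributes value 0 and
    sets the ``any_undetermined`` flag.
    """
    if not input_wells:
        raise ValueError("no matched input well")
    amplicons = {w.amplicon for w in list(ip) + list(input_wells)}
    conditions = {w.condition for w in list(ip) + list(input_wells)}
    if len(amplicons) > 1 or len(conditions) > 1:
        raise ValueError("IP and input wells must share amplicon and condition")

    def adjusted(w: QpcrWell) -> float:
        return w.ct + math.log(w.input_fraction, efficiency)

    by_rep = {w.replicate: w for w in input_wells if w.ct is not None}
    if not by_rep:
        raise ValueError("all input wells are undetermined")
    mean_input = float(np.mean([adjusted(w) for w in by_rep.values()]))

    values, undetermined = [], False
    for well in ip:
        if well.ct is None:
            values.append(0.0)
            undetermined = True
            continue
        ref = adjusted(by_rep[well.replicate]) if well.replicate in by_rep \
            else mean_input
        values.append(efficiency ** (ref - well.ct))
    if not values:
        raise ValueError("no IP wells supplied")
    mean, sem = _mean_sem(values)
    return RelativeAbundance(
        amplicon=amplicons.pop(), condition=conditions.pop(),
        value=mean, n_replicates=len(values), sem=sem,
        any_undetermined=undetermined)


def rnaseh_sensitivity(untreated: RelativeAbundance,
                       treated: RelativeAbundance) -> Optional[float]:
    """treated / untreated relative abundance; None when undefined (0/0)."""
    if untreated.amplicon != treated.amplicon:
        raise ValueError("RNase H ratio needs matching amplicons")
    if untreated.value == 0:
        return None
    return treated.value / untreated.value


def relative_expression(
    target_treated: Sequence[QpcrWell],
    ref_treated: Sequence[QpcrWell],
    target_control: Sequence[QpcrWell],
    ref_control: Sequence[QpcrWell],
    efficiency: float = DEFAULT_EFFICIENCY,
) -> RelativeAbundance:
    """Comparative-Ct (ΔΔCt) fold change of a target gene vs a reference gene.

    ΔCt = Ct_target − Ct_ref per condition (replicates paired by replicate
    number); fold = E ** −(mean ΔCt_treated − mean ΔCt_control). The SEM is
    that of the per-treated-replicate folds against the mean control ΔCt.
    """
    for name, wells in (("ref_treated", ref_treated),
                        ("ref_control", ref_control)):
        if not wells:
            raise ValueError(f"missing reference wells: {name}")
    if not target_treated or not target_control:
        raise ValueError("missing target wells")

    def delta_cts(targets, refs) -> List[float]:
        ref_by_rep = {w.replicate: w.ct for w in refs if w.ct is not None}
        if not ref_by_rep:
            raise ValueError("all reference wells are undetermined")
        mean_ref = float(np.mean(list(ref_by_rep.values())))
        out = []
        for w in targets:
            if w.ct is None:
                continue
            out.append(w.ct - ref_by_rep.get(w.replicate, mean_ref))
        if not out:
            raise ValueError("all target wells are undetermined")
        return out

    d_treated = delta_cts(target_treated, ref_treated)
    d_control = delta_cts(target_control, ref_control)
    mean_control = float(np.mean(d_control))
    folds = [efficiency ** (-(d - mean_control)) for d in d_treated]
    mean, sem = _mean_sem(folds)
    return RelativeAbundance(
        amplicon=target_treated[0].amplicon,
        condition=target_treated[0].condition,
        value=mean, n_replicates=len(folds), sem=sem)


# ---------------------------------------------------------------------------
# table I/O


def read_wells(path: Path | str) -> List[QpcrWell]:
    """Read wells from CSV with columns sample_id, amplicon, role, condition,
    rnaseh, input_fraction, replicate, ct ('' or 'Undetermined' = absent)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "amplicon": str})
    wells = []
    for _, row in df.iterrows():
        raw_ct = row.get("ct")
        ct = None
        if raw_ct is not None and not pd.isna(raw_ct):
            if not (isinstance(raw_ct, str)
                    and raw_ct.strip().lower() in ("", "undetermined", "na")):
                ct = float(raw_ct)
        wells.append(QpcrWell(
            sample_id=str(row["sample_id"]),
            amplicon=str(row["amplicon"]),
            ct=ct,
            role=str(row["role"]),
            condition=str(row.get("condition", "")),
            rnaseh_pretreated=bool(row.get("rnaseh", False)),
            input_fraction=float(row.get("input_fraction", 1.0)),
            replicate=int(row.get("replicate", 1)),
        ))
    return wells


def drip_table(wells: Sequence[QpcrWell],
               efficiency: float = DEFAULT_EFFICIENCY) -> pd.DataFrame:
    """Per-amplicon/condition/RNase-H relative-abundance table."""
    groups: Dict[Tuple[str, str, bool], Dict[str, List[QpcrWell]]] = {}
    for w in wells:
        if w.role not in ("IP", "input"):
            continue
        key = (w.amplicon, w.condition, w.rnaseh_pretreated)
        groups.setdefault(key, {"IP": [], "input": []})[w.role].append(w)
    rows = []
    for (amplicon, condition, rnaseh), g in sorted(groups.items()):
        ra = drip_relative_abundance(g["IP"], g["input"], efficiency)
        rows.append((amplicon, condition, rnaseh, ra.value, ra.n_replicates,
                     ra.sem, ra.any_undetermined))
    return pd.DataFrame(rows, columns=[
        "amplicon", "condition", "rnaseh_pretreated", "relative_abundance",
        "n_replicates", "sem", "any_undetermined"])
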