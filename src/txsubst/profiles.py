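"""Derived per-bin statistics: strand-asymmetry ratios, W->S/S->W, skews, GC*.

All statistics are reported on the non-template strand.  Complementary
ratios [X->Y]/[X'->Y'] equal one under strand-symmetric mutation; their
departure from one is the transcription-associated strand asymmetry.  The
weak-to-strong and strong-to-weak frequencies are composition-weighted
averages of the relevant single-base frequencies, with the CpG
methylation-deamination channel entering through the CpG dinucleotide
density; GC* and the stationary skews are read off the stationary
composition implied by a branch's RateSet.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CPG_NAMES,
    SINGLE_NAMES,
    Composition,
    RateSet,
    stationary_composition,
)

logger = logging.getLogger(__name__)

#: the five symmetry-breaking complementary pairs reported by the analysis
RATIO_PAIRS: list[tuple[str, str]] = [
    ("A>G", "T>C"),
    ("C>T", "G>A"),
    ("G>T", "C>A"),
    ("C>G", "G>C"),
    ("A>T", "T>A"),
]

STATISTICS = (
    [f"ratio_{a}_{b}" for a, b in RATIO_PAIRS]
    + [
        "ws_ratio_with_cpg",
        "ws_ratio_noncpg",
        "gc_current",
        "gc_star",
        "ta_skew",
        "gc_skew",
        "ta_skew_star",
        "gc_skew_star",
    ]
    + SINGLE_NAMES
    + CPG_NAMES
)


@dataclasses.dataclass
class ProfileRow:
    anchor: str
    bin_index: int
    gene_class: str
    branch: str
    statistic: str
    value: float
    ci_lo: float | None = None
    ci_hi: float | None = None

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic}")


def complementary_ratio(rates: RateSet, pair: tuple[str, str]) -> float:
    """[X->Y]/[X'->Y']; NaN marks an undefined (zero-denominator) ratio."""
    num = rates.single[pair[0]]
    den = rates.single[pair[1]]
    if den == 0:
        return math.nan
    return num / den


def ws_frequencies(
    rates: RateSet, comp: Composition, include_cpg: bool = True
) -> tuple[float, float]:
    """([W->S], [S->W]) per weak / strong base.

    [W->S] = ([A]([A>C]+[A>G]) + [T]([T>C]+[T>G])) / ([A]+[T]);
    [S->W] = ([C]([C>A]+[C>T]) + [G]([G>A]+[G>T])
              + [CpG]([CpG>TpG]+[CpG>CpA]+[CpG>ApG]+[CpG>CpT])) / ([C]+[G]),
    the [CpG] term dropped with include_cpg=False.  The S->S processes
    CpG>CpC and CpG>GpG never contribute.  NaN marks undefined values.
    """
    a, c, g, t = (float(x) for x in comp.mono)
    s = rates.single
    w_den = a + t
    s_den = c + g
    if w_den == 0 or s_den == 0:
        return math.nan, math.nan
    ws = (a * (s["A>C"] + s["A>G"]) + t * (s["T>C"] + s["T>G"])) / w_den
    sw = c * (s["C>A"] + s["C>T"]) + g * (s["G>A"] + s["G>T"])
    if include_cpg:
        sw += comp.cpg_density * (
            rates.cpg["CpG>TpG"]
            + rates.cpg["CpG>CpA"]
            + rates.cpg["CpG>ApG"]
            + rates.cpg["CpG>CpT"]
        )
    return ws, sw / s_den


def skew(comp: Composition) -> tuple[float, float]:
    """(TA skew, GC skew) = (([T]-[A])/([T]+[A]), ([G]-[C])/([G]+[C]))."""
    a, c, g, t = (float(x) for x in comp.mono)
    ta = (t - a) / (t + a) if (t + a) > 0 else math.nan
    gc = (g - c) / (g + c) if (g + c) > 0 else math.nan
    return ta, gc


def gc_star(rates: RateSet) -> float:
    """Stationary GC content [C*]+[G*] under the branch's dynamics."""
    return stationary_composition(rates).gc


def _statistics_for(rates: RateSet, comp: Composition) -> dict[str, float]:
    out: dict[str, float] = {}
    for a, b in RATIO_PAIRS:
        out[f"ratio_{a}_{b}"] = complementary_ratio(rates, (a, b))
    star = stationary_composition(rates)
    ws, sw = ws_frequencies(rates, comp, include_cpg=True)
    out["ws_ratio_with_cpg"] = ws / sw if sw else math.nan
    ws_n, sw_n = ws_frequencies(rates, comp, include_cpg=False)
    out["ws_ratio_noncpg"] = ws_n / sw_n if sw_n else math.nan
    out["gc_current"] = comp.gc
    out["gc_star"] = star.gc
    out["ta_skew"], out["gc_skew"] = skew(comp)
    out["ta_skew_star"], out["gc_skew_star"] = skew(star)
    for name in SINGLE_NAMES:
        out[name] = rates.single[name]
    for name in CPG_NAMES:
        out[name] = rates.cpg[name]
    return out


def assemble_profiles(
    estimates: Mapping[tuple[str, int, str], Mapping[str, RateSet]],
    compositions: Mapping[tuple[str, int, str], Composition],
    branches: Sequence[str] | None = None,
    replicates: Sequence[Mapping[tuple[str, int, str], Mapping[str, RateSet]]] = (),
) -> list[ProfileRow]:
    """One ProfileRow per (anchor, bin, class, branch, statistic).

    ``estimates`` maps (anchor, bin_index, gene_class) to per-branch
    RateSets; ``compositions`` holds the current (reference-species)
    composition of the same keys.  ``replicates`` — per-bootstrap-resample
    estimates of the same structure — add 2.5/97.5 percentile CIs.
    Missing bins simply yield no rows (logged).
    """
    rows: list[ProfileRow] = []
    for key in sorted(estimates):
        anchor, bin_index, cls = key
        if key not in compositions:
            logger.warning("no composition for %s; rows skipped", key)
            continue
        comp = compositions[key]
        per_branch = estimates[key]
        for branch in branches if branches is not None else sorted(per_branch):
            stats = _statistics_for(per_branch[branch], comp)
            reps: dict[str, list[float]] = {}
            for rep in replicates:
                if key in rep and branch in rep[key]:
                    for k, v in _statistics_for(rep[key][branch], comp).items():
                        reps.setdefault(k, []).append(v)
            for stat, value in stats.items():
                lo = hi = None
                if reps.get(stat):
                    lo = float(np.nanpercentile(reps[stat], 2.5))
                    hi = float(np.nanpercentile(reps[stat], 97.5))
                rows.append(
                    ProfileRow(anchor, bin_index, cls, branch, stat, value, lo, hi)
                )
    return rows


def profiles_to_frame(rows: Sequence[ProfileRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def write_profiles_tsv(rows: Sequence[ProfileRow], path, header: str = "") -> None:
    df = profiles_to_frame(rows)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_profiles_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
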