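"""Assay decisions from barcode count tables.

Three positivity rules, applied in conjunction (each individually
toggleable and recorded per call):

* ``min_reads`` — a prey barcode with fewer than 10 reads is negative;
* ``control_exceed`` — the prey signal must strictly exceed the matched
  negative control (barcoded HaloTag-only protein);
* ``noise_floor`` — the signal must reach mean + 3 SD of the read counts
  attributed to barcodes not used in the assay (sequencing background).

Also here: the positive/random reference-set (PRS/RRS) screen summary
with its two-tailed Fisher's exact test, and the immunoprecipitation
dilution-series caller with replicate-barcode summation and the
serum-reference specificity ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from numbers import Number
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .counting import MoleculeCountTable

__all__ = [
    "NoiseFloor",
    "AssayCall",
    "ScreenSummary",
    "IPSeriesResult",
    "noise_floor",
    "call_ppi",
    "fisher_exact_two_tailed",
    "summarize_screen",
    "call_screen",
    "call_ip_series",
]

RULES = ("min_reads", "control_exceed", "noise_floor")


@dataclass(frozen=True)
class NoiseFloor:
    """Sequencing-background threshold: mean + 3 SD (sample SD, n-1) of
    reads attributed to unused barcodes."""

    unused_mean: float
    unused_sd: float

    @property
    def threshold(self) -> float:
        return self.unused_mean + 3.0 * self.unused_sd


def noise_floor(count_table: MoleculeCountTable) -> NoiseFloor:
    """Estimate the noise floor from the count table's unused-role rows."""
    reads = count_table.unused_read_counts()
    if len(reads) < 2:
        raise ValueError(
            "noise floor undefined: need >= 2 unused identifiers, "
            f"found {len(reads)}"
        )
    return NoiseFloor(
        unused_mean=float(np.mean(reads)),
        unused_sd=float(np.std(reads, ddof=1)),
    )


@dataclass(frozen=True)
class AssayCall:
    """A positive/negative decision with the rules that fired.

    ``rules_fired`` maps each enabled rule to whether it passed; a call is
    positive iff every enabled rule passed.  ``background_noise`` marks
    signals that failed only the noise-floor rule.
    """

    protein: str
    reads: int
    call: str  # positive | negative | background_noise
    rules_fired: dict[str, bool]
    thresholds_used: dict[str, float]

    @property
    def positive(self) -> bool:
        return self.call == "positive"


def call_ppi(
    prey_reads: int,
    control_reads: int,
    floor: NoiseFloor | None = None,
    min_reads: int = 10,
    protein: str = "",
    rules: Sequence[str] = RULES,
) -> AssayCall:
    """Score one prey barcode against the three conjunct positivity rules.

    ``exceeded`` is strict: a tie with the control is negative.  A signal
    passing the read-count and control rules but sitting below the noise
    floor is labelled ``background_noise``.
    """
    if prey_reads < 0 or control_reads < 0:
        raise ValueError("read counts must be non-negative")
    fired: dict[str, bool] = {}
    if "min_reads" in rules:
        fired["min_reads"] = prey_reads >= min_reads
    if "control_exceed" in rules:
        fired["control_exceed"] = prey_reads > control_reads
    if "noise_floor" in rules:
        if floor is None:
            raise ValueError("noise_floor rule enabled but no NoiseFloor given")
        fired["noise_floor"] = prey_reads >= floor.threshold
    if all(fired.values()):
        call = "positive"
    elif fired.get("noise_floor") is False and all(
        v for k, v in fired.items() if k != "noise_floor"
    ):
        call = "background_noise"
    else:
        call = "negative"
    thresholds = {"min_reads": float(min_reads), "control_reads": float(control_reads)}
    if floor is not None:
        thresholds["noise_floor"] = floor.threshold
    return AssayCall(
        protein=protein,
        reads=int(prey_reads),
        call=call,
        rules_fired=fired,
        thresholds_used=thresholds,
    )


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact test p for the 2x2 table [[a, b], [c, d]].

    Point-probability method: the sum over all tables with the observed
    margins whose hypergeometric probability does not exceed that of the
    observed table.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("degenerate table: all margins zero")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class ScreenSummary:
    """Positive-rate comparison between the positive and random reference sets."""

    prs_positive: int
    prs_total: int
    rrs_positive: int
    rrs_total: int

    @property
    def prs_rate(self) -> float:
        return self.prs_positive / self.prs_total

    @property
    def rrs_rate(self) -> float:
        return self.rrs_positive / self.rrs_total

    @property
    def p_two_tailed(self) -> float:
        return fisher_exact_two_tailed(
            self.prs_positive,
            self.prs_total - self.prs_positive,
            self.rrs_positive,
            self.rrs_total - self.rrs_positive,
        )

    def as_dict(self) -> dict:
        return {
            "prs_positive": self.prs_positive,
            "prs_total": self.prs_total,
            "rrs_positive": self.rrs_positive,
            "rrs_total": self.rrs_total,
            "prs_rate": self.prs_rate,
            "rrs_rate": self.rrs_rate,
            "p_two_tailed": self.p_two_tailed,
        }


def summarize_screen(
    prs_calls: Iterable[AssayCall], rrs_calls: Iterable[AssayCall]
) -> ScreenSummary:
    """Tally positives per reference set and test the rates against each other."""
    prs = list(prs_calls)
    rrs = list(rrs_calls)
    if not prs or not rrs:
        raise ValueError("both call lists must be non-empty")
    return ScreenSummary(
        prs_positive=sum(c.positive for c in prs),
        prs_total=len(prs),
        rrs_positive=sum(c.positive for c in rrs),
        rrs_total=len(rrs),
    )


def call_screen(
    count_table: MoleculeCountTable,
    assay_sheet: pd.DataFrame,
    floor: NoiseFloor | None = None,
    min_reads: int = 10,
    on: str = "reads",
    rules: Sequence[str] = RULES,
) -> tuple[pd.DataFrame, ScreenSummary | None]:
    """Call every prey in an assay sheet against its matched control.

    ``assay_sheet`` columns: ``protein`` (prey label in the count table),
    ``set`` (PRS, RRS or other), ``control`` (label of the matched
    negative-control protein).  When the noise-floor rule is enabled and
    no floor is passed, it is estimated from the table's unused rows.
    Returns the per-protein calls and, when both PRS and RRS rows exist,
    a :class:`ScreenSummary`.
    """
    if "noise_floor" in rules and floor is None:
        floor = noise_floor(count_table)
    calls: list[AssayCall] = []
    sets: list[str] = []
    for r in assay_sheet.itertuples(index=False):
        prey = count_table.reads_for(r.protein, on=on)
        ctrl = count_table.reads_for(r.control, on=on)
        calls.append(
            call_ppi(prey, ctrl, floor, min_reads=min_reads, protein=r.protein, rules=rules)
        )
        sets.append(r.set)
    frame = pd.DataFrame(
        {
            "protein": [c.protein for c in calls],
            "set": sets,
            "reads": [c.reads for c in calls],
            "call": [c.call for c in calls],
            "failed_rules": [
                ",".join(k for k, v in c.rules_fired.items() if not v) for c in calls
            ],
        }
    )
    prs = [c for c, s in zip(calls, sets) if s == "PRS"]
    rrs = [c for c, s in zip(calls, sets) if s == "RRS"]
    summary = summarize_screen(prs, rrs) if prs and rrs else None
    return frame, summary


def _step_sum(reads) -> int:
    if isinstance(reads, Mapping):
        return int(sum(reads.values()))
    if isinstance(reads, Number):
        return int(reads)
    return int(sum(reads))


@dataclass
class IPSeriesResult:
    """Immunoprecipitation dilution-ladder outcome.

    ``steps`` has one row per dilution (reads = summed replicate-barcode
    reads); ``detection_limit`` is the largest dilution factor still
    called positive, or None if no step is.
    """

    steps: pd.DataFrame
    detection_limit: float | None


def call_ip_series(
    series: Sequence[tuple[float, Mapping[str, int] | Sequence[int] | int]],
    control_series: Mapping[float, Mapping[str, int] | Sequence[int] | int],
    serum_reference: Mapping[float, int] | float | None = None,
) -> IPSeriesResult:
    """Call an antigen immunoprecipitation dilution series.

    Per dilution step the replicate barcode reads (e.g. four barcodes per
    antigen) are summed; the step is positive iff the sum strictly exceeds
    the matched background-control sum.  Positive steps get a specificity
    ratio: summed reads divided by the reads recovered after
    immunoprecipitation with reference human serum.  A step lacking a
    control is marked ``uncallable``.
    """
    rows = []
    detection: float | None = None
    for dilution, reads in series:
        s = _step_sum(reads)
        if dilution not in control_series:
            rows.append((dilution, s, math.nan, "uncallable", math.nan))
            continue
        ctrl = _step_sum(control_series[dilution])
        positive = s > ctrl
        ratio = math.nan
        if positive and serum_reference is not None:
            ref = (
                serum_reference.get(dilution)
                if isinstance(serum_reference, Mapping)
                else serum_reference
            )
            if ref:
                ratio = s / _step_sum(ref)
        call = "positive" if positive else "negative"
        if positive and (detection is None or dilution > detection):
            detection = dilution
        rows.append((dilution, s, float(ctrl), call, ratio))
    steps = pd.DataFrame(
        rows,
        columns=["dilution", "reads", "control_reads", "call", "specificity_ratio"],
    )
    return IPSeriesResult(steps=steps, detection_limit=detection)
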