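"""The shared filter battery every candidate precursor must pass.

Criteria (defaults): length 50-130 nt, at most one hairpin loop, GC content
in [0.30, 0.70], strictly more than 55 % paired positions, and
MFE <= -0.31*L + 6.00.  Two curation-stage checks are automated: the largest
unpaired run on one stem side must not exceed ``max_bulge`` and at least 90 %
of an attached mature must lie outside the hairpin loop; both are skipped
(pass) when no mature is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import PrecursorCandidate, SequenceRecord
from .rna_structure import (MFE_INTERCEPT, MFE_SLOPE, fold, gc_fraction,
                            hairpin_loop_runs, mfe_threshold,
                            structure_metrics)


@dataclass(frozen=True)
class FilterCriteria:
    len_min: int = 50
    len_max: int = 130
    max_loops: int = 1
    gc_min: float = 0.30
    gc_max: float = 0.70
    paired_min: float = 0.55           # strict >
    mfe_slope: float = MFE_SLOPE       # kcal/mol per nt
    mfe_intercept: float = MFE_INTERCEPT
    max_bulge: int = 10
    require_mature_in_stem: bool = True
    mature_outside_loop_min: float = 0.90

    def __post_init__(self):
        if not self.len_min < self.len_max:
            raise ValueError("len_min must be < len_max")
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("GC bounds must satisfy 0 <= gc_min < gc_max <= 1")

    def mfe_threshold(self, length: int) -> float:
        return self.mfe_slope * length + self.mfe_intercept


#: evaluation order; the rejection log records the first failing criterion
CRITERIA_ORDER = ("length", "loops", "mfe", "gc", "paired", "bulge",
                  "mature_in_stem")


@dataclass(frozen=True)
class FilterReport:
    candidate_id: str
    values: dict
    passed: dict

    @property
    def pass_all(self) -> bool:
        return all(self.passed.values())

    def first_failure(self) -> str | None:
        for name in CRITERIA_ORDER:
            if not self.passed[name]:
                return name
        return None


def evaluate(candidate: PrecursorCandidate,
             criteria: FilterCriteria = FilterCriteria()) -> FilterReport:
    """Evaluate every criterion independently for one folded candidate."""
    if candidate.fold is None:
        raise ValueError(
            f"candidate {candidate.id} has no fold attached; fold it first")
    m = structure_metrics(candidate.sequence, candidate.fold.dotbracket)
    thr = criteria.mfe_threshold(m.length)
    values = {
        "length": m.length,
        "loops": m.loop_count,
        "mfe": candidate.fold.mfe,
        "mfe_threshold": thr,
        "gc": m.gc_fraction,
        "paired": m.paired_fraction,
        "bulge": m.max_unpaired_run_in_stem,
        "mature_outside_loop": None,
    }
    passed = {
        "length": criteria.len_min <= m.length <= criteria.len_max,
        "loops": 1 <= m.loop_count <= criteria.max_loops,
        "mfe": candidate.fold.mfe <= thr,
        "gc": criteria.gc_min <= m.gc_fraction <= criteria.gc_max,
        "paired": m.paired_fraction > criteria.paired_min,
    }
    if candidate.mature is None or not criteria.require_mature_in_stem:
        # curation-stage checks apply only once a mature is attached
        passed["bulge"] = True
        passed["mature_in_stem"] = True
    else:
        passed["bulge"] = m.max_unpaired_run_in_stem <= criteria.max_bulge
        loops = hairpin_loop_runs(candidate.fold.dotbracket)
        frac = _fraction_outside_loops(candidate.mature, loops)
        values["mature_outside_loop"] = frac
        passed["mature_in_stem"] = frac >= criteria.mature_outside_loop_min
    return FilterReport(candidate.id, values, passed)


def _fraction_outside_loops(mature, loops) -> float:
    """Smallest per-arm fraction of mature positions outside hairpin loops."""
    fracs = []
    for arm in (mature.p5, mature.p3):
        start, end = arm
        n = end - start
        if n <= 0:
            continue
        inside = 0
        for ls, le in loops:
            inside += max(0, min(end, le) - max(start, ls))
        fracs.append(1.0 - inside / n)
    return min(fracs) if fracs else 1.0


def apply_filters(
    candidates: Iterable[PrecursorCandidate],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[PrecursorCandidate], list[tuple[str, str]]]:
    """Split candidates into (passing, rejection log).

    The rejection log holds ``(candidate_id, first_failing_criterion)``.
    """
    passing, rejections = [], []
    for cand in candidates:
        report = evaluate(cand, criteria)
        cand.meta["filter_report"] = report
        if report.pass_all:
            passing.append(cand)
        else:
            rejections.append((cand.id, report.first_failure()))
    return passing, rejections


# ---------------------------------------------------------------------------
# compendium benchmark


@dataclass
class CriteriaReport:
    n_precursors: int
    n_skipped: int
    pct: dict                       # per-criterion pass percentage
    pct_all: float
    length_hist: dict = field(default_factory=dict)
    loop_hist: dict = field(default_factory=dict)
    gc_hist: dict = field(default_factory=dict)
    paired_hist: dict = field(default_factory=dict)
    mfe_vs_length: list = field(default_factory=list)


def benchmark_compendium(
    precursors: Sequence[SequenceRecord],
    criteria: FilterCriteria = FilterCriteria(),
    temperature: float = 37.0,
) -> CriteriaReport:
    """Fold a precursor compendium and report per-criterion pass percentages.

    Each record is folded at ``temperature``; the five sequence/structure
    criteria are evaluated independently and jointly.  Records that cannot be
    folded (ambiguous bases, too short) are skipped and counted.
    """
    n_skipped = 0
    flags = {k: [] for k in ("length", "loops", "mfe", "gc", "paired")}
    lengths, loop_counts, gcs, paireds, mfe_pairs = [], [], [], [], []
    for rec in precursors:
        seq = rec.as_rna()
        try:
            fr = fold(seq, temperature=temperature)
        except ValueError:
            n_skipped += 1
            continue
        m = structure_metrics(seq, fr.dotbracket)
        flags["length"].append(criteria.len_min <= m.length <= criteria.len_max)
        flags["loops"].append(1 <= m.loop_count <= criteria.max_loops)
        flags["mfe"].append(fr.mfe <= criteria.mfe_threshold(m.length))
        flags["gc"].append(criteria.gc_min <= m.gc_fraction <= criteria.gc_max)
        flags["paired"].append(m.paired_fraction > criteria.paired_min)
        lengths.append(m.length)
        loop_counts.append(m.loop_count)
        gcs.append(m.gc_fraction)
        paireds.append(m.paired_fraction)
        mfe_pairs.append((m.length, fr.mfe))
    n = len(lengths)
    if n == 0:
        return CriteriaReport(0, n_skipped, {k: 0.0 for k in flags}, 0.0)
    arr = {k: np.asarray(v) for k, v in flags.items()}
    pct = {k: 100.0 * v.mean() for k, v in arr.items()}
    all_pass = np.logical_and.reduce(list(arr.values()))
    return CriteriaReport(
        n_precursors=n,
        n_skipped=n_skipped,
        pct=pct,
        pct_all=100.0 * all_pass.mean(),
        length_hist=_hist(lengths, np.arange(0, 301, 10)),
        loop_hist={int(k): int(v) for k, v in
                   zip(*np.unique(loop_counts, return_counts=True))},
        gc_hist=_hist(gcs, np.arange(0, 1.01, 0.05)),
        paired_hist=_hist(paireds, np.arange(0, 1.01, 0.05)),
        mfe_vs_length=mfe_pairs,
    )


def _hist(values, bins) -> dict:
    counts, edges = np.histogram(values, bins=bins)
    return {float(edges[i]): int(counts[i]) for i in range(len(counts))}


def fit_mfe_length(mfe_pairs: Sequence[tuple[int, float]]) -> tuple[float, float]:
    """Least-squares slope/intercept of MFE on precursor length.

    Utility for re-deriving threshold coefficients from a compendium; the
    shipped defaults remain the fixed constants.
    """
    if len(mfe_pairs) < 2:
        raise ValueError("need at least two (length, mfe) pairs")
    L = np.asarray([p[0] for p in mfe_pairs], dtype=float)
    G = np.asarray([p[1] for p in mfe_pairs], dtype=float)
    slope, intercept = np.polyfit(L, G, 1)
    return float(slope), float(intercept)
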