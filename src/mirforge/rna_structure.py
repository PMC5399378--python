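"""Secondary-structure folding and the structural metrics used by every
candidate filter.

:func:`fold` predicts the minimum-free-energy (MFE) structure of an RNA under
a nearest-neighbor thermodynamic model (see :mod:`mirforge._zuker`); the
remaining functions are cheap, structure-only metrics computed from the
dot-bracket string: hairpin-loop count, paired fraction, GC content and the
linear MFE-versus-length acceptance threshold

    threshold(L) = -0.31 * L + 6.00   [kcal/mol]

A candidate passes the energy criterion iff  mfe <= threshold(L).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._params import encode_sequence, params_for_temperature
from ._zuker import fold_encoded

MFE_SLOPE = -0.31
MFE_INTERCEPT = 6.00

MIN_FOLD_LENGTH = 10

_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (T accepted on input)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FoldResult:
    """MFE structure of one sequence at one temperature."""

    sequence: str
    dotbracket: str
    mfe: float  # kcal/mol
    temperature: float = 37.0

    def __post_init__(self):
        if len(self.dotbracket) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")


@dataclass(frozen=True)
class StructureMetrics:
    length: int
    loop_count: int
    paired_fraction: float
    gc_fraction: float
    max_unpaired_run_in_stem: int


def fold(sequence: str, temperature: float = 37.0) -> FoldResult:
    """Predict the MFE secondary structure of ``sequence``.

    Deterministic for a fixed (sequence, temperature); T and U are treated as
    the same base.  Sequences containing N are rejected.
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) < MIN_FOLD_LENGTH:
        raise ValueError(f"sequence shorter than {MIN_FOLD_LENGTH} nt")
    if not set(seq) <= set("ACGU"):
        bad = sorted(set(seq) - set("ACGU"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    enc = encode_sequence(seq)
    pair, mfe = fold_encoded(enc, params_for_temperature(temperature))
    db = np.full(len(seq), ".", dtype="U1")
    for i, j in enumerate(pair):
        if j > i:
            db[i] = "("
            db[j] = ")"
    return FoldResult(seq, "".join(db), mfe, temperature)


def pair_table(dotbracket: str) -> np.ndarray:
    """Partner index per position (-1 if unpaired); rejects unbalanced input."""
    pt = np.full(len(dotbracket), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


def count_hairpin_loops(dotbracket: str) -> int:
    """Number of hairpin loops: base pairs enclosing no other pair."""
    pair_table(dotbracket)  # validation
    return len(re.findall(r"\(\.*\)", dotbracket))


def hairpin_loop_runs(dotbracket: str) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of the unpaired run of each hairpin loop."""
    pair_table(dotbracket)
    return [(m.start() + 1, m.end() - 1)
            for m in re.finditer(r"\(\.*\)", dotbracket)]


def paired_fraction(dotbracket: str) -> float:
    """Fraction of positions engaged in a base pair."""
    pt = pair_table(dotbracket)
    if len(pt) == 0:
        raise ValueError("empty structure")
    return float(np.count_nonzero(pt >= 0)) / len(pt)


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+U); N positions are excluded entirely."""
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    n_acgu = sum(seq.count(c) for c in "ACGU")
    if n_acgu == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / n_acgu


def mfe_threshold(length: int) -> float:
    """Linear MFE acceptance threshold for a precursor of ``length`` nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return MFE_SLOPE * length + MFE_INTERCEPT


def max_unpaired_run_in_stem(dotbracket: str) -> int:
    """Longest unpaired run on one side of a bulge or interior loop.

    Hairpin-loop runs and runs outside / between helices (exterior and
    multiloop spacers) are not counted.
    """
    pair_table(dotbracket)
    best = 0
    for m in re.finditer(r"\.+", dotbracket):
        left = dotbracket[m.start() - 1] if m.start() > 0 else None
        right = dotbracket[m.end()] if m.end() < len(dotbracket) else None
        if (left, right) in {("(", "("), (")", ")")}:
            best = max(best, m.end() - m.start())
    return best


def stem_span(dotbracket: str, target: tuple[int, int] | None = None,
              max_gap: int | None = None) -> tuple[int, int] | None:
    """Span of the maximal simple stem-loop around one hairpin.

    From each hairpin loop's closing pair, the stem is walked outward
    through bulges and interior loops and stops at a multiloop branch point
    or the exterior; with ``max_gap`` set, also at any bulge/interior side
    longer than ``max_gap``.  With ``target`` given, the stem overlapping it
    most is returned (ties to the nearer one); otherwise the longest stem.
    Returns a half-open span or None when the structure has no pairs.
    """
    pt = pair_table(dotbracket)
    spans = []
    for ls, le in hairpin_loop_runs(dotbracket):
        i, j = ls - 1, le
        while True:
            a, b = i - 1, j + 1
            while a >= 0 and pt[a] == -1:
                a -= 1
            while b < len(dotbracket) and pt[b] == -1:
                b += 1
            if a >= 0 and b < len(dotbracket) and pt[a] == b:
                if max_gap is not None and \
                        max(i - a - 1, b - j - 1) > max_gap:
                    break
                i, j = a, b
            else:
                break
        spans.append((i, j + 1))
    if not spans:
        return None
    if target is None:
        return max(spans, key=lambda s: s[1] - s[0])

    def score(span):
        ov = max(0, min(span[1], target[1]) - max(span[0], target[0]))
        center_dist = abs((span[0] + span[1]) - (target[0] + target[1])) / 2
        return (-ov, center_dist)

    return min(spans, key=score)


def stem_spans_nested(dotbracket: str, target: tuple[int, int]
                      ) -> list[tuple[int, int]]:
    """Nested spans of the stem around the hairpin nearest ``target``.

    Returns the half-open spans of every enclosing pair along the outward
    stem walk (innermost first, full stem last); same walk rules as
    :func:`stem_span`.
    """
    pt = pair_table(dotbracket)
    best_spans: list[tuple[int, int]] = []
    best_key = None
    for ls, le in hairpin_loop_runs(dotbracket):
        i, j = ls - 1, le
        spans = [(i, j + 1)]
        while True:
            a, b = i - 1, j + 1
            while a >= 0 and pt[a] == -1:
                a -= 1
            while b < len(dotbracket) and pt[b] == -1:
                b += 1
            if a >= 0 and b < len(dotbracket) and pt[a] == b:
                i, j = a, b
                spans.append((i, j + 1))
            else:
                break
        outer = spans[-1]
        ov = max(0, min(outer[1], target[1]) - max(outer[0], target[0]))
        center_dist = abs((outer[0] + outer[1]) - (target[0] + target[1])) / 2
        key = (-ov, center_dist)
        if best_key is None or key < best_key:
            best_key, best_spans = key, spans
    return best_spans


def structure_metrics(sequence: str, dotbracket: str) -> StructureMetrics:
    """All filter-relevant metrics for one candidate."""
    return StructureMetrics(
        length=len(sequence),
        loop_count=count_hairpin_loops(dotbracket),
        paired_fraction=paired_fraction(dotbracket),
        gc_fraction=gc_fraction(sequence),
        max_unpaired_run_in_stem=max_unpaired_run_in_stem(dotbracket),
    )
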