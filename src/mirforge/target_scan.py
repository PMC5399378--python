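"""miRNA target scanning over 3'UTRs.

Hybridization is modelled as an intermolecular-only duplex: Watson-Crick and
G-U pairs score with the nearest-neighbor stack table, asymmetric gaps with
the bulge/interior size tables, plus a duplex initiation term — no
intramolecular structure on either molecule.  A helix constraint (a, b)
requires miRNA positions a..b (1-based) to be paired.  Site significance
comes from an extreme-value (Gumbel) null fitted per miRNA on
dinucleotide-shuffled UTRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import stats

from ._params import INF, PAIR_TYPE, RTYPE, encode_sequence, params_for_temperature
from .core_io import GenomeInterval, Gff3Feature, SequenceRecord
from .rna_structure import reverse_complement

log = logging.getLogger(__name__)

HELIX_FRAMES = ((1, 6), (2, 7), (3, 8), (4, 9), (5, 10), (6, 11))
UTR_LENGTH = 400
MAX_GAP = 10  # per-side unpaired run cap inside a duplex


@dataclass(frozen=True)
class UTRRecord:
    gene_id: str
    interval: GenomeInterval
    sequence: str
    clipped: bool = False


@dataclass(frozen=True)
class TargetSite:
    gene_id: str
    mirna_id: str
    utr_position: int     # 0-based position of the duplex 3' end on the UTR
    duplex_energy: float  # kcal/mol
    p_value: float
    helix_frame: tuple[int, int]


def extract_utr3(gene_models: Sequence[Gff3Feature],
                 genome: Mapping[str, str],
                 length: int = UTR_LENGTH) -> list[UTRRecord]:
    """The ``length`` bases immediately downstream of each CDS stop.

    Minus-strand genes are reverse-complemented; UTRs clipped at scaffold
    edges are flagged; models without a CDS feature are skipped.
    """
    out = []
    for ft in gene_models:
        if ft.type != "CDS":
            continue
        gene_id = ft.attributes.get("ID") or ft.attributes.get("Parent")
        if gene_id is None:
            log.info("skipping CDS without ID/Parent at %s", ft.interval)
            continue
        scaffold = genome[ft.interval.scaffold_id]
        if ft.interval.strand == "+":
            lo = ft.interval.end
            hi = min(len(scaffold), lo + length)
        else:
            hi = ft.interval.start
            lo = max(0, hi - length)
        if hi <= lo:
            continue
        clipped = (hi - lo) < length
        seq = scaffold[lo:hi].upper().replace("T", "U")
        if ft.interval.strand == "-":
            seq = reverse_complement(seq)
        out.append(UTRRecord(
            gene_id,
            GenomeInterval(ft.interval.scaffold_id, lo, hi,
                           ft.interval.strand),
            seq, clipped))
    return out


@njit(cache=False)
def _duplex_dp(mir, tgt_rev, a, b, stack, rtype, bulge, internal,
               ninio, ninio_max, duplex_init, terminal_au, max_gap):
    """Minimum duplex energy with miRNA positions a..b (0-based, inclusive)
    forced to pair.

    ``tgt_rev`` is the target window reversed (3'->5'), so paired indices on
    both molecules advance together.  Returns (energy_dekacal, index of the
    last-paired target base in ``tgt_rev``) or (INF, -1).
    """
    pt = PAIR_TYPE
    nm, nt = len(mir), len(tgt_rev)
    D = np.full((nm, nt), INF, np.int32)
    for i in range(nm):
        for j in range(nt):
            t = pt[mir[i], tgt_rev[j]]
            if t == 0:
                continue
            best = INF
            if i <= a:  # opening pair: no constrained position may precede it
                best = duplex_init + (terminal_au if t > 2 else 0)
            for ip in range(max(0, i - max_gap - 1), i):
                # constrained positions may not sit in the skipped gap
                if max(ip + 1, a) <= min(i - 1, b):
                    continue
                for jp in range(max(0, j - max_gap - 1), j):
                    dprev = D[ip, jp]
                    if dprev >= INF:
                        continue
                    tp = pt[mir[ip], tgt_rev[jp]]
                    n1 = i - ip - 1
                    n2 = j - jp - 1
                    if n1 == 0 and n2 == 0:
                        e = stack[tp, rtype[t]]
                    elif n1 == 0 or n2 == 0:
                        nl = n1 + n2
                        e = bulge[nl]
                        if nl == 1:
                            e += stack[tp, rtype[t]]
                        else:
                            if tp > 2:
                                e += terminal_au
                            if t > 2:
                                e += terminal_au
                    else:
                        e = internal[min(30, n1 + n2)]
                        e += min(ninio_max, abs(n1 - n2) * ninio)
                    if dprev + e < best:
                        best = dprev + e
            D[i, j] = best
    best = INF
    bj = -1
    for i in range(b, nm):  # constrained positions may not follow the close
        for j in range(nt):
            if D[i, j] >= INF:
                continue
            t = pt[mir[i], tgt_rev[j]]
            e = D[i, j] + (terminal_au if t > 2 else 0)
            if e < best:
                best = e
                bj = j
    return best, bj


def _check_constraint_coverage(nm: int, frame: tuple[int, int]) -> tuple[int, int]:
    a, b = frame
    if not (1 <= a < b <= nm):
        raise ValueError(f"helix frame {frame} outside miRNA length {nm}")
    return a - 1, b - 1


def duplex_energy(mirna: str, utr_window: str,
                  helix_frame: tuple[int, int] = (2, 7)) -> float | None:
    """Minimum intermolecular hybridization energy (kcal/mol) or None.

    miRNA positions ``a..b`` (1-based) must all be paired; the duplex is
    ungapped beyond bounded bulge/interior gaps; None when the constraint is
    unsatisfiable.
    """
    mir = encode_sequence(mirna.upper().replace("T", "U"))
    if not (18 <= len(mir) <= 27):
        raise ValueError("miRNA must be 18-27 nt")
    if len(utr_window) > 60:
        raise ValueError("window longer than 60 nt; use scan_targets")
    a, b = _check_constraint_coverage(len(mir), helix_frame)
    # target encoded 3'->5' so both indices advance together
    tgt = encode_sequence(utr_window.upper().replace("T", "U"))[::-1]
    p = params_for_temperature(37.0)
    e, _ = _duplex_dp(mir, tgt, a, b, p.stack, RTYPE, p.bulge, p.internal,
                      p.ninio, p.ninio_max, p.duplex_init, p.terminal_au,
                      MAX_GAP)
    return None if e >= INF else e / 100.0


def _best_site(mir_enc, utr_enc, frames, p) -> tuple[float, int, tuple]:
    best = (np.inf, -1, frames[0])
    nt_len = len(utr_enc)
    tgt = utr_enc[::-1]
    for frame in frames:
        a, b = frame[0] - 1, frame[1] - 1
        if b >= len(mir_enc):
            continue
        e, bj = _duplex_dp(mir_enc, tgt, a, b, p.stack, RTYPE, p.bulge,
                           p.internal, p.ninio, p.ninio_max, p.duplex_init,
                           p.terminal_au, MAX_GAP)
        if e < INF and e / 100.0 < best[0]:
            best = (e / 100.0, nt_len - 1 - bj, frame)
    return best


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence preserving exact dinucleotide counts (Eulerian walk)."""
    if len(seq) < 3:
        return seq
    chars = list(seq)
    edges: dict[str, list[str]] = {}
    for x, y in zip(chars, chars[1:]):
        edges.setdefault(x, []).append(y)
    last = chars[-1]
    for _ in range(200):
        trial = {k: list(v) for k, v in edges.items()}
        # pick a random terminal edge per non-final vertex (Altschul-Erickson)
        terminal = {}
        ok = True
        for v in trial:
            if v == last:
                continue
            terminal[v] = trial[v][int(rng.integers(len(trial[v])))]
        # check the terminal edges form paths reaching `last`
        for v in terminal:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in terminal:
                    ok = False
                    break
                seen.add(cur)
                cur = terminal[cur]
            if not ok:
                break
        if not ok:
            continue
        for v, w in terminal.items():
            trial[v].remove(w)
        for v in trial:
            rng.shuffle(trial[v])
        for v, w in terminal.items():
            trial[v].append(w)
        out = [chars[0]]
        cur = chars[0]
        counts = {k: 0 for k in trial}
        while True:
            lst = trial.get(cur)
            if lst is None or counts[cur] >= len(lst):
                break
            nxt = lst[counts[cur]]
            counts[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(chars):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to converge")


@dataclass
class _NullModel:
    loc: float
    scale: float
    n: int

    def p_value(self, energy: float) -> float:
        # more negative energy -> larger score -> smaller p
        p = float(stats.gumbel_r.sf(-energy, loc=self.loc, scale=self.scale))
        return max(p, np.finfo(float).tiny)


def fit_null(mirna: str, utrs: Sequence[str], rng: np.random.Generator,
             n_shuffles: int = 400,
             frames: Sequence[tuple[int, int]] = HELIX_FRAMES) -> _NullModel:
    """Fit a Gumbel null for one miRNA on dinucleotide-shuffled UTRs."""
    if n_shuffles < 100:
        raise ValueError(f"need at least 100 shuffles to fit the null, "
                         f"got {n_shuffles}")
    mir_enc = encode_sequence(mirna.upper().replace("T", "U"))
    p = params_for_temperature(37.0)
    pool = [u for u in utrs if len(u) >= 40]
    if not pool:
        raise ValueError("no UTRs of usable length for null fitting")
    scores = []
    for k in range(n_shuffles):
        utr = pool[int(rng.integers(len(pool)))]
        shuf = dinucleotide_shuffle(utr, rng)
        e, _, _ = _best_site(mir_enc, encode_sequence(shuf), frames, p)
        if np.isfinite(e):
            scores.append(-e)
    if len(scores) < n_shuffles * 0.9:
        raise ValueError("too many degenerate shuffles for null fitting")
    # quantile matching in the upper tail, which decides significance,
    # calibrates better than a bulk-dominated MLE fit
    qlo, qhi = 0.7, 0.98
    zlo, zhi = -np.log(-np.log(qlo)), -np.log(-np.log(qhi))
    s_lo, s_hi = np.quantile(scores, [qlo, qhi])
    scale = (s_hi - s_lo) / (zhi - zlo)
    if scale <= 0:
        raise ValueError("degenerate null score distribution")
    loc = s_lo - scale * zlo
    return _NullModel(float(loc), float(scale), len(scores))


def scan_targets(mirnas: Sequence[SequenceRecord],
                 utrs: Sequence[UTRRecord],
                 p_max: float = 0.01,
                 n_shuffles: int = 400,
                 seed: int = 0,
                 bh_correct: bool = False) -> list[TargetSite]:
    """Best site per miRNA x UTR over the six helix frames, p <= p_max kept.

    The null is fitted per miRNA on dinucleotide-shuffled UTRs drawn from
    the input set.  Benjamini-Hochberg correction is available but off by
    default.
    """
    if not utrs:
        return []
    rng = np.random.default_rng(seed)
    p = params_for_temperature(37.0)
    utr_seqs = [u.sequence for u in utrs]
    sites: list[TargetSite] = []
    for mir in mirnas:
        mseq = mir.as_rna()
        null = fit_null(mseq, utr_seqs, rng, n_shuffles=n_shuffles)
        mir_enc = encode_sequence(mseq)
        for utr in utrs:
            e, pos, frame = _best_site(mir_enc, encode_sequence(utr.sequence),
                                       HELIX_FRAMES, p)
            if not np.isfinite(e):
                continue
            pv = null.p_value(e)
            sites.append(TargetSite(utr.gene_id, mir.id, pos, e, pv, frame))
    if bh_correct:
        sites = _bh_filter(sites, p_max)
    else:
        sites = [s for s in sites if s.p_value <= p_max]
    return sorted(sites, key=lambda s: (s.mirna_id, s.p_value))


def _bh_filter(sites: list[TargetSite], q: float) -> list[TargetSite]:
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: s.p_value)
    m = len(ordered)
    keep_upto = -1
    for r, s in enumerate(ordered, start=1):
        if s.p_value <= q * r / m:
            keep_upto = r
    return ordered[:keep_upto] if keep_upto > 0 else []
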