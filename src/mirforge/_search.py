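"""Exact mismatch-limited (Hamming) search of short queries against a genome.

Seed-and-extend with a pigeonhole guarantee: a query of length L matched with
at most m mismatches must contain one exact chunk of length floor(L/(m+1)),
so every true hit is recovered by looking up m+1 non-overlapping exact chunks
in a sorted k-mer index and verifying the full window.  Matching is ungapped,
on both strands, with T and U equivalent; windows containing N never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from ._params import NT_CODE
from .rna_structure import reverse_complement

_MAX_K = 12


def _encode(seq: str) -> np.ndarray:
    return np.array([NT_CODE.get(c, 0) for c in seq.upper()], dtype=np.int8)


@dataclass(frozen=True)
class RawHit:
    query_index: int
    scaffold_id: str
    start: int          # 0-based plus-strand
    strand: str
    mismatches: int


class _KmerIndex:
    """Sorted k-mer code index over one encoded scaffold."""

    def __init__(self, enc: np.ndarray, k: int):
        self.k = k
        n = len(enc) - k + 1
        if n <= 0:
            self.codes = np.empty(0, np.int64)
            self.order = np.empty(0, np.int64)
            return
        e = enc.astype(np.int64)
        codes = np.zeros(n, np.int64)
        valid = np.ones(n, bool)
        for t in range(k):
            codes = codes * 4 + (e[t:t + n] - 1)
            valid &= e[t:t + n] > 0
        codes[~valid] = -1
        self.order = np.argsort(codes, kind="stable")
        self.codes = codes[self.order]

    def positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.order[lo:hi]


def _query_code(enc: np.ndarray) -> int | None:
    if np.any(enc <= 0):
        return None
    code = 0
    for v in enc:
        code = code * 4 + int(v) - 1
    return code


class GenomeSearcher:
    """Reusable mismatch-limited searcher over a genome."""

    def __init__(self, genome: Mapping[str, str]):
        self._enc = {sid: _encode(seq) for sid, seq in genome.items()}
        self._indexes: dict[tuple[str, int], _KmerIndex] = {}

    def _index(self, sid: str, k: int) -> _KmerIndex:
        key = (sid, k)
        if key not in self._indexes:
            self._indexes[key] = _KmerIndex(self._enc[sid], k)
        return self._indexes[key]

    def find(self, queries: Sequence[str], max_mismatches: int,
             min_query_length: int = 15) -> list[RawHit]:
        """All genomic windows within Hamming distance of any query.

        Queries shorter than ``min_query_length`` are rejected.  Each
        (query, window, strand) hit is reported exactly once.
        """
        hits: list[RawHit] = []
        for qi, q in enumerate(queries):
            if len(q) < min_query_length:
                raise ValueError(
                    f"query {qi} is {len(q)} nt; minimum {min_query_length}")
            for strand, qseq in (("+", q), ("-", reverse_complement(q))):
                qenc = _encode(qseq)
                hits.extend(self._find_one(qi, qenc, strand, max_mismatches))
        return hits

    def _find_one(self, qi: int, qenc: np.ndarray, strand: str,
                  max_mm: int) -> Iterator[RawHit]:
        L = len(qenc)
        n_chunks = max_mm + 1
        k = min(_MAX_K, L // n_chunks)
        if k < 1:
            raise ValueError(f"query too short for {max_mm} mismatches")
        for sid in sorted(self._enc):
            enc = self._enc[sid]
            if len(enc) < L:
                continue
            idx = self._index(sid, k)
            starts: set[int] = set()
            for c in range(n_chunks):
                off = c * k
                code = _query_code(qenc[off:off + k])
                if code is None:
                    continue
                pos = self._index(sid, k).positions(code)
                for p in pos:
                    st = int(p) - off
                    if 0 <= st <= len(enc) - L:
                        starts.add(st)
            for st in sorted(starts):
                window = enc[st:st + L]
                # N (code 0) never matches, even vs an N in the query
                mm = int(np.count_nonzero((window != qenc) | (window == 0)))
                if mm <= max_mm:
                    yield RawHit(qi, sid, st, strand, mm)
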