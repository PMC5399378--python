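"""Minimum-free-energy secondary structure prediction.

A standard Zuker dynamic program over the nearest-neighbor energy model
(hairpin / stacked pair / bulge / interior / multibranch / exterior loops,
double-dangle treatment of helix ends, special tri-/tetra-/hexaloop bonuses,
interior loops capped at 30 unpaired bases).  Energies are integers in
0.01 kcal/mol; kernels are numba-compiled for speed.

The model intentionally excludes pseudoknots and suboptimal structures.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._params import INF, MAXLOOP, PAIR_TYPE, EnergyParams

_MIN_HP = 3  # minimum unpaired bases in a hairpin loop


@njit(cache=False)
def _special_val(sk, sv, key):
    lo, hi = 0, len(sk)
    while lo < hi:
        mid = (lo + hi) // 2
        if sk[mid] < key:
            lo = mid + 1
        elif sk[mid] > key:
            hi = mid
        else:
            return sv[mid]
    return INF


@njit(cache=False)
def _e_hairpin(s, i, j, t, hp, mmh, sk, sv, term_au, lxc):
    size = j - i - 1
    if size < _MIN_HP:
        return INF
    if size <= 30:
        e = hp[size]
    else:
        e = hp[30] + int(lxc * np.log(size / 30.0))
    if size == 4 or size == 6 or size == 3:
        key = 0
        for k in range(i, j + 1):
            key = key * 5 + s[k]
        sp = _special_val(sk, sv, key)
        if sp < INF:
            return sp
        if size == 3:
            if t > 2:
                e += term_au
            return e
    e += mmh[t, s[i + 1], s[j - 1]]
    return e


@njit(cache=False)
def _e_intloop(n1, n2, t1, t2, si1, sj1, sp1, sq1,
               stack, mmi, mm1n, mm23, i11, i21, i22,
               bulge, internal, ninio, ninio_max, term_au, lxc):
    if n1 > n2:
        nl, ns = n1, n2
    else:
        nl, ns = n2, n1
    if nl == 0:
        return stack[t1, t2]
    if ns == 0:  # bulge
        if nl <= 30:
            e = bulge[nl]
        else:
            e = bulge[30] + int(lxc * np.log(nl / 30.0))
        if nl == 1:
            e += stack[t1, t2]
        else:
            if t1 > 2:
                e += term_au
            if t2 > 2:
                e += term_au
        return e
    if ns == 1:
        if nl == 1:
            return i11[t1, t2, si1, sj1]
        if nl == 2:
            if n1 == 1:
                return i21[t1, t2, si1, sq1, sj1]
            return i21[t2, t1, sq1, si1, sp1]
        # 1 x n loop
        if nl + 1 <= 30:
            e = internal[nl + 1]
        else:
            e = internal[30] + int(lxc * np.log((nl + 1) / 30.0))
        e += min(ninio_max, (nl - ns) * ninio)
        e += mm1n[t1, si1, sj1] + mm1n[t2, sq1, sp1]
        return e
    if ns == 2:
        if nl == 2:
            return i22[t1, t2, si1, sp1, sq1, sj1]
        if nl == 3:  # 2x3 interior loop
            e = internal[5] + ninio
            e += mm23[t1, si1, sj1] + mm23[t2, sq1, sp1]
            return e
    u = nl + ns
    if u <= 30:
        e = internal[u]
    else:
        e = internal[30] + int(lxc * np.log(u / 30.0))
    e += min(ninio_max, (nl - ns) * ninio)
    e += mmi[t1, si1, sj1] + mmi[t2, sq1, sp1]
    return e


@njit(cache=False)
def _e_mlstem(t, s5, s3, mmm, ml_intern, term_au):
    e = mmm[t, s5, s3] + ml_intern
    if t > 2:
        e += term_au
    return e


@njit(cache=False)
def _e_extstem(t, s5, s3, mme, d5, d3, term_au):
    # s5/s3 == 0 only at the sequence edges (N is rejected upstream)
    if s5 > 0 and s3 > 0:
        e = mme[t, s5, s3]
    elif s5 > 0:
        e = d5[t, s5]
    elif s3 > 0:
        e = d3[t, s3]
    else:
        e = 0
    if t > 2:
        e += term_au
    return e


@njit(cache=False)
def _c_interior_min(s, i, j, C, pt,
                    stack, mmi, mm1n, mm23, i11, i21, i22,
                    bulge, internal, ninio, ninio_max, term_au, lxc):
    t1 = pt[s[i], s[j]]
    best = INF
    pmax = min(i + MAXLOOP + 1, j - _MIN_HP - 2)
    for p in range(i + 1, pmax + 1):
        n1 = p - i - 1
        qmin = max(p + _MIN_HP + 1, j - 1 - (MAXLOOP - n1))
        for q in range(qmin, j):
            if C[p, q] >= INF:
                continue
            t2 = pt[s[q], s[p]]
            if t2 == 0:
                continue
            e = _e_intloop(n1, j - q - 1, t1, t2,
                           s[i + 1], s[j - 1], s[p - 1], s[q + 1],
                           stack, mmi, mm1n, mm23, i11, i21, i22,
                           bulge, internal, ninio, ninio_max, term_au, lxc)
            tot = e + C[p, q]
            if tot < best:
                best = tot
    return best


@njit(cache=False)
def _fold_dp(s, stack, mmh, mmi, mm1n, mm23, mmm, mme, d5, d3,
             i11, i21, i22, hp, bulge, internal,
             sk, sv, ml_base, ml_closing, ml_intern,
             ninio, ninio_max, term_au, lxc):
    n = len(s)
    pt = PAIR_TYPE
    C = np.full((n, n), INF, np.int32)
    M = np.full((n, n), INF, np.int32)
    M1 = np.full((n, n), INF, np.int32)
    for i in range(n - 2, -1, -1):
        for j in range(i + _MIN_HP + 1, n):
            t = pt[s[i], s[j]]
            if t > 0:
                e = _e_hairpin(s, i, j, t, hp, mmh, sk, sv, term_au, lxc)
                ei = _c_interior_min(s, i, j, C, pt,
                                     stack, mmi, mm1n, mm23, i11, i21, i22,
                                     bulge, internal, ninio, ninio_max,
                                     term_au, lxc)
                if ei < e:
                    e = ei
                # multibranch closing
                if j - i > 2 * (_MIN_HP + 2):
                    base = ml_closing + _e_mlstem(
                        pt[s[j], s[i]], s[j - 1], s[i + 1],
                        mmm, ml_intern, term_au)
                    for k in range(i + 2, j - 2):
                        if M[i + 1, k] < INF and M1[k + 1, j - 1] < INF:
                            em = base + M[i + 1, k] + M1[k + 1, j - 1]
                            if em < e:
                                e = em
                C[i, j] = e
            # M1: exactly one branch starting at i
            e1 = INF
            if M1[i, j - 1] < INF:
                e1 = M1[i, j - 1] + ml_base
            if t > 0 and C[i, j] < INF and 0 < i and j < n - 1:
                es = C[i, j] + _e_mlstem(t, s[i - 1], s[j + 1],
                                         mmm, ml_intern, term_au)
                if es < e1:
                    e1 = es
            M1[i, j] = e1
            # M: at least one branch in [i, j]
            em = INF
            if M[i, j - 1] < INF:
                em = M[i, j - 1] + ml_base
            if i + 1 < n - 1 and M[i + 1, j] < INF and M[i + 1, j] + ml_base < em:
                em = M[i + 1, j] + ml_base
            if M1[i, j] < em:
                em = M1[i, j]
            for k in range(i + 1, j - _MIN_HP):
                if M[i, k - 1] < INF and C[k, j] < INF and j < n - 1:
                    ee = M[i, k - 1] + C[k, j] + _e_mlstem(
                        pt[s[k], s[j]], s[k - 1], s[j + 1],
                        mmm, ml_intern, term_au)
                    if ee < em:
                        em = ee
            M[i, j] = em
    # exterior loop
    f = np.zeros(n, np.int32)
    for j in range(_MIN_HP + 1, n):
        best = f[j - 1]
        for i in range(0, j - _MIN_HP):
            if C[i, j] >= INF:
                continue
            t = pt[s[i], s[j]]
            s5 = s[i - 1] if i > 0 else 0
            s3 = s[j + 1] if j < n - 1 else 0
            e = C[i, j] + _e_extstem(t, s5, s3, mme, d5, d3, term_au)
            if i > 0:
                e += f[i - 1]
            if e < best:
                best = e
        f[j] = best
    return C, M, M1, f


@njit(cache=False)
def _traceback(s, C, M, M1, f, stack, mmh, mmi, mm1n, mm23, mmm, mme, d5, d3,
               i11, i21, i22, hp, bulge, internal, sk, sv,
               ml_base, ml_closing, ml_intern, ninio, ninio_max,
               term_au, lxc):
    n = len(s)
    pt = PAIR_TYPE
    pair = np.full(n, -1, np.int64)
    # stack entries: (i, j, mode) mode 0=C, 1=M, 2=M1
    st_i = np.empty(2 * n + 4, np.int64)
    st_j = np.empty(2 * n + 4, np.int64)
    st_m = np.empty(2 * n + 4, np.int64)
    top = 0
    # exterior decomposition
    j = n - 1
    while j > _MIN_HP:
        if f[j] == f[j - 1]:
            j -= 1
            continue
        found = False
        for i in range(0, j - _MIN_HP):
            if C[i, j] >= INF:
                continue
            t = pt[s[i], s[j]]
            s5 = s[i - 1] if i > 0 else 0
            s3 = s[j + 1] if j < n - 1 else 0
            e = C[i, j] + _e_extstem(t, s5, s3, mme, d5, d3, term_au)
            prev = f[i - 1] if i > 0 else 0
            if prev + e == f[j]:
                st_i[top] = i
                st_j[top] = j
                st_m[top] = 0
                top += 1
                j = i - 1
                found = True
                break
        if not found:
            j -= 1
    while top > 0:
        top -= 1
        i, j, mode = st_i[top], st_j[top], st_m[top]
        if mode == 0:
            pair[i] = j
            pair[j] = i
            t = pt[s[i], s[j]]
            target = C[i, j]
            if target == _e_hairpin(s, i, j, t, hp, mmh, sk, sv, term_au, lxc):
                continue
            done = False
            pmax = min(i + MAXLOOP + 1, j - _MIN_HP - 2)
            for p in range(i + 1, pmax + 1):
                n1 = p - i - 1
                qmin = max(p + _MIN_HP + 1, j - 1 - (MAXLOOP - n1))
                for q in range(qmin, j):
                    if C[p, q] >= INF:
                        continue
                    t2 = pt[s[q], s[p]]
                    if t2 == 0:
                        continue
                    e = _e_intloop(n1, j - q - 1, t, t2,
                                   s[i + 1], s[j - 1], s[p - 1], s[q + 1],
                                   stack, mmi, mm1n, mm23, i11, i21, i22,
                                   bulge, internal, ninio, ninio_max,
                                   term_au, lxc)
                    if e + C[p, q] == target:
                        st_i[top] = p
                        st_j[top] = q
                        st_m[top] = 0
                        top += 1
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            base = ml_closing + _e_mlstem(pt[s[j], s[i]], s[j - 1], s[i + 1],
                                          mmm, ml_intern, term_au)
            for k in range(i + 2, j - 2):
                if M[i + 1, k] < INF and M1[k + 1, j - 1] < INF:
                    if base + M[i + 1, k] + M1[k + 1, j - 1] == target:
                        st_i[top] = i + 1
                        st_j[top] = k
                        st_m[top] = 1
                        top += 1
                        st_i[top] = k + 1
                        st_j[top] = j - 1
                        st_m[top] = 2
                        top += 1
                        done = True
                        break
        elif mode == 1:
            # M segment
            while True:
                if M[i, j - 1] < INF and M[i, j] == M[i, j - 1] + ml_base:
                    j -= 1
                    continue
                if (i + 1 < n - 1 and M[i + 1, j] < INF
                        and M[i, j] == M[i + 1, j] + ml_base):
                    i += 1
                    continue
                break
            if M[i, j] == M1[i, j]:
                st_i[top] = i
                st_j[top] = j
                st_m[top] = 2
                top += 1
                continue
            for k in range(i + 1, j - _MIN_HP):
                if M[i, k - 1] < INF and C[k, j] < INF and j < n - 1:
                    ee = M[i, k - 1] + C[k, j] + _e_mlstem(
                        pt[s[k], s[j]], s[k - 1], s[j + 1],
                        mmm, ml_intern, term_au)
                    if ee == M[i, j]:
                        st_i[top] = i
                        st_j[top] = k - 1
                        st_m[top] = 1
                        top += 1
                        st_i[top] = k
                        st_j[top] = j
                        st_m[top] = 0
                        top += 1
                        break
        else:
            # M1 segment: single branch starting at i
            while M1[i, j - 1] < INF and M1[i, j] == M1[i, j - 1] + ml_base:
                j -= 1
            st_i[top] = i
            st_j[top] = j
            st_m[top] = 0
            top += 1
    return pair


def fold_encoded(s: np.ndarray, p: EnergyParams) -> tuple[np.ndarray, float]:
    """Fold an encoded sequence; returns (pair table, mfe in kcal/mol)."""
    args = (p.stack, p.mismatch_hairpin, p.mismatch_internal, p.mismatch_1n,
            p.mismatch_23, p.mismatch_multi, p.mismatch_exterior,
            p.dangle5, p.dangle3,
            p.int11, p.int21, p.int22, p.hairpin, p.bulge, p.internal,
            p.special_keys, p.special_vals,
            p.ml_base, p.ml_closing, p.ml_intern,
            p.ninio, p.ninio_max, p.terminal_au, p.lxc)
    C, M, M1, f = _fold_dp(s, *args)
    mfe10 = int(f[-1]) if len(s) > _MIN_HP else 0
    pair = _traceback(s, C, M, M1, f, *args)
    return pair, mfe10 / 100.0
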