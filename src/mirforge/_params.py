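"""Nearest-neighbor energy parameter handling.

Loads the Turner 2004 free-energy/enthalpy bundle shipped with the package
and rescales it to a requested folding temperature via

    dG(T) = dH - (dH - dG37) * T / 310.15      (T in Kelvin)

All energies are integers in units of 0.01 kcal/mol (the native unit of the
parameter set); the public folding API converts to kcal/mol at the end.

Index conventions (shared with the DP kernels in :mod:`mirforge._zuker`):

* nucleotides: 0 = none/N, 1 = A, 2 = C, 3 = G, 4 = U
* pair types:  0 = no pair, 1 = CG, 2 = GC, 3 = GU, 4 = UG, 5 = AU, 6 = UA
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources
from typing import NamedTuple

import numpy as np

INF = 10_000_000
MAXLOOP = 30
_T37 = 310.15  # Kelvin
_K0 = 273.15
_LXC37 = 107.856  # loop-size extrapolation constant at 37 C, dekacal

NT_CODE = {"A": 1, "C": 2, "G": 3, "U": 4, "T": 4, "N": 0}

#: pair-type lookup, PAIR_TYPE[a, b] for encoded nucleotides a, b
PAIR_TYPE = np.zeros((5, 5), dtype=np.int32)
for _a, _b, _t in [(2, 3, 1), (3, 2, 2), (3, 4, 3), (4, 3, 4), (1, 4, 5), (4, 1, 6)]:
    PAIR_TYPE[_a, _b] = _t

#: reversed pair type (type of (j,i) given type of (i,j))
RTYPE = np.array([0, 2, 1, 4, 3, 6, 5], dtype=np.int32)


class EnergyParams(NamedTuple):
    """Temperature-scaled integer energy tables (units: 0.01 kcal/mol)."""

    stack: np.ndarray            # (7,7)
    mismatch_hairpin: np.ndarray  # (7,5,5)
    mismatch_internal: np.ndarray
    mismatch_1n: np.ndarray
    mismatch_23: np.ndarray
    mismatch_multi: np.ndarray
    mismatch_exterior: np.ndarray
    dangle5: np.ndarray          # (7,5)
    dangle3: np.ndarray
    int11: np.ndarray            # (7,7,5,5)
    int21: np.ndarray            # (7,7,5,5,5)
    int22: np.ndarray            # (7,7,5,5,5,5)
    hairpin: np.ndarray          # (31,)
    bulge: np.ndarray
    internal: np.ndarray
    ml_base: int
    ml_closing: int
    ml_intern: int
    ninio: int
    ninio_max: int
    terminal_au: int
    duplex_init: int
    lxc: float
    special_keys: np.ndarray     # encoded special hairpin loops (tri/tetra/hexa)
    special_vals: np.ndarray
    temperature: float


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("mirforge.data").joinpath("turner2004.json").open() as fh:
        return json.load(fh)


def _scale(g37, h, tempf: float):
    g37 = np.asarray(g37, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    out = h - (h - g37) * tempf
    out = np.where(np.asarray(g37) >= INF, INF, out)
    return np.trunc(out).astype(np.int32)  # C-style truncation, as RNAlib does


def encode_loop(seq: str) -> int:
    """Encode a short RNA string as a base-5 integer key (A..U -> 1..4)."""
    key = 0
    for ch in seq:
        key = key * 5 + NT_CODE[ch.upper()]
    return key


@lru_cache(maxsize=8)
def params_for_temperature(temperature: float = 37.0) -> EnergyParams:
    """Build the integer parameter bundle rescaled to ``temperature`` (C)."""
    raw = _raw()
    tempf = (temperature + _K0) / _T37

    def tab(name, shape):
        return _scale(raw[name], raw[name + "_enthalpies"], tempf).reshape(shape)

    stack7 = tab("stack", (7, 7))
    stack = np.full((7, 7), INF, np.int32)
    stack[1:, 1:] = stack7[:6, :6]

    int11 = np.full((7, 7, 5, 5), INF, np.int32)
    int11[1:, 1:] = tab("int11", (7, 7, 5, 5))[:6, :6]
    int21 = np.full((7, 7, 5, 5, 5), INF, np.int32)
    int21[1:, 1:] = tab("int21", (7, 7, 5, 5, 5))[:6, :6]

    int22 = np.full((7, 7, 5, 5, 5, 5), INF, np.int32)
    if raw["int22_layout"] == "reduced":
        t = _scale(raw["int22"], raw["int22_enthalpies"], tempf).reshape(6, 6, 4, 4, 4, 4)
        int22[1:7, 1:7, 1:, 1:, 1:, 1:] = t
    else:
        int22[1:, 1:] = tab("int22", (7, 7, 5, 5, 5, 5))[:6, :6]

    # dangling-end contributions are clamped to <= 0 after rescaling
    d5 = np.minimum(
        np.concatenate([np.zeros((1, 5), np.int32), tab("dangle5", (7, 5))])[:7], 0)
    d3 = np.minimum(
        np.concatenate([np.zeros((1, 5), np.int32), tab("dangle3", (7, 5))])[:7], 0)

    ml = raw["ML_params"]
    ml_base = int(math.trunc(ml[1] - (ml[1] - ml[0]) * tempf))
    ml_closing = int(math.trunc(ml[3] - (ml[3] - ml[2]) * tempf))
    ml_intern = int(math.trunc(ml[5] - (ml[5] - ml[4]) * tempf))
    ninio = int(math.trunc(raw["NINIO"][1] - (raw["NINIO"][1] - raw["NINIO"][0]) * tempf))
    ninio_max = int(raw["NINIO"][2])
    misc = raw["Misc"]
    duplex_init = int(math.trunc(misc[1] - (misc[1] - misc[0]) * tempf))
    terminal_au = int(math.trunc(misc[3] - (misc[3] - misc[2]) * tempf))

    keys, vals = [], []
    for section in ("Triloops", "Tetraloops", "Hexaloops"):
        for seq, g37, h in raw[section]:
            keys.append(encode_loop(seq))
            vals.append(int(math.trunc(h - (h - g37) * tempf)))
    order = np.argsort(keys)

    def pad_mm(name):
        t = np.zeros((7, 5, 5), np.int32)
        t[1:] = tab(name, (7, 5, 5))[:6]
        return t

    return EnergyParams(
        stack=stack,
        mismatch_hairpin=pad_mm("mismatch_hairpin"),
        mismatch_internal=pad_mm("mismatch_internal"),
        mismatch_1n=pad_mm("mismatch_internal_1n"),
        mismatch_23=pad_mm("mismatch_internal_23"),
        mismatch_multi=pad_mm("mismatch_multi"),
        mismatch_exterior=pad_mm("mismatch_exterior"),
        dangle5=d5,
        dangle3=d3,
        int11=int11,
        int21=int21,
        int22=int22,
        hairpin=_scale(raw["hairpin"], raw["hairpin_enthalpies"], tempf),
        bulge=_scale(raw["bulge"], raw["bulge_enthalpies"], tempf),
        internal=_scale(raw["internal"], raw["internal_enthalpies"], tempf),
        ml_base=ml_base,
        ml_closing=ml_closing,
        ml_intern=ml_intern,
        ninio=ninio,
        ninio_max=ninio_max,
        terminal_au=terminal_au,
        duplex_init=duplex_init,
        lxc=_LXC37 * tempf,
        special_keys=np.asarray(keys, np.int64)[order],
        special_vals=np.asarray(vals, np.int32)[order],
        temperature=temperature,
    )


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string to the 1..4 integer alphabet (0 for N)."""
    try:
        return np.array([NT_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None
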