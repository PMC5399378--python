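"""Convert a ViennaRNA v2.0 RNA parameter file into the JSON bundle shipped
with mirforge (src/mirforge/data/turner2004.json).

Run once against an installed copy of the Turner 2004 parameter file:

    python scripts/extract_turner_params.py \
        /path/to/rna_turner2004.par src/mirforge/data/turner2004.json

The JSON stores free energies (dG at 37 C) and enthalpies (dH) in units of
0.01 kcal/mol, exactly as the source file does.  Table shapes follow the
nearest-neighbor convention: pair types indexed 1..7
(CG, GC, GU, UG, AU, UA, NN), nucleotides indexed 1..4 (A, C, G, U) with 0
meaning "no base".
"""

from __future__ import annotations

import json
import re
import sys

# number of values each section must contain (pairs 1..7, nucleotides 0..4)
SECTION_SIZES = {
    "stack": 49,
    "stack_enthalpies": 49,
    "mismatch_hairpin": 175,
    "mismatch_hairpin_enthalpies": 175,
    "mismatch_internal": 175,
    "mismatch_internal_enthalpies": 175,
    "mismatch_internal_1n": 175,
    "mismatch_internal_1n_enthalpies": 175,
    "mismatch_internal_23": 175,
    "mismatch_internal_23_enthalpies": 175,
    "mismatch_multi": 175,
    "mismatch_multi_enthalpies": 175,
    "mismatch_exterior": 175,
    "mismatch_exterior_enthalpies": 175,
    "dangle5": 35,
    "dangle5_enthalpies": 35,
    "dangle3": 35,
    "dangle3_enthalpies": 35,
    "int11": 7 * 7 * 25,
    "int11_enthalpies": 7 * 7 * 25,
    "int21": 7 * 7 * 125,
    "int21_enthalpies": 7 * 7 * 125,
    "int22": None,  # stored for pairs 1..6 / nucs 1..4 in some releases
    "int22_enthalpies": None,
    "hairpin": 31,
    "hairpin_enthalpies": 31,
    "bulge": 31,
    "bulge_enthalpies": 31,
    "internal": 31,
    "internal_enthalpies": 31,
    "ML_params": 6,
    "NINIO": 3,
    "Misc": 4,
}

LOOP_SECTIONS = {"Hexaloops", "Tetraloops", "Triloops"}
INF = 10000000  # sentinel used by ViennaRNA for forbidden entries


def parse(path: str) -> dict:
    sections: dict[str, list] = {}
    current = None
    for raw in open(path):
        line = re.sub(r"/\*.*?\*/", " ", raw).strip()
        if line.startswith("##") or not line:
            continue
        if line.startswith("#"):
            current = line[1:].strip()
            sections[current] = []
            continue
        if current is None:
            continue
        if current in LOOP_SECTIONS:
            parts = line.split()
            if len(parts) == 3:
                sections[current].append((parts[0], int(parts[1]), int(parts[2])))
        else:
            for tok in line.split():
                sections[current].append(INF if tok == "INF" else int(tok))
    return sections


def main(par_path: str, out_path: str) -> None:
    sections = parse(par_path)
    out: dict = {}
    for name, expect in SECTION_SIZES.items():
        vals = sections.get(name)
        if vals is None:
            raise SystemExit(f"missing section: {name}")
        if expect is not None and len(vals) != expect:
            raise SystemExit(f"section {name}: expected {expect} values, got {len(vals)}")
        out[name] = vals
    n22 = len(sections["int22"])
    if n22 == 7 * 7 * 625:
        out["int22_layout"] = "full"
    elif n22 == 6 * 6 * 256:
        out["int22_layout"] = "reduced"
    else:
        raise SystemExit(f"unrecognised int22 size: {n22}")
    for name in LOOP_SECTIONS:
        out[name] = [[s, g, h] for s, g, h in sections.get(name, [])]
    json.dump(out, open(out_path, "w"))
    print(f"wrote {out_path}: int22 layout {out['int22_layout']}")


if __name__ == "__main__":
    main(sys.argv[1], sys.argv[2])
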