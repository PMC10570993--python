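#!/usr/bin/env python
"""Optional helper: derive a label-site table from a pseudoatomic NPC model.

Reads an mmCIF/PDB structure (e.g. 5A9Q, 5IJN, 5IJO, 7R5K, 7PEQ, 7PER,
7R5J), locates the N- and C-terminal residues of every copy of the
requested nucleoporin chains inside one rotational unit, and writes the
npcsim model-table CSV (columns: model_id, nup_name, terminus, copy, z, r,
alpha, subcomplex, unit).

This script needs `gemmi` (install the `npcsim[pdb]` extra) and a local
structure file; it is a documented utility, not part of the tested core -
all shipped tests use synthetic reference units instead.  Subcomplex
assignment must be supplied by the user (--subcomplex per chain), since it
is an annotation of the deposition, not something inferable from z alone.

Usage:
  python scripts/extract_reference_unit.py model.cif --model-id 5A9Q \
      --chain A:Nup96:CR --chain B:Nup96:NR --out nup96_table.csv

Coordinates are re-expressed relative to the symmetry axis: the axis is
estimated as the centroid of all selected atoms over all symmetric copies
(pass --axis x,y to override), z is measured along the axis, and alpha is
the in-plane angle of each site relative to the unit's mean angle.
"""

from __future__ import annotations

import argparse
import sys

import numpy as np
import pandas as pd


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("structure", help="mmCIF or PDB file")
    ap.add_argument("--model-id", required=True)
    ap.add_argument(
        "--chain",
        action="append",
        required=True,
        metavar="CHAIN:NUP:SUBCOMPLEX",
        help="chain id, nucleoporin name, and subcomplex tag (repeatable)",
    )
    ap.add_argument("--axis", default=None, help="x,y of the symmetry axis in Angstrom")
    ap.add_argument("--out", required=True)
    args = ap.parse_args(argv)

    try:
        import gemmi
    except ImportError:
        print("this helper needs gemmi: pip install npcsim[pdb]", file=sys.stderr)
        return 2

    st = gemmi.read_structure(args.structure)
    st.setup_entities()
    model = st[0]

    selections = []
    for spec in args.chain:
        chain_id, nup, sub = spec.split(":")
        selections.append((chain_id, nup, sub))

    if args.axis:
        ax, ay = (float(t) for t in args.axis.split(","))
    else:
        pts = np.array(
            [a.pos.tolist() for ch in model for res in ch for a in res if a.name == "CA"]
        )
        ax, ay = pts[:, 0].mean(), pts[:, 1].mean()

    rows = []
    copy_counter: dict[tuple[str, str], int] = {}
    for chain_id, nup, sub in selections:
        chain = model[chain_id]
        polymer = chain.get_polymer()
        residues = list(polymer)
        if not residues:
            print(f"chain {chain_id}: no polymer residues", file=sys.stderr)
            return 1
        for terminus, res in (("N", residues[0]), ("C", residues[-1])):
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            x, y, z = ca.pos.x - ax, ca.pos.y - ay, ca.pos.z
            key = (nup, terminus)
            copy_counter[key] = copy_counter.get(key, 0) + 1
            rows.append(
                {
                    "model_id": args.model_id,
                    "nup_name": nup,
                    "terminus": terminus,
                    "copy": copy_counter[key],
                    "z": z,
                    "r": float(np.hypot(x, y)),
                    "alpha": float(np.arctan2(y, x)),
                    "subcomplex": sub,
                    "unit": "angstrom",
                }
            )

    df = pd.DataFrame(rows)
    # express alpha relative to the unit mean and wrap to [-pi, pi)
    df["alpha"] = np.mod(df["alpha"] - df["alpha"].mean() + np.pi, 2 * np.pi) - np.pi
    df.to_csv(args.out, index=False)
    print(f"wrote {len(df)} sites to {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
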