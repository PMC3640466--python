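#!/usr/bin/env python
"""Offline converter: wwPDB chemical component dictionary -> compound library.

Reads an mmCIF chemical-component file (one or many components, e.g. the
full ``components.cif`` from the wwPDB) with gemmi and writes the JSON
table format that :func:`molkit.conop.load_compound_library` consumes.
Hydrogens are dropped to match the bundled library's heavy-atom topology.

This is a maintenance utility; the repository ships a ready-made library
and no test depends on this script.

Usage:  python scripts/ccd_to_library.py components.cif library.json [CODES...]
"""

import json
import sys

import gemmi

_CLASS = {
    "L-PEPTIDE LINKING": "amino_acid", "PEPTIDE LINKING": "amino_acid",
    "RNA LINKING": "nucleotide", "DNA LINKING": "nucleotide",
}


def convert(cif_path, codes=None):
    doc = gemmi.cif.read(cif_path)
    out = {}
    for block in doc:
        code = block.name
        if codes and code not in codes:
            continue
        atoms = {}
        for name, elem in zip(block.find_loop("_chem_comp_atom.atom_id"),
                              block.find_loop("_chem_comp_atom.type_symbol")):
            name = name.strip('"')
            if elem.upper() != "H":
                atoms[name] = elem.upper()
        bonds = []
        for a, b in zip(block.find_loop("_chem_comp_bond.atom_id_1"),
                        block.find_loop("_chem_comp_bond.atom_id_2")):
            a, b = a.strip('"'), b.strip('"')
            if a in atoms and b in atoms:
                bonds.append([a, b])
        comp_type = (block.find_value("_chem_comp.type") or "").strip(
            "'\"").upper()
        one = (block.find_value("_chem_comp.one_letter_code") or "X").strip(
            "'\"") or "X"
        chem_class = _CLASS.get(comp_type,
                                "water" if code == "HOH" else "ligand")
        out[code] = {"one_letter": one[:1].upper(), "chem_class": chem_class,
                     "atoms": atoms, "bonds": bonds}
    return out


if __name__ == "__main__":
    if len(sys.argv) < 3:
        sys.exit(__doc__)
    lib = convert(sys.argv[1], set(sys.argv[3:]) or None)
    with open(sys.argv[2], "w") as fh:
        json.dump(lib, fh, indent=1, sort_keys=True)
    print(f"{len(lib)} components -> {sys.argv[2]}")
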