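"""Esterification bookkeeping shared by the nanopore assembler and the
network builder.

The condensation convention: forming one ester bridge between a chain
hydroxyl and a linker carboxylate deletes the hydroxyl hydrogen from the
chain and one terminal oxygen from the carboxylate, then bonds the chain
oxygen to the carboxyl carbon.  Two atoms (one H, one O) leave per ester —
the water-equivalent of the condensation, given that the carboxylate is
already deprotonated.  Net charge stays equal to the sum of the remaining
partial charges by construction.
"""

from __future__ import annotations

import numpy as np

from .core import ArgumentError, Bond, Molecule


def remove_atoms(mol: Molecule, atom_ids) -> Molecule:
    drop = set(atom_ids)
    atoms = [a for a in mol.atoms if a.atom_id not in drop]
    bonds = [b for b in mol.bonds if b.a not in drop and b.b not in drop]
    meta = dict(mol.meta)
    for key in ("hydroxyl_sites", "backbone_carbons"):
        if key in meta:
            meta[key] = [i for i in meta[key] if i not in drop]
    return Molecule(atoms=atoms, bonds=bonds, name=mol.name, meta=meta)


def strip_hydroxyl_hydrogen(chain: Molecule, site_o: int) -> Molecule:
    """Delete the H bonded to a hydroxyl-site oxygen (ester precursor)."""
    by_id = {a.atom_id: a for a in chain.atoms}
    hs = [n for n in chain.neighbors(site_o) if by_id[n].element == "H"]
    if not hs:
        raise ArgumentError(f"hydroxyl site {site_o} carries no hydrogen")
    return remove_atoms(chain, [hs[0]])


def strip_carboxylate_oxygen(linker: Molecule, carboxyl_c: int,
                             keep_toward: np.ndarray | None = None) -> Molecule:
    """Delete one terminal oxygen of a carboxylate.

    When ``keep_toward`` is given, the oxygen pointing *away* from that
    direction is deleted, so the surviving C=O looks outward from the new
    ester bond.
    """
    by_id = {a.atom_id: a for a in linker.atoms}
    term_o = []
    for n in linker.neighbors(carboxyl_c):
        if by_id[n].element != "O":
            continue
        others = [m for m in linker.neighbors(n)
                  if m != carboxyl_c and by_id[m].element != "H"]
        if not others:
            term_o.append(n)
    if len(term_o) < 2:
        raise ArgumentError(f"atom {carboxyl_c} is not a carboxylate carbon")
    if keep_toward is None:
        drop = term_o[0]
    else:
        cpos = np.array(by_id[carboxyl_c].position)
        d = np.asarray(keep_toward, float)
        # drop the oxygen most aligned with the incoming ester direction
        drop = max(term_o, key=lambda o: (np.array(by_id[o].position) - cpos) @ d)
    return remove_atoms(linker, [drop])
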