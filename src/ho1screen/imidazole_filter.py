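"""Structural filter: non-fused, 2-unsubstituted imidazole rings.

The classical HO-1 inhibitor chemotype anchors to the heme Fe(II) through
the lone pair of the imidazole N3; this requires a free (non-fused)
imidazole whose C2 — the carbon between the two ring nitrogens — bears
only hydrogen. N1 substitution is allowed: the classical inhibitors are
N1-linked (sulconazole, tioconazole). Benzimidazoles and purines (fused)
and 2-substituted imidazoles are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem

from .chem_io import MoleculeRecord, SmilesParseError, mol_from_smiles

log = logging.getLogger("ho1screen.imidazole_filter")

# Aromatic 1,3-diazole ring, any N1 substitution / tautomer; fusion and C2
# substitution are checked on the match, not in the pattern.
IMIDAZOLE_SMARTS = "c1ncnc1"  # unused directly; ring walk below is authoritative


@dataclass(frozen=True)
class ImidazoleMatch:
    """One aromatic five-membered 1,3-diaza ring found in a molecule."""

    ring_atom_indices: tuple
    c2_index: int
    fused: bool
    c2_substituted: bool

    @property
    def qualifies(self) -> bool:
        return not self.fused and not self.c2_substituted


def _ring_matches(mol: Chem.Mol):
    """Aromatic 5-rings with exactly two nitrogens in a 1,3 relationship."""
    ri = mol.GetRingInfo()
    rings = [tuple(r) for r in ri.AtomRings() if len(r) == 5]
    for ring in rings:
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() for a in atoms):
            continue
        ns = [a for a in atoms if a.GetAtomicNum() == 7]
        cs = [a for a in atoms if a.GetAtomicNum() == 6]
        if len(ns) != 2 or len(cs) != 3:
            continue
        ring_set = set(ring)
        n_idx = {a.GetIdx() for a in ns}
        # C2 = the unique ring carbon bonded to both nitrogens (1,3-diaza);
        # in pyrazole (1,2-diaza) no such carbon exists.
        c2 = [a for a in cs
              if n_idx <= {nb.GetIdx() for nb in a.GetNeighbors()}]
        if len(c2) != 1:
            continue
        c2_atom = c2[0]
        fused = any(
            len(ring_set & set(other)) >= 2
            for other in ri.AtomRings() if tuple(other) != ring)
        c2_substituted = any(
            nb.GetIdx() not in ring_set and nb.GetAtomicNum() > 1
            for nb in c2_atom.GetNeighbors())
        yield ImidazoleMatch(ring_atom_indices=ring,
                             c2_index=c2_atom.GetIdx(),
                             fused=fused,
                             c2_substituted=c2_substituted)


def find_imidazole_matches(record: MoleculeRecord | str) -> list[ImidazoleMatch]:
    """Every distinct aromatic imidazole (1,3-diazole) ring in the molecule.

    Both NH-tautomer spellings and N1-substituted rings are matched; each
    match carries ``fused`` and ``c2_substituted`` flags. Raises
    :class:`~ho1screen.chem_io.SmilesParseError` on unparseable input.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = mol_from_smiles(smiles)
    return list(_ring_matches(mol))


def passes_structural_filter(record: MoleculeRecord | str) -> bool:
    """True iff the molecule has >=1 non-fused, 2-unsubstituted imidazole ring.

    A parse failure counts as a fail with a logged warning (screening must
    not abort on one bad library entry).
    """
    try:
        matches = find_imidazole_matches(record)
    except SmilesParseError as e:
        log.warning("structural filter: %s -> fail", e)
        return False
    return any(m.qualifies for m in matches)


def filter_library(records) -> tuple[list, list]:
    """Partition records into (passing, failing) by the structural filter."""
    passing, failing = [], []
    for r in records:
        (passing if passes_structural_filter(r) else failing).append(r)
    return passing, failing
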