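"""Transformation-level similarity: reaction centers and degree-k regions.

The reaction center is found from atom-atom maps as the set of mapped
atoms incident to a bond that exists on one side only or whose order
differs between sides, plus mapped heavy atoms whose implicit-hydrogen
count changes (proton transfers leave the heavy-atom bond multiset
unchanged). Stereo-only changes do not create center atoms unless
explicitly requested.

Automatic atom mapping is out of scope: reactions must arrive mapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from rdkit import Chem

from .chem_io import Molecule, Reaction
from .errors import AtomMappingError
from .measures import DEFAULT_MEASURE
from .pairing import ReactionSimilarity, fingerprints_for, sides_similarity

logger = logging.getLogger(__name__)

DEFAULT_DEGREE = 1

BondKey = tuple[int, int]  # unordered map-number pair, stored sorted


@dataclass
class TransformationRegion:
    """Degree-k neighborhood of the reaction center, split per side into
    connected fragments."""

    degree: int
    center_atoms: frozenset[int]  # map numbers
    substrate_fragments: list[Molecule]
    product_fragments: list[Molecule]

    @property
    def empty(self) -> bool:
        return not self.center_atoms

    def atom_count(self) -> int:
        return sum(
            f.num_atoms for f in self.substrate_fragments + self.product_fragments
        )

    def bond_count(self) -> int:
        return sum(
            f.rdmol.GetNumBonds()
            for f in self.substrate_fragments + self.product_fragments
        )


def _side_bonds(mols: list[Molecule]) -> dict[BondKey, float]:
    bonds: dict[BondKey, float] = {}
    for mol in mols:
        for bond in mol.rdmol.GetBonds():
            m1 = bond.GetBeginAtom().GetAtomMapNum()
            m2 = bond.GetEndAtom().GetAtomMapNum()
            key = (min(m1, m2), max(m1, m2))
            bonds[key] = bond.GetBondTypeAsDouble()
    return bonds


def _side_h_counts(mols: list[Molecule]) -> dict[int, int]:
    return {
        atom.GetAtomMapNum(): atom.GetTotalNumHs()
        for mol in mols
        for atom in mol.rdmol.GetAtoms()
    }


def _require_mapped(rxn: Reaction) -> None:
    if not rxn.mapped:
        raise AtomMappingError(
            f"reaction {rxn.id!r} is not fully atom-mapped; supply atom-map "
            "numbers on every heavy atom (automatic mapping is not performed)"
        )


def find_reaction_center(
    rxn: Reaction, include_h_changes: bool = True
) -> frozenset[int]:
    """Map numbers of atoms whose bonding changes between the two sides."""
    _require_mapped(rxn)
    sub_bonds = _side_bonds(rxn.substrates)
    prod_bonds = _side_bonds(rxn.products)
    center: set[int] = set()
    for key in set(sub_bonds) | set(prod_bonds):
        if sub_bonds.get(key) != prod_bonds.get(key):
            center.update(key)
    if include_h_changes:
        sub_h = _side_h_counts(rxn.substrates)
        prod_h = _side_h_counts(rxn.products)
        for m, h in sub_h.items():
            if prod_h.get(m) != h:
                center.add(m)
    return frozenset(center)


def _region_fragments(
    mols: list[Molecule], center: frozenset[int], k: int
) -> list[Molecule]:
    fragments: list[Molecule] = []
    for mol in mols:
        rdmol = mol.rdmol
        seeds = {
            a.GetIdx() for a in rdmol.GetAtoms() if a.GetAtomMapNum() in center
        }
        if not seeds:
            continue
        selected = set(seeds)
        frontier = set(seeds)
        for _ in range(k):
            nxt = {
                n.GetIdx()
                for idx in frontier
                for n in rdmol.GetAtomWithIdx(idx).GetNeighbors()
                if n.GetIdx() not in selected
            }
            if not nxt:
                break
            selected |= nxt
            frontier = nxt
        fragments.extend(_induced_submolecules(rdmol, selected))
    return fragments


def _induced_submolecules(rdmol: Chem.Mol, keep: set[int]) -> list[Molecule]:
    """Induced subgraph on ``keep``, one Molecule per connected component.

    Kekulized first so partial aromatic rings stay valid; cut bonds are
    healed with implicit hydrogens, and full sanitization restores
    aromaticity when a complete ring survives.
    """
    work = Chem.RWMol(rdmol)
    try:
        Chem.Kekulize(work, clearAromaticFlags=True)
    except Chem.KekulizeException:  # pragma: no cover - defensive
        pass
    for idx in sorted(set(range(rdmol.GetNumAtoms())) - keep, reverse=True):
        work.RemoveAtom(idx)
    sub = work.GetMol()
    for atom in sub.GetAtoms():
        atom.SetNoImplicit(False)
    try:
        Chem.SanitizeMol(sub)
    except Exception:  # noqa: BLE001 - fall back to a permissive pass
        Chem.SanitizeMol(
            sub,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
        )
    frags = Chem.GetMolFrags(sub, asMols=True, sanitizeFrags=False)
    return [Molecule(f) for f in frags]


def extract_transformation_region(
    rxn: Reaction,
    k: int = DEFAULT_DEGREE,
    include_h_changes: bool = True,
) -> TransformationRegion:
    """Breadth-first expansion of the center to bond distance ``k`` on each
    side independently; each connected component becomes one fragment."""
    if k < 0:
        raise ValueError(f"transformation degree must be >= 0, got {k}")
    center = find_reaction_center(rxn, include_h_changes=include_h_changes)
    if not center:
        logger.warning(
            "reaction %r has an empty reaction center (identity reaction); "
            "its transformation-level score against anything is 0",
            rxn.id,
        )
        return TransformationRegion(k, center, [], [])
    return TransformationRegion(
        degree=k,
        center_atoms=center,
        substrate_fragments=_region_fragments(rxn.substrates, center, k),
        product_fragments=_region_fragments(rxn.products, center, k),
    )


def transformation_similarity(
    rxn_a: Reaction,
    rxn_b: Reaction,
    k: int = DEFAULT_DEGREE,
    fp_type: str = "extended",
    measure: str = DEFAULT_MEASURE,
    fp_kwargs: Optional[dict] = None,
    include_h_changes: bool = True,
) -> ReactionSimilarity:
    """Score the degree-k transformation regions of two mapped reactions
    with the whole-reaction pairing procedure."""
    fp_kwargs = fp_kwargs or {}
    region_a = extract_transformation_region(rxn_a, k, include_h_changes)
    region_b = extract_transformation_region(rxn_b, k, include_h_changes)
    if region_a.empty or region_b.empty:
        from .pairing import PairingResult

        empty_sub = PairingResult([], [], [], "substrates")
        empty_prod = PairingResult([], [], [], "products")
        return ReactionSimilarity(0.0, empty_sub, empty_prod)
    return sides_similarity(
        fingerprints_for(region_a.substrate_fragments, fp_type, **fp_kwargs),
        fingerprints_for(region_b.substrate_fragments, fp_type, **fp_kwargs),
        fingerprints_for(region_a.product_fragments, fp_type, **fp_kwargs),
        fingerprints_for(region_b.product_fragments, fp_type, **fp_kwargs),
        measure,
    )
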