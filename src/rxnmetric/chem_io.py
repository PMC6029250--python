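"""Parsing, validation and serialization of molecules and reactions.

Reaction SMILES (with atom-map numbers) is the primary dialect; MDL RXN
V2000 blocks are converted on read. Hydrogens are implicit throughout:
explicit hydrogens in input are collapsed to implicit counts before any
downstream computation. Aromaticity is perceived once here, with RDKit's
default model, and reused by every other module.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import (
    AtomMappingError,
    ConfigError,
    MoleculeParseError,
    ReactionValidationError,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}

_BOND_STEREO = {
    Chem.BondStereo.STEREOE: "E",
    Chem.BondStereo.STEREOTRANS: "E",
    Chem.BondStereo.STEREOZ: "Z",
    Chem.BondStereo.STEREOCIS: "Z",
}


@dataclass(frozen=True)
class AtomRecord:
    """Read-only view of one heavy atom."""

    symbol: str
    charge: int
    stereo: str  # "R", "S" or "" for unassigned/achiral
    map_number: int  # 0 = unmapped
    n_hs: int


@dataclass(frozen=True)
class BondRecord:
    """Read-only view of one bond."""

    begin: int
    end: int
    order: float  # 1, 2, 3 or 1.5 (aromatic)
    stereo: str  # "E", "Z" or ""


class Molecule:
    """A connected molecular graph backed by an RDKit mol.

    Carries formal charges, tetrahedral R/S descriptors, double-bond E/Z
    flags and optional atom-map numbers. Hydrogens are implicit.
    """

    def __init__(self, rdmol: Chem.Mol):
        if rdmol is None or rdmol.GetNumAtoms() == 0:
            raise MoleculeParseError("empty molecule")
        self._rdmol = rdmol

    @property
    def rdmol(self) -> Chem.Mol:
        return self._rdmol

    @property
    def smiles(self) -> str:
        """Canonical SMILES, retaining atom-map numbers."""
        return Chem.MolToSmiles(self._rdmol)

    @property
    def num_atoms(self) -> int:
        return self._rdmol.GetNumAtoms()

    @property
    def atoms(self) -> list[AtomRecord]:
        chiral = dict(
            Chem.FindMolChiralCenters(
                self._rdmol, includeUnassigned=False, useLegacyImplementation=False
            )
        )
        return [
            AtomRecord(
                symbol=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                stereo=chiral.get(a.GetIdx(), ""),
                map_number=a.GetAtomMapNum(),
                n_hs=a.GetTotalNumHs(),
            )
            for a in self._rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[BondRecord]:
        return [
            BondRecord(
                begin=b.GetBeginAtomIdx(),
                end=b.GetEndAtomIdx(),
                order=_BOND_ORDER[b.GetBondType()],
                stereo=_BOND_STEREO.get(b.GetStereo(), ""),
            )
            for b in self._rdmol.GetBonds()
        ]

    @property
    def map_numbers(self) -> list[int]:
        """Nonzero atom-map numbers, in atom order."""
        return [
            a.GetAtomMapNum() for a in self._rdmol.GetAtoms() if a.GetAtomMapNum()
        ]

    @property
    def net_charge(self) -> int:
        return sum(a.GetFormalCharge() for a in self._rdmol.GetAtoms())

    def without_maps(self) -> "Molecule":
        clone = Chem.Mol(self._rdmol)
        for atom in clone.GetAtoms():
            atom.SetAtomMapNum(0)
        return Molecule(clone)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Molecule({self.smiles!r})"


def _positional_syntax_check(text: str) -> None:
    """Cheap bracket/parenthesis balance scan to report token positions."""
    stack = []
    pairs = {")": "(", "]": "["}
    for pos, ch in enumerate(text):
        if ch in "([":
            stack.append((ch, pos))
        elif ch in ")]":
            if not stack or stack[-1][0] != pairs[ch]:
                raise MoleculeParseError(
                    f"unbalanced {ch!r} at position {pos} in {text!r}"
                )
            stack.pop()
    if stack:
        ch, pos = stack[-1]
        raise MoleculeParseError(f"unclosed {ch!r} at position {pos} in {text!r}")


def parse_molecule(text: str, require_connected: bool = True) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Atom maps, formal charges and stereo descriptors are preserved;
    explicit hydrogens collapse to implicit counts.

    Raises
    ------
    MoleculeParseError
        On syntactically invalid SMILES (reporting the offending token
        position when it can be localized) or a disconnected graph when
        ``require_connected`` is set.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty SMILES string")
    text = text.strip()
    _positional_syntax_check(text)
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise MoleculeParseError(f"invalid SMILES: {text!r}")
    if require_connected and len(Chem.GetMolFrags(rdmol)) > 1:
        raise MoleculeParseError(
            f"disconnected graph in {text!r}: one molecule must be one component"
        )
    _check_unique_maps(rdmol, text)
    return Molecule(rdmol)


def _check_unique_maps(rdmol: Chem.Mol, context: str) -> None:
    counts = Counter(
        a.GetAtomMapNum() for a in rdmol.GetAtoms() if a.GetAtomMapNum()
    )
    dups = sorted(m for m, k in counts.items() if k > 1)
    if dups:
        raise AtomMappingError(
            f"duplicate atom-map numbers {dups} within one molecule: {context!r}"
        )


class Reaction:
    """Substrates and products, with optional EC label and identifier."""

    def __init__(
        self,
        substrates: Sequence[Molecule],
        products: Sequence[Molecule],
        id: str = "",
        ec: Optional[str] = None,
    ):
        if not substrates or not products:
            raise ReactionValidationError(
                "a reaction needs at least one substrate and one product"
            )
        self.substrates = list(substrates)
        self.products = list(products)
        self.id = id
        self.ec = ec
        for side_name, side in (("substrate", substrates), ("product", products)):
            counts = Counter(m for mol in side for m in mol.map_numbers)
            dups = sorted(m for m, k in counts.items() if k > 1)
            if dups:
                raise AtomMappingError(
                    f"duplicate atom-map numbers {dups} on the {side_name} side"
                    f" of reaction {id!r}"
                )
        self.mapped = self._compute_mapped()

    def _compute_mapped(self) -> bool:
        sub_maps: list[int] = []
        for mol in self.substrates:
            for atom in mol.rdmol.GetAtoms():
                if atom.GetAtomMapNum() == 0:
                    return False
                sub_maps.append(atom.GetAtomMapNum())
        prod_maps: list[int] = []
        for mol in self.products:
            for atom in mol.rdmol.GetAtoms():
                if atom.GetAtomMapNum() == 0:
                    return False
                prod_maps.append(atom.GetAtomMapNum())
        return sorted(sub_maps) == sorted(prod_maps)

    @property
    def smiles(self) -> str:
        subs = ".".join(m.smiles for m in self.substrates)
        prods = ".".join(m.smiles for m in self.products)
        return f"{subs}>>{prods}"

    def reversed(self) -> "Reaction":
        return Reaction(self.products, self.substrates, id=self.id, ec=self.ec)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Reaction(id={self.id!r}, {self.smiles!r})"


def parse_reaction(text: str, id: str = "", ec: Optional[str] = None) -> Reaction:
    """Parse reaction SMILES ``subs>agents>prods`` or an MDL RXN V2000 block.

    The agents field of reaction SMILES is ignored. Dot-separated
    components become separate molecules, in text order.
    """
    text = text.strip()
    if not text:
        raise ReactionValidationError("empty reaction text")
    if text.startswith("$RXN"):
        return _parse_rxn_block(text, id=id, ec=ec)
    parts = text.split(">")
    if len(parts) == 3:
        sub_text, _agents, prod_text = parts
    else:
        raise ReactionValidationError(
            f"reaction SMILES must have the form 'subs>>prods': {text!r}"
        )
    if not sub_text.strip() or not prod_text.strip():
        raise ReactionValidationError(
            f"both reaction sides must be non-empty: {text!r}"
        )
    substrates = [parse_molecule(t) for t in sub_text.split(".") if t.strip()]
    products = [parse_molecule(t) for t in prod_text.split(".") if t.strip()]
    return Reaction(substrates, products, id=id, ec=ec)


def _parse_rxn_block(text: str, id: str = "", ec: Optional[str] = None) -> Reaction:
    rxn = AllChem.ReactionFromRxnBlock(text)
    if rxn is None:
        raise MoleculeParseError(f"invalid RXN block for reaction {id!r}")

    def _clean(template: Chem.Mol) -> Molecule:
        mol = Chem.Mol(template)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # noqa: BLE001 - rdkit raises generic types
            raise MoleculeParseError(
                f"unsanitizable molecule in RXN block for reaction {id!r}: {exc}"
            ) from exc
        mol = Chem.RemoveHs(mol)
        _check_unique_maps(mol, Chem.MolToSmiles(mol))
        return Molecule(mol)

    substrates = [_clean(m) for m in rxn.GetReactants()]
    products = [_clean(m) for m in rxn.GetProducts()]
    return Reaction(substrates, products, id=id, ec=ec)


def reaction_to_rxn_block(rxn: Reaction) -> str:
    """Serialize a reaction as an MDL RXN V2000 block."""
    chem_rxn = AllChem.ChemicalReaction()
    for mol in rxn.substrates:
        chem_rxn.AddReactantTemplate(mol.rdmol)
    for mol in rxn.products:
        chem_rxn.AddProductTemplate(mol.rdmol)
    return AllChem.ReactionToRxnBlock(chem_rxn)


def read_reaction_table(
    path: str | Path,
    dialect: str = "tsv",
    strict: bool = True,
) -> list[Reaction]:
    """Read a batch table with columns ``id``, ``reaction`` and optional ``ec``.

    Malformed rows raise in strict mode; otherwise they are skipped with a
    logged warning carrying the 1-based row number.
    """
    if dialect not in ("tsv", "csv"):
        raise ConfigError(f"unknown table dialect {dialect!r} (use 'tsv' or 'csv')")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"id", "reaction"} - set(df.columns)
    if missing:
        raise ConfigError(
            f"reaction table {path} is missing mandatory column(s): {sorted(missing)}"
        )
    has_ec = "ec" in df.columns
    reactions: list[Reaction] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        text = getattr(row, "reaction").strip()
        ec = (getattr(row, "ec").strip() or None) if has_ec else None
        try:
            if not text:
                raise ReactionValidationError("empty reaction cell")
            reactions.append(parse_reaction(text, id=getattr(row, "id"), ec=ec))
        except Exception as exc:  # noqa: BLE001
            if strict:
                raise type(exc)(f"row {row_no}: {exc}") from exc
            logger.warning("skipping row %d of %s: %s", row_no, path, exc)
    return reactions


def write_reaction_table(
    reactions: Iterable[Reaction], path: str | Path, dialect: str = "tsv"
) -> None:
    sep = "\t" if dialect == "tsv" else ","
    rows = [
        {"id": r.id, "reaction": r.smiles, "ec": r.ec or ""} for r in reactions
    ]
    pd.DataFrame(rows, columns=["id", "reaction", "ec"]).to_csv(
        path, sep=sep, index=False
    )
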