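"""Physicochemical layer: mass, additive volume, pH-dependent charges and
the Jaccard property correction of the fingerprint score.

The corrected score is Rs = Rf / (1 + Jdist), where Jdist = 1 - mean(Js)
over the N equivalent molecule pairs of the greedy pairing, and
Js = min(a, b) / max(a, b) for the paired property values a and b.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem_io import Molecule, Reaction
from .errors import UndefinedCorrectionError, UnsupportedElementError
from .measures import DEFAULT_MEASURE
from .pairing import ReactionSimilarity, reaction_similarity

logger = logging.getLogger(__name__)

DEFAULT_PH = 7.0
PROPERTY_NAMES = ("mass", "volume")


@dataclass(frozen=True)
class PropertyPair:
    """Property values (mass in Da or volume in cubic angstroms) of the two
    molecules of one equivalent pair."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("property values must be strictly positive")


@dataclass
class SimilarityResult:
    """Fingerprint score, property correction, and pairing size."""

    rf: float
    jdist: float
    rs: float
    properties_used: tuple[str, ...]
    n_pairs: int
    trace: Optional[ReactionSimilarity] = None


def molecular_mass(mol: Molecule) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    return float(Descriptors.MolWt(mol.rdmol))


@lru_cache(maxsize=1)
def _volume_params() -> dict:
    text = (
        resources.files("rxnmetric.data").joinpath("volume_params.json").read_text()
    )
    return json.loads(text)


def molecular_volume(mol: Molecule) -> float:
    """Additive van der Waals volume in cubic angstroms.

    Sum of bundled atom contributions (hydrogens included) minus bond,
    aromatic-ring and aliphatic-ring corrections.
    """
    params = _volume_params()
    contrib = params["atom_contributions"]
    rdmol = mol.rdmol
    total = 0.0
    n_h = 0
    for atom in rdmol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in contrib:
            raise UnsupportedElementError(
                f"element {symbol!r} is outside the volume parameter table"
            )
        total += contrib[symbol]
        n_h += atom.GetTotalNumHs()
    total += n_h * contrib["H"]
    ring_info = rdmol.GetRingInfo()
    n_rings = ring_info.NumRings()
    n_aromatic = sum(
        1
        for ring in ring_info.BondRings()
        if all(rdmol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
    )
    n_atoms = rdmol.GetNumAtoms() + n_h
    n_bonds = n_atoms - 1 + n_rings
    total -= params["bond_correction"] * n_bonds
    total -= params["aromatic_ring_correction"] * n_aromatic
    total -= params["nonaromatic_ring_correction"] * (n_rings - n_aromatic)
    return total


@dataclass(frozen=True)
class IonizableGroup:
    name: str
    smarts: str
    pka: float
    kind: str  # "acid" or "base"


@lru_cache(maxsize=1)
def ionizable_groups() -> tuple[IonizableGroup, ...]:
    """The bundled (SMARTS, pKa, acid/base) rule table. The first atom of
    each SMARTS is the titratable atom."""
    text = (
        resources.files("rxnmetric.data").joinpath("pka_groups.tsv").read_text()
    )
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    return tuple(
        IonizableGroup(r["name"], r["smarts"], float(r["pka"]), r["kind"])
        for r in rows
    )


@lru_cache(maxsize=1)
def _compiled_groups() -> tuple[tuple[IonizableGroup, Chem.Mol], ...]:
    return tuple(
        (g, Chem.MolFromSmarts(g.smarts)) for g in ionizable_groups()
    )


def assign_charges_at_pH(mol: Molecule, ph: float = DEFAULT_PH) -> Molecule:
    """Set each matched ionizable group to its majority protonation state.

    Acids are deprotonated (formal charge -1 on the titratable atom) iff
    pH > pKa; bases protonated (+1) iff pH < pKa. Matching happens against
    the input state, so the operation is idempotent at a fixed pH.
    Molecules with no ionizable groups pass through unchanged.
    """
    if not 0 <= ph <= 14:
        raise ValueError(f"pH must be within [0, 14], got {ph}")
    clone = Chem.RWMol(mol.rdmol)
    touched: set[int] = set()
    for group, patt in _compiled_groups():
        if group.kind == "acid" and ph <= group.pka:
            continue
        if group.kind == "base" and ph >= group.pka:
            continue
        for match in mol.rdmol.GetSubstructMatches(patt):
            idx = match[0]
            if idx in touched:
                continue
            atom = clone.GetAtomWithIdx(idx)
            if group.kind == "acid":
                atom.SetFormalCharge(atom.GetFormalCharge() - 1)
                if atom.GetNumExplicitHs():
                    atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
            else:
                atom.SetFormalCharge(atom.GetFormalCharge() + 1)
            atom.SetNoImplicit(False)
            touched.add(idx)
    if not touched:
        return mol
    out = clone.GetMol()
    Chem.SanitizeMol(out)
    return Molecule(out)


def jaccard_similarity(pair: PropertyPair) -> float:
    """Js = min(a, b) / max(a, b), in (0, 1], symmetric."""
    return min(pair.a, pair.b) / max(pair.a, pair.b)


def jaccard_distance(
    pairs_by_property: dict[str, Sequence[PropertyPair]],
) -> float:
    """Jdist = 1 - mean(Js) per property; multiple selected properties are
    averaged, keeping the result in [0, 1)."""
    if not pairs_by_property:
        raise UndefinedCorrectionError("no properties selected")
    per_property = []
    for prop, pairs in pairs_by_property.items():
        if not pairs:
            raise UndefinedCorrectionError(
                f"no equivalent pairs available for property {prop!r}"
            )
        js = [jaccard_similarity(p) for p in pairs]
        per_property.append(1.0 - sum(js) / len(js))
    return sum(per_property) / len(per_property)


def corrected_similarity(rf: float, jdist: float) -> float:
    """Rs = Rf / (1 + Jdist)."""
    if not 0 <= rf <= 1:
        raise ValueError(f"Rf must be in [0, 1], got {rf}")
    if not 0 <= jdist <= 1:
        raise ValueError(f"Jdist must be in [0, 1], got {jdist}")
    return rf / (1.0 + jdist)


_PROPERTY_FUNCS = {"mass": molecular_mass, "volume": molecular_volume}


def apply_correction(
    trace: ReactionSimilarity,
    subs_a: Sequence[Molecule],
    subs_b: Sequence[Molecule],
    prods_a: Sequence[Molecule],
    prods_b: Sequence[Molecule],
    properties: Sequence[str],
) -> SimilarityResult:
    """Correct a pairing trace's score using the trace's own pairs.

    Works for whole reactions and for transformation-region fragment lists
    alike; with no formable pairs the correction is skipped (Rs = Rf).
    """
    for p in properties:
        if p not in _PROPERTY_FUNCS:
            raise ValueError(f"unknown property {p!r}; choose from {PROPERTY_NAMES}")
    mol_pairs: list[tuple[Molecule, Molecule]] = []
    for side, i, j, _ in trace.pairs:
        if side == "substrates":
            mol_pairs.append((subs_a[i], subs_b[j]))
        else:
            mol_pairs.append((prods_a[i], prods_b[j]))
    if not properties:
        return SimilarityResult(
            trace.score, 0.0, trace.score, (), len(mol_pairs), trace
        )
    if not mol_pairs:
        logger.warning("no equivalent pairs; skipping property correction (Rs = Rf)")
        return SimilarityResult(
            trace.score, 0.0, trace.score, tuple(properties), 0, trace
        )
    pairs_by_property = {
        p: [
            PropertyPair(_PROPERTY_FUNCS[p](ma), _PROPERTY_FUNCS[p](mb))
            for ma, mb in mol_pairs
        ]
        for p in properties
    }
    jdist = jaccard_distance(pairs_by_property)
    rs = corrected_similarity(trace.score, jdist)
    return SimilarityResult(
        trace.score, jdist, rs, tuple(properties), len(mol_pairs), trace
    )


def corrected_reaction_similarity(
    rxn_a: Reaction,
    rxn_b: Reaction,
    fp_type: str = "extended",
    measure: str = DEFAULT_MEASURE,
    properties: Sequence[str] = ("mass", "volume"),
    orientation: str = "forward",
    fp_kwargs: Optional[dict] = None,
) -> SimilarityResult:
    """Whole-reaction score with the property correction applied to the
    same greedy pairing that produced Rf.

    With zero formable pairs the correction is skipped (Rs = Rf) and a
    warning logged.
    """
    trace = reaction_similarity(
        rxn_a, rxn_b, fp_type, measure, orientation, fp_kwargs
    )
    if trace.orientation == "reverse":
        rxn_b = rxn_b.reversed()
    return apply_correction(
        trace,
        rxn_a.substrates,
        rxn_b.substrates,
        rxn_a.products,
        rxn_b.products,
        properties,
    )
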