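"""The four molecular fingerprint types.

All four are pure functions of the molecular graph (plus stereo/charge for
the enhanced type): atom-map numbers are stripped before hashing and atom
input order is irrelevant. Extension bits beyond what RDKit's generators
provide (ring descriptors, charge/stereo signatures) are hashed with CRC-32
at a fixed seed, so bit positions are stable across runs and platforms.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import Molecule
from .errors import ConfigError

logger = logging.getLogger(__name__)

DEFAULT_LENGTH = 1024
SUBSTRUCTURE_KEY_COUNT = 307
ENHANCED_EXTENSION_BITS = 64
CIRCULAR_RADIUS = 1  # ECFP-2 equivalent

FP_TYPES = ("circular", "extended", "substructure", "enhanced")

_HASH_SEED = 0x5F3C1B2A


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary feature vector tagged with its type."""

    bits: np.ndarray  # bool array
    fp_type: str

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def length(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> list[int]:
        return np.flatnonzero(self.bits).tolist()


def _hash_bit(token: str, length: int) -> int:
    return zlib.crc32(token.encode("utf-8"), _HASH_SEED) % length


def _bare_mol(mol: Molecule) -> Chem.Mol:
    """Copy with atom maps stripped so they can never reach a hash."""
    clone = Chem.Mol(mol.rdmol)
    for atom in clone.GetAtoms():
        atom.SetAtomMapNum(0)
    return clone


def circular_fingerprint(mol: Molecule, length: int = DEFAULT_LENGTH) -> Fingerprint:
    """Hashed circular-environment fingerprint of radius 1.

    Atom invariants cover element, degree, charge, attached-H count and
    ring membership (the ECFP invariant set).
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=CIRCULAR_RADIUS, fpSize=length
    )
    bv = gen.GetFingerprint(_bare_mol(mol))
    bits = np.zeros(length, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(bits, "circular")


def _path_bits(rdmol: Chem.Mol, length: int, max_path_depth: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=1,
        maxPath=max_path_depth,
        fpSize=length,
        branchedPaths=False,
        numBitsPerFeature=1,
    )
    bv = gen.GetFingerprint(rdmol)
    bits = np.zeros(length, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return bits


def _ring_descriptor_bits(rdmol: Chem.Mol, length: int) -> np.ndarray:
    """Ring-system descriptors folded into the same vector: one bit per
    ring size present plus one for the total ring count."""
    bits = np.zeros(length, dtype=bool)
    ring_info = rdmol.GetRingInfo()
    sizes = sorted({len(ring) for ring in ring_info.AtomRings()})
    for size in sizes:
        bits[_hash_bit(f"ring-size:{size}", length)] = True
    n_rings = ring_info.NumRings()
    if n_rings:
        bits[_hash_bit(f"ring-count:{n_rings}", length)] = True
    return bits


def extended_fingerprint(
    mol: Molecule, length: int = DEFAULT_LENGTH, max_path_depth: int = 7
) -> Fingerprint:
    """Hashed linear-path fingerprint augmented with ring descriptors.

    Paths up to ``max_path_depth`` bonds; ring-size and ring-count bits are
    folded into the same ``length``-bit vector.
    """
    bare = _bare_mol(mol)
    bits = _path_bits(bare, length, max_path_depth)
    bits |= _ring_descriptor_bits(bare, length)
    if not bits.any():
        logger.warning("extended fingerprint is all-zero for %s", mol.smiles)
    return Fingerprint(bits, "extended")


@lru_cache(maxsize=1)
def substructure_keys() -> tuple[str, ...]:
    """The bundled substructure key set: one SMARTS per bit position."""
    text = (
        resources.files("rxnmetric.data")
        .joinpath("substructure_keys.smarts")
        .read_text()
    )
    keys = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(keys) != SUBSTRUCTURE_KEY_COUNT:
        raise ConfigError(
            f"substructure key file must contain exactly "
            f"{SUBSTRUCTURE_KEY_COUNT} SMARTS, found {len(keys)}"
        )
    return keys


@lru_cache(maxsize=1)
def _compiled_keys() -> tuple[Chem.Mol, ...]:
    compiled = []
    for i, smarts in enumerate(substructure_keys()):
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ConfigError(f"unparseable SMARTS key at index {i}: {smarts!r}")
        compiled.append(patt)
    return tuple(compiled)


def substructure_fingerprint(mol: Molecule) -> Fingerprint:
    """Structural-key fingerprint: bit i set iff key i matches at least once."""
    bare = _bare_mol(mol)
    bits = np.zeros(SUBSTRUCTURE_KEY_COUNT, dtype=bool)
    for i, patt in enumerate(_compiled_keys()):
        if bare.HasSubstructMatch(patt):
            bits[i] = True
    return Fingerprint(bits, "substructure")


def _atom_environment_signature(rdmol: Chem.Mol, idx: int) -> str:
    """Order-independent radius-1 signature of one atom's environment."""
    atom = rdmol.GetAtomWithIdx(idx)
    neighbors = sorted(
        f"{n.GetSymbol()}{rdmol.GetBondBetweenAtoms(idx, n.GetIdx()).GetBondTypeAsDouble():g}"
        for n in atom.GetNeighbors()
    )
    return (
        f"{atom.GetSymbol()};d{atom.GetDegree()};h{atom.GetTotalNumHs()};"
        f"r{int(atom.IsInRing())};[{','.join(neighbors)}]"
    )


_BOND_STEREO_CODE = {
    Chem.BondStereo.STEREOE: "E",
    Chem.BondStereo.STEREOTRANS: "E",
    Chem.BondStereo.STEREOZ: "Z",
    Chem.BondStereo.STEREOCIS: "Z",
}


def _stereo_charge_block(rdmol: Chem.Mol, n_bits: int) -> np.ndarray:
    block = np.zeros(n_bits, dtype=bool)
    for atom in rdmol.GetAtoms():
        q = atom.GetFormalCharge()
        if q != 0:
            sig = f"chg:{_atom_environment_signature(rdmol, atom.GetIdx())}:{q:+d}"
            block[_hash_bit(sig, n_bits)] = True
    centers = Chem.FindMolChiralCenters(
        rdmol, includeUnassigned=False, useLegacyImplementation=False
    )
    for idx, code in centers:
        sig = f"tet:{_atom_environment_signature(rdmol, idx)}:{code}"
        block[_hash_bit(sig, n_bits)] = True
    for bond in rdmol.GetBonds():
        code = _BOND_STEREO_CODE.get(bond.GetStereo())
        if code:
            ends = sorted(
                _atom_environment_signature(rdmol, i)
                for i in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
            )
            block[_hash_bit(f"dbl:{'|'.join(ends)}:{code}", n_bits)] = True
    return block


def enhanced_fingerprint(
    mol: Molecule,
    length: int = DEFAULT_LENGTH,
    extension_bits: int = ENHANCED_EXTENSION_BITS,
    max_path_depth: int = 7,
) -> Fingerprint:
    """Extended fingerprint plus a dedicated stereo/charge extension block.

    The base ``length`` bits equal :func:`extended_fingerprint`; the
    appended block hashes (environment, formal charge) signatures for every
    charged atom and (environment, parity) signatures for every assigned
    tetrahedral center and stereo double bond. Molecules differing only in
    one parity or one formal charge therefore yield different fingerprints.
    """
    base = extended_fingerprint(mol, length=length, max_path_depth=max_path_depth)
    bare = _bare_mol(mol)
    block = _stereo_charge_block(bare, extension_bits)
    return Fingerprint(np.concatenate([base.bits, block]), "enhanced")


_FP_FUNCS = {
    "circular": circular_fingerprint,
    "extended": extended_fingerprint,
    "substructure": substructure_fingerprint,
    "enhanced": enhanced_fingerprint,
}


def fingerprint(mol: Molecule, fp_type: str, **kwargs) -> Fingerprint:
    """Dispatch to the named fingerprint type."""
    try:
        func = _FP_FUNCS[fp_type]
    except KeyError:
        raise ConfigError(
            f"unknown fingerprint type {fp_type!r}; choose from {list(FP_TYPES)}"
        ) from None
    return func(mol, **kwargs)
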