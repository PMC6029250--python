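"""Deterministic generator of small atom-mapped toy reactions.

Each reaction family is a hand-curated mapped template (ester hydrolysis,
transamination, phosphoryl transfer, dehydrogenation) instantiated with
varying alkyl R-groups drawn deterministically from a seed. Families carry
synthetic EC-style labels sharing the first three fields within a family
and differing across families at field one or two, together with the
manually derived reaction-center annotation for each instance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .chem_io import Reaction, parse_reaction, reaction_to_rxn_block, write_reaction_table
from .errors import ConfigError

#: family tag -> first three EC fields
FAMILY_EC = {
    "ester_hydrolysis": "3.1.1",
    "transamination": "2.6.1",
    "phosphoryl_transfer": "2.7.1",
    "dehydrogenation": "1.1.1",
}

FAMILIES = tuple(FAMILY_EC)


@dataclass
class FixtureReaction:
    reaction: Reaction
    family: str
    #: manual bond-set-difference annotation: expected center map numbers
    expected_center: frozenset[int]


@dataclass
class FixtureSet:
    reactions: list[FixtureReaction]
    seed: int
    families: tuple[str, ...]

    def as_reactions(self) -> list[Reaction]:
        return [fr.reaction for fr in self.reactions]

    def ec_by_id(self) -> dict[str, str]:
        return {fr.reaction.id: fr.reaction.ec for fr in self.reactions}

    def write_table(self, path: str | Path) -> None:
        write_reaction_table(self.as_reactions(), path)

    def write_rxn_files(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for fr in self.reactions:
            p = directory / f"{fr.reaction.id}.rxn"
            p.write_text(reaction_to_rxn_block(fr.reaction))
            written.append(p)
        return written


def _chain(length: int, start: int, tail: bool = False) -> tuple[str, int]:
    """Mapped linear alkyl chain of ``length`` carbons.

    With ``tail=False`` the chain ends at its attachment carbon (written
    left of the group it bonds to); with ``tail=True`` it starts at the
    attachment carbon. Returns (smiles fragment, next free map number).
    """
    if length < 1:
        return "", start
    attach_pos = 0 if tail else length - 1
    atoms = []
    for pos in range(length):
        m = start + pos
        if length == 1:
            chain_bonds = 0
        elif pos in (0, length - 1):
            chain_bonds = 1
        else:
            chain_bonds = 2
        n_h = 4 - chain_bonds - (1 if pos == attach_pos else 0)
        atoms.append(f"[CH{n_h}:{m}]")
    return "".join(atoms), start + length


def _ester_hydrolysis(r1: int, r2: int) -> tuple[str, frozenset[int]]:
    """R1-C(=O)-O-R2 + H2O >> R1-COOH + HO-R2; the ester C-O bond breaks
    and the water oxygen bonds to the carbonyl carbon."""
    acyl, m = _chain(r1, 1)
    c_a, o_b, o_d = m, m + 1, m + 2
    alkyl, m2 = _chain(r2, o_d + 1, tail=True)
    w = m2
    subs = f"{acyl}[C:{c_a}](=[O:{o_b}])[O:{o_d}]{alkyl}.[OH2:{w}]"
    acyl_p, _ = _chain(r1, 1)
    alkyl_p, _ = _chain(r2, o_d + 1, tail=True)
    prods = f"{acyl_p}[C:{c_a}](=[O:{o_b}])[OH:{w}].[OH:{o_d}]{alkyl_p}"
    return f"{subs}>>{prods}", frozenset({c_a, o_d, w})


def _transamination(r1: int, r2: int) -> tuple[str, frozenset[int]]:
    """Amino acid + 2-oxoacid >> 2-oxoacid + amino acid: the amine nitrogen
    and the keto oxygen swap alpha carbons."""
    ch1, m = _chain(r1, 1)
    a, n_, b, c, d = m, m + 1, m + 2, m + 3, m + 4
    ch2, m2 = _chain(r2, d + 1)
    e, f, g, h, i = m2, m2 + 1, m2 + 2, m2 + 3, m2 + 4
    subs = (
        f"{ch1}[CH:{a}]([NH2:{n_}])[C:{b}](=[O:{c}])[OH:{d}]"
        f".{ch2}[C:{e}](=[O:{f}])[C:{g}](=[O:{h}])[OH:{i}]"
    )
    prods = (
        f"{ch1}[C:{a}](=[O:{f}])[C:{b}](=[O:{c}])[OH:{d}]"
        f".{ch2}[CH:{e}]([NH2:{n_}])[C:{g}](=[O:{h}])[OH:{i}]"
    )
    return f"{subs}>>{prods}", frozenset({a, n_, e, f})


def _phosphoryl_transfer(r1: int) -> tuple[str, frozenset[int]]:
    """R-OH + methyl phosphate >> R-O-PO3H2 + methanol: the phosphoryl
    group migrates from the donor oxygen to the acceptor oxygen."""
    ch, m = _chain(r1, 1)
    o_acc = m
    p_, o_q, o_s, o_t, o_u, c_me = m + 1, m + 2, m + 3, m + 4, m + 5, m + 6
    subs = (
        f"{ch}[OH:{o_acc}]"
        f".[CH3:{c_me}][O:{o_q}][P:{p_}](=[O:{o_s}])([OH:{o_t}])[OH:{o_u}]"
    )
    prods = (
        f"{ch}[O:{o_acc}][P:{p_}](=[O:{o_s}])([OH:{o_t}])[OH:{o_u}]"
        f".[CH3:{c_me}][OH:{o_q}]"
    )
    return f"{subs}>>{prods}", frozenset({o_acc, p_, o_q})


def _dehydrogenation(r1: int, r2: int) -> tuple[str, frozenset[int]]:
    """Secondary alcohol >> ketone (cofactor omitted): the C-O bond order
    rises and both atoms lose a hydrogen."""
    ch1, m = _chain(r1, 1)
    x, y = m, m + 1
    ch2, _ = _chain(r2, y + 1, tail=True)
    subs = f"{ch1}[CH:{x}]([OH:{y}]){ch2}"
    prods = f"{ch1}[C:{x}](=[O:{y}]){ch2}"
    return f"{subs}>>{prods}", frozenset({x, y})


def _variants(family: str, rng: random.Random, n: int) -> list[tuple]:
    """Deterministically sample n distinct R-group tuples for a family."""
    two_group = family != "phosphoryl_transfer"
    if two_group:
        space = [(i, j) for i in range(1, 7) for j in range(1, 7)]
    else:
        space = [(i,) for i in range(1, 13)]
    if n > len(space):
        raise ConfigError(
            f"family {family!r} supports at most {len(space)} variants, asked {n}"
        )
    return rng.sample(space, n)


_BUILDERS = {
    "ester_hydrolysis": _ester_hydrolysis,
    "transamination": _transamination,
    "phosphoryl_transfer": _phosphoryl_transfer,
    "dehydrogenation": _dehydrogenation,
}


def generate_fixtures(
    seed: int = 0,
    n_per_family: int = 3,
    families: Optional[Sequence[str]] = None,
) -> FixtureSet:
    """Instantiate mapped reaction templates with seed-determined R-groups.

    EC labels are ``<family prefix>.<variant index + 1>``. Calling twice
    with the same arguments yields byte-identical output.
    """
    if n_per_family < 1:
        raise ConfigError("n_per_family must be >= 1")
    families = tuple(families) if families is not None else FAMILIES
    unknown = [f for f in families if f not in _BUILDERS]
    if unknown:
        raise ConfigError(
            f"unknown family tag(s) {unknown}; valid: {list(FAMILIES)}"
        )
    rng = random.Random(seed)
    out: list[FixtureReaction] = []
    for family in families:
        builder = _BUILDERS[family]
        for i, args in enumerate(_variants(family, rng, n_per_family)):
            smiles, center = builder(*args)
            rxn_id = f"{family}_{i + 1:02d}"
            ec = f"{FAMILY_EC[family]}.{i + 1}"
            rxn = parse_reaction(smiles, id=rxn_id, ec=ec)
            out.append(FixtureReaction(rxn, family, center))
    return FixtureSet(out, seed, families)
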