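"""Whole-reaction similarity via greedy molecule pairing.

Molecules are paired side-wise (substrates against substrates, products
against products) by repeatedly taking the globally highest-similarity
unmatched pair; unpaired molecules are dropped. The reaction score is the
unweighted mean of pair scores over both sides combined. Greedy pairing is
intentionally not an optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem_io import Molecule, Reaction
from .fingerprints import Fingerprint, fingerprint
from .measures import DEFAULT_MEASURE, fingerprint_similarity


@dataclass
class PairingResult:
    """Trace of one greedy side-wise pairing."""

    pairs: list[tuple[int, int, float]]  # (index in A, index in B, score)
    unpaired_a: list[int]
    unpaired_b: list[int]
    side: str  # "substrates" or "products"

    @property
    def scores(self) -> list[float]:
        return [s for _, _, s in self.pairs]


@dataclass
class ReactionSimilarity:
    """Score plus the pairing traces that produced it."""

    score: float
    substrate_pairing: PairingResult
    product_pairing: PairingResult
    orientation: str = "forward"

    @property
    def pairs(self) -> list[tuple[str, int, int, float]]:
        out = [("substrates", i, j, s) for i, j, s in self.substrate_pairing.pairs]
        out += [("products", i, j, s) for i, j, s in self.product_pairing.pairs]
        return out

    @property
    def n_pairs(self) -> int:
        return len(self.substrate_pairing.pairs) + len(self.product_pairing.pairs)

    @property
    def n_unpaired(self) -> int:
        return (
            len(self.substrate_pairing.unpaired_a)
            + len(self.substrate_pairing.unpaired_b)
            + len(self.product_pairing.unpaired_a)
            + len(self.product_pairing.unpaired_b)
        )


def greedy_pair(
    mols_a: Sequence[Fingerprint],
    mols_b: Sequence[Fingerprint],
    measure: str = DEFAULT_MEASURE,
    side: str = "substrates",
) -> PairingResult:
    """Greedily pair fingerprints to maximize the selected measure.

    Ties are broken by the lower index in A, then the lower index in B, so
    batch runs are reproducible. Picked scores are non-increasing.
    """
    n_a, n_b = len(mols_a), len(mols_b)
    if n_a == 0 or n_b == 0:
        return PairingResult([], list(range(n_a)), list(range(n_b)), side)
    scores = np.empty((n_a, n_b), dtype=float)
    for i, fa in enumerate(mols_a):
        for j, fb in enumerate(mols_b):
            scores[i, j] = fingerprint_similarity(fa, fb, measure)
    free_a = list(range(n_a))
    free_b = list(range(n_b))
    pairs: list[tuple[int, int, float]] = []
    while free_a and free_b:
        sub = scores[np.ix_(free_a, free_b)]
        # argmax in row-major order == (lowest i, then lowest j) tie-break
        flat = int(np.argmax(sub))
        ai, bj = divmod(flat, len(free_b))
        i, j = free_a[ai], free_b[bj]
        pairs.append((i, j, float(scores[i, j])))
        free_a.remove(i)
        free_b.remove(j)
    return PairingResult(pairs, free_a, free_b, side)


def fingerprints_for(
    mols: Sequence[Molecule], fp_type: str, **fp_kwargs
) -> list[Fingerprint]:
    return [fingerprint(m, fp_type, **fp_kwargs) for m in mols]


def sides_similarity(
    subs_a: Sequence[Fingerprint],
    subs_b: Sequence[Fingerprint],
    prods_a: Sequence[Fingerprint],
    prods_b: Sequence[Fingerprint],
    measure: str = DEFAULT_MEASURE,
) -> ReactionSimilarity:
    """Pair substrates with substrates and products with products; the
    score is the mean over all pairs from both sides combined."""
    sub_pairing = greedy_pair(subs_a, subs_b, measure, side="substrates")
    prod_pairing = greedy_pair(prods_a, prods_b, measure, side="products")
    all_scores = sub_pairing.scores + prod_pairing.scores
    score = float(np.mean(all_scores)) if all_scores else 0.0
    return ReactionSimilarity(score, sub_pairing, prod_pairing)


def reaction_similarity(
    rxn_a: Reaction,
    rxn_b: Reaction,
    fp_type: str = "extended",
    measure: str = DEFAULT_MEASURE,
    orientation: str = "forward",
    fp_kwargs: Optional[dict] = None,
) -> ReactionSimilarity:
    """Whole-reaction similarity score in [0, 1] with its pairing trace.

    ``orientation="auto"`` additionally evaluates ``rxn_b`` reversed and
    returns the larger score; the default ``"forward"`` never crosses
    sides.
    """
    fp_kwargs = fp_kwargs or {}
    subs_a = fingerprints_for(rxn_a.substrates, fp_type, **fp_kwargs)
    prods_a = fingerprints_for(rxn_a.products, fp_type, **fp_kwargs)
    subs_b = fingerprints_for(rxn_b.substrates, fp_type, **fp_kwargs)
    prods_b = fingerprints_for(rxn_b.products, fp_type, **fp_kwargs)
    forward = sides_similarity(subs_a, subs_b, prods_a, prods_b, measure)
    if orientation == "forward":
        return forward
    if orientation != "auto":
        raise ValueError(f"orientation must be 'forward' or 'auto': {orientation!r}")
    reverse = sides_similarity(subs_a, prods_b, prods_a, subs_b, measure)
    reverse.orientation = "reverse"
    return forward if forward.score >= reverse.score else reverse
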