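"""Nine binary similarity measures over the (a, b, c, d) bit contingency.

For two bit vectors of common length n: a = set in both, b = set in the
first only, c = set in the second only, d = unset in both, n = a+b+c+d.

The Tanimoto coefficient is implemented in its standard form a/(a+b+c).
A historical variant that simplifies to a/(2a+b) is exposed as
``tanimoto_printed`` for auditability but is not part of the canonical set.

Identity convention (applied uniformly): two identical vectors
(b == c == 0) score 1.0 under every measure, which also resolves every
zero-denominator case; a remaining zero denominator (possible only for
non-identical vectors, e.g. one empty vector under ochiai) scores 0.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FingerprintMismatchError, UnknownMeasureError
from .fingerprints import Fingerprint

#: The nine canonical measure identifiers, in presentation order.
MEASURES = (
    "tanimoto",
    "dice",
    "ochiai",
    "simpson",
    "russell_rao",
    "sokal_michener",
    "faith",
    "gower_legendre",
    "rogers_tanimoto",
)

DEFAULT_MEASURE = "tanimoto"


@dataclass(frozen=True)
class BitCounts:
    """The 2x2 contingency of two equal-length bit vectors."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("bit counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def identical(self) -> bool:
        return self.b == 0 and self.c == 0

    def swapped(self) -> "BitCounts":
        return BitCounts(self.a, self.c, self.b, self.d)


def bit_counts(fp_a: Fingerprint, fp_b: Fingerprint) -> BitCounts:
    """Exact contingency counts of two fingerprints of matching type/length."""
    if fp_a.fp_type != fp_b.fp_type:
        raise FingerprintMismatchError(
            f"fingerprint types differ: {fp_a.fp_type!r} vs {fp_b.fp_type!r}"
        )
    if fp_a.length != fp_b.length:
        raise FingerprintMismatchError(
            f"fingerprint lengths differ: {fp_a.length} vs {fp_b.length}"
        )
    x, y = fp_a.bits, fp_b.bits
    a = int(np.count_nonzero(x & y))
    b = int(np.count_nonzero(x & ~y))
    c = int(np.count_nonzero(~x & y))
    d = int(np.count_nonzero(~x & ~y))
    return BitCounts(a, b, c, d)


def _ratio(num: float, den: float, counts: BitCounts) -> float:
    if den == 0:
        return 1.0 if counts.identical else 0.0
    return num / den


def _tanimoto(t: BitCounts) -> float:
    return _ratio(t.a, t.a + t.b + t.c, t)


def _tanimoto_printed(t: BitCounts) -> float:
    # (a+b)+(a+c)-c = 2a+b
    return _ratio(t.a, 2 * t.a + t.b, t)


def _dice(t: BitCounts) -> float:
    return _ratio(2 * t.a, 2 * t.a + t.b + t.c, t)


def _ochiai(t: BitCounts) -> float:
    return _ratio(t.a, math.sqrt((t.a + t.b) * (t.a + t.c)), t)


def _simpson(t: BitCounts) -> float:
    return _ratio(t.a, min(t.a + t.b, t.a + t.c), t)


def _russell_rao(t: BitCounts) -> float:
    return _ratio(t.a, t.n, t)


def _sokal_michener(t: BitCounts) -> float:
    return _ratio(t.a + t.d, t.n, t)


def _faith(t: BitCounts) -> float:
    return _ratio(t.a + 0.5 * t.d, t.n, t)


def _gower_legendre(t: BitCounts) -> float:
    return _ratio(t.a + t.d, t.a + 0.5 * (t.b + t.c) + t.d, t)


def _rogers_tanimoto(t: BitCounts) -> float:
    return _ratio(t.a + t.d, t.a + 2 * (t.b + t.c) + t.d, t)


_MEASURE_FUNCS = {
    "tanimoto": _tanimoto,
    "dice": _dice,
    "ochiai": _ochiai,
    "simpson": _simpson,
    "russell_rao": _russell_rao,
    "sokal_michener": _sokal_michener,
    "faith": _faith,
    "gower_legendre": _gower_legendre,
    "rogers_tanimoto": _rogers_tanimoto,
    "tanimoto_printed": _tanimoto_printed,  # audit variant, not canonical
}


def similarity(counts: BitCounts, measure: str = DEFAULT_MEASURE) -> float:
    """Evaluate one measure on a contingency; result is always in [0, 1]."""
    try:
        func = _MEASURE_FUNCS[measure]
    except KeyError:
        raise UnknownMeasureError(
            f"unknown measure {measure!r}; valid names: {list(MEASURES)}"
        ) from None
    if counts.identical:
        return 1.0
    return func(counts)


def fingerprint_similarity(
    fp_a: Fingerprint, fp_b: Fingerprint, measure: str = DEFAULT_MEASURE
) -> float:
    return similarity(bit_counts(fp_a, fp_b), measure)
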