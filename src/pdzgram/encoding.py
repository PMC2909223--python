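"""Reduced-alphabet encoding of protein sequences into n-gram frequency vectors.

The 20 standard amino acids are grouped into seven classes by side-chain
volume and dipole moment, so that residues with similar electrostatic and
hydrophobic character share a class:

====== ============== =====================================
class  residues       character
====== ============== =====================================
1      A, G, V        small, apolar
2      I, L, F, P     large, apolar
3      Y, M, T, S     large, weakly polar
4      H, N, Q, W     large, polar
5      R, K           large, positively charged
6      D, E           large, negatively charged
7      C              cysteine (kept apart: disulfides)
====== ============== =====================================

A sequence of length ``L`` over this alphabet yields ``L - n + 1``
overlapping n-grams; the feature vector of a sequence is the normalized
count of every possible n-gram (49 bigrams, 343 trigrams), indexed
lexicographically over class digits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AA_CLASS",
    "CLASS_MEMBERS",
    "InvalidResidueError",
    "SequenceTooShortError",
    "ReducedSequence",
    "NGramVector",
    "reduce_residue",
    "reduce_sequence",
    "enumerate_ngrams",
    "ngram_frequency_vector",
    "gram_index",
    "gram_label",
    "feature_names",
]

#: Amino-acid letter -> reduced class digit (1..7).
AA_CLASS: dict[str, int] = {
    "A": 1, "G": 1, "V": 1,
    "I": 2, "L": 2, "F": 2, "P": 2,
    "Y": 3, "M": 3, "T": 3, "S": 3,
    "H": 4, "N": 4, "Q": 4, "W": 4,
    "R": 5, "K": 5,
    "D": 6, "E": 6,
    "C": 7,
}

#: Reduced class digit -> member residues (informational).
CLASS_MEMBERS: dict[int, str] = {
    1: "AGV", 2: "ILFP", 3: "YMTS", 4: "HNQW", 5: "RK", 6: "DE", 7: "C",
}

#: Placeholder digit used for ambiguous residues when masking is requested.
_AMBIGUOUS = "0"


class InvalidResidueError(ValueError):
    """A residue outside the 20 standard amino acids was encountered."""

    def __init__(self, residue: str, position: int | None = None, seq_id: str | None = None):
        self.residue = residue
        self.position = position
        self.seq_id = seq_id
        where = "" if position is None else f" at position {position}"
        ident = "" if seq_id is None else f" in sequence '{seq_id}'"
        super().__init__(f"invalid residue {residue!r}{where}{ident}: not a standard amino acid")


class SequenceTooShortError(ValueError):
    """Sequence shorter than the n-gram window, so no frequencies exist."""


@dataclass(frozen=True)
class ReducedSequence:
    """A sequence mapped onto the 7-class alphabet.

    ``digits`` is a string over ``{1..7}`` (or ``0`` marking masked
    ambiguous residues), one digit per source residue.
    """

    id: str
    digits: str
    source_length: int

    def __post_init__(self) -> None:
        if len(self.digits) != self.source_length:
            raise ValueError("digits length must equal source_length")


@dataclass(frozen=True)
class NGramVector:
    """Normalized n-gram frequency vector of one sequence.

    ``values`` has length ``7**n`` and sums to 1 for any sequence long
    enough to contain at least one window.
    """

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.n not in (2, 3):
            raise ValueError(f"n must be 2 or 3, got {self.n}")
        if len(self.values) != 7 ** self.n:
            raise ValueError(f"expected {7 ** self.n} values, got {len(self.values)}")


def reduce_residue(aa: str) -> int:
    """Map one amino-acid letter (case-insensitive) to its class digit."""
    try:
        return AA_CLASS[aa.upper()]
    except KeyError:
        raise InvalidResidueError(aa) from None


def reduce_sequence(residues: str, seq_id: str = "", *, ambiguous: str = "error") -> ReducedSequence:
    """Reduce a full sequence to class digits.

    Parameters
    ----------
    residues:
        Amino-acid string; lower case is accepted.
    ambiguous:
        ``"error"`` (default) raises :class:`InvalidResidueError` on any
        non-standard letter (X, B, Z, U, J, O, gaps...); ``"mask"`` replaces
        it with the digit ``0`` so downstream window counting can skip it.
    """
    if ambiguous not in ("error", "mask"):
        raise ValueError(f"ambiguous must be 'error' or 'mask', got {ambiguous!r}")
    out = []
    for pos, aa in enumerate(residues):
        cls = AA_CLASS.get(aa.upper())
        if cls is None:
            if ambiguous == "error":
                raise InvalidResidueError(aa, position=pos, seq_id=seq_id or None)
            out.append(_AMBIGUOUS)
        else:
            out.append(str(cls))
    return ReducedSequence(id=seq_id, digits="".join(out), source_length=len(residues))


def enumerate_ngrams(digits: str, n: int) -> list[str]:
    """All consecutive length-``n`` windows of a digit string, in order.

    Returns the empty list when the string is shorter than ``n``.
    """
    if n not in (2, 3):
        raise ValueError(f"n must be 2 or 3, got {n}")
    return [digits[i:i + n] for i in range(len(digits) - n + 1)]


def ngram_frequency_vector(reduced: ReducedSequence, n: int) -> NGramVector:
    """Normalized n-gram counts of a reduced sequence.

    Each window's count is divided by the number of windows counted, so the
    vector sums to 1. Windows containing a masked ambiguous residue (digit
    ``0``) are dropped and the normalization runs over the remaining
    windows only.
    """
    grams = enumerate_ngrams(reduced.digits, n)
    grams = [g for g in grams if _AMBIGUOUS not in g]
    if not grams:
        raise SequenceTooShortError(
            f"sequence '{reduced.id}' has no valid {n}-gram window "
            f"(length {reduced.source_length})"
        )
    values = np.zeros(7 ** n)
    for g in grams:
        values[gram_index(g)] += 1.0
    values /= len(grams)
    return NGramVector(n=n, values=values)


def gram_index(gram: str) -> int:
    """Lexicographic index of a digit gram: ``c1c2c3 -> 49(c1-1) + 7(c2-1) + (c3-1)``."""
    if len(gram) not in (2, 3):
        raise ValueError(f"gram must have length 2 or 3, got {gram!r}")
    idx = 0
    for ch in gram:
        if ch not in "1234567":
            raise ValueError(f"gram digit out of range in {gram!r}")
        idx = idx * 7 + (int(ch) - 1)
    return idx


def gram_label(index: int, n: int) -> str:
    """Inverse of :func:`gram_index`."""
    if n not in (2, 3):
        raise ValueError(f"n must be 2 or 3, got {n}")
    if not 0 <= index < 7 ** n:
        raise ValueError(f"index {index} out of range for n={n}")
    digits = []
    for _ in range(n):
        digits.append(str(index % 7 + 1))
        index //= 7
    return "".join(reversed(digits))


def feature_names(n: int, prefix: str) -> list[str]:
    """Serialized feature names, e.g. ``pdz_tg_111`` ... ``pep_bg_77``."""
    tag = "tg" if n == 3 else "bg"
    return [f"{prefix}_{tag}_{gram_label(i, n)}" for i in range(7 ** n)]
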