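"""Information-redundancy and composition statistics of coding sequences.

The "genetic language" view treats a coding sequence as text: its
vocabulary is the base composition, its phraseology the adjacent-base
dependence.  Three statistics capture this:

* ``D1 = 2 + Σ_i p_i log2 p_i`` — single-base information redundancy, i.e.
  2 bits minus the Shannon entropy of the base composition.  0 for a
  uniform composition, 2 for a single-base sequence.
* ``D2 = −2 Σ_i p_i log2 p_i + Σ_ij p_ij log2 p_ij`` — adjacent-base
  related information redundancy, approximately the mutual information
  between a base and its successor.  ``p_ij`` is the overlapping
  dinucleotide frequency.
* ``C_GC = (N_G + N_C) / N`` — GC content.

Each statistic is also computed on the three codon-position subsequences
(all first-codon-position bases in order, etc.), giving the 12-parameter
set CGC, D1, D2, CGC1, D11, D21, CGC2, D12, D22, CGC3, D13, D23.

Estimation conventions: plain frequency estimates without pseudocounts;
``0·log2 0 := 0``; dinucleotide counts are overlapping on the linear
(non-circular) sequence with denominator N−1, while single-base
probabilities use all N bases.  Because the marginals of the pair
distribution then differ slightly from the single-base distribution at the
sequence ends, D2 can be marginally negative for short sequences; this is
the literal reading of the defining equations and is left as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import (
    AmbiguousBaseError,
    EmptySequenceError,
    FramingError,
    SequenceTooShortError,
)
from .sequence_io import BASES, PARAMETER_COLUMNS, StudyDataset

__all__ = [
    "BaseComposition",
    "DinucleotideComposition",
    "ParameterSet",
    "base_probabilities",
    "d1",
    "dinucleotide_probabilities",
    "d2",
    "gc_content",
    "codon_subsequences",
    "parameter_set",
    "compute_parameter_table",
]

# byte value -> base index (A=0, C=1, G=2, U=3); 255 marks a foreign byte
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        raise AmbiguousBaseError(
            "sequence not normalized to {A,C,G,U}; call normalize_sequence first"
        )
    return codes


@dataclass(frozen=True)
class BaseComposition:
    """Base probabilities p_i (i = A, C, G, U) and the count they came from."""

    p: Mapping[str, float]
    n: int


@dataclass(frozen=True)
class DinucleotideComposition:
    """Overlapping dinucleotide probabilities p_ij over the 16 ordered pairs."""

    p2: Mapping[tuple[str, str], float]
    n_pairs: int


@dataclass(frozen=True)
class ParameterSet:
    """The 12 per-sequence statistics, in the fixed reporting order."""

    cgc: float
    d1: float
    d2: float
    cgc1: float
    d11: float
    d21: float
    cgc2: float
    d12: float
    d22: float
    cgc3: float
    d13: float
    d23: float

    def to_dict(self) -> dict[str, float]:
        vals = (
            self.cgc, self.d1, self.d2,
            self.cgc1, self.d11, self.d21,
            self.cgc2, self.d12, self.d22,
            self.cgc3, self.d13, self.d23,
        )
        return dict(zip(PARAMETER_COLUMNS, vals))


def _base_probs(seq: str) -> np.ndarray:
    if not seq:
        raise EmptySequenceError("empty sequence")
    codes = _encode(seq)
    return np.bincount(codes, minlength=4) / codes.size


def _pair_probs(seq: str) -> np.ndarray:
    if len(seq) < 2:
        raise SequenceTooShortError("need at least 2 bases for dinucleotides")
    codes = _encode(seq)
    pairs = 4 * codes[:-1].astype(np.intp) + codes[1:]
    return np.bincount(pairs, minlength=16) / (codes.size - 1)


def _plogp(p: np.ndarray) -> float:
    """Σ p log2 p with the convention 0·log2 0 = 0."""
    nz = p[p > 0]
    return float(np.sum(nz * np.log2(nz)))


def base_probabilities(seq: str) -> BaseComposition:
    """Empirical base probabilities p_i = count(i)/N; absent bases get 0."""
    p = _base_probs(seq)
    return BaseComposition(p=dict(zip(BASES, map(float, p))), n=len(seq))


def dinucleotide_probabilities(seq: str) -> DinucleotideComposition:
    """Overlapping adjacent-pair probabilities, denominator N−1."""
    p2 = _pair_probs(seq)
    mapping = {
        (BASES[i], BASES[j]): float(p2[4 * i + j])
        for i in range(4)
        for j in range(4)
    }
    return DinucleotideComposition(p2=mapping, n_pairs=len(seq) - 1)


def d1(seq: str) -> float:
    """Single-base information redundancy, in bits; always in [0, 2]."""
    return 2.0 + _plogp(_base_probs(seq))


def d2(seq: str) -> float:
    """Adjacent-base related information redundancy, in bits."""
    p = _base_probs(seq)
    if len(seq) < 2:
        raise SequenceTooShortError("need at least 2 bases for D2")
    p2 = _pair_probs(seq)
    return -2.0 * _plogp(p) + _plogp(p2)


def gc_content(seq: str) -> float:
    """Fraction of G and C bases."""
    p = _base_probs(seq)
    return float(p[1] + p[2])  # C and G indices in BASES order


def codon_subsequences(seq: str) -> tuple[str, str, str]:
    """Split a framed sequence into its three codon-position subsequences.

    Subsequence k is the concatenation, in codon order, of the position-k
    base of every codon; each has length N/3 and together they partition
    the bases of the input.
    """
    if len(seq) % 3 != 0:
        raise FramingError(f"length {len(seq)} is not a codon multiple")
    if len(seq) < 6:
        raise FramingError("need at least 2 codons")
    return seq[0::3], seq[1::3], seq[2::3]


def parameter_set(seq: str) -> ParameterSet:
    """Compute all 12 statistics for one framed, normalized sequence."""
    s1, s2, s3 = codon_subsequences(seq)
    return ParameterSet(
        cgc=gc_content(seq), d1=d1(seq), d2=d2(seq),
        cgc1=gc_content(s1), d11=d1(s1), d21=d2(s1),
        cgc2=gc_content(s2), d12=d1(s2), d22=d2(s2),
        cgc3=gc_content(s3), d13=d1(s3), d23=d2(s3),
    )


def compute_parameter_table(dataset: StudyDataset):
    """Per-protein parameter table: one row per record, id + 12 columns."""
    import pandas as pd

    rows = []
    for rec in dataset:
        row = {"id": rec.id}
        row.update(parameter_set(rec.sequence).to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", *PARAMETER_COLUMNS])
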