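"""Motif models: position and dinucleotide weight matrices.

A :class:`Pwm` stores per-position nucleotide probabilities estimated from an
aligned set of binding sites with an additive pseudocount (a flat Dirichlet
prior).  A :class:`Dwm` additionally stores, for every ordered pair of
positions ``i < j``, a 4x4 joint probability table over the dinucleotide at
those positions; the prior for the joint tables is the outer product of the
corresponding marginal columns, scaled to a total prior mass (16 by default,
one unit per dinucleotide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
_CODES = {c: i for i, c in enumerate(NUCLEOTIDES)}
_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")
#: integer-code complement (A<->T, C<->G, N->N)
COMPLEMENT_CODES = np.array([3, 2, 1, 0, 4], dtype=np.int8)


@dataclass(frozen=True)
class Alphabet:
    """The nucleotide alphabet with its complement map."""

    symbols: tuple[str, ...] = ("A", "C", "G", "T")
    complement: Mapping[str, str] = field(
        default_factory=lambda: {"A": "T", "T": "A", "C": "G", "G": "C"}
    )

    def __post_init__(self) -> None:
        if len(self.symbols) != 4 or len(set(self.symbols)) != 4:
            raise ValueError("alphabet must contain exactly 4 distinct symbols")
        for s in self.symbols:
            if self.complement[self.complement[s]] != s:
                raise ValueError("complement map must be an involution")


DNA = Alphabet()


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes (A,C,G,T -> 0..3, other -> 4)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, 4, dtype=np.int8)
    for ch, code in _CODES.items():
        out[raw == ord(ch)] = code
    return out


def decode(codes: Iterable[int]) -> str:
    return "".join("ACGTN"[c] for c in codes)


def reverse_complement_seq(seq: str) -> str:
    return seq.upper().translate(_COMP_TABLE)[::-1]


@dataclass
class SiteAlignment:
    """A gapless alignment of equal-length binding-site sequences."""

    sequences: list[str]
    source_ids: list[str] | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.sequences:
            inferred = len(self.sequences[0])
            if self.length is None:
                self.length = inferred
        elif self.length is None:
            raise ValueError("an empty alignment requires an explicit length")
        for k, s in enumerate(self.sequences):
            label = self.source_ids[k] if self.source_ids else f"#{k}"
            if len(s) != self.length:
                raise ValueError(
                    f"sequence {label} has length {len(s)}, expected {self.length}"
                )
            codes = encode(s)
            if (codes > 3).any():
                bad = s[int(np.argmax(codes > 3))]
                raise ValueError(
                    f"sequence {label} contains non-ACGT character {bad!r}: {s!r}"
                )
        if self.source_ids is not None and len(self.source_ids) != len(self.sequences):
            raise ValueError("source_ids must match sequences one-to-one")

    @property
    def count(self) -> int:
        return len(self.sequences)

    def codes(self) -> np.ndarray:
        """Integer-coded alignment as an (N, L) array."""
        if not self.sequences:
            return np.zeros((0, self.length), dtype=np.int8)
        return np.stack([encode(s) for s in self.sequences])


@dataclass
class Pwm:
    """Per-position nucleotide probability table (rows sum to 1)."""

    probs: np.ndarray  # (L, 4) in A C G T order
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("Pwm probabilities must be an (L, 4) table with L >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if np.any(self.probs < 0):
            raise ValueError("Pwm probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every Pwm row must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)

    @property
    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[a] for a in self.probs.argmax(axis=1))


@dataclass
class BackgroundModel:
    """Genome-wide mononucleotide frequencies."""

    probs: np.ndarray  # (4,) in A C G T order

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4,):
            raise ValueError("background must give exactly 4 probabilities")
        if np.any(self.probs < 0):
            raise ValueError("background probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("background probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "BackgroundModel":
        counts = np.zeros(4)
        for seq in sequences:
            codes = encode(seq)
            counts += np.bincount(codes[codes <= 3], minlength=4)[:4]
        if counts.sum() == 0:
            return cls.uniform()
        return cls(counts / counts.sum())

    @cached_property
    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)


@dataclass
class Dwm:
    """Joint dinucleotide probability tables for every position pair.

    Only tables for ``i < j`` are stored; access for ``i > j`` goes through the
    symmetry convention ``pair(i, j)[a, b] == pair(j, i)[b, a]``.
    """

    marginal: Pwm
    pairs: dict[tuple[int, int], np.ndarray]  # (i, j) with i < j -> 4x4 joint
    prior_mass: float = 16.0

    def __post_init__(self) -> None:
        L = self.marginal.length
        if self.prior_mass <= 0:
            raise ValueError("prior_mass must be positive")
        expected = {(i, j) for i in range(L) for j in range(i + 1, L)}
        if set(self.pairs) != expected:
            raise ValueError("Dwm must store one table per ordered pair i < j")
        for key, table in self.pairs.items():
            table = np.asarray(table, dtype=float)
            self.pairs[key] = table
            if table.shape != (4, 4) or np.any(table < 0):
                raise ValueError(f"pair table {key} must be a non-negative 4x4 table")
            if abs(table.sum() - 1.0) > 1e-9:
                raise ValueError(f"pair table {key} must sum to 1")

    @property
    def length(self) -> int:
        return self.marginal.length

    def pair(self, i: int, j: int) -> np.ndarray:
        """Joint table for positions (i, j); transposed view when i > j."""
        if i == j:
            raise ValueError("pair tables are defined for distinct positions only")
        if i < j:
            return self.pairs[(i, j)]
        return self.pairs[(j, i)].T

    @cached_property
    def log_pair_tensor(self) -> np.ndarray:
        """Full (L, L, 4, 4) log joint tensor; the diagonal is zero-filled."""
        L = self.length
        lp = np.zeros((L, L, 4, 4))
        with np.errstate(divide="ignore"):
            for (i, j), table in self.pairs.items():
                logt = np.log(table)
                lp[i, j] = logt
                lp[j, i] = logt.T
        return lp


def nucleotide_counts(codes: np.ndarray, length: int) -> np.ndarray:
    """Per-column nucleotide counts, an (L, 4) array."""
    counts = np.zeros((length, 4))
    for i in range(length):
        counts[i] = np.bincount(codes[:, i], minlength=4)[:4]
    return counts


def dinucleotide_counts(codes: np.ndarray, length: int) -> np.ndarray:
    """Joint counts m[i, j, a, b] for i < j (other entries left zero)."""
    m = np.zeros((length, length, 4, 4))
    for i in range(length):
        col_i = codes[:, i].astype(np.int64)
        for j in range(i + 1, length):
            idx = col_i * 4 + codes[:, j]
            m[i, j] = np.bincount(idx, minlength=16).reshape(4, 4)
    return m


def pwm_from_counts(counts: np.ndarray, n: int, pseudocount: float = 1.0) -> Pwm:
    if pseudocount <= 0 and n == 0:
        raise ValueError("need a positive pseudocount for an empty alignment")
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return Pwm(probs, pseudocount=pseudocount)


def build_pwm(alignment: SiteAlignment, pseudocount: float = 1.0) -> Pwm:
    """Estimate a Pwm with probabilities (n_count + k) / (N + 4k)."""
    codes = alignment.codes()
    counts = nucleotide_counts(codes, alignment.length)
    return pwm_from_counts(counts, alignment.count, pseudocount)


def dwm_from_counts(
    pair_counts: np.ndarray,
    counts: np.ndarray,
    n: int,
    pseudocount: float = 1.0,
    prior_mass: float = 16.0,
) -> Dwm:
    """Build a Dwm from joint and marginal count arrays.

    The joint prior for pair (i, j) is the outer product of the marginal
    columns scaled to total mass ``prior_mass``, giving table entries
    ``(m + prior_mass * w_i w_j) / (N + prior_mass)``.
    """
    marginal = pwm_from_counts(counts, n, pseudocount)
    L = marginal.length
    w = marginal.probs
    pairs: dict[tuple[int, int], np.ndarray] = {}
    for i in range(L):
        for j in range(i + 1, L):
            prior = prior_mass * np.outer(w[i], w[j])
            pairs[(i, j)] = (pair_counts[i, j] + prior) / (n + prior_mass)
    return Dwm(marginal=marginal, pairs=pairs, prior_mass=prior_mass)


def build_dwm(
    alignment: SiteAlignment, pseudocount: float = 1.0, prior_mass: float = 16.0
) -> Dwm:
    """Estimate a Dwm; the marginal Pwm is built with the same pseudocount."""
    codes = alignment.codes()
    counts = nucleotide_counts(codes, alignment.length)
    pair_counts = dinucleotide_counts(codes, alignment.length)
    return dwm_from_counts(pair_counts, counts, alignment.count, pseudocount, prior_mass)


def dwm_from_pwm(pwm: Pwm) -> Dwm:
    """Embed a Pwm as a Dwm with exactly independent columns."""
    L = pwm.length
    pairs = {
        (i, j): np.outer(pwm.probs[i], pwm.probs[j])
        for i in range(L)
        for j in range(i + 1, L)
    }
    return Dwm(marginal=pwm, pairs=pairs)


def column_information_content(pwm: Pwm, i: int) -> float:
    """Information content of column i in bits: 2 + sum_a w log2 w."""
    w = pwm.probs[i]
    nz = w[w > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def reverse_complement(model: Pwm | Dwm) -> Pwm | Dwm:
    """The model for the reverse-complement strand (an involution)."""
    if isinstance(model, Pwm):
        return Pwm(model.probs[::-1, ::-1].copy(), pseudocount=model.pseudocount)
    if isinstance(model, Dwm):
        L = model.length
        pairs = {}
        for i in range(L):
            for j in range(i + 1, L):
                # pair'(i,j)[a,b] = pair(L-1-j, L-1-i)[comp(b), comp(a)]
                old = model.pairs[(L - 1 - j, L - 1 - i)]
                pairs[(i, j)] = old[::-1, ::-1].T.copy()
        return Dwm(
            marginal=reverse_complement(model.marginal),
            pairs=pairs,
            prior_mass=model.prior_mass,
        )
    raise TypeError(f"cannot reverse-complement {type(model).__name__}")


def extend_alignment_with_flank(
    alignment_sites: Sequence[tuple[str, int, int, str]],
    genome: Mapping[str, str],
    flank: int,
) -> SiteAlignment:
    """Extract site windows widened by ``flank`` bp on both sides.

    Sites are given as (sequence_id, start, end, strand) with 0-based
    half-open coordinates.  Minus-strand sites are reverse-complemented so the
    alignment is in motif orientation.  Sites whose widened window overruns
    the sequence bounds, or that contain non-ACGT characters, are dropped and
    logged rather than padded.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    sequences: list[str] = []
    ids: list[str] = []
    dropped = 0
    for seq_id, start, end, strand in alignment_sites:
        source = genome[seq_id]
        lo, hi = start - flank, end + flank
        if lo < 0 or hi > len(source):
            dropped += 1
            logger.debug("dropping site %s:%d-%d: flank overruns bounds", seq_id, start, end)
            continue
        window = source[lo:hi].upper()
        if (encode(window) > 3).any():
            dropped += 1
            logger.debug("dropping site %s:%d-%d: non-ACGT content", seq_id, start, end)
            continue
        if strand == "-":
            window = reverse_complement_seq(window)
        sequences.append(window)
        ids.append(seq_id)
    if dropped:
        logger.info("dropped %d of %d sites during flank extension", dropped, len(alignment_sites))
    if not sequences:
        raise ValueError(f"all {len(alignment_sites)} sites were dropped; empty alignment")
    return SiteAlignment(sequences, source_ids=ids)
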