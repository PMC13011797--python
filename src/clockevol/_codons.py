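"""Codon-level constants shared by the simulator, counting methods and ML models.

The sense-codon state space (61 codons under the standard nuclear code) and the
single-nucleotide neighbour structure defined here are the substrate of the
GY94-style rate matrices: a codon substitution has nonzero rate only if it
changes exactly one nucleotide, and its rate is modulated by whether that
change is a transition and whether it changes the encoded amino acid.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: purine/pyrimidine partners; a substitution within a set is a transition
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(n1: str, n2: str) -> bool:
    """True when the single-nucleotide change n1->n2 is a transition."""
    return (n1 in _PURINES and n2 in _PURINES) or (
        n1 in _PYRIMIDINES and n2 in _PYRIMIDINES
    )


def _standard_table() -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[1]


ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)
STOP_CODONS: frozenset[str] = frozenset(_standard_table().stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)  # 61 codons, alphabetical
N_SENSE = len(SENSE_CODONS)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA: tuple[str, ...] = tuple(
    _standard_table().forward_table[c] for c in SENSE_CODONS
)


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for stop, 'X' otherwise (gap/ambiguous)."""
    if codon in CODON_INDEX:
        return CODON_AA[CODON_INDEX[codon]]
    if codon in STOP_CODONS:
        return "*"
    return "X"


@lru_cache(maxsize=1)
def neighbor_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-nucleotide neighbour pairs among sense codons.

    Returns (i, j, is_ts, is_syn): parallel int/bool arrays over ordered codon
    pairs that differ at exactly one position, with transition and synonymy
    flags.  Pairs through stop codons never appear because the state space
    excludes them.
    """
    ii, jj, ts, syn = [], [], [], []
    for a, ca in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == ca[pos]:
                    continue
                cb = ca[:pos] + nt + ca[pos + 1 :]
                b = CODON_INDEX.get(cb)
                if b is None:
                    continue
                ii.append(a)
                jj.append(b)
                ts.append(is_transition(ca[pos], nt))
                syn.append(CODON_AA[a] == CODON_AA[b])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


def encode_codon_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string into codon-state indices.

    Sense codons map to 0..60; anything else (gap-containing codon, ambiguous
    base, stop) maps to -1 and is treated as missing data downstream.
    """
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        out[k] = CODON_INDEX.get(seq[3 * k : 3 * k + 3].upper(), -1)
    return out


def codon_frequencies(kind, aln=None):
    """Stationary codon frequencies over the 61 sense codons.

    Parameters
    ----------
    kind : {"uniform", "F1x4", "F3x4"} or array-like of length 61
    aln : CodonAlignment, required for the empirical F1x4/F3x4 variants.
    """
    if not isinstance(kind, str):
        pi = np.asarray(kind, dtype=float)
        if pi.shape != (N_SENSE,):
            raise ValueError(f"explicit frequencies must have length {N_SENSE}")
        if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
            raise ValueError("explicit frequencies must be a probability vector")
        return pi / pi.sum()
    kind = kind.upper()
    if kind == "UNIFORM":
        return np.full(N_SENSE, 1.0 / N_SENSE)
    if aln is None:
        raise ValueError(f"{kind} frequencies require an alignment")
    # empirical nucleotide counts, per codon position for F3x4
    counts = np.zeros((3, 4))
    for seq in aln.sequences:
        for pos in range(3):
            sub = seq[pos::3]
            for nt, idx in _NT_INDEX.items():
                counts[pos, idx] += sub.count(nt)
    if kind == "F1X4":
        tot = counts.sum(axis=0)
        counts = np.tile(tot / tot.sum(), (3, 1))
    elif kind == "F3X4":
        counts = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown codon frequency model: {kind}")
    pi = np.array(
        [
            counts[0, _NT_INDEX[c[0]]]
            * counts[1, _NT_INDEX[c[1]]]
            * counts[2, _NT_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    if pi.sum() <= 0:
        raise ValueError("degenerate codon frequencies (empty alignment?)")
    return pi / pi.sum()
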