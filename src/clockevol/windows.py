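"""Sliding-window divergence (Dxy) and NG86 Ka/Ks tracks over codon alignments.

Dxy is the mean, over all unordered sequence pairs, of the proportion of
differing sites among positions where both sequences carry an unambiguous
base (pairwise deletion).  Ka/Ks uses Nei-Gojobori (1986) counting: each
codon contributes synonymous/nonsynonymous site fractions derived from the
genetic code, differences between codons are partitioned by averaging over
all minimal substitution pathways (pathways through stop codons excluded),
and proportions are Jukes-Cantor corrected.  The gene summary statistic Ka*
is the maximum windowed Ka among windows with few gaps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._codons import (
    CODON_AA,
    CODON_INDEX,
    NUCLEOTIDES,
    SENSE_CODONS,
    is_transition,
    translate_codon,
)
from .errors import ConfigurationError, DegenerateAlignmentError
from .io_core import CodonAlignment

DEFAULT_KA_STAR_GAP_FRACTION = 1000 / 6630  # "few gaps" cutoff, as a fraction

# ---------------------------------------------------------------------------
# NG86 primitives


@lru_cache(maxsize=1)
def _syn_site_fractions() -> np.ndarray:
    """Synonymous site count per sense codon (0..3; N + S = 3 always).

    Changes producing stop codons count as nonsynonymous so that site counts
    are conserved.
    """
    out = np.zeros(len(SENSE_CODONS))
    for idx, codon in enumerate(SENSE_CODONS):
        syn = 0.0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt in CODON_INDEX and CODON_AA[CODON_INDEX[alt]] == CODON_AA[idx]:
                    syn += 1.0
        out[idx] = syn / 3.0
    return out


@lru_cache(maxsize=1)
def _pair_difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """(Nd, Sd) tables over ordered sense-codon pairs.

    Multi-difference pairs are averaged over all minimal substitution
    pathways; pathways passing through a stop codon are excluded (with a
    fallback to all pathways if every one is blocked).
    """
    n = len(SENSE_CODONS)
    nd = np.zeros((n, n))
    sd = np.zeros((n, n))
    for a, ca in enumerate(SENSE_CODONS):
        for b, cb in enumerate(SENSE_CODONS):
            if a == b:
                continue
            positions = [k for k in range(3) if ca[k] != cb[k]]
            path_counts = []
            for order in itertools.permutations(positions):
                cur = ca
                nsyn = nnon = 0.0
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if nxt not in CODON_INDEX:
                        blocked = True
                        break
                    if CODON_AA[CODON_INDEX[cur]] == CODON_AA[CODON_INDEX[nxt]]:
                        nsyn += 1
                    else:
                        nnon += 1
                    cur = nxt
                path_counts.append((blocked, nsyn, nnon))
            valid = [(s, x) for bl, s, x in path_counts if not bl]
            if not valid:  # every pathway runs through a stop; use them all
                valid = [(s, x) for _, s, x in path_counts]
            sd[a, b] = np.mean([s for s, _ in valid])
            nd[a, b] = np.mean([x for _, x in valid])
    return nd, sd


class NG86Result(NamedTuple):
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    omega: float  # nan when masked (Ks = 0 or JC argument out of range)
    n_codons: int  # codon pairs actually compared


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; nan outside the admissible range."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return np.nan
    return -0.75 * np.log(arg)


def _encode_for_ng86(seq: str) -> np.ndarray:
    out = np.full(len(seq) // 3, -1, dtype=np.int64)
    for k in range(len(seq) // 3):
        out[k] = CODON_INDEX.get(seq[3 * k : 3 * k + 3], -1)
    return out


def ng86_from_codes(codes_i: np.ndarray, codes_j: np.ndarray) -> NG86Result:
    valid = (codes_i >= 0) & (codes_j >= 0)
    syn_frac = _syn_site_fractions()
    nd_t, sd_t = _pair_difference_tables()
    a, b = codes_i[valid], codes_j[valid]
    S = float((syn_frac[a] + syn_frac[b]).sum() / 2.0)
    n_cmp = int(valid.sum())
    N = 3.0 * n_cmp - S
    Nd = float(nd_t[a, b].sum())
    Sd = float(sd_t[a, b].sum())
    pN = Nd / N if N > 0 else np.nan
    pS = Sd / S if S > 0 else np.nan
    Ka = jukes_cantor(pN) if np.isfinite(pN) else np.nan
    Ks = jukes_cantor(pS) if np.isfinite(pS) else np.nan
    omega = Ka / Ks if np.isfinite(Ka) and np.isfinite(Ks) and Ks > 0 else np.nan
    return NG86Result(N, S, Nd, Sd, pN, pS, Ka, Ks, omega, n_cmp)


def ng86_pair(codons_i: str, codons_j: str) -> NG86Result:
    """Nei-Gojobori counting between two equal-length in-frame codon strings.

    Codon pairs containing gaps, ambiguity or stops are skipped entirely
    (excluded from site counts and difference counts).
    """
    if len(codons_i) != len(codons_j):
        raise ConfigurationError("sequences must have equal length")
    if len(codons_i) % 3:
        raise ConfigurationError("sequence length must be divisible by 3")
    return ng86_from_codes(_encode_for_ng86(codons_i.upper()), _encode_for_ng86(codons_j.upper()))


# ---------------------------------------------------------------------------
# window tracks


@dataclass
class WindowTrack:
    """Per-window statistic series; windows are 0-based half-open nt spans."""

    gene_id: str
    statistic: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray  # nan = masked
    n_valid_pairs: np.ndarray
    gap_fraction: np.ndarray
    mask_reason: list[str]

    def __len__(self):
        return len(self.starts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_id,
                "start": self.starts,
                "end": self.ends,
                "stat": self.statistic,
                "value": self.values,
                "n_valid_pairs": self.n_valid_pairs,
                "gap_fraction": self.gap_fraction,
                "mask_reason": self.mask_reason,
            }
        )


def _window_spans(length: int, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    if window < 1 or step < 1:
        raise ConfigurationError("window and step must be >= 1")
    if window > length:
        raise ConfigurationError(f"window {window} exceeds alignment length {length}")
    starts = np.arange(0, length - window + 1, step)
    return starts, starts + window


def _gap_fractions(aln: CodonAlignment, starts, ends) -> np.ndarray:
    chars = aln.char_matrix()
    isgap = (chars == "-").sum(axis=0).astype(float)
    cum = np.concatenate([[0.0], np.cumsum(isgap)])
    return (cum[ends] - cum[starts]) / ((ends - starts) * aln.n_taxa)


def _sequence_pairs(aln: CodonAlignment, reference: str | None):
    """All unordered pairs, or only pairs involving a reference species."""
    if reference is None:
        return list(itertools.combinations(range(aln.n_taxa), 2))
    r = aln.taxa.index(reference)
    return [(r, j) for j in range(aln.n_taxa) if j != r]


def sliding_dxy(
    aln: CodonAlignment,
    window_nt: int = 180,
    step_nt: int = 6,
    min_coverage: float = 0.5,
    reference: str | None = None,
) -> WindowTrack:
    """Average pairwise nucleotide divergence in sliding windows.

    A window is masked when the mean number of comparable (both-unambiguous)
    positions per pair drops below ``min_coverage`` of the window length.
    """
    if aln.n_taxa < 2:
        raise DegenerateAlignmentError("Dxy needs at least 2 sequences")
    starts, ends = _window_spans(aln.length_nt, window_nt, step_nt)
    chars = aln.char_matrix()
    codes = np.full(chars.shape, -1, dtype=np.int8)
    for v, nt in enumerate("ACGT"):
        codes[chars == nt] = v

    pairs = _sequence_pairs(aln, reference)
    n_win = len(starts)
    sum_ratio = np.zeros(n_win)
    n_valid = np.zeros(n_win, dtype=int)
    mean_compared = np.zeros(n_win)
    for i, j in pairs:
        both = (codes[i] >= 0) & (codes[j] >= 0)
        diff = both & (codes[i] != codes[j])
        cum_b = np.concatenate([[0], np.cumsum(both)])
        cum_d = np.concatenate([[0], np.cumsum(diff)])
        compared = cum_b[ends] - cum_b[starts]
        mism = cum_d[ends] - cum_d[starts]
        ok = compared > 0
        sum_ratio[ok] += mism[ok] / compared[ok]
        n_valid += ok
        mean_compared += compared
    mean_compared /= len(pairs)

    values = np.where(n_valid > 0, sum_ratio / np.maximum(n_valid, 1), np.nan)
    mask = mean_compared < min_coverage * window_nt
    values[mask] = np.nan
    reasons = [
        "low_coverage" if m else ("no_valid_pairs" if v == 0 else "")
        for m, v in zip(mask, n_valid)
    ]
    return WindowTrack(
        aln.gene_id, "Dxy", starts, ends, values, n_valid,
        _gap_fractions(aln, starts, ends), reasons,
    )


def _pairwise_site_arrays(aln: CodonAlignment, reference: str | None = None):
    """Per-pair per-codon NG86 site/difference arrays, for window cumsums."""
    syn_frac = _syn_site_fractions()
    nd_t, sd_t = _pair_difference_tables()
    codes = np.stack([_encode_for_ng86(s) for s in aln.sequences])
    pairs = _sequence_pairs(aln, reference)
    out = []
    for i, j in pairs:
        a, b = codes[i], codes[j]
        valid = (a >= 0) & (b >= 0)
        av, bv = np.where(valid, a, 0), np.where(valid, b, 0)
        s_sites = np.where(valid, (syn_frac[av] + syn_frac[bv]) / 2.0, 0.0)
        n_sites = np.where(valid, 3.0 - s_sites, 0.0)
        nd = np.where(valid, nd_t[av, bv], 0.0)
        sd = np.where(valid, sd_t[av, bv], 0.0)
        out.append((valid.astype(float), n_sites, s_sites, nd, sd))
    return pairs, out


def sliding_kaks(
    aln: CodonAlignment,
    window_nt: int = 150,
    step_nt: int = 6,
    min_pair_fraction: float = 0.25,
    reference: str | None = None,
) -> tuple[WindowTrack, WindowTrack, WindowTrack]:
    """NG86 Ka, Ks and omega tracks in codon-aligned sliding windows.

    Per window each statistic is the mean over sequence pairs of the per-pair
    NG86 value; omega is the mean of per-pair omegas over pairs with a valid
    (positive, JC-correctable) Ks and is masked when fewer than
    ``min_pair_fraction`` of pairs qualify.
    """
    if window_nt % 3:
        raise ConfigurationError("window must be divisible by 3 (codon-aligned)")
    if aln.n_taxa < 2:
        raise DegenerateAlignmentError("Ka/Ks needs at least 2 sequences")
    starts, ends = _window_spans(aln.length_nt, window_nt, step_nt)
    # restrict to codon-aligned starts so windows hold whole codons
    keep = (starts % 3) == 0
    starts, ends = starts[keep], ends[keep]
    cs, ce = starts // 3, ends // 3

    pairs, arrays = _pairwise_site_arrays(aln, reference)
    n_win = len(starts)
    ka_sum = np.zeros(n_win); ka_n = np.zeros(n_win, dtype=int)
    ks_sum = np.zeros(n_win); ks_n = np.zeros(n_win, dtype=int)
    om_sum = np.zeros(n_win); om_n = np.zeros(n_win, dtype=int)
    for valid, n_sites, s_sites, nd, sd in arrays:
        cums = [np.concatenate([[0.0], np.cumsum(x)]) for x in (n_sites, s_sites, nd, sd)]
        N = cums[0][ce] - cums[0][cs]
        S = cums[1][ce] - cums[1][cs]
        Nd = cums[2][ce] - cums[2][cs]
        Sd = cums[3][ce] - cums[3][cs]
        with np.errstate(divide="ignore", invalid="ignore"):
            pN = np.where(N > 0, Nd / np.maximum(N, 1e-12), np.nan)
            pS = np.where(S > 0, Sd / np.maximum(S, 1e-12), np.nan)
            ka = -0.75 * np.log(1.0 - 4.0 * pN / 3.0)
            ks = -0.75 * np.log(1.0 - 4.0 * pS / 3.0)
        ka[~np.isfinite(ka)] = np.nan
        ks[~np.isfinite(ks)] = np.nan
        ok_a = np.isfinite(ka)
        ok_s = np.isfinite(ks)
        ka_sum[ok_a] += ka[ok_a]; ka_n += ok_a
        ks_sum[ok_s] += ks[ok_s]; ks_n += ok_s
        ok_o = ok_a & ok_s & (ks > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            om_sum[ok_o] += (ka / ks)[ok_o]
        om_n += ok_o

    npairs = len(pairs)
    gapf = _gap_fractions(aln, starts, ends)

    def make(name, total, count, min_frac=0.0):
        vals = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        reasons = []
        for k in range(n_win):
            if count[k] == 0:
                reasons.append("no_valid_pairs")
                vals[k] = np.nan
            elif count[k] < min_frac * npairs:
                reasons.append("few_valid_pairs")
                vals[k] = np.nan
            else:
                reasons.append("")
        return WindowTrack(aln.gene_id, name, starts, ends, vals, count, gapf, reasons)

    return (
        make("Ka", ka_sum, ka_n),
        make("Ks", ks_sum, ks_n),
        make("omega", om_sum, om_n, min_pair_fraction),
    )


def gene_wide_ka(aln: CodonAlignment) -> float:
    """Full-length NG86 Ka averaged over all sequence pairs."""
    codes = np.stack([_encode_for_ng86(s) for s in aln.sequences])
    vals = []
    for i, j in itertools.combinations(range(aln.n_taxa), 2):
        r = ng86_from_codes(codes[i], codes[j])
        if np.isfinite(r.Ka):
            vals.append(r.Ka)
    return float(np.mean(vals)) if vals else np.nan


def ka_summary(
    aln: CodonAlignment,
    ka_track: WindowTrack | None = None,
    max_gap_fraction: float = DEFAULT_KA_STAR_GAP_FRACTION,
    window_nt: int = 150,
    step_nt: int = 6,
) -> tuple[float, float]:
    """(gene-wide Ka, Ka*) where Ka* is the max windowed Ka among low-gap windows.

    Ka* is nan (masked) when no window passes the gap filter.
    """
    if ka_track is None:
        ka_track, _, _ = sliding_kaks(aln, window_nt, step_nt)
    if len(ka_track) == 0:
        raise ConfigurationError("empty window track")
    ok = (ka_track.gap_fraction < max_gap_fraction) & np.isfinite(ka_track.values)
    ka_star = float(ka_track.values[ok].max()) if ok.any() else np.nan
    return gene_wide_ka(aln), ka_star
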