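"""CAPS-style detection of correlated amino-acid evolution.

For a protein alignment column, every sequence pair (i, j) receives a score
derived from the BLOSUM62 transition value B(a_i, a_j) of its residue pair,
corrected for the divergence time t_ij of the two species (patristic distance
on the tree, or a Poisson-corrected protein distance when no tree is given).
The correction is applied by detrending: within a column the linear trend of
B on t across sequence pairs is removed, leaving a mean-centred residual
vector theta.  Dividing B by t instead (the classic formulation) makes every
vector proportional to 1/t — close relatives dominate and all column pairs
correlate near 1 — so the detrended residual is used as the time correction
throughout.

Two columns coevolve when their theta vectors correlate across sequence
pairs (Pearson).  Significance comes from an explicit permutation null — the
taxon assignment of one column's residues is reshuffled and the statistic
recomputed — with add-one p-values, Benjamini-Hochberg FDR across all tested
pairs, and a retention rule that also requires the observed |r| to fall in
the top (1 - bootstrap_level) tail of all tested pairs, mirroring the
confidence-level thresholding of the original method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from statsmodels.stats.multitest import multipletests

from ._codons import translate_codon
from .errors import ConfigurationError
from .io_core import CodonAlignment

DEFAULT_EPSILON = 1e-6


def patristic_distances(
    tree: dendropy.Tree, taxa: list[str], epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Symmetric matrix of path-length distances between the named tips.

    Zero distances are floored at ``epsilon``.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ConfigurationError(
                "tree is missing branch lengths; supply lengths or use the NJ fallback"
            )
    pdm = tree.phylogenetic_distance_matrix()
    label_to_taxon = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in label_to_taxon]
    if missing:
        raise ConfigurationError(f"taxa absent from tree: {missing}")
    n = len(taxa)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(label_to_taxon[taxa[i]], label_to_taxon[taxa[j]])
        out[i, j] = out[j, i] = max(d, epsilon)
    return out


def poisson_protein_distances(
    protein: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Poisson-corrected p-distance fallback when no tree is available."""
    n = protein.shape[0]
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        valid = (protein[i] != "-") & (protein[j] != "-")
        if valid.sum() == 0:
            d = epsilon
        else:
            p = float(np.mean(protein[i][valid] != protein[j][valid]))
            d = -np.log(max(1.0 - p, 1e-9))
        out[i, j] = out[j, i] = max(d, epsilon)
    return out


def translate_alignment(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_codons) amino-acid matrix; unresolvable codons become '-'."""
    rows = []
    for seq in aln.sequences:
        aa = [translate_codon(seq[3 * k : 3 * k + 3]) for k in range(aln.n_codons)]
        rows.append(["-" if a in ("X", "*") else a for a in aa])
    return np.array(rows)


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def _blosum_codes():
    m = _blosum62()
    idx = {a: i for i, a in enumerate(m.alphabet)}
    return np.array(m), idx


def _detrend_rows(Y: np.ndarray, valid: np.ndarray, tvec: np.ndarray) -> np.ndarray:
    """Remove each row's linear trend on tvec over its valid entries.

    Invalid entries are zeroed in the output; rows are mean-centred.
    """
    Y = np.atleast_2d(Y)
    valid = np.atleast_2d(valid)
    m = valid.sum(axis=1).astype(float)
    m_safe = np.maximum(m, 1.0)
    Yv = np.where(valid, Y, 0.0)
    Tv = np.where(valid, tvec[None, :], 0.0)
    ybar = Yv.sum(axis=1) / m_safe
    tbar = Tv.sum(axis=1) / m_safe
    Yc = np.where(valid, Y - ybar[:, None], 0.0)
    Tc = np.where(valid, tvec[None, :] - tbar[:, None], 0.0)
    tss = (Tc**2).sum(axis=1)
    slope = np.where(tss > 0, (Yc * Tc).sum(axis=1) / np.where(tss > 0, tss, 1.0), 0.0)
    return Yc - slope[:, None] * Tc


def caps_site_vector(column: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred, time-detrended BLOSUM62 score vector for one column.

    ``column`` holds one residue per taxon ('-' = gap); ``times`` is the
    square divergence-time matrix.  Returns (theta, valid) over the unordered
    sequence pairs in lexicographic order; pairs where either residue is a
    gap are invalid (theta 0, excluded downstream).  Raises when fewer than 3
    valid pairs remain.
    """
    B, idx = _blosum_codes()
    n = len(column)
    iu, ju = np.triu_indices(n, k=1)
    valid = (column[iu] != "-") & (column[ju] != "-")
    if valid.sum() < 3:
        raise ConfigurationError("column untestable: fewer than 3 valid pairs")
    ai = np.array([idx.get(a, idx["X"]) for a in column])
    raw = B[ai[iu], ai[ju]].astype(float)
    theta = _detrend_rows(raw, valid, times[iu, ju])[0]
    return theta, valid


@dataclass(frozen=True)
class CoevolPair:
    protein_a: str
    protein_b: str
    site_a: int  # 1-based alignment column (codon / residue index)
    site_b: int
    r: float
    p: float
    q: float
    n_pairs_used: int


def _perm_p(r_obs, r_perm, n_permutations, one_sided):
    """Add-one permutation p-value, one- or two-sided."""
    if one_sided:
        exceed = np.sum(r_perm >= r_obs - 1e-12)
    else:
        exceed = np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)
    return (1.0 + exceed) / (1.0 + n_permutations)


def _pearson(x, y):
    sx = x - x.mean()
    sy = y - y.mean()
    d = np.sqrt((sx**2).sum() * (sy**2).sum())
    return float((sx * sy).sum() / d) if d > 0 else 0.0


def _testable_columns(protein: np.ndarray, min_variability: int) -> list[int]:
    cols = []
    for k in range(protein.shape[1]):
        col = protein[:, k]
        residues = set(col[col != "-"])
        if len(residues) >= min_variability:
            cols.append(k)
    return cols


def _masked_pearson(x_fixed: np.ndarray, Yc: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Pearson r of x against each (already detrended) row of Yc over valid entries."""
    Xv = np.where(valid, x_fixed[None, :], 0.0)
    m = valid.sum(axis=1).astype(float)
    m_safe = np.maximum(m, 1.0)
    Xc = np.where(valid, Xv - (Xv.sum(axis=1) / m_safe)[:, None], 0.0)
    Yv = np.where(valid, Yc, 0.0)
    Yc2 = np.where(valid, Yv - (Yv.sum(axis=1) / m_safe)[:, None], 0.0)
    num = (Xc * Yc2).sum(axis=1)
    den = np.sqrt((Xc**2).sum(axis=1) * (Yc2**2).sum(axis=1))
    return np.where((den > 0) & (m >= 3), num / np.where(den > 0, den, 1.0), 0.0)


def caps_scan(
    aln_a: CodonAlignment,
    aln_b: CodonAlignment | None = None,
    tree: dendropy.Tree | None = None,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    min_variability: int = 2,
    seed: int = 0,
    fdr: float = 0.05,
    bootstrap_level: float = 0.95,
    is_protein: bool = False,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Scan all inter-protein column pairs for correlated evolution.

    With ``aln_b`` omitted the scan runs intra-protein (all within-alignment
    column pairs).  Permutation p-values use the add-one estimator, either
    two-sided on |r| (default) or one-sided for positive correlation
    (``alternative="greater"``, the directional hypothesis of compensatory
    coevolution); a pair is
    flagged when its BH q < ``fdr``, its raw p passes the (1 - alpha) cut,
    and its |r| lies in the top (1 - bootstrap_level) tail of tested pairs.
    Returns the full pair table (protein_a, site_a, protein_b, site_b, r, p,
    q, n_pairs_used, flagged) sorted by p.
    """
    intra = aln_b is None
    if intra:
        aln_b = aln_a
    shared = [t for t in aln_a.taxa if t in set(aln_b.taxa)]
    if len(shared) < 4:
        raise ConfigurationError("need at least 4 shared taxa")
    a = aln_a.subset(shared)
    b = aln_b.subset(shared) if not intra else a
    prot_a = a.char_matrix() if is_protein else translate_alignment(a)
    prot_b = prot_a if intra else (b.char_matrix() if is_protein else translate_alignment(b))

    if tree is not None:
        times = patristic_distances(tree, shared)
    else:
        times = poisson_protein_distances(
            prot_a if intra else np.concatenate([prot_a, prot_b], axis=1)
        )

    cols_a = _testable_columns(prot_a, min_variability)
    cols_b = cols_a if intra else _testable_columns(prot_b, min_variability)
    if not cols_a or not cols_b:
        raise ConfigurationError("no testable columns")

    n = len(shared)
    iu, ju = np.triu_indices(n, k=1)
    tvec = times[iu, ju]
    B, idx = _blosum_codes()
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])

    def observed(prot, k):
        col = prot[:, k]
        ai = np.array([idx.get(c, idx["X"]) for c in col])
        valid = (col[iu] != "-") & (col[ju] != "-")
        theta = _detrend_rows(B[ai[iu], ai[ju]].astype(float), valid, tvec)[0]
        return theta, valid, ai, col == "-"

    obs_a = {k: observed(prot_a, k) for k in cols_a}
    obs_b = obs_a if intra else {k: observed(prot_b, k) for k in cols_b}

    if alternative not in ("two-sided", "greater"):
        raise ConfigurationError("alternative must be 'two-sided' or 'greater'")
    one_sided = alternative == "greater"
    gap_free = not (np.any(prot_a == "-") or (not intra and np.any(prot_b == "-")))

    rows = []
    for kb in cols_b:
        partners = [ka for ka in cols_a if ka < kb] if intra else cols_a
        if not partners:
            continue
        tb, vb, ai_col, gap_col = obs_b[kb]
        # permutation null for this B column, shared by all its partners
        ai_p = ai_col[perms]
        theta_raw = B[ai_p[:, iu], ai_p[:, ju]].astype(float)
        if gap_free:
            # fast path: detrended vectors are mean-centred, so Pearson r is
            # the inner product of L2-normalised vectors
            theta_p = _detrend_rows(theta_raw, np.ones_like(theta_raw, bool), tvec)
            tpn = theta_p / np.sqrt(
                (theta_p**2).sum(axis=1, keepdims=True) + 1e-300
            )
            tbn = tb / np.sqrt((tb**2).sum() + 1e-300)
            for ka in partners:
                ta, va, _, _ = obs_a[ka]
                tan = ta / np.sqrt((ta**2).sum() + 1e-300)
                r_obs = float(np.clip(tan @ tbn, -1.0, 1.0))
                r_perm = tpn @ tan
                p = _perm_p(r_obs, r_perm, n_permutations, one_sided)
                rows.append((ka + 1, kb + 1, r_obs, p, len(ta)))
            continue
        gap_p = gap_col[perms]
        valid_p = ~gap_p[:, iu] & ~gap_p[:, ju]
        theta_p = _detrend_rows(theta_raw, valid_p, tvec)
        for ka in partners:
            ta, va, _, _ = obs_a[ka]
            both = va & vb
            m = int(both.sum())
            if m < 3:
                continue
            r_obs = float(np.clip(_pearson(ta[both], tb[both]), -1.0, 1.0))
            r_perm = _masked_pearson(ta, theta_p, valid_p & va[None, :])
            p = _perm_p(r_obs, r_perm, n_permutations, one_sided)
            rows.append((ka + 1, kb + 1, r_obs, p, m))

    if not rows:
        raise ConfigurationError("no testable column pairs")
    df = pd.DataFrame(rows, columns=["site_a", "site_b", "r", "p", "n_pairs_used"])
    df.insert(0, "protein_b", aln_b.gene_id)
    df.insert(0, "protein_a", aln_a.gene_id)
    _, qvals, _, _ = multipletests(df["p"].values, method="fdr_bh")
    df["q"] = qvals
    r_cut = df["r"].abs().quantile(bootstrap_level)
    df["flagged"] = (
        (df["q"] < fdr) & (df["p"] <= alpha) & (df["r"].abs() >= r_cut)
    )
    return df.sort_values("p", kind="stable").reset_index(drop=True)
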