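"""Synthetic trees, codon alignments, coevolving columns, and pleiotropy tables.

This module generates the ground-truth worlds every analysis stage is tested
against: Yule trees rescaled to a chosen root-to-tip height, codon alignments
evolved site-by-site under GY94 mixtures (exact Gillespie simulation along
each branch, so the generator and the estimators share one definition of the
process but not one code path), coupled column pairs in which a
nonsynonymous event at one site triggers a compensating nonsynonymous event
at its partner with probability rho, i.i.d. whole-codon gap injection, and
gene tables in which the nonsynonymous rate Ka depends log-linearly on a
negative-binomially distributed pleiotropy score.

Default scales mirror the study design this package re-implements: 65
species, several-hundred-codon genes, and a tree deep enough to produce
pairwise nucleotide divergences in the 0.1-0.3 range.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._codons import CODON_AA, N_SENSE, SENSE_CODONS, codon_frequencies, neighbor_arrays
from .errors import ConfigurationError
from .io_core import GAP, CodonAlignment
from .siteclasses import SiteClassSpec, spec_m0


@dataclass
class SimulationConfig:
    """Bundle of generator settings for one end-to-end synthetic dataset."""

    n_taxa: int = 65
    n_codons: int = 400
    tree_height: float = 0.5  # expected substitutions per codon site, root to tip
    site_class_spec: SiteClassSpec = field(default_factory=lambda: spec_m0(0.2, 2.0))
    codon_freqs: str | np.ndarray = "uniform"
    coevolution: tuple = ()  # (site_a, site_b, rho) triples
    gap_rate: float = 0.01
    pleiotropy_effect: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_taxa: int, height: float, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) tree rescaled so the mean root-to-tip path = height."""
    if n_taxa < 2:
        raise ConfigurationError("need at least 2 taxa")
    if height <= 0:
        raise ConfigurationError("height must be positive")
    taxa = dendropy.TaxonNamespace([f"T{i+1}" for i in range(n_taxa)])
    if n_taxa == 2:
        tree = dendropy.Tree.get(
            data=f"(T1:{height},T2:{height});",
            schema="newick",
            taxon_namespace=taxa,
        )
        return tree
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=random.Random(int(seed)),
    )
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    mean_depth = float(np.mean(depths))
    factor = height / mean_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


# ---------------------------------------------------------------------------
# codon evolution


class _GillespieProcess:
    """Exact continuous-time simulation helpers for one (kappa, omega) class."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray, rate_norm: float):
        ii, jj, ts, syn = neighbor_arrays()
        R = np.zeros((N_SENSE, N_SENSE))
        R[ii, jj] = pi[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
        R /= rate_norm
        self.exit_rates = R.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump = R / self.exit_rates[:, None]
        jump[self.exit_rates == 0] = 0.0
        self.jump_cum = np.cumsum(jump, axis=1)

    def evolve(self, states: np.ndarray, t: float, rng: np.random.Generator):
        """Evolve a vector of codon states for time t (vectorised rounds)."""
        states = states.copy()
        remaining = np.full(states.shape, float(t))
        active = self.exit_rates[states] > 0
        while True:
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            rates = self.exit_rates[states[idx]]
            waits = rng.exponential(1.0 / rates)
            jumping = waits < remaining[idx]
            ji = idx[jumping]
            remaining[ji] -= waits[jumping]
            if ji.size:
                u = rng.random(ji.size)
                rows = self.jump_cum[states[ji]]
                states[ji] = (u[:, None] > rows).sum(axis=1)
            active[idx[~jumping]] = False
            active[ji] = self.exit_rates[states[ji]] > 0
        return states


def _mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    ii, jj, ts, syn = neighbor_arrays()
    w = pi[ii] * pi[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    return float(w.sum())


def simulate_codon_alignment(
    tree: dendropy.Tree,
    spec: SiteClassSpec,
    n_codons: int,
    freqs="uniform",
    seed: int = 0,
    gap_rate: float = 0.0,
    gene_id: str = "sim",
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment along `tree` under a site-class mixture.

    Each site independently draws an omega class (returned as the true-label
    array for recovery tests), the root codon is drawn from the stationary
    frequencies, and substitutions are simulated exactly along each branch.
    Branch lengths are expected substitutions per codon site under the class
    mixture, matching the estimator's normalisation.
    """
    rng = np.random.default_rng(seed)
    pi = codon_frequencies(freqs, None) if isinstance(freqs, str) else codon_frequencies(freqs)
    rbar = sum(
        p * _mean_rate(spec.kappa, w, pi) for w, p in zip(spec.omegas, spec.probs)
    )
    procs = [
        _GillespieProcess(spec.kappa, w, pi, rbar) for w in spec.omegas
    ]
    labels = rng.choice(spec.n_classes, size=n_codons, p=np.asarray(spec.probs))

    root_states = rng.choice(N_SENSE, size=n_codons, p=pi)
    tip_states: dict[str, np.ndarray] = {}

    def descend(node, states):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_states = states.copy()
            if t > 0:
                for c in range(spec.n_classes):
                    mask = labels == c
                    if mask.any():
                        child_states[mask] = procs[c].evolve(states[mask], t, rng)
            if child.is_leaf():
                tip_states[child.taxon.label] = child_states
            else:
                descend(child, child_states)

    descend(tree.seed_node, root_states)

    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    seqs = []
    for taxon in taxa:
        states = tip_states[taxon]
        codons = [SENSE_CODONS[s] for s in states]
        if gap_rate > 0:
            gap_mask = rng.random(n_codons) < gap_rate
            codons = [GAP * 3 if g else c for c, g in zip(codons, gap_mask)]
        seqs.append("".join(codons))
    aln = CodonAlignment(gene_id, tuple(taxa), tuple(seqs))
    return aln, labels


def inject_coevolving_pair(
    aln_a: CodonAlignment,
    aln_b: CodonAlignment,
    tree: dendropy.Tree,
    site_a: int,
    site_b: int,
    rho: float,
    seed: int = 0,
    omega_pair: float = 3.0,
    rate_multiplier: float = 1.0,
    kappa: float = 2.0,
    freqs="uniform",
) -> tuple[CodonAlignment, CodonAlignment]:
    """Re-simulate one column in each alignment as a coupled pair.

    Both sites evolve under a GY94 process with ratio ``omega_pair`` at
    ``rate_multiplier`` times the gene-average substitution rate; whenever a nonsynonymous substitution occurs at
    one site, the partner site takes a compensating single-nucleotide
    nonsynonymous jump on the same branch with probability rho
    (symmetrically).  rho = 0 reduces to independent evolution; sites are
    0-based codon columns.
    """
    if not 0 <= rho <= 1:
        raise ConfigurationError("rho must be in [0, 1]")
    if not 0 <= site_a < aln_a.n_codons:
        raise ConfigurationError(f"site_a {site_a} out of range")
    if not 0 <= site_b < aln_b.n_codons:
        raise ConfigurationError(f"site_b {site_b} out of range")
    if set(aln_a.taxa) != set(aln_b.taxa):
        raise ConfigurationError("alignments must share their taxa")

    rng = np.random.default_rng(seed)
    pi = codon_frequencies(freqs, None) if isinstance(freqs, str) else codon_frequencies(freqs)
    rnorm = _mean_rate(kappa, omega_pair, pi)
    ii, jj, ts, syn = neighbor_arrays()
    R = np.zeros((N_SENSE, N_SENSE))
    R[ii, jj] = pi[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega_pair)
    R *= rate_multiplier / rnorm
    exit_rates = R.sum(axis=1)
    # nonsynonymous single-step neighbours for the compensating jumps
    nonsyn_targets = [jj[(ii == a) & ~syn] for a in range(N_SENSE)]
    aa_codes = {a: i for i, a in enumerate(sorted(set(CODON_AA)))}
    aa_of = np.array([aa_codes[a] for a in CODON_AA])

    def gillespie_pair(a_state, b_state, t):
        """Joint evolution of the coupled pair along one branch."""
        remaining = t
        while True:
            ra, rb = exit_rates[a_state], exit_rates[b_state]
            total = ra + rb
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait >= remaining:
                break
            remaining -= wait
            if rng.random() < ra / total:
                new = _draw_jump(a_state)
                changed_aa = aa_of[new] != aa_of[a_state]
                a_state = new
                if changed_aa and rng.random() < rho:
                    b_state = _forced_nonsyn(b_state)
            else:
                new = _draw_jump(b_state)
                changed_aa = aa_of[new] != aa_of[b_state]
                b_state = new
                if changed_aa and rng.random() < rho:
                    a_state = _forced_nonsyn(a_state)
        return a_state, b_state

    def _draw_jump(state):
        row = R[state]
        cum = np.cumsum(row)
        return int((rng.random() * cum[-1] > cum).sum())

    def _forced_nonsyn(state):
        targets = nonsyn_targets[state]
        if targets.size == 0:
            return state
        w = pi[targets]
        return int(rng.choice(targets, p=w / w.sum()))

    root_a = int(rng.choice(N_SENSE, p=pi))
    root_b = int(rng.choice(N_SENSE, p=pi))
    tip_pairs: dict[str, tuple[int, int]] = {}

    def descend(node, a_state, b_state):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            ca, cb = gillespie_pair(a_state, b_state, t) if t > 0 else (a_state, b_state)
            if child.is_leaf():
                tip_pairs[child.taxon.label] = (ca, cb)
            else:
                descend(child, ca, cb)

    descend(tree.seed_node, root_a, root_b)

    def replace_column(aln, site, which):
        seqs = []
        for taxon, seq in zip(aln.taxa, aln.sequences):
            state = tip_pairs[taxon][which]
            codon = SENSE_CODONS[state]
            seqs.append(seq[: 3 * site] + codon + seq[3 * site + 3 :])
        return CodonAlignment(aln.gene_id, aln.taxa, tuple(seqs))

    return replace_column(aln_a, site_a, 0), replace_column(aln_b, site_b, 1)


# ---------------------------------------------------------------------------
# pleiotropy tables


def simulate_pleiotropy_table(
    n_genes: int,
    effect_slope: float,
    noise_sd: float,
    seed: int = 0,
    go_mean: float = 25.0,
    go_dispersion: float = 2.0,
    ka_intercept: float = -3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic gene table: GO annotations plus a Ka with a known effect.

    GO Biological Process counts are negative-binomial (mean ``go_mean``,
    shape ``go_dispersion``); Ka = exp(intercept + slope * count + N(0, sd)).
    Returns (go_table, gene_table): the long-format annotation rows and a
    per-gene frame with the true score and Ka.
    """
    if n_genes < 10:
        raise ConfigurationError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    p = go_dispersion / (go_dispersion + go_mean)
    counts = rng.negative_binomial(go_dispersion, p, size=n_genes)
    genes = [f"g{i+1:04d}" for i in range(n_genes)]
    ka = np.exp(
        ka_intercept + effect_slope * counts + rng.normal(0.0, noise_sd, n_genes)
    )
    rows = []
    term_pool_size = max(200, int(counts.max()) + 1)
    for g, c in zip(genes, counts):
        terms = rng.choice(term_pool_size, size=c, replace=False)
        for t in terms:
            rows.append((g, f"GO:{t+1:07d}", "biological_process"))
    go_table = pd.DataFrame(rows, columns=["gene_id", "term_id", "namespace"])
    gene_table = pd.DataFrame(
        {"gene_id": genes, "go_bp_count": counts, "ka": ka}
    )
    return go_table, gene_table
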