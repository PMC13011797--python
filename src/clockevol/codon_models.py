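"""Maximum-likelihood codon site models and selection tests.

Implements the standard site-model ladder (M0, M1a, M2a, M7, M8) on a
GY94-style codon rate matrix: substitutions changing more than one nucleotide
have rate zero; transitions are multiplied by kappa; nonsynonymous changes by
the class omega; and every rate carries the stationary frequency of the
target codon.  Log-likelihoods are computed by Felsenstein pruning over the
61 sense-codon states with per-site rescaling, sites with gaps handled by
summing over all codon states at the missing tips.

Selection inference follows the classic recipe: nested likelihood-ratio tests
(M0 vs M1a, M1a vs M2a, M7 vs M8) against chi-square nulls, naive empirical
Bayes (NEB) posteriors for the positive-selection class, and a fixed-effects
per-site scan in which each codon column gets its own synonymous rate alpha
and nonsynonymous rate beta, tested one-sided for beta > alpha against the
half-and-half chi-square mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.stats import chi2

from ._codons import N_SENSE, codon_frequencies, encode_codon_sequence, neighbor_arrays
from .errors import ConfigurationError, NumericError
from .io_core import CodonAlignment
from .siteclasses import (
    DEFAULT_NCAT,
    SiteClassSpec,
    spec_m0,
    spec_m1a,
    spec_m2a,
    spec_m7,
    spec_m8,
)

# ---------------------------------------------------------------------------
# rate matrices


def gy94_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """GY94 codon rate matrix Q (61x61), optionally scaled to mean rate 1."""
    ii, jj, ts, syn = neighbor_arrays()
    Q = np.zeros((N_SENSE, N_SENSE))
    rates = pi[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    Q[ii, jj] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        r = mean_rate(kappa, omega, pi)
        if r <= 0:
            raise NumericError("degenerate rate matrix (mean rate 0)")
        Q = Q / r
    return Q


def _rate_coefficients(pi: np.ndarray) -> np.ndarray:
    """Coefficients [syn&tv, syn&ts, non&tv, non&ts] of the mean flow rate."""
    ii, jj, ts, syn = neighbor_arrays()
    w = pi[ii] * pi[jj]
    return np.array(
        [
            w[syn & ~ts].sum(),
            w[syn & ts].sum(),
            w[~syn & ~ts].sum(),
            w[~syn & ts].sum(),
        ]
    )


def mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Mean substitution rate of the unnormalised GY94 matrix at stationarity."""
    a = _rate_coefficients(pi)
    return float(a[0] + kappa * a[1] + omega * a[2] + kappa * omega * a[3])


def mixture_mean_rate(spec: SiteClassSpec, pi: np.ndarray) -> float:
    return float(
        sum(
            p * mean_rate(spec.kappa, w, pi)
            for w, p in zip(spec.omegas, spec.probs)
        )
    )


def transition_matrices(
    kappa: float, omega: float, pi: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """P(t) = expm(Q t) for every t in `times`; Q unnormalised GY94."""
    Q = gy94_rate_matrix(kappa, omega, pi, normalize=False)
    sq = np.sqrt(pi)
    B = (sq[:, None] * Q) / sq[None, :]
    lam, U = eigh(B)
    left = U / sq[:, None]
    right = U.T * sq[None, :]
    E = np.exp(np.outer(times, lam))
    P = np.matmul(left[None, :, :] * E[:, None, :], right)
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# likelihood engine


class CodonLikelihood:
    """Pruning-based log-likelihood for one alignment on one tree.

    Site patterns are compressed once; per-class conditional likelihood
    columns are cached on (kappa, omega, time multiplier) so mixture models
    and finite-difference gradients only recompute what actually changed.
    """

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree, freqs="F3x4"):
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        missing = set(tips) - set(aln.taxa)
        if missing:
            raise ConfigurationError(
                f"tree tips absent from alignment: {sorted(missing)}"
            )
        if len(tips) < 2:
            raise ConfigurationError("tree must have at least 2 tips")
        self.aln = aln
        self.tree = tree
        self.taxa = tips
        self.pi = codon_frequencies(freqs, aln)
        self.freq_model = freqs if isinstance(freqs, str) else "explicit"

        states = np.stack([encode_codon_sequence(aln.sequence(t)) for t in tips])
        patterns, inverse, counts = np.unique(
            states, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_tips, n_patterns)
        self.pattern_index = inverse  # site -> pattern
        self.weights = counts.astype(float)
        self.n_sites = states.shape[1]
        self.n_patterns = patterns.shape[1]

        # flatten the tree into a postorder program
        self._nodes = list(tree.postorder_node_iter())
        self._node_id = {id(n): i for i, n in enumerate(self._nodes)}
        self._tip_row = {}
        for row, label in enumerate(tips):
            for n in self._nodes:
                if n.is_leaf() and n.taxon.label == label:
                    self._tip_row[self._node_id[id(n)]] = row
        self._branch_lengths = np.array(
            [
                (n.edge.length or 0.0)
                for n in self._nodes
                if n is not tree.seed_node
            ]
        )
        self._cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        self._cache_order: list[tuple] = []

    # -- single-class pruning ------------------------------------------------

    def _class_column(
        self, kappa: float, omega: float, tmult: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """(site-pattern likelihood, log scaling) for one omega class."""
        key = (round(float(kappa), 12), round(float(omega), 12), round(float(tmult), 12))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        times = np.array(
            [
                (n.edge.length or 0.0) * tmult
                for n in self._nodes
                if n is not self.tree.seed_node
            ]
        )
        # map node -> P index
        P_list = transition_matrices(kappa, omega, self.pi, times)
        npat = self.n_patterns
        logscale = np.zeros(npat)
        partial: dict[int, np.ndarray] = {}
        p_idx = 0
        p_index_of: dict[int, int] = {}
        for i, n in enumerate(self._nodes):
            if n is not self.tree.seed_node:
                p_index_of[i] = p_idx
                p_idx += 1
        for i, n in enumerate(self._nodes):
            if n.is_leaf():
                continue
            L = np.ones((N_SENSE, npat))
            for child in n.child_nodes():
                ci = self._node_id[id(child)]
                P = P_list[p_index_of[ci]]
                if child.is_leaf():
                    s = self.patterns[self._tip_row[ci]]
                    T = P[:, np.clip(s, 0, N_SENSE - 1)]
                    T = np.where(s[None, :] >= 0, T, 1.0)
                    L *= T
                else:
                    L *= P @ partial.pop(ci)
            m = L.max(axis=0)
            bad = m <= 0
            if bad.any():
                m = np.where(bad, 1.0, m)
            L /= m
            logscale += np.log(m)
            partial[i] = L
        root = self._node_id[id(self.tree.seed_node)]
        lik = self.pi @ partial.pop(root)
        result = (lik, logscale)
        self._cache[key] = result
        self._cache_order.append(key)
        if len(self._cache_order) > 256:
            old = self._cache_order.pop(0)
            self._cache.pop(old, None)
        return result

    # -- mixtures ------------------------------------------------------------

    def class_site_logliks(
        self, spec: SiteClassSpec, scale: float = 1.0
    ) -> np.ndarray:
        """(n_classes, n_patterns) log site likelihoods, classes unweighted."""
        rbar = mixture_mean_rate(spec, self.pi)
        tmult = scale / rbar
        out = np.empty((spec.n_classes, self.n_patterns))
        for c, omega in enumerate(spec.omegas):
            lik, logsc = self._class_column(spec.kappa, omega, tmult)
            with np.errstate(divide="ignore"):
                out[c] = np.log(lik) + logsc
        return out

    def loglik(self, spec: SiteClassSpec, scale: float = 1.0) -> float:
        cls = self.class_site_logliks(spec, scale)
        logp = np.log(np.asarray(spec.probs))[:, None]
        m = (cls + logp).max(axis=0)
        site_log = m + np.log(np.exp(cls + logp - m).sum(axis=0))
        total = float(self.weights @ site_log)
        if not np.isfinite(total):
            bad = int(np.argmax(~np.isfinite(site_log)))
            raise NumericError(f"non-finite likelihood at pattern {bad}")
        return total

    def site_posteriors(self, spec: SiteClassSpec, scale: float = 1.0) -> np.ndarray:
        """(n_classes, n_sites) NEB posterior class memberships."""
        cls = self.class_site_logliks(spec, scale)
        logp = np.log(np.asarray(spec.probs))[:, None]
        joint = cls + logp
        joint -= joint.max(axis=0, keepdims=True)
        post = np.exp(joint)
        post /= post.sum(axis=0, keepdims=True)
        return post[:, self.pattern_index]


# ---------------------------------------------------------------------------
# model fitting


@dataclass(frozen=True)
class CodonModelFit:
    model_name: str
    spec: SiteClassSpec
    params: dict
    loglik: float
    branch_scale: float
    freq_model: str
    converged: bool
    n_restarts: int
    restart_logliks: tuple[float, ...]
    message: str = ""


# parameter table: name -> (init, lower, upper, log-scale?)
_PARAM_TABLES = {
    "M0": {"kappa": (2.0, 0.01, 100.0, True), "omega": (0.3, 1e-4, 50.0, True)},
    "M1a": {
        "kappa": (2.0, 0.01, 100.0, True),
        "p0": (0.7, 1e-6, 1 - 1e-6, False),
        "omega0": (0.2, 1e-4, 1 - 1e-6, True),
    },
    "M2a": {
        "kappa": (2.0, 0.01, 100.0, True),
        "p0": (0.6, 1e-6, 1 - 1e-6, False),
        "s1": (0.75, 1e-6, 1 - 1e-6, False),
        "omega0": (0.2, 1e-4, 1 - 1e-6, True),
        "omega2": (2.0, 1.0, 50.0, True),
    },
    "M7": {
        "kappa": (2.0, 0.01, 100.0, True),
        "p": (0.8, 0.005, 99.0, True),
        "q": (1.5, 0.005, 99.0, True),
    },
    "M8": {
        "kappa": (2.0, 0.01, 100.0, True),
        "p": (0.8, 0.005, 99.0, True),
        "q": (1.5, 0.005, 99.0, True),
        "p0": (0.9, 1e-6, 1 - 1e-6, False),
        "omega_s": (2.0, 1.0, 50.0, True),
    },
}


def _spec_from_params(model_name: str, d: dict, ncat: int) -> SiteClassSpec:
    if model_name == "M0":
        return spec_m0(d["omega"], d["kappa"])
    if model_name == "M1a":
        return spec_m1a(d["p0"], d["omega0"], d["kappa"])
    if model_name == "M2a":
        p0 = d["p0"]
        p1 = d["s1"] * (1 - p0)
        return spec_m2a(p0, p1, d["omega0"], d["omega2"], d["kappa"])
    if model_name == "M7":
        return spec_m7(d["p"], d["q"], d["kappa"], ncat)
    if model_name == "M8":
        return spec_m8(d["p"], d["q"], d["p0"], d["omega_s"], d["kappa"], ncat)
    raise ConfigurationError(f"unknown model {model_name}")


def fit_model(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    model_name: str,
    freqs="F3x4",
    *,
    engine: CodonLikelihood | None = None,
    optimize_scale: bool = False,
    branch_scale: float = 1.0,
    n_restarts: int = 3,
    seed: int = 0,
    init: dict | None = None,
    ncat: int = DEFAULT_NCAT,
    maxiter: int = 200,
) -> CodonModelFit:
    """Fit a site model by bounded quasi-Newton maximisation of the likelihood.

    Branch lengths are taken from the tree; with ``optimize_scale`` a single
    global multiplier is estimated alongside the model parameters (the usual
    workflow estimates it once under M0 and passes it to the richer models via
    ``branch_scale``).  Restarts perturb the starting point deterministically
    from ``seed``; the best optimum wins.
    """
    if model_name not in _PARAM_TABLES:
        raise ConfigurationError(f"unknown model {model_name}")
    eng = engine if engine is not None else CodonLikelihood(aln, tree, freqs)
    table = dict(_PARAM_TABLES[model_name])
    if optimize_scale:
        table["_scale"] = (branch_scale, 0.02, 50.0, True)

    names = list(table)
    inits = np.array([table[k][0] for k in names])
    if init:
        for i, k in enumerate(names):
            if k in init:
                inits[i] = init[k]
    los = np.array([table[k][1] for k in names])
    his = np.array([table[k][2] for k in names])
    logsp = np.array([table[k][3] for k in names])

    def pack(vals):
        return np.where(logsp, np.log(vals), vals)

    def unpack(x):
        return np.where(logsp, np.exp(x), x)

    bounds = list(zip(pack(los), pack(his)))

    def negloglik(x):
        vals = unpack(np.clip(x, pack(los), pack(his)))
        d = dict(zip(names, vals))
        scale = d.pop("_scale", branch_scale)
        spec = _spec_from_params(model_name, d, ncat)
        try:
            return -eng.loglik(spec, scale)
        except NumericError:
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    restart_lls = []
    x0 = pack(np.clip(inits, los, his))
    for r in range(max(1, n_restarts)):
        if r == 0:
            start = x0
        else:
            jitter = rng.uniform(-0.5, 0.5, size=len(names))
            start = np.clip(x0 + jitter, pack(los), pack(his))
        res = minimize(
            negloglik,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-9},
        )
        restart_lls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res

    converged = bool(best.success)
    vals = unpack(np.clip(best.x, pack(los), pack(his)))
    d = dict(zip(names, vals))
    scale = d.pop("_scale", branch_scale)
    spec = _spec_from_params(model_name, d, ncat)
    ll = -float(best.fun)
    msg = "" if best.success else f"optimizer: {best.message}"
    if not best.success:
        warnings.warn(
            f"{model_name} fit did not report clean convergence: {best.message}",
            stacklevel=2,
        )
    return CodonModelFit(
        model_name=model_name,
        spec=spec,
        params=d,
        loglik=ll,
        branch_scale=float(scale),
        freq_model=eng.freq_model,
        converged=converged,
        n_restarts=max(1, n_restarts),
        restart_logliks=tuple(restart_lls),
        message=msg,
    )


def fit_site_models(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    models=("M0", "M1a", "M2a", "M7", "M8"),
    freqs="F3x4",
    seed: int = 0,
    n_restarts: int = 3,
    ncat: int = DEFAULT_NCAT,
) -> dict[str, CodonModelFit]:
    """Fit a ladder of site models sharing one branch-length scale.

    The scale is optimised under M0 and reused, and beta-model fits warm-start
    each other (M8 from M7) so nesting (l_M8 >= l_M7) holds numerically.
    """
    eng = CodonLikelihood(aln, tree, freqs)
    fits: dict[str, CodonModelFit] = {}
    m0 = fit_model(
        aln, tree, "M0", engine=eng, optimize_scale=True,
        n_restarts=n_restarts, seed=seed, ncat=ncat,
    )
    scale = m0.branch_scale
    fits["M0"] = m0
    kappa0 = m0.params["kappa"]
    for name in models:
        if name == "M0" or name in fits:
            continue
        init = {"kappa": kappa0}
        if name == "M8" and "M7" in fits:
            init.update({k: fits["M7"].params[k] for k in ("p", "q")})
            init["kappa"] = fits["M7"].params["kappa"]
        fit = fit_model(
            aln, tree, name, engine=eng, branch_scale=scale,
            n_restarts=n_restarts, seed=seed + 1, init=init, ncat=ncat,
        )
        if name == "M8" and "M7" in fits and fit.loglik < fits["M7"].loglik:
            # enforce nesting: refit from the boundary (p0 -> 1, omega_s -> 1)
            init2 = dict(init, p0=1 - 1e-6, omega_s=1.0)
            fit2 = fit_model(
                aln, tree, name, engine=eng, branch_scale=scale,
                n_restarts=1, seed=seed + 2, init=init2, ncat=ncat,
            )
            if fit2.loglik > fit.loglik:
                fit = fit2
        fits[name] = fit
    return {m: fits[m] for m in fits if m in set(models) | {"M0"}}


# ---------------------------------------------------------------------------
# likelihood ratio tests


@dataclass(frozen=True)
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float  # clamped at 0
    raw_statistic: float
    df: int
    p_value: float
    clamped: bool


_NESTED_DF = {("M0", "M1a"): 1, ("M1a", "M2a"): 2, ("M7", "M8"): 2}


def lrt_from_stats(stat: float, df: int, null="null", alt="alt") -> LRTResult:
    """LRT p-value from a 2*delta-log-likelihood statistic and df."""
    clamped = stat < 0
    s = max(stat, 0.0)
    return LRTResult(null, alt, s, float(stat), df, float(chi2.sf(s, df)), clamped)


def lrt(null_fit: CodonModelFit, alt_fit: CodonModelFit) -> LRTResult:
    key = (null_fit.model_name, alt_fit.model_name)
    if key not in _NESTED_DF:
        raise ConfigurationError(f"models {key} are not a supported nested pair")
    raw = 2.0 * (alt_fit.loglik - null_fit.loglik)
    return lrt_from_stats(
        raw, _NESTED_DF[key], null_fit.model_name, alt_fit.model_name
    )


def lrt_table(fits: dict[str, CodonModelFit], gene_id: str = "") -> pd.DataFrame:
    """Nested-model LRT summary with the usual columns (gene, models, df, 2dl, p)."""
    rows = []
    for (n0, n1), df in _NESTED_DF.items():
        if n0 in fits and n1 in fits:
            r = lrt(fits[n0], fits[n1])
            rows.append(
                {
                    "gene": gene_id,
                    "comparison": f"{n0} vs {n1}",
                    "df": df,
                    "lrt_2dl": r.raw_statistic,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# site-level inference


@dataclass(frozen=True)
class SitePosterior:
    site: int  # 1-based codon column
    ref_site: int | None  # position in the ungapped reference sequence
    posterior: float
    selected: bool


def reference_projection(aln: CodonAlignment, reference: str) -> list[int | None]:
    """Map codon columns to 1-based ungapped codon positions of `reference`."""
    seq = aln.sequence(reference)
    out: list[int | None] = []
    pos = 0
    for k in range(aln.n_codons):
        codon = seq[3 * k : 3 * k + 3]
        if "-" in codon:
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def neb_sites(
    fit: CodonModelFit,
    aln: CodonAlignment,
    tree: dendropy.Tree,
    threshold: float = 0.95,
    reference: str | None = None,
    engine: CodonLikelihood | None = None,
) -> list[SitePosterior]:
    """Naive-empirical-Bayes positively selected sites under an M2a/M8 fit."""
    pos_classes = [c for c, w in enumerate(fit.spec.omegas) if w > 1.0]
    if not pos_classes:
        raise ConfigurationError(
            f"{fit.model_name} fit has no omega > 1 class; NEB not applicable"
        )
    eng = engine if engine is not None else CodonLikelihood(aln, tree, fit.freq_model)
    post = eng.site_posteriors(fit.spec, fit.branch_scale)
    p_pos = post[pos_classes].sum(axis=0)
    ref_map = reference_projection(aln, reference) if reference else [None] * len(p_pos)
    return [
        SitePosterior(
            site=i + 1,
            ref_site=ref_map[i],
            posterior=float(p),
            selected=bool(p > threshold) and threshold < 1.0,
        )
        for i, p in enumerate(p_pos)
    ]


def site_episodic_scan(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    alpha_level: float = 0.05,
    freqs="F3x4",
    kappa: float | None = None,
    branch_scale: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-effects per-site selection scan.

    Each codon column gets its own synonymous rate alpha_s and nonsynonymous
    rate beta_s (null: beta_s = alpha_s), fitted by ML on the fixed tree; the
    one-sided test for beta > alpha uses p = 0.5 chi2_1 + 0.5 chi2_0.
    Returns a per-site table (site, alpha, beta, lrt_2dl, p_value, flagged).
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 3:
        raise ConfigurationError("episodic scan needs at least 3 taxa")
    eng = CodonLikelihood(aln, tree, freqs)
    if kappa is None or branch_scale is None:
        m0 = fit_model(
            aln, tree, "M0", engine=eng, optimize_scale=True, n_restarts=1, seed=seed
        )
        kappa = m0.params["kappa"] if kappa is None else kappa
        branch_scale = m0.branch_scale if branch_scale is None else branch_scale
    r1 = mean_rate(kappa, 1.0, eng.pi)

    def site_nll(pattern_col, alpha, beta):
        # one-class likelihood with syn rate alpha, nonsyn rate beta: the GY94
        # matrix at omega = beta/alpha run for time alpha*t (matrix scaled at
        # omega=1), so a single cached column per (alpha, beta) pair suffices.
        if alpha <= 0:
            alpha = 1e-8
        lik, logsc = eng._class_column(kappa, beta / alpha, branch_scale * alpha / r1)
        with np.errstate(divide="ignore"):
            val = np.log(lik[pattern_col]) + logsc[pattern_col]
        return -val

    rows = []
    for site in range(eng.n_sites):
        pat = eng.pattern_index[site]
        col = eng.patterns[:, pat]
        observed = col[col >= 0]
        if len(np.unique(observed)) <= 1:
            rows.append((site + 1, 0.0, 0.0, 0.0, 1.0, False))
            continue

        def nll_alt(x, pat=pat):
            return site_nll(pat, np.exp(x[0]), np.exp(x[1]))

        def nll_null(x, pat=pat):
            return site_nll(pat, np.exp(x[0]), np.exp(x[0]))

        b = (np.log(1e-4), np.log(100.0))
        res0 = minimize(nll_null, [0.0], method="L-BFGS-B", bounds=[b])
        res1 = minimize(
            nll_alt,
            [res0.x[0], res0.x[0]],
            method="L-BFGS-B",
            bounds=[b, b],
        )
        # also try a beta-heavy start so the one-sided optimum is not missed
        res1b = minimize(
            nll_alt,
            [res0.x[0], res0.x[0] + 1.5],
            method="L-BFGS-B",
            bounds=[b, b],
        )
        if res1b.fun < res1.fun:
            res1 = res1b
        stat = max(0.0, 2.0 * (res0.fun - res1.fun))
        alpha_hat, beta_hat = np.exp(res1.x)
        if beta_hat > alpha_hat and stat > 0:
            p = 0.5 * float(chi2.sf(stat, 1))
        else:
            p = 1.0
        rows.append(
            (site + 1, float(alpha_hat), float(beta_hat), stat, p, p <= alpha_level)
        )
    return pd.DataFrame(
        rows, columns=["site", "alpha", "beta", "lrt_2dl", "p_value", "flagged"]
    )
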