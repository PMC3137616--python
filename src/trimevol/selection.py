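"""Maximum-likelihood codon site models, LRTs and empirical-Bayes sites.

Implements the M0/M1a/M2a/M7/M8 family of GY94xHKY85 site models on a fixed
tree topology: per-site likelihoods by Felsenstein pruning over the 61 sense
codons, mixture log-likelihood maximised over (kappa, class proportions,
class omegas, beta shapes, branch scale) with a box-constrained quasi-Newton
optimiser on log/logit-transformed parameters.  Nested models are compared
by likelihood-ratio test (2*delta-lnL vs chi-square); positively selected
sites are identified by naive empirical Bayes at the MLEs or, for M2a, by
Bayes empirical Bayes over the standard 10-point grid prior on
(p0, p1, omega0, omega_pos).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

from .alignment import CodonAlignment, ColumnMap
from .codon import (
    N_CODONS,
    SpectralRates,
    f3x4_frequencies,
    f61_frequencies,
    mixture_rate_matrices,
    position_frequencies_from_codons,
)
from .likelihood import PruningEngine, compress_columns
from .models import FREE_PARAMS, MODEL_IDS, SelectionRegime, discretize_beta
from .trees import Tree, jc_distance_matrix, nj_tree

POSTERIOR_THRESHOLD = 0.95
_NEG_LNL_CLIP = 1e-4

_LOGIT_LO, _LOGIT_HI = -12.0, 12.0
_BOUNDS = {
    "log_kappa": (np.log(0.05), np.log(50.0)),
    "log_scale": (-6.0, 6.0),
    "logit": (_LOGIT_LO, _LOGIT_HI),
    "log_omega": (np.log(1e-6), np.log(50.0)),
    "log_beta": (np.log(0.02), np.log(50.0)),
    "log_wpos": (np.log(1e-6), np.log(50.0)),  # omega_pos = 1 + exp(x)
}

_PARAM_LAYOUT = {
    "M0": ("log_kappa", "log_omega", "log_scale"),
    "M1a": ("log_kappa", "logit", "logit", "log_scale"),
    "M2a": ("log_kappa", "logit", "logit", "logit", "log_wpos", "log_scale"),
    "M7": ("log_kappa", "log_beta", "log_beta", "log_scale"),
    "M8": ("log_kappa", "logit", "log_beta", "log_beta", "log_wpos", "log_scale"),
}


@dataclass
class FitOptions:
    """Optimiser settings for :func:`fit_site_model`."""

    n_starts: int = 3
    seed: int = 0
    jitter: float = 0.4
    maxiter: int = 300
    beta_ncat: int = 10
    max_restarts: int = 2  # extra attempts when the optimiser fails outright


@dataclass
class SiteModelFit:
    model_id: str
    lnl: float
    kappa: float
    scale: float
    class_omegas: np.ndarray
    class_proportions: np.ndarray
    beta_p: float | None = None
    beta_q: float | None = None
    omega_pos: float | None = None
    p_pos: float | None = None
    n_free: int = 0
    converged: bool = True
    message: str = ""
    n: int = 0
    c: int = 0
    tree_newick: str = ""
    frequency_model: str = "F3x4"
    column_map: ColumnMap | None = None

    def regime(self) -> SelectionRegime:
        return SelectionRegime(
            self.model_id,
            self.kappa,
            tuple(self.class_omegas),
            tuple(self.class_proportions),
            beta_p=self.beta_p,
            beta_q=self.beta_q,
            omega_pos=self.omega_pos,
        )


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    two_delta_lnl: float
    df: int
    p_value: float


_NESTED_PAIRS = {("M0", "M1a"), ("M1a", "M2a"), ("M7", "M8")}


def _sigmoid_clip(x):
    return np.clip(expit(x), 1e-9, 1.0 - 1e-9)


def _theta_to_params(model_id: str, theta: np.ndarray, beta_ncat: int):
    """Unpack the unconstrained vector into (kappa, omegas, props, scale, extras)."""
    kappa = float(np.exp(theta[0]))
    scale = float(np.exp(theta[-1]))
    extras: dict = {}
    if model_id == "M0":
        omegas = np.array([np.exp(theta[1])])
        props = np.array([1.0])
    elif model_id == "M1a":
        p0 = _sigmoid_clip(theta[1])
        w0 = _sigmoid_clip(theta[2])
        omegas = np.array([w0, 1.0])
        props = np.array([p0, 1.0 - p0])
    elif model_id == "M2a":
        s0 = _sigmoid_clip(theta[1])
        s1 = _sigmoid_clip(theta[2])
        p0 = s0
        p1 = (1.0 - s0) * s1
        w0 = _sigmoid_clip(theta[3])
        wpos = 1.0 + np.exp(theta[4])
        omegas = np.array([w0, 1.0, wpos])
        props = np.array([p0, p1, 1.0 - p0 - p1])
        extras = {"omega_pos": float(wpos), "p_pos": float(1.0 - p0 - p1)}
    elif model_id == "M7":
        p, q = np.exp(theta[1]), np.exp(theta[2])
        omegas = discretize_beta(p, q, beta_ncat)
        props = np.full(beta_ncat, 1.0 / beta_ncat)
        extras = {"beta_p": float(p), "beta_q": float(q)}
    elif model_id == "M8":
        p0 = _sigmoid_clip(theta[1])
        p, q = np.exp(theta[2]), np.exp(theta[3])
        wpos = 1.0 + np.exp(theta[4])
        omegas = np.append(discretize_beta(p, q, beta_ncat), wpos)
        props = np.append(np.full(beta_ncat, p0 / beta_ncat), 1.0 - p0)
        extras = {
            "beta_p": float(p),
            "beta_q": float(q),
            "omega_pos": float(wpos),
            "p_pos": float(1.0 - p0),
        }
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    return kappa, omegas, props, scale, extras


def _initial_theta(model_id: str, init_from: SiteModelFit | None) -> np.ndarray:
    defaults = {
        "M0": [np.log(2.0), np.log(0.4), 0.0],
        "M1a": [np.log(2.0), logit(0.7), logit(0.2), 0.0],
        "M2a": [np.log(2.0), logit(0.65), logit(0.75), logit(0.2), np.log(1.5), 0.0],
        "M7": [np.log(2.0), np.log(0.8), np.log(1.8), 0.0],
        "M8": [np.log(2.0), logit(0.9), np.log(0.8), np.log(1.8), np.log(1.0), 0.0],
    }
    theta = np.array(defaults[model_id], dtype=float)
    if init_from is None:
        return theta
    f = init_from
    theta[0] = np.log(max(f.kappa, 0.06))
    theta[-1] = np.log(max(f.scale, 1e-3))
    clip01 = lambda x: float(np.clip(x, 1e-6, 1.0 - 1e-6))
    if model_id == "M2a" and f.model_id == "M1a":
        # start at the boundary neighbourhood: tiny positive class
        p0, p1 = f.class_proportions[0] * 0.98, f.class_proportions[1] * 0.98
        theta[1] = logit(clip01(p0))
        theta[2] = logit(clip01(p1 / (1.0 - p0)))
        theta[3] = logit(clip01(f.class_omegas[0]))
        theta[4] = np.log(1.0)  # omega_pos = 2
    elif model_id == "M8" and f.model_id == "M7":
        theta[1] = logit(1.0 - 1e-3)
        theta[2] = np.log(max(f.beta_p, 0.03))
        theta[3] = np.log(max(f.beta_q, 0.03))
        theta[4] = np.log(1.0)
    elif model_id == "M1a" and f.model_id == "M0":
        theta[2] = logit(clip01(min(f.class_omegas[0], 0.9)))
    return theta


def _boundary_embedding(model_id: str, init_from: SiteModelFit | None):
    """Theta reproducing a nested null fit at the alternative's boundary.

    Starting one optimisation run here guarantees the alternative model
    never scores below its nested null (up to ~1e-6 in lnL), which keeps
    2*delta-lnL non-negative when the truth sits on the boundary.
    """
    if init_from is None:
        return None
    f = init_from
    clip01 = lambda x: float(np.clip(x, 1e-6, 1.0 - 1e-6))
    if model_id == "M2a" and f.model_id == "M1a":
        return np.array(
            [
                np.log(max(f.kappa, 0.06)),
                logit(clip01(f.class_proportions[0])),
                _LOGIT_HI,  # p1 absorbs (almost) all non-p0 mass
                logit(clip01(f.class_omegas[0])),
                _BOUNDS["log_wpos"][0],  # omega_pos ~ 1
                np.log(max(f.scale, 1e-3)),
            ]
        )
    if model_id == "M8" and f.model_id == "M7":
        return np.array(
            [
                np.log(max(f.kappa, 0.06)),
                _LOGIT_HI,  # p0 -> 1: beta component only
                np.log(max(f.beta_p, 0.03)),
                np.log(max(f.beta_q, 0.03)),
                _BOUNDS["log_wpos"][0],
                np.log(max(f.scale, 1e-3)),
            ]
        )
    if model_id == "M1a" and f.model_id == "M0" and f.class_omegas[0] < 1.0:
        return np.array(
            [
                np.log(max(f.kappa, 0.06)),
                _LOGIT_HI,  # p0 -> 1
                logit(clip01(f.class_omegas[0])),
                np.log(max(f.scale, 1e-3)),
            ]
        )
    return None


class _SiteModelObjective:
    """Negative mixture log-likelihood with caching of class likelihoods.

    Class-conditional site log-likelihoods depend only on (kappa, omegas,
    scale); a one-slot cache makes finite-difference steps in the proportion
    parameters nearly free.
    """

    def __init__(self, engine, weights, pi, model_id, beta_ncat):
        self.engine = engine
        self.weights = weights
        self.pi = pi
        self.model_id = model_id
        self.beta_ncat = beta_ncat
        self.n_calls = 0
        self._cache_key = None
        self._cache_val = None

    def class_site_logl(self, kappa, omegas, props, scale) -> np.ndarray:
        key = (round(kappa, 14), tuple(np.round(omegas, 14)),
               tuple(np.round(props, 14)), round(scale, 14))
        # proportions enter only via the shared mixture rate normalisation
        if self._cache_key == key:
            return self._cache_val
        self.n_calls += 1
        qs = mixture_rate_matrices(kappa, omegas, props, self.pi)
        tree = self.engine.tree
        times = tree.lengths * scale
        pmats = np.empty((len(omegas), tree.n_nodes, N_CODONS, N_CODONS))
        for k, q in enumerate(qs):
            pmats[k] = SpectralRates(q, self.pi).probabilities(times)
        logl = self.engine.site_log_likelihoods(pmats, self.pi)
        self._cache_key, self._cache_val = key, logl
        return logl

    def neg_log_likelihood(self, theta: np.ndarray) -> float:
        kappa, omegas, props, scale, _ = _theta_to_params(
            self.model_id, theta, self.beta_ncat
        )
        logl = self.class_site_logl(kappa, omegas, props, scale)
        logw = np.log(np.maximum(props, 1e-300))
        site = logsumexp(logl + logw[:, None], axis=0)
        return -float(site @ self.weights)


def _default_tree(alignment: CodonAlignment) -> Tree:
    """NJ tree on JC-corrected nucleotide distances, lengths in subs/site."""
    d = jc_distance_matrix(alignment.nucleotide_matrix())
    return nj_tree(alignment.ids, d)


def _prepare(alignment: CodonAlignment, tree: Tree | None, frequencies: str):
    column_map = None
    if any(("-" in s) or ("." in s) for s in alignment.seqs):
        alignment, column_map = alignment.remove_gapped_columns()
    if tree is None:
        tree = _default_tree(alignment)
    missing = [t for t in tree.taxa if t not in alignment.ids]
    if missing:
        raise ValueError(f"tree leaves without sequence: {missing}")
    codon_matrix = alignment.codon_matrix()
    order = [alignment.ids.index(t) for t in tree.taxa]
    codon_matrix = codon_matrix[order]
    if frequencies == "F3x4":
        pi = f3x4_frequencies(position_frequencies_from_codons(codon_matrix))
    elif frequencies == "F61":
        pi = f61_frequencies(codon_matrix)
    elif frequencies == "uniform":
        pi = f3x4_frequencies(None)
    else:
        raise ValueError(f"unknown frequency model {frequencies!r}")
    patterns, weights, inverse = compress_columns(codon_matrix)
    engine = PruningEngine(tree, patterns, N_CODONS)
    return alignment, tree, pi, engine, weights, inverse, column_map


def fit_site_model(
    alignment: CodonAlignment,
    tree: Tree | None,
    model_id: str,
    frequencies: str = "F3x4",
    options: FitOptions | None = None,
    init_from: SiteModelFit | None = None,
) -> SiteModelFit:
    """Fit one codon site model by maximum likelihood.

    The tree topology is fixed (built by neighbor joining when ``tree`` is
    None); relative branch lengths are kept and a single global scale is
    re-optimised together with the substitution parameters.  Multi-start
    jitter is driven by ``options.seed``, so the fit is deterministic.
    Non-convergence is reported on the returned fit, not raised.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    options = options or FitOptions()
    alignment, tree, pi, engine, weights, _, column_map = _prepare(
        alignment, tree, frequencies
    )
    obj = _SiteModelObjective(engine, weights, pi, model_id, options.beta_ncat)
    layout = _PARAM_LAYOUT[model_id]
    bounds = [_BOUNDS[kind] for kind in layout]
    theta0 = _initial_theta(model_id, init_from)
    rng = np.random.default_rng(options.seed)
    starts = [theta0]
    for _ in range(max(1, options.n_starts) - 1):
        starts.append(theta0 + rng.normal(0.0, options.jitter, size=theta0.shape))
    embed = _boundary_embedding(model_id, init_from)
    if embed is not None:
        starts.append(embed)
    best = None
    n_fail = 0
    for theta_init in starts:
        theta_init = np.clip(
            theta_init, [b[0] for b in bounds], [b[1] for b in bounds]
        )
        res = optimize.minimize(
            obj.neg_log_likelihood,
            theta_init,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
        if not res.success:
            n_fail += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = best is not None and np.isfinite(best.fun)
    if n_fail >= len(starts):  # no start converged cleanly
        converged = False
    kappa, omegas, props, scale, extras = _theta_to_params(
        model_id, best.x, options.beta_ncat
    )
    return SiteModelFit(
        model_id=model_id,
        lnl=-float(best.fun),
        kappa=kappa,
        scale=scale,
        class_omegas=omegas,
        class_proportions=props,
        beta_p=extras.get("beta_p"),
        beta_q=extras.get("beta_q"),
        omega_pos=extras.get("omega_pos"),
        p_pos=extras.get("p_pos"),
        n_free=FREE_PARAMS[model_id] + 1,  # + branch scale
        converged=converged,
        message=str(getattr(best, "message", "")),
        n=alignment.n,
        c=alignment.c,
        tree_newick=tree.to_newick(),
        frequency_model=frequencies,
        column_map=column_map,
    )


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> LRTResult:
    """Likelihood-ratio test of a nested model pair (chi-square reference)."""
    pair = (null_fit.model_id, alt_fit.model_id)
    if pair not in _NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    two_delta = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if two_delta < 0:
        level = "tiny" if two_delta > -_NEG_LNL_CLIP else "substantial"
        warnings.warn(
            f"negative 2*delta-lnL ({two_delta:.3g}, {level}) clipped to 0 "
            "(optimizer noise; consider more starts)",
            stacklevel=2,
        )
        two_delta = 0.0
    df = alt_fit.n_free - null_fit.n_free
    p = float(stats.chi2.sf(two_delta, df)) if two_delta > 0 else 1.0
    return LRTResult(null_fit.model_id, alt_fit.model_id, float(two_delta), df, p)


# ---------------------------------------------------------------------------
# empirical Bayes site identification


def _class_logl_at(
    fit: SiteModelFit,
    alignment: CodonAlignment,
    tree: Tree | None,
    omegas,
    props,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site class-conditional log-likelihoods at the fitted (kappa, scale)."""
    alignment2, tree, pi, engine, weights, inverse, _ = _prepare(
        alignment, tree, fit.frequency_model
    )
    obj = _SiteModelObjective(engine, weights, pi, fit.model_id, len(omegas))
    logl = obj.class_site_logl(fit.kappa, np.asarray(omegas), np.asarray(props), fit.scale)
    return logl[:, inverse], inverse  # expand patterns back to sites


def site_posteriors(
    fit: SiteModelFit,
    alignment: CodonAlignment,
    tree: Tree | None = None,
    method: str = "NEB",
) -> pd.DataFrame:
    """Posterior probability that each codon site belongs to the omega>1 class.

    NEB evaluates class posteriors at the MLEs; BEB (M2a: full published
    grid over p0, p1, omega0, omega_pos; M8: grid over p0 and omega_pos with
    the beta shape fixed at its MLE) averages over parameter uncertainty.
    Sites with posterior > 0.95 are flagged significant.  Site indices are
    1-based codon positions in the original (pre-gap-removal) coordinates.
    """
    if fit.model_id not in ("M2a", "M8"):
        raise ValueError(f"site posteriors require M2a or M8, not {fit.model_id}")
    if method not in ("NEB", "BEB"):
        raise ValueError(f"unknown method {method!r}")
    if tree is None and fit.tree_newick:
        tree = Tree.from_newick(fit.tree_newick)
    pos_class = len(fit.class_omegas) - 1
    if method == "NEB":
        logl, _ = _class_logl_at(
            fit, alignment, tree, fit.class_omegas, fit.class_proportions
        )
        props = np.asarray(fit.class_proportions)
        with np.errstate(divide="ignore"):
            logw = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
        log_post = logl + logw[:, None]
        log_post -= logsumexp(log_post, axis=0, keepdims=True)
        post = np.exp(log_post)
        p_pos = post[pos_class]
        mean_omega = np.asarray(fit.class_omegas) @ post
    else:
        p_pos, mean_omega = _beb(fit, alignment, tree)
    n_sites = p_pos.shape[0]
    sites = np.arange(1, n_sites + 1)
    if fit.column_map is not None:
        sites = fit.column_map.to_original(sites - 1) + 1
    return pd.DataFrame(
        {
            "site": sites,
            "p_pos": p_pos,
            "mean_omega": mean_omega,
            "method": method,
            "significant": p_pos > POSTERIOR_THRESHOLD,
        }
    )


def _grid_midpoints(n: int = 10) -> np.ndarray:
    return (2.0 * np.arange(1, n + 1) - 1.0) / (2.0 * n)


def _beb(fit: SiteModelFit, alignment: CodonAlignment, tree: Tree | None):
    """Bayes-empirical-Bayes posterior of the positive class, 10-point grids."""
    d = 10
    mids = _grid_midpoints(d)
    if fit.model_id == "M2a":
        w0_grid = mids
        wpos_grid = 1.0 + 10.0 * mids
        omegas = np.concatenate([w0_grid, [1.0], wpos_grid])
        prop_pairs = [
            (p0, p1)
            for p0 in mids
            for p1 in mids
            if p0 + p1 <= 1.0 + 1e-12
        ]
        logl, _ = _class_logl_at(
            fit, alignment, tree, omegas, np.full(len(omegas), 1.0 / len(omegas))
        )
        f_w0 = logl[:d]
        f_neu = logl[d]
        f_pos = logl[d + 1 :]
        thetas = []
        for i0 in range(d):
            for i2 in range(d):
                F = np.stack([f_w0[i0], f_neu, f_pos[i2]])  # (3, sites)
                thetas.append((F, np.array([omegas[i0], 1.0, wpos_grid[i2]])))
        p_arr = np.array(
            [[p0, p1, 1.0 - p0 - p1] for p0, p1 in prop_pairs]
        )  # (M, 3)
    else:  # M8: p0 and omega_pos grids, beta shape at the MLE
        beta_oms = discretize_beta(fit.beta_p, fit.beta_q, d)
        wpos_grid = 1.0 + 10.0 * mids
        omegas = np.concatenate([beta_oms, wpos_grid])
        logl, _ = _class_logl_at(
            fit, alignment, tree, omegas, np.full(len(omegas), 1.0 / len(omegas))
        )
        f_beta = logl[:d]
        f_pos = logl[d:]
        thetas = []
        for i2 in range(d):
            F = np.vstack([f_beta, f_pos[i2]])  # (d+1, sites)
            thetas.append((F, np.append(beta_oms, wpos_grid[i2])))
        p_arr = np.stack(
            [np.append(np.full(d, p0 / d), 1.0 - p0) for p0 in mids]
        )  # (M, d+1)

    log_marginals = []
    pos_posts = []
    mean_oms = []
    for F, om in thetas:
        m = F.max(axis=0)
        G = np.exp(F - m)  # (K, sites)
        denom = p_arr @ G  # (M, sites)
        log_marginals.append((np.log(denom) + m).sum(axis=1))  # (M,)
        pos_num = p_arr[:, -1:] * G[-1]
        pos_posts.append(pos_num / denom)  # (M, sites)
        mean_oms.append(np.einsum("mk,ks,k->ms", p_arr, G, om) / denom)
    log_marginals = np.concatenate(log_marginals)  # (T*M,)
    weights = np.exp(log_marginals - logsumexp(log_marginals))
    pos = np.concatenate(pos_posts, axis=0)
    mo = np.concatenate(mean_oms, axis=0)
    p_pos = weights @ pos
    mean_omega = weights @ mo
    return p_pos, mean_omega
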