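"""Felsenstein pruning over an arbitrary finite state space.

One engine serves both the 61-state codon models and the 4-state HKY85
nucleotide model used for breakpoint scanning.  Likelihoods are computed for
a batch of rate categories at once (site classes for codon mixtures, gamma
categories for nucleotide rates) with per-node rescaling to avoid underflow.
"""

from __future__ import annotations

import numpy as np

from .trees import Tree

_TINY = 1e-300


def compress_columns(states: np.ndarray):
    """Collapse identical alignment columns into weighted patterns.

    ``states`` has shape (n_sequences, n_sites).  Returns (patterns, weights,
    inverse) where ``patterns`` is (n_sequences, n_patterns) and
    ``states[:, i] == patterns[:, inverse[i]]``.
    """
    patterns, inverse, counts = np.unique(
        np.asarray(states).T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse.ravel()


class PruningEngine:
    """Pruning likelihoods on a fixed tree and leaf-state matrix."""

    def __init__(self, tree: Tree, leaf_states: np.ndarray, n_states: int):
        leaf_states = np.asarray(leaf_states)
        if leaf_states.shape[0] != tree.n_leaves:
            raise ValueError("leaf_states rows must match tree leaves")
        if leaf_states.min() < 0 or leaf_states.max() >= n_states:
            raise ValueError("leaf state index out of range")
        self.tree = tree
        self.leaf_states = leaf_states
        self.n_states = n_states
        self.n_sites = leaf_states.shape[1]

    def site_log_likelihoods(
        self, pmats: np.ndarray, root_frequencies: np.ndarray
    ) -> np.ndarray:
        """Per-category, per-site log-likelihoods.

        ``pmats`` has shape (n_categories, n_nodes, S, S), indexed by the
        *child* node of each branch (the root entry is ignored).
        """
        tree = self.tree
        ncat = pmats.shape[0]
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros((ncat, self.n_sites))
        for node in tree.postorder_internal:
            part = np.ones((ncat, self.n_sites, self.n_states))
            for child in tree.children[node]:
                p = pmats[:, child]
                if child < tree.n_leaves:
                    obs = self.leaf_states[child]
                    contrib = p[:, :, obs].transpose(0, 2, 1)
                else:
                    contrib = np.einsum(
                        "cij,cnj->cni", p, partials.pop(child), optimize=True
                    )
                part *= contrib
            scale = part.max(axis=2, keepdims=True)
            np.maximum(scale, _TINY, out=scale)
            part /= scale
            logscale += np.log(scale[:, :, 0])
            partials[node] = part
        root_part = partials[tree.root]
        site_lik = root_part @ np.asarray(root_frequencies, dtype=float)
        return np.log(np.maximum(site_lik, _TINY)) + logscale


def log_likelihood_mixture(
    class_site_logl: np.ndarray,
    class_weights: np.ndarray,
    site_weights: np.ndarray | None = None,
) -> float:
    """Total log-likelihood of a site-class mixture.

    ``class_site_logl`` is (K, n_sites); ``class_weights`` sums to one.
    ``site_weights`` carries pattern multiplicities when columns were
    compressed.
    """
    from scipy.special import logsumexp

    logw = np.log(np.maximum(np.asarray(class_weights, dtype=float), _TINY))
    site_logl = logsumexp(class_site_logl + logw[:, None], axis=0)
    if site_weights is None:
        return float(site_logl.sum())
    return float(site_logl @ np.asarray(site_weights, dtype=float))
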