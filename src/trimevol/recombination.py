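"""Recombination breakpoint detection and per-segment selection testing.

Breakpoints are found by comparing a single-phylogeny fit against
segmented-phylogeny fits under the small-sample corrected Akaike criterion
(c-AIC): a greedy forward search adds, at each round, the grid breakpoint
that most improves the total c-AIC, stopping when no candidate improves it.
Per-segment trees are built by neighbor joining on JC-corrected nucleotide
distances and scored under HKY85 with a discrete-gamma distribution of rates
across sites.  Accepted segments can then be re-tested for positive
selection independently with the codon site models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammainc, logsumexp

from .alignment import CodonAlignment
from .likelihood import PruningEngine, compress_columns
from .selection import FitOptions, SiteModelFit, fit_site_model, lrt, site_posteriors
from .trees import Tree, jc_distance_matrix, nj_tree

DEFAULT_GRID_STEP = 3  # codons
DEFAULT_MIN_SEGMENT = 10  # codons
DEFAULT_GAMMA_NCAT = 4

_HKY_TRANSITION = np.zeros((4, 4), dtype=bool)  # TCAG order
_HKY_TRANSITION[0, 1] = _HKY_TRANSITION[1, 0] = True  # T <-> C
_HKY_TRANSITION[2, 3] = _HKY_TRANSITION[3, 2] = True  # A <-> G


def hky_rate_matrix(kappa: float, base_freqs: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix (TCAG order), normalised to rate 1."""
    pi = np.asarray(base_freqs, dtype=float)
    q = np.tile(pi, (4, 1))
    q[_HKY_TRANSITION] *= kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    return q / rate


def discrete_gamma_rates(alpha: float, ncat: int = DEFAULT_GAMMA_NCAT) -> np.ndarray:
    """Mean rates of equal-probability categories of Gamma(alpha, mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    edges = stats.gamma.ppf(np.linspace(0.0, 1.0, ncat + 1), a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * edges)
    return np.diff(upper) * ncat


def corrected_aic(lnl: float, k: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); infinite when n <= k+1."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class SegmentFit:
    start: int  # 1-based first codon
    end: int  # 1-based last codon
    lnl: float
    kappa: float
    alpha: float
    scale: float
    k_params: int
    tree_newick: str


@dataclass
class BreakpointPartition:
    breakpoints: list  # codon position of the last codon of each left segment
    segments: list  # (start, end) 1-based inclusive codon intervals
    segment_fits: list
    caic_single: float
    caic_total: float
    n_codons: int
    grid_step: int
    min_segment: int

    @property
    def delta_caic(self) -> float:
        return self.caic_single - self.caic_total

    def breakpoints_nt(self) -> list:
        """Breakpoints in nucleotide coordinates (3 x codon position)."""
        return [3 * b for b in self.breakpoints]

    def to_global_codon(self, segment_index: int, local_site: int) -> int:
        """Map a 1-based site within a segment to the whole-alignment codon."""
        start, end = self.segments[segment_index]
        if not (1 <= local_site <= end - start + 1):
            raise ValueError("local site outside segment")
        return start + local_site - 1


class _SegmentScorer:
    """Caches per-segment HKY+gamma fits during the greedy scan."""

    def __init__(self, alignment: CodonAlignment, gamma_ncat: int, maxiter: int):
        self.nt = alignment.nucleotide_matrix()
        self.ids = list(alignment.ids)
        self.gamma_ncat = gamma_ncat
        self.maxiter = maxiter
        freqs = np.bincount(self.nt.ravel(), minlength=4).astype(float)
        freqs = np.maximum(freqs, 1.0)
        self.base_freqs = freqs / freqs.sum()
        n = len(self.ids)
        self.k_segment = (2 * n - 3) + 2  # branch lengths + kappa + gamma shape
        self._cache: dict = {}

    def fit(self, start: int, end: int) -> SegmentFit:
        """Fit codons [start, end) (0-based half-open)."""
        key = (start, end)
        if key in self._cache:
            return self._cache[key]
        sub = self.nt[:, 3 * start : 3 * end]
        tree = nj_tree(self.ids, jc_distance_matrix(sub))
        patterns, weights, _ = compress_columns(sub[[self.ids.index(t) for t in tree.taxa]])
        engine = PruningEngine(tree, patterns, 4)
        pi = self.base_freqs
        ncat = self.gamma_ncat
        logw = -np.log(ncat)

        def neg_lnl(x):
            kappa, alpha, scale = np.exp(x)
            rates = discrete_gamma_rates(alpha, ncat)
            q = hky_rate_matrix(kappa, pi)
            from .codon import SpectralRates

            spectral = SpectralRates(q, pi)
            pmats = np.stack(
                [spectral.probabilities(tree.lengths * scale * r) for r in rates]
            )
            site_logl = engine.site_log_likelihoods(pmats, pi)
            mix = logsumexp(site_logl + logw, axis=0)
            return -float(mix @ weights)

        res = optimize.minimize(
            neg_lnl,
            np.array([np.log(2.0), np.log(0.5), 0.0]),
            method="Nelder-Mead",
            bounds=[(np.log(0.05), np.log(50.0)), (np.log(0.05), np.log(20.0)), (-6.0, 6.0)],
            options={"maxiter": self.maxiter, "fatol": 0.05, "xatol": 0.01},
        )
        kappa, alpha, scale = np.exp(res.x)
        fit = SegmentFit(
            start + 1,
            end,
            -float(res.fun),
            float(kappa),
            float(alpha),
            float(scale),
            self.k_segment,
            tree.to_newick(),
        )
        self._cache[key] = fit
        return fit


def _partition_caic(scorer: _SegmentScorer, bounds, n_columns: int):
    fits = [scorer.fit(s, e) for s, e in bounds]
    lnl = sum(f.lnl for f in fits)
    k = sum(f.k_params for f in fits)
    return corrected_aic(lnl, k, n_columns), fits


def scan_breakpoints(
    alignment: CodonAlignment,
    max_breakpoints: int = 8,
    grid_step: int = DEFAULT_GRID_STEP,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    gamma_ncat: int = DEFAULT_GAMMA_NCAT,
    segment_maxiter: int = 80,
    coarse_factor: int = 4,
) -> BreakpointPartition:
    """Greedy forward breakpoint search under c-AIC.

    Candidate breakpoints lie on a codon grid of ``grid_step``; a candidate
    is never allowed to create a segment shorter than ``min_segment``
    codons.  Large candidate sets are screened coarsely first and refined
    around the best coarse position (a deterministic stand-in for exhaustive
    per-round evaluation).  The c-AIC sample size is the number of
    nucleotide columns; each segment contributes its branch lengths plus
    kappa and the gamma shape to the parameter count.
    """
    c = alignment.c
    if c < 2 * min_segment:
        raise ValueError(f"alignment of {c} codons too short for two segments")
    if max_breakpoints < 1:
        raise ValueError("max_breakpoints must be >= 1")
    scorer = _SegmentScorer(alignment, gamma_ncat, segment_maxiter)
    n_columns = 3 * c
    caic_single, _ = _partition_caic(scorer, [(0, c)], n_columns)
    breakpoints: list = []  # 0-based split points (codons in left part)
    current_caic = caic_single

    def bounds_for(bps):
        edges = [0] + sorted(bps) + [c]
        return list(zip(edges[:-1], edges[1:]))

    while len(breakpoints) < max_breakpoints:
        candidates = [
            b
            for b in range(grid_step, c, grid_step)
            if b not in breakpoints
            and all(
                (e - s) >= min_segment for s, e in bounds_for(breakpoints + [b])
            )
        ]
        if not candidates:
            break

        def evaluate(b):
            caic, _ = _partition_caic(scorer, bounds_for(breakpoints + [b]), n_columns)
            return caic

        evaluated: dict = {}
        if len(candidates) > 24:
            coarse = candidates[:: max(1, coarse_factor)]
            if candidates[-1] not in coarse:
                coarse.append(candidates[-1])
            for b in coarse:
                evaluated[b] = evaluate(b)
            best_coarse = min(evaluated, key=evaluated.get)
            window = coarse_factor * grid_step
            for b in candidates:
                if abs(b - best_coarse) <= window and b not in evaluated:
                    evaluated[b] = evaluate(b)
        else:
            for b in candidates:
                evaluated[b] = evaluate(b)
        best = min(evaluated, key=evaluated.get)
        if evaluated[best] >= current_caic:
            break
        breakpoints.append(best)
        current_caic = evaluated[best]

    bounds = bounds_for(breakpoints)
    caic_total, fits = _partition_caic(scorer, bounds, n_columns)
    return BreakpointPartition(
        breakpoints=sorted(breakpoints),
        segments=[(s + 1, e) for s, e in bounds],
        segment_fits=fits,
        caic_single=caic_single,
        caic_total=caic_total,
        n_codons=c,
        grid_step=grid_step,
        min_segment=min_segment,
    )


@dataclass
class SegmentSelection:
    start: int
    end: int
    fits: dict = field(default_factory=dict)
    lrts: dict = field(default_factory=dict)
    positive_sites: dict = field(default_factory=dict)
    error: str | None = None


def segment_selection_tests(
    alignment: CodonAlignment,
    partition: BreakpointPartition,
    pairs=(("M1a", "M2a"), ("M7", "M8")),
    options: FitOptions | None = None,
    posterior_method: str = "BEB",
) -> list:
    """Re-run the site-model LRTs independently on each non-recombinant segment.

    Positively selected sites (posterior > 0.95 under the alternative model)
    are reported in whole-alignment codon coordinates.  A failure in one
    segment is recorded on its result and does not abort the others.
    """
    results = []
    for seg_index, (start, end) in enumerate(partition.segments):
        res = SegmentSelection(start, end)
        sub = alignment.slice_codons(start - 1, end)
        try:
            for null_id, alt_id in pairs:
                null_fit = fit_site_model(sub, None, null_id, options=options)
                alt_fit = fit_site_model(
                    sub, None, alt_id, options=options, init_from=null_fit
                )
                res.fits[null_id] = null_fit
                res.fits[alt_id] = alt_fit
                res.lrts[(null_id, alt_id)] = lrt(null_fit, alt_fit)
                method = posterior_method if alt_id == "M2a" else "NEB"
                post = site_posteriors(alt_fit, sub, method=method)
                sig = post.loc[post["significant"], "site"].astype(int)
                res.positive_sites[alt_id] = [
                    partition.to_global_codon(seg_index, s) for s in sig
                ]
        except Exception as exc:  # keep scanning the other segments
            res.error = f"{type(exc).__name__}: {exc}"
        results.append(res)
    return results
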