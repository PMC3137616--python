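"""Genetic-code tables and Goldman-Yang codon substitution machinery.

The state space is the 61 sense codons of the universal genetic code; stop
codons are excluded, as is conventional for codon substitution models.  The
instantaneous rate matrix follows the GY94 structure with HKY85-style
nucleotide exchangeabilities: single-nucleotide changes only, a
transition/transversion ratio ``kappa`` and a nonsynonymous/synonymous rate
ratio ``omega`` (dN/dS).
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: nucleotide ordering used throughout (PAML convention)
NUCLEOTIDES = "TCAG"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in _TABLE.stop_codons
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = tuple(_TABLE.forward_table[c] for c in CODONS)

_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _pairwise_tables():
    diff_pos = np.full((N_CODONS, N_CODONS), -1, dtype=np.int8)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    synonymous = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            diff_pos[i, j] = k
            transition[i, j] = _is_transition(ci[k], cj[k])
            synonymous[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return diff_pos, transition, synonymous


DIFF_POS, IS_TRANSITION, IS_SYNONYMOUS = _pairwise_tables()
SINGLE_CHANGE = DIFF_POS >= 0

# target nucleotide (index into NUCLEOTIDES) of each single-nucleotide change
_TARGET_NT = np.full((N_CODONS, N_CODONS), -1, dtype=np.int8)
for _i in range(N_CODONS):
    for _j in range(N_CODONS):
        _k = DIFF_POS[_i, _j]
        if _k >= 0:
            _TARGET_NT[_i, _j] = NT_INDEX[CODONS[_j][_k]]

_FREQ_FLOOR = 1e-8


def uniform_position_frequencies() -> np.ndarray:
    """Uniform per-position nucleotide composition, shape (3, 4)."""
    return np.full((3, 4), 0.25)


def position_frequencies_from_codons(codon_matrix: np.ndarray) -> np.ndarray:
    """Per-position nucleotide frequencies from a matrix of codon indices."""
    counts = np.zeros((3, 4))
    flat = np.asarray(codon_matrix).ravel()
    flat = flat[flat >= 0]
    for pos in range(3):
        nt_of_codon = np.array([NT_INDEX[c[pos]] for c in CODONS])
        counts[pos] = np.bincount(nt_of_codon[flat], minlength=4)
    total = counts.sum(axis=1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("cannot estimate nucleotide frequencies from empty data")
    return counts / total


def f3x4_frequencies(position_freqs: np.ndarray | None = None) -> np.ndarray:
    """F3x4 equilibrium codon frequencies over the 61 sense codons.

    ``position_freqs`` is a (3, 4) array of nucleotide frequencies per codon
    position in TCAG order; ``None`` means uniform composition.  Frequencies
    are floored at a small positive value so the matrix stays reversible and
    diagonalisable even when a nucleotide is unobserved at some position.
    """
    if position_freqs is None:
        position_freqs = uniform_position_frequencies()
    position_freqs = np.asarray(position_freqs, dtype=float)
    if position_freqs.shape != (3, 4):
        raise ValueError("position_freqs must have shape (3, 4)")
    if np.any(position_freqs < 0):
        raise ValueError("nucleotide frequencies must be non-negative")
    pi = np.array(
        [
            position_freqs[0, NT_INDEX[c[0]]]
            * position_freqs[1, NT_INDEX[c[1]]]
            * position_freqs[2, NT_INDEX[c[2]]]
            for c in CODONS
        ]
    )
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


def f61_frequencies(codon_matrix: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Empirical (F61) codon frequencies with a small pseudocount."""
    flat = np.asarray(codon_matrix).ravel()
    flat = flat[flat >= 0]
    counts = np.bincount(flat, minlength=N_CODONS).astype(float) + pseudocount
    return counts / counts.sum()


def codon_rate_matrix(
    kappa: float,
    omega: float,
    frequencies: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """GY94xHKY85 instantaneous rate matrix (61 x 61).

    Off-diagonal rates are zero for multi-nucleotide changes and otherwise
    proportional to the target codon frequency, multiplied by ``kappa`` for
    transitions and by ``omega`` for nonsynonymous changes.  When
    ``normalize`` is true the matrix is scaled so the expected substitution
    rate at equilibrium is one per codon per unit time.
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be non-negative")
    pi = np.asarray(frequencies, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must be 61 positive values summing to 1")
    q = np.where(SINGLE_CHANGE, pi[None, :], 0.0)
    q = np.where(IS_TRANSITION & SINGLE_CHANGE, q * kappa, q)
    q = np.where(SINGLE_CHANGE & ~IS_SYNONYMOUS, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        rate = -(pi * np.diag(q)).sum()
        if rate > 0:
            q = q / rate
    return q


def mixture_rate_matrices(
    kappa: float,
    omegas,
    proportions,
    frequencies: np.ndarray,
) -> list[np.ndarray]:
    """Rate matrices of a site-class mixture sharing one time scale.

    All classes are normalised by the mixture-averaged substitution rate
    ``sum_k p_k r_k`` (not per class), so a branch length is the expected
    number of substitutions per codon for a random site, and sites in
    high-omega classes genuinely evolve faster.
    """
    pi = np.asarray(frequencies, dtype=float)
    props = np.asarray(proportions, dtype=float)
    qs = [codon_rate_matrix(kappa, w, pi, normalize=False) for w in omegas]
    rates = np.array([-(pi * np.diag(q)).sum() for q in qs])
    mean_rate = float(props @ rates)
    if mean_rate <= 0:
        mean_rate = 1.0
    return [q / mean_rate for q in qs]


class SpectralRates:
    """Eigendecomposition of a reversible rate matrix for fast P(t).

    Reversibility (``pi_i q_ij = pi_j q_ji``) lets the matrix be symmetrised
    as ``S = D^{1/2} Q D^{-1/2}`` with ``D = diag(pi)``; transition
    probabilities are then ``P(t) = A exp(L t) A^{-1}`` with orthogonal
    eigenvectors of S.
    """

    def __init__(self, q: np.ndarray, frequencies: np.ndarray):
        pi = np.asarray(frequencies, dtype=float)
        sqrt_pi = np.sqrt(pi)
        s = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        s = 0.5 * (s + s.T)  # symmetrise away rounding noise
        lam, v = np.linalg.eigh(s)
        self.eigenvalues = lam
        self._a = v / sqrt_pi[:, None]
        self._a_inv = v.T * sqrt_pi[None, :]

    def probabilities(self, times: np.ndarray) -> np.ndarray:
        """Transition matrices for an array of times, shape (T, S, S)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        e = np.exp(self.eigenvalues[None, :] * times[:, None])  # (T, S)
        w = self._a[None, :, :] * e[:, None, :]
        p = w @ self._a_inv
        np.clip(p, 0.0, None, out=p)
        # renormalise rows (clipping perturbs them at the ~1e-15 level)
        p /= p.sum(axis=2, keepdims=True)
        return p

    def probability(self, t: float) -> np.ndarray:
        return self.probabilities(np.array([t]))[0]
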