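"""Site-wise Shannon entropy on protein alignments.

Entropy is computed in bits over the 20 amino acids: with the threshold of
2 bits used to call hypervariable sites, only the base-2 reading is natural
(the maximum over 20 states is log2(20) ~ 4.32).  Gaps and ambiguous
residues (X, B, Z) are excluded from the frequency denominator; columns with
a gap fraction above ``max_gap_fraction`` are masked (entropy undefined,
never reported as 0).  Hypervariability uses the strict inequality H > 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

HYPERVARIABLE_THRESHOLD = 2.0
MAX_ENTROPY = np.log2(20.0)

AMINO_ACIDS_20 = "ACDEFGHIKLMNPQRSTVWY"
_COUNTED = frozenset(AMINO_ACIDS_20)
_IGNORED = frozenset("-.XBZ*?")


@dataclass
class EntropyProfile:
    alignment_id: str
    H: np.ndarray  # bits; NaN where masked
    masked: np.ndarray
    hypervariable: np.ndarray
    n_effective: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.H)

    @property
    def hypervariable_sites(self) -> np.ndarray:
        """0-based column indices with H > 2 (masked columns excluded)."""
        return np.flatnonzero(self.hypervariable)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "H": self.H,
                "n_effective": self.n_effective,
                "hypervariable": self.hypervariable.astype(int),
                "masked": self.masked.astype(int),
            }
        )


def column_entropy(column) -> float:
    """Shannon entropy (bits) of one alignment column.

    Gaps and ambiguity codes are dropped before counting; a column with no
    countable residue raises (callers mask such columns instead).
    """
    counts = Counter(r for r in (str(c).upper() for c in column) if r in _COUNTED)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("column has no unambiguous residues")
    freqs = np.array(list(counts.values()), dtype=float) / total
    return float(-(freqs * np.log2(freqs)).sum())


def profile_alignment(
    alignment, max_gap_fraction: float = 0.5, alignment_id: str = ""
) -> EntropyProfile:
    """Per-column entropy profile of a rectangular protein alignment.

    ``alignment`` may be a ProteinAlignment, a Bio.Align.MultipleSeqAlignment
    or a list of equal-length strings.
    """
    if hasattr(alignment, "seqs"):
        seqs = list(alignment.seqs)
    else:
        seqs = [str(getattr(rec, "seq", rec)) for rec in alignment]
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    seqs = [s.upper() for s in seqs]
    n_rows = len(seqs)
    n_cols = lengths.pop()
    H = np.full(n_cols, np.nan)
    masked = np.zeros(n_cols, dtype=bool)
    hyper = np.zeros(n_cols, dtype=bool)
    n_eff = np.zeros(n_cols, dtype=int)
    for i in range(n_cols):
        col = [s[i] for s in seqs]
        gap_fraction = sum(c in "-." for c in col) / n_rows
        counted = [c for c in col if c in _COUNTED]
        n_eff[i] = len(counted)
        if gap_fraction > max_gap_fraction or not counted:
            masked[i] = True
            continue
        H[i] = column_entropy(counted)
        hyper[i] = H[i] > HYPERVARIABLE_THRESHOLD
    return EntropyProfile(alignment_id, H, masked, hyper, n_eff)


def shared_hypervariable(profile_a: EntropyProfile, profile_b: EntropyProfile, site_map):
    """Hypervariable-site overlap between two profiles under a column map.

    ``site_map`` is an iterable of (column_a, column_b) 0-based pairs from a
    joint alignment; it must be injective on both sides.  Returns a dict
    with the counts of hypervariable sites in a, in b, and shared under the
    mapping (restricted to mapped columns for the shared count).
    """
    pairs = [(int(a), int(b)) for a, b in site_map]
    a_side = [a for a, _ in pairs]
    b_side = [b for _, b in pairs]
    if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
        raise ValueError("site_map must be injective")
    for a, b in pairs:
        if not (0 <= a < profile_a.n_columns) or not (0 <= b < profile_b.n_columns):
            raise ValueError(f"site_map entry ({a}, {b}) outside column range")
    hyper_a = set(profile_a.hypervariable_sites.tolist())
    hyper_b = set(profile_b.hypervariable_sites.tolist())
    shared = sum(1 for a, b in pairs if a in hyper_a and b in hyper_b)
    return {
        "hypervariable_a": len(hyper_a),
        "hypervariable_b": len(hyper_b),
        "shared": shared,
    }
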