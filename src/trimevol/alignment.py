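"""Alignment containers and FASTA I/O.

Two thin containers are used across the pipeline: ``ProteinAlignment`` for
entropy profiling and ``CodonAlignment`` for selection/recombination work.
Reading goes through Bio.AlignIO; the containers add the frame/stop-codon
validation that codon models require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .codon import CODON_INDEX, NT_INDEX, STOP_CODONS

GAP_CHARS = frozenset("-.")


class AlignmentError(ValueError):
    """Base class for alignment input problems."""


class RaggedAlignmentError(AlignmentError):
    pass


class DuplicateIdError(AlignmentError):
    pass


class FrameError(AlignmentError):
    """Codon alignment length not divisible by 3, or internal stop codon."""


@dataclass
class ColumnMap:
    """Mapping between original and gap-stripped column coordinates (0-based).

    ``kept`` lists, for each retained column, its index in the original
    alignment; ``old_to_new[i]`` is the new index of original column ``i`` or
    -1 if it was removed.  Units are residues for protein alignments and
    codons for codon alignments.
    """

    kept: np.ndarray
    n_original: int
    old_to_new: np.ndarray = field(init=False)

    def __post_init__(self):
        self.kept = np.asarray(self.kept, dtype=int)
        self.old_to_new = np.full(self.n_original, -1, dtype=int)
        self.old_to_new[self.kept] = np.arange(len(self.kept))

    def to_original(self, new_indices):
        """Map retained-column indices back to original coordinates."""
        return self.kept[np.asarray(new_indices, dtype=int)]


def _check_ids(ids):
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIdError(f"duplicate sequence ids: {dupes}")


@dataclass
class ProteinAlignment:
    ids: list
    seqs: list

    def __post_init__(self):
        _check_ids(self.ids)
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise RaggedAlignmentError(f"unequal row lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def column(self, i: int) -> list:
        return [s[i] for s in self.seqs]

    def remove_gapped_columns(self):
        keep = [
            i
            for i in range(self.length)
            if not any(s[i] in GAP_CHARS for s in self.seqs)
        ]
        if not keep:
            raise AlignmentError("no columns left after gap removal")
        seqs = ["".join(s[i] for i in keep) for s in self.seqs]
        return ProteinAlignment(list(self.ids), seqs), ColumnMap(keep, self.length)


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences.

    Gaps are tolerated on input (whole gapped codons are removed by
    :meth:`remove_gapped_columns` before model fitting); stop codons are
    rejected outright.
    """

    ids: list
    seqs: list

    def __post_init__(self):
        _check_ids(self.ids)
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise RaggedAlignmentError(f"unequal row lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]
        if self.seqs and len(self.seqs[0]) % 3 != 0:
            raise FrameError(f"alignment length {len(self.seqs[0])} not divisible by 3")
        for sid, s in zip(self.ids, self.seqs):
            for k in range(0, len(s), 3):
                codon = s[k : k + 3]
                if codon in STOP_CODONS:
                    raise FrameError(f"stop codon {codon} in {sid} at codon {k//3 + 1}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def c(self) -> int:
        """Number of codons."""
        return len(self.seqs[0]) // 3 if self.seqs else 0

    def codon_matrix(self) -> np.ndarray:
        """(n, c) matrix of codon-state indices; requires a gap-free alignment."""
        mat = np.empty((self.n, self.c), dtype=np.int16)
        for r, s in enumerate(self.seqs):
            for k in range(self.c):
                codon = s[3 * k : 3 * k + 3]
                idx = CODON_INDEX.get(codon)
                if idx is None:
                    raise AlignmentError(
                        f"unresolvable codon {codon!r} in {self.ids[r]} at codon {k+1}"
                        " (remove gapped/ambiguous columns first)"
                    )
                mat[r, k] = idx
        return mat

    def nucleotide_matrix(self) -> np.ndarray:
        """(n, 3c) matrix of nucleotide-state indices (TCAG), gap-free only."""
        mat = np.empty((self.n, 3 * self.c), dtype=np.int8)
        for r, s in enumerate(self.seqs):
            for k, ch in enumerate(s):
                idx = NT_INDEX.get(ch)
                if idx is None:
                    raise AlignmentError(
                        f"unresolvable nucleotide {ch!r} in {self.ids[r]}"
                    )
                mat[r, k] = idx
        return mat

    def slice_codons(self, start: int, end: int) -> "CodonAlignment":
        """Sub-alignment of codons [start, end) in 0-based codon coordinates."""
        seqs = [s[3 * start : 3 * end] for s in self.seqs]
        return CodonAlignment(list(self.ids), seqs)

    def remove_gapped_columns(self):
        keep = []
        for k in range(self.c):
            col = [s[3 * k : 3 * k + 3] for s in self.seqs]
            if not any(ch in GAP_CHARS for codon in col for ch in codon):
                keep.append(k)
        if not keep:
            raise AlignmentError("no codons left after gap removal")
        seqs = ["".join(s[3 * k : 3 * k + 3] for k in keep) for s in self.seqs]
        return CodonAlignment(list(self.ids), seqs), ColumnMap(keep, self.c)


def read_alignment(path, kind: str = "protein"):
    """Read an aligned FASTA file as a Protein- or CodonAlignment."""
    if kind not in ("protein", "codon"):
        raise ValueError(f"unknown alignment kind {kind!r}")
    try:
        msa = AlignIO.read(path, "fasta")
    except ValueError as exc:
        raise RaggedAlignmentError(str(exc)) from exc
    ids = [rec.id for rec in msa]
    seqs = [str(rec.seq) for rec in msa]
    if kind == "protein":
        return ProteinAlignment(ids, seqs)
    return CodonAlignment(ids, seqs)


def write_alignment(alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(records, path, "fasta")


def to_biopython(alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(alignment.ids, alignment.seqs)
    )
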