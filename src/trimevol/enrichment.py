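"""Marker-neighbourhood co-localization analysis.

Builds fixed-width neighbourhoods (default 5 Mb each side, the size of the
MHC proper) around marker loci, optionally collapses tandem runs of
same-family genes into single occurrences to avoid pseudo-replication from
recent duplications, and tests enrichment of a gene family inside the merged
neighbourhoods with a 2x2 Pearson chi-square independence test (df=1, no
continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FLANK = 5_000_000
DEFAULT_MAX_GAP = 500_000

GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "family"]
MARKER_COLUMNS = ["chrom", "pos", "marker_id"]


class AnnotationError(ValueError):
    pass


@dataclass
class GenomeAnnotation:
    """Gene coordinates (0-based half-open), marker loci and chromosome sizes."""

    chromosomes: dict
    genes: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self):
        self.genes = self.genes.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise AnnotationError(f"gene table missing column {col!r}")
        for col in MARKER_COLUMNS:
            if col not in self.markers.columns:
                raise AnnotationError(f"marker table missing column {col!r}")
        if self.genes["gene_id"].duplicated().any():
            raise AnnotationError("duplicate gene ids")
        sizes = self.genes["chrom"].map(self.chromosomes)
        if sizes.isna().any():
            bad = self.genes.loc[sizes.isna(), "gene_id"].iloc[0]
            raise AnnotationError(f"gene {bad} on unknown chromosome")
        start = self.genes["start"].to_numpy(dtype=float)
        end = self.genes["end"].to_numpy(dtype=float)
        bad = (start < 0) | (start >= end) | (end > sizes.to_numpy(dtype=float))
        if bad.any():
            g = self.genes.iloc[int(np.flatnonzero(bad)[0])]
            raise AnnotationError(
                f"gene {g.gene_id} coordinates [{g.start}, {g.end}) outside "
                f"chromosome {g.chrom}"
            )
        msizes = self.markers["chrom"].map(self.chromosomes)
        pos = self.markers["pos"].to_numpy(dtype=float)
        mbad = msizes.isna().to_numpy() | (pos < 0) | (pos > msizes.to_numpy(dtype=float))
        if mbad.any():
            m = self.markers.iloc[int(np.flatnonzero(mbad)[0])]
            raise AnnotationError(
                f"marker {m.marker_id} at {m.chrom}:{m.pos} off chromosome"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class NeighbourhoodSet:
    """Merged marker-flank intervals per chromosome."""

    intervals: dict
    flank: float
    total_length: float
    n_genes_inside: int

    def contains(self, chrom: str, pos) -> np.ndarray:
        """Vectorised membership test for positions on one chromosome."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return np.zeros(pos.shape, dtype=bool)
        inside = np.zeros(pos.shape, dtype=bool)
        for lo, hi in ivs:
            inside |= (pos >= lo) & (pos < hi)
        return inside


@dataclass
class EnrichmentResult:
    table: np.ndarray  # rows: family/other, cols: inside/outside
    chi2: float
    p_value: float
    df: int = 1
    collapsed: bool = False


def merge_intervals(intervals) -> list:
    """Merge overlapping/touching [lo, hi) intervals."""
    ivs = sorted((float(lo), float(hi)) for lo, hi in intervals)
    merged: list = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def build_neighbourhoods(
    annotation: GenomeAnnotation, flank: float = DEFAULT_FLANK
) -> NeighbourhoodSet:
    """Marker +/- flank windows, clipped to chromosome bounds and merged.

    A gene counts as inside a neighbourhood iff its start coordinate lies in
    a merged interval.
    """
    per_chrom: dict = {}
    for _, m in annotation.markers.iterrows():
        size = annotation.chromosomes[m.chrom]
        lo = max(0.0, m.pos - flank)
        hi = min(float(size), m.pos + flank)
        per_chrom.setdefault(m.chrom, []).append((lo, hi))
    intervals = {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}
    total = sum(hi - lo for ivs in intervals.values() for lo, hi in ivs)
    nb = NeighbourhoodSet(intervals, flank, total, 0)
    inside = genes_inside(annotation.genes, nb)
    nb.n_genes_inside = int(inside.sum())
    return nb


def genes_inside(
    genes: pd.DataFrame, neighbourhoods: NeighbourhoodSet, rule: str = "start"
) -> np.ndarray:
    """Boolean mask of genes inside the neighbourhood set.

    ``rule`` is the coordinate tested: the gene ``start`` (default) or the
    interval ``midpoint``.
    """
    if rule not in ("start", "midpoint"):
        raise ValueError(f"unknown inside rule {rule!r}")
    mask = np.zeros(len(genes), dtype=bool)
    for chrom, sub in genes.groupby("chrom", sort=False):
        if rule == "start":
            pos = sub["start"].to_numpy(dtype=float)
        else:
            pos = (sub["start"].to_numpy(float) + sub["end"].to_numpy(float)) / 2.0
        mask[sub.index.to_numpy()] = neighbourhoods.contains(chrom, pos)
    return mask


def collapse_tandem_clusters(
    genes: pd.DataFrame, max_gap: float = DEFAULT_MAX_GAP
) -> pd.DataFrame:
    """Collapse tandem runs of same-family genes into single occurrences.

    Genes are grouped family-wise per chromosome; consecutive genes whose
    inter-gene gap (next start minus previous end) is <= ``max_gap`` join one
    cluster.  Each cluster yields one occurrence at the cluster midpoint.
    """
    rows = []
    for (family, chrom), sub in genes.groupby(["family", "chrom"], sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=float)
        ends = sub["end"].to_numpy(dtype=float)
        ids = sub["gene_id"].tolist()
        cluster_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or starts[i] - ends[i - 1] > max_gap:
                lo = starts[cluster_start]
                hi = ends[i - 1]
                rows.append(
                    {
                        "family": family,
                        "chrom": chrom,
                        "pos": (lo + hi) / 2.0,
                        "n_genes": i - cluster_start,
                        "gene_ids": ",".join(ids[cluster_start:i]),
                    }
                )
                cluster_start = i
    return pd.DataFrame(rows, columns=["family", "chrom", "pos", "n_genes", "gene_ids"])


def enrichment_test(
    n_family_inside: float,
    n_family_outside: float,
    n_genes_inside: float,
    n_genes_outside: float,
    collapsed: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square independence test on the 2x2 co-localization table.

    Rows are family vs other genes (other = total minus family), columns are
    inside vs outside the neighbourhoods.  No continuity correction.
    """
    if n_family_inside > n_genes_inside or n_family_outside > n_genes_outside:
        raise ValueError("family counts exceed gene totals")
    table = np.array(
        [
            [n_family_inside, n_family_outside],
            [n_genes_inside - n_family_inside, n_genes_outside - n_family_outside],
        ],
        dtype=float,
    )
    if np.any(table < 0):
        raise ValueError("negative cell count")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if row[0] == 0:
        raise ValueError("empty margin: no family genes")
    if row[1] == 0:
        raise ValueError("empty margin: no non-family genes")
    if col[0] == 0:
        raise ValueError("empty margin: no genes inside neighbourhoods")
    if col[1] == 0:
        raise ValueError("empty margin: no genes outside neighbourhoods")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(table, float(chi2), float(p), int(df), collapsed)


def run_colocalization(
    annotation: GenomeAnnotation,
    family: str,
    flank: float = DEFAULT_FLANK,
    max_gap: float = DEFAULT_MAX_GAP,
    collapse: bool = True,
    rule: str = "start",
):
    """Full neighbourhood-enrichment analysis for one gene family.

    With ``collapse=True`` the family is counted in collapsed tandem-cluster
    occurrences while the inside/outside gene totals stay raw gene counts
    (an occurrence-vs-genome contrast); without collapsing, raw family genes
    are counted.  Returns (EnrichmentResult, NeighbourhoodSet, occurrences).
    """
    fam_genes = annotation.genes[annotation.genes["family"] == family]
    if fam_genes.empty:
        raise AnnotationError(f"family {family!r} absent from annotation")
    nb = build_neighbourhoods(annotation, flank)
    inside_all = genes_inside(annotation.genes, nb, rule=rule)
    n_inside = int(inside_all.sum())
    n_outside = annotation.n_genes - n_inside
    if collapse:
        occurrences = collapse_tandem_clusters(fam_genes, max_gap)
        occ_inside = np.concatenate(
            [
                nb.contains(chrom, sub["pos"].to_numpy(dtype=float))
                for chrom, sub in occurrences.groupby("chrom", sort=False)
            ]
        ) if len(occurrences) else np.zeros(0, dtype=bool)
        fam_in = int(occ_inside.sum())
        fam_out = len(occurrences) - fam_in
    else:
        occurrences = fam_genes.copy()
        fam_mask = inside_all[fam_genes.index.to_numpy()]
        fam_in = int(fam_mask.sum())
        fam_out = len(fam_genes) - fam_in
    result = enrichment_test(fam_in, fam_out, n_inside, n_outside, collapsed=collapse)
    return result, nb, occurrences


def read_gene_table(path, dialect: str = "bed") -> pd.DataFrame:
    """Read a TSV gene table (chrom, start, end, gene_id, family).

    ``dialect='bed'`` means 0-based half-open input; ``dialect='one-based'``
    converts 1-based inclusive coordinates.
    """
    df = pd.read_csv(path, sep="\t", names=GENE_COLUMNS, header=None, comment="#")
    if dialect == "one-based":
        df["start"] = df["start"] - 1
    elif dialect != "bed":
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    return df


def read_marker_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=MARKER_COLUMNS, header=None, comment="#")


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", names=["chrom", "length"], header=None, comment="#")
    return dict(zip(df["chrom"], df["length"]))


def write_neighbourhood_bed(nb: NeighbourhoodSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(nb.intervals):
            for lo, hi in nb.intervals[chrom]:
                fh.write(f"{chrom}\t{int(lo)}\t{int(hi)}\n")
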