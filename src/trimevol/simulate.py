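"""Synthetic-data generators for every pipeline stage.

Codon alignments are evolved on a phylogeny under a mixture-omega
(site-class) GY94 regime by exact matrix-exponential sampling along each
branch; recombinant alignments concatenate simulations on discordant
topologies; genome annotations emulate tandemly clustered gene families with
a tunable enrichment of one family inside marker neighbourhoods; domain
tables realise architecture strings as ordered, non-overlapping intervals.

Randomness: each generator takes one integer seed.  For codon alignments the
per-site class labels are drawn from a dedicated stream seeded by a stable
digest of (n_codons, proportions), so the true-class metadata is invariant
to the substitution seed; pass ``class_seed`` to override.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codon import CODONS, SpectralRates, f3x4_frequencies, mixture_rate_matrices
from .enrichment import GenomeAnnotation, merge_intervals
from .models import SelectionRegime
from .trees import Tree

__all__ = [
    "SimulatedAlignment",
    "RecombinantAlignment",
    "FamilySpec",
    "SyntheticGenomeSpec",
    "simulate_codon_alignment",
    "simulate_recombinant_alignment",
    "simulate_genome_annotation",
    "simulate_domain_table",
    "example_genome_spec",
]


@dataclass
class SimulatedAlignment:
    alignment: CodonAlignment
    site_classes: np.ndarray  # (c,) class index per codon
    regime: SelectionRegime
    frequencies: np.ndarray


@dataclass
class RecombinantAlignment:
    alignment: CodonAlignment
    breakpoints: list  # codon position of the last codon of each left segment
    segment_lengths: list
    site_classes: np.ndarray
    regime: SelectionRegime


def _class_label_rng(n_codons: int, proportions, class_seed) -> np.random.Generator:
    if class_seed is None:
        key = repr((int(n_codons), tuple(round(float(p), 12) for p in proportions)))
        class_seed = zlib.crc32(key.encode())
    return np.random.default_rng(class_seed)


def _sample_markov(
    parent_states: np.ndarray, pmat: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Child states given parent states under transition matrix rows."""
    cum = np.cumsum(pmat, axis=1)
    u = rng.random(parent_states.shape[0])
    return (cum[parent_states] > u[:, None]).argmax(axis=1)


def simulate_codon_alignment(
    tree: Tree,
    regime: SelectionRegime,
    n_codons: int,
    seed: int,
    position_freqs: np.ndarray | None = None,
    class_seed: int | None = None,
) -> SimulatedAlignment:
    """Evolve a gap-free codon alignment on ``tree`` under ``regime``.

    Site classes are i.i.d. from ``regime.proportions``; each site evolves
    under the GY94xHKY85 matrix with its class omega and the shared kappa.
    Equilibrium codon frequencies are F3x4 from ``position_freqs`` (uniform
    nucleotide composition by default).  Branch lengths are expected
    substitutions per codon.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if np.any(tree.lengths < 0):
        raise ValueError("negative branch lengths")
    rng = np.random.default_rng(seed)
    label_rng = _class_label_rng(n_codons, regime.proportions, class_seed)
    pi = f3x4_frequencies(position_freqs)
    site_classes = label_rng.choice(
        regime.n_classes, size=n_codons, p=np.asarray(regime.proportions)
    )
    states = np.empty((tree.n_nodes, n_codons), dtype=np.int64)
    qs = mixture_rate_matrices(regime.kappa, regime.omegas, regime.proportions, pi)
    # process classes in index order; within a class, root then preorder edges
    preorder = list(reversed(tree.postorder_internal))
    for k in range(regime.n_classes):
        sites = np.flatnonzero(site_classes == k)
        if sites.size == 0:
            continue
        spectral = SpectralRates(qs[k], pi)
        cum_root = np.cumsum(pi)
        u = rng.random(sites.size)
        states[tree.root, sites] = np.searchsorted(cum_root, u, side="right")
        for node in preorder:
            for child in tree.children[node]:
                pmat = spectral.probability(tree.lengths[child])
                states[child, sites] = _sample_markov(
                    states[node, sites], pmat, rng
                )
    seqs = [
        "".join(CODONS[s] for s in states[leaf]) for leaf in range(tree.n_leaves)
    ]
    aln = CodonAlignment(list(tree.taxa), seqs)
    return SimulatedAlignment(aln, site_classes, regime, pi)


def simulate_recombinant_alignment(
    trees,
    regime: SelectionRegime,
    segment_lengths,
    seed: int,
    position_freqs: np.ndarray | None = None,
) -> RecombinantAlignment:
    """Concatenate per-tree simulations to mimic recombinant histories.

    ``trees[i]`` governs segment ``i`` of ``segment_lengths[i]`` codons; all
    trees must share one leaf-label set.  Breakpoints are reported as the
    codon index (1-based) of the last codon of each segment but the final
    one, in concatenated-alignment coordinates; they are a function of the
    segment lengths only, never of the seed.
    """
    trees = list(trees)
    segment_lengths = [int(s) for s in segment_lengths]
    if len(trees) != len(segment_lengths):
        raise ValueError("segment count must equal tree count")
    leafset = set(trees[0].taxa)
    for t in trees[1:]:
        if set(t.taxa) != leafset:
            raise ValueError("all trees must share the same leaf label set")
    taxa = list(trees[0].taxa)
    seed_streams = np.random.SeedSequence(seed).spawn(len(trees))
    parts = []
    classes = []
    for i, (tree, length) in enumerate(zip(trees, segment_lengths)):
        sim = simulate_codon_alignment(
            tree,
            regime,
            length,
            seed=seed_streams[i].generate_state(1)[0] % (2**31),
            position_freqs=position_freqs,
            class_seed=zlib.crc32(
                repr((i, length, tuple(regime.proportions))).encode()
            ),
        )
        order = [sim.alignment.ids.index(t) for t in taxa]
        parts.append([sim.alignment.seqs[j] for j in order])
        classes.append(sim.site_classes)
    seqs = ["".join(p[r] for p in parts) for r in range(len(taxa))]
    breakpoints = list(np.cumsum(segment_lengths)[:-1])
    return RecombinantAlignment(
        CodonAlignment(taxa, seqs),
        [int(b) for b in breakpoints],
        segment_lengths,
        np.concatenate(classes),
        regime,
    )


# ---------------------------------------------------------------------------
# genome annotations


@dataclass(frozen=True)
class FamilySpec:
    """One clustered gene family: label, cluster count, genes per cluster,
    intra-cluster gap (bp)."""

    label: str
    n_clusters: int
    genes_per_cluster: int
    gap: float = 20_000.0


@dataclass
class SyntheticGenomeSpec:
    """Layout of a synthetic genome annotation.

    ``enrichment_factor`` multiplies the density of ``enriched_family``
    cluster anchors inside marker neighbourhoods (marker +/- ``flank``);
    factor 1 means uniform placement, 0 forbids the family inside.
    """

    chromosome_lengths: list
    n_background_genes: int
    family_specs: list
    markers: list  # (chrom_name, position)
    enriched_family: str | None = None
    enrichment_factor: float = 1.0
    flank: float = 5_000_000.0
    gene_length: float = 5_000.0
    seed: int = 0

    def chromosome_names(self):
        return [f"chr{i+1}" for i in range(len(self.chromosome_lengths))]


def _sample_from_intervals(intervals, rng: np.random.Generator):
    lengths = np.array([hi - lo for _, lo, hi in intervals])
    if lengths.sum() <= 0:
        raise ValueError("no room to place gene cluster")
    idx = rng.choice(len(intervals), p=lengths / lengths.sum())
    chrom, lo, hi = intervals[idx]
    return chrom, rng.uniform(lo, hi)


def simulate_genome_annotation(spec: SyntheticGenomeSpec) -> GenomeAnnotation:
    """Place background genes uniformly and family clusters per the spec."""
    if spec.enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    rng = np.random.default_rng(spec.seed)
    names = spec.chromosome_names()
    sizes = dict(zip(names, [float(c) for c in spec.chromosome_lengths]))
    glen = float(spec.gene_length)
    total_bp = sum(sizes.values())
    needed = spec.n_background_genes * glen + sum(
        f.n_clusters * (f.genes_per_cluster * glen + (f.genes_per_cluster - 1) * f.gap)
        for f in spec.family_specs
    )
    if needed > 0.5 * total_bp:
        raise ValueError(
            f"infeasible packing: {needed:.3g} bp of genes for {total_bp:.3g} bp genome"
        )
    markers = pd.DataFrame(
        [
            {"chrom": chrom, "pos": float(pos), "marker_id": f"mk{i+1}"}
            for i, (chrom, pos) in enumerate(spec.markers)
        ],
        columns=["chrom", "pos", "marker_id"],
    )
    for _, m in markers.iterrows():
        if m.chrom not in sizes or not (0 <= m.pos <= sizes[m.chrom]):
            raise ValueError(f"marker off-chromosome: {m.chrom}:{m.pos}")

    # merged neighbourhood intervals, for enrichment-aware placement
    nb: dict = {c: [] for c in names}
    for _, m in markers.iterrows():
        nb[m.chrom].append(
            (max(0.0, m.pos - spec.flank), min(sizes[m.chrom], m.pos + spec.flank))
        )
    nb = {c: merge_intervals(ivs) for c, ivs in nb.items()}

    def placement_intervals(span: float):
        """(inside, outside) anchor intervals such that the anchor start
        stays in/out of the neighbourhood set and the cluster fits."""
        inside, outside = [], []
        for c in names:
            limit = sizes[c] - span
            if limit <= 0:
                continue
            cursor = 0.0
            for lo, hi in nb[c]:
                if cursor < min(lo, limit):
                    outside.append((c, cursor, min(lo, limit)))
                if lo < min(hi, limit):
                    inside.append((c, lo, min(hi, limit)))
                cursor = hi
            if cursor < limit:
                outside.append((c, cursor, limit))
        return inside, outside

    rows = []
    bg_inside, bg_outside = placement_intervals(glen)
    bg_pool = bg_inside + bg_outside
    for b in range(spec.n_background_genes):
        chrom, start = _sample_from_intervals(bg_pool, rng)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + glen,
                "gene_id": f"bg{b+1:05d}",
                "family": "background",
            }
        )

    def in_neighbourhood(chrom, pos):
        return any(lo <= pos < hi for lo, hi in nb[chrom])

    for fam in spec.family_specs:
        span = fam.genes_per_cluster * glen + (fam.genes_per_cluster - 1) * fam.gap
        inside, outside = placement_intervals(span)
        l_in = sum(hi - lo for _, lo, hi in inside)
        l_out = sum(hi - lo for _, lo, hi in outside)
        if l_in + l_out <= 0:
            raise ValueError(f"infeasible packing for family {fam.label}")
        enriched = (
            spec.enriched_family is not None and fam.label == spec.enriched_family
        )
        f = spec.enrichment_factor if enriched else 1.0
        for cl in range(fam.n_clusters):
            for _attempt in range(1000):
                if enriched and f != 1.0:
                    p_in = (f * l_in) / (f * l_in + l_out) if (f * l_in + l_out) else 0.0
                    pool = inside if rng.random() < p_in else outside
                    chrom, anchor = _sample_from_intervals(pool, rng)
                else:
                    chrom, anchor = _sample_from_intervals(inside + outside, rng)
                starts = [
                    anchor + i * (glen + fam.gap) for i in range(fam.genes_per_cluster)
                ]
                if enriched and f == 0.0 and any(
                    in_neighbourhood(chrom, s) for s in starts
                ):
                    continue  # the whole cluster must stay outside
                break
            else:
                raise ValueError(
                    f"could not place cluster of {fam.label} outside neighbourhoods"
                )
            for i, start in enumerate(starts):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + glen,
                        "gene_id": f"{fam.label}_c{cl+1}_g{i+1}",
                        "family": fam.label,
                    }
                )
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "family"])
    return GenomeAnnotation(sizes, genes, markers)


def example_genome_spec(
    seed: int = 0,
    n_background: int = 2000,
    n_family: int = 50,
    genes_per_cluster: int = 1,
    enrichment_factor: float = 1.0,
) -> SyntheticGenomeSpec:
    """A zebrafish-scale layout: 25 chromosomes of 60 Mb, markers whose
    merged 5 Mb neighbourhoods cover ~24% of the genome (the share observed
    for the real marker set), one focal family placed with the requested
    enrichment."""
    n_chrom = 25
    lengths = [60e6] * n_chrom
    markers = []
    for i in range(18):
        markers.append((f"chr{i+1}", 15e6))
        markers.append((f"chr{i+1}", 45e6))
    n_clusters = max(1, n_family // genes_per_cluster)
    return SyntheticGenomeSpec(
        chromosome_lengths=lengths,
        n_background_genes=n_background,
        family_specs=[FamilySpec("classIV", n_clusters, genes_per_cluster)],
        markers=markers,
        enriched_family="classIV",
        enrichment_factor=enrichment_factor,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# domain tables


def simulate_domain_table(
    n_proteins: int,
    architecture_mix: dict,
    seed: int,
) -> pd.DataFrame:
    """Per-protein domain intervals realising architecture strings.

    ``architecture_mix`` maps comma-separated architecture strings (e.g.
    ``"RING,BBOX,CC,B30.2"``) to frequencies summing to one.
    """
    from .classify import DOMAIN_VOCABULARY

    archs = list(architecture_mix)
    freqs = np.array([architecture_mix[a] for a in archs], dtype=float)
    if archs:
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("architecture frequencies must sum to 1")
        for a in archs:
            for token in a.split(","):
                if token not in DOMAIN_VOCABULARY:
                    raise ValueError(f"unknown domain token {token!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_proteins):
        if not archs:
            break
        arch = archs[rng.choice(len(archs), p=freqs)]
        cursor = 1
        for token in arch.split(","):
            length = int(rng.integers(45, 120))
            start = cursor
            end = start + length - 1
            rows.append(
                {
                    "protein_id": f"prot{p+1:04d}",
                    "domain": token,
                    "start": start,
                    "end": end,
                }
            )
            cursor = end + int(rng.integers(5, 40))
    return pd.DataFrame(rows, columns=["protein_id", "domain", "start", "end"])
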