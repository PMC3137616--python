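import numpy as np
import pandas as pd
import pytest

from trimevol.enrichment import (
    GenomeAnnotation,
    build_neighbourhoods,
    collapse_tandem_clusters,
    enrichment_test,
    genes_inside,
    merge_intervals,
    run_colocalization,
)


def _annotation(sizes, genes, markers):
    return GenomeAnnotation(
        sizes,
        pd.DataFrame(genes, columns=["chrom", "start", "end", "gene_id", "family"]),
        pd.DataFrame(markers, columns=["chrom", "pos", "marker_id"]),
    )


def test_single_marker_window():
    ann = _annotation(
        {"chr1": 30e6},
        [("chr1", 1e6, 1.005e6, "g1", "fam")],
        [("chr1", 10e6, "m1")],
    )
    nb = build_neighbourhoods(ann)
    assert nb.intervals["chr1"] == [(5e6, 15e6)]
    assert nb.total_length == 10e6


def test_marker_near_chromosome_start_is_clipped():
    ann = _annotation(
        {"chr1": 30e6}, [("chr1", 1e6, 1.005e6, "g1", "fam")], [("chr1", 2e6, "m1")]
    )
    nb = build_neighbourhoods(ann)
    assert nb.intervals["chr1"] == [(0.0, 7e6)]


def test_overlapping_windows_merge_and_match_scan_oracle():
    ann = _annotation(
        {"chr1": 30e6},
        [("chr1", 1e6, 1.005e6, "g1", "fam")],
        [("chr1", 10e6, "m1"), ("chr1", 14e6, "m2")],
    )
    nb = build_neighbourhoods(ann)
    assert nb.intervals["chr1"] == [(5e6, 19e6)]
    assert nb.total_length == 14e6
    # oracle: brute-force scan of grid positions against raw windows
    grid = np.linspace(0, 30e6, 3001)
    raw = [(5e6, 15e6), (9e6, 19e6)]
    expect = np.array([any(lo <= x < hi for lo, hi in raw) for x in grid])
    got = nb.contains("chr1", grid)
    assert np.array_equal(got, expect)


def test_neighbourhood_length_invariant_to_marker_order():
    markers_fwd = [("chr1", 10e6, "m1"), ("chr1", 14e6, "m2"), ("chr1", 28e6, "m3")]
    genes = [("chr1", 1e6, 1.005e6, "g1", "fam")]
    nb1 = build_neighbourhoods(_annotation({"chr1": 40e6}, genes, markers_fwd))
    nb2 = build_neighbourhoods(
        _annotation({"chr1": 40e6}, genes, list(reversed(markers_fwd)))
    )
    assert nb1.total_length == nb2.total_length
    assert nb1.intervals == nb2.intervals


def test_off_chromosome_marker_rejected():
    with pytest.raises(ValueError):
        _annotation({"chr1": 30e6}, [("chr1", 0, 100, "g", "f")], [("chr2", 1, "m")])


def _gene_row(chrom, start, gid, family, length=5_000):
    return (chrom, start, start + length, gid, family)


def test_collapse_single_tandem_run():
    genes = pd.DataFrame(
        [_gene_row("chr1", 1e6 + i * 25_000, f"g{i}", "fam") for i in range(5)],
        columns=["chrom", "start", "end", "gene_id", "family"],
    )
    occ = collapse_tandem_clusters(genes, max_gap=500_000)
    assert len(occ) == 1
    assert occ.iloc[0]["n_genes"] == 5


def test_distant_genes_stay_separate():
    genes = pd.DataFrame(
        [_gene_row("chr1", 1e6, "g1", "fam"), _gene_row("chr1", 3e6, "g2", "fam")],
        columns=["chrom", "start", "end", "gene_id", "family"],
    )
    occ = collapse_tandem_clusters(genes, max_gap=500_000)
    assert len(occ) == 2


def brute_force_clusters(rows, max_gap):
    """Oracle: family-wise exhaustive grouping by pairwise chaining."""
    out = {}
    for family in {r[4] for r in rows}:
        fam = sorted((r for r in rows if r[4] == family), key=lambda r: (r[0], r[1]))
        clusters = []
        for r in fam:
            if (
                clusters
                and clusters[-1][-1][0] == r[0]
                and r[1] - clusters[-1][-1][2] <= max_gap
            ):
                clusters[-1].append(r)
            else:
                clusters.append([r])
        out[family] = len(clusters)
    return out


def test_interleaved_families_grouped_family_wise():
    rows = [
        _gene_row("chr1", 1_000_000, "a1", "A"),
        _gene_row("chr1", 1_050_000, "b1", "B"),
        _gene_row("chr1", 1_100_000, "a2", "A"),
        _gene_row("chr1", 4_000_000, "a3", "A"),
        _gene_row("chr2", 500_000, "b2", "B"),
    ]
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "family"])
    occ = collapse_tandem_clusters(genes, max_gap=500_000)
    counts = occ.groupby("family").size().to_dict()
    assert counts == brute_force_clusters(rows, 500_000)


def test_random_layouts_match_grouping_oracle():
    rng = np.random.default_rng(17)
    for _ in range(25):
        rows = []
        for i in range(rng.integers(2, 25)):
            rows.append(
                _gene_row(
                    f"chr{rng.integers(1, 3)}",
                    float(rng.integers(0, 10_000_000)),
                    f"g{i}",
                    rng.choice(["A", "B"]),
                )
            )
        genes = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gene_id", "family"]
        )
        occ = collapse_tandem_clusters(genes, max_gap=300_000)
        counts = occ.groupby("family").size().to_dict()
        assert counts == brute_force_clusters(rows, 300_000)


def test_chi_square_on_published_genome_wide_counts():
    """31/31 class-IV occurrences among 7884 vs 16263 genes: chi2 ~ 8.5, p = 0.0035."""
    result = enrichment_test(31, 31, 7884, 16263)
    assert result.df == 1
    assert result.chi2 == pytest.approx(8.5, abs=0.1)
    assert result.p_value == pytest.approx(0.0035, abs=0.00005)


def test_equal_proportions_give_zero_statistic():
    result = enrichment_test(10, 20, 100, 200)
    assert result.chi2 == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def chi2_textbook(table):
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return ((table - expected) ** 2 / expected).sum()


def test_chi_square_matches_expected_count_oracle_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        fam_in, fam_out = rng.integers(1, 50, size=2)
        other_in, other_out = rng.integers(50, 500, size=2)
        result = enrichment_test(
            fam_in, fam_out, fam_in + other_in, fam_out + other_out
        )
        oracle = chi2_textbook(result.table)
        assert result.chi2 == pytest.approx(oracle, abs=1e-10)


def test_zero_margin_raises_named_error():
    with pytest.raises(ValueError, match="inside"):
        enrichment_test(0, 10, 0, 100)
    with pytest.raises(ValueError, match="family"):
        enrichment_test(0, 0, 50, 100)


def test_run_colocalization_margins_sum_to_totals():
    genes = [_gene_row("chr1", 6e6 + i * 1e6, f"g{i}", "bg") for i in range(10)]
    genes += [
        _gene_row("chr1", 10.2e6, "f1", "fam"),
        _gene_row("chr1", 10.25e6, "f2", "fam"),
        _gene_row("chr1", 28e6, "f3", "fam"),
    ]
    ann = _annotation({"chr1": 40e6}, genes, [("chr1", 10e6, "m1")])
    result, nb, occ = run_colocalization(ann, "fam", max_gap=500_000)
    assert result.collapsed
    assert len(occ) == 2  # f1+f2 merge, f3 separate
    assert result.table[0].sum() == 2  # occurrences
    assert result.table.sum() == ann.n_genes  # margins match the raw totals
    inside = genes_inside(ann.genes, nb)
    assert inside.sum() + (~inside).sum() == ann.n_genes


def test_unknown_family_rejected():
    ann = _annotation(
        {"chr1": 30e6}, [("chr1", 1e6, 1.005e6, "g1", "fam")], [("chr1", 10e6, "m1")]
    )
    with pytest.raises(ValueError):
        run_colocalization(ann, "nope")


def test_merge_intervals_basic():
    assert merge_intervals([(5, 10), (9, 12), (20, 25)]) == [(5.0, 12.0), (20.0, 25.0)]
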