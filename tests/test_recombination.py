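import numpy as np
import pytest

from trimevol.models import SelectionRegime
from trimevol.recombination import (
    BreakpointPartition,
    corrected_aic,
    discrete_gamma_rates,
    hky_rate_matrix,
    scan_breakpoints,
    segment_selection_tests,
)
from trimevol.selection import FitOptions
from trimevol.simulate import simulate_codon_alignment
from trimevol.trees import random_tree


def test_hky_matrix_properties():
    pi = np.array([0.2, 0.3, 0.35, 0.15])
    q = hky_rate_matrix(3.0, pi)
    assert np.abs(q.sum(axis=1)).max() < 1e-12
    assert abs(-(pi * np.diag(q)).sum() - 1.0) < 1e-12
    flux = pi[:, None] * q - (pi[None, :] * q.T).T
    assert np.abs(flux).max() < 1e-12  # reversible
    # transitions faster than transversions
    assert q[0, 1] / q[0, 2] == pytest.approx(3.0 * pi[1] / pi[2])


def test_discrete_gamma_categories_average_to_one():
    for alpha in (0.2, 0.7, 2.5, 20.0):
        rates = discrete_gamma_rates(alpha, 4)
        assert rates.shape == (4,)
        assert np.all(np.diff(rates) > 0)
        assert rates.mean() == pytest.approx(1.0, abs=1e-8)
    # shape -> infinity approaches rate homogeneity
    assert np.allclose(discrete_gamma_rates(500.0, 4), 1.0, atol=0.1)


def test_corrected_aic_formula_and_small_sample_guard():
    assert corrected_aic(-100.0, 5, 1000) == pytest.approx(
        200 + 10 + 2 * 5 * 6 / (1000 - 6), abs=1e-12
    )
    assert corrected_aic(-100.0, 5, 6) == np.inf


@pytest.fixture(scope="module")
def small_null_scan():
    tree = random_tree(8, np.random.default_rng(40), mean_branch=0.2)
    regime = SelectionRegime.m1a(0.7, 0.2)
    sim = simulate_codon_alignment(tree, regime, 60, seed=1)
    return scan_breakpoints(sim.alignment, grid_step=3, min_segment=10)


def test_zero_breakpoint_partition_caics_coincide(small_null_scan):
    part = small_null_scan
    if part.breakpoints:
        pytest.skip("stochastic: breakpoint accepted on this fixture")
    assert part.caic_total == part.caic_single
    assert part.delta_caic == 0.0
    assert part.segments == [(1, part.n_codons)]


def test_accepted_partition_improves_caic():
    labels = [f"t{i}" for i in range(10)]
    rng = np.random.default_rng(77)
    t_a = random_tree(10, rng, mean_branch=0.2, labels=labels)
    t_b = random_tree(10, rng, mean_branch=0.2, labels=labels)
    from trimevol.simulate import simulate_recombinant_alignment

    rec = simulate_recombinant_alignment(
        [t_a, t_b], SelectionRegime.m1a(0.7, 0.2), [60, 60], seed=5
    )
    part = scan_breakpoints(rec.alignment)
    assert part.breakpoints  # discordant topologies must be detected
    assert part.caic_total < part.caic_single
    assert part.delta_caic > 0
    assert part.breakpoints_nt() == [3 * b for b in part.breakpoints]


def test_segment_coordinate_round_trip():
    part = BreakpointPartition(
        breakpoints=[30, 70],
        segments=[(1, 30), (31, 70), (71, 100)],
        segment_fits=[],
        caic_single=0.0,
        caic_total=0.0,
        n_codons=100,
        grid_step=3,
        min_segment=10,
    )
    seen = set()
    for seg_index, (start, end) in enumerate(part.segments):
        for local in range(1, end - start + 2 - 1 + 1):
            g = part.to_global_codon(seg_index, local)
            seen.add(g)
            assert start <= g <= end
    assert seen == set(range(1, 101))  # bijective onto whole-alignment codons
    with pytest.raises(ValueError):
        part.to_global_codon(0, 31)


def test_alignment_too_short_rejected(null_alignment):
    sub = null_alignment.alignment.slice_codons(0, 15)
    with pytest.raises(ValueError):
        scan_breakpoints(sub, min_segment=10)


def test_forced_split_on_null_data_keeps_segments_non_significant():
    """Both halves of a non-recombinant neutral alignment stay non-significant."""
    regime = SelectionRegime.m1a(0.7, 0.2)
    non_sig = 0
    n_seeds = 5
    for seed in range(n_seeds):
        tree = random_tree(8, np.random.default_rng(500 + seed), mean_branch=0.25)
        sim = simulate_codon_alignment(tree, regime, 140, seed=seed)
        part = BreakpointPartition(
            breakpoints=[70],
            segments=[(1, 70), (71, 140)],
            segment_fits=[],
            caic_single=0.0,
            caic_total=0.0,
            n_codons=140,
            grid_step=3,
            min_segment=10,
        )
        results = segment_selection_tests(
            sim.alignment,
            part,
            pairs=(("M1a", "M2a"),),
            options=FitOptions(n_starts=1),
        )
        assert all(r.error is None for r in results)
        ps = [r.lrts[("M1a", "M2a")].p_value for r in results]
        non_sig += all(p >= 0.001 for p in ps)
    assert non_sig >= n_seeds - 1


def test_segment_tests_recover_positive_selection_in_labeled_segment():
    """Positive sites land in the segment that contains them, in global coords."""
    labels = [f"t{i}" for i in range(12)]
    rng = np.random.default_rng(909)
    t_a = random_tree(12, rng, mean_branch=0.3, labels=labels)
    sim = simulate_codon_alignment(
        t_a, SelectionRegime.m2a(0.5, 0.3, 0.2, 6.0, kappa=2.0), 160, seed=3
    )
    part = BreakpointPartition(
        breakpoints=[80],
        segments=[(1, 80), (81, 160)],
        segment_fits=[],
        caic_single=0.0,
        caic_total=0.0,
        n_codons=160,
        grid_step=3,
        min_segment=10,
    )
    results = segment_selection_tests(
        sim.alignment, part, pairs=(("M1a", "M2a"),), options=FitOptions(n_starts=1)
    )
    assert all(r.error is None for r in results)
    sites = [s for r in results for s in r.positive_sites.get("M2a", [])]
    assert sites, "strong selection must yield significant sites"
    true_pos = set((np.flatnonzero(sim.site_classes == 2) + 1).tolist())
    hits = sum(1 for s in sites for seg, (a, b) in enumerate(part.segments)
               if a <= s <= b)
    assert hits == len(sites)  # every site maps inside a segment
    precision = len(set(sites) & true_pos) / len(sites)
    assert precision >= 0.7
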