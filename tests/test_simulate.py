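import numpy as np
import pytest
from scipy import stats

from trimevol.classify import classify_table
from trimevol.codon import AMINO_ACIDS, CODON_INDEX, CODONS, f3x4_frequencies
from trimevol.enrichment import collapse_tandem_clusters, genes_inside, build_neighbourhoods
from trimevol.models import SelectionRegime
from trimevol.simulate import (
    FamilySpec,
    SyntheticGenomeSpec,
    example_genome_spec,
    simulate_codon_alignment,
    simulate_domain_table,
    simulate_genome_annotation,
    simulate_recombinant_alignment,
)
from trimevol.trees import Tree, random_tree


def translate(seq: str) -> str:
    return "".join(AMINO_ACIDS[CODON_INDEX[seq[i : i + 3]]] for i in range(0, len(seq), 3))


def test_omega_zero_yields_only_synonymous_differences():
    tree = random_tree(6, np.random.default_rng(2), mean_branch=0.4)
    regime = SelectionRegime.m0(0.0, kappa=2.0)
    sim = simulate_codon_alignment(tree, regime, 100, seed=9)
    proteins = {translate(s) for s in sim.alignment.seqs}
    assert len(proteins) == 1  # every difference is silent
    assert len({s for s in sim.alignment.seqs}) > 1  # but DNA did diverge


def test_fixed_seed_reproduces_alignment_byte_identically(tree12, m2a_regime):
    a = simulate_codon_alignment(tree12, m2a_regime, 50, seed=4)
    b = simulate_codon_alignment(tree12, m2a_regime, 50, seed=4)
    assert a.alignment.seqs == b.alignment.seqs
    assert np.array_equal(a.site_classes, b.site_classes)


def test_site_class_fractions_follow_proportions():
    tree = random_tree(4, np.random.default_rng(1), mean_branch=0.1)
    regime = SelectionRegime.m2a(0.6, 0.3, 0.2, 4.0)
    sim = simulate_codon_alignment(tree, regime, 10_000, seed=0)
    frac = (sim.site_classes == 2).mean()
    bound = 3 * np.sqrt(0.1 * 0.9 / 10_000)
    assert abs(frac - 0.1) <= bound


def test_negative_branch_lengths_rejected(m2a_regime):
    tree = random_tree(4, np.random.default_rng(0))
    tree.lengths[0] = -0.1
    with pytest.raises(ValueError):
        simulate_codon_alignment(tree, m2a_regime, 10, seed=0)


def test_equilibrium_codon_frequencies_reached():
    """On a long two-taxon branch, leaf codon counts match F3x4 equilibrium."""
    tree = Tree.from_newick("(a:4.0,b:4.0);")
    regime = SelectionRegime.m0(1.0, kappa=2.0)
    sim = simulate_codon_alignment(tree, regime, 10_000, seed=13)
    pi = f3x4_frequencies(None)
    counts = np.bincount(sim.alignment.codon_matrix().ravel(), minlength=61)
    _, p = stats.chisquare(counts, pi * counts.sum())
    assert p > 0.01


# --- Nei-Gojobori counting oracle for dN/dS recovery ----------------------

_NT = "TCAG"


def _syn_fraction(codon: str, pos: int) -> float:
    syn = 0
    for alt in _NT:
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if mutant in CODON_INDEX:
            if AMINO_ACIDS[CODON_INDEX[mutant]] == AMINO_ACIDS[CODON_INDEX[codon]]:
                syn += 1
    return syn / 3.0


def nei_gojobori(seq1: str, seq2: str):
    """NG86 proportions of synonymous/nonsynonymous differences and sites."""
    S = N = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1 = sum(_syn_fraction(c1, p) for p in range(3))
        s2 = sum(_syn_fraction(c2, p) for p in range(3))
        S += (s1 + s2) / 2
        N += 3 - (s1 + s2) / 2
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        if len(diffs) == 1:
            p = diffs[0]
            mutant = c1[:p] + c2[p] + c1[p + 1 :]
            if mutant in CODON_INDEX and AMINO_ACIDS[CODON_INDEX[mutant]] == AMINO_ACIDS[CODON_INDEX[c1]]:
                sd += 1
            else:
                nd += 1
        elif len(diffs) == 2:
            # average over the two mutational pathways
            for p in diffs:
                mutant = c1[:p] + c2[p] + c1[p + 1 :]
                if mutant in CODON_INDEX and AMINO_ACIDS[CODON_INDEX[mutant]] == AMINO_ACIDS[CODON_INDEX[c1]]:
                    sd += 0.5
                else:
                    nd += 0.5
    ps, pn = sd / S, nd / N
    jc = lambda p: -0.75 * np.log(1 - 4 * p / 3)
    return jc(pn) / jc(ps)


@pytest.mark.parametrize("omega", [0.2, 1.0, 2.0])
def test_counting_dnds_recovers_generating_omega(omega):
    tree = Tree.from_newick("(a:0.15,b:0.15);")
    regime = SelectionRegime.m0(omega, kappa=1.0)  # NG86 assumes no ts/tv bias
    sim = simulate_codon_alignment(tree, regime, 20_000, seed=21)
    est = nei_gojobori(sim.alignment.seqs[0], sim.alignment.seqs[1])
    assert abs(est - omega) / omega < 0.15


# --- recombinant alignments ------------------------------------------------


def test_single_segment_has_no_breakpoints(tree12, m1a_regime):
    rec = simulate_recombinant_alignment([tree12], m1a_regime, [50], seed=0)
    assert rec.breakpoints == []
    assert rec.alignment.c == 50


def test_breakpoint_position_and_seed_invariance(m1a_regime):
    labels = [f"t{i}" for i in range(8)]
    t_a = Tree.from_newick(
        "((((t0:.1,t1:.1):.1,t2:.1):.1,(t3:.1,t4:.1):.1):.1,(t5:.1,(t6:.1,t7:.1):.1):.1);"
    )
    t_b = Tree.from_newick(
        "((((t0:.1,t7:.1):.1,t5:.1):.1,(t2:.1,t6:.1):.1):.1,(t4:.1,(t1:.1,t3:.1):.1):.1);"
    )
    r1 = simulate_recombinant_alignment([t_a, t_b], m1a_regime, [100, 100], seed=1)
    r2 = simulate_recombinant_alignment([t_a, t_b], m1a_regime, [100, 100], seed=2)
    assert r1.breakpoints == [100] == r2.breakpoints
    assert np.array_equal(r1.site_classes, r2.site_classes)  # metadata seed-invariant
    assert r1.alignment.seqs != r2.alignment.seqs
    assert sorted(r1.alignment.ids) == sorted(labels)


def test_mismatched_leaf_sets_rejected(m1a_regime):
    t_a = Tree.from_newick("((a:.1,b:.1):.1,c:.1);")
    t_b = Tree.from_newick("((a:.1,b:.1):.1,d:.1);")
    with pytest.raises(ValueError):
        simulate_recombinant_alignment([t_a, t_b], m1a_regime, [10, 10], seed=0)


# --- genome annotations -----------------------------------------------------


def test_enrichment_factor_zero_keeps_family_out_of_neighbourhoods():
    spec = example_genome_spec(seed=3, enrichment_factor=0.0)
    ann = simulate_genome_annotation(spec)
    nb = build_neighbourhoods(ann, flank=spec.flank)
    fam = ann.genes[ann.genes["family"] == "classIV"]
    inside = genes_inside(fam.reset_index(drop=True), nb)
    assert inside.sum() == 0


def test_cluster_construction_matches_collapsing_rule():
    spec = SyntheticGenomeSpec(
        chromosome_lengths=[50e6],
        n_background_genes=0,
        family_specs=[FamilySpec("fam", 3, 5, gap=10_000)],
        markers=[("chr1", 25e6)],
        seed=5,
    )
    ann = simulate_genome_annotation(spec)
    fam = ann.genes[ann.genes["family"] == "fam"].reset_index(drop=True)
    assert len(fam) == 15
    occurrences = collapse_tandem_clusters(fam, max_gap=500_000)
    assert len(occurrences) == 3
    assert set(occurrences["n_genes"]) == {5}


def test_infeasible_packing_rejected():
    spec = SyntheticGenomeSpec(
        chromosome_lengths=[1e5],
        n_background_genes=100,  # 100 x 5 kb into 100 kb cannot fit
        family_specs=[],
        markers=[],
    )
    with pytest.raises(ValueError):
        simulate_genome_annotation(spec)


# --- domain tables ----------------------------------------------------------


def test_single_architecture_mix_classifies_uniformly():
    table = simulate_domain_table(10, {"RING,BBOX,CC,B30.2": 1.0}, seed=1)
    calls = classify_table(table)
    assert len(calls) == 10
    assert all(c.trim_class == "IV" for c in calls)


def test_novel_architecture_flagged():
    table = simulate_domain_table(5, {"RING,TM,B30.2": 1.0}, seed=2)
    calls = classify_table(table)
    assert all("novel_combination" in c.flags for c in calls)


def test_empty_mix_gives_empty_table():
    table = simulate_domain_table(5, {}, seed=3)
    assert len(table) == 0


def test_unknown_domain_token_rejected():
    with pytest.raises(ValueError):
        simulate_domain_table(5, {"RING,WD40": 1.0}, seed=0)
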