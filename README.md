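# trimevol

Evolutionary analysis of fish TRIM gene families: codon site-model
positive-selection inference, recombination-aware segmentation, site-wise
hypervariability profiling, domain-architecture classification, and
MHC-neighbourhood co-localization enrichment — with a synthetic-data
generator so every stage runs and is testable without external downloads.

## The problem

Teleost fish genomes carry large, fast-evolving families of TRIM
(tripartite-motif, RING–B-box–coiled-coil) genes whose C-terminal B30.2
domains mediate pathogen recognition. Characterising such a repertoire
involves four recurring analyses:

1. **Architecture classification** — assign each protein to one of the
   nine TRIM structural classes from its ordered domain string
   (e.g. RING,BBOX,CC,B30.2 → class IV), flag incomplete RBCC modules and
   novel domain gains (chromodomain, RanBD/cyclophilin-A, RING–TM–B30.2).
2. **Hypervariability profiling** — per-column Shannon entropy
   H = −Σ f_a log2 f_a over the 20 amino acids; sites with H > 2 bits are
   hypervariable, and overlap of hypervariable sets is compared across
   families through a joint alignment.
3. **Positive selection** — maximum-likelihood codon site models
   (GY94×HKY85; M0, M1a, M2a, M7, M8) on a fixed tree, where ω = dN/dS
   varies across sites. Nested pairs are compared by likelihood-ratio test
   (2ΔlnL vs χ², df 2), and positively selected sites are identified by
   (Bayes) empirical Bayes at posterior > 0.95.
4. **Recombination-aware re-testing** — a greedy breakpoint scan that
   compares single- vs segmented-phylogeny fits under small-sample
   corrected AIC (per-segment NJ trees, HKY85 + Γ4), then re-runs the
   selection tests per non-recombinant segment.
5. **MHC co-localization** — merge ±5 Mb neighbourhoods around MHC(-paralogue)
   markers, collapse tandem gene clusters to single occurrences, and test
   family enrichment inside neighbourhoods with a 2×2 Pearson χ² (df 1, no
   continuity correction).

`docs/methods.md` documents the models, defaults and numerical choices.

## Worked example

Simulate an alignment with known positive selection, fit the site models,
and test:

```python
import numpy as np
from trimevol.models import SelectionRegime
from trimevol.simulate import simulate_codon_alignment
from trimevol.selection import fit_site_model, lrt, site_posteriors
from trimevol.trees import random_tree

tree = random_tree(24, np.random.default_rng(42), mean_branch=0.15)
regime = SelectionRegime.m2a(0.60, 0.25, 0.20, 4.0, kappa=2.0)  # 15% of sites at dN/dS = 4
sim = simulate_codon_alignment(tree, regime, 400, seed=5)

m1a = fit_site_model(sim.alignment, tree, "M1a")
m2a = fit_site_model(sim.alignment, tree, "M2a", init_from=m1a)
test = lrt(m1a, m2a)
post = site_posteriors(m2a, sim.alignment, tree, method="BEB")
print(f"omega_pos = {m2a.omega_pos:.2f}  p_pos = {m2a.p_pos:.3f}")
print(f"2dlnL = {test.two_delta_lnl:.1f}  df = {test.df}  p = {test.p_value:.3g}")
print(f"positive sites (posterior > 0.95): {int(post['significant'].sum())}"
      f" of {int((sim.site_classes == 2).sum())} truly positive")
```

prints

```
omega_pos = 4.69  p_pos = 0.142
2dlnL = 599.6  df = 2  p = 6.39e-131
positive sites (posterior > 0.95): 60 of 62 truly positive
```

The fitted positive class (ω̂ = 4.69 on 14.2% of sites) recovers the
generating regime (ω = 4 on 15%), the likelihood-ratio test is decisive,
and empirical Bayes flags most of the truly selected sites.

The enrichment stage reproduces the published genome-wide worked example
exactly: 31 of 62 collapsed class-IV occurrences inside neighbourhoods
holding 7,884 of 24,147 genes gives

```python
from trimevol.enrichment import enrichment_test
r = enrichment_test(31, 31, 7884, 16263)
print(f"chi2 = {r.chi2:.2f}  p = {r.p_value:.4f}")   # chi2 = 8.51  p = 0.0035
```

A command-line interface mirrors the library
(`trimevol classify|entropy|select|recomb|coloc|simulate|run`); `run`
executes a YAML-configured multi-stage pipeline with deterministic,
diffable plain-text reports.

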