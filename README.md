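# ssgblup

Single-step genomic evaluation of superovulatory response traits in
donor cows: relationship matrices (pedigree **A**, genomic **G**,
blended single-step **H**), AI-REML variance components for a two-trait
repeatability animal model, BLUP breeding values with PEV-based
reliabilities, and selection/kinship diagnostics — plus a synthetic
herd generator so the whole pipeline is testable without proprietary
records.

## Who this is for

Animal breeders and quantitative geneticists evaluating repeatedly
measured traits — here the total number of embryos/oocytes per flush
(TNE) and the number of good embryos (NGE) in embryo-transfer donor
herds — when only a subset of animals is genotyped.  Single-step GBLUP
keeps non-genotyped animals in the evaluation through the pedigree
while genotyped animals contribute realized marker relationships.

## The model

For traits *i* ∈ {TNE, NGE}:

```
y_i = X_i b_i + Z_i a_i + W_i pe_i + e_i

var[a; pe; e] = [Ga ⊗ K, 0, 0; 0, Gpe ⊗ I, 0; 0, 0, Re ⊗ I],  K ∈ {A, H}
```

with fixed effects year, month, program, technician and linear +
quadratic age covariates; `pe` is the donor's permanent environmental
effect shared by all her flushes.  The single-step matrix is

```
G* = 0.95 G + 0.05 A22
H  = A + block-correction driven by (G* − A22)
H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹]
```

with `G` from VanRaden's first method on QC'd dosages (MAF > 0.01,
call rate > 0.95, HWE p > 0.001).  Components are estimated by
average-information REML; reliability of cow *i*'s EBV is
`rel_i = 1 − PEV_i/(k_ii σ²_a)`.  Selected elites are judged against
empirical nulls of mean kinship `R_ij = m_ij/√(m_ii m_jj)` over random
candidate subsets.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from ssgblup import (SimSpec, simulate_dataset, run_four_settings,
                     select_top, mean_kinship, empirical_null, empirical_p)

spec = SimSpec(n_cows=200, mean_flushes=6.0, n_markers=1000, seed=42)
data = simulate_dataset(spec, effect_matrix="A")

results, reml, mats = run_four_settings(
    data.phenotypes, data.pedigree, data.genotypes,
    reml_kwargs={"max_iter": 60},
)
for m in ("A", "H"):
    r = reml[m]
    h2 = r.vc.heritability()
    print(f"REML with {m}: h2(TNE) = {h2[0]:.2f} +- {r.derived_se['h2_tne']:.2f}, "
          f"h2(NGE) = {h2[1]:.2f} +- {r.derived_se['h2_nge']:.2f}, "
          f"r_g = {r.vc.genetic_correlation():.2f}")

cands = mats["G"].ids
for (bm, rm), pr in sorted(results.items()):
    t = pr.table.query("trait == 'tne' and cow_id in @cands")
    print(f"BLUP {bm}, components {rm}: mean reliability (TNE, genotyped cows) "
          f"= {t['reliability'].mean():.3f}")

ebv = results[("H", "A")].table.query("trait == 'tne' and cow_id in @cands")
top = select_top(ebv.set_index("cow_id")["ebv"], 25)
null = empirical_null(mats["A"], cands, n=25, iters=100_000, seed=1)
mk = mean_kinship(top, mats["A"])
print(f"top-25 mean pedigree kinship = {mk:.3f} "
      f"(random-set null mean {null.draws.mean():.3f}, "
      f"p = {empirical_p(null, mk):.3f})")
```

Output:

```
REML with A: h2(TNE) = 0.18 +- 0.09, h2(NGE) = 0.08 +- 0.06, r_g = 0.80
REML with H: h2(TNE) = 0.13 +- 0.09, h2(NGE) = 0.08 +- 0.06, r_g = 0.71
BLUP A, components A: mean reliability (TNE, genotyped cows) = 0.458
BLUP A, components H: mean reliability (TNE, genotyped cows) = 0.362
BLUP H, components A: mean reliability (TNE, genotyped cows) = 0.468
BLUP H, components H: mean reliability (TNE, genotyped cows) = 0.370
top-25 mean pedigree kinship = 0.071 (random-set null mean 0.071, p = 0.485)
```

Reading it: heritability estimates on this small 200-cow herd carry
large standard errors but sit in the expected low-to-moderate range;
with the *same* variance components, predicting with **H** yields a
slightly higher mean reliability than **A** (0.468 vs 0.458, 0.370 vs
0.362) because genomic ties add information for genotyped cows; and the
EBV-selected top 25 of these 80 candidates happens to be no more
related than a random subset (p ≈ 0.5) — with a realistic selected
fraction (25 of several hundred candidates) selection concentrates
relatives and the p-value drops, which is exactly what the diagnostic
is for.

A command-line pipeline wraps the same functions:

```sh
ssgblup simulate --seed 3 --n-cows 200 --out-dir sim
ssgblup qc --genotypes sim/genotypes.csv --out-dir qc
ssgblup reml --matrix H --pedigree sim/pedigree.csv \
    --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv \
    --gaussian-traits
ssgblup blup --matrix H --varcomp-from H ... && ssgblup select ebv_H_H.csv ...
```

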