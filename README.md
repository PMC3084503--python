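# surfcons

Structural exposure and evolutionary conservation profiling of missense
variants on protein structures.

## The problem

Why do some amino-acid substitutions in platelet membrane glycoproteins
(integrin αIIbβ3, the GPIb-IX-V complex, integrin α2β1, CD109) act as
alloantigens — provoking antibodies that cause neonatal alloimmune
thrombocytopenia and transfusion refractoriness — while others at the very
same receptors cause inherited bleeding disorders (Glanzmann
thrombasthenia, Bernard-Soulier syndrome), and others still are silent?
A structural/evolutionary answer: alloantigenic polymorphisms sit on
**solvent-exposed, evolutionarily variable** positions (tolerated, but
visible to the immune system), while disease mutations hit **buried,
conserved** positions that maintain the fold.

`surfcons` implements the full quantitative workflow behind that contrast
as a reusable, tested pipeline:

1. **Solvent accessibility** — Shrake–Rupley style numerical SASA with a
   rolling probe (radius 1.4 Å), per atom and per residue:
   `A_i = (m_i / n) · 4π(r_i + r_probe)²`, with `m_i` the unoccluded points
   of a deterministic golden-spiral lattice. Relative accessibility
   normalises to the same residue X as the centre of an extended Gly-X-Gly
   tripeptide computed with identical engine parameters; a residue is
   *buried* when its relative SASA is below 5%.
2. **Conservation** — empirical-Bayes per-column rate inference: the
   Felsenstein pruning likelihood of each alignment column under a
   reversible 20-state model, averaged over a discrete-gamma rate prior
   (`E[r | column] = Σ_k r_k L_k p_k / Σ_k L_k p_k`), then binned into
   conservation grades 9 (conserved) … 1 (variable).
3. **Variant annotation** — joins variant tables (e.g. `Leu33Pro`,
   `Lys611del`) to structures through a curated numbering map with a
   mandatory wild-type identity check, keeping explicit sentinels for
   disordered regions and proteins without structures.
4. **Group statistics** — tie-corrected Kruskal–Wallis H with chi-square
   (or permutation) p, pairwise exact/asymptotic rank-sum follow-ups, and
   mean ± SD group summaries.
5. **Synthetic data** — toy folds with known buried cores, ideal
   tripeptides, alignments simulated along trees with planted site rates,
   and a seeded end-to-end benchmark with planted group structure.

The package bundles transcriptions of the published annotation tables for
the three variant groups (17 platelet alloantigens, 13 disease mutations,
8 non-immunogenic SNPs) as TSV data.

## Worked example

```python
import numpy as np
from surfcons import (SasaParams, sasa_profile, reference_sasa,
                      published_group_values, GroupedSample, kruskal_wallis)
from surfcons.synthetic import make_tripeptide

# Gly-X-Gly reference scale (Å²), computed by the engine itself
for x in ("GLY", "ALA", "TRP"):
    print(x, round(reference_sasa(x), 1))
# GLY 87.2
# ALA 111.6
# TRP 256.4

# three-group comparison on the bundled published accessibility values
groups = published_group_values()["sasa"]
comp = kruskal_wallis(GroupedSample(groups))
print(comp.summary())
```

prints (abridged):

```
Kruskal-Wallis rank comparison
==============================
H = 21.8977 on 2 df, tie correction 0.9997
p = 1.757e-05  (significant at 0.05)

  group  n      mean        sd
    hpa 14 53.345238 21.868167
disease 13  5.418718  7.547336
neutral  8 21.132917 18.555468
```

i.e. alloantigen residues average 53% relative accessibility, disease
mutations 5.4%, non-immunogenic SNPs 21%, and the three groups differ
(H = 21.9, p < 10⁻⁴). The same call on the conservation grades gives
H = 21.3, p = 2.4 × 10⁻⁵ (alloantigens mean grade 2.8 = variable, disease
mean 8.2 = conserved).

The conservation fit follows the model/results idiom:

```python
from surfcons import SiteRateModel
result = SiteRateModel.from_files("alignment.fasta", "tree.nwk").fit()
print(result.summary())          # rates, grade histogram, parameters
result.profile                   # DataFrame: column, rate, grade, label, variety
```

A CLI mirrors the stages: `surfcons sasa`, `conserve`, `profile`, `stats`,
`run --config run.yaml`, `make-fixtures --seed N --out dir`, `config
--defaults`.

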