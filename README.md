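# adductscan

Tools for asking which self-peptides can carry an isolevuglandin (IsoLG)
lysine adduct and still be presented by class I MHC.

IsoLGs are lipid-peroxidation electrophiles (C20H32O4) that covalently adduct
protein lysine ε-amines, forming pyrrole/lactam-family species. Adducted
self-peptides presented by MHC-I can activate autoreactive CD8+ T cells, a
mechanism implicated in hypertension. `adductscan` implements the
computational side of that screening problem for immunologists and structural
bioinformaticians:

- **Peptide chemistry** — validated peptide objects, lysine-adduct species
  with user-editable elemental deltas, monoisotopic masses, and PRM precursor
  m/z targets (`(M + z·m_p)/z`) for the pyrrole, lactam, anhydropyrrole and
  anhydrolactam chemotypes, singly and doubly charged.
- **Template selection and threading** — pick the best solved peptide–MHC
  template by ungapped BLOSUM62 score and thread a query sequence onto its
  backbone.
- **Adduct accommodation scoring** — a transparent surrogate for all-atom
  refinement energies: `score(i) = −PSSM(i, aa_i) + κ·w_s·(1 − exposure_i)`,
  lower is better. The change on in-silico adduction at lysine *i*,
  ΔScore = score(adducted) − score(unadducted), is zero exactly when the
  position is fully solvent-exposed. An adapter slot accepts external
  all-atom backends.
- **Binder prediction** — position-specific scoring matrices
  (log2-odds, Laplace pseudocounts), percentile ranks against a 100 000-
  peptide random background, with "strong binder" = rank ≤ 0.5; binary
  binder calls from IC50 (binder ⇔ IC50 ≤ 500 nM).
- **Statistics** — exact (full-enumeration) and tie-corrected asymptotic
  Mann–Whitney rank-sum tests; per-position ΔScore aggregation over
  non-anchor lysines and the "favorable position" call (≥ m peptides with
  no score increase).
- **The screening funnel** — kidney-overexpression filter (fold > 4 vs the
  max over other tissues), ortholog mapping, 9-mer enumeration, strong-binder
  filter, favorable-lysine filter, deduplication — plus the population-based
  HLA panel selection rule (top 10 alleles with phenotype frequency > 5 %
  per population, union over populations).
- **Synthetic data** — seeded generators for every input with planted ground
  truth, so the whole pipeline is testable without downloads.

## Worked example

```python
from adductscan import (parse_peptide, apply_adduct, precursor_mz,
                        default_h2db, delta_score, ComplexModel)
import numpy as np

p = parse_peptide("LAGKNLTHI", acetylated=True)   # SGLT2-derived 9-mer
print(sorted(p.lysine_positions()))               # [4]

q = apply_adduct(p, 4, "pyrrole")
print(round(precursor_mz(q, 1), 4), round(precursor_mz(q, 2), 4))
# 1308.7926 654.8999   <- PRM targets for the N-acetylated pyrrole adduct

db = default_h2db()
model = ComplexModel(parse_peptide("LAGKNLTHI"), None, np.empty((0, 4)), "none")
print(delta_score(model, 4, "pyrrole", db))
# 0.0   <- position 4 is fully exposed in the default H-2Db profile:
#          the adduct is accommodated with no score increase
```

The same computation from the shell:

```
$ adductscan mass-calc --peptide LAGKNLTHI --acetyl --adduct pyrrole@4 --charges 1,2
species  z  mz
pyrrole  1  1308.792586
pyrrole  2  654.899931
```

`adductscan screen` runs the full candidate funnel over a proteome FASTA plus
expression/ortholog tables, and `adductscan make-fixtures --seed N --out DIR`
writes a complete synthetic input set with planted truth.

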