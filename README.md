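# myotcr

Analysis of T-cell receptor beta-chain (TCRβ) repertoires from paired
muscle and peripheral-blood samples of idiopathic inflammatory myopathy
(IIM) patients — for immunologists and clinical researchers working with
UMI-counted AIRR-seq clone tables.

In inflammatory myopathies, T cells infiltrate muscle tissue, and the
clonal composition of the muscle repertoire carries information about the
disease process. `myotcr` quantifies that composition and relates it to
clinical disease activity:

* **Clonality and diversity.** Each sample is randomly subsampled to a
  common depth of 10,000 UMI reads (sampling individual reads without
  replacement), clone frequencies `f_i` are expressed as percent of the
  subsampled total, and three statistics summarise the distribution:
  the **Gini index** `G = Σ_i Σ_j |f_i − f_j| / (2 n Σ f)` (overall clonal
  expansion; 0 = perfectly even, →1 = one clone holds all reads), the
  **Shannon entropy** `H = −Σ f_i ln f_i` and the **Gini–Simpson index**
  `D = 1 − Σ f_i²` (larger = more diverse). Clones with `f_i ≥ 0.5%` are
  **dominant**; the *impact* of a clone set is its cumulative frequency.
* **Tissue restriction.** Within a subject, each clone
  (V gene, CDR3 amino acids, J gene) is labelled *muscle-restricted*
  (not retraced in the paired blood repertoire at the analysis depth),
  *shared*, or *blood-restricted*, and dominant-muscle-clone restriction
  is pooled across the cohort.
* **CDR3 features.** Per-clone CDR3 length, net side-chain charge and
  mean Kyte–Doolittle hydrophobicity, plus V-gene usage, compared across
  compartments and overlap classes with nonparametric tests.
* **Clone clustering.** Pairwise Hamming distances between CDR3 amino-acid
  sequences; a per-pool *dynamic threshold* is the valley between the two
  modes of the distance density (Gaussian KDE, floored at 3 amino acids);
  clones closer than the threshold form single-linkage clusters, and
  clusters spanning several patients expose shared clonal signatures.
* **Clinical association.** Pearson correlation of Gini/Shannon/Simpson
  with serum creatine kinase (CK, U/L) and manual muscle testing (MMT)
  scores, per compartment.

A fully ground-truthed **synthetic cohort generator** (20 patients with
paired blood+muscle, 10 blood-only healthy controls by default) emulates
the statistical structure the analysis assumes — skewed clone-frequency
distributions with stronger expansion in muscle, a configurable fraction
of dominant muscle clones absent from blood, longer and more hydrophobic
CDR3s with TRBV20-1 bias in muscle-restricted clones, TRBV29-1 bias in
blood, and CK/MMT linearly coupled to muscle clonality — so the whole
pipeline is exercisable, and testable against planted truth, without any
sequencing data.

## Worked example

```python
from myotcr import CohortConfig, generate_cohort, diversity, overlap

samples, meta, truth = generate_cohort(CohortConfig(), seed=1)
sub = {s.sample_id: diversity.subsample_reads(s, depth=10_000, seed=k)
       for k, s in enumerate(sorted(samples, key=lambda s: s.sample_id))}
profiles = diversity.profile_frame([diversity.diversity_profile(s)
                                    for s in sub.values()])
print(profiles.groupby("compartment")[["gini", "shannon", "simpson"]]
      .median().round(3))
```

```
              gini  shannon  simpson
compartment
blood        0.520    7.033    0.997
muscle       0.727    5.587    0.977
```

Muscle repertoires are markedly more clonal than blood (higher Gini,
lower entropy and Simpson diversity), as planted by the generator.

```python
cls = [overlap.classify_overlap(sub[f"P{i:02d}_M"], sub[f"P{i:02d}_B"])
       for i in range(1, 21)]
summary, per_subject = overlap.cohort_overlap_summary(cls)
print(summary[["n_dominant_muscle", "n_dominant_muscle_restricted",
               "pct_restricted_rounded"]].to_string(index=False))
```

```
 n_dominant_muscle  n_dominant_muscle_restricted  pct_restricted_rounded
               480                           133                      28
```

Of 480 dominant muscle clones pooled over the 20 synthetic patients, 133
(28%) cannot be retraced in the paired blood sample — matching the
generator's planted restriction fraction of 0.28.

The same run from the shell, end to end (simulate → ingest → subsample →
metrics → overlap → features → cluster → associate, with a manifest):

```bash
myotcr run --out run1 --seed 1
```

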