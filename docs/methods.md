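# Methods

## Data model

The unit of observation is the clonotype: within a sample a clone is
identified by the triple (V gene, CDR3 amino-acid sequence, J gene), and
its abundance is the number of unique UMIs observed for it — the
molecule count used as "reads" everywhere. Duplicate keys in an input
table are merged by summing counts at ingest, which makes ingest
idempotent and row-order invariant. Compartments are fixed to
{blood, muscle}: every downstream rule is a two-compartment rule, so
other labels are rejected rather than silently carried along. Clone
tables are AIRR-rearrangement-style TSV (`v_call`, `j_call`,
`junction_aa`, `duplicate_count`), with a dialect map for arbitrary
headers. Whether upstream clonotype calling was nucleotide- or
amino-acid-level is not observable here; the amino-acid key is the
default and a CDR3-only key is available wherever clones are matched
across compartments (`classify_overlap(key="cdr3")`), because V-gene
annotation noise between samples is common.

## Depth normalisation and diversity statistics

Samples are normalised to a fixed depth of 10,000 reads by sampling
individual UMI reads without replacement — a multivariate-hypergeometric
draw over clones — with a recorded seed; one draw per sample is the
default (repeat-averaging can be scripted over seeds). Samples below the
target depth are a hard error; a logged keep-all fallback exists for
exploratory use. UMIs, not clones, are resampled because the UMI is the
countable molecule.

On the subsampled frequencies (percent of total reads, dominance cutoff
0.5% applied after subsampling):

* Gini index, mean-absolute-difference form, computed via the sorted
  identity in O(n log n) and property-tested against the O(n²) pairwise
  oracle. Its ceiling at finite n is (n−1)/n; an optional normalised
  variant (× n/(n−1)) makes the single-clone limit exactly 1.
* Shannon entropy in nats (base switchable); group comparisons are
  base-invariant.
* Simpson diversity in the Gini–Simpson form 1 − Σf², so that larger
  values mean more diversity; inverse Simpson available.

## Overlap classification

A clone is "found" in a compartment when it has ≥ 1 UMI at the analysis
depth (`min_umi` configurable). Labels partition the union of the
subject's clone keys and are symmetric under swapping compartments.
Restriction is assessed post-subsampling, and is monotone in blood
depth: removing blood reads can only create, never destroy, restriction.
Pooled summaries report the restricted percentage at full precision and
rounded to whole percent.

## CDR3 features

Length is the residue count. Net charge is side-chain counting at pH 7,
(#K + #R) − (#D + #E) + 0.1·#H; a Henderson–Hasselbalch mode with
configurable pH sums per-residue ionisation instead (side chains only —
the CDR3 is an internal segment, so termini are ignored).
Hydrophobicity is the residue mean on the Kyte–Doolittle scale (higher =
more hydrophobic); Eisenberg and (sign-flipped) Hopp–Woods scales are
offered under the same orientation. Group summaries are per unique
clone, unweighted by UMI count; a read-weighted mode exists. V-gene
usage defaults to percent of distinct clones (`by_clone`), with
`by_read` emitted alongside since the two can rank genes differently
when a single clone is highly expanded.

Feature-group comparisons use pairwise two-sided Mann-Whitney tests with
Bonferroni adjustment over the pairs within each feature. A literal
two-factor ANOVA was considered and not implemented: with group and
feature as crossed factors the features live on incommensurable scales,
so the factorial model has no clean interpretation here.

## Clone clustering

Distances are Hamming distances between CDR3 amino-acid sequences;
unequal-length pairs are undefined and default to infinite distance
(never clustered), with an optional Levenshtein mode (via edlib) for
users who prefer edit distance. The dynamic threshold is estimated from
a Gaussian KDE (Silverman bandwidth, grid step 0.01) over the finite
pairwise distances: the two highest local maxima are located and the
density minimum strictly between them is the valley, rounded half-up,
floored at 3 amino acids. Two robustness rules apply:

* fewer than two local maxima → unimodal fallback, threshold 3;
* the valley must dip below 0.8 × the lower flanking peak. Pools mixing
  several CDR3 lengths produce one distance mode per length class;
  those ripples are shallow, unlike the deep valley separating related
  (distance 1–3) from unrelated (distance ≈ sequence length) pairs, and
  must not be mistaken for bimodality. Shallow-valley densities fall
  back to the floor.

Clusters are connected components of the graph with an edge for every
finite distance strictly below the threshold (`edge_rule="le"` switches
to ≤, giving "up to 3 mismatches" semantics at the floor). Components
are single-linkage groups, so relatedness is transitive; raising the
threshold only coarsens the partition (property-tested). Within-sample
clustering uses per-sample thresholds; the cross-patient analysis pools
dominant muscle clones cohort-wide and uses one pooled threshold.

## Statistics

Two groups: two-sided Mann-Whitney U (exact for small tie-free samples,
normal approximation with tie correction otherwise — verified against
full enumeration over rank assignments at n₁ = n₂ = 4). Three or more:
Kruskal-Wallis omnibus plus pairwise Mann-Whitney with Bonferroni over
the pairs. Descriptives are medians with IQR. Correlations are Pearson r
with two-sided p from the t-distribution on n−2 df; incomplete pairs are
dropped and logged; CK can optionally be log10-transformed (it spans
orders of magnitude) but the default is the raw scale. The association
panel is the 3 metrics × 2 covariates × 2 compartments grid over
patients, α = 0.05.

## Synthetic cohort

Defaults: 20 patients (paired blood + muscle) and 10 blood-only healthy
controls; 2,000 clones per sample realised multinomially at 25,000 reads
(depth conserved exactly), then analysed at the standard 10,000-read
subsample. Generating frequencies follow a one-parameter rank power law
`p_i ∝ i^(−s)`: a single skew knob is the simplest family producing
realistically heavy-tailed rank-frequency curves, with blood shape 0.6
and muscle shape 1.0 ± 0.15 (uniform per-patient jitter, which is what
spreads clonality across patients). At these settings a muscle sample
carries a few dozen dominant clones and its model Gini lies around
0.63–0.85, strictly above blood.

Each muscle clone is independently flagged *restricted* with probability
0.28; restricted clones are removed from the paired blood generating
pool entirely (hard restriction). An optional detection-limit mode
instead down-weights them by a factor of 0.02, modelling presence in
blood below the detection limit — in that mode the measured restricted
fraction exceeds the hard-restriction truth of zero by construction.
Blood draws 30% of its reads from the shared muscle clones
(proportionally to their muscle frequencies) and 70% from a private
power-law pool, so dominant shared clones are essentially always
retraced in blood at the analysis depth.

CDR3s are random strings "C…F" with length 8 + Poisson(6) (≈14 residues;
restricted clones add +3 to the Poisson mean) and i.i.d. interior
residues; restricted clones draw residues from an exponentially tilted
alphabet whose tilt is solved numerically so the mean Kyte–Doolittle
value rises by 0.5. No attempt is made at biologically valid V(D)J
junctions, positional CDR3 composition, or convergent recombination —
so passing tests demonstrate correct measurement of planted effects, not
realism of TCR sequence space. V genes come from a 20-gene TRBV
vocabulary: restricted clones triple the TRBV20-1 weight, blood-private
clones triple TRBV29-1, shared muscle clones are neutral.

Clinical markers are linear in the muscle generating-model Gini:
CK = −3000 + 8000·G + N(0, 800) (clipped at 1 U/L, a rarely hit guard),
MMT = 100 − 40·G + N(0, 6). With the default Gini spread these couplings
give analytic population correlations of about +0.54 (CK) and −0.40
(MMT), of the magnitude reported for myositis cohorts, computed in
closed form as `b·sd(G)/sqrt(b²·var(G) + σ²)` with var(G) integrated
numerically over the shape jitter. MMT is a linear surrogate score and
is not clipped to an instrument range. When studying null behaviour
(couplings set to zero) the CK intercept must be raised into the
physiologic range, since the negative default intercept exists only to
offset the slope term.

All randomness flows from one seed through spawned per-subject streams,
so any subject's repertoire is independent of cohort size. An optional
public-motif plant seeds one dominant clone within Hamming distance 1 of
a shared motif into the first k patients, for exercising cross-patient
cluster detection.

## Problem sizes and numerical choices

The test suite exercises replicate-cohort properties at the default
cohort design: 100 cohorts for parameter recovery (muscle-vs-blood
clonality ordering, CK–Gini correlation within ±0.1 of the analytic
target, restricted-fraction recovery within ±0.05), and 100 null cohorts
(1,200 panel correlations) for type-I calibration at α = 0.05 ± 2
percentage points. The 200-replicate restricted-fraction Monte Carlo
runs at a reduced per-cohort size (2 patients, 800 clones), which leaves
the fraction estimand unchanged. Gini values are clamped to 0 below
1e-15 to absorb rounding at perfect evenness; subsampled-metric bias
against the infinite-depth model values is below 0.02 in Gini at the
default depth for 1,000-clone repertoires (reported by
`truth_recovery_report`).

## Known limitations

* Hamming-only distances ignore indels; unequal-length relatives are
  invisible to the default clustering.
* The dynamic threshold depends on kernel and bandwidth choices the
  underlying method leaves open; Silverman + grid 0.01 are defaults, and
  both are overridable.
* The generator's frequency model is a rank power law, not a fitted
  repertoire distribution; absolute diversity values are not calibrated
  to any real cohort, only the orderings and couplings are.
* Statistical tests assume independent subjects; no repeated-measures
  structure is modelled.
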