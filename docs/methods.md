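# Methods

## Data model and cleaning

Genotypes are diploid, ordered nucleotide pairs read directly from the GT
field; phased and unphased separators are equivalent, and the pair order is
preserved so the 16 ordered symbols AA…TT form the working alphabet
((A,G) and (G,A) are distinct symbols; a config flag in `preprocess` can
canonicalise pairs alphabetically for sensitivity analysis, off by
default). Records containing any missing genotype, and records whose REF or
ALT is longer than one base, are dropped at parse time with logged counts —
every downstream statistic assumes complete single-base diploid data.

Site-level cleaning applies three rules in order: (1) multi-base reference
removed; (2) any ALT containing the reference nucleotide removed; (3) sites
where every individual is homozygous-reference removed. After cleaning,
individuals homozygous for the reference are masked per site; sites whose
retained individuals all share one symbol (the similarity set) carry no
between-individual contrast and are excluded. Only the dissimilarity set
feeds panel selection.

## Selection stages

**Stage 1 (α/β).** For each (SNP, population) over training individuals:
α = n_p^i/n_p, β = f_p^i/n_p^i (β undefined at n_p^i = 0; modal-count ties
do not affect β). A SNP is diagnostic for p iff α = β = 1. The stage keeps
the union of diagnostic sets over populations, then drops SNPs whose pooled
retained training symbols are uniform. One shared, population-stratified
80/20 split (floor rounding of the train count per stratum, both sides
non-empty) serves selection and every later evaluation, so no test
individual ever influences selection.

**Stage 2 (DBSCAN outliers).** Stage-1 SNPs are rows of an integer matrix
(symbol codes 1–16, masked samples 0 — masked entries participate in the
Euclidean distance like any coordinate, since nothing in the 16-symbol
encoding distinguishes them otherwise). DBSCAN is implemented from first
principles: a core point has ≥ MinPts points (itself included) within ε;
clusters are maximal density-connected sets grown in input order; border
points join the first-discovered cluster; everything else is an outlier.
Distances are exact (chunked `cdist`; no spatial index at these scales).
Defaults MinPts = 2 and ε = 0.1 are the published operating point; with
integer codes and ε < 1 the clusters are exactly the duplicate-row groups,
so the outliers are the SNPs with a unique genotype pattern across training
samples. The matrix is not normalised before clustering (a `--normalize`
style option was considered and rejected as the default: the integer
encoding is the documented operating point). `scan_epsilon` reproduces the
empirical choice of ε by maximising downstream 26-class accuracy over a
grid, ties to the smaller ε.

**Stage 3 (correlation pruning).** Each candidate SNP is fit as a
single-feature 26-class softmax classifier on its allele-context value
(count of non-reference nucleotides, 0/1/2) and scored on the test split:
overall accuracy plus, for each continent j, the percentage of continent-j
test individuals whose *predicted population's continent* is j
(continent-level credit; the alternative — exact-population credit — would
conflate sub-population confusion with continental signal in the very
profiles used to judge continental redundancy). Pearson correlation is
taken over the five continent elements only; zero-variance profiles have
undefined correlation and never trigger pruning. The greedy scan ranks by
the overall column (continental panels) or one continent column (pairwise
panels), ties broken by input (genomic) order, and keeps a SNP iff its
correlation with **every** previously kept SNP is ≤ th. The threshold scan
covers th = 0.10…0.99 in 0.01 steps and reports the best small panel:
highest accuracy subject to a 206-SNP cap, ties to the smaller panel, then
the smaller threshold.

Panel size is **not** guaranteed monotone in th under this forward scan: a
SNP retained only at a higher threshold can itself prune several
lower-ranked SNPs that a lower threshold would have kept. This is a
property of the algorithm (the single-blocker variant, checking only
against the seed SNP, would be monotone but prunes less safely); a unit
test pins a deterministic counterexample.

## Classifier

Softmax regression (no hidden layer): z = Wx + b, probabilities by
exponentiation and normalisation with max-subtraction (mathematically
identical, overflow-safe). Training minimises weighted-mean cross-entropy
with an L2 penalty on the weights by full-batch gradient descent from zero
initialisation — deterministic without a seed. Defaults: learning rate 0.1,
500 epochs, L2 1e-4, raw 0/1/2 features without standardisation. An
optional single tanh hidden layer (`hidden_units`, seeded init) exists for
sensitivity analysis only. `predict` takes the first class within 1e-9
relative of the maximal probability: single-feature 26-class fits contain
exact symmetries between populations with identical genotype-count
profiles, and a bitwise argmax would break those ties by floating-point
summation noise; the tolerant argmax makes predictions invariant to
mathematically equivalent computation orders while preserving the
documented first-class tie-break. The per-SNP scoring fits on the unique
(feature value, label) pairs with multiplicities as sample weights, which
has identical gradients to the naive per-sample fit (the suite checks the
equivalence).

## Synthetic data

The generator emulates a 26-population / 5-continent design (population
codes and continental assignment follow the standard 1000-Genomes-style
layout) under a two-level Balding–Nichols model: ancestral REF frequency
p ~ U(0.05, 0.95); continental frequency Beta(p(1−F_c)/F_c,
(1−p)(1−F_c)/F_c); sub-population frequency drawn analogously around the
continental value with F_s; genotypes are two independent allele draws kept
in draw order. Defaults — 20 samples per sub-population, 5,000 SNPs,
F_c = 0.15, F_s = 0.05, 2 planted AIMs per population — are the conditions
used throughout the test suite; 0.15 is a realistic continental-scale
divergence and 0.05 a realistic within-continent one, and 5,000 independent
SNPs keep a full pipeline run around a minute on one CPU.

Planted AIMs make the ground truth exact: the target population is
homozygous-ALT and every *other* population carries exactly one
heterozygous (REF, ALT) sentinel individual, the rest homozygous-REF. A
perfectly fixed difference (no sentinels) would leave only one genotype
symbol among retained individuals and land in the similarity set, silently
removing the AIM before Stage 1; the sentinels keep the site dissimilar
while preserving the exact α = β = 1 signature of the target population,
and one sentinel per population makes the probability that a train/test
split strands them all in the test set negligible (0.2^25).

What the simulator deliberately omits: linkage disequilibrium (SNPs are
independent, so DBSCAN finds almost no duplicate rows and nearly all
Stage-1 SNPs emerge as outliers — on real, LD-rich data the clustering
prunes far more), admixed individuals, genotyping error and missingness
beyond what tests inject by hand, and realistic allele-frequency spectra.
Passing tests therefore demonstrate the machinery's correctness and the
end-to-end recovery of planted and drift-generated signal, not real-data
performance levels.

`estimate_fst` (validation only) is a multi-locus Weir–Cockerham-style
ratio-of-averages estimator from genotype counts; on the default simulation
it recovers the configured continental F_st within a few hundredths.

## Numerical and reproducibility choices

All artifacts are written deterministically (fixed float formatting, sorted
JSON keys, gzip with zeroed mtime), so reruns with the same config are
byte-identical. A single pipeline seed drives the split; the simulator has
its own seed. Degenerate cases: a candidate SNP constant on the training
set trains to the prior and scores as a constant (majority-class)
classifier, logged; an empty Stage-1 selection aborts the pipeline with the
stage name; empty matrices cluster to empty label sets.

## Known limitations

Evaluation granularity at the default scale is coarse — pairwise tasks
hold only 8 test individuals (accuracy steps of 12.5%), so comparisons
against baselines saturate at the 100% ceiling. The published headline
numbers (96.75% at 206 SNPs, the confusion matrix, the per-pair
sub-population table) depend on the full-scale reference dataset and are
not reproduced here; the package reproduces the *procedure* and verifies
it on synthetic ground truth. Softmax training has no early stopping; the
fixed epoch budget is part of the deterministic contract.
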