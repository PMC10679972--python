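# Methods

`spatial_ith` implements the analysis layer of a multi-region,
multi-omics tumour heterogeneity study design: per patient, a
superficial primary subregion (PT_sup, roughly endoscopic-biopsy depth),
a deep primary subregion (PT_deep), a lymph-node metastasis (LN_met) and
a matched normal. The package consumes called variants, cancer cell
fractions, HLA copy-number tables, DSP probe counts and per-gene
differential statistics; it does not perform alignment, variant calling,
copy-number or purity estimation, HLA typing or neoantigen prediction.

## Somatic filtering and region partitions

Variants are identified by the key (chrom, pos, ref, alt). The quality
gates exclude records with VAF < 0.02 or total coverage < 10 reads; both
bounds are exclusion conditions, so records sitting exactly on a
threshold are retained. Region partitions tabulate, for every non-empty
subset of tumour regions, the number of keys called in exactly that
subset; unique fractions divide single-region counts by the number of
distinct keys. Gene frequencies treat each (patient, region) pair as one
sample and count samples with at least one non-silent mutation in the
gene ("non-silent" = every class except silent, the usual oncoprint
convention).

## Clonal architecture and the ITH index

A mutation with CCF > 0.8 (strict) is clonal. For each region-sample the
main cluster C_main is the cluster with the largest mean CCF among
clusters comprising more than one mutation (ties: larger size, then
smaller id); every other cluster is subclonal, and

    ITH = n_sub / (n_main + n_sub)

where the denominator counts all clustered mutations. When no cluster
has more than one mutation the computation refuses rather than guessing.
CCF values and cluster labels are expected as inputs (from a clonal
deconvolution tool or the simulator). When labels are absent, a
deliberately simple stand-in clusterer is applied: a one-dimensional
Gaussian-mixture EM with means initialised at evenly spaced quantiles,
fitted for k = 1..6 and selected by BIC. Quantile initialisation makes
the fit a function of the value multiset only, so labels are
deterministic and stable under input permutation without any seed. A
hard-assignment k-means residual criterion was rejected here because,
with a BIC-style penalty, it over-splits tight well-separated CCF modes
(splitting a Gaussian in half keeps paying for itself in residual
reduction); the soft-likelihood BIC does not have this pathology.

## Parsimony phylogenies

Each patient's regions plus an artificial all-zero outgroup ("normal")
form a binary character matrix (mutation presence/absence). With at
most 8 taxa the package enumerates every unrooted binary topology
(unrooted trees on n taxa correspond to rooted trees on the n-1
non-outgroup taxa), scores each topology by summed per-character
minimum changes — Fitch small parsimony, which is exact for binary
characters — and roots the best at the outgroup. Ties between
topologies are resolved by enumeration order, which is fixed by the
taxon order of the matrix; the number of co-optimal topologies is
reported.

Branch lengths are integer mutation counts: for each character, all
assignments of states to internal nodes are enumerated, minimum-change
assignments are kept, and among them the one minimising the total depth
of change-bearing edges is chosen, with a preference for state 0 at
shallower nodes on exact ties. This pulls ambiguous changes toward the
root, maximising trunk attribution, and guarantees that branch lengths
sum to the parsimony score. The rule is a documented choice: with
homoplasy there is no unique most-parsimonious placement, and published
multi-region trees of this kind are typically finalised by hand.

Trunk / shared / private classification is intentionally *not* read off
the tree: a mutation is truncal iff present in all tumour regions,
private iff present in exactly one, shared otherwise. This makes the
classification well-defined even under topology ties, and the truncal
count equals the number of all-ones rows regardless of the search.

Driver-trunk enrichment builds the 2x2 table (driver vs other) x
(trunk vs branch, branch = shared + private) and computes the two-sided
Fisher exact p by hypergeometric tail enumeration.

## Driver calling

A non-silent variant in a curated driver-gene list is a putative driver
if (a) the exact variant, the same genomic site, or at least three
catalogue entries within a closed ±15 bp window on the same chromosome
appear in the COSMIC-style catalogue, or (b) the gene is annotated
recessive and the variant is truncating (nonsense / frameshift /
splice) with SIFT < 0.05 or PolyPhen > 0.995. Criterion (a) takes
precedence for reporting. "Site" is read as genomic position rather
than amino-acid residue, and the ±15 bp window is closed; both readings
are assumptions recorded here because the source rules do not pin them
down. The driver gene list and catalogue are user-supplied tables.

## Genomic biomarkers

TMB = non-synonymous mutations (substitutions and indels alike) per Mb
of captured exome; graded H (> 10), M ([2.5, 10]) and L (< 2.5). TNB is
graded analogously at 4.5 and 0.5 neoantigens/Mb; the neoantigen count
is an input. MSI score is the percentage of unstable microsatellite
loci, MSI-H iff ≥ 20. The capture size defaults to 40 Mb (typical whole
exome) and is configurable everywhere it is used.

## HLA LOH

An allele is lost iff its copy number is < 0.5 **and** the allelic
imbalance between the two allele-specific coverage tracks is significant
at p < 0.01, both strict. The imbalance p comes either precomputed or
from a paired two-sided Student t-test over the per-window tracks
(t = mean(d)/(sd(d)/√n), n−1 df; zero-variance differences give p = 1
with a warning). A sample is LOH if any of its six class-I alleles is
lost; a patient is LOH if any region-sample is — the any-region rule is
a documented choice, since region-discordant LOH is common and the
patient-level convention is not otherwise fixed. Region association uses
an exact Fisher test; the R x 2 generalisation enumerates all tables
with fixed margins under the multivariate hypergeometric null, feasible
at cohort scale (n ≤ 45).

## Mutational spectra and refitting

SNVs with trinucleotide context map onto the canonical 96 classes (six
pyrimidine-centred substitutions × 16 flanking contexts,
substitution-major COSMIC ordering); purine-reference mutations are
reverse-complemented. Exposure refitting against a user-supplied
signature matrix uses forward selection with non-negative least-squares
refinement: signatures enter greedily while the squared reconstruction
error improves by more than a relative tolerance (1e-4), weights below
0.06 — the convention of refitting tools of this family — are dropped
and the remainder renormalised to sum to one. The procedure is
deterministic and its reconstruction error can never exceed that of the
best single signature. De novo extraction and opportunity-matrix
renormalisation are out of scope.

## DSP protein profiling

AOIs pass QC iff FOV detection > 75, binding density in [0.1, 2.25] and
(nuclei > 20 or area > 1600 μm²); the rejection report counts every rule
an AOI fails. Technical normalisation divides each AOI by the ratio of
its positive-control geometric mean (S6, Histone H3, GAPDH) to a
reference — by default the cohort geometric mean of those values, which
preserves relative expression between AOIs; a fixed reference can be
supplied to pin the absolute scale. Background normalisation divides
each target by the geometric mean of the three IgG isotype controls
(ratio rather than subtraction, the GeoMx convention), yielding
signal-to-background values whose log2 is the conventional SNR display.
Optional per-AOI division by area or nuclei count is available but off
by default, as the order of those adjustments is not standardised.

Simulated bulk values are arithmetic means over a sample's AOIs (all,
tumour-only or stroma-only). Differential proteins use the two-sided
Wilcoxon rank-sum test with Benjamini-Hochberg correction across
proteins; a protein is significant iff FDR ≤ 0.05 and the linear fold
change exceeds 1.5 in either direction (|FC| > 1.5 read as FC > 1.5 or
FC < 2/3). Cell-abundance scores are the mean of log2 marker signals
per cell type, hence translation-equivariant under uniform rescaling.

## DEG partitioning

A gene is differentially expressed iff FDR < 0.05 and |log2FC| > 1,
both strict. Venn partitions of two contrasts sharing a reference group
are directional: concordant overlaps are counted per direction, and a
gene significant in both contrasts with opposite directions lands in an
explicit discordant cell instead of being dropped. `partition_consistency`
checks the arithmetic overlap = total − unique for any direction slice.
The bundled `simple_de_test` (library-size scaling, +0.5 pseudocount,
rank-sum p, BH) is a stand-in for a negative-binomial DE model and is
documented as such.

## Synthetic data

The generators emit the study conditions rather than arbitrary toys:
15 patients × 3 tumour regions for the genomic arm; 40 truncal, 25
shared (two-region subsets in a fixed rotation) and 35 private
mutations per patient, private counts allocated 15.72 : 5.02 : 32.00
across PT_sup : PT_deep : LN_met — the unique-mutation make-up the
design emulates; subclonal fraction 0.35 per region with the subclone
at CCF 0.3–0.5 and the clonal cluster at 0.85–1.0; purities 0.6 / 0.7 /
0.5 and mean depth 300×. Observed VAFs are Binomial(depth,
purity·CCF/2)/depth under a diploid heterozygous simplification —
copy-number-aware read models are out of scope because downstream code
consumes CCFs directly. Detected variants are resampled to pass the
calling gates; filter-failing calls are modelled separately as planted
low-quality records (10% rate) flagged only in the ground-truth sidecar.
Ten percent of mutations are drivers, selected with 2:1 truncal odds,
and the generator emits a catalogue plus SIFT/PolyPhen fields that make
the driver rules recover the planted flags exactly.

The DSP generator covers 21 patients × 3 regions × 2 compartments × 2
AOIs with a 24-protein immune panel: lognormal counts (log2 sd 0.5)
on a per-AOI lognormal technical factor (sd 0.3) that also scales the
positive controls; IgG background at level 20; planted effects CD8 ×2,
CD20 ×2 and SMA ×0.5 in LN_met stroma, mirroring the immune-infiltrated
lymph-node phenotype; QC failures injected at 8% with the failing rule
recorded in the truth file. The DE generator emits statistic tables
whose thresholded sets equal an arbitrary planted directional overlap
structure, parameterised by default to 841 = 715 up + 126 down,
373 = 221 + 152, overlap 235 = 177 + 58.

What the generators do **not** emulate: copy-number variation and its
effect on VAF, clustering uncertainty (CCF cluster labels are emitted
noise-free, so parameter-recovery tests check bookkeeping, not
inference), spatial correlation between neighbouring AOIs, batch
effects beyond a scalar per-AOI factor, and count overdispersion beyond
lognormal noise. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic and rule logic are faithful, not that the methods
are robust to real-data noise sources outside the model.

## Numerical and determinism notes

Every stochastic generator draws from a single `numpy.random.default_rng`
stream per call, so fixed seeds give bit-identical tables. Fisher tail
sums compare table probabilities with a 1e-7 relative guard against
floating-point noise. The exhaustive tree search refuses more than 8
taxa by design (10,395 topologies at 8); the test suite checks it
against a split-enumeration, state-assignment brute force on matrices
of up to 6 taxa and 40 characters. Problem sizes used by the bundled
acceptance script — 5,000-gene DE tables, a 15-patient genomic cohort
(1,500 mutation keys), a 21-patient DSP cohort (252 AOIs), 10-seed
power/size sweeps — are the package's chosen desk-scale defaults and
run in a few seconds.
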