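# Methods

## Model

A gene's annotated transcripts define exon start sites (3' acceptor
splice sites plus transcription start sites) and exon end sites (5'
donor sites plus transcription end sites).  These sites cut the gene
into M contiguous segments X_1..X_M, ordered 5' to 3' in transcription
direction, such that any transcript either contains a segment completely
or not at all.  The gene's outermost TSS and TES bound the first and
last segment and carry no parameters; every other distinct site is a
typed internal boundary, so M = M_s + M_e + 1 where M_s and M_e count
modeled start and end sites.

A transcript is a binary state path Z = (Z_1, ..., Z_M), Z_i = 1 iff X_i
is transcribed.  Relative transcript abundance w(Z) is modeled by an
inhomogeneous first-order Markov chain:

* P(Z_1 = 1) = pi, the fraction of transcript output containing X_1;
* at start site s_m: P(1 -> 1) = 1 (a transcribing process ignores an
  acceptor) and P(0 -> 1) = p_m, the conditional usage of the site;
* at end site e_m: P(0 -> 0) = 1 and P(1 -> 0) = q_m.

Reads of fixed length L are generated by drawing a transcript with
probability proportional to l(Z)·w(Z), where l(Z) = max(tl(Z) - L + 1, 0)
is the effective length (number of read start positions; transcripts
shorter than a read emit nothing, including the all-zero path, which
retains its chain probability but never generates data), then a start
position uniformly among the l(Z) possibilities.  A read is summarized
by its *signature*: the ordered set of segments it covers.  The
probability of observing signature g is

    P(g | Theta) = n_g · P_Z(g | Theta) / D(Theta),

with n_g the number of start positions producing g (a pure function of
the segment lengths in g and L), P_Z(g) the chain mass of paths whose
states match g over its span (transcribed on g's segments, silent on the
segments g skips, free elsewhere), and D(Theta) = Σ_Z l(Z) w(Z).  These
probabilities sum to one over all geometrically possible signatures, so
signature counts (c_1..c_J, Σc_j = N) are sufficient statistics.

The package reports both the conditional usages (the parameters
themselves) and marginal usages — P(Z_i = 0)·p_m for a start site,
P(Z_i = 1)·q_m for an end site, i.e. the probability that an exon
actually starts/ends at the site.  The two coincide exactly at sites
every transcript "considers"; ground-truth comparisons against
transcript abundances are defined on the marginal scale.  The default
estimate column is the conditional usage, with the marginal alongside.

## Estimation

EM treats each read's path and start position as latent.  Because n_g
does not depend on the path, the posterior over paths given a signature
is the chain conditioned on the signature's state constraints, computed
by a scaled forward–backward pass per signature (O(J·M) per iteration).
The E-step accumulates expected transition counts A_m (site used),
B_m (site considered but not used) per boundary and the expected count
of reads with Z_1 = 1.

The M-step maximizes Q(Theta) = Σ_m [A_m log x_m + B_m log(1 - x_m)]
− N log D(Theta).  The denominator couples all parameters, so no global
closed form exists; however D is affine in each single parameter
(D = a + b·x with a, b obtained from two evaluations of the
effective-length dynamic program), so each coordinate optimum solves a
quadratic exactly.  One coordinate sweep is therefore an exact partial
M-step and each sweep increases the observed likelihood (generalized
EM).  The quadratic roots use the numerically stable form
t = −(c_1 + sign(c_1)·√disc)/2, roots t/c_2 and c_0/t; the naive formula
loses the interior root to cancellation when the quadratic coefficient
is tiny, which in testing produced likelihood decreases near the
parameter boundary.

D(Theta) itself is computed exactly by a dynamic program over
(state, transcribed-length-capped-at-L) cells that tracks, per cell,
probability mass and the expectation of the true transcribed length,
yielding E[tl; tl ≥ L] − (L−1) P(tl ≥ L) in O(M·L).

Convergence of plain EM is slow on likelihood ridges (strong coupling
between pi and downstream start-site usages), so the fixed-point map is
accelerated with SQUAREM extrapolation.  Every extrapolated proposal is
stabilized by one EM step and accepted only if it improves the observed
likelihood over the plain double step, so the accepted trace remains
monotone (slack 1e-8); on the worked example this cuts iteration counts
from thousands to tens.

Numerical choices: parameters are clamped to [1e-9, 1 − 1e-9] during
iteration and snapped to exact 0/1 on reporting; single-path
probabilities are computed in log space with exact zeros
short-circuiting; the forward–backward and effective-length recursions
use per-step scaling (the standard HMM safeguard, equivalent to log
space but vectorizable).  Default initialization is the maximum-entropy
point 0.5 for every parameter, with up to three seeded random restarts
if an initialization yields a non-finite likelihood.  Convergence is
declared when the relative log-likelihood change falls below 1e-6
(default), capped at 1000 iterations.  The hot kernels (E-step,
effective-length DP, coordinate maximizer) are numba-compiled; results
are identical to the pure-numpy reference paths, which remain in place
for the externally-facing single-call functions.

Signatures that no read geometry or chain path can produce (e.g. a
junction spliced at a modeled boundary of the wrong type) carry zero
likelihood for every parameter value; they are dropped with a warning
and tallied rather than allowed to poison the fit.  A parameter is
reported NA when no observed signature's span touches a segment
adjacent to its boundary (and pi when M = 1, where the likelihood is
flat): this structural rule errs on the side of reporting a number
whenever reads could, even indirectly, inform the parameter.

## Uncertainty

B bootstrap replicates are drawn from multinomial(c/N; N), refit by EM
warm-started at the point estimate, and summarized by percentile
intervals (empirical quantiles of the replicate estimates).  B defaults
to 100 and the level to 95%.  The helper that declares two samples'
usages different when their intervals do not overlap applies no
multiple-testing correction; across many sites this inflates false
positives, and users comparing many sites should correct externally.

## Simulator

The simulator draws reads exactly from the generative model above:
paths are enumerated (genes with M ≤ 20), a path is drawn per read with
probability ∝ l(Z) w(Z), and a start offset uniformly within the path.
It emits signature counts, the implied ground truth (per-path
abundances w renormalized over expressed transcripts and per-boundary
marginal usages), and optionally a SAM file of the reads on a toy
reference so the alignment-input path is testable end to end.

What it deliberately does not emulate: sequencing errors, indels and
soft-clipping, fragment-length and positional bias, variable read
lengths, multimapping, annotation errors.  Passing tests therefore
demonstrate correctness of segmentation, counting and inference under
the model's own assumptions, not robustness to real-library artifacts.

The worked-example gene used across tests and docs has three
transcripts on eight segments with mammalian-scale geometry (exonic
segments 180–300 bp, introns 800 and 1000 bp).  Its default true
parameters — pi = 0.45, p = (0.35, 0.75, 0.55, 0.30),
q = (0.80, 0.85, 0.70) — describe a gene with high donor usage (introns
mostly spliced) and moderately used alternative acceptors.  The setting
was fixed after a Fisher-information analysis of the example geometry:
it is a regime in which 10^5 reads of 100 bp carry enough information
that the maximum-likelihood estimate of every parameter has a sampling
standard deviation well below 0.01–0.015, so recovery within ±0.02 is a
meaningful test of the estimator rather than of luck.  Conditional
usages of start sites deep in a gene are intrinsically the noisiest:
they divide a well-estimated marginal flow by the probability that the
site is considered, inheriting accumulated upstream uncertainty.

Bootstrap calibration is exercised on a five-segment cassette-exon gene
(exon–intron–cassette–intron–exon, 150/200/120/250/180 bp) at
pi = 0.9, p = (0.6, 0.9), q = (0.85, 0.8), with 2000 reads of 50 bp per
repetition and B = 200 — desk-scale sizes chosen so that one hundred
repetitions complete in about a minute while leaving interval coverage
close to nominal.

## Evaluation

Estimated vs true usage at a site is scored by the Bernoulli
Kullback–Leibler divergence u log(u/û) + (1−u) log((1−u)/(1−û)) in
natural log, with the estimate clamped to [1e-6, 1 − 1e-6] and
0·log 0 = 0.  Sites whose true usage is exactly 0 or 1 (unused or
constitutive) are flagged non-variable and excluded from accuracy
summaries.  KL between two usage values is the only divergence
well-defined without additional structure, and it is used for internal
benchmarking only.

## Design notes and limitations

* Coordinates are 0-based half-open internally; GTF input (1-based
  inclusive) is converted on read and all reported tables are 1-based.
  A boundary is reported at the acceptor position (first exonic base)
  for start sites and the donor position (last exonic base) for end
  sites.
* Minus-strand genes are flipped so segment 1 is 5' in transcription
  direction; exon genomic ends become start sites and vice versa.
* Alternative TSS/TES inside the gene are modeled as ordinary start/end
  sites — the chain formalism does not distinguish them; only the
  outermost pair is unparameterized.  Short-read data inform them
  weakly, as they do for any method.
* Transcripts sharing a gene_id but not overlapping are split into
  independent loci (suffixed gene ids) because the chain assumes one
  contiguous TSS-to-TES span.
* Paired-end mates are counted as independent single-end reads;
  fragment-length information is not modeled.
* Reads of non-modal length are skipped with a tally; junctions not on
  modeled boundaries are discarded, not used to extend the model
  (novel-site discovery belongs to upstream assembly).
* The first-order Markov assumption cannot represent long-range
  coupling between distant splice choices; individual site usages can
  remain accurate while implied transcript frequencies are not.
* A single-sample tool: no differential testing across conditions or
  individuals beyond the interval-overlap helper.
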