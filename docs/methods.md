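# Methods

## The meta-QTL model

A QTL report from a mapping study is treated as a noisy observation of an
underlying locus: the reported position `x_i` (cM) is modeled as Gaussian
around the true locus position with a **known** standard deviation derived
from the report's 95% confidence interval, `s_i = CI_i / 3.92`
(3.92 = 2 × 1.96, the width of a 95% normal interval in sd units). Treating
`s_i` as known — rather than estimating component variances — is the
defining feature of the model: precise QTL (narrow CIs) pull consensus
positions harder than vague ones, and the likelihood has no degenerate
zero-variance optima.

Per chromosome, for each candidate K the mixture

    L(π, μ) = Σ_i log Σ_k π_k N(x_i; μ_k, s_i²)

is maximized over the K means and K−1 free weights (p = 2K−1 parameters) by
EM. The E-step computes responsibilities; the M-step sets each mean to the
responsibility- and precision-weighted average
`μ_k = Σ_i r_ik x_i/s_i² / Σ_i r_ik/s_i²` and each weight to the mean
responsibility. K = 1 is closed-form (the precision-weighted mean).

### Model selection

K ranges over 1..min(n, K_max) with K_max = 10 by default. Five criteria are
computed per fit:

- AIC = −2lnL + 2p, AIC3 = −2lnL + 3p, BIC = −2lnL + p·ln n
- AICc = AIC + 2p(p+1)/(n−p−1), reported missing when n ≤ p+1
- AWE = −2lnL_c + 2p(3/2 + ln n), with L_c the classification
  (complete-data) likelihood under hard max-responsibility labels
  (Banfield–Raftery form; no standard closed form exists for "average
  weight of evidence", so this documented choice is used)

Each criterion votes for its minimizing K; the majority wins and ties break
toward smaller K (parsimony). "Choose the lowest value of five criteria" is
not well defined when they disagree, so the vote — with the full criterion
table retained in the output for audit — is this package's documented
resolution.

### Consensus loci

Members go to their maximum-responsibility component (ties: nearer mean,
then lower index; empty components are dropped and logged). The consensus
position is the precision-weighted mean over members, the consensus variance
`1/Σ_i 1/s_i²`, and the 95% CI is ±1.96 sd. Since precisions add, the
consensus CI is never wider than the narrowest member CI and shrinks ~√m for
m comparable members. MQTL are numbered left-to-right per chromosome
(`MQTL{chr}_{index}`).

### Numerical choices

EM runs to a log-likelihood change < 1e-8 or 500 iterations, whichever comes
first, and asserts the monotone-likelihood guarantee every iteration. Each
K > 1 fit takes the best of 10 starts (one quantile start plus
K-means++-style random seeds); the RNG seed defaults to 20240412 and is
recorded in every run's config. Component log-densities are evaluated in log
space with logsumexp, so very distant points cannot underflow.

## Confidence-interval imputation

Missing 95% CIs are imputed as CI = 530/(N·R²) for F2/backcross and
163/(N·R²) for RIL populations, with R² = PVE/100 (PVE is stored on the
percent scale; using percent directly would give sub-0.3 cM intervals,
contradicting the tens-of-cM CIs that mapping studies actually report). DH
and immortalized-F2 populations are homozygous-line designs and use the RIL
constant; unknown types conservatively get the wider F2/BC constant, both
overridable per study. Imputation fills only *missing* CIs and centers them
on the reported position.

## Projection

Study maps and the reference map are related through shared markers. Within
a chromosome, shared markers whose order conflicts between the maps (local
inversions) are discarded — a longest order-consistent subset is kept and
conflicts logged. Position and CI endpoints are then mapped
piecewise-linearly between flanking shared markers, each endpoint using the
scale of the interval it falls in; positions outside the anchored span are
extrapolated at the nearest interval's scale and flagged
(`unanchored_extrapolated`; configurable to drop instead). Projected CIs are
clamped to the chromosome and the position variance is recomputed from the
projected width, so a QTL projected into a compressed region properly gains
precision. QTL already on the reference map pass through unchanged.

## Physical anchoring

The genetic CI maps to base pairs via the nearest physically placed markers
*outside* each CI bound (conservative; nearest-inside available as an
option). When one side has no outside marker the chromosome-end marker is
used and the anchor is downgraded to `interpolated`; physically inverted
flank pairs are swapped and flagged. The physical peak is
`start_bp + (end_bp−start_bp)/(end_cM−start_cM) × CI/2`, literally measuring
half the genetic CI from the left physical bound at the interval's bp-per-cM
rate, rounded to integer bp and clamped to the interval (with a warning)
when the CI exceeds twice the anchored genetic span. Coordinates are
1-based closed (GFF3 convention); BED export converts to 0-based half-open.

## Verification and classification thresholds

All thresholds are config keys whose defaults are the published study's
values, with strict inequalities exactly as printed:

| quantity | default | semantics |
|---|---|---|
| quality filter | CI > 200 cM, PVE < 1%, LOD < 1.5 | removal side strict; at-threshold records kept; missing fields pass unless `strict_filters` |
| MTA window | 500,000 bp | inclusive bounds, same chromosome |
| breeders' MQTL | < 1 Mb and < 4 cM and > 2 members | all strict |
| MTA-MQTL | > 3 overlapping MTAs | `mta_min` configurable — reported counts elsewhere group "3–10 MTAs", so ≥ 3 is a defensible alternative reading |
| homology | E-value < 1e−10 and identity > 40% | strict; best hit per query–subject pair |
| expression | max-over-tissues TPM > 2 (secondary report at 10) | "expressed in at least one tissue"; heat-map export uses log2(TPM+1) |

The core set is the union of breeders' and MTA-verified MQTL.

## The synthetic generator

The generator emulates the statistical structure of the maize drought
compendium, not its biology. Defaults: a 10-chromosome reference map of
789.8 cM each (7898 cM total) carrying 1911 markers per chromosome (~19k
loci, the density of the real reference map) with monotone physical
positions at ~265 kb/cM plus log-normal increment noise (≈2.1 Gb genome);
27 studies with population sizes 49–450 (RIL/F2/BC/DH mix); 511 QTL around
83 planted loci (per-chromosome counts 9/10/9/9/6/8/8/10/7/7). Study maps
are 50% marker subsets of the reference with a per-study linear cM
rescaling (0.85–1.15×), so projection must actually undo a coordinate
change. Each QTL's scatter sd follows from its own Darvasi–Soller CI
(capped marginally inside 200 cM so every record survives the quality
filter, including after decimal round-trips through TSV); 20% of CIs are
withheld to exercise imputation.

LOD and PVE marginals reproduce the published histogram counts
(31/329/119/32 and 101/243/95/72 at n = 511; proportions at other n) by
largest-remainder quota allocation with uniform draws inside each bin, and
trait categories likewise (GY/FR/PM/DTI = 306/122/60/23, i.e.
59.9/23.9/11.7/4.5%). The two marginals are sampled independently — only
marginal bins are published — so any real LOD–PVE correlation is not
emulated. Annotations plant genes inside ±400 kb of true loci (plus uniform
background), MTAs within ±300 kb (a quarter of loci get 4–8, enough to clear
the "> 3" verification bar), homology rows that straddle the E-value and
identity cutoffs exactly, and TPM rows straddling 2 and 10.

What passing tests on this generator show: the estimator recovers planted
cluster structure, the projection inverts known map distortions, and every
filter implements its printed boundary. What they do not show: behavior
under real-data pathologies — correlated LOD/PVE, non-affine map
distortions, misassigned chromosomes, segregation-distorted regions — or
agreement with any particular legacy implementation's EM details.

## Scale choices

The acceptance script runs the full default scenario (511 QTL, 83 loci,
~19k-marker map; ~30 s end to end). The test suite uses a reduced
2-chromosome scenario (80 QTL, 6 loci) for pipeline tests and 100 seeded
replicates of ~6–18 points for the recovery experiment; these sizes give
stable pass/fail behavior while keeping the suite around a minute.

## Known limitations

- No consensus-map construction: the reference map is an input.
- Markers without physical positions are skipped at anchoring; resolving
  them (e.g. by primer BLASTN) must happen upstream.
- No bit-compatibility with legacy meta-QTL GUIs is attempted; the
  parameter count p = 2K−1 reflects the known-variance model and may differ
  from tools that count variances as free.
- GO/KEGG enrichment, heat-map rendering, and qualitative expression-pattern
  classification are out of scope; the package exports the matrices and
  tables those analyses consume.
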