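# Methods

This note records the models, conventions and numerical choices behind
`paired16s`, in the order a reader meets them in the pipeline.

## Study design and data model

The unit of observation is a water sample identified by (station, date,
nucleic-acid type). Stations belong to one of two zones — *Lagoon* (a
semi-enclosed, dam-regulated basin) or *Seaward* (adjacent open water) —
and the zone is a study-design fact: it is validated against a
station→zone map from the config, never inferred from data. Dates are
ISO-8601; "month" always means calendar month. DNA (16S rRNA gene) and RNA
(16S rRNA transcript) samples from the same station and date form a pair;
pairing tolerates missing cells (a station-month with only one assemblage
is reported as unpaired, never silently dropped).

Count tables are samples × taxa matrices of non-negative integers. On disk
the default orientation is taxa × samples (the common amplicon dialect)
with an explicit flag for the transpose, because both dialects circulate
and silent misorientation is a classic failure mode.

## Alpha diversity

* **Rarefaction** draws once per sample from the multivariate
  hypergeometric distribution — the exact model of subsampling reads
  without replacement — to a fixed depth (config default 11,542; samples
  below depth are excluded and listed). One draw with a recorded seed is
  the contract; averaging repeated draws would only shrink a noise term
  that the downstream analyses never interpret.
* **Shannon** uses the natural logarithm (the vegan convention).
* **Faith's PD** is root-inclusive (picante `include.root=TRUE`): the
  minimal spanning subtree always contains the root, so a single-tip
  sample scores its root-to-tip path, not zero. Stated explicitly because
  it changes single-tip values. Missing branch lengths in input newick
  default to 0 with a warning, keeping PD well-defined.

## Beta diversity and ordination

Bray-Curtis BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) is the abundance-based metric;
Sørensen = 1 − 2a/(2a+b+c) is its incidence-based counterpart and is
computed, exactly, as Bray-Curtis on presence/absence.

PCoA is classical scaling: double-centre −½D², eigendecompose, scale
eigenvectors by √λ. **Negative eigenvalues are discarded without
Cailliez/Lingoes correction**, and explained-variation proportions are
taken over the positive eigenvalues only. The Δ-distance framework needs
only the leading-75% subspace, and a correction would perturb exactly the
axis proportions that the 75% rule reads. Eigenvalues with |λ| ≤ 10⁻¹⁰·λmax
are treated as zero. The n₇₅ rule returns the smallest k whose cumulative
proportion reaches the fraction, with a closed boundary (a cumulative sum
exactly at 0.75 qualifies) and a 10⁻¹² float guard.

PERMANOVA uses Anderson's pseudo-F from within/between sums of squared
distances; p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) with raw-label
permutations (999 by default, so the smallest attainable p is 0.001). The
multi-factor table uses sequential sums of squares in the stated term
order (main effects before interactions) via the distance-based linear
model (hat-matrix traces of the Gower-centred matrix); with non-Euclidean
dissimilarities individual term SS can be slightly negative — a known
property of the partition, reported as computed.

## Δ-distance assembly inference

One joint PCoA per metric is computed over **all** samples — both zones,
all months, DNA and RNA together (per-zone ordinations would make the
subspaces incomparable across zones). Each pair's distance is Euclidean in
its metric's own leading-75% subspace; Bray-Curtis and Sørensen
ordinations retain different axis counts by construction, and each uses
its own. Δ = m_BC − m_S exactly. The zone × month summary averages pairs
and classifies by sign with a dead-band ε (default 0: any nonzero mean
classifies, since only the sign is interpreted; ε is configurable for
users who want an explicit indeterminate band). The API deliberately
offers no cross-dataset comparison of absolute Δ. Δ pairs default to the
equal-depth (rarefied) tables; the generator emits equal-depth samples, so
the default is trivially satisfied there.

## RNA:DNA activity ratios

The phantom correction sets DNA = 1 read for every (RNA > 0, DNA = 0)
observation of a pair, *before* proportion normalisation; no other cell
changes, and the change count equals the phantom-cell count exactly. After
normalisation, ratio = RNA proportion / DNA proportion; undefined (NaN,
serialised blank, never 0) only where both assemblages had zero counts.

Genus-level ratios collapse counts to genus **first**, then run adjust →
normalise → ratio. Sum-then-ratio is the only order under which the
phantom rule stays well-defined at coarser ranks (a genus with one
phantom ZOTU and one detected ZOTU is not a phantom genus). Taxa
unclassified at the target rank group under "unclassified <deepest
classified name>". Proportions are always per-sample over the full
(adjusted) taxon set, never over an analysed subset, because normalisation
precedes taxon selection in the pipeline order.

Top-N ZOTU selection ranks by total count over the whole dataset with
lexicographic tie-breaking (deterministic across runs). L/(L+S) averages
stations within zone within month; a month missing a zone gives an
undefined cell. Spearman screens use average ranks and the two-sided
t-approximation, raw (uncorrected) p-values with the conventional 0.05
mask, and flag constant vectors or <4 complete pairs as NaN.

## Time-decay and recurrence

Points are within-station ordered sample pairs (similarity = 1 −
Bray-Curtis; days from calendar dates), pooled across a zone's stations;
cross-station pairs would conflate spatial and temporal turnover.
Zero-similarity points are dropped with a reported count (no
pseudo-count). Both axes are log₁₀-transformed; linear and quadratic OLS
fits report coefficients, adjusted R² = 1 − (1−R²)(n−1)/(n−k−1), and the
model F-test. DNA and RNA are always fitted separately.

**Classification inference.** The 66 pairs of one station reuse the same
12 samples, so pooled OLS t-tests on individual terms are wildly
anti-conservative. When at least three stations contribute, term
significance is therefore assessed at the station level: each station's
points get their own fit and the coefficients are t-tested across
stations (stations are the independent replicates within a zone). With
fewer stations the pooled tests are the fallback. The shape rules:
*recurrent* if the quadratic term is significantly positive and the
quadratic adjusted R² beats the linear; *linear_decay* if the linear
slope is significantly negative and the quadratic term is not
significant; otherwise *indeterminate*.

## Synthetic panel generator

The generator produces the statistical structure the analyses assume, with
ground truth, so regime recovery can be scored. Defaults are the emulated
survey conditions: 2 + 4 stations × 12 months × DNA/RNA, 150 resident
taxa (+50 immigrant pool), depth 12,000 reads (near the survey's
rarefaction depth), lognormal base abundances with σ = 1.5 (few dominant
taxa over a long rare tail), zone-preference blocks (±1 log-unit for 30%
lagoon- and 30% seaward-preferring taxa), per-station-month log noise
σ = 0.15, multinomial read sampling (every row sums to depth exactly), and
phantom injection at rate 0.05 (cells made RNA-positive by moving 1–3
reads from the sample's most abundant RNA taxon, preserving the row sum;
every injected cell is recorded in the ground truth).

**Assembly regimes.** *selection*: RNA = DNA profile × per-taxon lognormal
activity factors (σ = 1 in log space) — same support, different
abundances, hence Δ > 0. *mass_effect*: 30% of resident taxa (drawn from
ranks below the top 30 — dominant residents persist through water-mass
intrusion) are replaced in the RNA assemblage by immigrants entering at
moderate abundance (lognormal, σ = 1) — many presence changes carrying
little abundance mass, hence Δ < 0. Increasing the swap fraction deepens
negative Δ monotonically.

**Temporal regimes.** *recurrent*: a shared seasonal sinusoid per taxon
(amplitude U(0,2) log-units, random phase, 12-month period), so the
community returns toward its starting composition at the annual revisit —
the U-shaped time-decay signature. *drift*: each station follows an
independent Gaussian-process trajectory whose month-lag structure function
is calibrated **in closed loop** so that the expected log₁₀ similarity
declines linearly in log₁₀ lag between two targets (0.80 at 1 month, 0.55
at 11 months) — i.e. the drift regime is *defined* as power-law distance
decay, the canonical monotone-turnover form. The closed loop simulates
the full generative chain (trajectory, station noise, multinomial reads),
compares realised mean log-similarity per lag with the target line, and
rescales the variogram over six iterations; this is necessary because
read sampling and the similarity→log map bend any open-loop schedule. A
plain random walk was rejected at the design stage: it makes
log-similarity linear in *time*, which is curved on log-log axes and
therefore cannot express monotone power-law turnover. Drift displacements
are damped (×0.4) on the top-30 dominants, concentrating turnover in the
mid/rare ranks where it is observed in such systems and stabilising the
decay curve across realisations.

Environment tables couple linearly to the latent season (peaking in
August) and zone signals with Gaussian noise: the lagoon runs fresher,
less turbid, lower-nitrate/phosphate and richer in humus-like FDOM (C2);
temperature anticorrelates with dissolved oxygen and ORP over the season.
Values are clipped at 0 — a zero is a valid below-detection observation.
All randomness flows from a single seed through named
`numpy.random.SeedSequence` child streams ("taxa", "temporal", "station",
"rna", "counts", "phantom", "env").

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real taxonomies and phylogenetic signal in
abundances (labels and the test tree are synthetic), compositional
sequencing artefacts (primer/copy-number bias, chimeras), overdispersion
beyond multinomial noise, spatial autocorrelation between stations, and
mixed or time-varying assembly regimes (each panel has one regime
throughout). Regime-recovery rates measured here are best-case rates for
data whose structure matches the generator.

## Problem sizes and runtime choices

The test suite and the acceptance script run replicate-panel experiments
at 100 panels per regime condition (50 per point of the swap-fraction
grid) and 500 replicates for PERMANOVA null calibration — sizes chosen so
the full suite completes in about a minute on one CPU while keeping the
binomial noise on any reported fraction below ~5 percentage points.

## Known limitations

* The sequential PERMANOVA partition can report slightly negative term SS
  with non-Euclidean dissimilarities (inherited from the distance-based
  linear model, not a bug).
* The station-level decay inference needs ≥3 stations; a two-station zone
  (like the lagoon) falls back to anti-conservative pooled tests, so its
  "recurrent" calls are more confident than its "linear_decay" calls.
* Δ-distance sign recovery assumes a common ordination is meaningful for
  all samples; with very strong batch structure between DNA and RNA
  libraries the joint ordination could absorb the pairing signal itself.
* The phantom correction perturbs DNA profiles by one read per phantom
  cell; at very shallow depths this floor is no longer negligible
  relative to real proportions.
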