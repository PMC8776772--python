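# Methods

This note documents the models behind `protpool`: what the synthetic
community emulates, how acquisition and quantification are modeled, which
numerical conventions are fixed, and what the simulations do and do not
demonstrate about real metaproteomic data.

## Synthetic community model

`simulate_community` builds a ground-truth metaproteome for a small number
of coarse taxonomic groups (default 3) observed over a short time series
(default 4 weekly timepoints) and three filter size fractions
(3.0 / 0.8 / 0.1 µm).

**Sequences.** Protein sequences are i.i.d. over the 20 standard residues
with a marine-proteome-like composition (K+R ≈ 11% combined), so tryptic
peptides average ~9 residues. Lengths are uniform over
`protein_length_range` (default 80–240 residues). Sequence realism beyond
residue composition is irrelevant here: only exact peptide identity drives
mapping ambiguity.

**Sequence sharing.** `shared_sequence_fraction = s` makes each protein of
taxa 2..n, with probability *s*, a byte-identical copy of a same-pool
protein from a uniformly chosen earlier taxon (annotation and id stay
taxon-specific, as for conserved orthologs). Whole-protein duplication is
the chosen operationalization of sequence conservation because only
identical tryptic peptides create mapping ambiguity; partial homology
would only dilute the effect per protein. Copies point backwards, so the
realized shared fraction in taxa 2..n is Binomial(*n* proteins, *s*), and
source taxa lose uniqueness symmetrically.

**Allocation and dynamics.** Each taxon allocates its biomass over three
pools (ribosomal / photosynthetic / other) by `pool_fractions`.
Within a pool, protein shares are lognormal
(`within_pool_abundance_sd`, default 1.0 — a few dominant proteins per
pool, a long dim tail) and fixed over time. Optionally
`n_proteins_by_pool` sets per-(taxon, pool) protein counts; counts
proportional to pool mass keep per-protein brightness comparable across
pools, which is the realistic regime (ribosomal proteins are few but
individually abundant). A fraction `env_dependent_fraction` (default 0.3)
of proteins is environment-dependent: their abundance is multiplied per
timepoint by a mean-one lognormal factor with log-SD `env_effect_sd`
(default 1.0). Constitutive proteins therefore hold an exactly constant
share of taxon biomass, and realized pool fractions drift around their
configured values only through this modulation — the truth table always
reports the realized values.

**Filtration and injections.** Each taxon's protein mass splits across the
three filters by a leaky retention row (default 80/15/5 for the larger
taxa and the reverse for small ones), emulating cell breakage during
sequential filtration. Replicate injections (default 3/2/2 for the
3.0/0.8/0.1 µm fractions) receive independent mean-one multiplicative
lognormal noise with CV `noise_cv` (default 0.1).

**Annotations.** Pool membership is encoded as free-text annotation
phrases drawn from the same keyword families the mapping stage searches
for (e.g. "50S ribosomal protein L12", "chlorophyll a-b binding protein"),
so the keyword classifier is exercised end to end rather than bypassed.

**Replicate cultures.** `simulate_replicate_cultures` generates the
calibration data for the CV cutoff: per condition, protein abundances are
lognormal across replicates with per-protein target CVs drawn from a
configurable profile, using the moment identity CV² = exp(σ²) − 1.

## Measurement model

**Peptide intensities.** A protein's mass signal is apportioned equally
among its mapped peptides, so summed peptide intensity conserves protein
mass exactly; a shared peptide receives the sum of its parents'
contributions. This convention is what makes the exhaustive-sampling
oracle check exact (see below); the alternative — every peptide inheriting
the full parent abundance — would make inferred mass fractions depend on
each protein's peptide count. On top of the apportioned signal, each
peptide carries a fixed mean-one lognormal response factor
(`detectability_sd`, default 1.0) standing in for ionization-efficiency
differences; it is constant across injections, filters and timepoints.

**Retention times.** An additive per-residue hydrophobicity-coefficient
model predicts retention, affinely mapped onto the LC gradient (default
125 min) and clipped. The model is deliberately simple and swappable
behind `RTModel`: the acquisition loop and the cofragmentation score need
only a realistic relative co-elution structure, not accurate absolute
retention. Elution profiles are Gaussian with σ = peak_width/4, so ±2σ
spans the nominal 1.44 min peak width.

**Acquisition.** `simulate_dda_run` walks the gradient in MS1 cycles
(default 0.02 min). Each cycle selects the `top_n` (default 10) most
intense non-excluded precursors whose instantaneous intensity clears the
detection limit; selected peptides are flagged identified, their full
feature intensity recorded, and they enter dynamic exclusion for
`exclusion_duration` (default 0.5 min). The TIC of a run is the summed
intensity of all features, identified or not — the database-independent
normalization channel. The detection limit is expressed as a multiple of
the run's mean feature intensity (default 1.6): intensities are in
arbitrary units, so pinning instrument sensitivity to the typical feature
keeps identification depth comparable across community sizes. The default
was chosen so that per-grain identified-unique-peptide counts span roughly
1–10³ across the sharing sweep — the regime in which the peptide-support
analysis below is informative. `top_n`, exclusion and cycle time are
declared defaults for a generic Orbitrap-class top-N method.
`max_injection_time` (0.008333 min) and `sparse_sampling_degree` (5) are
consumed by the cofragmentation score, not by the acquisition loop.

## Quantification conventions

* Presence rule: a peptide counts in a (timepoint, filter) sample only if
  observed with positive intensity in **every** injection of that sample.
* Normalization: per injection, by the summed identified intensity
  (default) or by the TIC (`normalization="tic"`); injections are averaged
  after normalization (arithmetic mean). All downstream quantities are
  invariant under per-injection intensity rescaling.
* Filter weights for a combined mass fraction use the counts of that
  estimate's own supporting peptides per filter (the worked-example
  reading); filters with undefined estimates get weight zero and the rest
  renormalize, keeping the result a convex combination.
* Taxon relative abundance uses one weight set common to all taxa — all
  observed peptides per filter, times the filter's share of total protein
  mass — because per-taxon weights could push the per-timepoint abundance
  total above one.
* Undefined estimates (no taxon-unique signal) are reported as missing,
  never as zero.
* Pool labels: the keyword classifier returns "none" for proteins outside
  both keyword families; the truth table calls the same grain "other".
  Bias assessment treats them as one grain.
* A protein matching both keyword families is conservatively assigned no
  pool (with a logged warning), replacing the manual curation a real
  analysis would apply. The ribosomal family is the prefix "ribosom" minus
  a small exclusion list for ribosome synthesis/biogenesis and rRNA terms.
* Isoleucine/leucine are distinct residues here: quantification is
  sequence-level, not spectral.

## Trait classification conventions

* Peptide CVs use the sample standard deviation (n−1) over the mean of
  taxon-normalized, filter-combined intensities across timepoints;
  timepoints where the peptide was unobserved are missing values, and
  peptides with fewer than two observations are excluded (and counted).
* The cutoff is the mean across culture conditions of the per-condition
  third quartile (linear-interpolation quantile) of protein-level CVs.
  A CV exactly at the cutoff classifies independent (a deterministic
  boundary rule is required; ties are measure-zero in practice).
* The calibration set is protein-level while field classification is
  peptide-level, mirroring how the cutoff is used in practice.
* Whether filters contribute variance to the field CV is configurable;
  the default combines across filters first (per-filter CVs behind
  `per_filter=True`).

## Bias assessment and the support threshold

`assess_bias` compares, per (taxon, pool) grain: the inferred within-taxon
mass fraction against the true realized fraction, and the grain's inferred
share of total community signal against its true retention-weighted share,
recording the grain's support (identified peptides unique to both taxon
and pool). `sharing_bias_sweep` runs 3-taxon communities (201
proteins/taxon, equal pool allocations, 60–160-residue proteins, one
timepoint, one filter, one injection) across sharing levels
{0, 0.3, 0.6, 0.9} × 10 seeds. `support_threshold` bins grains by support
over the grid (0, 10, 25, 50, 100, 200, 400) and reports the smallest grid
value from which every populated bin has |median relative bias| ≤ 5%.

Two mechanisms produce the low-support underestimation. Sharing removes a
grain's unique peptides, and when pools differ in uniqueness the depleted
pool's numerator falls faster than the taxon denominator. Independently,
a grain supported by few identified peptides has a heavy-tailed numerator
whose median falls below its mean, biasing the median fraction downward.
Both mechanisms attach to low support, which is why peptide count is a
usable sufficiency diagnostic: in the shipped configuration the threshold
lands at 25–50 peptides depending on seed.

## What the tests do and do not show

Passing tests show the inference chain is self-consistent and its biases
behave as designed under the generator's assumptions: i.i.d. sequences,
whole-protein sharing, lognormal abundance and noise, Gaussian elution, a
hard detection limit, no chimeric identifications, no FDR, no
post-translational modifications, no protein-level roll-up. Real
metaproteomes add search-engine error, co-eluting near-isobaric
interference, database incompleteness, and run-to-run retention drift —
none of which are modeled. Conclusions about real data should lean on the
package's *relative* statements (which grains have enough support; how
biases scale with sharing), not on absolute error magnitudes.

## Numerical and design choices

* Oracle equivalence: with exhaustive sampling (top-N above the co-elution
  count, no exclusion, no detection limit, no noise, no sharing) inferred
  pool fractions reproduce the truth table to < 1e-9 — exactness follows
  from the equal-apportioning intensity model.
* Parameter-recovery experiments disable sharing and environmental
  modulation: sharing biases small pools through asymmetric uniqueness
  loss (studied separately by the sweep), and modulation makes realized
  fractions drift from configured targets.
* Quantile convention: linear interpolation between order statistics
  everywhere, so cutoff tests can assert exact equality against an
  independent implementation.
* Degenerate inputs: empty samples, all-zero weights, missing TICs,
  sub-minimum replicate counts and invalid residues raise typed errors
  naming the offending field; estimates with empty denominators are
  undefined rather than zero.
* Determinism: every stochastic stage draws from `numpy` Generator streams
  keyed by the configuration seed (per-injection streams are spawned from
  it); identical configs produce byte-identical outputs, and the pipeline
  manifest records seeds and parameters sufficient to reproduce a run.
* Problem sizes in the shipped tests (tens of proteins per pool for unit
  tests, ~200–500 proteins per taxon for the sweep and recovery
  experiments) are the package's default desk-scale conditions; all are
  plain configuration values and scale up unchanged.
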