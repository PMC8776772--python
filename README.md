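# protpool

Coarse-grained proteomic trait inference from metaproteomes — with a
synthetic-community and data-dependent-acquisition (DDA) simulator for
quantifying when those inferences can be trusted.

## The problem

Shotgun metaproteomics measures peptide intensities from a mixed microbial
community. Summarized into a few **coarse-grained pools** per taxon
(ribosomal proteins, photosynthetic proteins, everything else), those
intensities become interpretable resource-allocation traits: how much of a
taxon's proteome is translation machinery, how much is light harvesting,
and how much of it is produced constitutively regardless of conditions (a
proxy for low regulatory cost). Each inference step, however, carries
biases — peptides shared between taxa cannot be attributed and are dropped,
the instrument samples stochastically and misses dim peptides, and the
normalization factor depends on the search database. `protpool` implements
the inference chain and the simulation machinery needed to measure those
biases against a known ground truth.

## The quantities

**Proteomic mass fraction.** For taxon *t* and pool *g* (e.g. diatom
ribosomes),

```
f_{t,g} = Σ_{p unique to (t,g)} I_p  /  Σ_{p unique to t} I_p
```

where `I_p` are peptide intensities normalized per injection (by the summed
identified intensity, or by the database-independent TIC), kept only if the
peptide was observed in **every** replicate injection of a sample, and
averaged across injections.

**Filter combination.** Size-fractionated filtration (3.0 / 0.8 / 0.1 µm)
is leaky, so each grain is estimated on several filters. Per-filter
estimates are combined as a convex combination with weights
`w_f = n_f / Σ_f n_f` from the supporting peptide counts per filter; 100
supporting peptides split 90/10 across two filters weight them 0.9/0.1.
Taxon *relative abundances* additionally weight each filter by its share of
total protein mass.

**Environment-independent fraction.** Each taxon-unique peptide gets a
coefficient of variation (CV) of its taxon-normalized, filter-combined
intensity across sampling timepoints. The dependent/independent cutoff is
calibrated on replicate cultures grown under identical conditions: per
condition, the third quartile of protein-level CVs; the cutoff is the mean
of those quartiles. The environment-independent fraction of a taxon is the
summed mean intensity of its independent peptides over all its classified
peptides.

**Cofragmentation score.** The expected number of database peptides inside
a peptide's precursor isolation window (default 3 m/z) and chromatographic
peak width (default 1.44 min, retention times from an additive
hydrophobicity model), averaged over charge states 2–3 and discounted by
the degree of sparse sampling (default 5) — a per-peptide risk score for
co-isolation bias.

**The simulator.** `simulate_community` generates a multi-taxon proteome
with configurable pool allocations, inter-taxon sequence sharing
(byte-identical protein copies — the source of mapping ambiguity),
environment-dependent vs constitutive proteins, filter leakage, and
per-peptide response factors. `simulate_dda_run` acquires it with a top-N /
dynamic-exclusion / detection-limit acquisition loop, and `assess_bias`
scores every inferred (taxon, pool) grain against the truth table.

## Worked example

```python
import protpool as pp

config = pp.CommunityConfig(
    n_taxa=3,
    taxon_names=("diatom", "haptophyte", "bacterium"),
    pool_fractions=[
        {"ribosomal": 0.15, "photosynthetic": 0.35, "other": 0.50},
        {"ribosomal": 0.25, "photosynthetic": 0.35, "other": 0.40},
        {"ribosomal": 0.30, "photosynthetic": 0.05, "other": 0.65},
    ],
    n_proteins_per_pool=40,
    seed=1,
)
dataset = pp.simulate_dataset(config, pp.DDAParams())
table = dataset.table.presence_filter()

for taxon in config.taxon_names:
    est = pp.combined_mass_fraction(table, taxon, "ribosomal", 1, dataset.pepmap)
    print(f"{taxon:10s} ribosomal mass fraction week 1: "
          f"{est.value:.3f}  ({est.n_peptides} supporting peptides)")

cultures = pp.simulate_replicate_cultures(
    n_conditions=5, n_replicates=3, n_proteins=500,
    cv_profile={"kind": "uniform", "low": 0.05, "high": 0.5}, seed=2)
cutoff = pp.derive_cutoff(cultures)
records = pp.compute_cv_records(table, dataset.pepmap, taxa=config.taxon_names)
classified = pp.classify_peptides(records, cutoff)
print(f"CV cutoff from replicate cultures: {cutoff.cutoff:.3f}")
for taxon in config.taxon_names:
    frac = pp.environment_independent_fraction(classified, taxon)
    print(f"{taxon:10s} environment-independent fraction: {frac:.3f}")
```

prints

```
diatom     ribosomal mass fraction week 1: 0.091  (88 supporting peptides)
haptophyte ribosomal mass fraction week 1: 0.248  (230 supporting peptides)
bacterium  ribosomal mass fraction week 1: 0.277  (362 supporting peptides)
CV cutoff from replicate cultures: 0.330
diatom     environment-independent fraction: 0.695
haptophyte environment-independent fraction: 0.649
bacterium  environment-independent fraction: 0.748
```

The estimates land near the configured allocations (0.15/0.25/0.30) after
one simulated DDA pass: the diatom value sits lowest on its configured
value because its grain has the fewest supporting peptides. The
environment-independent fractions reflect the default community, in which
30% of proteins respond to conditions.

A subcommand CLI wraps the same stages
(`protpool simulate-community | simulate-dda | quantify | traits | cofrag |
run-all`); `run-all` writes tidy TSVs plus a JSON manifest that records
seeds and parameters for exact reproduction.

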