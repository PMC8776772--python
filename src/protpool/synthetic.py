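"""Ground-truth metaproteome and replicate-culture generators.

The generator emulates the structure of a size-fractionated marine microbial
community sampled over a short time series: a handful of coarse taxonomic
groups, each allocating proteome mass to three coarse-grained pools
(ribosomal, photosynthetic, other), with controllable inter-taxon sequence
sharing (whole-protein duplication, the source of peptide-mapping
ambiguity), environment-dependent vs constitutive proteins across
timepoints, leaky partitioning of each taxon's protein mass across the
3.0/0.8/0.1 um filter fractions, and replicate injections with
multiplicative noise.

Everything downstream (digestion, DDA sampling, quantification, trait
classification) can therefore be scored against a known truth table.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import ProteinRecord

POOLS = ("ribosomal", "photosynthetic", "other")
FILTERS = (3.0, 0.8, 0.1)

# i.i.d. residue frequencies with marine-proteome-like K/R content (~11%
# combined) so that tryptic peptides have realistic lengths (~9 residues).
RESIDUE_FREQS = {
    "A": 0.090, "C": 0.012, "D": 0.053, "E": 0.062, "F": 0.040,
    "G": 0.082, "H": 0.021, "I": 0.055, "K": 0.058, "L": 0.096,
    "M": 0.024, "N": 0.043, "P": 0.046, "Q": 0.038, "R": 0.052,
    "S": 0.065, "T": 0.054, "V": 0.066, "W": 0.012, "Y": 0.031,
}

_RIBOSOMAL_SUBUNITS = ("30S", "50S", "40S", "60S")
_PHOTO_ANNOTATIONS = (
    "photosystem II reaction center protein",
    "photosystem I P700 apoprotein",
    "chlorophyll a-b binding protein",
    "light harvesting complex I protein",
    "plastocyanin",
    "flavodoxin",
)
_OTHER_ANNOTATIONS = (
    "hypothetical protein",
    "ABC transporter substrate-binding protein",
    "DNA-directed RNA polymerase subunit beta",
    "heat shock protein 70",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "elongation factor Tu",
    "citrate synthase",
    "ATP synthase subunit alpha",
    "ketol-acid reductoisomerase",
    "actin",
)


class ConfigError(ValueError):
    """A community configuration violates its invariants."""


def _as_pool_fraction_list(pool_fractions, n_taxa) -> list[dict]:
    if isinstance(pool_fractions, Mapping):
        pool_fractions = [dict(pool_fractions)] * n_taxa
    out = [dict(pf) for pf in pool_fractions]
    if len(out) != n_taxa:
        raise ConfigError("pool_fractions: need one mapping per taxon")
    return out


def default_filter_retention(n_taxa: int) -> np.ndarray:
    """Leaky filter partition: large taxa mostly on the 3.0 um filter
    (80/15/5), small (bacteria-like) taxa reversed."""
    n_large = (n_taxa + 1) // 2
    rows = [[0.80, 0.15, 0.05]] * n_large + [[0.05, 0.15, 0.80]] * (n_taxa - n_large)
    return np.array(rows, dtype=float)


@dataclass
class CommunityConfig:
    """Study conditions for one synthetic community.

    ``biomass_series`` has shape (n_timepoints, n_taxa) and each row sums to
    one; ``pool_fractions`` maps each of ribosomal/photosynthetic/other to a
    per-taxon mass fraction summing to one; ``shared_sequence_fraction`` is
    the probability that a protein of taxa 2..n is a byte-identical copy of
    a protein (same pool) from an earlier taxon; ``env_dependent_fraction``
    is the fraction of proteins whose abundance is modulated across
    timepoints with log-scale SD ``env_effect_sd`` (mean-one multiplicative
    lognormal, so constitutive proteins keep identical expected abundance at
    every timepoint); ``noise_cv`` is the injection-level multiplicative
    noise CV; ``detectability_sd`` is the log-scale SD of the fixed
    per-peptide response factor (ionization efficiency), mean one.
    """

    n_taxa: int = 3
    taxon_names: tuple | None = None
    n_timepoints: int = 4
    biomass_series: np.ndarray | None = None
    pool_fractions: object = None
    n_proteins_per_pool: int = 40
    n_proteins_by_pool: object = None
    shared_sequence_fraction: float = 0.1
    env_dependent_fraction: float = 0.3
    env_effect_sd: float = 1.0
    noise_cv: float = 0.1
    detectability_sd: float = 1.0
    within_pool_abundance_sd: float = 1.0
    protein_length_range: tuple = (80, 240)
    filter_retention: np.ndarray | None = None
    n_injections: tuple = (3, 2, 2)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ConfigError("n_taxa: must be >= 1")
        if self.n_timepoints < 1:
            raise ConfigError("n_timepoints: must be >= 1")
        if self.n_proteins_per_pool < 1:
            raise ConfigError("n_proteins_per_pool: must be >= 1")
        if self.n_proteins_by_pool is not None:
            if isinstance(self.n_proteins_by_pool, Mapping):
                self.n_proteins_by_pool = [dict(self.n_proteins_by_pool)] * self.n_taxa
            self.n_proteins_by_pool = [dict(d) for d in self.n_proteins_by_pool]
            if len(self.n_proteins_by_pool) != self.n_taxa:
                raise ConfigError("n_proteins_by_pool: need one mapping per taxon")
            for d in self.n_proteins_by_pool:
                if set(d) != set(POOLS):
                    raise ConfigError(f"n_proteins_by_pool: keys must be {POOLS}")
                if any(int(v) < 1 for v in d.values()):
                    raise ConfigError("n_proteins_by_pool: counts must be >= 1")
        if self.taxon_names is None:
            self.taxon_names = tuple(f"taxon{i + 1}" for i in range(self.n_taxa))
        else:
            self.taxon_names = tuple(self.taxon_names)
            if len(self.taxon_names) != self.n_taxa:
                raise ConfigError("taxon_names: need one name per taxon")
        if self.pool_fractions is None:
            self.pool_fractions = {"ribosomal": 0.2, "photosynthetic": 0.3, "other": 0.5}
        self.pool_fractions = _as_pool_fraction_list(self.pool_fractions, self.n_taxa)
        for pf in self.pool_fractions:
            if set(pf) != set(POOLS):
                raise ConfigError(f"pool_fractions: keys must be {POOLS}")
            vals = np.array([pf[p] for p in POOLS], float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ConfigError("pool_fractions: values must be in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError("pool_fractions: must sum to 1 per taxon")
        if self.biomass_series is None:
            self.biomass_series = np.full(
                (self.n_timepoints, self.n_taxa), 1.0 / self.n_taxa
            )
        self.biomass_series = np.asarray(self.biomass_series, float)
        if self.biomass_series.shape != (self.n_timepoints, self.n_taxa):
            raise ConfigError("biomass_series: shape must be (n_timepoints, n_taxa)")
        if np.any(self.biomass_series < 0):
            raise ConfigError("biomass_series: fractions must be >= 0")
        if np.any(np.abs(self.biomass_series.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigError("biomass_series: each timepoint must sum to 1")
        if not 0.0 <= self.shared_sequence_fraction <= 1.0:
            raise ConfigError("shared_sequence_fraction: must be in [0, 1]")
        if not 0.0 <= self.env_dependent_fraction <= 1.0:
            raise ConfigError("env_dependent_fraction: must be in [0, 1]")
        for name in ("env_effect_sd", "noise_cv", "detectability_sd",
                     "within_pool_abundance_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.filter_retention is None:
            self.filter_retention = default_filter_retention(self.n_taxa)
        self.filter_retention = np.asarray(self.filter_retention, float)
        if self.filter_retention.shape != (self.n_taxa, len(FILTERS)):
            raise ConfigError("filter_retention: shape must be (n_taxa, 3)")
        if np.any(self.filter_retention < 0) or np.any(self.filter_retention > 1):
            raise ConfigError("filter_retention: values must be in [0, 1]")
        if np.any(np.abs(self.filter_retention.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigError("filter_retention: rows must sum to 1")
        self.n_injections = tuple(int(n) for n in self.n_injections)
        if len(self.n_injections) != len(FILTERS) or any(n < 1 for n in self.n_injections):
            raise ConfigError("n_injections: need a count >= 1 per filter")
        lo, hi = self.protein_length_range
        if lo < 10 or hi < lo:
            raise ConfigError("protein_length_range: need 10 <= min <= max")

    def pool_count(self, taxon_index: int, pool: str) -> int:
        """Number of proteins generated for one (taxon, pool)."""
        if self.n_proteins_by_pool is not None:
            return int(self.n_proteins_by_pool[taxon_index][pool])
        return int(self.n_proteins_per_pool)

    def retention(self, taxon: str, filt: float) -> float:
        return float(
            self.filter_retention[self.taxon_names.index(taxon), FILTERS.index(filt)]
        )

    def injections_for(self, filt: float) -> int:
        return self.n_injections[FILTERS.index(filt)]


@dataclass
class TruthTable:
    """Ground truth for one simulated community.

    ``proteins`` is indexed by protein id with columns ``taxon``, ``pool``,
    ``env_dependent``; ``abundance`` is indexed by protein id with one
    column per timepoint (1-based ints) holding true mass abundance in
    arbitrary units (community total is 1 per timepoint).
    """

    proteins: pd.DataFrame
    abundance: pd.DataFrame
    config: CommunityConfig

    def pool_fractions(self) -> pd.DataFrame:
        """True within-taxon pool mass fractions, tidy over
        (taxon, pool, timepoint)."""
        rows = []
        for tp in self.abundance.columns:
            ab = self.abundance[tp]
            for taxon in self.config.taxon_names:
                sel = self.proteins["taxon"] == taxon
                total = ab[sel].sum()
                for pool in POOLS:
                    mass = ab[sel & (self.proteins["pool"] == pool)].sum()
                    rows.append(
                        (taxon, pool, tp, mass / total if total > 0 else np.nan)
                    )
        return pd.DataFrame(rows, columns=["taxon", "pool", "timepoint", "fraction"])

    def community_share(self, taxon: str, pool: str, timepoint: int,
                        filt: float | None = None) -> float:
        """True share of total community protein mass held by (taxon, pool),
        optionally weighted by filter retention for one filter fraction."""
        ab = self.abundance[timepoint]
        if filt is None:
            weights = np.ones(len(ab))
        else:
            weights = np.array(
                [self.config.retention(t, filt) for t in self.proteins["taxon"]]
            )
        total = float((ab * weights).sum())
        sel = (self.proteins["taxon"] == taxon) & (self.proteins["pool"] == pool)
        return float((ab[sel] * weights[sel.to_numpy()]).sum() / total)

    def protein_mass_per_filter(self, timepoint: int) -> dict:
        """Total protein mass landing on each filter fraction (the analogue
        of a per-filter protein assay used for abundance weighting)."""
        ab = self.abundance[timepoint]
        out = {}
        for j, filt in enumerate(FILTERS):
            ret = np.array(
                [self.config.filter_retention[
                    self.config.taxon_names.index(t), j]
                 for t in self.proteins["taxon"]]
            )
            out[filt] = float((ab * ret).sum())
        return out

    def peptide_env_class(self, parents: Sequence[str]) -> str:
        """A peptide is environment-dependent iff any parent protein is."""
        dep = self.proteins.loc[list(parents), "env_dependent"].any()
        return "dependent" if dep else "independent"


def _random_sequence(rng: np.random.Generator, length: int,
                     residues: np.ndarray, probs: np.ndarray) -> str:
    return "".join(rng.choice(residues, size=length, p=probs))


def _annotation_for(rng: np.random.Generator, pool: str) -> str:
    if pool == "ribosomal":
        sub = rng.choice(_RIBOSOMAL_SUBUNITS)
        chain = rng.choice(["L", "S"])
        return f"{sub} ribosomal protein {chain}{rng.integers(1, 36)}"
    if pool == "photosynthetic":
        return str(rng.choice(_PHOTO_ANNOTATIONS))
    return str(rng.choice(_OTHER_ANNOTATIONS))


def simulate_community(config: CommunityConfig) -> tuple[list[ProteinRecord], TruthTable]:
    """Generate a protein database and matching truth table.

    With ``shared_sequence_fraction = s``, each protein of taxa 2..n is,
    with probability s, a byte-identical sequence copy of a same-pool
    protein from a uniformly chosen earlier taxon (its annotation and id
    remain taxon-specific, as for genuinely conserved orthologs).
    Environment-independent proteins have identical expected abundance at
    every timepoint; dependent proteins are modulated by a mean-one
    lognormal factor per (protein, timepoint).
    """
    rng = np.random.default_rng(config.seed)
    residues = np.array(list(RESIDUE_FREQS))
    probs = np.array(list(RESIDUE_FREQS.values()))
    probs = probs / probs.sum()

    lo, hi = config.protein_length_range
    s = config.shared_sequence_fraction

    sequences: dict[tuple[int, str, int], str] = {}
    records: list[ProteinRecord] = []
    prot_meta = []
    counter = 0
    for ti, taxon in enumerate(config.taxon_names):
        for pool in POOLS:
            for i in range(config.pool_count(ti, pool)):
                if ti > 0 and rng.random() < s:
                    src_tax = int(rng.integers(0, ti))
                    src_idx = int(rng.integers(0, config.pool_count(src_tax, pool)))
                    seq = sequences[(src_tax, pool, src_idx)]
                else:
                    length = int(rng.integers(lo, hi + 1))
                    seq = _random_sequence(rng, length, residues, probs)
                sequences[(ti, pool, i)] = seq
                pid = f"prot{counter:05d}"
                counter += 1
                records.append(
                    ProteinRecord(
                        id=pid,
                        taxon=taxon,
                        sequence=seq,
                        annotations=(_annotation_for(rng, pool),),
                    )
                )
                prot_meta.append((pid, taxon, pool))

    proteins = pd.DataFrame(
        prot_meta, columns=["id", "taxon", "pool"]
    ).set_index("id")
    proteins["env_dependent"] = rng.random(len(proteins)) < config.env_dependent_fraction

    # fixed baseline allocation: heavy-tailed within-pool shares, scaled so
    # each pool holds exactly its configured fraction of taxon biomass
    base_share = np.exp(
        config.within_pool_abundance_sd * rng.standard_normal(len(proteins))
    )
    base = np.empty(len(proteins), float)
    taxon_index = np.empty(len(proteins), int)
    pos = 0
    for ti in range(config.n_taxa):
        pf = config.pool_fractions[ti]
        for pool in POOLS:
            npool = config.pool_count(ti, pool)
            w = base_share[pos: pos + npool]
            base[pos: pos + npool] = pf[pool] * w / w.sum()
            taxon_index[pos: pos + npool] = ti
            pos += npool

    # environment-dependent proteins are modulated multiplicatively around
    # that baseline (mean-one), so constitutive proteins keep an identical
    # expected share of taxon biomass at every timepoint and realized pool
    # fractions drift around the configured values only through modulation
    abundance = {}
    sd = config.env_effect_sd
    dep = proteins["env_dependent"].to_numpy()
    for t in range(config.n_timepoints):
        mod = np.ones(len(proteins))
        if sd > 0:
            z = rng.standard_normal(len(proteins))
            mod[dep] = np.exp(sd * z[dep] - 0.5 * sd * sd)
        biomass = config.biomass_series[t, taxon_index]
        abundance[t + 1] = biomass * base * mod
    abundance = pd.DataFrame(abundance, index=proteins.index)

    truth = TruthTable(proteins=proteins, abundance=abundance, config=config)
    return records, truth


@dataclass
class ReplicateCultureSet:
    """Replicate-culture protein abundances used to calibrate the CV cutoff.

    ``tables`` maps a condition label to a (protein x replicate) abundance
    frame; ``target_cvs`` holds the per-protein CVs each condition was
    generated with.
    """

    conditions: tuple
    tables: dict
    target_cvs: dict

    def __post_init__(self):
        for cond in self.conditions:
            if self.tables[cond].shape[1] < 2:
                raise ConfigError(
                    f"condition {cond!r}: need >= 2 replicates for a CV"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.conditions:
            tab = self.tables[cond]
            for prot, row in tab.iterrows():
                for rep, val in row.items():
                    rows.append((cond, prot, rep, val))
        return pd.DataFrame(
            rows, columns=["condition", "protein", "replicate", "abundance"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReplicateCultureSet":
        tables = {}
        for cond, sub in frame.groupby("condition", sort=True):
            tables[cond] = sub.pivot(
                index="protein", columns="replicate", values="abundance"
            )
        conditions = tuple(tables)
        return cls(conditions=conditions, tables=tables,
                   target_cvs={c: None for c in conditions})


def _draw_target_cvs(rng, cv_profile, n_proteins) -> np.ndarray:
    if isinstance(cv_profile, (int, float)):
        return np.full(n_proteins, float(cv_profile))
    kind = cv_profile.get("kind", "constant")
    if kind == "constant":
        return np.full(n_proteins, float(cv_profile["value"]))
    if kind == "uniform":
        return rng.uniform(cv_profile["low"], cv_profile["high"], n_proteins)
    if kind == "lognormal":
        return rng.lognormal(cv_profile["mean_log"], cv_profile["sd_log"], n_proteins)
    raise ConfigError(f"cv_profile: unknown kind {kind!r}")


def simulate_replicate_cultures(
    n_conditions: int,
    n_replicates: int,
    n_proteins: int,
    cv_profile,
    seed: int = 0,
) -> ReplicateCultureSet:
    """Lognormal replicate-culture abundances with known per-protein CVs.

    ``cv_profile`` is either a float (all proteins share that CV) or a dict
    such as ``{"kind": "uniform", "low": 0.05, "high": 0.5}``.  Replicate
    values for a protein with target CV c are drawn from a mean-preserving
    lognormal with sigma = sqrt(log(1 + c^2)), the moment identity
    CV = sqrt(exp(sigma^2) - 1).
    """
    if n_replicates < 2:
        raise ConfigError("n_replicates: must be >= 2 (CV undefined otherwise)")
    if n_conditions < 1:
        raise ConfigError("n_conditions: must be >= 1")
    rng = np.random.default_rng(seed)
    conditions = tuple(f"condition{i + 1}" for i in range(n_conditions))
    index = [f"prot{i:05d}" for i in range(n_proteins)]
    tables, targets = {}, {}
    for cond in conditions:
        cvs = _draw_target_cvs(rng, cv_profile, n_proteins)
        sigma = np.sqrt(np.log1p(cvs**2))
        means = rng.lognormal(mean=np.log(1e4), sigma=1.0, size=n_proteins)
        z = rng.standard_normal((n_proteins, n_replicates))
        values = means[:, None] * np.exp(
            sigma[:, None] * z - 0.5 * sigma[:, None] ** 2
        )
        tables[cond] = pd.DataFrame(
            values, index=index,
            columns=[f"rep{j + 1}" for j in range(n_replicates)],
        )
        targets[cond] = cvs
    return ReplicateCultureSet(conditions=conditions, tables=tables, target_cvs=targets)
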