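"""Normalization, presence filtering, coarse-grained mass fractions, and
filter-size weighting.

The central quantity is the proteomic mass fraction of a (taxon, pool)
coarse grain: the summed intensity of peptides unique to both the taxon and
the pool, divided by the summed intensity of peptides unique to the taxon.
Per-injection intensities are first normalized by the injection's
normalization factor (the sum of identified peptide intensities, or the
database-independent TIC), averaged across replicate injections, and a
peptide only counts as present in a sample if it was observed in every
injection of that sample.

Because sequential filtration is leaky, the same grain is typically
estimated on several filter fractions; per-filter estimates are combined as
a convex combination weighted by the number of supporting peptides observed
per filter.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .synthetic import FILTERS


class QuantifyError(ValueError):
    pass


class SampleKey(NamedTuple):
    timepoint: int
    filter: float
    injection: int


_DATA_COLUMNS = ["peptide", "timepoint", "filter", "injection", "intensity"]


class IntensityTable:
    """Peptide x sample intensity matrix in long form.

    Parameters
    ----------
    data : DataFrame
        Columns ``peptide, timepoint, filter, injection, intensity``; a
        missing row means the peptide was not observed in that injection.
    tic : DataFrame, optional
        Columns ``timepoint, filter, injection, tic`` — the
        database-independent total ion current per injection.
    protein_mass : DataFrame, optional
        Columns ``timepoint, filter, mass`` — total protein per filter,
        used to weight taxon relative-abundance estimates.
    """

    def __init__(self, data: pd.DataFrame, tic: pd.DataFrame | None = None,
                 protein_mass: pd.DataFrame | None = None):
        missing = set(_DATA_COLUMNS) - set(data.columns)
        if missing:
            raise QuantifyError(f"data is missing columns: {sorted(missing)}")
        if (data["intensity"] < 0).any():
            raise QuantifyError("intensities must be >= 0")
        self.data = data.reset_index(drop=True)
        self.tic = tic
        self.protein_mass = protein_mass
        self._norm_cache: dict = {}

    @classmethod
    def from_observed(cls, runs: Mapping[SampleKey, "ObservedTable"],
                      protein_mass: pd.DataFrame | None = None) -> "IntensityTable":
        """Assemble a table from per-injection DDA outcomes."""
        rows, tic_rows = [], []
        for key in sorted(runs):
            obs = runs[key]
            ident = obs.identified()
            for pep, val in ident.items():
                rows.append((pep, key.timepoint, key.filter, key.injection, val))
            tic_rows.append((key.timepoint, key.filter, key.injection, obs.tic))
        data = pd.DataFrame(rows, columns=_DATA_COLUMNS)
        tic = pd.DataFrame(tic_rows, columns=["timepoint", "filter", "injection", "tic"])
        return cls(data, tic=tic, protein_mass=protein_mass)

    def samples(self) -> list[SampleKey]:
        cols = self.data[["timepoint", "filter", "injection"]].drop_duplicates()
        return sorted(SampleKey(*row) for row in cols.itertuples(index=False))

    def injections(self, timepoint, filt) -> list[int]:
        sub = self.data[(self.data["timepoint"] == timepoint)
                        & (self.data["filter"] == filt)]
        return sorted(sub["injection"].unique())

    def injection_frame(self, sample: SampleKey) -> pd.DataFrame:
        m = ((self.data["timepoint"] == sample.timepoint)
             & (self.data["filter"] == sample.filter)
             & (self.data["injection"] == sample.injection))
        return self.data[m]

    def presence_filter(self) -> "IntensityTable":
        """Keep a peptide's intensities at (timepoint, filter) only if it
        was observed with positive intensity in every injection of that
        sample."""
        data = self.data[self.data["intensity"] > 0]
        n_inj = (data.groupby(["timepoint", "filter"])["injection"]
                 .nunique().rename("n_inj"))
        seen = (data.groupby(["peptide", "timepoint", "filter"])["injection"]
                .nunique().rename("n_seen").reset_index())
        seen = seen.merge(n_inj.reset_index(), on=["timepoint", "filter"])
        keep = seen[seen["n_seen"] == seen["n_inj"]][["peptide", "timepoint", "filter"]]
        out = data.merge(keep, on=["peptide", "timepoint", "filter"], how="inner")
        return IntensityTable(out, tic=self.tic, protein_mass=self.protein_mass)

    def rescale_injection(self, sample: SampleKey, factor: float) -> "IntensityTable":
        """Multiply all intensities of one injection by ``factor`` (used to
        check normalization invariances)."""
        data = self.data.copy()
        m = ((data["timepoint"] == sample.timepoint)
             & (data["filter"] == sample.filter)
             & (data["injection"] == sample.injection))
        data.loc[m, "intensity"] *= factor
        tic = self.tic
        if tic is not None:
            tic = tic.copy()
            mt = ((tic["timepoint"] == sample.timepoint)
                  & (tic["filter"] == sample.filter)
                  & (tic["injection"] == sample.injection))
            tic.loc[mt, "tic"] *= factor
        return IntensityTable(data, tic=tic, protein_mass=self.protein_mass)

    def mean_normalized(self, timepoint, filt, normalization: str = "sum") -> pd.Series:
        """Per-peptide normalized intensity at (timepoint, filter):
        normalize each injection by its normalization factor, then average
        across the injections of the sample (absent = 0 within the sample's
        observed peptide set)."""
        key = (timepoint, filt, normalization)
        if key in self._norm_cache:
            return self._norm_cache[key]
        injections = self.injections(timepoint, filt)
        if not injections:
            return pd.Series(dtype=float)
        per_inj = []
        for inj in injections:
            key = SampleKey(timepoint, filt, inj)
            frame = self.injection_frame(key)
            series = frame.set_index("peptide")["intensity"]
            if normalization == "sum":
                factor = normalization_factor(self, key)
            elif normalization == "tic":
                factor = tic_normalization_factor(self, key)
            else:
                raise QuantifyError(f"unknown normalization {normalization!r}")
            per_inj.append(series / factor)
        combined = pd.concat(per_inj, axis=1).fillna(0.0)
        result = combined.mean(axis=1)
        self._norm_cache[key] = result
        return result


def normalization_factor(table: IntensityTable, sample: SampleKey) -> float:
    """Sum of identified peptide intensities in one injection (the
    database-dependent normalization factor)."""
    frame = table.injection_frame(sample)
    if len(frame) == 0:
        raise QuantifyError(f"sample {sample} has no identified peptides")
    return float(frame["intensity"].sum())


def tic_normalization_factor(table: IntensityTable, sample: SampleKey) -> float:
    """Total ion current of one injection — database independent."""
    if table.tic is None:
        raise QuantifyError("no TIC recorded for this table")
    t = table.tic
    m = ((t["timepoint"] == sample.timepoint) & (t["filter"] == sample.filter)
         & (t["injection"] == sample.injection))
    if not m.any():
        raise QuantifyError(f"no TIC recorded for sample {sample}")
    return float(t.loc[m, "tic"].iloc[0])


def normalization_sensitivity(raw_intensity: float,
                              relative_variation: float) -> tuple[float, float]:
    """Interval of inferred abundance under a symmetric normalization-factor
    variation: raw_intensity * (1 -/+ relative_variation / 2).

    A peptide of raw intensity 100 under 16% normalization variation maps
    to (92, 108).
    """
    if raw_intensity < 0:
        raise QuantifyError("raw_intensity must be >= 0")
    if not 0 <= relative_variation < 2:
        raise QuantifyError("relative_variation must be in [0, 2)")
    half = relative_variation / 2.0
    return (raw_intensity * (1 - half), raw_intensity * (1 + half))


@dataclass(frozen=True)
class MassFractionEstimate:
    taxon: str
    pool: str
    timepoint: int
    filter: float | None  # None for filter-combined estimates
    value: float | None   # None when the taxon denominator is empty
    n_peptides: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def _unique_masks(pepmap: pd.DataFrame, peptides: pd.Index, taxon: str,
                  pool: str | None = None):
    sub = pepmap.loc[peptides]
    taxon_mask = sub["taxon_unique"].to_numpy() & (sub["taxon"].to_numpy(object) == taxon)
    if pool is None:
        return taxon_mask
    pool_mask = taxon_mask & sub["pool_unique"].to_numpy() & (
        sub["pool"].to_numpy(object) == pool
    )
    return taxon_mask, pool_mask


def taxon_normalize(table: IntensityTable, taxon: str, pepmap: pd.DataFrame,
                    timepoint, filt, normalization: str = "sum") -> pd.Series:
    """Taxon-specific peptide intensities as a proportion of the taxon's
    protein biomass on one sample: taxon-unique peptide intensities divided
    by their sum (result sums to one)."""
    mean_norm = table.mean_normalized(timepoint, filt, normalization)
    if len(mean_norm) == 0:
        raise QuantifyError(f"no observations at timepoint {timepoint}, filter {filt}")
    mask = _unique_masks(pepmap, mean_norm.index, taxon)
    vals = mean_norm[mask]
    total = float(vals.sum())
    if total <= 0:
        raise QuantifyError(
            f"taxon {taxon!r} has no taxon-unique peptides in this sample"
        )
    return vals / total


def mass_fraction(table: IntensityTable, taxon: str, pool: str,
                  timepoint, filt, pepmap: pd.DataFrame,
                  normalization: str = "sum") -> MassFractionEstimate:
    """Proteomic mass fraction of a (taxon, pool) grain on one sample.

    Expects a presence-filtered table; injections are averaged after
    per-injection normalization.  The value is the summed intensity of
    taxon-and-pool-unique peptides over the summed intensity of
    taxon-unique peptides; ``n_peptides`` counts the supporting
    (numerator) peptides.
    """
    mean_norm = table.mean_normalized(timepoint, filt, normalization)
    if len(mean_norm) == 0:
        return MassFractionEstimate(taxon, pool, timepoint, filt, None, 0)
    taxon_mask, pool_mask = _unique_masks(pepmap, mean_norm.index, taxon, pool)
    vals = mean_norm.to_numpy(float)
    denom = float(vals[taxon_mask].sum())
    if denom <= 0:
        return MassFractionEstimate(taxon, pool, timepoint, filt, None, 0)
    num = float(vals[pool_mask].sum())
    n_peptides = int((pool_mask & (vals > 0)).sum())
    return MassFractionEstimate(taxon, pool, timepoint, filt, num / denom, n_peptides)


def filter_weights(counts: Mapping[float, int]) -> dict[float, float]:
    """Per-filter weighting coefficients from observed peptide counts.

    weight_f = n_f / sum_f n_f; weights sum to one and a filter with no
    observations gets weight zero.  With 100 peptides split 90/10 between
    the 3.0 and 0.8 um filters the weights are 0.9 and 0.1.
    """
    total = sum(counts.values())
    if total <= 0:
        raise QuantifyError("all-zero peptide counts: weights undefined")
    if any(c < 0 for c in counts.values()):
        raise QuantifyError("peptide counts must be >= 0")
    return {f: c / total for f, c in counts.items()}


def combine_across_filters(
    estimates: Mapping[float, MassFractionEstimate | float | None],
    weights: Mapping[float, float],
) -> float | None:
    """Convex combination of per-filter estimates.

    Filters with undefined estimates get weight zero and the remaining
    weights are renormalized, so the result stays within [min, max] of the
    defined inputs.  Returns None when nothing is defined.
    """
    pairs = []
    for f, est in estimates.items():
        value = est.value if isinstance(est, MassFractionEstimate) else est
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        if f not in weights:
            raise QuantifyError(f"no weight defined for filter {f}")
        pairs.append((weights[f], float(value)))
    if not pairs:
        return None
    wsum = sum(w for w, _ in pairs)
    if wsum <= 0:
        return None
    return sum(w * v for w, v in pairs) / wsum


def combined_mass_fraction(table: IntensityTable, taxon: str, pool: str,
                           timepoint, pepmap: pd.DataFrame,
                           normalization: str = "sum") -> MassFractionEstimate:
    """Filter-combined mass fraction: per-filter estimates weighted by the
    counts of the estimate's own supporting peptides per filter."""
    estimates, counts = {}, {}
    for filt in FILTERS:
        if not table.injections(timepoint, filt):
            continue
        est = mass_fraction(table, taxon, pool, timepoint, filt, pepmap, normalization)
        estimates[filt] = est
        counts[filt] = est.n_peptides if est.defined else 0
    if not estimates or sum(counts.values()) == 0:
        # no supporting peptides anywhere: fall back to taxon-level counts
        # so an all-zero numerator still yields a defined 0.0 estimate
        defined = [e for e in estimates.values() if e.defined]
        if not defined:
            return MassFractionEstimate(taxon, pool, timepoint, None, None, 0)
        value = float(np.mean([e.value for e in defined]))
        return MassFractionEstimate(taxon, pool, timepoint, None, value, 0)
    weights = filter_weights(counts)
    value = combine_across_filters(estimates, weights)
    n = sum(counts.values())
    return MassFractionEstimate(taxon, pool, timepoint, None, value, n)


def taxon_relative_abundance(
    table: IntensityTable,
    taxon: str,
    timepoint,
    pepmap: pd.DataFrame,
    protein_mass: Mapping[float, float] | None = None,
    normalization: str = "sum",
) -> float | None:
    """Relative protein-biomass abundance of a taxon at one timepoint.

    Each filter contributes the taxon's share of that filter's normalized
    identified intensity; filter weights are the per-filter counts of all
    observed peptides, additionally multiplied by the filter's share of
    total protein mass on that day, then renormalized.  Using one weight
    set common to all taxa keeps the per-timepoint abundances summing to
    at most one (the shortfall is signal from non-taxon-unique peptides).
    """
    if protein_mass is None:
        if table.protein_mass is None:
            raise QuantifyError("no protein mass per filter available")
        pm = table.protein_mass
        sub = pm[pm["timepoint"] == timepoint]
        protein_mass = dict(zip(sub["filter"], sub["mass"]))

    shares, weights = {}, {}
    for filt in FILTERS:
        if not table.injections(timepoint, filt):
            continue
        if filt not in protein_mass:
            raise QuantifyError(f"missing protein mass for filter {filt}")
        if protein_mass[filt] <= 0:
            raise QuantifyError(f"protein mass must be > 0 on filter {filt}")
        mean_norm = table.mean_normalized(timepoint, filt, normalization)
        if len(mean_norm) == 0:
            continue
        mask = _unique_masks(pepmap, mean_norm.index, taxon)
        total = float(mean_norm.sum())
        shares[filt] = float(mean_norm[mask].sum()) / total if total > 0 else None
        weights[filt] = len(mean_norm) * protein_mass[filt]
    if not shares:
        return None
    wsum = sum(weights.values())
    norm_weights = {f: w / wsum for f, w in weights.items()}
    return combine_across_filters(shares, norm_weights)


def mass_fraction_table(
    table: IntensityTable,
    pepmap: pd.DataFrame,
    taxa: Sequence[str],
    pools: Sequence[str] = ("ribosomal", "photosynthetic", "none"),
    normalization: str = "sum",
) -> pd.DataFrame:
    """Tidy per-filter and filter-combined mass fractions for every
    (taxon, pool, timepoint)."""
    timepoints = sorted(table.data["timepoint"].unique())
    rows = []
    for tp in timepoints:
        for taxon in taxa:
            for pool in pools:
                for filt in FILTERS:
                    if not table.injections(tp, filt):
                        continue
                    est = mass_fraction(table, taxon, pool, tp, filt, pepmap,
                                        normalization)
                    rows.append((taxon, pool, tp, filt, est.value, est.n_peptides))
                comb = combined_mass_fraction(table, taxon, pool, tp, pepmap,
                                              normalization)
                rows.append((taxon, pool, tp, "combined", comb.value, comb.n_peptides))
    return pd.DataFrame(
        rows, columns=["taxon", "pool", "timepoint", "filter", "value", "n_peptides"]
    )
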