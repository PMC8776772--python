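"""Environment-independent proteomic fraction (a regulatory-cost proxy).

A peptide whose taxon-normalized intensity is stable across sampling
timepoints is operationally "environment-independent": its parent protein
is produced constitutively rather than regulated against conditions.  The
classification threshold on the per-peptide coefficient of variation (CV)
is calibrated externally, from replicate cultures grown under identical
conditions: for each culture condition the third quartile of the
protein-level CV distribution is taken, and the cutoff is the mean of
those third quartiles.  The environment-independent fraction of a taxon's
proteome is then the summed mean intensity of its independent peptides
over all its classified peptides.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import IntensityTable, filter_weights, taxon_normalize, QuantifyError
from .synthetic import FILTERS, ReplicateCultureSet


class TraitError(ValueError):
    pass


def peptide_cv(series) -> float:
    """Coefficient of variation (sample SD over mean, n-1 denominator) of a
    peptide's normalized intensities across timepoints; NaN when fewer than
    two values are defined or the mean is zero."""
    vals = np.asarray(pd.Series(series).dropna(), dtype=float)
    if len(vals) < 2:
        return float("nan")
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(vals.std(ddof=1) / mean)


@dataclass(frozen=True)
class CutoffSpec:
    """Replicate-culture-derived CV threshold: the mean of per-condition
    third quartiles."""

    q3_values: tuple
    cutoff: float

    def __post_init__(self):
        if abs(self.cutoff - float(np.mean(self.q3_values))) > 1e-12:
            raise TraitError("cutoff must equal the mean of the stored Q3 values")
        if self.cutoff < 0:
            raise TraitError("cutoff must be >= 0")


def derive_cutoff(cultures: ReplicateCultureSet) -> CutoffSpec:
    """Protein-level CVs per condition -> per-condition Q3 (linear
    interpolation quantile) -> mean across conditions."""
    if not cultures.conditions:
        raise TraitError("need at least one culture condition")
    q3s = []
    for cond in cultures.conditions:
        tab = cultures.tables[cond]
        if tab.shape[1] < 2:
            raise TraitError(f"condition {cond!r} has fewer than 2 replicates")
        vals = tab.to_numpy(float)
        cvs = vals.std(axis=1, ddof=1) / vals.mean(axis=1)
        q3s.append(float(np.quantile(cvs, 0.75)))
    return CutoffSpec(q3_values=tuple(q3s), cutoff=float(np.mean(q3s)))


def compute_cv_records(
    table: IntensityTable,
    pepmap: pd.DataFrame,
    taxa: Sequence[str],
    normalization: str = "sum",
    per_filter: bool = False,
) -> pd.DataFrame:
    """Per-peptide CVs of taxon-normalized intensity across timepoints.

    By default intensities are combined across filter sizes before the CV
    is taken: per (timepoint, filter) the taxon-unique peptide intensities
    are normalized to sum to one, then per-filter vectors are mixed with
    weights proportional to the taxon's observed peptide count per filter.
    With ``per_filter=True`` a CV is emitted per (peptide, filter) instead.

    Returns a frame with columns ``peptide, taxon, mean_norm_intensity,
    cv, n_timepoints`` (plus ``filter`` in per-filter mode); timepoints
    where the peptide was not observed are treated as missing, and
    peptides observed at fewer than two timepoints get a NaN CV.
    """
    timepoints = sorted(table.data["timepoint"].unique())
    rows = []
    for taxon in taxa:
        if per_filter:
            for filt in FILTERS:
                series_by_tp = {}
                for tp in timepoints:
                    if not table.injections(tp, filt):
                        continue
                    try:
                        series_by_tp[tp] = taxon_normalize(
                            table, taxon, pepmap, tp, filt, normalization)
                    except QuantifyError:
                        continue
                if series_by_tp:
                    frame = pd.DataFrame(series_by_tp)
                    for pep, vals in frame.iterrows():
                        rows.append((pep, taxon, filt, vals.mean(),
                                     peptide_cv(vals), int(vals.notna().sum())))
            continue
        series_by_tp = {}
        for tp in timepoints:
            per_filter_series, counts = {}, {}
            for filt in FILTERS:
                if not table.injections(tp, filt):
                    continue
                try:
                    s = taxon_normalize(table, taxon, pepmap, tp, filt, normalization)
                except QuantifyError:
                    continue
                per_filter_series[filt] = s
                counts[filt] = len(s)
            if not per_filter_series:
                continue
            weights = filter_weights(counts)
            combined = None
            for filt, s in per_filter_series.items():
                term = s * weights[filt]
                combined = term if combined is None else combined.add(term, fill_value=0.0)
            series_by_tp[tp] = combined
        if not series_by_tp:
            continue
        frame = pd.DataFrame(series_by_tp)  # peptides x timepoints, NaN = unobserved
        for pep, vals in frame.iterrows():
            rows.append((pep, taxon, vals.mean(), peptide_cv(vals),
                         int(vals.notna().sum())))
    if per_filter:
        cols = ["peptide", "taxon", "filter", "mean_norm_intensity", "cv", "n_timepoints"]
    else:
        cols = ["peptide", "taxon", "mean_norm_intensity", "cv", "n_timepoints"]
    return pd.DataFrame(rows, columns=cols)


def classify_peptides(cv_records: pd.DataFrame,
                      cutoff: CutoffSpec | float) -> pd.DataFrame:
    """Label peptides environment-independent (cv <= cutoff; ties count as
    independent) or -dependent.  Peptides with undefined CV are excluded;
    their count is kept in ``result.attrs["n_undefined_cv"]``."""
    threshold = cutoff.cutoff if isinstance(cutoff, CutoffSpec) else float(cutoff)
    defined = cv_records[cv_records["cv"].notna()].copy()
    defined["env_class"] = np.where(defined["cv"] <= threshold,
                                    "independent", "dependent")
    defined.attrs["n_undefined_cv"] = int(cv_records["cv"].isna().sum())
    defined.attrs["cutoff"] = threshold
    return defined


def environment_independent_fraction(classified: pd.DataFrame, taxon: str) -> float:
    """Share of a taxon's classified peptide mass that is
    environment-independent (independent and dependent shares sum to one)."""
    sub = classified[classified["taxon"] == taxon]
    total = float(sub["mean_norm_intensity"].sum())
    if len(sub) == 0 or total <= 0:
        raise TraitError(f"taxon {taxon!r} has no classified peptides")
    indep = float(sub.loc[sub["env_class"] == "independent",
                          "mean_norm_intensity"].sum())
    return indep / total


def functional_class_balance(classified: pd.DataFrame,
                             clusters: Mapping[str, str]) -> pd.Series:
    """Per protein-cluster signed count: environment-dependent peptides
    minus environment-independent peptides (positive = mostly dependent)."""
    sub = classified[classified["peptide"].isin(clusters)]
    labels = sub["peptide"].map(clusters)
    signed = np.where(sub["env_class"] == "dependent", 1, -1)
    return pd.Series(signed, index=labels).groupby(level=0).sum().sort_index()
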