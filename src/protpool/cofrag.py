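"""Peptide retention-time prediction and cofragmentation-risk scores.

In data-dependent acquisition, peptides that co-elute within one another's
precursor isolation window can be co-isolated and co-fragmented, biasing
MS1-based quantification.  The cofragmentation score of a peptide is the
expected number of database peptides that fall inside both its m/z
isolation window and its chromatographic peak width, discounted by the
degree of sparse sampling; it is a per-peptide risk measure, not a spectral
simulation.

Retention times come from an additive hydrophobicity-coefficient model
(Guo-style per-residue retention coefficients), affinely mapped onto the LC
gradient.  The model is deliberately simple and swappable: the score only
requires a realistic relative co-elution structure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digestion import AMINO_ACIDS, CHARGES

#: additive per-residue retention coefficients (min-scale, reversed-phase
#: C18 at acidic pH; Guo et al.-style hydrophobicity values)
GUO_COEFFICIENTS = {
    "W": 8.8, "F": 8.1, "L": 8.1, "I": 7.4, "M": 5.5, "V": 5.0,
    "Y": 4.5, "C": 2.6, "A": 2.0, "P": 2.0, "E": 1.1, "T": 0.6,
    "D": 0.2, "Q": 0.0, "S": -0.2, "G": -0.2, "N": -0.6, "R": -0.6,
    "H": -2.1, "K": -2.1,
}


class CofragError(ValueError):
    pass


@dataclass
class RTModel:
    """Additive retention model: raw RT = intercept + sum of residue
    coefficients, affinely rescaled onto [0, gradient_length] after
    calibration against a reference peptide set."""

    coefficients: dict = field(default_factory=lambda: dict(GUO_COEFFICIENTS))
    intercept: float = 0.0
    raw_min: float | None = None
    raw_max: float | None = None
    gradient_length: float | None = None

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.coefficients)
        if missing:
            raise CofragError(f"coefficients missing residues: {sorted(missing)}")

    def predict_raw(self, sequence: str) -> float:
        try:
            return self.intercept + sum(self.coefficients[a] for a in sequence)
        except KeyError as exc:
            raise CofragError(f"invalid residue {exc.args[0]!r} in {sequence!r}")

    def predict_raw_many(self, sequences: Iterable[str]) -> np.ndarray:
        return np.array([self.predict_raw(s) for s in sequences], dtype=float)

    def calibrate(self, sequences: Iterable[str], gradient_length: float) -> "RTModel":
        """Fit the affine mapping so the reference set spans the gradient."""
        raw = self.predict_raw_many(sequences)
        self.raw_min = float(raw.min())
        self.raw_max = float(raw.max())
        self.gradient_length = float(gradient_length)
        return self

    def predict(self, sequence: str) -> float:
        return float(self.predict_many([sequence])[0])

    def predict_many(self, sequences: Iterable[str]) -> np.ndarray:
        if self.gradient_length is None:
            raise CofragError("RTModel is not calibrated; call calibrate() first")
        raw = self.predict_raw_many(sequences)
        span = self.raw_max - self.raw_min
        if span <= 0:
            scaled = np.full_like(raw, 0.5 * self.gradient_length)
        else:
            scaled = (raw - self.raw_min) / span * self.gradient_length
        return np.clip(scaled, 0.0, self.gradient_length)


def predict_rt(sequence: str, model: RTModel) -> float:
    """Retention time (min) of one peptide under a calibrated model."""
    return model.predict(sequence)


@dataclass(frozen=True)
class CofragResult:
    peptide: str
    score: float
    contributors: tuple


def _mz_rt_arrays(pepmap: pd.DataFrame, model: RTModel) -> tuple[np.ndarray, np.ndarray]:
    rts = model.predict_many(pepmap.index)
    mzs = np.stack([pepmap[f"mz{z}"].to_numpy(float) for z in CHARGES])
    return mzs, rts


def cofragmentation_score(
    peptide: str,
    pepmap: pd.DataFrame,
    params,
    model: RTModel | None = None,
) -> CofragResult:
    """Cofragmentation risk for one peptide against a database.

    For each modeled charge state of the peptide, database peptides (any
    modeled charge) within half the precursor isolation window in m/z and
    within one ion peak width in retention time are counted (the peptide
    itself excluded); counts are averaged over the peptide's charge states
    and divided by the degree of sparse sampling.
    """
    if len(pepmap) == 0:
        raise CofragError("database is empty")
    if peptide not in pepmap.index:
        raise CofragError(f"peptide {peptide!r} not in the database")
    if model is None:
        model = RTModel().calibrate(pepmap.index, params.gradient_length)
    mzs, rts = _mz_rt_arrays(pepmap, model)
    pos = pepmap.index.get_loc(peptide)
    rt0 = rts[pos]
    half_window = params.isolation_window / 2.0
    in_rt = np.abs(rts - rt0) <= params.peak_width
    contributors: set[str] = set()
    total = 0
    for zi in range(len(CHARGES)):
        mz0 = mzs[zi, pos]
        hits = in_rt & (np.abs(mzs - mz0) <= half_window).any(axis=0)
        hits[pos] = False
        total += int(hits.sum())
        contributors.update(pepmap.index[hits])
    score = total / len(CHARGES) / params.sparse_sampling_degree
    return CofragResult(peptide=peptide, score=score,
                        contributors=tuple(sorted(contributors)))


def cofragmentation_scores(
    pepmap: pd.DataFrame,
    params,
    model: RTModel | None = None,
) -> pd.DataFrame:
    """Vectorized cofragmentation scores for every peptide in a map.

    Returns a frame indexed like ``pepmap`` with columns ``score`` and
    ``n_contributors`` (number of distinct co-locating peptides over all
    charge pairs).
    """
    if len(pepmap) == 0:
        raise CofragError("database is empty")
    if model is None:
        model = RTModel().calibrate(pepmap.index, params.gradient_length)
    mzs, rts = _mz_rt_arrays(pepmap, model)
    n = len(pepmap)
    half_window = params.isolation_window / 2.0
    order = np.argsort(rts, kind="stable")
    rts_s = rts[order]
    mzs_s = mzs[:, order]

    counts = np.zeros(n, dtype=float)
    ncontrib = np.zeros(n, dtype=int)
    lo = np.searchsorted(rts_s, rts_s - params.peak_width, side="left")
    hi = np.searchsorted(rts_s, rts_s + params.peak_width, side="right")
    for i in range(n):
        sl = slice(lo[i], hi[i])
        cand_mz = mzs_s[:, sl]
        any_hit = np.zeros(hi[i] - lo[i], dtype=bool)
        total = 0
        for zi in range(len(CHARGES)):
            hit = (np.abs(cand_mz - mzs_s[zi, i]) <= half_window).any(axis=0)
            hit[i - lo[i]] = False
            total += int(hit.sum())
            any_hit |= hit
        counts[i] = total / len(CHARGES) / params.sparse_sampling_degree
        ncontrib[i] = int(any_hit.sum())

    out = pd.DataFrame(index=pepmap.index.copy())
    out["score"] = 0.0
    out["n_contributors"] = 0
    out.iloc[order, out.columns.get_loc("score")] = counts
    out.iloc[order, out.columns.get_loc("n_contributors")] = ncontrib
    return out
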