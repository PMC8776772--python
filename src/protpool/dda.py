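"""Data-dependent acquisition (DDA) sampling of a simulated peptide mixture.

The acquisition loop mimics a top-N instrument method: MS1 survey scans at a
fixed cycle time across the LC gradient, selection of the N most intense
precursors whose instantaneous elution intensity clears the detection limit
and that are not on the dynamic-exclusion list, and exclusion of selected
precursors for a fixed duration.  A selected peptide counts as identified
and its MS1 feature intensity (the integrated elution profile) is recorded.
No MS2 spectra are generated: "identified" is a sampling outcome.

`assess_bias` closes the loop against the generator's truth table, so that
inference bias can be quantified as a function of sequence sharing and of
the number of uniquely mapping identified peptides per coarse grain.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cofrag import RTModel
from .synthetic import FILTERS, POOLS, TruthTable

#: truth tables label the unassigned pool "other"; keyword mapping labels it
#: "none" — one coarse grain, two vocabularies
POOL_ALIASES = {"none": "other", "other": "other",
                "ribosomal": "ribosomal", "photosynthetic": "photosynthetic"}


class DDAError(ValueError):
    pass


@dataclass
class DDAParams:
    """Acquisition and scoring parameters.

    ``gradient_length`` (125 min) matches a non-linear nano-LC gradient;
    ``max_injection_time`` (0.008333 min = 0.5 s), ``isolation_window``
    (3 m/z), ``peak_width`` (1.44 min) and ``sparse_sampling_degree`` (5)
    are the cofragmentation-score parameters; ``top_n``,
    ``exclusion_duration`` and ``ms1_cycle_time`` drive the acquisition
    loop.  ``detection_limit`` is the minimum instantaneous feature
    intensity for precursor selection, expressed as a multiple of the run's
    mean feature intensity: feature intensities are in arbitrary units, so
    the instrument's effective sensitivity floor is pinned to the typical
    feature rather than to an absolute scale, keeping identification depth
    comparable across community sizes.
    """

    gradient_length: float = 125.0
    max_injection_time: float = 0.008333
    isolation_window: float = 3.0
    peak_width: float = 1.44
    sparse_sampling_degree: int = 5
    top_n: int = 10
    exclusion_duration: float = 0.5
    ms1_cycle_time: float = 0.02
    detection_limit: float = 1.6
    seed: int | None = None

    def __post_init__(self):
        for name in ("gradient_length", "max_injection_time", "isolation_window",
                     "peak_width", "ms1_cycle_time"):
            if getattr(self, name) <= 0:
                raise DDAError(f"{name}: must be positive")
        if self.sparse_sampling_degree < 1:
            raise DDAError("sparse_sampling_degree: must be >= 1")
        if self.top_n < 1:
            raise DDAError("top_n: must be >= 1")
        if self.exclusion_duration < 0:
            raise DDAError("exclusion_duration: must be >= 0")
        if self.detection_limit < 0:
            raise DDAError("detection_limit: must be >= 0")

    @property
    def elution_sigma(self) -> float:
        """Gaussian elution SD; +/- 2 sigma spans the nominal peak width."""
        return self.peak_width / 4.0


@dataclass
class FeatureMap:
    """MS1 features of one injection: per peptide an apex retention time,
    Gaussian elution sigma and total (integrated) intensity."""

    frame: pd.DataFrame  # index peptide; columns rt, sigma, intensity
    gradient_length: float

    def __post_init__(self):
        f = self.frame
        if len(f) and (f["intensity"] <= 0).any():
            raise DDAError("feature intensities must be > 0")
        if len(f) and ((f["rt"] < 0) | (f["rt"] > self.gradient_length)).any():
            raise DDAError("apex RT must lie within the gradient")

    @property
    def total_signal(self) -> float:
        return float(self.frame["intensity"].sum())

    def with_noise(self, noise_cv: float, rng: np.random.Generator) -> "FeatureMap":
        """Injection-level multiplicative lognormal noise, mean one."""
        if noise_cv <= 0:
            return self
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factor = np.exp(
            sigma * rng.standard_normal(len(self.frame)) - 0.5 * sigma**2
        )
        frame = self.frame.copy()
        frame["intensity"] = frame["intensity"] * factor
        return FeatureMap(frame=frame, gradient_length=self.gradient_length)


def peptide_detectability(pepmap: pd.DataFrame, sd: float, seed: int) -> pd.Series:
    """Fixed per-peptide response factors (mean-one lognormal).

    Keyed by the community seed and drawn over the lexicographic peptide
    order, so the same peptide keeps the same factor across timepoints,
    filters and injections.
    """
    if sd <= 0:
        return pd.Series(1.0, index=pepmap.index)
    rng = np.random.default_rng([seed, 0xD47EC7])
    z = rng.standard_normal(len(pepmap))
    return pd.Series(np.exp(sd * z - 0.5 * sd * sd), index=pepmap.index)


def generate_features(
    pepmap: pd.DataFrame,
    truth: TruthTable,
    timepoint: int,
    filt: float,
    params: DDAParams,
    rt_model: RTModel | None = None,
    detectability: pd.Series | None = None,
) -> FeatureMap:
    """Build the MS1 feature map for one (timepoint, filter) sample.

    A protein's mass signal is apportioned equally among its mapped
    peptides (so summed peptide intensity conserves protein mass), scaled
    by the taxon's retention on the filter, multiplied by the peptide's
    fixed response factor, and summed over all parent proteins of the
    peptide.  Injection-level noise is applied separately via
    :meth:`FeatureMap.with_noise`.
    """
    if timepoint not in truth.abundance.columns:
        raise DDAError(f"timepoint {timepoint} not in the truth table")
    config = truth.config
    abundance = truth.abundance[timepoint]
    taxa = truth.proteins["taxon"]

    # peptides per parent protein (k in the equal-apportioning rule)
    parent_counts: dict[str, int] = {}
    for parents in pepmap["parents"]:
        for p in parents:
            parent_counts[p] = parent_counts.get(p, 0) + 1

    per_protein = {}
    for pid, k in parent_counts.items():
        try:
            ab = float(abundance.loc[pid])
        except KeyError:
            raise DDAError(f"peptide parent {pid!r} has no truth abundance")
        ret = config.retention(taxa.loc[pid], filt)
        per_protein[pid] = ab * ret / k

    intensity = np.array(
        [sum(per_protein[p] for p in parents) for parents in pepmap["parents"]],
        dtype=float,
    )
    if detectability is None:
        detectability = peptide_detectability(
            pepmap, config.detectability_sd, config.seed
        )
    intensity = intensity * detectability.to_numpy(float)

    if rt_model is None:
        rt_model = RTModel().calibrate(pepmap.index, params.gradient_length)
    rts = rt_model.predict_many(pepmap.index)

    frame = pd.DataFrame(
        {
            "rt": rts,
            "sigma": params.elution_sigma,
            "intensity": intensity,
        },
        index=pepmap.index.copy(),
    )
    frame = frame[frame["intensity"] > 0]
    return FeatureMap(frame=frame, gradient_length=params.gradient_length)


@dataclass
class ObservedTable:
    """Outcome of one simulated injection: per-peptide identification flag
    and MS1 intensity, plus the run's total ion current (all features,
    identified or not)."""

    frame: pd.DataFrame  # index peptide; columns intensity, identified
    tic: float

    def identified(self) -> pd.Series:
        sub = self.frame[self.frame["identified"]]
        return sub["intensity"]


def simulate_dda_run(features: FeatureMap, params: DDAParams) -> ObservedTable:
    """Run the top-N + dynamic-exclusion acquisition loop over one injection.

    Deterministic given the feature map: ties in instantaneous intensity are
    broken by feature order.  Selected peptides are flagged identified and
    their full (integrated) MS1 intensity recorded; the TIC is the total
    feature intensity of the run regardless of identification.
    """
    frame = features.frame
    tic = float(frame["intensity"].sum())
    if len(frame) == 0:
        out = pd.DataFrame(columns=["intensity", "identified"])
        return ObservedTable(frame=out, tic=0.0)

    order = np.argsort(frame["rt"].to_numpy(), kind="stable")
    rt = frame["rt"].to_numpy()[order]
    inten = frame["intensity"].to_numpy()[order]
    sigma = frame["sigma"].to_numpy()[order]
    n = len(rt)
    identified = np.zeros(n, dtype=bool)
    excluded_until = np.full(n, -np.inf)

    min_inst = params.detection_limit * tic / n
    window = 3.0 * float(sigma.max())
    n_cycles = int(np.floor(params.gradient_length / params.ms1_cycle_time)) + 1
    times = np.arange(n_cycles) * params.ms1_cycle_time

    for t in times:
        a = np.searchsorted(rt, t - window, side="left")
        b = np.searchsorted(rt, t + window, side="right")
        if a == b:
            continue
        inst = inten[a:b] * np.exp(-0.5 * ((t - rt[a:b]) / sigma[a:b]) ** 2)
        elig = (inst >= min_inst) & (excluded_until[a:b] <= t) & (inst > 0)
        idx = np.nonzero(elig)[0]
        if idx.size == 0:
            continue
        if idx.size > params.top_n:
            # most intense first; stable tie-break on position
            top = idx[np.argsort(-inst[idx], kind="stable")[: params.top_n]]
        else:
            top = idx
        sel = top + a
        identified[sel] = True
        excluded_until[sel] = t + params.exclusion_duration

    out = pd.DataFrame(
        {"intensity": frame["intensity"].to_numpy()[order], "identified": identified},
        index=frame.index.to_numpy()[order],
    )
    out = out.loc[frame.index]  # restore input order
    return ObservedTable(frame=out, tic=tic)


def assess_bias(
    observed: ObservedTable,
    truth: TruthTable,
    pepmap: pd.DataFrame,
    timepoint: int,
    filt: float,
) -> pd.DataFrame:
    """Score inferred coarse-grain quantities against the truth table.

    For every (taxon, pool) grain, computes from the identified,
    uniquely-mapping peptides of one injection:

    - the within-taxon pool mass fraction (pool-specific intensity over
      taxon-specific intensity), against the true mass fraction;
    - the grain's share of total community protein mass on the filter
      (grain-specific intensity over all identified intensity), against the
      true retention-weighted share;
    - ``n_unique_identified``, the grain's support: identified peptides
      unique to both the taxon and the pool.
    """
    ident = observed.identified()
    idx = ident.index
    sub = pepmap.loc[idx]
    total_ident = float(ident.sum())

    tu = sub["taxon_unique"].to_numpy()
    taxon_arr = sub["taxon"].to_numpy(object)
    pool_arr = sub["pool"].to_numpy(object)
    pu = sub["pool_unique"].to_numpy()
    vals = ident.to_numpy(float)

    rows = []
    for taxon in truth.config.taxon_names:
        taxon_mask = tu & (taxon_arr == taxon)
        taxon_total = float(vals[taxon_mask].sum())
        for pool in POOLS:
            grain_mask = taxon_mask & pu & (
                np.array([POOL_ALIASES.get(p, p) if p is not None else None
                          for p in pool_arr], dtype=object) == pool
            )
            grain_total = float(vals[grain_mask].sum())
            n_unique = int(grain_mask.sum())
            rows.append((taxon, pool, n_unique, grain_total, taxon_total))

    true_fracs = truth.pool_fractions()
    true_fracs = true_fracs[true_fracs["timepoint"] == timepoint].set_index(
        ["taxon", "pool"]
    )["fraction"]

    out_rows = []
    for taxon, pool, n_unique, grain_total, taxon_total in rows:
        inferred_frac = grain_total / taxon_total if taxon_total > 0 else np.nan
        inferred_share = grain_total / total_ident if total_ident > 0 else np.nan
        tf = float(true_fracs.loc[(taxon, pool)])
        ts = truth.community_share(taxon, pool, timepoint, filt)
        out_rows.append(
            {
                "taxon": taxon,
                "pool": pool,
                "timepoint": timepoint,
                "filter": filt,
                "n_unique_identified": n_unique,
                "true_fraction": tf,
                "inferred_fraction": inferred_frac,
                "bias_fraction": inferred_frac - tf,
                "rel_bias_fraction": (inferred_frac - tf) / tf if tf > 0 else np.nan,
                "true_share": ts,
                "inferred_share": inferred_share,
                "bias_share": inferred_share - ts,
                "rel_bias_share": (inferred_share - ts) / ts if ts > 0 else np.nan,
            }
        )
    return pd.DataFrame(out_rows)


def sharing_bias_sweep(
    shared_fractions: Sequence[float] = (0.0, 0.3, 0.6, 0.9),
    seeds: Sequence[int] = tuple(range(10)),
    n_proteins_per_pool: int = 67,
    params: DDAParams | None = None,
) -> pd.DataFrame:
    """Quantify coarse-grain inference bias as a function of inter-taxon
    sequence sharing.

    For each (shared_sequence_fraction, seed) a 3-taxon community with
    equal pool allocations is simulated, one injection is acquired with the
    DDA loop, and every (taxon, pool) grain is scored against truth via
    :func:`assess_bias`.  A single timepoint and filter fraction are used:
    sequence sharing, not environmental or filtration structure, is the
    variable under study.  Returns the concatenated bias table with ``s``
    and ``seed`` columns.
    """
    from .cofrag import RTModel
    from .digestion import build_peptide_map
    from .synthetic import CommunityConfig, simulate_community

    params = params or DDAParams()
    frames = []
    for s in shared_fractions:
        for seed in seeds:
            config = CommunityConfig(
                n_taxa=3,
                n_proteins_per_pool=n_proteins_per_pool,
                pool_fractions={"ribosomal": 1 / 3, "photosynthetic": 1 / 3,
                                "other": 1 / 3},
                n_timepoints=1,
                env_dependent_fraction=0.0,
                shared_sequence_fraction=float(s),
                protein_length_range=(60, 160),
                filter_retention=np.array([[1.0, 0.0, 0.0]] * 3),
                n_injections=(1, 1, 1),
                seed=int(seed),
            )
            proteins, truth = simulate_community(config)
            pepmap = build_peptide_map(proteins, compute_masses=False)
            rt_model = RTModel().calibrate(pepmap.index, params.gradient_length)
            features = generate_features(pepmap, truth, 1, FILTERS[0], params,
                                         rt_model=rt_model)
            noise_rng = np.random.default_rng([config.seed, 0x5EED])
            noisy = features.with_noise(config.noise_cv, noise_rng)
            observed = simulate_dda_run(noisy, params)
            frame = assess_bias(observed, truth, pepmap, 1, FILTERS[0])
            frame["s"] = float(s)
            frame["seed"] = int(seed)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


DEFAULT_SUPPORT_GRID = (0, 10, 25, 50, 100, 200, 400)


def support_threshold(
    bias: pd.DataFrame,
    grid: Sequence[int] = DEFAULT_SUPPORT_GRID,
    tol: float = 0.05,
    column: str = "rel_bias_fraction",
    min_bin: int = 5,
) -> int | None:
    """Peptide support needed for an unbiased coarse-grain estimate.

    Grains are binned by their number of uniquely-mapping identified
    peptides into the intervals between consecutive grid points (the last
    interval is open-ended).  The threshold is the smallest grid value T
    such that every populated bin (>= ``min_bin`` grains) at or above T has
    a median relative bias within +/- ``tol``.  Returns None if even the
    top bin is biased."""
    vals = bias.dropna(subset=[column])
    edges = list(grid) + [np.inf]
    ok = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = vals[(vals["n_unique_identified"] >= lo)
                   & (vals["n_unique_identified"] < hi)]
        if len(sub) < min_bin:
            ok.append(None)  # unpopulated: no evidence either way
        else:
            ok.append(abs(float(sub[column].median())) <= tol)
    # walk down from the top bin: a failing bin stops the descent, an
    # unpopulated bin is transparent but contributes no evidence, and the
    # threshold is the left edge of the lowest populated passing bin in
    # the contiguous run
    threshold = None
    for t, passed in zip(reversed(grid), reversed(ok)):
        if passed is False:
            break
        if passed is True:
            threshold = int(t)
    return threshold
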