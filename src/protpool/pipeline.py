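"""End-to-end orchestration: simulate -> acquire -> quantify -> traits ->
cofragmentation, with TSV/JSON outputs and a reproducibility manifest."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cofrag import RTModel, cofragmentation_scores
from .dda import (DDAParams, ObservedTable, assess_bias, generate_features,
                  peptide_detectability, simulate_dda_run)
from .digestion import build_peptide_map
from .io import (write_cultures, write_fasta, write_peptide_map, write_tsv)
from .quantify import (IntensityTable, SampleKey, mass_fraction_table,
                       taxon_relative_abundance)
from .synthetic import (FILTERS, CommunityConfig, TruthTable,
                        simulate_community, simulate_replicate_cultures)
from .traits import (classify_peptides, compute_cv_records, derive_cutoff,
                     environment_independent_fraction)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    community: CommunityConfig = field(default_factory=CommunityConfig)
    dda: DDAParams = field(default_factory=DDAParams)
    normalization: str = "sum"
    # replicate-culture calibration set for the CV cutoff
    n_culture_conditions: int = 5
    n_culture_replicates: int = 3
    n_culture_proteins: int = 500
    culture_cv_profile: object = field(
        default_factory=lambda: {"kind": "uniform", "low": 0.05, "high": 0.5})
    compute_cofrag: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        payload = dict(payload)
        if "community" in payload:
            payload["community"] = CommunityConfig(**payload["community"])
        if "dda" in payload:
            payload["dda"] = DDAParams(**payload["dda"])
        return cls(**payload)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls.from_dict(payload)


@dataclass
class SimulatedDataset:
    proteins: list
    truth: TruthTable
    pepmap: pd.DataFrame
    table: IntensityTable          # raw observed intensities (all injections)
    runs: dict                     # SampleKey -> ObservedTable


def _protein_mass_frame(truth: TruthTable) -> pd.DataFrame:
    rows = []
    for tp in truth.abundance.columns:
        for filt, mass in truth.protein_mass_per_filter(tp).items():
            rows.append((tp, filt, mass))
    return pd.DataFrame(rows, columns=["timepoint", "filter", "mass"])


def simulate_dataset(
    config: CommunityConfig,
    params: DDAParams,
    compute_masses: bool = False,
    rt_model: RTModel | None = None,
) -> SimulatedDataset:
    """Simulate a community and acquire every (timepoint, filter, injection)
    with the DDA loop.  Per-injection noise streams are spawned
    deterministically from the community seed."""
    proteins, truth = simulate_community(config)
    pepmap = build_peptide_map(proteins, compute_masses=compute_masses)
    if rt_model is None:
        rt_model = RTModel().calibrate(pepmap.index, params.gradient_length)
    detect = peptide_detectability(pepmap, config.detectability_sd, config.seed)

    noise_rng = np.random.default_rng([config.seed, 0x5EED])
    runs: dict[SampleKey, ObservedTable] = {}
    for tp in truth.abundance.columns:
        for fi, filt in enumerate(FILTERS):
            features = generate_features(pepmap, truth, tp, filt, params,
                                         rt_model=rt_model, detectability=detect)
            for inj in range(1, config.n_injections[fi] + 1):
                noisy = features.with_noise(config.noise_cv, noise_rng)
                runs[SampleKey(tp, filt, inj)] = simulate_dda_run(noisy, params)
    table = IntensityTable.from_observed(runs, protein_mass=_protein_mass_frame(truth))
    return SimulatedDataset(proteins=proteins, truth=truth, pepmap=pepmap,
                            table=table, runs=runs)


def exhaustive_intensity_table(
    config: CommunityConfig,
    params: DDAParams | None = None,
    noise: bool = True,
) -> tuple[SimulatedDataset, IntensityTable]:
    """Observed table under exhaustive sampling (every feature identified),
    bypassing the acquisition loop.  Useful for calibration-style analyses
    where acquisition stochasticity is not under study."""
    params = params or DDAParams()
    proteins, truth = simulate_community(config)
    pepmap = build_peptide_map(proteins, compute_masses=False)
    rt_model = RTModel().calibrate(pepmap.index, params.gradient_length)
    detect = peptide_detectability(pepmap, config.detectability_sd, config.seed)
    noise_rng = np.random.default_rng([config.seed, 0x5EED])
    runs: dict[SampleKey, ObservedTable] = {}
    for tp in truth.abundance.columns:
        for fi, filt in enumerate(FILTERS):
            features = generate_features(pepmap, truth, tp, filt, params,
                                         rt_model=rt_model, detectability=detect)
            for inj in range(1, config.n_injections[fi] + 1):
                noisy = (features.with_noise(config.noise_cv, noise_rng)
                         if noise else features)
                frame = pd.DataFrame(
                    {"intensity": noisy.frame["intensity"], "identified": True},
                    index=noisy.frame.index,
                )
                runs[SampleKey(tp, filt, inj)] = ObservedTable(
                    frame=frame, tic=float(noisy.frame["intensity"].sum()))
    table = IntensityTable.from_observed(runs, protein_mass=_protein_mass_frame(truth))
    ds = SimulatedDataset(proteins=proteins, truth=truth, pepmap=pepmap,
                          table=table, runs=runs)
    return ds, table


def biomarker_vs_coarse_grain(coarse: Sequence[float],
                              biomarker: Sequence[float]) -> dict:
    """Correlation report between a coarse-grained mass-fraction series and
    a single-protein biomarker series (e.g. photosynthetic fraction vs
    plastocyanin)."""
    coarse = np.asarray(coarse, float)
    biomarker = np.asarray(biomarker, float)
    if len(coarse) != len(biomarker):
        raise ValueError("series lengths differ")
    if len(coarse) < 3:
        raise ValueError("need at least 3 paired observations")
    pearson = stats.pearsonr(coarse, biomarker)
    spearman = stats.spearmanr(coarse, biomarker)
    return {
        "n": int(len(coarse)),
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "scatter": pd.DataFrame({"coarse_grain": coarse, "biomarker": biomarker}),
    }


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full simulate/acquire/quantify/traits/cofrag chain and
    write TSV outputs plus a JSON manifest into ``outdir``.

    Outputs are byte-identical across reruns with the same config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "protpool_version": __version__,
        "seed": config.seed,
        "normalization": config.normalization,
        "community": _jsonable(dataclasses.asdict(config.community)),
        "dda": dataclasses.asdict(config.dda),
        "outputs": [],
        "stages": {},
    }

    def _write(frame: pd.DataFrame, name: str):
        write_tsv(frame, outdir / name)
        manifest["outputs"].append(name)

    try:
        community = dataclasses.replace(config.community, seed=config.seed)
        ds = simulate_dataset(community, config.dda,
                              compute_masses=config.compute_cofrag)
        write_fasta(ds.proteins, outdir / "database.fasta")
        manifest["outputs"].append("database.fasta")
        write_peptide_map(ds.pepmap, outdir / "peptides.tsv")
        manifest["outputs"].append("peptides.tsv")
        _write(ds.table.data, "observed.tsv")
        _write(ds.table.tic, "tic.tsv")
        manifest["stages"]["simulate"] = "ok"

        filtered = ds.table.presence_filter()
        fractions = mass_fraction_table(filtered, ds.pepmap,
                                        taxa=community.taxon_names,
                                        normalization=config.normalization)
        _write(fractions, "fractions.tsv")

        abund_rows = []
        for tp in ds.truth.abundance.columns:
            for taxon in community.taxon_names:
                value = taxon_relative_abundance(filtered, taxon, tp, ds.pepmap,
                                                 normalization=config.normalization)
                abund_rows.append((taxon, tp, value))
        _write(pd.DataFrame(abund_rows,
                            columns=["taxon", "timepoint", "abundance"]),
               "abundances.tsv")
        manifest["stages"]["quantify"] = "ok"

        cultures = simulate_replicate_cultures(
            config.n_culture_conditions, config.n_culture_replicates,
            config.n_culture_proteins, config.culture_cv_profile,
            seed=config.seed + 1)
        write_cultures(cultures, outdir / "cultures.tsv")
        manifest["outputs"].append("cultures.tsv")
        cutoff = derive_cutoff(cultures)
        manifest["cv_cutoff"] = cutoff.cutoff
        cv_records = compute_cv_records(filtered, ds.pepmap,
                                        taxa=community.taxon_names,
                                        normalization=config.normalization)
        classified = classify_peptides(cv_records, cutoff)
        _write(classified, "peptide_cvs.tsv")
        trait_rows = []
        for taxon in community.taxon_names:
            try:
                frac = environment_independent_fraction(classified, taxon)
            except Exception:
                frac = np.nan
            trait_rows.append((taxon, frac, cutoff.cutoff))
        _write(pd.DataFrame(trait_rows,
                            columns=["taxon", "env_independent_fraction",
                                     "cv_cutoff"]),
               "traits.tsv")
        manifest["stages"]["traits"] = "ok"

        bias_frames = []
        for tp in ds.truth.abundance.columns:
            for fi, filt in enumerate(FILTERS):
                key = SampleKey(tp, filt, 1)
                if key in ds.runs:
                    bias_frames.append(
                        assess_bias(ds.runs[key], ds.truth, ds.pepmap, tp, filt))
        _write(pd.concat(bias_frames, ignore_index=True), "bias.tsv")
        manifest["stages"]["bias"] = "ok"

        if config.compute_cofrag:
            scores = cofragmentation_scores(ds.pepmap, config.dda)
            scores.index.name = "peptide"
            _write(scores.reset_index(), "cofrag.tsv")
            manifest["stages"]["cofrag"] = "ok"
    except Exception as exc:  # partial outputs flagged in the manifest
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
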