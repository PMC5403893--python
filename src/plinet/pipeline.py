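"""End-to-end orchestration: cohort -> filtering -> PLI -> networks -> statistics.

Stages
------
connectivity
    Per subject, epoch and band: zero-phase band-pass, analytic-signal
    phase (with symmetric edge trim), PLI adjacency matrix; per-epoch
    matrices are averaged per subject for the edge-wise statistics.
network
    Per epoch: surrogate-normalized Cw/Lw and the MST metric suite, then
    averaged over epochs per subject.
stats
    Edge-wise (averaged PLI), node-wise (averaged MST betweenness and
    degree fraction) and global permutation tests per band, with BH-FDR
    within each (family, band).

Optionally, network statistics are restricted to the bands whose
edge-wise tests showed uncorrected significance (band-selection flag).

All randomness derives from one master seed: surrogate streams are keyed
by (subject, epoch, band) and permutation relabelings by band, shared
across feature families within the band.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import CANONICAL_BANDS, FrequencyBand, get_band
from .connectivity import pli_matrix_from_phases
from .io import read_cohort_manifest
from .mst import (
    BC_NORMALIZATION,
    DEGREE_NORMALIZATION,
    build_mst,
    mst_metrics,
)
from .smallworld import normalized_metrics
from .spectral import (
    FILTER_DESIGN,
    bandpass,
    default_edge_trim,
    instantaneous_phase,
)
from .stats import run_group_comparison
from .synthetic import CohortConfig, EpochedCohort, generate_cohort

logger = logging.getLogger("plinet")

_BAND_INDEX = {b.name: i for i, b in enumerate(CANONICAL_BANDS)}

GLOBAL_METRICS = (
    "normalized_cw",
    "normalized_lw",
    "leaf_fraction",
    "tree_hierarchy",
    "kappa",
    "diameter",
    "bc_max",
    "degree_correlation_r",
)


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    cohort_config: CohortConfig | None = None
    manifest_path: str | Path | None = None
    bands: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
    n_surrogates: int = 50
    n_permutations: int = 2000
    alpha: float = 0.05
    fdr_q: float = 0.05
    master_seed: int = 0
    output_dir: str | Path | None = None
    restrict_network_to_significant_bands: bool = False
    edge_trim: int | None = None  # None: one low-edge cycle, <= 10% of epoch

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "synthetic" and self.cohort_config is None:
            raise ValueError("synthetic mode requires cohort_config")
        if self.mode == "files" and self.manifest_path is None:
            raise ValueError("files mode requires manifest_path")
        unknown = [b for b in self.bands if b not in _BAND_INDEX]
        if unknown:
            raise ValueError(
                f"bands {unknown} are not among the canonical six "
                f"{sorted(_BAND_INDEX)}"
            )
        for name, v in (
            ("n_surrogates", self.n_surrogates),
            ("n_permutations", self.n_permutations),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ResultsBundle:
    averaged_connectivity: dict[str, dict[str, np.ndarray]]
    network_globals: pd.DataFrame | None
    node_metrics: pd.DataFrame | None
    stats_tables: dict[tuple[str, str], pd.DataFrame]
    manifest: dict
    output_dir: Path | None = None


def _surrogate_seed(master: int, s: int, e: int, b: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master, 1, s, e, b)))


def _permutation_seed(master: int, b: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master, 2, b)))


def compute_band_connectivity(
    cohort: EpochedCohort,
    band: FrequencyBand,
    edge_trim: int | None = None,
) -> tuple[dict[str, list[np.ndarray]], dict[str, np.ndarray]]:
    """Per-epoch and epoch-averaged PLI matrices for every subject."""
    fs = cohort.sampling_rate
    n_samples = cohort.subjects[0].epochs.shape[2]
    trim = (
        default_edge_trim(band, fs, n_samples)
        if edge_trim is None
        else edge_trim
    )
    per_epoch: dict[str, list[np.ndarray]] = {}
    averaged: dict[str, np.ndarray] = {}
    for s in cohort.subjects:
        mats = []
        for k in range(s.epochs.shape[0]):
            filtered = bandpass(s.epochs[k], band, fs)
            phase = instantaneous_phase(
                filtered,
                band=band,
                subject_id=s.subject_id,
                epoch_index=k,
                edge_trim=trim,
                roi_labels=cohort.roi_labels,
            )
            mats.append(pli_matrix_from_phases(phase.phases))
        per_epoch[s.subject_id] = mats
        averaged[s.subject_id] = np.mean(mats, axis=0)
    return per_epoch, averaged


def compute_band_network_metrics(
    cohort: EpochedCohort,
    per_epoch: dict[str, list[np.ndarray]],
    band_name: str,
    n_surrogates: int,
    master_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject epoch-averaged global and per-node network metrics."""
    b_idx = _BAND_INDEX[band_name]
    global_rows = []
    node_rows = []
    for s_idx, s in enumerate(cohort.subjects):
        per_epoch_globals = []
        bc_acc = []
        degf_acc = []
        ecc_acc = []
        for e_idx, w in enumerate(per_epoch[s.subject_id]):
            rng = _surrogate_seed(master_seed, s_idx, e_idx, b_idx)
            sw = normalized_metrics(w, n_surrogates=n_surrogates, seed=rng)
            tree = build_mst(w)
            tm = mst_metrics(tree)
            per_epoch_globals.append(
                [
                    sw.normalized_cw,
                    sw.normalized_lw,
                    tm.leaf_fraction,
                    tm.tree_hierarchy,
                    tm.kappa,
                    float(tm.diameter),
                    tm.bc_max,
                    tm.degree_correlation_r,
                ]
            )
            bc_acc.append(tm.bc)
            degf_acc.append(tm.degree_fraction)
            ecc_acc.append(tm.eccentricity.astype(float))
        means = np.mean(per_epoch_globals, axis=0)
        global_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group_label,
                "band": band_name,
                **dict(zip(GLOBAL_METRICS, means)),
            }
        )
        bc_mean = np.mean(bc_acc, axis=0)
        degf_mean = np.mean(degf_acc, axis=0)
        ecc_mean = np.mean(ecc_acc, axis=0)
        for r, roi in enumerate(cohort.roi_labels):
            node_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group_label,
                    "band": band_name,
                    "roi": roi,
                    "bc": bc_mean[r],
                    "degree_fraction": degf_mean[r],
                    "eccentricity": ecc_mean[r],
                }
            )
    return pd.DataFrame(global_rows), pd.DataFrame(node_rows)


def _edge_feature_table(
    cohort: EpochedCohort, averaged: dict[str, np.ndarray]
) -> pd.DataFrame:
    n = cohort.n_rois
    iu = np.triu_indices(n, k=1)
    cols = [
        f"pli:{cohort.roi_labels[i]}|{cohort.roi_labels[j]}"
        for i, j in zip(*iu)
    ]
    data = np.stack(
        [averaged[s.subject_id][iu] for s in cohort.subjects]
    )
    return pd.DataFrame(
        data, index=[s.subject_id for s in cohort.subjects], columns=cols
    )


def _node_feature_table(node_df: pd.DataFrame, band: str) -> pd.DataFrame:
    sub = node_df[node_df["band"] == band]
    bc = sub.pivot(index="subject_id", columns="roi", values="bc")
    deg = sub.pivot(
        index="subject_id", columns="roi", values="degree_fraction"
    )
    bc.columns = [f"bc:{c}" for c in bc.columns]
    deg.columns = [f"degree:{c}" for c in deg.columns]
    return pd.concat([bc, deg], axis=1)


def _global_feature_table(global_df: pd.DataFrame, band: str) -> pd.DataFrame:
    sub = global_df[global_df["band"] == band].set_index("subject_id")
    return sub[list(GLOBAL_METRICS)]


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = ("connectivity", "network", "stats"),
) -> ResultsBundle:
    """Execute the requested stages and (optionally) write the results."""
    config.validate()
    t0 = time.perf_counter()
    if config.mode == "synthetic":
        cohort = generate_cohort(config.cohort_config)
    else:
        cohort = read_cohort_manifest(config.manifest_path)
    logger.info(
        "cohort ready: %d subjects, %d ROIs, %d epochs (%.1f s)",
        len(cohort.subjects),
        cohort.n_rois,
        cohort.n_epochs,
        time.perf_counter() - t0,
    )
    groups = cohort.groups()
    subject_order = [s.subject_id for s in cohort.subjects]

    averaged_all: dict[str, dict[str, np.ndarray]] = {}
    stats_tables: dict[tuple[str, str], pd.DataFrame] = {}
    global_frames: list[pd.DataFrame] = []
    node_frames: list[pd.DataFrame] = []
    selected_bands: dict[str, bool] = {}

    for band_name in config.bands:
        band = get_band(band_name)
        t1 = time.perf_counter()
        per_epoch, averaged = compute_band_connectivity(
            cohort, band, edge_trim=config.edge_trim
        )
        averaged_all[band_name] = averaged
        logger.info(
            "connectivity[%s] done in %.1f s",
            band_name,
            time.perf_counter() - t1,
        )

        band_selected = True
        if "stats" in stages:
            edge_table = _edge_feature_table(cohort, averaged)
            rng = _permutation_seed(config.master_seed, _BAND_INDEX[band_name])
            edge_stats = run_group_comparison(
                edge_table,
                groups,
                n_permutations=config.n_permutations,
                seed=rng,
                alpha=config.alpha,
                fdr_q=config.fdr_q,
            )
            stats_tables[(band_name, "edges")] = edge_stats
            if config.restrict_network_to_significant_bands:
                band_selected = bool(
                    edge_stats["significant_uncorrected"].any()
                )
        selected_bands[band_name] = band_selected

        if "network" in stages and band_selected:
            t2 = time.perf_counter()
            gdf, ndf = compute_band_network_metrics(
                cohort,
                per_epoch,
                band_name,
                n_surrogates=config.n_surrogates,
                master_seed=config.master_seed,
            )
            global_frames.append(gdf)
            node_frames.append(ndf)
            logger.info(
                "network[%s] done in %.1f s",
                band_name,
                time.perf_counter() - t2,
            )
            if "stats" in stages:
                rng = _permutation_seed(
                    config.master_seed, _BAND_INDEX[band_name]
                )
                node_table = _node_feature_table(ndf, band_name).loc[
                    subject_order
                ]
                stats_tables[(band_name, "nodes")] = run_group_comparison(
                    node_table,
                    groups,
                    n_permutations=config.n_permutations,
                    seed=rng,
                    alpha=config.alpha,
                    fdr_q=config.fdr_q,
                )
                rng = _permutation_seed(
                    config.master_seed, _BAND_INDEX[band_name]
                )
                global_table = _global_feature_table(gdf, band_name).loc[
                    subject_order
                ]
                stats_tables[(band_name, "globals")] = run_group_comparison(
                    global_table,
                    groups,
                    n_permutations=config.n_permutations,
                    seed=rng,
                    alpha=config.alpha,
                    fdr_q=config.fdr_q,
                )

    network_globals = (
        pd.concat(global_frames, ignore_index=True) if global_frames else None
    )
    node_metrics = (
        pd.concat(node_frames, ignore_index=True) if node_frames else None
    )
    manifest = _run_manifest(config, cohort, selected_bands)
    bundle = ResultsBundle(
        averaged_connectivity=averaged_all,
        network_globals=network_globals,
        node_metrics=node_metrics,
        stats_tables=stats_tables,
        manifest=manifest,
        output_dir=Path(config.output_dir) if config.output_dir else None,
    )
    if config.output_dir is not None:
        _write_bundle(bundle, cohort)
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return bundle


def _run_manifest(
    config: PipelineConfig,
    cohort: EpochedCohort,
    selected_bands: dict[str, bool],
) -> dict:
    cfg = dataclasses.asdict(config)
    if config.cohort_config is not None:
        from .io import _config_echo

        cfg["cohort_config"] = _config_echo(config.cohort_config)
    cfg["manifest_path"] = (
        str(config.manifest_path) if config.manifest_path else None
    )
    cfg["output_dir"] = str(config.output_dir) if config.output_dir else None
    return {
        "plinet_version": __version__,
        "config": cfg,
        "filter_design": FILTER_DESIGN,
        "bc_normalization": BC_NORMALIZATION,
        "degree_normalization": DEGREE_NORMALIZATION,
        "master_seed": config.master_seed,
        "seed_scheme": {
            "surrogates": "SeedSequence((master, 1, subject, epoch, band))",
            "permutations": "SeedSequence((master, 2, band)); shared across families",
        },
        "n_subjects": len(cohort.subjects),
        "n_rois": cohort.n_rois,
        "n_epochs": cohort.n_epochs,
        "bands_selected_for_network_stats": selected_bands,
    }


def _write_bundle(bundle: ResultsBundle, cohort: EpochedCohort) -> None:
    out = bundle.output_dir
    out.mkdir(parents=True, exist_ok=True)
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for band_name, per_subject in bundle.averaged_connectivity.items():
        for sid, w in per_subject.items():
            np.savetxt(
                mat_dir / f"{sid}_{band_name}_pli.txt", w, fmt="%.10g"
            )
    if bundle.network_globals is not None:
        bundle.network_globals.to_csv(
            out / "network_metrics.csv", index=False
        )
    if bundle.node_metrics is not None:
        bundle.node_metrics.to_csv(out / "node_metrics.csv", index=False)
    for (band_name, family), df in bundle.stats_tables.items():
        df.to_csv(out / f"stats_{family}_{band_name}.csv", index=False)
    (out / "run_manifest.json").write_text(
        json.dumps(bundle.manifest, indent=1, default=str)
    )
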