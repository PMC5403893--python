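"""Cohort on-disk layout: one array file per subject-epoch plus a manifest.

Each epoch is stored as an ROI x sample ``.npy`` array; the JSON manifest
records subject ids, group labels, relative file paths, sampling rate,
ROI labels and an echo of the generator config when one was used.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .synthetic import CohortConfig, EpochedCohort, SubjectRecording

MANIFEST_NAME = "cohort_manifest.json"


def _config_echo(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["band_targets"] = [
        {"name": b.name, "low": b.low, "high": b.high}
        for b in config.band_targets
    ]
    d["coupling_spec"] = {
        g: [dataclasses.asdict(e) for e in edges]
        for g, edges in config.coupling_spec.items()
    }
    return d


def write_cohort(
    cohort: EpochedCohort,
    out_dir: str | Path,
    config: CohortConfig | None = None,
) -> Path:
    """Write epoch arrays and the cohort manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sampling_rate": cohort.sampling_rate,
        "roi_labels": cohort.roi_labels,
        "subjects": [],
    }
    if config is not None:
        manifest["generator_config"] = _config_echo(config)
    for s in cohort.subjects:
        paths = []
        for k in range(s.epochs.shape[0]):
            rel = f"{s.subject_id}_epoch{k:03d}.npy"
            np.save(out / rel, s.epochs[k])
            paths.append(rel)
        manifest["subjects"].append(
            {
                "subject_id": s.subject_id,
                "group_label": s.group_label,
                "epoch_files": paths,
            }
        )
    manifest_path = out / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort_manifest(path: str | Path) -> EpochedCohort:
    """Load and validate a cohort written by :func:`write_cohort`.

    Raises with the offending file/subject named on missing files, shape
    mismatches, or non-finite samples.
    """
    manifest_path = Path(path)
    base = manifest_path.parent
    meta = json.loads(manifest_path.read_text())
    roi_labels = list(meta["roi_labels"])
    subjects: list[SubjectRecording] = []
    expected_shape: tuple[int, int] | None = None
    for entry in meta["subjects"]:
        sid = entry["subject_id"]
        epochs = []
        for rel in entry["epoch_files"]:
            f = base / rel
            if not f.exists():
                raise FileNotFoundError(f"missing epoch file: {f}")
            arr = np.load(f)
            if arr.ndim != 2 or arr.shape[0] != len(roi_labels):
                raise ValueError(
                    f"{f}: expected ({len(roi_labels)}, T) ROI x sample "
                    f"array, got shape {arr.shape}"
                )
            if expected_shape is None:
                expected_shape = arr.shape
            elif arr.shape != expected_shape:
                raise ValueError(
                    f"{f}: shape {arr.shape} differs from {expected_shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"non-finite samples in subject {sid}, file {f}"
                )
            epochs.append(arr)
        subjects.append(
            SubjectRecording(
                subject_id=sid,
                group_label=entry["group_label"],
                epochs=np.stack(epochs),
            )
        )
    cohort = EpochedCohort(
        subjects=subjects,
        sampling_rate=float(meta["sampling_rate"]),
        roi_labels=roi_labels,
    )
    cohort.validate()
    return cohort
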