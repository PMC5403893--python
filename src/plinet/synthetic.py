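"""Synthetic two-group cohorts of epoched oscillatory ROI time series.

The generator builds, per epoch and per frequency band, narrowband
Gaussian noise (white noise brick-wall filtered to the band in the
frequency domain, unit variance per ROI).  Phase-lagged coupling on an
edge (i, j) replaces ROI j's band component with

    x_j <- sqrt(1 - c^2) * x_j + c * shift(x_i, phi)

where ``shift`` rotates the analytic phase of the narrowband component by
``phi``, so the instantaneous phase difference between i and j
concentrates around ``phi`` with concentration increasing in the coupling
strength c.  Zero-lag field spread is modeled separately as instantaneous
linear mixing of one shared source into every ROI
(``x <- sqrt(1-m^2) x + m s``, with s carrying the same per-band spectral
makeup as the ROI signals) — the in-band leakage a phase-lag-based
connectivity measure must ignore.  Coupling phase
offsets are therefore required to be strictly inside (0, pi) mod pi;
encoding "coupling" at zero lag would make the ground truth unrecoverable
by construction.

Band components are summed across bands, then broadband sensor noise of
standard deviation ``noise_sd`` is added.  Everything is reproducible from
the config seed via a spawned per-subject random stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bands import CANONICAL_BANDS, BandConfigurationError, FrequencyBand

MAX_SUBJECT_BYTES = 512 * 1024**2

GROUP_LABELS = ("A", "B")


@dataclass(frozen=True)
class CoupledEdge:
    """One phase-lagged coupling between two ROIs in one band."""

    i: int
    j: int
    strength: float
    phase_offset: float
    band: str


@dataclass(frozen=True)
class CohortConfig:
    n_rois: int = 78
    n_subjects_per_group: int = 29
    n_epochs: int = 20
    epoch_samples: int = 4096
    sampling_rate: float = 1000.0
    band_targets: tuple[FrequencyBand, ...] = CANONICAL_BANDS
    coupling_spec: dict[str, tuple[CoupledEdge, ...]] = field(
        default_factory=lambda: {"A": (), "B": ()}
    )
    zero_lag_mix: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name, value in (
            ("n_rois", self.n_rois),
            ("n_subjects_per_group", self.n_subjects_per_group),
            ("n_epochs", self.n_epochs),
            ("epoch_samples", self.epoch_samples),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        per_subject = self.n_epochs * self.n_rois * self.epoch_samples * 8
        if per_subject > MAX_SUBJECT_BYTES:
            raise ValueError(
                f"per-subject array would need {per_subject} bytes "
                f"(limit {MAX_SUBJECT_BYTES})"
            )
        for band in self.band_targets:
            band.validate(self.sampling_rate)  # names offending band
        if not 0.0 <= self.zero_lag_mix < 1.0:
            raise ValueError("zero_lag_mix must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        band_names = {b.name for b in self.band_targets}
        for group, edges in self.coupling_spec.items():
            if group not in GROUP_LABELS:
                raise ValueError(f"unknown group label {group!r}")
            for e in edges:
                if not (0 <= e.i < self.n_rois and 0 <= e.j < self.n_rois):
                    raise ValueError(f"edge ({e.i}, {e.j}) out of ROI range")
                if e.i == e.j:
                    raise ValueError("self-coupling is not allowed")
                if not 0.0 <= e.strength <= 1.0:
                    raise ValueError("coupling strength must lie in [0, 1]")
                wrapped = e.phase_offset % math.pi
                if wrapped <= 0.0 or wrapped >= math.pi:
                    raise ValueError(
                        f"phase offset {e.phase_offset} is zero-lag mod pi; "
                        "use zero_lag_mix for instantaneous leakage"
                    )
                if e.band not in band_names:
                    raise BandConfigurationError(
                        f"coupling refers to band {e.band!r} absent from "
                        f"band_targets {sorted(band_names)}"
                    )


def full_scale_config(**overrides) -> CohortConfig:
    """The study-scale preset: 78 ROIs, 29+29 subjects, 20 x 4096 @ 1000 Hz."""
    return replace(CohortConfig(), **overrides)


def desk_scale_config(**overrides) -> CohortConfig:
    """Reduced preset for fast runs: 30 ROIs, 10+10 subjects, 10 x 1024 @ 250 Hz."""
    base = CohortConfig(
        n_rois=30,
        n_subjects_per_group=10,
        n_epochs=10,
        epoch_samples=1024,
        sampling_rate=250.0,
    )
    return replace(base, **overrides)


@dataclass
class SubjectRecording:
    subject_id: str
    group_label: str
    epochs: np.ndarray  # (n_epochs, n_rois, n_samples)


@dataclass
class EpochedCohort:
    subjects: list[SubjectRecording]
    sampling_rate: float
    roi_labels: list[str]

    def validate(self) -> None:
        if not self.subjects:
            raise ValueError("cohort has no subjects")
        shape = self.subjects[0].epochs.shape
        for s in self.subjects:
            if s.epochs.shape != shape:
                raise ValueError(
                    f"subject {s.subject_id}: epoch array shape "
                    f"{s.epochs.shape} differs from {shape}"
                )
            if s.epochs.shape[1] != len(self.roi_labels):
                raise ValueError(
                    f"subject {s.subject_id}: ROI count mismatch with labels"
                )
            if not np.all(np.isfinite(s.epochs)):
                raise ValueError(
                    f"subject {s.subject_id}: non-finite samples present"
                )

    @property
    def n_epochs(self) -> int:
        return self.subjects[0].epochs.shape[0]

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def groups(self) -> np.ndarray:
        return np.array([s.group_label for s in self.subjects])


def _narrowband_noise(
    rng: np.random.Generator,
    n_rois: int,
    n_samples: int,
    sampling_rate: float,
    band: FrequencyBand,
) -> np.ndarray:
    """Unit-variance Gaussian noise brick-wall limited to the band."""
    white = rng.standard_normal((n_rois, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    spec[:, (freqs < band.low) | (freqs > band.high)] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _phase_shift(x: np.ndarray, phase_offset: float) -> np.ndarray:
    """Rotate the analytic phase of a narrowband signal by -phase_offset."""
    spec = np.fft.rfft(x)
    spec[1:] = spec[1:] * np.exp(-1j * phase_offset)
    return np.fft.irfft(spec, n=x.shape[-1])


def _subject_epochs(
    rng: np.random.Generator, config: CohortConfig, group: str
) -> np.ndarray:
    edges_by_band: dict[str, list[CoupledEdge]] = {}
    for e in config.coupling_spec.get(group, ()):
        edges_by_band.setdefault(e.band, []).append(e)
    out = np.empty(
        (config.n_epochs, config.n_rois, config.epoch_samples), dtype=float
    )
    for k in range(config.n_epochs):
        sig = np.zeros((config.n_rois, config.epoch_samples))
        for band in config.band_targets:
            comp = _narrowband_noise(
                rng,
                config.n_rois,
                config.epoch_samples,
                config.sampling_rate,
                band,
            )
            # edges apply in listed order; sources read the current component
            for e in edges_by_band.get(band.name, []):
                shifted = _phase_shift(comp[e.i], e.phase_offset)
                comp[e.j] = (
                    math.sqrt(1.0 - e.strength**2) * comp[e.j]
                    + e.strength * shifted
                )
            sig += comp
        if config.zero_lag_mix > 0.0:
            # one shared source with the same per-band spectral makeup, so
            # the leakage is in-band and instantaneous in every analysis band
            common = np.zeros(config.epoch_samples)
            for band in config.band_targets:
                common += _narrowband_noise(
                    rng, 1, config.epoch_samples, config.sampling_rate, band
                )[0]
            m = config.zero_lag_mix
            sig = math.sqrt(1.0 - m**2) * sig + m * common[None, :]
        if config.noise_sd > 0.0:
            sig = sig + config.noise_sd * rng.standard_normal(sig.shape)
        out[k] = sig
    return out


def generate_cohort(config: CohortConfig) -> EpochedCohort:
    """Generate the two-group cohort described by ``config``.

    Deterministic: identical (config, seed) gives bit-identical output.
    Each subject draws from an independent spawned stream so cohorts are
    also stable under changes of n_subjects_per_group prefix ordering.
    """
    config.validate()
    n_total = 2 * config.n_subjects_per_group
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    width = len(str(config.n_subjects_per_group))
    subjects: list[SubjectRecording] = []
    for idx in range(n_total):
        group = GROUP_LABELS[idx // config.n_subjects_per_group]
        number = idx % config.n_subjects_per_group + 1
        rng = np.random.default_rng(streams[idx])
        subjects.append(
            SubjectRecording(
                subject_id=f"{group}{number:0{width}d}",
                group_label=group,
                epochs=_subject_epochs(rng, config, group),
            )
        )
    roi_labels = [f"ROI_{r:03d}" for r in range(config.n_rois)]
    cohort = EpochedCohort(
        subjects=subjects,
        sampling_rate=config.sampling_rate,
        roi_labels=roi_labels,
    )
    cohort.validate()
    return cohort
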