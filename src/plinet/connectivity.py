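"""Phase lag index (PLI) connectivity matrices.

The PLI between two phase series quantifies the asymmetry of the
distribution of their instantaneous phase differences:

    PLI = | < sign( sin(phi_a(t) - phi_b(t)) ) > |

where <> is the mean over time samples.  A value of 0 means no consistent
coupling, or coupling at zero lag (mod pi) — which is exactly what
instantaneous field spread / volume conduction produces, so the PLI is
insensitive to it.  A value of 1 means a perfectly consistent non-zero
phase lag.  sign(0) contributes 0, so a constant phase difference of pi
also yields 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import FrequencyBand
from .spectral import PhaseEpoch

AVERAGED = "averaged"

# |sin(dphi)| below this counts as an exact zero so that constructed
# inputs with lags of exactly 0 or pi contribute sign(0) = 0
_SIN_ZERO_TOL = 1e-9


def _lag_signs(delta_phi: np.ndarray) -> np.ndarray:
    s = np.sin(delta_phi)
    return np.where(np.abs(s) < _SIN_ZERO_TOL, 0.0, np.sign(s))


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative ROI x ROI PLI matrix with zero diagonal."""

    weights: np.ndarray
    band: FrequencyBand | None = None
    subject_id: str | None = None
    epoch_index: int | str | None = None  # epoch number or "averaged"
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        self.weights = w

    def validate(self) -> None:
        w = self.weights
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("PLI weights must lie in [0, 1]")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


def pli_pair(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """PLI between two instantaneous-phase series.

    Phase differences are used as given; adding any multiple of 2*pi to the
    difference leaves the value unchanged, as does a common phase shift.
    """
    a = np.asarray(phi_a, dtype=float).ravel()
    b = np.asarray(phi_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"phase series length mismatch: {a.size} vs {b.size}"
        )
    if a.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(_lag_signs(a - b))))


def pli_matrix_from_phases(phases: np.ndarray) -> np.ndarray:
    """PLI for all unordered ROI pairs of a (n_rois, n_samples) phase array."""
    phi = np.asarray(phases, dtype=float)
    n = phi.shape[0]
    if n < 2:
        raise ValueError("need at least 2 ROIs")
    out = np.zeros((n, n))
    # row-block broadcasting keeps peak memory at one (n-i) x T slab
    for i in range(n - 1):
        s = _lag_signs(phi[i] - phi[i + 1 :])
        out[i, i + 1 :] = np.abs(s.mean(axis=1))
    out += out.T
    return out


def pli_matrix(phase_epoch: PhaseEpoch) -> ConnectivityMatrix:
    """Compute the full PLI adjacency matrix of a phase epoch."""
    m = ConnectivityMatrix(
        weights=pli_matrix_from_phases(phase_epoch.phases),
        band=phase_epoch.band,
        subject_id=phase_epoch.subject_id,
        epoch_index=phase_epoch.epoch_index,
        roi_labels=phase_epoch.roi_labels,
    )
    return m


def average_connectivity(
    per_epoch: list[ConnectivityMatrix],
) -> ConnectivityMatrix:
    """Entrywise mean of per-epoch matrices for one subject and band."""
    if not per_epoch:
        raise ValueError("no matrices to average")
    first = per_epoch[0]
    for m in per_epoch[1:]:
        if m.band != first.band:
            raise ValueError(
                f"cannot average across bands: {m.band} vs {first.band}"
            )
        if m.subject_id != first.subject_id:
            raise ValueError(
                f"cannot average across subjects: "
                f"{m.subject_id} vs {first.subject_id}"
            )
        if m.weights.shape != first.weights.shape:
            raise ValueError("matrix shape mismatch")
    mean = np.mean([m.weights for m in per_epoch], axis=0)
    return ConnectivityMatrix(
        weights=mean,
        band=first.band,
        subject_id=first.subject_id,
        epoch_index=AVERAGED,
        roi_labels=first.roi_labels,
    )
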