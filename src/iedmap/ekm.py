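"""Excess-kurtosis mapping (EKM) baseline.

Voxelwise excess kurtosis of unit-gain scalar-beamformer reconstructions on
a regular grid: sharply contoured, non-Gaussian activity (spikes, sharps)
produces heavy-tailed voxel time courses and hence high kurtosis.  Voxels
above a kurtosis threshold are marked as peaks, and temporal markers are
placed on the broadband peak virtual electrode wherever the peak-to-RMS
ratio exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .beamformer import BeamformerWeights, CovarianceSpec, data_covariance, lcmv_weights, project_timecourses
from .containers import ConductorModel, Recording, SensorArray, SourceGrid
from .exceptions import DomainError, ParameterError
from .forward import Leadfield, compute_leadfield

__all__ = [
    "MarkerSet",
    "excess_kurtosis",
    "kurtosis_map",
    "kurtosis_peaks",
    "place_markers",
]


def excess_kurtosis(x: np.ndarray) -> float:
    """Population excess kurtosis g2 = m4 / m2^2 - 3 (Gaussian -> 0)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise ParameterError("need at least 4 samples for kurtosis")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 <= 0:
        raise DomainError("kurtosis undefined for a zero-variance signal")
    m4 = np.mean(xc**4)
    return float(m4 / m2**2 - 3.0)


def kurtosis_map(
    rec: Recording,
    grid: SourceGrid,
    conductor: ConductorModel,
    sensors: SensorArray,
    leadfield: Optional[Leadfield] = None,
    cov: Optional[CovarianceSpec] = None,
    weights: Optional[BeamformerWeights] = None,
    run_id: Optional[str] = None,
):
    """Excess kurtosis of the scalar-beamformer reconstruction at each voxel.

    The recording must already be filtered to the mapping band (20-70 Hz in
    the standard pipeline).  Precomputed lead field / covariance / weights
    may be passed to avoid recomputation across runs.
    """
    from .state_maps import VolumetricMap  # local import to avoid a cycle

    if weights is None:
        if leadfield is None:
            leadfield = compute_leadfield(grid, conductor, sensors)
        if cov is None:
            cov = data_covariance(rec)
        weights = lcmv_weights(leadfield, cov)
    V = weights.weights.shape[0]
    values = np.full(V, -3.0)
    valid = weights.valid.copy()
    for sl, block in project_timecourses(weights, rec.data):
        bc = block - block.mean(axis=1, keepdims=True)
        m2 = np.mean(bc**2, axis=1)
        m4 = np.mean(bc**4, axis=1)
        ok = m2 > 0
        vals = np.full(block.shape[0], -3.0)
        vals[ok] = m4[ok] / m2[ok] ** 2 - 3.0
        values[sl] = vals
        valid[sl] &= ok
    return VolumetricMap(
        grid=weights.leadfield.grid, values=values, valid=valid,
        method="excess_kurtosis", run_id=run_id or rec.run_id,
    )


def kurtosis_peaks(vmap, kurtosis_min: float = 0.5, min_separation_mm: float = 20.0):
    """Kurtosis peaks: local maxima strictly above ``kurtosis_min``.

    Nearby maxima are merged with the same greedy separation rule as state
    maps.  May return an empty list (a negative run).
    """
    from .state_maps import find_peak

    peaks = find_peak(vmap, n_peaks=vmap.values.size, min_separation_mm=min_separation_mm)
    return [p for p in peaks if p.value > kurtosis_min]


@dataclass
class MarkerSet:
    """Temporal markers on a peak virtual electrode."""

    peak_position: np.ndarray  # (3,) metres
    times: np.ndarray  # s, strictly increasing
    kurtosis_min: float
    peak_to_rms_min: float
    run_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise DomainError("marker times must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return int(self.times.size)


def place_markers(
    trace: np.ndarray,
    fs: float,
    peak_position: np.ndarray,
    peak_to_rms_min: float = 6.0,
    refractory_ms: float = 200.0,
    kurtosis_min: float = 0.5,
    run_id: str = "",
) -> MarkerSet:
    """Markers wherever |x(t)| / RMS(x) exceeds the threshold.

    RMS is global over the trace.  Candidate samples closer than
    ``refractory_ms`` collapse to the absolute-maximum sample of their
    cluster, so one spike yields one marker.
    """
    x = np.asarray(trace, dtype=float).ravel()
    rms = float(np.sqrt(np.mean(x**2)))
    if rms <= 0:
        raise DomainError("marker placement undefined on a zero trace")
    cand = np.flatnonzero(np.abs(x) > peak_to_rms_min * rms)
    gap = int(round(refractory_ms / 1000.0 * fs))
    markers: list[int] = []
    i = 0
    while i < len(cand):
        j = i
        while j + 1 < len(cand) and cand[j + 1] - cand[j] <= gap:
            j += 1
        cluster = cand[i : j + 1]
        markers.append(int(cluster[np.argmax(np.abs(x[cluster]))]))
        i = j + 1
    return MarkerSet(
        peak_position=np.asarray(peak_position, dtype=float).reshape(3),
        times=np.asarray(markers, dtype=float) / fs,
        kurtosis_min=kurtosis_min,
        peak_to_rms_min=peak_to_rms_min,
        run_id=run_id,
    )
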