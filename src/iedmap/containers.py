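"""Core in-memory containers: sensor geometry, conductor model, source grids,
recordings, and synthetic-run ground truth.

Positions are in metres throughout; grid spacings are quoted in millimetres
because that is how reconstruction grids are conventionally specified.
Magnetic fields are in tesla, dipole moments in nAm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError, ParameterError

__all__ = [
    "SensorArray",
    "ConductorModel",
    "SourceGrid",
    "Recording",
    "EventSpec",
    "PropagationSpec",
    "Scenario",
    "GroundTruth",
]

_ORIENT_TOL = 1e-9


@dataclass
class SensorArray:
    """Point-magnetometer array: positions and sensing orientations.

    Orientations must be unit vectors; for the radial arrays produced by
    :func:`iedmap.forward.make_sensor_array` they point away from the
    conductor centre.
    """

    channel_ids: list[str]
    positions: np.ndarray  # (n, 3) metres
    orientations: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = len(self.channel_ids)
        if n < 8:
            raise ParameterError(f"need at least 8 channels, got {n}")
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ParameterError("positions/orientations must be (n_channels, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > _ORIENT_TOL):
            raise ParameterError("orientations must be unit-norm to 1e-9")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)


@dataclass
class ConductorModel:
    """Homogeneous conducting sphere (single-sphere head model)."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.09

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not self.radius > 0:
            raise ParameterError("conductor radius must be positive")

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts - self.center, axis=1)
        return r < self.radius - margin


@dataclass
class SourceGrid:
    """Regular lattice of candidate source locations inside the conductor."""

    spacing_mm: float
    positions: np.ndarray  # (n_voxels, 3) metres, masked voxels only
    inside_mask: np.ndarray  # (n_voxels,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.inside_mask = np.asarray(self.inside_mask, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ParameterError("grid positions must be (n, 3)")
        if self.inside_mask.shape != (self.positions.shape[0],):
            raise ParameterError("inside_mask length mismatch")

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def regular(
        cls,
        conductor: ConductorModel,
        spacing_mm: float,
        min_radius: float = 0.01,
        margin: float = 0.004,
    ) -> "SourceGrid":
        """Regular isotropic lattice covering the conductor interior.

        Voxels closer than ``min_radius`` to the centre are excluded: sources
        there are near-silent in a sphere and cannot be localized.  A
        ``margin`` keeps voxels strictly inside the conductor surface.
        """
        if spacing_mm <= 0:
            raise ParameterError("spacing must be positive")
        s = spacing_mm / 1000.0
        rmax = conductor.radius - margin
        k = int(np.floor(rmax / s))
        axis = np.arange(-k, k + 1) * s
        xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]) + conductor.center
        r = np.linalg.norm(pts - conductor.center, axis=1)
        keep = (r <= rmax) & (r >= min_radius)
        pts = pts[keep]
        if pts.shape[0] == 0:
            raise DomainError("grid has no voxels inside the conductor")
        return cls(spacing_mm=spacing_mm, positions=pts, inside_mask=np.ones(pts.shape[0], bool))


@dataclass
class Recording:
    """Multichannel run: channels x samples at a fixed sample rate.

    ``history`` is an append-only log of processing steps (name + parameters)
    so that the provenance of any derived recording is machine readable.
    """

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    sensors: Optional[SensorArray] = None
    run_id: str = "run"
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be channels x samples")
        if not self.fs > 0:
            raise ParameterError("sample rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DomainError("recording contains non-finite samples")
        if self.sensors is not None and self.sensors.n_channels != self.data.shape[0]:
            raise DomainError("channel count does not match sensor array")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def evolve(self, data: np.ndarray, fs: Optional[float] = None, step: Optional[dict] = None) -> "Recording":
        """Return a copy with new data, same geometry, and extended history."""
        hist = list(self.history)
        if step is not None:
            hist.append(step)
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            sensors=self.sensors,
            run_id=self.run_id,
            history=hist,
        )


_EVENT_KINDS = ("spike_wave", "polymorphic_burst")
_WAVEFORM_POLICIES = ("fixed_template", "resample_each_event")


@dataclass
class EventSpec:
    """Description of one source's interictal event stream."""

    kind: str
    rate: float = 0.2  # events / s
    duration: float = 0.5  # s, length of one event window
    amplitude: float = 40.0  # nAm peak moment
    jitter: float = 0.0  # s, applied to propagated events
    waveform_policy: str = "fixed_template"

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ParameterError(f"unknown event kind {self.kind!r}")
        if self.rate < 0:
            raise ParameterError("event rate must be >= 0")
        if not self.duration > 0:
            raise ParameterError("event duration must be positive")
        if self.waveform_policy not in _WAVEFORM_POLICIES:
            raise ParameterError(f"unknown waveform policy {self.waveform_policy!r}")
        if self.kind == "polymorphic_burst" and self.waveform_policy != "resample_each_event":
            raise ParameterError("polymorphic bursts must resample the waveform on each event")


@dataclass
class PropagationSpec:
    """Directed propagation: events at ``from_idx`` trigger events at ``to_idx``."""

    from_idx: int
    to_idx: int
    lag: float  # s, onset-to-onset
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ParameterError("propagation probability must be in [0, 1]")
        if self.from_idx == self.to_idx:
            raise ParameterError("propagation must link two distinct sources")


@dataclass
class Scenario:
    """Full description of one synthetic run."""

    sources: list[tuple[np.ndarray, EventSpec]]
    duration: float = 120.0
    fs: float = 1200.0
    seed: int = 0
    propagation: Optional[PropagationSpec] = None
    background_rms: float = 120e-15  # T, per-channel brain-noise RMS (broadband)
    alpha_fraction: float = 0.35  # fraction of brain-noise dipoles carrying the ~10 Hz rhythm
    sensor_noise_rms: float = 25e-15  # T, white sensor noise per sample

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError("scenario duration must be positive")
        if not self.fs > 0:
            raise ParameterError("scenario sample rate must be positive")
        self.sources = [(np.asarray(p, dtype=float).reshape(3), spec) for p, spec in self.sources]
        if self.propagation is not None:
            n = len(self.sources)
            if not (0 <= self.propagation.from_idx < n and 0 <= self.propagation.to_idx < n):
                raise ParameterError("propagation indices out of range")

    def validate_geometry(self, conductor: ConductorModel) -> None:
        for pos, _ in self.sources:
            if not conductor.contains(pos)[0]:
                raise DomainError("scenario source position outside conductor")


@dataclass
class GroundTruth:
    """True source geometry and event timing for a synthetic run."""

    source_positions: np.ndarray  # (n_sources, 3) metres
    event_intervals: list[list[tuple[float, float]]]  # per source, (start, end) s
    event_peaks: list[list[float]]  # per source, time of waveform peak, s
    propagation_links: list[tuple[tuple[int, int], tuple[int, int]]]  # ((src, evt), (src, evt))

    def __post_init__(self) -> None:
        self.source_positions = np.asarray(self.source_positions, dtype=float)

    def validate(self, duration: float) -> None:
        for intervals in self.event_intervals:
            prev_end = -np.inf
            for start, end in intervals:
                if start < 0 or end > duration or end <= start:
                    raise DomainError("event interval outside run bounds")
                if start < prev_end:
                    raise DomainError("overlapping event intervals for one source")
                prev_end = end
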