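"""Pipeline configuration with the standard clinical defaults.

Defaults: 20-70 Hz mapping band, 60 Hz notch, downsampling to 150 Hz, 73 ms
embedding window, 50 principal components, 5 states binarized at 2/3, 4 mm
HMM mapping grid, 5 mm EKM grid, kurtosis peak threshold 0.5, peak-to-RMS
marker threshold 6, and a +/-73 ms coincidence window.  Every field is
validated against the corresponding operation's preconditions at load time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    band: tuple[float, float] = (20.0, 70.0)
    notch_hz: float = 60.0
    fs_hmm: float = 150.0
    window_ms: float = 73.0
    n_components: int = 50
    n_states: int = 5
    probability_threshold: float = 2.0 / 3.0
    standardize: bool = True
    hmm_grid_mm: float = 4.0
    ekm_grid_mm: float = 5.0
    kurtosis_min: float = 0.5
    peak_to_rms_min: float = 6.0
    refractory_ms: float = 200.0
    coincidence_window_ms: float = 73.0
    ve_band: tuple[float, float] = (1.0, 150.0)
    max_iter: int = 200
    free_energy_tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.band = tuple(self.band)
        self.ve_band = tuple(self.ve_band)
        if not 0 < self.band[0] < self.band[1]:
            raise ParameterError("mapping band must satisfy 0 < low < high")
        if not 0 < self.ve_band[0] < self.ve_band[1]:
            raise ParameterError("VE band must satisfy 0 < low < high")
        if self.band[1] > self.fs_hmm / 2:
            raise ParameterError("mapping band exceeds the HMM-rate Nyquist")
        if not 0.5 < self.probability_threshold <= 1.0:
            raise ParameterError("probability threshold must be in (0.5, 1]")
        if self.n_states < 2 or self.n_components < 1:
            raise ParameterError("need at least 2 states and 1 component")
        if self.hmm_grid_mm <= 0 or self.ekm_grid_mm <= 0:
            raise ParameterError("grid spacings must be positive")
        if self.peak_to_rms_min <= 0 or self.coincidence_window_ms <= 0:
            raise ParameterError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: "str | Path") -> None:
        d = asdict(self)
        d["band"] = list(self.band)
        d["ve_band"] = list(self.ve_band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def hmm_config(self):
        from .tde_hmm import HMMConfig

        return HMMConfig(
            n_states=self.n_states,
            window_ms=self.window_ms,
            n_components=self.n_components,
            max_iter=self.max_iter,
            free_energy_tol=self.free_energy_tol,
            n_restarts=self.n_restarts,
            seed=self.seed,
            probability_threshold=self.probability_threshold,
        )
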