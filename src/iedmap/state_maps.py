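"""Volumetric maps of HMM state activity: active/inactive variance-ratio
maps, peak finding, peak virtual electrodes, and a ranking heuristic that
stands in for expert selection of the epileptiform state on synthetic data.

The variance-ratio map evaluates, for every voxel's beamformed time course,
``var(VE | state active) / var(VE | state inactive)``; regions whose
reconstructed variance rises when a state switches on light up.  Variance is
computed about the segment mean within each condition separately, which
removes any DC offset in the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .beamformer import BeamformerWeights, virtual_electrode
from .containers import Recording, SourceGrid
from .ekm import excess_kurtosis
from .exceptions import DomainError, ParameterError
from .tde_hmm import HMMModel, StateTimeCourse

__all__ = [
    "VolumetricMap",
    "Peak",
    "state_variance_map",
    "find_peak",
    "state_peak_timecourse",
    "rank_epileptiform_states",
    "select_state_by_ground_truth",
    "PeakTrace",
]


@dataclass
class VolumetricMap:
    """Scalar value per grid voxel (variance ratio or kurtosis)."""

    grid: SourceGrid
    values: np.ndarray  # (V,) over masked voxels
    valid: np.ndarray  # (V,) bool
    method: str
    run_id: str = ""
    state: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(~np.isfinite(self.values[self.valid])):
            raise DomainError("map values must be finite on valid voxels")

    @property
    def positions(self) -> np.ndarray:
        return self.grid.positions[self.grid.inside_mask]


@dataclass
class Peak:
    position: np.ndarray  # (3,) metres
    value: float
    voxel: int  # index into the map's masked voxels


def condition_masks(
    stc: StateTimeCourse, state: int, fs_target: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Active/inactive sample masks mapped onto another time base by seconds.

    Whole active visits are mapped inclusively; samples outside the valid
    (edge-trimmed) span of the state time course belong to neither condition.
    """
    active = np.zeros(n_samples, dtype=bool)
    covered = np.zeros(n_samples, dtype=bool)
    t = stc.times
    t0, t1 = t[0], t[-1]
    i0 = max(0, int(np.ceil(t0 * fs_target)))
    i1 = min(n_samples - 1, int(np.floor(t1 * fs_target)))
    covered[i0 : i1 + 1] = True
    for a, b in stc.visit_intervals(state):
        ja = max(0, int(np.floor(a * fs_target)))
        jb = min(n_samples - 1, int(np.ceil(b * fs_target)))
        active[ja : jb + 1] = True
    active &= covered
    inactive = covered & ~active
    return active, inactive


def _masked_covariance(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    X = data[:, mask]
    Xc = X - X.mean(axis=1, keepdims=True)
    return (Xc @ Xc.T) / max(X.shape[1] - 1, 1)


def state_variance_map(
    weights: BeamformerWeights,
    rec: Recording,
    stc: StateTimeCourse,
    state: int,
    min_condition_s: float = 0.5,
) -> VolumetricMap:
    """Active/inactive variance-ratio map for one state.

    The per-voxel ratio is computed from the active- and inactive-condition
    channel covariances (quadratic forms through the beamformer weights), so
    no voxel time course is ever materialized.
    """
    active, inactive = condition_masks(stc, state, rec.fs, rec.n_samples)
    if active.sum() / rec.fs < min_condition_s:
        raise DomainError(f"state {state} active for less than {min_condition_s} s")
    if inactive.sum() / rec.fs < min_condition_s:
        raise DomainError(f"state {state} inactive for less than {min_condition_s} s")
    C_act = _masked_covariance(rec.data, active)
    C_inact = _masked_covariance(rec.data, inactive)
    W = weights.weights
    var_act = np.einsum("vc,cd,vd->v", W, C_act, W)
    var_inact = np.einsum("vc,cd,vd->v", W, C_inact, W)
    valid = weights.valid & (var_inact > 0)
    values = np.ones_like(var_act)
    values[valid] = var_act[valid] / var_inact[valid]
    return VolumetricMap(
        grid=weights.leadfield.grid, values=values, valid=valid,
        method="state_variance_ratio", run_id=rec.run_id, state=state,
    )


def find_peak(
    vmap: VolumetricMap, n_peaks: int = 1, min_separation_mm: float = 20.0
) -> list[Peak]:
    """Greedy descending-value peak selection with a minimum separation.

    Candidates are visited in order of decreasing value (ties broken by
    voxel index); a candidate is kept only if it lies at least
    ``min_separation_mm`` from every already-selected peak.
    """
    if not np.any(vmap.valid):
        raise DomainError("map has no valid voxels")
    idx = np.flatnonzero(vmap.valid)
    values = vmap.values[idx]
    order = np.lexsort((idx, -values))
    pos = vmap.positions[idx]
    sep_m = min_separation_mm / 1000.0
    peaks: list[Peak] = []
    for o in order:
        p = pos[o]
        if all(np.linalg.norm(p - pk.position) >= sep_m for pk in peaks):
            peaks.append(Peak(position=p.copy(), value=float(values[o]), voxel=int(idx[o])))
            if len(peaks) >= n_peaks:
                break
    return peaks


@dataclass
class PeakTrace:
    """Broadband VE at a map peak with the state's active intervals."""

    times: np.ndarray  # s
    trace: np.ndarray
    peak: Peak
    state_intervals: list[tuple[float, float]]  # s


def state_peak_timecourse(
    vmap: VolumetricMap,
    weights_broadband: BeamformerWeights,
    rec: Recording,
    stc: Optional[StateTimeCourse] = None,
) -> PeakTrace:
    """Broadband virtual electrode at the map peak, with active intervals.

    ``weights_broadband`` must be defined on the same grid as the map (their
    voxel indexing is shared); ``rec`` should be the broadband (1-150 Hz)
    recording the weights' covariance was estimated from.
    """
    peak = find_peak(vmap, n_peaks=1)[0]
    row = int(np.flatnonzero(weights_broadband.voxel_indices == peak.voxel)[0]) \
        if weights_broadband.voxel_indices.shape[0] != vmap.values.shape[0] else peak.voxel
    trace = virtual_electrode(weights_broadband, rec, row)
    intervals = stc.visit_intervals(vmap.state) if (stc is not None and vmap.state is not None) else []
    for a, b in intervals:
        if a < 0 or b > rec.duration:
            raise DomainError("state interval outside run bounds")
    return PeakTrace(times=rec.times, trace=trace, peak=peak, state_intervals=intervals)


@dataclass
class StateRanking:
    order: list[int]  # states, best candidate first
    scores: np.ndarray  # (K,)
    low_confidence: bool


def rank_epileptiform_states(
    model: HMMModel,
    maps: dict[int, VolumetricMap],
    peak_traces: dict[int, PeakTrace],
    stc: Optional[StateTimeCourse] = None,
    kurtosis_floor: float = 0.5,
) -> StateRanking:
    """Heuristic ordering of states by how epileptiform they look.

    Score = excess kurtosis of the state's peak VE (computed over samples in
    the state's active intervals when enough are available, else the whole
    trace) weighted by the rank of the state's map peak value.  The final
    selection remains the user's; when no state shows super-Gaussian peak
    activity the ranking is flagged low-confidence.
    """
    states = sorted(maps.keys())
    peak_values = np.array([find_peak(maps[k], 1)[0].value for k in states])
    ranks = np.empty(len(states))
    ranks[np.argsort(-peak_values, kind="stable")] = np.arange(len(states))
    rank_weight = (len(states) - ranks) / len(states)  # 1 for the largest peak
    kurts = np.empty(len(states))
    for i, k in enumerate(states):
        pt = peak_traces[k]
        x = pt.trace
        if pt.state_intervals:
            sel = np.zeros(len(x), dtype=bool)
            for a, b in pt.state_intervals:
                sel |= (pt.times >= a) & (pt.times <= b)
            if sel.sum() >= 100 and np.std(x[sel]) > 0:
                x = x[sel]
        kurts[i] = excess_kurtosis(x) if np.std(x) > 0 else -3.0
    scores = kurts * rank_weight
    order = [states[i] for i in np.lexsort((np.arange(len(states)), -scores))]
    low_confidence = bool(np.max(kurts) < kurtosis_floor)
    return StateRanking(order=order, scores=scores, low_confidence=low_confidence)


def select_state_by_ground_truth(stc: StateTimeCourse, intervals: list[tuple[float, float]]) -> tuple[int, float]:
    """State whose activations best match true event intervals (max F1).

    Used on synthetic runs in place of expert visual selection.  Returns
    (state, F1 score).
    """
    if not intervals:
        raise ParameterError("ground truth has no event intervals")
    t = stc.times
    truth = np.zeros(len(t), dtype=bool)
    for a, b in intervals:
        truth |= (t >= a) & (t <= b)
    best_k, best_f1 = 0, -1.0
    for k in range(stc.n_states):
        a = stc.active[:, k]
        tp = float(np.sum(a & truth))
        prec = tp / max(a.sum(), 1)
        rec_ = tp / max(truth.sum(), 1)
        f1 = 2 * prec * rec_ / (prec + rec_) if (prec + rec_) > 0 else 0.0
        if f1 > best_f1:
            best_k, best_f1 = k, f1
    return best_k, best_f1
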