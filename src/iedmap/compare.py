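"""Agreement metrics between the HMM arm and the EKM baseline.

Spatial correspondence is the Euclidean distance (mm) between the HMM
state-variance peak and the nearest kurtosis peak.  Temporal coincidence
counts, for each EKM marker, the number of distinct HMM state visits whose
interval intersects a +/-73 ms window around the marker, divided by the
number of markers; because one marker can be straddled by more than one
visit, the metric can exceed 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ekm import MarkerSet
from .exceptions import ParameterError
from .tde_hmm import StateTimeCourse

__all__ = [
    "PeakMatch",
    "Correspondence",
    "Coincidence",
    "spatial_correspondence",
    "temporal_coincidence",
    "state_occupancy",
]


@dataclass
class PeakMatch:
    hmm_index: int
    ekm_index: int
    distance_mm: float


@dataclass
class Correspondence:
    matches: list[PeakMatch]
    unmatched_hmm: list[int]
    unmatched_ekm: list[int]
    no_correspondence: bool = False

    @property
    def distances_mm(self) -> np.ndarray:
        return np.array([m.distance_mm for m in self.matches])


def _positions(peaks: Sequence) -> np.ndarray:
    out = []
    for p in peaks:
        out.append(np.asarray(getattr(p, "position", p), dtype=float).reshape(3))
    return np.array(out) if out else np.zeros((0, 3))


def spatial_correspondence(hmm_peaks: Sequence, ekm_peaks: Sequence) -> Correspondence:
    """Greedy nearest-neighbour pairing (closest pairs first), distances in mm.

    Accepts peak objects with a ``position`` attribute or bare 3-vectors in
    metres.  An empty list on either side yields a flagged
    ``no_correspondence`` result rather than an exception.
    """
    P = _positions(hmm_peaks)
    Q = _positions(ekm_peaks)
    if P.shape[0] == 0 or Q.shape[0] == 0:
        return Correspondence(
            matches=[], unmatched_hmm=list(range(P.shape[0])),
            unmatched_ekm=list(range(Q.shape[0])), no_correspondence=True,
        )
    D = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=-1) * 1000.0
    matches: list[PeakMatch] = []
    used_p: set[int] = set()
    used_q: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(D, axis=None), D.shape))[0]
    for i, j in order:
        if i in used_p or j in used_q:
            continue
        matches.append(PeakMatch(int(i), int(j), float(D[i, j])))
        used_p.add(int(i))
        used_q.add(int(j))
        if len(used_p) == P.shape[0] or len(used_q) == Q.shape[0]:
            break
    return Correspondence(
        matches=matches,
        unmatched_hmm=[i for i in range(P.shape[0]) if i not in used_p],
        unmatched_ekm=[j for j in range(Q.shape[0]) if j not in used_q],
    )


@dataclass
class Coincidence:
    """Visit-counting temporal-coincidence result."""

    percentage: Optional[float]
    matches_per_marker: np.ndarray = field(default_factory=lambda: np.empty(0))
    defined: bool = True


def temporal_coincidence(
    markers: MarkerSet,
    stc: StateTimeCourse,
    state: int,
    window_ms: float = 73.0,
) -> Coincidence:
    """Per-marker count of state visits within +/-``window_ms``.

    A visit counts when its (seconds) interval intersects
    ``[t - window, t + window]`` around the marker; the percentage is
    ``100 * total matches / n_markers`` and can exceed 100 when several
    visits straddle one marker.  With no markers the metric is undefined and
    flagged, not silently zero.
    """
    if markers.n_markers == 0:
        return Coincidence(percentage=None, defined=False)
    w = window_ms / 1000.0
    visits = stc.visit_intervals(state)
    counts = np.zeros(markers.n_markers, dtype=int)
    for i, t in enumerate(markers.times):
        lo, hi = t - w, t + w
        counts[i] = sum(1 for a, b in visits if (b >= lo) and (a <= hi))
    pct = 100.0 * counts.sum() / markers.n_markers
    return Coincidence(percentage=float(pct), matches_per_marker=counts)


def state_occupancy(stc: StateTimeCourse, state: int) -> float:
    """Percentage of valid samples in which the state is active."""
    if not 0 <= state < stc.n_states:
        raise ParameterError("state index out of range")
    return float(100.0 * stc.active[:, state].mean())
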