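"""Scalar LCMV beamformer: data covariance, unit-gain weights with optimal
orientation, and virtual-electrode time courses.

The spatial filter at a voxel passes unit gain from that location along a
chosen tangential orientation while minimizing total output variance:
``w = C^-1 L theta / (theta^T L^T C^-1 L theta)``.  The orientation
``theta`` is the eigenvector of the 2x2 matrix ``L^T C^-1 L`` with the
smallest eigenvalue, which maximizes unit-gain output power — the standard
scalar-beamformer orientation choice.

"No regularization" is implemented as an eigenvalue-truncated pseudo-inverse
of the covariance at its numerical rank: filtered or rank-deficient data
would make a plain inverse meaningless, and truncation is the minimal
faithful reading of an unregularized inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import Recording
from .exceptions import DomainError, ParameterError
from .forward import Leadfield
from .preprocess import bandpass

__all__ = [
    "CovarianceSpec",
    "BeamformerWeights",
    "data_covariance",
    "lcmv_weights",
    "virtual_electrode",
    "project_timecourses",
]

_RANK_RTOL = 1e-10


@dataclass
class CovarianceSpec:
    """Channel covariance with the band/window it was estimated in."""

    matrix: np.ndarray  # (C, C)
    band: Optional[tuple[float, float]]
    window: Optional[tuple[float, float]]
    rank: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12 * max(1.0, np.abs(self.matrix).max())):
            raise DomainError("covariance must be symmetric")

    def truncated_inverse(self) -> np.ndarray:
        """Pseudo-inverse keeping only the ``rank`` leading eigenvalues."""
        eigval, eigvec = np.linalg.eigh(self.matrix)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        r = self.rank
        inv = np.zeros_like(eigval)
        inv[:r] = 1.0 / eigval[:r]
        return (eigvec * inv) @ eigvec.T


def data_covariance(
    rec: Recording,
    band: Optional[tuple[float, float]] = None,
    window: Optional[tuple[float, float]] = None,
) -> CovarianceSpec:
    """Covariance of (optionally band-filtered) data over a time window.

    ``band=None`` uses the data as-is (appropriate when the recording is
    already filtered to the mapping band); ``window=None`` spans the whole
    recording.  The numerical rank (eigenvalues above ``1e-10 * max``) is
    recorded for the truncated pseudo-inversion.
    """
    r = bandpass(rec, band[0], band[1]) if band is not None else rec
    if window is not None:
        i0 = int(round(window[0] * r.fs))
        i1 = int(round(window[1] * r.fs))
        if not (0 <= i0 < i1 <= r.n_samples):
            raise ParameterError("covariance window outside the recording")
        X = r.data[:, i0:i1]
    else:
        X = r.data
    if X.shape[1] == 0:
        raise ParameterError("empty covariance window")
    if X.shape[1] / r.fs < 1.0:
        warnings.warn("covariance window shorter than 1 s; estimate may be unstable", stacklevel=2)
    Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / max(X.shape[1] - 1, 1)
    eigval = np.linalg.eigvalsh(C)
    rank = int(np.sum(eigval > _RANK_RTOL * eigval.max())) if eigval.max() > 0 else 0
    return CovarianceSpec(matrix=C, band=band, window=window, rank=rank)


@dataclass
class BeamformerWeights:
    """Unit-gain scalar weights per voxel."""

    weights: np.ndarray  # (V, C)
    orientations: np.ndarray  # (V, 3) chosen tangential orientation
    valid: np.ndarray  # (V,) bool
    leadfield: Leadfield
    cov: CovarianceSpec
    voxel_indices: np.ndarray  # (V,) indices into leadfield voxels

    @property
    def positions(self) -> np.ndarray:
        pos = self.leadfield.grid.positions[self.leadfield.grid.inside_mask]
        return pos[self.voxel_indices]


def _smallest_eigvec_2x2(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of symmetric 2x2 matrices, smallest eigenpair.

    ``M`` is (V, 2, 2).  Returns (lambda_min (V,), v (V, 2)), with a
    deterministic sign convention: the component of larger magnitude is
    non-negative (first component preferred on ties).
    """
    a, b, c = M[:, 0, 0], M[:, 0, 1], M[:, 1, 1]
    half_tr = 0.5 * (a + c)
    disc = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b**2, 0.0))
    lam = half_tr - disc
    v = np.stack([b, lam - a], axis=1)
    alt = np.stack([lam - c, b], axis=1)
    use_alt = np.linalg.norm(v, axis=1) < np.linalg.norm(alt, axis=1)
    v[use_alt] = alt[use_alt]
    degenerate = np.linalg.norm(v, axis=1) < 1e-300
    # isotropic case: pick the first basis direction
    v[degenerate] = np.array([1.0, 0.0])
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    lead = np.where(np.abs(v[:, 0]) >= np.abs(v[:, 1]), v[:, 0], v[:, 1])
    sign = np.where(lead < 0, -1.0, 1.0)
    return lam, v * sign[:, None]


def lcmv_weights(
    leadfield: Leadfield,
    cov: CovarianceSpec,
    regularization: float = 0.0,
    voxel_indices: Optional[Sequence[int]] = None,
) -> BeamformerWeights:
    """Unit-gain scalar LCMV weights at every usable voxel.

    ``regularization`` adds an isotropic loading ``reg * mean(eig)`` before
    inversion; at the default 0 the truncated pseudo-inverse is used.
    ``voxel_indices`` restricts computation to a subset of voxels.
    """
    if cov.rank < 2:
        raise DomainError("covariance rank must be at least 2")
    if regularization > 0:
        C = cov.matrix + regularization * np.trace(cov.matrix) / cov.matrix.shape[0] * np.eye(cov.matrix.shape[0])
        Ci = np.linalg.inv(C)
    else:
        Ci = cov.truncated_inverse()
    if voxel_indices is None:
        idx = np.arange(leadfield.n_voxels)
    else:
        idx = np.asarray(voxel_indices, dtype=int)
    L = leadfield.values[idx]  # (V, C, 2)
    basis = leadfield.basis[idx]  # (V, 3, 2)
    usable = leadfield.usable[idx]
    CiL = np.einsum("cd,vdj->vcj", Ci, L)
    M = np.einsum("vcj,vck->vjk", L, CiL)  # (V, 2, 2), symmetric
    lam, theta = _smallest_eigvec_2x2(M)
    valid = usable & (lam > 0)
    denom = np.where(valid, lam, 1.0)
    w = np.einsum("vcj,vj->vc", CiL, theta) / denom[:, None]
    w[~valid] = 0.0
    orientations = np.einsum("vdj,vj->vd", basis, theta)
    return BeamformerWeights(
        weights=w, orientations=orientations, valid=valid,
        leadfield=leadfield, cov=cov, voxel_indices=idx,
    )


def virtual_electrode(
    weights: BeamformerWeights,
    rec: Recording,
    voxel: int,
    band: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Beamformer-reconstructed time course at one voxel.

    ``voxel`` indexes the rows of ``weights`` (i.e. the voxels the weights
    were computed for).  ``band`` optionally band-filters the data first;
    the weights should have been built from a covariance in the same band.
    """
    if not 0 <= voxel < weights.weights.shape[0]:
        raise ParameterError("voxel index out of range")
    if not weights.valid[voxel]:
        raise DomainError("requested voxel has invalid (silent) beamformer weights")
    r = bandpass(rec, band[0], band[1]) if band is not None else rec
    return weights.weights[voxel] @ r.data


def project_timecourses(weights: BeamformerWeights, data: np.ndarray, chunk: int = 1024):
    """All-voxel VE projection, chunked over voxels (generator of blocks).

    Yields ``(voxel_slice, block)`` pairs where ``block`` is
    ``(n_chunk, n_samples)``; avoids materializing the full voxels-by-samples
    matrix.
    """
    V = weights.weights.shape[0]
    for lo in range(0, V, chunk):
        hi = min(lo + chunk, V)
        yield slice(lo, hi), weights.weights[lo:hi] @ data
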