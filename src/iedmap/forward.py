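"""Magnetostatic forward model: current dipoles in a homogeneous conducting
sphere (Sarvas closed form), radial point-magnetometer arrays, and tangential
lead fields on regular source grids.

Two classical identities of the spherical conductor are load-bearing here and
exploited downstream: a dipole at the sphere centre and any radially oriented
dipole are magnetically silent, so only the two tangential moment components
per source location carry signal.  Lead fields therefore have two columns per
voxel, spanning an orthonormal tangential basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ConductorModel, SensorArray, SourceGrid
from .exceptions import DomainError, ParameterError

__all__ = ["make_sensor_array", "dipole_field", "compute_leadfield", "tangential_basis", "Leadfield"]

_MU0_4PI = 1e-7  # mu_0 / 4 pi, T m / A
_NAM = 1e-9  # moments are quoted in nAm

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def make_sensor_array(n_channels: int, head_radius: float = 0.09, standoff: float = 0.02) -> SensorArray:
    """Quasi-uniform radial magnetometer array on the upper hemisphere.

    Channels are laid out on a golden-angle (Fibonacci) spiral covering the
    hemisphere ``z >= 0`` at radius ``head_radius + standoff`` and oriented
    radially (away from the sphere centre).  The layout is deterministic.
    """
    if n_channels < 8:
        raise ParameterError("need at least 8 channels")
    if head_radius <= 0 or standoff <= 0:
        raise ParameterError("head radius and standoff must be positive")
    r = head_radius + standoff
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels  # (0, 1]: upper hemisphere
    rho = np.sqrt(1.0 - z**2)
    phi = i * _GOLDEN_ANGLE
    units = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    units /= np.linalg.norm(units, axis=1, keepdims=True)
    ids = [f"MEG{k:03d}" for k in range(n_channels)]
    return SensorArray(channel_ids=ids, positions=r * units, orientations=units)


def _sarvas_field(q_pos: np.ndarray, q_moment: np.ndarray, sensor_pos: np.ndarray) -> np.ndarray:
    """Vectorized Sarvas formula.

    Parameters are broadcast: ``q_pos``/``q_moment`` are (V, 3) in metres /
    nAm (sphere-centred coordinates), ``sensor_pos`` is (C, 3) metres.
    Returns the magnetic field vector (V, C, 3) in tesla.
    """
    r = sensor_pos[None, :, :]  # (1, C, 3)
    r0 = q_pos[:, None, :]  # (V, 1, 3)
    q = q_moment[:, None, :] * _NAM  # A m
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)  # (V, C)
    rn = np.linalg.norm(r, axis=-1)  # (1, C)
    adotr = np.sum(a_vec * r, axis=-1)
    r0dotr = np.sum(r0 * r, axis=-1)
    F = a * (rn * a + rn**2 - r0dotr)
    # grad F with respect to the sensor coordinate
    c1 = a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + adotr / a
    gradF = c1[..., None] * r - c2[..., None] * r0
    qxr0 = np.cross(np.broadcast_to(q, a_vec.shape), np.broadcast_to(r0, a_vec.shape))
    qxr0_dot_r = np.sum(qxr0 * r, axis=-1)
    B = _MU0_4PI / F[..., None] ** 2 * (F[..., None] * qxr0 - qxr0_dot_r[..., None] * gradF)
    return B


def dipole_field(
    q_pos: np.ndarray,
    q_moment: np.ndarray,
    conductor: ConductorModel,
    sensors: SensorArray,
) -> np.ndarray:
    """Field of one current dipole, projected on each sensing orientation.

    ``q_pos`` in metres, ``q_moment`` in nAm.  Returns per-channel values in
    tesla.  The dipole must be strictly inside the conductor.
    """
    q_pos = np.asarray(q_pos, dtype=float).reshape(3)
    q_moment = np.asarray(q_moment, dtype=float).reshape(3)
    if not conductor.contains(q_pos)[0]:
        raise DomainError("dipole position outside the conductor sphere")
    B = _sarvas_field(
        (q_pos - conductor.center)[None, :],
        q_moment[None, :],
        sensors.positions - conductor.center,
    )[0]
    return np.sum(B * sensors.orientations, axis=-1)


def tangential_basis(positions: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal tangential basis at each source position.

    Returns (V, 3, 2).  The first vector is the z-axis Gram-Schmidt
    orthogonalized against the radial direction (x-axis fallback when the
    radial direction is within ~1e-6 of +/-z); the second completes a
    right-handed triplet radial x e1 = e2.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float)) - center
    rad = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (pos.shape[0], 1))
    collinear = np.abs(rad[:, 2]) > 1.0 - 1e-6
    ref[collinear] = np.array([1.0, 0.0, 0.0])
    e1 = ref - np.sum(ref * rad, axis=1, keepdims=True) * rad
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(rad, e1)
    return np.stack([e1, e2], axis=-1)


@dataclass
class Leadfield:
    """Tangential lead field on a source grid.

    ``values[v, c, j]`` is the field at channel ``c`` of a 1 nAm dipole along
    tangential basis vector ``j`` at voxel ``v``.  ``usable`` marks voxels
    whose lead field is numerically non-silent.
    """

    grid: SourceGrid
    values: np.ndarray  # (V, C, 2) tesla per nAm
    basis: np.ndarray  # (V, 3, 2)
    usable: np.ndarray  # (V,) bool

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def compute_leadfield(
    grid: SourceGrid,
    conductor: ConductorModel,
    sensors: SensorArray,
    chunk: int = 4096,
    silent_rtol: float = 1e-9,
) -> Leadfield:
    """Lead field of unit (1 nAm) tangential dipoles at every masked voxel."""
    pos = grid.positions[grid.inside_mask]
    if pos.shape[0] == 0:
        raise DomainError("source grid mask is empty")
    if not np.all(conductor.contains(pos)):
        raise DomainError("masked grid voxels must lie inside the conductor")
    basis = tangential_basis(pos, conductor.center)
    V, C = pos.shape[0], sensors.n_channels
    values = np.empty((V, C, 2))
    spos = sensors.positions - conductor.center
    cpos = pos - conductor.center
    for lo in range(0, V, chunk):
        hi = min(lo + chunk, V)
        for j in range(2):
            B = _sarvas_field(cpos[lo:hi], basis[lo:hi, :, j], spos)
            values[lo:hi, :, j] = np.sum(B * sensors.orientations[None, :, :], axis=-1)
    norms = np.linalg.norm(values.reshape(V, -1), axis=1)
    usable = norms > silent_rtol * norms.max()
    return Leadfield(grid=grid, values=values, basis=basis, usable=usable)
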