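"""Fourier-space linear elasticity for a bonded elastic layer.

Small-strain reference solution for a flat, isotropic, linearly elastic
layer of thickness ``h`` bonded to a rigid support at the bottom, with
displacement prescribed on the top surface.  Each in-plane wavevector
``(kx, ky)`` decouples into a 6-component two-point boundary value
problem in the state ``y = (u, v, w, s_xz, s_yz, s_zz)`` with
``dy/dz = A(kx, ky) y`` and constant ``A``; the propagator ``expm(A h)``
connects the clamped bottom to the loaded surface, yielding the surface
traction for a prescribed surface displacement.

This solver shares no machinery with the nonlinear finite-element module
and serves as its independent cross-check in the small-strain limit.  For
``k h >> 1`` the layer responds as a half-space; the thickness is capped
at ``12 / k`` per mode (relative error ~e^-24) to keep the propagator
well-conditioned.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def _system_matrix(kx: float, ky: float, mu: float, lam: float) -> np.ndarray:
    """d/dz [u, v, w, sxz, syz, szz] = A @ [.] for fields ~ e^{i(kx x + ky y)}."""
    ikx, iky = 1j * kx, 1j * ky
    A = np.zeros((6, 6), dtype=complex)
    # kinematics
    A[0, 3] = 1.0 / mu
    A[0, 2] = -ikx
    A[1, 4] = 1.0 / mu
    A[1, 2] = -iky
    A[2, 5] = 1.0 / (lam + 2 * mu)
    A[2, 0] = -lam / (lam + 2 * mu) * ikx
    A[2, 1] = -lam / (lam + 2 * mu) * iky
    # in-plane stresses in terms of the state
    # e = tr(strain) = ikx u + iky v + dw/dz
    c_e_u = 2 * mu / (lam + 2 * mu) * ikx
    c_e_v = 2 * mu / (lam + 2 * mu) * iky
    c_e_s = 1.0 / (lam + 2 * mu)

    # sxx = lam e + 2 mu ikx u ; syy = lam e + 2 mu iky v ; sxy = mu(iky u + ikx v)
    def put(row, cu, cv, cs):
        A[row, 0] += cu
        A[row, 1] += cv
        A[row, 5] += cs

    # d sxz/dz = -(ikx sxx + iky sxy)
    put(3, -ikx * (lam * c_e_u + 2 * mu * ikx) - iky * (mu * iky),
        -ikx * (lam * c_e_v) - iky * (mu * ikx),
        -ikx * lam * c_e_s)
    # d syz/dz = -(ikx sxy + iky syy)
    put(4, -ikx * (mu * iky) - iky * (lam * c_e_u),
        -ikx * (mu * ikx) - iky * (lam * c_e_v + 2 * mu * iky),
        -iky * lam * c_e_s)
    # d szz/dz = -(ikx sxz + iky syz)
    A[5, 3] = -ikx
    A[5, 4] = -iky
    return A


def layer_traction(displacement: np.ndarray, dx: float, h: float,
                   shear_modulus: float, nu: float,
                   kh_cap: float = 12.0) -> np.ndarray:
    """Surface traction for a prescribed top-surface displacement field.

    Parameters
    ----------
    displacement : (ny, nx, 3) array
        Prescribed (u, v, w) on a periodic grid of spacing ``dx`` (um).
    dx, h : float
        Grid spacing and layer thickness, um.
    shear_modulus : float
        Small-strain shear modulus (kPa).
    nu : float
        Poisson ratio (< 0.5).

    Returns
    -------
    (ny, nx, 3) array of surface tractions (kPa), same grid.
    """
    d = np.asarray(displacement, dtype=float)
    ny, nx, _ = d.shape
    mu = shear_modulus
    lam = 2 * mu * nu / (1 - 2 * nu)
    kxs = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
    kys = 2 * np.pi * np.fft.fftfreq(ny, d=dx)
    dhat = np.fft.fft2(d, axes=(0, 1))
    that = np.zeros_like(dhat, dtype=complex)
    for iy, ky in enumerate(kys):
        for ix, kx in enumerate(kxs):
            k = np.hypot(kx, ky)
            heff = h if k * h <= kh_cap else kh_cap / k
            M = expm(_system_matrix(kx, ky, mu, lam) * heff)
            M12 = M[:3, 3:]
            M22 = M[3:, 3:]
            t0 = np.linalg.solve(M12, dhat[iy, ix])
            that[iy, ix] = M22 @ t0
    return np.real(np.fft.ifft2(that, axes=(0, 1)))
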