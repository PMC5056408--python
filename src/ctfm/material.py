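"""Two-term Ogden hyperelasticity for the soft silicone substrate.

The substrate is a very soft, nearly incompressible silicone elastomer
characterized in uniaxial tension and equibiaxial inflation up to large
strains.  Its response is modelled with a two-term Ogden strain-energy
density in the convention used by the major commercial FE codes,

    W = sum_i 2 mu_i / alpha_i^2 * (l1^alpha_i + l2^alpha_i + l3^alpha_i - 3)
        + kappa/2 (J - 1)^2,

where ``l_a`` are (deviatoric, in the compressible case) principal
stretches and the initial shear modulus is ``mu_0 = sum_i mu_i``.  In this
convention the small-strain Young modulus is ``E = 2 (1 + nu) mu_0``; with
the calibrated parameters (mu1 = 4.073 kPa, alpha1 = 2.132, mu2 = 0.167
kPa, alpha2 = -0.600) and nu = 0.49 this gives E = 12.64 kPa, matching the
measured ~12.6 kPa modulus of the 9:10 mixing-ratio silicone.  (The
classical Ogden convention ``W = sum mu_i/alpha_i (...)`` with
``mu_0 = 1/2 sum mu_i alpha_i`` would give 12.79 kPa instead; the
convention below is the one under which the published parameters reproduce
the published modulus.)

Closed-form incompressible nominal (first Piola-Kirchhoff) stresses:

    uniaxial     P(l) = sum_i 2 mu_i / alpha_i (l^(alpha_i-1) - l^(-alpha_i/2-1))
    equibiaxial  P(l) = sum_i 2 mu_i / alpha_i (l^(alpha_i-1) - l^(-2 alpha_i-1))

All stresses are in kPa, stretches dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional
import json

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass(frozen=True)
class OgdenMaterial:
    """Two-term Ogden parameters (kPa / dimensionless) + Poisson ratio."""

    mu1: float
    alpha1: float
    mu2: float = 0.0
    alpha2: float = 1.0
    nu: float = 0.49

    def __post_init__(self) -> None:
        if self.alpha1 == 0 or self.alpha2 == 0:
            raise ValueError("Ogden exponents alpha_i must be nonzero")
        if self.mu0 <= 0:
            raise ValueError("initial shear modulus mu1 + mu2 must be > 0")
        if not (self.nu < 0.5):
            raise ValueError("Poisson ratio must be < 0.5")

    @property
    def mu0(self) -> float:
        """Initial shear modulus, kPa."""
        return self.mu1 + self.mu2

    @property
    def kappa(self) -> float:
        """Bulk modulus of the quadratic volumetric penalty, kPa."""
        return 2.0 * self.mu0 * (1.0 + self.nu) / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def terms(self) -> tuple[tuple[float, float], ...]:
        return ((self.mu1, self.alpha1), (self.mu2, self.alpha2))


#: Calibration of the 9:10 mixing-ratio CY52-276 substrate.
SUBSTRATE_9_10 = OgdenMaterial(mu1=4.073, alpha1=2.132, mu2=0.167,
                               alpha2=-0.600, nu=0.49)


def strain_energy(mat: OgdenMaterial, l1, l2, l3) -> np.ndarray:
    """Strain-energy density W(l1, l2, l3) in kPa.

    Deviatoric Ogden part evaluated on the isochoric stretches
    ``J^(-1/3) l_a`` plus the quadratic volumetric penalty consistent with
    the material's Poisson ratio.  At J = 1 the penalty vanishes and the
    expression is the classical incompressible Ogden energy.
    """
    l = np.broadcast_arrays(np.asarray(l1, float), np.asarray(l2, float),
                            np.asarray(l3, float))
    l = np.stack(l, axis=-1)
    if np.any(l <= 0):
        raise ValueError("principal stretches must be positive")
    J = np.prod(l, axis=-1)
    lb = l * J[..., None] ** (-1.0 / 3.0)
    W = np.zeros_like(J)
    for mu, al in ((mat.mu1, mat.alpha1), (mat.mu2, mat.alpha2)):
        if mu == 0.0:
            continue
        W = W + 2.0 * mu / al ** 2 * (np.sum(lb ** al, axis=-1) - 3.0)
    W = W + 0.5 * mat.kappa * (J - 1.0) ** 2
    return W


def _check_stretch(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    return lam


def nominal_stress_uniaxial(mat: OgdenMaterial, lam) -> np.ndarray:
    """Incompressible uniaxial nominal stress P(lambda), kPa."""
    lam = _check_stretch(lam)
    P = np.zeros_like(lam)
    for mu, al in ((mat.mu1, mat.alpha1), (mat.mu2, mat.alpha2)):
        if mu == 0.0:
            continue
        P = P + 2.0 * mu / al * (lam ** (al - 1.0) - lam ** (-al / 2.0 - 1.0))
    return P


def nominal_stress_equibiaxial(mat: OgdenMaterial, lam) -> np.ndarray:
    """Incompressible equibiaxial nominal stress P(lambda), kPa."""
    lam = _check_stretch(lam)
    P = np.zeros_like(lam)
    for mu, al in ((mat.mu1, mat.alpha1), (mat.mu2, mat.alpha2)):
        if mu == 0.0:
            continue
        P = P + 2.0 * mu / al * (lam ** (al - 1.0) - lam ** (-2.0 * al - 1.0))
    return P


def initial_youngs_modulus(mat: OgdenMaterial) -> float:
    """Small-strain Young modulus E = 2 (1 + nu) (mu1 + mu2), kPa."""
    return 2.0 * (1.0 + mat.nu) * mat.mu0


@dataclass
class StressStrainCurve:
    """Sampled nominal stress-stretch curve from a bench test."""

    lam: np.ndarray
    P: np.ndarray                       # kPa
    mode: Literal["uniaxial", "equibiaxial"]

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if np.any(self.lam <= 0):
            raise ValueError("stretches must be positive")
        if self.mode not in ("uniaxial", "equibiaxial"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class OgdenFit:
    material: OgdenMaterial
    residual_rms: float                 # kPa
    residuals: np.ndarray
    cov: Optional[np.ndarray]           # J^T J inverse proxy, may be None
    n_starts: int


def _stack_curves(curves: Iterable[StressStrainCurve]):
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one stress-strain curve")
    lam = np.concatenate([c.lam for c in curves])
    P = np.concatenate([c.P for c in curves])
    modes = np.concatenate([np.repeat(c.mode == "equibiaxial", len(c.lam))
                            for c in curves])
    if np.unique(lam).size < 4:
        raise ValueError("stress-strain data too rank-deficient to fit "
                         "four Ogden parameters")
    return lam, P, modes


def fit_ogden(curves: Iterable[StressStrainCurve], nu: float = 0.49,
              n_starts: int = 8, seed: int = 0) -> OgdenFit:
    """Least-squares fit of (mu1, alpha1, mu2, alpha2) to bench-test curves.

    Joint fit over all supplied curves (both loading modes weighted
    equally).  Multi-start local least squares around a neo-Hookean
    initial guess whose shear modulus comes from the small-strain slope;
    the best local optimum is returned.
    """
    lam, P, is_eq = _stack_curves(curves)

    # small-strain slope -> mu0 guess (uniaxial slope 3 mu0, equibiaxial 6 mu0)
    near = np.abs(lam - 1.0) < 0.25
    if near.sum() >= 2:
        denom = np.where(is_eq[near], 6.0, 3.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = P[near] / ((lam[near] - 1.0) * denom)
        mu0_guess = float(np.nanmedian(slopes[np.isfinite(slopes)]))
    else:
        mu0_guess = 1.0
    if not np.isfinite(mu0_guess) or mu0_guess <= 0:
        mu0_guess = 1.0

    def resid(p):
        mu1, a1, mu2, a2 = p
        try:
            m = OgdenMaterial(mu1=mu1, alpha1=a1, mu2=mu2, alpha2=a2, nu=nu)
        except ValueError:
            return 1e6 * np.ones_like(P)
        model = np.where(is_eq, nominal_stress_equibiaxial(m, lam),
                         nominal_stress_uniaxial(m, lam))
        return model - P

    rng = np.random.default_rng(seed)
    starts = [np.array([0.9 * mu0_guess, 2.0, 0.1 * mu0_guess, -0.5])]
    for _ in range(n_starts - 1):
        starts.append(np.array([
            mu0_guess * rng.uniform(0.3, 1.5), rng.uniform(0.5, 4.0),
            mu0_guess * rng.uniform(0.01, 0.7), rng.uniform(-3.0, -0.1)]))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("Ogden fit failed to converge from any start")
    mu1, a1, mu2, a2 = best.x
    mat = OgdenMaterial(mu1=mu1, alpha1=a1, mu2=mu2, alpha2=a2, nu=nu)
    J = best.jac
    cov = None
    try:
        JTJ = J.T @ J
        cov = np.linalg.inv(JTJ) * 2 * best.cost / max(len(P) - 4, 1)
    except np.linalg.LinAlgError:
        pass
    return OgdenFit(material=mat,
                    residual_rms=float(np.sqrt(np.mean(best.fun ** 2))),
                    residuals=best.fun, cov=cov, n_starts=len(starts))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_curves_csv(path) -> list[StressStrainCurve]:
    """Read curves from CSV with columns lambda, nominal_stress_kPa, mode."""
    df = pd.read_csv(path)
    out = []
    for mode, g in df.groupby("mode"):
        out.append(StressStrainCurve(lam=g["lambda"].to_numpy(),
                                     P=g["nominal_stress_kPa"].to_numpy(),
                                     mode=str(mode)))
    return out


def write_material_json(path, mat: OgdenMaterial) -> None:
    with open(path, "w") as f:
        json.dump({"mu1_kPa": mat.mu1, "alpha1": mat.alpha1,
                   "mu2_kPa": mat.mu2, "alpha2": mat.alpha2, "nu": mat.nu,
                   "E_kPa": initial_youngs_modulus(mat)}, f, indent=2)


def read_material_json(path) -> OgdenMaterial:
    with open(path) as f:
        d = json.load(f)
    return OgdenMaterial(mu1=d["mu1_kPa"], alpha1=d["alpha1"],
                         mu2=d["mu2_kPa"], alpha2=d["alpha2"], nu=d["nu"])
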