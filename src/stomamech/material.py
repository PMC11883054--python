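"""Transverse isotropic Saint-Venant Kirchhoff wall material (plane stress).

The cell wall is modelled with one stiff direction along the cellulose
microfibrils (modulus ``E2`` in the field's notation) and an isotropic
transverse response (``E1 = E3``).  The Poisson ratios are collapsed to a
single parameter ``nu``; symmetry of the stiffness is restored through the
reciprocal relation nu21 = nu * E1 / E2.  Stresses are MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MaterialError(ValueError):
    """Invalid material parameter combination."""


@dataclass(frozen=True)
class WallMaterial:
    """Plane-stress transverse isotropic SVK parameters.

    Parameters
    ----------
    fibre_modulus : float
        Young's modulus E2 along the microfibril direction, MPa.
    transverse_modulus : float
        Young's modulus E1 (= E3) transverse to the fibres, MPa.
    poisson : float
        Single Poisson-like compressibility parameter, 0 <= nu < 0.5.
    """

    fibre_modulus: float
    transverse_modulus: float
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if self.fibre_modulus <= 0 or self.transverse_modulus <= 0:
            raise MaterialError("Young's moduli must be positive")
        if not 0 <= self.poisson < 0.5:
            raise MaterialError("poisson must satisfy 0 <= nu < 0.5")
        C = self.stiffness()
        if np.any(np.linalg.eigvalsh(C) <= 0):
            raise MaterialError(
                f"stiffness matrix not positive definite for {self!r}"
            )

    def stiffness(self) -> np.ndarray:
        """3x3 plane-stress stiffness in Voigt order (11, 22, 12).

        Axis 1 is the fibre direction.  With Ef = E2, Et = E1, nu12 = nu and
        nu21 = nu Et / Ef the compliance is symmetric; inverting it in closed
        form gives

            C11 = Ef / d,  C22 = Et / d,  C12 = nu Et / d,  d = 1 - nu^2 Et/Ef

        and the shear entry uses G = sqrt(Ef Et) / (2 (1 + nu)), which reduces
        to the isotropic shear modulus when Ef = Et.
        """
        ef, et, nu = self.fibre_modulus, self.transverse_modulus, self.poisson
        d = 1.0 - nu * nu * et / ef
        if d <= 0:
            raise MaterialError("1 - nu^2 E1/E2 must be positive")
        g = np.sqrt(ef * et) / (2.0 * (1.0 + nu))
        return np.array(
            [
                [ef / d, nu * et / d, 0.0],
                [nu * et / d, et / d, 0.0],
                [0.0, 0.0, g],
            ]
        )

    def compliance(self) -> np.ndarray:
        """Plane-stress compliance matrix (inverse of :meth:`stiffness`)."""
        ef, et, nu = self.fibre_modulus, self.transverse_modulus, self.poisson
        g = np.sqrt(ef * et) / (2.0 * (1.0 + nu))
        return np.array(
            [
                [1.0 / ef, -nu / ef, 0.0],
                [-nu / ef, 1.0 / et, 0.0],
                [0.0, 0.0, 1.0 / g],
            ]
        )


def isotropic(young: float, poisson: float = 0.3) -> WallMaterial:
    """Degenerate isotropic case E1 = E2."""
    return WallMaterial(fibre_modulus=young, transverse_modulus=young, poisson=poisson)
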