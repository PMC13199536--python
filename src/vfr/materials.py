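"""Density-to-material mapping for homogenised trabecular bone.

The calibrated QCT density is interpreted as ash density and converted to
apparent density (rho_QCT = rho_ash = 0.6 * rho_app).  Elasticity and
strength follow the standard phenomenological power laws for vertebral
trabecular bone:

    E      = 4730 * rho_app^1.56   [MPa]
    sigma_y = 21.7 * rho_app^1.52  [MPa]
    E_py   = 0.05 * E              [MPa]   (post-yield tangent modulus)

i.e. yielding uses a von Mises criterion with isotropic hardening and a 95%
reduction of the elastic modulus past yield.  A small apparent-density
floor keeps fully lytic (zero-density) elements from producing a singular
stiffness; the floor default (0.01 g/cm^3, E ~= 3.5e-2 MPa) is orders of
magnitude below bone and does not influence intact elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaterialLaw", "ElementMaterials", "material_from_density",
           "DEFAULT_LAW"]


@dataclass(frozen=True)
class MaterialLaw:
    """Constants of the density-material relationships (config-overridable)."""

    e_coeff: float = 4730.0        # MPa
    e_exp: float = 1.56
    sy_coeff: float = 21.7         # MPa
    sy_exp: float = 1.52
    post_yield_ratio: float = 0.05
    ash_per_app: float = 0.6       # rho_ash / rho_app
    floor_app: float = 0.01        # g/cm^3, apparent-density floor
    poisson: float = 0.3           # not density-dependent

    def __post_init__(self):
        if not 0 < self.post_yield_ratio < 1:
            raise ValueError("post-yield ratio must be in (0, 1)")
        if self.floor_app < 0:
            raise ValueError("density floor must be >= 0")


DEFAULT_LAW = MaterialLaw()


@dataclass
class ElementMaterials:
    """Per-element material arrays, all the same length."""

    rho_qct: np.ndarray    # g/cm^3 (= ash density)
    rho_app: np.ndarray    # g/cm^3
    E: np.ndarray          # MPa
    sigma_y: np.ndarray    # MPa
    E_py: np.ndarray       # MPa
    law: MaterialLaw


def material_from_density(rho_qct, law: MaterialLaw = DEFAULT_LAW,
                          apply_floor: bool = True) -> ElementMaterials:
    """Map QCT (ash) density to apparent density and elasto-plastic moduli.

    ``rho_qct`` may be a scalar or array; negative densities are rejected.
    Densities whose apparent value falls below ``law.floor_app`` are mapped
    to the floor material when ``apply_floor`` is set.
    """
    rho_qct = np.atleast_1d(np.asarray(rho_qct, float))
    if (rho_qct < 0).any():
        raise ValueError("negative density is not physical")
    rho_app = rho_qct / law.ash_per_app
    if apply_floor:
        rho_app = np.maximum(rho_app, law.floor_app)
    E = law.e_coeff * rho_app ** law.e_exp
    sigma_y = law.sy_coeff * rho_app ** law.sy_exp
    return ElementMaterials(rho_qct=rho_qct, rho_app=rho_app, E=E,
                            sigma_y=sigma_y,
                            E_py=law.post_yield_ratio * E, law=law)
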