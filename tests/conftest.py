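"""Shared fixtures: analytic phantoms, rendered scans and bar FE models."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from vfr.anatomy import AnatomicalFrame
from vfr.calibration import DensitometricCalibration
from vfr.config import GeometryCfg, ScannerCfg, SolveCfg, StudyConfig
from vfr.image import SegmentationMask
from vfr.imaging import ScannerModel, render_qct
from vfr.materials import ElementMaterials, MaterialLaw
from vfr.meshing import mask_to_tet10_mesh
from vfr.model import FEModel
from vfr.phantoms import PhantomGeometry, make_vertebra_phantom

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """Elliptic-cylinder body, no lesions, 0.6 mm grid, no rod zone."""
    geom = PhantomGeometry(a=8.0, b=6.0, height=16.0, waist=0.12)
    return make_vertebra_phantom(geom, spacing=0.6)


@pytest.fixture(scope="session")
def small_scanner():
    """Noise-free scanner with small-diameter rods (desk-scale grid)."""
    return ScannerModel(hu_slope=1000.0, hu_intercept=-15.0, noise_sd=0.0,
                        psf_sd_mm=0.0, voxel_mm=0.6, rod_diameter=9.0)


@pytest.fixture(scope="session")
def scan_setup(small_scanner):
    """(phantom, scanner, noise-free HU image) with rods in frame."""
    geom = PhantomGeometry(a=8.0, b=6.0, height=16.0, waist=0.12)
    ph = make_vertebra_phantom(
        geom, spacing=0.6, rod_zone_mm=small_scanner.rod_zone_mm,
        min_grid_xy_mm=small_scanner.rod_row_extent + 10)
    img = render_qct(ph, small_scanner, seed=0)
    return ph, small_scanner, img


@pytest.fixture(scope="session")
def calibrated_setup(scan_setup):
    ph, scanner, img = scan_setup
    est = DensitometricCalibration().fit(img)
    return ph, scanner, est.transform(img), est


def make_bar_model(lx=10.0, ly=10.0, lz=20.0, elem=2.0, E=1000.0, nu=0.0,
                   sigma_y=1e12, E_py_ratio=0.05, spacing=1.0) -> FEModel:
    """Homogeneous cuboid bar model with trivial anatomical frame.

    ``sigma_y=1e12`` keeps the response purely elastic.
    """
    shape = (int(round(lx / spacing)), int(round(ly / spacing)),
             int(round(lz / spacing)))
    mask = SegmentationMask(np.ones(shape, bool), (spacing,) * 3)
    mesh = mask_to_tet10_mesh(mask, elem_size=elem)
    ne = mesh.n_elems
    law = MaterialLaw(poisson=nu)
    mats = ElementMaterials(
        rho_qct=np.full(ne, 0.15), rho_app=np.full(ne, 0.25),
        E=np.full(ne, float(E)), sigma_y=np.full(ne, float(sigma_y)),
        E_py=np.full(ne, E_py_ratio * float(E)), law=law)
    z = mesh.nodes[:, 2]
    cranial = np.flatnonzero(z >= z.max() - 1e-9)
    caudal = np.flatnonzero(z <= z.min() + 1e-9)
    frame = AnatomicalFrame(rotation=np.eye(3), center=np.zeros(3),
                            offset=np.zeros(3),
                            cranial_plane=(np.zeros(3), np.array([0, 0, 1.0])),
                            caudal_plane=(np.zeros(3), np.array([0, 0, 1.0])))
    return FEModel(mesh=mesh, frame=frame, materials=mats,
                   cranial_nodes=cranial, caudal_nodes=caudal,
                   hm_mm=lz, csa_mm2=lx * ly, bmc_g=0.0,
                   landmarks_world=np.zeros((6, 3)))


@pytest.fixture
def bar_model():
    return make_bar_model()


def fast_study_config(seed: int = 0, n_control: int = 1, n_lytic: int = 1,
                      geometry: GeometryCfg | None = None,
                      **solve_kw) -> StudyConfig:
    """Scaled-down study conditions used for the statistical suites."""
    solve = dict(elem_size=3.0, n_increments=2)
    solve.update(solve_kw)
    return StudyConfig(
        n_control=n_control, n_lytic=n_lytic, seed=seed,
        geometry=geometry or GeometryCfg(a=7.5, b=6.0, height=15.0,
                                         waist=0.1),
        scanner=ScannerCfg(noise_sd=5.0, psf_sd_mm=0.4, voxel_mm=0.8,
                           rod_diameter=9.0),
        solve=SolveCfg(**solve),
        local_metrics=False,
    )
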