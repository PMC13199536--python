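"""Mechanical outcome metrics and local strain probing of an FE result.

Global metrics: ultimate force F_U (the axial reaction at the final imposed
apparent strain), ultimate stress sigma_U = F_U / CSA, apparent stiffness K
(slope of the linear range of the force-displacement curve) and the
normalised apparent modulus E_APP = K * Hm / CSA.

Local metrics: nodal principal-strain frequency tables over the middle 50%
of the body height, and mean strains in a 3x3x3 lattice of 27 spherical
probes (2 mm radius) placed symmetrically about the body centre in the
anatomical frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import FEResult, nodal_principal_strains
from .model import FEModel

__all__ = [
    "MechanicalSummary",
    "ProbeSet",
    "ultimate_force",
    "apparent_stiffness",
    "mechanical_summary",
    "strain_histogram",
    "probe_grid",
    "probe_mean_strains",
]


@dataclass(frozen=True)
class MechanicalSummary:
    f_u_n: float          # ultimate force, N (compression positive)
    sigma_u_mpa: float    # F_U / CSA
    k_n_mm: float         # apparent stiffness
    e_app_mpa: float      # K * Hm / CSA
    hm_mm: float
    csa_mm2: float
    delta_l_mm: float     # final imposed displacement

    def as_dict(self) -> dict:
        return {
            "F_U_N": self.f_u_n, "sigma_U_MPa": self.sigma_u_mpa,
            "K_N_per_mm": self.k_n_mm, "E_APP_MPa": self.e_app_mpa,
            "Hm_mm": self.hm_mm, "CSA_mm2": self.csa_mm2,
            "delta_l_mm": self.delta_l_mm,
        }


def ultimate_force(result: FEResult) -> float:
    """Axial reaction at the final imposed apparent strain, N (positive).

    Raises if the solve stopped short of the target apparent strain.
    """
    target = result.apparent_strain * result.hm_mm
    if result.final_delta_l_mm < target * (1 - 1e-9):
        raise RuntimeError(
            f"solve stopped early: reached {result.final_delta_l_mm:.4f} of "
            f"{target:.4f} mm")
    return abs(result.final_force_n)


def apparent_stiffness(result: FEResult, method: str = "preyield",
                       force_fraction: float = 0.5) -> float:
    """Slope of the linear range of the force-displacement curve, N/mm.

    ``method='preyield'`` regresses force on displacement over the origin
    plus all increments with zero plastic activity.  If yielding starts in
    the very first increment it falls back to the first-increment secant
    (with a warning).  ``method='fraction'`` instead uses all increments
    with force below ``force_fraction`` of the final force.
    """
    h = result.history
    dl = np.concatenate([[0.0], h["delta_l_mm"].to_numpy()])
    f = np.concatenate([[0.0], np.abs(h["force_n"].to_numpy())])
    if method == "preyield":
        n_lin = int(np.argmax(h["plastic"].to_numpy())) \
            if h["plastic"].any() else len(h)
        if n_lin == 0:
            warnings.warn("yielding in first increment: secant stiffness")
            return float(f[1] / dl[1])
        sel = slice(0, n_lin + 1)
    elif method == "fraction":
        keep = f <= force_fraction * f[-1] + 1e-12
        sel = keep
        if keep.sum() < 2:
            sel = slice(0, 2)
    else:
        raise ValueError("method must be 'preyield' or 'fraction'")
    x, y = dl[sel], f[sel]
    slope = float(np.polyfit(x, y, 1)[0])
    return slope


def mechanical_summary(result: FEResult, model: FEModel,
                       stiffness_method: str = "preyield") -> MechanicalSummary:
    """Apply the CSA and Hm normalisations to F_U and K."""
    if model.csa_mm2 <= 0:
        raise ValueError("CSA must be positive")
    f_u = ultimate_force(result)
    k = apparent_stiffness(result, method=stiffness_method)
    return MechanicalSummary(
        f_u_n=f_u,
        sigma_u_mpa=f_u / model.csa_mm2,
        k_n_mm=k,
        e_app_mpa=k * model.hm_mm / model.csa_mm2,
        hm_mm=model.hm_mm,
        csa_mm2=model.csa_mm2,
        delta_l_mm=result.final_delta_l_mm,
    )


def _mid_band_nodes(model: FEModel) -> np.ndarray:
    """Nodes with z in the central 50% of the endplate-to-endplate span."""
    z = model.mesh.nodes[:, 2]
    z_cr = z[model.cranial_nodes].mean()
    z_ca = z[model.caudal_nodes].mean()
    lo, hi = sorted((z_ca, z_cr))
    span = hi - lo
    band = (z >= lo + 0.25 * span) & (z <= hi - 0.25 * span)
    if not band.any():
        raise ValueError("empty mid-height band")
    return np.flatnonzero(band)


def strain_histogram(result: FEResult, model: FEModel, n_bins: int = 40,
                     strain_range: tuple[float, float] = (-0.04, 0.04)
                     ) -> pd.DataFrame:
    """Normalised frequency tables of nodal principal strains.

    Uses the nodes across the middle 50% of the body height; signed strains
    binned on fixed edges; frequencies normalised to sum to 1 over the
    in-range nodes (out-of-range values are dropped).
    """
    e1, e3 = nodal_principal_strains(result, model)
    sel = _mid_band_nodes(model)
    edges = np.linspace(strain_range[0], strain_range[1], n_bins + 1)
    rows = {"bin_lo": edges[:-1], "bin_hi": edges[1:]}
    for name, vals in (("eps_p1", e1[sel]), ("eps_p3", e3[sel])):
        counts, _ = np.histogram(vals, bins=edges)
        total = counts.sum()
        rows[f"freq_{name}"] = counts / total if total else counts * 0.0
    return pd.DataFrame(rows)


def plot_strain_frequencies(hist: pd.DataFrame, path) -> None:
    """Frequency plot of the mid-height nodal principal strains."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (hist["bin_lo"] + hist["bin_hi"])
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.step(centers, hist["freq_eps_p1"], where="mid",
            label=r"$\varepsilon_{p1}$")
    ax.step(centers, hist["freq_eps_p3"], where="mid",
            label=r"$\varepsilon_{p3}$")
    ax.set_xlabel("principal strain")
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class ProbeSet:
    centers: np.ndarray        # (27, 3), anatomical mm
    radius_mm: float
    inside_body: np.ndarray    # bool flags: probe fully sampled

    def __post_init__(self):
        if len(self.centers) != 27:
            raise ValueError("probe lattice must have exactly 27 spheres")
        if self.radius_mm <= 0:
            raise ValueError("probe radius must be positive")


def probe_grid(model: FEModel, radius_mm: float = 2.0,
               offset_fraction: float = 0.25) -> ProbeSet:
    """3x3x3 probe lattice, symmetric about the body centre.

    Offsets are ``offset_fraction`` of the body half-extent per axis, in
    the anatomical frame, so placement is consistent relative to each
    vertebra's own coordinate system.  Probes protruding outside the
    meshed body are flagged (never silently dropped).
    """
    nodes = model.mesh.nodes
    lo, hi = nodes.min(axis=0), nodes.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    offsets = np.array([-1.0, 0.0, 1.0]) * offset_fraction
    pts = np.array([center + half * np.array([ox, oy, oz])
                    for ox in offsets for oy in offsets for oz in offsets])
    # flag probes whose sphere is not fully inside the node bounding box
    inside = np.all((pts - radius_mm >= lo - 1e-9)
                    & (pts + radius_mm <= hi + 1e-9), axis=1)
    return ProbeSet(centers=pts, radius_mm=radius_mm, inside_body=inside)


def probe_mean_strains(result: FEResult, model: FEModel,
                       probes: ProbeSet) -> pd.DataFrame:
    """Volume-weighted mean principal strains inside each probe sphere.

    Averages nodal strains weighted by the nodal volume share of adjacent
    elements.  The lesion flag is set when any element centroid within the
    sphere lies inside a (synthetically known) lesion.
    """
    e1, e3 = nodal_principal_strains(result, model)
    mesh = model.mesh
    vol = mesh.signed_volumes()
    node_w = np.zeros(mesh.n_nodes)
    for a in range(10):
        np.add.at(node_w, mesh.elems[:, a], vol / 10.0)
    centroids = mesh.nodes[mesh.elems[:, :4]].mean(axis=1)

    lesions = model.meta.get("lesion_centers")
    lesion_radii = model.meta.get("lesion_radii")
    in_lesion = np.zeros(len(centroids), dtype=bool)
    if lesions is not None:
        for li, c in enumerate(np.atleast_2d(lesions)):
            r = (np.asarray(lesion_radii[li])
                 if lesion_radii is not None else np.full(3, 5.0))
            d = (centroids - c) / r
            in_lesion |= (d ** 2).sum(axis=1) <= 1.0

    rows = []
    for pid, (c, ok) in enumerate(zip(probes.centers, probes.inside_body)):
        d_nodes = np.linalg.norm(mesh.nodes - c, axis=1)
        sel = d_nodes <= probes.radius_mm
        if not sel.any():
            raise ValueError(f"probe {pid} samples no nodes")
        w = node_w[sel]
        d_cent = np.linalg.norm(centroids - c, axis=1)
        les = bool(in_lesion[d_cent <= probes.radius_mm].any())
        rows.append({
            "probe": pid, "x": c[0], "y": c[1], "z": c[2],
            "mean_eps_p1": float(np.average(e1[sel], weights=w)),
            "mean_eps_p3": float(np.average(e3[sel], weights=w)),
            "lesion": les, "inside_body": bool(ok),
        })
    return pd.DataFrame(rows).set_index("probe")
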