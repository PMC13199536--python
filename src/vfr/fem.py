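"""Quasi-static small-strain FE solver for heterogeneous elasto-plasticity.

Quadratic tetrahedra (TET10) with 4-point Gauss quadrature, von Mises (J2)
plasticity with linear isotropic hardening integrated by radial return, and
displacement-controlled uniaxial compression solved by Newton-Raphson with
algorithmically consistent tangents and automatic increment bisection.

Because the structured meshes have midside nodes exactly at edge midpoints
the geometry map is affine, so barycentric gradients — and hence the strain
operator — are constant per element and evaluated once.

Voigt convention: [xx, yy, zz, xy, yz, zx] with engineering shear strains.
The hardening modulus is chosen so the uniaxial post-yield tangent equals
the prescribed post-yield modulus: H = E * E_py / (E - E_py).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import TET10_EDGES, Tet10Mesh
from .model import FEModel

__all__ = [
    "BCConfig",
    "PlasticState",
    "FEResult",
    "j2_update",
    "solve_compression",
    "nodal_principal_strains",
]

# 4-point Gauss rule for tetrahedra (degree 2), barycentric coordinates
_GA = 0.5854101966249685
_GB = 0.13819660112501051
GAUSS_BARY = np.array([
    [_GA, _GB, _GB, _GB],
    [_GB, _GA, _GB, _GB],
    [_GB, _GB, _GA, _GB],
    [_GB, _GB, _GB, _GA],
])
GAUSS_W = np.full(4, 0.25)

#: barycentric coordinates of the 10 local nodes (C3D10 order)
NODE_BARY = np.vstack([
    np.eye(4),
    [[0.5, 0.5, 0.0, 0.0], [0.0, 0.5, 0.5, 0.0], [0.5, 0.0, 0.5, 0.0],
     [0.5, 0.0, 0.0, 0.5], [0.0, 0.5, 0.0, 0.5], [0.0, 0.0, 0.5, 0.5]],
])


def shape_weight_matrix(bary: np.ndarray) -> np.ndarray:
    """dN/dL weights (n_pts, 10, 4) of the TET10 shape functions."""
    bary = np.atleast_2d(bary)
    n = bary.shape[0]
    W = np.zeros((n, 10, 4))
    for c in range(4):
        W[:, c, c] = 4.0 * bary[:, c] - 1.0
    for m, (i, j) in enumerate(TET10_EDGES):
        W[:, 4 + m, i] = 4.0 * bary[:, j]
        W[:, 4 + m, j] = 4.0 * bary[:, i]
    return W


def barycentric_gradients(mesh: Tet10Mesh) -> np.ndarray:
    """grad L_c wrt x per element, shape (ne, 4, 3); constant (affine map)."""
    x = mesh.corner_coords()
    J = x[:, 1:] - x[:, :1]                      # rows are edge vectors
    Jinv = np.linalg.inv(J)                      # dL_{1:3}/dx = J^{-T}
    g = np.transpose(Jinv, (0, 2, 1))            # (ne, 3, 3) rows = grad L_i
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1)


def shape_gradients(mesh: Tet10Mesh, bary: np.ndarray) -> np.ndarray:
    """grad N_a wrt x at the given barycentric points: (n_pts, ne, 10, 3)."""
    gl = barycentric_gradients(mesh)
    W = shape_weight_matrix(bary)
    return np.einsum("pac,ecx->peax", W, gl)


def strain_at_points(grad: np.ndarray, u: np.ndarray,
                     elems: np.ndarray) -> np.ndarray:
    """Small strain (Voigt, engineering shear) from nodal displacements.

    ``grad`` is (n_pts, ne, 10, 3); returns (n_pts, ne, 6).
    """
    ue = u.reshape(-1, 3)[elems]                 # (ne, 10, 3)
    g = np.einsum("peax,eay->pexy", grad, ue)    # displacement gradient
    eps = np.empty(g.shape[:2] + (6,))
    eps[..., 0] = g[..., 0, 0]
    eps[..., 1] = g[..., 1, 1]
    eps[..., 2] = g[..., 2, 2]
    eps[..., 3] = g[..., 0, 1] + g[..., 1, 0]
    eps[..., 4] = g[..., 1, 2] + g[..., 2, 1]
    eps[..., 5] = g[..., 2, 0] + g[..., 0, 2]
    return eps


def b_matrices(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (n_pts, ne, 6, 30) from shape gradients."""
    npts, ne = grad.shape[:2]
    B = np.zeros((npts, ne, 6, 30))
    gx, gy, gz = grad[..., 0], grad[..., 1], grad[..., 2]
    for a in range(10):
        B[..., 0, 3 * a + 0] = gx[..., a]
        B[..., 1, 3 * a + 1] = gy[..., a]
        B[..., 2, 3 * a + 2] = gz[..., a]
        B[..., 3, 3 * a + 0] = gy[..., a]
        B[..., 3, 3 * a + 1] = gx[..., a]
        B[..., 4, 3 * a + 1] = gz[..., a]
        B[..., 4, 3 * a + 2] = gy[..., a]
        B[..., 5, 3 * a + 0] = gz[..., a]
        B[..., 5, 3 * a + 2] = gx[..., a]
    return B


# ---------------------------------------------------------------------------
# J2 radial return with linear isotropic hardening
# ---------------------------------------------------------------------------

_IDEV = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5]) \
    - np.pad(np.full((3, 3), 1.0 / 3.0), ((0, 3), (0, 3)))
_ONE = np.zeros((6, 6))
_ONE[:3, :3] = 1.0


def hardening_modulus(E, E_py):
    """Plastic modulus H giving a uniaxial post-yield tangent of E_py."""
    E = np.asarray(E, float)
    E_py = np.asarray(E_py, float)
    if np.any(E_py >= E):
        raise ValueError("post-yield modulus must be below E")
    return E * E_py / (E - E_py)


def _radial_return(eps, eps_p, alpha, lam, mu, sy0, H):
    """Vectorised stress update.  Leading dims of all arrays must broadcast.

    Returns (sigma, eps_p_new, alpha_new, dgamma, q_trial).
    """
    eps_e = eps - eps_p
    tr = eps_e[..., :3].sum(axis=-1)
    sig = np.empty_like(eps)
    sig[..., :3] = lam[..., None] * tr[..., None] + 2 * mu[..., None] * eps_e[..., :3]
    sig[..., 3:] = mu[..., None] * eps_e[..., 3:]
    mean = sig[..., :3].sum(axis=-1) / 3.0
    s = sig.copy()
    s[..., :3] -= mean[..., None]
    q = np.sqrt(1.5 * ((s[..., :3] ** 2).sum(-1) + 2 * (s[..., 3:] ** 2).sum(-1)))
    f = q - (sy0 + H * alpha)
    plastic = f > 1e-12 * np.maximum(sy0, 1.0)
    dgamma = np.where(plastic, f / (3 * mu + H), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fac = np.where(plastic, 3 * mu * dgamma / np.maximum(q, 1e-300), 0.0)
    sig_new = sig - fac[..., None] * s
    deps_p = np.empty_like(s)
    scale = np.where(plastic, dgamma / np.maximum(q, 1e-300), 0.0)
    deps_p[..., :3] = 1.5 * scale[..., None] * s[..., :3]
    deps_p[..., 3:] = 3.0 * scale[..., None] * s[..., 3:]
    return sig_new, eps_p + deps_p, alpha + dgamma, dgamma, q, s


def _consistent_tangent(lam, mu, H, dgamma, q_trial, s_trial):
    """Algorithmic tangent per point, (..., 6, 6)."""
    shape = dgamma.shape
    Kb = lam + 2 * mu / 3.0
    C = (Kb[..., None, None] * _ONE
         + 2 * mu[..., None, None] * _IDEV)
    plastic = dgamma > 0
    if np.any(plastic):
        q = np.maximum(q_trial, 1e-300)
        beta_red = 3 * mu * dgamma / q                 # 1 - beta
        gbar = 3 * mu / (3 * mu + H)
        gstar = gbar - beta_red
        snorm = np.sqrt((s_trial[..., :3] ** 2).sum(-1)
                        + 2 * (s_trial[..., 3:] ** 2).sum(-1))
        n = s_trial / np.maximum(snorm, 1e-300)[..., None]
        nn = n[..., :, None] * n[..., None, :]
        corr = (2 * mu * beta_red)[..., None, None] * _IDEV \
            + (2 * mu * gstar)[..., None, None] * nn
        C = C - np.where(plastic[..., None, None], corr, 0.0)
    return C.reshape(shape + (6, 6))


@dataclass
class PlasticState:
    """Per-Gauss-point internal variables."""

    eps_p: np.ndarray       # plastic strain, Voigt engineering
    alpha: np.ndarray       # accumulated equivalent plastic strain

    @classmethod
    def zeros(cls, shape) -> "PlasticState":
        return cls(np.zeros(shape + (6,)), np.zeros(shape))

    def copy(self) -> "PlasticState":
        return PlasticState(self.eps_p.copy(), self.alpha.copy())

    def yield_stress(self, sy0, H):
        return sy0 + H * self.alpha


def j2_update(strain, state: PlasticState, E: float, nu: float,
              sigma_y: float, E_py: float):
    """Single-point radial-return update.

    Parameters: total strain (Voigt engineering), the committed plastic
    state, and the material (E, nu, initial yield stress, post-yield
    uniaxial tangent).  Returns ``(stress, consistent_tangent, new_state)``.
    """
    if E_py >= E:
        raise ValueError("post-yield modulus must be below E")
    H = float(hardening_modulus(E, E_py))
    lam = np.atleast_1d(E * nu / ((1 + nu) * (1 - 2 * nu)))
    mu = np.atleast_1d(E / (2 * (1 + nu)))
    eps = np.asarray(strain, float).reshape(1, 6)
    sig, eps_p, alpha, dg, q, s = _radial_return(
        eps, state.eps_p.reshape(1, 6), np.atleast_1d(state.alpha),
        lam, mu, np.atleast_1d(sigma_y), np.atleast_1d(H))
    C = _consistent_tangent(lam, mu, np.atleast_1d(H), dg, q, s)
    return sig[0], C[0], PlasticState(eps_p[0], alpha[0])


# ---------------------------------------------------------------------------
# Displacement-controlled compression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BCConfig:
    """Endplate boundary conditions.

    ``caudal='fixed'`` clamps the caudal endplate in all directions (the
    default protocol); ``'slide'`` fixes only the axial DOF and pins two
    nodes against rigid-body motion (frictionless platen).  ``cranial``
    is ``'slide'`` (axial displacement prescribed, transverse free) or
    ``'tied'`` (transverse clamped too — fully bonded platen).
    """

    caudal: str = "fixed"
    cranial: str = "slide"

    def __post_init__(self):
        if self.caudal not in ("fixed", "slide"):
            raise ValueError("caudal must be 'fixed' or 'slide'")
        if self.cranial not in ("slide", "tied"):
            raise ValueError("cranial must be 'slide' or 'tied'")


@dataclass
class FEResult:
    """Converged load history and final fields."""

    history: pd.DataFrame          # delta_l_mm, force_n, plastic, n_iter
    u: np.ndarray                  # final nodal displacements (n, 3), mm
    state: PlasticState            # final per-Gauss-point plastic state
    reaction_caudal_n: float       # axial reaction on the caudal set
    apparent_strain: float
    hm_mm: float
    dissipation_history: list[float] = field(default_factory=list)

    @property
    def final_force_n(self) -> float:
        return float(self.history["force_n"].iloc[-1])

    @property
    def final_delta_l_mm(self) -> float:
        return float(self.history["delta_l_mm"].iloc[-1])


def _dof_sets(model: FEModel, bc: BCConfig, n_nodes: int):
    """Return (fixed_zero_dofs, prescribed_z_dofs)."""
    cr, ca = model.cranial_nodes, model.caudal_nodes
    fixed = []
    if bc.caudal == "fixed":
        fixed.extend((3 * ca + c).tolist() for c in range(3))
        fixed = [d for sub in fixed for d in sub]
    else:
        fixed = (3 * ca + 2).tolist()
        nodes = model.mesh.nodes
        centroid = nodes[ca].mean(axis=0)
        p0 = ca[np.argmin(np.linalg.norm(nodes[ca, :2] - centroid[:2], axis=1))]
        p1 = ca[np.argmax(np.abs(nodes[ca, 0] - nodes[p0, 0]))]
        fixed.extend([3 * p0, 3 * p0 + 1, 3 * p1 + 1])
    if bc.cranial == "tied":
        fixed.extend((3 * cr).tolist())
        fixed.extend((3 * cr + 1).tolist())
    prescribed = 3 * cr + 2
    return np.unique(np.asarray(fixed, int)), np.asarray(prescribed, int)


class _System:
    """Assembled quantities for one model (geometry fixed, material state varies)."""

    def __init__(self, model: FEModel):
        mesh = model.mesh
        self.mesh = mesh
        self.model = model
        self.grad = shape_gradients(mesh, GAUSS_BARY)      # (4, ne, 10, 3)
        self.B = b_matrices(self.grad)                      # (4, ne, 6, 30)
        self.vol = mesh.signed_volumes()                    # (ne,)
        self.wvol = GAUSS_W[:, None] * self.vol[None, :]    # (4, ne)
        E, nu = model.materials.E, model.nu
        self.lam = np.broadcast_to(E * nu / ((1 + nu) * (1 - 2 * nu)),
                                   (4, len(E)))
        self.mu = np.broadcast_to(E / (2 * (1 + nu)), (4, len(E)))
        self.sy0 = np.broadcast_to(model.materials.sigma_y, (4, len(E)))
        self.H = np.broadcast_to(hardening_modulus(E, model.materials.E_py),
                                 (4, len(E)))
        edof = (3 * mesh.elems[:, :, None]
                + np.arange(3)[None, None, :]).reshape(-1, 30)
        self.edof = edof
        self.rows = np.repeat(edof, 30, axis=1).ravel()
        self.cols = np.tile(edof, (1, 30)).ravel()
        self.ndof = 3 * mesh.n_nodes

    def stress(self, u, state: PlasticState):
        eps = strain_at_points(self.grad, u, self.mesh.elems)
        return _radial_return(eps, state.eps_p, state.alpha,
                              self.lam, self.mu, self.sy0, self.H)

    def internal_force(self, sig) -> np.ndarray:
        fe = np.einsum("ge,geai,gea->ei", self.wvol, self.B, sig)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edof.ravel(), fe.ravel())
        return f

    def tangent_matrix(self, dgamma, q, s) -> sp.csc_matrix:
        C = _consistent_tangent(self.lam, self.mu, self.H, dgamma, q, s)
        Ke = np.einsum("ge,geai,geab,gebj->eij", self.wvol, self.B, C, self.B,
                       optimize=True)
        K = sp.coo_matrix((Ke.ravel(), (self.rows, self.cols)),
                          shape=(self.ndof, self.ndof))
        return K.tocsc()


def solve_compression(model: FEModel, bc: BCConfig | None = None,
                      apparent_strain: float = 0.019,
                      n_increments: int = 10,
                      tol: float = 1e-6,
                      max_iter: int = 25,
                      max_cutbacks: int = 6,
                      verbose: bool = False) -> FEResult:
    """Compress the model to ``apparent_strain * Hm`` axial displacement.

    The cranial endplate is displaced axially in equal increments (with
    automatic bisection on non-convergence); the caudal endplate is fixed
    per ``bc``.  Compression is reported with positive sign.

    Raises
    ------
    RuntimeError
        On non-convergence after all cutbacks, with a diagnostic message.
    """
    bc = bc or BCConfig()
    sys_ = _System(model)
    ndof = sys_.ndof
    fixed, prescribed = _dof_sets(model, bc, model.mesh.n_nodes)
    constrained = np.union1d(fixed, prescribed)
    free = np.setdiff1d(np.arange(ndof), constrained)

    total_dl = apparent_strain * model.hm_mm
    u = np.zeros(ndof)
    state = PlasticState.zeros(sys_.grad.shape[:2])
    committed_dl = 0.0
    step = total_dl / n_increments
    history = []
    dissipation = []
    factor = None
    cutbacks = 0

    while committed_dl < total_dl - 1e-12 * total_dl:
        target = min(committed_dl + step, total_dl)
        u_trial = u.copy()
        u_trial[prescribed] = -target
        trial_state = state
        converged = False
        refactor = factor is None
        prev_res = np.inf
        for it in range(max_iter + 1):
            sig, eps_p_new, alpha_new, dgamma, q, s = sys_.stress(
                u_trial, state)
            f_int = sys_.internal_force(sig)
            r_free = f_int[free]
            ref = max(float(np.linalg.norm(f_int)), 1e-8)
            res = float(np.linalg.norm(r_free))
            if verbose:
                print(f"  dl={target:.5f} it={it} |r|={res:.3e} ref={ref:.3e}")
            if res <= tol * ref or res < 1e-12:
                converged = True
                trial_state = PlasticState(eps_p_new, alpha_new)
                any_plastic = bool((dgamma > 0).any())
                break
            if it == max_iter:
                break
            # lazy refactoring: a factorisation is reused while it keeps
            # producing good descent; slow progress (or an engaged line
            # search) triggers reassembly of the consistent tangent
            if refactor or res > 0.5 * prev_res:
                K = sys_.tangent_matrix(dgamma, q, s)
                factor = spla.splu(K[free][:, free].tocsc())
                refactor = False
            prev_res = res
            du = factor.solve(-r_free)
            # backtracking line search: plastic-set changes between
            # iterations can make the full Newton step non-descending
            scale = 1.0
            for _ in range(6):
                u_cand = u_trial.copy()
                u_cand[free] += scale * du
                sig_c = sys_.stress(u_cand, state)[0]
                res_c = float(np.linalg.norm(sys_.internal_force(sig_c)[free]))
                if res_c < res * (1.0 - 1e-4 * scale) or scale < 1e-2:
                    break
                scale *= 0.5
            if scale < 1.0:
                refactor = True
            u_trial[free] += scale * du
        if not converged:
            cutbacks += 1
            if cutbacks > max_cutbacks:
                raise RuntimeError(
                    f"compression solve failed at delta_l={target:.4f} mm "
                    f"(residual {res:.3e}, ref {ref:.3e}) after "
                    f"{max_cutbacks} bisections")
            step *= 0.5
            continue
        # commit increment
        dwork = float(np.einsum(
            "ge,gea,gea->", sys_.wvol, sig,
            trial_state.eps_p - state.eps_p))
        dissipation.append(dwork)
        u = u_trial
        state = trial_state
        committed_dl = target
        reaction = float(f_int[prescribed].sum())
        history.append({
            "delta_l_mm": committed_dl,
            "force_n": -reaction,
            "plastic": any_plastic,
            "n_iter": it,
        })

    caudal_dofs = 3 * model.caudal_nodes + 2
    hist = pd.DataFrame(history)
    return FEResult(history=hist, u=u.reshape(-1, 3), state=state,
                    reaction_caudal_n=float(f_int[caudal_dofs].sum()),
                    apparent_strain=apparent_strain, hm_mm=model.hm_mm,
                    dissipation_history=dissipation)


def nodal_principal_strains(result: FEResult, model: FEModel):
    """Maximum and minimum principal strains at every node.

    Element strains are evaluated at the 10 local node positions from the
    shape-function gradients, volume-weight-averaged over the elements
    adjacent to each node, and eigen-decomposed.  Returns ``(eps_p1,
    eps_p3)`` with ``eps_p1 >= eps_p3`` everywhere.
    """
    mesh = model.mesh
    grad = shape_gradients(mesh, NODE_BARY)           # (10, ne, 10, 3)
    eps = strain_at_points(grad, result.u.ravel(), mesh.elems)   # (10, ne, 6)
    vol = mesh.signed_volumes()
    acc = np.zeros((mesh.n_nodes, 6))
    wsum = np.zeros(mesh.n_nodes)
    for a in range(10):
        np.add.at(acc, mesh.elems[:, a], vol[:, None] * eps[a])
        np.add.at(wsum, mesh.elems[:, a], vol)
    avg = acc / wsum[:, None]
    T = np.empty((mesh.n_nodes, 3, 3))
    T[:, 0, 0] = avg[:, 0]
    T[:, 1, 1] = avg[:, 1]
    T[:, 2, 2] = avg[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = 0.5 * avg[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = 0.5 * avg[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = 0.5 * avg[:, 5]
    w = np.linalg.eigvalsh(T)
    return w[:, 2], w[:, 0]
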