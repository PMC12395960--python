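"""Linear-elastic and elastic-perfectly-plastic voxel FE solvers.

Small-strain compression of a voxel HEX8 mesh under prescribed axial
displacement.  All elements share one cubic geometry, so the element
stiffness is a single unit-modulus template scaled by each element's
modulus.  Units: coordinates mm, moduli and stresses MPa, forces reported
in kN (1 MPa * mm^2 = 1 N); compression is positive.

The nonlinear solver uses incremental displacement control with von Mises
elastic-perfectly-plastic radial return.  Equilibrium iterations start from
the factorized elastic stiffness (modified Newton) and switch to the
algorithmically consistent tangent when convergence stalls; convergence is
monitored with the maximum relative displacement norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hex8 import gauss_b_matrices, hex8_stiffness_template, isotropic_d, von_mises
from .materials import MaterialTable
from .mesh import SurfaceSets, VoxelMesh

__all__ = [
    "BoundarySpec",
    "SolveResult",
    "FDCurve",
    "compression_bc",
    "solve_linear",
    "solve_elastoplastic",
    "reaction_force",
    "stiffness_from_curve",
]

_VOIGT_M = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
# deviatoric projector acting on engineering-shear strain
_I_DEV = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5]) - np.outer(_VOIGT_M, _VOIGT_M) / 3.0


@dataclass
class BoundarySpec:
    """Uniaxial-compression boundary conditions.

    ``fixed_nodes`` are clamped in all three directions; ``driven_nodes``
    get a prescribed axial (z) displacement of ``-applied_displacement``
    (compression), with lateral motion left free.  ``extra`` holds
    additional single-DOF constraints ``(node, axis, value)`` for
    benchmark load cases (rollers, symmetry planes).
    """

    fixed_nodes: np.ndarray
    driven_nodes: np.ndarray
    applied_displacement: float          # mm, magnitude
    loaded_height: float                 # mm, height over which strain is defined
    extra: list = field(default_factory=list)

    def __post_init__(self):
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.driven_nodes = np.asarray(self.driven_nodes, dtype=np.int64)
        if len(self.fixed_nodes) == 0 or len(self.driven_nodes) == 0:
            raise ValueError("fixed and driven node sets must be nonempty")
        if np.intersect1d(self.fixed_nodes, self.driven_nodes).size:
            raise ValueError("fixed and driven node sets must be disjoint")

    @property
    def apparent_strain(self) -> float:
        return self.applied_displacement / self.loaded_height

    def dirichlet(self, scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(dof indices, prescribed values) with driven values scaled."""
        dofs = [np.repeat(self.fixed_nodes * 3, 3) + np.tile([0, 1, 2], len(self.fixed_nodes))]
        vals = [np.zeros(3 * len(self.fixed_nodes))]
        dofs.append(self.driven_nodes * 3 + 2)
        vals.append(np.full(len(self.driven_nodes), -self.applied_displacement * scale))
        for node, axis, value in self.extra:
            dofs.append(np.array([node * 3 + axis]))
            vals.append(np.array([value * scale]))
        d = np.concatenate(dofs)
        v = np.concatenate(vals)
        d, idx = np.unique(d, return_index=True)
        return d, v[idx]


def compression_bc(mesh: VoxelMesh, surfaces: SurfaceSets,
                   apparent_strain: float) -> BoundarySpec:
    """Standard vertebral load case: inferior surface fully fixed, superior
    surface driven axially to ``apparent_strain`` of the loaded mesh height."""
    height = mesh.z_extent_mm(include_pmma=True)
    return BoundarySpec(
        fixed_nodes=surfaces.inferior_nodes,
        driven_nodes=surfaces.superior_nodes,
        applied_displacement=apparent_strain * height,
        loaded_height=height,
    )


@dataclass
class SolveResult:
    nodal_displacement: np.ndarray       # (n_nodes, 3) mm
    reaction_force: float                # kN, compression positive
    element_vm_stress: np.ndarray        # MPa
    element_vm_strain: np.ndarray        # unitless equivalent strain
    yielded_flags: np.ndarray            # bool per element
    iterations: int
    converged: bool
    internal_force: np.ndarray = None    # (3*n_nodes,) N, for reaction queries


@dataclass
class FDCurve:
    """Apparent-strain vs. reaction-force samples from incremental solves."""

    apparent_strain: np.ndarray
    force: np.ndarray                    # kN
    loaded_height: float = np.nan        # mm
    converged: bool = True

    def __post_init__(self):
        self.apparent_strain = np.asarray(self.apparent_strain, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.apparent_strain) != len(self.force):
            raise ValueError("strain and force arrays differ in length")
        if len(self.apparent_strain) and self.apparent_strain[0] != 0:
            raise ValueError("curve must start at zero strain")
        if np.any(np.diff(self.apparent_strain) <= 0):
            raise ValueError("strains must be strictly increasing")


class _Model:
    """Precomputed kinematics shared by the linear and nonlinear solvers."""

    def __init__(self, mesh: VoxelMesh, materials: MaterialTable):
        self.mesh = mesh
        self.nu = materials.nu
        self.b_all, self.weight = gauss_b_matrices(mesh.voxel_size)
        self.k_template = hex8_stiffness_template(mesh.voxel_size, self.nu)
        self.d_unit = isotropic_d(1.0, self.nu)
        self.E = materials.element_modulus()
        self.sigma_y = materials.element_yield()
        self.mu = self.E / (2 * (1 + self.nu))
        self.kappa = self.E / (3 * (1 - 2 * self.nu))
        en = mesh.element_nodes
        self.edofs = (en[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(-1, 24)
        self.ndof = 3 * mesh.n_nodes
        self._rows = np.repeat(self.edofs, 24, axis=1).ravel()
        self._cols = np.tile(self.edofs, (1, 24)).ravel()

    def assemble_elastic(self) -> sp.csr_matrix:
        data = (self.E[:, None, None] * self.k_template[None]).ravel()
        k = sp.coo_matrix((data, (self._rows, self._cols)), shape=(self.ndof, self.ndof))
        return k.tocsr()

    def strains(self, u: np.ndarray) -> np.ndarray:
        """Gauss-point strains (n_elem, 8, 6) from the flat displacement vector."""
        ue = u[self.edofs]                              # (n, 24)
        return np.einsum("gij,nj->ngi", self.b_all, ue)

    def radial_return(self, eps: np.ndarray, eps_p: np.ndarray):
        """Stress update from total strain and committed plastic strain.

        Returns (stress (n,8,6), new plastic strain, yielded (n,8)).
        """
        eps_e = eps - eps_p
        sigma_tr = self.E[:, None, None] * np.einsum("ij,ngj->ngi", self.d_unit, eps_e)
        q_tr = von_mises(sigma_tr)
        sy = self.sigma_y[:, None]
        yielded = q_tr > sy
        if not yielded.any():
            return sigma_tr, eps_p, yielded

        p = sigma_tr[..., :3].mean(axis=-1)
        s_tr = sigma_tr.copy()
        s_tr[..., :3] -= p[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(yielded, sy / q_tr, 1.0)
        sigma = s_tr * scale[..., None]
        sigma[..., :3] += p[..., None]

        # plastic-strain increment consistent with the returned stress:
        # s = s_tr - 2 mu * deps_p  (engineering shear doubled in Voigt)
        d_ep = (1.0 - scale[..., None]) * s_tr / (2 * self.mu[:, None, None])
        d_ep[..., 3:] *= 2.0
        d_ep[~yielded] = 0.0
        return sigma, eps_p + d_ep, yielded

    def internal_force(self, sigma: np.ndarray) -> np.ndarray:
        fe = self.weight * np.einsum("gij,ngi->nj", self.b_all, sigma)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        return f

    def consistent_tangent(self, eps: np.ndarray, eps_p: np.ndarray) -> sp.csr_matrix:
        """Assemble the algorithmic tangent stiffness from the current state.

        For perfect plasticity the radial-return tangent is
        ``K m m^T + 2 mu theta (I_dev - n n^T)``; a small multiple of the
        elastic shear term stabilizes the rank deficiency along the flow
        direction.
        """
        eps_e = eps - eps_p
        sigma_tr = self.E[:, None, None] * np.einsum("ij,ngj->ngi", self.d_unit, eps_e)
        q_tr = von_mises(sigma_tr)
        sy = self.sigma_y[:, None]
        yielded = q_tr > sy

        n_el = self.mesh.n_elements
        d_gp = np.broadcast_to(
            (self.E[:, None, None, None] * self.d_unit[None, None]), (n_el, 8, 6, 6)
        ).copy()
        if yielded.any():
            p = sigma_tr[..., :3].mean(axis=-1)
            s_tr = sigma_tr.copy()
            s_tr[..., :3] -= p[..., None]
            norm2 = (s_tr[..., :3] ** 2).sum(-1) + 2 * (s_tr[..., 3:] ** 2).sum(-1)
            norm = np.sqrt(np.maximum(norm2, 1e-300))
            theta = np.sqrt(2.0 / 3.0) * sy / norm          # = sy/q_tr
            n_hat = s_tr / norm[..., None]
            nn = np.einsum("ngi,ngj->ngij", n_hat, n_hat)
            mm = np.outer(_VOIGT_M, _VOIGT_M)
            mu = self.mu[:, None, None, None]
            kap = self.kappa[:, None, None, None]
            th = theta[..., None, None]
            d_pl = kap * mm[None, None] + 2 * mu * (
                th * (_I_DEV[None, None] - nn) + 1e-8 * _I_DEV[None, None]
            )
            d_gp = np.where(yielded[..., None, None], d_pl, d_gp)

        ke = self.weight * np.einsum(
            "gai,ngaj->nij", self.b_all, np.einsum("ngab,gbj->ngaj", d_gp, self.b_all)
        )
        ke = 0.5 * (ke + ke.transpose(0, 2, 1))
        k = sp.coo_matrix((ke.ravel(), (self._rows, self._cols)), shape=(self.ndof, self.ndof))
        return k.tocsr()


def _split(k: sp.csr_matrix, dofs: np.ndarray, vals: np.ndarray, ndof: int):
    free = np.setdiff1d(np.arange(ndof), dofs)
    return free, k[free][:, free].tocsr(), k[free][:, dofs] @ vals


def solve_linear(mesh: VoxelMesh, materials: MaterialTable, bc: BoundarySpec,
                 tol: float = 1e-6, max_iter: int = 30000,
                 method: str = "cg") -> SolveResult:
    """One linear-elastic solve under the given boundary conditions.

    ``method='cg'`` uses Jacobi-preconditioned conjugate gradients with a
    relative-residual tolerance; ``method='direct'`` uses a sparse direct
    factorization (useful as an independent cross-check on small meshes).
    Non-convergence is reported on the result, not raised.
    """
    model = _Model(mesh, materials)
    k = model.assemble_elastic()
    dofs, vals = bc.dirichlet()
    free, kff, load = _split(k, dofs, vals, model.ndof)

    u = np.zeros(model.ndof)
    u[dofs] = vals
    converged = True
    iters = 0
    if len(free):
        rhs = -load
        if method == "direct":
            u[free] = spla.spsolve(kff.tocsc(), rhs)
        else:
            diag = kff.diagonal()
            m_inv = spla.LinearOperator(kff.shape, lambda x: x / diag)
            counter = _IterCounter()
            uf, info = spla.cg(kff, rhs, rtol=tol, atol=0.0, maxiter=max_iter,
                               M=m_inv, callback=counter)
            u[free] = uf
            converged = info == 0
            iters = counter.n

    f_int = k @ u
    eps = model.strains(u)
    sigma = model.E[:, None, None] * np.einsum("ij,ngj->ngi", model.d_unit, eps)
    vm = von_mises(sigma).mean(axis=1)
    reaction = -f_int[bc.driven_nodes * 3 + 2].sum() / 1000.0
    return SolveResult(
        nodal_displacement=u.reshape(-1, 3),
        reaction_force=float(reaction),
        element_vm_stress=vm,
        element_vm_strain=vm / model.E,
        yielded_flags=np.zeros(mesh.n_elements, dtype=bool),
        iterations=iters,
        converged=bool(converged),
        internal_force=f_int,
    )


class _IterCounter:
    def __init__(self):
        self.n = 0

    def __call__(self, _xk):
        self.n += 1


def solve_elastoplastic(mesh: VoxelMesh, materials: MaterialTable, bc: BoundarySpec,
                        n_increments: int = 20, plastic_iter_max: int = 10000,
                        tol: float = 1e-6,
                        reform_interval: int = 100) -> tuple[FDCurve, SolveResult]:
    """Incremental elastoplastic solve to the target apparent strain.

    Displacement is applied in ``n_increments`` equal steps.  Each increment
    iterates to equilibrium with the radial-return stress update, starting
    from the factorized elastic stiffness and reassembling the consistent
    tangent every ``reform_interval`` stalled iterations.  A non-converged
    increment terminates the curve early and flags the result.
    """
    if n_increments < 1:
        raise ValueError("need at least one increment")
    model = _Model(mesh, materials)
    k0 = model.assemble_elastic()
    dofs, vals_full = bc.dirichlet()
    free = np.setdiff1d(np.arange(model.ndof), dofs)
    kff = k0[free][:, free].tocsc()
    lu = spla.splu(kff)
    k_fp = k0[free][:, dofs]

    u = np.zeros(model.ndof)
    eps_p = np.zeros((mesh.n_elements, 8, 6))
    strains_out = [0.0]
    forces_out = [0.0]
    total_iters = 0
    converged_all = True
    sigma = np.zeros((mesh.n_elements, 8, 6))
    yielded = np.zeros((mesh.n_elements, 8), dtype=bool)

    dt = 1.0 / n_increments
    predictor = lu.solve(-(k_fp @ (vals_full * dt)))
    # the factorized tangent persists across increments: the plastic zone
    # only grows under monotonic loading, so the last reformed tangent is a
    # far better operator than the elastic stiffness
    lu_current = lu
    for inc in range(1, n_increments + 1):
        t = inc / n_increments
        u[dofs] = vals_full * t
        # incremental elastic predictor avoids the transient strain
        # concentration a bare prescribed-displacement jump would create
        u[free] += predictor
        inc_converged = False
        since_reform = 0
        prev_norm = np.inf
        for _ in range(plastic_iter_max):
            eps = model.strains(u)
            sigma, eps_p_new, yielded = model.radial_return(eps, eps_p)
            f_int = model.internal_force(sigma)
            du = lu_current.solve(-f_int[free])
            u[free] += du
            total_iters += 1
            since_reform += 1
            u_ref = np.abs(u).max()
            du_norm = np.abs(du).max()
            if u_ref == 0 or du_norm / u_ref <= tol:
                inc_converged = True
                break
            # Reform the tangent only when the stationary iteration contracts
            # too slowly to beat the cost of a new factorization (a reform is
            # worth roughly 50-100 cheap iterations), diverges, or stalls.
            ratio = du_norm / prev_norm
            slow = since_reform >= 5 and ratio > 0.85
            if slow or since_reform >= reform_interval:
                kt = model.consistent_tangent(model.strains(u), eps_p)
                lu_current = spla.splu(kt[free][:, free].tocsc())
                since_reform = 0
                prev_norm = np.inf
            else:
                prev_norm = du_norm
        if not inc_converged:
            converged_all = False
            break
        eps = model.strains(u)
        sigma, eps_p, yielded = model.radial_return(eps, eps_p)
        f_int = model.internal_force(sigma)
        reaction = -f_int[bc.driven_nodes * 3 + 2].sum() / 1000.0
        strains_out.append(bc.apparent_strain * t)
        forces_out.append(float(reaction))

    curve = FDCurve(np.array(strains_out), np.array(forces_out),
                    loaded_height=bc.loaded_height, converged=converged_all)
    vm = von_mises(sigma).mean(axis=1)
    eps_dev = model.strains(u)
    dev = eps_dev.copy()
    dev[..., 3:] *= 0.5
    tr = dev[..., :3].sum(-1)
    dev[..., :3] -= tr[..., None] / 3.0
    eq_strain = np.sqrt(2.0 / 3.0 * ((dev[..., :3] ** 2).sum(-1) + 2 * (dev[..., 3:] ** 2).sum(-1)))
    result = SolveResult(
        nodal_displacement=u.reshape(-1, 3),
        reaction_force=forces_out[-1],
        element_vm_stress=vm,
        element_vm_strain=eq_strain.mean(axis=1),
        yielded_flags=yielded.any(axis=1),
        iterations=total_iters,
        converged=converged_all,
        internal_force=model.internal_force(sigma),
    )
    return curve, result


def reaction_force(result: SolveResult, nodes: np.ndarray, axis: int = 2) -> float:
    """Sum of nodal reactions (kN) over a node set; compression positive."""
    dofs = np.asarray(nodes, dtype=np.int64) * 3 + axis
    return float(-result.internal_force[dofs].sum() / 1000.0)


def stiffness_from_curve(curve: FDCurve, initial_fraction: float = 0.1) -> float:
    """Model stiffness K_FE (kN/mm): slope of the initial linear region.

    Fits a least-squares line through the samples with strain within
    ``initial_fraction`` of the maximum (always keeping the origin and the
    first loaded point), then converts the per-strain slope to per-mm using
    the curve's loaded height.
    """
    s, f = curve.apparent_strain, curve.force
    if len(s) < 2:
        raise ValueError("need at least two points on the curve")
    keep = s <= initial_fraction * s.max()
    if keep.sum() < 2:
        keep = np.zeros(len(s), dtype=bool)
        keep[:2] = True
    slope = np.polyfit(s[keep], f[keep], 1)[0]    # kN per unit strain
    if not np.isfinite(curve.loaded_height) or curve.loaded_height <= 0:
        raise ValueError("curve has no valid loaded height")
    return float(slope / curve.loaded_height)
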