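"""Eight-node hexahedral (HEX8) element kernels for cubic voxels.

Every element in a voxel mesh is the same axis-aligned cube, so the
strain-displacement matrices at the 2x2x2 Gauss points and the unit-modulus
stiffness template are computed once and shared by all elements.  Element
stiffness is then ``K_e = E_e * K_template`` because Poisson's ratio is the
same for every material.

Local node order (right-handed, VTK hexahedron convention), reference
coordinates (xi, eta, zeta) in [-1, 1]^3 mapping to (x, y, z):

    0:(-,-,-) 1:(+,-,-) 2:(+,+,-) 3:(-,+,-)
    4:(-,-,+) 5:(+,-,+) 6:(+,+,+) 7:(-,+,+)

Voigt order for stress/strain: [xx, yy, zz, xy, yz, zx] with engineering
shear strains (gamma = 2*eps).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "NODE_SIGNS",
    "gauss_b_matrices",
    "isotropic_d",
    "hex8_stiffness_template",
    "von_mises",
]

# (xi_i, eta_i, zeta_i) signs per local node
NODE_SIGNS = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)

_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = NODE_SIGNS * _G  # 2x2x2 rule, weights all 1 in reference space


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN/d(xi,eta,zeta) at a reference point; returns (8, 3)."""
    grads = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = NODE_SIGNS[a]
        grads[a, 0] = sx * (1 + sy * xi[1]) * (1 + sz * xi[2]) / 8.0
        grads[a, 1] = (1 + sx * xi[0]) * sy * (1 + sz * xi[2]) / 8.0
        grads[a, 2] = (1 + sx * xi[0]) * (1 + sy * xi[1]) * sz / 8.0
    return grads


def gauss_b_matrices(voxel: float) -> tuple[np.ndarray, float]:
    """B matrices (8 Gauss points, 6x24) and per-point integration weight.

    For a cube of edge ``voxel`` the Jacobian is diagonal (voxel/2) and the
    integration weight per Gauss point is det(J) = (voxel/2)^3.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    inv_j = 2.0 / voxel
    b_all = np.zeros((8, 6, 24))
    for g, xi in enumerate(GAUSS_POINTS):
        grads = _shape_gradients(xi) * inv_j  # dN/dx, (8, 3)
        for a in range(8):
            dx, dy, dz = grads[a]
            c = 3 * a
            b = b_all[g]
            b[0, c + 0] = dx
            b[1, c + 1] = dy
            b[2, c + 2] = dz
            b[3, c + 0] = dy
            b[3, c + 1] = dx
            b[4, c + 1] = dz
            b[4, c + 2] = dy
            b[5, c + 0] = dz
            b[5, c + 2] = dx
    weight = (voxel / 2.0) ** 3
    return b_all, weight


def isotropic_d(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt notation (engineering shear)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] = lam + 2 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


def hex8_stiffness_template(voxel: float, nu: float = 0.3) -> np.ndarray:
    """24x24 element stiffness for unit elastic modulus.

    Symmetric positive semidefinite with a null space of exactly the six
    rigid-body modes (2x2x2 Gauss integration; no spurious zero-energy modes).
    """
    b_all, w = gauss_b_matrices(voxel)
    d = isotropic_d(1.0, nu)
    k = np.zeros((24, 24))
    for g in range(8):
        b = b_all[g]
        k += w * (b.T @ d @ b)
    return 0.5 * (k + k.T)


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt stress (..., 6)."""
    sx, sy, sz = stress[..., 0], stress[..., 1], stress[..., 2]
    txy, tyz, tzx = stress[..., 3], stress[..., 4], stress[..., 5]
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
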