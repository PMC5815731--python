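"""Trilinear hexahedron (hex8) reference-element utilities.

Node ordering follows the VTK_HEXAHEDRON convention: nodes 0-3 are the
bottom face counter-clockwise (viewed from +z), nodes 4-7 the top face
in the same order.  Natural coordinates (xi, eta, zeta) in [-1, 1]^3.
"""

from __future__ import annotations

import numpy as np

# natural coordinates of the 8 corners, VTK ordering
CORNER_XI = np.array(
    [
        [-1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [1.0, -1.0, 1.0],
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, 1.0],
    ]
)

_G = 1.0 / np.sqrt(3.0)
#: 2x2x2 Gauss points and (unit) weights
GAUSS_2 = CORNER_XI * _G
GAUSS_2_W = np.ones(8)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points ``xi`` of shape (..., 3)."""
    xi = np.asarray(xi, dtype=float)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * CORNER_XI, axis=-1)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi_j at points ``xi``; result shape (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    terms = 1.0 + xi[..., None, :] * CORNER_XI  # (..., 8, 3)
    grads = np.empty(terms.shape)
    for j in range(3):
        prod = np.ones(terms.shape[:-1])
        for k in range(3):
            if k == j:
                prod = prod * CORNER_XI[:, k]
            else:
                prod = prod * terms[..., k]
        grads[..., j] = prod
    return 0.125 * grads


# gradients at the 8 standard Gauss points, shape (8, 8, 3): [gp, node, dim]
GRAD_AT_GAUSS = shape_gradients(GAUSS_2)


def jacobians(coords: np.ndarray) -> np.ndarray:
    """det J at the 2x2x2 Gauss points for element corner coords (E, 8, 3).

    Returns an (E, 8) array of Jacobian determinants.
    """
    # J[e, g, i, j] = sum_a dN_a/dxi_i * x[e, a, j]
    J = np.einsum("gai,eaj->egij", GRAD_AT_GAUSS, coords)
    return np.linalg.det(J)


def physical_gradients(coords: np.ndarray):
    """Shape-function gradients w.r.t. physical coordinates at Gauss points.

    Parameters
    ----------
    coords : (E, 8, 3) element corner coordinates.

    Returns
    -------
    grads : (E, 8, 8, 3) array [element, gauss point, node, dim].
    detJ : (E, 8) Jacobian determinants.
    """
    J = np.einsum("gai,eaj->egij", GRAD_AT_GAUSS, coords)  # J[i,j] = dx_j/dxi_i
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    # dN_a/dx_j = sum_i (J^-1)_ji dN_a/dxi_i
    grads = np.einsum("egji,gai->egaj", Jinv, GRAD_AT_GAUSS)
    return grads, detJ


def invert_trilinear(coords: np.ndarray, x: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Natural coordinates of physical point ``x`` inside one hex (Newton)."""
    xi = np.zeros(3)
    for _ in range(50):
        N = shape_functions(xi)
        r = N @ coords - x
        if np.dot(r, r) < tol * tol:
            break
        dN = shape_gradients(xi)
        J = dN.T @ coords  # d x_j / d xi_i -> (3, 3) with rows xi
        xi = xi - np.linalg.solve(J.T, r)
    return xi
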