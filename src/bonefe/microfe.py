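"""Voxel-conversion micro-finite-element analysis of three-point bending.

Every bone voxel of a segmented micro-CT mask becomes one 8-node trilinear
hexahedral element with identical isotropic linear-elastic material, so a
single precomputed 24x24 element stiffness matrix serves the whole mesh.
Boundary conditions idealize the bending rig: the bottom-surface nodes at
the two roller planes are fixed vertically (rolling-pin supports, plus
minimal stabilizers against rigid-body motion), and a vertical displacement
is prescribed at the top-surface nodes where the top roller contacts the
bone. The FE bending stiffness is the total vertical reaction at the loaded
nodes divided by the prescribed displacement, mirroring the experimental
stiffness definition.

Units: lengths mm, moduli GPa at the interface (converted to N/mm^2
internally), forces N, stiffness N/mm.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .imageproc import BoneMask, SpanCrop

__all__ = [
    "Material",
    "BCSet",
    "FEModel",
    "FESolution",
    "ConvergenceError",
    "hex8_element_matrix",
    "voxel_mesh",
    "build_model",
    "assemble",
    "solve",
    "export_mesh",
    "read_vtk_mesh",
]

# local corner c has lattice offset (bit0, bit1, bit2) along (axis0, axis1, axis2)
CORNER_OFFSETS = np.array(
    [[(c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)], dtype=np.int64
)


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic tissue material."""

    youngs_modulus_gpa: float = 10.0
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not self.youngs_modulus_gpa > 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5) (0.5 is incompressible)")

    @property
    def shear_modulus_gpa(self) -> float:
        return self.youngs_modulus_gpa / (2.0 * (1.0 + self.poisson_ratio))


def hex8_element_matrix(material: Material, edge_um: float) -> np.ndarray:
    """24x24 stiffness matrix of a cubic trilinear hexahedron.

    Full 2x2x2 Gauss integration, which is exact for this element. DOF
    ordering is (node0_x, node0_y, node0_z, node1_x, ...), nodes ordered per
    :data:`CORNER_OFFSETS`. Scales linearly in E and in the edge length.
    """
    if not edge_um > 0:
        raise ValueError("edge length must be positive")
    E = material.youngs_modulus_gpa * 1000.0  # N/mm^2
    nu = material.poisson_ratio
    h = edge_um / 1000.0  # mm
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2.0 * mu
    D[3:, 3:] = mu * np.eye(3)  # engineering shear strains

    signs = CORNER_OFFSETS * 2.0 - 1.0  # natural-coordinate corner signs
    g = 1.0 / np.sqrt(3.0)
    K = np.zeros((24, 24))
    for gx, gy, gz in itertools.product((-g, g), repeat=3):
        dN = 0.125 * np.column_stack(
            [
                signs[:, 0] * (1 + signs[:, 1] * gy) * (1 + signs[:, 2] * gz),
                signs[:, 1] * (1 + signs[:, 0] * gx) * (1 + signs[:, 2] * gz),
                signs[:, 2] * (1 + signs[:, 0] * gx) * (1 + signs[:, 1] * gy),
            ]
        )
        dNdx = dN * (2.0 / h)  # cube Jacobian is (h/2) * I
        B = np.zeros((6, 24))
        for i in range(8):
            bx, by, bz = dNdx[i]
            B[0, 3 * i] = bx
            B[1, 3 * i + 1] = by
            B[2, 3 * i + 2] = bz
            B[3, 3 * i] = by
            B[3, 3 * i + 1] = bx
            B[4, 3 * i + 1] = bz
            B[4, 3 * i + 2] = by
            B[5, 3 * i] = bz
            B[5, 3 * i + 2] = bx
        K += (B.T @ D @ B) * (h / 2.0) ** 3
    return 0.5 * (K + K.T)


@dataclass
class BCSet:
    """Node sets and prescribed displacement of the bending boundary value
    problem (node ids index the compressed mesh node array)."""

    support_nodes_a: np.ndarray
    support_nodes_b: np.ndarray
    stabilizer_node: int               # one node of set a, fixed along axis 1
    load_nodes: np.ndarray
    prescribed_displacement_mm: float = -0.01

    def __post_init__(self) -> None:
        for name in ("support_nodes_a", "support_nodes_b", "load_nodes"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.size == 0:
                raise ValueError(f"{name} is empty")
            setattr(self, name, arr)
        if self.prescribed_displacement_mm == 0:
            raise ValueError("prescribed displacement must be nonzero")
        supports = np.concatenate([self.support_nodes_a, self.support_nodes_b])
        if np.intersect1d(supports, self.load_nodes).size:
            raise ValueError("support and load node sets overlap: span too short")


@dataclass
class FEModel:
    """Hexahedral voxel mesh plus material and boundary conditions."""

    mask: BoneMask
    element_size_um: float
    material: Material
    elem_nodes: np.ndarray      # (n_elements, 8) compressed node ids
    node_ijk: np.ndarray        # (n_nodes, 3) lattice indices of each node
    bc: BCSet

    @property
    def n_elements(self) -> int:
        return self.elem_nodes.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.node_ijk.shape[0]

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def node_coords_mm(self) -> np.ndarray:
        return self.node_ijk * (self.element_size_um / 1000.0)


@dataclass
class FESolution:
    """Solved displacement field and the derived bending stiffness."""

    displacements: np.ndarray   # (n_nodes, 3) mm
    reaction_force_n: float     # total vertical reaction at the load nodes
    fe_stiffness_n_per_mm: float
    solver_iterations: int
    residual: float
    support_reaction_n: float = 0.0


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residual_history: list[float]):
        super().__init__(msg)
        self.residual_history = residual_history


# ---------------------------------------------------------------------------
# Meshing and boundary conditions


def voxel_mesh(mask: BoneMask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a bone mask to a hexahedral mesh.

    Returns ``(elem_nodes, node_ijk, node_id_lattice)`` where
    ``node_id_lattice`` maps corner-lattice (i, j, k) to compressed node id
    (-1 where no bone node exists).
    """
    if not mask.grid.any():
        raise ValueError("empty mask has no elements")
    nx, ny, nz = mask.grid.shape
    vox = np.argwhere(mask.grid)  # lexicographic element order
    dims = (nx + 1, ny + 1, nz + 1)

    def flat(ijk):
        return (ijk[:, 0] * dims[1] + ijk[:, 1]) * dims[2] + ijk[:, 2]

    corner_flat = np.stack(
        [flat(vox + off) for off in CORNER_OFFSETS], axis=1
    )  # (n_el, 8)
    used, inverse = np.unique(corner_flat, return_inverse=True)
    elem_nodes = inverse.reshape(corner_flat.shape).astype(np.int64)
    node_ijk = np.column_stack(
        np.unravel_index(used, dims)
    ).astype(np.int64)
    node_id = np.full(dims, -1, dtype=np.int64)
    node_id[tuple(node_ijk.T)] = np.arange(len(used))
    return elem_nodes, node_ijk, node_id


def _surface_nodes_in_band(
    node_id: np.ndarray, center_plane: int, halfwidth: int, top: bool
) -> np.ndarray:
    """Bottom-most (or top-most) existing node per (axis0, axis1) column,
    restricted to axis0 node planes within +-halfwidth of ``center_plane``."""
    exists = node_id >= 0
    lo = max(center_plane - halfwidth, 0)
    hi = min(center_plane + halfwidth + 1, exists.shape[0])
    if hi <= lo:
        return np.empty(0, dtype=np.int64)
    sub = exists[lo:hi]  # (band, ny+1, nz+1)
    any_col = sub.any(axis=2)
    if top:
        k_sel = sub.shape[2] - 1 - np.argmax(sub[:, :, ::-1], axis=2)
    else:
        k_sel = np.argmax(sub, axis=2)
    ii, jj = np.nonzero(any_col)
    return node_id[lo + ii, jj, k_sel[ii, jj]]


def build_model(
    mask: BoneMask,
    material: Material,
    crop: SpanCrop,
    contact_halfwidth_vox: int = 1,
    prescribed_displacement_mm: float = -0.01,
) -> FEModel:
    """Build the bending FE model from a (cropped, connected) bone mask.

    Roller and load positions in ``crop`` are interpreted in the coordinate
    frame of ``mask`` (use :func:`bonefe.imageproc.local_span_crop` after
    cropping). Support sets are the bottom bone-surface nodes in a
    ``+-contact_halfwidth_vox`` axis-0 band around each roller plane; load
    nodes are the top-surface analogue at the load position.
    """
    elem_nodes, node_ijk, node_id = voxel_mesh(mask)
    s = mask.voxel_size_mm
    sets = {}
    for name, pos, top in (
        ("bottom roller a", min(crop.roller_positions_mm), False),
        ("bottom roller b", max(crop.roller_positions_mm), False),
        ("top roller", crop.load_position_mm, True),
    ):
        plane = int(round(pos / s))
        nodes = _surface_nodes_in_band(node_id, plane, contact_halfwidth_vox, top)
        if nodes.size == 0:
            raise ValueError(
                f"no bone surface at the {name} plane ({pos} mm): "
                "bone does not reach the roller"
            )
        sets[name] = np.sort(nodes)
    bc = BCSet(
        support_nodes_a=sets["bottom roller a"],
        support_nodes_b=sets["bottom roller b"],
        stabilizer_node=int(sets["bottom roller a"][0]),
        load_nodes=sets["top roller"],
        prescribed_displacement_mm=prescribed_displacement_mm,
    )
    return FEModel(
        mask=mask,
        element_size_um=mask.voxel_size_um,
        material=material,
        elem_nodes=elem_nodes,
        node_ijk=node_ijk,
        bc=bc,
    )


def _constraints(model: FEModel) -> tuple[np.ndarray, np.ndarray]:
    """Constrained dof indices and their prescribed values.

    Supports: vertical (axis 2) freedom fixed on both roller sets; axis 0
    fixed on set a and axis 1 on one node of set a to remove the remaining
    rigid-body modes. Load nodes: vertical freedom set to the prescribed
    displacement.
    """
    bc = model.bc
    dofs = [
        bc.support_nodes_a * 3 + 2,
        bc.support_nodes_b * 3 + 2,
        bc.support_nodes_a * 3 + 0,
        np.array([bc.stabilizer_node * 3 + 1]),
        bc.load_nodes * 3 + 2,
    ]
    vals = [
        np.zeros(bc.support_nodes_a.size),
        np.zeros(bc.support_nodes_b.size),
        np.zeros(bc.support_nodes_a.size),
        np.zeros(1),
        np.full(bc.load_nodes.size, bc.prescribed_displacement_mm),
    ]
    fixed = np.concatenate(dofs)
    values = np.concatenate(vals)
    fixed, order = np.unique(fixed, return_index=True)
    return fixed, values[order]


# ---------------------------------------------------------------------------
# Assembly and solution


def assemble(
    elem_nodes: np.ndarray, ke: np.ndarray, n_nodes: int, chunk: int = 40000
) -> sp.csr_array:
    """Assemble the global stiffness as CSR, scattering the single element
    matrix; chunked to bound peak memory."""
    ndof = 3 * n_nodes
    K = sp.csr_array((ndof, ndof))
    for start in range(0, elem_nodes.shape[0], chunk):
        en = elem_nodes[start : start + chunk]
        dofs = (en[:, :, None] * 3 + np.arange(3)).reshape(en.shape[0], 24)
        rows = np.repeat(dofs, 24, axis=1).ravel()
        cols = np.tile(dofs, (1, 24)).ravel()
        vals = np.tile(ke.ravel(), en.shape[0])
        K = K + sp.coo_array((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


class _MatFreeOperator:
    """Element-by-element K @ u without assembling the global matrix."""

    def __init__(self, elem_nodes: np.ndarray, ke: np.ndarray, n_nodes: int):
        en = elem_nodes
        self.eldofs = (en[:, :, None] * 3 + np.arange(3)).reshape(en.shape[0], 24)
        self.ke = ke
        self.ndof = 3 * n_nodes

    def matvec(self, u: np.ndarray) -> np.ndarray:
        fe = u[self.eldofs] @ self.ke
        return np.bincount(self.eldofs.ravel(), weights=fe.ravel(), minlength=self.ndof)

    def diagonal(self) -> np.ndarray:
        d = np.tile(np.diag(self.ke), self.eldofs.shape[0])
        return np.bincount(self.eldofs.ravel(), weights=d, minlength=self.ndof)


def _pcg(matvec, b, inv_diag, tol, max_iter):
    """Jacobi-preconditioned conjugate gradients; returns (x, iters, relres,
    history). Serial and deterministic."""
    x = np.zeros_like(b)
    r = b.copy()
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return x, 0, 0.0, [0.0]
    z = inv_diag * r
    p = z.copy()
    rz = float(r @ z)
    history = []
    for it in range(1, max_iter + 1):
        Ap = matvec(p)
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        rel = float(np.linalg.norm(r)) / bnorm
        history.append(rel)
        if rel <= tol:
            return x, it, rel, history
        z = inv_diag * r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise ConvergenceError(
        f"PCG did not reach tol={tol:g} in {max_iter} iterations "
        f"(last relative residual {history[-1]:.3e})",
        history,
    )


def solve(
    model: FEModel,
    tol: float = 1e-6,
    max_iter: int | None = None,
    method: str = "auto",
) -> FESolution:
    """Solve the bending boundary value problem.

    ``method``: ``"cg"`` (assembled-sparse PCG), ``"matfree"``
    (element-by-element PCG), ``"dense"`` (direct solve, small meshes only)
    or ``"auto"`` (dense below 1000 dofs, else assembled PCG). Stiffness is
    |total vertical load-node reaction| / |prescribed displacement|; by
    linearity it is independent of the displacement magnitude.
    """
    fixed, fixed_vals = _constraints(model)
    ndof = model.n_dofs
    free = np.ones(ndof, dtype=bool)
    free[fixed] = False
    free_idx = np.flatnonzero(free)
    if max_iter is None:
        max_iter = max(2000, min(ndof, 60000))
    if method == "auto":
        method = "dense" if ndof < 1000 else "cg"

    ke = hex8_element_matrix(model.material, model.element_size_um)
    u = np.zeros(ndof)
    u[fixed] = fixed_vals

    if method == "matfree":
        op = _MatFreeOperator(model.elem_nodes, ke, model.n_nodes)
        b = -op.matvec(u)[free_idx]
        inv_diag = 1.0 / op.diagonal()[free_idx]

        def mv_free(v):
            tmp = np.zeros(ndof)
            tmp[free_idx] = v
            return op.matvec(tmp)[free_idx]

        x, iters, rel, _ = _pcg(mv_free, b, inv_diag, tol, max_iter)
        u[free_idx] = x
        r_all = op.matvec(u)
    else:
        K = assemble(model.elem_nodes, ke, model.n_nodes)
        b = -(K[:, fixed] @ fixed_vals)[free_idx]
        Kff = K[free_idx][:, free_idx]
        if method == "dense":
            if Kff.shape[0] > 20000:
                raise ValueError("dense solve requested on a large system")
            x = np.linalg.solve(Kff.toarray(), b)
            iters, rel = 1, float(
                np.linalg.norm(Kff @ x - b) / max(np.linalg.norm(b), 1e-300)
            )
        elif method == "cg":
            inv_diag = 1.0 / Kff.diagonal()
            x, iters, rel, _ = _pcg(lambda v: Kff @ v, b, inv_diag, tol, max_iter)
        else:
            raise ValueError(f"unknown method {method!r}")
        u[free_idx] = x
        r_all = K @ u

    load_zdofs = model.bc.load_nodes * 3 + 2
    support_zdofs = np.concatenate(
        [model.bc.support_nodes_a, model.bc.support_nodes_b]
    ) * 3 + 2
    reaction = float(r_all[load_zdofs].sum())
    support_reaction = float(r_all[support_zdofs].sum())
    delta = model.bc.prescribed_displacement_mm
    stiffness = abs(reaction) / abs(delta)
    if not stiffness > 0:
        raise RuntimeError("nonpositive FE stiffness: degenerate model")
    return FESolution(
        displacements=u.reshape(-1, 3),
        reaction_force_n=reaction,
        fe_stiffness_n_per_mm=stiffness,
        solver_iterations=iters,
        residual=rel,
        support_reaction_n=support_reaction,
    )


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII unstructured grid)

_VTK_HEX_ORDER = [0, 1, 3, 2, 4, 5, 7, 6]  # our corner order -> VTK hexahedron


def export_mesh(model: FEModel, solution: FESolution, path: str | os.PathLike) -> None:
    """Write the mesh with nodal displacements and vertical reactions as a
    legacy-ASCII VTK unstructured grid."""
    path = os.fspath(path)
    coords = model.node_coords_mm()
    reactions = np.zeros(model.n_nodes)
    ke = hex8_element_matrix(model.material, model.element_size_um)
    op = _MatFreeOperator(model.elem_nodes, ke, model.n_nodes)
    r_all = op.matvec(solution.displacements.ravel())
    fixed, _ = _constraints(model)
    zfixed = fixed[fixed % 3 == 2]
    reactions[zfixed // 3] = r_all[zfixed]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("bonefe micro-FE bending model\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {model.n_nodes} double\n")
        np.savetxt(fh, coords, fmt="%.9g")
        n_el = model.n_elements
        fh.write(f"CELLS {n_el} {n_el * 9}\n")
        cells = np.column_stack(
            [np.full(n_el, 8), model.elem_nodes[:, _VTK_HEX_ORDER]]
        )
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {n_el}\n")
        np.savetxt(fh, np.full(n_el, 12), fmt="%d")
        fh.write(f"POINT_DATA {model.n_nodes}\n")
        fh.write("VECTORS displacement double\n")
        np.savetxt(fh, solution.displacements, fmt="%.9g")
        fh.write("SCALARS vertical_reaction double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, reactions, fmt="%.9g")


def read_vtk_mesh(path: str | os.PathLike):
    """Minimal legacy-VTK reader (points, cells, point data) used to verify
    exports round-trip; not a general VTK parser."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0

    def seek(prefix):
        nonlocal i
        while not lines[i].startswith(prefix):
            i += 1
        return lines[i].split()

    n_pts = int(seek("POINTS")[1])
    pts = np.loadtxt(lines[i + 1 : i + 1 + n_pts])
    n_cells = int(seek("CELLS")[1])
    cells = np.loadtxt(lines[i + 1 : i + 1 + n_cells], dtype=int)[:, 1:]
    seek("VECTORS")
    disp = np.loadtxt(lines[i + 1 : i + 1 + n_pts])
    seek("SCALARS")
    reac = np.loadtxt(lines[i + 2 : i + 2 + n_pts])
    return pts.reshape(n_pts, 3), cells, disp.reshape(n_pts, 3), reac
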