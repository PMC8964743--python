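"""Quasi-static large-deflection solver for the meshed foot structure.

Plane frame elements (2 nodes, 3 DOF each: u, v, rotation) with axial and
Euler-Bernoulli bending response.  Geometric nonlinearity is handled with a
corotational formulation: element rigid rotation is removed via the current
chord, local deformational quantities feed linear section laws, and the
consistent tangent includes the geometric stiffness.  Loads are applied in
increments with full Newton iterations per increment.

The foot is cantilevered from the shank adapter: the attachment node is
fully fixed and the ground reaction force is applied as a point load at the
sole node mapped from the center of pressure.

Section moduli: bending uses the flexural modulus ``E_f`` and axial the
tensile modulus ``E`` (both measured for the build material); the stress
safety check uses the flexural yield, as the structure is bending dominated.
Shear deformation and self-weight are neglected (slender elements,
quasi-static stance loads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .parametrization import FrameMesh

__all__ = [
    "Material",
    "NYLON_66",
    "PointLoad",
    "SolverOptions",
    "DeformedState",
    "StressField",
    "solve_quasi_static",
    "recover_stresses",
    "max_stress",
    "passes_safety",
    "SolverError",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class Material:
    """Isotropic material constants for the extruded foot."""

    tensile_modulus: float  # E, Pa
    tensile_yield: float  # sigma_y, Pa
    flexural_modulus: float  # E_f, Pa
    flexural_yield: float  # sigma_yf, Pa
    poisson: float
    density: float  # kg/m^3

    def __post_init__(self) -> None:
        if min(self.tensile_modulus, self.tensile_yield, self.flexural_modulus,
               self.flexural_yield, self.density) <= 0:
            raise ValueError("material constants must be positive")
        if not 0.0 < self.poisson < 0.5:
            raise ValueError("poisson ratio must lie in (0, 0.5)")

    def scaled(self, factor: float) -> "Material":
        """Copy with both moduli multiplied by ``factor`` (rigidity studies)."""
        return Material(self.tensile_modulus * factor, self.tensile_yield,
                        self.flexural_modulus * factor, self.flexural_yield,
                        self.poisson, self.density)


#: Nylon 6/6, the low-cost build material used for the prototype feet.
NYLON_66 = Material(
    tensile_modulus=2.51e9,
    tensile_yield=82.7e6,
    flexural_modulus=3.15e9,
    flexural_yield=92.0e6,
    poisson=0.41,
    density=1130.0,
)


@dataclass(frozen=True)
class PointLoad:
    """A point force (and optional couple) applied at one mesh node.

    The application point may be given either directly as a node index or as
    a foot-frame x-station along the sole (mapped to the nearest sole node).
    """

    force: np.ndarray  # (2,) N, foot frame
    node: int | None = None
    sole_station_x: float | None = None
    moment: float = 0.0  # N*m nodal couple

    def __post_init__(self) -> None:
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        if self.force.shape != (2,):
            raise ValueError("force must be a 2-vector")
        if (self.node is None) == (self.sole_station_x is None):
            raise ValueError("give exactly one of node or sole_station_x")

    def resolve_node(self, mesh: FrameMesh) -> int:
        if self.node is not None:
            return int(self.node)
        lo = mesh.sole.bottom[:, 0].min() - 1e-9
        hi = mesh.sole.bottom[:, 0].max() + 1e-9
        if not lo <= self.sole_station_x <= hi:
            raise ValueError("load station outside the sole extent")
        return mesh.sole.station_node(self.sole_station_x)


@dataclass(frozen=True)
class SolverOptions:
    increments: int = 10
    tol: float = 1e-6  # relative residual
    disp_tol: float = 1e-12  # absolute Newton-update norm (near-rigid floor)
    max_iter: int = 50  # Newton iterations per increment
    use_flexural_modulus_for_bending: bool = True

    def bending_modulus(self, mat: Material) -> float:
        return mat.flexural_modulus if self.use_flexural_modulus_for_bending \
            else mat.tensile_modulus


@dataclass
class DeformedState:
    """Equilibrium (or last-iterate) response of the foot under one load case."""

    displacements: np.ndarray  # (N, 3): u, v [m], rotation [rad]
    reaction: np.ndarray  # (3,): Rx, Ry [N], Mz [N*m] at the attachment
    converged: bool
    increments_used: int
    residual: float
    local_forces: np.ndarray  # (E, 3): axial N, end moments M1, M2

    def node_position(self, mesh: FrameMesh, node: int) -> np.ndarray:
        return mesh.nodes[node] + self.displacements[node, :2]


@dataclass(frozen=True)
class StressField:
    """Extreme-fiber stresses per element end (axial + bending recovery)."""

    axial: np.ndarray  # (E,) Pa, signed
    bending: np.ndarray  # (E, 2) Pa, magnitude at each end
    combined: np.ndarray  # (E, 2) Pa, |axial| + |bending|


def _element_state(mesh, coords, theta, EA, EI):
    """Batched corotational element kinematics, local forces and matrices."""
    i = mesh.elements[:, 0]
    j = mesh.elements[:, 1]
    X0 = mesh.nodes
    d0 = X0[j] - X0[i]
    L0 = np.hypot(d0[:, 0], d0[:, 1])
    beta0 = np.arctan2(d0[:, 1], d0[:, 0])
    d = coords[j] - coords[i]
    Ln = np.hypot(d[:, 0], d[:, 1])
    if np.any(Ln < 1e-12):
        raise SolverError("element collapsed to zero length")
    c = d[:, 0] / Ln
    s = d[:, 1] / Ln
    beta = np.arctan2(d[:, 1], d[:, 0])
    # rigid chord rotation, unwrapped near the initial orientation
    alpha = beta - beta0
    alpha = np.mod(alpha + np.pi, 2 * np.pi) - np.pi
    ubar = (Ln**2 - L0**2) / (Ln + L0)
    t1 = theta[i] - alpha
    t2 = theta[j] - alpha
    N = EA / L0 * ubar
    M1 = EI / L0 * (4.0 * t1 + 2.0 * t2)
    M2 = EI / L0 * (2.0 * t1 + 4.0 * t2)
    return i, j, L0, Ln, c, s, N, M1, M2, EA, EI


def _assemble(mesh, coords, theta, EA, EI):
    """Internal force vector and tangent stiffness (COO triplets)."""
    i, j, L0, Ln, c, s, N, M1, M2, EA, EI = _element_state(mesh, coords, theta, EA, EI)
    E = mesh.n_elements
    zeros = np.zeros(E)
    ones = np.ones(E)
    r = np.stack([-c, -s, zeros, c, s, zeros], axis=1)  # (E, 6)
    z = np.stack([s, -c, zeros, -s, c, zeros], axis=1)
    e3 = np.stack([zeros, zeros, ones, zeros, zeros, zeros], axis=1)
    e6 = np.stack([zeros, zeros, zeros, zeros, zeros, ones], axis=1)
    B1 = r
    B2 = e3 - z / Ln[:, None]
    B3 = e6 - z / Ln[:, None]

    f_local = np.stack([N, M1, M2], axis=1)
    f_int_e = (B1 * N[:, None] + B2 * M1[:, None] + B3 * M2[:, None])  # (E, 6)

    k11 = EA / L0
    k22 = 4.0 * EI / L0
    k23 = 2.0 * EI / L0
    # material part: B^T K_l B
    K_e = (
        np.einsum("ei,ej->eij", B1, B1) * k11[:, None, None]
        + np.einsum("ei,ej->eij", B2, B2) * k22[:, None, None]
        + np.einsum("ei,ej->eij", B3, B3) * k22[:, None, None]
        + (np.einsum("ei,ej->eij", B2, B3)
           + np.einsum("ei,ej->eij", B3, B2)) * k23[:, None, None]
    )
    # geometric part
    K_e += np.einsum("ei,ej->eij", z, z) * (N / Ln)[:, None, None]
    K_e += (np.einsum("ei,ej->eij", r, z) + np.einsum("ei,ej->eij", z, r)) \
        * ((M1 + M2) / Ln**2)[:, None, None]

    dofs = np.stack([3 * i, 3 * i + 1, 3 * i + 2, 3 * j, 3 * j + 1, 3 * j + 2], axis=1)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    vals = K_e.ravel()

    n_dof = 3 * mesh.n_nodes
    f_int = np.zeros(n_dof)
    np.add.at(f_int, dofs.ravel(), f_int_e.ravel())
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n_dof, n_dof)).tocsc()
    return f_int, K, f_local


def solve_quasi_static(mesh: FrameMesh, mat: Material, load: PointLoad,
                       opts: SolverOptions | None = None) -> DeformedState:
    """Solve for equilibrium under ``load`` with the attachment node clamped.

    The load is ramped in ``opts.increments`` equal steps with the element
    frames corotated at every Newton iteration, which captures the large
    sole deflections of compliant feet while reducing exactly to linear
    frame analysis for small loads.
    """
    opts = opts or SolverOptions()
    E_b = opts.bending_modulus(mat)
    EA = mat.tensile_modulus * mesh.area
    EI = E_b * mesh.inertia

    n_dof = 3 * mesh.n_nodes
    load_node = load.resolve_node(mesh)
    f_full = np.zeros(n_dof)
    f_full[3 * load_node:3 * load_node + 2] = load.force
    f_full[3 * load_node + 2] = load.moment

    fixed = np.array([3 * mesh.attachment_node,
                      3 * mesh.attachment_node + 1,
                      3 * mesh.attachment_node + 2])
    free = np.setdiff1d(np.arange(n_dof), fixed)

    u = np.zeros(n_dof)
    converged = True
    residual = 0.0
    ref_force = max(float(np.linalg.norm(load.force)) + abs(load.moment), 1e-12)

    for inc in range(1, opts.increments + 1):
        f_target = f_full * (inc / opts.increments)
        ok = False
        for _ in range(opts.max_iter):
            coords = mesh.nodes + u.reshape(-1, 3)[:, :2]
            theta = u.reshape(-1, 3)[:, 2]
            f_int, K, f_local = _assemble(mesh, coords, theta, EA, EI)
            g = f_target - f_int
            residual = float(np.linalg.norm(g[free])) / ref_force
            if residual < opts.tol:
                ok = True
                break
            Kff = K[np.ix_(free, free)]
            try:
                du = spla.spsolve(Kff.tocsc(), g[free])
            except Exception as exc:  # singular stiffness
                raise SolverError(f"singular stiffness matrix: {exc}") from exc
            if not np.all(np.isfinite(du)):
                raise SolverError("singular stiffness matrix (non-finite update)")
            u[free] += du
            # near-rigid structures: the force residual floors at round-off
            # while the update is already negligible
            if np.linalg.norm(du) < opts.disp_tol:
                ok = True
                break
        if not ok:
            converged = False
            break

    coords = mesh.nodes + u.reshape(-1, 3)[:, :2]
    theta = u.reshape(-1, 3)[:, 2]
    f_int, _, f_local = _assemble(mesh, coords, theta, EA, EI)
    reaction = f_int[fixed] - f_full[fixed] * (1.0 if converged else 0.0)
    return DeformedState(
        displacements=u.reshape(-1, 3).copy(),
        reaction=reaction,
        converged=converged,
        increments_used=inc,
        residual=residual,
        local_forces=f_local,
    )


def recover_stresses(mesh: FrameMesh, mat: Material,
                     state: DeformedState) -> StressField:
    """Extreme-fiber stress recovery from element-end forces.

    Per element end: ``axial = N/A``, ``bending = M c / I`` with
    ``c = thickness/2``; the combined stress is the sum of magnitudes.
    """
    if not state.converged:
        raise SolverError("cannot recover stresses from an unconverged state")
    N = state.local_forces[:, 0]
    M = state.local_forces[:, 1:3]
    axial = N / mesh.area
    cdist = mesh.thickness / 2.0
    bending = np.abs(M) * (cdist / mesh.inertia)[:, None]
    combined = np.abs(axial)[:, None] + bending
    return StressField(axial=axial, bending=bending, combined=combined)


def max_stress(field: StressField) -> float:
    """Maximum combined extreme-fiber stress over all element ends, Pa."""
    if field.combined.size == 0:
        raise ValueError("empty stress field")
    return float(np.max(field.combined))


def passes_safety(field: StressField, mat: Material, safety_factor: float = 1.75) -> bool:
    """True when the peak combined stress stays below the flexural yield
    divided by the prescribed safety factor."""
    return max_stress(field) <= mat.flexural_yield / safety_factor
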