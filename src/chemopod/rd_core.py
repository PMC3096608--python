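"""Activator / two-inhibitor reaction-diffusion system on the cell perimeter.

The chemistry driving pseudopods is a Meinhardt-type system of one
autocatalytic activator ``a``, one global inhibitor ``b`` and one local,
slowly diffusing inhibitor ``c``, posed on the closed one-dimensional cell
boundary:

    da/dt = D_a Lap a + s * (a^2/b + b_a) / ((s_c + c) (1 + s_a a^2)) - r_a a
    db/dt = r_b * (<a> - b)                     (<a> = perimeter mean of a)
    dc/dt = D_c Lap c + b_c a - r_c c

``s`` is the per-node signal produced by :mod:`chemopod.stimulus` — the only
route by which chemoattractant reaches the chemistry.  The activator's
``a^2/b`` production is the positive feedback that lets a pseudopod sustain
itself; ``b`` (membrane-tension analogue) caps total protrusion and ``c``
(substrate-depletion analogue) destabilises standing peaks so pseudopods
stay dynamic.

Spatial discretisation is a piecewise-linear surface finite element method
on the polygonal perimeter; time stepping is first-order IMEX (diffusion
implicit, reactions explicit).  Stretching of the boundary dilutes the
surface-bound species: the transfer of fields between successive meshes is
conservative, dividing concentrations by the local stretch factor.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .boundary import MeshError, PerimeterMesh, closest_point_query
from .stimulus import SignalParameters

logger = logging.getLogger("chemopod")

#: floor applied to b and c wherever they appear in a denominator
ZERO_FLOOR = 1e-12


class TransferError(RuntimeError):
    """Raised when two meshes are too dissimilar for field transfer."""


class NumericalError(RuntimeError):
    """Raised when the implicit solve fails or produces non-finite values."""


@dataclasses.dataclass
class ModelParameters:
    """Rate and diffusion constants of the activator/inhibitor system.

    All rates are per model time unit; diffusivities are length^2 per time
    with the cell diameter normalised to 10 length units.  Defaults follow
    Meinhardt's published orientation-model constants, rescaled to these
    length units and adjusted so that the chemistry stays patterned while
    the leading edge expands and dilutes the activator (see docs/methods.md).
    """

    D_a: float = 0.0075      # activator diffusivity
    D_c: float = 0.05        # local-inhibitor diffusivity
    r_a: float = 0.02        # activator decay rate
    r_b: float = 0.03        # global-inhibitor relaxation rate
    b_c: float = 0.005       # local-inhibitor production per unit activator
    r_c: float = 0.009       # local-inhibitor decay rate
    basal_production: float = 0.1    # Meinhardt b_a: signal-independent seed
    activator_saturation: float = 0.01   # Meinhardt s_a: caps peak height
    inhibitor_offset: float = 0.2    # Meinhardt s_c: softens 1/c divergence
    dt: float = 1.0          # solver step, model time
    signal: SignalParameters = dataclasses.field(default_factory=SignalParameters)

    def __post_init__(self) -> None:
        for name in ("D_a", "D_c", "r_a", "r_b", "b_c", "r_c", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class SurfaceFields:
    """Chemical state on the perimeter: per-node a and c, scalar global b."""

    a: np.ndarray
    c: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.b = float(self.b)

    def validate(self, mesh: PerimeterMesh) -> None:
        if len(self.a) != mesh.n_nodes or len(self.c) != mesh.n_nodes:
            raise ValueError("field arrays do not match mesh nodes")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.c)) and np.isfinite(self.b)):
            raise NumericalError("non-finite field values")
        if self.a.min() < 0 or self.c.min() < 0 or self.b < 0:
            raise NumericalError("negative field values")


def assemble_operators(mesh: PerimeterMesh) -> Tuple[sp.csr_matrix, sp.csr_matrix]:
    """P1 finite-element mass and stiffness matrices on the closed curve.

    The consistent mass matrix encodes element lengths (its total equals the
    perimeter); the stiffness matrix is the discrete Laplace-Beltrami
    operator and annihilates constants.
    """
    if mesh.n_nodes < 8:
        raise MeshError("perimeter mesh needs at least 8 nodes")
    h = mesh.element_lengths
    if np.any(h <= 0.0):
        raise MeshError("degenerate (zero-length) element")
    n = mesh.n_nodes
    i = np.arange(n)
    ip = (i + 1) % n
    # mass: element e contributes [[h/3, h/6], [h/6, h/3]] to nodes (e, e+1)
    rows = np.concatenate([i, ip, i, ip])
    cols = np.concatenate([i, ip, ip, i])
    mvals = np.concatenate([h / 3, h / 3, h / 6, h / 6])
    M = sp.csr_matrix(sp.coo_matrix((mvals, (rows, cols)), shape=(n, n)))
    kvals = np.concatenate([1 / h, 1 / h, -1 / h, -1 / h])
    K = sp.csr_matrix(sp.coo_matrix((kvals, (rows, cols)), shape=(n, n)))
    return M, K


def perimeter_mean(a: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Length-weighted mean of a nodal field over the perimeter."""
    a = np.asarray(a, dtype=float)
    if weights is None:
        return float(a.mean())
    return float(np.average(a, weights=weights))


def activator_production(a, b, c, s, params: ModelParameters) -> np.ndarray:
    """Non-linear activator source ``s (a^2/b + b_a) / ((s_c+c)(1+s_a a^2))``."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    b_safe = max(float(b), ZERO_FLOOR)
    if b < ZERO_FLOOR:
        logger.debug("global inhibitor floored at %g", ZERO_FLOOR)
    denom = (params.inhibitor_offset + np.maximum(c, 0.0)) \
        * (1.0 + params.activator_saturation * a * a)
    denom = np.maximum(denom, ZERO_FLOOR)
    return np.asarray(s) * (a * a / b_safe + params.basal_production) / denom


def reaction_terms(a, b, c, s, params: ModelParameters,
                   weights: Optional[np.ndarray] = None):
    """Pointwise non-diffusive right-hand sides ``(da/dt, db/dt, dc/dt)``.

    ``db/dt`` is a scalar: the global inhibitor relaxes toward the
    length-weighted perimeter mean of the activator at rate ``r_b``.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    fa = activator_production(a, b, c, s, params) - params.r_a * a
    fb = params.r_b * (perimeter_mean(a, weights) - float(b))
    fc = params.b_c * a - params.r_c * c
    return fa, fb, fc


class Operators:
    """Pre-factorised IMEX operators for one mesh (reused across substeps)."""

    def __init__(self, mesh: PerimeterMesh, params: ModelParameters):
        self.M, self.K = assemble_operators(mesh)
        self.weights = mesh.node_weights()
        dt = params.dt
        self.solve_a = spla.factorized(sp.csc_matrix(self.M + dt * params.D_a * self.K))
        self.solve_c = spla.factorized(sp.csc_matrix(self.M + dt * params.D_c * self.K))


def step_fields(fields: SurfaceFields, mesh: PerimeterMesh, s: np.ndarray,
                params: ModelParameters, dt: Optional[float] = None,
                operators: Optional[Operators] = None) -> SurfaceFields:
    """One semi-implicit (IMEX) time step of the surface system.

    Diffusion is implicit (unconditionally stable), reactions explicit, and
    the scalar global inhibitor is advanced by explicit Euler.  Small
    negative round-off values are clipped to zero and logged.
    """
    if dt is not None and operators is not None and dt != params.dt:
        raise ValueError("dt must match the dt the operators were factorised with")
    if operators is None:
        if dt is not None:
            params = dataclasses.replace(params, dt=dt)
        operators = Operators(mesh, params)
    dt = params.dt
    fa, fb, fc = reaction_terms(fields.a, fields.b, fields.c, s, params,
                                weights=operators.weights)
    rhs_a = operators.M @ (fields.a + dt * fa)
    rhs_c = operators.M @ (fields.c + dt * fc)
    a_new = operators.solve_a(rhs_a)
    c_new = operators.solve_c(rhs_c)
    b_new = fields.b + dt * fb
    if not (np.all(np.isfinite(a_new)) and np.all(np.isfinite(c_new)) and np.isfinite(b_new)):
        raise NumericalError("implicit solve produced non-finite values")
    nneg = int((a_new < 0).sum() + (c_new < 0).sum())
    if nneg:
        logger.debug("clipped %d negative nodal values to zero", nneg)
    out = SurfaceFields(np.maximum(a_new, 0.0), np.maximum(c_new, 0.0), max(b_new, 0.0))
    out.validate(mesh)
    return out


def transfer_fields(old_mesh: PerimeterMesh, new_mesh: PerimeterMesh,
                    fields: SurfaceFields, conservative: bool = True,
                    max_distance: Optional[float] = None) -> SurfaceFields:
    """Remap surface fields from ``old_mesh`` to ``new_mesh``.

    Each new node is projected to its closest point on the old polygon and
    the fields are interpolated there (periodic cubic interpolation in old
    arc length).  With ``conservative=True`` the interpolated concentration
    is divided by the local stretch factor J = d(new arc)/d(old arc), so the
    line integral of each species is preserved: where the boundary expands
    the species are geometrically *diluted* — the mechanism by which growth
    of a pseudopod feeds back as an effective inhibitor.
    """
    if old_mesh is new_mesh or np.array_equal(old_mesh.nodes, new_mesh.nodes):
        return SurfaceFields(fields.a.copy(), fields.c.copy(), fields.b)
    if max_distance is None:
        max_distance = 0.25 * old_mesh.perimeter
    dist, seg, t = closest_point_query(old_mesh, new_mesh.nodes)
    if dist.max() > max_distance:
        raise TransferError(
            f"meshes too dissimilar for transfer (max projection distance {dist.max():.3g})")
    arcs_old = old_mesh.arc_positions
    h_old = old_mesh.element_lengths
    u = arcs_old[seg] + t * h_old[seg]  # old arc coordinate of each new node

    L_old = old_mesh.perimeter

    def _interp(values: np.ndarray) -> np.ndarray:
        x = np.concatenate([arcs_old, [L_old]])
        y = np.concatenate([values, [values[0]]])
        return CubicSpline(x, y, bc_type="periodic")(np.mod(u, L_old))

    a_new = _interp(fields.a)
    c_new = _interp(fields.c)
    if conservative:
        # local stretch: d(new arc)/d(old arc), centred differences on the ring
        s_new = new_mesh.arc_positions
        L_new = new_mesh.perimeter
        ds = (np.roll(s_new, -1) - np.roll(s_new, 1)) % L_new
        du = (np.roll(u, -1) - np.roll(u, 1)) % L_old
        J = ds / np.maximum(du, 1e-12 * L_old)
        # dilution is a smooth geometric effect: average out node-scale
        # projection noise and guard against fold-over artefacts
        win = max(3, new_mesh.n_nodes // 40)
        kernel = np.ones(win) / win
        n = len(J)
        J = np.convolve(np.concatenate([J[-win:], J, J[:win]]), kernel, mode="same")[win:win + n]
        J = np.clip(J, 0.5, 2.0)
        a_new = a_new / J
        c_new = c_new / J
    out = SurfaceFields(np.maximum(a_new, 0.0), np.maximum(c_new, 0.0), fields.b)
    out.validate(new_mesh)
    return out


def uniform_steady_state(params: ModelParameters, s0: float) -> Tuple[float, float, float]:
    """Spatially uniform rest state of the reaction system for constant signal.

    At a uniform steady state ``b* = a*`` (global inhibitor tracks the mean)
    and ``c* = (b_c/r_c) a*``; the remaining scalar equation for ``a*`` is
    solved by bracketed root finding.  With ``s0 = 0`` the trivial rest state
    ``(0, 0, 0)`` is returned.
    """
    if s0 < 0:
        raise ValueError("signal must be nonnegative")
    q = params.b_c / params.r_c

    def g(a: float) -> float:
        b = max(a, ZERO_FLOOR)
        prod = s0 * (a * a / b + params.basal_production) / (
            (params.inhibitor_offset + q * a) * (1.0 + params.activator_saturation * a * a))
        return prod - params.r_a * a

    if s0 == 0.0:
        return 0.0, 0.0, 0.0
    hi = 1.0
    while g(hi) > 0 and hi < 1e8:
        hi *= 2.0
    if hi >= 1e8:
        logger.warning("no positive steady state found; returning trivial root")
        return 0.0, 0.0, 0.0
    a_star = brentq(g, 1e-12, hi, xtol=1e-14, rtol=1e-14)
    return float(a_star), float(a_star), float(q * a_star)
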