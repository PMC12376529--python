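"""Energies, forces and overdamped dynamics of the pressurized elastic shell.

The nuclear envelope is a closed triangulated shell whose vertices move by
a damped, inertia-free (overdamped Langevin, zero temperature) equation

    eta * dr_i/dt = -grad_i U + F_i^rep + P_i^ext

with total shape energy U = U_e + U_b + U_V:

* stretching   U_e = sum_edges Ke/2 (l - l0)^2
* bending      U_b = sum_edges Kb/2 |n1_hat - n2_hat|^2
* volume       U_V = sum_faces KV/2 (V_f - V0)^2

where V_f is the signed tetrahedron volume of face f against the origin,
so sum_f V_f is the exact enclosed volume.  A 6-12 vertex-vertex repulsion
acts between non-bonded vertices closer than a threshold D, and a uniform
external pressure P (the coarse-grained cytoskeletal load; higher on
stiffer substrates) contributes the non-conservative-looking but exactly
potential force -P * grad_i V.

The individual term functions below are straightforward NumPy and serve as
the readable reference; production integration runs through the fused
numba kernels in :mod:`nucleomech._kernels`, which the test suite checks
against these functions and against finite differences.

Because a perfectly symmetric sphere is a (unstable) fixed point of the
deterministic flow, runs start from a seeded Gaussian radial perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .errors import IntegrationError, NumericalDegeneracyError
from .shell_mesh import TriangulatedShell, build_icosphere

__all__ = [
    "ShellParameters",
    "ShellState",
    "ShellTrajectory",
    "preset_parameters",
    "reference_shell",
    "REFERENCE_EDGE_LENGTH",
    "stretching_term",
    "bending_term",
    "volume_term",
    "repulsion_forces",
    "pressure_forces",
    "total_potential",
    "radial_perturbation",
    "relax_shell",
    "advance",
    "simulate",
    "save_trajectory",
    "load_trajectory",
]

#: Rest edge length of the reference normalization.
#:
#: The parameter table fixes no absolute length unit.  Normalizing the mesh
#: to unit rest edge length makes the repulsion law meaningful -- its 6-12
#: crossover sits exactly at the rest spacing (the pair force vanishes at
#: r = 1) and the cutoff D = 0.9 engages only below rest spacing -- and
#: puts the shell in the membrane-dominated regime where the pressure
#: presets drive a genuine buckling cascade.  At level 4 the sphere radius
#: is then ~13.2 rest edge lengths.
REFERENCE_EDGE_LENGTH = 1.0

_PRESET_PRESSURES = {"soft": 500.0, "medium": 600.0, "stiff": 750.0}


@dataclass(frozen=True)
class ShellParameters:
    """Mechanical constants and run controls.

    The mechanical defaults are the published parameter set: Ke = 1000,
    Kb = 4, KV = 3, Kr = 1e-13, eta = 1, dt = 0.005, D = 0.9, with the
    external pressure P_ext in {500, 600, 750} (in units of the
    characteristic pressure P0) for the soft / medium / stiff substrate
    conditions.  P0, F0 and t0 are the characteristic pressure, force and
    time units; all are 1 in simulation units.

    ``dt`` is the reporting/bookkeeping step; the integrator subdivides it
    adaptively as the local stiffness requires (see module docstring of
    :mod:`nucleomech._kernels`).
    """

    K_e: float = 1000.0
    K_b: float = 4.0
    K_V: float = 3.0
    K_r: float = 1e-13
    D: float = 0.9
    eta: float = 1.0
    dt: float = 0.005
    P_ext: float = 600.0
    P0: float = 1.0
    F0: float = 1.0
    t0: float = 1.0
    perturbation_amplitude: float = 1e-3  # in units of l0
    seed: int = 0
    contact_distance: float | None = None  # default: 0.1 * l0
    t_max: float = 5.0
    include_bonded_repulsion: bool = False

    def __post_init__(self):
        if min(self.K_e, self.K_b, self.K_V, self.K_r) < 0:
            raise ValueError("moduli must be nonnegative")
        if self.dt <= 0 or self.eta <= 0 or self.D <= 0:
            raise ValueError("dt, eta and D must be positive")

    def resolved_contact_distance(self, shell: TriangulatedShell) -> float:
        return 0.1 * shell.l0 if self.contact_distance is None else self.contact_distance


def preset_parameters(substrate: str, **overrides) -> ShellParameters:
    """Parameters for a named substrate-stiffness condition.

    ``substrate`` is 'soft', 'medium' or 'stiff', mapping to external
    pressures 500, 600 and 750 P0.
    """
    try:
        p = _PRESET_PRESSURES[substrate]
    except KeyError:
        raise ValueError(f"unknown substrate preset {substrate!r}; use soft/medium/stiff")
    return ShellParameters(P_ext=p, **overrides)


def reference_shell(subdivision_level: int = 4) -> TriangulatedShell:
    """The normalized shell used for substrate-stiffness simulations.

    An icosphere with unit mean rest edge length (see
    :data:`REFERENCE_EDGE_LENGTH`).
    """
    return build_icosphere(subdivision_level, l0_target=REFERENCE_EDGE_LENGTH)


@dataclass
class ShellState:
    """Vertex positions at a time point, plus the termination flag."""

    positions: np.ndarray
    time: float = 0.0
    breakdown: bool = False

    def copy(self) -> "ShellState":
        return ShellState(self.positions.copy(), self.time, self.breakdown)


@dataclass
class ShellTrajectory:
    """Sampled states of one run.

    ``positions`` has shape (n_samples, V, 3); ``sample_times`` starts at 0
    and increases strictly.  ``breakdown_time`` is None if the run reached
    t_max without membrane self-contact.
    """

    sample_times: np.ndarray
    positions: np.ndarray
    stride: int
    breakdown_time: float | None = None

    def state(self, k: int) -> ShellState:
        broke = self.breakdown_time is not None and k == len(self.sample_times) - 1
        return ShellState(self.positions[k].copy(), float(self.sample_times[k]), broke)

    def __len__(self) -> int:
        return len(self.sample_times)


# ---------------------------------------------------------------------------
# Reference (NumPy) energy terms


def _positions(state) -> np.ndarray:
    return state.positions if isinstance(state, ShellState) else np.asarray(state, dtype=float)


def stretching_term(shell: TriangulatedShell, state, params: ShellParameters):
    """Edge-spring energy sum Ke/2 (l - l0)^2 and its analytic forces."""
    pos = _positions(state)
    d = pos[shell.edges[:, 0]] - pos[shell.edges[:, 1]]
    l = np.linalg.norm(d, axis=1)
    if (l < 1e-12).any():
        raise NumericalDegeneracyError("zero-length edge in stretching term")
    ext = l - shell.l0
    energy = 0.5 * params.K_e * np.sum(ext**2)
    g = (params.K_e * ext / l)[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, shell.edges[:, 0], -g)
    np.add.at(forces, shell.edges[:, 1], g)
    return energy, forces


def _face_normals(pos, faces):
    a, b, c = pos[faces[:, 0]], pos[faces[:, 1]], pos[faces[:, 2]]
    N = np.cross(b - a, c - a)
    norms = np.linalg.norm(N, axis=1)
    return N, norms


def bending_term(shell: TriangulatedShell, state, params: ShellParameters):
    """Dihedral energy sum Kb/2 |n1_hat - n2_hat|^2 over edges, with forces.

    The gradient flows through the *normalized* face normals; with
    g = dE/dN for a face (a, b, c) the chain rule gives
    dE/dr_a = (r_b - r_c) x g and cyclic permutations.
    """
    pos = _positions(state)
    faces = shell.faces
    N, norms = _face_normals(pos, faces)
    if (norms < 1e-12).any():
        raise NumericalDegeneracyError("zero-area face in bending term")
    nhat = N / norms[:, None]
    f1, f2 = shell.edge_faces[:, 0], shell.edge_faces[:, 1]
    cosang = np.einsum("ij,ij->i", nhat[f1], nhat[f2])
    energy = params.K_b * np.sum(1.0 - cosang)

    # accumulate dE/dN per face
    dEdN = np.zeros_like(N)
    w1 = -params.K_b * (nhat[f2] - cosang[:, None] * nhat[f1]) / norms[f1][:, None]
    w2 = -params.K_b * (nhat[f1] - cosang[:, None] * nhat[f2]) / norms[f2][:, None]
    np.add.at(dEdN, f1, w1)
    np.add.at(dEdN, f2, w2)

    forces = np.zeros_like(pos)
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    forces_a = -np.cross(pos[b] - pos[c], dEdN)
    forces_b = -np.cross(pos[c] - pos[a], dEdN)
    forces_c = -np.cross(pos[a] - pos[b], dEdN)
    np.add.at(forces, a, forces_a)
    np.add.at(forces, b, forces_b)
    np.add.at(forces, c, forces_c)
    return energy, forces


def _volume_gradients(pos, faces):
    """Per-face gradients of the signed tetra volume w.r.t. its 3 vertices."""
    a, b, c = pos[faces[:, 0]], pos[faces[:, 1]], pos[faces[:, 2]]
    return np.cross(b, c) / 6.0, np.cross(c, a) / 6.0, np.cross(a, b) / 6.0


def volume_term(shell: TriangulatedShell, state, params: ShellParameters):
    """Per-element volume elasticity sum KV/2 (V_f - V0)^2 with forces.

    Each V_f is the signed tetrahedron volume of face f against the
    *instantaneous centroid*, which makes the energy translation invariant
    (the per-face volumes against a fixed origin are not); the analytic
    gradient includes the centroid chain term.  The total sum_f V_f is
    reference-independent either way.
    """
    pos = _positions(state)
    faces = shell.faces
    rel = pos - pos.mean(axis=0)
    ga, gb, gc = _volume_gradients(rel, faces)
    Vf = np.einsum("ij,ij->i", rel[faces[:, 0]], 6.0 * ga) / 6.0  # a' . (b' x c')
    dV = Vf - shell.V0
    energy = 0.5 * params.K_V * np.sum(dV**2)
    forces = np.zeros_like(pos)
    coef = (params.K_V * dV)[:, None]
    np.add.at(forces, faces[:, 0], -coef * ga)
    np.add.at(forces, faces[:, 1], -coef * gb)
    np.add.at(forces, faces[:, 2], -coef * gc)
    # dV_f/d(centroid) = -N_f/6 with N_f the unnormalized face normal;
    # every vertex moves the centroid by 1/V_count
    a, b, c = rel[faces[:, 0]], rel[faces[:, 1]], rel[faces[:, 2]]
    Nf = np.cross(b - a, c - a)
    G = (coef * Nf / 6.0).sum(axis=0)
    forces += G / len(pos)
    return energy, forces


def pressure_forces(shell: TriangulatedShell, state, params: ShellParameters):
    """External pressure force -P * grad_i V (inward on an outward mesh)."""
    pos = _positions(state)
    faces = shell.faces
    ga, gb, gc = _volume_gradients(pos, faces)
    P = params.P_ext * params.P0
    forces = np.zeros_like(pos)
    np.add.at(forces, faces[:, 0], -P * ga)
    np.add.at(forces, faces[:, 1], -P * gb)
    np.add.at(forces, faces[:, 2], -P * gc)
    return forces


def repulsion_forces(shell: TriangulatedShell, state, params: ShellParameters):
    """6-12 repulsion between non-bonded vertices closer than D.

    The pair force is -Kr * (d^-6 - d^-12) * (r_i - r_j): purely repulsive
    below the crossover distance 1 and vanishing exactly at d = 1.  Pairs
    sharing a mesh edge are excluded by default (the edge spring already
    acts there); set ``include_bonded_repulsion`` to keep them.
    """
    pos = _positions(state)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=params.D, output_type="ndarray")
    forces = np.zeros_like(pos)
    if len(pairs) == 0:
        return forces
    if not params.include_bonded_repulsion:
        n = len(pos)
        bonded = set((int(i) * n + int(j)) for i, j in np.sort(shell.edges, axis=1))
        keys = pairs[:, 0] * n + pairs[:, 1]
        keep = np.array([k not in bonded for k in keys])
        pairs = pairs[keep]
        if len(pairs) == 0:
            return forces
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    dist = np.linalg.norm(d, axis=1)
    if (dist < 1e-9).any():
        raise NumericalDegeneracyError("coincident vertices inside the hard core")
    g = params.K_r * (dist**-12 - dist**-6)
    np.add.at(forces, pairs[:, 0], g[:, None] * d)
    np.add.at(forces, pairs[:, 1], -g[:, None] * d)
    return forces


def total_potential(shell: TriangulatedShell, state, params: ShellParameters) -> float:
    """Total shape energy U = U_e + U_b + U_V (repulsion and pressure act
    as forces in the equation of motion, not through U)."""
    return (
        stretching_term(shell, state, params)[0]
        + bending_term(shell, state, params)[0]
        + volume_term(shell, state, params)[0]
    )


def radial_perturbation(shell: TriangulatedShell, amplitude: float, seed: int) -> ShellState:
    """Rest positions plus seeded Gaussian radial noise of sd amplitude*l0."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E11]))
    pos = shell.vertices.copy()
    if amplitude > 0:
        r = np.linalg.norm(pos, axis=1)
        rhat = pos / r[:, None]
        pos = pos + rhat * rng.normal(0.0, amplitude * shell.l0, len(pos))[:, None]
    return ShellState(pos, time=0.0, breakdown=False)


def relax_shell(shell: TriangulatedShell, params: ShellParameters | None = None,
                gtol: float = 1e-9, maxiter: int = 5000) -> TriangulatedShell:
    """Settle the shell into its zero-pressure elastic equilibrium.

    The icosphere is not exactly equilateral, so with a *shared* rest
    length l0 the as-built sphere carries a small prestress and is not an
    exact equilibrium of U.  This minimizes U (stretching + bending +
    volume, no pressure) over the vertex positions with L-BFGS and returns
    a shell whose vertices are the relaxed configuration; l0, V0 and the
    topology are unchanged.  The relaxed shell is a genuine fixed point of
    the unpressurized dynamics up to the gradient tolerance.
    """
    from scipy.optimize import minimize

    if params is None:
        params = ShellParameters(P_ext=0.0)
    shape = shell.vertices.shape

    def fun(x):
        pos = x.reshape(shape)
        e1, f1 = stretching_term(shell, pos, params)
        e2, f2 = bending_term(shell, pos, params)
        e3, f3 = volume_term(shell, pos, params)
        return e1 + e2 + e3, -(f1 + f2 + f3).ravel()

    res = minimize(fun, shell.vertices.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 0.0,
                            "maxcor": 30})
    pos = res.x.reshape(shape)
    pos = pos - pos.mean(axis=0)
    return replace(shell, vertices=np.ascontiguousarray(pos))


# ---------------------------------------------------------------------------
# Integration driver


class _Driver:
    """Holds the persistent integrator state between macro steps."""

    def __init__(self, shell: TriangulatedShell, state: ShellState, params: ShellParameters):
        self.shell = shell
        self.params = params
        self.pos = np.ascontiguousarray(state.positions, dtype=np.float64).copy()
        self.t = float(state.time)
        n = len(self.pos)
        se = np.sort(shell.edges, axis=1)
        if params.include_bonded_repulsion:
            self.bonded_keys = np.empty(0, dtype=np.int64)
        else:
            self.bonded_keys = np.sort(se[:, 0].astype(np.int64) * n + se[:, 1])
        self.contact = params.resolved_contact_distance(shell)
        self.cutoff = max(params.D, self.contact)
        self.skin = 0.5 * self.cutoff
        self.pairs = _kernels.build_pairs(self.pos, self.cutoff + self.skin, self.bonded_keys)
        self.ref_pos = self.pos.copy()
        self.disp_acc = 0.0
        self.Vref = shell.V0 * shell.n_faces
        self.F = np.zeros_like(self.pos)
        P = params.P_ext * params.P0
        out = _kernels.forces_energy(
            self.pos, shell.faces, shell.edges, shell.edge_faces, self.pairs,
            shell.l0, shell.V0, params.K_e, params.K_b, params.K_V, params.K_r,
            params.D, P, self.Vref, self.F)
        self.E = out[0]
        self.Vt = out[1]
        self.fmemb = out[6]
        self.dt_try = min(params.dt, 1e-5 * params.eta)
        self.breakdown = bool(state.breakdown)

    def step_to(self, t_target: float) -> None:
        p = self.params
        sh = self.shell
        (self.t, self.dt_try, self.E, self.disp_acc, status, n_sub, n_rej,
         self.pairs, Vt, fmemb, min_d) = _kernels.integrate(
            self.pos, self.F, sh.faces, sh.edges, sh.edge_faces,
            self.bonded_keys, self.pairs, self.ref_pos,
            sh.l0, sh.V0, p.K_e, p.K_b, p.K_V, p.K_r, p.D,
            p.P_ext * p.P0, p.eta, self.Vref,
            self.contact, self.cutoff, self.skin,
            self.t, t_target, self.dt_try, p.dt,
            self.E, self.disp_acc, 1e-9)
        if n_sub > 0:
            self.Vt = Vt
            self.fmemb = fmemb
        if status == _kernels.STEP_COLLAPSE:
            raise IntegrationError(
                f"substep collapsed below {1e-15} at t={self.t:.6g} "
                f"(max force {np.abs(self.F).max():.3g})",
                time=self.t, max_force=float(np.abs(self.F).max()))
        if status == _kernels.HARD_CORE:
            raise NumericalDegeneracyError(
                f"vertices coincided within the hard core at t={self.t:.6g}")
        if status == _kernels.BREAKDOWN:
            self.breakdown = True

    def state(self) -> ShellState:
        return ShellState(self.pos.copy(), self.t, self.breakdown)


def advance(shell: TriangulatedShell, state: ShellState, params: ShellParameters) -> ShellState:
    """One macro time step ``params.dt`` of the overdamped dynamics.

    The macro step is internally subdivided as stability requires; the
    breakdown flag is set (and the state returned early) if any non-bonded
    vertex pair comes closer than the contact distance.
    """
    if state.breakdown:
        raise ValueError("cannot advance a state past membrane breakdown")
    drv = _Driver(shell, state, params)
    drv.step_to(state.time + params.dt)
    return drv.state()


def simulate(shell: TriangulatedShell, params: ShellParameters,
             sample_stride: int = 1) -> ShellTrajectory:
    """Run the seeded, perturbed shell to ``t_max`` or membrane contact.

    Applies the seeded Gaussian radial perturbation (amplitude
    ``perturbation_amplitude * l0``), integrates the damped gradient flow,
    and records a snapshot every ``sample_stride`` macro steps (of length
    ``dt`` each).  Identical parameters and seed give identical output.
    """
    if params.t_max <= 0:
        raise ValueError("t_max must be positive")
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    state0 = radial_perturbation(shell, params.perturbation_amplitude, params.seed)
    drv = _Driver(shell, state0, params)
    interval = sample_stride * params.dt
    n_samples = int(np.floor(params.t_max / interval + 1e-9))
    times = [0.0]
    snaps = [drv.pos.copy()]
    breakdown_time = None
    for k in range(1, n_samples + 1):
        drv.step_to(k * interval)
        times.append(drv.t)
        snaps.append(drv.pos.copy())
        if drv.breakdown:
            breakdown_time = drv.t
            break
    return ShellTrajectory(
        sample_times=np.array(times),
        positions=np.array(snaps),
        stride=sample_stride,
        breakdown_time=breakdown_time,
    )


def save_trajectory(traj: ShellTrajectory, path: str | Path) -> None:
    np.savez_compressed(
        path,
        sample_times=traj.sample_times,
        positions=traj.positions,
        stride=np.int64(traj.stride),
        breakdown_time=np.float64(np.nan if traj.breakdown_time is None else traj.breakdown_time),
    )


def load_trajectory(path: str | Path) -> ShellTrajectory:
    with np.load(path) as z:
        bt = float(z["breakdown_time"])
        return ShellTrajectory(
            sample_times=z["sample_times"],
            positions=z["positions"],
            stride=int(z["stride"]),
            breakdown_time=None if np.isnan(bt) else bt,
        )
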