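"""Observables and event detection on shell trajectories.

A pressurized run passes through three morphological stages: the *smooth*
(near-spherical) shell, a faceted low-mode *buckyball* pattern once the
first buckling sets in, and a deeply folded *labyrinth* once short
wavelengths take over.  Two event times summarize a run:

* ``t_first`` -- when the surface first leaves the smooth stage;
* ``t_second`` -- the "accelerated collapse": the time at which the
  relative-volume curve dV/V0 bends downward the hardest (most negative
  smoothed second derivative), marking the transition into the
  labyrinthine regime.

The volume-curve detector is authoritative for ``t_second``; the
spectral stage classifier provides ``t_first`` and an independent
cross-check of the buckyball-to-labyrinth flip.

Membrane tension is reported through the mean edge spring force
F_memb = <Ke (l - l0)> / F0, the only tension proxy fully determined by
the model's stated quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.special import sph_harm_y

from .shell_mesh import TriangulatedShell, enclosed_volume
from .shell_model import ShellParameters, ShellState, ShellTrajectory

__all__ = [
    "MorphoSeries",
    "total_volume",
    "volume_change_series",
    "membrane_tension_series",
    "displacement_field",
    "classify_stage",
    "detect_buckling_times",
    "morpho_series",
]

STAGES = ("smooth", "buckyball", "labyrinth")


@dataclass
class MorphoSeries:
    """Per-sample observables of one run plus detected event times."""

    times: np.ndarray
    dV_over_V0: np.ndarray
    F_memb_over_F0: np.ndarray
    stage: list[str]
    t_first: float | None
    t_second: float | None
    t_breakdown: float | None


def total_volume(state: ShellState, shell: TriangulatedShell) -> float:
    """Enclosed volume by signed-tetrahedron summation (orientation-aware)."""
    pos = state.positions if isinstance(state, ShellState) else np.asarray(state)
    return enclosed_volume(pos, shell.faces)


def volume_change_series(traj: ShellTrajectory, shell: TriangulatedShell) -> np.ndarray:
    """(V(t) - V(0)) / V(0) per sample; first entry exactly zero."""
    vols = np.array([enclosed_volume(p, shell.faces) for p in traj.positions])
    return (vols - vols[0]) / vols[0]


def membrane_tension_series(traj: ShellTrajectory, shell: TriangulatedShell,
                            params: ShellParameters) -> np.ndarray:
    """Mean edge spring force Ke*(l - l0), per sample, in units of F0."""
    i, j = shell.edges[:, 0], shell.edges[:, 1]
    out = np.empty(len(traj))
    for k, pos in enumerate(traj.positions):
        l = np.linalg.norm(pos[i] - pos[j], axis=1)
        out[k] = params.K_e * np.mean(l - shell.l0)
    return out / params.F0


def displacement_field(state: ShellState, reference_state: ShellState) -> np.ndarray:
    """Per-vertex displacement magnitude after removing the centroid shift."""
    p = state.positions if isinstance(state, ShellState) else np.asarray(state)
    q = reference_state.positions if isinstance(reference_state, ShellState) else np.asarray(reference_state)
    if p.shape != q.shape:
        raise ValueError(f"vertex count mismatch: {p.shape} vs {q.shape}")
    d = (p - p.mean(axis=0)) - (q - q.mean(axis=0))
    return np.linalg.norm(d, axis=1)


# ---------------------------------------------------------------------------
# Spectral stage classification


def _real_harmonic_basis(directions: np.ndarray, lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Real spherical-harmonic design matrix evaluated at unit directions.

    Returns (basis, degrees) with one column per (l, m), l <= lmax.
    """
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    degrees = []
    for l in range(lmax + 1):
        Y = sph_harm_y(l, np.arange(0, l + 1), theta[:, None], phi[:, None])
        cols.append(Y[:, 0].real[:, None])
        degrees.append(l)
        for m in range(1, l + 1):
            cols.append(np.sqrt(2.0) * Y[:, m].real[:, None])
            cols.append(np.sqrt(2.0) * Y[:, m].imag[:, None])
            degrees += [l, l]
    return np.hstack(cols), np.array(degrees)


_BASIS_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _projection_operator(reference_dirs: np.ndarray, lmax: int, cache_key=None):
    """Pseudoinverse of the harmonic design matrix, cached per reference.

    ``cache_key`` identifies the reference-positions array; without it the
    operator is rebuilt each call (correct, just slower).
    """
    key = None if cache_key is None else (*cache_key, lmax)
    if key is not None and key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    B, degrees = _real_harmonic_basis(reference_dirs, lmax)
    out = (np.linalg.pinv(B), degrees)
    if key is not None:
        if len(_BASIS_CACHE) > 8:
            _BASIS_CACHE.pop(next(iter(_BASIS_CACHE)))
        _BASIS_CACHE[key] = out
    return out


def _radial_deviation(state, reference_state):
    """Radial deviation from the reference shape, uniform part removed.

    u_i = (|r_i - centroid| - |ref_i - ref centroid|) minus its mean: the
    discrete rest shell is not perfectly round (shared-l0 prestress), so
    deviations are measured against the rest radius profile, and a uniform
    inflation/shrinkage (an l = 0 motion) does not count as waviness.
    Also returns the reference directions and mean radius.
    """
    p = state.positions if isinstance(state, ShellState) else np.asarray(state)
    q = reference_state.positions if isinstance(reference_state, ShellState) else np.asarray(reference_state)
    if p.shape != q.shape:
        raise ValueError("state and reference vertex counts differ")
    qc = q - q.mean(axis=0)
    r_ref = np.linalg.norm(qc, axis=1)
    dirs = qc / r_ref[:, None]
    pc = p - p.mean(axis=0)
    u = np.linalg.norm(pc, axis=1) - r_ref
    u = u - u.mean()
    return u, dirs, float(r_ref.mean())


def radial_power_spectrum(state: ShellState, reference_state: ShellState,
                          lmax: int = 30) -> np.ndarray:
    """Power per spherical-harmonic degree of the radial deviation field.

    The deviation from the reference shape (see ``_radial_deviation``) is
    projected by least squares onto real harmonics evaluated at the
    *reference* sphere directions; entry l of the result is sum_m a_lm^2.
    """
    u, dirs, _ = _radial_deviation(state, reference_state)
    # the least-squares projection needs fewer basis functions than sample
    # points; cap the band limit on coarse meshes
    lmax = min(lmax, int(np.sqrt(len(dirs))) - 2)
    q = reference_state.positions if isinstance(reference_state, ShellState) else reference_state
    pinv, degrees = _projection_operator(dirs, lmax, cache_key=(id(q), len(dirs)))
    coeffs = pinv @ u
    power = np.zeros(lmax + 1)
    np.add.at(power, degrees, coeffs**2)
    return power


def classify_stage(state: ShellState, shell: TriangulatedShell,
                   reference_state: ShellState, *, eps_smooth: float = 0.01,
                   q_concentration: float = 0.5, l_low: int = 10,
                   lmax: int = 30) -> str:
    """Label a snapshot smooth / buckyball / labyrinth.

    smooth      rms radial fluctuation (about the rest shape, uniform
                shrink removed) below ``eps_smooth`` * mean rest radius;
    buckyball   a single degree l in [2, l_low] holds at least
                ``q_concentration`` of the non-trivial (l >= 2) power;
    labyrinth   otherwise (power spread over many / high degrees).
    """
    u, _, R = _radial_deviation(state, reference_state)
    if np.sqrt(np.mean(u**2)) < eps_smooth * R:
        return "smooth"
    power = radial_power_spectrum(state, reference_state, lmax=lmax)
    p_nontrivial = power[2:].sum()
    if p_nontrivial <= 0:
        return "smooth"
    if power[2 : l_low + 1].max() >= q_concentration * p_nontrivial:
        return "buckyball"
    return "labyrinth"


# ---------------------------------------------------------------------------
# Event detection


def detect_buckling_times(times: np.ndarray, dV_over_V0: np.ndarray,
                          stages: list[str] | None = None, *,
                          window: int = 11, rel_floor: float = 0.2):
    """First-buckling and accelerated-collapse times from a morpho series.

    ``t_first`` is the first time the stage classifier leaves 'smooth'
    (None when no stage labels are given or the run never leaves smooth).
    ``t_second`` is the *last* prominent bend of the volume curve at or
    after ``t_first``: the final local maximum of the smoothed
    second-derivative magnitude that clears the noise floor.  A bend can
    be an accelerating collapse (negative curvature) or its arrest
    (positive curvature); taking the last one selects the late transition
    event rather than the initial pressurization transient.  Returns None
    for ``t_second`` when no bend clears the floor (e.g. a strictly
    linear decline).  The detector commutes with a uniform rescaling of
    the time axis.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(dV_over_V0, dtype=float)
    if len(times) < 20:
        raise ValueError("need at least 20 samples to detect buckling times")

    t_first = None
    if stages is not None:
        for t, s in zip(times, stages):
            if s != "smooth":
                t_first = float(t)
                break

    w = min(window, len(y) if len(y) % 2 == 1 else len(y) - 1)
    if w < 5:
        w = 5
    dt = float(np.median(np.diff(times)))
    d2 = savgol_filter(y, window_length=w, polyorder=2, deriv=2, delta=dt)

    lo = 0
    if t_first is not None:
        lo = int(np.searchsorted(times, t_first))
    # ignore filter edge effects at the very ends
    edge = w // 2
    valid = np.arange(max(lo, edge), len(y) - edge)
    if len(valid) == 0:
        return t_first, None
    seg = np.abs(d2[valid])
    # noise floor: a real bend must exceed the curvature a mere trend of
    # this amplitude would have over the whole observation span
    span = times[-1] - times[0]
    floor = rel_floor * max(np.max(np.abs(y)), 1e-30) / span**2
    if seg.max() <= floor:
        return t_first, None
    # local maxima of the curvature magnitude above the floor; fall back
    # to the global maximum when the profile is monotone
    interior = np.arange(1, len(seg) - 1)
    is_peak = (seg[interior] >= seg[interior - 1]) & (seg[interior] > seg[interior + 1])
    peaks = interior[is_peak & (seg[interior] > floor)]
    k = int(peaks[-1]) if len(peaks) else int(np.argmax(seg))
    return t_first, float(times[valid[k]])


def morpho_series(traj: ShellTrajectory, shell: TriangulatedShell,
                  params: ShellParameters, *, classify: bool = True,
                  classify_stride: int = 1, lmax: int = 30) -> MorphoSeries:
    """Assemble the full observable series and detected events for a run."""
    dv = volume_change_series(traj, shell)
    fm = membrane_tension_series(traj, shell, params)
    # stages measure deviation from the *rest* shape; the shell's own
    # vertices (not the perturbed first sample) are the reference, which
    # also lets the harmonic projection operator be reused across runs
    ref = ShellState(shell.vertices)
    stages: list[str] | None = None
    if classify:
        stages = []
        last = "smooth"
        for k in range(len(traj)):
            if k % classify_stride == 0:
                last = classify_stage(traj.state(k), shell, ref, lmax=lmax)
            stages.append(last)
    if len(traj) >= 20:
        t_first, t_second = detect_buckling_times(traj.sample_times, dv, stages)
    else:
        # too short for curvature-based detection: onset from stages only
        t_second = None
        t_first = None
        if stages is not None:
            for t, s in zip(traj.sample_times, stages):
                if s != "smooth":
                    t_first = float(t)
                    break
    return MorphoSeries(
        times=traj.sample_times.copy(),
        dV_over_V0=dv,
        F_memb_over_F0=fm,
        stage=stages if stages is not None else ["smooth"] * len(traj),
        t_first=t_first,
        t_second=t_second,
        t_breakdown=traj.breakdown_time,
    )
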