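"""Seeded generators emulating the pipeline's input data.

Each generator is a pure function of its arguments (seed included):
repeated calls are bit-identical, and every generator returns its ground
truth alongside the data so recovery tests never hand-copy numbers.
Separate fixed stream keys per generator kind keep the draws independent
of one another even under a shared seed.

What is emulated (and what is not): wrinkled-nucleus images carry a
filamentous above-mean texture of exactly known pixel fraction, FRET
pairs a ring-localized sensor signal of known ratio, tracks the three
canonical motion models, and time courses Richards sigmoids on the
20-min / 36-h live-imaging grid -- all with optional additive Gaussian
noise only (no PSF, shot noise or camera artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from .chromatin_msd import Track
from .kinetics import TimeSeries, richards
from .nucleus_quant import IntensityImage, RegionMask, make_ring_mask
from .shell_mesh import TriangulatedShell
from .shell_model import ShellState, radial_perturbation

__all__ = [
    "GeneratorSpec",
    "gen_wrinkled_nucleus_image",
    "gen_fret_pair",
    "gen_tracks",
    "gen_sigmoid_timecourse",
    "perturb_shell",
]

_STREAM = {"nucleus_image": 11, "fret_pair": 12, "tracks": 13, "sigmoid_series": 14}


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[kind]]))


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset."""

    seed: int
    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)

    def generate(self):
        fn = {
            "nucleus_image": gen_wrinkled_nucleus_image,
            "fret_pair": gen_fret_pair,
            "tracks": gen_tracks,
            "sigmoid_series": gen_sigmoid_timecourse,
        }[self.kind]
        return fn(seed=self.seed, **self.parameters)


def _ellipse_mask(shape, axes, center=None) -> np.ndarray:
    ny, nx = shape
    cy, cx = center if center is not None else (ny / 2.0, nx / 2.0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    a, b = axes  # semi-axes (rows, cols)
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def gen_wrinkled_nucleus_image(seed: int = 0, *, wrinkle_fraction: float = 0.3,
                               contrast: float = 3.0, noise_sd: float = 0.0,
                               shape=(256, 256), axes=(50, 100), base: float = 100.0):
    """Elliptical nucleus with a bright filamentous texture of known area.

    Exactly ``round(wrinkle_fraction * area)`` nucleus pixels are set to
    ``contrast * base`` along thread-like ridges (the near-zero set of a
    smooth random field); the rest of the nucleus sits at ``base`` and the
    background at 0.  With ``contrast > 1`` and no noise the mean-threshold
    wrinkling fraction equals the planted fraction exactly.

    Returns ``(IntensityImage, RegionMask, true_wrinkle_fraction)``.
    """
    if not (0 <= wrinkle_fraction < 1):
        raise ValueError("wrinkle_fraction must be in [0, 1); the mean threshold "
                         "degenerates on a fully bright nucleus")
    if contrast <= 1:
        raise ValueError("contrast must exceed 1 for wrinkles to be bright")
    rng = _rng(seed, "nucleus_image")
    mask = _ellipse_mask(shape, axes)
    n = int(mask.sum())
    k = int(round(wrinkle_fraction * n))

    img = np.zeros(shape, dtype=float)
    img[mask] = base
    if k > 0:
        fil = gaussian_filter(rng.standard_normal(shape), sigma=6.0)
        score = np.abs(fil)
        score[~mask] = np.inf
        flat = np.argpartition(score.ravel(), k - 1)[:k]
        img.ravel()[flat] = contrast * base
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd * base, shape), 0.0, None)
    return IntensityImage(img), RegionMask(mask, kind="nucleus"), k / n


def gen_fret_pair(seed: int = 0, *, true_ratio: float = 1.5,
                  donor_level: float = 150.0, donor_bg: float = 100.0,
                  acceptor_bg: float = 100.0, noise_frac: float = 0.0,
                  shape=(256, 256), radius: int = 60, thickness: int = 4):
    """Donor/acceptor image pair with a ring-localized sensor of known ratio.

    The donor carries ``donor_bg + donor_level`` on the ring and its
    background elsewhere; the acceptor is constructed pixelwise as
    ``acceptor_bg + true_ratio * (donor - donor_bg)``.  Optional Gaussian
    noise of sd ``noise_frac * donor_level`` is added to both channels.

    Returns ``(acceptor, donor, ring RegionMask, true_ratio)``.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if donor_level <= 0:
        raise ValueError("donor signal must exceed its background")
    ny, nx = shape
    if radius + 1 >= min(ny, nx) / 2:
        raise ValueError("ring does not fit inside the image bounds")
    rng = _rng(seed, "fret_pair")
    nucleus = _ellipse_mask(shape, (radius, radius))
    ring = make_ring_mask(RegionMask(nucleus, kind="nucleus"), thickness=thickness)

    donor = np.full(shape, donor_bg, dtype=float)
    donor[ring.mask] += donor_level
    acceptor = acceptor_bg + true_ratio * (donor - donor_bg)
    if noise_frac > 0:
        sd = noise_frac * donor_level
        donor = donor + rng.normal(0.0, sd, shape)
        acceptor = acceptor + rng.normal(0.0, sd, shape)
    return (IntensityImage(np.clip(acceptor, 0, None)),
            IntensityImage(np.clip(donor, 0, None)), ring, true_ratio)


def gen_tracks(seed: int = 0, *, model: str = "brownian", n_tracks: int = 1,
               n_frames: int = 4285, frame_interval: float = 0.07,
               D: float = 0.01, sigma: float = 0.1, theta: float = 1.0,
               v=(0.1, 0.0)):
    """2-D particle tracks from one of three motion models.

    brownian      free diffusion with coefficient ``D`` (MSD = 4 D tau);
    confined_ou   Ornstein-Uhlenbeck tether, per-axis stationary sd
                  ``sigma`` and correlation time ``theta`` (exact
                  discretization; long-lag MSD plateau 4 sigma^2);
    ballistic     straight-line motion at velocity ``v`` (MSD = |v|^2 tau^2).

    Defaults follow the live-imaging cadence: 0.07 s frames for 5 min.
    Returns ``(list of Track, truth dict)``.
    """
    rng = _rng(seed, "tracks")
    dt = frame_interval
    tracks = []
    if model == "brownian":
        if D <= 0:
            raise ValueError("D must be positive")
        truth = {"model": model, "D": D}
        for i in range(n_tracks):
            steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), (n_frames - 1, 2))
            pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            tracks.append(Track(pos, dt, id=f"brownian_{i}"))
    elif model == "confined_ou":
        if sigma <= 0 or theta <= 0:
            raise ValueError("sigma and theta must be positive")
        truth = {"model": model, "sigma": sigma, "theta": theta,
                 "plateau": 4.0 * sigma**2}
        a = np.exp(-dt / theta)
        innov_sd = sigma * np.sqrt(1.0 - a * a)
        for i in range(n_tracks):
            pos = np.empty((n_frames, 2))
            pos[0] = rng.normal(0.0, sigma, 2)
            noise = rng.normal(0.0, innov_sd, (n_frames - 1, 2))
            for k in range(1, n_frames):
                pos[k] = a * pos[k - 1] + noise[k - 1]
            tracks.append(Track(pos, dt, id=f"ou_{i}"))
    elif model == "ballistic":
        vel = np.broadcast_to(np.asarray(v, dtype=float), (2,))
        truth = {"model": model, "v": vel.copy(), "speed": float(np.linalg.norm(vel))}
        t = np.arange(n_frames)[:, None] * dt
        for i in range(n_tracks):
            tracks.append(Track(t * vel[None, :].reshape(1, 2), dt, id=f"ballistic_{i}"))
    else:
        raise ValueError(f"unknown motion model {model!r}")
    return tracks, truth


def gen_sigmoid_timecourse(seed: int = 0, *, lower: float = 0.0, upper: float = 1.0,
                           rate: float = 0.5, t_infl: float = 20.0,
                           asymmetry: float = 1.0, noise_sd: float = 0.05,
                           t_end: float = 36.0, sample_minutes: float = 20.0):
    """Richards time course on the live-imaging grid plus Gaussian noise.

    Sampled every ``sample_minutes`` over [0, t_end] hours.  Returns
    ``(TimeSeries, truth dict)`` with the generating parameters, including
    the requested inflection time.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if asymmetry <= 0:
        raise ValueError("asymmetry must be positive")
    rng = _rng(seed, "sigmoid_series")
    t = np.arange(0.0, t_end + 1e-9, sample_minutes / 60.0)
    t_c = t_infl + np.log(asymmetry) / rate
    y = richards(t, lower, upper, rate, t_c, asymmetry)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, len(t))
    truth = {"lower": lower, "upper": upper, "rate": rate, "t_infl": t_infl,
             "asymmetry": asymmetry, "t_c": t_c, "noise_sd": noise_sd}
    return TimeSeries(times=t, values=y, label=f"sigmoid_seed{seed}"), truth


def perturb_shell(shell: TriangulatedShell, seed: int = 0,
                  amplitude: float = 1e-3) -> ShellState:
    """Seeded Gaussian radial displacement of sd ``amplitude * l0``.

    Amplitude 0 returns the rest state unchanged; identical seeds give
    identical states.  This is the symmetry-breaking initial condition of
    the shell dynamics.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    return radial_perturbation(shell, amplitude, seed)
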