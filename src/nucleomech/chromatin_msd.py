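"""Mean-squared-displacement analysis of chromatin (telomere) tracks.

Tracks are 2-D positions sampled at a uniform frame interval (0.07 s in
the reference live-imaging protocol).  The MSD at lag tau = k*dt is the
time average over all overlapping frame pairs,

    MSD(k dt) = < |r(t + k dt) - r(t)|^2 >_t ,

and the log-log slope alpha of MSD = 4 D_app tau^alpha classifies the
motion: a plateaued curve (alpha ~ 0 at long lags) indicates confinement,
alpha ~ 1 free diffusion, alpha ~ 2 directed motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "MSDCurve",
    "compute_msd",
    "ensemble_msd",
    "fit_motion_model",
    "read_tracks_csv",
    "msd_to_frame",
]

#: alpha thresholds bounding the motion regimes (conventions; the
#: confined label additionally requires a detected plateau)
REGIME_THRESHOLDS = {"confined": 0.3, "subdiffusive": 0.8, "diffusive_upper": 1.2}


@dataclass(frozen=True)
class Track:
    """One particle trajectory at uniform frame interval."""

    positions: np.ndarray  # (T, 2)
    frame_interval: float = 0.07
    id: str = ""

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("positions must be (T, 2)")
        if len(p) < 10:
            raise ValueError(f"track needs >= 10 frames, got {len(p)}")
        if not np.isfinite(p).all():
            raise ValueError("track contains non-finite coordinates")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MSDCurve:
    """Lag-wise MSD with pair counts and (for ensembles) standard errors."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    sem: np.ndarray | None = None


def compute_msd(track: Track, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD with overlapping windows.

    Lags run from 1 frame up to ``max_lag_fraction`` of the track length;
    each lag k averages |r(t+k) - r(t)|^2 over all T-k frame pairs.
    """
    if not (0 < max_lag_fraction <= 0.5):
        raise ValueError("max_lag_fraction must be in (0, 0.5]")
    p = np.asarray(track.positions, dtype=float)
    T = len(p)
    kmax = int(np.floor(max_lag_fraction * T))
    if kmax < 1:
        raise ValueError(
            f"track of {T} frames too short for max_lag_fraction={max_lag_fraction}")
    msd = np.empty(kmax)
    n_pairs = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        d = p[k:] - p[:-k]
        msd[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
        n_pairs[k - 1] = T - k
    lags = np.arange(1, kmax + 1) * track.frame_interval
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def ensemble_msd(tracks, max_lag_fraction: float = 0.25,
                 weight_by_pairs: bool = True) -> MSDCurve:
    """Per-lag weighted mean of per-track MSDs with standard errors.

    All tracks must share a frame interval; weights are the per-track pair
    counts by default (or uniform).  Lags extend to the longest per-track
    curve; the standard error at each lag is that of the weighted mean
    across the tracks contributing to it.
    """
    tracks = list(tracks)
    if len(tracks) < 2:
        raise ValueError("ensemble needs at least 2 tracks")
    dts = {t.frame_interval for t in tracks}
    if len(dts) != 1:
        raise ValueError(f"tracks mix frame intervals: {sorted(dts)}")
    curves = [compute_msd(t, max_lag_fraction) for t in tracks]
    kmax = max(len(c.msd) for c in curves)
    dt = tracks[0].frame_interval

    msd = np.empty(kmax)
    sem = np.empty(kmax)
    n_pairs = np.zeros(kmax, dtype=int)
    for k in range(kmax):
        vals = np.array([c.msd[k] for c in curves if len(c.msd) > k])
        w = np.array([c.n_pairs[k] for c in curves if len(c.msd) > k], dtype=float)
        if not weight_by_pairs:
            w = np.ones_like(w)
        wsum = w.sum()
        mean = np.sum(w * vals) / wsum
        msd[k] = mean
        n_pairs[k] = int(wsum)
        if len(vals) > 1:
            var = np.sum(w * (vals - mean) ** 2) / wsum
            sem[k] = np.sqrt(var / len(vals))
        else:
            sem[k] = 0.0
    return MSDCurve(lags=np.arange(1, kmax + 1) * dt, msd=msd, n_pairs=n_pairs, sem=sem)


def fit_motion_model(curve: MSDCurve, fit_lags: slice | np.ndarray | None = None,
                     plateau_slope: float = 0.1):
    """Power-law fit MSD = 4 D_app tau^alpha and regime classification.

    The fit is linear least squares in log-log space over ``fit_lags``
    (all lags by default; a slice or boolean/index array otherwise).
    A plateau is reported as the median of the top-lag quartile of the
    curve when the local log-log slope there falls below
    ``plateau_slope``.  Regimes: confined (alpha < 0.3 with plateau),
    subdiffusive, diffusive, superdiffusive per the module thresholds.

    Returns ``(alpha, D_app, plateau_or_None, regime)``.
    """
    lags = np.asarray(curve.lags, dtype=float)
    msd = np.asarray(curve.msd, dtype=float)
    if fit_lags is None:
        sel = np.ones(len(lags), dtype=bool)
    elif isinstance(fit_lags, slice):
        sel = np.zeros(len(lags), dtype=bool)
        sel[fit_lags] = True
    else:
        sel = np.zeros(len(lags), dtype=bool)
        sel[np.asarray(fit_lags)] = True
    if sel.sum() < 5:
        raise ValueError("need at least 5 lags in the fit range")
    if (msd[sel] <= 0).any():
        raise ValueError("non-positive MSD values in the fit range")

    alpha, intercept = np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)
    D_app = np.exp(intercept) / 4.0

    # plateau: top-lag quartile, local slope test
    q = max(len(lags) // 4, 2)
    tail_l, tail_m = lags[-q:], msd[-q:]
    plateau = None
    if (tail_m > 0).all():
        tail_slope = np.polyfit(np.log(tail_l), np.log(tail_m), 1)[0]
        if abs(tail_slope) < plateau_slope:
            plateau = float(np.median(tail_m))

    if alpha < REGIME_THRESHOLDS["confined"] and plateau is not None:
        regime = "confined"
    elif alpha < REGIME_THRESHOLDS["subdiffusive"]:
        regime = "subdiffusive"
    elif alpha <= REGIME_THRESHOLDS["diffusive_upper"]:
        regime = "diffusive"
    else:
        regime = "superdiffusive"
    return float(alpha), float(D_app), plateau, regime


# ---------------------------------------------------------------------------
# I/O


def read_tracks_csv(path, frame_interval: float = 0.07) -> list[Track]:
    """Read tracks from CSV with columns track_id, frame, x, y."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"track CSV needs columns {sorted(required)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(Track(positions=g[["x", "y"]].to_numpy(dtype=float),
                            frame_interval=frame_interval, id=str(tid)))
    return tracks


def msd_to_frame(curve: MSDCurve) -> pd.DataFrame:
    """MSD curve as a tidy DataFrame (lag_s, msd, n_pairs, sem)."""
    data = {"lag_s": curve.lags, "msd": curve.msd, "n_pairs": curve.n_pairs}
    if curve.sem is not None:
        data["sem"] = curve.sem
    return pd.DataFrame(data)
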