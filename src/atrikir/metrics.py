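"""Quantification of re-entry: phase maps, tip tracking, DF, APD dispersion.

Spiral-wave cores are located as phase singularities.  The phase is built
by delay embedding of the voltage recordings,

    phi(x, t) = atan2(V(x, t - tau) - Vbar(x), V(x, t) - Vbar(x)),

with a node-wise mean Vbar and delay tau (5 ms by default).  A phase
singularity is a plaquette of the 2D grid around which the wrapped phase
differences wind by +-2pi; its charge is the winding sign.  Tips are linked
across frames by nearest neighbour (2 mm gate) into trajectories, from
which re-entry lifespan and meander (convex-hull area over sliding
windows) are measured.  The dominant frequency (DF) is the frequency of
the largest peak of the Hann-windowed periodogram of a local voltage
recording, searched between 0.5 and 20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram
from scipy.spatial import ConvexHull, QhullError

from .geometry import TissueField

__all__ = [
    "SpiralMetrics",
    "APDMap",
    "phase_map",
    "find_singularities",
    "track_tips",
    "spiral_metrics",
    "dominant_frequency",
    "apd_dispersion_map",
]

EXCITED_MV = -20.0


@dataclass(frozen=True)
class SpiralMetrics:
    """Stability measures of a re-entrant episode."""

    lifespan_s: float
    meander_area_mm2: float
    dominant_frequency_hz: float | None
    n_tips_final: int
    tracks: list = field(repr=False, default_factory=list)


@dataclass(frozen=True)
class APDMap:
    """Per-node APD90 of one paced beat, relative to the shortest APD."""

    apd_plus: np.ndarray  # APD90 - min(APD90 over excited), ms; NaN if unexcited
    excited: np.ndarray  # bool mask (peak V above -20 mV)
    delta_apd: float  # max - min over excited nodes, ms


def phase_map(movie: np.ndarray, times: np.ndarray, embed_delay: float = 5.0):
    """Delay-embedded phase of a voltage movie.

    Parameters
    ----------
    movie : (n_frames, ...) voltage recordings
    times : frame times, ms (uniformly sampled)
    embed_delay : embedding delay tau, ms

    Returns
    -------
    (phase, lag_times) where ``phase`` has shape (n_frames - lag, ...) and
    ``lag_times`` are the corresponding times; entries are in (-pi, pi].
    Nodes with negligible amplitude (< 1 mV span) get NaN phase.
    """
    movie = np.asarray(movie, dtype=float)
    times = np.asarray(times, dtype=float)
    if movie.shape[0] != times.size:
        raise ValueError("times length must match the number of frames")
    dt = float(times[1] - times[0]) if times.size > 1 else np.inf
    lag = int(round(embed_delay / dt))
    if lag < 1 or lag >= movie.shape[0]:
        raise ValueError("recording window shorter than the embedding delay")
    vbar = movie.mean(axis=0)
    a = movie[lag:] - vbar
    b = movie[:-lag] - vbar
    phase = np.arctan2(b, a)
    flat = movie.max(axis=0) - movie.min(axis=0) < 1.0
    phase[:, flat] = np.nan
    return phase, times[lag:]


def _wrap(x):
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def find_singularities(phase2d: np.ndarray, dx: float = 1.0):
    """Phase singularities of a 2D phase field.

    Sums the wrapped phase differences around every 2x2 plaquette; a
    winding of +-2pi marks a spiral tip at the plaquette centre.

    Returns
    -------
    list of (x_mm, y_mm, charge) with charge +-1.
    """
    p = np.asarray(phase2d, dtype=float)
    if p.ndim != 2:
        raise ValueError("expects a 2D phase field")
    d1 = _wrap(p[1:, :-1] - p[:-1, :-1])   # (i,j)   -> (i+1,j)
    d2 = _wrap(p[1:, 1:] - p[1:, :-1])     # (i+1,j) -> (i+1,j+1)
    d3 = _wrap(p[:-1, 1:] - p[1:, 1:])     # (i+1,j+1) -> (i,j+1)
    d4 = _wrap(p[:-1, :-1] - p[:-1, 1:])   # (i,j+1) -> (i,j)
    winding = d1 + d2 + d3 + d4
    tips = []
    hits = np.argwhere(np.abs(winding) > np.pi)  # winding is ~ +-2pi or 0
    for i, j in hits:
        if np.isnan(winding[i, j]):
            continue
        charge = 1 if winding[i, j] > 0 else -1
        tips.append(((i + 1.0) * dx, (j + 1.0) * dx, charge))
    return tips


def track_tips(tip_frames, frame_times, gate_mm: float = 2.0):
    """Link per-frame tip lists into trajectories by nearest neighbour.

    Returns a list of tracks; each is a list of (t_ms, x_mm, y_mm, charge).
    """
    tracks: list[list] = []
    open_tracks: list[list] = []
    for t, tips in zip(frame_times, tip_frames):
        unmatched = list(tips)
        next_open = []
        for tr in open_tracks:
            _, px, py, pc = tr[-1]
            best = None
            for k, (x, y, c) in enumerate(unmatched):
                if c != pc:
                    continue
                d = np.hypot(x - px, y - py)
                if d <= gate_mm and (best is None or d < best[0]):
                    best = (d, k)
            if best is not None:
                x, y, c = unmatched.pop(best[1])
                tr.append((t, x, y, c))
                next_open.append(tr)
        for x, y, c in unmatched:
            tr = [(t, x, y, c)]
            tracks.append(tr)
            next_open.append(tr)
        open_tracks = next_open
    return tracks


def _hull_area(points: np.ndarray) -> float:
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2-D hull "volume" is area
    except QhullError:
        return 0.0  # collinear trajectory


def spiral_metrics(
    movie: np.ndarray,
    times: np.ndarray,
    geom: TissueField,
    probe_trace=None,
    probe_fs_khz: float | None = None,
    embed_delay: float = 5.0,
    window_ms: float = 1000.0,
    t_origin: float | None = None,
) -> SpiralMetrics:
    """Tip trajectory, lifespan, meander area and DF of a re-entry episode.

    Lifespan is the time from ``t_origin`` (default: the first frame) to
    the last frame containing at least one in-domain phase singularity.
    Meander area is the convex-hull area of the dominant track's tip
    positions over sliding windows of ``window_ms``, averaged.
    """
    phase, pt = phase_map(movie, times, embed_delay)
    tip_frames = [find_singularities(phase[k], geom.dx) for k in range(phase.shape[0])]
    tracks = track_tips(tip_frames, pt)

    alive = [k for k, tips in enumerate(tip_frames) if tips]
    origin = float(times[0]) if t_origin is None else float(t_origin)
    lifespan_ms = (pt[alive[-1]] - origin) if alive else 0.0

    meander = 0.0
    if tracks:
        main = max(tracks, key=len)
        arr = np.array([(t, x, y) for t, x, y, _ in main])
        t0, t1 = arr[0, 0], arr[-1, 0]
        if t1 - t0 <= window_ms:
            meander = _hull_area(arr[:, 1:])
        else:
            areas = []
            w0 = t0
            while w0 + window_ms <= t1:
                sel = (arr[:, 0] >= w0) & (arr[:, 0] < w0 + window_ms)
                areas.append(_hull_area(arr[sel, 1:]))
                w0 += window_ms / 2.0
            meander = float(np.mean(areas)) if areas else 0.0

    df = None
    if probe_trace is not None:
        fs = probe_fs_khz
        if fs is None:
            fs = 1.0 / (times[1] - times[0])
        df = dominant_frequency(probe_trace, fs)

    return SpiralMetrics(
        lifespan_s=float(lifespan_ms) / 1000.0,
        meander_area_mm2=float(meander),
        dominant_frequency_hz=df,
        n_tips_final=len(tip_frames[-1]) if tip_frames else 0,
        tracks=tracks,
    )


def dominant_frequency(trace, fs_khz: float, f_lo: float = 0.5,
                       f_hi: float = 20.0, min_window_s: float = 2.0):
    """Largest-peak frequency (Hz) of the power spectrum of a recording.

    ``fs_khz`` is the sampling rate in kHz (trace time base in ms).
    Returns None (absent) for quiescent traces -- voltage span below 10 mV,
    as after self-termination of re-entry.  Raises if the window is
    shorter than ``min_window_s``.
    """
    v = np.asarray(trace, dtype=float)
    fs_hz = fs_khz * 1000.0
    if v.size / fs_hz < min_window_s:
        raise ValueError(f"need at least {min_window_s} s of recording")
    if v.max() - v.min() < 10.0:
        return None
    freqs, power = periodogram(v - v.mean(), fs=fs_hz, window="hann")
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any() or power[band].max() <= 0:
        return None
    return float(freqs[band][np.argmax(power[band])])


def apd_dispersion_map(movie: np.ndarray, times: np.ndarray,
                       geom: TissueField, stim_onset: float = 0.0) -> APDMap:
    """Per-node APD90 of one paced beat and its spatial dispersion.

    Nodes whose peak potential stays below -20 mV are masked as unexcited.
    APD90 runs from the node's maximum-dV/dt time to 90% repolarisation.
    """
    n_frames = movie.shape[0]
    flat = movie.reshape(n_frames, -1)
    t = np.asarray(times, dtype=float)
    pre = flat[t <= stim_onset]
    rmp = pre[-1] if len(pre) else flat[0]
    peak = flat.max(axis=0)
    excited = peak >= EXCITED_MV

    dvdt = np.gradient(flat, t, axis=0)
    i_up = np.argmax(dvdt, axis=0)
    i_peak = np.argmax(flat, axis=0)
    level = peak - 0.9 * (peak - rmp)

    apd = np.full(flat.shape[1], np.nan)
    for k in np.nonzero(excited)[0]:
        seg = flat[i_peak[k]:, k]
        below = np.nonzero(seg <= level[k])[0]
        if below.size == 0:
            excited[k] = False  # did not repolarise within the window
            continue
        j = i_peak[k] + below[0]
        if j > 0 and flat[j, k] != flat[j - 1, k]:
            frac = (flat[j - 1, k] - level[k]) / (flat[j - 1, k] - flat[j, k])
            tc = t[j - 1] + frac * (t[j] - t[j - 1])
        else:
            tc = t[j]
        apd[k] = tc - t[i_up[k]]

    if not excited.any():
        raise RuntimeError("no excited nodes in the recording")
    amin = np.nanmin(apd[excited])
    amax = np.nanmax(apd[excited])
    apd_plus = apd - amin
    apd_plus[~excited] = np.nan
    return APDMap(
        apd_plus=apd_plus.reshape(geom.shape),
        excited=excited.reshape(geom.shape),
        delta_apd=float(amax - amin),
    )
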