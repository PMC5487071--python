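"""Single-cell experiments: biomarker extraction and S1-S2 APD restitution.

Biomarker conventions:

* RMP -- membrane potential immediately before the stimulus;
* APA -- peak potential minus RMP;
* APD50/APD90 -- time from the instant of maximum dV/dt to 50% / 90%
  repolarisation of the amplitude;
* MUV -- maximum upstroke velocity (V/s).

Action potential durations are measured from the maximum-dV/dt time rather
than stimulus onset, which is robust to the stimulus artefact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import CellParams, pace, initial_state, _pace_kernel

__all__ = [
    "Biomarkers",
    "RestitutionCurve",
    "NoCaptureError",
    "biomarkers",
    "steady_state_biomarkers",
    "apd_restitution",
    "max_restitution_slope",
]


class NoCaptureError(RuntimeError):
    """Raised when a trace contains no stimulated action potential."""


@dataclass(frozen=True)
class Biomarkers:
    """Action-potential biomarkers of a single beat."""

    apa: float  # mV
    rmp: float  # mV
    apd50: float  # ms
    apd90: float  # ms
    muv: float  # V/s

    def __post_init__(self) -> None:
        if not (self.apd90 >= self.apd50 >= 0.0):
            raise ValueError("APD90 >= APD50 >= 0 violated")


@dataclass(frozen=True)
class RestitutionCurve:
    """(interval, measurement) pairs with a kind label.

    ``x`` is strictly increasing: diastolic interval for APD restitution,
    BCL or S1-S2 interval for tissue curves.
    """

    x: np.ndarray
    y: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and equal length")
        if x.size >= 2 and np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")


def _apd_crossing(t, v, i_up, i_peak, level):
    """Interpolated time from t[i_up] to the post-peak fall through ``level``."""
    below = np.nonzero(v[i_peak:] <= level)[0]
    if below.size == 0:
        return np.nan
    j = i_peak + below[0]
    if j == i_peak:
        return t[j] - t[i_up]
    # linear interpolation between j-1 and j
    t0, t1 = t[j - 1], t[j]
    v0, v1 = v[j - 1], v[j]
    frac = (v0 - level) / (v0 - v1) if v1 != v0 else 0.0
    return t0 + frac * (t1 - t0) - t[i_up]


def biomarkers(t, v, stim_onset: float = 0.0) -> Biomarkers:
    """Biomarkers of the first stimulated AP in a (t, V) trace.

    ``stim_onset`` is the stimulus time in the trace's clock; RMP is read
    just before it.  Raises :class:`NoCaptureError` if the peak stays below
    -20 mV.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size < 3:
        raise ValueError("trace too short")
    pre = v[t <= stim_onset]
    rmp = float(pre[-1]) if pre.size else float(v[0])
    post = t >= stim_onset
    tp = t[post]
    vp = v[post]
    peak = float(vp.max())
    if peak < -20.0:
        raise NoCaptureError(f"no action potential detected (peak {peak:.1f} mV)")
    dvdt = np.gradient(vp, tp)
    i_up = int(np.argmax(dvdt))
    i_peak = int(np.argmax(vp))
    apa = peak - rmp
    apd50 = _apd_crossing(tp, vp, i_up, i_peak, peak - 0.5 * apa)
    apd90 = _apd_crossing(tp, vp, i_up, i_peak, peak - 0.9 * apa)
    if not np.isfinite(apd90):
        raise NoCaptureError("AP did not repolarise to 90% within the trace")
    return Biomarkers(
        apa=apa, rmp=rmp, apd50=float(apd50), apd90=float(apd90),
        muv=float(dvdt.max()),  # mV/ms == V/s
    )


def steady_state_biomarkers(
    params: CellParams,
    bcl: float = 1000.0,
    n_beats: int = 50,
    dt: float = 0.005,
    stim_amp: float = 20.0,
    stim_dur: float = 2.0,
) -> tuple[Biomarkers, dict]:
    """Pace to steady state and measure the final beat.

    The final two beats are recorded; drift is assessed by comparing their
    APD90 values (reported as ``rec['apd90_drift']``).
    """
    rec = pace(params, bcl=bcl, n_beats=n_beats, dt=dt,
               stim_amp=stim_amp, stim_dur=stim_dur, record_last=2)
    t, v = rec["t"], rec["V"]
    last = biomarkers(t[t >= bcl] - bcl, v[t >= bcl], stim_onset=0.0)
    penult = biomarkers(t[t < bcl], v[t < bcl], stim_onset=0.0)
    rec["apd90_drift"] = abs(last.apd90 - penult.apd90)
    rec["penultimate"] = penult
    return last, rec


def apd_restitution(
    params: CellParams,
    s1_bcl: float = 1000.0,
    s2_intervals=None,
    n_conditioning: int = 20,
    dt: float = 0.005,
    stim_amp: float = 20.0,
    stim_dur: float = 2.0,
) -> RestitutionCurve:
    """S1-S2 APD restitution: APD90 of the S2 beat against diastolic interval.

    The cell is conditioned with ``n_conditioning`` S1 stimuli at ``s1_bcl``;
    a single S2 is then delivered at each coupling interval (measured from
    the last S1).  DI = S2 interval - APD90 of the last S1 beat.  Couplings
    that fail to capture (S2 peak below -20 mV) are excluded.

    When no explicit S2 set is given, the coupling is scanned from
    ``s1_bcl`` downward -- coarsely at long couplings, in 10 ms steps below
    400 ms, and refined to 2 ms adjacent to the loss of capture -- so the
    steep foot of the curve is resolved.
    """
    # condition once, snapshot the state at the moment of the would-be S2
    cond = pace(params, bcl=s1_bcl, n_beats=n_conditioning, dt=dt,
                stim_amp=stim_amp, stim_dur=stim_dur, record_last=1)
    s1_bm = biomarkers(cond["t"], cond["V"], stim_onset=0.0)
    base_state = cond["state"]
    p = params.to_vector()

    def s2_apd(s2):
        y = np.array(base_state)
        # deliver the final S1, wait out the coupling, then the S2 + 600 ms
        t, v, _ = _pace_kernel(y, p, float(s2), 1, dt, stim_amp, stim_dur, 1, 1)
        t, v, _ = _pace_kernel(y, p, 600.0, 1, dt, stim_amp, stim_dur, 0, 4)
        # capture requires a fresh upstroke (upward -20 mV crossing), not
        # merely a still-depolarised membrane from the preceding S1 beat
        if not np.any((v[:-1] < -20.0) & (v[1:] >= -20.0)):
            return None
        try:
            return biomarkers(t, v, stim_onset=0.0).apd90
        except NoCaptureError:
            return None

    dis, apds = [], []

    def record(s2, apd):
        dis.append(s2 - s1_bm.apd90)
        apds.append(apd)

    if s2_intervals is not None:
        for s2 in np.asarray(s2_intervals, dtype=float):
            apd = s2_apd(s2)
            if apd is not None:
                record(s2, apd)
    else:
        coarse = [s2 for s2 in (s1_bcl, 800.0, 600.0, 500.0, 450.0)
                  if s2 <= s1_bcl]
        for s2 in coarse:
            apd = s2_apd(s2)
            if apd is not None:
                record(s2, apd)
        s2 = 400.0
        last_ok = None
        while s2 >= 50.0:  # 10 ms descent to loss of capture
            apd = s2_apd(s2)
            if apd is None:
                break
            record(s2, apd)
            last_ok = s2
            s2 -= 10.0
        if last_ok is not None:  # refine the foot in 2 ms steps
            for s2r in np.arange(last_ok - 2.0, s2, -2.0):
                apd = s2_apd(s2r)
                if apd is None:
                    break
                record(s2r, apd)
    if not dis:
        return RestitutionCurve(np.array([]), np.array([]), kind="APD90-vs-DI")
    order = np.argsort(dis)
    return RestitutionCurve(
        np.asarray(dis)[order], np.asarray(apds)[order], kind="APD90-vs-DI"
    )


def max_restitution_slope(curve: RestitutionCurve) -> float:
    """Maximum forward finite-difference slope over adjacent curve points."""
    if curve.x.size < 2:
        raise ValueError("need at least 2 points to compute a slope")
    return float(np.max(np.diff(curve.y) / np.diff(curve.x)))
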