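"""Tissue measurement and re-entry initiation protocols.

1D strand protocols (25 mm, dx 0.25 mm, D = 0.21 mm^2/ms unless stated):

* conduction velocity from activation times at the quarter / three-quarter
  nodes (activation = first upward crossing of -40 mV);
* effective refractory period (ERP) by bisection over the S1-S2 coupling to
  1 ms, propagation judged by a -20 mV crossing at the 16.25 mm node;
* re-entry wavelength WL = CV x ERP;
* excitation threshold by bisection over the S2 amplitude to 1 pA/pF;
* temporal vulnerability window at a two-region (e.g. CT|PM) junction:
  premature stimuli at the junction are classified as bidirectional block /
  unidirectional conduction / bidirectional conduction, the unidirectional
  range being the vulnerable window.

2D protocols: cross-field S1-S2 spiral-wave initiation (plane-wave
conditioning beats, premature quadrant S2) and the phase-distribution
method (node states sampled from a one-cycle limit trajectory at a phase
set by the angular coordinate about a filament).

Strand protocols condition with five S1 beats; the expensive conditioning
portion is computed once per (parameter set, cycle length) and reused
across bisection trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import CellParams, initial_state, N_STATE
from .geometry import TissueField, make_geometry
from .protocols_cell import RestitutionCurve, pace
from .tissue import StimulusEvent, run_monodomain

__all__ = [
    "VulnerabilityWindow",
    "default_strand",
    "measure_cv",
    "cv_from_activation",
    "measure_erp",
    "wavelength",
    "excitation_threshold",
    "vulnerability_window",
    "init_cross_field",
    "init_phase_distribution",
]

ACTIVATION_MV = -40.0  # timing threshold
EXCITED_MV = -20.0  # excitation-classification threshold


def default_strand(d_iso: float = 0.21) -> TissueField:
    """The standard 25 mm, dx 0.25 mm measurement strand."""
    return make_geometry("cable", 25.0, 0.25, d_iso=d_iso)


def _stim_nodes(geom: TissueField, size_mm: float = 2.5) -> np.ndarray:
    """Node set of the stimulated segment at the x = 0 end."""
    n = max(int(round(size_mm / geom.dx)), 1)
    idx = np.arange(geom.n_nodes).reshape(geom.shape)
    return idx[:n].ravel()


def _crossing_time(t, v, level, after=None):
    """First upward crossing of ``level`` (linearly interpolated); None if
    the trace never crosses."""
    v = np.asarray(v)
    up = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    for i in up:
        if after is None or t[i + 1] > after:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def cv_from_activation(t_a: float, t_b: float, distance_mm: float) -> float:
    """Conduction velocity in m/s from two activation times (ms)."""
    if t_b == t_a:
        raise ValueError("coincident activation times")
    return abs(distance_mm) / abs(t_b - t_a)  # mm/ms == m/s


def measure_cv(rec: dict, geom: TissueField, probe_positions=(0.25, 0.75)) -> float:
    """CV (m/s) from a strand recording probed at fractional positions.

    ``rec`` must contain probe traces at the quarter and three-quarter
    nodes (in that order); activation is the first -40 mV upward crossing.
    Raises if a probe never activates (conduction failure).
    """
    t = rec["t"]
    times = []
    for k, frac in enumerate(probe_positions):
        tc = _crossing_time(t, rec["probes"][:, k], ACTIVATION_MV)
        if tc is None:
            raise RuntimeError(f"no activation at the {frac:.0%} node")
        times.append(tc)
    distance = abs(probe_positions[1] - probe_positions[0]) * geom.dims_mm[0]
    return cv_from_activation(times[0], times[1], distance)


# --------------------------------------------------------------------------
# conditioned-state cache
# --------------------------------------------------------------------------
_COND_CACHE: dict = {}


def _condition_strand(
    geom: TissueField, params, bcl: float, n_s1: int = 5,
    stim_amp: float = 20.0, stim_dur: float = 2.0, dt: float = 0.02,
):
    """State of the strand at the onset of the last of ``n_s1`` S1 beats.

    The cell models are first paced to steady state in a single-cell
    environment; the strand then receives the first ``n_s1 - 1`` beats.
    """
    key = (_geom_key(geom), _params_key(params), bcl, n_s1, stim_amp,
           stim_dur, dt)
    if key in _COND_CACHE:
        return _COND_CACHE[key].copy()
    init = _single_cell_initial(geom, params, bcl)
    stims = [StimulusEvent(_stim_nodes(geom), stim_amp, stim_dur, k * bcl)
             for k in range(n_s1 - 1)]
    rec = run_monodomain(geom, params, stims, duration=(n_s1 - 1) * bcl,
                         dt=dt, initial=init)
    _COND_CACHE[key] = rec["state"].copy()
    return rec["state"]


def _geom_key(geom: TissueField):
    return (geom.shape, geom.dx, geom.d_iso, geom.anisotropy_ratio,
            geom.region_names, geom.region_ids.tobytes(),
            geom.active.tobytes())


def _params_key(params):
    if isinstance(params, CellParams):
        return tuple(params.to_vector())
    return tuple((k, tuple(v.to_vector())) for k, v in sorted(params.items()))


_SS_CACHE: dict = {}


def _steady_state(params: CellParams, bcl: float) -> np.ndarray:
    key = (tuple(params.to_vector()), bcl)
    if key not in _SS_CACHE:
        _SS_CACHE[key] = pace(params, bcl=bcl, n_beats=25, dt=0.01)["state"]
    return _SS_CACHE[key]


def _single_cell_initial(geom: TissueField, params, bcl: float) -> np.ndarray:
    """Per-node initial states from single-cell steady-state pacing."""
    n = geom.n_nodes
    init = np.empty((n, N_STATE))
    if isinstance(params, CellParams):
        init[:] = _steady_state(params, bcl)
    else:
        for k, label in enumerate(geom.region_names):
            init[(geom.region_ids == k).ravel()] = _steady_state(params[label], bcl)
    return init


def _s2_trial(
    geom, params, cond_state, bcl, coupling, s2_amp, stim_amp=20.0,
    stim_dur=2.0, dt=0.02, observe_frac=0.65, post_ms=400.0,
):
    """Deliver the final S1 then an S2 after ``coupling`` ms.

    Returns the S2-attributable activation time at the observation node
    (fraction of strand length from the stimulated end), or None.
    """
    stims = [
        StimulusEvent(_stim_nodes(geom), stim_amp, stim_dur, 0.0),
        StimulusEvent(_stim_nodes(geom), s2_amp, stim_dur, coupling),
    ]
    obs = int(round(observe_frac * geom.dims_mm[0] / geom.dx))
    rec = run_monodomain(
        geom, params, stims, duration=coupling + post_ms, dt=dt,
        initial=cond_state, probes=[obs], sample_ms=0.5,
    )
    return _crossing_time(rec["t"], rec["probes"][:, 0], EXCITED_MV,
                          after=coupling)


def measure_erp(
    params, bcl: float = 1000.0, geom: TissueField | None = None,
    stim_amp: float = 20.0, stim_dur: float = 2.0, dt: float = 0.02,
    scan=(50.0, None),
) -> float:
    """Effective refractory period of the strand at a pacing cycle length.

    Five conditioning S1 beats (2.5 mm stimulated segment), then bisection
    over the S1-S2 coupling to 1 ms; an S2 counts as propagated if the
    16.25 mm node crosses -20 mV after the S2.
    """
    geom = default_strand() if geom is None else geom
    cond = _condition_strand(geom, params, bcl, stim_amp=stim_amp,
                             stim_dur=stim_dur, dt=dt)
    lo, hi = scan[0], scan[1] if scan[1] is not None else bcl

    def captures(coupling):
        return _s2_trial(geom, params, cond.copy(), bcl, coupling, stim_amp,
                         stim_amp, stim_dur, dt) is not None

    if not captures(hi):
        raise RuntimeError(f"S2 does not capture even at coupling {hi} ms")
    if captures(lo):
        return lo
    while hi - lo > 1.0:
        mid = round(0.5 * (lo + hi))
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def wavelength(cv_m_s: float, erp_ms: float) -> float:
    """Re-entry wavelength WL = CV x ERP in mm."""
    if not (np.isfinite(cv_m_s) and np.isfinite(erp_ms)):
        raise ValueError("CV and ERP must be finite")
    return cv_m_s * erp_ms  # (mm/ms) * ms


def excitation_threshold(
    params, si: float = 300.0, stim_duration: float = 2.0,
    geom: TissueField | None = None, ceiling: float = 1000.0,
    dt: float = 0.02, test_size_mm: float = 0.25,
) -> float:
    """Minimum S2 amplitude (pA/pF) eliciting a propagating AP at an S1-S2
    interval ``si``, after five conditioning S1 beats at that interval.

    The test stimulus is applied to a single node (0.25 mm) at the paced
    end, which reproduces the reported threshold scale; the conditioning
    S1 segment remains 2.5 mm.  Bisection to 1 pA/pF; returns ``inf``
    (non-excitable) if even the scan ceiling fails to propagate.
    """
    geom = default_strand() if geom is None else geom
    cond = _condition_strand(geom, params, si, stim_dur=stim_duration, dt=dt)
    test_nodes = _stim_nodes(geom, test_size_mm)

    def captures(amp):
        stims = [
            StimulusEvent(_stim_nodes(geom), 20.0, stim_duration, 0.0),
            StimulusEvent(test_nodes, amp, stim_duration, si),
        ]
        obs = int(round(0.65 * geom.dims_mm[0] / geom.dx))
        rec = run_monodomain(geom, params, stims, duration=si + 400.0, dt=dt,
                             initial=cond.copy(), probes=[obs], sample_ms=0.5)
        return _crossing_time(rec["t"], rec["probes"][:, 0], EXCITED_MV,
                              after=si) is not None

    lo, hi = 0.0, ceiling
    if not captures(hi):
        return np.inf
    while hi - lo > 1.0:
        mid = round(0.5 * (lo + hi))
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


# --------------------------------------------------------------------------
# vulnerability window at a heterogeneous junction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VulnerabilityWindow:
    """Range of S2 timings producing uni-directional conduction block."""

    t_lo: float
    t_hi: float
    classes: dict  # timing -> {"bidirectional-block", "unidirectional",
    #                           "bidirectional-conduction"}

    @property
    def width(self) -> float:
        return self.t_hi - self.t_lo


def vulnerability_window(
    geom: TissueField, params: dict, timings,
    s2_site_mm: float | None = None, s2_width_mm: float = 2.5,
    s2_amp: float = 40.0, stim_dur: float = 2.0, dt: float = 0.02,
    bcl: float = 1000.0, s1_uniform: bool = False,
) -> VulnerabilityWindow:
    """Classify premature junction stimuli by conduction direction.

    An S1 (by default a plane wave from the x = 0 end; uniform
    whole-strand activation with ``s1_uniform=True``) is launched from
    regional 1 Hz steady states; at each timing (ms after S1 onset) an S2
    is applied locally at the junction and the response is classified by
    S2-attributable activations at flank nodes (20% and 80% of the
    strand).  The vulnerable window is the contiguous range of
    unidirectional timings (width 0 if none).

    With a propagating S1 even a homogeneous strand has a finite window
    equal to the flank-to-flank conduction delay (~15 ms here); uniform S1
    activation removes that term, leaving the regional-refractoriness
    contribution alone (zero for a homogeneous strand by construction).
    """
    if s2_site_mm is None:
        # junction position: first region-label change, else the midpoint
        rid = geom.region_ids
        changes = np.nonzero(np.diff(rid))[0]
        s2_site_mm = ((changes[0] + 1) * geom.dx if changes.size
                      else 0.5 * geom.dims_mm[0])
    x = (np.arange(geom.shape[0]) + 0.5) * geom.dx
    s2_nodes = np.nonzero(np.abs(x - s2_site_mm) <= 0.5 * s2_width_mm)[0]
    flank_l = int(round(0.20 * geom.shape[0]))
    flank_r = int(round(0.80 * geom.shape[0]))

    init = _single_cell_initial(geom, params, bcl)
    s1_nodes = (np.arange(geom.n_nodes) if s1_uniform
                else _stim_nodes(geom))
    classes = {}
    for timing in timings:
        stims = [
            StimulusEvent(s1_nodes, 20.0, 2.0, 0.0),
            StimulusEvent(s2_nodes, s2_amp, stim_dur, float(timing)),
        ]
        rec = run_monodomain(
            geom, params, stims, duration=float(timing) + 250.0, dt=dt,
            initial=init, probes=[flank_l, flank_r], sample_ms=0.5,
        )
        t = rec["t"]
        s2_end = timing + stim_dur
        left = _crossing_time(t, rec["probes"][:, 0], EXCITED_MV, after=s2_end)
        right = _crossing_time(t, rec["probes"][:, 1], EXCITED_MV, after=s2_end)
        if left is not None and right is not None:
            classes[float(timing)] = "bidirectional-conduction"
        elif left is None and right is None:
            classes[float(timing)] = "bidirectional-block"
        else:
            classes[float(timing)] = "unidirectional"

    uni = sorted(tm for tm, c in classes.items() if c == "unidirectional")
    if not uni:
        mid = float(np.median(list(classes))) if classes else 0.0
        return VulnerabilityWindow(t_lo=mid, t_hi=mid, classes=classes)
    return VulnerabilityWindow(t_lo=uni[0], t_hi=uni[-1], classes=classes)


# --------------------------------------------------------------------------
# 2D re-entry initiation
# --------------------------------------------------------------------------

def crossfield_conditioning(
    geom: TissueField, params, s1_bcl: float = 400.0, n_s1: int = 4,
    stim_amp: float = 20.0, dt: float = 0.02, settle_ms: float = 20.0,
):
    """Plane-wave conditioning for the cross-field protocol.

    Paces the left edge with ``n_s1`` S1 beats at ``s1_bcl`` (single-cell
    steady states as initial condition) and returns ``(state, t_ref)``
    where ``t_ref`` is the onset time of the last S1 and ``state`` the
    field ``settle_ms`` after it (the final plane wave under way).
    """
    idx = np.arange(geom.n_nodes).reshape(geom.shape)
    edge = idx[:2].ravel() if geom.ndim == 1 else idx[:2, :].ravel()
    init = _single_cell_initial(geom, params, s1_bcl)
    stims = [StimulusEvent(edge, stim_amp, 2.0, k * s1_bcl) for k in range(n_s1)]
    t_ref = (n_s1 - 1) * s1_bcl
    rec = run_monodomain(geom, params, stims, duration=t_ref + settle_ms,
                         dt=dt, initial=init)
    return rec["state"], t_ref, settle_ms


def init_cross_field(
    geom: TissueField, params, s1_bcl: float = 400.0, s2_delay: float = 240.0,
    duration: float = 2000.0, dt: float = 0.02, conditioning=None,
    s2_amp: float = 30.0, movie_ms: float = 4.0, probes=(), stop_quiescent=True,
):
    """Cross-field S1-S2 spiral-wave initiation on a 2D sheet.

    After four plane-wave conditioning beats from the left edge, a
    premature S2 covering the lower-left quadrant is applied ``s2_delay``
    ms after the last S1 onset (choose s2_delay >= ERP; inside the ERP the
    S2 captures nothing, far beyond full recovery it captures as a plane
    wave and no singularity forms).  Returns the recording of the evolving
    field from the last S1 onward, with the S2 time under ``"t_s2"``.
    """
    if conditioning is None:
        conditioning = crossfield_conditioning(geom, params, s1_bcl, dt=dt)
    state, t_ref, settle = conditioning
    idx = np.arange(geom.n_nodes).reshape(geom.shape)
    nx, ny = geom.shape
    quad = idx[: nx // 2, : ny // 2].ravel()
    s2 = StimulusEvent(quad, s2_amp, 2.0, t_ref + s2_delay)
    rec = run_monodomain(
        geom, params, [s2], duration=s2_delay + duration - settle, dt=dt,
        initial=state.copy(), movie_ms=movie_ms, probes=probes,
        t_start=t_ref + settle, stop_quiescent=stop_quiescent,
    )
    rec["t_s2"] = t_ref + s2_delay
    return rec


def limit_cycle_library(params: CellParams, bcl: float = 300.0,
                        n_samples: int = 256, dt: float = 0.005,
                        stim_amp: float = 20.0, stim_dur: float = 2.0):
    """States sampled over one paced cycle (used by the phase-distribution
    initiation); sample 0 is the stimulus onset (phase 0 = upstroke)."""
    from .cell import _step

    y = pace(params, bcl=bcl, n_beats=20, dt=dt,
             stim_amp=stim_amp, stim_dur=stim_dur)["state"].copy()
    p = params.to_vector()
    lib = np.empty((n_samples, N_STATE))
    steps_total = int(round(bcl / dt))
    stim_steps = int(round(stim_dur / dt))
    next_sample = 0
    for s in range(steps_total):
        k = (s * n_samples) // steps_total
        if k == next_sample:
            lib[k] = y
            next_sample += 1
        _step(y, dt, p, stim_amp if s < stim_steps else 0.0)
    return lib


def init_phase_distribution(
    geom: TissueField, params, filament=None, bcl: float = 300.0,
    chirality: int = +1,
) -> np.ndarray:
    """Initial condition with a rotor made by the phase-distribution method.

    Every node's full state is sampled from a one-cycle limit trajectory at
    phase theta(x) = chirality * atan2(y - y0, x - x0) about the filament
    (a point in 2D, a line along z in 3D).  ``filament`` is the (x0, y0)
    position in mm (domain centre by default) and must lie inside the
    domain.  The resulting field contains one phase singularity of charge
    ``chirality`` on its first rotation.
    """
    if geom.ndim < 2:
        raise ValueError("phase-distribution initiation needs a 2D/3D domain")
    dims = geom.dims_mm
    if filament is None:
        filament = (0.5 * dims[0], 0.5 * dims[1])
    x0, y0 = filament
    if not (0 <= x0 <= dims[0] and 0 <= y0 <= dims[1]):
        raise ValueError("filament lies outside the domain")
    cell_params = params if isinstance(params, CellParams) else None
    if cell_params is None:
        raise ValueError("phase-distribution initiation expects uniform CellParams")
    lib = limit_cycle_library(cell_params, bcl=bcl)
    n_samples = lib.shape[0]
    coords = geom.node_coords().reshape(-1, geom.ndim)
    theta = np.arctan2(coords[:, 1] - y0, coords[:, 0] - x0) * chirality
    frac = (theta + np.pi) / (2.0 * np.pi)  # [0, 1)
    sample = np.minimum((frac * n_samples).astype(int), n_samples - 1)
    return lib[sample]
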