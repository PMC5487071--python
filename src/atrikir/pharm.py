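"""In-silico multi-channel drug screen for SQT3 genotypes.

Interventions are multiplicative scalings of maximal conductances
(e.g. 50% I_Kr block is ``{"I_Kr": 0.5}``; a "250% increase" in I_CaL is
``{"I_CaL": 3.5}``, i.e. the current raised *by* 250%).  The standard
screen mirrors the channel combinations studied for SQT3: individual and
combined I_K1 / I_Kr / I_Kur block and L-type calcium agonism.

Two testbeds are used:

* single cell + CT|PM junction strand for APD prolongation and spatial
  APD dispersion under pacing (with an excitation-failure flag);
* a 2D sheet with a rotor initiated by the phase-distribution method for
  re-entry lifespan and dominant frequency.

The re-entry screen runs on idealised synthetic geometry, so its outcomes
are orderings (termination vs persistence, DF shifts), not predictions of
anatomical-atria frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import CellParams, apply_intervention
from .geometry import TissueField, make_geometry
from .metrics import APDMap, apd_dispersion_map, spiral_metrics, SpiralMetrics
from .protocols_cell import steady_state_biomarkers
from .protocols_tissue import (
    _single_cell_initial, _stim_nodes, init_phase_distribution,
)
from .tissue import StimulusEvent, run_monodomain

__all__ = [
    "STANDARD_SCREEN",
    "InterventionOutcome",
    "junction_delta_apd",
    "apd_prolongation_summary",
    "run_drug_screen",
]

#: The standard intervention set, label -> per-current multipliers.
STANDARD_SCREEN = {
    "control": {},
    "IK1-50": {"I_K1": 0.5},
    "IKr-50": {"I_Kr": 0.5},
    "IK1+IKr-50": {"I_K1": 0.5, "I_Kr": 0.5},
    "IKur-50": {"I_Kur": 0.5},
    "IKr+IKur-50": {"I_Kr": 0.5, "I_Kur": 0.5},
    "ICaL+100": {"I_CaL": 2.0},
    "ICaL+250": {"I_CaL": 3.5},
}


@dataclass(frozen=True)
class InterventionOutcome:
    """Outcome of one intervention on one genotype."""

    intervention: str
    genotype: str
    dominant_frequency_hz: float | None
    lifespan_s: float
    delta_apd_ms: float | None
    excitation_failure: bool


def _junction_geom() -> TissueField:
    return make_geometry("junction", 25.0, 0.25, regions=("CT", "PM"),
                         split_mm=12.5)


def junction_delta_apd(
    genotype: str, intervention: dict | None = None,
    bcl: float = 1000.0, dt: float = 0.02,
) -> tuple[float, bool]:
    """Spatial APD dispersion of a paced CT|PM junction strand.

    Returns (delta_apd_ms, excitation_failure); the failure flag is set
    when any node stays below -20 mV during the paced beat.
    """
    geom = _junction_geom()
    params = {
        r: CellParams.for_genotype(genotype, region=r, intervention=intervention)
        for r in ("CT", "PM")
    }
    init = _single_cell_initial(geom, params, bcl)
    stim = StimulusEvent(_stim_nodes(geom), 20.0, 2.0, 0.0)
    rec = run_monodomain(geom, params, [stim], duration=min(bcl, 600.0),
                         dt=dt, initial=init, movie_ms=1.0)
    amap = apd_dispersion_map(rec["movie"], rec["movie_t"], geom)
    return amap.delta_apd, bool(~amap.excited.all())


def apd_prolongation_summary(
    genotype: str, interventions: dict | None = None, bcl: float = 1000.0,
) -> dict:
    """Cell APD90 and junction dispersion per intervention at 1 Hz.

    Returns a dict label -> {"apd90_ms", "delta_apd_ms",
    "excitation_failure"}.
    """
    interventions = STANDARD_SCREEN if interventions is None else interventions
    out = {}
    for label, spec in interventions.items():
        p = CellParams.for_genotype(genotype, intervention=spec)
        bm, _ = steady_state_biomarkers(p, bcl=bcl, n_beats=30, dt=0.005)
        dapd, fail = junction_delta_apd(genotype, spec, bcl=bcl)
        out[label] = {
            "apd90_ms": bm.apd90,
            "delta_apd_ms": dapd,
            "excitation_failure": fail,
        }
    return out


def run_drug_screen(
    genotype: str,
    interventions: dict | None = None,
    testbed: TissueField | None = None,
    duration: float = 2000.0,
    dt: float = 0.02,
    with_dispersion: bool = True,
) -> list[InterventionOutcome]:
    """Screen interventions on paced dispersion and re-entry dynamics.

    For each intervention: (1) a paced junction-strand run gives the APD
    dispersion and excitation-failure flag; (2) a rotor started with the
    phase-distribution method on the 2D testbed (default 40 x 40 mm sheet,
    dx 0.5 mm) is followed for ``duration`` ms, yielding lifespan and DF.
    Deterministic throughout.
    """
    interventions = STANDARD_SCREEN if interventions is None else interventions
    if testbed is None:
        testbed = make_geometry("sheet", (40.0, 40.0), 0.5)
    outcomes = []
    probe = (testbed.shape[0] // 4, testbed.shape[1] // 4)
    for label, spec in interventions.items():
        params = CellParams.for_genotype(genotype, intervention=spec)
        if with_dispersion:
            dapd, fail = junction_delta_apd(genotype, spec)
        else:
            dapd, fail = None, False
        init = init_phase_distribution(testbed, params)
        rec = run_monodomain(
            testbed, params, [], duration=duration, dt=dt, initial=init,
            movie_ms=4.0, probes=[probe], sample_ms=1.0,
            stop_quiescent=True,
        )
        trace = rec["probes"][:, 0]
        df = None
        sm = spiral_metrics(rec["movie"], rec["movie_t"], testbed)
        lifespan = sm.lifespan_s
        if rec["duration"] >= duration - dt and trace.size >= 2000:
            from .metrics import dominant_frequency
            df = dominant_frequency(trace, fs_khz=1.0)
        outcomes.append(InterventionOutcome(
            intervention=label, genotype=genotype,
            dominant_frequency_hz=df, lifespan_s=lifespan,
            delta_apd_ms=dapd, excitation_failure=fail,
        ))
    return outcomes
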