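"""Synthetic inputs for the pipeline: I-V datasets, AP-clamp waveform, geometries.

Voltage-clamp I-V relationships per genotype are generated from the fixture
rectifier templates of :mod:`atrikir.ik1` with additive homoscedastic
Gaussian noise, emulating steady-state Kir2.1 current recordings:

* WT -- inward rectification with an outward peak near -60 mV;
* D172N (het/hom) -- increased outward current between -75 and -45 mV with
  preserved rectification;
* E299V (het/hom) -- weakened/abolished rectification, i.e. large outward
  current at depolarised potentials.

The AP-clamp waveform is a piecewise-analytic human atrial AP shape (fast
upstroke, decaying plateau near -5..-20 mV, sigmoidal terminal
repolarisation to -78 mV) standing in for a digitised model AP cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ik1 import IVCurve, genotype_params, ik1_current, nernst_potassium, GENOTYPES
from .geometry import make_geometry, TissueField  # re-exported geometry factory

__all__ = ["APWaveform", "make_iv_dataset", "make_ap_waveform", "make_geometry",
           "DEFAULT_IV_GRID"]

#: Default voltage-clamp step family: -120 to +20 mV in 5 mV steps.
DEFAULT_IV_GRID = np.arange(-120.0, 20.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class APWaveform:
    """One cycle of an atrial AP used for AP-clamp simulations."""

    times: np.ndarray  # ms, strictly increasing from 0
    voltages: np.ndarray  # mV
    cycle_length: float  # ms

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and voltages must be 1-D of equal length")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must increase strictly from 0")
        if abs(v[0] - v[-1]) > 2.0:
            raise ValueError("waveform endpoints differ by more than 2 mV")


def make_iv_dataset(
    genotype: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    voltages=None,
) -> IVCurve:
    """Genotype I-V template plus i.i.d. Gaussian noise (same seed, same data).

    Parameters
    ----------
    genotype : one of ``GENOTYPES``
    noise_sd : standard deviation of additive noise, pA/pF (>= 0)
    seed : RNG seed; the noiseless template is independent of it
    voltages : sampling grid, mV (default -120..+20 in 5 mV steps)
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    params = genotype_params(genotype)  # raises on unknown label
    v = DEFAULT_IV_GRID if voltages is None else np.asarray(voltages, dtype=float)
    e_k = nernst_potassium()
    i = ik1_current(v, params, e_k)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=v.shape)
    return IVCurve(voltages=v, currents=i, genotype=genotype)


def make_ap_waveform(cycle_length: float = 1000.0, dt: float = 0.5) -> APWaveform:
    """Piecewise-analytic atrial AP cycle for AP-clamp studies.

    The shape has a <2 ms upstroke from -78 mV to +25 mV, an exponentially
    decaying spike-and-dome plateau between roughly -5 and -20 mV, and a
    sigmoidal terminal repolarisation back to -78 mV whose midpoint scales
    with cycle length (capped at the 1000-ms shape), giving an APD90 around
    255 ms at a cycle length of 1000 ms.
    """
    if cycle_length <= 200:
        raise ValueError("cycle_length must exceed 200 ms")
    if dt > 0.5:
        raise ValueError("sampling interval must be <= 0.5 ms")
    t = np.arange(0.0, cycle_length + 1e-9, dt)
    v_rest = -78.0
    v_peak = 25.0
    t_up = 1.5  # ms
    cl_eff = min(cycle_length, 1000.0)
    t90 = 0.23 * cl_eff  # terminal-repolarisation midpoint
    w = 18.0

    v = np.full_like(t, v_rest)
    up = t < t_up
    v[up] = v_rest + (v_peak - v_rest) * np.sin(0.5 * np.pi * t[up] / t_up)
    tr = t[~up] - t_up
    plateau = -5.0 - 15.0 * (1.0 - np.exp(-tr / 80.0))
    spike = (v_peak - plateau) * np.exp(-tr / 8.0)
    sigma = 1.0 / (1.0 + np.exp((t[~up] - t90) / w))
    v[~up] = v_rest + (plateau + spike - v_rest) * sigma
    return APWaveform(times=t, voltages=v, cycle_length=float(cycle_length))
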