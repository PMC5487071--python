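"""Inward-rectifier potassium current (I_K1) formulations for Kir2.1 genotypes.

The current carried by Kir2.1 channels is modelled with a chord-conductance
rectifier of the Courtemanche-Ramirez-Nattel (CRN) family,

    I_K1(V) = g_K1 * (V - E_K) * 2 / (1 + exp(a * (V - b)))   [pA/pF],

with conductance ``g_K1`` (nS/pF), rectification steepness ``a`` (1/mV) and
rectification midpoint ``b`` (mV).  The Boltzmann factor is normalised so
that ``a = 0`` yields exactly the ohmic current ``g_K1 * (V - E_K)``,
continuously in ``a``; the CRN native rectifier corresponds to
``(g_K1, a, b) = (0.045, 0.07, -80)``.  The family thus spans strong inward
rectification (large ``a``, as in wild-type Kir2.1) through the essentially
linear I-V relationship of the homozygous E299V mutant, whose rectification
is abolished over physiological potentials.

Heterozygous channel populations can either be described by directly fitted
parameters (the default: each genotype label carries its own parameter set)
or as a 50:50 mixture of a wild-type and a mutant component.

Parameters are recovered from voltage-clamp I-V data by Nelder-Mead
least-squares fitting (:func:`fit_ik1`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "GENOTYPES",
    "IK1Params",
    "IVCurve",
    "FitResult",
    "nernst_potassium",
    "ik1_current",
    "chord_conductance",
    "fit_ik1",
    "simulate_ap_clamp",
    "genotype_params",
]

#: Physical constants (CRN conventions, 37 degrees C).
GAS_CONSTANT = 8.3143  # J / (mol K)
FARADAY = 96.4867  # C / mmol
TEMPERATURE = 310.0  # K

#: Valid genotype labels, ordered WT -> heterozygous -> homozygous.
GENOTYPES = ("WT", "WT-D172N", "D172N", "WT-E299V", "E299V")


def nernst_potassium(k_out: float = 5.4, k_in: float = 139.0) -> float:
    """Potassium reversal potential E_K (mV) from the Nernst equation."""
    return GAS_CONSTANT * TEMPERATURE / FARADAY * np.log(k_out / k_in)


@dataclass(frozen=True)
class IK1Params:
    """Parameters of a single-population rectifier component.

    Attributes
    ----------
    g_k1 : float
        Maximal chord conductance, nS/pF.  Must be >= 0.
    a : float
        Rectification steepness, 1/mV.  ``a = 0`` gives an ohmic current
        of conductance ``g_k1 / 2``.
    b : float
        Rectification midpoint, mV.
    mixture_weight : float or None
        If not None, this parameter set is interpreted as the *mutant*
        component of a WT/mutant mixture and ``mixture_weight`` is the WT
        fraction ``w`` in ``w*I_WT + (1-w)*I_mut``.  The WT component is
        the fixture WT parameter set.
    genotype : str or None
        Optional genotype label.
    """

    g_k1: float
    a: float
    b: float
    mixture_weight: float | None = None
    genotype: str | None = None

    def __post_init__(self) -> None:
        if self.g_k1 < 0:
            raise ValueError(f"g_k1 must be >= 0, got {self.g_k1}")
        if self.a < 0:
            raise ValueError(f"rectification steepness a must be >= 0, got {self.a}")
        if self.mixture_weight is not None and not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must lie in [0, 1]")


@dataclass(frozen=True)
class IVCurve:
    """A voltage-clamp I-V relationship (steady-state current density)."""

    voltages: np.ndarray  # mV, strictly increasing
    currents: np.ndarray  # pA/pF
    genotype: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)
        if v.ndim != 1 or i.shape != v.shape:
            raise ValueError("voltages and currents must be 1-D arrays of equal length")
        if v.size < 5:
            raise ValueError("an I-V curve needs at least 5 points")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares I_K1 parameter fit."""

    params: IK1Params
    residual: float  # sum of squared residuals, (pA/pF)^2
    converged: bool
    n_iter: int


def _component_current(v, g_k1: float, a: float, b: float, e_k: float):
    v = np.asarray(v, dtype=float)
    # Clip the Boltzmann argument to keep exp() finite for extreme V.
    z = np.clip(a * (v - b), -500.0, 500.0)
    return g_k1 * (v - e_k) * 2.0 / (1.0 + np.exp(z))


def ik1_current(v, params: IK1Params, e_k: float, wt_params: IK1Params | None = None):
    """Evaluate I_K1 (pA/pF) at membrane potential(s) ``v`` (mV).

    In mixture mode (``params.mixture_weight`` set) the returned current is
    ``w * I(wt_params) + (1 - w) * I(params)``; ``wt_params`` defaults to the
    fixture WT parameter set.
    """
    i_mut = _component_current(v, params.g_k1, params.a, params.b, e_k)
    if params.mixture_weight is None:
        return i_mut
    w = params.mixture_weight
    wt = wt_params if wt_params is not None else genotype_params("WT")
    i_wt = _component_current(v, wt.g_k1, wt.a, wt.b, e_k)
    return w * i_wt + (1.0 - w) * i_mut


def chord_conductance(curve: IVCurve, e_k: float, exclusion_mv: float = 1.0):
    """Chord conductance g(V) = I(V)/(V - E_K) in nS/pF.

    Points within ``exclusion_mv`` of the reversal potential are excluded
    (0/0 limit); the retained voltages are returned alongside g.

    Returns
    -------
    (voltages, conductances) : tuple of ndarray
    """
    keep = np.abs(curve.voltages - e_k) > exclusion_mv
    if not np.any(keep):
        raise ValueError("all points lie at the reversal potential")
    v = curve.voltages[keep]
    g = curve.currents[keep] / (v - e_k)
    return v, g


_DEFAULT_BOUNDS = ((0.0, 1.0), (0.0, 0.5), (-120.0, 0.0))


def fit_ik1(
    data: IVCurve,
    e_k: float,
    init: IK1Params | None = None,
    bounds: Sequence[tuple[float, float]] = _DEFAULT_BOUNDS,
    max_iter: int = 4000,
) -> FitResult:
    """Fit rectifier parameters (g_K1, a, b) to an I-V relationship.

    Nelder-Mead simplex minimisation of the sum of squared differences
    between the model and the data; restarted once from a perturbed
    initial point if the first attempt does not converge.
    """
    v, i_data = data.voltages, data.currents
    if v.size < 5:
        raise ValueError("need at least 5 data points")
    if not (v.min() < e_k < v.max()):
        raise ValueError("data must span both sides of the reversal potential")

    if init is None:
        # Ohmic guess for the conductance from the most hyperpolarised point.
        g0 = abs(i_data[0] / (v[0] - e_k)) if v[0] != e_k else 0.1
        init = IK1Params(g_k1=min(max(g0, 1e-3), 0.9), a=0.07, b=-80.0)

    def loss(theta):
        g, a, b = theta
        model = _component_current(v, g, a, b, e_k)
        return float(np.sum((model - i_data) ** 2))

    x0 = np.array([init.g_k1, init.a, init.b], dtype=float)
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(2):
        res = minimize(
            loss,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        # perturb and retry once
        x0 = x0 * (1.0 + 0.05 * rng.standard_normal(3)) + 1e-3

    g, a, b = best.x
    params = IK1Params(g_k1=float(g), a=float(a), b=float(b), genotype=data.genotype)
    return FitResult(
        params=params,
        residual=float(best.fun),
        converged=bool(best.success),
        n_iter=int(best.nit),
    )


def simulate_ap_clamp(params: IK1Params, times, voltages, e_k: float,
                      wt_params: IK1Params | None = None):
    """I_K1 trace along an action-potential clamp waveform.

    The current is instantaneous in V (no gating kinetics), so the trace is
    simply the I-V relationship evaluated along V(t).

    Returns
    -------
    currents : ndarray, pA/pF, same shape as ``times``.
    """
    times = np.asarray(times, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    if times.shape != voltages.shape:
        raise ValueError("times and voltages must have equal shapes")
    return ik1_current(voltages, params, e_k, wt_params=wt_params)


# ---------------------------------------------------------------------------
# Fixture genotype parameter sets
# ---------------------------------------------------------------------------
# These parameter sets define the genotype templates used throughout the
# package.  The WT set was calibrated so that the baseline atrial cell model
# paced at 1 Hz reproduces reported human atrial AP biomarkers (APD90 ~260 ms,
# RMP ~ -75 mV); each mutant set was calibrated against the corresponding
# reported biomarkers while preserving the qualitative voltage-clamp
# phenotype of the mutation:
#   * D172N forms: increased outward current between -75 and -45 mV with
#     preserved rectification (hyperpolarised resting potential, shorter APD);
#   * E299V forms: weakened (heterozygous) or abolished (homozygous)
#     rectification, i.e. large outward current at depolarised potentials.
# Digitised experimental I-V points, if available, can be fitted with
# fit_ik1() and substituted for these fixtures.
_GENOTYPE_PARAMS: dict[str, IK1Params] = {
    "WT": IK1Params(g_k1=0.012286, a=0.052016, b=-52.814, genotype="WT"),
    "WT-D172N": IK1Params(g_k1=0.017238, a=0.055350, b=-52.090, genotype="WT-D172N"),
    "D172N": IK1Params(g_k1=0.020402, a=0.052310, b=-50.990, genotype="D172N"),
    "WT-E299V": IK1Params(g_k1=0.014224, a=0.014990, b=-33.480, genotype="WT-E299V"),
    "E299V": IK1Params(g_k1=0.019050, a=0.0, b=-80.0, genotype="E299V"),
}


def genotype_params(genotype: str) -> IK1Params:
    """The fixture I_K1 parameter set for a genotype label."""
    try:
        return _GENOTYPE_PARAMS[genotype]
    except KeyError:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of {GENOTYPES}"
        ) from None
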