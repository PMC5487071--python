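"""Human atrial action-potential model (Courtemanche-Ramirez-Nattel lineage).

The model describes a single human atrial myocyte with Hodgkin-Huxley-type
ionic currents (I_Na, I_to, I_Kur, I_Kr, I_Ks, I_CaL, I_K1), pumps and
exchangers (I_NaK, I_NaCa, I_pCa), background currents, and a two-compartment
sarcoplasmic-reticulum calcium subsystem.  The native inward rectifier is
replaced by the genotype-specific formulation of :mod:`atrikir.ik1`, which is
the quantity of interest in this package: gain-of-function Kir2.1 mutations
(D172N, E299V) reshape I_K1 and thereby resting potential and repolarisation.

Numerics follow the standard explicit scheme for this model family:
Rush-Larsen exponential updates for gating variables, forward Euler for the
membrane potential and intracellular concentrations.  The stimulus current is
assigned to the K+ flux so that long paced runs conserve charge.

State vector (length 21)::

    0  V      membrane potential, mV
    1  m      I_Na activation
    2  h      I_Na fast inactivation
    3  j      I_Na slow inactivation
    4  oa     I_to activation
    5  oi     I_to inactivation
    6  ua     I_Kur activation
    7  ui     I_Kur inactivation
    8  xr     I_Kr activation
    9  xs     I_Ks activation
    10 d      I_CaL activation
    11 f      I_CaL voltage inactivation
    12 w      SR release voltage inactivation
    13 fca    I_CaL calcium inactivation
    14 u      SR release activation
    15 v      SR release inactivation
    16 Na_i   mM
    17 K_i    mM
    18 Ca_i   mM
    19 Ca_up  SR uptake compartment, mM
    20 Ca_rel SR release compartment, mM

All membrane currents are in pA/pF; conductances in nS/pF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .ik1 import IK1Params, genotype_params, GENOTYPES

__all__ = [
    "N_STATE",
    "STATE_NAMES",
    "CURRENT_NAMES",
    "CellParams",
    "initial_state",
    "derivatives",
    "step",
    "apply_intervention",
    "pace",
    "region_scalings",
    "REGIONS",
]

N_STATE = 21
STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "w", "fca", "u", "v", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)
CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
    "I_pCa", "I_NaK", "I_NaCa", "I_bNa", "I_bCa",
)

# Physical constants and cell geometry (model-native values)
R_GAS = 8.3143
T_KELVIN = 310.0
F_CONST = 96.4867
RTF = R_GAS * T_KELVIN / F_CONST
CM_PF = 100.0  # membrane capacitance, pF
V_I = 13668.0  # intracellular volume, um^3
V_UP = 1109.52
V_REL = 96.48
NA_O = 140.0  # mM
K_O = 5.4
CA_O = 1.8
KQ10 = 3.0

# Parameter-vector layout (float64 row consumed by the numba kernels)
NP_PARAMS = 17
(
    IP_GNA, IP_GTO, IP_GKUR, IP_GKR, IP_GKS, IP_GCAL,
    IP_INAK, IP_INACA, IP_IPCA, IP_GBNA, IP_GBCA,
    IP_WG1, IP_A1, IP_B1, IP_WG2, IP_A2, IP_B2,
) = range(NP_PARAMS)

#: Intervention / scaling keys understood by :func:`apply_intervention`.
_CURRENT_KEYS = {
    "I_Na": "g_na", "I_to": "g_to", "I_Kur": "g_kur", "I_Kr": "g_kr",
    "I_Ks": "g_ks", "I_CaL": "g_cal", "I_NaK": "i_nak", "I_NaCa": "i_naca",
    "I_pCa": "i_pca", "I_bNa": "g_b_na", "I_bCa": "g_b_ca", "I_K1": "g_k1_scale",
}

#: Regional conductance-scaling sets, multiplicative relative to the baseline
#: right-atrial model.  These are documented approximations of the regional
#: electrophysiological gradients reported for human/canine atria (crista
#: terminalis with larger I_CaL and long APD; pectinate muscles with larger
#: I_to and slightly shorter APD; left atrium and pulmonary-vein sleeves with
#: higher I_Kr and, for PV, reduced I_K1/I_CaL giving short APD and
#: depolarised resting potential).
REGIONS = {
    "RA": {},
    "CT": {"I_CaL": 1.6, "I_to": 1.35},
    "PM": {"I_CaL": 0.90, "I_to": 1.05},
    "RAA": {"I_to": 0.68, "I_Kur": 0.68},
    "AVR": {"I_CaL": 0.67, "I_to": 0.6},
    "AS": {"I_CaL": 0.8},
    "BB": {"I_CaL": 1.3, "I_to": 1.2},
    "LA": {"I_Kr": 1.6},
    "LAA": {"I_Kr": 1.6, "I_to": 0.68},
    "PV": {"I_Kr": 1.6, "I_K1": 0.7, "I_CaL": 0.7, "I_to": 0.75},
}


def region_scalings(region: str) -> dict[str, float]:
    try:
        return dict(REGIONS[region])
    except KeyError:
        raise ValueError(f"unknown region {region!r}; expected one of {sorted(REGIONS)}") from None


@dataclass(frozen=True)
class CellParams:
    """Maximal conductances/fluxes of the atrial cell model.

    The I_K1 component is carried as one or two rectifier populations
    ``(weight * g, a, b)``; two populations implement the heterozygote-as-
    mixture mode.  ``g_k1_scale`` is a plain multiplier applied on top
    (used by regional scalings and interventions).
    """

    g_na: float = 7.8
    g_to: float = 0.1652
    g_kur: float = 1.0          # multiplier on the native V-dependent g_Kur
    g_kr: float = 0.029411765
    g_ks: float = 0.12941176
    g_cal: float = 0.12375
    i_nak: float = 0.59933874
    i_naca: float = 1600.0
    i_pca: float = 0.275
    g_b_na: float = 0.0006744375
    g_b_ca: float = 0.001131
    ik1: IK1Params = field(default_factory=lambda: genotype_params("WT"))
    ik1_wt: IK1Params | None = None   # WT component for mixture mode
    g_k1_scale: float = 1.0
    cm: float = CM_PF
    genotype: str = "WT"
    region: str = "RA"

    @classmethod
    def for_genotype(
        cls,
        genotype: str = "WT",
        ik1: IK1Params | None = None,
        region: str = "RA",
        intervention: dict[str, float] | None = None,
    ) -> "CellParams":
        """Baseline parameters with the genotype's I_K1 formulation.

        ``ik1`` overrides the fixture parameter set (e.g. with freshly
        fitted parameters).  Region scalings and interventions compose
        multiplicatively and commute.
        """
        if ik1 is None:
            ik1 = genotype_params(genotype)
        p = cls(ik1=ik1, genotype=genotype, region=region)
        if region != "RA":
            p = apply_intervention(p, region_scalings(region))
        if intervention:
            p = apply_intervention(p, intervention)
        return p

    def to_vector(self) -> np.ndarray:
        vec = np.zeros(NP_PARAMS)
        vec[IP_GNA] = self.g_na
        vec[IP_GTO] = self.g_to
        vec[IP_GKUR] = self.g_kur
        vec[IP_GKR] = self.g_kr
        vec[IP_GKS] = self.g_ks
        vec[IP_GCAL] = self.g_cal
        vec[IP_INAK] = self.i_nak
        vec[IP_INACA] = self.i_naca
        vec[IP_IPCA] = self.i_pca
        vec[IP_GBNA] = self.g_b_na
        vec[IP_GBCA] = self.g_b_ca
        s = self.g_k1_scale
        if self.ik1.mixture_weight is None:
            vec[IP_WG1] = s * self.ik1.g_k1
            vec[IP_A1] = self.ik1.a
            vec[IP_B1] = self.ik1.b
        else:
            w = self.ik1.mixture_weight
            wt = self.ik1_wt if self.ik1_wt is not None else genotype_params("WT")
            vec[IP_WG1] = s * w * wt.g_k1
            vec[IP_A1] = wt.a
            vec[IP_B1] = wt.b
            vec[IP_WG2] = s * (1.0 - w) * self.ik1.g_k1
            vec[IP_A2] = self.ik1.a
            vec[IP_B2] = self.ik1.b
        return vec


def apply_intervention(params: CellParams, spec: dict[str, float]) -> CellParams:
    """Scale maximal conductances by per-current multipliers.

    ``spec`` maps current names (``"I_Kr"``, ``"I_CaL"``, ...) to
    non-negative multipliers; unnamed currents are untouched and the input
    object is not modified.
    """
    updates: dict[str, float] = {}
    for name, mult in spec.items():
        if name not in _CURRENT_KEYS:
            raise ValueError(f"unknown current {name!r}; expected one of {sorted(_CURRENT_KEYS)}")
        if mult < 0:
            raise ValueError(f"multiplier for {name} must be >= 0, got {mult}")
        attr = _CURRENT_KEYS[name]
        updates[attr] = getattr(params, attr) * mult
    return replace(params, **updates)


def initial_state() -> np.ndarray:
    """Model-native resting state (quiescent, ~-81 mV with the native I_K1)."""
    y = np.zeros(N_STATE)
    y[0] = -81.18
    y[1] = 2.908e-3
    y[2] = 9.649e-1
    y[3] = 9.775e-1
    y[4] = 3.043e-2
    y[5] = 9.992e-1
    y[6] = 4.966e-3
    y[7] = 9.986e-1
    y[8] = 3.296e-5
    y[9] = 1.869e-2
    y[10] = 1.367e-4
    y[11] = 9.996e-1
    y[12] = 9.992e-1   # w
    y[13] = 7.755e-1   # fca
    y[14] = 0.0        # u
    y[15] = 1.0        # v
    y[16] = 11.17
    y[17] = 139.0
    y[18] = 1.013e-4
    y[19] = 1.488
    y[20] = 1.488
    return y


# ---------------------------------------------------------------------------
# Rate and current kernels (scalar, numba-compiled)
# ---------------------------------------------------------------------------

N_VGATE = 12  # V-dependent HH gates, contiguous at state indices 1..12


@njit(cache=True)
def _vgate_coeffs(v, inf, tau):
    """Steady states and time constants of the 12 V-dependent gates."""
    # I_Na m
    if abs(v + 47.13) < 1e-7:
        am = 3.2
    else:
        am = 0.32 * (v + 47.13) / (1.0 - np.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * np.exp(-v / 11.0)
    inf[0] = am / (am + bm)
    tau[0] = 1.0 / (am + bm)
    # I_Na h, j
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * np.exp(-(v + 80.0) / 6.8)
        bh = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        aj = ((-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    inf[1] = ah / (ah + bh)
    tau[1] = 1.0 / (ah + bh)
    inf[2] = aj / (aj + bj)
    tau[2] = 1.0 / (aj + bj)
    # I_to oa, oi
    aoa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    boa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    inf[3] = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))
    tau[3] = 1.0 / ((aoa + boa) * KQ10)
    aoi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    boi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    inf[4] = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))
    tau[4] = 1.0 / ((aoi + boi) * KQ10)
    # I_Kur ua, ui (ua shares rate constants with oa)
    inf[5] = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))
    tau[5] = tau[3]
    aui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    bui = np.exp((v - 158.0) / 16.0)
    inf[6] = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))
    tau[6] = 1.0 / ((aui + bui) * KQ10)
    # I_Kr xr
    if abs(v + 14.1) < 1e-7:
        axr = 0.0015
    else:
        axr = 0.0003 * (v + 14.1) / (1.0 - np.exp(-(v + 14.1) / 5.0))
    if abs(v - 3.3328) < 1e-7:
        bxr = 3.7836118e-4
    else:
        bxr = 7.3898e-5 * (v - 3.3328) / (np.exp((v - 3.3328) / 5.1237) - 1.0)
    inf[7] = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))
    tau[7] = 1.0 / (axr + bxr)
    # I_Ks xs
    if abs(v - 19.9) < 1e-7:
        axs = 0.00068
        bxs = 0.000315
    else:
        axs = 4e-5 * (v - 19.9) / (1.0 - np.exp(-(v - 19.9) / 17.0))
        bxs = 3.5e-5 * (v - 19.9) / (np.exp((v - 19.9) / 9.0) - 1.0)
    inf[8] = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))
    tau[8] = 0.5 / (axs + bxs)
    # I_CaL d, f
    if abs(v + 10.0) < 1e-7:
        tau[9] = 2.28954  # analytic limit at v = -10
    else:
        e = np.exp(-(v + 10.0) / 6.24)
        tau[9] = (1.0 - e) / (0.035 * (v + 10.0) * (1.0 + e))
    inf[9] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0))
    inf[10] = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))
    tau[10] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    # SR release w
    if abs(v - 7.9) < 1e-7:
        tau[11] = 6.0 * 0.2 / 1.3
    else:
        e = np.exp(-(v - 7.9) / 5.0)
        tau[11] = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * (v - 7.9))
    inf[11] = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))


SIGMA_NAK = (np.exp(NA_O / 67.3) - 1.0) / 7.0


@njit(cache=True)
def _currents(y, p, cur):
    """Membrane currents in pA/pF.

    ``cur`` layout matches CURRENT_NAMES:
    0 I_Na, 1 I_K1, 2 I_to, 3 I_Kur, 4 I_Kr, 5 I_Ks, 6 I_CaL,
    7 I_pCa, 8 I_NaK, 9 I_NaCa, 10 I_bNa, 11 I_bCa
    """
    v = y[0]
    nai = y[16]
    ki = y[17]
    cai = y[18]
    e_na = RTF * np.log(NA_O / nai)
    e_k = RTF * np.log(K_O / ki)
    e_ca = 0.5 * RTF * np.log(CA_O / cai)

    cur[0] = p[IP_GNA] * y[1] ** 3 * y[2] * y[3] * (v - e_na)
    # genotype-specific inward rectifier (up to two populations); the
    # Boltzmann factor is normalised so a = 0 is exactly ohmic
    ik1 = p[IP_WG1] * (v - e_k) * 2.0 / (
        1.0 + np.exp(min(p[IP_A1] * (v - p[IP_B1]), 80.0)))
    if p[IP_WG2] > 0.0:
        ik1 += p[IP_WG2] * (v - e_k) * 2.0 / (
            1.0 + np.exp(min(p[IP_A2] * (v - p[IP_B2]), 80.0)))
    cur[1] = ik1
    cur[2] = p[IP_GTO] * y[4] ** 3 * y[5] * (v - e_k)
    gkur = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    cur[3] = p[IP_GKUR] * gkur * y[6] ** 3 * y[7] * (v - e_k)
    cur[4] = p[IP_GKR] * y[8] * (v - e_k) / (1.0 + np.exp((v + 15.0) / 22.4))
    cur[5] = p[IP_GKS] * y[9] ** 2 * (v - e_k)
    cur[6] = p[IP_GCAL] * y[10] * y[11] * y[13] * (v - 65.0)
    cur[7] = p[IP_IPCA] * cai / (0.0005 + cai)
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                  + 0.0365 * SIGMA_NAK * np.exp(-v / RTF))
    cur[8] = (p[IP_INAK] * fnak * K_O / (K_O + 1.5)
              / (1.0 + (10.0 / nai) ** 1.5))
    e1 = np.exp(0.35 * v / RTF)
    e2 = np.exp((0.35 - 1.0) * v / RTF)
    cur[9] = (p[IP_INACA] * (e1 * nai ** 3 * CA_O - e2 * NA_O ** 3 * cai)
              / ((87.5 ** 3 + NA_O ** 3) * (1.38 + CA_O) * (1.0 + 0.1 * e2)))
    cur[10] = p[IP_GBNA] * (v - e_na)
    cur[11] = p[IP_GBCA] * (v - e_ca)
    return cur


@njit(cache=True)
def _calcium_subsystem(y, cur, dy):
    """SR fluxes, Ca-dependent gate rates, and concentration derivatives.

    Fills dy[12..14] (fca, u, v as (inf - x)/tau pairs encoded directly)
    and dy[16..20]; also returns (fca_inf, u_inf, v_inf, tau_v) for
    Rush-Larsen updates.
    """
    cai = y[18]
    caup = y[19]
    carel = y[20]

    irel = 30.0 * y[14] ** 2 * y[15] * y[12] * (carel - cai)
    itr = (caup - carel) / 180.0
    iup = 0.005 / (1.0 + 0.00092 / cai)
    iupleak = 0.005 * caup / 15.0

    # SR release gating driven by flux Fn (currents converted to pA).  The
    # sigmoids are near-step functions of Fn; saturate them outside +-40
    # widths (exp(-40) ~ 4e-18, below double-precision resolution here).
    fn = 1e-12 * V_REL * irel - 5e-13 / F_CONST * (
        0.5 * cur[6] * CM_PF - 0.2 * cur[9] * CM_PF)
    zu = (fn - 3.4175e-13) / 1.367e-15
    if zu > 40.0:
        u_inf = 1.0
    elif zu < -40.0:
        u_inf = 0.0
    else:
        u_inf = 1.0 / (1.0 + np.exp(-zu))
    zv = (fn - 6.835e-14) / 1.367e-15
    if zv > 40.0:
        v_inf = 0.0
    elif zv < -40.0:
        v_inf = 1.0
    else:
        v_inf = 1.0 - 1.0 / (1.0 + np.exp(-zv))
    tau_v = 1.91 + 2.09 * u_inf
    fca_inf = 1.0 / (1.0 + cai / 0.00035)

    c = CM_PF / (F_CONST * V_I)
    dy[16] = (-3.0 * cur[8] - 3.0 * cur[9] - cur[10] - cur[0]) * c
    dy[17] = (2.0 * cur[8] - cur[1] - cur[2] - cur[3] - cur[4] - cur[5]) * c
    b1 = ((2.0 * cur[9] - cur[7] - cur[6] - cur[11]) * CM_PF / (2.0 * F_CONST * V_I)
          + (V_UP * (iupleak - iup) + irel * V_REL) / V_I)
    b2 = (1.0 + 0.07 * 0.0005 / (cai + 0.0005) ** 2
          + 0.05 * 0.00238 / (cai + 0.00238) ** 2)
    dy[18] = b1 / b2
    dy[19] = iup - iupleak - itr * V_REL / V_UP
    dy[20] = (itr - irel) / (1.0 + 10.0 * 0.8 / (carel + 0.8) ** 2)
    return fca_inf, u_inf, v_inf, tau_v


@njit(cache=True)
def _derivatives(y, p, i_stim, dy, cur):
    """Full right-hand side dy/dt; i_stim > 0 depolarises."""
    inf = np.empty(N_VGATE)
    tau = np.empty(N_VGATE)
    _vgate_coeffs(y[0], inf, tau)
    _currents(y, p, cur)
    fca_inf, u_inf, v_inf, tau_v = _calcium_subsystem(y, cur, dy)

    i_ion = 0.0
    for k in range(12):
        i_ion += cur[k]
    dy[0] = -(i_ion - i_stim)
    # stimulus carried by K+ (keeps the paced limit cycle charge-conserving)
    dy[17] += i_stim * CM_PF / (F_CONST * V_I)

    for g in range(N_VGATE):
        dy[1 + g] = (inf[g] - y[1 + g]) / tau[g]
    dy[13] = (fca_inf - y[13]) / 2.0
    dy[14] = (u_inf - y[14]) / 8.0
    dy[15] = (v_inf - y[15]) / tau_v
    return dy


@njit(cache=True)
def _step(y, dt, p, i_stim):
    """Advance one step in place: Rush-Larsen gates, Euler V/concentrations."""
    inf = np.empty(N_VGATE)
    tau = np.empty(N_VGATE)
    cur = np.empty(12)
    dy = np.empty(N_STATE)
    _vgate_coeffs(y[0], inf, tau)
    _currents(y, p, cur)
    fca_inf, u_inf, v_inf, tau_v = _calcium_subsystem(y, cur, dy)

    i_ion = 0.0
    for k in range(12):
        i_ion += cur[k]
    v_new = y[0] - dt * (i_ion - i_stim)

    for g in range(N_VGATE):
        x = inf[g] + (y[1 + g] - inf[g]) * np.exp(-dt / tau[g])
        y[1 + g] = min(max(x, 0.0), 1.0)
    y[13] = fca_inf + (y[13] - fca_inf) * np.exp(-dt / 2.0)
    y[14] = u_inf + (y[14] - u_inf) * np.exp(-dt / 8.0)
    y[15] = v_inf + (y[15] - v_inf) * np.exp(-dt / tau_v)

    y[16] += dt * dy[16]
    y[17] += dt * (dy[17] + i_stim * CM_PF / (F_CONST * V_I))
    y[18] += dt * dy[18]
    y[19] += dt * dy[19]
    y[20] += dt * dy[20]
    # positivity floors (guard against Euler overshoot under extreme stimuli)
    y[16] = max(y[16], 1.0)
    y[17] = max(y[17], 1.0)
    for k in (18, 19, 20):
        y[k] = max(y[k], 1e-7)
    y[0] = v_new
    return y


@njit(cache=True)
def _pace_kernel(y, p, bcl, n_beats, dt, stim_amp, stim_dur, rec_from_beat, rec_stride):
    """Pace with rectangular stimuli; record V from ``rec_from_beat`` on.

    Returns (times, voltages, ik1_trace) sampled every ``rec_stride`` steps.
    """
    steps_per_beat = int(round(bcl / dt))
    stim_steps = int(round(stim_dur / dt))
    n_rec_beats = n_beats - rec_from_beat
    n_samp = (n_rec_beats * steps_per_beat) // rec_stride + 1
    t_out = np.empty(n_samp)
    v_out = np.empty(n_samp)
    ik1_out = np.empty(n_samp)
    cur = np.empty(12)
    k = 0
    isamp = 0
    for beat in range(n_beats):
        for s in range(steps_per_beat):
            if beat >= rec_from_beat and (k % rec_stride) == 0 and isamp < n_samp:
                t_out[isamp] = (beat - rec_from_beat) * bcl + s * dt
                _currents(y, p, cur)
                v_out[isamp] = y[0]
                ik1_out[isamp] = cur[1]
                isamp += 1
            stim = stim_amp if s < stim_steps else 0.0
            _step(y, dt, p, stim)
            if beat >= rec_from_beat:
                k += 1
        if not np.isfinite(y[0]):
            break
    return t_out[:isamp], v_out[:isamp], ik1_out[:isamp]


def derivatives(state: np.ndarray, params: CellParams, i_stim: float = 0.0):
    """Rate of change of the state and the traced current components.

    Returns
    -------
    dy : ndarray of shape (21,), per-ms rates
    currents : dict mapping CURRENT_NAMES to pA/pF values
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state (numerical blow-up)")
    dy = np.empty(N_STATE)
    cur = np.empty(12)
    _derivatives(y, params.to_vector(), i_stim, dy, cur)
    return dy, dict(zip(CURRENT_NAMES, cur))


def step(state: np.ndarray, dt: float, params: CellParams, i_stim: float = 0.0):
    """One Rush-Larsen / forward-Euler step; returns the new state."""
    if dt <= 0 or dt > 0.02:
        raise ValueError("dt must lie in (0, 0.02] ms")
    y = np.array(state, dtype=float)
    _step(y, dt, params.to_vector(), i_stim)
    if not np.isfinite(y[0]):
        raise FloatingPointError("membrane potential diverged")
    return y


def pace(
    params: CellParams,
    bcl: float = 1000.0,
    n_beats: int = 50,
    dt: float = 0.005,
    stim_amp: float = 20.0,
    stim_dur: float = 2.0,
    record_last: int = 2,
    sample_ms: float = 0.05,
    state: np.ndarray | None = None,
):
    """Pace to (near) steady state and record the final beats.

    Returns
    -------
    dict with keys ``t`` (ms, zeroed at the start of the recorded window),
    ``V`` (mV), ``I_K1`` (pA/pF) and ``state`` (final state vector).
    """
    y = initial_state() if state is None else np.array(state, dtype=float)
    rec_from = max(n_beats - record_last, 0)
    stride = max(int(round(sample_ms / dt)), 1)
    t, v, ik1 = _pace_kernel(
        y, params.to_vector(), bcl, n_beats, dt, stim_amp, stim_dur, rec_from, stride
    )
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("membrane potential diverged during pacing")
    return {"t": t, "V": v, "I_K1": ik1, "state": y, "bcl": bcl, "stim_dur": stim_dur}
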