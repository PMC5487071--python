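import numpy as np
import pytest

from atrikir.cell import CellParams
from atrikir.ik1 import GENOTYPES, genotype_params, nernst_potassium


@pytest.fixture(scope="session")
def e_k():
    return nernst_potassium()


@pytest.fixture(scope="session")
def wt_params():
    return CellParams.for_genotype("WT")


@pytest.fixture(scope="session")
def fitted_genotype_biomarkers():
    """Steady-state 1 Hz biomarkers per genotype through the full pipeline:
    synthetic noiseless I-V data -> Nelder-Mead fit -> cell model -> pacing.

    Session-scoped: this drives both the single-cell acceptance checks and
    the genotype-ordering tests.
    """
    from atrikir.ik1 import fit_ik1
    from atrikir.protocols_cell import steady_state_biomarkers
    from atrikir.synthetic import make_iv_dataset

    ek = nernst_potassium()
    out = {}
    for g in GENOTYPES:
        curve = make_iv_dataset(g, noise_sd=0.0)
        fit = fit_ik1(curve, ek, init=genotype_params(g))
        params = CellParams.for_genotype(g, ik1=fit.params)
        bm, rec = steady_state_biomarkers(params, bcl=1000.0, n_beats=50,
                                          dt=0.005)
        out[g] = bm
    return out


@pytest.fixture(scope="session")
def acceptance_thresholds():
    """Strand excitation thresholds at SI = 300 ms for all genotypes."""
    from atrikir.protocols_tissue import excitation_threshold

    return {g: excitation_threshold(CellParams.for_genotype(g), si=300.0)
            for g in GENOTYPES}


@pytest.fixture(scope="session")
def genotype_restitution():
    """S1-S2 APD restitution curves and maximal slopes per genotype."""
    from atrikir.protocols_cell import apd_restitution, max_restitution_slope

    curves, slopes = {}, {}
    for g in GENOTYPES:
        c = apd_restitution(CellParams.for_genotype(g), s1_bcl=1000.0,
                            n_conditioning=15)
        curves[g] = c
        slopes[g] = max_restitution_slope(c)
    return curves, slopes


@pytest.fixture(scope="session")
def strand_erp_cv():
    """ERP (ms) and CV (m/s) on the measurement strand at BCL 1000 ms."""
    from atrikir.protocols_tissue import (
        _condition_strand, _stim_nodes, default_strand, measure_cv,
        measure_erp,
    )
    from atrikir.tissue import StimulusEvent, run_monodomain

    geom = default_strand()
    erp, cv = {}, {}
    for g in GENOTYPES:
        params = CellParams.for_genotype(g)
        erp[g] = measure_erp(params, 1000.0, geom=geom)
        cond = _condition_strand(geom, params, 1000.0)
        rec = run_monodomain(
            geom, params, [StimulusEvent(_stim_nodes(geom), 20.0, 2.0, 0.0)],
            duration=200.0, dt=0.02, initial=cond, probes=[25, 75],
            sample_ms=0.25)
        cv[g] = measure_cv(rec, geom)
    return erp, cv


@pytest.fixture(scope="session")
def junction_vw():
    """Vulnerability-window widths (ms) at the CT|PM junction strand."""
    from atrikir.geometry import make_geometry
    from atrikir.protocols_tissue import vulnerability_window

    geom = make_geometry("junction", 25.0, 0.25, regions=("CT", "PM"),
                         split_mm=12.5)
    widths = {}
    for g in GENOTYPES:
        params = {r: CellParams.for_genotype(g, region=r)
                  for r in ("CT", "PM")}
        timings = np.arange(100.0, 432.0, 4.0)
        vw = vulnerability_window(geom, params, timings)
        widths[g] = vw.width
    return widths
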