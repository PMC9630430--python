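import numpy as np
import pytest

from nickfret.accessible_volume import compute_av
from nickfret.burst_pipeline import (CorrectionFactors, burst_search,
                                     correct_burst, select_fret_events)
from nickfret.dna_models import build_dumbbell, ligand_design
from nickfret.fret_forward import PhotophysicsParameters, simulate_efficiency
from nickfret.photon_sim import (Diffusion3DConfig, FretState, StreamConfig,
                                 simulate_stream, simulate_stream_dynamic_3d)


@pytest.fixture(scope="session")
def design():
    return ligand_design()


@pytest.fixture(scope="session")
def straight_model(design):
    return build_dumbbell(design)


@pytest.fixture(scope="session")
def straight_avs(straight_model, design):
    av_d = compute_av(straight_model, design.donor_site)
    av_a = compute_av(straight_model, design.acceptor_site)
    return av_d, av_a


@pytest.fixture(scope="session")
def straight_simulation(straight_avs):
    """Full-scale simulated efficiency of the straight B-form model."""
    av_d, av_a = straight_avs
    return simulate_efficiency(av_d, av_a,
                               PhotophysicsParameters(seed=2024))


@pytest.fixture(scope="session")
def static_stream():
    """Single-state (E = 0.5) stream with realistic corrections."""
    cfg = StreamConfig(duration=90.0, seed=5, burst_rate=4, brightness=200,
                       crosstalk=0.05, direct_excitation=0.05, gamma=1.2,
                       beta=1.1, background=(0.2,) * 6)
    return simulate_stream(cfg)


@pytest.fixture(scope="session")
def static_correction_factors():
    return CorrectionFactors(alpha=0.05, delta=0.05, gamma=1.2, beta=1.1,
                             b_dd=0.4, b_da=0.4, b_aa=0.4)


@pytest.fixture(scope="session")
def static_bursts(static_stream, static_correction_factors):
    stream, _ = static_stream
    bursts = burst_search(stream)
    for b in bursts:
        correct_burst(b, static_correction_factors)
    return bursts


@pytest.fixture(scope="session")
def two_state_dynamic_3d():
    """3D-diffusion PIE stream with two-state interconversion at
    k12 = k21 = 2000 / s (tau_R = 250 us, the regime of the fFCS
    analyses) plus its burst table."""
    tau_d = 1.3e-3
    vol = Diffusion3DConfig(duration=60.0, n_molecules=12,
                            diffusion_coefficient=0.35 ** 2 / (4 * tau_d),
                            waist_xy=0.35, waist_ratio=5.0, box_half=1.2,
                            peak_rate=120e3, time_step=6e-6, seed=3)
    cfg = StreamConfig(duration=60.0, seed=22, brightness=120,
                       states=(FretState(0.3, "linear"),
                               FretState(0.92, "kinked")),
                       transition_rates=((0.0, 2000.0), (2000.0, 0.0)),
                       background=(0.2,) * 6)
    stream, gt = simulate_stream_dynamic_3d(cfg, vol)
    bursts = burst_search(stream)
    cf = CorrectionFactors(b_dd=0.4, b_da=0.4, b_aa=0.4)
    for b in bursts:
        correct_burst(b, cf)
    sel, _ = select_fret_events(bursts, alex_2cde_max=np.inf, min_photons=50)
    return {"stream": stream, "ground_truth": gt, "bursts": sel,
            "tau_d": tau_d, "tau_r_true": 1.0 / 4000.0}
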