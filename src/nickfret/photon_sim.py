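"""Synthetic PIE confocal photon streams with full ground truth.

Emulates time-correlated single-photon counting of freely diffusing,
dual-labeled molecules under pulsed interleaved excitation (PIE): a
green pulse at the start of each cycle probes the FRET pair, a red pulse
shifted by ~20 ns probes the acceptor directly.  Molecules arrive as a
Poisson process; each transit produces a Gaussian burst envelope whose
width is set by the diffusion time.  Within a burst the molecule
interconverts between FRET states by a continuous-time Markov chain;
detected photons carry crosstalk, direct excitation, detection-factor
(gamma/beta) asymmetries, acceptor dark states, polarized detection and
Poisson background, and microtimes follow the state-dependent donor
lifetime.  An optional 3D mode propagates Brownian motion through a 3D
Gaussian detection volume for quantitative FCS work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

# detection channels
CH_DD_P, CH_DD_S = 0, 1   # donor excitation, donor emission (par/perp)
CH_DA_P, CH_DA_S = 2, 3   # donor excitation, acceptor emission (FRET)
CH_AA_P, CH_AA_S = 4, 5   # acceptor excitation, acceptor emission
CHANNEL_NAMES = {CH_DD_P: "DD_par", CH_DD_S: "DD_perp",
                 CH_DA_P: "DA_par", CH_DA_S: "DA_perp",
                 CH_AA_P: "AA_par", CH_AA_S: "AA_perp"}
GREEN_CHANNELS = (CH_DD_P, CH_DD_S, CH_DA_P, CH_DA_S)
RED_CHANNELS = (CH_AA_P, CH_AA_S)
DD_CHANNELS = (CH_DD_P, CH_DD_S)
DA_CHANNELS = (CH_DA_P, CH_DA_S)


@dataclass(frozen=True)
class FretState:
    efficiency: float
    label: str = ""


@dataclass(frozen=True)
class StreamConfig:
    """Acquisition and sample parameters of the synthetic measurement.

    ``brightness`` is the peak detected photon rate per excitation color
    (kHz) at the center of the confocal volume; ``background`` rates are
    kHz per detection channel.  ``transition_rates[i][j]`` is the i->j
    interconversion rate (1/s) between FRET states.
    """

    duration: float = 30.0               # s
    repetition_rate: float = 20e6        # Hz
    pulse_shift: float = 20e-9           # s, green -> red pulse
    burst_rate: float = 4.0              # molecules per second (<= 13)
    diffusion_time: float = 1.3e-3       # s, transit envelope scale
    brightness: float = 80.0             # kHz peak, per excitation color
    states: tuple[FretState, ...] = (FretState(0.5, "single"),)
    transition_rates: tuple[tuple[float, ...], ...] | None = None
    state_weights: tuple[float, ...] | None = None  # initial/static mixture
    donor_lifetime: float = 3.5e-9       # s, unquenched
    acceptor_lifetime: float = 1.5e-9    # s
    background: tuple[float, ...] = (0.3, 0.3, 0.3, 0.3, 0.3, 0.3)  # kHz
    crosstalk: float = 0.0               # alpha
    direct_excitation: float = 0.0       # delta
    gamma: float = 1.0
    beta: float = 1.0
    stoichiometry: float = 0.5           # sets the red/green brightness ratio
    dark_on_rate: float = 0.0            # 1/s, acceptor bright -> dark
    dark_off_rate: float = 150_000.0     # 1/s, dark -> bright
    anisotropy: float = 0.15             # steady-state r for the pol. split
    l1: float = 0.0
    l2: float = 0.0
    g_factor: float = 1.0
    macrotime_tick: float = 12.5e-9      # s
    microtime_unit: float = 16e-12       # s
    seed: int = 0

    def __post_init__(self):
        if self.pulse_shift >= 1.0 / self.repetition_rate:
            raise ValueError("repetition period must exceed the pulse shift")
        if not all(0 <= s.efficiency <= 1 for s in self.states):
            raise ValueError("state efficiencies must lie in [0, 1]")
        if self.transition_rates is not None:
            k = np.asarray(self.transition_rates)
            if k.shape != (len(self.states),) * 2 or (k < 0).any():
                raise ValueError("transition_rates must be a nonnegative "
                                 "square matrix matching the states")
        # dead-time realism: never more than ~1 photon per pulse
        if self.brightness * 1e3 > self.repetition_rate:
            raise ValueError("brightness exceeds one photon per pulse")

    @property
    def period(self) -> float:
        return 1.0 / self.repetition_rate


@dataclass
class PhotonStream:
    """Time-ordered photon records.

    ``macrotime`` is in clock ticks of ``macrotime_tick`` seconds (the
    pulse-cycle start), ``microtime`` in units of ``microtime_unit``
    within the PIE cycle (green-excited photons fall before the pulse
    shift, red-excited after).
    """

    macrotime: np.ndarray          # int64 ticks
    channel: np.ndarray            # int8
    microtime: np.ndarray          # int32
    macrotime_tick: float
    microtime_unit: float
    duration: float
    period: float
    pulse_shift: float

    def __post_init__(self):
        if np.any(np.diff(self.macrotime) < 0):
            raise ValueError("macrotimes must be non-decreasing")

    def __len__(self) -> int:
        return len(self.macrotime)

    @property
    def times(self) -> np.ndarray:
        """Arrival times in seconds (macrotime resolution)."""
        return self.macrotime * self.macrotime_tick

    @property
    def microtimes_s(self) -> np.ndarray:
        return self.microtime * self.microtime_unit

    def channel_mask(self, channels) -> np.ndarray:
        return np.isin(self.channel, np.asarray(channels, dtype=self.channel.dtype))


@dataclass
class GroundTruth:
    config: StreamConfig
    bursts: pd.DataFrame  # t_center, sigma, n_photons, occupancy_i, true E

    def summary(self) -> pd.DataFrame:
        return self.bursts


def _stationary_occupancy(k: np.ndarray) -> np.ndarray:
    """Stationary distribution of the CTMC with rate matrix off-diagonals k."""
    n = k.shape[0]
    q = k.copy().astype(float)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0, None) / pi.sum()


def _ctmc_trajectory(rng, k: np.ndarray, t0: float, t1: float,
                     pi0: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(switch times, states) over [t0, t1]; states[i] holds from
    switch_times[i] to switch_times[i+1]."""
    n = k.shape[0]
    pi = _stationary_occupancy(k) if pi0 is None else np.asarray(pi0) / np.sum(pi0)
    s = rng.choice(n, p=pi)
    times = [t0]
    states = [s]
    t = t0
    exit_rates = k.sum(axis=1) - np.diag(k)
    while True:
        rate = exit_rates[s]
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= t1:
            break
        p = k[s].copy()
        p[s] = 0.0
        s = rng.choice(n, p=p / p.sum())
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states, dtype=np.int64)


def simulate_stream(config: StreamConfig) -> tuple[PhotonStream, GroundTruth]:
    """Generate a PIE photon stream plus per-burst ground truth."""
    rng = np.random.default_rng(config.seed)
    cycles_total = int(config.duration / config.period)
    sigma = config.diffusion_time / 2.0  # Gaussian envelope SD of a transit

    n_states = len(config.states)
    if config.transition_rates is None:
        k_matrix = np.zeros((n_states, n_states))
    else:
        k_matrix = np.asarray(config.transition_rates, dtype=float)
    e_of_state = np.array([s.efficiency for s in config.states])

    # detection probabilities implementing gamma (acceptor/donor detection
    # asymmetry): an excited molecule emits; transfer happens with the
    # state efficiency; the photon is then detected with a color-dependent
    # probability whose ratio is gamma
    q_ref = 1.0 / max(1.0, config.gamma)
    q_donor = q_ref
    q_acceptor = config.gamma * q_ref

    peak_green = config.brightness * 1e3  # excitation events/s at peak
    # mean detected green photons per transit (integral of the envelope)
    area = math.sqrt(2 * math.pi) * sigma
    mean_exc_green = peak_green * area
    # red excitation scaled to hit the target stoichiometry (gamma-, beta-
    # corrected) for the mean-efficiency species
    # gamma-corrected green signal F_gc = gamma F_DD + F_DA is
    # E-independent: mean_exc * gamma * q_ref
    f_green_corr = mean_exc_green * config.gamma * q_ref
    s_t = config.stoichiometry
    mean_aa = f_green_corr * (1 - s_t) / s_t * config.beta
    n_bursts = rng.poisson(config.burst_rate * config.duration)
    burst_centers = np.sort(rng.uniform(0, config.duration, n_bursts))

    mt_list, ch_list, nt_list = [], [], []
    gt_rows = []

    tau_a = config.acceptor_lifetime
    shift = config.pulse_shift
    period = config.period
    dark = config.dark_on_rate > 0

    for b_id, t0 in enumerate(burst_centers):
        n_exc = rng.poisson(mean_exc_green)
        t_exc = np.sort(t0 + sigma * rng.standard_normal(n_exc))
        t_exc = t_exc[(t_exc >= 0) & (t_exc < config.duration)]
        n_aa = rng.poisson(mean_aa)
        t_aa = np.sort(t0 + sigma * rng.standard_normal(n_aa))
        t_aa = t_aa[(t_aa >= 0) & (t_aa < config.duration)]
        lo = t0 - 5 * sigma
        hi = t0 + 5 * sigma

        sw_t, sw_s = _ctmc_trajectory(rng, k_matrix, lo, hi,
                                      pi0=config.state_weights)
        state_at = sw_s[np.clip(np.searchsorted(sw_t, t_exc, side="right") - 1,
                                0, len(sw_s) - 1)] if len(t_exc) else \
            np.empty(0, dtype=np.int64)
        if dark:
            kd = np.array([[0.0, config.dark_on_rate],
                           [config.dark_off_rate, 0.0]])
            dk_t, dk_s = _ctmc_trajectory(rng, kd, lo, hi)

            def is_bright(t):
                i = np.clip(np.searchsorted(dk_t, t, side="right") - 1,
                            0, len(dk_s) - 1)
                return dk_s[i] == 0
        else:
            def is_bright(t):
                return np.ones(len(t), dtype=bool)

        # --- green-excited photons -------------------------------------
        e_state = e_of_state[state_at] if len(t_exc) else np.empty(0)
        bright = is_bright(t_exc)
        e_eff = np.where(bright, e_state, 0.0)
        u = rng.uniform(size=len(t_exc))
        transfer = u < e_eff
        det = rng.uniform(size=len(t_exc)) < np.where(transfer, q_acceptor,
                                                      q_donor)
        # crosstalk: donor emission spills into the FRET channel as an
        # additional, independent detection with probability alpha times
        # the donor detection probability (keeping the donor microtime),
        # matching the correction convention F_DA' = F_DA - alpha F_DD
        leak = rng.uniform(size=len(t_exc)) < config.crosstalk * q_donor
        occupancy = np.bincount(state_at, minlength=n_states) / max(len(t_exc), 1)

        tau_dd = config.donor_lifetime * np.clip(1 - e_state, 1e-3, 1.0)
        micro_d = rng.exponential(tau_dd)
        micro_a = rng.exponential(tau_a, size=len(t_exc))
        keep = det
        t_keep = t_exc[keep]
        is_fret = transfer[keep]
        micro = np.where(is_fret, micro_a[keep], micro_d[keep]) % shift
        ch = np.where(is_fret, CH_DA_P, CH_DD_P).astype(np.int8)
        mt_list.append(t_keep)
        ch_list.append(ch)
        nt_list.append(micro)
        # spilled-over donor photons (extra FRET-channel detections)
        spill = (~transfer) & leak
        t_spill = t_exc[spill]
        mt_list.append(t_spill)
        ch_list.append(np.full(len(t_spill), CH_DA_P, dtype=np.int8))
        nt_list.append(micro_d[spill] % shift)
        n_green_det = len(t_keep) + len(t_spill)

        # direct excitation of the acceptor by the green pulse
        n_dir = rng.poisson(config.direct_excitation * mean_aa)
        if n_dir:
            t_dir = t0 + sigma * rng.standard_normal(n_dir)
            t_dir = t_dir[(t_dir >= 0) & (t_dir < config.duration)]
            t_dir = t_dir[is_bright(t_dir)]
            mt_list.append(t_dir)
            ch_list.append(np.full(len(t_dir), CH_DA_P, dtype=np.int8))
            nt_list.append(rng.exponential(tau_a, len(t_dir)) % shift)

        # --- red-excited photons ---------------------------------------
        t_aa = t_aa[is_bright(t_aa)]
        mt_list.append(t_aa)
        ch_list.append(np.full(len(t_aa), CH_AA_P, dtype=np.int8))
        nt_list.append(shift + rng.exponential(tau_a, len(t_aa))
                       % (period - shift))

        true_e = float(np.sum(occupancy * e_of_state))
        row = {"burst_id": b_id, "t_center": t0, "sigma": sigma,
               "n_green_detected": n_green_det, "n_red": len(t_aa),
               "true_E": true_e,
               "true_S": s_t}
        for i in range(n_states):
            row[f"occupancy_{i}"] = occupancy[i]
        gt_rows.append(row)

    t_all = np.concatenate(mt_list) if mt_list else np.empty(0)
    ch_all = np.concatenate(ch_list) if ch_list else np.empty(0, np.int8)
    nt_all = np.concatenate(nt_list) if nt_list else np.empty(0)

    # polarization split of the molecular photons from the steady-state
    # anisotropy (with the G-factor as a parallel-channel detection
    # efficiency); background is unpolarized and added per channel below
    r = config.anisotropy
    w_par = (1 + 2 * r) / config.g_factor
    w_perp = (1 - r)
    p_par = w_par / (w_par + w_perp)
    perp = rng.uniform(size=len(ch_all)) >= p_par
    ch_all = np.where((ch_all % 2 == 0) & perp, ch_all + 1, ch_all
                      ).astype(np.int8)

    # --- background ----------------------------------------------------
    bg_t, bg_ch, bg_nt = [t_all], [ch_all], [nt_all]
    for ch_id in range(6):
        rate = config.background[ch_id] * 1e3
        n_bg = rng.poisson(rate * config.duration)
        t_bg = rng.uniform(0, config.duration, n_bg)
        if ch_id in GREEN_CHANNELS:
            micro = rng.uniform(0, shift, n_bg)
        else:
            micro = rng.uniform(shift, period, n_bg)
        bg_t.append(t_bg)
        bg_ch.append(np.full(n_bg, ch_id, dtype=np.int8))
        bg_nt.append(micro)
    t_all = np.concatenate(bg_t)
    ch_all = np.concatenate(bg_ch)
    nt_all = np.concatenate(bg_nt)

    # quantize: macrotime to the pulse cycle, microtime to the TCSPC unit
    cycle = np.clip((t_all / period).astype(np.int64), 0, cycles_total - 1)
    ticks_per_cycle = period / config.macrotime_tick
    macro = (cycle * ticks_per_cycle).astype(np.int64)
    micro_units = np.clip((nt_all / config.microtime_unit).astype(np.int32),
                          0, int(period / config.microtime_unit) - 1)
    order = np.lexsort((micro_units, macro))
    stream = PhotonStream(
        macrotime=macro[order], channel=ch_all[order],
        microtime=micro_units[order],
        macrotime_tick=config.macrotime_tick,
        microtime_unit=config.microtime_unit,
        duration=config.duration, period=period, pulse_shift=shift)
    gt = GroundTruth(config=config, bursts=pd.DataFrame(gt_rows))
    return stream, gt


def ground_truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """Per-burst state occupancies, true E/S and transit info."""
    return gt.bursts.copy()


def merge_streams(streams: list[PhotonStream]) -> PhotonStream:
    """Merge photon streams recorded with identical settings (used to
    compose mixtures of labeled species, e.g. donor-only + FRET)."""
    ref = streams[0]
    for s in streams[1:]:
        if (s.macrotime_tick != ref.macrotime_tick
                or s.period != ref.period):
            raise ValueError("streams must share acquisition settings")
    macro = np.concatenate([s.macrotime for s in streams])
    ch = np.concatenate([s.channel for s in streams])
    micro = np.concatenate([s.microtime for s in streams])
    order = np.lexsort((micro, macro))
    return PhotonStream(
        macrotime=macro[order], channel=ch[order], microtime=micro[order],
        macrotime_tick=ref.macrotime_tick, microtime_unit=ref.microtime_unit,
        duration=max(s.duration for s in streams), period=ref.period,
        pulse_shift=ref.pulse_shift)


# ---------------------------------------------------------------------------
# optional 3D mode: Brownian motion through a 3D Gaussian detection volume

@dataclass(frozen=True)
class Diffusion3DConfig:
    duration: float = 20.0
    n_molecules: int = 10
    diffusion_coefficient: float = 400.0  # µm^2/s
    waist_xy: float = 0.35                # µm (1/e^2 radius)
    waist_ratio: float = 5.0              # p = axial/lateral
    box_half: float = 1.5                 # µm, periodic box half-size (x, y)
    box_half_z: float | None = None       # µm; defaults to 3x the axial waist
    peak_rate: float = 60e3               # detected photons/s at the center
    background_rate: float = 300.0        # photons/s
    time_step: float = 2e-6               # s
    efficiency: float = 0.5               # split DD vs DA
    seed: int = 0

    @property
    def diffusion_time(self) -> float:
        """tau_D = w_xy^2 / (4 D) of the 2D/3D Gaussian volume."""
        return self.waist_xy ** 2 / (4 * self.diffusion_coefficient)

    @property
    def half_z(self) -> float:
        # the axial box must comfortably contain the axial detection
        # profile, otherwise periodic wrap-around decorrelates the signal
        return (3.0 * self.waist_xy * self.waist_ratio
                if self.box_half_z is None else self.box_half_z)


def simulate_stream_3d(config: Diffusion3DConfig) -> PhotonStream:
    """Photon stream from Brownian motion in a periodic box with a 3D
    Gaussian detection profile; used for quantitative FCS diffusion fits."""
    rng = np.random.default_rng(config.seed)
    n_steps = int(config.duration / config.time_step)
    n_mol = config.n_molecules
    sig = math.sqrt(2 * config.diffusion_coefficient * config.time_step)
    halves = np.array([config.box_half, config.box_half, config.half_z])
    pos = rng.uniform(-halves, halves, size=(n_mol, 3))
    wz = config.waist_xy * config.waist_ratio
    t_out, ch_out = [], []
    chunk = 200_000
    lam_peak = config.peak_rate * config.time_step
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        steps = rng.standard_normal((m, n_mol, 3)) * sig
        traj = pos[None, :, :] + np.cumsum(steps, axis=0)
        pos = ((traj[-1] + halves) % (2 * halves)) - halves
        wrapped = ((traj + halves) % (2 * halves)) - halves
        rate = lam_peak * np.exp(
            -2 * (wrapped[..., 0] ** 2 + wrapped[..., 1] ** 2)
            / config.waist_xy ** 2
            - 2 * wrapped[..., 2] ** 2 / wz ** 2)
        counts = rng.poisson(rate.sum(axis=1))
        hits = np.nonzero(counts)[0]
        for i in hits:
            t_base = (start + i) * config.time_step
            for _ in range(counts[i]):
                t_out.append(t_base + rng.uniform(0, config.time_step))
    n_bg = rng.poisson(config.background_rate * config.duration)
    t_out.extend(rng.uniform(0, config.duration, n_bg))
    t_all = np.sort(np.array(t_out))
    e = config.efficiency
    ch = np.where(rng.uniform(size=len(t_all)) < e, CH_DA_P, CH_DD_P
                  ).astype(np.int8)
    period = 50e-9
    macro = (t_all / 12.5e-9).astype(np.int64)
    micro = np.zeros(len(t_all), dtype=np.int32)
    return PhotonStream(
        macrotime=macro, channel=ch, microtime=micro,
        macrotime_tick=12.5e-9, microtime_unit=16e-12,
        duration=config.duration, period=period, pulse_shift=20e-9)


def simulate_stream_dynamic_3d(config: StreamConfig, vol: Diffusion3DConfig
                               ) -> tuple[PhotonStream, GroundTruth]:
    """PIE photon stream from Brownian motion through a 3D Gaussian
    detection volume with two-state FRET interconversion.

    Unlike the burst-envelope generator, the intensity fluctuations here
    come from actual free diffusion, so the ensemble correlation follows
    the standard Gaussian-volume diffusion model exactly -- this is the
    mode to use for quantitative FCS/fFCS parameter recovery.  Acceptor
    dark states and direct excitation are not modeled in this mode.
    """
    rng = np.random.default_rng(config.seed)
    n_states = len(config.states)
    if config.transition_rates is None:
        k_matrix = np.zeros((n_states, n_states))
    else:
        k_matrix = np.asarray(config.transition_rates, dtype=float)
    e_of_state = np.array([s.efficiency for s in config.states])
    q_ref = 1.0 / max(1.0, config.gamma)
    q_donor = q_ref
    q_acceptor = config.gamma * q_ref

    duration = config.duration
    n_mol = vol.n_molecules
    dt = vol.time_step
    n_steps = int(duration / dt)
    sig = math.sqrt(2 * vol.diffusion_coefficient * dt)
    halves = np.array([vol.box_half, vol.box_half, vol.half_z])
    wz = vol.waist_xy * vol.waist_ratio
    lam_g = vol.peak_rate * dt
    s_t = config.stoichiometry
    lam_r = lam_g * (1 - s_t) / s_t * config.beta * config.gamma * q_ref

    pos = rng.uniform(-halves, halves, size=(n_mol, 3))
    t_g, mol_g, t_r = [], [], []
    chunk = 100_000
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        steps = rng.standard_normal((m, n_mol, 3)) * sig
        traj = pos[None, :, :] + np.cumsum(steps, axis=0)
        pos = ((traj[-1] + halves) % (2 * halves)) - halves
        w = ((traj + halves) % (2 * halves)) - halves
        rate = np.exp(-2 * (w[..., 0] ** 2 + w[..., 1] ** 2)
                      / vol.waist_xy ** 2 - 2 * w[..., 2] ** 2 / wz ** 2)
        for arr, lam, is_green in ((t_g, lam_g, True), (t_r, lam_r, False)):
            counts = rng.poisson(rate * lam)  # (m, n_mol)
            idx_t, idx_m = np.nonzero(counts)
            reps = counts[idx_t, idx_m]
            tt = ((start + np.repeat(idx_t, reps)) * dt
                  + rng.uniform(0, dt, reps.sum()))
            arr.append(tt)
            if is_green:
                mol_g.append(np.repeat(idx_m, reps))
    t_g = np.concatenate(t_g)
    mol_g = np.concatenate(mol_g)
    t_r = np.concatenate(t_r)

    # per-molecule CTMC state trajectories
    state_g = np.zeros(len(t_g), dtype=np.int64)
    for mi in range(n_mol):
        sw_t, sw_s = _ctmc_trajectory(rng, k_matrix, 0.0, duration,
                                      pi0=config.state_weights)
        sel = mol_g == mi
        state_g[sel] = sw_s[np.clip(
            np.searchsorted(sw_t, t_g[sel], side="right") - 1,
            0, len(sw_s) - 1)]

    e_state = e_of_state[state_g]
    transfer = rng.uniform(size=len(t_g)) < e_state
    det = rng.uniform(size=len(t_g)) < np.where(transfer, q_acceptor, q_donor)
    leak = (~transfer) & (rng.uniform(size=len(t_g))
                          < config.crosstalk * q_donor)
    shift = config.pulse_shift
    period = config.period
    tau_dd = config.donor_lifetime * np.clip(1 - e_state, 1e-3, 1.0)
    micro_d = rng.exponential(tau_dd)
    micro_a = rng.exponential(config.acceptor_lifetime, len(t_g))

    mt = [t_g[det], t_g[leak], t_r]
    ch = [np.where(transfer[det], CH_DA_P, CH_DD_P).astype(np.int8),
          np.full(leak.sum(), CH_DA_P, dtype=np.int8),
          np.full(len(t_r), CH_AA_P, dtype=np.int8)]
    nt = [np.where(transfer[det], micro_a[det], micro_d[det]) % shift,
          micro_d[leak] % shift,
          shift + rng.exponential(config.acceptor_lifetime, len(t_r))
          % (period - shift)]

    t_all = np.concatenate(mt)
    ch_all = np.concatenate(ch)
    nt_all = np.concatenate(nt)
    r = config.anisotropy
    w_par = (1 + 2 * r) / config.g_factor
    p_par = w_par / (w_par + (1 - r))
    perp = rng.uniform(size=len(ch_all)) >= p_par
    ch_all = np.where((ch_all % 2 == 0) & perp, ch_all + 1,
                      ch_all).astype(np.int8)

    bg_t, bg_ch, bg_nt = [t_all], [ch_all], [nt_all]
    for ch_id in range(6):
        n_bg = rng.poisson(config.background[ch_id] * 1e3 * duration)
        tb = rng.uniform(0, duration, n_bg)
        micro = (rng.uniform(0, shift, n_bg) if ch_id in GREEN_CHANNELS
                 else rng.uniform(shift, period, n_bg))
        bg_t.append(tb)
        bg_ch.append(np.full(n_bg, ch_id, dtype=np.int8))
        bg_nt.append(micro)
    t_all = np.concatenate(bg_t)
    ch_all = np.concatenate(bg_ch)
    nt_all = np.concatenate(bg_nt)

    cycle = np.clip((t_all / period).astype(np.int64), 0,
                    int(duration / period) - 1)
    macro = (cycle * (period / config.macrotime_tick)).astype(np.int64)
    micro_units = np.clip((nt_all / config.microtime_unit).astype(np.int32),
                          0, int(period / config.microtime_unit) - 1)
    order = np.lexsort((micro_units, macro))
    stream = PhotonStream(
        macrotime=macro[order], channel=ch_all[order],
        microtime=micro_units[order], macrotime_tick=config.macrotime_tick,
        microtime_unit=config.microtime_unit, duration=duration,
        period=period, pulse_shift=shift)
    occ = np.bincount(state_g, minlength=n_states) / max(len(state_g), 1)
    row = {"burst_id": -1, "t_center": duration / 2, "sigma": math.nan,
           "n_green_detected": int(det.sum()), "n_red": len(t_r),
           "true_E": float(np.sum(occ * e_of_state)), "true_S": s_t}
    for i in range(n_states):
        row[f"occupancy_{i}"] = occ[i]
    gt = GroundTruth(config=config, bursts=pd.DataFrame([row]))
    return stream, gt


# ---------------------------------------------------------------------------
# photon-HDF5-compatible persistence

def write_photon_hdf5(stream: PhotonStream, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.macrotime)
        g.create_dataset("detectors", data=stream.channel)
        g.create_dataset("nanotimes", data=stream.microtime)
        g.attrs["timestamps_unit"] = stream.macrotime_tick
        g.attrs["nanotimes_unit"] = stream.microtime_unit
        m = f.create_group("measurement")
        m.attrs["duration"] = stream.duration
        m.attrs["laser_repetition_period"] = stream.period
        m.attrs["pulse_shift"] = stream.pulse_shift


def read_photon_hdf5(path: str) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        m = f["measurement"]
        return PhotonStream(
            macrotime=g["timestamps"][:], channel=g["detectors"][:],
            microtime=g["nanotimes"][:],
            macrotime_tick=float(g.attrs["timestamps_unit"]),
            microtime_unit=float(g.attrs["nanotimes_unit"]),
            duration=float(m.attrs["duration"]),
            period=float(m.attrs["laser_repetition_period"]),
            pulse_shift=float(m.attrs["pulse_shift"]))
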