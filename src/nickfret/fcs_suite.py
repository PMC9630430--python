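"""Correlation analysis: FCS, FRET-FCS and species-filtered FCS (fFCS).

Correlations are computed directly from photon timestamps (optionally
weighted) on a quasi-logarithmic lag grid,

    G(tau_k) + 1 = [ sum_{i,j} w_a(i) w_b(j) 1(tau in bin k) ]
                   * (T - tau_k) / (W_a W_b dtau_k),

which is the standard symmetric-normalized photon-pair estimator.
Curves are fitted with the diffusion model

    G(tau) = G_diff(tau) [1 + sum_i A_i exp(-tau / tau_R_i)] + offset
    G_diff(tau) = 1/(N sqrt(8)) (1 + tau/tau_D)^-1
                  (1 + tau/(p^2 tau_D))^-1/2

where N is the mean occupancy of the observation volume, tau_D the
translational diffusion time and p the ratio of the axial and lateral
dimensions of the confocal volume.  (The 1/sqrt(8) prefactor is part of
the model definition used here; it differs from the common 1/N
normalization by a constant.)

For fFCS, species are separated by their stacked TCSPC microtime
patterns (donor-parallel, donor-perpendicular and FRET channels):
filters are the weighted pseudo-inverse of the pattern matrix, so that
applying the filter of species i to the pure pattern of species k
returns delta_ik; the four auto- and cross-correlations of the filtered
photon weights share a global relaxation time tau_R whose standard
error comes from repeating the analysis on contiguous record segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from numba import njit

from .burst_pipeline import Burst
from .photon_sim import (CH_DA_P, CH_DA_S, CH_DD_P, CH_DD_S, GREEN_CHANNELS,
                         PhotonStream)


def lag_grid(lag_min: float = 1e-6, lag_max: float = 1.0,
             points_per_octave: int = 16) -> np.ndarray:
    """Quasi-logarithmic lag-bin edges (multi-tau style), seconds."""
    n = int(math.ceil(math.log2(lag_max / lag_min) * points_per_octave)) + 1
    return lag_min * 2.0 ** (np.arange(n + 1) / points_per_octave)


@dataclass
class CorrelationCurve:
    lags: np.ndarray       # bin centers (geometric mean), s
    g: np.ndarray
    sem: np.ndarray
    kind: str = "auto"

    def __post_init__(self):
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@njit(cache=True)
def _pair_sums(t, wa, wb, edges):
    """sum_i wa_i * (sum over j with t_j - t_i in [edges_k, edges_k+1)) wb_j
    for every lag bin k, via monotone two-pointer sweeps."""
    n = len(t)
    nb = len(edges) - 1
    cum = np.zeros(n + 1)
    for i in range(n):
        cum[i + 1] = cum[i] + wb[i]
    lo = np.zeros(nb, dtype=np.int64)
    hi = np.zeros(nb, dtype=np.int64)
    s = np.zeros(nb)
    for i in range(n):
        if wa[i] == 0.0:
            continue
        ti = t[i]
        for k in range(nb):
            a = lo[k]
            while a < n and t[a] < ti + edges[k]:
                a += 1
            lo[k] = a
            b = hi[k]
            if b < a:
                b = a
            while b < n and t[b] < ti + edges[k + 1]:
                b += 1
            hi[k] = b
            if b > a:
                s[k] += wa[i] * (cum[b] - cum[a])
    return s


def correlate_photons(times: np.ndarray, w_a: np.ndarray, w_b: np.ndarray,
                      duration: float, edges: np.ndarray | None = None,
                      kind: str = "auto") -> CorrelationCurve:
    """Weighted photon correlation over one stationary record.

    ``w_a``/``w_b`` are per-photon weights (1 for plain FCS, fFCS filter
    values otherwise).  Only forward pairs (t_j > t_i) enter; lag bins
    start above zero so self-pairs never contribute.
    """
    if edges is None:
        edges = lag_grid()
    if len(times) < 2:
        raise ValueError("need at least 2 photons to correlate")
    s = _pair_sums(times.astype(np.float64), w_a.astype(np.float64),
                   w_b.astype(np.float64), edges.astype(np.float64))
    a_tot = w_a.sum()
    b_tot = w_b.sum()
    centers = np.sqrt(edges[:-1] * edges[1:])
    t_eff = np.maximum(duration - centers, 1e-12)
    dtau = np.diff(edges)
    g = s * duration * duration / (t_eff * a_tot * b_tot * dtau) - 1.0
    return CorrelationCurve(lags=centers, g=g, sem=np.zeros_like(g),
                            kind=kind)


def correlate(times: np.ndarray, w_a: np.ndarray, w_b: np.ndarray,
              duration: float, edges: np.ndarray | None = None,
              n_segments: int = 1, kind: str = "auto") -> CorrelationCurve:
    """Correlation with per-point SEM estimated by splitting the record
    into ``n_segments`` contiguous segments."""
    full = correlate_photons(times, w_a, w_b, duration, edges, kind)
    if n_segments >= 2:
        gs = []
        bounds = np.linspace(0, duration, n_segments + 1)
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            m = (times >= s0) & (times < s1)
            if m.sum() < 2 or w_a[m].sum() == 0 or w_b[m].sum() == 0:
                continue
            seg = correlate_photons(times[m] - s0, w_a[m], w_b[m],
                                    s1 - s0, edges, kind)
            gs.append(seg.g)
        if len(gs) >= 2:
            gs = np.array(gs)
            full.sem = gs.std(axis=0, ddof=1) / math.sqrt(len(gs))
    return full


# ---------------------------------------------------------------------------
# model and fitting

def g_diffusion(tau: np.ndarray, n_occ: float, tau_d: float,
                p: float) -> np.ndarray:
    """Translational diffusion term with the 1/(N sqrt(8)) prefactor."""
    return (1.0 / (n_occ * math.sqrt(8.0))
            / (1.0 + tau / tau_d)
            / np.sqrt(1.0 + tau / (p * p * tau_d)))


def g_model(tau: np.ndarray, n_occ: float, tau_d: float, p: float,
            kinetic_terms: list[tuple[float, float]],
            offset: float = 0.0) -> np.ndarray:
    """Full FRET-FCS model: diffusion modulated by exponential kinetic
    terms (photophysics and conformational relaxation) plus an offset."""
    mod = np.ones_like(tau)
    for amp, tau_r in kinetic_terms:
        mod = mod + amp * np.exp(-tau / tau_r)
    return g_diffusion(tau, n_occ, tau_d, p) * mod + offset


@dataclass
class FcsFit:
    n_occ: float
    tau_d: float
    p: float
    kinetic_terms: list[tuple[float, float]]
    offset: float
    stderr: dict[str, float] = field(default_factory=dict)
    red_chi2: float = math.nan


def fit_fret_fcs(curve: CorrelationCurve,
                 n_kinetic: int = 1,
                 fixed: dict[str, float] | None = None,
                 guess: dict[str, float] | None = None) -> FcsFit:
    """Weighted least-squares fit of one correlation curve.

    ``fixed`` maps parameter names (``n_occ``, ``tau_d``, ``p``,
    ``a1``, ``tau_r1``, ``a2``, ``tau_r2``, ``offset``) to frozen
    values; ``guess`` overrides starting values.
    """
    if len(curve.lags) < 20:
        raise ValueError("need >= 20 lag points spanning the decay")
    if np.ptp(curve.g) < 1e-12:
        raise ValueError("flat curve: model parameters not identifiable")
    fixed = fixed or {}
    guess = guess or {}
    g0 = max(curve.g.max(), 1e-3)
    defaults = {"n_occ": 1.0 / (g0 * math.sqrt(8)), "tau_d": 1e-3, "p": 5.0,
                "a1": 0.1, "tau_r1": 1e-5, "a2": 0.1, "tau_r2": 3e-4,
                "offset": 0.0}
    defaults.update(guess)
    params = Parameters()
    params.add("n_occ", value=defaults["n_occ"], min=1e-6)
    params.add("tau_d", value=defaults["tau_d"], min=1e-7)
    params.add("p", value=defaults["p"], min=0.5)
    for i in range(1, 3):
        use = i <= n_kinetic
        params.add(f"a{i}", value=defaults[f"a{i}"] if use else 0.0,
                   vary=use)
        params.add(f"tau_r{i}", value=defaults[f"tau_r{i}"], min=1e-8,
                   vary=use)
    params.add("offset", value=defaults["offset"])
    for name, val in fixed.items():
        params[name].set(value=val, vary=False)

    w = np.where(curve.sem > 0, 1.0 / np.maximum(curve.sem, 1e-12), 1.0)

    def resid(pars):
        kt = [(pars[f"a{i}"].value, pars[f"tau_r{i}"].value)
              for i in range(1, n_kinetic + 1)]
        model = g_model(curve.lags, pars["n_occ"].value, pars["tau_d"].value,
                        pars["p"].value, kt, pars["offset"].value)
        return (model - curve.g) * w

    out = minimize(resid, params)
    pv = out.params
    kt = [(pv[f"a{i}"].value, pv[f"tau_r{i}"].value)
          for i in range(1, n_kinetic + 1)]
    stderr = {k: (pv[k].stderr if pv[k].stderr is not None else math.nan)
              for k in pv}
    return FcsFit(n_occ=pv["n_occ"].value, tau_d=pv["tau_d"].value,
                  p=pv["p"].value, kinetic_terms=kt,
                  offset=pv["offset"].value, stderr=stderr,
                  red_chi2=out.redchi)


# ---------------------------------------------------------------------------
# species-filtered FCS

@dataclass
class FfcsFilterSet:
    """Microtime-pattern filters of two species.

    Patterns and filters are stacked over three channel groups
    (donor-parallel, donor-perpendicular, FRET) x ``n_micro_bins``
    microtime bins spanning the green excitation window.
    """

    patterns: np.ndarray       # (2, J) normalized reference patterns
    filters: np.ndarray        # (2, J) unmixing weights
    n_micro_bins: int
    micro_bin_width: float     # s
    e_windows: dict[int, tuple[float, float]]

    def bin_index(self, channel: np.ndarray, microtime_s: np.ndarray
                  ) -> np.ndarray:
        """Stacked bin index per photon; -1 for photons outside the
        donor-excitation channel groups."""
        group = np.full(len(channel), -1, dtype=np.int64)
        group[channel == CH_DD_P] = 0
        group[channel == CH_DD_S] = 1
        group[(channel == CH_DA_P) | (channel == CH_DA_S)] = 2
        mb = np.clip((microtime_s / self.micro_bin_width).astype(np.int64),
                     0, self.n_micro_bins - 1)
        idx = group * self.n_micro_bins + mb
        idx[group < 0] = -1
        return idx

    def photon_weights(self, stream: PhotonStream
                       ) -> tuple[np.ndarray, np.ndarray]:
        idx = self.bin_index(stream.channel, stream.microtimes_s)
        w1 = np.where(idx >= 0, self.filters[0][np.clip(idx, 0, None)], 0.0)
        w2 = np.where(idx >= 0, self.filters[1][np.clip(idx, 0, None)], 0.0)
        return w1, w2


def build_ffcs_filters(stream: PhotonStream, bursts: list[Burst],
                       e_windows: dict[int, tuple[float, float]],
                       n_micro_bins: int = 64,
                       min_photons: int = 1000) -> FfcsFilterSet:
    """Statistical fFCS filters from species-pure reference patterns.

    Bursts inside each species' FRET-efficiency window provide that
    species' stacked TCSPC reference pattern; the filters are the
    Poisson-weighted pseudo-inverse of the pattern matrix and satisfy
    filter_i . pattern_k = delta_ik.
    """
    if set(e_windows) != {1, 2}:
        raise ValueError("e_windows must define species 1 and 2")
    width = stream.pulse_shift / n_micro_bins
    fs = FfcsFilterSet(patterns=np.zeros((2, 3 * n_micro_bins)),
                       filters=np.zeros((2, 3 * n_micro_bins)),
                       n_micro_bins=n_micro_bins, micro_bin_width=width,
                       e_windows=dict(e_windows))
    raw = np.zeros((2, 3 * n_micro_bins))
    for sp, (lo, hi) in e_windows.items():
        sel = [b for b in bursts if b.valid and lo < b.e_corr < hi]
        idx_all = []
        for b in sel:
            sl = slice(b.first, b.last + 1)
            idx = fs.bin_index(stream.channel[sl], stream.microtimes_s[sl])
            idx_all.append(idx[idx >= 0])
        counts = (np.bincount(np.concatenate(idx_all),
                              minlength=3 * n_micro_bins)
                  if idx_all else np.zeros(3 * n_micro_bins))
        if counts.sum() < min_photons:
            raise ValueError(
                f"species {sp} window {lo}-{hi}: only {int(counts.sum())} "
                f"pattern photons (< {min_photons})")
        raw[sp - 1] = counts
    patterns = raw / raw.sum(axis=1, keepdims=True)
    cosine = (patterns[0] @ patterns[1]
              / (np.linalg.norm(patterns[0]) * np.linalg.norm(patterns[1])))
    if cosine > 0.99:
        raise np.linalg.LinAlgError(
            f"species patterns are (nearly) linearly dependent "
            f"(cosine similarity {cosine:.4f}); the unmixing is singular")
    m_total = raw.sum(axis=0)
    d = 1.0 / np.maximum(m_total, 1.0)
    pdp = patterns @ (d[:, None] * patterns.T)
    try:
        inv = np.linalg.inv(pdp)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "species patterns are linearly dependent") from exc
    filters = inv @ (patterns * d[None, :])
    fs.patterns = patterns
    fs.filters = filters
    return fs


def species_correlations(stream: PhotonStream, filters: FfcsFilterSet,
                         bursts: list[Burst], edge_padding: float = 50e-3,
                         edges: np.ndarray | None = None,
                         n_segments: int = 1
                         ) -> dict[str, CorrelationCurve]:
    """The 2x2 matrix of species-filtered correlations.

    Photons outside the padded burst windows get zero weight, making
    this the burst-wise variant of fFCS (the between-burst dead record
    carries no filtered signal)."""
    if edges is None:
        edges = lag_grid(1e-6, 0.1)
    t = stream.times
    w1, w2 = filters.photon_weights(stream)
    in_burst = np.zeros(len(t), dtype=bool)
    for b in bursts:
        lo = np.searchsorted(t, b.start - edge_padding)
        hi = np.searchsorted(t, b.stop + edge_padding, side="right")
        in_burst[lo:hi] = True
    w1 = np.where(in_burst, w1, 0.0)
    w2 = np.where(in_burst, w2, 0.0)
    keep = (w1 != 0) | (w2 != 0)
    tk, w1k, w2k = t[keep], w1[keep], w2[keep]
    out = {}
    for name, wa, wb in (("11", w1k, w1k), ("12", w1k, w2k),
                         ("21", w2k, w1k), ("22", w2k, w2k)):
        out[name] = correlate(tk, wa, wb, stream.duration, edges,
                              n_segments=n_segments, kind=f"species {name}")
    return out


def global_fit_ffcs(curves: dict[str, CorrelationCurve], tau_d: float,
                    tau_phot: float, p: float = 5.0,
                    tau_r_guess: float = 3e-4) -> dict:
    """Global fit of the four species correlations with tau_R linked.

    tau_D and the photophysics relaxation tau_phot are fixed (taken from
    a FRET-FCS fit); each curve keeps its own occupancy, amplitudes
    (cross-correlation amplitudes may be negative) and offset.  Returns
    the linked relaxation time and the per-curve parameters.
    """
    names = ("11", "12", "21", "22")
    if set(curves) != set(names):
        raise ValueError("need the four curves 11, 12, 21, 22")
    params = Parameters()
    params.add("tau_r", value=tau_r_guess, min=1e-6, max=1.0)
    for nm in names:
        g0 = max(abs(curves[nm].g[:5]).max(), 1e-4)
        params.add(f"n_{nm}", value=1.0 / (g0 * math.sqrt(8)), min=1e-6)
        params.add(f"aphot_{nm}", value=0.05)
        params.add(f"ar_{nm}", value=0.3 if nm in ("11", "22") else -0.3)
        params.add(f"off_{nm}", value=0.0)

    def resid(pars):
        res = []
        for nm in names:
            c = curves[nm]
            w = np.where(c.sem > 0, 1.0 / np.maximum(c.sem, 1e-12), 1.0)
            model = g_model(
                c.lags, pars[f"n_{nm}"].value, tau_d, p,
                [(pars[f"aphot_{nm}"].value, tau_phot),
                 (pars[f"ar_{nm}"].value, pars["tau_r"].value)],
                pars[f"off_{nm}"].value)
            res.append((model - c.g) * w)
        return np.concatenate(res)

    out = minimize(resid, params)
    tau_r = out.params["tau_r"]
    if tau_r.stderr is None or not np.isfinite(tau_r.stderr):
        stderr = math.nan
    else:
        stderr = tau_r.stderr
    amps = {nm: out.params[f"ar_{nm}"].value for nm in names}
    if all(abs(a) < 1e-4 for a in amps.values()):
        raise RuntimeError("no kinetic amplitude: tau_R not identifiable "
                           "(static sample?)")
    return {"tau_r": tau_r.value, "tau_r_stderr": stderr,
            "amplitudes": amps, "red_chi2": out.redchi, "result": out}


def ffcs_relaxation_analysis(stream: PhotonStream, bursts: list[Burst],
                             e_windows: dict[int, tuple[float, float]],
                             tau_d: float, tau_phot: float = 7e-6,
                             p: float = 5.0, n_segments: int = 6,
                             edge_padding: float = 50e-3,
                             edges: np.ndarray | None = None) -> dict:
    """Full burst-wise fFCS analysis with segment-based uncertainty.

    Builds species filters from the corrected bursts, computes the four
    species correlations, globally fits the linked relaxation time, and
    repeats the correlation + fit on ``n_segments`` contiguous time
    periods of the record; the SEM of the per-segment relaxation times
    is the reported uncertainty.
    """
    if n_segments < 5:
        raise ValueError("need at least 5 segments for the SEM")
    filters = build_ffcs_filters(stream, bursts, e_windows)
    curves = species_correlations(stream, filters, bursts,
                                  edge_padding=edge_padding, edges=edges,
                                  n_segments=n_segments)
    fit = global_fit_ffcs(curves, tau_d=tau_d, tau_phot=tau_phot, p=p)

    seg_tau = []
    bounds = np.linspace(0.0, stream.duration, n_segments + 1)
    t = stream.times
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        m = (t >= s0) & (t < s1)
        if m.sum() < 100:
            continue
        sub = PhotonStream(
            macrotime=stream.macrotime[m] - stream.macrotime[m][0],
            channel=stream.channel[m], microtime=stream.microtime[m],
            macrotime_tick=stream.macrotime_tick,
            microtime_unit=stream.microtime_unit,
            duration=s1 - s0, period=stream.period,
            pulse_shift=stream.pulse_shift)
        first = int(np.argmax(m))
        seg_bursts = []
        for b in bursts:
            if b.start >= s0 and b.stop < s1:
                nb = Burst(first=b.first - first, last=b.last - first,
                           start=b.start - s0, stop=b.stop - s0,
                           counts=b.counts, e_corr=b.e_corr,
                           s_corr=b.s_corr, valid=b.valid)
                seg_bursts.append(nb)
        if len(seg_bursts) < 10:
            continue
        try:
            seg_curves = species_correlations(
                sub, filters, seg_bursts, edge_padding=edge_padding,
                edges=edges, n_segments=1)
            seg_fit = global_fit_ffcs(seg_curves, tau_d=tau_d,
                                      tau_phot=tau_phot, p=p,
                                      tau_r_guess=fit["tau_r"])
            seg_tau.append(seg_fit["tau_r"])
        except (RuntimeError, ValueError):
            continue
    if len(seg_tau) < 5:
        raise RuntimeError(
            f"only {len(seg_tau)} segments with sufficient bursts "
            f"(need >= 5 for the SEM)")
    seg_tau = np.array(seg_tau)
    sem = seg_tau.std(ddof=1) / math.sqrt(len(seg_tau))
    return {"tau_r": fit["tau_r"], "sem": sem,
            "segment_tau_r": seg_tau, "curves": curves,
            "filters": filters, "global_fit": fit}
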