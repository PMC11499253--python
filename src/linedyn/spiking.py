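"""Mechanistic spiking network: an excitatory LIF population with feedback
inhibition and an integration subnetwork of long synaptic time constants.

Membrane dynamics (current-based leaky integrate-and-fire):

    tau_m dx_i/dt = -x_i + g * (sum_j W_ij p_j - g_inh I_inh) + w_i s(t)

with threshold theta (reset to 0, unit spike indicator r_i), a single graded
inhibitory unit driven by the population mean rate,

    tau_I dI_inh/dt = -I_inh + mean_i r_i ,

and synaptic activations low-passing the spikes with unit-specific time
constants,

    tau_s,i dp_i/dt = -p_i + r_i .

A subnetwork of N_p units (20%) has dense recurrent connectivity (12% vs 1%)
and very slow synapses (20 s vs 100 ms): repeated input pulses make its
synaptic activation ramp across pulses (integration), while the rest of the
network decays back between pulses.  Two alternative hypotheses are
exposed as config manipulations: h1 removes the slow synapses; h2 reweights
the external input between subnetwork and rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import sparse
from scipy.stats import spearmanr

__all__ = ["SpikingConfig", "SpikingNetState", "build_network",
           "pulse_stimulus", "simulate", "apply_hypothesis",
           "subnetwork_summary"]


@dataclass
class SpikingConfig:
    n: int = 1000
    n_sub: int = 200
    tau_m: float = 0.020          # s
    theta: float = 0.1
    g: float = 2.5
    g_inh: float = 4.25
    tau_i: float = 0.050          # s
    density_sub: float = 0.12
    density_rest: float = 0.01
    tau_s_sub: float = 20.0       # s
    tau_s_rest: float = 0.1       # s
    dt: float = 0.001             # s
    # reference width of the unit spike indicator: a spike contributes a
    # fixed pulse area (spike_width / tau) to the synaptic and inhibitory
    # low-passes, independent of the integration step, so refining dt does
    # not change the effective synaptic drive
    spike_width: float = 0.001    # s
    # Gaussian noise entering the membrane derivative; per-step sd is
    # noise_scale * dt / tau_m (the derivative-form reading of "N(0,1)/5")
    noise_scale: float = 0.2
    input_gain_sub: float = 1.0
    input_gain_rest: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_i", "tau_s_sub", "tau_s_rest", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("density_sub", "density_rest"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.n_sub <= self.n:
            raise ValueError("need 0 < n_sub <= n")


@dataclass
class SpikingNetState:
    """Downsampled simulation record plus final state."""

    t: np.ndarray                 # record times, s
    p_sub: np.ndarray             # mean synaptic activation, subnetwork
    p_rest: np.ndarray
    rate_sub: np.ndarray          # mean rate (spikes/step) over record bin
    rate_rest: np.ndarray
    i_inh: np.ndarray
    spike_counts: np.ndarray      # (N,) total spikes
    x_final: np.ndarray
    p_final: np.ndarray
    config: SpikingConfig | None = None
    stimulus: dict = field(default_factory=dict)


def build_network(config: SpikingConfig) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse non-negative weight matrix and the subnetwork index set.

    Overall weights ~ U(0, 1/sqrt(N)) at the background density; the
    subnetwork block is resampled at U(0, 1/sqrt(N_p)) and its denser
    connectivity.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed % (2**31))
    n, n_sub = config.n, config.n_sub
    if config.density_rest * n * n < 1 and config.density_sub * n_sub**2 < 1:
        import warnings
        warnings.warn("requested densities give an (almost) empty matrix")
    mask = rng.random((n, n)) < config.density_rest
    W = np.where(mask, rng.uniform(0, 1 / np.sqrt(n), size=(n, n)), 0.0)
    sub = np.arange(n_sub)
    mask_sub = rng.random((n_sub, n_sub)) < config.density_sub
    W[:n_sub, :n_sub] = np.where(
        mask_sub, rng.uniform(0, 1 / np.sqrt(n_sub), size=(n_sub, n_sub)), 0.0)
    np.fill_diagonal(W, 0.0)
    return sparse.csr_matrix(W), sub


def pulse_stimulus(config: SpikingConfig, n_pulses: int = 20,
                   isi_seconds: float = 2.5, width_seconds: float = 1.0,
                   amplitude: float = 2.0, target_fraction: float = 0.25,
                   lead_seconds: float = 5.0, tail_seconds: float = 10.0,
                   seed: int | None = None) -> dict:
    """Step-pulse external input targeting a random fraction of each
    subnetwork.

    Returns the scalar pulse series ``s`` (per step), per-unit input weights
    ``w`` (uniform on targeted units, zero elsewhere), pulse onset times and
    the target index set.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed)
                                % (2**31))
    dt = config.dt
    total = lead_seconds + n_pulses * isi_seconds + tail_seconds
    steps = int(round(total / dt))
    s = np.zeros(steps)
    onsets = []
    for k in range(n_pulses):
        a = int(round((lead_seconds + k * isi_seconds) / dt))
        b = min(steps, a + int(round(width_seconds / dt)))
        s[a:b] = amplitude
        onsets.append(a * dt)
    n, n_sub = config.n, config.n_sub
    k_sub = int(round(target_fraction * n_sub))
    k_rest = int(round(target_fraction * (n - n_sub)))
    targets = np.concatenate([
        rng.choice(n_sub, size=k_sub, replace=False),
        n_sub + rng.choice(n - n_sub, size=k_rest, replace=False)])
    w = np.zeros(n)
    w[targets] = rng.uniform(0, 1, size=len(targets))
    return {"s": s, "w": w, "targets": np.sort(targets),
            "onsets": np.array(onsets), "width": width_seconds,
            "isi": isi_seconds, "n_pulses": n_pulses}


@njit(cache=True)
def _simulate_core(steps, dt, tau_m, theta, g, g_inh, tau_i, noise_step,
                   Wdata, Windices, Windptr, tau_s, w_in, s, seed,
                   record_every, n_sub, spike_width):
    # event-driven recurrent drive: W @ p is maintained as two accumulators
    # (columns from the slow subnetwork vs the rest), each decaying by its
    # group's scalar synaptic factor, with spike columns added as they occur
    # - algebraically identical to recomputing the matvec every step.
    n = len(tau_s)
    np.random.seed(seed)
    x = np.zeros(n)
    p = np.zeros(n)
    r = np.zeros(n)
    a_sub = np.zeros(n)       # sum_j<n_sub W_ij p_j
    a_rest = np.zeros(n)
    i_inh = 0.0
    spike_counts = np.zeros(n)
    n_rec = steps // record_every
    rec_p_sub = np.zeros(n_rec)
    rec_p_rest = np.zeros(n_rec)
    rec_rate_sub = np.zeros(n_rec)
    rec_rate_rest = np.zeros(n_rec)
    rec_i = np.zeros(n_rec)
    acc_rate_sub = 0.0
    acc_rate_rest = 0.0
    dt_m = dt / tau_m
    dt_i = dt / tau_i
    k_inh = spike_width / tau_i      # inhibitory gain per spike (area 1 ms)
    k_sub = spike_width / tau_s[0]   # synaptic gain per spike
    k_rest = spike_width / tau_s[n - 1]
    dec_sub = 1.0 - dt / tau_s[0]
    dec_rest = 1.0 - dt / tau_s[n - 1]
    for t in range(steps):
        st = s[t]
        nsp_sub = 0.0
        nsp_rest = 0.0
        for i in range(n):
            drive = -x[i] + g * (a_sub[i] + a_rest[i] - g_inh * i_inh) \
                + w_in[i] * st
            x[i] += dt_m * drive + noise_step * np.random.normal()
            if x[i] > theta:
                x[i] = 0.0
                r[i] = 1.0
                spike_counts[i] += 1.0
                if i < n_sub:
                    nsp_sub += 1.0
                else:
                    nsp_rest += 1.0
            else:
                r[i] = 0.0
            if not np.isfinite(x[i]):
                raise FloatingPointError("non-finite membrane potential")
        i_inh += -dt_i * i_inh + k_inh * (nsp_sub + nsp_rest) / n
        # synaptic decay (uniform within each tau group)
        for i in range(n):
            a_sub[i] *= dec_sub
            a_rest[i] *= dec_rest
        for i in range(n_sub):
            p[i] *= dec_sub
        for i in range(n_sub, n):
            p[i] *= dec_rest
        # spike contributions (CSC columns of spiking units)
        for j in range(n):
            if r[j] == 1.0:
                if j < n_sub:
                    p[j] += k_sub
                    for jj in range(Windptr[j], Windptr[j + 1]):
                        a_sub[Windices[jj]] += k_sub * Wdata[jj]
                else:
                    p[j] += k_rest
                    for jj in range(Windptr[j], Windptr[j + 1]):
                        a_rest[Windices[jj]] += k_rest * Wdata[jj]
        acc_rate_sub += nsp_sub / n_sub
        acc_rate_rest += nsp_rest / max(1, n - n_sub)
        if (t + 1) % record_every == 0:
            k = (t + 1) // record_every - 1
            rec_p_sub[k] = p[:n_sub].mean()
            rec_p_rest[k] = p[n_sub:].mean()
            rec_rate_sub[k] = acc_rate_sub / record_every
            rec_rate_rest[k] = acc_rate_rest / record_every
            rec_i[k] = i_inh
            acc_rate_sub = 0.0
            acc_rate_rest = 0.0
    return (rec_p_sub, rec_p_rest, rec_rate_sub, rec_rate_rest, rec_i,
            spike_counts, x, p)


def simulate(config: SpikingConfig, stimulus: dict | None = None,
             W: sparse.csr_matrix | None = None,
             duration_seconds: float | None = None,
             record_every_steps: int = 10) -> SpikingNetState:
    """Euler-integrate the network at ``config.dt`` (default 1 ms).

    ``stimulus`` comes from :func:`pulse_stimulus` (or is zero input when
    omitted, in which case ``duration_seconds`` sets the length).  Spiking
    uses threshold/reset with the spike indicator feeding both inhibition
    and the synaptic low-pass.  Aborts on non-finite state.
    """
    if W is None:
        W, _ = build_network(config)
    n, n_sub = config.n, config.n_sub
    if stimulus is None:
        if duration_seconds is None:
            raise ValueError("need stimulus or duration_seconds")
        steps = int(round(duration_seconds / config.dt))
        s = np.zeros(steps)
        w_in = np.zeros(n)
        stim_meta = {}
    else:
        s = stimulus["s"]
        w_in = stimulus["w"].astype(float)
        steps = len(s)
        stim_meta = {k: v for k, v in stimulus.items() if k != "s"}
    tau_s = np.full(n, config.tau_s_rest)
    tau_s[:n_sub] = config.tau_s_sub
    gain = np.full(n, config.input_gain_rest)
    gain[:n_sub] = config.input_gain_sub
    noise_step = config.noise_scale * config.dt / config.tau_m
    Wc = sparse.csc_matrix(W)
    out = _simulate_core(
        steps, config.dt, config.tau_m, config.theta, config.g,
        config.g_inh, config.tau_i, noise_step,
        Wc.data, Wc.indices, Wc.indptr, tau_s, w_in * gain,
        np.ascontiguousarray(s, dtype=float),
        config.seed % (2**31), record_every_steps, n_sub,
        config.spike_width)
    (p_sub, p_rest, rate_sub, rate_rest, i_inh, counts, x, p) = out
    t = (np.arange(len(p_sub)) + 1) * record_every_steps * config.dt
    return SpikingNetState(t=t, p_sub=p_sub, p_rest=p_rest,
                           rate_sub=rate_sub, rate_rest=rate_rest,
                           i_inh=i_inh, spike_counts=counts, x_final=x,
                           p_final=p, config=config, stimulus=stim_meta)


def apply_hypothesis(config: SpikingConfig, which: str) -> SpikingConfig:
    """Mechanistic manipulations of the integration subnetwork.

    ``h1``: slow synapses removed (subnetwork tau_s -> 100 ms).
    ``h2``: external input gain halved for the subnetwork and raised 50%
    for the rest of the network.  All other parameters untouched.
    """
    if which == "h1":
        return replace(config, tau_s_sub=0.1)
    if which == "h2":
        return replace(config, input_gain_sub=0.5 * config.input_gain_sub,
                       input_gain_rest=1.5 * config.input_gain_rest)
    raise ValueError("hypothesis must be 'h1' or 'h2'")


def subnetwork_summary(state: SpikingNetState, pulse_onsets: np.ndarray,
                       isi_seconds: float, width_seconds: float = 1.0,
                       persistence_floor: float = 0.01) -> dict:
    """Ramp metrics across pulses.

    Per pulse: mean synaptic activation of each subpopulation in a window at
    the end of the inter-pulse interval (i.e. just before the next pulse,
    capturing what persists) and at the pulse peak.  Hold values below
    ``persistence_floor`` of the mean pulse peak count as fully decayed
    (zero persistence) so that rank statistics are not computed on
    numerical residue.  Reports the Spearman correlation of the persisting
    subnetwork activation against pulse index (the ramp statistic) and the
    between-pulse decay fraction of the rest population.
    """
    t = state.t
    per_pulse_sub, per_pulse_rest, peak_rest, peak_sub = [], [], [], []
    hold_span = max(0.4 * isi_seconds, 0.2)
    for k, onset in enumerate(pulse_onsets):
        # persistence window: the tail of the inter-pulse interval
        m_hold = (t >= onset + isi_seconds - hold_span) & \
                 (t < onset + isi_seconds)
        m_peak = (t >= onset) & (t < onset + width_seconds + 0.2)
        if not m_hold.any() or not m_peak.any():
            continue
        per_pulse_sub.append(state.p_sub[m_hold].mean())
        per_pulse_rest.append(state.p_rest[m_hold].mean())
        peak_rest.append(state.p_rest[m_peak].max())
        peak_sub.append(state.p_sub[m_peak].max())
    per_pulse_sub = np.array(per_pulse_sub)
    per_pulse_rest = np.array(per_pulse_rest)
    peak_rest = np.array(peak_rest)
    peak_sub = np.array(peak_sub)
    if len(peak_sub):
        floor = persistence_floor * max(peak_sub.mean(), 1e-12)
        per_pulse_sub = np.where(per_pulse_sub < floor, 0.0, per_pulse_sub)
    if len(per_pulse_sub) < 2 or np.all(per_pulse_sub == 0):
        return {"ramp_rho_sub": 0.0, "ramp_rho_rest": 0.0,
                "rest_decay_fraction": 0.0, "per_pulse_sub": per_pulse_sub,
                "per_pulse_rest": per_pulse_rest}
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rho_sub = spearmanr(np.arange(len(per_pulse_sub)), per_pulse_sub)[0]
        rho_rest = spearmanr(np.arange(len(per_pulse_rest)), per_pulse_rest)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(peak_rest > 0, per_pulse_rest /
                          np.maximum(peak_rest, 1e-300), np.nan)
        decay = np.nanmean(ratios) if np.any(np.isfinite(ratios)) else 0.0
    return {"ramp_rho_sub": float(np.nan_to_num(rho_sub)),
            "ramp_rho_rest": float(np.nan_to_num(rho_rest)),
            "rest_decay_fraction": float(np.nan_to_num(decay)),
            "per_pulse_sub": per_pulse_sub,
            "per_pulse_rest": per_pulse_rest}
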