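"""Synthetic session generator: bout structure, latent dynamics, emissions.

Generates ground-truth datasets emulating a female-mouse mating-assay imaging
session: male behaviour bouts (sniff / mount / intromission) with realistic
durations and inter-bout intervals, a latent linear dynamical system with one
slow input-integrating dimension (the line attractor, "receptive" regime) or
only fast dimensions ("unreceptive" regime), linear-Gaussian calcium
emissions, and female behaviour annotations whose acceptance probability
depends on the slow latent.

All randomness flows through one seeded generator with per-component
sub-streams, so identical (config, seed) pairs give bit-identical sessions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BoutTable
from .containers import LatentTrajectory, PopulationRaster, zscore_rows

__all__ = [
    "SimConfig",
    "SyntheticSession",
    "simulate_male_bouts",
    "simulate_latents",
    "simulate_emissions",
    "simulate_female_behavior",
    "simulate_perturbation",
    "simulate_session",
]

_MALE_LABELS = ("sniff", "mount", "intromission")


def _default_kick_gain(regime: str, d: int) -> dict[str, np.ndarray]:
    """Impulse input (latent units) applied at each male bout onset."""
    if regime == "receptive":
        # dim 0 = slow integrator; dim 1 = contact-locked fast dimension
        # (tracks the bout envelope); dim 2 = transient fast dimension
        g = {
            "sniff": np.array([0.03, 0.2, 0.8]),
            "mount": np.array([0.05, 0.4, 1.6]),
            "intromission": np.array([0.05, 0.4, 1.6]),
        }
    else:
        # fast transients time-locked to male contact, no integration
        g = {
            "sniff": np.array([0.8, 1.5]),
            "mount": np.array([2.0, 0.5]),
            "intromission": np.array([2.0, 0.5]),
        }
    return {k: _pad(v, d) for k, v in g.items()}


def _default_sustained_gain(regime: str, d: int) -> dict[str, np.ndarray]:
    """Per-frame input applied while a male bout is ongoing.

    The slow dimension is charged mainly by sustained drive during copulation
    at a roughly stationary bout rate: this produces the gradual session-long
    ramp seen in real integration dimensions while keeping the unexplained
    innovation small.
    """
    if regime == "receptive":
        g = {
            "sniff": np.array([0.001, 0.010, 0.0]),
            "mount": np.array([0.010, 0.030, 0.0]),
            "intromission": np.array([0.010, 0.030, 0.0]),
        }
    else:
        # unreceptive sessions carry no sustained integrating drive
        g = {
            "sniff": np.zeros(2),
            "mount": np.zeros(2),
            "intromission": np.zeros(2),
        }
    return {k: _pad(v, d) for k, v in g.items()}


def _pad(v: np.ndarray, d: int) -> np.ndarray:
    out = np.zeros(d)
    n = min(d, len(v))
    out[:n] = v[:n]
    return out


@dataclass
class SimConfig:
    """Configuration of a synthetic imaging session.

    ``tau_slow``/``tau_fast`` are the latent time constants in seconds; in the
    receptive regime dimension 0 carries ``tau_slow`` and the rest ``tau_fast``
    (default 5 s), while the unreceptive regime has only fast, behaviour-locked
    dimensions, all at ``tau_fast`` (default 1.5 s: transients comparable to
    the calcium indicator decay, with no integration).
    """

    duration_frames: int = 6000
    frame_rate: float = 10.0
    n_neurons: int = 100
    latent_dim: int | None = None
    tau_slow: float = 100.0
    tau_fast: float | None = None
    mean_ibi_s: float = 13.7
    emission_noise_sd: float = 0.3
    loading_sparsity: float = 0.3
    regime: str = "receptive"
    seed: int = 0
    innovation_sd: np.ndarray | None = None
    kick_gain: dict[str, np.ndarray] | None = None
    sustained_gain: dict[str, np.ndarray] | None = None
    # latent dimensions whose onset kicks take a random sign per event:
    # fast transient dimensions deflect either way across events (mixed
    # excited/suppressed population responses), while the integrating slow
    # dimension keeps uniformly positive drive
    kick_sign_dims: tuple | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("receptive", "unreceptive"):
            raise ValueError("regime must be 'receptive' or 'unreceptive'")
        if self.tau_fast is None:
            self.tau_fast = 5.0 if self.regime == "receptive" else 1.5
        if self.latent_dim is None:
            # receptive sessions carry the slow integrator plus a
            # contact-locked and a transient fast dimension
            self.latent_dim = 3 if self.regime == "receptive" else 2
        if self.duration_frames < 0:
            raise ValueError("duration_frames must be >= 0")
        if not (self.tau_slow > self.tau_fast > 0):
            raise ValueError("need tau_slow > tau_fast > 0")
        if self.emission_noise_sd < 0:
            raise ValueError("emission_noise_sd must be >= 0")
        if not (0 <= self.loading_sparsity <= 1):
            raise ValueError("loading_sparsity must lie in [0, 1]")
        d = self.latent_dim
        if self.innovation_sd is None:
            sd = np.full(d, 0.05)
            if self.regime == "receptive":
                sd[0] = 0.004
            self.innovation_sd = sd
        else:
            self.innovation_sd = _pad(np.asarray(self.innovation_sd, float), d)
        if np.any(self.innovation_sd < 0):
            raise ValueError("innovation_sd must be >= 0")
        if self.kick_gain is None:
            self.kick_gain = _default_kick_gain(self.regime, d)
        if self.sustained_gain is None:
            self.sustained_gain = _default_sustained_gain(self.regime, d)
        if self.kick_sign_dims is None:
            if self.regime == "unreceptive":
                self.kick_sign_dims = tuple(range(d))
            else:
                # only the transient dimension(s) deflect with random sign;
                # the integrator and the contact-locked dimension keep
                # positive drive
                self.kick_sign_dims = tuple(range(2, d))

    def latent_taus_seconds(self) -> np.ndarray:
        """Ground-truth per-dimension time constants (seconds)."""
        d = self.latent_dim
        taus = np.full(d, self.tau_fast)
        if self.regime == "receptive":
            taus[0] = self.tau_slow
            if d >= 3:
                # the contact-locked dimension tracks the bout envelope
                # with a shorter time constant than the transient dimension
                taus[1] = 0.5 * self.tau_fast
        return taus

    def dynamics_matrix(self) -> np.ndarray:
        """Diagonal generative dynamics matrix A (per-frame)."""
        return np.diag(np.exp(-1.0 / (self.latent_taus_seconds() * self.frame_rate)))


@dataclass
class SyntheticSession:
    raster: PopulationRaster
    latents: LatentTrajectory
    male_bouts: BoutTable
    female_bouts: BoutTable
    true_params: dict = field(default_factory=dict)
    config: SimConfig | None = None


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent per-component substream derived from the config seed."""
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed) % (2**31),
                               spawn_key=(key,))
    )


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Draw from a log-normal with the given arithmetic mean."""
    mu = np.log(mean) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


def simulate_male_bouts(config: SimConfig) -> BoutTable:
    """Male behaviour bouts: an appetitive sniffing phase followed by
    copulation bouts (mount then escalating to intromission) at a roughly
    stationary rate, with sniff bouts interleaved during inter-bout intervals.

    Durations and IBIs are drawn log-normal; the copulation IBI mean defaults
    to 13.7 s.  Escalation ordering holds by construction: sniffing precedes
    the first mount and mounting precedes the first intromission.
    """
    rng = _rng(config, "male_bouts")
    fr = config.frame_rate
    T = config.duration_frames
    rows: list[tuple] = []
    if T <= 0:
        return BoutTable(pd.DataFrame(columns=["actor", "behavior", "start", "stop"]),
                         frame_rate=fr, warning=True)

    def add(label: str, start_f: int, dur_s: float) -> int:
        stop_f = min(T, start_f + max(1, int(round(dur_s * fr))))
        if stop_f > start_f:
            rows.append(("male", label, start_f, stop_f))
        return stop_f

    t = int(round(3.0 * fr))  # brief empty lead-in
    # appetitive phase: sniff bouts only (~40 s)
    phase_end = min(T, int(round(40.0 * fr)))
    while t < phase_end:
        t = add("sniff", t, _lognormal(rng, 2.5, 0.4))
        t += max(1, int(round(_lognormal(rng, 4.0, 0.4) * fr)))
    # copulation phase: first two bouts are mounts, then mount/intromission
    # mix at a roughly stationary bout rate
    k = 0
    while t < T:
        if k < 2:
            label = "mount"
        else:
            label = "intromission" if rng.random() < 0.7 else "mount"
        mean_dur = 5.0 if label == "mount" else 8.0
        t = add(label, t, _lognormal(rng, mean_dur, 0.25))
        ibi = _lognormal(rng, config.mean_ibi_s, 0.35)
        ibi_frames = max(2, int(round(ibi * fr)))
        # interleave a sniff bout inside longer IBIs
        if ibi_frames > int(5 * fr) and rng.random() < 0.7:
            off = int(round(1.0 * fr))
            add("sniff", t + off, min(_lognormal(rng, 2.0, 0.3),
                                      (ibi_frames - off) / fr - 0.5))
        t += ibi_frames
        k += 1
    if not rows:
        return BoutTable(pd.DataFrame(columns=["actor", "behavior", "start", "stop"]),
                         frame_rate=fr, warning=True)
    df = pd.DataFrame(rows, columns=["actor", "behavior", "start", "stop"])
    return BoutTable(df, frame_rate=fr)


def male_input_series(config: SimConfig, male_bouts: BoutTable) -> np.ndarray:
    """Per-frame latent input W.u_t implied by the bout table (D x T)."""
    d, T = config.latent_dim, config.duration_frames
    sign_rng = _rng(config, "kick_signs")
    u = np.zeros((d, T))
    for label in _MALE_LABELS:
        sub = male_bouts.select(actor="male", group=label).df
        kick = config.kick_gain.get(label, np.zeros(d))
        sus = config.sustained_gain.get(label, np.zeros(d))
        sign_dims = np.array(config.kick_sign_dims, dtype=int)
        for start, stop in zip(sub["start"], sub["stop"]):
            if 0 <= start < T:
                signs = np.ones(d)
                if len(sign_dims):
                    signs[sign_dims] = sign_rng.choice([-1.0, 1.0],
                                                       size=len(sign_dims))
                u[:, start] += kick * signs
            u[:, max(0, start):min(T, stop)] += sus[:, None]
    return u


def simulate_latents(config: SimConfig, male_bouts: BoutTable,
                     x0: np.ndarray | None = None) -> LatentTrajectory:
    """Evolve the latent linear system x_t = A x_{t-1} + W u_t + eps_t.

    Male bout onsets deliver impulse inputs and ongoing bouts sustained
    drive; innovation noise is Gaussian per dimension.  In the receptive
    regime dimension 0 integrates the input with time constant ``tau_slow``
    and ramps monotonically in expectation across bouts.
    """
    A = config.dynamics_matrix()
    if np.any(np.abs(np.linalg.eigvals(A)) > 1.0 + 1e-9):
        raise ValueError("unstable requested dynamics (|eigenvalue| > 1)")
    rng = _rng(config, "latents")
    d, T = config.latent_dim, config.duration_frames
    u = male_input_series(config, male_bouts)
    x = np.zeros((d, T))
    prev = np.zeros(d) if x0 is None else np.asarray(x0, float)
    noise = rng.standard_normal((d, T)) * config.innovation_sd[:, None]
    a_diag = np.diag(A)
    for t in range(T):
        prev = a_diag * prev + u[:, t] + noise[:, t]
        x[:, t] = prev
    return LatentTrajectory(x=x, frame_rate=config.frame_rate)


def simulate_emissions(latents: LatentTrajectory, config: SimConfig) -> PopulationRaster:
    """Linear-Gaussian calcium emissions y_t = C x_t + d + noise, z-scored
    per neuron (matching the preprocessing applied to extracted traces)."""
    if config.n_neurons < config.latent_dim:
        raise ValueError("n_neurons must be >= latent_dim")
    rng = _rng(config, "emissions")
    n, d = config.n_neurons, latents.n_dims
    C = rng.standard_normal((n, d))
    mask = rng.random((n, d)) >= config.loading_sparsity
    # guarantee every latent dim is read out by someone
    for j in range(d):
        if not mask[:, j].any():
            mask[rng.integers(n), j] = True
    C = C * mask
    bias = rng.standard_normal(n) * 0.1
    y = C @ latents.x + bias[:, None]
    if config.emission_noise_sd > 0:
        y = y + rng.standard_normal(y.shape) * config.emission_noise_sd
    z, _ = zscore_rows(y)
    raster = PopulationRaster(z, frame_rate=config.frame_rate)
    raster.loading = C  # generative loading, pre z-scoring
    raster.offset = bias
    return raster


def simulate_female_behavior(
    latents: LatentTrajectory,
    male_bouts: BoutTable,
    link_gain: float = 2.0,
    link_threshold: float = 1.5,
    seed: int = 0,
    slow_dim: int = 0,
) -> BoutTable:
    """Female behaviour annotations driven by the slow latent.

    During male copulation bouts the female accepts (lordose/wiggle) with a
    per-bout probability given by a logistic link on the slow-latent value
    (in latent units, so sessions with a higher ramp accept more), and
    resists (dart/kick) with the complementary tendency.  Appetitive
    approach/sniff bouts are placed during inter-bout intervals.  A zero
    ``link_gain`` decouples acceptance from the latent.
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    fr = male_bouts.frame_rate
    T = latents.n_frames
    xs = latents.x[slow_dim]
    rows = []
    cop = male_bouts.select(actor="male", group="copulation").df
    for start, stop in zip(cop["start"], cop["stop"]):
        start, stop = int(start), int(min(stop, T))
        if stop <= start:
            continue
        level = xs[start:stop].mean()
        p_accept = 1.0 / (1.0 + np.exp(-(link_gain * (level - link_threshold))))
        off = min(2, stop - start - 1)
        if rng.random() < p_accept:
            label = "lordose" if rng.random() < 0.7 else "wiggle"
            rows.append(("female", label, start + off, stop))
        elif rng.random() < 0.8:
            label = "dart" if rng.random() < 0.5 else "kick"
            rows.append(("female", label, start + off,
                         min(stop, start + off + int(2 * fr))))
    # appetitive bouts during gaps between male bouts
    male_any = male_bouts.frame_mask(T, actor="male")
    gaps = _mask_to_intervals(~male_any)
    for s, e in gaps:
        if e - s > int(4 * fr) and rng.random() < 0.5:
            label = "approach" if rng.random() < 0.5 else "sniff"
            b0 = s + int(1 * fr)
            rows.append(("female", label, b0, min(e, b0 + int(2 * fr))))
    df = pd.DataFrame(rows, columns=["actor", "behavior", "start", "stop"])
    out = BoutTable(df, frame_rate=fr) if len(df) else BoutTable(
        pd.DataFrame(columns=["actor", "behavior", "start", "stop"]), frame_rate=fr)
    return out


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def simulate_perturbation(
    latents: LatentTrajectory,
    config: SimConfig,
    male_bouts: BoutTable,
    windows: list[tuple[int, int]],
    kick: np.ndarray,
) -> LatentTrajectory:
    """Re-simulate the session with an additive off-manifold kick held on
    during each window; relaxation afterwards follows the generative A.

    The kick defaults to directions orthogonal to the slow dimension, so the
    slow-latent value at window end stays within noise of its value at the
    window start while fast dimensions are displaced and relax back.
    """
    windows = sorted((int(a), int(b)) for a, b in windows)
    for i in range(1, len(windows)):
        if windows[i][0] < windows[i - 1][1]:
            raise ValueError("overlapping perturbation windows")
    T = latents.n_frames
    for a, b in windows:
        if not (0 <= a < b <= T):
            raise ValueError("window outside session")
    kick = _pad(np.asarray(kick, float), config.latent_dim)
    if not np.any(kick):
        return latents
    # rebuild with identical noise stream plus the perturbation input
    rng = _rng(config, "latents")
    d = config.latent_dim
    u = male_input_series(config, male_bouts)
    for a, b in windows:
        u[:, a:b] += kick[:, None]
    noise = rng.standard_normal((d, T)) * config.innovation_sd[:, None]
    a_diag = np.diag(config.dynamics_matrix())
    x = np.zeros((d, T))
    prev = np.zeros(d)
    for t in range(T):
        prev = a_diag * prev + u[:, t] + noise[:, t]
        x[:, t] = prev
    return LatentTrajectory(x=x, frame_rate=config.frame_rate)


def suppress_bouts(bouts: BoutTable, windows: list[tuple[int, int]],
                   margin_frames: int = 0) -> BoutTable:
    """Remove bouts overlapping perturbation windows (plus a margin).

    Emulates the behavioural effect of remotely interrupting the male:
    during stimulation and the ensuing pause no male behaviour occurs, so
    the latent relaxation after a kick is input-free.
    """
    df = bouts.df
    keep = np.ones(len(df), dtype=bool)
    for a, b in windows:
        keep &= (df["stop"].to_numpy() <= a) | \
                (df["start"].to_numpy() >= b + margin_frames)
    out = df[keep].reset_index(drop=True)
    from dataclasses import replace as _replace
    return _replace(bouts, df=out)


def simulate_session(config: SimConfig, link_gain: float = 2.0) -> SyntheticSession:
    """End-to-end synthetic session: bouts -> latents -> emissions -> female
    annotations, with the generative parameters recorded."""
    male = simulate_male_bouts(config)
    lat = simulate_latents(config, male)
    raster = simulate_emissions(lat, config)
    female = simulate_female_behavior(
        lat, male, link_gain=link_gain,
        seed=int(np.random.SeedSequence(config.seed % (2**31)).generate_state(1)[0]
                 % (2**31)))
    true_params = {
        "A": config.dynamics_matrix(),
        "taus_s": config.latent_taus_seconds(),
        "C": raster.loading,
        "d": raster.offset,
        "innovation_sd": config.innovation_sd,
    }
    return SyntheticSession(raster=raster, latents=lat, male_bouts=male,
                            female_bouts=female, true_params=true_params,
                            config=config)
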