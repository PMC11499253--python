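"""FORCE-trained rate RNN and fixed-point analysis.

A chaotic tanh rate network

    tau dx_i/dt = -x_i + g * sum_j J_ij r(x_j) + H_i(t),    r = tanh

is trained by recursive least squares (RLS) on the full recurrent matrix J
so that the recurrent drive z_i(t) = sum_j J_ij r_j(t) reproduces target
traces f_i(t) (recorded or synthetic calcium).  Reverse-engineering the
trained network by minimizing the speed q = 1/2 ||dx/dt||^2 recovers its
fixed and slow points; their geometry (e.g. a collinear band of slow
points) provides method-independent confirmation of attractor structure
found by state-space modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["ForceConfig", "ForceRNN", "FixedPointSet", "train_force",
           "find_fixed_points", "project_points"]


@dataclass
class ForceConfig:
    g: float = 1.5               # recurrent gain (chaotic regime)
    tau: float = 0.5             # unit time constant, seconds
    dt: float = 0.05             # Euler step, seconds
    n_passes: int = 5            # training passes through the targets
    learn_every: int = 2         # RLS update cadence in steps
    alpha: float = 1.0           # RLS regularization (P0 = I/alpha)
    gain_mode: str = "sum"       # 'sum': g*(J r); 'matrix': J init scaled by g
    seed: int = 0


@dataclass
class ForceRNN:
    J: np.ndarray                # (N, N) recurrent matrix (trained)
    W_in: np.ndarray             # (N, m) input weights
    config: ForceConfig
    train_error: list = field(default_factory=list)   # mean |e| per pass
    r2: np.ndarray | None = None # per-unit reconstruction r^2, eval pass

    @property
    def n_units(self) -> int:
        return self.J.shape[0]

    def generate(self, steps: int, x0: np.ndarray | None = None,
                 u: np.ndarray | None = None) -> np.ndarray:
        """Autonomous (closed-loop) rollout of the trained network; returns
        the readout z over time.  Long free-running generation accumulates
        drift away from the training trajectory."""
        cfg = self.config
        N = self.n_units
        x = np.zeros(N) if x0 is None else np.asarray(x0, float).copy()
        geff = cfg.g if cfg.gain_mode == "sum" else 1.0
        dt_tau = cfg.dt / cfg.tau
        Z = np.zeros((N, steps))
        for t in range(steps):
            r = np.tanh(x)
            z = self.J @ r
            Z[:, t] = z
            h = self.W_in @ u[:, t] if u is not None else 0.0
            x = x + dt_tau * (-x + geff * z + h)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(f"divergence at step {t}")
        return Z

    def drift(self, x: np.ndarray, h: np.ndarray | None = None) -> np.ndarray:
        """dx/dt at state x under constant input h."""
        cfg = self.config
        rec = self.J @ np.tanh(x)
        if cfg.gain_mode == "sum":
            rec = cfg.g * rec
        out = (-x + rec) / cfg.tau
        if h is not None:
            out = out + h / cfg.tau
        return out


@dataclass
class FixedPointSet:
    points: np.ndarray           # (n_points, N)
    speeds: np.ndarray           # ||dx/dt|| at each point
    jacobian_eigs: list          # leading eigenvalues per point
    accepted: np.ndarray         # speed < tol
    tol: float


def trajectory_divergence(rnn: ForceRNN, settle_seconds: float = 50.0,
                          measure_seconds: float = 150.0,
                          seed: int = 0) -> float:
    """Largest-Lyapunov-style divergence rate (1/s) of the autonomous
    dynamics, from renormalized perturbation growth along a trajectory.

    Positive values indicate chaos (expected for an untrained network at
    g = 1.5 and a couple hundred units); training toward smooth targets
    reduces it.
    """
    cfg = rnn.config
    N = rnn.n_units
    rng = np.random.default_rng(seed)
    geff = cfg.g if cfg.gain_mode == "sum" else 1.0
    dt_tau = cfg.dt / cfg.tau
    x = rng.standard_normal(N)
    for _ in range(int(settle_seconds / cfg.dt)):
        x = x + dt_tau * (-x + geff * (rnn.J @ np.tanh(x)))
    eps = 1e-8
    d = eps * rng.standard_normal(N)
    d *= eps / np.linalg.norm(d)
    lam = 0.0
    steps = int(measure_seconds / cfg.dt)
    for _ in range(steps):
        xp = x + d
        x = x + dt_tau * (-x + geff * (rnn.J @ np.tanh(x)))
        xp = xp + dt_tau * (-xp + geff * (rnn.J @ np.tanh(xp)))
        d = xp - x
        nd = np.linalg.norm(d)
        lam += np.log(nd / eps)
        d *= eps / nd
    return lam / (steps * cfg.dt)


def _resample(targets: np.ndarray, frame_rate: float, dt: float) -> np.ndarray:
    """Linear interpolation of targets from the imaging clock to the
    integration step."""
    n, T = targets.shape
    t_src = np.arange(T) / frame_rate
    t_dst = np.arange(0, t_src[-1], dt)
    return np.vstack([np.interp(t_dst, t_src, targets[i]) for i in range(n)])


def train_force(targets: np.ndarray, frame_rate: float = 10.0,
                inputs: np.ndarray | None = None,
                config: ForceConfig | None = None) -> ForceRNN:
    """Train the recurrent matrix with RLS so the recurrent readout
    z_i = sum_j J_ij r_j matches the target traces.

    Training passes are teacher-forced: since a perfect solution has
    J r = f, the recurrent drive is clamped to the targets while RLS fits
    J on the visited states (the standard stabilisation for fitting a
    recurrent matrix to recorded trajectories).  A final held-out pass with
    learning off reports the per-unit reconstruction r^2.  Use
    :meth:`generate` for fully autonomous (closed-loop) rollouts.

    ``targets`` is (n_units, n_frames) on the imaging clock; ``inputs`` an
    optional (m, n_frames) behaviour series fed through random input
    weights.  Raises on divergence (non-finite state).
    """
    config = config or ForceConfig()
    targets = np.asarray(targets, float)
    if targets.ndim != 2 or targets.shape[0] < 2:
        raise ValueError("need >= 2 target traces")
    rng = np.random.default_rng(config.seed % (2**31))
    N = targets.shape[0]
    f = _resample(targets, frame_rate, config.dt)
    steps = f.shape[1]
    if inputs is not None:
        u = _resample(np.atleast_2d(np.asarray(inputs, float)),
                      frame_rate, config.dt)
        m = u.shape[0]
    else:
        u = None
        m = 1
    W_in = rng.uniform(-1, 1, size=(N, m))
    scale = 1.0 / np.sqrt(N)
    J = rng.standard_normal((N, N)) * scale
    if config.gain_mode == "matrix":
        J = J * config.g
    geff = config.g if config.gain_mode == "sum" else 1.0
    P = np.eye(N) / config.alpha
    x0 = 0.5 * rng.standard_normal(N)
    dt_tau = config.dt / config.tau
    errors = []
    rnn = ForceRNN(J=J, W_in=W_in, config=config)
    for p in range(config.n_passes):
        x = x0.copy()
        pass_err = 0.0
        n_upd = 0
        for t in range(steps):
            r = np.tanh(x)
            if t % config.learn_every == 0:
                e = rnn.J @ r - f[:, t]
                Pr = P @ r
                c = 1.0 / (1.0 + float(r @ Pr))
                P -= np.outer(Pr, Pr) * c
                rnn.J -= np.outer(e * c, Pr)
                pass_err += np.abs(e).mean()
                n_upd += 1
            # teacher forcing: recurrent drive clamped to the target
            h = W_in @ u[:, t] if u is not None else 0.0
            x = x + dt_tau * (-x + geff * f[:, t] + h)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(f"divergence at step {t}, pass {p}")
        errors.append(pass_err / max(1, n_upd))
    rnn.train_error = errors
    # held-out evaluation pass: learning off, same drive protocol
    x = x0.copy()
    Z = np.zeros_like(f)
    for t in range(steps):
        r = np.tanh(x)
        Z[:, t] = rnn.J @ r
        h = W_in @ u[:, t] if u is not None else 0.0
        x = x + dt_tau * (-x + geff * f[:, t] + h)
    r2 = np.zeros(N)
    for i in range(N):
        if f[i].std() > 0 and Z[i].std() > 0:
            r2[i] = np.corrcoef(Z[i], f[i])[0, 1]**2
    rnn.r2 = r2
    rnn._x0 = x0
    rnn._f = f
    rnn._u = u
    return rnn


def find_fixed_points(rnn: ForceRNN, n_inits: int = 30,
                      tol: float = 1e-6, slow_tol: float | None = None,
                      inits: np.ndarray | None = None,
                      h: np.ndarray | None = None,
                      dedup_radius: float = 0.1,
                      seed: int = 0) -> FixedPointSet:
    """Gradient-based search for fixed/slow points of the trained network.

    Minimizes q(x) = 1/2 ||dx/dt||^2 from multiple initial states (visited
    states when provided, otherwise random), deduplicates converged points
    within a radius, and classifies each by the Jacobian spectrum.  Points
    with residual speed below ``tol`` are accepted as fixed points;
    ``slow_tol`` (when given) is the looser acceptance used for slow points.
    """
    cfg = rnn.config
    N = rnn.n_units
    rng = np.random.default_rng(seed)
    if inits is None:
        inits = rng.standard_normal((n_inits, N))
    else:
        inits = np.asarray(inits, float)
        if len(inits) > n_inits:
            inits = inits[rng.choice(len(inits), n_inits, replace=False)]
    geff = cfg.g if cfg.gain_mode == "sum" else 1.0

    def q_and_grad(x):
        th = np.tanh(x)
        F = (-x + geff * (rnn.J @ th) + (h if h is not None else 0.0)) / cfg.tau
        q = 0.5 * F @ F
        Jac = (-np.eye(N) + geff * rnn.J * (1 - th**2)[None, :]) / cfg.tau
        return q, Jac.T @ F

    found, speeds = [], []
    accept_tol = slow_tol if slow_tol is not None else tol
    for x0 in inits:
        res = minimize(q_and_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "gtol": 1e-12})
        x = res.x
        th = np.tanh(x)
        F = (-x + geff * (rnn.J @ th) + (h if h is not None else 0.0)) / cfg.tau
        speed = float(np.linalg.norm(F))
        if speed > accept_tol:
            continue
        if any(np.linalg.norm(x - p) < dedup_radius for p in found):
            continue
        found.append(x)
        speeds.append(speed)
    if not found:
        return FixedPointSet(points=np.empty((0, N)), speeds=np.empty(0),
                             jacobian_eigs=[], accepted=np.empty(0, bool),
                             tol=tol)
    pts = np.vstack(found)
    speeds = np.array(speeds)
    eigs = []
    for x in pts:
        th = np.tanh(x)
        Jac = (-np.eye(N) + geff * rnn.J * (1 - th**2)[None, :]) / cfg.tau
        ev = np.linalg.eigvals(Jac)
        eigs.append(ev[np.argsort(-ev.real)][:5])
    return FixedPointSet(points=pts, speeds=speeds, jacobian_eigs=eigs,
                         accepted=speeds < tol, tol=tol)


def project_points(points: FixedPointSet, emissions_C: np.ndarray,
                   emissions_d: np.ndarray, basis: np.ndarray,
                   center: np.ndarray,
                   slow_mask: np.ndarray | None = None,
                   grid_x: np.ndarray | None = None,
                   grid_y: np.ndarray | None = None) -> dict:
    """Project RNN fixed/slow points into an rSLDS 2-D state-space plane.

    RNN states live in neuron (readout) space; the emission pseudo-inverse
    maps them to rSLDS latents, then ``basis``/``center`` (from the flow
    field) project to the PC plane.  When a slow-region mask and its grid
    are given, returns the fraction of points landing inside the mask.
    """
    if points.points.shape[0] == 0:
        return {"coords": np.empty((0, 2)), "overlap": np.nan}
    if points.points.shape[1] != emissions_C.shape[0]:
        raise ValueError("point dimensionality does not match emissions")
    pinv = np.linalg.pinv(emissions_C)
    lat = (pinv @ (points.points.T - emissions_d[:, None]))
    coords = (basis @ (lat - center[:, None])).T
    overlap = np.nan
    if slow_mask is not None and grid_x is not None and grid_y is not None:
        inside = 0
        for cx, cy in coords:
            ix = int(np.argmin(np.abs(grid_x - cx)))
            iy = int(np.argmin(np.abs(grid_y - cy)))
            if abs(grid_x[ix] - cx) <= (grid_x[1] - grid_x[0]) and \
               abs(grid_y[iy] - cy) <= (grid_y[1] - grid_y[0]) and \
               slow_mask[iy, ix]:
                inside += 1
        overlap = inside / len(coords)
    return {"coords": coords, "overlap": overlap}
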