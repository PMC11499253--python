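"""Recurrent switching linear dynamical systems (rSLDS) for neural rasters.

The generative model: a discrete state ``z_t in {1..K}`` selects a linear
dynamical system for the continuous latents,

    x_t = A_{z_t} x_{t-1} + b_{z_t} + eps_t,        eps_t ~ N(0, Q_{z_t})
    y_t = C x_t + d + delta_t,                      delta_t ~ N(0, S)

with recurrent transitions p(z_{t+1} | z_t, x_t) = softmax(R x_t + r + P[z_t]).
Fitting uses structured EM: forward-backward over discrete states given the
current latent path, Kalman smoothing of the continuous latents under the
state-blended dynamics, closed-form M-steps for dynamics and emissions, and a
multinomial-logistic fit of the transition parameters.

Each latent dimension of a fitted state has a time constant derived from the
eigenvalues ``lam`` of its dynamics matrix,

    tau = | 1 / log|lam| |            (frames; divide by frame rate for s)

and the log2 ratio of the two longest time constants is the line-attractor
score: a large score means one dominant slow mode, the signature of an
approximate line attractor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression

from .containers import LatentTrajectory, PopulationRaster

__all__ = [
    "RSLDSParams",
    "FitConfig",
    "FitDiagnostics",
    "TimeConstantSet",
    "FlowField2D",
    "fit_rslds",
    "select_model_order",
    "forward_sim_accuracy",
    "time_constants",
    "line_attractor_score",
    "integration_dimension",
    "flow_field_2d",
    "project_into_model",
    "fit_excluding_windows",
    "pls_integration_dimension",
]

TAU_CEILING_FRAMES = 1e5  # cap for |eigenvalue| >= 1


@dataclass
class RSLDSParams:
    """Full parameter set theta of the model."""

    A: np.ndarray          # (K, D, D)
    b: np.ndarray          # (K, D)
    Q: np.ndarray          # (K, D, D)
    R: np.ndarray          # (K, D)  recurrent logit weights on x_t
    r: np.ndarray          # (K,)    logit biases
    P: np.ndarray          # (K, K)  state-to-state logit biases
    C: np.ndarray          # (N, D)
    d: np.ndarray          # (N,)
    S: np.ndarray          # (N,)    diagonal observation variances

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_dims(self) -> int:
        return self.A.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.C.shape[0]

    def transition_logits(self, x: np.ndarray, z_prev: int) -> np.ndarray:
        return self.R @ x + self.r + self.P[z_prev]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("A", "b", "Q", "R", "r", "P", "C", "d", "S")}

    @classmethod
    def from_dict(cls, d: dict) -> "RSLDSParams":
        return cls(**{k: np.asarray(v) for k, v in d.items()})


@dataclass
class FitConfig:
    n_iters: int = 40
    tol: float = 1e-5
    n_restarts: int = 1
    seed: int = 0
    ridge: float = 1e-6
    min_state_frac: float = 0.01  # states occupied less often are pruned
    verbose: bool = False


@dataclass
class FitDiagnostics:
    elbo_trace: list = field(default_factory=list)
    converged: bool = False
    n_iters_run: int = 0
    pruned_states: int = 0
    unstable: bool = False
    forward_sim_acc: float | None = None
    variance_explained: float | None = None


@dataclass
class TimeConstantSet:
    """Per-state time constants from dynamics eigenvalues."""

    taus_frames: list          # per state: sorted descending, pairs deduped
    taus_seconds: list
    eigenvalues: list
    frame_rate: float
    state_occupancy: np.ndarray
    capped: bool = False

    def slowest_state(self) -> int:
        """State housing the single longest time constant."""
        best = max(range(len(self.taus_frames)),
                   key=lambda k: self.taus_frames[k][0]
                   if len(self.taus_frames[k]) else -np.inf)
        return best


@dataclass
class FlowField2D:
    basis: np.ndarray        # (2, D) orthonormal rows (top PCs of latents)
    center: np.ndarray       # (D,) latent mean
    grid_x: np.ndarray
    grid_y: np.ndarray
    velocity: np.ndarray     # (ny, nx, 2)
    speed: np.ndarray        # (ny, nx)
    slow_mask: np.ndarray    # (ny, nx) bool
    trajectory: np.ndarray   # (2, T) projected latents


# ---------------------------------------------------------------------------
# inference internals

def _kalman_smoother(y, C, d, S, A_t, b_t, Q_t, x0_mean, x0_cov):
    """RTS smoother with per-frame dynamics.  Returns means, covs, lag-one
    cross-covariances and the filter log-likelihood."""
    N, T = y.shape
    D = C.shape[1]
    CtSi = (C / S[:, None]).T            # D x N
    CtSiC = CtSi @ C                     # D x D
    I = np.eye(D)
    mf = np.zeros((T, D))
    Vf = np.zeros((T, D, D))
    mp = np.zeros((T, D))
    Vp = np.zeros((T, D, D))
    ll = 0.0
    m, V = x0_mean, x0_cov
    logdetS = np.sum(np.log(S))
    for t in range(T):
        if t > 0:
            A, b, Q = A_t[t], b_t[t], Q_t[t]
            m = A @ mf[t - 1] + b
            V = A @ Vf[t - 1] @ A.T + Q
        mp[t], Vp[t] = m, V
        # measurement update in information form
        Vinv = np.linalg.inv(V + 1e-12 * I)
        post_prec = Vinv + CtSiC
        Vf[t] = np.linalg.inv(post_prec)
        resid = y[:, t] - d
        mf[t] = Vf[t] @ (Vinv @ m + CtSi @ resid)
        # innovation log-likelihood via matrix inversion lemma
        # S_t = C V C' + diag(S); use determinant lemma for logdet
        sign, logdet_post = np.linalg.slogdet(post_prec)
        sign2, logdet_prior = np.linalg.slogdet(Vinv)
        logdet_innov = logdetS + logdet_post - logdet_prior
        r = resid - C @ m
        # quadratic form via Woodbury: r' Sinv r - r' Sinv C (post_prec)^-1 C' Sinv r
        rs = r / S
        u = CtSi @ r
        quad = r @ rs - u @ (Vf[t] @ u)
        ll += -0.5 * (logdet_innov + quad + N * np.log(2 * np.pi))
    # RTS backward pass
    ms = np.zeros((T, D))
    Vs = np.zeros((T, D, D))
    Vlag = np.zeros((T, D, D))           # Cov(x_t, x_{t-1}) smoothed, index t
    ms[-1], Vs[-1] = mf[-1], Vf[-1]
    for t in range(T - 2, -1, -1):
        A = A_t[t + 1]
        J = Vf[t] @ A.T @ np.linalg.inv(Vp[t + 1] + 1e-12 * I)
        ms[t] = mf[t] + J @ (ms[t + 1] - mp[t + 1])
        Vs[t] = Vf[t] + J @ (Vs[t + 1] - Vp[t + 1]) @ J.T
        Vlag[t + 1] = Vs[t + 1] @ J.T
    return ms, Vs, Vlag, ll


def _segment_smoother(blend, C, d, S):
    """Run the smoother per contiguous segment; collect results."""
    out_m, out_V, out_lag, lls = [], [], [], []
    D = C.shape[1]
    for (y, A_t, b_t, Q_t) in blend:
        m0 = np.zeros(D)
        V0 = 10.0 * np.eye(D)
        ms, Vs, Vlag, ll = _kalman_smoother(y, C, d, S, A_t, b_t, Q_t, m0, V0)
        out_m.append(ms)
        out_V.append(Vs)
        out_lag.append(Vlag)
        lls.append(ll)
    return out_m, out_V, out_lag, float(np.sum(lls))


def _forward_backward(loglik, logtrans, logpi):
    """HMM forward-backward with per-transition log matrices.

    loglik: (T, K) frame log-likelihoods; logtrans: (T-1, K, K) with
    logtrans[t, i, j] = log p(z_{t+1}=j | z_t=i, x_t).
    """
    T, K = loglik.shape
    alpha = np.zeros((T, K))
    c = np.zeros(T)
    a = logpi + loglik[0]
    m = a.max()
    alpha[0] = np.exp(a - m)
    c[0] = m + np.log(alpha[0].sum())
    alpha[0] /= alpha[0].sum()
    for t in range(1, T):
        a = np.log(alpha[t - 1] @ np.exp(logtrans[t - 1]) + 1e-300) + loglik[t]
        m = a.max()
        alpha[t] = np.exp(a - m)
        s = alpha[t].sum()
        c[t] = m + np.log(s)
        alpha[t] /= s
    beta = np.ones((T, K))
    gamma = np.zeros((T, K))
    gamma[-1] = alpha[-1]
    for t in range(T - 2, -1, -1):
        b = np.exp(logtrans[t]) @ (beta[t + 1] * np.exp(loglik[t + 1]
                                                        - loglik[t + 1].max()))
        beta[t] = b / (b.max() + 1e-300)
        g = alpha[t] * beta[t]
        gamma[t] = g / g.sum()
    return gamma, float(c.sum())


def _state_loglik(ms, A, b, Q):
    """Per-frame log N(x_t; A_k x_{t-1} + b_k, Q_k) for each state."""
    T, D = ms.shape
    K = A.shape[0]
    out = np.zeros((T, K))
    for k in range(K):
        Qk = Q[k] + 1e-9 * np.eye(D)
        Qinv = np.linalg.inv(Qk)
        _, logdet = np.linalg.slogdet(Qk)
        pred = ms[:-1] @ A[k].T + b[k]
        resid = ms[1:] - pred
        out[1:, k] = -0.5 * (np.einsum("ti,ij,tj->t", resid, Qinv, resid)
                             + logdet + D * np.log(2 * np.pi))
    out[0] = 0.0
    return out


def _fit_transitions(ms_list, z_list, K, D, ridge=1.0):
    """Multinomial logistic fit of z_{t+1} on [x_t, onehot(z_t)]."""
    X, Y = [], []
    for ms, z in zip(ms_list, z_list):
        X.append(np.hstack([ms[:-1], np.eye(K)[z[:-1]]]))
        Y.append(z[1:])
    X = np.vstack(X)
    Y = np.concatenate(Y)
    classes = np.unique(Y)
    R = np.zeros((K, D))
    r = np.zeros(K)
    P = np.zeros((K, K))
    if len(classes) < 2:
        r[classes[0]] = 5.0
        return R, r, P
    lr = LogisticRegression(C=1.0 / ridge, max_iter=200)
    lr.fit(X, Y)
    coef = np.zeros((K, D + K))
    intercept = np.zeros(K)
    for i, cls in enumerate(lr.classes_):
        coef[cls] = lr.coef_[i] if len(lr.classes_) > 2 else (
            lr.coef_[0] if cls == lr.classes_[1] else -lr.coef_[0])
        intercept[cls] = lr.intercept_[i] if len(lr.classes_) > 2 else (
            lr.intercept_[0] if cls == lr.classes_[1] else -lr.intercept_[0])
    R = coef[:, :D]
    P = coef[:, D:].T  # P[z_prev, z_next]
    r = intercept
    return R, r, P


def _m_step_dynamics(ms_list, Vs_list, Vlag_list, gamma_list, K, D, ridge):
    A = np.zeros((K, D, D))
    b = np.zeros((K, D))
    Q = np.zeros((K, D, D))
    for k in range(K):
        Sxx = ridge * np.eye(D + 1)
        Syx = np.zeros((D, D + 1))
        Syy = np.zeros((D, D))
        wtot = 0.0
        for ms, Vs, Vlag, gamma in zip(ms_list, Vs_list, Vlag_list, gamma_list):
            w = gamma[1:, k]
            mprev, mcur = ms[:-1], ms[1:]
            Exx_prev = np.einsum("t,tij->ij", w, Vs[:-1]) + \
                (mprev * w[:, None]).T @ mprev
            Excur_xprev = np.einsum("t,tij->ij", w, Vlag[1:]) + \
                (mcur * w[:, None]).T @ mprev
            Exx_cur = np.einsum("t,tij->ij", w, Vs[1:]) + \
                (mcur * w[:, None]).T @ mcur
            sw = w.sum()
            sprev = (mprev * w[:, None]).sum(0)
            scur = (mcur * w[:, None]).sum(0)
            Sxx[:D, :D] += Exx_prev
            Sxx[:D, D] += sprev
            Sxx[D, :D] += sprev
            Sxx[D, D] += sw
            Syx[:, :D] += Excur_xprev
            Syx[:, D] += scur
            Syy += Exx_cur
            wtot += sw
        if wtot < D + 1:
            A[k] = np.eye(D) * 0.9
            Q[k] = np.eye(D) * 0.01
            continue
        W = Syx @ np.linalg.inv(Sxx)
        A[k] = W[:, :D]
        b[k] = W[:, D]
        resid = Syy - W @ Syx.T
        Qk = resid / wtot
        Qk = 0.5 * (Qk + Qk.T)
        ev = np.linalg.eigvalsh(Qk)
        if ev.min() < 1e-10:
            Qk += (1e-10 - min(ev.min(), 0)) * np.eye(D)
        Q[k] = Qk
    return A, b, Q


def _m_step_emissions(y_list, ms_list, Vs_list, ridge):
    N = y_list[0].shape[0]
    D = ms_list[0].shape[1]
    Sxx = ridge * np.eye(D + 1)
    Syx = np.zeros((N, D + 1))
    Tn = 0
    for y, ms, Vs in zip(y_list, ms_list, Vs_list):
        Exx = Vs.sum(axis=0) + ms.T @ ms
        Sxx[:D, :D] += Exx
        Sxx[:D, D] += ms.sum(0)
        Sxx[D, :D] += ms.sum(0)
        Sxx[D, D] += ms.shape[0]
        Syx[:, :D] += y @ ms
        Syx[:, D] += y.sum(1)
        Tn += ms.shape[0]
    W = Syx @ np.linalg.inv(Sxx)
    C = W[:, :D]
    d = W[:, D]
    S = np.zeros(N)
    for y, ms, Vs in zip(y_list, ms_list, Vs_list):
        pred = C @ ms.T + d[:, None]
        resid = y - pred
        S += (resid**2).sum(1) + np.einsum("ij,tjk,ik->i", C, Vs, C)
    S = np.maximum(S / Tn, 1e-6)
    return C, d, S


def _blend_dynamics(gamma, A, b, Q):
    """Per-frame dynamics as posterior-weighted mixtures."""
    A_t = np.einsum("tk,kij->tij", gamma, A)
    b_t = gamma @ b
    Q_t = np.einsum("tk,kij->tij", gamma, Q)
    return A_t, b_t, Q_t


def _init_latents(y_list, D):
    """PCA initialization of emissions and latents."""
    Yc = np.hstack(y_list)
    mu = Yc.mean(axis=1)
    Yc0 = Yc - mu[:, None]
    U, s, Vt = np.linalg.svd(Yc0, full_matrices=False)
    scale = s[:D] / np.sqrt(Yc.shape[1])
    C = U[:, :D] * scale
    xs = (Vt[:D] * np.sqrt(Yc.shape[1]))
    ms_list = []
    i = 0
    for y in y_list:
        ms_list.append(xs[:, i:i + y.shape[1]].T.copy())
        i += y.shape[1]
    return C, mu, ms_list


def _init_states(ms_list, K, rng):
    """Initial discrete path: k-means on [x, dx] features."""
    from sklearn.cluster import KMeans
    z_list = []
    if K == 1:
        return [np.zeros(len(m), dtype=int) for m in ms_list]
    feats = []
    for ms in ms_list:
        dx = np.vstack([np.zeros((1, ms.shape[1])), np.diff(ms, axis=0)])
        feats.append(np.hstack([ms, dx]))
    F = np.vstack(feats)
    km = KMeans(n_clusters=K, n_init=3,
                random_state=int(rng.integers(2**31)))
    lab = km.fit_predict(F)
    i = 0
    for ms in ms_list:
        z_list.append(lab[i:i + len(ms)].astype(int))
        i += len(ms)
    return z_list


def _fit_segments(y_list, K, D, config: FitConfig):
    """Core structured-EM loop over a list of contiguous raster segments."""
    rng = np.random.default_rng(config.seed % (2**31))
    C, d, ms_list = _init_latents(y_list, D)
    N = y_list[0].shape[0]
    S = np.full(N, 1.0)
    z_list = _init_states(ms_list, K, rng)
    gamma_list = [np.eye(K)[z] for z in z_list]
    Vs_list = [np.tile(np.eye(D)[None] * 1e-3, (len(m), 1, 1)) for m in ms_list]
    Vlag_list = [np.zeros((len(m), D, D)) for m in ms_list]
    A, b, Q = _m_step_dynamics(ms_list, Vs_list, Vlag_list, gamma_list,
                               K, D, config.ridge)
    R = np.zeros((K, D))
    r = np.zeros(K)
    P = np.zeros((K, K))
    diagnostics = FitDiagnostics()
    prev_obj = -np.inf
    for it in range(config.n_iters):
        # discrete E-step given latent means
        if K > 1:
            new_gamma, new_z = [], []
            for ms in ms_list:
                loglik = _state_loglik(ms, A, b, Q)
                T = len(ms)
                logits = ms[:-1] @ R.T + r           # (T-1, K) recurrent part
                logtrans = logits[:, None, :] + P[None]
                logtrans -= _logsumexp(logtrans, axis=2, keepdims=True)
                gamma, _ = _forward_backward(loglik, logtrans,
                                             np.full(K, -np.log(K)))
                new_gamma.append(gamma)
                new_z.append(gamma.argmax(axis=1))
            gamma_list, z_list = new_gamma, new_z
        # continuous E-step
        blend = []
        for y, gamma in zip(y_list, gamma_list):
            A_t, b_t, Q_t = _blend_dynamics(gamma, A, b, Q)
            blend.append((y, A_t, b_t, Q_t))
        ms_list, Vs_list, Vlag_list, ll = _segment_smoother(blend, C, d, S)
        diagnostics.elbo_trace.append(ll)
        # M-steps
        A, b, Q = _m_step_dynamics(ms_list, Vs_list, Vlag_list, gamma_list,
                                   K, D, config.ridge)
        C, d, S = _m_step_emissions(y_list, ms_list, Vs_list, config.ridge)
        if K > 1:
            R, r, P = _fit_transitions(ms_list, z_list, K, D)
        if it > 2 and abs(ll - prev_obj) < config.tol * abs(prev_obj):
            diagnostics.converged = True
            diagnostics.n_iters_run = it + 1
            break
        prev_obj = ll
    else:
        diagnostics.n_iters_run = config.n_iters
    # prune never-occupied states
    occ = np.concatenate(gamma_list).mean(axis=0)
    keep = occ >= config.min_state_frac
    if K > 1 and not keep.all() and keep.sum() >= 1:
        idx = np.flatnonzero(keep)
        diagnostics.pruned_states = K - len(idx)
        warnings.warn(f"pruned {diagnostics.pruned_states} unoccupied state(s)")
        A, b, Q = A[idx], b[idx], Q[idx]
        R, r, P = R[idx], r[idx], P[np.ix_(idx, idx)]
        remap = {old: new for new, old in enumerate(idx)}
        z_list = [np.array([remap.get(zi, 0) for zi in z]) for z in z_list]
        gamma_list = [g[:, idx] / g[:, idx].sum(1, keepdims=True)
                      for g in gamma_list]
    params = RSLDSParams(A=A, b=b, Q=Q, R=R, r=r, P=P, C=C, d=d, S=S)
    for k in range(params.n_states):
        if np.abs(np.linalg.eigvals(params.A[k])).max() > 1 + 1e-6:
            diagnostics.unstable = True
    return params, ms_list, gamma_list, z_list, diagnostics


def _logsumexp(a, axis=None, keepdims=False):
    m = a.max(axis=axis, keepdims=True)
    out = m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)


# ---------------------------------------------------------------------------
# public operations

def fit_rslds(raster: PopulationRaster, K: int = 1, D: int = 2,
              config: FitConfig | None = None
              ) -> tuple[RSLDSParams, LatentTrajectory, FitDiagnostics]:
    """Fit an rSLDS to a z-scored population raster.

    Runs ``config.n_restarts`` restarts and keeps the best objective.  The
    returned latents are the smoothed posterior means with per-frame discrete
    state posteriors.
    """
    config = config or FitConfig()
    if raster.n_frames < K * D + 2:
        raise ValueError("raster too short for requested model order")
    y = raster.data
    best = None
    for rs in range(max(1, config.n_restarts)):
        cfg = FitConfig(**{**config.__dict__, "seed": config.seed + 97 * rs})
        params, ms_list, gamma_list, z_list, diag = _fit_segments([y], K, D, cfg)
        score = diag.elbo_trace[-1] if diag.elbo_trace else -np.inf
        if best is None or score > best[-1]:
            best = (params, ms_list, gamma_list, z_list, diag, score)
    params, ms_list, gamma_list, z_list, diag, _ = best
    lat = LatentTrajectory(x=ms_list[0].T, z=z_list[0],
                           credences=gamma_list[0],
                           frame_rate=raster.frame_rate)
    return params, lat, diag


def project_into_model(params: RSLDSParams, raster: PopulationRaster
                       ) -> LatentTrajectory:
    """Infer latents for a raster with all model parameters frozen.

    The raster must have the same neurons, in the same order, as the raster
    the model was fit on (cross-day registration is assumed given).
    """
    if raster.n_neurons != params.n_neurons:
        raise ValueError("neuron count mismatch with fitted emissions")
    y = raster.data
    K, D = params.n_states, params.n_dims
    T = raster.n_frames
    gamma = np.full((T, K), 1.0 / K)
    ms = None
    for _ in range(3 if K > 1 else 1):
        A_t, b_t, Q_t = _blend_dynamics(gamma, params.A, params.b, params.Q)
        ms, Vs, Vlag, _ = _kalman_smoother(
            y, params.C, params.d, params.S, A_t, b_t, Q_t,
            np.zeros(D), 10.0 * np.eye(D))
        if K == 1:
            break
        loglik = _state_loglik(ms, params.A, params.b, params.Q)
        logits = ms[:-1] @ params.R.T + params.r
        logtrans = logits[:, None, :] + params.P[None]
        logtrans -= _logsumexp(logtrans, axis=2, keepdims=True)
        gamma, _ = _forward_backward(loglik, logtrans,
                                     np.full(K, -np.log(K)))
    return LatentTrajectory(x=ms.T, z=gamma.argmax(axis=1), credences=gamma,
                            frame_rate=raster.frame_rate)


def time_constants(params: RSLDSParams, frame_rate: float,
                   latents: LatentTrajectory | None = None) -> TimeConstantSet:
    """Time constants tau = |1/log|lam|| of every state's dynamics matrix.

    Complex conjugate pairs contribute a single tau (from the shared
    magnitude).  Eigenvalues with |lam| >= 1 are capped at a large ceiling
    and flagged.
    """
    taus_f, taus_s, eigs = [], [], []
    capped = False
    for k in range(params.n_states):
        lam = np.linalg.eigvals(params.A[k])
        # every eigenvalue contributes; a complex conjugate pair yields two
        # equal taus from the shared magnitude (so a rotational plane scores 0)
        mags = np.abs(lam)
        seen = list(lam)
        t = []
        for m in mags:
            if m <= 0:
                t.append(0.0)
            elif m >= 1.0:
                t.append(TAU_CEILING_FRAMES)
                capped = True
            else:
                t.append(abs(1.0 / np.log(m)))
        t = sorted(t, reverse=True)
        taus_f.append(np.array(t))
        taus_s.append(np.array(t) / frame_rate)
        eigs.append(np.array(seen))
    if latents is not None and latents.credences is not None \
            and latents.credences.shape[1] == params.n_states:
        occ = latents.credences.mean(axis=0)
    else:
        occ = np.full(params.n_states, 1.0 / params.n_states)
    return TimeConstantSet(taus_frames=taus_f, taus_seconds=taus_s,
                           eigenvalues=eigs, frame_rate=frame_rate,
                           state_occupancy=occ, capped=capped)


def line_attractor_score(tcs: TimeConstantSet, state: int | None = None) -> float:
    """log2 ratio of the two longest time constants of one state's dynamics.

    By default uses the state housing the overall slowest dimension.  A large
    score (one dominant slow mode) indicates an approximate line attractor.
    """
    k = tcs.slowest_state() if state is None else state
    taus = tcs.taus_frames[k]
    if len(taus) < 2:
        raise ValueError("need >= 2 dimensions for a line-attractor score")
    if taus[1] <= 0:
        return np.inf
    return float(np.log2(taus[0] / taus[1]))


def integration_dimension(params: RSLDSParams, latents: LatentTrajectory,
                          normalize: str = "minmax",
                          min_ratio: float = 3.0) -> dict:
    """Extract the slowest latent mode (the integration dimension).

    Projects the latents onto the slow eigenvector of the slowest state's
    dynamics; returns the (normalized) mode time series, per-neuron weights
    (the corresponding emission direction), and a flag when no dimension is
    at least ``min_ratio`` times slower than the next.
    """
    tcs = time_constants(params, latents.frame_rate, latents)
    k = tcs.slowest_state()
    lam, V = np.linalg.eig(params.A[k])
    order = np.argsort(-np.abs(lam))
    lam, V = lam[order], V[:, order]
    Vinv = np.linalg.inv(V)
    series = np.real(Vinv[0] @ latents.x)
    taus = tcs.taus_frames[k]
    present = len(taus) >= 2 and taus[1] > 0 and taus[0] / taus[1] >= min_ratio
    weights = np.real(params.C @ V[:, 0])
    if normalize == "minmax":
        span = series.max() - series.min()
        norm = (series - series.min()) / span if span > 0 else series * 0
    elif normalize == "zscore":
        sd = series.std()
        norm = (series - series.mean()) / sd if sd > 0 else series * 0
    else:
        norm = series
    return {"series": norm, "raw_series": series, "weights": weights,
            "state": k, "tau_frames": taus[0], "tau_seconds": taus[0] /
            latents.frame_rate, "attractor_present": bool(present)}


def forward_sim_accuracy(params: RSLDSParams, latents: LatentTrajectory,
                         delta_t: int = 10) -> dict:
    """Forward-simulation accuracy: from each frame's posterior latent,
    simulate ``delta_t`` frames ahead under the (most likely state's)
    dynamics and compare with the inferred latents.

    Returns per-frame accuracy 1 - normalized MSE (min-max normalized over
    the session, hence in [0, 1]) and the mean per-dimension Pearson R^2
    between predictions and observations (the variance-explained measure).
    """
    if delta_t < 1:
        raise ValueError("delta_t must be >= 1 frame")
    x = latents.x
    z = latents.z
    D, T = x.shape
    if T <= delta_t:
        raise ValueError("session shorter than delta_t")
    preds = np.full((D, T), np.nan)
    for t in range(T - delta_t):
        xt = x[:, t]
        k = int(z[t])
        for _ in range(delta_t):
            xt = params.A[k] @ xt + params.b[k]
        preds[:, t + delta_t] = xt
    valid = ~np.isnan(preds[0])
    mse = ((preds[:, valid] - x[:, valid])**2).mean(axis=0)
    span = mse.max() - mse.min()
    acc = 1.0 - (mse - mse.min()) / span if span > 0 else np.ones_like(mse)
    r2 = []
    for i in range(D):
        p, o = preds[i, valid], x[i, valid]
        if p.std() > 0 and o.std() > 0:
            r2.append(np.corrcoef(p, o)[0, 1]**2)
    return {"accuracy": acc, "mse": mse,
            "variance_explained": float(np.mean(r2)) if r2 else np.nan}


def select_model_order(raster: PopulationRaster, K_grid=(1, 2),
                       D_grid=(1, 2, 3), folds: int = 5,
                       config: FitConfig | None = None) -> tuple[int, int]:
    """Choose (K, D) by k-fold cross-validated predictive likelihood.

    Folds are contiguous time blocks; each candidate is fit on the remaining
    blocks and scored by the Kalman-filter log-likelihood of the held-out
    block under frozen parameters.  Ties break toward smaller D, then K.
    """
    if not K_grid or not D_grid:
        raise ValueError("grids must be non-empty")
    config = config or FitConfig(n_iters=15)
    y = raster.data
    T = raster.n_frames
    edges = np.linspace(0, T, folds + 1).astype(int)
    results = {}
    for K in K_grid:
        for D in D_grid:
            scores = []
            for f in range(folds):
                a, bnd = edges[f], edges[f + 1]
                train = [y[:, :a], y[:, bnd:]]
                train = [s for s in train if s.shape[1] > 10 * D]
                try:
                    params, *_ = _fit_segments(train, K, D, config)
                except Exception:
                    scores.append(-np.inf)
                    continue
                test = PopulationRaster(y[:, a:bnd], raster.frame_rate)
                try:
                    lat = project_into_model(params, test)
                    A_t, b_t, Q_t = _blend_dynamics(
                        lat.credences, params.A, params.b, params.Q)
                    _, _, _, ll = _kalman_smoother(
                        test.data, params.C, params.d, params.S,
                        A_t, b_t, Q_t, np.zeros(D), 10.0 * np.eye(D))
                    scores.append(ll / test.n_frames)
                except Exception:
                    scores.append(-np.inf)
            results[(K, D)] = float(np.mean(scores))
    if all(not np.isfinite(v) for v in results.values()):
        raise RuntimeError("all candidate fits failed")
    best_score = max(results.values())
    # tie tolerance: within 0.1% of best counts as a tie
    cands = [kd for kd, v in results.items()
             if v >= best_score - 1e-3 * abs(best_score)]
    K, D = min(cands, key=lambda kd: (kd[1], kd[0]))
    return K, D


def fit_excluding_windows(raster: PopulationRaster,
                          windows: list[tuple[int, int]],
                          K: int = 1, D: int = 2,
                          config: FitConfig | None = None,
                          post_seconds: float = 20.0) -> dict:
    """Fit on data outside perturbation windows (and a post-window margin),
    then evaluate how well the frozen model predicts the held-out relaxation.

    For each window, latents are inferred from the full raster with frozen
    parameters; the model is then forward-simulated from the state at window
    end through the post-window period and compared with the inferred
    latents (pooled cvR^2 across windows).
    """
    config = config or FitConfig()
    T = raster.n_frames
    post = int(round(post_seconds * raster.frame_rate))
    windows = sorted((int(a), int(b)) for a, b in windows)
    mask = np.ones(T, dtype=bool)
    for a, b in windows:
        if not (0 <= a < b <= T):
            raise ValueError("window outside session")
        mask[a:min(T, b + post)] = False
    segments = []
    y = raster.data
    for s, e in _true_runs(mask):
        if e - s > max(20, 5 * D):
            segments.append(y[:, s:e])
    if sum(s.shape[1] for s in segments) < 20 * D:
        raise ValueError("not enough unperturbed data to fit")
    params, ms_list, gamma_list, z_list, diag = _fit_segments(
        segments, K, D, config)
    if not windows:
        lat = LatentTrajectory(x=ms_list[0].T, z=z_list[0],
                               credences=gamma_list[0],
                               frame_rate=raster.frame_rate)
        return {"params": params, "latents": lat, "diagnostics": diag,
                "cv_r2": np.nan, "predictions": []}
    lat_full = project_into_model(params, raster)
    preds, obs = [], []
    records = []
    for a, b in windows:
        end = min(T, b + post)
        if b >= T:
            continue
        xt = lat_full.x[:, b - 1]
        k = int(lat_full.z[b - 1])
        sim = np.zeros((params.n_dims, end - b))
        for i in range(end - b):
            xt = params.A[k] @ xt + params.b[k]
            sim[:, i] = xt
        preds.append(sim)
        obs.append(lat_full.x[:, b:end])
        records.append({"window": (a, b), "pred": sim,
                        "observed": lat_full.x[:, b:end]})
    if preds:
        p = np.hstack(preds)
        o = np.hstack(obs)
        ss_res = ((p - o)**2).sum()
        ss_tot = ((o - o.mean(axis=1, keepdims=True))**2).sum()
        cv_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    else:
        cv_r2 = np.nan
    return {"params": params, "latents": lat_full, "diagnostics": diag,
            "cv_r2": float(cv_r2), "predictions": records}


def attractor_line_distance(params: RSLDSParams, latents: LatentTrajectory,
                            state: int | None = None) -> dict:
    """Per-frame distance from the fitted attractor line, in innovation-sd
    units of the fast modes.

    The attractor line of the slowest state is the set of latent points
    whose fast eigen-mode coordinates sit at their fixed-point values; the
    returned series is the root-sum-square deviation of the fast
    coordinates, normalized by each mode's innovation s.d.
    """
    tcs = time_constants(params, latents.frame_rate, latents)
    k = tcs.slowest_state() if state is None else state
    lam, V = np.linalg.eig(params.A[k])
    order = np.argsort(-np.abs(lam))
    lam, V = lam[order], V[:, order]
    Vinv = np.linalg.inv(V)
    w = Vinv @ latents.x                      # mode coordinates (complex ok)
    wb = Vinv @ params.b[k]
    Qm = Vinv @ params.Q[k] @ Vinv.conj().T
    dev = np.zeros(latents.n_frames)
    for m in range(1, params.n_dims):         # fast modes only
        denom = 1.0 - lam[m]
        w_star = wb[m] / denom if abs(denom) > 1e-12 else 0.0
        sd = np.sqrt(max(np.real(Qm[m, m]), 1e-18))
        dev += (np.abs(w[m] - w_star) / sd)**2
    return {"distance_sd": np.sqrt(dev), "state": k}


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def flow_field_2d(params: RSLDSParams, latents: LatentTrajectory,
                  grid_n: int = 24, slow_percentile: float = 5.0,
                  margin: float = 0.1) -> FlowField2D:
    """Velocity field of the fitted dynamics in the top-2 PC plane of the
    latents, with the slow region (candidate fixed points) masked at the
    given speed percentile."""
    x = latents.x
    if x.shape[0] < 2:
        raise ValueError("need >= 2 latent dimensions")
    center = x.mean(axis=1)
    xc = x - center[:, None]
    U, s, _ = np.linalg.svd(xc, full_matrices=False)
    basis = U[:, :2].T  # (2, D), orthonormal
    proj = basis @ xc
    lo = proj.min(axis=1)
    hi = proj.max(axis=1)
    pad = margin * (hi - lo)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_n)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_n)
    vel = np.zeros((grid_n, grid_n, 2))
    speed = np.zeros((grid_n, grid_n))
    for iy, py in enumerate(gy):
        for ix, px in enumerate(gx):
            xl = center + basis.T @ np.array([px, py])
            k = _most_likely_state(params, xl)
            v = (params.A[k] - np.eye(params.n_dims)) @ xl + params.b[k]
            v2 = basis @ v
            vel[iy, ix] = v2
            speed[iy, ix] = np.linalg.norm(v)
    thr = np.percentile(speed, slow_percentile)
    return FlowField2D(basis=basis, center=center, grid_x=gx, grid_y=gy,
                       velocity=vel, speed=speed, slow_mask=speed <= thr,
                       trajectory=proj)


def _most_likely_state(params: RSLDSParams, x: np.ndarray) -> int:
    if params.n_states == 1:
        return 0
    logits = params.R @ x + params.r
    return int(np.argmax(logits))


def pls_integration_dimension(raster: PopulationRaster,
                              ramp_target: np.ndarray,
                              holdout_frac: float = 0.25) -> dict:
    """Supervised targeted dimensionality reduction: first PLS component of
    the raster regressed on a ramping target vector.

    Returns the neuron weight vector, the projected series, and the
    correlation between projection and target on a held-out final segment.
    """
    target = np.asarray(ramp_target, float).ravel()
    if len(target) != raster.n_frames:
        raise ValueError("target length must equal raster frames")
    if target.std() == 0:
        raise ValueError("zero-variance target")
    T = raster.n_frames
    split = int(T * (1 - holdout_frac))
    X = raster.data.T
    pls = PLSRegression(n_components=1, scale=False)
    pls.fit(X[:split], target[:split])
    w = pls.x_weights_[:, 0]
    w = w / np.linalg.norm(w)
    series = X @ w
    held = np.corrcoef(series[split:], target[split:])[0, 1] \
        if target[split:].std() > 0 and series[split:].std() > 0 else 0.0
    return {"weights": w, "series": series,
            "holdout_corr": float(held)}
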