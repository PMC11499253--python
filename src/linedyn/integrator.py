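"""Input-driven integrator model of the slow (integration) dimension.

Models the integration-dimension time series as a single-state linear
dynamical system with behavioural inputs,

    x_t = A_z x_{t-1} + b + W u_t + eps_t

where ``u_t`` holds binary per-frame indicators of the three male behaviours
(sniff, mount, intromission) and ``W`` linearly combines them into drive
along the integrator.  A large fitted intrinsic time constant together with
high cross-validated accuracy identifies the dimension as an integrator of
male contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BoutTable

__all__ = ["IntegratorModel", "fit_input_driven_integrator",
           "transformed_input", "behavior_indicators"]

INPUT_BEHAVIORS = ("sniff", "mount", "intromission")


@dataclass
class IntegratorModel:
    a: float                    # scalar dynamics A_z
    bias: float
    w: np.ndarray               # (m,) input loading
    w_se: np.ndarray            # OLS standard errors of w
    cv_r2: float
    tau_frames: float
    tau_seconds: float
    frame_rate: float
    behaviors: tuple
    input_free: bool = False    # True when fitted as a plain AR(1)
    flagged_no_input: bool = False


def behavior_indicators(bouts: BoutTable, n_frames: int,
                        behaviors=INPUT_BEHAVIORS) -> np.ndarray:
    """Binary per-frame indicator matrix (m, T) for the input behaviours."""
    return np.vstack([bouts.frame_mask(n_frames, group=b).astype(float)
                      for b in behaviors])


def _tau(a: float) -> float:
    m = abs(a)
    if m <= 0:
        return 0.0
    if m >= 1:
        return np.inf
    return abs(1.0 / np.log(m))


def fit_input_driven_integrator(x_slow: np.ndarray, male_bouts: BoutTable,
                                folds: int = 5, frame_rate: float = 10.0,
                                behaviors=INPUT_BEHAVIORS,
                                include_inputs: bool = True
                                ) -> IntegratorModel:
    """Least-squares fit of the input-driven integrator to a slow-dimension
    series, with contiguous-fold cross-validated one-step R^2.

    With all-zero inputs the model reduces to an AR(1) and is flagged.
    """
    x = np.asarray(x_slow, float).ravel()
    T = len(x)
    u = behavior_indicators(male_bouts, T, behaviors)
    m = u.shape[0]
    no_input = not u.any()
    use_inputs = include_inputs and not no_input
    if use_inputs:
        X = np.column_stack([x[:-1], u[:, 1:].T, np.ones(T - 1)])
    else:
        X = np.column_stack([x[:-1], np.ones(T - 1)])
    y = x[1:]
    edges = np.linspace(0, T - 1, folds + 1).astype(int)
    ss_res = ss_tot = 0.0
    for f in range(folds):
        te = np.zeros(T - 1, bool)
        te[edges[f]:edges[f + 1]] = True
        beta, *_ = np.linalg.lstsq(X[~te], y[~te], rcond=None)
        pred = X[te] @ beta
        ss_res += ((y[te] - pred)**2).sum()
        ss_tot += ((y[te] - y[te].mean())**2).sum()
    cv_r2 = 1.0 - ss_res / max(ss_tot, 1e-12)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(1, len(y) - X.shape[1])
    sigma2 = (resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    a = float(beta[0])
    if use_inputs:
        w, w_se = beta[1:1 + m], se[1:1 + m]
        bias = float(beta[-1])
    else:
        w, w_se = np.zeros(m), np.zeros(m)
        bias = float(beta[-1])
    return IntegratorModel(a=a, bias=bias, w=np.asarray(w),
                           w_se=np.asarray(w_se), cv_r2=float(cv_r2),
                           tau_frames=_tau(a),
                           tau_seconds=_tau(a) / frame_rate,
                           frame_rate=frame_rate, behaviors=tuple(behaviors),
                           input_free=not use_inputs,
                           flagged_no_input=no_input)


def transformed_input(model: IntegratorModel, u: np.ndarray) -> np.ndarray:
    """Collapse the m-channel behaviour indicators into the model's scalar
    per-frame input drive W.u_t."""
    u = np.atleast_2d(np.asarray(u, float))
    if u.shape[0] != len(model.w):
        raise ValueError("indicator channels do not match fitted W")
    return model.w @ u
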