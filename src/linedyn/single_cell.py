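"""Per-neuron tuning and persistence metrics.

Choice probability (ROC discrimination between two behaviours), the
autocorrelation half-width (ACHW) persistence proxy, ridge GLMs predicting
single-neuron activity from behaviour (with optional neuron-neuron
coupling), isosbestic photometry normalization, and a frame-wise linear SVM
behaviour decoder with bout-shuffled controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from .behavior import BoutTable, merge_bouts
from .containers import PopulationRaster

__all__ = [
    "ChoiceProbabilityResult",
    "AutocorrResult",
    "GLMModel",
    "DecoderResult",
    "choice_probability",
    "autocorr_halfwidth",
    "fit_behavior_glm",
    "fit_coupled_glm",
    "photometry_normalize",
    "framewise_svm_decoder",
]

MALE_GLM_BEHAVIORS = ("sniff", "mount", "intromission")


# ---------------------------------------------------------------------------
# choice probability

@dataclass
class ChoiceProbabilityResult:
    cp: np.ndarray              # (n_neurons,) ROC-AUC in [0, 1]
    shuffle_mean: np.ndarray
    shuffle_sd: np.ndarray
    tuned: np.ndarray           # bool per neuron
    n_bins: tuple[int, int]
    flagged: bool = False


def _binned_responses(raster: PopulationRaster, bouts: BoutTable,
                      group: str, bin_seconds: float) -> np.ndarray:
    """Per-neuron responses in non-overlapping bins inside a behaviour's
    bouts; returns (n_neurons, n_bins)."""
    bin_frames = max(1, int(round(bin_seconds * raster.frame_rate)))
    cols = []
    sub = bouts.select(group=group).df
    for start, stop in zip(sub["start"], sub["stop"]):
        start, stop = max(0, int(start)), min(raster.n_frames, int(stop))
        for b0 in range(start, stop, bin_frames):
            b1 = min(b0 + bin_frames, stop)
            cols.append(raster.data[:, b0:b1].mean(axis=1))
    if not cols:
        return np.empty((raster.n_neurons, 0))
    return np.column_stack(cols)


def _auc(a: np.ndarray, b: np.ndarray) -> float:
    """ROC area for samples of class a (positive) vs b, with tie handling
    (equivalent to the Mann-Whitney U statistic divided by n*m)."""
    n, m = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    return float(u / (n * m))


def choice_probability(raster: PopulationRaster, bouts_a: BoutTable,
                       bouts_b: BoutTable, group_a: str | None = None,
                       group_b: str | None = None, bin_seconds: float = 1.0,
                       n_shuffles: int = 1000, seed: int = 0,
                       hi: float = 0.7, lo: float = 0.3
                       ) -> ChoiceProbabilityResult:
    """Choice probability of each neuron for a pair of behaviours.

    Binned (default 1-s) responses during each behaviour's bouts form the two
    ROC sample sets; CP is the ROC area.  0.5 means no discrimination.  The
    shuffle null permutes the behaviour assignment of the binned samples; a
    neuron is flagged tuned when CP > ``hi`` or < ``lo`` and deviates from
    the shuffle mean by more than two shuffle s.d.
    """
    resp_a = _binned_responses(raster, bouts_a,
                               group_a or _only_group(bouts_a), bin_seconds)
    resp_b = _binned_responses(raster, bouts_b,
                               group_b or _only_group(bouts_b), bin_seconds)
    n_neurons = raster.n_neurons
    na, nb = resp_a.shape[1], resp_b.shape[1]
    if na == 0 or nb == 0:
        nan = np.full(n_neurons, np.nan)
        return ChoiceProbabilityResult(cp=nan, shuffle_mean=nan,
                                       shuffle_sd=nan,
                                       tuned=np.zeros(n_neurons, bool),
                                       n_bins=(na, nb), flagged=True)
    cp = np.array([_auc(resp_a[i], resp_b[i]) for i in range(n_neurons)])
    rng = np.random.default_rng(seed)
    pooled = np.hstack([resp_a, resp_b])
    sh = np.zeros((n_shuffles, n_neurons))
    for s in range(n_shuffles):
        perm = rng.permutation(na + nb)
        pa, pb = pooled[:, perm[:na]], pooled[:, perm[na:]]
        sh[s] = [_auc(pa[i], pb[i]) for i in range(n_neurons)]
    mean, sd = sh.mean(axis=0), sh.std(axis=0)
    tuned = ((cp > hi) | (cp < lo)) & (np.abs(cp - mean) > 2 * sd)
    return ChoiceProbabilityResult(cp=cp, shuffle_mean=mean, shuffle_sd=sd,
                                   tuned=tuned, n_bins=(na, nb))


def _only_group(bouts: BoutTable) -> str | None:
    labels = bouts.df["behavior"].unique()
    return labels[0] if len(labels) == 1 else None


# ---------------------------------------------------------------------------
# autocorrelation half-width

@dataclass
class AutocorrResult:
    lags: np.ndarray            # frames
    r: np.ndarray               # autocorrelation, r[0] = 1
    achw_seconds: float
    censored: bool = False
    flagged: bool = False


def autocorr_halfwidth(trace: np.ndarray, frame_rate: float,
                       max_lag_seconds: float = 100.0) -> AutocorrResult:
    """Autocorrelation half-width of a single trace.

    r_k = c_k / c_0 with c_k = (1/T) sum_t (y_t - ybar)(y_{t+k} - ybar);
    the ACHW is the (linearly interpolated) lag at which r first reaches
    0.5, in seconds.  Traces whose r never drops below 0.5 within the
    maximum lag are censored there.  ACHW is invariant to affine transforms
    of the trace.
    """
    y = np.asarray(trace, float)
    T = len(y)
    max_lag = min(T - 2, int(round(max_lag_seconds * frame_rate)))
    if T < 10 * frame_rate:
        raise ValueError("trace shorter than 10 s")
    yc = y - y.mean()
    c0 = (yc @ yc) / T
    if c0 <= 0:
        return AutocorrResult(lags=np.arange(1), r=np.ones(1),
                              achw_seconds=np.nan, flagged=True)
    lags = np.arange(max_lag + 1)
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = (yc[:-k] @ yc[k:]) / T / c0
    below = np.flatnonzero(r < 0.5)
    if len(below) == 0:
        return AutocorrResult(lags=lags, r=r,
                              achw_seconds=max_lag / frame_rate,
                              censored=True)
    k1 = below[0]
    k0 = k1 - 1
    # linear interpolation between bracketing lags
    frac = (r[k0] - 0.5) / (r[k0] - r[k1])
    achw = (k0 + frac) / frame_rate
    return AutocorrResult(lags=lags, r=r, achw_seconds=float(achw))


# ---------------------------------------------------------------------------
# GLMs

@dataclass
class GLMModel:
    filters: np.ndarray          # (n_neurons, n_behaviors, n_lags)
    intercepts: np.ndarray
    cv_r2: np.ndarray            # (n_neurons,)
    ridge: float
    behaviors: tuple
    lag_seconds: float
    coupling: np.ndarray | None = None   # (n_neurons, n_neurons), 0 diagonal
    dropped: list | None = None


def _lagged_design(bouts: BoutTable, n_frames: int, lag_frames: int,
                   behaviors=MALE_GLM_BEHAVIORS) -> tuple[np.ndarray, list]:
    """Binary behaviour indicators at lags t-D..t: (T, B*(D+1))."""
    cols, dropped = [], []
    for bname in behaviors:
        ind = bouts.frame_mask(n_frames, group=bname).astype(float)
        if ind.std() == 0:
            dropped.append(bname)
        block = np.zeros((n_frames, lag_frames + 1))
        for lag in range(lag_frames + 1):
            if lag == 0:
                block[:, 0] = ind
            else:
                block[lag:, lag] = ind[:-lag]
        cols.append(block)
    return np.hstack(cols), dropped


def _interleaved_folds(T: int, folds: int):
    # frame-interleaved folds: robust to the slow nonstationarity of the
    # sessions (a contiguous held-out block sits at an activity level the
    # behaviour regressors cannot encode, driving R^2 negative)
    assign = np.arange(T) % folds
    for f in range(folds):
        test = assign == f
        yield ~test, test


def _ridge_cv_r2(X: np.ndarray, Y: np.ndarray, folds: int,
                 ridge: float | None, ridge_grid=None) -> tuple:
    """Multi-target ridge with contiguous-fold cvR^2; optional nested
    selection of the ridge strength on a log grid."""
    T = X.shape[0]
    if ridge is None:
        ridge_grid = ridge_grid if ridge_grid is not None else \
            np.logspace(0, 4, 5)
    else:
        ridge_grid = [ridge]
    Xm = X.mean(axis=0)
    best = None
    for lam in ridge_grid:
        ss_res = np.zeros(Y.shape[1])
        ss_tot = np.zeros(Y.shape[1])
        for train, test in _interleaved_folds(T, folds):
            Xt = X[train] - Xm
            Yt = Y[train]
            ym = Yt.mean(axis=0)
            G = Xt.T @ Xt + lam * np.eye(X.shape[1])
            B = np.linalg.solve(G, Xt.T @ (Yt - ym))
            pred = (X[test] - Xm) @ B + ym
            ss_res += ((Y[test] - pred)**2).sum(axis=0)
            ss_tot += ((Y[test] - Y[test].mean(axis=0))**2).sum(axis=0)
        r2 = 1.0 - ss_res / np.maximum(ss_tot, 1e-12)
        score = r2.mean()
        if best is None or score > best[0]:
            best = (score, lam, r2)
    _, lam, r2 = best
    Xc = X - Xm
    G = Xc.T @ Xc + lam * np.eye(X.shape[1])
    B = np.linalg.solve(G, Xc.T @ (Y - Y.mean(axis=0)))
    return B, Y.mean(axis=0) - Xm @ B, r2, lam


def fit_behavior_glm(raster: PopulationRaster, male_bouts: BoutTable,
                     lag_seconds: float = 10.0, folds: int = 10,
                     ridge: float | None = None,
                     behaviors=MALE_GLM_BEHAVIORS) -> GLMModel:
    """Ridge GLM predicting each neuron from lagged binary male-behaviour
    indicators (sniff, mount, intromission) over a 10-s filter window.

    Performance is the cross-validated R^2 on held-out contiguous folds;
    ridge strength is chosen by nested CV over a log grid when not given.
    Constant regressors are dropped with a warning record.
    """
    lag_frames = int(round(lag_seconds * raster.frame_rate))
    X, dropped = _lagged_design(male_bouts, raster.n_frames, lag_frames,
                                behaviors)
    Y = raster.data.T
    B, b0, r2, lam = _ridge_cv_r2(X, Y, folds, ridge)
    n_lags = lag_frames + 1
    filters = B.T.reshape(raster.n_neurons, len(behaviors), n_lags)
    return GLMModel(filters=filters, intercepts=b0, cv_r2=r2, ridge=lam,
                    behaviors=tuple(behaviors), lag_seconds=lag_seconds,
                    dropped=dropped)


def fit_coupled_glm(raster: PopulationRaster, male_bouts: BoutTable,
                    lag_seconds: float = 10.0, folds: int = 10,
                    ridge: float | None = None,
                    behaviors=MALE_GLM_BEHAVIORS) -> GLMModel:
    """Behaviour GLM augmented with the simultaneous activity of the other
    neurons as regressors (self-coupling excluded).

    Returns per-neuron cvR^2 with coupling and the fitted coupling matrix.
    """
    if raster.n_neurons < 2:
        raise ValueError("coupled GLM needs >= 2 neurons")
    lag_frames = int(round(lag_seconds * raster.frame_rate))
    Xb, dropped = _lagged_design(male_bouts, raster.n_frames, lag_frames,
                                 behaviors)
    N = raster.n_neurons
    act = raster.data.T  # (T, N)
    n_lags = lag_frames + 1
    cv_r2 = np.zeros(N)
    coupling = np.zeros((N, N))
    filters = np.zeros((N, len(behaviors), n_lags))
    intercepts = np.zeros(N)
    lam_used = 0.0
    for i in range(N):
        others = np.delete(np.arange(N), i)
        X = np.hstack([Xb, act[:, others]])
        B, b0, r2, lam = _ridge_cv_r2(X, act[:, [i]], folds, ridge)
        cv_r2[i] = r2[0]
        filters[i] = B[:Xb.shape[1], 0].reshape(len(behaviors), n_lags)
        coupling[i, others] = B[Xb.shape[1]:, 0]
        intercepts[i] = b0[0]
        lam_used = lam
    return GLMModel(filters=filters, intercepts=intercepts, cv_r2=cv_r2,
                    ridge=lam_used, behaviors=tuple(behaviors),
                    lag_seconds=lag_seconds, coupling=coupling,
                    dropped=dropped)


# ---------------------------------------------------------------------------
# photometry

def photometry_normalize(f470: np.ndarray, f405: np.ndarray,
                         control_fit: np.ndarray | None = None) -> np.ndarray:
    """Motion/bleaching-corrected photometry signal.

    The isosbestic (405 nm) channel is least-squares fit to the signal
    channel (scale + offset) and the normalized series is
    ``Fn = 100 * (F470 - F405fit) / F405fit`` (percent change).  A
    precomputed ``control_fit`` (F405fit) may be passed to bypass the
    internal fit.  Invariant to joint rescaling of both channels.
    """
    f470 = np.asarray(f470, float)
    f405 = np.asarray(f405, float)
    if control_fit is None:
        A = np.column_stack([f405, np.ones_like(f405)])
        coef, *_ = np.linalg.lstsq(A, f470, rcond=None)
        fit = A @ coef
    else:
        fit = np.asarray(control_fit, float)
    if np.any(fit <= 0):
        raise ValueError("fitted control channel must be strictly positive")
    return 100.0 * (f470 - fit) / fit


# ---------------------------------------------------------------------------
# frame-wise SVM decoder

@dataclass
class DecoderResult:
    f1_actual: float
    f1_shuffles: np.ndarray
    chance: float = 0.5
    flagged: bool = False


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def framewise_svm_decoder(raster: PopulationRaster, bouts_a: BoutTable,
                          bouts_b: BoutTable, group_a: str | None = None,
                          group_b: str | None = None,
                          merge_gap_seconds: float = 5.0,
                          n_shuffles: int = 20, folds: int = 5,
                          seed: int = 0) -> DecoderResult:
    """Linear SVM discriminating two behaviours from population activity.

    Bouts closer than ``merge_gap_seconds`` are merged into trials, frames
    are balanced across classes (chance = 0.5), and the decoder is trained
    trial-wise and scored by the average F1 on held-out frames.  The shuffle
    control reassigns class labels randomly across whole bouts.
    """
    rng = np.random.default_rng(seed)
    ta = merge_bouts(bouts_a, merge_gap_seconds)
    tb = merge_bouts(bouts_b, merge_gap_seconds)
    da = ta.select(group=group_a).df if group_a else ta.df
    db = tb.select(group=group_b).df if group_b else tb.df
    trials = [(1, int(s), int(e)) for s, e in zip(da["start"], da["stop"])] +\
             [(0, int(s), int(e)) for s, e in zip(db["start"], db["stop"])]
    trials = [(c, s, min(e, raster.n_frames)) for c, s, e in trials
              if s < raster.n_frames]
    if not any(c == 1 for c, *_ in trials) or \
            not any(c == 0 for c, *_ in trials):
        return DecoderResult(f1_actual=np.nan,
                             f1_shuffles=np.full(n_shuffles, np.nan),
                             flagged=True)

    def score(trial_labels: list[int]) -> float:
        f1s = []
        order = rng.permutation(len(trials))
        fold_of = {int(ti): int(i % folds) for i, ti in enumerate(order)}
        for f in range(folds):
            tr_frames, tr_y, te_frames, te_y = [], [], [], []
            for ti, (c, s, e) in enumerate(trials):
                dest = (te_frames, te_y) if fold_of[ti] == f \
                    else (tr_frames, tr_y)
                dest[0].extend(range(s, e))
                dest[1].extend([trial_labels[ti]] * (e - s))
            tr_y = np.array(tr_y)
            te_y = np.array(te_y)
            if len(np.unique(tr_y)) < 2 or len(te_y) == 0:
                continue
            tr_frames = np.array(tr_frames)
            te_frames = np.array(te_frames)
            # balance training classes by subsampling the majority
            i1 = np.flatnonzero(tr_y == 1)
            i0 = np.flatnonzero(tr_y == 0)
            nmin = min(len(i0), len(i1))
            keep = np.concatenate([rng.choice(i1, nmin, replace=False),
                                   rng.choice(i0, nmin, replace=False)])
            clf = LinearSVC(dual="auto", max_iter=5000, C=1.0)
            clf.fit(raster.data[:, tr_frames[keep]].T, tr_y[keep])
            pred = clf.predict(raster.data[:, te_frames].T)
            f1s.append(_f1(te_y, pred))
        return float(np.mean(f1s)) if f1s else np.nan

    actual = score([c for c, *_ in trials])
    labels = np.array([c for c, *_ in trials])
    shuffles = np.zeros(n_shuffles)
    for s in range(n_shuffles):
        shuffles[s] = score(list(rng.permutation(labels)))
    return DecoderResult(f1_actual=actual, f1_shuffles=shuffles)
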