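"""Behaviour bout tables, interval statistics and event-triggered averaging.

Behavioural annotations are intervals (actor, label, start, stop) on the
imaging frame clock.  Intervals are half-open ``[start, stop)`` in 0-based
frames.  Labels are grouped into functional classes (accepting, resistance,
appetitive, ...) following the standard annotation scheme for female mouse
mating assays: lordose and wiggle count as accepting; approach and sniff as
appetitive; dart, top-up, kick and turn as resistance; mount and intromission
as male copulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GROUPS",
    "BoutTable",
    "PETH",
    "merge_bouts",
    "behavior_probability",
    "bout_ibi_stats",
    "initiation_split",
    "engagement_fractions",
    "event_triggered_average",
]

#: Label -> group memberships used throughout the pipeline.
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "accept": frozenset({"lordose", "wiggle"}),
    "appetitive": frozenset({"approach", "sniff"}),
    "resistance": frozenset({"dart", "top_up", "kick", "turn"}),
    "self_initiated": frozenset({"approach", "sniff", "check_genital"}),
    "responsive": frozenset(
        {"lordose", "wiggle", "stay", "dart", "top_up", "kick", "turn"}
    ),
    "social": frozenset(
        {"lordose", "wiggle", "approach", "sniff", "dart", "top_up", "kick", "turn"}
    ),
    "disengaged": frozenset({"rear", "dig", "chew"}),
    "copulation": frozenset({"mount", "intromission"}),
    "male_self_initiated": frozenset({"sniff", "mount", "intromission"}),
}

_COLUMNS = ["actor", "behavior", "start", "stop"]


@dataclass
class BoutTable:
    """Ordered table of annotated behaviour bouts.

    Parameters
    ----------
    df
        DataFrame with columns ``actor`` ({"male","female"}), ``behavior``
        (label string), ``start``, ``stop`` (frames; half-open, 0-based).
    frame_rate
        Acquisition rate in Hz.
    groups
        Mapping group name -> set of labels belonging to the group.
    warning
        Set when an operation produced a degenerate result (e.g. the session
        was too short to place any bout).
    """

    df: pd.DataFrame
    frame_rate: float = 10.0
    groups: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    warning: bool = False

    def __post_init__(self) -> None:
        if self.df is None or len(self.df) == 0:
            self.df = pd.DataFrame(columns=_COLUMNS)
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"bout table missing columns {missing}")
        df = self.df[_COLUMNS].copy()
        df["start"] = df["start"].astype(int)
        df["stop"] = df["stop"].astype(int)
        if (df["start"] >= df["stop"]).any():
            bad = df.index[df["start"] >= df["stop"]].tolist()
            raise ValueError(f"bouts with start >= stop at rows {bad}")
        df = df.sort_values(["actor", "start"], kind="stable").reset_index(drop=True)
        self.df = df
        self._check_overlap()

    def _check_overlap(self) -> None:
        for (actor, label), sub in self.df.groupby(["actor", "behavior"]):
            starts = sub["start"].to_numpy()
            stops = sub["stop"].to_numpy()
            if np.any(starts[1:] < stops[:-1]):
                raise ValueError(
                    f"overlapping bouts for actor={actor!r} label={label!r}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def labels_in_group(self, group: str) -> frozenset[str]:
        if group in self.groups:
            return self.groups[group]
        return frozenset({group})  # a bare label acts as its own group

    def select(self, actor: str | None = None, group: str | None = None) -> "BoutTable":
        df = self.df
        if actor is not None:
            df = df[df["actor"] == actor]
        if group is not None:
            df = df[df["behavior"].isin(self.labels_in_group(group))]
        return replace(self, df=df.reset_index(drop=True))

    def frame_mask(self, n_frames: int, actor: str | None = None,
                   group: str | None = None) -> np.ndarray:
        """Boolean per-frame occupancy mask for a (actor, group) selection."""
        mask = np.zeros(n_frames, dtype=bool)
        sub = self.select(actor=actor, group=group).df
        for start, stop in zip(sub["start"], sub["stop"]):
            mask[max(0, start):min(n_frames, stop)] = True
        return mask

    def durations_seconds(self) -> np.ndarray:
        return (self.df["stop"] - self.df["start"]).to_numpy() / self.frame_rate

    def onsets(self, actor: str | None = None, group: str | None = None) -> np.ndarray:
        return self.select(actor=actor, group=group).df["start"].to_numpy()


@dataclass
class PETH:
    """Peri-event average: baseline-z-scored signal aligned to events.

    ``mean``/``sem`` run over ``lags`` (seconds relative to the event);
    ``n_events`` counts events entering the average; ``flagged`` marks
    degenerate baselines (zero variance, floored at ``sd_floor``).
    """

    lags: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    flagged: bool = False


def merge_bouts(bouts: BoutTable, max_gap: float) -> BoutTable:
    """Merge same-label bouts separated by less than ``max_gap`` seconds.

    Idempotent; merging with gap 0 is the identity.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    gap_frames = max_gap * bouts.frame_rate
    out = []
    for (actor, label), sub in bouts.df.groupby(["actor", "behavior"], sort=False):
        starts = sub["start"].to_numpy()
        stops = sub["stop"].to_numpy()
        cur_start, cur_stop = starts[0], stops[0]
        for s, e in zip(starts[1:], stops[1:]):
            if s - cur_stop < gap_frames:
                cur_stop = max(cur_stop, e)
            else:
                out.append((actor, label, cur_start, cur_stop))
                cur_start, cur_stop = s, e
        out.append((actor, label, cur_start, cur_stop))
    df = pd.DataFrame(out, columns=_COLUMNS)
    return replace(bouts, df=df)


def behavior_probability(
    bouts: BoutTable,
    n_frames: int,
    bin_seconds: float = 20.0,
    groups: tuple[str, ...] = ("accept", "appetitive", "resistance"),
    actor: str = "female",
    mode: str = "occupancy",
) -> pd.DataFrame:
    """Binned behaviour probability per group.

    ``mode='occupancy'`` gives the fraction of frames in each bin occupied by
    the group; ``mode='occurrence'`` gives 1 if the group occurs at all in the
    bin.  Groups are multi-label: columns need not sum to 1.
    """
    if mode not in ("occupancy", "occurrence"):
        raise ValueError("mode must be 'occupancy' or 'occurrence'")
    bin_frames = max(1, int(round(bin_seconds * bouts.frame_rate)))
    if n_frames < bin_frames:
        raise ValueError("session shorter than one bin")
    n_bins = n_frames // bin_frames
    result = {}
    for g in groups:
        mask = bouts.frame_mask(n_frames, actor=actor, group=g)
        trimmed = mask[: n_bins * bin_frames].reshape(n_bins, bin_frames)
        occ = trimmed.mean(axis=1)
        result[g] = (occ > 0).astype(float) if mode == "occurrence" else occ
    idx = (np.arange(n_bins) + 0.5) * bin_frames / bouts.frame_rate
    return pd.DataFrame(result, index=pd.Index(idx, name="time_s"))


def bout_ibi_stats(bouts: BoutTable, group: str = "copulation",
                   actor: str = "male") -> dict:
    """Durations and inter-bout intervals (IBIs) of a bout group.

    Consecutive bouts of the group (labels pooled, overlaps unioned) define
    IBIs as the gaps between them, in seconds.
    """
    sub = bouts.select(actor=actor, group=group).df
    if len(sub) == 0:
        return {"durations_s": np.array([]), "ibis_s": np.array([]),
                "mean_duration_s": np.nan, "mean_ibi_s": np.nan,
                "median_ibi_s": np.nan}
    # union overlapping bouts across labels within the group
    ivs = sorted(zip(sub["start"], sub["stop"]))
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    merged = np.asarray(merged, dtype=float)
    durations = (merged[:, 1] - merged[:, 0]) / bouts.frame_rate
    ibis = (merged[1:, 0] - merged[:-1, 1]) / bouts.frame_rate
    return {
        "durations_s": durations,
        "ibis_s": ibis,
        "mean_duration_s": float(durations.mean()),
        "mean_ibi_s": float(ibis.mean()) if len(ibis) else np.nan,
        "median_ibi_s": float(np.median(ibis)) if len(ibis) else np.nan,
    }


def initiation_split(female: BoutTable, male: BoutTable,
                     n_frames: int) -> dict:
    """Self-initiated vs responsive female mating time, and the male/female
    self-initiated time ratio.

    Fractions are over total female mating time (self-initiated + responsive
    frame union) and sum to 1 when that time is non-zero.
    """
    self_mask = female.frame_mask(n_frames, actor="female", group="self_initiated")
    resp_mask = female.frame_mask(n_frames, actor="female", group="responsive")
    total = np.logical_or(self_mask, resp_mask).sum()
    if total == 0:
        return {"responsive_fraction": np.nan, "self_initiated_fraction": np.nan,
                "male_female_self_ratio": np.nan, "flagged": True}
    # frames in both classes split proportionally is overkill; responsive takes
    # precedence on overlap (a responsive label is by definition a reaction)
    resp = resp_mask.sum()
    self_only = np.logical_and(self_mask, ~resp_mask).sum()
    male_self = male.frame_mask(n_frames, actor="male",
                                group="male_self_initiated").sum()
    ratio = male_self / self_mask.sum() if self_mask.sum() > 0 else np.inf
    return {
        "responsive_fraction": resp / total,
        "self_initiated_fraction": self_only / total,
        "male_female_self_ratio": float(ratio),
        "flagged": False,
    }


def engagement_fractions(female: BoutTable, male: BoutTable,
                         n_frames: int) -> pd.DataFrame:
    """Female social / disengaged / other time fractions per male copulation
    bout and per IBI."""
    cop = male.select(actor="male", group="copulation").df
    ivs = sorted(zip(cop["start"], cop["stop"]))
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    social = female.frame_mask(n_frames, actor="female", group="social")
    diseng = female.frame_mask(n_frames, actor="female", group="disengaged")
    rows = []
    intervals = [("bout", s, e) for s, e in merged]
    intervals += [("ibi", merged[i][1], merged[i + 1][0])
                  for i in range(len(merged) - 1)]
    for kind, s, e in intervals:
        n = e - s
        if n <= 0:
            continue
        fs = social[s:e].mean()
        fd = diseng[s:e].mean()
        rows.append({"kind": kind, "start": s, "stop": e,
                     "social": fs, "disengaged": fd,
                     "others": 1.0 - fs - fd})
    return pd.DataFrame(rows)


def event_triggered_average(
    signal: np.ndarray,
    events: np.ndarray,
    frame_rate: float,
    window: tuple[float, float] = (-10.0, 30.0),
    baseline: tuple[float, float] = (-5.0, -3.0),
    sd_floor: float = 1e-6,
) -> PETH:
    """Event-aligned average of a baseline-z-scored signal.

    For each event the signal in ``baseline`` (seconds relative to the event)
    supplies a mean F0 and s.d.; the windowed trace is z-scored against them
    before averaging.  Events whose window falls outside the session are
    dropped; a zero-variance baseline is floored at ``sd_floor`` and flags
    the result.
    """
    signal = np.asarray(signal, dtype=float)
    events = np.asarray(events, dtype=int)
    pre = int(round(window[0] * frame_rate))
    post = int(round(window[1] * frame_rate))
    b0 = int(round(baseline[0] * frame_rate))
    b1 = int(round(baseline[1] * frame_rate))
    if not (b0 < b1 <= 0):
        raise ValueError("baseline window must precede the event")
    lo = min(pre, b0)
    snippets, flagged = [], False
    for ev in events:
        if ev + lo < 0 or ev + post > len(signal):
            continue
        base = signal[ev + b0: ev + b1]
        f0, sd0 = base.mean(), base.std()
        if sd0 < sd_floor:
            sd0, flagged = sd_floor, True
        snippets.append((signal[ev + pre: ev + post] - f0) / sd0)
    lags = np.arange(pre, post) / frame_rate
    if not snippets:
        nan = np.full(post - pre, np.nan)
        return PETH(lags=lags, mean=nan, sem=nan, n_events=0, flagged=True)
    arr = np.vstack(snippets)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 \
        else np.zeros(arr.shape[1])
    return PETH(lags=lags, mean=arr.mean(axis=0), sem=sem,
                n_events=len(arr), flagged=flagged)
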