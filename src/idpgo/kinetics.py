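"""Three-state kinetic decomposition of binding-and-folding trajectories.

Frames are labeled unbound (U), collision complex (CC) or bound (B) from
running-average-smoothed contact counts:

* U  - no specific and no nonspecific intermolecular contact,
* CC - at least one nonspecific but no specific intermolecular contact,
* B  - at least ``n_inter_min`` specific (native intermolecular) contacts.

Frames with an intermediate number of specific contacts inherit the
previous unambiguous label, so intermediates never form a fourth state.
Direct U<->B label changes are split through a zero-length CC visit to keep
the three-state bookkeeping closed.

From the labeled episodes: transition counts, mean first passage times,
the reversible transition rate k_TS = N_TS/t_tot, the collision-complex
rates k_cap = 1/MFPT(U->CC), k_esc = N_esc/T_CC, k_evo = N_evo/T_CC, and
on/off rates from macro-state residence times.  Uncertainties are
first-half/second-half differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

U, CC, B = 0, 1, 2
STATE_NAMES = ("U", "CC", "B")


def smooth_series(series, window_ps: float, frame_spacing_ps: float) -> np.ndarray:
    """Centered running average over ceil(window/spacing) frames.

    The window shrinks at the series edges; ``window_ps = 0`` is the
    identity.  Smoothing contact-count series before state assignment
    suppresses fictitious transitions from rapid small fluctuations.
    """
    series = np.asarray(series, dtype=float)
    if window_ps < 0:
        raise ValueError("window must be non-negative")
    w = math.ceil(window_ps / frame_spacing_ps) if window_ps > 0 else 0
    if w <= 1:
        return series.copy()
    left = (w - 1) // 2
    right = w - 1 - left
    n = len(series)
    cs = np.concatenate([[0.0], np.cumsum(series)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n - 1, idx + right)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


@dataclass(frozen=True)
class StateThresholds:
    """Bound-state threshold on the native intermolecular contact count and
    the smoothing window.  Published thresholds for the three complexes:
    p53-TAD1/TAZ2 11; HIF-1a/TAZ1 26 (no charge) / 23 (charged) / 24
    (charged + 0.05 M salt); NCBD/ACTR 30."""

    n_inter_min: int
    smoothing_window_ps: float = 15.0

    def __post_init__(self):
        if self.n_inter_min < 1:
            raise ValueError("bound threshold must be >= 1")
        if self.smoothing_window_ps < 0:
            raise ValueError("smoothing window must be >= 0")


@dataclass
class Episode:
    state: int
    start: int          # frame index of first frame (boundary index for
                        # zero-length virtual CC visits)
    n_frames: int

    @property
    def end(self) -> int:
        return self.start + self.n_frames


@dataclass
class StateTrajectory:
    labels: np.ndarray              # (F,) int, in {U, CC, B}
    frame_spacing_ps: float
    smoothing_window_ps: float = 0.0
    episodes: list[Episode] = field(init=False)

    def __post_init__(self):
        self.episodes = _episodes_with_virtual_cc(self.labels)

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def total_time_ps(self) -> float:
        return self.n_frames * self.frame_spacing_ps

    def state_fraction(self, state: int) -> float:
        return float(np.mean(self.labels == state))


def assign_states(n_inter_series, n_nonspec_series,
                  thresholds: StateThresholds,
                  frame_spacing_ps: float = 1.0,
                  presmoothed: bool = True) -> StateTrajectory:
    """Label frames U/CC/B from (smoothed) specific and nonspecific
    intermolecular contact-count series.

    With ``presmoothed=False`` the running average of
    ``thresholds.smoothing_window_ps`` is applied here first.
    """
    n_inter = np.asarray(n_inter_series, dtype=float)
    n_nonspec = np.asarray(n_nonspec_series, dtype=float)
    if n_inter.shape != n_nonspec.shape:
        raise ValueError("contact-count series must have equal length")
    if not presmoothed:
        n_inter = smooth_series(n_inter, thresholds.smoothing_window_ps,
                                frame_spacing_ps)
        n_nonspec = smooth_series(n_nonspec, thresholds.smoothing_window_ps,
                                  frame_spacing_ps)
    labels = np.full(len(n_inter), -1, dtype=np.int64)
    labels[(n_inter < 0.5) & (n_nonspec < 0.5)] = U
    labels[(n_inter < 0.5) & (n_nonspec >= 0.5)] = CC
    labels[n_inter >= thresholds.n_inter_min] = B
    # frames with 0.5 <= N_inter < threshold inherit the previous
    # unambiguous label (CC at trajectory start)
    amb = labels < 0
    if amb.any():
        filled = labels.copy()
        last = CC
        for k in range(len(filled)):
            if filled[k] < 0:
                filled[k] = last
            else:
                last = filled[k]
        labels = filled
    return StateTrajectory(labels, frame_spacing_ps,
                           thresholds.smoothing_window_ps)


def _episodes_with_virtual_cc(labels: np.ndarray) -> list[Episode]:
    """Run-length episodes; direct U<->B changes get a zero-length CC."""
    episodes: list[Episode] = []
    if len(labels) == 0:
        return episodes
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            episodes.append(Episode(int(labels[start]), start, k - start))
            if k < len(labels) and {labels[start], labels[k]} == {U, B}:
                episodes.append(Episode(CC, k, 0))
            start = k
    return episodes


@dataclass
class RateSummary:
    """Transition counts, MFPTs and effective rates of the U/CC/B chain.

    ``mfpt_first_passage[x][y]`` is the mean elapsed time (ns) from entering
    state x to first arrival in y.  ``mfpt_conditional[(x, y)]`` is the mean
    residence time of an x episode given that it exits directly to y (this
    is the convention under which MFPTs depend on both endpoints).  Rates:
    k_TS in 1/us; k_cap, k_esc, k_evo, k_on, k_off in 1/ns.
    """

    t_tot_ns: float
    counts: dict
    mfpt_first_passage: np.ndarray          # (3, 3) ns, NaN when unreached
    mfpt_conditional: dict
    k_ts: float
    k_cap: float
    k_esc: float
    k_evo: float
    k_on: float
    k_off: float
    evolution_fraction: float
    state_fractions: dict
    uncertainties: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "t_tot_ns": self.t_tot_ns,
            "counts": dict(self.counts),
            "mfpt_first_passage_ns": {
                f"{STATE_NAMES[x]}->{STATE_NAMES[y]}":
                    self.mfpt_first_passage[x, y]
                for x in range(3) for y in range(3) if x != y
            },
            "mfpt_conditional_ns": {
                f"{STATE_NAMES[x]}->{STATE_NAMES[y]}": v
                for (x, y), v in self.mfpt_conditional.items()
            },
            "k_TS_per_us": self.k_ts,
            "k_cap_per_ns": self.k_cap,
            "k_esc_per_ns": self.k_esc,
            "k_evo_per_ns": self.k_evo,
            "k_on_per_ns": self.k_on,
            "k_off_per_ns": self.k_off,
            "evolution_fraction": self.evolution_fraction,
            "state_fractions": dict(self.state_fractions),
            "uncertainties": dict(self.uncertainties),
            "flags": list(self.flags),
        }


def capture_rate_from_mfpt(mfpt_u_to_cc_ns: float) -> float:
    """k_cap (1/ns) from the mean encounter time: k_cap = 1/MFPT(U->CC)."""
    if mfpt_u_to_cc_ns <= 0:
        raise ValueError("MFPT must be positive")
    return 1.0 / mfpt_u_to_cc_ns


def branching_fraction(k_evo: float, k_esc: float) -> float:
    """Probability that a collision complex evolves to the bound state
    rather than escaping: k_evo / (k_evo + k_esc)."""
    if k_evo < 0 or k_esc < 0 or k_evo + k_esc == 0:
        raise ValueError("rates must be non-negative and not both zero")
    return k_evo / (k_evo + k_esc)


def _core_stats(episodes: list[Episode], n_frames: int, spacing_ps: float):
    """Counts, residence times and MFPTs from an episode list."""
    dt = spacing_ps
    counts = {"N_cap": 0, "N_esc": 0, "N_evo": 0, "N_TS": 0,
              "N_B_to_CC": 0}
    res_time = {U: 0.0, CC: 0.0, B: 0.0}
    cond: dict[tuple[int, int], list[float]] = {}
    for e, nxt in zip(episodes, episodes[1:] + [None]):
        res_time[e.state] += e.n_frames * dt
        if nxt is None:
            continue
        key = (e.state, nxt.state)
        cond.setdefault(key, []).append(e.n_frames * dt)
        if key == (U, CC):
            counts["N_cap"] += 1
        elif key == (CC, U):
            counts["N_esc"] += 1
        elif key == (CC, B):
            counts["N_evo"] += 1
        elif key == (B, CC):
            counts["N_B_to_CC"] += 1

    # macro U/B alternations (reversible binding-and-folding transitions)
    macro = [e.state for e in episodes if e.state in (U, B)]
    for a, b in zip(macro, macro[1:]):
        if a != b:
            counts["N_TS"] += 1

    # first-passage times: start of each x episode to first later y episode
    n_ep = len(episodes)
    nxt_idx = {s: np.full(n_ep + 1, -1, dtype=np.int64) for s in (U, CC, B)}
    for s in (U, CC, B):
        nx = -1
        for k in range(n_ep - 1, -1, -1):
            nxt_idx[s][k] = nx
            if episodes[k].state == s:
                nx = k
    fp_sums = np.zeros((3, 3))
    fp_counts = np.zeros((3, 3), dtype=np.int64)
    starts = np.array([e.start for e in episodes], dtype=float) * dt
    for k, e in enumerate(episodes):
        for y in (U, CC, B):
            if y == e.state:
                continue
            j = nxt_idx[y][k]
            if j >= 0:
                fp_sums[e.state, y] += starts[j] - starts[k]
                fp_counts[e.state, y] += 1
    with np.errstate(invalid="ignore"):
        mfpt_fp = np.where(fp_counts > 0, fp_sums / np.maximum(fp_counts, 1), np.nan)
    np.fill_diagonal(mfpt_fp, np.nan)

    mfpt_cond = {k: float(np.mean(v)) for k, v in cond.items()}

    # macro residence: arrival at B until next arrival at U and vice versa
    macro_bound, macro_unbound = [], []
    arrival = None
    for e in episodes:
        if e.state not in (U, B):
            continue
        if arrival is None or e.state != arrival[0]:
            if arrival is not None:
                dur = e.start * dt - arrival[1]
                (macro_bound if arrival[0] == B else macro_unbound).append(dur)
            arrival = (e.state, e.start * dt)
    return counts, res_time, mfpt_fp, mfpt_cond, macro_bound, macro_unbound


def transition_stats(states: StateTrajectory,
                     t_tot_ps: float | None = None,
                     half_split: bool = True) -> RateSummary:
    """Rate summary of a labeled trajectory.

    A rate whose transition count is zero is reported as 0 and flagged
    rather than raised.  Half-split uncertainties compare the first and
    second halves of the frames.
    """
    if len(states.episodes) < 1:
        raise ValueError("trajectory has no episodes")
    dt = states.frame_spacing_ps
    if t_tot_ps is None:
        t_tot_ps = states.total_time_ps

    def build(episodes, n_frames, tot_ps):
        counts, res, mfpt_fp, mfpt_cond, mb, mu = _core_stats(
            episodes, n_frames, dt)
        flags = []
        t_cc_ns = res[CC] / 1000.0
        tot_ns = tot_ps / 1000.0
        k_ts = counts["N_TS"] / (tot_ps / 1e6)            # 1/us
        fp_ucc = mfpt_fp[U, CC] / 1000.0                  # ns
        if np.isfinite(fp_ucc) and fp_ucc > 0:
            k_cap = 1.0 / fp_ucc
        else:
            k_cap = 0.0
            flags.append("k_cap: no U->CC passage observed")
        if t_cc_ns > 0:
            k_esc = counts["N_esc"] / t_cc_ns
            k_evo = counts["N_evo"] / t_cc_ns
        else:
            k_esc = k_evo = 0.0
            flags.append("k_esc/k_evo: no CC residence time observed")
        if counts["N_esc"] == 0:
            flags.append("k_esc: zero escape count")
        if counts["N_evo"] == 0:
            flags.append("k_evo: zero evolution count")
        k_on = 1.0 / (np.mean(mu) / 1000.0) if mu else 0.0
        k_off = 1.0 / (np.mean(mb) / 1000.0) if mb else 0.0
        if not mu:
            flags.append("k_on: no completed unbound residence")
        if not mb:
            flags.append("k_off: no completed bound residence")
        n_branch = counts["N_esc"] + counts["N_evo"]
        evo_frac = counts["N_evo"] / n_branch if n_branch else float("nan")
        return RateSummary(
            t_tot_ns=tot_ns, counts=counts,
            mfpt_first_passage=mfpt_fp / 1000.0,
            mfpt_conditional={k: v / 1000.0 for k, v in mfpt_cond.items()},
            k_ts=k_ts, k_cap=k_cap, k_esc=k_esc, k_evo=k_evo,
            k_on=k_on, k_off=k_off, evolution_fraction=evo_frac,
            state_fractions={
                STATE_NAMES[s]: res[s] / tot_ps for s in (U, CC, B)
            },
            flags=flags,
        )

    summary = build(states.episodes, states.n_frames, t_tot_ps)
    if half_split and states.n_frames >= 4:
        h = states.n_frames // 2
        halves = []
        for lab in (states.labels[:h], states.labels[h:]):
            eps = _episodes_with_virtual_cc(lab)
            halves.append(build(eps, len(lab), len(lab) * dt))
        summary.uncertainties = {
            name: abs(getattr(halves[0], attr) - getattr(halves[1], attr))
            for name, attr in [
                ("k_TS_per_us", "k_ts"), ("k_cap_per_ns", "k_cap"),
                ("k_esc_per_ns", "k_esc"), ("k_evo_per_ns", "k_evo"),
            ]
        }
    return summary


def evolution_fraction(states: StateTrajectory) -> float:
    """Fraction of completed collision-complex episodes that evolve to the
    bound state rather than escaping: N_evo / (N_evo + N_esc).

    CC episodes truncated by the end of the trajectory are excluded.
    """
    n_esc = n_evo = 0
    eps = states.episodes
    for e, nxt in zip(eps, eps[1:]):
        if e.state != CC:
            continue
        if nxt.state == U:
            n_esc += 1
        elif nxt.state == B:
            n_evo += 1
    if n_esc + n_evo == 0:
        raise ValueError("no completed collision-complex episode")
    return n_evo / (n_esc + n_evo)
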