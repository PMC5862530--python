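"""Colony-scale dynamics: state series, negative-feedback flow fits,
foraging cycles, and perturbation response.

The colony state ``F(t)`` is the total food delivered by foragers divided by
the colony's intake target — the post-hoc saturation level of accumulated
food — so it runs from 0 (starved) toward 1 (satiated).  It decomposes
exactly into per-forager contributions ``F(t) = Σ_i f_i(t)``.  The central
macroscopic law is the negative feedback ``df_i/dt ≈ m·(1 − F)``: each
forager's inflow is proportional to the space left to fill, regardless of
when she started foraging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ColonyExperiment

__all__ = [
    "ColonyStateSeries",
    "FlowFit",
    "estimate_intake_target",
    "compute_colony_state",
    "smooth_and_differentiate",
    "fit_individual_flow",
    "fit_all_flows",
    "predict_colony_trajectory",
    "extract_foraging_cycles",
    "fit_frequency_vs_vacancy",
    "perturbation_response",
]


@dataclass
class ColonyStateSeries:
    """F(t) with its per-forager decomposition on the uniform time grid."""

    t: np.ndarray
    F: np.ndarray
    f: pd.DataFrame          # one column per forager, F(t) = row-sum
    intake_target: float
    target_flagged: bool = False  # accumulation still rising at record end

    def interp_F(self, times, smooth_window: float | None = 2000.0) -> np.ndarray:
        """Colony state at arbitrary times (linear interpolation, optionally
        of the smoothed series)."""
        y = self.F
        if smooth_window:
            y = _moving_average(self.t, y, smooth_window)
        return np.interp(np.asarray(times, dtype=float), self.t, y)


@dataclass
class FlowFit:
    m_i: dict
    r2_i: dict
    m: float = field(init=False)

    def __post_init__(self):
        self.m = float(np.mean(list(self.m_i.values()))) if self.m_i else np.nan


def _moving_average(t, y, window):
    dt = t[1] - t[0]
    k = max(int(round(window / dt)), 1)
    if k % 2 == 0:
        k += 1
    return (
        pd.Series(y).rolling(k, center=True, min_periods=1).mean().to_numpy()
    )


def estimate_intake_target(
    t: np.ndarray,
    accumulation: np.ndarray,
    final_fraction: float = 0.1,
    smooth_window: float = 2000.0,
    rise_tolerance: float = 0.02,
    rise_window: float = 3600.0,
) -> tuple[float, bool]:
    """Post-hoc intake target: plateau level of total accumulated food.

    The target is the mean of the smoothed accumulation over the final
    ``final_fraction`` of the record.  If accumulation still rose by more
    than ``rise_tolerance`` (relative) over the last ``rise_window`` seconds
    the plateau is suspect and a flag is raised — mirroring the saturation
    criterion used to time the perturbation experiments (no rise for 1 hr).
    """
    s = _moving_average(t, accumulation, smooth_window)
    n_tail = max(int(len(t) * final_fraction), 1)
    target = float(np.mean(s[-n_tail:]))
    if target <= 0:
        raise ValueError("no accumulated food; intake target undefined")
    k = min(int(round(rise_window / (t[1] - t[0]))), len(t) - 1)
    rise = (s[-1] - s[-1 - k]) / target
    return target, bool(rise > rise_tolerance)


def compute_colony_state(
    experiment: ColonyExperiment,
    intake_target: float | None = None,
) -> ColonyStateSeries:
    """Cumulative signed forager-to-colony volumes, normalized to the target.

    Each forager's contribution ``f_i(t)`` is the running sum of her signed
    interaction volumes (positive out of the forager); ``F`` is their sum
    over the intake target.  When no target is supplied it is estimated
    post hoc from the accumulation plateau.
    """
    t = experiment.t_grid
    foragers = experiment.foragers
    forager_set = set(foragers)
    ia = experiment.interactions
    f_cols = {}
    for fid in foragers:
        # forager <-> non-forager events only; the stored volume is already
        # signed by the convention (positive = net flow out of the forager)
        partner = np.where(ia["donor_id"] == fid, ia["recipient_id"],
                           ia["donor_id"])
        involved = ((ia["donor_id"] == fid) | (ia["recipient_id"] == fid)) \
            & ~pd.Series(partner).isin(forager_set).to_numpy()
        mine = ia[involved]
        cum = np.zeros_like(t, dtype=float)
        if len(mine):
            idx = np.searchsorted(t, mine["t_end"].to_numpy(), side="left")
            np.add.at(cum, np.clip(idx, 0, len(t) - 1),
                      mine["volume"].to_numpy())
            cum = np.cumsum(cum)
        f_cols[fid] = cum
    f = pd.DataFrame(f_cols, index=t)
    total = f.sum(axis=1).to_numpy() if len(f_cols) else np.zeros_like(t)
    if not len(ia) or not foragers:
        warnings.warn("no forager interactions; colony state is empty (F=0)")
        target = intake_target if intake_target else 1.0
        return ColonyStateSeries(t, np.zeros_like(t, dtype=float), f, target)
    flagged = False
    if intake_target is None:
        intake_target, flagged = estimate_intake_target(t, total)
    if intake_target <= 0:
        raise ValueError("intake_target must be positive")
    F = total / intake_target
    return ColonyStateSeries(t, F, f / intake_target, float(intake_target),
                             flagged)


def smooth_and_differentiate(
    t: np.ndarray,
    y: np.ndarray,
    smooth_window: float = 2000.0,
    diff_window: float = 300.0,
) -> np.ndarray:
    """Moving-average smoothing followed by windowed finite differencing.

    The accumulation is first smoothed with a centered moving average wide
    enough to span several trophallactic events, then the flow is the
    symmetric difference quotient over ``diff_window``.  The integral of the
    returned flow reproduces the net accumulation (up to boundary effects),
    which is the criterion used to pick the window sizes.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    dt = t[1] - t[0]
    if smooth_window > t[-1] - t[0] or diff_window > t[-1] - t[0]:
        raise ValueError("window longer than the series")
    s = _moving_average(t, y, smooth_window)
    h = max(int(round(diff_window / (2 * dt))), 1)
    flow = np.empty_like(s)
    flow[h:-h] = (s[2 * h:] - s[:-2 * h]) / (2 * h * dt)
    # one-sided at the boundaries
    flow[:h] = (s[h:2 * h] - s[:h]) / (h * dt)
    flow[-h:] = (s[-h:] - s[-2 * h:-h]) / (h * dt)
    return flow


def fit_individual_flow(flow, F, mask=None) -> tuple[float, float]:
    """Through-origin least squares of a forager's flow against vacancy.

    Fits ``flow = m·(1 − F)`` over the (optionally masked) record and
    returns ``(m, R²)`` with the ``R² = 1 − SS_res/SS_tot`` convention.
    """
    flow = np.asarray(flow, float)
    u = 1.0 - np.asarray(F, float)
    if mask is not None:
        flow, u = flow[mask], u[mask]
    if len(u) == 0 or np.allclose(u.var(), 0.0):
        raise ValueError("vacancy (1-F) has zero variance; fit degenerate")
    m = float(np.sum(flow * u) / np.sum(u * u))
    ss_res = float(np.sum((flow - m * u) ** 2))
    ss_tot = float(np.sum((flow - flow.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return m, r2


def fit_all_flows(
    state: ColonyStateSeries,
    onset_times: dict,
    smooth_window: float = 2000.0,
    diff_window: float = 300.0,
) -> FlowFit:
    """Per-forager feedback slopes m_i from her onset to the end of record."""
    m_i, r2_i = {}, {}
    F_s = _moving_average(state.t, state.F, smooth_window)
    for fid in state.f.columns:
        flow = smooth_and_differentiate(
            state.t, state.f[fid].to_numpy(), smooth_window, diff_window)
        mask = state.t >= onset_times.get(fid, state.t[0])
        m_i[fid], r2_i[fid] = fit_individual_flow(flow, F_s, mask)
    return FlowFit(m_i, r2_i)


def predict_colony_trajectory(m, onsets, t_grid, F0: float = 0.0) -> np.ndarray:
    """Integrate ``dF/dt = n(t)·m·(1 − F)`` with ``n(t) = #{onsets ≤ t}``.

    Between consecutive onsets the coefficient is constant, so the ODE is
    integrated exactly piecewise: ``F = 1 − (1 − F_k)·exp(−n·m·(t − t_k))``.
    """
    if not np.isfinite(m) or m < 0:
        raise ValueError("m must be a finite non-negative rate")
    t_grid = np.asarray(t_grid, dtype=float)
    onsets = np.sort(np.asarray(onsets, dtype=float))
    F = np.empty_like(t_grid)
    F_k, t_k = float(F0), t_grid[0]
    for i, t in enumerate(t_grid):
        n = np.searchsorted(onsets, t, side="right")
        # advance through any onsets crossed since the previous grid point
        crossed = onsets[(onsets > t_k) & (onsets <= t)]
        for oc in crossed:
            n_before = np.searchsorted(onsets, oc, side="left")
            F_k = 1.0 - (1.0 - F_k) * np.exp(-n_before * m * (oc - t_k))
            t_k = oc
        F[i] = 1.0 - (1.0 - F_k) * np.exp(-n * m * (t - t_k))
        F_k, t_k = F[i], t
    return F


def extract_foraging_cycles(
    experiment: ColonyExperiment,
    state: ColonyStateSeries | None = None,
) -> pd.DataFrame:
    """One row per pair of consecutive feedings of a forager.

    The cycle interval is the time between consecutive feeding starts; the
    indoor/outdoor split comes from the ``in_nest`` timeline flags; the crop
    at exit (per-forager-normalized) is read at the first grid point where
    ``in_nest`` flips false after the nest visit began; interactions in the
    visit are counted from the event log.
    """
    if state is None:
        state = compute_colony_state(experiment)
    rows = []
    ia = experiment.interactions
    for fid, g in experiment.feedings.groupby("forager_id"):
        if experiment.roles.get(fid) != "forager":
            continue
        g = g.sort_values("t_start").reset_index(drop=True)
        if len(g) < 2:
            warnings.warn(f"forager {fid}: fewer than 2 feedings, no cycles")
            continue
        tl = experiment.timeline_of(fid)
        crop_max = tl["crop"].max()
        t_tl = tl["t"].to_numpy()
        in_nest = tl["in_nest"].to_numpy()
        crop = tl["crop"].to_numpy() / (crop_max if crop_max > 0 else 1.0)
        for k in range(len(g) - 1):
            t0, t1 = g.loc[k, "t_start"], g.loc[k + 1, "t_start"]
            interval = t1 - t0
            win = (t_tl >= t0) & (t_tl < t1)
            indoor = float(in_nest[win].sum()) * experiment.dt
            outdoor = interval - indoor
            # exit instant: first in-nest -> out flip after the visit began
            vis = np.where(win & in_nest)[0]
            if len(vis):
                after = vis[-1] + 1
                t_exit = t_tl[after] if after < len(t_tl) else t_tl[-1]
                crop_at_exit = crop[min(after, len(crop) - 1)]
            else:
                t_exit, crop_at_exit = t1, np.nan
            n_int = int(((ia["donor_id"] == fid) | (ia["recipient_id"] == fid))
                        [(ia["t_start"] >= t0) & (ia["t_start"] < t1)].sum())
            rows.append({
                "forager_id": fid,
                "t_feed_start": float(t0),
                "cycle_interval": float(interval),
                "indoor_duration": indoor,
                "outdoor_duration": float(outdoor),
                "colony_state_at_cycle": float(state.interp_F([t0])[0]),
                "crop_at_exit": float(crop_at_exit),
                "t_exit": float(t_exit),
                "n_interactions_in_visit": n_int,
            })
    return pd.DataFrame(rows)


def _equal_state_bins(values, n_bins):
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(values, edges) - 1, 0, n_bins - 1)
    return edges, idx


def fit_frequency_vs_vacancy(cycles: pd.DataFrame, n_bins: int = 5) -> dict:
    """Linear fit of binned foraging frequency against colony vacancy.

    Cycle frequencies (1/interval) are grouped into equally spaced colony
    state bins; bin means are fit linearly against ``1 − F``.  Spearman rank
    correlations of the indoor and outdoor phase durations against colony
    state are reported alongside, since the indoor phase carries the trend.
    """
    if len(cycles) < 2:
        raise ValueError("need at least two cycles")
    F = cycles["colony_state_at_cycle"].to_numpy()
    freq = 1.0 / cycles["cycle_interval"].to_numpy()
    edges, idx = _equal_state_bins(F, n_bins)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            warnings.warn(f"empty colony-state bin {b}; collapsed")
            continue
        rows.append({
            "bin": b,
            "F_mean": float(F[sel].mean()),
            "vacancy": float(1.0 - F[sel].mean()),
            "freq_mean": float(freq[sel].mean()),
            "freq_sem": float(freq[sel].std(ddof=1) / np.sqrt(sel.sum()))
            if sel.sum() > 1 else np.nan,
            "n": int(sel.sum()),
        })
    binned = pd.DataFrame(rows)
    if len(binned) < 2:
        raise ValueError("need >= 2 non-empty colony-state bins")
    slope, intercept, r, _, _ = stats.linregress(
        binned["vacancy"], binned["freq_mean"])
    rs_in = stats.spearmanr(F, cycles["indoor_duration"])
    rs_out = stats.spearmanr(F, cycles["outdoor_duration"])
    return {
        "binned": binned,
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(r ** 2),
        "spearman_indoor": (float(rs_in.statistic), float(rs_in.pvalue)),
        "spearman_outdoor": (float(rs_out.statistic), float(rs_out.pvalue)),
    }


def perturbation_response(
    cycles: pd.DataFrame,
    perturbation_time: float,
    n_bins: int = 8,
    duration_col: str = "indoor_duration",
) -> dict:
    """Time-binned in-nest durations around a perturbation.

    Returns the binned mean ± SEM profile and the contrast statistic
    (last pre-perturbation bin mean minus first post-perturbation bin mean);
    a positive contrast means durations dropped when hungry ants arrived.
    """
    t = cycles["t_feed_start"].to_numpy()
    if perturbation_time >= t.max() or perturbation_time <= t.min():
        raise ValueError("perturbation time outside the cycle record")
    y = cycles[duration_col].to_numpy()
    # the perturbation instant is a bin edge, so no bin mixes pre and post
    n_pre = max(int(round(n_bins * (perturbation_time - t.min())
                          / (t.max() - t.min()))), 1)
    n_post = max(n_bins - n_pre, 1)
    edges = np.concatenate([
        np.linspace(t.min(), perturbation_time, n_pre + 1)[:-1],
        np.linspace(perturbation_time, t.max() + 1e-9, n_post + 1),
    ])
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({
            "bin": b,
            "t_mid": float(edges[b:b + 2].mean()),
            "mean": float(y[sel].mean()),
            "sem": float(y[sel].std(ddof=1) / np.sqrt(sel.sum()))
            if sel.sum() > 1 else np.nan,
            "n": int(sel.sum()),
        })
    binned = pd.DataFrame(rows)
    pre = binned[binned["t_mid"] < perturbation_time]
    post = binned[binned["t_mid"] >= perturbation_time]
    if not len(post):
        raise ValueError("no post-perturbation data")
    contrast = float(pre["mean"].iloc[-1] - post["mean"].iloc[0]) if len(pre) else np.nan
    return {"binned": binned, "contrast": contrast}
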