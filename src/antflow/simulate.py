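"""Agent-based synthetic colony: foragers shuttle food from a source to a
colony of partially fillable crops.

The simulator realizes the microscopic rules measured on real colonies:

* **Volume rule** — a trophallactic transfer from a forager to a recipient
  with crop load ``c`` and personal target ``c_target`` is an exponentially
  distributed random fraction of the recipient's remaining crop space,
  ``v = ṽ·(c_target − c)`` with ``ṽ ~ Exp(mean 1/λ0)``, truncated at the
  physical limits (donor load, available space).

* **Interaction rule** — while in the nest a forager attempts one
  interaction per time step with probability ``r(F)·dt``,
  ``r(F) = r0 − r1·F``; partners are drawn uniformly from the non-foragers,
  which realizes the observed "representative sample" of recipients.

* **Exit rule** — each time a forager has unloaded a further ``Δcrop``
  fraction of her capacity she makes a Bernoulli exit decision with
  probability ``G(crop) = logistic(a + b·crop)`` (optionally
  ``+ g·colony`` for the colony-dependent negative control); an empty crop
  forces an exit.  Outdoor trips have constant duration and refill the crop
  to capacity.

The emitted event logs and timelines use the canonical schemas of
:mod:`antflow.data`, so the analysis stages run unchanged on synthetic and
imported data.  A ground-truth record (drawn fractions ṽ, censoring flags,
the latent decision log, the true colony-state series) rides along for
estimator validation.

The mean-field helpers (:func:`mean_field_flow`, :func:`analytic_m`) give a
closed-form/deterministic-ODE account of the same rules and serve as
independent oracles for the macroscopic fits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ColonyExperiment

__all__ = [
    "SimulationConfig",
    "SyntheticExperiment",
    "draw_interaction_volume",
    "simulate_colony",
    "apply_perturbation",
    "mean_field_flow",
    "mean_field_trajectory",
    "analytic_m",
]


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic colony.

    Defaults are the study conditions of the observation experiments: a
    colony of ~60 ants with a handful of foragers, volume-rule constants
    ``lambda0 = 7.01`` and mean recipient target ``C0 = 1.14`` (crop loads in
    90th-percentile-normalized units), a near-constant in-nest interaction
    rate ``r(F) = 0.032 − 0.0·F`` per second (the measured rate decline is
    available via ``r1`` but off by default since interaction volumes, not
    rates, dominate the feedback), decision increments of 10% of the forager's
    capacity, and the crop-only exit logistic measured under the
    unloading-rate decision model.
    """

    n_ants: int = 62
    n_foragers: int = 4
    duration: float = 14400.0
    dt: float = 2.0
    crop_target_mean: float = 1.14     # C0, mean recipient target
    crop_target_sd_frac: float = 0.05  # targets ~ Normal(C0, frac*C0), >0
    lambda0: float = 7.01
    r0: float = 0.032                  # interactions / s in nest
    r1: float = 0.0                    # rate decline with colony state
    outdoor_duration: float = 200.0
    delta_crop: float = 0.10           # decision increment, fraction of capacity
    exit_intercept: float = -0.093
    exit_crop_coef: float = -3.092
    exit_colony_coef: float = 0.0      # negative control when non-zero
    forager_capacity: float = 1.0
    forager_onsets: list | None = None  # first nest-return times; default staggered
    perturbation: tuple | None = None   # (time, n_added_hungry)
    seed: int = 0

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if not (0 < self.delta_crop <= 1):
            raise ValueError("delta_crop must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_ants - self.n_foragers <= 0 and self.n_foragers > 0:
            raise ValueError("colony must contain at least one non-forager")
        if self.perturbation is not None:
            t_p, n_p = self.perturbation
            if not (0 < t_p < self.duration):
                raise ValueError("perturbation time outside the run")
            if n_p < 0:
                raise ValueError("n_added_hungry must be >= 0")

    def onsets(self) -> np.ndarray:
        """First nest-return time per forager.

        Defaults to uniform staggering over the first 10% of the run, which
        reproduces the initial rise of the collective inflow as foragers
        gradually join.
        """
        if self.forager_onsets is not None:
            o = np.asarray(self.forager_onsets, dtype=float)
            if len(o) != self.n_foragers:
                raise ValueError("one onset per forager required")
            if ((o < 0) | (o > self.duration)).any():
                raise ValueError("onsets must lie within [0, duration]")
            return o
        if self.n_foragers == 0:
            return np.empty(0)
        span = 0.1 * self.duration
        return self.outdoor_duration + span * np.arange(self.n_foragers) / max(
            self.n_foragers - 1, 1
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "perturbation" in raw and raw["perturbation"] is not None:
            raw["perturbation"] = tuple(raw["perturbation"])
        return cls(**raw)


@dataclass
class SyntheticExperiment:
    """A simulated :class:`~antflow.data.ColonyExperiment` plus ground truth."""

    experiment: ColonyExperiment
    config: SimulationConfig
    vtilde: np.ndarray          # drawn fraction per interaction row
    censored: np.ndarray        # True where truncation bound, not ṽ, set v
    decision_log: pd.DataFrame  # t, forager_id, crop, colony, exit, forced
    colony_state_true: pd.DataFrame  # t, F (recipient-pool satiety)
    targets: dict               # ant_id -> crop target

    def ground_truth_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "targets": {str(k): float(v) for k, v in self.targets.items()},
            "vtilde": [float(x) for x in self.vtilde],
            "censored": [bool(x) for x in self.censored],
            "decision_log": self.decision_log.to_dict(orient="list"),
        }

    def write_ground_truth(self, path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth_dict()))


def draw_interaction_volume(donor_load, recipient_load, recipient_target,
                            lambda0, rng):
    """One application of the volume rule.

    Returns ``(v, vtilde, censored)`` where ``v = ṽ·(recipient_target −
    recipient_load)`` with ``ṽ ~ Exp(mean 1/λ0)``, truncated so the transfer
    never exceeds the donor's load nor the recipient's available space;
    ``censored`` marks draws where a physical bound, not ṽ, set the volume.
    """
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    space = max(recipient_target - recipient_load, 0.0)
    vtilde = rng.exponential(1.0 / lambda0)
    v = vtilde * space
    censored = False
    if v > space:  # vtilde > 1
        v, censored = space, True
    if v > donor_load:
        v, censored = donor_load, True
    return v, vtilde, censored


class _SimState:
    """Mutable world state while a simulation is running."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        nf = config.n_foragers
        nr = config.n_ants - nf
        self.forager_ids = [f"f{i:02d}" for i in range(nf)]
        self.recipient_ids = [f"a{i:03d}" for i in range(nr)]
        self.targets = {
            a: self._draw_target() for a in self.recipient_ids
        }
        self.crop = {a: 0.0 for a in self.recipient_ids}
        for f in self.forager_ids:
            self.crop[f] = 0.0
        self.join_time = {a: 0.0 for a in list(self.crop)}

    def _draw_target(self) -> float:
        c0 = self.config.crop_target_mean
        sd = self.config.crop_target_sd_frac * c0
        if sd == 0:
            return c0
        t = self.rng.normal(c0, sd)
        while t <= 0:
            t = self.rng.normal(c0, sd)
        return float(t)

    def colony_state(self) -> float:
        """Recipient-pool satiety: total stored food over total target."""
        tot = sum(self.crop[a] for a in self.recipient_ids)
        cap = sum(self.targets[a] for a in self.recipient_ids)
        return tot / cap if cap > 0 else 0.0

    def add_hungry(self, n: int, t: float) -> None:
        start = len(self.recipient_ids)
        for i in range(start, start + n):
            aid = f"a{i:03d}"
            self.recipient_ids.append(aid)
            self.targets[aid] = self._draw_target()
            self.crop[aid] = 0.0
            self.join_time[aid] = t


def apply_perturbation(state: _SimState, n_added_hungry: int, t: float) -> _SimState:
    """Introduce hungry ants mid-run.

    The newcomers join the recipient pool with empty crops and the
    colony-state normalizer is recomputed over the enlarged colony (the
    denominator of :meth:`_SimState.colony_state` includes their targets from
    this moment on), so the perceived satiety drops discontinuously by the
    added vacancy fraction.
    """
    if n_added_hungry > 0:
        state.add_hungry(n_added_hungry, t)
    return state


def simulate_colony(config: SimulationConfig) -> SyntheticExperiment:
    """Run the agent-based colony and emit canonical event logs.

    Foragers cycle between constant-duration outdoor feeding trips (crop
    refills linearly to capacity) and in-nest unloading via the volume rule;
    exit decisions fire at every cumulative ``delta_crop`` unloaded.  All
    interactions are recorded with one-``dt`` duration and the crop loads of
    both participants immediately before the transfer; mass moves from donor
    to recipient exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    state = _SimState(cfg, rng)
    n_steps = int(round(cfg.duration / cfg.dt))
    t_grid = np.arange(n_steps + 1) * cfg.dt
    onsets = cfg.onsets()
    out_steps = max(int(round(cfg.outdoor_duration / cfg.dt)), 1)

    # per-forager phase machines
    phase = {}           # "pre", "out", "in"
    phase_until = {}     # step index at which current outdoor trip ends
    exit_crop = {}       # crop at nest exit (for the outdoor refill ramp)
    accum = {f: 0.0 for f in state.forager_ids}
    pending_exit = {f: False for f in state.forager_ids}
    for f, o in zip(state.forager_ids, onsets):
        phase[f] = "pre"
        phase_until[f] = int(round(max(o - cfg.outdoor_duration, 0.0) / cfg.dt))
        exit_crop[f] = 0.0

    all_ids = state.forager_ids + list(state.recipient_ids)
    max_added = cfg.perturbation[1] if cfg.perturbation else 0
    ncols = len(all_ids) + max_added
    crop_mat = np.zeros((n_steps + 1, ncols))
    troph = np.zeros((n_steps + 1, ncols), dtype=bool)
    at_food = np.zeros((n_steps + 1, ncols), dtype=bool)
    in_nest = np.ones((n_steps + 1, ncols), dtype=bool)
    col_of = {a: i for i, a in enumerate(all_ids)}

    interactions = []
    vtilde_list, censored_list = [], []
    feedings = []
    decisions = []
    F_true = np.zeros(n_steps + 1)
    F_true[0] = state.colony_state()
    perturb_step = None
    if cfg.perturbation is not None:
        perturb_step = int(round(cfg.perturbation[0] / cfg.dt))

    def record_row(k):
        for a in state.crop:
            crop_mat[k, col_of[a]] = state.crop[a]

    record_row(0)

    for k in range(n_steps):
        t = t_grid[k]
        if perturb_step is not None and k == perturb_step:
            before = len(state.recipient_ids)
            apply_perturbation(state, cfg.perturbation[1], t)
            for a in state.recipient_ids[before:]:
                col_of[a] = len(col_of)
        F = state.colony_state()
        rate = max(cfg.r0 - cfg.r1 * F, 0.0)
        p_int = min(rate * cfg.dt, 1.0)

        for f in state.forager_ids:
            ph = phase[f]
            if ph == "pre":
                if k >= phase_until[f]:
                    # begin first outdoor trip
                    phase[f] = "out"
                    exit_crop[f] = state.crop[f]
                    phase_until[f] = k + out_steps
                    feedings.append((f, t, t_grid[k + out_steps]
                                     if k + out_steps <= n_steps else t_grid[-1]))
                continue
            if ph == "out":
                frac = (k + 1 - (phase_until[f] - out_steps)) / out_steps
                state.crop[f] = exit_crop[f] + frac * (
                    cfg.forager_capacity - exit_crop[f])
                at_food[k, col_of[f]] = True
                in_nest[k, col_of[f]] = False
                if k + 1 >= phase_until[f]:
                    phase[f] = "in"
                    state.crop[f] = cfg.forager_capacity
                    accum[f] = 0.0
                    pending_exit[f] = False
                continue
            # in nest
            if pending_exit[f]:
                phase[f] = "out"
                exit_crop[f] = state.crop[f]
                phase_until[f] = k + out_steps
                t_back = t_grid[min(k + out_steps, n_steps)]
                feedings.append((f, t, t_back))
                at_food[k, col_of[f]] = True
                in_nest[k, col_of[f]] = False
                continue
            if state.crop[f] <= 1e-12:
                # empty crop: nothing left to unload, exit is forced
                decisions.append((t, f, 0.0, F, True, True))
                pending_exit[f] = True
                continue
            if rng.random() >= p_int:
                continue
            partner = state.recipient_ids[rng.integers(len(state.recipient_ids))]
            v, vt, cen = draw_interaction_volume(
                state.crop[f], state.crop[partner], state.targets[partner],
                cfg.lambda0, rng)
            if v <= 0:
                continue
            interactions.append((t, t + cfg.dt, f, partner, v,
                                 state.crop[f], state.crop[partner]))
            vtilde_list.append(vt)
            censored_list.append(cen)
            troph[k, col_of[f]] = True
            troph[k, col_of[partner]] = True
            state.crop[f] -= v
            state.crop[partner] += v
            accum[f] += v
            delta = cfg.delta_crop * cfg.forager_capacity
            crop_norm = state.crop[f] / cfg.forager_capacity
            F_now = state.colony_state()
            while accum[f] >= delta:
                accum[f] -= delta
                p_exit = float(_logistic(
                    cfg.exit_intercept
                    + cfg.exit_crop_coef * crop_norm
                    + cfg.exit_colony_coef * F_now))
                go = bool(rng.random() < p_exit)
                decisions.append((t + cfg.dt, f, crop_norm, F_now, go, False))
                if go:
                    pending_exit[f] = True
                    break

        record_row(k + 1)
        F_true[k + 1] = state.colony_state()

    # assemble canonical logs ------------------------------------------------
    ia = pd.DataFrame(
        interactions,
        columns=["t_start", "t_end", "donor_id", "recipient_id", "volume",
                 "donor_crop", "recipient_crop"],
    )
    ia["forager_is_donor"] = True
    ia["experiment_id"] = "sim"
    fe = pd.DataFrame(feedings, columns=["forager_id", "t_start", "t_end"])
    fe["experiment_id"] = "sim"

    frames = []
    for a, j in col_of.items():
        k0 = int(round(state.join_time[a] / cfg.dt))
        frames.append(pd.DataFrame({
            "ant_id": a,
            "t": t_grid[k0:],
            "crop": crop_mat[k0:, j],
            "in_trophallaxis": troph[k0:, j],
            "at_food": at_food[k0:, j],
            "in_nest": in_nest[k0:, j],
            "experiment_id": "sim",
        }))
    tl = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["ant_id", "t", "crop", "in_trophallaxis", "at_food",
                 "in_nest", "experiment_id"])

    roles = {a: "forager" for a in state.forager_ids}
    roles.update({a: "non-forager" for a in state.recipient_ids})
    onset_map = {}
    for f, g in fe.groupby("forager_id"):
        onset_map[f] = float(g["t_end"].min())
    exp = ColonyExperiment(
        interactions=ia, feedings=fe, timelines=tl, roles=roles,
        onset_times=onset_map,
    )
    dec = pd.DataFrame(
        decisions,
        columns=["t", "forager_id", "crop", "colony", "exit", "forced"])
    truth_F = pd.DataFrame({"t": t_grid, "F": F_true})
    return SyntheticExperiment(
        experiment=exp, config=cfg,
        vtilde=np.asarray(vtilde_list), censored=np.asarray(censored_list, bool),
        decision_log=dec, colony_state_true=truth_F,
        targets=dict(state.targets),
    )


# --------------------------------------------------------------------------
# Mean-field oracles
# --------------------------------------------------------------------------

def _expected_unload_per_visit(cfg: SimulationConfig, F: float) -> tuple[float, float]:
    """Expected volume unloaded per nest visit and mean interaction volume.

    Decision ``j`` fires when cumulative unloading first crosses ``j·Δ``; by
    memorylessness of (approximately) exponential interaction volumes the
    overshoot beyond the boundary is itself ~Exp with the mean interaction
    volume μ(F), so the crop at decision ``j`` is ``1 − jΔ − O`` with
    ``O ~ Exp(μ)``.  The exit chance per decision averages the logistic exit
    rule over that overshoot; an overshoot past an empty crop forces exit.
    """
    mu = cfg.crop_target_mean * max(1.0 - F, 0.0) / cfg.lambda0
    delta = cfg.delta_crop * cfg.forager_capacity
    if mu <= 0:
        return 0.0, 0.0
    o = np.linspace(0, 8 * mu, 400)
    w = np.exp(-o / mu) / mu
    e_k, surv = 0.0, 1.0
    j = 1
    while True:
        level = cfg.forager_capacity - j * delta
        if level <= 0:
            e_k += surv  # increment j is the last; crop empties, forced exit
            break
        crop = np.clip(level - o, 0.0, None)
        g = _logistic(cfg.exit_intercept
                      + cfg.exit_crop_coef * crop / cfg.forager_capacity
                      + cfg.exit_colony_coef * F)
        g = np.where(level - o <= 0, 1.0, g)  # empty crop: forced exit
        p_j = float(np.trapezoid(g * w, o) / np.trapezoid(w, o))
        e_k += surv
        surv *= 1.0 - p_j
        if surv < 1e-6:
            break
        j += 1
    return e_k * delta + mu, mu


def mean_field_flow(cfg: SimulationConfig, F) -> np.ndarray:
    """Deterministic per-forager volume inflow (units of crop volume / s).

    Composes the interaction rate, the volume rule and the exit-decision
    chain: unloading in the nest proceeds at ``r(F)·μ(F)`` until an exit
    decision succeeds, then a constant-duration outdoor trip restarts the
    cycle, so the time-averaged flow is (unload per visit)/(cycle time).
    """
    F = np.atleast_1d(np.asarray(F, dtype=float))
    out = np.zeros_like(F)
    for i, f in enumerate(F):
        u, mu = _expected_unload_per_visit(cfg, f)
        rate = max(cfg.r0 - cfg.r1 * f, 0.0)
        if u <= 0 or mu <= 0 or rate <= 0:
            out[i] = 0.0
            continue
        indoor = (u / mu) / rate
        out[i] = u / (cfg.outdoor_duration + indoor)
    return out


def mean_field_trajectory(cfg: SimulationConfig, t_grid=None):
    """Deterministic colony-state trajectory under the mean-field rules.

    Integrates ``dF/dt = n(t)·φ(F)/W`` where ``φ`` is the per-forager flow
    and ``W`` the recipient pool's total target volume; ``n(t)`` counts
    forager onsets.  Euler steps on the simulation grid are ample because
    flows change on thousand-second scales.
    """
    if t_grid is None:
        t_grid = np.arange(int(round(cfg.duration / cfg.dt)) + 1) * cfg.dt
    onsets = np.sort(cfg.onsets())
    W = (cfg.n_ants - cfg.n_foragers) * cfg.crop_target_mean
    # tabulate the flow curve once; it is smooth in F
    F_tab = np.linspace(0.0, 1.0, 201)
    flow_tab = mean_field_flow(cfg, F_tab)
    F = np.zeros_like(t_grid, dtype=float)
    for k in range(len(t_grid) - 1):
        n = np.searchsorted(onsets, t_grid[k], side="right")
        dF = n * np.interp(F[k], F_tab, flow_tab) / W
        F[k + 1] = min(F[k] + dF * (t_grid[k + 1] - t_grid[k]), 1.0)
    return t_grid, F


def analytic_m(cfg: SimulationConfig, per_forager: bool = False):
    """Mean-field prediction of the per-forager feedback slope ``m``.

    The observable ``m_i`` is the through-origin least-squares slope of
    forager *i*'s flow (in colony-state units) against the vacancy ``1 − F``
    from her onset onward; evaluating the same estimator on the
    deterministic mean-field trajectory — same per-forager windows — gives
    an oracle that is independent of any one stochastic realization.
    Returns the pooled mean, or the per-onset slopes with
    ``per_forager=True``.
    """
    t, F = mean_field_trajectory(cfg)
    onsets = np.sort(cfg.onsets())
    W = (cfg.n_ants - cfg.n_foragers) * cfg.crop_target_mean
    F_tab = np.linspace(0.0, 1.0, 201)
    flow_tab = mean_field_flow(cfg, F_tab)
    slopes = []
    for o in (onsets if len(onsets) else [0.0]):
        mask = t >= o
        u = 1.0 - F[mask]
        flow = np.interp(F[mask], F_tab, flow_tab) / W
        slopes.append(float(np.sum(flow * u) / np.sum(u * u)))
    if per_forager:
        return np.asarray(slopes)
    return float(np.mean(slopes))


def mean_field_m_measured(
    cfg: SimulationConfig,
    smooth_window: float = 2000.0,
    diff_window: float = 300.0,
):
    """The feedback slope a measurement would report on the mean-field run.

    Builds the per-forager mean-field accumulations ``f_i(t)`` and pushes
    them through the very estimator used on data (moving-average smoothing,
    windowed differentiation, through-origin fit from each forager's onset),
    so the oracle carries the same filter attenuation as the measurement.
    Returns ``(pooled_m, per_forager_m)``.
    """
    from .macro import smooth_and_differentiate, fit_individual_flow

    t, F = mean_field_trajectory(cfg)
    onsets = cfg.onsets()
    W = (cfg.n_ants - cfg.n_foragers) * cfg.crop_target_mean
    F_tab = np.linspace(0.0, 1.0, 201)
    flow_tab = mean_field_flow(cfg, F_tab)
    flow_F = np.interp(F, F_tab, flow_tab) / W
    dt = t[1] - t[0]
    slopes = []
    for o in onsets:
        rate_i = np.where(t >= o, flow_F, 0.0)
        f_i = np.concatenate([[0.0], np.cumsum(0.5 * (rate_i[1:] + rate_i[:-1]) * dt)])
        flow_i = smooth_and_differentiate(t, f_i, smooth_window, diff_window)
        m_i, _ = fit_individual_flow(flow_i, F, t >= o)
        slopes.append(m_i)
    return float(np.mean(slopes)), np.asarray(slopes)
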