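"""Shared fixtures: simulated colonies at the study conditions.

Session-scoped because each simulation is a full four-hour colony run; all
tests read, never mutate, the returned objects.
"""

import numpy as np
import pandas as pd
import pytest

from antflow.data import ColonyExperiment
from antflow.macro import compute_colony_state
from antflow.simulate import SimulationConfig, simulate_colony


@pytest.fixture(scope="session")
def default_sim():
    """Observation-experiment conditions: 62 ants, 4 staggered foragers."""
    return simulate_colony(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def preset_sim():
    """Parameter-recovery preset: identical recipient targets (C0 exactly)."""
    return simulate_colony(SimulationConfig(seed=102, crop_target_sd_frac=0.0))


@pytest.fixture(scope="session")
def rate_sim():
    """Colony with the measured interaction-rate decline r(F)=0.032-0.017F,
    needed for the interaction-rate decision schedule to sit between the
    constant and unloading-rate schedules."""
    return simulate_colony(SimulationConfig(seed=103, r1=0.017))


@pytest.fixture(scope="session")
def negctrl_sim():
    """Negative control: the exit rule itself depends on the colony state."""
    return simulate_colony(
        SimulationConfig(seed=103, r1=0.017, exit_colony_coef=-3.0))


@pytest.fixture(scope="session")
def perturb_sim():
    """Manipulation-protocol colony: a small accessible group (31 ants,
    16 foragers) satiates, then 64 hungry nestmates join at t=3600 s."""
    return simulate_colony(SimulationConfig(
        n_ants=31, n_foragers=16, duration=9000.0,
        perturbation=(3600.0, 64), seed=104))


@pytest.fixture(scope="session")
def default_state(default_sim):
    return compute_colony_state(
        default_sim.experiment,
        intake_target=sum(default_sim.targets.values()))


@pytest.fixture(scope="session")
def preset_state(preset_sim):
    return compute_colony_state(
        preset_sim.experiment,
        intake_target=sum(preset_sim.targets.values()))


@pytest.fixture(scope="session")
def m_recovery(default_sim):
    """Feedback slopes fitted on three replicate default colonies, plus the
    mean-field oracle evaluated with the same estimator and windows."""
    from antflow.macro import fit_all_flows
    from antflow.simulate import mean_field_m_measured

    cfg = SimulationConfig()
    oracle_pooled, oracle_per_onset = mean_field_m_measured(cfg)
    sims = [default_sim] + [
        simulate_colony(SimulationConfig(seed=s)) for s in (102, 103)]
    pooled, per_forager = [], []
    for sx in sims:
        state = compute_colony_state(
            sx.experiment, intake_target=sum(sx.targets.values()))
        ff = fit_all_flows(state, sx.experiment.onset_times)
        pooled.append(ff.m)
        per_forager.append([ff.m_i[f] for f in sorted(ff.m_i)])
    return {
        "oracle": oracle_pooled,
        "oracle_per_onset": oracle_per_onset,
        "pooled": np.asarray(pooled),
        "per_forager": np.asarray(per_forager),
    }


@pytest.fixture(scope="session")
def separation_report(rate_sim):
    from antflow.exits import separation_of_variables_test
    state = compute_colony_state(
        rate_sim.experiment, intake_target=sum(rate_sim.targets.values()))
    return separation_of_variables_test(rate_sim.experiment, 0.10, state)


@pytest.fixture(scope="session")
def negctrl_report(negctrl_sim):
    from antflow.exits import separation_of_variables_test
    state = compute_colony_state(
        negctrl_sim.experiment,
        intake_target=sum(negctrl_sim.targets.values()))
    return separation_of_variables_test(negctrl_sim.experiment, 0.10, state)


def make_tiny_experiment(interactions=None, feedings=None, dt=2.0,
                         n_steps=10, foragers=("f00",), ants=("a000", "a001")):
    """Hand-buildable minimal experiment for oracle tests."""
    t = np.arange(n_steps + 1) * dt
    frames = []
    for aid in list(foragers) + list(ants):
        frames.append(pd.DataFrame({
            "ant_id": aid, "t": t, "crop": 0.5,
            "in_trophallaxis": False, "at_food": False, "in_nest": True,
            "experiment_id": "tiny",
        }))
    tl = pd.concat(frames, ignore_index=True)
    ia = pd.DataFrame(
        interactions or [],
        columns=["t_start", "t_end", "donor_id", "recipient_id", "volume",
                 "donor_crop", "recipient_crop", "forager_is_donor",
                 "experiment_id"])
    fe = pd.DataFrame(
        feedings or [],
        columns=["forager_id", "t_start", "t_end", "experiment_id"])
    roles = {a: "forager" for a in foragers}
    roles.update({a: "non-forager" for a in ants})
    return ColonyExperiment(interactions=ia, feedings=fe, timelines=tl,
                            roles=roles, onset_times={f: 0.0 for f in foragers})
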