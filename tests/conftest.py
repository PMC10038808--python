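import numpy as np
import pytest

from glyco import io_grid, physio, synthdata


def make_series(n, t0=0, cgm=None, **channels):
    """Small helper: an empty grid with selected channels filled."""
    s = io_grid.empty_series(t0, n)
    if cgm is not None:
        s.channels["cgm"][:] = cgm
        s.provenance["cgm"][~np.isnan(s.channels["cgm"])] = io_grid.PROV_OBSERVED
    for name, vals in channels.items():
        s.channels[name][:] = vals
        s.provenance[name][~np.isnan(s.channels[name])] = io_grid.PROV_OBSERVED
    return s


@pytest.fixture(scope="session")
def twin_day():
    """One simulated day with three meals: ground truth for state
    estimation experiments."""
    params = physio.HovorkaParams()
    n = 288
    meals = [96, 150, 222]
    grams = [50.0, 40.0, 60.0]
    ug = physio.meal_ug_profile(n, meals, grams, params)
    insulin = np.full(n, 0.33) * 1000 / 60
    for k, g in zip(meals, grams):
        insulin[k] += (g / 30.0) * 1000 / 5
    x0 = physio.basal_steady_state(params, 0.33)
    traj = physio.simulate_hovorka(params, insulin, ug, x0=x0)
    return {"params": params, "n": n, "meals": meals, "grams": grams,
            "ug": ug, "traj": traj, "x0": x0,
            "gsub": traj[:, physio.GSUB], "pic": traj[:, physio.I]}


@pytest.fixture(scope="session")
def small_dataset():
    """A 7-day corrupted synthetic dataset with truth and ledger."""
    corrupted, rendered, ledger = synthdata.generate_dataset(
        synthdata.Scenario(days=7), seed=42)
    return corrupted, rendered, ledger
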