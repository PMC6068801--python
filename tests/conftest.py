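import numpy as np
import pytest

from stepfuse import simulate as sim
from stepfuse.types import Activity, LabeledRow


def make_separable_rows(n_per_class=120, seed=0, sep=7.0, sd=1.0):
    """Five Gaussian blobs on a line in 18-d, weak label == manual label.

    ``sep`` controls class-mean spacing in units of ``sd``; at 7 the classes
    are essentially separable, at ~3.5 adjacent classes overlap slightly.
    The line arrangement is deliberately asymmetric so uniform label noise
    shifts end-class centroids toward the global mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, act in enumerate(Activity):
        mean = np.zeros(18)
        mean[0] = i * sep
        X = rng.normal(0.0, sd, (n_per_class, 18)) + mean
        for j in range(n_per_class):
            rows.append(LabeledRow(act, act, 1.0, X[j], float(i * n_per_class + j)))
    return rows


def sustained_blocks(repeats=1):
    """(duration, activity) blocks with prolonged, cadence-distinct activities.

    Cycling and transportation are bracketed by walking so their near-zero
    cadence never sits next to a sitting block (which would merge the two
    into one ambiguous segment — a known failure mode of the heuristic).
    """
    return [
        (2400.0, Activity.SITTING),
        (1800.0, Activity.WALKING),
        (1200.0, Activity.RUNNING),
        (600.0, Activity.WALKING),
        (1500.0, Activity.CYCLING),
        (600.0, Activity.WALKING),
        (1500.0, Activity.TRANSPORTATION),
        (600.0, Activity.WALKING),
        (1800.0, Activity.SITTING),
    ] * repeats


@pytest.fixture(scope="session")
def sim_config():
    return sim.SimulationConfig()


@pytest.fixture(scope="session")
def mini_trace(sim_config):
    """A ~3.3-h unambiguous trace with accel, steps, GPS and ground truth."""
    schedule = sim.explicit_schedule(sustained_blocks())
    accel, steps, fixes = sim.synth_trace(schedule, sim_config, seed=3)
    return schedule, accel, steps, fixes
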