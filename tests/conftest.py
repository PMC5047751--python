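import logging

import numpy as np
import pytest

import crossact as ca
from crossact.config import PipelineConfig
from crossact.pipeline import (
    classification_stage,
    detect_day_events,
    pairing_stage,
    sequence_stage,
    template_stage,
    tuning_stage,
)

logging.getLogger("crossact").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def day06(pipeline_config):
    """One synthetic day with strong injected cross-activation, with the
    intermediate pipeline products most tests need."""
    cfg = ca.SimConfig(seed=2, cross_activation_fraction=0.6)
    day = ca.simulate_day(cfg)
    events = detect_day_events(day, pipeline_config)
    cls = classification_stage(day, events, pipeline_config)
    return {"sim_config": cfg, "day": day, "events": events, "cls": cls}


def run_replicate(seed: int, f: float, config: PipelineConfig):
    """Simulate one day at cross-activation fraction f and return the
    pairing table and the group matching result (or None)."""
    day = ca.simulate_day(ca.SimConfig(seed=seed,
                                       cross_activation_fraction=f))
    events = detect_day_events(day, config)
    cls = classification_stage(day, events, config)
    pairing = pairing_stage(cls)
    rng = np.random.default_rng(seed)
    tun = tuning_stage(day, events, cls, config, rng,
                       per_cell_statistics=False)
    templates = template_stage(tun, cls, config)
    group = None
    if templates:
        group = sequence_stage(day, events, templates, config, rng)["group"]
    return pairing, group


@pytest.fixture(scope="session")
def replicate_sweep(pipeline_config):
    """20 replicate synthetic days at f in {0, 0.3, 0.6}: pairing tables
    and group match p-values, shared by the parameter-recovery tests."""
    out = {}
    for f in (0.0, 0.3, 0.6):
        pairings, pvals = [], []
        for rep in range(20):
            pairing, group = run_replicate(1000 + rep, f, pipeline_config)
            pairings.append(pairing)
            if group is not None:
                pvals.append(group.p_value)
        out[f] = {"pairings": pairings, "p_values": pvals}
    return out
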