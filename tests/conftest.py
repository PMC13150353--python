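"""Shared fixtures: small simulated columns reused across the suite.

The columns are deliberately narrow (120 um wide) so a full
simulate -> segment -> measure cycle stays in the seconds range; tests that
need the full preset geometry build their own stacks.
"""

import logging

import numpy as np
import pytest

import cortexcount as cc

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def human_column():
    """Simulated human-like column plus its segmentation products."""
    config = cc.human_ba21(seed=101, width_um=120.0)
    stack, cells, vessels = cc.simulate_column(config)
    labels = cc.segment_nuclei(stack)
    nuclei = cc.measure_nuclei(labels, stack)
    return {"config": config, "stack": stack, "cells": cells,
            "vessels": vessels, "labels": labels, "nuclei": nuclei}


@pytest.fixture(scope="session")
def mouse_column():
    """Simulated mouse-like column (all three channels) plus segmentation."""
    config = cc.mouse_s1hl(seed=102, width_um=120.0)
    stack, cells, vessels = cc.simulate_column(config)
    labels = cc.segment_nuclei(stack)
    nuclei = cc.measure_nuclei(labels, stack)
    return {"config": config, "stack": stack, "cells": cells,
            "vessels": vessels, "labels": labels, "nuclei": nuclei}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def single_layer_config(composition=(0.55, 0.28, 0.17), label="II",
                        thickness_um=100.0, width_um=150.0,
                        density=3.0e5, seed=0, **kwargs):
    """One-layer simulation config used by focused tests."""
    layer = cc.LayerSpec(label=label, thickness_um=thickness_um,
                         density_per_mm3=density, composition=composition)
    return cc.SimulationConfig(layers=[layer], width_um=width_um, seed=seed,
                               **kwargs)
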