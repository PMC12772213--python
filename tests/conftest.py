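"""Shared fixtures: simulated trap datasets reused across test modules."""

from __future__ import annotations

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pytest

import trapcycle as tc

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def acceptance_module():
    """The acceptance script imported as a module (its target registry)."""
    spec = importlib.util.spec_from_file_location(
        "acceptance", REPO_ROOT / "scripts" / "acceptance.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def wt_unloaded_dataset():
    """Simulated + detected unloaded recordings with WT-like kinetics.

    Returns a list of (trace, truth, detected) triples; detected events
    carry substeps.  1 µM-ATP-like rates: ADP release 62 /s, ATP-induced
    detachment 5.5 /s, attachment 2 /s.
    """
    out = []
    for i in range(12):
        params = tc.TrapSimParams(
            seed=2000 + i,
            duration=15.0,
            attachment_rate=2.0,
            detachment_rate=5.5,
            substep2_rate=62.0,
            substep1=3.88,
            substep2=0.94,
        )
        trace, truth = tc.simulate_unloaded_trace(params)
        cov = tc.running_covariance(trace)
        thr = tc.fit_cov_double_gaussian(cov, seed=0)
        detected = tc.detect_events(cov, thr, dead_time=0.016)
        tc.annotate_substeps(trace, detected)
        out.append((trace, truth, detected))
    return out


@pytest.fixture(scope="session")
def wt_event_pairs(wt_unloaded_dataset):
    """(trace, event) pairs pooled over the WT dataset, for ensembles."""
    return [
        (trace, ev)
        for trace, _, detected in wt_unloaded_dataset
        for ev in detected
    ]
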