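"""Shared fixtures: simulated campaigns and their flux time courses.

The two-campaign study (a 24-batch 10-day training campaign and a 22-batch
9-day validation campaign, half/partly temperature-shifted) is expensive
enough to build once per session; individual tests slice what they need.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from cmpmonitor import (
    BatchRecord, FluxMatrix, SimParams, builtin_toy_network,
    estimate_specific_rates, run_time_course, simulate_campaign,
)
from cmpmonitor.simdata import METABOLITES


@dataclass
class Campaign:
    records: list[BatchRecord]
    matrices: list[FluxMatrix]

    def by_condition(self, condition: str) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.condition == condition]


def _build_campaign(seed: int, n_normal: int, n_shifted: int, days: int,
                    tag: str) -> Campaign:
    net = builtin_toy_network()
    records = simulate_campaign(SimParams(seed=seed), n_normal, n_shifted, days)
    matrices = []
    for rec in records:
        rec.batch_id = f"{tag}-{rec.batch_id}"
        rates = [estimate_specific_rates(rec, met) for met in METABOLITES]
        matrices.append(run_time_course(net, rec, rates))
    return Campaign(records=records, matrices=matrices)


@pytest.fixture(scope="session")
def training_campaign() -> Campaign:
    """24 batches (12 normal, 12 shifted), 10 days, seed 42."""
    return _build_campaign(42, 12, 12, 10, "c1")


@pytest.fixture(scope="session")
def validation_campaign() -> Campaign:
    """22 batches (12 normal, 10 shifted), 9 days, seed 43."""
    return _build_campaign(43, 12, 10, 9, "c2")


@pytest.fixture(scope="session")
def toy_network():
    return builtin_toy_network()


@pytest.fixture()
def default_params() -> SimParams:
    return SimParams(seed=42)


@pytest.fixture()
def noiseless_params() -> SimParams:
    return SimParams(seed=42, noise_cv=0.0)
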