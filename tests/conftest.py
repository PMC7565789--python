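"""Shared fixtures: simulated control/blocked datasets reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from embrseq.align import align_exact
from embrseq.quant import classify_and_count
from embrseq.reference import annotation_from_records
from embrseq.simulate import build_reference, control_preset, embr_preset, simulate_reads

SIM_SEED = 11
SIM_READS = 50_000


@dataclass
class SimulatedSample:
    config: object
    ref: object
    pairs: list
    truth: object
    alignments: list
    counts: object


def _make_sample(config, sample_id: str) -> SimulatedSample:
    ref = build_reference(config)
    pairs, truth = simulate_reads(ref, config)
    alignments = align_exact([(rid, right) for rid, _, right in pairs], ref, k=25)
    counts = classify_and_count(alignments, annotation_from_records(ref), sample_id=sample_id)
    return SimulatedSample(config, ref, pairs, truth, alignments, counts)


@pytest.fixture(scope="session")
def control_sample() -> SimulatedSample:
    return _make_sample(control_preset(n_reads=SIM_READS, seed=SIM_SEED), "control")


@pytest.fixture(scope="session")
def embr_sample() -> SimulatedSample:
    return _make_sample(embr_preset(n_reads=SIM_READS, seed=SIM_SEED), "embr")
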