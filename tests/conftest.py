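"""Shared fixtures: desk-scale synthetic experiments.

The scaled design keeps the full block counts (9 SPN + 8 task per session)
but shortens blocks (10 s task / 5 s SPN), so every split-arithmetic
property of the full design holds while simulation stays fast.
"""

import numpy as np
import pytest

import eegstates as es


@pytest.fixture(scope="session")
def scaled_design() -> es.ExperimentDesign:
    return es.ExperimentDesign(task_block_duration=10.0, spn_block_duration=5.0)


@pytest.fixture(scope="session")
def tiny_design() -> es.ExperimentDesign:
    # smallest design whose scheme-1 folds still hold every class in training
    return es.ExperimentDesign(
        n_spn_per_session=3,
        n_task_per_session=3,
        task_block_duration=6.0,
        spn_block_duration=3.0,
    )


@pytest.fixture(scope="session")
def default_experiment(scaled_design):
    """Scaled experiment carrying the default workload signature."""
    return es.generate_experiment(scaled_design, es.default_signature(), seed=3)


@pytest.fixture(scope="session")
def null_experiment(scaled_design):
    """Scaled experiment with no condition-dependent structure."""
    return es.generate_experiment(scaled_design, es.null_signature(), seed=5)


def make_annotations(n_spn=18, n_mec=8, n_mer=8, block_len=100):
    """Annotation lists with the requested counts (no signal attached),
    alternating SPN and task blocks within each session."""
    anns = []
    cursor = 0
    per_session = {1: ("MEC", n_mec), 2: ("MER", n_mer)}
    spn_per_session = n_spn // 2
    for session, (task, n_task) in per_session.items():
        n_s, n_t = spn_per_session, n_task
        while n_s or n_t:
            if n_s:
                anns.append(es.BlockAnnotation("SPN", session, cursor, cursor + block_len))
                cursor += block_len
                n_s -= 1
            if n_t:
                anns.append(es.BlockAnnotation(task, session, cursor, cursor + block_len))
                cursor += block_len
                n_t -= 1
    return anns
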