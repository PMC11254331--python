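import pytest

from toxflow import (
    Observation,
    ObservationTable,
    SeverityScale,
    TrajectoryMatrix,
    ctcae_display_scale,
    ctcae_scale,
)


@pytest.fixture
def ae_scale() -> SeverityScale:
    return ctcae_scale()


@pytest.fixture
def display_scale() -> SeverityScale:
    return ctcae_display_scale()


@pytest.fixture
def tiny_table(ae_scale) -> ObservationTable:
    """Three patients, one term, three 6-month stages (one patient unobserved)."""
    stages = ("6 mo", "12 mo", "18 mo")
    obs = (
        Observation("P1", "A", "arthralgia", "6 mo", "2"),
        Observation("P1", "A", "arthralgia", "12 mo", "2"),
        Observation("P2", "A", "arthralgia", "6 mo", "3"),
        Observation("P2", "A", "arthralgia", "12 mo", "1"),
        Observation("P2", "A", "arthralgia", "18 mo", "0"),
        Observation("P3", "A", "headache", "6 mo", "1"),
    )
    return ObservationTable(scale=ae_scale, stage_order=stages, observations=obs)


def make_matrix(scale, rows, stages):
    """Convenience constructor for hand-written trajectory matrices."""
    pids = tuple(f"P{i + 1:03d}" for i in range(len(rows)))
    return TrajectoryMatrix(scale=scale, patient_ids=pids, stages=tuple(stages), states=tuple(rows))
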