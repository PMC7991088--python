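import numpy as np
import pytest

from fretforge import ForsterParams, GeneratorConfig, TrajectoryRecord, simulate_tether


@pytest.fixture(scope="session")
def params() -> ForsterParams:
    return ForsterParams(r0_iso=4.9)


def make_record(
    efficiency,
    state: str = "bound",
    conformer_id: str = "c0",
    frame_spacing_ps: float = 100.0,
    distance=None,
    kappa2=None,
) -> TrajectoryRecord:
    """Record with given E series and placeholder D/kappa^2 unless provided."""
    e = np.asarray(efficiency, dtype=float)
    n = len(e)
    return TrajectoryRecord(
        conformer_id=conformer_id,
        state=state,
        frame_spacing_ps=frame_spacing_ps,
        time_ns=np.arange(n) * frame_spacing_ps * 1e-3,
        distance_nm=np.full(n, 6.0) if distance is None else np.asarray(distance, float),
        kappa2=np.full(n, 2.0 / 3.0) if kappa2 is None else np.asarray(kappa2, float),
        efficiency=e,
    )


@pytest.fixture(scope="session")
def short_bound_record() -> TrajectoryRecord:
    """A 0.1 us bound-state synthetic conformer (1000 frames), reused across tests."""
    return simulate_tether(GeneratorConfig(state="bound", length_us=0.1, seed=11))
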