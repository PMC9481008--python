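import numpy as np
import pytest

from pmrtox import (
    PHASES,
    EffectModel,
    PMRProtocol,
    bin_per_second,
    compute_phase_auc,
    score_traces,
    simulate_embryo_trace,
)


@pytest.fixture
def protocol():
    return PMRProtocol()


@pytest.fixture
def toy_protocol():
    """Tiny 4 s protocol at 1 fps for hand-checkable integrals."""
    return PMRProtocol(
        background=(0.0, 2.0),
        excitatory=(2.0, 3.0),
        refractory=(3.0, 4.0),
        flash_times=(2.0, 3.0),
        frame_rate=1.0,
    )


def simulate_cohort_scores(protocol, effect, n, concentration, seedseq, age_hpf=30.0):
    """Simulate `n` embryos and return their scored PhaseScores table."""
    traces = []
    for i, child in enumerate(seedseq.spawn(n)):
        tr = simulate_embryo_trace(
            protocol, effect, concentration, age_hpf=age_hpf,
            seed=np.random.default_rng(child), well_id=f"W{i}",
        )
        traces.append(bin_per_second(tr))
    return score_traces(traces, protocol)


def cohort_phase_aucs(protocol, effect, n, concentration, seedseq, age_hpf=30.0):
    """AUC arrays per phase for `n` simulated embryos (lighter than a frame)."""
    out = {p: [] for p in PHASES}
    for child in seedseq.spawn(n):
        tr = simulate_embryo_trace(
            protocol, effect, concentration, age_hpf=age_hpf,
            seed=np.random.default_rng(child),
        )
        ps = compute_phase_auc(bin_per_second(tr), protocol)
        for p, v in zip(PHASES, ps.triple()):
            out[p].append(v)
    return {p: np.asarray(v) for p, v in out.items()}
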