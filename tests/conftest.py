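import numpy as np
import pandas as pd
import pytest

from follistage.synthetic import (
    NoiseConfig,
    StageTruth,
    simulate_follicle_events,
    simulate_loop_arrays,
)


@pytest.fixture(scope="session")
def stage_assignment():
    """Four biological samples per stage, names G1..A4."""
    return {
        f"{s[0].upper()}{i + 1}": s
        for s in ("growing", "plateau", "atretic")
        for i in range(4)
    }


@pytest.fixture(scope="session")
def mixed_events():
    """10k-event sample at truth (5, 70, 15, 10) with debris and doublets."""
    truth = StageTruth(stage="plateau", p_subG1=5, p_G1=70, p_S=15, p_G2=10)
    noise = NoiseConfig(debris_frac=0.05, doublet_frac=0.03)
    return truth, simulate_follicle_events(truth, 10_000, noise, seed=1)


@pytest.fixture(scope="session")
def null_loop_arrays(stage_assignment):
    """Small pure-null loop design with dye bias, shared across tests."""
    return simulate_loop_arrays(
        stage_assignment, n_probes=400, de_config={}, dye_bias=0.5, seed=11
    )


def normalized_profile(p_subG1, p_G1, p_S, p_G2):
    from follistage.cytometry import PhaseProfile, normalize_proportions

    return normalize_proportions(
        PhaseProfile(p_subG1=p_subG1, p_G1=p_G1, p_S=p_S, p_G2=p_G2)
    )
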