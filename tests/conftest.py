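import pytest

from panicleheat import (
    build_background,
    default_promoter_config,
    generate_expression_dataset,
    generate_promoter_set,
    scan_motifs,
)
from panicleheat.simulate import ExpressionSimConfig


def planted_design_config(seed: int = 0) -> ExpressionSimConfig:
    """1,000-probe design with exactly 50 planted differential probes per
    time point at 4-fold (log2FC = 2): single-time-point spikes in both
    directions, an early pair, a late pair, and continuous profiles."""
    one_hot_up = [tuple(2.0 if i == t else 0.0 for i in range(5)) for t in range(5)]
    one_hot_down = [tuple(-2.0 if i == t else 0.0 for i in range(5)) for t in range(5)]
    profiles = one_hot_up + one_hot_down + [
        (2.0, 2.0, 0.0, 0.0, 0.0),   # early pair
        (0.0, 0.0, 0.0, 2.0, 2.0),   # late pair
        (2.0, 2.0, 2.0, 2.0, 2.0),   # continuous up
        (-2.0, -2.0, -2.0, -2.0, -2.0),  # continuous down
    ]
    counts = [10, 10, 20, 10, 10] + [10] * 5 + [10, 10, 12, 8]
    return ExpressionSimConfig(
        n_probes=1000,
        n_planted_per_cluster=counts,
        cluster_profiles=profiles,
        noise_sd=0.0,
        flag_absent_rate=0.0,
        frac_unannotated=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def zero_noise_data():
    """Deterministic zero-noise dataset plus its ground truth."""
    return generate_expression_dataset(planted_design_config(seed=7))


@pytest.fixture(scope="session")
def planted_promoter_db():
    """Default planted-promoter experiment scanned into a background DB.

    Returns (promoters, library, truth, occurrences, background)."""
    promoters, library, truth = generate_promoter_set(default_promoter_config(seed=11))
    occurrences = scan_motifs(promoters, library)
    background = build_background(occurrences, promoters, window=250)
    return promoters, library, truth, occurrences, background
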