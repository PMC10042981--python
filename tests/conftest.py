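import numpy as np
import pandas as pd
import pytest

from metabotrend.preprocess import log2_transform, qc_correct
from metabotrend.simulate import (
    DesignSpec,
    VarietySpec,
    generate_design,
    generate_ground_truth,
    simulate_abundances,
)


def three_variety_spec(seed: int = 1) -> DesignSpec:
    return DesignSpec(
        varieties=(
            VarietySpec("Backlim", "open_field", first_calendar_week=19, n_weeks=8),
            VarietySpec("Fortems", "mini_tunnel", first_calendar_week=13, n_weeks=8),
            VarietySpec("Gijnlim", "mini_tunnel", first_calendar_week=14, n_weeks=8),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def design3():
    """3 varieties x 8 weeks x 3 replicates plus interleaved QCs."""
    return generate_design(three_variety_spec())


@pytest.fixture(scope="session")
def noisy_study(design3):
    """A moderately noisy simulated study used by several modules."""
    truth = generate_ground_truth(
        design3, n_compounds=120, residual_sd=0.3, flat_fraction=0.4, seed=11
    )
    matrix, truth = simulate_abundances(design3, truth, seed=12)
    corrected = qc_correct(log2_transform(matrix), design3)
    return design3, truth, matrix, corrected


@pytest.fixture(scope="session")
def noisefree_study(design3):
    """Noise-free study: every downstream estimate must be exact."""
    truth = generate_ground_truth(
        design3, n_compounds=40, residual_sd=0.0, flat_fraction=0.3, seed=21
    )
    matrix, truth = simulate_abundances(design3, truth, seed=22)
    corrected = qc_correct(log2_transform(matrix), design3)
    return design3, truth, matrix, corrected


def true_curve_frame(truth) -> pd.DataFrame:
    """Long-format true weekly logFC curves for comparison with fits."""
    rows = []
    for g, comp in enumerate(truth.compound_ids):
        for key in truth.series:
            variety = key.split("/")[0]
            for w, val in enumerate(truth.true_curve(g, key), start=1):
                rows.append((comp, variety, w, val))
    return pd.DataFrame(rows, columns=["compound_id", "variety", "week", "true_logfc"])


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
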