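import numpy as np
import pytest

from urimet import (
    SimConfig,
    CohortDesign,
    SpectrumSet,
    build_signature_library,
    simulate_cohort,
    normalize_to_reference,
    build_matrix,
    pareto_scale,
)


@pytest.fixture(scope="session")
def library():
    return build_signature_library()


@pytest.fixture(scope="session")
def small_cohort():
    """A 20+20 cohort at reduced resolution: fast, clearly separable."""
    cfg = SimConfig(seed=42, n_points=4096, noise_sd=0.005)
    design = CohortDesign(n_control=20, n_case=20, fold_change=2.0)
    sset, labels = simulate_cohort(design, cfg)
    return sset, labels


def tsp_normalize(sset: SpectrumSet) -> SpectrumSet:
    norm = np.vstack(
        [normalize_to_reference(sset.spectrum(i)).intensity for i in range(len(sset))]
    )
    return SpectrumSet(sset.ppm, norm, sset.sample_ids, sset.labels)


@pytest.fixture(scope="session")
def small_scaled(small_cohort):
    """(X_scaled, labels, matrix) for the small cohort after the full
    normalization/binning/Pareto pipeline."""
    sset, labels = small_cohort
    matrix = build_matrix(tsp_normalize(sset))
    X, params = pareto_scale(matrix)
    return X, labels, matrix
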