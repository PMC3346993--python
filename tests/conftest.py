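import numpy as np
import pandas as pd
import pytest

from tricalib import (
    ComponentSpec,
    FitOptions,
    SimulationConfig,
    paperlike_dataset,
    simulate_cube,
)


def two_component_config(**overrides):
    """Small two-species cube config used across test modules."""
    defaults = dict(
        components=(
            ComponentSpec("x", 2.0, 0.25, ((230.0, 25.0, 1.0),)),
            ComponentSpec("y", 2.4, 0.30, ((280.0, 20.0, 1.0), (220.0, 15.0, 0.4))),
        ),
        concentration_ranges={"x": (1.0, 10.0), "y": (1.0, 10.0)},
        n_calibration=5,
        n_prediction=3,
        n_blank=0,
        noise_sd=0.0,
        time_axis=(0.0, 5.0, 61),
        wavelength_axis=(200.0, 380.0, 46),
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_two_component():
    """Exactly trilinear rank-2 cube with ground truth."""
    return simulate_cube(two_component_config())


@pytest.fixture(scope="session")
def noisy_two_component():
    """Same design at 1% additive noise."""
    return simulate_cube(two_component_config(noise_sd=0.01, seed=2))


@pytest.fixture(scope="session")
def paperlike():
    """The emulated determination study (1 interferent, 0.5% noise)."""
    return paperlike_dataset(seed=0)


@pytest.fixture(scope="session")
def paperlike_resolved(paperlike):
    """Aligned PARAFAC loadings and prediction report for `paperlike`."""
    from tricalib import align_factors, parafac_als, predict_concentrations

    cube, design, truth = paperlike
    loadings = parafac_als(cube, FitOptions(n_components=3))
    refs = pd.DataFrame(
        truth.B[:, :2],
        index=cube.wavelength_axis,
        columns=list(design.analyte_names),
    )
    aligned = align_factors(loadings, refs, wavelength_axis=cube.wavelength_axis)
    report = predict_concentrations(aligned, design)
    return aligned, report


def reference_frame(cube, design, truth):
    return pd.DataFrame(
        truth.B[:, : len(design.analyte_names)],
        index=cube.wavelength_axis,
        columns=list(design.analyte_names),
    )
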