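import numpy as np
import pytest

from proma import (
    assemble_matrix,
    average_replicates,
    background_correct,
    detect_controls,
    log_transform,
    select_channels,
    validate_consistency,
)
from proma.controls import match_control_types
from proma.synthetic import SyntheticConfig, generate_experiment


SMALL_CONFIG = dict(
    n_proteins=50,
    n_blocks=4,
    n_samples_per_group=(3, 3),
    replicates_per_protein=2,
    n_control_proteins=6,
    n_differential=5,
    seed=7,
)


@pytest.fixture(scope="session")
def small_run():
    """A small but fully featured synthetic experiment (shared, read-only)."""
    return generate_experiment(SyntheticConfig(**SMALL_CONFIG))


def pipeline_to_logged(files, floor=0.5):
    """Parse-free path from in-memory GPR files to the logged matrix."""
    catalog = select_channels(validate_consistency(files))
    fg, bg = assemble_matrix(files, catalog)
    corrected = background_correct(fg, bg, floor=floor)
    control_like = match_control_types(corrected.annotations)
    exempt = set(corrected.row_keys()[control_like.notna()])
    return log_transform(average_replicates(corrected, exempt))


@pytest.fixture(scope="session")
def small_logged(small_run):
    files, _ = small_run
    return pipeline_to_logged(files)


@pytest.fixture(scope="session")
def small_panel(small_logged):
    return detect_controls(small_logged)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
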