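"""Shared fixtures for the clusterscan test suite.

All randomness is seeded with fixed literals so the suite is deterministic
run-to-run and machine-to-machine.
"""

import pytest

from clusterscan.synth import (SyntheticTruth, generate_cluster_dataset,
                               generate_normative_cohort, make_grid_mesh)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (3 tp x 2 days x 2 sess x 8)."""
    ds, truth = generate_cluster_dataset(SyntheticTruth(seed=123))
    return ds, truth


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Every variance component zero: thickness equals the cell means."""
    truth = SyntheticTruth(sigma_day=0.0, sigma_session=0.0, sigma_scan=0.0,
                           resid_sd={"core": 0.0, "control": 0.0},
                           motion_effect=0.0, seed=7)
    ds, truth = generate_cluster_dataset(truth)
    return ds, truth


@pytest.fixture(scope="session")
def grid_mesh():
    return make_grid_mesh(8, 8)


@pytest.fixture(scope="session")
def random_cohort():
    return generate_normative_cohort(n=25, n_units=4,
                                     unit_names=("u0", "u1", "u2", "u3"),
                                     seed=42)


def dataset_from_cells(cell_means, design=(3, 2, 2, 8)):
    """Noise-free ClusterScanDataset whose thickness equals ``cell_means``."""
    truth = SyntheticTruth(cell_means=dict(cell_means), sigma_day=0.0,
                           sigma_session=0.0, sigma_scan=0.0,
                           resid_sd={"core": 0.0, "control": 0.0},
                           motion_effect=0.0, seed=0)
    ds, _ = generate_cluster_dataset(truth, design=design)
    return ds


@pytest.fixture()
def toy_scan_table(tmp_path):
    path = tmp_path / "scans.tsv"
    path.write_text(
        "participant\ttimepoint\tday\tsession\tscan\tunit_type\tunit\t"
        "thickness_mm\trmspm\n"
        "P01\tBL\t1\t1\t1\tcore\tcluster0\t1.80\t2.5\n"
        "P01\tBL\t1\t1\t1\tcontrol\tprepost\t2.30\t2.5\n"
        "P01\tM6\t1\t1\t1\tcore\tcluster0\t1.75\t3.1\n"
        "P01\tM6\t1\t1\t1\tcontrol\tprepost\t2.29\t3.1\n")
    return path
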