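import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark_table():
    """Seeded 1000-cell labelled benchmark (70% intact rods, 30% split over
    touching pairs, rounded cells and fragments), measured through the real
    segmentation + descriptor stages."""
    from cardiomorph.benchmark import labeled_benchmark_table

    return labeled_benchmark_table(n_cells=1000, seed=7)


@pytest.fixture(scope="session")
def trained_qc(benchmark_table):
    """Qualification model trained on the benchmark with a stratified
    20% held-out split, plus its held-out metrics."""
    from cardiomorph.qc import train_qc

    return train_qc(benchmark_table, test_fraction=0.2, seed=7)


@pytest.fixture()
def rod_scene():
    """One noise-free intact rod with reference control-like geometry."""
    from cardiomorph.synth import CellSpec, render_scene

    spec = CellSpec("intact_rod", 137.81, 28.53, orientation_deg=30.0,
                    center_um=(120.0, 100.0), sarcomere_period_um=1.8)
    return render_scene((320, 320), 0.65, [spec], noise_sd=0.0, seed=1)


def disc_mask(radius_px: int, pad: int = 10) -> np.ndarray:
    n = 2 * (radius_px + pad)
    yy, xx = np.mgrid[:n, :n]
    c = n / 2 - 0.5
    return ((yy - c) ** 2 + (xx - c) ** 2) <= radius_px ** 2
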