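import numpy as np
import pytest

from orgrowth import AcquisitionGeometry, SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def small_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry(tile_shape_px=(256, 256), z_planes=3, n_frames=5)


@pytest.fixture(scope="session")
def small_recording(small_geometry):
    """A small noise-on recording with 12 organoids, 5 frames, one condition."""
    cfg = SimulationConfig(
        geometry=small_geometry,
        n_organoids=12,
        conditions=[("untreated", 0.0)],
        initial_radius_um=(15.0, 0.12),
        epithelial_ring_thickness_um=5.0,
        seed=7,
    )
    stacks, gt = simulate_recording(cfg)
    return cfg, stacks["untreated"], gt


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full pipeline run of the two-condition recovery benchmark."""
    from orgrowth import run_pipeline
    from orgrowth.benchmark import two_condition_benchmark_config

    cfg = two_condition_benchmark_config(
        seed=1, output_dir=str(tmp_path_factory.mktemp("recovery"))
    )
    out = run_pipeline(cfg)
    return cfg, out


def draw_disks(shape, disks):
    """Synthetic label image: ``disks`` is a list of (cy, cx, r, label)."""
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx, r, lab in disks:
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = lab
    return labels
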