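import numpy as np
import pytest

from patchcascade.cohort import AtrophySite, CohortConfig, generate_cohort_arrays


def tiny_cohort_config(delta=0.4, seed=0, n=24, het=0.0, noise=0.05):
    """A very small cohort (18x22x18) for fast training-path tests."""
    return CohortConfig(
        n_subjects=n,
        class_fraction_ad=0.5,
        volume_shape=(18, 22, 18),
        voxel_size_mm=1.5,
        atrophy_sites=(AtrophySite(center=(6, 9, 7), radius=4.0, delta=delta),),
        heterogeneity_fraction=het,
        noise_sd=noise,
        background_smoothness_mm=4.5,
        jitter_voxels=0.5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Records plus stacked arrays for the default tiny cohort."""
    cfg = tiny_cohort_config()
    records, volumes = generate_cohort_arrays(cfg)
    X = np.stack([volumes[r.subject_id].data for r in records])
    y = np.array([r.label for r in records])
    return cfg, records, volumes, X, y
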