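import numpy as np
import pytest

import loopfold as lf


def open_loop_curve(n: int = 600, scale: float = 320.0) -> np.ndarray:
    """C-shaped smooth 3D loop curve with clearly separated open ends.

    Emulates the geometry of a chromatin loop with flanking fiber: a loop
    body whose ends do not rejoin, so the longest-edge opening of a cyclic
    tour is unambiguous.
    """
    t = np.linspace(0.15 * np.pi, 1.85 * np.pi, n)
    return np.column_stack(
        [scale * np.cos(t), scale * np.sin(t), 0.4 * scale * np.sin(2 * t)]
    )


@pytest.fixture(scope="session")
def target_truth_model() -> lf.PolymerModel:
    """Ground-truth 3331-bead model of the target region on a smooth curve."""
    beads = lf.spline_interpolate(
        open_loop_curve(), lf.n_beads_for(lf.TARGET_MODEL_REGION)
    )
    return lf.map_genome(beads, lf.TARGET_MODEL_REGION, lf.BP_PER_BEAD)


@pytest.fixture(scope="session")
def noise_free_image(target_truth_model):
    """Full-efficiency, zero-noise synthetic localization image + oligo truth."""
    cfg = lf.SynthImageConfig(
        efficiency=1.0,
        events_per_oligo=3,
        sigma_xyz=(0.0, 0.0, 0.0),
        seed=2,
        poisson_events=False,
    )
    return lf.synth_localizations(target_truth_model, cfg)


@pytest.fixture(scope="session")
def saw_truths():
    """Small ensemble of 120-bead self-avoiding walks used across tests."""
    return lf.saw_ensemble(4, lf.SAWConfig(n_beads=120, seed=9))
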