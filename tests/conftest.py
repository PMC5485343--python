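import numpy as np
import pytest

import corneaheal as ch


@pytest.fixture(scope="session")
def model():
    return ch.CorneaModel()


@pytest.fixture(scope="session")
def wound():
    return ch.WoundSpec()


@pytest.fixture(scope="session")
def scan96():
    return ch.ScanSpec.reduced(96)


@pytest.fixture(scope="session")
def noisefree_vol96(model, wound, scan96):
    """Noise-free 96^3 phantom with the default 6-mm wound."""
    return ch.generate_oct_volume(model, wound, scan96, ch.NoiseSpec(speckle_contrast=0.0), seed=0)


@pytest.fixture(scope="session")
def speckled_vol96(model, wound, scan96):
    return ch.generate_oct_volume(model, wound, scan96, ch.NoiseSpec(), seed=1)


@pytest.fixture(scope="session")
def healed_vol96(model, scan96):
    return ch.generate_oct_volume(
        model, ch.WoundSpec(chord_diameter=0.0), scan96, ch.NoiseSpec(), seed=1
    )


@pytest.fixture(scope="session")
def default_photo(model, wound):
    return ch.generate_fluoro_photo(model, wound, seed=3, fluoro_bias=1.25)


@pytest.fixture(scope="session")
def fast_study(tmp_path_factory):
    """Default 20-animal fast-mode study, seed 1."""
    outdir = tmp_path_factory.mktemp("fast_study")
    return ch.run_simulated_study(ch.RunConfig(seed=1), outdir)


def random_balanced_table(seed, n_arms=2, n_subj=4, n_time=3):
    """Random balanced long-format measurement table for ANOVA checks."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_arms):
        for s in range(n_subj):
            subj = f"arm{a}-s{s}"
            base = rng.normal(20 + 2 * a, 3)
            for k in range(n_time):
                rows.append(
                    {
                        "animal_id": subj,
                        "arm": f"arm{a}",
                        "timepoint_h": 12.0 * k,
                        "method": "OCT",
                        "area_mm2": base - rng.normal(1 + a, 0.5) * k + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)
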