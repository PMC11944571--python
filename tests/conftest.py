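import numpy as np
import pytest

import chlorospec as cs


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 species x 2 months x 2 reps on a 200-band grid (seed 1)."""
    return cs.simulate_dataset(cs.tiny_config(1))


@pytest.fixture(scope="session")
def study_absorbance():
    """Full 350 x 2151 study design (seed 1), preprocessed to smoothed
    absorbance, with its metadata."""
    spectra, meta = cs.simulate_dataset(cs.GeneratorConfig(seed=1))
    return cs.preprocess(spectra), meta


@pytest.fixture(scope="session")
def study_split(study_absorbance):
    """Kennard-Stone 280/70 split of the study set in 99%-variance PC
    space, plus the nominated-size KS subset of the calibration pool."""
    absorb, meta = study_absorbance
    pcs = cs.fit_pca(absorb.values, var_threshold=0.99).scores
    cal, val = cs.ks_split(pcs, 280)
    results, nominated = cs.msd_sweep(absorb.values[cal], absorb.values[val])
    sub_space = cs.fit_pca(absorb.values[cal], var_threshold=0.99).scores
    sub = cal[cs.kennard_stone(sub_space, nominated)]
    y = meta["chlorophyll"].to_numpy(float)
    return {
        "absorb": absorb,
        "meta": meta,
        "cal": cal,
        "val": val,
        "sub": sub,
        "y": y,
        "msd_results": results,
        "nominated": nominated,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
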