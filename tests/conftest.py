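import numpy as np
import pandas as pd
import pytest

import lysokit as lk


@pytest.fixture(scope="session")
def noiseless_dsilac():
    """Small noise-free dSILAC dataset with its planted truth."""
    design = lk.DSilacDesign(n_proteins=30, peptides_per_protein=3,
                             n_replicates=2, noise_cv=0.0)
    return lk.generate_dsilac(design, seed=42)


@pytest.fixture(scope="session")
def noisy_dsilac():
    """Moderate-noise dSILAC dataset (20% CV) with truth."""
    design = lk.DSilacDesign(n_proteins=60, peptides_per_protein=3,
                             n_replicates=3, noise_cv=0.2)
    return lk.generate_dsilac(design, seed=43)


@pytest.fixture()
def linear_curve():
    """Exact linear calibration curve ratio = 0.5*pH - 1.5 over pH 4-8."""
    ph = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
    return lk.CalibrationModel(ph, 0.5 * ph - 1.5, model="linear").fit()


@pytest.fixture()
def small_protein_table():
    """5 proteins + PCCA reference over 2x3 samples."""
    rng = np.random.default_rng(0)
    proteins = [f"P{i}" for i in range(5)] + ["PCCA"]
    samples = [f"bait_{i}" for i in range(3)] + [f"ctrl_{i}" for i in range(3)]
    intens = pd.DataFrame(rng.lognormal(10, 0.2, (6, 6)),
                          index=proteins, columns=samples)
    meta = pd.DataFrame({
        "group": ["bait"] * 3 + ["control"] * 3,
        "probe": ["lyso_bait"] * 3 + ["no_probe_control"] * 3,
        "replicate": [1, 2, 3, 1, 2, 3],
    }, index=pd.Index(samples, name="sample_id"))
    return lk.ProteinIntensityTable(intens, meta)
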