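import numpy as np
import pandas as pd
import pytest

from scmetab.containers import FeatureMatrix, Spectrum
from scmetab.preprocess import preprocess_spectra
from scmetab.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def light_dark_sim():
    """Default light/dark simulation (ambiguity-screened library), with the
    preprocessed feature matrix. Session-scoped: treat as read-only."""
    cfg = SimulationConfig(
        scenario="light_dark", rng_seed=1, min_library_mz_separation=0.06
    )
    spectra, truth = simulate_experiment(cfg)
    fm, reports = preprocess_spectra(spectra)
    return cfg, spectra, truth, fm, reports


@pytest.fixture(scope="session")
def clean_sim():
    """Jitter-free, noise-free simulation: feature positions are exact."""
    cfg = SimulationConfig(
        scenario="light_dark",
        rng_seed=3,
        mz_jitter_sd=0.0,
        n_noise_peaks_mean=0.0,
        n_background_ions=0,
        min_library_mz_separation=0.06,
    )
    spectra, truth = simulate_experiment(cfg)
    return cfg, spectra, truth


@pytest.fixture(scope="session")
def n_limitation_run():
    """N-limitation scenario: per-cell elemental ratios over the
    significant-annotated scope plus the group comparison."""
    from scmetab.annotate import annotate_matrix
    from scmetab.library import builtin_library
    from scmetab.stats import differential_features
    from scmetab.stoichiometry import compare_ratios, elemental_ratios

    cfg = SimulationConfig(
        scenario="n_limitation", rng_seed=5, min_library_mz_separation=0.06
    )
    spectra, truth = simulate_experiment(cfg)
    fm, _ = preprocess_spectra(spectra)
    ann = annotate_matrix(fm, builtin_library())
    diff = differential_features(fm)
    scope = set(ann.annotated_features()) & set(diff.significant_features())
    res = elemental_ratios(fm, ann, scope)
    return res, compare_ratios(res)


def make_matrix(values, conditions, consensus_mz=None, feature_ids=None):
    """Hand-build a FeatureMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_cells, n_features = values.shape
    if consensus_mz is None:
        consensus_mz = 100.0 + np.arange(n_features, dtype=float)
    if feature_ids is None:
        feature_ids = [f"{mz:.4f}" for mz in consensus_mz]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    df = pd.DataFrame(values, index=pd.Index(cell_ids, name="cell_id"),
                      columns=feature_ids)
    return FeatureMatrix(
        values=df,
        consensus_mz=np.asarray(consensus_mz, dtype=float),
        conditions=pd.Series(list(conditions), index=df.index),
    )


def make_spectrum(mz, intensity, cell_id="cell", condition="a"):
    return Spectrum(cell_id=cell_id, condition=condition,
                    mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))
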