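"""Synthetic-data generator: determinism, traceability, and effect recovery."""

import math

import numpy as np
import pytest

from scmetab.chem import element_count
from scmetab.library import builtin_library, envelope_positions
from scmetab.preprocess import preprocess_spectra
from scmetab.simulate import (
    N_FREE_CLASSES,
    SimulationConfig,
    simulate_experiment,
    write_experiment,
)


def _spectra_equal(sa, sb):
    return all(
        a.cell_id == b.cell_id
        and np.array_equal(a.mz, b.mz)
        and np.array_equal(a.intensity, b.intensity)
        for a, b in zip(sa, sb)
    )


def test_identical_seed_identical_output():
    cfg = SimulationConfig(rng_seed=7, n_cells_per_group=3, library_size=40)
    s1, t1 = simulate_experiment(cfg)
    s2, t2 = simulate_experiment(cfg)
    assert _spectra_equal(s1, s2)
    assert t1.metabolites.equals(t2.metabolites)
    assert t1.cells.equals(t2.cells)


def test_distinct_seeds_differ():
    a, _ = simulate_experiment(SimulationConfig(rng_seed=1, n_cells_per_group=2,
                                                library_size=40))
    b, _ = simulate_experiment(SimulationConfig(rng_seed=2, n_cells_per_group=2,
                                                library_size=40))
    assert not _spectra_equal(a, b)


def test_noise_free_null_is_reproducible_across_cells():
    cfg = SimulationConfig(
        rng_seed=5, n_cells_per_group=3, library_size=30,
        mz_jitter_sd=0.0, n_noise_peaks_mean=0.0, n_background_ions=0,
        fraction_differential=0.0, intensity_floor=0.0,
    )
    spectra, truth = simulate_experiment(cfg)
    assert truth.metabolites["differential"].sum() == 0
    ref = spectra[0].mz
    for s in spectra[1:]:
        np.testing.assert_array_equal(s.mz, ref)


def test_differential_count_follows_rounding_rule():
    cfg = SimulationConfig(rng_seed=0, n_cells_per_group=2, library_size=100,
                           fraction_differential=0.3)
    _, truth = simulate_experiment(cfg)
    n_lib = len(truth.metabolites)
    assert truth.metabolites["differential"].sum() == round(0.3 * n_lib)


def test_scenario_group_sizes_and_labels():
    sp_ld, _ = simulate_experiment(SimulationConfig(scenario="light_dark",
                                                    library_size=20))
    assert len(sp_ld) == 30
    assert {s.condition for s in sp_ld} == {"light", "dark"}
    sp_nl, _ = simulate_experiment(SimulationConfig(scenario="n_limitation",
                                                    library_size=20))
    assert len(sp_nl) == 20
    assert {s.condition for s in sp_nl} == {"replete", "deplete"}


def test_every_clean_peak_traces_to_an_envelope(clean_sim):
    """With zero jitter and no noise, every peak lies on a true isotope
    envelope position of some simulated ion."""
    cfg, spectra, truth = clean_sim
    lib = {r.name: r for r in builtin_library()}
    positions = np.sort(
        np.concatenate(
            [envelope_positions(lib[n], cfg.isotope_max_replicas)
             for n in truth.ions["name"]]
        )
    )
    for s in spectra[:4]:
        idx = np.searchsorted(positions, s.mz)
        idx = np.clip(idx, 0, positions.size - 1)
        near = np.minimum(
            np.abs(s.mz - positions[idx]),
            np.abs(s.mz - positions[np.clip(idx - 1, 0, None)]),
        )
        assert np.all(near < 1e-9)


def test_ion_mapping_is_injective(light_dark_sim):
    _, _, truth, _, _ = light_dark_sim
    assert truth.ions["name"].is_unique
    assert truth.ions["mz"].is_unique


def test_n_limitation_differentials_are_n_free_and_up():
    cfg = SimulationConfig(scenario="n_limitation", rng_seed=4,
                           min_library_mz_separation=0.06)
    _, truth = simulate_experiment(cfg)
    diff = truth.metabolites[truth.metabolites["differential"]]
    assert (diff["log2_fold_change"] > 0).all()  # up in deplete
    from scmetab.chem import parse_formula

    n_free = diff["formula"].map(lambda f: element_count(parse_formula(f), "N") == 0)
    # drawn preferentially from N-free pools
    assert n_free.mean() > 0.8
    # implied true weighted C:N rises under depletion
    mets = truth.metabolites
    forms = mets["formula"].map(parse_formula)
    c = np.array([element_count(f, "C") for f in forms])
    n_at = np.array([element_count(f, "N") for f in forms])
    cn = {
        cond: (c * mets[f"mean_abundance_{cond}"]).sum()
        / (n_at * mets[f"mean_abundance_{cond}"]).sum()
        for cond in ("replete", "deplete")
    }
    assert cn["deplete"] > cn["replete"]


def test_light_dark_regulates_both_directions(light_dark_sim):
    _, _, truth, _, _ = light_dark_sim
    lfc = truth.metabolites.loc[truth.metabolites["differential"],
                                "log2_fold_change"]
    assert (lfc > 0).any() and (lfc < 0).any()


def test_empirical_fold_change_converges():
    """Raw (pre-normalization) log2 fold changes of differential ions
    approach the programmed effect size at large n. Measured on raw peak
    intensities because total-ion-current normalization compositionally
    compresses one-sided fold changes."""
    cfg = SimulationConfig(
        scenario="n_limitation", rng_seed=9, n_cells_per_group=200,
        library_size=30, log2_effect_sd=0.0, mz_jitter_sd=0.0,
        n_noise_peaks_mean=0.0, n_background_ions=0, intensity_floor=0.0,
        min_library_mz_separation=0.06,
    )
    spectra, truth = simulate_experiment(cfg)
    diff_ions = truth.ions[truth.ions["differential"]]
    lfcs = []
    for _, row in diff_ions.iterrows():
        by_cond = {"replete": [], "deplete": []}
        for s in spectra:
            i = int(np.searchsorted(s.mz, row["mz"]))
            i = min(i, s.mz.size - 1)
            j = i if abs(s.mz[i] - row["mz"]) < 1e-9 else i - 1
            assert abs(s.mz[j] - row["mz"]) < 1e-9
            by_cond[s.condition].append(s.intensity[j])
        lfcs.append(
            math.log2(np.mean(by_cond["deplete"]) / np.mean(by_cond["replete"]))
        )
    lfcs = np.asarray(lfcs)
    se = lfcs.std(ddof=1) / math.sqrt(lfcs.size)
    assert abs(lfcs.mean() - cfg.log2_effect_mean) < 3 * se + 0.05


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(fraction_differential=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_cells_per_group=1)
    with pytest.raises(ValueError):
        SimulationConfig(scenario="drought")
    with pytest.raises(ValueError):
        SimulationConfig(mz_jitter_sd=-0.1)


def test_write_experiment_round_trip(tmp_path):
    from scmetab.io import load_spectra, read_manifest

    cfg = SimulationConfig(rng_seed=2, n_cells_per_group=2, library_size=25)
    spectra, truth = simulate_experiment(cfg)
    write_experiment(spectra, truth, tmp_path)
    manifest = read_manifest(tmp_path / "manifest.tsv")
    back = load_spectra(manifest)
    assert len(back) == len(spectra)
    np.testing.assert_allclose(back[0].mz, spectra[0].mz, atol=1e-6)
    assert (tmp_path / "truth_metabolites.tsv").exists()
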