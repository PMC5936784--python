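"""Synthetic single-cell spectra with known ground truth.

The generator emulates direct-infusion positive-mode spectra of individual
phytoplankton cells in two-condition designs:

* ``light_dark`` — 15 cells per group by default; differential metabolites
  are drawn across compound classes and regulated in both directions
  (lipids included), emulating a diurnal response;
* ``n_limitation`` — 10 cells per group by default; differential
  metabolites are drawn preferentially from nitrogen-free compound classes
  (glycerolipids, sugars, organic acids) and are up-regulated in the
  nitrogen-deplete group, so the true abundance-weighted C:N of the
  metabolome rises under depletion.

Each expressed metabolite contributes its preferred singly charged adduct
ion at the theoretical m/z plus Gaussian jitter, followed by a 13C isotope
envelope: replica k sits at k x 1.00336 Da above the monoisotopic peak with
intensity ratio given by the binomial 13C model on the carbon count
(I(M+1)/I(M) ~ 0.0107 x nC). Per-metabolite abundances are log-normal with
a condition shift of +/- log2-fold-change/2 on differential metabolites;
each cell has a log-normal total-ion-current scale factor. Noise comes in
two realistic flavors: shared chemical-background ions (solvent clusters,
membrane debris, ubiquitous contaminants) that appear at the same m/z in
every cell with non-differential log-normal intensity, and per-cell
spurious peaks at uniform m/z positions. Both are kept away from true
isotope envelopes by default so recovery tests have unambiguous truth. All
randomness flows from one seed, so identical configs give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .chem import C13_ABUNDANCE, element_count
from .containers import Spectrum
from .io import ExperimentManifest, write_manifest, write_peaklist
from .library import (
    LIPID_CLASSES,
    MetaboliteRecord,
    builtin_library,
    envelope_positions,
    select_separated,
)

SCENARIOS = ("light_dark", "n_limitation")
SCENARIO_CONDITIONS = {
    "light_dark": ("light", "dark"),
    "n_limitation": ("replete", "deplete"),
}
SCENARIO_DEFAULT_CELLS = {"light_dark": 15, "n_limitation": 10}

#: Compound classes counted as nitrogen-free for the n_limitation scenario.
N_FREE_CLASSES = ("PA", "PG", "PI", "MG", "DG", "TG", "carbohydrate", "organic_acid")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults mirror the study designs
    (15 cells/group light-dark, 10 cells/group N-limitation, ~200-metabolite
    library, 30% differential at a mean |log2 fold change| of 1)."""

    scenario: str = "light_dark"
    n_cells_per_group: int | None = None  # None -> scenario default
    library_size: int = 200
    fraction_differential: float = 0.3
    log2_effect_mean: float = 1.0
    log2_effect_sd: float = 0.25
    baseline_log_intensity_mean: float = 11.0  # ln(ion counts)
    baseline_log_intensity_sd: float = 1.2
    cell_log_intensity_sd: float = 0.5  # within-group biological variability
    tic_scale_sd: float = 0.3
    mz_jitter_sd: float = 0.002  # Da
    n_background_ions: int = 120  # shared chemical-background ions
    n_noise_peaks_mean: float = 20.0  # per-cell spurious peaks
    noise_intensity_range: tuple[float, float] = (500.0, 5.0e4)
    noise_exclusion_halfwidth: float = 0.05  # Da around true envelopes
    isotope_max_replicas: int = 5
    intensity_floor: float = 100.0  # instrument detection floor, counts
    min_library_mz_separation: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if not 0.0 <= self.fraction_differential <= 1.0:
            raise ValueError("fraction_differential must be in [0, 1]")
        for name in ("log2_effect_sd", "baseline_log_intensity_sd",
                     "cell_log_intensity_sd", "tic_scale_sd", "mz_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells and self.n_cells < 2:
            raise ValueError("n_cells_per_group must be >= 2")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        lo, hi = self.noise_intensity_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid noise_intensity_range")
        if self.isotope_max_replicas < 1:
            raise ValueError("isotope_max_replicas must be >= 1")
        if self.n_background_ions < 0:
            raise ValueError("n_background_ions must be >= 0")

    @property
    def n_cells(self) -> int:
        if self.n_cells_per_group is None:
            return SCENARIO_DEFAULT_CELLS[self.scenario]
        return self.n_cells_per_group

    @property
    def conditions(self) -> tuple[str, str]:
        return SCENARIO_CONDITIONS[self.scenario]


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests.

    ``metabolites``: one row per simulated metabolite — true per-condition
    mean abundance, signed log2 fold change (second condition over first),
    and the differential flag. ``cells``: per-cell condition and TIC scale.
    ``ions``: one row per (metabolite, adduct) ion with its theoretical
    monoisotopic m/z; the mapping ion -> metabolite is injective.
    """

    metabolites: pd.DataFrame
    cells: pd.DataFrame
    ions: pd.DataFrame
    conditions: tuple[str, str]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.metabolites.to_csv(directory / "truth_metabolites.tsv", sep="\t", index=False)
        self.cells.to_csv(directory / "truth_cells.tsv", sep="\t", index=False)
        self.ions.to_csv(directory / "truth_ions.tsv", sep="\t", index=False)


def isotope_ratios(n_carbons: int, max_replicas: int) -> np.ndarray:
    """I(M+k)/I(M) for k = 0..max_replicas-1 under the binomial 13C model."""
    ks = np.arange(min(max_replicas, n_carbons + 1))
    pmf = binom.pmf(ks, n_carbons, C13_ABUNDANCE)
    return pmf / pmf[0]


def _choose_differential(
    cfg: SimulationConfig, lib: list[MetaboliteRecord], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Differential flags and signs (+1 = up in the second condition)."""
    n = len(lib)
    n_diff = round(cfg.fraction_differential * n)
    flags = np.zeros(n, dtype=bool)
    signs = np.zeros(n)
    if n_diff == 0:
        return flags, signs
    if cfg.scenario == "n_limitation":
        n_free = [i for i, r in enumerate(lib)
                  if element_count(r.formula, "N") == 0]
        rest = [i for i in range(n) if i not in set(n_free)]
        pool = list(rng.permutation(n_free)) + list(rng.permutation(rest))
        chosen = [int(i) for i in pool[:n_diff]]
        flags[chosen] = True
        signs[chosen] = 1.0  # up under depletion
    else:
        chosen = rng.choice(n, size=n_diff, replace=False)
        flags[chosen] = True
        signs[chosen] = rng.choice([-1.0, 1.0], size=n_diff)
    return flags, signs


def simulate_experiment(
    cfg: SimulationConfig, lib: list[MetaboliteRecord] | None = None
) -> tuple[list[Spectrum], GroundTruth]:
    """Generate per-cell spectra and the matching ground truth."""
    rng = np.random.default_rng(cfg.rng_seed)
    if lib is None:
        lib = builtin_library()
    if not lib:
        raise ValueError("empty metabolite library")
    if cfg.min_library_mz_separation is not None:
        lib = select_separated(
            lib,
            envelope_gap=cfg.min_library_mz_separation,
            max_replicas=cfg.isotope_max_replicas,
        )
    if cfg.library_size < len(lib):
        idx = np.sort(rng.choice(len(lib), size=cfg.library_size, replace=False))
        lib = [lib[int(i)] for i in idx]

    cond_a, cond_b = cfg.conditions
    n = len(lib)
    flags, signs = _choose_differential(cfg, lib, rng)
    magnitudes = np.clip(
        rng.normal(cfg.log2_effect_mean, cfg.log2_effect_sd, size=n), 0.0, None
    )
    log2fc = np.where(flags, signs * magnitudes, 0.0)

    baseline = rng.normal(
        cfg.baseline_log_intensity_mean, cfg.baseline_log_intensity_sd, size=n
    )
    shift = log2fc * math.log(2.0) / 2.0
    mean_log = {cond_a: baseline - shift, cond_b: baseline + shift}

    theo_mz = np.array([r.mz for r in lib])
    ratios = [isotope_ratios(element_count(r.formula, "C"), cfg.isotope_max_replicas)
              for r in lib]
    envelopes = [envelope_positions(r, cfg.isotope_max_replicas) for r in lib]
    forbidden = np.sort(np.concatenate(envelopes)) if envelopes else np.array([])

    # shared chemical-background ions: same m/z in every cell, non-differential
    bg_mz = np.array([])
    bg_log_baseline = np.array([])
    if cfg.n_background_ions > 0:
        draw = _sample_noise_mz(rng, cfg.n_background_ions, forbidden,
                                cfg.noise_exclusion_halfwidth)
        draw = np.sort(draw)
        keep = np.ones(draw.size, dtype=bool)
        keep[1:] = np.diff(draw) > max(cfg.noise_exclusion_halfwidth, 0.02)
        bg_mz = draw[keep]
        lo, hi = cfg.noise_intensity_range
        bg_log_baseline = rng.uniform(
            np.log(max(lo, 1.0)), np.log(max(hi, 2.0)), size=bg_mz.size
        )
        forbidden = np.sort(np.concatenate([forbidden, bg_mz]))

    cells_rows = []
    spectra: list[Spectrum] = []
    for cond in (cond_a, cond_b):
        for j in range(cfg.n_cells):
            cell_id = f"{cond}_{j + 1:02d}"
            tic_scale = float(np.exp(rng.normal(0.0, cfg.tic_scale_sd)))
            abundance = np.exp(
                rng.normal(mean_log[cond], cfg.cell_log_intensity_sd)
            ) * tic_scale
            mz_list, int_list = [], []
            for i in range(n):
                r = ratios[i]
                peak_int = abundance[i] * r
                jitter = rng.normal(0.0, cfg.mz_jitter_sd, size=r.size)
                positions = envelopes[i][: r.size] + jitter
                keep = peak_int >= cfg.intensity_floor
                mz_list.append(positions[keep])
                int_list.append(peak_int[keep])
            if bg_mz.size:
                bg_int = np.exp(
                    rng.normal(bg_log_baseline, cfg.cell_log_intensity_sd)
                ) * tic_scale
                keep = bg_int >= cfg.intensity_floor
                mz_list.append(bg_mz[keep])
                int_list.append(bg_int[keep])
            n_noise = int(rng.poisson(cfg.n_noise_peaks_mean))
            if n_noise:
                noise_mz = _sample_noise_mz(rng, n_noise, forbidden,
                                            cfg.noise_exclusion_halfwidth)
                lo, hi = cfg.noise_intensity_range
                noise_int = rng.uniform(lo, hi, size=noise_mz.size)
                keep = noise_int >= cfg.intensity_floor
                mz_list.append(noise_mz[keep])
                int_list.append(noise_int[keep])
            mz = np.concatenate(mz_list)
            inten = np.concatenate(int_list)
            order = np.argsort(mz)
            mz, inten = mz[order], inten[order]
            # merge exactly coincident m/z (vanishingly rare with jitter)
            dup = np.flatnonzero(np.diff(mz) == 0)
            if dup.size:
                np.add.at(inten, dup, inten[dup + 1])
                mz = np.delete(mz, dup + 1)
                inten = np.delete(inten, dup + 1)
            spectra.append(Spectrum(cell_id=cell_id, condition=cond, mz=mz, intensity=inten))
            cells_rows.append({"cell_id": cell_id, "condition": cond,
                               "tic_scale": tic_scale})

    metabolites = pd.DataFrame(
        {
            "name": [r.name for r in lib],
            "formula": [str(r.formula) for r in lib],
            "compound_class": [r.compound_class for r in lib],
            "adduct": [r.preferred_adduct.name for r in lib],
            f"mean_abundance_{cond_a}": np.exp(mean_log[cond_a]),
            f"mean_abundance_{cond_b}": np.exp(mean_log[cond_b]),
            "log2_fold_change": log2fc,
            "differential": flags,
        }
    )
    ions = pd.DataFrame(
        {
            "name": [r.name for r in lib],
            "adduct": [r.preferred_adduct.name for r in lib],
            "mz": theo_mz,
            "differential": flags,
        }
    ).sort_values("mz", kind="stable", ignore_index=True)
    truth = GroundTruth(
        metabolites=metabolites,
        cells=pd.DataFrame(cells_rows),
        ions=ions,
        conditions=(cond_a, cond_b),
    )
    return spectra, truth


def _sample_noise_mz(
    rng: np.random.Generator,
    n: int,
    forbidden: np.ndarray,
    halfwidth: float,
    mz_min: float = 100.0,
    mz_max: float = 1500.0,
) -> np.ndarray:
    """Uniform noise m/z positions outside +/- halfwidth of true envelopes."""
    out: list[float] = []
    attempts = 0
    while len(out) < n and attempts < 50:
        draw = rng.uniform(mz_min, mz_max, size=2 * (n - len(out)))
        if forbidden.size and halfwidth > 0:
            idx = np.searchsorted(forbidden, draw)
            left = np.abs(draw - forbidden[np.clip(idx - 1, 0, forbidden.size - 1)])
            right = np.abs(forbidden[np.clip(idx, 0, forbidden.size - 1)] - draw)
            draw = draw[np.minimum(left, right) > halfwidth]
        out.extend(draw[: n - len(out)].tolist())
        attempts += 1
    return np.asarray(out)


def write_experiment(
    spectra: list[Spectrum], truth: GroundTruth, directory: str | Path
) -> ExperimentManifest:
    """Write per-cell peak lists, a manifest, and ground-truth sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in spectra:
        fname = f"{s.cell_id}.tsv"
        write_peaklist(s, directory / fname)
        entries.append((fname, s.cell_id, s.condition))
    manifest = ExperimentManifest([(str(directory / f), c, cond) for f, c, cond in entries])
    write_manifest(ExperimentManifest([(f, c, cond) for f, c, cond in entries]),
                   directory / "manifest.tsv")
    truth.write(directory)
    return manifest
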