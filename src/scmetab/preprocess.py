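"""Spectral preprocessing: intensity filtering, TIC normalization,
isotope-envelope collapsing, and cross-cell m/z alignment.

The pipeline order is fixed — filter, normalize, deisotope, align — and each
stage is pure (returns new objects). Intensity filtering keeps peaks whose
ion intensity is strictly above the export threshold (default 10^3 counts)
and accounts for the excluded fraction. TIC normalization divides by the
total ion current so intensities are relative abundances comparable across
cells. Deisotoping collapses 13C isotope envelopes (replicas spaced
1.00336 Da at z = 1, up to 5 replicas, 0.05 Da tolerance) onto the
monoisotopic peak, summing intensity. Alignment pools deisotoped peaks from
all cells, restricts to the 100-1500 m/z analysis window, and cuts the
sorted pool into features wherever the gap between consecutive peaks
exceeds 0.01 Da.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import ISOTOPE_SPACING
from .containers import FeatureMatrix, Spectrum

logger = logging.getLogger(__name__)

DEFAULT_INTENSITY_THRESHOLD = 1e3


@dataclass(frozen=True)
class FilterReport:
    """Accounting for one spectrum's low-intensity filtering."""

    n_peaks_in: int
    n_peaks_kept: int
    fraction_peaks_removed: float
    fraction_intensity_retained: float


@dataclass(frozen=True)
class AlignmentParams:
    """Preprocessing parameters (defaults follow the standard direct-infusion
    single-cell workflow: 100-1500 m/z window, up to 5 isotope replicas,
    0.05 Da isotope tolerance, 0.01 Da alignment tolerance)."""

    mz_min: float = 100.0
    mz_max: float = 1500.0
    max_isotope_replicas: int = 5
    isotope_delta: float = 0.05
    align_delta: float = 0.01
    isotope_spacing: float = ISOTOPE_SPACING

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.isotope_delta <= 0 or self.align_delta <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_isotope_replicas < 1:
            raise ValueError("max_isotope_replicas must be >= 1")


def filter_low_intensity(
    s: Spectrum, threshold: float = DEFAULT_INTENSITY_THRESHOLD
) -> tuple[Spectrum, FilterReport]:
    """Keep peaks with intensity strictly above ``threshold``.

    Returns the filtered spectrum and a report with the removed-peak and
    retained-intensity fractions. An empty input yields an empty output with
    0 removed / 1.0 retained by convention.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n_in = len(s)
    if n_in == 0:
        return s, FilterReport(0, 0, 0.0, 1.0)
    keep = s.intensity > threshold
    total = s.intensity.sum()
    kept = s.replace_peaks(s.mz[keep], s.intensity[keep])
    return kept, FilterReport(
        n_peaks_in=n_in,
        n_peaks_kept=len(kept),
        fraction_peaks_removed=1.0 - len(kept) / n_in,
        fraction_intensity_retained=float(kept.intensity.sum() / total) if total > 0 else 1.0,
    )


def tic_normalize(s: Spectrum) -> Spectrum:
    """Divide intensities by the total ion current (sums to 1 afterwards)."""
    total = s.tic
    if total <= 0:
        raise ValueError(f"spectrum {s.cell_id!r}: zero total ion current")
    return s.replace_peaks(s.mz, s.intensity / total)


def collapse_isotopes(s: Spectrum, p: AlignmentParams | None = None) -> Spectrum:
    """Collapse 13C isotope envelopes onto their monoisotopic peaks.

    Scanning peaks in ascending m/z, a peak joins an open envelope when it
    lies within ``isotope_delta`` of the envelope's expected next replica
    position (monoisotopic m/z + k * spacing for the next unfilled slot k,
    k < max_isotope_replicas). When two open envelopes both accept a peak the
    one with the smaller |observed - expected| wins; exact ties go to the
    lower monoisotopic m/z. Each envelope becomes a single output peak at the
    monoisotopic m/z carrying the summed intensity, so total signal is
    conserved.
    """
    p = p or AlignmentParams()
    if len(s) == 0:
        return s
    mono_mz: list[float] = []
    summed: list[float] = []
    # open envelopes: (envelope index, expected next position, replicas used)
    open_env: list[list[float]] = []
    for mz, inten in zip(s.mz, s.intensity):
        # close envelopes that can no longer accept any peak (sorted scan)
        open_env = [e for e in open_env if mz <= e[1] + p.isotope_delta]
        best = None
        for env in open_env:
            dist = abs(mz - env[1])
            if dist <= p.isotope_delta:
                key = (dist, mono_mz[int(env[0])])
                if best is None or key < best[0]:
                    best = (key, env)
        if best is not None:
            env = best[1]
            i = int(env[0])
            summed[i] += inten
            env[2] += 1
            if env[2] >= p.max_isotope_replicas:
                open_env.remove(env)
            else:
                env[1] = mono_mz[i] + env[2] * p.isotope_spacing
        else:
            mono_mz.append(mz)
            summed.append(inten)
            open_env.append([len(mono_mz) - 1, mz + p.isotope_spacing, 1])
    return s.replace_peaks(np.asarray(mono_mz), np.asarray(summed))


def align_features(
    spectra: list[Spectrum], p: AlignmentParams | None = None
) -> FeatureMatrix:
    """Align deisotoped spectra into a cells x features matrix.

    Peaks outside [mz_min, mz_max] are dropped. The pooled peaks of all
    cells are sorted by m/z and cut greedily into clusters wherever the gap
    between consecutive peaks exceeds ``align_delta``. Each cluster becomes
    one feature whose consensus m/z is the intensity-weighted mean; a cell's
    value is the sum of its peaks in the cluster (0 when absent).
    """
    p = p or AlignmentParams()
    if len(spectra) < 2:
        raise ValueError("alignment needs at least two spectra")
    cell_ids = [s.cell_id for s in spectra]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell ids")
    mz_all, int_all, cell_all = [], [], []
    for ci, s in enumerate(spectra):
        in_range = (s.mz >= p.mz_min) & (s.mz <= p.mz_max)
        mz_all.append(s.mz[in_range])
        int_all.append(s.intensity[in_range])
        cell_all.append(np.full(int(in_range.sum()), ci))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    cell = np.concatenate(cell_all)
    if mz.size == 0:
        raise ValueError("no peaks inside the alignment m/z window")
    order = np.argsort(mz, kind="stable")
    mz, inten, cell = mz[order], inten[order], cell[order]
    cluster = np.zeros(mz.size, dtype=int)
    if mz.size > 1:
        cluster[1:] = np.cumsum(np.diff(mz) > p.align_delta)
    n_clusters = int(cluster[-1]) + 1

    weighted = np.zeros(n_clusters)
    weights = np.zeros(n_clusters)
    np.add.at(weighted, cluster, mz * inten)
    np.add.at(weights, cluster, inten)
    plain_mean = np.zeros(n_clusters)
    counts = np.zeros(n_clusters)
    np.add.at(plain_mean, cluster, mz)
    np.add.at(counts, cluster, 1.0)
    consensus = np.where(weights > 0, weighted / np.maximum(weights, 1e-300),
                         plain_mean / counts)

    values = np.zeros((len(spectra), n_clusters))
    np.add.at(values, (cell, cluster), inten)

    # a cell contributing >1 peak to a cluster is summed but logged
    seen = np.zeros((len(spectra), n_clusters), dtype=int)
    np.add.at(seen, (cell, cluster), 1)
    multi_clusters = np.where((seen > 1).any(axis=0))[0]
    for c in multi_clusters:
        logger.info(
            "alignment: cluster at m/z %.4f received multiple peaks from one cell "
            "(summed)", consensus[c],
        )

    feature_ids = _feature_ids(consensus)
    df = pd.DataFrame(values, index=pd.Index(cell_ids, name="cell_id"), columns=feature_ids)
    conditions = pd.Series([s.condition for s in spectra], index=df.index)
    return FeatureMatrix(values=df, consensus_mz=consensus, conditions=conditions)


def _feature_ids(consensus_mz: np.ndarray) -> list[str]:
    ids: list[str] = []
    seen: dict[str, int] = {}
    for mz in consensus_mz:
        base = f"{mz:.4f}"
        if base in seen:
            seen[base] += 1
            ids.append(f"{base}_{seen[base]}")
        else:
            seen[base] = 1
            ids.append(base)
    return ids


def preprocess_spectra(
    spectra: list[Spectrum],
    threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    params: AlignmentParams | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Run filter -> TIC-normalize -> deisotope -> align on raw spectra.

    Returns the feature matrix and a per-cell filter-report table.
    """
    params = params or AlignmentParams()
    processed = []
    reports = []
    for s in spectra:
        filtered, report = filter_low_intensity(s, threshold)
        if len(filtered) == 0:
            raise ValueError(f"cell {s.cell_id!r}: no peaks above intensity threshold")
        normalized = tic_normalize(filtered)
        deisotoped = collapse_isotopes(normalized, params)
        processed.append(deisotoped)
        reports.append(
            {
                "cell_id": s.cell_id,
                "condition": s.condition,
                "n_peaks_in": report.n_peaks_in,
                "n_peaks_kept": report.n_peaks_kept,
                "fraction_peaks_removed": report.fraction_peaks_removed,
                "fraction_intensity_retained": report.fraction_intensity_retained,
                "n_features_deisotoped": len(deisotoped),
            }
        )
    fm = align_features(processed, params)
    return fm, pd.DataFrame(reports)
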