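"""Core in-memory containers: one cell's spectrum and the cells x features matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Spectrum:
    """One cell's centroided peak list plus cell and condition identifiers.

    ``mz`` is strictly increasing; intensities are non-negative. Both arrays
    are validated on construction, so every operation downstream can assume
    sortedness.
    """

    cell_id: str
    condition: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError(
                f"spectrum {self.cell_id!r}: m/z values must be strictly increasing "
                "(duplicates are not allowed)"
            )
        if np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.cell_id!r}: negative intensity")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all peak intensities."""
        return float(self.intensity.sum())

    def replace_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.cell_id, self.condition, mz, intensity)


@dataclass
class FeatureMatrix:
    """TIC-normalized intensities of aligned features across cells.

    ``values`` is a cells x features DataFrame indexed by cell_id with feature
    ids as columns; ``consensus_mz`` gives each feature's intensity-weighted
    consensus m/z in the same column order; ``conditions`` maps cell_id to its
    group label.
    """

    values: pd.DataFrame
    consensus_mz: np.ndarray
    conditions: pd.Series

    def __post_init__(self) -> None:
        self.consensus_mz = np.asarray(self.consensus_mz, dtype=float)
        if self.consensus_mz.size != self.values.shape[1]:
            raise ValueError("consensus_mz length must equal the number of features")
        if self.consensus_mz.size and np.any(np.diff(self.consensus_mz) <= 0):
            raise ValueError("consensus m/z must be strictly increasing")
        if not self.values.index.equals(self.conditions.index):
            self.conditions = self.conditions.reindex(self.values.index)
            if self.conditions.isna().any():
                raise ValueError("every cell needs a condition label")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated feature ids")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def condition_labels(self) -> list[str]:
        """The distinct condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c, None)
        return list(seen)

    def group_mask(self, label: str) -> np.ndarray:
        return (self.conditions == label).to_numpy()

    def subset_features(self, feature_ids: list[str]) -> "FeatureMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        order = np.argsort(self.consensus_mz[idx])
        idx = [idx[i] for i in order]
        return FeatureMatrix(
            values=self.values.iloc[:, idx].copy(),
            consensus_mz=self.consensus_mz[idx],
            conditions=self.conditions.copy(),
        )
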