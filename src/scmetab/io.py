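"""Readers and writers for on-disk artifacts.

Formats are deliberately plain text:

* per-cell peak lists: two tab-separated columns (m/z, intensity), optional
  header, ``#`` comments — the dialect produced by exporting centroided
  spectra from vendor software;
* experiment manifest: TSV with columns ``path``, ``cell_id``, ``condition``;
* feature matrix: CSV with ``cell_id`` and ``condition`` as the first two
  columns and features keyed by consensus m/z;
* annotation tables: TSV.

Readers reject malformed rows with the offending line number rather than
silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, Spectrum


class PeaklistError(ValueError):
    """Malformed peak-list or manifest input."""


def read_peaklist(path: str | Path, cell_id: str, condition: str) -> Spectrum:
    """Read one cell's tab-delimited (m/z, intensity) peak list.

    The first line may be a header (detected as non-numeric); lines starting
    with ``#`` and blank lines are ignored. Peaks are sorted ascending by m/z.
    """
    path = Path(path)
    mzs: list[float] = []
    intensities: list[float] = []
    first_data_line = True
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PeaklistError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                mz = float(fields[0])
                inten = float(fields[1])
            except ValueError:
                if first_data_line:
                    first_data_line = False
                    continue  # header line
                raise PeaklistError(f"{path}:{lineno}: non-numeric data row {line!r}")
            first_data_line = False
            mzs.append(mz)
            intensities.append(inten)
    if not mzs:
        raise PeaklistError(f"{path}: no peaks found")
    order = np.argsort(mzs, kind="stable")
    mz_arr = np.asarray(mzs)[order]
    int_arr = np.asarray(intensities)[order]
    if np.any(np.diff(mz_arr) == 0):
        raise PeaklistError(f"{path}: duplicate m/z values within one spectrum")
    return Spectrum(cell_id=cell_id, condition=condition, mz=mz_arr, intensity=int_arr)


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("mz\tintensity\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6f}\n")


@dataclass
class ExperimentManifest:
    """Maps peak-list files to cell ids and the two condition labels."""

    entries: list[tuple[str, str, str]]  # (path, cell_id, condition)

    def __post_init__(self) -> None:
        cell_ids = [e[1] for e in self.entries]
        if len(set(cell_ids)) != len(cell_ids):
            raise PeaklistError("duplicate cell_id in manifest")
        conditions = pd.Series([e[2] for e in self.entries])
        labels = conditions.unique()
        if len(labels) != 2:
            raise PeaklistError(
                f"manifest must have exactly two condition labels, found {list(labels)}"
            )
        counts = conditions.value_counts()
        if (counts < 2).any():
            raise PeaklistError("each condition needs at least two cells")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, c in self.entries:
            seen.setdefault(c, None)
        return list(seen)


def read_manifest(path: str | Path) -> ExperimentManifest:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"path", "cell_id", "condition"}
    if not required.issubset(df.columns):
        raise PeaklistError(f"{path}: manifest needs columns {sorted(required)}")
    base = path.parent
    entries = []
    for _, row in df.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = base / p
        entries.append((str(p), str(row["cell_id"]), str(row["condition"])))
    return ExperimentManifest(entries)


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("path\tcell_id\tcondition\n")
        for p, cid, cond in manifest.entries:
            fh.write(f"{p}\t{cid}\t{cond}\n")


def load_spectra(manifest: ExperimentManifest) -> list[Spectrum]:
    return [read_peaklist(p, cid, cond) for p, cid, cond in manifest.entries]


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV (cells x features, 12 significant digits)."""
    df = fm.values.copy()
    df.insert(0, "condition", fm.conditions.values)
    df.index.name = "cell_id"
    header_mz = ",".join(f"{mz:.6f}" for mz in fm.consensus_mz)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# consensus_mz,{header_mz}\n")
        df.to_csv(fh, float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# consensus_mz,"):
            raise PeaklistError(f"{path}: missing consensus_mz header")
        consensus = np.array([float(x) for x in first.split(",")[1:]])
        header = fh.readline().strip().split(",")
        if len(set(header)) != len(header):
            raise PeaklistError(f"{path}: duplicated feature id")
        df = pd.read_csv(fh, names=header, index_col="cell_id")
    conditions = df.pop("condition")
    if consensus.size != df.shape[1]:
        raise PeaklistError(f"{path}: consensus m/z count does not match feature count")
    df.index = df.index.astype(str)
    conditions.index = df.index
    return FeatureMatrix(values=df, consensus_mz=consensus, conditions=conditions)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
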