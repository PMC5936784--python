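"""Metabolite library: records, TSV loading, and the packaged builtin library.

A library record carries a neutral molecular formula, a compound-class label
(including the glycerolipid / glycerophospholipid classes PA, PE, PG, PS, PI,
PC, MG, DG, TG used for lipid heat maps), pathway memberships (most records
have none, as is typical when mapping an algal metabolome against curated
pathway databases), and the counter-ion under which the metabolite is
observed in positive mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ADDUCTS, AdductSpec, Formula, ISOTOPE_SPACING, adduct_mz, get_adduct

#: Lipid-class labels recognized for heat-map selection.
LIPID_CLASSES = ("PA", "PE", "PG", "PS", "PI", "PC", "MG", "DG", "TG")


@dataclass(frozen=True)
class MetaboliteRecord:
    name: str
    formula: Formula
    compound_class: str
    preferred_adduct: AdductSpec
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def mz(self) -> float:
        """m/z of the preferred singly charged adduct ion."""
        return adduct_mz(self.formula, self.preferred_adduct)


def load_library(path: str | Path) -> list[MetaboliteRecord]:
    """Load a library TSV (name, formula, compound_class, adduct, pathways)."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    required = {"name", "formula", "compound_class", "adduct", "pathways"}
    if not required.issubset(df.columns):
        raise ValueError(f"library file needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        pathways = frozenset(p for p in str(row["pathways"]).split(";") if p)
        records.append(
            MetaboliteRecord(
                name=str(row["name"]),
                formula=Formula.parse(str(row["formula"])),
                compound_class=str(row["compound_class"]),
                preferred_adduct=get_adduct(str(row["adduct"])),
                pathway_ids=pathways,
            )
        )
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate metabolite names in library")
    return records


def builtin_library() -> list[MetaboliteRecord]:
    """The packaged metabolite library (~170 records, adduct m/z in 100-1500)."""
    with resources.as_file(
        resources.files("scmetab.data").joinpath("metabolite_library.tsv")
    ) as p:
        return load_library(p)


def load_pathways(path: str | Path | None = None) -> pd.DataFrame:
    """Pathway id -> name table (packaged fixture when ``path`` is None)."""
    if path is None:
        with resources.as_file(
            resources.files("scmetab.data").joinpath("pathways.tsv")
        ) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def envelope_positions(record: MetaboliteRecord, max_replicas: int = 5) -> np.ndarray:
    """m/z positions of the preferred-adduct isotope envelope (z = 1)."""
    return record.mz + ISOTOPE_SPACING * np.arange(max_replicas)


def select_separated(
    records: list[MetaboliteRecord],
    envelope_gap: float = 0.06,
    annotation_gap: float = 0.025,
    max_replicas: int = 5,
) -> list[MetaboliteRecord]:
    """Greedily keep records whose ions cannot be confused with each other.

    Two guarantees for the kept subset:

    * every pair of preferred-adduct isotope-envelope positions is at least
      ``envelope_gap`` apart, so deisotoping and gap-cut alignment cannot
      merge ions of different metabolites;
    * the preferred-adduct m/z of each kept record is at least
      ``annotation_gap`` from *every* adduct m/z (all four counter-ions) of
      every other kept record, so mass matching at tolerances up to
      ``annotation_gap``/2 is unambiguous.

    Records are scanned in library order, so the result is deterministic.
    """
    kept: list[MetaboliteRecord] = []
    env_positions: list[np.ndarray] = []
    all_adduct_mz: list[np.ndarray] = []
    adduct_specs = list(ADDUCTS.values())
    for rec in records:
        env = envelope_positions(rec, max_replicas)
        adds = np.array([adduct_mz(rec.formula, a) for a in adduct_specs])
        ok = True
        for other_env, other_adds in zip(env_positions, all_adduct_mz):
            if np.min(np.abs(env[:, None] - other_env[None, :])) < envelope_gap:
                ok = False
                break
            if (
                np.min(np.abs(env[0] - other_adds)) < annotation_gap
                or np.min(np.abs(other_env[0] - adds)) < annotation_gap
            ):
                ok = False
                break
        if ok:
            kept.append(rec)
            env_positions.append(env)
            all_adduct_mz.append(adds)
    return kept
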