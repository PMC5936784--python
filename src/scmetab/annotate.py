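"""Tentative metabolite annotation and pathway roll-up.

Aligned features are matched against a metabolite library by adduct-aware
monoisotopic m/z within a mass tolerance (default 0.01 Da, optionally ppm).
Matching is tentative by design: a feature may have several candidates
(true isomers share a formula and are all retained), and most features of a
real single-cell metabolome match nothing at all. Significantly regulated,
annotated features are then rolled up to pathways, keeping pathways with at
least ``min_hits`` (default 2) distinct metabolite hits — a guard against
over-interpreting single m/z-only assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import AdductSpec, adduct_mz, resolve_adducts
from .containers import FeatureMatrix
from .library import MetaboliteRecord

DEFAULT_TOLERANCE = 0.01  # Da
DEFAULT_MIN_HITS = 2


@dataclass(frozen=True)
class Candidate:
    """One (metabolite, adduct) assignment for a feature."""

    name: str
    formula: str
    compound_class: str
    adduct: str
    theoretical_mz: float
    mass_error: float  # observed - theoretical, Da

    @property
    def abs_error(self) -> float:
        return abs(self.mass_error)


class MassIndex:
    """Sorted index over library x adduct theoretical m/z for fast matching."""

    def __init__(
        self,
        lib: list[MetaboliteRecord],
        adducts: list[AdductSpec | str] | None = None,
    ) -> None:
        self.lib = list(lib)
        self.adducts = resolve_adducts(adducts)
        mzs, refs = [], []
        for rec in self.lib:
            for a in self.adducts:
                mzs.append(adduct_mz(rec.formula, a))
                refs.append((rec, a))
        order = np.argsort(mzs, kind="stable")
        self._mz = np.asarray(mzs)[order]
        self._refs = [refs[int(i)] for i in order]

    def query(self, mz: float, tolerance: float, ppm: bool = False) -> list[Candidate]:
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        tol = mz * tolerance * 1e-6 if ppm else tolerance
        lo = int(np.searchsorted(self._mz, mz - tol, side="left"))
        hi = int(np.searchsorted(self._mz, mz + tol, side="right"))
        cands = []
        for i in range(lo, hi):
            rec, a = self._refs[i]
            err = mz - self._mz[i]
            if abs(err) <= tol:
                cands.append(
                    Candidate(
                        name=rec.name,
                        formula=str(rec.formula),
                        compound_class=rec.compound_class,
                        adduct=a.name,
                        theoretical_mz=float(self._mz[i]),
                        mass_error=float(err),
                    )
                )
        cands.sort(key=lambda c: (c.abs_error, c.name, c.adduct))
        return cands


def match_feature(
    mz: float,
    lib: list[MetaboliteRecord],
    adducts: list[AdductSpec | str] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    ppm: bool = False,
) -> list[Candidate]:
    """All (metabolite, adduct) pairs within ``tolerance`` of ``mz``.

    Candidates are sorted by |mass error| with a deterministic (name, adduct)
    tie-break; true isomers produce equal-error candidates and are all
    returned. An empty list is a perfectly normal outcome.
    """
    return MassIndex(lib, adducts).query(mz, tolerance, ppm=ppm)


@dataclass
class AnnotationTable:
    """Per-feature candidate assignments.

    ``table`` has one row per (feature, candidate) with candidates ranked by
    |mass error| (rank 1 = best); ``is_best`` marks every rank-1 candidate —
    equal-error isomers share the rank, and the lexicographically smallest
    name carries the best flag.
    """

    table: pd.DataFrame
    n_features: int

    @property
    def n_annotated(self) -> int:
        if self.table.empty:
            return 0
        return int(self.table["feature_id"].nunique())

    @property
    def n_unannotated(self) -> int:
        return self.n_features - self.n_annotated

    def best_candidates(self) -> pd.DataFrame:
        """One row per annotated feature: the best-flagged candidate."""
        if self.table.empty:
            return self.table
        return self.table[self.table["is_best"]].set_index("feature_id")

    def annotated_features(self) -> list[str]:
        if self.table.empty:
            return []
        return list(dict.fromkeys(self.table["feature_id"]))


def annotate_matrix(
    fm: FeatureMatrix,
    lib: list[MetaboliteRecord],
    adducts: list[AdductSpec | str] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    ppm: bool = False,
) -> AnnotationTable:
    """Match every feature's consensus m/z against the library."""
    index = MassIndex(lib, adducts)
    rows = []
    for fid, mz in zip(fm.feature_ids, fm.consensus_mz):
        cands = index.query(float(mz), tolerance, ppm=ppm)
        if not cands:
            continue
        best_err = cands[0].abs_error
        for rank_pos, c in enumerate(cands):
            # equal-error candidates share rank 1; best flag on the first
            rank = 1 if np.isclose(c.abs_error, best_err, atol=1e-12) else rank_pos + 1
            rows.append(
                {
                    "feature_id": fid,
                    "feature_mz": float(mz),
                    "rank": rank,
                    "name": c.name,
                    "formula": c.formula,
                    "compound_class": c.compound_class,
                    "adduct": c.adduct,
                    "theoretical_mz": c.theoretical_mz,
                    "mass_error": c.mass_error,
                    "is_best": rank_pos == 0,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "feature_mz", "rank", "name", "formula",
            "compound_class", "adduct", "theoretical_mz", "mass_error", "is_best",
        ],
    )
    return AnnotationTable(table=table, n_features=fm.n_features)


def pathway_rollup(
    ann: AnnotationTable,
    significant_features: set[str] | list[str],
    lib: list[MetaboliteRecord],
    pathway_table: pd.DataFrame,
    min_hits: int = DEFAULT_MIN_HITS,
) -> pd.DataFrame:
    """Count distinct annotated metabolites per pathway over significant
    features; keep pathways with at least ``min_hits`` hits.

    Counting is per metabolite name, not per feature, so one metabolite hit
    by several features counts once.
    """
    sig = set(significant_features)
    # significant features without annotation simply contribute nothing
    membership = {r.name: r.pathway_ids for r in lib}
    hits: dict[str, set[str]] = {}
    if not ann.table.empty:
        sub = ann.table[ann.table["feature_id"].isin(sig)]
        for name in sub["name"].unique():
            for pw in membership.get(name, frozenset()):
                hits.setdefault(pw, set()).add(name)
    names = dict(zip(pathway_table["pathway_id"], pathway_table["name"]))
    rows = [
        {
            "pathway_id": pw,
            "pathway_name": names.get(pw, pw),
            "n_hits": len(mets),
            "metabolites": ";".join(sorted(mets)),
        }
        for pw, mets in sorted(hits.items())
        if len(mets) >= min_hits
    ]
    return pd.DataFrame(
        rows, columns=["pathway_id", "pathway_name", "n_hits", "metabolites"]
    )
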