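"""Abundance-weighted elemental stoichiometry (C:N, C:P) of the metabolome.

For each cell, the weighted sum of an element is
``sum_i count(element, formula_i) * abundance_i`` over the annotated
metabolites in scope, where abundance is the TIC-normalized feature
intensity. C:N is the ratio of the weighted carbon sum to the weighted
nitrogen sum (likewise C:P); the ratios are invariant to rescaling a
cell's abundance vector, and a zero denominator yields an explicitly
flagged undefined ratio, never an infinity. Scope defaults to features that
are both significantly regulated and annotated; equal-mass isomer
ambiguity is harmless here because isomers share a formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import AnnotationTable
from .chem import Formula, element_count
from .containers import FeatureMatrix
from .stats import t_test_feature

SCOPES = ("significant-annotated", "all-annotated")


def weighted_element_sum(
    abundances: dict[str, float] | pd.Series, formulas: dict[str, Formula], element: str
) -> float:
    """``sum_i count(element, formula_i) * abundance_i`` over the scope.

    Every metabolite in ``abundances`` must have a formula; an empty scope
    sums to 0.
    """
    total = 0.0
    items = abundances.items() if isinstance(abundances, dict) else abundances.items()
    for name, abundance in items:
        if name not in formulas:
            raise ValueError(f"metabolite {name!r} has no formula in scope")
        total += element_count(formulas[name], element) * float(abundance)
    return total


@dataclass
class ElementalRatioResult:
    """Per-cell weighted elemental sums and ratios, plus the scope used."""

    per_cell: pd.DataFrame  # cell_id, condition, weighted C/N/P, cn, cp, defined flags
    scope: str
    n_features_in_scope: int

    def defined(self, ratio: str) -> pd.DataFrame:
        flag = {"cn": "cn_defined", "cp": "cp_defined"}[ratio]
        return self.per_cell[self.per_cell[flag]]


def elemental_ratios(
    fm: FeatureMatrix,
    annotations: AnnotationTable,
    scope_features: list[str] | set[str],
    scope_name: str = "significant-annotated",
) -> ElementalRatioResult:
    """Per-cell weighted C, N, P sums and C:N / C:P ratios.

    ``scope_features`` must all be annotated; each feature contributes the
    elemental counts of its best-candidate formula weighted by the cell's
    feature intensity. Undefined ratios (zero denominator) are flagged.
    """
    feature_ids = list(fm.feature_ids)
    unknown = set(scope_features) - set(feature_ids)
    if unknown:
        raise ValueError(f"scope features not in the matrix: {sorted(unknown)[:3]}")
    scope = sorted(set(scope_features), key=feature_ids.index)
    best = annotations.best_candidates()
    missing = [f for f in scope if f not in best.index]
    if missing:
        raise ValueError(
            f"{len(missing)} feature(s) in scope lack annotations, e.g. {missing[:3]}"
        )
    counts = np.array(
        [
            [element_count(Formula.parse(best.loc[f, "formula"]), el) for f in scope]
            for el in ("C", "N", "P")
        ],
        dtype=float,
    )  # 3 x features
    X = fm.values.loc[:, scope].to_numpy(dtype=float)  # cells x features
    sums = X @ counts.T  # cells x 3
    c, n, p = sums[:, 0], sums[:, 1], sums[:, 2]
    cn_defined = n > 0
    cp_defined = p > 0
    per_cell = pd.DataFrame(
        {
            "cell_id": fm.cell_ids,
            "condition": fm.conditions.to_numpy(),
            "weighted_C": c,
            "weighted_N": n,
            "weighted_P": p,
            "cn": np.where(cn_defined, c / np.where(n > 0, n, 1.0), np.nan),
            "cp": np.where(cp_defined, c / np.where(p > 0, p, 1.0), np.nan),
            "cn_defined": cn_defined,
            "cp_defined": cp_defined,
        }
    )
    return ElementalRatioResult(
        per_cell=per_cell, scope=scope_name, n_features_in_scope=len(scope)
    )


def compare_ratios(result: ElementalRatioResult) -> pd.DataFrame:
    """Welch-test each ratio (C:N, C:P) between the two conditions.

    Cells with undefined ratios are excluded and counted. Raises when fewer
    than two defined ratios remain in either group.
    """
    conditions = list(dict.fromkeys(result.per_cell["condition"]))
    if len(conditions) != 2:
        raise ValueError("ratio comparison needs exactly two conditions")
    rows = []
    for ratio in ("cn", "cp"):
        defined = result.defined(ratio)
        groups = [
            defined.loc[defined["condition"] == cond, ratio].to_numpy()
            for cond in conditions
        ]
        n_excluded = len(result.per_cell) - len(defined)
        if any(g.size < 2 for g in groups):
            raise ValueError(
                f"ratio {ratio}: fewer than two defined values in a group"
            )
        t, df, p = t_test_feature(groups[0], groups[1])
        rows.append(
            {
                "ratio": "C:N" if ratio == "cn" else "C:P",
                f"mean_{conditions[0]}": groups[0].mean(),
                f"mean_{conditions[1]}": groups[1].mean(),
                "t": t,
                "df": df,
                "p": p,
                "n_undefined_excluded": n_excluded,
            }
        )
    return pd.DataFrame(rows)
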