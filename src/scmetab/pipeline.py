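"""Config-driven end-to-end runs and the run summary.

A run executes: filter -> TIC-normalize -> deisotope -> align -> annotate ->
differential tests -> PLS-DA (fit, permutation test, Q2) -> lipid heat-map
matrices -> elemental stoichiometry -> pathway roll-up, writing every stage
table to the output directory plus a machine-readable RunSummary. All
randomness (simulation, permutations, CV folds) fans out from one root seed
via ``numpy.random.SeedSequence``, so identical configs give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann_mod
from . import stats as stats_mod
from .io import load_spectra, read_manifest, write_feature_matrix, write_table
from .library import LIPID_CLASSES, MetaboliteRecord, builtin_library, load_library, load_pathways
from .preprocess import AlignmentParams, DEFAULT_INTENSITY_THRESHOLD, preprocess_spectra
from .simulate import SimulationConfig, simulate_experiment
from .stoichiometry import SCOPES, compare_ratios, elemental_ratios

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; mirrors the YAML config file."""

    manifest: str | None = None
    simulation: SimulationConfig | None = None
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    annotation_tolerance: float = ann_mod.DEFAULT_TOLERANCE
    annotation_ppm: bool = False
    library_path: str | None = None  # None -> packaged builtin library
    pathway_path: str | None = None
    min_hits: int = ann_mod.DEFAULT_MIN_HITS
    alpha: float = stats_mod.DEFAULT_ALPHA
    n_components: int = stats_mod.DEFAULT_N_COMPONENTS
    n_permutations: int = stats_mod.DEFAULT_N_PERMUTATIONS
    cv_folds: int = stats_mod.DEFAULT_CV_FOLDS
    plsda_scale: str = "pareto"
    ratio_scope: str = "significant-annotated"
    seed: int = 0
    output_dir: str = "scmetab_out"

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.simulation is None):
            raise ValueError("exactly one of manifest or simulation must be given")
        if self.ratio_scope not in SCOPES:
            raise ValueError(f"ratio_scope must be one of {SCOPES}")
        if self.plsda_scale not in stats_mod.SCALING_MODES:
            raise ValueError(
                f"plsda_scale must be one of {stats_mod.SCALING_MODES}"
            )
        for path_attr in ("manifest", "library_path", "pathway_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{path_attr} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: str | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation")
        simulation = SimulationConfig(**sim) if sim is not None else None
        align = AlignmentParams(**raw.get("alignment", {}))
        annotation = raw.get("annotation", {})
        stats_cfg = raw.get("stats", {})
        kwargs = dict(
            manifest=raw.get("manifest"),
            simulation=simulation,
            intensity_threshold=raw.get("filter", {}).get(
                "threshold", DEFAULT_INTENSITY_THRESHOLD
            ),
            alignment=align,
            annotation_tolerance=annotation.get("tolerance", ann_mod.DEFAULT_TOLERANCE),
            annotation_ppm=annotation.get("ppm", False),
            library_path=annotation.get("library"),
            pathway_path=annotation.get("pathways"),
            min_hits=annotation.get("min_hits", ann_mod.DEFAULT_MIN_HITS),
            alpha=stats_cfg.get("alpha", stats_mod.DEFAULT_ALPHA),
            n_components=stats_cfg.get("n_components", stats_mod.DEFAULT_N_COMPONENTS),
            n_permutations=stats_cfg.get("n_permutations", stats_mod.DEFAULT_N_PERMUTATIONS),
            cv_folds=stats_cfg.get("cv_folds", stats_mod.DEFAULT_CV_FOLDS),
            plsda_scale=stats_cfg.get("scale", "pareto"),
            ratio_scope=raw.get("stoichiometry", {}).get("scope", "significant-annotated"),
            seed=raw.get("seed", 0),
            output_dir=output_dir or raw.get("output", {}).get("dir", "scmetab_out"),
        )
        return cls(**kwargs)


@dataclass
class RunSummary:
    """One record per stage; every number is recomputable from stage files."""

    seed: int
    conditions: tuple[str, str]
    n_cells: dict[str, int]
    filter_totals: dict[str, float]
    n_peaks_pre_deisotoping: int
    n_features: int
    n_annotated: int
    n_unannotated: int
    n_significant: int
    n_significant_per_direction: dict[str, int]
    plsda_permutation_p: float
    plsda_q2: float
    plsda_explained_x: list[float]
    ratio_scope: str
    ratio_comparison: list[dict] | None
    retained_pathways: list[dict]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["conditions"] = list(self.conditions)
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def to_text(self) -> str:
        c0, c1 = self.conditions
        lines = [
            f"conditions: {c0} vs {c1} "
            f"({self.n_cells[c0]} + {self.n_cells[c1]} cells), seed {self.seed}",
            f"filtering: kept {self.filter_totals['n_peaks_kept']:.0f} of "
            f"{self.filter_totals['n_peaks_in']:.0f} peaks "
            f"({100 * self.filter_totals['fraction_intensity_retained']:.1f}% of "
            "total intensity retained)",
            f"features: {self.n_peaks_pre_deisotoping} peaks pre-deisotoping -> "
            f"{self.n_features} aligned features "
            f"({self.n_annotated} annotated, {self.n_unannotated} unannotated)",
            f"differential: {self.n_significant} significant "
            f"(higher in {c0}: {self.n_significant_per_direction[c0]}, "
            f"higher in {c1}: {self.n_significant_per_direction[c1]})",
            f"PLS-DA: permutation p = {self.plsda_permutation_p:.6g}, "
            f"Q2 = {self.plsda_q2:.4f}",
        ]
        if self.ratio_comparison:
            for row in self.ratio_comparison:
                means = [(k, v) for k, v in row.items() if k.startswith("mean_")]
                mean_txt = ", ".join(f"{k[5:]} {v:.3f}" for k, v in means)
                lines.append(
                    f"stoichiometry {row['ratio']} ({self.ratio_scope}): "
                    f"{mean_txt}, p = {row['p']:.3g}"
                )
        else:
            lines.append("stoichiometry: not computed (insufficient defined ratios)")
        lines.append(
            "pathways retained: "
            + (", ".join(f"{p['pathway_name']} ({p['n_hits']})"
                         for p in self.retained_pathways) or "none")
        )
        return "\n".join(lines) + "\n"


def _load_run_library(cfg: PipelineConfig) -> list[MetaboliteRecord]:
    if cfg.library_path is not None:
        return load_library(cfg.library_path)
    return builtin_library()


def run_pipeline(cfg: PipelineConfig) -> RunSummary:
    """Execute the full pipeline and write all artifacts to cfg.output_dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    perm_seed, cv_seed = root.spawn(2)

    lib = _load_run_library(cfg)
    pathways = load_pathways(cfg.pathway_path)

    if cfg.simulation is not None:
        spectra, truth = simulate_experiment(cfg.simulation, lib)
        truth.write(out)
    else:
        spectra = load_spectra(read_manifest(cfg.manifest))

    fm, reports = preprocess_spectra(spectra, cfg.intensity_threshold, cfg.alignment)
    write_table(reports, out / "filter_reports.tsv")
    write_feature_matrix(fm, out / "feature_matrix.csv")

    annotations = ann_mod.annotate_matrix(
        fm, lib, tolerance=cfg.annotation_tolerance, ppm=cfg.annotation_ppm
    )
    write_table(annotations.table, out / "annotations.tsv")

    diff = stats_mod.differential_features(fm, cfg.alpha)
    write_table(diff.table, out / "differential.tsv")

    plsda = stats_mod.plsda_fit(fm, cfg.n_components, scale=cfg.plsda_scale)
    plsda.permutation_p = stats_mod.plsda_permutation_test(
        fm, cfg.n_components, cfg.n_permutations,
        seed=np.random.default_rng(perm_seed), scale=cfg.plsda_scale,
    )
    plsda.q2 = stats_mod.plsda_q2(
        fm, cfg.n_components, cfg.cv_folds,
        seed=np.random.default_rng(cv_seed), scale=cfg.plsda_scale,
    )
    write_table(plsda.scores_frame(), out / "plsda_scores.tsv", index=True)

    sig_features = diff.significant_features()
    best = annotations.best_candidates()
    lipid_sig = [
        f for f in sig_features
        if f in best.index and best.loc[f, "compound_class"] in LIPID_CLASSES
    ]
    if len(lipid_sig) >= 2:
        hm = stats_mod.heatmap_data(fm, lipid_sig)
        write_table(hm.ordered(), out / "lipid_heatmap.tsv", index=True)

    annotated = set(annotations.annotated_features())
    scope = annotated if cfg.ratio_scope == "all-annotated" else (
        annotated & set(sig_features)
    )
    ratio_rows = None
    if scope:
        ratios = elemental_ratios(fm, annotations, scope, cfg.ratio_scope)
        write_table(ratios.per_cell, out / "elemental_ratios.tsv")
        try:
            ratio_rows = compare_ratios(ratios).to_dict(orient="records")
        except ValueError as exc:
            logger.warning("stoichiometry comparison skipped: %s", exc)

    pathway_hits = ann_mod.pathway_rollup(
        annotations, sig_features, lib, pathways, cfg.min_hits
    )
    write_table(pathway_hits, out / "pathway_hits.tsv")

    labels = fm.condition_labels()
    summary = RunSummary(
        seed=cfg.seed,
        conditions=(labels[0], labels[1]),
        n_cells={c: int((fm.conditions == c).sum()) for c in labels},
        filter_totals={
            "n_peaks_in": float(reports["n_peaks_in"].sum()),
            "n_peaks_kept": float(reports["n_peaks_kept"].sum()),
            "fraction_intensity_retained": float(
                reports["fraction_intensity_retained"].mean()
            ),
        },
        n_peaks_pre_deisotoping=int(reports["n_peaks_kept"].sum()),
        n_features=fm.n_features,
        n_annotated=annotations.n_annotated,
        n_unannotated=annotations.n_unannotated,
        n_significant=diff.n_significant,
        n_significant_per_direction={
            c: diff.n_significant_up_in(c) for c in labels
        },
        plsda_permutation_p=float(plsda.permutation_p),
        plsda_q2=float(plsda.q2),
        plsda_explained_x=[float(v) for v in plsda.explained_x_variance],
        ratio_scope=cfg.ratio_scope,
        ratio_comparison=ratio_rows,
        retained_pathways=pathway_hits.to_dict(orient="records"),
    )
    (out / "run_summary.json").write_text(summary.to_json())
    (out / "run_summary.txt").write_text(summary.to_text())
    return summary
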