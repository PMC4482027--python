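"""End-to-end experiment orchestration.

One experiment is the four-step procedure: preprocess (impute, optional
outlier exclusion), normalize, train-and-select a SOM over several seeded
runs, label the best map, extract class clusters, and run the requested
class comparisons.  ``run_paper_suite`` chains the full catalogue of
experiments for a dataset in dependency order: baseline all-protein maps
first, then reclusterings with the discriminant subsets those baselines
produce.

All randomness flows from explicit base seeds recorded in the report
manifest, so every table is reproducible from configuration alone.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import dataset as dio, discriminant as disc, maps as _maps, som as _som
from .classes import MouseClass
from .dataset import ExpressionDataset
from .synthetic import SyntheticConfig, generate


class StageError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ExperimentConfig:
    name: str = "experiment"
    input_path: str | None = None
    dialect: str = "csv"
    synthetic: SyntheticConfig | None = None
    classes: Sequence[str] | None = None
    proteins: Sequence[str] | None = None
    outlier_threshold: float = 0.5
    drop_flagged_mice: bool = False
    drop_mice: Sequence[str] = field(default_factory=tuple)
    side: int | str = "auto"
    n_runs: int = 10
    params: _som.TrainingParams = field(default_factory=_som.TrainingParams)
    base_seed: int = 1
    comparisons: Sequence[str] = field(default_factory=tuple)
    extra_comparisons: Mapping[str, disc.Comparison] = field(default_factory=dict)
    nominal_replicates: int = 15
    allow_missing_comparisons: bool = False
    render: bool = False


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    side: int
    selection: _som.RunSelection
    labeled: _maps.LabeledMap
    clusters: list[_maps.ClassCluster]
    discriminant: dict[str, disc.DiscriminantResult]
    protein_names: list[str]
    comparison_errors: dict[str, str]
    flagged_mice: list[str]
    dropped_mice: list[str]
    imputation_log: list

    @property
    def significant_sets(self) -> dict[str, set[str]]:
        return {k: set(v.significant) for k, v in self.discriminant.items()}

    def manifest(self) -> dict:
        cfg = self.config
        return {
            "name": cfg.name,
            "classes": list(cfg.classes) if cfg.classes else None,
            "n_proteins": len(cfg.proteins) if cfg.proteins else None,
            "side": self.side,
            "n_runs": cfg.n_runs,
            "base_seed": cfg.base_seed,
            "best_seed": self.selection.best.seed,
            "epsilon_q": self.selection.best.epsilon_q,
            "n_mixed_nodes": self.selection.best.n_mixed_nodes,
            "n_measurements_in_mixed": self.selection.best.n_measurements_in_mixed,
            "flagged_mice": self.flagged_mice,
            "dropped_mice": self.dropped_mice,
            "n_imputed": len(self.imputation_log),
            "clusters": [
                {"class": c.mouse_class.code, "n_nodes": len(c.nodes),
                 "n_measurements": c.n_measurements}
                for c in self.clusters],
            "significant_set_sizes": {k: len(v) for k, v in
                                      self.significant_sets.items()},
            "comparison_errors": self.comparison_errors,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        name = self.config.name
        self.selection.table().to_csv(outdir / f"{name}_runs.tsv",
                                      sep="\t", index=False)
        _maps.render_map(self.labeled, self.clusters,
                         outdir / f"{name}_map.txt"
                         if self.config.render else None)
        (outdir / f"{name}_map.txt").write_text(
            _maps.render_text(self.labeled))
        for cname, res in self.discriminant.items():
            res.table().to_csv(outdir / f"{name}_{cname}_discriminant.tsv",
                               sep="\t", index=False)
        (outdir / f"{name}_manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n")


def _load(cfg: ExperimentConfig) -> ExpressionDataset:
    if cfg.synthetic is not None:
        ds, _ = generate(cfg.synthetic)
        return ds
    if cfg.input_path is None:
        raise StageError("input", "no input_path and no synthetic block")
    try:
        return dio.read_expression_table(cfg.input_path, dialect=cfg.dialect)
    except Exception as e:
        raise StageError("input", str(e)) from e


def preprocess(ds: ExpressionDataset, cfg: ExperimentConfig
               ) -> tuple[ExpressionDataset, list[str], list[str], list]:
    """Outlier flagging/dropping followed by class-mean imputation."""
    flagged = dio.flag_outlier_mice(ds, cfg.outlier_threshold)
    to_drop = list(cfg.drop_mice)
    if cfg.drop_flagged_mice:
        to_drop.extend(m for m in flagged if m not in to_drop)
    if to_drop:
        ds = dio.drop_mice(ds, to_drop)
    ds, log = dio.impute_class_mean(ds)
    return ds, flagged, to_drop, log


def run_experiment(cfg: ExperimentConfig,
                   ds: ExpressionDataset | None = None) -> ExperimentReport:
    """Execute one experiment; any stage failure raises :class:`StageError`."""
    if ds is None:
        ds = _load(cfg)
    try:
        ds, flagged, dropped, log = preprocess(ds, cfg)
    except StageError:
        raise
    except Exception as e:
        raise StageError("preprocess", str(e)) from e

    try:
        sub = dio.subset(ds, classes=cfg.classes, proteins=cfg.proteins)
        sub = dio.normalize_minmax(sub)
    except Exception as e:
        raise StageError("subset", str(e)) from e

    side = (_som.choose_grid_side(len(sub.mice))
            if cfg.side == "auto" else int(cfg.side))
    try:
        selection = _som.multi_run_select(sub.values, sub.class_codes, side,
                                          n_runs=cfg.n_runs, params=cfg.params,
                                          base_seed=cfg.base_seed)
    except Exception as e:
        raise StageError("train", str(e)) from e

    best = selection.best.som
    assignment = _maps.assign_measurements(best, sub.values, sub.class_codes,
                                           sub.mouse_ids)
    labeled = _maps.label_nodes(assignment)
    clusters = _maps.extract_clusters(
        labeled, nominal_replicates=cfg.nominal_replicates)

    catalogue = {**disc.COMPARISONS, **disc.EXTRA_COMPARISONS,
                 **cfg.extra_comparisons}
    results: dict[str, disc.DiscriminantResult] = {}
    errors: dict[str, str] = {}
    for cname in cfg.comparisons:
        if cname not in catalogue:
            raise StageError("discriminant", f"unknown comparison {cname!r}")
        try:
            results[cname] = disc.discriminant_proteins(
                best, clusters, catalogue[cname], sub.protein_names)
        except ValueError as e:
            if not cfg.allow_missing_comparisons:
                raise StageError("discriminant", f"{cname}: {e}") from e
            errors[cname] = str(e)
    return ExperimentReport(cfg, side, selection, labeled, clusters,
                            results, list(sub.protein_names), errors,
                            flagged, dropped, log)


# ---------------------------------------------------------------------------
# the full experiment catalogue
# ---------------------------------------------------------------------------

#: Ad-hoc contrasts used by the mixed and multi-class experiments.
SUITE_COMPARISONS: dict[str, disc.Comparison] = {c.name: c for c in [
    disc.Comparison("NL-ms", MouseClass.from_code("c-CS-m"),
                    MouseClass.from_code("c-SC-s"), "learning, memantine vs saline baseline"),
    disc.Comparison("NL-sm", MouseClass.from_code("c-CS-s"),
                    MouseClass.from_code("c-SC-m"), "learning, saline vs memantine baseline"),
    disc.Comparison("FLvNL", MouseClass.from_code("t-CS-s"),
                    MouseClass.from_code("c-CS-s"), "failed vs normal learning"),
    disc.Comparison("FLvNLm", MouseClass.from_code("t-CS-s"),
                    MouseClass.from_code("c-CS-m"), "failed vs normal learning (memantine)"),
]}


def run_paper_suite(ds: ExpressionDataset, outdir: str | Path | None = None,
                    base_seed: int = 1, n_runs: int = 10,
                    params: _som.TrainingParams | None = None,
                    nominal_replicates: int = 15) -> dict:
    """Run the experiment catalogue on a dataset in dependency order.

    Stage 1 clusters the four control classes with the full panel, derives
    the learning-discriminant sets and their four-way intersection, and
    revalidates by reclustering with the intersection, its complement and
    the memantine-augmented subsets.  Stage 2 does the analogous loop for
    the trisomic classes.  Stage 3 mixes genotypes (five-class map, the
    failed-vs-normal-learning contrast, and the shock-context contrast).

    Returns a nested report dict; per-experiment artifacts are written
    under ``outdir`` when given.
    """
    params = params or _som.TrainingParams()
    control = [f"c-{b}-{t}" for b in ("CS", "SC") for t in ("s", "m")]
    trisomic = [f"t-{b}-{t}" for b in ("CS", "SC") for t in ("s", "m")]
    reports: dict[str, ExperimentReport] = {}
    summary: dict = {"base_seed": base_seed, "experiments": {}}

    def run(name: str, **kw) -> ExperimentReport:
        cfg = ExperimentConfig(name=name, n_runs=n_runs, params=params,
                               base_seed=base_seed,
                               nominal_replicates=nominal_replicates,
                               allow_missing_comparisons=True, **kw)
        rep = run_experiment(cfg, ds=ds)
        reports[name] = rep
        summary["experiments"][name] = rep.manifest()
        if outdir is not None:
            rep.write(outdir)
        return rep

    # --- stage 1: control classes -------------------------------------
    ctl = run("control-77", classes=control,
              comparisons=["NL", "NLm", "NL-ms", "NL-sm", "MEM-base", "MEM-end"],
              extra_comparisons=SUITE_COMPARISONS)
    sets = ctl.significant_sets
    learning = disc.set_algebra(sets, "NL & NLm & NL-ms & NL-sm") \
        if all(k in sets for k in ("NL", "NLm", "NL-ms", "NL-sm")) else set()
    summary["learning_intersection"] = sorted(learning)
    if learning:
        order = [p for p in ds.protein_names if p in learning]
        run("control-learning-subset", classes=control, proteins=order)
        complement = [p for p in ds.protein_names if p not in learning]
        if complement:
            run("control-learning-complement", classes=control, proteins=complement)
        for extra_name, extra_set in (("MEM-end", "control-learning+memend"),
                                      ("MEM-base", "control-learning+membase")):
            if extra_name in sets:
                union = learning | sets[extra_name]
                run(extra_set, classes=control,
                    proteins=[p for p in ds.protein_names if p in union])

    # --- stage 2: trisomic classes ------------------------------------
    tri = run("trisomic-77", classes=trisomic,
              comparisons=["FL", "RL", "RL-s", "tMEM-base", "tMEM-end"])
    tsets = tri.significant_sets
    rescued = disc.set_algebra(tsets, "RL & RL-s") \
        if all(k in tsets for k in ("RL", "RL-s")) else set()
    summary["rescued_intersection"] = sorted(rescued)
    if rescued and "tMEM-base" in tsets:
        union = rescued | tsets["tMEM-base"]
        run("trisomic-rescued+membase", classes=trisomic,
            proteins=[p for p in ds.protein_names if p in union])
    if rescued and "tMEM-end" in tsets:
        union = rescued | tsets["tMEM-end"]
        run("trisomic-rescued+memend", classes=trisomic,
            proteins=[p for p in ds.protein_names if p in union])

    # --- stage 3: mixed genotypes -------------------------------------
    present = {c.code for c in ds.present_classes()}
    five = [c for c in ("c-CS-s", "c-CS-m", "t-CS-m", "t-CS-s", "c-SC-s")
            if c in present]
    if len(five) >= 2:
        run("five-class-77", classes=five)
    cs_mix = [c for c in ("t-CS-s", "c-CS-s", "c-CS-m") if c in present]
    if len(cs_mix) == 3:
        mix = run("cs-mix-77", classes=cs_mix, side=8,
                  comparisons=["FLvNL", "FLvNLm"],
                  extra_comparisons=SUITE_COMPARISONS)
        msets = mix.significant_sets
        if all(k in msets for k in ("FLvNL", "FLvNLm")):
            common = disc.set_algebra(msets, "FLvNL & FLvNLm")
            summary["failed_vs_normal_intersection"] = sorted(common)
            if common:
                order = [p for p in ds.protein_names if p in common]
                run("cs-mix-subset", classes=cs_mix, side=8, proteins=order)
                if "t-CS-m" in present:
                    run("rescued-mix-subset", side=8,
                        classes=["t-CS-m", "c-CS-s", "c-CS-m"], proteins=order)
    sc = [c for c in ("t-SC-s", "t-SC-m", "c-SC-s", "c-SC-m") if c in present]
    if len(sc) == 4:
        screp = run("sc-mix-77", classes=sc)
        try:
            pooled = pooled_discriminant(screp, "t-SC-s",
                                         [c for c in sc if c != "t-SC-s"])
            summary["sc_pooled_set"] = sorted(pooled.significant)
            if pooled.significant:
                run("sc-mix-subset", classes=sc,
                    proteins=[p for p in ds.protein_names
                              if p in pooled.significant])
        except ValueError as e:
            summary["sc_pooled_error"] = str(e)

    summary["reports"] = reports
    if outdir is not None:
        clean = {k: v for k, v in summary.items() if k != "reports"}
        Path(outdir, "suite_summary.json").write_text(
            json.dumps(clean, indent=2, sort_keys=True) + "\n")
    return summary


def pooled_discriminant(report: ExperimentReport, target: str,
                        others: Sequence[str], alpha: float = 0.05,
                        mode: str = "pooled") -> disc.DiscriminantResult:
    """Contrast one class's cluster weights against several other classes.

    ``mode="pooled"`` (default) pools the other classes' cluster nodes into
    a single sample; ``mode="pairwise"`` intersects the pairwise
    significant sets.  The result is labeled with the mode used.
    """
    best = report.selection.best.som
    clusters = report.clusters
    proteins = list(report.protein_names)
    target_cls = MouseClass.from_code(target)
    wa = disc.cluster_weight_sets(best, clusters, target_cls)
    cmp = disc.Comparison(f"{target}-vs-rest[{mode}]", target_cls,
                          MouseClass.from_code(others[0]),
                          "one class vs pooled others")
    if mode == "pooled":
        wb = np.vstack([disc.cluster_weight_sets(best, clusters, c)
                        for c in others])
        pvals = {p: disc.wilcoxon_rank_sum(wa[:, j], wb[:, j])
                 for j, p in enumerate(proteins)}
        significant = {p for p, v in pvals.items() if v < alpha}
        return disc.DiscriminantResult(cmp, pvals, alpha, significant,
                                       wa.shape[0], wb.shape[0])
    if mode == "pairwise":
        sig: set[str] | None = None
        pvals = {}
        for c in others:
            wb = disc.cluster_weight_sets(best, clusters, c)
            pv = {p: disc.wilcoxon_rank_sum(wa[:, j], wb[:, j])
                  for j, p in enumerate(proteins)}
            s = {p for p, v in pv.items() if v < alpha}
            sig = s if sig is None else (sig & s)
            for p, v in pv.items():
                pvals[p] = max(pvals.get(p, 0.0), v)
        return disc.DiscriminantResult(cmp, pvals, alpha, sig or set(),
                                       wa.shape[0], -1)
    raise ValueError(f"unknown mode {mode!r}")
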