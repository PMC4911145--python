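"""End-to-end two-group comparison: screen -> test -> classify -> model.

A comparison takes per-feature curve matrices (and optional low-resolution
scalar tables) with a shared binary group labeling, and produces:

* a feature-screening report (redundant features dropped),
* per-feature interval-testing results for every requested statistic and
  basis, with IDL/LDL/NS classification,
* a univariate permutation-test table for scalar features,
* single-predictor logistic fits, dominant-predictor set-aside, LASSO
  scalar subset, and the final stepwise multiple model with RCDE,
* a run manifest (config, seeds, versions) for reproducibility.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curves import CurveMatrix, ScalarFeatureTable
from .flr import (
    FLRFit,
    PredictorSpec,
    build_predictors,
    fit_single,
    screen_dominant,
    select_scalars_lasso,
    stepwise_multiple_flr,
)
from .itp import (
    IDL,
    LDL,
    NS,
    BasisSpec,
    Classification,
    ITPResult,
    classify_feature,
    export_heatmap,
    itp_on_curves,
)
from .permtest import PermConfig, make_plan, univariate_perm_test
from .screen import ScreenResult, screen_features

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonConfig:
    """All thresholds of one comparison, with defaults matching the study
    design this pipeline implements (alpha 0.05, 10,000 permutations,
    0.8 screening correlation, 20% dominant-DE threshold, 1% minimum DE
    gain)."""

    name: str = "comparison"
    alpha: float = 0.05
    n_perm: int = 10_000
    statistics: tuple[str, ...] = ("mean_diff", "median_diff", "var_ratio")
    seed: int = 0
    basis_nodes: tuple[int, ...] = (65, 33)
    combining: str = "fisher"
    screen_threshold: float | None = 0.8
    de_threshold: float = 0.20
    min_de_gain: float = 0.01
    p_remove: float = 0.05
    cv_folds: int = 10
    skew_trigger: float = 1.0

    def perm_config(self) -> PermConfig:
        return PermConfig(
            n_perm=self.n_perm, statistics=self.statistics, seed=self.seed
        )


@dataclass
class FeatureCall:
    feature: str
    label: str  # IDL | LDL | NS
    classification: Classification | None  # the one driving predictor construction
    per_test: dict[tuple[int, str], Classification]  # (basis nodes, statistic)


@dataclass
class ComparisonReport:
    config: ComparisonConfig
    screen: ScreenResult | None
    itp_results: dict[tuple[str, int, str], ITPResult]  # (feature, nodes, statistic)
    calls: dict[str, FeatureCall]
    scalar_tests: pd.DataFrame
    single_fits: dict[str, FLRFit]
    dominant: list[str]
    lasso_selected: list[str]
    final_fit: FLRFit | None
    step_log: pd.DataFrame
    timings: pd.DataFrame

    def classification_table(self) -> pd.DataFrame:
        rows = []
        for name, call in sorted(self.calls.items()):
            c = call.classification
            sig = c.significant if c is not None else None
            rows.append(
                {
                    "feature": name,
                    "call": call.label,
                    "scale": c.scale if c is not None else "",
                    "n_significant": int(sig.sum()) if sig is not None else 0,
                    "predominant_sign": _predominant_sign(c),
                }
            )
        return pd.DataFrame(
            rows, columns=["feature", "call", "scale", "n_significant", "predominant_sign"]
        )

    def single_fit_table(self) -> pd.DataFrame:
        rows = []
        for name, f in sorted(self.single_fits.items()):
            p = f.predictors[0]
            coefs = [f.params.get(c, np.nan) for c in p.column_names()]
            sign = int(np.sign(coefs[int(np.nanargmax(np.abs(coefs)))])) if coefs else 0
            rows.append(
                {"feature": name, "kind": p.kind, "de": f.de, "sign": sign,
                 "dominant": name in self.dominant}
            )
        return pd.DataFrame(rows, columns=["feature", "kind", "de", "sign", "dominant"])


def _predominant_sign(c: Classification | None) -> int:
    if c is None or not c.significant.any():
        return 0
    s = c.signs[c.significant]
    return int(np.sign(s.sum()))


def _combine_calls(
    per_test: dict[tuple[int, str], Classification], raw_nodes: int
) -> tuple[str, Classification | None]:
    """Feature-level call across statistics and bases; localization wins.

    Significance under any statistic or basis counts. An LDL call at the
    raw basis takes priority for predictor construction, then a smoothed
    LDL, then any IDL.
    """
    ldl = [(k, c) for k, c in per_test.items() if c.label == LDL]
    if ldl:
        raw = [c for (nodes, _), c in ldl if nodes == raw_nodes]
        return LDL, raw[0] if raw else ldl[0][1]
    idl = [c for c in per_test.values() if c.label == IDL]
    if idl:
        return IDL, idl[0]
    return NS, None


def run_comparison(
    curves: dict[str, CurveMatrix],
    labels: np.ndarray,
    cfg: ComparisonConfig,
    scalars: dict[str, ScalarFeatureTable] | None = None,
) -> ComparisonReport:
    labels = np.asarray(labels).astype(int).ravel()
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (1 = group 1, 0 = group 2)")
    n1, n2 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 regions")
    scalars = scalars or {}
    timings: list[dict] = []

    # stage 1: feature screening
    t0 = time.perf_counter()
    screen = None
    active = dict(curves)
    if cfg.screen_threshold is not None and len(curves) >= 2:
        screen = screen_features(curves, threshold_corr=cfg.screen_threshold)
        active = {n: curves[n] for n in screen.retained}
        logger.info("screening kept %d/%d features", len(active), len(curves))
    timings.append({"stage": "screen", "seconds": time.perf_counter() - t0,
                    "records": len(active)})

    # stage 2: interval testing + classification
    pcfg = cfg.perm_config()
    raw_nodes = max(cfg.basis_nodes)
    itp_results: dict[tuple[str, int, str], ITPResult] = {}
    calls: dict[str, FeatureCall] = {}
    for name, cm in sorted(active.items()):
        t0 = time.perf_counter()
        per_test: dict[tuple[int, str], Classification] = {}
        for nodes in cfg.basis_nodes:
            res = itp_on_curves(
                cm, labels, pcfg, basis=BasisSpec(n_nodes=nodes), combining=cfg.combining
            )
            for stat, r in res.items():
                itp_results[(name, nodes, stat)] = r
                per_test[(nodes, stat)] = classify_feature(r, alpha=cfg.alpha)
        label, chosen = _combine_calls(per_test, raw_nodes)
        calls[name] = FeatureCall(
            feature=name, label=label, classification=chosen, per_test=per_test
        )
        timings.append({"stage": f"itp:{name}", "seconds": time.perf_counter() - t0,
                        "records": cm.n_regions})

    # stage 3: univariate tests of low-resolution features
    t0 = time.perf_counter()
    scalar_rows = []
    scalar_pvalues: dict[str, float] = {}
    if scalars:
        plan = make_plan(n1, n2, pcfg)
        for name, table in sorted(scalars.items()):
            v = np.asarray(table.values)
            res = univariate_perm_test(v[labels == 1], v[labels == 0], pcfg, plan=plan)
            p_min = np.nanmin([res.pvalues[s] for s in pcfg.statistics])
            scalar_pvalues[name] = float(p_min)
            for stat in pcfg.statistics:
                scalar_rows.append(
                    {"feature": name, "statistic": stat, "p_value": res.pvalues[stat],
                     "observed": res.observed[stat], "significant": res.pvalues[stat] < cfg.alpha}
                )
    scalar_tests = pd.DataFrame(
        scalar_rows, columns=["feature", "statistic", "p_value", "observed", "significant"]
    )
    timings.append({"stage": "scalar_tests", "seconds": time.perf_counter() - t0,
                    "records": len(scalars)})

    # stage 4: predictor construction + single fits
    t0 = time.perf_counter()
    classifications = {n: c.classification for n, c in calls.items()
                       if c.label in (IDL, LDL)}
    predictors = build_predictors(
        classifications,
        active,
        labels,
        scalars=scalars,
        scalar_pvalues=scalar_pvalues,
        alpha=cfg.alpha,
        skew_trigger=cfg.skew_trigger,
    )
    single_fits = {p.name: fit_single(p, labels) for p in predictors}
    dominant, retained = screen_dominant(single_fits, threshold=cfg.de_threshold)
    timings.append({"stage": "single_flr", "seconds": time.perf_counter() - t0,
                    "records": len(predictors)})

    # stage 5: LASSO scalar subset + stepwise multiple model
    t0 = time.perf_counter()
    pool = [p for p in predictors if p.name in retained]
    scalar_pool = [p for p in pool if p.kind == "scalar"]
    functional_pool = [p for p in pool if p.kind == "functional"]
    selected = select_scalars_lasso(
        scalar_pool, labels, cv_folds=cfg.cv_folds, seed=cfg.seed
    )
    final_fit: FLRFit | None = None
    step_log = pd.DataFrame(columns=["step", "predictor", "de", "aic"])
    if selected or functional_pool:
        final_fit, step_log = stepwise_multiple_flr(
            [p for p in scalar_pool if p.name in selected],
            functional_pool,
            labels,
            min_de_gain=cfg.min_de_gain,
            p_remove=cfg.p_remove,
        )
    timings.append({"stage": "multiple_flr", "seconds": time.perf_counter() - t0,
                    "records": len(pool)})

    return ComparisonReport(
        config=cfg,
        screen=screen,
        itp_results=itp_results,
        calls=calls,
        scalar_tests=scalar_tests,
        single_fits=single_fits,
        dominant=dominant,
        lasso_selected=selected,
        final_fit=final_fit,
        step_log=step_log,
        timings=pd.DataFrame(timings, columns=["stage", "seconds", "records"]),
    )


def write_report(report: ComparisonReport, out_dir: str | Path) -> Path:
    """Serialize all report tables as TSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.screen is not None:
        report.screen.report.to_csv(out / "screen_report.tsv", sep="\t", index=False)
    report.classification_table().to_csv(
        out / "classifications.tsv", sep="\t", index=False
    )
    heatmaps = [export_heatmap(r) for r in report.itp_results.values()]
    if heatmaps:
        pd.concat(heatmaps, ignore_index=True).to_csv(
            out / "itp_adjusted_pvalues.tsv", sep="\t", index=False
        )
    report.scalar_tests.to_csv(out / "scalar_tests.tsv", sep="\t", index=False)
    report.single_fit_table().to_csv(out / "single_flr.tsv", sep="\t", index=False)
    if report.final_fit is not None:
        report.final_fit.summary_frame().to_csv(
            out / "final_flr.tsv", sep="\t", index=False
        )
    report.step_log.to_csv(out / "flr_steps.tsv", sep="\t", index=False)
    report.timings.to_csv(out / "timings.tsv", sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "config": asdict(report.config),
        "n_features": len(report.calls),
        "dominant": report.dominant,
        "lasso_selected": report.lasso_selected,
        "final_model": (
            report.final_fit.predictor_names() if report.final_fit else []
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# config-file entry point


def load_comparison_inputs(
    config: dict, base_dir: Path
) -> tuple[dict[str, CurveMatrix], np.ndarray, dict[str, ScalarFeatureTable]]:
    """Load curves/labels/scalars declared in a parsed config mapping."""
    curves: dict[str, CurveMatrix] = {}
    for entry in config.get("curves", []):
        path = base_dir / entry["path"]
        cm = CurveMatrix.from_tsv(
            path, feature_name=entry["name"],
            measure=entry.get("measure", "weighted_average"),
        )
        curves[entry["name"]] = cm
    labels_path = base_dir / config["labels"]
    ldf = pd.read_csv(labels_path, sep="\t", dtype={"region_id": str})
    if "label" not in ldf.columns:
        raise ValueError(f"{labels_path}: needs a 'label' column")
    ref_ids = next(iter(curves.values())).region_ids if curves else ldf["region_id"].tolist()
    ldf = ldf.set_index("region_id").loc[ref_ids]
    labels = ldf["label"].astype(int).to_numpy()
    scalars: dict[str, ScalarFeatureTable] = {}
    for entry in config.get("scalars", []):
        table = ScalarFeatureTable.from_tsv(base_dir / entry["path"])
        table.feature_name = entry.get("name", table.feature_name)
        scalars[table.feature_name] = table
    return curves, labels, scalars


def run_from_config(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run one comparison from a YAML config file; returns the report dir."""
    import yaml

    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    base_dir = config_path.parent
    cfg_fields = {f for f in ComparisonConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in raw.items() if k in cfg_fields}
    for key in ("statistics", "basis_nodes"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    cfg = ComparisonConfig(**kwargs)
    curves, labels, scalars = load_comparison_inputs(raw, base_dir)
    report = run_comparison(curves, labels, cfg, scalars=scalars)
    out = Path(out_dir) if out_dir is not None else base_dir / f"run_{cfg.name}"
    return write_report(report, out)
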