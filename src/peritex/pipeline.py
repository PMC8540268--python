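"""End-to-end orchestration: simulate -> segment -> extract -> analyze -> report.

A single ``RunConfig`` carries every constant of the analysis (peritumoral
margin 10 mm, adipose window -200..-50 HU, node SUVmax cutoff 1.58 and the
GLCM-entropy stratification cutoff 3.16 as named defaults), the phantom and
discretisation settings, and the seed. A run is fully deterministic given
config + seed and writes a manifest tying every output to the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import ValidationError, write_cohort_table
from .phantom import PhantomSpec, simulate_imaging_cohort
from .roi import ATWindow, build_roi_set
from .stats import delong_paired_test, roc_summary, stratify_combination
from .texture import FEATURE_NAMES, DiscretizationSpec, extract_all

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort", "render_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic run.

    ``strat_cutoffs`` maps feature names to fixed stratification cutoffs for
    the combination table; features not listed are stratified at their
    empirical Youden cutoff.
    """

    seed: int = 0
    n_patients: int = 20
    prevalence: float = 0.4
    effect: float = 2.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    window: ATWindow = field(default_factory=ATWindow)
    margin_mm: float = 10.0
    guard_mm: float | None = None
    suv_cap: float | None = None
    disc: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    features: tuple[str, ...] | None = None  # None = all 38
    ln_cutoff: float = 1.58
    strat_cutoffs: dict = field(default_factory=lambda: {"glcm_entropy": 3.16,
                                                         "suv_hist_entropy": 1.90})
    bonferroni_m: int | None = None

    @staticmethod
    def from_yaml(path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key, cls in (("phantom", PhantomSpec), ("window", ATWindow),
                         ("disc", DiscretizationSpec)):
            if key in raw and isinstance(raw[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()}
                raw[key] = cls(**sub)
        if "features" in raw and raw["features"] is not None:
            raw["features"] = tuple(raw["features"])
        return RunConfig(**raw)

    def to_jsonable(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _extract_cohort(config: RunConfig) -> pd.DataFrame:
    """Stages 1-3: phantoms, ROI sets, features -> one row per patient."""
    cohort = simulate_imaging_cohort(
        config.n_patients, config.phantom, config.effect, config.prevalence, config.seed
    )
    rows = []
    for k, (ph, label) in enumerate(cohort):
        rois = build_roi_set(
            ph.pair, ph.tumor_mask, config.window, config.margin_mm,
            config.guard_mm, config.suv_cap,
        )
        fv = extract_all(ph.pair, rois.peritumoral_at, config.disc)
        contra = extract_all(ph.pair, rois.contralateral_at, config.disc)
        row = {"patient_id": f"S{k + 1:04d}", "label_metastasis": label,
               "visual_read": 0, "peritumoral_at_ml": rois.peritumoral_at_ml}
        row.update(fv.features)
        row.update({f"contra_{k_}": v for k_, v in contra.features.items()})
        row.update(fv.provenance)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort: pd.DataFrame,
    features: tuple[str, ...] | None = None,
    ln_cutoff: float = 1.58,
    strat_cutoffs: dict | None = None,
    bonferroni_m: int | None = None,
) -> dict:
    """The diagnostic-statistics stage on any cohort table.

    Returns a dict with a per-feature ROC summary table, combination
    stratification tables for the configured features, and paired DeLong
    comparisons of each stratified feature against the node-based scores.
    """
    labels = cohort["label_metastasis"].to_numpy(dtype=int)
    if features is None:
        features = tuple(f for f in FEATURE_NAMES if f in cohort.columns)
        if not features:
            features = tuple(
                c for c in cohort.columns
                if c not in ("patient_id", "label_metastasis", "visual_read",
                             "ln_suvmax", "group", "subtype", "tumor_size_cm")
                and pd.api.types.is_numeric_dtype(cohort[c])
            )
    strat_cutoffs = strat_cutoffs or {}
    rows = []
    summaries = {}
    for feat in features:
        vals = cohort[feat].to_numpy(dtype=float)
        if np.unique(vals).size < 2 or np.isnan(vals).any():
            continue
        s = roc_summary(vals, labels)
        summaries[feat] = s
        rows.append({"parameter": feat, "cutoff": s.cutoff, "auc": s.auc,
                     "ci_low": s.ci_low, "ci_high": s.ci_high,
                     "sensitivity_pct": s.sensitivity, "specificity_pct": s.specificity,
                     "ppv_pct": s.ppv, "npv_pct": s.npv, "n": s.n})
    # node-based reference scores
    node_scores = {}
    if "visual_read" in cohort.columns and cohort["visual_read"].nunique() > 1:
        v = cohort["visual_read"].to_numpy(dtype=float)
        s = roc_summary(v, labels)
        node_scores["visual_read"] = v
        rows.insert(0, {"parameter": "visual_analysis", "cutoff": np.nan, "auc": s.auc,
                        "ci_low": s.ci_low, "ci_high": s.ci_high,
                        "sensitivity_pct": s.sensitivity, "specificity_pct": s.specificity,
                        "ppv_pct": s.ppv, "npv_pct": s.npv, "n": s.n})
    if "ln_suvmax" in cohort.columns and cohort["ln_suvmax"].notna().sum() > 2:
        sub = cohort.loc[cohort["ln_suvmax"].notna()]
        if sub["label_metastasis"].nunique() > 1:
            s = roc_summary(sub["ln_suvmax"].to_numpy(float),
                            sub["label_metastasis"].to_numpy(int))
            node_scores["ln_suvmax"] = cohort["ln_suvmax"].to_numpy(float)
            rows.insert(1 if "visual_read" in node_scores else 0,
                        {"parameter": "ln_suvmax", "cutoff": s.cutoff, "auc": s.auc,
                         "ci_low": s.ci_low, "ci_high": s.ci_high,
                         "sensitivity_pct": s.sensitivity, "specificity_pct": s.specificity,
                         "ppv_pct": s.ppv, "npv_pct": s.npv, "n": s.n})
    table2 = pd.DataFrame(rows)

    # combination stratification + paired AUC comparisons
    strata: dict[str, pd.DataFrame] = {}
    comparisons = []
    strat_features = [f for f in strat_cutoffs if f in summaries] or (
        [max(summaries, key=lambda f: summaries[f].auc)] if summaries else []
    )
    pending = []
    for feat in strat_features:
        cut = strat_cutoffs.get(feat, summaries[feat].cutoff)
        vals = cohort[feat].to_numpy(dtype=float)
        if "visual_read" in node_scores:
            strata[f"{feat}_x_visual"] = stratify_combination(
                vals, cut, node_scores["visual_read"], labels)
        if "ln_suvmax" in node_scores:
            ln = node_scores["ln_suvmax"]
            with np.errstate(invalid="ignore"):
                node_bin = np.where(np.isnan(ln), np.nan, (ln > ln_cutoff).astype(float))
            strata[f"{feat}_x_ln_suvmax"] = stratify_combination(vals, cut, node_bin, labels)
        for name, ref in node_scores.items():
            keep = ~np.isnan(ref)
            if np.unique(labels[keep]).size < 2:
                continue
            pending.append((feat, name, vals[keep], ref[keep], labels[keep]))
    m = bonferroni_m or max(1, len(pending))
    for feat, name, a, b, lab in pending:
        cmp_ = delong_paired_test(a, b, lab, m_comparisons=m)
        comparisons.append({"feature": feat, "reference": name,
                            "auc_feature": cmp_.auc_a, "auc_reference": cmp_.auc_b,
                            "z": cmp_.z, "p": cmp_.p, "p_adjusted": cmp_.p_adjusted,
                            "m": cmp_.m_comparisons})
    return {"table2": table2, "strata": strata, "comparisons": comparisons}


def render_report(results: dict, n_patients: int | None = None) -> str:
    """Human-readable Markdown summary of an analyze stage."""
    lines = ["# Diagnostic summary", ""]
    t2: pd.DataFrame = results["table2"]
    if t2.empty:
        lines.append("no features analyzed")
        return "\n".join(lines) + "\n"
    if n_patients is not None:
        lines += [f"Cohort size: {n_patients}", ""]
    lines += ["## Diagnostic ability (per parameter)", ""]
    disp = t2.copy()
    disp["auc (95% CI)"] = disp.apply(
        lambda r: f"{r.auc:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})", axis=1)
    cols = ["parameter", "cutoff", "auc (95% CI)", "sensitivity_pct",
            "specificity_pct", "ppv_pct", "npv_pct"]
    for c in ("sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct"):
        disp[c] = disp[c].round(1)
    lines.append(disp[cols].to_markdown(index=False))
    lines.append("")
    for name, frame in results["strata"].items():
        lines += [f"## Combination stratification: {name}", ""]
        show = frame.copy()
        show["rate_pct"] = show["rate_pct"].round(1)
        lines.append(show.to_markdown(index=False))
        lines.append("")
    if results["comparisons"]:
        lines += ["## Paired AUC comparisons (DeLong, Bonferroni-adjusted)", ""]
        lines.append(pd.DataFrame(results["comparisons"]).round(4).to_markdown(index=False))
        lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write cohort CSV, analysis tables, a Markdown
    report and a JSON manifest into ``out_dir``. Returns the manifest."""
    if config.window.hu_low >= config.window.hu_high:  # ATWindow also validates
        raise ValidationError("hu_low must be < hu_high")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    cohort = _extract_cohort(config)
    stages["simulate_extract"] = {"patients": len(cohort)}
    write_cohort_table(cohort, out / "cohort_features.csv")

    results = analyze_cohort(cohort, config.features, config.ln_cutoff,
                             config.strat_cutoffs, config.bonferroni_m)
    results["table2"].to_csv(out / "diagnostic_ability.csv", index=False)
    for name, frame in results["strata"].items():
        frame.to_csv(out / f"stratification_{name}.csv", index=False)
    with open(out / "comparisons.json", "w") as fh:
        json.dump(results["comparisons"], fh, indent=2)
    stages["analyze"] = {"parameters": len(results["table2"]),
                         "strat_tables": len(results["strata"])}

    (out / "report.md").write_text(render_report(results, n_patients=len(cohort)))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_jsonable(),
        "stages": stages,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
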