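"""End-to-end orchestration: simulate -> fit -> summarize -> analyze -> report.

Every stage reads and writes plain files under the run's output
directory, so stages can be re-run individually from the CLI; a
manifest records every emitted file with its content hash. Re-running
with an identical configuration reproduces all outputs bit-for-bit.
"""

from __future__ import annotations

import json
import math
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom, stats as st
from .histogram import METRIC_NAMES, metric_column, summarize_lesion, COLUMN_DICTIONARY
from .io import (COHORT_COLUMNS, METRICS_COLUMNS, file_sha256, load_nifti,
                 save_nifti, validate_columns, write_json)
from .models import MAP_NAMES, fit_volume
from .schemes import FULL_SCHEME, read_bval, write_bval

__all__ = ["RunConfig", "RunManifest", "run_end_to_end",
           "stage_simulate", "stage_fit", "stage_summarize",
           "stage_analyze", "stage_report"]

#: parameter-map -> model grouping used for model-level combinations
MODEL_PARAMS = {
    "Mono": ("Mono-ADC",),
    "IVIM": ("IVIM-D", "IVIM-Dstar", "IVIM-f"),
    "DKI": ("DKI-Dapp", "DKI-Kapp"),
}


@dataclass
class RunConfig:
    """Fully serializable run configuration."""

    seed: int = 0
    n_lesions: int = 20          # analyzed (post-exclusion) lesions
    snr: float = 50.0            # inf for noiseless
    grid: int = 32               # in-plane mask grid (voxels)
    voxel_mm: float = 1.5        # in-plane voxel size for cm -> voxel
    alpha: float = st.DEFAULT_ALPHA
    reader_noise_frac: float = 0.05  # second-reader SD as fraction of metric SD
    out_dir: str = "dwihist_run"
    cohort: phantom.CohortConfig = field(default_factory=phantom.CohortConfig)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    """Per-stage file inventory with hashes, timing and warnings."""

    stages: dict = field(default_factory=dict)

    def record(self, stage: str, files: list, seconds: float, warnings=()):
        self.stages[stage] = {
            "files": {os.fspath(f): file_sha256(f) for f in files},
            "wall_seconds": round(seconds, 3),
            "warnings": list(warnings),
        }

    @property
    def all_files(self) -> set:
        return {f for s in self.stages.values() for f in s["files"]}

    def save(self, path):
        write_json(path, self.stages)


def _lesion_dir(out: Path, lesion_id: int) -> Path:
    return out / "lesions" / f"lesion_{lesion_id:03d}"


def _diameter_voxels(cfg: RunConfig, diameter_cm: float) -> float:
    d = diameter_cm * 10.0 / cfg.voxel_mm
    return float(np.clip(d, 4, cfg.grid - 4))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> list:
    """Sample the cohort, apply screening exclusions, emit DWI phantoms.

    Screens a pool sized so that, after the exclusion filter, at least
    ``cfg.n_lesions`` lesions remain, then keeps the first
    ``cfg.n_lesions`` of them.
    """
    if cfg.n_lesions <= 0:
        raise ValueError("simulate: configuration requests zero lesions")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    ss = np.random.SeedSequence(cfg.seed)
    cohort_seed, *lesion_seeds = ss.spawn(1 + 4 * cfg.n_lesions)

    retention = 143 / 216  # expected survival of the screening stage
    n_screened = max(cfg.n_lesions + 4, int(math.ceil(cfg.n_lesions / retention * 1.25)))
    cohort_cfg = phantom.CohortConfig(**{**asdict_cohort(cfg.cohort),
                                         "n_screened": n_screened})
    screened = phantom.sample_cohort(cohort_cfg, seed=cohort_seed)
    audit = phantom.apply_exclusion_filter(screened)
    if audit.n_retained < cfg.n_lesions:
        raise RuntimeError("simulate: screening pool too small after exclusions")
    retained = audit.retained[:cfg.n_lesions]

    screened_frame = phantom.cohort_to_frame(screened)
    screened_frame.to_csv(out / "cohort_screened.csv")
    write_json(out / "exclusion_audit.json", {
        "n_screened": audit.n_screened,
        "counts": audit.counts,
        "n_retained": audit.n_retained,
        "analyzed": [r.id for r in retained],
    })
    cohort_frame = phantom.cohort_to_frame(retained)
    cohort_frame.to_csv(out / "cohort.csv")
    files += [out / "cohort_screened.csv", out / "exclusion_audit.json",
              out / "cohort.csv"]

    noise = phantom.NoiseModel(snr=cfg.snr) if math.isfinite(cfg.snr) \
        else phantom.NoiseModel(snr=math.inf)
    for j, rec in enumerate(retained):
        try:
            mask_seed, field_seed, noise_seed, _ = (
                s.generate_state(1)[0] % (2 ** 31 - 1)
                for s in lesion_seeds[4 * j:4 * j + 4])
            d_vox = _diameter_voxels(cfg, rec.max_diameter)
            necrotic = 0.3 if rec.signal_label == 3 else 0.0  # rim lesions
            mask = phantom.render_lesion_mask(
                rec.shape_label, d_vox, (cfg.grid, cfg.grid),
                seed=mask_seed, necrotic_fraction=necrotic)
            fields = phantom.make_truth_fields(rec, (cfg.grid, cfg.grid),
                                               seed=field_seed)
            data = phantom.simulate_dwi_series(fields, mask, FULL_SCHEME,
                                               noise, seed=noise_seed)
            ldir = _lesion_dir(out, rec.id)
            ldir.mkdir(parents=True, exist_ok=True)
            save_nifti(ldir / "dwi.nii.gz", data)
            write_bval(ldir / "dwi.bval", FULL_SCHEME)
            save_nifti(ldir / "mask.nii.gz", mask[..., None])
            for key, fld in fields.items():
                save_nifti(ldir / f"truth_{key}.nii.gz", fld[..., None])
            files += [ldir / "dwi.nii.gz", ldir / "dwi.bval",
                      ldir / "mask.nii.gz"]
            files += [ldir / f"truth_{k}.nii.gz" for k in fields]
        except Exception as exc:
            raise RuntimeError(f"simulate: failed at lesion {rec.id}") from exc
    write_json(out / "run_config.json", cfg.to_dict())
    files.append(out / "run_config.json")
    return files


def asdict_cohort(c: phantom.CohortConfig) -> dict:
    d = asdict(c)
    d["parameters"] = c.parameters  # keep the dataclass, not its dict form
    return d


def stage_fit(cfg: RunConfig) -> list:
    """Voxel-wise fits of all three models inside every lesion ROI."""
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "cohort.csv", index_col=0)
    files = []
    for lesion_id in cohort.index:
        try:
            ldir = _lesion_dir(out, lesion_id)
            data, _ = load_nifti(ldir / "dwi.nii.gz")
            mask, _ = load_nifti(ldir / "mask.nii.gz")
            scheme = read_bval(ldir / "dwi.bval")
            maps = fit_volume(data, scheme, mask.astype(bool))
            mdir = out / "maps" / f"lesion_{lesion_id:03d}"
            mdir.mkdir(parents=True, exist_ok=True)
            for name in MAP_NAMES:
                save_nifti(mdir / f"{name}.nii.gz", maps.maps[name])
                files.append(mdir / f"{name}.nii.gz")
            quality = sum(maps.valid[n].astype(np.uint8) for n in MAP_NAMES)
            save_nifti(mdir / "fit_quality.nii.gz", quality)
            files.append(mdir / "fit_quality.nii.gz")
        except Exception as exc:
            raise RuntimeError(f"fit: failed at lesion {lesion_id}") from exc
    write_json(out / "fit_config.json", {
        "scheme": list(FULL_SCHEME.values),
        "models": list(MODEL_PARAMS),
        "diffusivity_units": "1e-3 mm^2/s",
    })
    files.append(out / "fit_config.json")
    return files


def stage_summarize(cfg: RunConfig) -> list:
    """ROI histogram metrics for every lesion (wide + long tables)."""
    from .models import ParameterMapSet

    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "cohort.csv", index_col=0)
    rows = []
    for lesion_id in cohort.index:
        try:
            mdir = out / "maps" / f"lesion_{lesion_id:03d}"
            ldir = _lesion_dir(out, lesion_id)
            mask, _ = load_nifti(ldir / "mask.nii.gz")
            mask = mask.astype(bool)
            maps, valid = {}, {}
            for name in MAP_NAMES:
                arr, _ = load_nifti(mdir / f"{name}.nii.gz")
                maps[name] = arr
                valid[name] = np.isfinite(arr)
            mset = ParameterMapSet(maps=maps, valid=valid, mask=mask)
            rows.append(summarize_lesion(mset, lesion_id=lesion_id))
        except Exception as exc:
            raise RuntimeError(f"summarize: failed at lesion {lesion_id}") from exc
    wide = pd.DataFrame(rows)
    wide.index.name = "id"
    wide.to_csv(out / "metrics_wide.csv")
    long = wide.reset_index().melt(id_vars="id", var_name="metric",
                                   value_name="value")
    long.to_csv(out / "metrics_long.csv", index=False)
    write_json(out / "column_dictionary.json", COLUMN_DICTIONARY)
    return [out / "metrics_wide.csv", out / "metrics_long.csv",
            out / "column_dictionary.json"]


def stage_analyze(cfg: RunConfig) -> list:
    """The statistical battery over all eight contrasts."""
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "cohort.csv", index_col=0)
    validate_columns(cohort, COHORT_COLUMNS, "cohort table")
    wide = pd.read_csv(out / "metrics_wide.csv", index_col=0)
    validate_columns(wide, METRICS_COLUMNS, "metrics table")
    labels = st.contrast_labels(cohort)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[-1])

    comparisons, auc_rows, combo_rows, delong_rows = [], [], [], []
    def _sd(x):
        return float(np.std(x, ddof=1)) if x.size > 1 else np.nan

    for contrast in st.CONTRASTS:
        y = labels[contrast].to_numpy()
        if min((y == 1).sum(), (y == 0).sum()) < 2:  # tiny-run degeneracy
            continue
        auc_table = pd.DataFrame(index=list(METRIC_NAMES),
                                 columns=list(MAP_NAMES), dtype=float)
        for map_name in MAP_NAMES:
            for metric in METRIC_NAMES:
                col = wide[metric_column(map_name, metric)].to_numpy()
                ok = np.isfinite(col)
                mw = st.mann_whitney(col[ok & (y == 1)], col[ok & (y == 0)],
                                     alpha=cfg.alpha)
                rho = st.spearman_correlation(col[ok], y[ok], alpha=cfg.alpha)
                roc = st.roc_auc_single(col[ok], y[ok],
                                        predictor=metric_column(map_name, metric))
                auc_table.loc[metric, map_name] = roc.auc
                comparisons.append({
                    "contrast": contrast, "map": map_name, "metric": metric,
                    "mean_pos": col[ok & (y == 1)].mean(),
                    "sd_pos": _sd(col[ok & (y == 1)]),
                    "mean_neg": col[ok & (y == 0)].mean(),
                    "sd_neg": _sd(col[ok & (y == 0)]),
                    "U": mw.statistic, "p": mw.p_value,
                    "significant": mw.significant,
                    "spearman_rho": rho.statistic, "spearman_p": rho.p_value,
                    "auc": roc.auc, "auc_p": roc.p_value,
                })
        best = st.select_best_metric_per_parameter(auc_table)
        for map_name in MAP_NAMES:
            for metric in METRIC_NAMES:
                auc_rows.append({"contrast": contrast, "map": map_name,
                                 "metric": metric,
                                 "auc": auc_table.loc[metric, map_name],
                                 "best_for_map": best[map_name] == metric})
        # model-level logistic combinations from the selected metrics
        if min((y == 1).sum(), (y == 0).sum()) < 3:
            continue  # too few subjects per class to combine models
        model_scores = {}
        for model, params in MODEL_PARAMS.items():
            cols = [metric_column(p, best[p]) for p in params]
            X = wide[cols]
            scores, roc, _, sep = st.fit_logistic_combination(
                X, y, predictor_name=f"{model} model")
            model_scores[model] = scores
            combo_rows.append({"contrast": contrast, "model": model,
                               "predictors": "+".join(cols), "auc": roc.auc,
                               "auc_p": roc.p_value, "separation": sep})
        all_cols = [metric_column(p, best[p]) for p in MAP_NAMES]
        scores3, roc3, _, sep3 = st.fit_logistic_combination(
            wide[all_cols], y, predictor_name="three models")
        combo_rows.append({"contrast": contrast, "model": "Three models",
                           "predictors": "+".join(all_cols), "auc": roc3.auc,
                           "auc_p": roc3.p_value, "separation": sep3})
        for model, scores in model_scores.items():
            dl = st.delong_compare(scores3, scores, y)
            delong_rows.append({"contrast": contrast,
                                "comparison": f"Three models vs {model}",
                                "auc_combined": dl.auc_a, "auc_single": dl.auc_b,
                                "difference": dl.difference, "z": dl.z,
                                "p": dl.p_value})

    # morphology contingency tables (shape / margin / signal x contrast)
    morph_rows = []
    for contrast in st.CONTRASTS:
        y = labels[contrast].to_numpy()
        if y.min() == y.max():
            continue
        for feature in ("shape_label", "margin_label", "signal_label"):
            codes = cohort[feature].to_numpy()
            try:
                res = st.chi_squared_morphology(codes, y)
            except ValueError:
                continue  # degenerate table in a tiny run
            morph_rows.append({"contrast": contrast, "feature": feature,
                               "chi2": res.statistic, "p": res.p_value,
                               "dof": res.dof,
                               "low_expected": res.low_expected,
                               "significant": res.p_value < cfg.alpha})

    # two-reader agreement on representative mean/median metrics
    icc_rows = []
    for map_name in MAP_NAMES:
        for metric in ("mean", "median"):
            col = wide[metric_column(map_name, metric)].dropna().to_numpy()
            if col.size < 5 or np.ptp(col) == 0:
                continue
            sd = col.std(ddof=1)
            reader2 = phantom.simulate_second_reader(
                col, cfg.reader_noise_frac * sd,
                seed=rng.integers(0, 2 ** 31 - 1))
            icc = st.icc_two_reader(col, reader2)
            icc_rows.append({"map": map_name, "metric": metric,
                             "icc": icc.icc, "ci_low": icc.ci95[0],
                             "ci_high": icc.ci95[1], "band": icc.band})

    # normality screen of every metric over the cohort
    norm_rows = []
    for column in METRICS_COLUMNS:
        col = wide[column].dropna().to_numpy()
        if col.size >= 3 and np.ptp(col) > 0:
            ks = st.ks_normality(col, alpha=cfg.alpha)
            norm_rows.append({"metric": column, "statistic": ks.statistic,
                              "p": ks.p_value, "normal": not ks.significant})

    tables = {
        "group_comparisons.csv": pd.DataFrame(comparisons),
        "auc_table.csv": pd.DataFrame(auc_rows),
        "combined_models.csv": pd.DataFrame(combo_rows),
        "delong.csv": pd.DataFrame(delong_rows),
        "morphology_chi2.csv": pd.DataFrame(morph_rows),
        "icc.csv": pd.DataFrame(icc_rows),
        "normality.csv": pd.DataFrame(norm_rows),
    }
    adir = out / "analysis"
    adir.mkdir(exist_ok=True)
    files = []
    for name, frame in tables.items():
        frame.to_csv(adir / name, index=False)
        files.append(adir / name)
    write_json(adir / "analysis_summary.json",
               {name: frame.to_dict(orient="records")
                for name, frame in tables.items()})
    files.append(adir / "analysis_summary.json")
    return files


def stage_report(cfg: RunConfig) -> list:
    """Fitted-vs-truth recovery report and the run manifest."""
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "cohort.csv", index_col=0)
    rows = []
    for lesion_id in cohort.index:
        ldir = _lesion_dir(out, lesion_id)
        mdir = out / "maps" / f"lesion_{lesion_id:03d}"
        mask, _ = load_nifti(ldir / "mask.nii.gz")
        mask = mask.astype(bool)
        row = {"id": lesion_id}
        for truth_key, map_name in (("D", "IVIM-D"), ("Dstar", "IVIM-Dstar"),
                                    ("f", "IVIM-f"), ("K", "DKI-Kapp"),
                                    ("D", "DKI-Dapp")):
            truth, _ = load_nifti(ldir / f"truth_{truth_key}.nii.gz")
            fitted, _ = load_nifti(mdir / f"{map_name}.nii.gz")
            scale = 1e3 if map_name not in ("IVIM-f", "DKI-Kapp") else 1.0
            t = np.median(truth[mask]) * scale
            sel = mask & np.isfinite(fitted)
            f_med = np.median(fitted[sel]) if sel.any() else np.nan
            row[f"true_{map_name}"] = t
            row[f"fitted_{map_name}"] = f_med
            row[f"relerr_{map_name}"] = abs(f_med - t) / abs(t)
        rows.append(row)
    report = pd.DataFrame(rows).set_index("id")
    report.to_csv(out / "recovery_report.csv")
    return [out / "recovery_report.csv"]


_STAGES = (("simulate", stage_simulate), ("fit", stage_fit),
           ("summarize", stage_summarize), ("analyze", stage_analyze),
           ("report", stage_report))


def run_end_to_end(cfg: RunConfig) -> RunManifest:
    """Run all stages in order; the manifest lists every emitted file."""
    manifest = RunManifest()
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        files = fn(cfg)
        manifest.record(name, files, time.perf_counter() - t0)
    manifest.save(Path(cfg.out_dir) / "manifest.json")
    return manifest
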