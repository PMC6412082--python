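"""End-to-end orchestration: simulate -> volumes -> train -> predict -> stats -> report.

Stages run in order under a single master seed; each stage is keyed by a
content hash of its configuration and inputs, and a stage whose key and
outputs are unchanged is skipped on re-runs. The manifest records seeds,
stage keys and output hashes so every number in the report is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import model as mdl
from . import stats as st
from . import synthetic as syn
from . import volumes as vo

logger = logging.getLogger(__name__)

STAGES = ("simulate", "volumes", "train", "predict", "stats", "report")

EXIT_OK, EXIT_VALIDATION, EXIT_STAGE = 0, 2, 3


class ValidationError(ValueError):
    """Configuration or input-contract failure (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class RunConfig:
    outdir: Path
    training_cohort: syn.CohortSpec
    test_cohort: syn.CohortSpec
    atrophy_model: syn.AtrophyModel
    seed: int = 0
    n_folds: int = 10
    n_perm: int = 0
    scale_mode: str = "by_voxel_count"
    hyper: str = "optimize"
    mask_threshold: float = 0.05
    analyses: tuple[str, ...] = ("group", "bmi", "iq", "gm", "wm", "icv", "interaction")
    patient_label: str | None = None
    make_figures: bool = False

    @classmethod
    def from_dict(cls, d: Mapping, outdir=None) -> "RunConfig":
        d = dict(d)
        out = Path(outdir or d.pop("outdir"))
        seed = int(d.pop("seed", 0))
        tr = dict(d.pop("training_cohort"))
        te = dict(d.pop("test_cohort"))
        tr.setdefault("seed", seed)
        te.setdefault("seed", seed + 1)
        model_cfg = d.pop("model", {})
        return cls(
            outdir=out,
            training_cohort=syn.CohortSpec.from_dict(tr),
            test_cohort=syn.CohortSpec.from_dict(te),
            atrophy_model=syn.AtrophyModel.from_dict(d.pop("atrophy_model", {})),
            seed=seed,
            n_folds=int(model_cfg.get("folds", 10)),
            n_perm=int(model_cfg.get("n_perm", 0)),
            scale_mode=model_cfg.get("scale_mode", "by_voxel_count"),
            hyper=model_cfg.get("hyper", "optimize"),
            mask_threshold=float(model_cfg.get("mask_threshold", 0.05)),
            analyses=tuple(d.pop("analyses", ("group", "bmi", "iq", "gm", "wm", "icv", "interaction"))),
            patient_label=d.pop("patient_label", None),
            make_figures=bool(d.pop("make_figures", False)),
        )

    @classmethod
    def from_file(cls, path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if seed is not None:
            d["seed"] = seed
        return cls.from_dict(d, outdir=outdir)

    def config_digest(self) -> str:
        def enc(obj):
            if isinstance(obj, np.ndarray):
                return hashlib.sha256(np.ascontiguousarray(obj).tobytes()).hexdigest()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, Mapping):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        payload = json.dumps(enc(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _cohort_paths(outdir: Path) -> dict[str, Path]:
    return {
        "training_csv": outdir / "training_cohort.csv",
        "test_csv": outdir / "test_cohort.csv",
        "volumes_dir": outdir / "volumes",
        "volumes_csv": outdir / "volumes.csv",
        "mask": outdir / "mask.nii.gz",
        "cv_json": outdir / "cv_metrics.json",
        "model": outdir / "model.npz",
        "predictions_csv": outdir / "predictions.csv",
        "stats_csv": outdir / "stats.csv",
        "report_md": outdir / "report.md",
        "manifest": outdir / "manifest.json",
    }


def _stage_key(name: str, config: RunConfig, input_hashes: Mapping[str, str]) -> str:
    payload = json.dumps(
        {"stage": name, "config": config.config_digest(), "inputs": dict(sorted(input_hashes.items()))},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_manifest(path: Path) -> dict:
    if path.exists():
        with open(path) as fh:
            return json.load(fh)
    return {"stages": {}}


def _stage_fresh(manifest: dict, name: str, key: str, outputs: list[Path]) -> bool:
    prev = manifest["stages"].get(name)
    if not prev or prev["key"] != key:
        return False
    for p, h in prev["outputs"].items():
        if not Path(p).exists() or _file_hash(Path(p)) != h:
            return False
    return True


def _record_stage(manifest: dict, name: str, key: str, outputs: list[Path], skipped: bool) -> None:
    manifest["stages"][name] = {
        "key": key,
        "outputs": {str(p): _file_hash(p) for p in outputs},
        "skipped": skipped,
    }


def _map_paths(volumes_dir: Path, subject_id: str) -> dict[str, Path]:
    return {t: volumes_dir / f"{subject_id}_{t}.nii.gz" for t in ("gm", "wm", "csf")}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, manifest: dict) -> None:
    paths = _cohort_paths(config.outdir)
    key = _stage_key("simulate", config, {})
    outputs = [paths["training_csv"], paths["test_csv"]]
    if _stage_fresh(manifest, "simulate", key, outputs):
        logger.info("simulate: cached, skipping")
        _record_stage(manifest, "simulate", key, outputs, skipped=True)
        return
    paths["volumes_dir"].mkdir(parents=True, exist_ok=True)
    for role, spec, csv_path in (
        ("training", config.training_cohort, paths["training_csv"]),
        ("test", config.test_cohort, paths["test_csv"]),
    ):
        subjects = syn.generate_cohort_table(spec)
        frame = syn.cohort_to_frame(subjects)
        frame.insert(1, "role", role)
        frame.to_csv(csv_path, index=False)
        group_index = {g: i for i, g in enumerate(spec.n_per_group)}
        offset = 0 if role == "training" else 1000
        for s in subjects:
            gi = group_index[s.group_label] + offset
            si = int(s.subject_id.rsplit("_", 1)[1])
            seed = syn.subject_map_seed(spec.seed, gi, si)
            gm, wm, csf = syn.generate_tissue_maps(s, config.atrophy_model, seed)
            mp = _map_paths(paths["volumes_dir"], f"{role}_{s.subject_id}")
            for tissue, vol in zip(("gm", "wm", "csf"), (gm, wm, csf)):
                vo.write_volume(vol, mp[tissue])
    _record_stage(manifest, "simulate", key, outputs, skipped=False)


def _read_cohort(csv_path: Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def _subject_maps(config: RunConfig, frame: pd.DataFrame) -> list[dict[str, Path]]:
    vol_dir = _cohort_paths(config.outdir)["volumes_dir"]
    out = []
    for _, row in frame.iterrows():
        mp = _map_paths(vol_dir, f"{row['role']}_{row['subject_id']}")
        for tissue, p in mp.items():
            if not p.exists():
                raise ValidationError(
                    f"missing {tissue} volume for subject {row['subject_id']}: {p}"
                )
        out.append(mp)
    return out


def stage_volumes(config: RunConfig, manifest: dict) -> None:
    paths = _cohort_paths(config.outdir)
    frames = [_read_cohort(paths["training_csv"]), _read_cohort(paths["test_csv"])]
    cohort = pd.concat(frames, ignore_index=True)
    key = _stage_key("volumes", config, {
        "training_csv": _file_hash(paths["training_csv"]),
        "test_csv": _file_hash(paths["test_csv"]),
    })
    outputs = [paths["volumes_csv"]]
    if _stage_fresh(manifest, "volumes", key, outputs):
        logger.info("volumes: cached, skipping")
        _record_stage(manifest, "volumes", key, outputs, skipped=True)
        return
    rows = []
    for (_, row), mp in zip(cohort.iterrows(), _subject_maps(config, cohort)):
        gm, wm, csf = (vo.read_volume(mp[t]) for t in ("gm", "wm", "csf"))
        gv, wv, cv = vo.tissue_volume(gm), vo.tissue_volume(wm), vo.tissue_volume(csf)
        rows.append({
            "subject_id": row["subject_id"], "role": row["role"], "group": row["group"],
            "gm_ml": gv, "wm_ml": wv, "csf_ml": cv, "icv_ml": gv + wv + cv,
        })
    pd.DataFrame(rows).to_csv(paths["volumes_csv"], index=False)
    _record_stage(manifest, "volumes", key, outputs, skipped=False)


def _features_for(config: RunConfig, frame: pd.DataFrame, mask: vo.Volume3D) -> list[vo.FeatureVector]:
    feats = []
    for (_, row), mp in zip(frame.iterrows(), _subject_maps(config, frame)):
        gm, wm = vo.read_volume(mp["gm"]), vo.read_volume(mp["wm"])
        f = vo.vectorize_concat(gm, wm, mask)
        f.subject_id = row["subject_id"]
        feats.append(f)
    return feats


def stage_train(config: RunConfig, manifest: dict) -> None:
    paths = _cohort_paths(config.outdir)
    train_frame = _read_cohort(paths["training_csv"])
    key = _stage_key("train", config, {"training_csv": _file_hash(paths["training_csv"])})
    outputs = [paths["mask"], paths["cv_json"], paths["model"]]
    if _stage_fresh(manifest, "train", key, outputs):
        logger.info("train: cached, skipping")
        _record_stage(manifest, "train", key, outputs, skipped=True)
        return
    maps = _subject_maps(config, train_frame)
    gms = [vo.read_volume(mp["gm"]) for mp in maps]
    wms = [vo.read_volume(mp["wm"]) for mp in maps]
    mask = vo.cohort_mask(gms, wms, threshold=config.mask_threshold)
    vo.write_volume(mask, paths["mask"])
    feats = _features_for(config, train_frame, mask)
    ages = train_frame["age"].to_numpy(dtype=float)
    kern = mdl.build_kernel(feats, scale_mode=config.scale_mode)
    cv = mdl.crossvalidate(kern, ages, seed=config.seed, n_folds=config.n_folds,
                           hyper=config.hyper)
    perm_p = None
    if config.n_perm > 0:
        perm = mdl.permutation_test(kern, ages, n_perm=config.n_perm, seed=config.seed,
                                    n_folds=config.n_folds, hyper=config.hyper)
        perm_p = perm.p
    with open(paths["cv_json"], "w") as fh:
        json.dump({
            "r": cv.r, "r2": cv.r2, "mae": cv.mae, "rmse": cv.rmse,
            "perm_p": perm_p, "n": int(ages.size), "n_folds": config.n_folds,
            "seed": config.seed,
        }, fh, indent=2, sort_keys=True)
    final = mdl.fit_gpr(kern, ages, hyper=config.hyper)
    mdl.save_model(final, paths["model"])
    _record_stage(manifest, "train", key, outputs, skipped=False)


def stage_predict(config: RunConfig, manifest: dict) -> None:
    paths = _cohort_paths(config.outdir)
    key = _stage_key("predict", config, {
        "model": _file_hash(paths["model"]),
        "test_csv": _file_hash(paths["test_csv"]),
        "mask": _file_hash(paths["mask"]),
    })
    outputs = [paths["predictions_csv"]]
    if _stage_fresh(manifest, "predict", key, outputs):
        logger.info("predict: cached, skipping")
        _record_stage(manifest, "predict", key, outputs, skipped=True)
        return
    test_frame = _read_cohort(paths["test_csv"])
    train_frame = _read_cohort(paths["training_csv"])
    mask = vo.read_volume(paths["mask"])
    model = mdl.load_model(paths["model"])
    test_feats = _features_for(config, test_frame, mask)
    train_feats = _features_for(config, train_frame, mask)
    cross = mdl.build_cross_kernel(test_feats, train_feats, scale_mode=model.scale_mode)
    records = mdl.predict_gpr(model, cross,
                              subject_ids=test_frame["subject_id"].tolist(),
                              chronological_ages=test_frame["age"].to_numpy(dtype=float))
    mdl.predictions_to_frame(records).to_csv(paths["predictions_csv"], index=False)
    _record_stage(manifest, "predict", key, outputs, skipped=False)


def _joined_test_table(paths: Mapping[str, Path]) -> pd.DataFrame:
    preds = pd.read_csv(paths["predictions_csv"])
    cohort = pd.read_csv(paths["test_csv"])
    vols = pd.read_csv(paths["volumes_csv"])
    out = preds.merge(cohort.drop(columns=["age"]), on="subject_id")
    return out.merge(vols[["subject_id", "gm_ml", "wm_ml", "icv_ml"]], on="subject_id")


def stage_stats(config: RunConfig, manifest: dict) -> None:
    paths = _cohort_paths(config.outdir)
    key = _stage_key("stats", config, {
        "predictions_csv": _file_hash(paths["predictions_csv"]),
        "volumes_csv": _file_hash(paths["volumes_csv"]),
    })
    outputs = [paths["stats_csv"]]
    if _stage_fresh(manifest, "stats", key, outputs):
        logger.info("stats: cached, skipping")
        _record_stage(manifest, "stats", key, outputs, skipped=True)
        return
    table = _joined_test_table(paths)
    y = table["brain_pad"].to_numpy(dtype=float)
    groups = table["group"].tolist()
    _, plabel = st._group_indicator(groups, config.patient_label)
    is_patient = np.asarray([g == plabel for g in groups])
    rows: list[dict] = []

    def add(analysis: str, term: str, gc: st.GroupComparison) -> None:
        rows.append({
            "analysis": analysis, "term": term, "effect": gc.effect, "se": gc.se,
            "ci_lo": gc.ci95[0], "ci_hi": gc.ci95[1], "stat": gc.t, "df": gc.df,
            "p": gc.p,
        })

    covariate_cols = {"bmi": "bmi", "iq": "iq", "gm": "gm_ml", "wm": "wm_ml", "icv": "icv_ml"}
    if "group" in config.analyses:
        add("group", "group", st.t_test_pooled(y[is_patient], y[~is_patient]))
    for name, col in covariate_cols.items():
        if name not in config.analyses:
            continue
        cov = table[col].to_numpy(dtype=float)
        fit = st.adjusted_group_effect(y, groups, {name: cov}, patient_label=plabel)
        add(f"group_adj_{name}", "group", fit.group_comparison())
        ts = fit.terms[name]
        rows.append({
            "analysis": f"group_adj_{name}", "term": name, "effect": ts.beta,
            "se": ts.se, "ci_lo": ts.ci95[0], "ci_hi": ts.ci95[1], "stat": ts.t,
            "df": fit.n - len(fit.terms), "p": ts.p,
        })
        if "interaction" in config.analyses:
            p_int = st.interaction_test(y, groups, cov, patient_label=plabel)
            rows.append({
                "analysis": f"interaction_{name}", "term": f"group_x_{name}",
                "effect": np.nan, "se": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                "stat": np.nan, "df": np.nan, "p": p_int,
            })
    if "bmi_match" in config.analyses and "bmi" in table:
        sub = st.bmi_match_filter(table, patient_label=plabel)
        sub_pat = sub["group"] == plabel
        if sub_pat.sum() >= 2 and (~sub_pat).sum() >= 2:
            add("bmi_matched_group", "group",
                st.t_test_pooled(sub.loc[sub_pat, "brain_pad"],
                                 sub.loc[~sub_pat, "brain_pad"]))
        else:
            logger.warning("BMI matching left fewer than 2 subjects in a group; "
                           "skipping the matched comparison")
    # single-subject z of every patient against the control norms
    norms = y[~is_patient]
    for sid, pad in zip(table.loc[is_patient, "subject_id"], y[is_patient]):
        z, pct = st.single_subject_vs_norm(pad, norms)
        rows.append({
            "analysis": "single_subject_z", "term": sid, "effect": pad,
            "se": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "stat": z,
            "df": np.nan, "p": np.nan, "percentile": pct,
        })
    pd.DataFrame(rows).to_csv(paths["stats_csv"], index=False)
    _record_stage(manifest, "stats", key, outputs, skipped=False)


def make_report(manifest: dict, outdir) -> str:
    """Render the run's numbers as deterministic markdown (no timestamps)."""
    paths = _cohort_paths(Path(outdir))
    missing = [s for s in ("train", "predict", "stats") if s not in manifest.get("stages", {})]
    if missing:
        raise StageError(f"manifest incomplete; missing stages: {missing}")
    with open(paths["cv_json"]) as fh:
        cv = json.load(fh)
    preds = pd.read_csv(paths["predictions_csv"])
    cohort = pd.read_csv(paths["test_csv"])
    stats_tbl = pd.read_csv(paths["stats_csv"])
    merged = preds.merge(cohort[["subject_id", "group"]], on="subject_id")
    lines = ["# Brain-age pipeline report", ""]
    lines += ["## Training cross-validation", ""]
    perm = f", permutation p = {cv['perm_p']:.4g}" if cv.get("perm_p") is not None else ""
    lines += [
        f"n = {cv['n']}, {cv['n_folds']}-fold CV (seed {cv['seed']}): "
        f"r = {cv['r']:.3f}, R^2 = {cv['r2']:.3f}, "
        f"MAE = {cv['mae']:.2f} y, RMSE = {cv['rmse']:.2f} y{perm}",
        "",
        "## brain-PAD by group",
        "",
    ]
    for g, sub in merged.groupby("group"):
        lines.append(
            f"- {g}: n = {len(sub)}, brain-PAD mean {sub['brain_pad'].mean():+.2f} "
            f"± SD {sub['brain_pad'].std(ddof=1):.2f} years"
        )
    lines += ["", "## Group comparisons", ""]
    main = stats_tbl[stats_tbl["analysis"] != "single_subject_z"]
    lines.append("| analysis | term | effect | se | ci95 | stat | df | p |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for _, r in main.iterrows():
        ci = f"[{r['ci_lo']:.2f}, {r['ci_hi']:.2f}]" if np.isfinite(r["ci_lo"]) else "-"
        eff = f"{r['effect']:.3f}" if np.isfinite(r["effect"]) else "-"
        se = f"{r['se']:.3f}" if np.isfinite(r["se"]) else "-"
        stat = f"{r['stat']:.3f}" if np.isfinite(r["stat"]) else "-"
        df = f"{r['df']:.0f}" if np.isfinite(r["df"]) else "-"
        lines.append(
            f"| {r['analysis']} | {r['term']} | {eff} | {se} | {ci} | {stat} | {df} | {r['p']:.4g} |"
        )
    zrows = stats_tbl[stats_tbl["analysis"] == "single_subject_z"]
    if len(zrows):
        lines += ["", "## Single-subject comparison vs control norms", ""]
        for _, r in zrows.iterrows():
            lines.append(
                f"- {r['term']}: brain-PAD {r['effect']:+.2f} y, z = {r['stat']:.2f}, "
                f"percentile {r.get('percentile', float('nan')):.1f}"
            )
    lines.append("")
    return "\n".join(lines)


def stage_report(config: RunConfig, manifest: dict) -> None:
    paths = _cohort_paths(config.outdir)
    key = _stage_key("report", config, {
        "stats_csv": _file_hash(paths["stats_csv"]),
        "cv_json": _file_hash(paths["cv_json"]),
    })
    outputs = [paths["report_md"]]
    if _stage_fresh(manifest, "report", key, outputs):
        logger.info("report: cached, skipping")
        _record_stage(manifest, "report", key, outputs, skipped=True)
        return
    text = make_report(manifest, config.outdir)
    paths["report_md"].write_text(text)
    if config.make_figures:
        _write_figures(paths)
    _record_stage(manifest, "report", key, outputs, skipped=False)


def _write_figures(paths: Mapping[str, Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    preds = pd.read_csv(paths["predictions_csv"])
    cohort = pd.read_csv(paths["test_csv"])
    merged = preds.merge(cohort[["subject_id", "group"]], on="subject_id")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for g, sub in merged.groupby("group"):
        axes[0].scatter(sub["age"], sub["predicted_age"], label=g, alpha=0.7)
        axes[1].scatter(sub["age"], sub["brain_pad"], label=g, alpha=0.7)
    lims = [merged["age"].min(), merged["age"].max()]
    axes[0].plot(lims, lims, "k:", lw=1)
    axes[0].set_xlabel("chronological age (y)")
    axes[0].set_ylabel("predicted age (y)")
    axes[1].axhline(0, color="k", ls=":", lw=1)
    axes[1].set_xlabel("chronological age (y)")
    axes[1].set_ylabel("brain-PAD (y)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(paths["report_md"].parent / "predicted_vs_age.png", dpi=100)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "volumes": stage_volumes,
    "train": stage_train,
    "predict": stage_predict,
    "stats": stage_stats,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, through: str = "report") -> dict:
    """Run all stages up to and including ``through``; returns the manifest."""
    if through not in STAGES:
        raise ValidationError(f"unknown stage {through!r}; choose from {STAGES}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    paths = _cohort_paths(config.outdir)
    manifest = _load_manifest(paths["manifest"])
    manifest["seed"] = config.seed
    manifest["config_digest"] = config.config_digest()
    for name in STAGES[: STAGES.index(through) + 1]:
        try:
            _STAGE_FUNCS[name](config, manifest)
        except ValidationError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
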