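"""End-to-end experiment: simulate, score text, classify, evaluate, audit.

One :class:`ExperimentConfig` drives the whole pipeline.  A development
pool (default ~19% of encounters) is carved out first and used only to
build text-scoring resources (the labeled sentence index for the kNN
chains); the remaining encounters feed nested cross-validation per feature
set, followed by the evaluation tables, pairwise comparison matrix and
subgroup fairness audits.  A single global seed fans out deterministically
to per-stage seeds so any stage can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import evaluation as ev
from .classification import CVConfig, CVResult, nested_cv
from .features import (
    FeatureSetId,
    TEXT_MODALITY,
    build_feature_matrix,
    write_feature_matrix,
)
from .synthetic_ehr import (
    CohortConfig,
    DX_CATEGORIES,
    cohort_to_frame,
    generate_cohort,
    write_encounters_csv,
    write_notes_jsonl,
)
from .text_scoring import (
    KnnConfig,
    build_labeled_index,
    get_backend,
    score_encounters_knn,
    score_encounters_likert,
)

logger = logging.getLogger("sitbdetect")

__all__ = ["ExperimentConfig", "RunManifest", "ValidationError",
           "run_experiment", "render_reports", "stage_seeds"]

ALL_FEATURE_SETS = [f.value for f in FeatureSetId]
ALL_MODALITIES = ("knn_general", "knn_medical", "likert")
_MODALITY_BACKEND = {"knn_general": "hashed-general", "knn_medical": "hashed-medical"}


class ValidationError(ValueError):
    """Experiment configuration failed validation."""


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    dev_fraction: float = 0.19  # development-pool share, ~724/3828
    feature_sets: list[str] = field(default_factory=lambda: list(ALL_FEATURE_SETS))
    text_modalities: list[str] = field(default_factory=lambda: list(ALL_MODALITIES))
    cv: CVConfig = field(default_factory=CVConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    auroc_bars: tuple[float, ...] = (0.90, 0.95)
    outdir: str = "runs/default"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not (0.0 < self.dev_fraction < 1.0):
            problems.append(f"dev_fraction must lie in (0, 1), got {self.dev_fraction}")
        if not self.feature_sets:
            problems.append("feature_sets must be nonempty")
        for fs in self.feature_sets:
            try:
                fsid = FeatureSetId(fs)
            except ValueError:
                problems.append(f"unknown feature set {fs!r}")
                continue
            modality = TEXT_MODALITY.get(fsid)
            if modality is not None and modality not in self.text_modalities:
                problems.append(
                    f"feature set {fs} needs text modality {modality!r}, "
                    f"which is not enabled"
                )
        try:
            self.cohort.validate()
        except ValueError as exc:
            problems.append(str(exc))
        try:
            self.cv.validate()
        except ValueError as exc:
            problems.append(str(exc))
        if problems:
            raise ValidationError("; ".join(problems))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], CohortConfig):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "cv" in d and not isinstance(d["cv"], CVConfig):
            d["cv"] = CVConfig(**d["cv"])
        if "knn" in d and not isinstance(d["knn"], KnnConfig):
            d["knn"] = KnnConfig(**d["knn"])
        if "auroc_bars" in d:
            d["auroc_bars"] = tuple(d["auroc_bars"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    files: list[str]
    wall_clock_s: float

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2))


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seed fan-out from the global seed."""
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(4)
    names = ("cohort", "split", "text", "cv")
    return {
        name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(names, children)
    }


def _demographic_families(df: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    """Mutually exclusive demographic stratifications (one stratum each)."""
    fams: dict[str, dict[str, np.ndarray]] = {}
    fams["age_group"] = {
        g: (df["age_group"] == g).to_numpy() for g in ("child", "adolescent")
    }
    fams["sex"] = {g: (df["sex"] == g).to_numpy() for g in ("female", "male")}
    fams["sex_age"] = {
        g: (df["stratum"] == g).to_numpy() for g in sorted(df["stratum"].unique())
    }
    fams["race"] = {
        g: (df["race_ethnicity"] == g).to_numpy()
        for g in sorted(df["race_ethnicity"].unique())
    }
    return fams


def _diagnostic_family(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Overlapping diagnostic strata (an encounter may carry several)."""
    return {c: (df[f"dx_{c}"] == 1).to_numpy() for c in DX_CATEGORIES}


def run_experiment(config: ExperimentConfig | str | Path) -> RunManifest:
    """Run the full pipeline; returns the manifest of written outputs."""
    t0 = time.time()
    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig.from_file(config)
    config.validate()
    seeds = stage_seeds(config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def _record(path: Path) -> Path:
        files.append(str(path.relative_to(outdir)))
        return path

    # ---- stage 1: simulate ------------------------------------------------
    logger.info("stage simulate: n=%d", config.cohort.n_encounters)
    cohort_cfg = CohortConfig.from_dict({**config.cohort.to_dict(), "seed": seeds["cohort"]})
    encounters, notes = generate_cohort(cohort_cfg)
    df = cohort_to_frame(encounters)
    write_encounters_csv(encounters, _record(outdir / "encounters.csv"))
    write_notes_jsonl(notes, _record(outdir / "notes.jsonl"))

    # ---- stage 2: development-pool carve-out ------------------------------
    idx = np.arange(len(df))
    dev_idx, eval_idx = train_test_split(
        idx, train_size=config.dev_fraction, random_state=seeds["split"],
        stratify=df["label"],
    )
    dev_ids = set(df.loc[dev_idx, "encounter_id"])
    eval_df = df.iloc[np.sort(eval_idx)].reset_index(drop=True)
    eval_ids = eval_df["encounter_id"].tolist()
    labels = eval_df["label"].to_numpy(dtype=int)
    logger.info("development pool %d encounters; evaluation pool %d", len(dev_idx), len(eval_idx))

    notes_by_enc: dict[str, list] = {}
    for n in notes:
        notes_by_enc.setdefault(n.encounter_id, []).append(n)
    eval_notes = {eid: notes_by_enc.get(eid, []) for eid in eval_ids}

    # ---- stage 3: text scoring -------------------------------------------
    needed = {
        TEXT_MODALITY[FeatureSetId(fs)]
        for fs in config.feature_sets
        if FeatureSetId(fs) in TEXT_MODALITY
    }
    text_scores: dict[str, dict[str, float]] = {}
    if needed & {"knn_general", "knn_medical"}:
        dev_sentences, dev_labels = [], []
        for eid in sorted(dev_ids):
            for note in notes_by_enc.get(eid, []):
                for s in note.sentences:
                    dev_sentences.append(s.text)
                    dev_labels.append(s.human_label if s.human_label is not None else 0.0)
        for modality in sorted(needed & {"knn_general", "knn_medical"}):
            backend = get_backend(_MODALITY_BACKEND[modality])
            index = build_labeled_index(dev_sentences, dev_labels, backend, config.knn)
            text_scores[modality] = score_encounters_knn(eval_notes, index)
            logger.info("scored modality %s over %d encounters", modality, len(eval_ids))
    if "likert" in needed:
        text_scores["likert"] = score_encounters_likert(eval_notes)
        logger.info("scored modality likert over %d encounters", len(eval_ids))
    for modality, scores in text_scores.items():
        pd.DataFrame(
            {"encounter_id": list(scores), "score": list(scores.values()), "modality": modality}
        ).to_csv(_record(outdir / f"scores_{modality}.csv"), index=False)

    # ---- stage 4: features + nested CV ------------------------------------
    cv_cfg = CVConfig(
        n_outer_folds=config.cv.n_outer_folds,
        inner_split_fraction=config.cv.inner_split_fraction,
        grid=config.cv.grid,
        probability_threshold=config.cv.probability_threshold,
        seed=seeds["cv"],
    )
    results: dict[str, CVResult] = {}
    for fs in config.feature_sets:
        fsid = FeatureSetId(fs)
        modality = TEXT_MODALITY.get(fsid)
        fm = build_feature_matrix(
            eval_df, fsid, text_scores[modality] if modality else None
        )
        write_feature_matrix(fm, _record(outdir / f"features_{fs}.csv"))
        _record(outdir / f"features_{fs}.manifest.json")
        res = nested_cv(fm.X, labels, cv_cfg, encounter_ids=eval_ids, feature_set_id=fs)
        res.to_json(_record(outdir / f"cv_{fs}.json"))
        pd.DataFrame(
            {"encounter_id": eval_ids, "probability": res.pooled_probabilities, "label": labels}
        ).to_csv(_record(outdir / f"predictions_{fs}.csv"), index=False)
        results[fs] = res
        logger.info("nested CV %s: mean fold AUROC %.3f", fs, res.fold_aurocs.mean())

    # ---- stage 5: evaluation ----------------------------------------------
    rows = []
    for fs, res in results.items():
        mean_auc, lo, hi = ev.cv_confidence_interval(res.fold_aurocs)
        preds = (res.pooled_probabilities >= cv_cfg.probability_threshold).astype(int)
        bundle = ev.confusion_metrics(preds, labels)
        row = {"feature_set": fs, "auroc_mean_fold": mean_auc,
               "auroc_ci_lo": lo, "auroc_ci_hi": hi,
               "auroc_pooled": ev.auroc(res.pooled_probabilities, labels)}
        row.update({k: v for k, v in bundle.as_dict().items() if k != "auroc"})
        rows.append(row)
        curves = [ev.roc_points(f.probabilities, labels[f.val_indices]) for f in res.folds]
        mc = ev.mean_roc(curves)
        pd.DataFrame({"fpr": mc.fpr, "tpr": mc.tpr}).to_csv(
            _record(outdir / f"roc_{fs}.csv"), index=False
        )
    pd.DataFrame(rows).to_csv(_record(outdir / "metrics.csv"), index=False)

    diff, pval = ev.pairwise_comparison_matrix(results, labels)
    diff.to_csv(_record(outdir / "pairwise_auroc_diff.csv"))
    pval.to_csv(_record(outdir / "pairwise_delong_p.csv"))

    # ---- stage 6: subgroup audits -----------------------------------------
    fam_masks = _demographic_families(eval_df)
    demo_rows, diag_rows = [], []
    gap_rows = []
    for fs, res in results.items():
        demographic_aurocs: list[float] = []
        for family, strata in fam_masks.items():
            report = ev.subgroup_audit(
                res.pooled_probabilities, labels, strata, family=family,
                threshold=cv_cfg.probability_threshold, bars=config.auroc_bars,
            )
            frame = report.to_frame()
            frame.insert(0, "feature_set", fs)
            demo_rows.append(frame)
            demographic_aurocs += [
                info["metrics"].auroc.value
                for info in report.strata.values()
                if info["metrics"].auroc.defined
            ]
        diag_report = ev.subgroup_audit(
            res.pooled_probabilities, labels, _diagnostic_family(eval_df),
            family="diagnostic", threshold=cv_cfg.probability_threshold,
            bars=config.auroc_bars,
        )
        frame = diag_report.to_frame()
        frame.insert(0, "feature_set", fs)
        diag_rows.append(frame)
        gap_rows.append({
            "feature_set": fs,
            "demographic_gap": (max(demographic_aurocs) - min(demographic_aurocs))
            if demographic_aurocs else None,
            "diagnostic_gap": diag_report.gap,
            **{f"demographic_n_auroc_ge_{bar}": sum(a >= bar for a in demographic_aurocs)
               for bar in config.auroc_bars},
        })
    pd.concat(demo_rows, ignore_index=True).to_csv(
        _record(outdir / "subgroup_demographic.csv"), index=False
    )
    pd.concat(diag_rows, ignore_index=True).to_csv(
        _record(outdir / "subgroup_diagnostic.csv"), index=False
    )
    pd.DataFrame(gap_rows).to_csv(_record(outdir / "subgroup_gaps.csv"), index=False)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_seeds=seeds,
        files=files,
        wall_clock_s=round(time.time() - t0, 3),
    )
    manifest.write(outdir / "manifest.json")
    for f in files:
        path = outdir / f
        assert path.exists() and path.stat().st_size > 0, f"missing output {f}"
    # held-out discipline: no development encounter may enter any CV fold
    assert not (dev_ids & set(eval_ids))
    return manifest


# --------------------------------------------------------------------------
# report rendering

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_reports(run_dir: str | Path) -> list[Path]:
    """Render figure analogs from a completed run directory.

    Writes the pairwise AUROC-difference heatmap with significance stars,
    stratified-performance heatmaps per family, and mean ROC plots.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"{run_dir} does not contain a completed run (no manifest)")
    written: list[Path] = []

    diff_path = run_dir / "pairwise_auroc_diff.csv"
    if diff_path.exists():
        diff = pd.read_csv(diff_path, index_col=0)
        pval = pd.read_csv(run_dir / "pairwise_delong_p.csv", index_col=0)
        if diff.empty:
            logger.warning("pairwise matrix is empty; skipping heatmap")
        else:
            fig, ax = plt.subplots(figsize=(1.1 * len(diff) + 2, 0.9 * len(diff) + 2))
            im = ax.imshow(diff.to_numpy(), cmap="RdYlBu", vmin=-0.3, vmax=0.3)
            ax.set_xticks(range(len(diff.columns)), diff.columns, rotation=45, ha="right")
            ax.set_yticks(range(len(diff.index)), diff.index)
            for i, a in enumerate(diff.index):
                for j, b in enumerate(diff.columns):
                    if i == j:
                        continue
                    ax.text(j, i, f"{diff.iloc[i, j]:+.3f}{_stars(pval.iloc[i, j])}",
                            ha="center", va="center", fontsize=7)
            fig.colorbar(im, ax=ax, label="AUROC difference (row - column)")
            ax.set_title("Pairwise AUROC differences with DeLong significance")
            fig.tight_layout()
            out = run_dir / "pairwise_heatmap.png"
            fig.savefig(out, dpi=120)
            plt.close(fig)
            written.append(out)

    for family_file in ("subgroup_demographic.csv", "subgroup_diagnostic.csv"):
        path = run_dir / family_file
        if not path.exists():
            continue
        table = pd.read_csv(path)
        if table.empty:
            continue
        pivot = table.pivot_table(index="feature_set", columns="stratum", values="auroc")
        fig, ax = plt.subplots(figsize=(0.8 * pivot.shape[1] + 3, 0.6 * pivot.shape[0] + 2))
        im = ax.imshow(pivot.to_numpy(), cmap="RdYlGn", vmin=0.5, vmax=1.0)
        ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
        ax.set_yticks(range(pivot.shape[0]), pivot.index)
        for i in range(pivot.shape[0]):
            for j in range(pivot.shape[1]):
                v = pivot.iloc[i, j]
                if pd.notna(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="stratum AUROC")
        ax.set_title(f"Stratified AUROC ({family_file.split('_')[1].split('.')[0]})")
        fig.tight_layout()
        out = run_dir / family_file.replace(".csv", "_heatmap.png")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)

    roc_files = sorted(run_dir.glob("roc_*.csv"))
    if roc_files:
        fig, ax = plt.subplots(figsize=(6, 5))
        for rf in roc_files:
            curve = pd.read_csv(rf)
            ax.plot(curve["fpr"], curve["tpr"], label=rf.stem.replace("roc_", ""))
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title("Mean ROC per feature set")
        ax.legend(fontsize=7)
        fig.tight_layout()
        out = run_dir / "mean_roc.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    if not written:
        logger.warning("render_reports: nothing to render in %s", run_dir)
    return written
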