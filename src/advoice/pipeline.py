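"""End-to-end runs: simulate/ingest -> features -> compare -> evaluate -> report.

A run directory collects every artifact: ``features.csv`` (43 features per
block row), ``table2.csv``/``table2.md`` (the group-comparison table),
``results.csv`` and ``summary.csv`` (fold metrics and their mean +- SD per
significant feature and classifier), ``roc.json`` (per-fold ROC points) and
``run_meta.json`` (config snapshot, library versions, seed, row counts).
Feature extraction is cached by input checksum: re-running with unchanged
inputs and extraction parameters reuses ``features.csv``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as avio
from .compare import compare_all, render_markdown
from .evaluate import (CLASSIFIERS, evaluate_all, results_frame, roc_payload,
                       summary_frame)
from .features import (FEATURE_NAMES, FrameGrid, cohort_feature_table,
                       read_feature_table, write_feature_table)
from .prep import Recording, build_noise_pool, extract_speech, remix_noise
from .synth import CohortSpec, generate_cohort, healthy_profile, null_cohort_spec, patient_profile

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every pipeline parameter, with defaults, serializable to/from YAML."""

    mode: str = "synthetic"            # "synthetic" | "manifest"
    manifest_path: str | None = None   # required in manifest mode
    out_dir: str = "advoice_run"
    seed: int = 0
    # synthetic cohort
    n_patient: int = 83
    n_healthy: int = 75
    duration_s: float = 120.0
    null_mode: bool = False            # identical zero-scatter profiles
    # preprocessing
    noise_chunk_s: float = 1.0
    noise_gain: float = 1.0
    block_length_s: float = 10.0
    block_hop_s: float = 5.0
    # frame grid / F0
    frame_length: int = 2048
    frame_hop: int = 512
    window: str = "hann"
    fmin_hz: float = 50.0
    fmax_hz: float = 400.0
    voicing_threshold: float = 0.45
    min_voiced_frames: int = 10
    # statistics / evaluation
    alpha: float = 0.05
    per_subject_compare: bool = False
    k_folds: int = 5
    group_by_subject: bool = False
    classifiers: tuple = tuple(CLASSIFIERS)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "classifiers" in data:
            data["classifiers"] = tuple(data["classifiers"])
        return cls(**data)


def _checksum(paths, extra: str = "") -> str:
    h = hashlib.sha256(extra.encode())
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _load_recordings(manifest: pd.DataFrame) -> list[Recording]:
    recs = []
    for row in manifest.itertuples():
        wav = Path(row.wav_path)
        if not wav.exists():
            raise FileNotFoundError(
                f"stage extract: subject {row.subject_id}: missing WAV {wav}")
        samples, sr = avio.load_wav(wav)
        ann = avio.read_annotations(avio.annotation_path_for(row._asdict()))
        recs.append(Recording.from_annotation_frame(
            row.subject_id, row.group, sr, samples, ann))
    return recs


def simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort for this run; returns the manifest path."""
    out = Path(config.out_dir)
    if config.null_mode:
        spec = null_cohort_spec(n_per_group=min(config.n_patient, config.n_healthy),
                                duration_s=config.duration_s, seed=config.seed)
        spec = dataclasses.replace(spec, n_patient=config.n_patient,
                                   n_healthy=config.n_healthy)
    else:
        spec = CohortSpec(n_patient=config.n_patient, n_healthy=config.n_healthy,
                          patient=patient_profile(), healthy=healthy_profile(),
                          duration_s=config.duration_s, seed=config.seed)
    return generate_cohort(spec, out / "cohort")


def extract(config: RunConfig, manifest_path) -> pd.DataFrame:
    """Speech extraction, noise remixing, blocking and feature computation.

    Cached: if ``features.csv`` exists and the manifest files plus extraction
    parameters are unchanged (checksum match), it is reused as-is.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = avio.read_manifest(manifest_path)
    extract_params = json.dumps({
        k: getattr(config, k) for k in
        ("noise_chunk_s", "noise_gain", "block_length_s", "block_hop_s",
         "frame_length", "frame_hop", "window", "fmin_hz", "fmax_hz",
         "voicing_threshold", "min_voiced_frames", "seed")}, sort_keys=True)
    checksum = _checksum([manifest_path], extra=extract_params)
    feat_path = out / "features.csv"
    meta_path = out / "features_meta.json"
    if feat_path.exists() and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("checksum") == checksum:
            log.info("features.csv up to date (checksum match); reusing")
            return read_feature_table(feat_path)

    recordings = _load_recordings(manifest)
    pool = build_noise_pool(recordings, chunk_s=config.noise_chunk_s,
                            rng=config.seed)
    sr = recordings[0].sample_rate
    grid = FrameGrid(frame_length=config.frame_length, hop=config.frame_hop,
                     window=config.window, sample_rate=sr)

    def speech_iter():
        for rec in recordings:
            speech = extract_speech(rec)
            yield rec.subject_id, rec.group, remix_noise(speech, pool,
                                                         config.noise_gain)

    table = cohort_feature_table(
        speech_iter(), sr, grid,
        block_length_s=config.block_length_s, block_hop_s=config.block_hop_s,
        fmin=config.fmin_hz, fmax=config.fmax_hz,
        voicing_threshold=config.voicing_threshold,
        min_voiced_frames=config.min_voiced_frames)
    write_feature_table(table, feat_path)
    meta_path.write_text(json.dumps(
        {"checksum": checksum, "n_subjects": int(table["subject_id"].nunique()),
         "n_blocks": int(len(table))}, indent=2))
    log.info("extracted %d blocks from %d subjects", len(table),
             table["subject_id"].nunique())
    return table


def compare(config: RunConfig, table: pd.DataFrame) -> pd.DataFrame:
    out = Path(config.out_dir)
    comparison = compare_all(table, alpha=config.alpha,
                             per_subject=config.per_subject_compare)
    comparison.to_csv(out / "table2.csv", index=False, float_format="%.12g")
    (out / "table2.md").write_text(render_markdown(comparison))
    return comparison


def evaluate(config: RunConfig, table: pd.DataFrame,
             comparison: pd.DataFrame):
    out = Path(config.out_dir)
    results = evaluate_all(table, comparison, classifiers=config.classifiers,
                           seed=config.seed, k=config.k_folds,
                           group_by_subject=config.group_by_subject)
    results_frame(results).to_csv(out / "results.csv", index=False,
                                  float_format="%.12g")
    summary_frame(results).to_csv(out / "summary.csv", index=False,
                                  float_format="%.12g")
    (out / "roc.json").write_text(json.dumps(roc_payload(results)))
    return results


def run(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with a stage-named message; artifacts of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("advoice")
    root.addHandler(handler)
    try:
        config.to_yaml(out / "config.yaml")
        if config.mode == "synthetic":
            manifest_path = simulate(config)
        elif config.mode == "manifest":
            if not config.manifest_path:
                raise ValueError("stage ingest: manifest mode requires manifest_path")
            manifest_path = Path(config.manifest_path)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        table = extract(config, manifest_path)
        comparison = compare(config, table)
        results = evaluate(config, table, comparison)
        meta = {
            "advoice_version": __version__,
            "numpy": np.__version__, "pandas": pd.__version__,
            "seed": config.seed,
            "n_subjects": int(table["subject_id"].nunique()),
            "n_blocks": int(len(table)),
            "n_features": len(FEATURE_NAMES),
            "n_significant": int(comparison["significant"].sum()),
            "n_evaluated": len({r.feature for r in results}),
        }
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


REQUIRED_ARTIFACTS = ["features.csv", "table2.csv", "table2.md",
                      "results.csv", "summary.csv", "roc.json", "run_meta.json"]


def report(run_dir, max_roc_features: int | None = None) -> Path:
    """Render a Markdown report with the comparison table, performance
    summaries, and per-feature ROC panels (one curve per fold, AUC annotated).

    Returns the report path; raises if the run is incomplete, listing the
    missing artifacts.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run_dir}: missing {missing}")

    comparison = pd.read_csv(run_dir / "table2.csv")
    summary = pd.read_csv(run_dir / "summary.csv")
    roc = json.loads((run_dir / "roc.json").read_text())
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    lines = ["# advoice run report", "", "## Group comparison", "",
             (run_dir / "table2.md").read_text(), "",
             "## Single-feature classifier performance (mean ± SD over folds)", "",
             "| Feature | Classifier | Accuracy | F1 | AUC |", "|---|---|---|---|---|"]
    for r in summary.itertuples():
        lines.append(
            f"| {r.feature} | {r.classifier} "
            f"| {r.accuracy_mean:.3f} ± {r.accuracy_sd:.3f} "
            f"| {r.f1_mean:.3f} ± {r.f1_sd:.3f} "
            f"| {r.auc_mean:.3f} ± {r.auc_sd:.3f} |")
    lines += ["", "## ROC curves", ""]

    features = list(roc)
    if max_roc_features is not None:
        features = features[:max_roc_features]
    for feat in features:
        clfs = list(roc[feat])
        fig, axes = plt.subplots(1, len(clfs), figsize=(4 * len(clfs), 4),
                                 squeeze=False)
        for ax, clf in zip(axes[0], clfs):
            for i, fold in enumerate(roc[feat][clf]):
                if fold is None:
                    continue
                area = np.trapezoid(fold["tpr"], fold["fpr"])
                ax.plot(fold["fpr"], fold["tpr"],
                        label=f"fold {i + 1} (AUC {area:.3f})")
            ax.plot([0, 1], [0, 1], "k--", lw=0.5)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.set_title(f"{feat} — {clf}")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fname = f"roc_{feat.replace('.', '_')}.png"
        fig.savefig(fig_dir / fname, dpi=100)
        plt.close(fig)
        lines.append(f"![{feat}](figures/{fname})")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
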