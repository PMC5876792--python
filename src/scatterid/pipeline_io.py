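"""End-to-end orchestration and file formats.

One reproducible run executes: simulate -> high-pass/epoch/reject ->
featurize -> per-particle averaging -> LDA fit + projection ->
statistical report, writing every intermediate artifact (CSV/JSON/HDF5)
plus a manifest of per-stage counts.  Everything downstream is a pure
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth_signals import (AcquisitionConfig, ParticleClassSpec,
                            SignalAcquisition, default_study_design,
                            generate_dataset)
from .preprocess import PreprocessParams, preprocess_acquisition
from .features import FEATURE_NAMES, METADATA_COLUMNS, featurize_epochs, \
    particle_average
from .lda import DEFAULT_EXCLUDED, LinearDiscriminant
from .class_stats import (StatReport, feature_screen, kruskal_4way,
                          pairwise_mann_whitney, separability_report,
                          spearman_vs_dnd)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    specs: list[ParticleClassSpec] = field(default_factory=default_study_design)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    excluded_features: tuple = DEFAULT_EXCLUDED
    ridge: float = 1e-6
    orient_reference: str | None = "no_particle"
    bhattacharyya_mode: str = "univariate"
    seed: int = 0
    write_acquisitions: bool = False

    def __post_init__(self) -> None:
        if self.seed != self.acquisition.seed:
            self.acquisition = dataclasses.replace(self.acquisition,
                                                   seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        specs = [ParticleClassSpec(**s) for s in raw.get("classes", [])] \
            or default_study_design()
        acq = AcquisitionConfig(**raw.get("acquisition", {}))
        pre = PreprocessParams(**raw.get("preprocess", {}))
        return cls(specs=specs, acquisition=acq, preprocess=pre,
                   excluded_features=tuple(raw.get("excluded_features",
                                                   DEFAULT_EXCLUDED)),
                   ridge=raw.get("ridge", 1e-6),
                   orient_reference=raw.get("orient_reference", "no_particle"),
                   bhattacharyya_mode=raw.get("bhattacharyya_mode",
                                              "univariate"),
                   seed=raw.get("seed", acq.seed),
                   write_acquisitions=raw.get("write_acquisitions", False))

    def config_hash(self) -> str:
        blob = json.dumps({
            "classes": [dataclasses.asdict(s) for s in self.specs],
            "acquisition": dataclasses.asdict(self.acquisition),
            "preprocess": dataclasses.asdict(self.preprocess),
            "excluded": list(self.excluded_features),
            "ridge": self.ridge, "orient": self.orient_reference,
            "bhat": self.bhattacharyya_mode, "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage bookkeeping of one run."""

    version: str
    config_hash: str
    n_acquisitions: int
    total_duration_s: float
    epochs_total: int
    epochs_accepted: int
    epochs_rejected: int
    n_particles: int
    output_files: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PipelineResult:
    """In-memory artifacts of one run (manifest plus all tables)."""

    manifest: RunManifest
    epoch_features: pd.DataFrame
    particle_features: pd.DataFrame
    particle_scores: pd.DataFrame
    lda_results: object
    report: StatReport


# ---------------------------------------------------------------------------
# acquisition / table file formats

def write_acquisition(acq: SignalAcquisition, path) -> None:
    """One numeric series per file (CSV, one sample per line, or a
    single-dataset HDF5 container) plus a JSON metadata sidecar."""
    path = Path(path)
    if path.suffix == ".csv":
        np.savetxt(path, acq.samples, fmt="%.12g")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("samples", data=acq.samples)
    else:
        raise ValueError(f"unsupported acquisition format {path.suffix!r}")
    sidecar = {
        "class_label": acq.class_label, "particle_id": acq.particle_id,
        "fs": acq.fs, "duration": acq.duration,
        "generator_params": {k: v for k, v in acq.provenance.items()
                             if isinstance(v, (int, float, str, list))},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_acquisition(path) -> SignalAcquisition:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "fs" not in sidecar:
        raise ValueError("sidecar missing required field 'fs'")
    if path.suffix == ".csv":
        samples = np.loadtxt(path)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            samples = fh["samples"][:]
    else:
        raise ValueError(f"unsupported acquisition format {path.suffix!r}")
    if not np.all(np.isfinite(samples)):
        raise ValueError("acquisition contains non-finite samples")
    return SignalAcquisition(samples=samples, fs=float(sidecar["fs"]),
                             class_label=sidecar.get("class_label", ""),
                             particle_id=sidecar.get("particle_id", ""),
                             provenance=sidecar.get("generator_params", {}))


def write_table(table: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    table.to_csv(path, sep=sep, index=False)


def read_feature_table(path, expect_features: bool = True) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    table = pd.read_csv(path, sep=sep)
    if expect_features:
        missing = [c for c in FEATURE_NAMES if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
    return table


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute the full study pipeline; optionally persist artifacts.

    Stages: generate acquisitions, preprocess each, compute the epoch
    feature table, average per particle, fit the discriminant on
    epoch-level rows, project the particle rows, and build the
    statistical report (screen, score tests, Bhattacharyya top-3 vs
    bottom-3, Spearman vs dn*d).
    """
    t0 = time.perf_counter()
    acquisitions = generate_dataset(config.specs, config.acquisition)
    total_duration = sum(a.duration for a in acquisitions)
    logger.info("stage simulate: %d acquisitions, %.0f s total (%.1fs)",
                len(acquisitions), total_duration, time.perf_counter() - t0)

    t1 = time.perf_counter()
    all_epochs = []
    for acq in acquisitions:
        all_epochs.extend(preprocess_acquisition(acq, config.preprocess).epochs)
    n_total = len(all_epochs)
    n_acc = sum(e.accepted for e in all_epochs)
    logger.info("stage preprocess: %d epochs, %d rejected (%.1fs)",
                n_total, n_total - n_acc, time.perf_counter() - t1)

    t2 = time.perf_counter()
    epoch_features = featurize_epochs(all_epochs)
    particle_features = particle_average(epoch_features)
    logger.info("stage featurize: %d epoch rows, %d particles (%.1fs)",
                len(epoch_features), len(particle_features),
                time.perf_counter() - t2)

    t3 = time.perf_counter()
    model = LinearDiscriminant.from_dataframe(
        epoch_features, exclude=config.excluded_features, ridge=config.ridge)
    results = model.fit(orient_reference=config.orient_reference)
    drop = [c for c in config.excluded_features
            if c in particle_features.columns]
    particle_scores = results.transform(particle_features.drop(columns=drop))
    particle_scores["class_label"] = particle_features["class_label"].to_numpy()
    logger.info("stage lda: eigenvalue %.4g (%.1fs)", results.eigenvalue,
                time.perf_counter() - t3)

    t4 = time.perf_counter()
    screen_table = particle_features.merge(
        particle_scores[["particle_id", "score"]], on="particle_id")
    screen = feature_screen(screen_table)
    labels = screen_table["class_label"].to_numpy()
    scores = screen_table["score"].to_numpy()
    score_kw = kruskal_4way(scores, labels)
    score_mw = pairwise_mann_whitney(scores, labels)
    weights = results.contribution_weights()
    top3 = weights["feature"].head(3).tolist()
    bottom3 = weights["feature"].tail(3).tolist()
    from .class_stats import PairwiseDistanceSet
    counts = pd.Series(labels).value_counts()
    if counts.min() >= 2:
        bhat_top = separability_report(screen_table, labels, top3,
                                       mode=config.bhattacharyya_mode)
        bhat_bottom = separability_report(screen_table, labels, bottom3,
                                          mode=config.bhattacharyya_mode)
    else:
        logger.warning("classes with a single particle: skipping "
                       "Bhattacharyya separability")
        bhat_top = bhat_bottom = PairwiseDistanceSet()
    class_means = {lb: float(scores[labels == lb].mean())
                   for lb in pd.unique(labels)}
    spearman = spearman_vs_dnd(class_means, config.specs)
    report = StatReport(screen=screen, score_kruskal=score_kw,
                        score_mann_whitney=score_mw,
                        bhattacharyya_top=bhat_top,
                        bhattacharyya_bottom=bhat_bottom,
                        spearman=spearman, top_features=top3,
                        bottom_features=bottom3)
    logger.info("stage stats: KW p=%.3g, rho=%.2f (%.1fs)",
                score_kw[1], spearman[0], time.perf_counter() - t4)

    from . import __version__
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(),
        n_acquisitions=len(acquisitions),
        total_duration_s=float(total_duration),
        epochs_total=n_total, epochs_accepted=int(n_acc),
        epochs_rejected=int(n_total - n_acc),
        n_particles=len(particle_features))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        if config.write_acquisitions:
            acq_dir = outdir / "acquisitions"
            acq_dir.mkdir(exist_ok=True)
            for acq in acquisitions:
                write_acquisition(acq, acq_dir / f"{acq.particle_id}.csv")
            files["acquisitions"] = str(acq_dir)
        write_table(epoch_features, outdir / "epoch_features.csv")
        write_table(particle_features, outdir / "particle_features.csv")
        write_table(particle_scores, outdir / "particle_scores.csv")
        results.to_json(outdir / "lda_model.json")
        report.to_json(outdir / "stat_report.json")
        files.update({
            "epoch_features": str(outdir / "epoch_features.csv"),
            "particle_features": str(outdir / "particle_features.csv"),
            "particle_scores": str(outdir / "particle_scores.csv"),
            "lda_model": str(outdir / "lda_model.json"),
            "stat_report": str(outdir / "stat_report.json"),
        })
        manifest.output_files = files
        manifest.to_json(outdir / "manifest.json")

    return PipelineResult(manifest=manifest, epoch_features=epoch_features,
                          particle_features=particle_features,
                          particle_scores=particle_scores,
                          lda_results=results, report=report)
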