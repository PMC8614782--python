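"""The study object: build from data, fit, inspect results.

:class:`SoacStudy` bundles the aligned descriptor table, fingerprint
table and log-rate-ratio targets and, on :meth:`SoacStudy.fit`, runs the
whole protocol — descriptor pruning, the algorithm x feature-set x
random-state evaluation grid, and the consensus importance ranking —
returning a :class:`SoacStudyResults` with the accuracy grid, the
selection report, the consensus rankings, a text ``summary()`` and
plotting/saving helpers.

:func:`run_all` is the end-to-end pipeline entry point used by the CLI:
it reads a config, executes featurize -> select -> train -> importance,
writes every artifact as delimited text and returns a
:class:`RunManifest` recording config snapshot, input digests, software
versions, seeds and per-stage outputs so a run can be reproduced and
checked bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .config import StudyConfig, default_config, load_config
from .consensus import ConsensusRanking, build_consensus, top_k
from .featurization import (RejectionReport, build_feature_tables, get_backend,
                            read_compounds)
from .selection import SelectionReport, select_features
from .suite import GridResult, ModelRun, default_n_test, run_experiment
from .synthetic import SyntheticSpec, generate_dataset
from .table import FeatureTable


class SoacStudy:
    """A singlet-oxygen-scavenging QSPR study, ready to fit.

    Parameters
    ----------
    descriptors, fingerprints
        Aligned feature tables (identical sample order).
    targets
        Log rate-ratio per sample, aligned with the tables.
    config
        A :class:`~soacml.config.StudyConfig`; defaults are used if None.
    """

    def __init__(self, descriptors: FeatureTable, fingerprints: FeatureTable,
                 targets: pd.Series, config: Optional[StudyConfig] = None,
                 rejections: Optional[RejectionReport] = None):
        if descriptors.sample_ids != fingerprints.sample_ids:
            raise ValueError("descriptor and fingerprint tables are misaligned")
        if descriptors.sample_ids != list(targets.index):
            raise ValueError("feature tables and targets are misaligned")
        self.descriptors = descriptors
        self.fingerprints = fingerprints
        self.targets = targets
        self.config = config or default_config(synthetic=SyntheticSpec())
        self.rejections = rejections or RejectionReport()

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_compounds(cls, path, config: Optional[StudyConfig] = None) -> "SoacStudy":
        """Featurize a compound table (id, name, smiles, soac|k_q)."""
        config = config or default_config(compounds_path=str(path))
        records, rejections = read_compounds(path, k_ref=config.k_ref)
        backend = get_backend(config.backend)
        tables = build_feature_tables(records, backend,
                                      radius=config.radius, n_bits=config.n_bits)
        for row in tables.rejections.rows:
            rejections.add(*row)
        return cls(tables.descriptors, tables.fingerprints, tables.targets,
                   config=config, rejections=rejections)

    @classmethod
    def from_synthetic(cls, spec: SyntheticSpec,
                       config: Optional[StudyConfig] = None) -> "SoacStudy":
        """Generate a ground-truth dataset and split it into the two
        feature sets by kind tag."""
        table, y, _truth = generate_dataset(spec)
        desc_names = [n for n in table.feature_names
                      if table.kind_of(n) == "descriptor"]
        fp_names = [n for n in table.feature_names
                    if table.kind_of(n) == "fingerprint_bit"]
        config = config or default_config(synthetic=spec)
        return cls(table.select(desc_names), table.select(fp_names), y,
                   config=config)

    @property
    def n_samples(self) -> int:
        return self.descriptors.n_samples

    # -- fitting --------------------------------------------------------
    def fit(self, logger=None) -> "SoacStudyResults":
        """Run selection, the evaluation grid and the consensus ranking."""
        cfg = self.config
        selected, report = select_features(self.descriptors, threshold=cfg.threshold)
        grid = run_experiment(
            selected, self.fingerprints, self.targets,
            algorithms=cfg.algorithms, random_states=cfg.random_states,
            hyperparameters=cfg.hyperparameters, n_test=cfg.n_test,
            compute_loocv=cfg.compute_loocv, logger=logger)
        desc_runs = [r for r in grid.runs if r.feature_set == "descriptor"]
        fp_runs = [r for r in grid.runs if r.feature_set == "fingerprint"]
        return SoacStudyResults(
            study=self,
            selected_descriptors=selected,
            selection_report=report,
            grid=grid,
            consensus_descriptor=build_consensus(desc_runs) if desc_runs else ConsensusRanking(),
            consensus_fingerprint=build_consensus(fp_runs) if fp_runs else ConsensusRanking(),
            consensus_combined=build_consensus(grid.runs) if grid.runs else ConsensusRanking(),
        )


@dataclass
class SoacStudyResults:
    """Everything a fitted study produces."""

    study: SoacStudy
    selected_descriptors: FeatureTable
    selection_report: SelectionReport
    grid: GridResult
    consensus_descriptor: ConsensusRanking
    consensus_fingerprint: ConsensusRanking
    consensus_combined: ConsensusRanking

    @property
    def runs(self) -> list[ModelRun]:
        return self.grid.runs

    def accuracy_grid(self) -> pd.DataFrame:
        return self.grid.to_frame()

    def consensus(self, feature_set: str = "descriptor") -> ConsensusRanking:
        return {"descriptor": self.consensus_descriptor,
                "fingerprint": self.consensus_fingerprint,
                "combined": self.consensus_combined}[feature_set]

    def top_features(self, k: Optional[int] = None,
                     feature_set: str = "descriptor") -> list[tuple[str, int]]:
        return top_k(self.consensus(feature_set), k or self.study.config.top_k)

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        cfg = self.study.config
        n = self.study.n_samples
        n_test = cfg.n_test if cfg.n_test is not None else default_n_test(n)
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("Singlet-oxygen-scavenging QSPR study".center(w))
        lines.append("=" * w)
        lines.append(f"Samples: {n}   Split: {n - n_test} train / {n_test} test   "
                     f"Random states: {list(cfg.random_states)}")
        lines.append(f"Descriptors: {self.study.descriptors.n_features} -> "
                     f"{self.selected_descriptors.n_features} after pruning "
                     f"(|r| < {cfg.threshold})   "
                     f"Fingerprint bits: {self.study.fingerprints.n_features}")
        if self.grid.failures:
            skipped = sorted({c[0] for c, _ in self.grid.failures})
            lines.append(f"Skipped (capability): {skipped}")
        lines.append("-" * w)
        grid = self.accuracy_grid()
        if len(grid):
            agg = (grid.groupby(["algorithm", "feature_set"])
                       [["r2", "rmse", "rmse_loo"]].mean().reset_index())
            lines.append("Mean over random states "
                         "(test R2 / test RMSE / RMSE_LOO):")
            for _, row in agg.iterrows():
                lines.append(f"  {row.algorithm:<14s} {row.feature_set:<12s} "
                             f"R2={row.r2: .3f}  RMSE={row.rmse:.3f}  "
                             f"RMSE_LOO={row.rmse_loo:.3f}")
        lines.append("-" * w)
        for fset in ("descriptor", "fingerprint"):
            ranking = self.consensus(fset)
            lines.append(f"Consensus importance — {fset} set "
                         f"({len(ranking.eligible_models)} eligible models, "
                         f"max score {ranking.max_possible_score}):")
            for feature, score in top_k(ranking, cfg.top_k) if ranking.scores else []:
                lines.append(f"  {feature:<24s} {score:>5d}")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_predictions(self, algorithm: str, feature_set: str = "descriptor",
                         ax=None):
        """Observed-vs-predicted scatter over this cell's random states."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        y = self.study.targets
        for run in self.runs:
            if run.algorithm == algorithm and run.feature_set == feature_set:
                ax.scatter(y.loc[run.predictions.index], run.predictions,
                           label=f"rs={run.random_state}", alpha=0.8)
        lo, hi = float(y.min()), float(y.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("observed ln(rate ratio)")
        ax.set_ylabel("predicted ln(rate ratio)")
        ax.set_title(f"{algorithm} / {feature_set}")
        ax.legend()
        return ax

    def plot_consensus(self, feature_set: str = "descriptor",
                       k: Optional[int] = None, ax=None):
        """Horizontal bar chart of the top consensus scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        top = self.top_features(k, feature_set)
        names = [f for f, _ in top][::-1]
        scores = [s for _, s in top][::-1]
        ax.barh(names, scores)
        ax.set_xlabel("summed rank score")
        ax.set_title(f"consensus importance ({feature_set})")
        return ax

    def save(self, out_dir) -> dict[str, Path]:
        """Write every artifact as delimited text; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "selected_features": out / "selected_features.csv",
            "selection_report": out / "selection_report.csv",
            "accuracy_grid": out / "accuracy_grid.csv",
            "consensus_descriptor": out / "consensus_descriptor.csv",
            "consensus_fingerprint": out / "consensus_fingerprint.csv",
            "consensus_combined": out / "consensus_combined.csv",
        }
        self.selected_descriptors.to_csv(paths["selected_features"])
        self.selection_report.to_csv(paths["selection_report"])
        self.accuracy_grid().to_csv(paths["accuracy_grid"], index=False)
        self.consensus_descriptor.to_csv(paths["consensus_descriptor"])
        self.consensus_fingerprint.to_csv(paths["consensus_fingerprint"])
        self.consensus_combined.to_csv(paths["consensus_combined"])
        if len(self.study.rejections):
            paths["rejections"] = out / "rejections.csv"
            self.study.rejections.to_csv(paths["rejections"])
        return paths


# ---------------------------------------------------------------------------
# end-to-end pipeline with manifest
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: "RunManifest", cause: Exception):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    """Provenance record enabling bit-identical re-runs."""

    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, list] = field(default_factory=dict)
    stage_outputs: dict[str, dict[str, str]] = field(default_factory=dict)  # stage -> {path: digest}
    timestamps: dict[str, str] = field(default_factory=dict)

    def record_stage(self, stage: str, paths: Sequence[Path]) -> None:
        self.stage_outputs[stage] = {str(p): _sha256(p) for p in paths}
        self.timestamps[stage] = datetime.now(timezone.utc).isoformat()

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True,
                                         default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _versions() -> dict[str, str]:
    import numpy
    import sklearn

    versions = {"soacml": __version__, "python": sys.version.split()[0],
                "numpy": numpy.__version__, "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__}
    for lib in ("xgboost", "lightgbm", "catboost", "rdkit"):
        try:
            versions[lib] = __import__(lib).__version__
        except ImportError:
            versions[lib] = "not installed"
    return versions


def run_all(config_path, out_dir, log=None) -> RunManifest:
    """Execute featurize -> select -> train -> importance from a config.

    Every artifact is delimited text under ``out_dir``; the returned
    manifest (also written as ``manifest.json``) lists config, digests,
    versions, seeds and per-stage outputs.  A stage failure raises
    :class:`StageError` carrying the partial manifest.
    """
    config = load_config(config_path)  # fail-fast, before any compute
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = (out / "run.log").open("a")

    def _log(msg: str) -> None:
        line = f"[soacml] {msg}"
        print(line, file=sys.stderr)
        print(line, file=log_file, flush=True)
        if log:
            log(msg)

    manifest = RunManifest(config=config.to_dict(), versions=_versions(),
                           seeds={"random_states": list(config.random_states),
                                  "synthetic_seed": ([config.synthetic.seed]
                                                     if config.synthetic else [])})
    if config.compounds_path:
        manifest.input_digests[config.compounds_path] = _sha256(Path(config.compounds_path))

    stage = "featurize"
    try:
        t0 = time.perf_counter()
        if config.synthetic is not None:
            study = SoacStudy.from_synthetic(config.synthetic, config=config)
        else:
            study = SoacStudy.from_compounds(config.compounds_path, config=config)
        feat_paths = [out / "descriptors.csv", out / "fingerprints.csv",
                      out / "targets.csv"]
        study.descriptors.to_csv(feat_paths[0])
        study.fingerprints.to_csv(feat_paths[1])
        study.targets.to_frame().to_csv(feat_paths[2], index_label="id")
        manifest.record_stage(stage, feat_paths)
        _log(f"stage={stage} rows_in={study.n_samples} "
             f"rows_out={study.n_samples} secs={time.perf_counter() - t0:.2f}")

        stage = "select+train+importance"
        t0 = time.perf_counter()
        results = study.fit(logger=_log)
        _log(f"stage=train rows_in={study.n_samples} "
             f"runs={len(results.runs)} secs={time.perf_counter() - t0:.2f}")

        saved = results.save(out)
        manifest.record_stage("select", [saved["selected_features"],
                                         saved["selection_report"]])
        manifest.record_stage("train", [saved["accuracy_grid"]])
        manifest.record_stage("importance", [saved["consensus_descriptor"],
                                             saved["consensus_fingerprint"],
                                             saved["consensus_combined"]])
        manifest.to_json(out / "manifest.json")
        _log(f"manifest written to {out / 'manifest.json'}")
        return manifest
    except Exception as exc:
        manifest.to_json(out / "manifest.partial.json")
        raise StageError(stage, manifest, exc) from exc
    finally:
        log_file.close()
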