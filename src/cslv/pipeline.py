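"""End-to-end pipeline: simulate/load → features → cohort → train → stratify.

Thin orchestration over the library modules, with every artifact written
to disk and a manifest JSON recording package versions, seeds, the
config hash and the hash of every output, so a run is auditable and
byte-reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import SplitSpec, split_train_test, undersample_matched
from .features import build_segments, compute_cslv
from .genome import default_build
from .io import (
    read_lrr,
    read_manifest,
    read_phenotypes,
    write_cslv,
    write_manifest,
    write_phenotypes,
)
from .model import ModelSpec, auc_ci, evaluate, fit, score
from .simulate import SimulationConfig, simulate_cohort
from .stratify import assign_quintiles, quintile_odds_ratios
from .transfer import transfer_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Either ``simulation`` is set (synthetic inputs are generated) or all
    three input paths are. Flat YAML key/value files map onto these
    fields; CLI flags override file values.
    """

    out_dir: str = "cslv_run"
    seed: int = 0
    k: int = 4
    manifest_path: str | None = None
    lrr_path: str | None = None
    lrr_dialect: str = "wide"
    phenotypes_path: str | None = None
    simulation: SimulationConfig | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    n_bins: int = 5
    train_groups: list[str] | None = None
    n_transfer_runs: int = 5

    def __post_init__(self) -> None:
        if self.simulation is None and not (
            self.manifest_path and self.lrr_path and self.phenotypes_path
        ):
            raise ValueError(
                "provide either a simulation config or all three input paths "
                "(manifest, LRR matrix, phenotypes)"
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if hasattr(o, "chromosomes"):
            return o.chromosomes
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Writes features.tsv, train.tsv/test.tsv, scores.tsv, fit_report.json,
    quintiles.tsv, optionally transfer.tsv, and run_manifest.json into
    ``config.out_dir``. Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            manifest, lrr, cohort, truth = simulate_cohort(sim)
            write_manifest(manifest, out / "manifest.tsv")
            write_phenotypes(cohort, out / "phenotypes.tsv")
            truth.events.to_csv(out / "ground_truth_events.tsv", sep="\t", index=False)
            logger.info(
                "simulate: %d samples (%d cases), %d markers",
                len(cohort), int(cohort["label"].sum()), len(manifest),
            )
        else:
            manifest = read_manifest(config.manifest_path)
            lrr = read_lrr(config.lrr_path, manifest, dialect=config.lrr_dialect)
            cohort = read_phenotypes(config.phenotypes_path)
            logger.info(
                "load: %d samples, %d markers (dropped %d sex / %d out-of-range)",
                lrr.shape[0], lrr.shape[1],
                manifest.dropped_sex, manifest.dropped_out_of_range,
            )

        stage = "features"
        segmap = build_segments(manifest.build, manifest, config.k)
        features = compute_cslv(lrr, segmap)
        write_cslv(features, out / "features.tsv")
        logger.info("features: %d samples x %d features (k=%d)",
                    features.shape[0], features.shape[1], config.k)

        stage = "cohort"
        split = dataclasses.replace(config.split, seed=config.seed)
        matched = undersample_matched(cohort, split)
        train, test = split_train_test(matched, split)
        write_phenotypes(train, out / "train.tsv")
        write_phenotypes(test, out / "test.tsv")
        logger.info(
            "cohort: matched %d -> %d (%d cases), train %d / test %d",
            len(cohort), len(matched), int(matched["label"].sum()),
            len(train), len(test),
        )

        stage = "train"
        spec = dataclasses.replace(config.model, seed=config.seed)
        result = fit(features, train, spec)
        evaluate(result, features, test)
        test_scores = score(result, features, test["sample_id"])
        _, ci_low, ci_high = auc_ci(
            test["label"].to_numpy(int), test_scores.to_numpy(), seed=config.seed
        )
        report = {
            "algorithm": spec.algorithm,
            "seed": config.seed,
            "cv_auc": result.cv_aucs,
            "train_auc": result.train_auc,
            "test_auc": result.test_auc,
            "ci": [ci_low, ci_high],
        }
        (out / "fit_report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(
            {"sample_id": test_scores.index, "score": test_scores.to_numpy()}
        ).to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.10g")
        logger.info("train: test AUC %.3f (CV mean %.3f)", result.test_auc,
                    sum(result.cv_aucs) / len(result.cv_aucs))

        stage = "stratify"
        bins = assign_quintiles(test_scores, config.n_bins)
        labels = pd.Series(
            test["label"].to_numpy(int), index=test["sample_id"].to_numpy()
        ).reindex(bins.index)
        qt = quintile_odds_ratios(labels, bins)
        qt.table.reset_index().to_csv(
            out / "quintiles.tsv", sep="\t", index=False, float_format="%.10g"
        )
        logger.info("stratify: top-vs-bottom fold %.2f", qt.top_vs_bottom_fold)

        if config.train_groups:
            stage = "transfer"
            tr = transfer_matrix(
                features, cohort, spec, config.train_groups,
                split=split, n_runs=config.n_transfer_runs,
            )
            tr.runs.to_csv(out / "transfer_runs.tsv", sep="\t", index=False,
                           float_format="%.10g")
            tr.summary.to_csv(out / "transfer.tsv", sep="\t", index=False,
                              float_format="%.10g")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    import numpy, scipy, sklearn  # noqa: PLC0415 - recorded versions

    manifest_doc = {
        "cslv_version": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit_learn": sklearn.__version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".tsv", ".json") and p.name != "run_manifest.json"
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_doc, indent=2))
    return manifest_doc
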