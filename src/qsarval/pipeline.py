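"""End-to-end model development pipeline.

Chains the stages a QSAR practitioner runs in order: descriptor
prefiltering, random 80/20 train/test split, exhaustive subset search on
the whole dataset, training-set fit, internal validation, external
validation on the held-out compounds, applicability-domain assessment and
the acceptance-criteria verdict.  Every stage's report is serialized to
JSON in the output directory, together with a manifest recording seeds,
versions and the row/column counts after each stage.  All randomness
flows from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .applicability import ad_assess
from .criteria import evaluate_criteria, sign_change_check
from .data import (
    Dataset,
    PairedPredictions,
    SplitSpec,
    read_descriptor_matrix,
    read_response,
)
from .modeling import all_subset_search, fit_mlr, predict, random_split
from .prefilter import prefilter_descriptors
from .validation_external import external_report
from .validation_internal import internal_report

log = logging.getLogger("qsarval")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults follow the field's
    conventional thresholds and the benchmark regime (k_sub=4, 80/20 split)."""

    x_csv: str | None = None
    y_csv: str | None = None
    endpoint: str | None = None
    split_csv: str | None = None
    out_dir: str = "qsarval_run"
    seed: int = 1
    test_fraction: float = 0.2
    k_sub: int = 4
    sort_key: str = "Q2_LOO"
    sd_min: float = 0.0001
    pair_r_max: float = 0.8
    resp_r_min: float = 0.3
    lmo_fraction: float = 0.3
    lmo_iterations: int = 1000
    yscr_iterations: int = 300
    subset_cap: int = 1_000_000

    @classmethod
    def from_mapping(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    ``dataset`` may be passed directly (e.g. a synthetic one); otherwise
    it is read from the configured CSV paths.  Returns a dict of the
    in-memory stage results.  Deterministic under a fixed config seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "qsarval_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t0, 3), **counts}
        log.info("stage %-18s %s", name, counts)

    if dataset is None:
        if not (config.x_csv and config.y_csv):
            raise ValueError("config needs x_csv and y_csv when no dataset is given")
        X = read_descriptor_matrix(config.x_csv)
        y = read_response(config.y_csv, config.endpoint)
        split = SplitSpec.read_csv(config.split_csv) if config.split_csv else None
        dataset = Dataset(X, y, split)
    stage("load", n_compounds=dataset.n_compounds,
          n_descriptors=len(dataset.descriptors.descriptor_names))

    # 1. prefilter on the full dataset
    Xf, pre_report = prefilter_descriptors(
        dataset.descriptors, dataset.response,
        sd_min=config.sd_min, pair_r_max=config.pair_r_max,
        resp_r_min=config.resp_r_min,
    )
    _dump(pre_report.to_dict(), out / "prefilter.json")
    stage("prefilter", surviving=len(pre_report.surviving),
          removed=pre_report.n_removed)
    dataset = Dataset(Xf, dataset.response, dataset.split)

    # 2. split (unless one was supplied)
    if dataset.split is None:
        split = random_split(dataset, config.test_fraction, seed=config.seed)
        dataset = Dataset(dataset.descriptors, dataset.response, split)
    split_frame = pd.DataFrame(
        {"id": list(dataset.split.assignment),
         "set": list(dataset.split.assignment.values())}
    )
    split_frame.to_csv(out / "split.csv", index=False)
    stage("split", n_train=len(dataset.split.train_ids),
          n_test=len(dataset.split.test_ids))

    # 3. all-subset search on the whole dataset
    search = all_subset_search(
        dataset.descriptors, dataset.response,
        k_sub=config.k_sub, sort_key=config.sort_key, cap=config.subset_cap,
    )
    search.to_frame().head(50).to_csv(out / "search_top.csv", index=False)
    best = list(search.best.descriptors)
    stage("search", n_evaluated=search.n_evaluated, best=",".join(best))

    # 4. fit on the training set
    train = dataset.subset("train")
    test = dataset.subset("test")
    model = fit_mlr(train.descriptors.select(best).frame, train.response)
    _dump(model.to_dict(), out / "model.json")
    stage("fit", n_tr=model.n_tr, R2=round(model.R2, 4))

    # 5. internal validation
    internal = internal_report(
        train.descriptors.select(best).frame, train.response,
        leave_fraction=config.lmo_fraction,
        lmo_iterations=config.lmo_iterations,
        yscr_iterations=config.yscr_iterations,
        seed=config.seed,
    )
    _dump(internal.to_dict(), out / "internal.json")
    stage("internal", Q2_LOO=round(internal.Q2_LOO, 4))

    # 6. external validation
    train_pairs = PairedPredictions(
        train.compound_ids, train.response.values,
        predict(model, train.descriptors.select(best).frame),
        ["train"] * train.n_compounds,
    )
    test_pairs = PairedPredictions(
        test.compound_ids, test.response.values,
        predict(model, test.descriptors.select(best).frame),
        ["test"] * test.n_compounds,
    )
    ext = external_report(test_pairs, train_pairs)
    _dump(ext.to_dict(), out / "external.json")
    stage("external", RMSE_ext=round(ext.RMSE_ext, 4))

    # 7. applicability domain
    ad = ad_assess(model, dataset)
    ad.to_csv(out / "williams.csv")
    stage("ad", h_star=round(ad.h_star, 4), n_outliers=len(ad.outlier_ids))

    # 8. criteria and descriptor diagnostics
    verdict = evaluate_criteria(fit=model, internal=internal, external=ext)
    _dump(verdict.to_dict(), out / "criteria.json")
    diag = sign_change_check(dataset, best)
    _dump(diag.to_dict(), out / "descriptor_diagnostics.json")
    stage("criteria", overall_pass=verdict.overall_pass)

    _dump(manifest, out / "manifest.json")
    return {
        "dataset": dataset,
        "prefilter": pre_report,
        "search": search,
        "model": model,
        "internal": internal,
        "external": ext,
        "ad": ad,
        "verdict": verdict,
        "diagnostics": diag,
        "manifest": manifest,
    }
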