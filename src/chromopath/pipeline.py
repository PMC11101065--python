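"""End-to-end orchestration: data -> features -> stats -> model -> report.

The pipeline mirrors the study design: feature extraction (or simulation),
benign/malignant univariate comparison, 7:3 random split, comparison of
training vs validation partitions, variable selection, multivariable
logistic fit with Wald table and nomogram, and evaluation (ROC/AUC with
bootstrap CI, Hosmer-Lemeshow, calibration curve, decision curve) on both
partitions.  All randomness flows from one run-level seed through
per-stage derived seeds, so each stage is individually reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import compare_groups, split_dataset
from .evaluation import evaluate_model
from .features import extract_features
from .model import BinaryNomogram, select_variables
from .reference import FEATURES
from .simulate import SimulationConfig, generate_dataset, load_config, simulate_feature_table

logger = logging.getLogger("chromopath")

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "split", "bootstrap_train", "bootstrap_val", "dca")


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Exactly one of *manifest* (CSV of image files to extract features from)
    or *simulation* (synthetic-data config) must be provided.  ``seed``
    deterministically derives per-stage seeds.
    """

    output_dir: Path
    manifest: Path | None = None
    simulation: SimulationConfig | None = None
    render_images: bool = False
    validation_fraction: float = 0.3
    alpha: float = 0.05
    n_boot: int = 1000
    hl_groups: int = 10
    dca_step: float = 0.01
    dca_boot: int = 0
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if (self.manifest is None) == (self.simulation is None):
            raise ValueError("provide exactly one of manifest or simulation")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(_STAGES, children)
        }

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: str | Path,
                  seed: int | None = None) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        pipe = raw.get("pipeline", {})
        manifest = raw.get("manifest")
        sim = None if manifest else load_config(path)
        cfg = cls(
            output_dir=Path(output_dir),
            manifest=Path(manifest) if manifest else None,
            simulation=sim,
            render_images=bool(pipe.get("render_images", False)),
            validation_fraction=float(pipe.get("validation_fraction", 0.3)),
            alpha=float(pipe.get("alpha", 0.05)),
            n_boot=int(pipe.get("n_boot", 1000)),
            hl_groups=int(pipe.get("hl_groups", 10)),
            dca_step=float(pipe.get("dca_step", 0.01)),
            dca_boot=int(pipe.get("dca_boot", 0)),
            seed=int(raw.get("seed", 0) if seed is None else seed),
            make_plots=bool(pipe.get("make_plots", False)),
        )
        return cfg


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report.

    Outputs under ``config.output_dir``: ``report.json`` (single source of
    truth for every number), ``tables/*.csv`` (feature table, comparisons,
    Wald table, split manifest, calibration/DCA tables), ``model.json``,
    and optional ``figures/*.png``.
    """
    out = config.output_dir
    (out / "tables").mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    from datetime import datetime, timezone

    report: dict = {
        "software": {"name": "chromopath", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seeds": {"run": config.seed, **seeds},
        "config": {
            "validation_fraction": config.validation_fraction,
            "alpha": config.alpha,
            "n_boot": config.n_boot,
            "hl_groups": config.hl_groups,
            "dca_step": config.dca_step,
        },
    }

    # --- data stage -------------------------------------------------------
    if config.simulation is not None:
        _stage("simulate")
        sim = config.simulation
        sim.seed = seeds["simulate"]
        if config.render_images:
            manifest = generate_dataset(sim, out / "images")
            table, failures = extract_features(manifest, root=out / "images")
            report["extraction_failures"] = failures
        else:
            table = simulate_feature_table(sim)
    else:
        _stage("extract")
        manifest = pd.read_csv(config.manifest)
        table, failures = extract_features(manifest, root=Path(config.manifest).parent)
        report["extraction_failures"] = failures
    if table["label"].nunique() < 2:
        raise RuntimeError("data stage: need both benign and malignant rows")
    table.to_csv(out / "tables" / "features.csv", index=False)
    report["n_images"] = len(table)
    report["n_by_class"] = table["label"].value_counts().to_dict()

    features = [f for f in FEATURES if f in table.columns]

    # --- univariate comparison (full cohort) ------------------------------
    _stage("cohort comparison")
    try:
        full_cmp = compare_groups(table, features,
                                  group_order=("benign", "malignant"))
    except ValueError as exc:
        raise RuntimeError(f"cohort-comparison stage: {exc}") from exc
    full_cmp.to_csv(out / "tables" / "class_comparison.csv", index=False)
    report["class_comparison"] = full_cmp.to_dict(orient="records")

    # --- split ------------------------------------------------------------
    _stage("split")
    split = split_dataset(table, config.validation_fraction, seeds["split"])
    train = table.iloc[split.train_idx].reset_index(drop=True)
    val = table.iloc[split.val_idx].reset_index(drop=True)
    part = pd.DataFrame(
        {
            "image_id": table["image_id"],
            "partition": np.where(
                np.isin(np.arange(len(table)), split.val_idx), "validation",
                "training"
            ),
        }
    )
    part.to_csv(out / "tables" / "split.csv", index=False)
    report["split"] = {
        "n_train": split.n_train,
        "n_val": split.n_val,
        "seed": split.seed,
    }

    # train-vs-validation balance (no class split within partitions)
    bal = table.copy()
    bal["partition"] = part["partition"].to_numpy()
    try:
        part_cmp = compare_groups(bal, features, group_key="partition",
                                  group_order=("validation", "training"))
    except ValueError as exc:
        raise RuntimeError(f"split-comparison stage: {exc}") from exc
    part_cmp.to_csv(out / "tables" / "partition_comparison.csv", index=False)
    report["partition_comparison"] = part_cmp.to_dict(orient="records")

    # --- selection + fit (training partition) -----------------------------
    _stage("variable selection and fit")
    if train["label"].nunique() < 2 or val["label"].nunique() < 2:
        raise RuntimeError("split stage: a partition lost one class entirely")
    try:
        selected, trace = select_variables(train, features, alpha=config.alpha)
    except ValueError as exc:
        raise RuntimeError(f"selection stage: {exc}") from exc
    report["selection"] = {"selected": selected, "trace": trace}
    if not selected:
        raise RuntimeError("fit stage: no variable survived selection")
    try:
        results = BinaryNomogram.from_dataframe(train, selected).fit()
    except ValueError as exc:
        raise RuntimeError(f"fit stage: {exc}") from exc
    wald = results.wald_table()
    wald.to_csv(out / "tables" / "wald_table.csv")
    report["model"] = {
        "features": selected,
        "beta": results.coefficients(),
        "se": {k: float(v) for k, v in results.bse.items()},
        "wald": wald.reset_index(names="variable").to_dict(orient="records"),
        "n_train": results.nobs,
    }
    results.to_json(out / "model.json", seed=config.seed)

    nomo = results.nomogram()
    report["nomogram"] = {
        "features": list(nomo.features),
        "ranges": {k: list(v) for k, v in nomo.ranges.items()},
        "reference_values": nomo.ref,
        "logodds_per_point": nomo.scale,
        "axis_maxima": {f: nomo.axis_maximum(f) for f in nomo.features},
    }

    # --- evaluation -------------------------------------------------------
    _stage("evaluation")
    evals = {}
    for name, part_tbl, bseed in (
        ("training", train, seeds["bootstrap_train"]),
        ("validation", val, seeds["bootstrap_val"]),
    ):
        probs = results.predict(part_tbl)
        y = (part_tbl["label"] == "malignant").to_numpy().astype(int)
        ev = evaluate_model(
            probs, y,
            n_boot=config.n_boot, seed=bseed, hl_groups=config.hl_groups,
            calibration_bins=config.hl_groups,
            dca_thresholds=np.arange(config.dca_step, 1.0, config.dca_step),
            dca_boot=config.dca_boot,
        )
        ev.calibration.to_csv(out / "tables" / f"calibration_{name}.csv",
                              index=False)
        ev.dca.to_csv(out / "tables" / f"dca_{name}.csv", index=False)
        evals[name] = ev
        report[f"evaluation_{name}"] = ev.to_dict()

    if config.make_plots:
        from . import plots

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        plots.plot_roc(
            {k: v.roc for k, v in evals.items()}, figdir / "roc.png"
        )
        plots.plot_calibration(
            {k: v.calibration for k, v in evals.items()},
            figdir / "calibration.png",
        )
        plots.plot_dca(evals["validation"].dca, figdir / "dca.png")
        plots.plot_nomogram(nomo, figdir / "nomogram.png")

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("report written to %s", out / "report.json")
    return report
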