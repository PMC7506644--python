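"""End-to-end runs: simulate/load -> extract -> balance -> select ->
evaluate, with a provenance manifest and deterministic seed flow.

All randomness derives from one master seed through named per-stage
child seeds recorded in the manifest, so rerunning an identical
configuration reproduces identical artifacts byte for byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import FeatureCatalog, GROUP_ORDER, builtin_catalog, ga_selected_mask
from .classify import EKNN, KNN1, SVM2, SVM3, ClassifierSpec, evaluate, smote_balance
from .features import FeatureMatrix, extract_matrix
from .io import read_generic
from .selection import GAConfig, ga_select, pca_select
from .synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "RunConfig",
    "run_pipeline",
    "reduction_report",
    "mask_to_json",
    "mask_from_json",
    "CLASSIFIER_ALIASES",
]

CLASSIFIER_ALIASES = {"svm3": SVM3, "svm2": SVM2, "knn1": KNN1, "eknn": EKNN}


def mask_to_json(mask: np.ndarray, path, ids=None, extra: Optional[dict] = None) -> None:
    """Serialize a feature mask with its selected descriptor ids."""
    mask = np.asarray(mask, dtype=bool)
    if ids is None:
        cat = builtin_catalog()
        ids = cat.ids if len(cat) == len(mask) else [f"f{i:02d}" for i in range(len(mask))]
    if len(ids) != len(mask):
        raise ValueError("ids length does not match mask length")
    doc = {
        "catalog_length": len(mask),
        "bits": "".join("1" if b else "0" for b in mask),
        "selected_ids": [i for i, b in zip(ids, mask) if b],
        "n_selected": int(mask.sum()),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def mask_from_json(path) -> np.ndarray:
    doc = json.loads(Path(path).read_text())
    return np.array([c == "1" for c in doc["bits"]], dtype=bool)


def reduction_report(full: FeatureCatalog, mask: np.ndarray) -> pd.DataFrame:
    """Per-group and overall feature-count reduction accounting.

    Rows: original count, selected count, and the percent reduction
    100 * (1 - selected/original), reported to two decimals.
    """
    mask = np.asarray(mask, dtype=bool)
    selected = full.subset(mask)
    orig_counts = full.group_counts()
    sel_counts = selected.group_counts()
    cols = list(GROUP_ORDER) + ["total"]
    orig = [orig_counts[g] for g in GROUP_ORDER] + [len(full)]
    sel = [sel_counts[g] for g in GROUP_ORDER] + [len(selected)]
    red = [
        round(100.0 * (1.0 - s / o), 2) if o else 0.0
        for s, o in zip(sel, orig)
    ]
    return pd.DataFrame(
        [orig, sel, red],
        index=["original", "selected", "reduction_pct"],
        columns=cols,
    )


@dataclass
class RunConfig:
    """Declarative configuration of one end-to-end run."""

    source: str = "simulate"  # simulate | generic
    input_path: Optional[str] = None  # for source=generic
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    catalog: str = "full"  # full | ga47 | mask:<path> | pca:<variance>
    classifier: str = "svm3"
    balance_to: Optional[int] = None  # SMOTE target per class; None = skip
    repetitions: int = 10
    folds: int = 10
    master_seed: int = 0
    out_dir: str = "run"
    ga: Optional[GAConfig] = None  # set to run GA selection instead of a fixed mask

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SyntheticConfig(**raw.pop("simulate", {}))
        ga_raw = raw.pop("ga", None)
        ga = GAConfig(**ga_raw) if ga_raw is not None else None
        return cls(simulate=sim, ga=ga, **raw)


def _child_seeds(master_seed: int) -> dict:
    ss = np.random.SeedSequence(master_seed)
    names = ("simulate", "smote", "select", "evaluate")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, ss.spawn(len(names)))
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, writing every artifact under ``out_dir``.

    Returns the run directory.  Any stage failure propagates with the
    stage name prepended; artifacts of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.master_seed)
    manifest = {
        "geomexpr_version": __version__,
        "python": platform.python_version(),
        "master_seed": config.master_seed,
        "child_seeds": seeds,
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("simulate", "ga")},
            "simulate": asdict(config.simulate),
            "ga": asdict(config.ga) if config.ga else None,
        },
        "stages": [],
    }

    def _stage(name):
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    try:
        # ----- acquisition -------------------------------------------------
        if config.source == "simulate":
            sim = SyntheticConfig(**{**asdict(config.simulate), "rng_seed": seeds["simulate"]})
            faces = generate_dataset(sim)
            from .io import write_generic

            write_generic(faces, out / "faces.csv")
        elif config.source == "generic":
            if not config.input_path or not Path(config.input_path).exists():
                raise FileNotFoundError(f"input file {config.input_path!r} not found")
            faces = read_generic(config.input_path)
        else:
            raise ValueError(f"unknown source {config.source!r}")
        _stage("acquisition")

        # ----- extraction --------------------------------------------------
        fm = extract_matrix(faces)
        fm.to_csv(out / "features.csv")
        _stage("extraction")

        # ----- balancing ---------------------------------------------------
        if config.balance_to is not None:
            Xb, yb = smote_balance(
                fm.X, fm.y, config.balance_to, rng=np.random.default_rng(seeds["smote"])
            )
            fm = FeatureMatrix(X=Xb, y=yb, ids=fm.ids)
            fm.to_csv(out / "features_balanced.csv")
            _stage("balancing")

        # ----- selection ---------------------------------------------------
        eval_matrix = fm
        if config.ga is not None:
            ga_cfg = GAConfig(**{**asdict(config.ga), "rng_seed": seeds["select"]})
            result = ga_select(fm.X, fm.y, ga_cfg)
            mask = result.best_mask
            mask_to_json(mask, out / "mask.json", extra={"best_fitness": result.best_fitness})
            pd.DataFrame(
                {"generation": range(len(result.fitness_history)),
                 "best_fitness": result.fitness_history}
            ).to_csv(out / "history.csv", index=False)
            eval_matrix = fm.select(mask)
            reduction_report(builtin_catalog(), mask).to_csv(out / "reduction.csv")
        elif config.catalog == "ga47":
            mask = ga_selected_mask()
            mask_to_json(mask, out / "mask.json")
            eval_matrix = fm.select(mask)
            reduction_report(builtin_catalog(), mask).to_csv(out / "reduction.csv")
        elif config.catalog.startswith("mask:"):
            mask = mask_from_json(config.catalog.split(":", 1)[1])
            eval_matrix = fm.select(mask)
            reduction_report(builtin_catalog(), mask).to_csv(out / "reduction.csv")
        elif config.catalog.startswith("pca:"):
            frac = float(config.catalog.split(":", 1)[1])
            sel, scores = pca_select(fm.X, frac)
            eval_matrix = FeatureMatrix(
                X=scores,
                y=fm.y,
                ids=[f"PC{i + 1}" for i in range(sel.n_components)],
                subjects=list(fm.subjects),
            )
            (out / "pca.json").write_text(
                json.dumps(
                    {
                        "variance_fraction": sel.variance_fraction,
                        "n_components": sel.n_components,
                        "explained_variance_ratio": sel.explained_variance_ratio.tolist(),
                    },
                    indent=1,
                )
            )
        elif config.catalog != "full":
            raise ValueError(f"unknown catalog choice {config.catalog!r}")
        _stage("selection")

        # ----- evaluation --------------------------------------------------
        spec = CLASSIFIER_ALIASES.get(config.classifier)
        if spec is None:
            raise ValueError(f"unknown classifier {config.classifier!r}")
        report = evaluate(
            spec,
            eval_matrix.X,
            eval_matrix.y,
            n_repetitions=config.repetitions,
            folds=config.folds,
            seed=seeds["evaluate"],
        )
        report.to_json(out / "report.json")
        report.confusion_frame().to_csv(out / "confusion.csv")
        _stage("evaluation")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {len(manifest['stages'])} failed after "
            f"{manifest['stages']}: {exc}"
        ) from exc
    return out
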