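"""End-to-end pipeline: clean → OAV → features → classify → screen → networks.

Driven by a single YAML/dict config with one root seed; every run writes its
intermediate tables, a JSON manifest (package and library versions, seed,
parameters, input checksums) and a log, so a run can be replayed and
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, datasets
from .classify import tune_and_evaluate
from .exceptions import PipelineStageError, ValidationError
from .network import group_networks
from .oav import compute_oav, compute_oav_sum
from .preprocess import filter_sparse_compounds, remove_outlier_samples
from .ratios import assemble_features
from .simulate import default_cohort_spec, generate_cohort, spec_from_yaml
from .stats import significance_screen
from .tables import read_groups, read_odor_map, read_quant_table, read_threshold_table, write_network

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("odorbalance")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 17,
    "input": {"quant": None, "unit": "ug/L", "thresholds": None, "odors": None, "groups": None},
    "simulate": {"spec": None},
    "clean": {"max_zero_fraction": 0.5, "lof_neighbors": 20, "lof_threshold": 1.5},
    "features": {"mode": "ratio"},
    "classify": {"folds": 10, "grid": None},
    "screen": {"alpha": 0.05},
    "network": {"threshold": 0.6, "include_negative": True},
}


def _merge(base: Mapping, override: Mapping | None) -> dict:
    out = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn

    return {
        "odorbalance": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }


def run_pipeline(config: Mapping[str, Any] | None, output_dir: str | Path) -> Path:
    """Run every stage on real or simulated input and write all artifacts.

    Returns the run directory.  Any stage failure raises
    :class:`~odorbalance.exceptions.PipelineStageError` naming the stage.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    checksums: dict[str, str] = {}
    artifacts: list[str] = []

    def emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        df.to_csv(outdir / name, **kwargs)
        artifacts.append(name)

    try:
        # ----- inputs ----------------------------------------------------
        stage = "input"
        inp = cfg["input"]
        for key in ("quant", "thresholds", "odors", "groups"):
            path = inp.get(key)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{key} file not found: {path}")
        if inp.get("quant"):
            quant = read_quant_table(inp["quant"], unit=inp.get("unit", "ug/L"))
            if not inp.get("groups"):
                raise ValidationError("a groups file is required with a real quantity table")
            groups = read_groups(inp["groups"], samples=quant.index)
            for key in ("quant", "groups"):
                checksums[key] = _sha256(Path(inp[key]))
        else:
            spec_path = cfg["simulate"].get("spec")
            spec = spec_from_yaml(spec_path) if spec_path else default_cohort_spec()
            if spec_path:
                checksums["simulate_spec"] = _sha256(Path(spec_path))
            quant, groups = generate_cohort(spec, seed=seed)
            log.info("simulated cohort: %d samples × %d compounds", *quant.shape)
        if inp.get("thresholds"):
            thresholds = read_threshold_table(inp["thresholds"])
            checksums["thresholds"] = _sha256(Path(inp["thresholds"]))
        else:
            thresholds = datasets.reference_thresholds()
        if inp.get("odors"):
            odors = read_odor_map(inp["odors"])
            checksums["odors"] = _sha256(Path(inp["odors"]))
        else:
            odors = datasets.reference_odor_map()
        emit(quant, "quant_raw.csv", index_label="sample")
        groups.rename_axis("sample").to_frame().to_csv(outdir / "groups.csv")
        artifacts.append("groups.csv")

        # ----- clean ------------------------------------------------------
        stage = "clean"
        c = cfg["clean"]
        quant, dropped = filter_sparse_compounds(quant, max_zero_fraction=c["max_zero_fraction"])
        emit(dropped, "removed_compounds.csv", index=False)
        quant, outliers = remove_outlier_samples(
            quant, groups, n_neighbors=int(c["lof_neighbors"]), lof_threshold=c["lof_threshold"]
        )
        groups = groups.loc[quant.index]
        emit(outliers, "removed_samples.csv", index=False)
        emit(quant, "quant_clean.csv", index_label="sample")
        log.info("cleaned table: %d samples × %d compounds", *quant.shape)

        # ----- OAV --------------------------------------------------------
        stage = "oav"
        oav = compute_oav(quant, thresholds)
        oav_sum = compute_oav_sum(oav, odors)
        emit(oav, "oav.csv", index_label="sample")
        emit(oav_sum, "oav_sum.csv", index_label="sample")

        # ----- features ---------------------------------------------------
        stage = "features"
        features, meta = assemble_features(oav, oav_sum, odors, mode=cfg["features"]["mode"])
        emit(features, "features.csv", index_label="sample")
        emit(meta, "feature_meta.csv", index=False)
        log.info("feature matrix: %d samples × %d features", *features.shape)

        # ----- classify ---------------------------------------------------
        stage = "classify"
        report = tune_and_evaluate(
            features, groups, grid=cfg["classify"]["grid"],
            folds=int(cfg["classify"]["folds"]), seed=seed,
        )
        report.to_json(outdir / "classifier_report.json")
        artifacts.append("classifier_report.json")
        emit(report.importances, "importances.csv", index=False)
        emit(
            pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr}),
            "roc.csv", index=False,
        )
        log.info("mean CV accuracy %.4f, AUC %.4f", report.mean_accuracy, report.roc_auc)

        # ----- screen -----------------------------------------------------
        stage = "screen"
        alpha = cfg["screen"]["alpha"]
        emit(significance_screen(quant, groups, alpha=alpha), "screen_compounds.csv", index=False)
        emit(significance_screen(oav_sum, groups, alpha=alpha), "screen_descriptors.csv", index=False)

        # ----- networks ---------------------------------------------------
        stage = "network"
        ncfg = cfg["network"]
        node_meta = pd.DataFrame(
            {
                f"mean_{g}": quant.loc[groups[groups == g].index].mean(axis=0)
                for g in pd.unique(groups)
            }
        )
        nets = group_networks(
            quant, groups, node_meta=node_meta,
            threshold=ncfg["threshold"], include_negative=ncfg["include_negative"],
        )
        for name, net in nets.items():
            fname = f"network_{name}.graphml"
            write_network(net, outdir / fname, format="graphml")
            artifacts.append(fname)

        # ----- manifest ---------------------------------------------------
        stage = "manifest"
        manifest = {
            "versions": _library_versions(),
            "seed": seed,
            "config": cfg,
            "input_checksums": checksums,
            "artifacts": sorted(artifacts),
            "n_samples": int(quant.shape[0]),
            "n_compounds": int(quant.shape[1]),
            "n_features": int(features.shape[1]),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except PipelineStageError:
        raise
    except Exception as exc:
        log.exception("stage '%s' failed", stage)
        raise PipelineStageError(stage, str(exc)) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
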