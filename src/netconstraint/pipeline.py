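"""End-to-end orchestration: network -> metrics -> classes -> models -> null.

A single top-level seed fans out deterministically to per-stage seeds
(CRC32 of ``"stage:seed"``), so stages never share a random stream and
any stage can be rerun in isolation.  Every run writes a manifest with
the config hash, the derived seeds and per-stage row counts; reruns
with the same config and seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import network as _network
from . import permutation as _permutation
from . import stats as _stats
from . import topology as _topology

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the published analysis values.

    0.7 edge-confidence cutoff, 1%/10%/10% seed percentiles (BC / NC /
    ASPL), 9-fold cross-validation with 1000 replicates, 1000 random
    draws for the null.
    """

    network_path: str = ""
    attributes_path: str = ""
    focal_path: str = ""
    outdir: str = "results"
    score_threshold: float = 0.7
    score_scale: str = "unit"
    pct_bc: float = 0.01
    pct_nc: float = 0.10
    pct_aspl: float = 0.10
    k_neighbors: int = 5
    folds: int = 9
    cv_replicates: int = 1000
    support_threshold: float = 0.5
    n_draws: int = 1000
    tail: str = "two-sided"
    include_uncertain_metrics: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(stage: str, seed: int) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    return zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write their outputs plus a manifest.

    Returns the manifest dict.  Stage errors propagate annotated with
    the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {s: stage_seed(s, config.seed)
                  for s in ("classify", "cv", "permutation")},
        "counts": {},
        "outputs": [],
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("network_io")
        g = _network.read_edge_table(config.network_path,
                                     score_threshold=config.score_threshold,
                                     score_scale=config.score_scale)
        g = _network.largest_connected_component(g)
        attrs = _network.read_attribute_table(config.attributes_path)
        attrs = _network.join_attributes(g, attrs)
        manifest["counts"]["nodes"] = g.number_of_nodes()
        manifest["counts"]["edges"] = g.number_of_edges()
        manifest["counts"]["attribute_rows"] = len(attrs)
    except Exception as e:
        raise RuntimeError(f"stage network_io failed: {e}") from e

    try:
        _stage("topology")
        metrics = _topology.node_metrics(g)
        _network.write_attribute_table(metrics, outdir / "metrics.tsv")
        manifest["outputs"].append("metrics.tsv")
    except Exception as e:
        raise RuntimeError(f"stage topology failed: {e}") from e

    try:
        _stage("classify")
        classes, training = _classify.classify_network(
            metrics,
            pct_bc=config.pct_bc, pct_nc=config.pct_nc, pct_aspl=config.pct_aspl,
            k_neighbors=config.k_neighbors,
            support_threshold=config.support_threshold,
            seed=stage_seed("classify", config.seed))
        reports = {}
        for strat in (False, True):
            reps = _classify.cross_validate(
                training, folds=config.folds, replicates=config.cv_replicates,
                stratified=strat, seed=stage_seed("cv", config.seed))
            reports["stratified" if strat else "plain"] = _classify.summarize_cv(reps)
        _network.write_attribute_table(classes, outdir / "classes.tsv")
        _write_json(reports, outdir / "cv_summary.json")
        manifest["outputs"] += ["classes.tsv", "cv_summary.json"]
        manifest["counts"]["class_counts"] = classes["label"].value_counts().to_dict()
    except Exception as e:
        raise RuntimeError(f"stage classify failed: {e}") from e

    try:
        _stage("stats")
        table = metrics.join(attrs, how="left").join(classes[["label"]])
        complete = table["mean_phylop"].notna()
        table.loc[complete, "phylop_norm"] = _stats.order_quantile_normalize(
            table.loc[complete, "mean_phylop"])
        mtab = table if config.include_uncertain_metrics else \
            table[table["label"] != "uncertain"]
        metrics_model = _stats.fit_metrics_model(mtab)
        category_model, category_contrasts = _stats.fit_category_model(table)
        models = {
            "metrics_model": metrics_model.to_dict(),
            "category_model": category_model.to_dict(),
            "category_contrasts": [c.to_dict() for c in category_contrasts],
        }
        focal = None
        if config.focal_path:
            focal = _network.read_attribute_table(config.focal_path)
            ftab = table.join(focal, how="inner")
            hib_model, hib_contrasts = _stats.fit_hibernation_model(ftab)
            models["hibernation_model"] = hib_model.to_dict()
            models["hibernation_contrasts"] = [c.to_dict() for c in hib_contrasts]
            manifest["counts"]["focal_matched"] = len(ftab)
        _write_json(models, outdir / "models.json")
        manifest["outputs"].append("models.json")
        manifest["counts"]["model_n"] = metrics_model.n
    except Exception as e:
        raise RuntimeError(f"stage stats failed: {e}") from e

    try:
        _stage("permutation")
        if focal is not None:
            frame = metrics.join(attrs, how="left")
            nulls = _permutation.random_draw_null(
                frame, list(focal.index), n_draws=config.n_draws,
                tail=config.tail, seed=stage_seed("permutation", config.seed))
            _write_json({m: r.to_dict() for m, r in nulls.items()},
                        outdir / "null.json")
            pd.DataFrame({m: r.null_means for m, r in nulls.items()}).to_csv(
                outdir / "null_draws.tsv", sep="\t", index=False,
                lineterminator="\n")
            manifest["outputs"] += ["null.json", "null_draws.tsv"]
    except Exception as e:
        raise RuntimeError(f"stage permutation failed: {e}") from e

    _write_json(manifest, outdir / "manifest.json")
    manifest["outputs"].append("manifest.json")
    return manifest
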