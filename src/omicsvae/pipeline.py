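"""Configuration-driven orchestration of the full workflow.

Stages run in fixed order — simulate, preprocess, train, embed, classify,
survival, biomarkers — each writing its artifacts plus a SHA-256 checksum
into the run manifest.  A single global seed fans out to per-stage seeds via
``numpy.random.SeedSequence((global_seed, stage_index))``, so any stage is
reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, biomarkers, classify, embedding, io, models, survival, synthetic

STAGES = ("simulate", "preprocess", "train", "embed", "classify",
          "survival", "biomarkers")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    simulate: Optional[dict] = None  # SyntheticSpec-shaped mapping
    inputs: Optional[dict] = None  # modality -> path, plus probe_map/clinical/labels
    preprocess: dict = field(default_factory=lambda: {"normalize": True})
    model: dict = field(default_factory=dict)  # ModelSpec overrides
    evaluation: dict = field(default_factory=lambda: {"folds": 5, "first_k": 2})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if "simulate" not in self.stages and not self.inputs and self.simulate is None:
            raise ValueError("config needs either a simulate block or input paths")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence((global_seed, idx)).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _synthetic_spec(cfg: RunConfig) -> synthetic.SyntheticSpec:
    sim = dict(cfg.simulate or {})
    blocks = [synthetic.BlockSpec(**b) for b in sim.pop("block_specs", [])] or None
    surv = sim.pop("survival", None)
    kwargs = dict(sim)
    if blocks:
        kwargs["block_specs"] = blocks
    if surv:
        if surv.get("hazard_coefficients") is not None:
            surv = {**surv, "hazard_coefficients": np.asarray(surv["hazard_coefficients"], float)}
        kwargs["survival"] = synthetic.SurvivalSpec(**surv)
    if "class_proportions" in kwargs:
        kwargs["class_proportions"] = tuple(kwargs["class_proportions"])
    kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
    return synthetic.SyntheticSpec(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the run manifest (also written)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "config": asdict(config),
        "stages": {},
        "artifacts": {},
    }
    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    manifest["config_hash"] = _sha256(cfg_path)

    state: Dict = {}

    def record(stage: str, t0: float, paths: Dict[str, str]):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for name, p in paths.items():
            manifest["artifacts"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            paths = _run_stage(stage, config, state, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, t0, paths)

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stage(stage: str, cfg: RunConfig, state: Dict, outdir: Path) -> Dict[str, str]:
    seed = stage_seed(cfg.seed, stage)
    if stage == "simulate":
        spec = _synthetic_spec(cfg)
        dataset, truth = synthetic.generate_multiomics(spec)
        state["dataset_raw"], state["truth"] = dataset, truth
        return synthetic.write_dataset(dataset, outdir / "data")

    if stage == "preprocess":
        if "dataset_raw" in state:
            dataset = state["dataset_raw"]
            blocks, labels, clinical = dataset.blocks, dataset.labels, dataset.clinical
        else:
            inputs = dict(cfg.inputs or {})
            pm = io.read_probe_map(inputs.pop("probe_map")) if "probe_map" in inputs else None
            clinical = io.read_clinical(inputs.pop("clinical")) if "clinical" in inputs else None
            labels = None
            if "labels" in inputs:
                labels = pd.read_csv(inputs.pop("labels"), sep="\t",
                                     index_col=0).iloc[:, 0]
            blocks = [io.read_genomic_matrix(p, modality=m, probe_map=pm)
                      for m, p in inputs.items()]
        ds = io.intersect_samples(blocks, labels=labels, clinical=clinical)
        cleaned = []
        removed_log = {}
        for b in ds.blocks:
            b2, removed = io.drop_degenerate_features(b)
            removed_log[b.modality] = removed
            if cfg.preprocess.get("normalize", True):
                b2 = io.minmax_normalize(b2)
            cleaned.append(b2)
        ds = io.MultiOmicsDataset(cleaned, labels=ds.labels, clinical=ds.clinical)
        state["dataset"] = ds
        state["integrated"] = io.concatenate_blocks(ds)
        p = outdir / "preprocess_report.json"
        with open(p, "w") as fh:
            json.dump({"n_samples": ds.n_samples, "total_features": ds.total_features,
                       "removed_features": removed_log}, fh, indent=2)
        return {"preprocess_report": str(p)}

    if stage == "train":
        ds = state["dataset"]
        mcfg = dict(cfg.model)
        if "hidden_widths" in mcfg:
            mcfg["hidden_widths"] = tuple(mcfg["hidden_widths"])
        mcfg.setdefault("seed", seed)
        if mcfg.get("beta", 0) > 0:
            mcfg.setdefault("n_classes", int(ds.labels.nunique()))
        spec = models.ModelSpec(**mcfg)
        model = models.build_model(spec, ds.schemas())
        labels = ds.labels.to_numpy() if ds.labels is not None else None
        models.train(model, ds.block_arrays(), labels=labels)
        state["model"] = model
        ckpt = outdir / "model.npz"
        model.save(ckpt)
        hist = outdir / "training_history.tsv"
        pd.DataFrame([asdict(h) for h in model.history]).to_csv(hist, sep="\t", index=False)
        lfs = models.extract_latent(model, ds.block_arrays())
        state["lfs"] = lfs
        lf_path = outdir / "latent_features.tsv"
        pd.DataFrame(lfs, index=ds.sample_ids,
                     columns=[f"LF{i}" for i in range(lfs.shape[1])]
                     ).rename_axis("sample_id").to_csv(lf_path, sep="\t")
        return {"model": str(ckpt), "history": str(hist), "latent_features": str(lf_path)}

    if stage == "embed":
        ds, lfs = state["dataset"], state["lfs"]
        k = cfg.evaluation.get("first_k", 2)
        emb = embedding.select_first_lfs(lfs, k=k)
        tsne = embedding.tsne_on_latent(lfs, k=2, seed=seed)
        paths = {}
        for name, e in (("first_lfs", emb), ("tsne_on_lfs", tsne)):
            p = outdir / f"embedding_{name}.tsv"
            pd.DataFrame(e.coordinates, index=ds.sample_ids).rename_axis(
                "sample_id").to_csv(p, sep="\t")
            paths[f"embedding_{name}"] = str(p)
            if ds.labels is not None:
                fig = outdir / f"embedding_{name}.png"
                embedding.plot_embedding(e, ds.labels.to_numpy(), fig)
                paths[f"embedding_{name}_plot"] = str(fig)
        if ds.labels is not None:
            acc, _ = embedding.cluster_purity(emb, ds.labels.to_numpy(),
                                              int(ds.labels.nunique()), seed=seed)
            state["cluster_purity"] = acc
        return paths

    if stage == "classify":
        ds, lfs = state["dataset"], state["lfs"]
        if ds.labels is None:
            raise ValueError("classification stage requires labels")
        folds = cfg.evaluation.get("folds", 5)
        report = classify.ann_classify_cv(lfs, ds.labels.to_numpy(),
                                          folds=folds, seed=seed)
        state["cv_report"] = report
        p = outdir / "classification_report.json"
        with open(p, "w") as fh:
            json.dump({
                "accuracy_mean_sd": report.accuracy,
                "precision_mean_sd": report.precision,
                "recall_mean_sd": report.recall,
                "f1_mean_sd": report.f1,
                "confusion_matrix": report.confusion.tolist(),
                "cluster_purity": state.get("cluster_purity"),
            }, fh, indent=2)
        return {"classification_report": str(p)}

    if stage == "survival":
        ds, lfs = state["dataset"], state["lfs"]
        if ds.clinical is None:
            raise ValueError("survival stage requires a clinical table")
        result = survival.run_survival_pipeline(lfs, ds.clinical, seed=seed)
        state["subgroups"] = result
        state["crlf_selection"] = survival.cox_univariate_per_lf(lfs, ds.clinical)
        p = outdir / "survival_metrics.json"
        with open(p, "w") as fh:
            json.dump({"K": result.K, **result.metrics,
                       "n_crlf": len(state["crlf_selection"].selected)},
                      fh, indent=2)
        return {"survival_metrics": str(p)}

    if stage == "biomarkers":
        lfs = state["lfs"]
        integrated = state["integrated"]
        sel = state.get("crlf_selection") or survival.cox_univariate_per_lf(
            lfs, state["dataset"].clinical)
        idx = sel.selected if len(sel.selected) >= 1 else list(range(lfs.shape[1]))
        r, pvals = biomarkers.map_crlfs_to_features(lfs[:, idx], integrated.values)
        bmap = biomarkers.filter_biomarkers(
            r, pvals, integrated.provenance,
            crlf_names=[f"LF{i}" for i in idx])
        paths = {}
        tsv = outdir / "biomarker_correlations.tsv"
        df = pd.DataFrame(bmap.correlations.T,
                          columns=bmap.crlf_names)
        df.insert(0, "modality", [m for m, _ in bmap.feature_provenance])
        df.insert(1, "feature_id", [f for _, f in bmap.feature_provenance])
        df.to_csv(tsv, sep="\t", index=False)
        paths["biomarker_correlations"] = str(tsv)
        if bmap.correlations.size:
            fig = outdir / "biomarker_heatmap.png"
            biomarkers.cluster_heatmap(bmap, path=fig)
            paths["biomarker_heatmap"] = str(fig)
        state["biomarkers"] = bmap
        return paths

    raise ValueError(f"unknown stage {stage!r}")
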