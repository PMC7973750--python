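"""Omics and clinical table I/O plus the four-step preprocessing.

File formats follow the UCSC Xena conventions: a "genomicMatrix" is a TSV
with feature identifiers in the first column and one column per sample
(features in rows); the probe map is a two-column TSV (probe_id, chromosome);
the clinical table is a TSV with sample_id, os_time, os_event, age, stage,
grade and an optional subtype column.

Preprocessing order is intersect -> clean -> normalize -> concatenate, with
optional Borderline-SMOTE-SVM rebalancing of a binary label set.  Min-max
parameters are computed once on the full matrix: preprocessing precedes any
modeling split in this workflow, which carries the usual information-leakage
caveat for downstream cross-validation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .models import BlockSchema
from .survival import SurvivalTable

MODALITIES = ("cnv", "mrna", "rnaseq", "methylation")

__all__ = [
    "OmicsBlock", "MultiOmicsDataset", "ProbeMap", "IntegratedMatrix",
    "read_genomic_matrix", "write_genomic_matrix", "read_probe_map",
    "write_probe_map", "read_clinical", "write_clinical",
    "intersect_samples", "drop_degenerate_features", "minmax_normalize",
    "inverse_minmax", "concatenate_blocks", "deconcatenate",
    "rebalance_borderline_smote_svm",
]


@dataclass
class OmicsBlock:
    """One modality's samples x features matrix with identifiers and metadata."""

    modality: str
    values: np.ndarray  # samples x features
    sample_ids: List[str]
    feature_ids: List[str]
    unit: str = ""
    chromosome_of: Optional[Dict[str, str]] = None  # methylation only
    normalized: bool = False
    norm_min: Optional[np.ndarray] = None
    norm_max: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"{self.modality}: values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} identifier(s): {list(dupes[:5])}")
        if self.normalized and self.values.size and (
                self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("normalized block has values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def schema(self) -> BlockSchema:
        """The model-facing schema; methylation features grouped by chromosome."""
        if self.modality != "methylation":
            return BlockSchema(self.modality, self.n_features)
        if not self.chromosome_of:
            raise ValueError("methylation block lacks chromosome assignments")
        groups: Dict[str, List[int]] = {}
        for i, fid in enumerate(self.feature_ids):
            groups.setdefault(self.chromosome_of[fid], []).append(i)
        chroms = [(label, groups[label]) for label in sorted(groups)]
        return BlockSchema("methylation", self.n_features, chroms)


@dataclass
class MultiOmicsDataset:
    """Sample-aligned blocks plus optional label and clinical tables."""

    blocks: List[OmicsBlock]
    labels: Optional[pd.Series] = None  # indexed by sample_id
    clinical: Optional[SurvivalTable] = None

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("dataset requires at least one block")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise ValueError(
                    f"block {b.modality} sample order differs from {self.blocks[0].modality}")

    @property
    def sample_ids(self) -> List[str]:
        return self.blocks[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def total_features(self) -> int:
        return sum(b.n_features for b in self.blocks)

    def schemas(self) -> List[BlockSchema]:
        return [b.schema() for b in self.blocks]

    def block_arrays(self) -> List[np.ndarray]:
        return [b.values for b in self.blocks]


@dataclass
class ProbeMap:
    """Assignment of methylation probes to chromosome labels."""

    entries: Dict[str, str]

    def chromosomes(self) -> List[str]:
        return sorted(set(self.entries.values()))


@dataclass
class IntegratedMatrix:
    """Concatenated multi-omics matrix with per-column provenance."""

    values: np.ndarray  # samples x D
    sample_ids: List[str]
    provenance: List[Tuple[str, str]]  # (modality, feature_id) per column

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# readers / writers


def read_genomic_matrix(path, modality: str, unit: str = "",
                        probe_map: Optional[ProbeMap] = None) -> OmicsBlock:
    """Read a Xena genomicMatrix TSV (features in rows) into samples x features."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate sample column(s): {list(dupes[:5])}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed TSV ({exc})") from exc
    dupe_rows = df.index[df.index.duplicated()]
    if len(dupe_rows):
        raise ValueError(f"{path}: duplicate feature row(s): {list(dupe_rows[:5])}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        row = bad.any(axis=1).to_numpy().nonzero()[0][0]
        col = bad.iloc[row].to_numpy().nonzero()[0][0]
        raise ValueError(
            f"{path}: non-numeric cell at data line {row + 2}, "
            f"feature {df.index[row]!r}, sample {df.columns[col]!r}")
    chromosome_of = None
    if modality == "methylation" and probe_map is not None:
        chromosome_of = {fid: probe_map.entries[fid] for fid in numeric.index}
    return OmicsBlock(
        modality=modality,
        values=numeric.to_numpy(float).T,  # transpose to samples x features
        sample_ids=list(numeric.columns),
        feature_ids=list(numeric.index),
        unit=unit,
        chromosome_of=chromosome_of,
    )


def write_genomic_matrix(block: OmicsBlock, path) -> None:
    df = pd.DataFrame(block.values.T, index=block.feature_ids, columns=block.sample_ids)
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["probe_id", "chromosome"]:
        raise ValueError(f"{path}: expected columns probe_id, chromosome")
    return ProbeMap(dict(zip(df["probe_id"], df["chromosome"])))


def write_probe_map(probe_map: ProbeMap, path) -> None:
    pd.DataFrame(sorted(probe_map.entries.items()),
                 columns=["probe_id", "chromosome"]).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> SurvivalTable:
    return SurvivalTable(pd.read_csv(path, sep="\t"))


def write_clinical(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing steps


def intersect_samples(blocks: Sequence[OmicsBlock],
                      labels: Optional[pd.Series] = None,
                      clinical: Optional[SurvivalTable] = None) -> MultiOmicsDataset:
    """Keep exactly the samples present in every block, in sorted order."""
    if not blocks:
        raise ValueError("need at least one block")
    common = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if not common:
        raise ValueError("sample intersection across blocks is empty")
    order = sorted(common)
    out = []
    for b in blocks:
        pos = {s: i for i, s in enumerate(b.sample_ids)}
        idx = [pos[s] for s in order]
        out.append(replace(b, values=b.values[idx], sample_ids=order))
    if labels is not None:
        labels = labels.loc[order]
    if clinical is not None:
        clin = clinical.data.set_index("sample_id").loc[order].reset_index()
        clinical = SurvivalTable(clin)
    return MultiOmicsDataset(out, labels=labels, clinical=clinical)


def drop_degenerate_features(block: OmicsBlock) -> Tuple[OmicsBlock, List[str]]:
    """Remove features that are entirely missing or identically zero."""
    vals = block.values
    all_na = np.all(np.isnan(vals), axis=0)
    with np.errstate(invalid="ignore"):
        all_zero = np.all(vals == 0, axis=0)
    drop = all_na | all_zero
    removed = [fid for fid, d in zip(block.feature_ids, drop) if d]
    keep = ~drop
    chrom = block.chromosome_of
    if chrom is not None:
        chrom = {fid: chrom[fid] for fid, k in zip(block.feature_ids, keep) if k}
    cleaned = replace(
        block,
        values=vals[:, keep],
        feature_ids=[fid for fid, k in zip(block.feature_ids, keep) if k],
        chromosome_of=chrom,
    )
    return cleaned, removed


def minmax_normalize(block: OmicsBlock) -> OmicsBlock:
    """Per-feature (v - min) / (max - min) into [0, 1]; constants map to 0."""
    vals = block.values
    if np.isnan(vals).any():
        raise ValueError("missing values present; clean the block first")
    lo = vals.min(axis=0) if len(vals) else np.zeros(block.n_features)
    hi = vals.max(axis=0) if len(vals) else np.ones(block.n_features)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    normalized = (vals - lo) / safe
    normalized[:, span == 0] = 0.0
    return replace(block, values=normalized, normalized=True,
                   norm_min=lo, norm_max=hi)


def inverse_minmax(block: OmicsBlock) -> OmicsBlock:
    """Undo minmax_normalize using the stored per-feature parameters."""
    if not block.normalized or block.norm_min is None:
        raise ValueError("block is not normalized or lacks stored parameters")
    span = block.norm_max - block.norm_min
    restored = block.values * span + block.norm_min
    return replace(block, values=restored, normalized=False,
                   norm_min=None, norm_max=None)


def concatenate_blocks(dataset: MultiOmicsDataset,
                       require_normalized: bool = True) -> IntegratedMatrix:
    """Column-concatenate all blocks into the integrated samples x D matrix."""
    for b in dataset.blocks:
        if require_normalized and not b.normalized:
            raise ValueError(f"block {b.modality} is not normalized")
    values = np.concatenate([b.values for b in dataset.blocks], axis=1) \
        if dataset.blocks[0].n_samples else \
        np.zeros((0, dataset.total_features))
    provenance = [(b.modality, fid) for b in dataset.blocks for fid in b.feature_ids]
    return IntegratedMatrix(values=values, sample_ids=dataset.sample_ids,
                            provenance=provenance)


def deconcatenate(integrated: IntegratedMatrix, dataset: MultiOmicsDataset
                  ) -> List[np.ndarray]:
    """Split the integrated matrix back into per-block arrays via provenance."""
    out = []
    offset = 0
    for b in dataset.blocks:
        out.append(integrated.values[:, offset:offset + b.n_features])
        offset += b.n_features
    return out


# ---------------------------------------------------------------------------
# class rebalancing


def rebalance_borderline_smote_svm(X: np.ndarray, y: np.ndarray,
                                   target_minority, seed: int = 0,
                                   k_neighbors: int = 5
                                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class near the SVM decision boundary.

    A support-vector classifier locates the borderline region; minority
    support vectors act as seeds, and synthetic points are linear
    interpolations between a seed and one of its k nearest minority
    neighbors, so every synthetic sample lies on a segment between two
    original minority points.  The majority class is untouched and the final
    minority count equals ``target_minority`` exactly.

    ``target_minority`` may be an absolute count or a ratio in (0, 1)
    interpreted as the desired minority share of the final dataset.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"rebalancing requires exactly 2 classes, got {len(classes)}")
    minority_class = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if 0 < target_minority < 1:
        target = int(np.ceil(target_minority * n_maj / (1 - target_minority)))
    else:
        target = int(target_minority)
    if target < n_min:
        raise ValueError(f"target_minority {target} below current minority count {n_min}")
    n_new = target - n_min
    if n_new == 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError(
            "minority class too small for neighbor interpolation (need >= 2); "
            "collect more minority samples or lower the target")
    k = min(k_neighbors, n_min - 1)
    if k < k_neighbors:
        pass  # silently clip; the caller asked for more neighbors than exist
    rng = np.random.default_rng(seed)
    X_min = X[y == minority_class]
    svc = SVC(kernel="rbf", gamma="scale").fit(X, y == minority_class)
    sv_idx = svc.support_[np.asarray(y == minority_class)[svc.support_]]
    # Map support-vector rows back into the minority submatrix.
    min_rows = np.flatnonzero(y == minority_class)
    row_of = {r: i for i, r in enumerate(min_rows)}
    seeds = np.array([row_of[r] for r in sv_idx], dtype=int)
    if len(seeds) == 0:
        seeds = np.arange(len(X_min))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    synth = np.empty((n_new, X.shape[1]))
    for i in range(n_new):
        s = seeds[rng.integers(len(seeds))]
        nb = neighbor_idx[s, rng.integers(k)]
        u = rng.uniform()
        synth[i] = X_min[s] + u * (X_min[nb] - X_min[s])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority_class, dtype=y.dtype)])
    return X_out, y_out
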