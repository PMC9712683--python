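"""Feature descriptors for antifreeze-protein prediction.

Four encoders turn a protein (its sequence, or its normalized PSSM profile)
into a fixed-length named feature vector:

* **GAAC** — grouped amino-acid composition: frequencies of five
  physicochemical residue groups (aliphatic AGLIMV, negatively charged DE,
  aromatic FWY, positively charged HRK, uncharged CNPQST). 5 features.
* **DPC** — dipeptide composition: frequencies of the 400 ordered adjacent
  residue pairs, normalized by L-1 so the vector sums to 1. 400 features.
* **PseTS-PSSM** — the normalized PSSM is tri-sliced by row; each slice
  contributes its 20 per-column means (and, optionally, pseudo
  sequence-order correlation factors: the per-column mean squared
  difference between entries a fixed rank apart). Default 60 features.
* **Sg-PSSM-ACT** — the normalized PSSM is split into three segments and
  each segment contributes, per column and lag, the lagged autocovariance
  around the segment's own column mean. Default (lag set {1}) 60 features.

Vectors from several encoders are fused per record into a rectangular
feature matrix whose column names are stable, human-auditable identifiers
such as ``DPC.AC``, ``PSETS.slice3.mean.W`` or ``SGACT.seg2.lag1.K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pssm_io import PSSM_ALPHABET, PSSMMatrix, PartitionPlan, partition_rows, plan_partition
from .sequence_io import STANDARD_ALPHABET, LabeledDataset, ProteinRecord

# ---------------------------------------------------------------------------
# Configuration

#: The five physicochemical residue groups, in fixed order.
GAAC_GROUPS: tuple[tuple[str, str], ...] = (
    ("G1", "AGLIMV"),   # aliphatic
    ("G2", "DE"),       # negatively charged
    ("G3", "FWY"),      # aromatic
    ("G4", "HRK"),      # positively charged
    ("G5", "CNPQST"),   # uncharged
)

#: Encoder provenance tags.
TAG_GAAC = "GAAC"
TAG_DPC = "DPC"
TAG_PSETS = "PseTS-PSSM"
TAG_SGACT = "Sg-PSSM-ACT"
TAG_FUSED = "FUSED"

DEFAULT_ENCODERS: tuple[str, ...] = (TAG_GAAC, TAG_DPC, TAG_PSETS, TAG_SGACT)

#: Lexicographic dipeptide order over the alphabetical 20-letter alphabet.
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a in STANDARD_ALPHABET for b in STANDARD_ALPHABET
)

PSE_MODES = ("means", "corr", "means+corr")


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable parameters shared by the four encoders.

    ``act_lags`` are the autocovariance lags of Sg-PSSM-ACT (default {1},
    giving the 60-dimensional vector; {1, 2} gives 120). ``pse_ranks`` are
    the ranks of the optional pseudo correlation factors of PseTS-PSSM and
    ``pse_mode`` selects slice means, correlation factors, or both; the
    default (means only, no ranks) gives the 60-dimensional vector.
    """

    gaac_groups: tuple[tuple[str, str], ...] = GAAC_GROUPS
    act_lags: tuple[int, ...] = (1,)
    pse_ranks: tuple[int, ...] = ()
    pse_mode: str = "means"

    def __post_init__(self) -> None:
        letters = "".join(g for _, g in self.gaac_groups)
        if sorted(letters) != sorted(STANDARD_ALPHABET):
            raise ValueError("gaac_groups must partition the 20 standard letters exactly")
        if self.pse_mode not in PSE_MODES:
            raise ValueError(f"pse_mode must be one of {PSE_MODES}, got {self.pse_mode!r}")
        if any(lag < 1 for lag in self.act_lags) or not self.act_lags:
            raise ValueError("act_lags must be a non-empty set of positive integers")
        if any(rank < 1 for rank in self.pse_ranks):
            raise ValueError("pse_ranks must be positive integers")
        if self.pse_mode != "means" and not self.pse_ranks:
            raise ValueError(f"pse_mode {self.pse_mode!r} requires at least one rank")


DEFAULT_CONFIG = EncoderConfig()


# ---------------------------------------------------------------------------
# Containers

@dataclass
class FeatureVector:
    """Named descriptor values for one record, tagged with their encoder."""

    record_id: str
    names: tuple[str, ...]
    values: np.ndarray
    encoder: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError(
                f"{self.encoder} vector for {self.record_id!r}: "
                f"{len(self.names)} names but {self.values.size} values"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate feature names in {self.encoder} vector")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FeatureMatrix:
    """A rectangular record-by-feature grid with an optional label column."""

    record_ids: list[str]
    names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix values must be 2-dimensional")
        if self.values.shape != (len(self.record_ids), len(self.names)):
            raise ValueError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.record_ids)} records x {len(self.names)} features"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.record_ids),):
                raise ValueError("label column length must match the number of records")

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    @property
    def n_features(self) -> int:
        return len(self.names)

    def subset_rows(self, index: np.ndarray) -> "FeatureMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return FeatureMatrix(
            record_ids=[self.record_ids[i] for i in index],
            names=list(self.names),
            values=self.values[index],
            labels=None if self.labels is None else self.labels[index],
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        lookup = {name: j for j, name in enumerate(self.names)}
        missing = [name for name in names if name not in lookup]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        cols = [lookup[name] for name in names]
        return FeatureMatrix(
            record_ids=list(self.record_ids),
            names=list(names),
            values=self.values[:, cols],
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.record_ids, columns=self.names)
        frame.index.name = "id"
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        labels = None
        if "label" in frame.columns:
            labels = frame["label"].to_numpy(dtype=int)
            frame = frame.drop(columns="label")
        return cls(
            record_ids=[str(i) for i in frame.index],
            names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            labels=labels,
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="id"))


# ---------------------------------------------------------------------------
# Sequence encoders

def encode_gaac(record: ProteinRecord, config: EncoderConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Grouped amino-acid composition: F(Gk) = n(Gk) / n over the 5 groups."""
    n = record.length
    if n == 0:
        raise ValueError(f"record {record.id!r}: cannot encode an empty sequence")
    values = np.empty(len(config.gaac_groups))
    for k, (_, letters) in enumerate(config.gaac_groups):
        group = set(letters)
        values[k] = sum(1 for ch in record.sequence if ch in group) / n
    names = tuple(f"{TAG_GAAC}.{gname}" for gname, _ in config.gaac_groups)
    return FeatureVector(record.id, names, values, TAG_GAAC)


def encode_dpc(record: ProteinRecord) -> FeatureVector:
    """Dipeptide composition: count of each ordered pair over L - 1 positions."""
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError(f"record {record.id!r}: sequence too short for DPC (L={len(seq)})")
    index = {dp: j for j, dp in enumerate(DIPEPTIDES)}
    counts = np.zeros(len(DIPEPTIDES))
    for i in range(len(seq) - 1):
        counts[index[seq[i : i + 2]]] += 1
    values = counts / (len(seq) - 1)
    names = tuple(f"{TAG_DPC}.{dp}" for dp in DIPEPTIDES)
    return FeatureVector(record.id, names, values, TAG_DPC)


# ---------------------------------------------------------------------------
# PSSM descriptor primitives

def _require_normalized(pssm: PSSMMatrix, encoder: str) -> None:
    if not pssm.normalized:
        raise ValueError(f"{encoder} requires a normalized PSSM (record {pssm.record_id!r})")


def slice_composition(
    pssm: PSSMMatrix, plan: PartitionPlan, slice_index: int
) -> np.ndarray:
    """Per-column arithmetic mean over the rows of one slice (20 values)."""
    _require_normalized(pssm, "slice_composition")
    if plan.mode != "slice":
        raise ValueError(f"expected a slice partition plan, got mode {plan.mode!r}")
    part = partition_rows(pssm, plan)[slice_index]
    if part.shape[0] == 0:
        raise ValueError(f"slice {slice_index + 1} of PSSM {pssm.record_id!r} is empty")
    return part.mean(axis=0)


def pse_correlation(part: np.ndarray, rank: int) -> np.ndarray:
    """Pseudo sequence-order correlation factors of one PSSM part.

    For each column n: the mean over m of [x(m, n) - x(m + rank, n)]^2,
    with the mean taken over the (rows - rank) in-part pairs.
    """
    part = np.asarray(part, dtype=float)
    rows = part.shape[0]
    if rows <= rank:
        raise ValueError(f"rank exceeds slice length: rank={rank}, rows={rows}")
    diffs = part[:-rank] - part[rank:]
    return (diffs**2).sum(axis=0) / (rows - rank)


def segment_act(
    pssm: PSSMMatrix, plan: PartitionPlan, segment_index: int, lag: int
) -> np.ndarray:
    """Lagged autocovariance of each column within one segment (20 values).

    Deviations are taken from the segment's own per-column mean and only
    in-segment pairs are used; the sum is divided by (segment length - lag).
    """
    _require_normalized(pssm, "segment_act")
    if plan.mode != "segment":
        raise ValueError(f"expected a segment partition plan, got mode {plan.mode!r}")
    part = partition_rows(pssm, plan)[segment_index]
    rows = part.shape[0]
    if rows <= lag:
        raise ValueError(
            f"segment {segment_index + 1} of PSSM {pssm.record_id!r} has "
            f"{rows} rows, too short for lag {lag}"
        )
    dev = part - part.mean(axis=0)
    return (dev[:-lag] * dev[lag:]).sum(axis=0) / (rows - lag)


# ---------------------------------------------------------------------------
# PSSM encoders

def encode_psets_pssm(
    pssm: PSSMMatrix, config: EncoderConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Tri-sliced PSSM descriptor with optional pseudo correlation factors.

    Per slice, in order: the 20 column means (modes ``means`` and
    ``means+corr``) then one 20-value correlation block per configured rank
    (modes ``corr`` and ``means+corr``). Default: 3 slices x 20 means = 60.
    """
    _require_normalized(pssm, TAG_PSETS)
    plan = plan_partition(pssm.length, "slice")
    parts = partition_rows(pssm, plan)
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for s, part in enumerate(parts, start=1):
        if config.pse_mode in ("means", "means+corr"):
            blocks.append(slice_composition(pssm, plan, s - 1))
            names.extend(f"PSETS.slice{s}.mean.{aa}" for aa in PSSM_ALPHABET)
        if config.pse_mode in ("corr", "means+corr"):
            for rank in sorted(config.pse_ranks):
                if part.shape[0] <= rank:
                    raise ValueError(
                        f"PSSM {pssm.record_id!r}: slice {s} has {part.shape[0]} rows, "
                        f"too short for pseudo rank {rank}"
                    )
                blocks.append(pse_correlation(part, rank))
                names.extend(f"PSETS.slice{s}.corr{rank}.{aa}" for aa in PSSM_ALPHABET)
    return FeatureVector(pssm.record_id, tuple(names), np.concatenate(blocks), TAG_PSETS)


def encode_sg_pssm_act(
    pssm: PSSMMatrix, config: EncoderConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Segmentation-autocorrelation PSSM descriptor.

    Per segment, one 20-value autocovariance block per lag in ``act_lags``.
    Default lag set {1}: 3 segments x 20 columns = 60 features.
    """
    _require_normalized(pssm, TAG_SGACT)
    plan = plan_partition(pssm.length, "segment")
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for s in range(1, 4):
        for lag in sorted(config.act_lags):
            blocks.append(segment_act(pssm, plan, s - 1, lag))
            names.extend(f"SGACT.seg{s}.lag{lag}.{aa}" for aa in PSSM_ALPHABET)
    return FeatureVector(pssm.record_id, tuple(names), np.concatenate(blocks), TAG_SGACT)


# ---------------------------------------------------------------------------
# Fusion

def fuse(
    vectors: Mapping[str, Sequence[FeatureVector]],
    which: Sequence[str] = DEFAULT_ENCODERS,
    labels: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Concatenate per-record encoder vectors into one rectangular matrix.

    ``vectors`` maps record id to that record's encoder outputs (order
    irrelevant); ``which`` fixes the encoder order of the concatenation.
    Every requested encoder must be present for every record.
    """
    if not vectors:
        raise ValueError("no feature vectors to fuse")
    record_ids = list(vectors.keys())
    names: list[str] | None = None
    rows: list[np.ndarray] = []
    for rid in record_ids:
        by_tag = {v.encoder: v for v in vectors[rid]}
        parts = []
        row_names: list[str] = []
        for tag in which:
            if tag not in by_tag:
                raise ValueError(f"record {rid!r} is missing encoder {tag!r}")
            parts.append(by_tag[tag].values)
            row_names.extend(by_tag[tag].names)
        if names is None:
            names = row_names
        elif names != row_names:
            raise ValueError(f"record {rid!r}: feature names differ from previous records")
        rows.append(np.concatenate(parts))
    label_col = None
    if labels is not None:
        label_col = np.array([labels[rid] for rid in record_ids], dtype=int)
    return FeatureMatrix(record_ids, list(names or []), np.vstack(rows), label_col)


def encode_dataset(
    dataset: LabeledDataset | Sequence[ProteinRecord],
    pssms: Mapping[str, PSSMMatrix] | None = None,
    which: Sequence[str] = DEFAULT_ENCODERS,
    config: EncoderConfig = DEFAULT_CONFIG,
) -> FeatureMatrix:
    """Encode every record with the requested encoders and fuse the results.

    ``pssms`` maps record id to its profile (raw profiles are normalized on
    the fly) and is required whenever a PSSM encoder is requested.
    """
    from .pssm_io import normalize_pssm  # local import to avoid cycle at module load

    records = list(dataset)
    needs_pssm = TAG_PSETS in which or TAG_SGACT in which
    if needs_pssm and pssms is None:
        raise ValueError("PSSM encoders requested but no PSSMs supplied")
    vectors: dict[str, list[FeatureVector]] = {}
    labels: dict[str, int] = {}
    for rec in records:
        vecs: list[FeatureVector] = []
        if TAG_GAAC in which:
            vecs.append(encode_gaac(rec, config))
        if TAG_DPC in which:
            vecs.append(encode_dpc(rec))
        if needs_pssm:
            if rec.id not in pssms:  # type: ignore[operator]
                raise ValueError(f"no PSSM supplied for record {rec.id!r}")
            pssm = pssms[rec.id]  # type: ignore[index]
            if not pssm.normalized:
                pssm = normalize_pssm(pssm)
            if TAG_PSETS in which:
                vecs.append(encode_psets_pssm(pssm, config))
            if TAG_SGACT in which:
                vecs.append(encode_sg_pssm_act(pssm, config))
        vectors[rec.id] = vecs
        if rec.label is not None:
            labels[rec.id] = rec.label
    label_map = labels if len(labels) == len(records) else None
    return fuse(vectors, which=which, labels=label_map)
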