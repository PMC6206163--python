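"""Labeled feature matrices and the data used to build them.

The canonical feature row has 5468 entries: the 5460 k-mer counts
(k = 1..6, canonical order) followed by the 8 walk features. This module
assembles such rows from sequences, generates GC/length-matched null
(negative) sequences from a reference genome, simulates labeled
two-class sequence sets for testing and calibration, performs the
per-feature two-class Welch comparison, and splits datasets for
training/evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta
from scipy import stats as sps
from sklearn.model_selection import train_test_split

from .errors import EnhwalkError
from .kmerfeat import N_KMER_FEATURES, count_kmers, kmer_order
from .seqio import GenomeInterval, SequenceRecord
from .walk import build_walk
from .walkfeat import N_WALK_FEATURES, WALK_FEATURE_NAMES, walk_features

logger = logging.getLogger(__name__)

N_FEATURES = N_KMER_FEATURES + N_WALK_FEATURES  # 5468

POSITIVE, NEGATIVE = "positive", "negative"

#: Canonical column names: literal k-mer strings, then the walk features.
FEATURE_NAMES: tuple[str, ...] = kmer_order() + WALK_FEATURE_NAMES


@dataclass(frozen=True)
class FeatureVector:
    id: str
    values: np.ndarray  # length 5468
    label: Optional[str] = None


@dataclass
class LabeledDataset:
    """Feature matrix with ids, binary labels and the feature-name registry."""

    X: np.ndarray  # (n_samples, 5468)
    ids: list[str]
    labels: np.ndarray  # int8: 1 = positive, 0 = negative
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self):
        if self.X.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.feature_names)} features"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in dataset")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def class_counts(self) -> tuple[int, int]:
        pos = int(self.labels.sum())
        return pos, len(self) - pos

    def subset(self, index: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[index],
            ids=[self.ids[i] for i in index],
            labels=self.labels[index],
            feature_names=self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "id", self.ids)
        df["label"] = np.where(self.labels == 1, POSITIVE, NEGATIVE)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        names = tuple(c for c in df.columns if c not in ("id", "label"))
        labels = (df["label"] == POSITIVE).to_numpy(dtype=np.int8) if "label" in df \
            else np.zeros(len(df), dtype=np.int8)
        return cls(
            X=df[list(names)].to_numpy(dtype=float),
            ids=[str(i) for i in df["id"]],
            labels=labels,
            feature_names=names,
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class GroupComparisonRow:
    """One feature's positive-vs-negative comparison (Welch two-tailed t)."""

    feature_name: str
    sd_pos: float
    mean_pos: float
    sd_neg: float
    mean_neg: float
    t_statistic: float
    p_value: float


def extract_features(seq: SequenceRecord) -> FeatureVector:
    """Concatenate k-mer counts (5460) and walk features (8) for one sequence."""
    kv = count_kmers(seq)
    wf = walk_features(build_walk(seq))
    return FeatureVector(
        id=seq.id,
        values=np.concatenate([kv.counts.astype(float), wf.as_array()]),
        label=seq.label,
    )


def build_dataset(records: Iterable[SequenceRecord], on_error: str = "raise") -> LabeledDataset:
    """Extract features for many records into one LabeledDataset.

    ``on_error='drop'`` skips sequences whose features are undefined
    (logged); ``'raise'`` propagates the first failure.
    """
    rows, ids, labels = [], [], []
    n_dropped = 0
    for rec in records:
        try:
            fv = extract_features(rec)
        except EnhwalkError as exc:
            if on_error != "drop":
                raise
            n_dropped += 1
            logger.warning("dropping sequence %s: %s", rec.id, exc)
            continue
        rows.append(fv.values)
        ids.append(fv.id)
        labels.append(1 if rec.label == POSITIVE else 0)
    if n_dropped:
        logger.info("build_dataset: dropped %d sequences with undefined features", n_dropped)
    if not rows:
        raise EnhwalkError("no sequences yielded feature vectors")
    return LabeledDataset(X=np.vstack(rows), ids=ids, labels=np.array(labels, dtype=np.int8))


def gc_content(seq: SequenceRecord | str) -> float:
    bases = seq.bases if isinstance(seq, SequenceRecord) else seq
    if not bases:
        raise EnhwalkError("gc_content of an empty sequence")
    return (bases.count("G") + bases.count("C")) / len(bases)


def generate_null_set(
    genome: str | Path,
    positives: Sequence[GenomeInterval],
    gc_tolerance: float = 0.02,
    n_ratio: float = 1.0,
    max_tries_per_positive: int = 1000,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Sample GC/length-matched null (negative) windows from a genome.

    For each positive interval (``n_ratio`` times over), rejection-sample
    a uniformly placed window of identical length whose GC content is
    within ``gc_tolerance`` of the positive's and which overlaps no
    positive interval. Positives whose GC cannot be matched within
    ``max_tries_per_positive`` draws are skipped with a warning.
    """
    if not positives:
        raise EnhwalkError("no positive intervals supplied")
    rng = np.random.default_rng(seed)
    fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    chroms = list(fa.keys())
    chrom_lens = {c: len(fa[c]) for c in chroms}

    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    for iv in positives:
        if iv.chrom in occupied:
            occupied[iv.chrom].addi(iv.start, iv.end)

    pos_gc = []
    for iv in positives:
        if iv.chrom not in chrom_lens or iv.end > chrom_lens[iv.chrom]:
            raise EnhwalkError(f"positive interval {iv.chrom}:{iv.start}-{iv.end} outside genome")
        pos_gc.append(gc_content(str(fa[iv.chrom][iv.start : iv.end])))

    n_per = max(int(round(n_ratio)), 1)
    nulls: list[SequenceRecord] = []
    n_skipped = 0
    for iv, target_gc in zip(positives, pos_gc):
        length = len(iv)
        for _ in range(n_per):
            found = False
            for _try in range(max_tries_per_positive):
                chrom = chroms[rng.integers(len(chroms))]
                if chrom_lens[chrom] < length:
                    continue
                start = int(rng.integers(chrom_lens[chrom] - length + 1))
                end = start + length
                if occupied[chrom].overlap(start, end):
                    continue
                seq = str(fa[chrom][start:end])
                if "N" in seq or abs(gc_content(seq) - target_gc) > gc_tolerance:
                    continue
                occupied[chrom].addi(start, end)  # nulls kept disjoint too
                nulls.append(
                    SequenceRecord(
                        id=f"null_{chrom}:{start}-{end}",
                        bases=seq,
                        source=GenomeInterval(chrom, start, end),
                        label=NEGATIVE,
                    )
                )
                found = True
                break
            if not found:
                n_skipped += 1
                logger.warning(
                    "no GC match (target %.3f +/- %.3f, length %d) within %d tries; skipped",
                    target_gc, gc_tolerance, length, max_tries_per_positive,
                )
    if n_skipped:
        logger.info("generate_null_set: skipped %d of %d requested nulls",
                    n_skipped, len(positives) * n_per)
    return nulls


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def simulate_labeled_set(
    n_pos: int,
    n_neg: int,
    length: int = 1500,
    motif: str = "GGCAG",
    pos_motif_rate: float = 5.0,
    gc_pos: float = 0.55,
    gc_neg: float = 0.40,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Simulate a two-class labeled sequence set.

    Positives are i.i.d. bases at GC fraction ``gc_pos`` with a
    Poisson(``pos_motif_rate``) number of planted ``motif`` copies at
    uniform positions; negatives are i.i.d. bases at ``gc_neg`` with no
    planting. This emulates the enhancer-vs-background regime the tool
    trains on — two classes separated by motif content and GC shift —
    typically at a ~1:7.7 positive:negative imbalance.
    """
    if not 0 <= gc_pos <= 1 and 0 <= gc_neg <= 1:
        raise ValueError("GC fractions must lie in [0, 1]")
    if len(motif) > length:
        raise EnhwalkError(f"motif ({len(motif)} bp) longer than sequence length {length}")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    for i in range(n_pos):
        arr = _random_bases(rng, length, gc_pos)
        for _ in range(rng.poisson(pos_motif_rate)):
            start = int(rng.integers(length - len(motif) + 1))
            arr[start : start + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
        records.append(SequenceRecord(id=f"pos_{i}", bases=arr.tobytes().decode(), label=POSITIVE))
    for i in range(n_neg):
        arr = _random_bases(rng, length, gc_neg)
        records.append(SequenceRecord(id=f"neg_{i}", bases=arr.tobytes().decode(), label=NEGATIVE))
    return records


def compare_groups(ds: LabeledDataset, features: Sequence[str]) -> list[GroupComparisonRow]:
    """Per-feature positive-vs-negative comparison: class means/SDs and an
    unpaired two-tailed Welch t-test."""
    name_to_col = {n: j for j, n in enumerate(ds.feature_names)}
    missing = [f for f in features if f not in name_to_col]
    if missing:
        raise EnhwalkError(f"unknown features requested: {missing}")
    pos = ds.X[ds.labels == 1]
    neg = ds.X[ds.labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise EnhwalkError("each class needs at least 2 samples for a t-test")
    rows = []
    for f in features:
        j = name_to_col[f]
        t, p = sps.ttest_ind(pos[:, j], neg[:, j], equal_var=False)
        rows.append(
            GroupComparisonRow(
                feature_name=f,
                sd_pos=float(pos[:, j].std(ddof=1)),
                mean_pos=float(pos[:, j].mean()),
                sd_neg=float(neg[:, j].std(ddof=1)),
                mean_neg=float(neg[:, j].mean()),
                t_statistic=float(t),
                p_value=float(p),
            )
        )
    return rows


def comparison_frame(rows: Sequence[GroupComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_name": [r.feature_name for r in rows],
            "sd_pos": [r.sd_pos for r in rows],
            "mean_pos": [r.mean_pos for r in rows],
            "sd_neg": [r.sd_neg for r in rows],
            "mean_neg": [r.mean_neg for r in rows],
            "t_statistic": [r.t_statistic for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )


def split(
    ds: LabeledDataset,
    test_fraction: float = 0.25,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint train/test split (default 75/25, stratified by class)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if stratified and min(ds.class_counts) < 2:
        raise EnhwalkError("stratified split needs >= 2 samples per class")
    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=ds.labels if stratified else None,
        random_state=seed,
    )
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))
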