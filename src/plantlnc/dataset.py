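"""Labeled feature datasets, SMOTE class balancing, synthetic transcripts.

The synthetic generator emulates the two transcript classes the
classifier separates: mRNA-like sequences carry one long embedded open
reading frame (>= 60% of the sequence, sense codons only between an AUG
and a sampled stop), while lncRNA-like sequences are i.i.d. nucleotide
draws whose natural stop-codon density makes long ORFs rare, with a
rejection step discarding draws whose longest ORF exceeds 40% of the
length.  The classes are separable but overlapping — enough structure
for end-to-end recovery experiments, with no claim of fidelity to real
plant transcript statistics.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .sequence_io import RnaSequence, SequenceSet

logger = logging.getLogger(__name__)

_SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in ("UAA", "UAG", "UGA")
)
_STOPS = ("UAA", "UAG", "UGA")


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels (1 = lncRNA, 0 = mRNA)."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    feature_names: list[str]
    fold_backend: str = "builtin"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        n = self.X.shape[0]
        if n == 0:
            raise ValueError("dataset must contain at least one row")
        if self.y.shape != (n,) or len(self.ids) != n:
            raise ValueError("X, y and ids must have consistent row counts")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("column count must match feature_names")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> dict[int, int]:
        return {0: int((self.y == 0).sum()), 1: int((self.y == 1).sum())}

    def subset_features(self, names: Sequence[str]) -> "LabeledDataset":
        """Column subset in the given order (unknown names raise KeyError)."""
        idx = []
        for n in names:
            try:
                idx.append(self.feature_names.index(n))
            except ValueError:
                raise KeyError(f"unknown feature name {n!r}") from None
        return replace(
            self, X=self.X[:, idx], feature_names=list(names),
            ids=list(self.ids),
        )

    def subset_rows(self, mask_or_idx) -> "LabeledDataset":
        idx = np.asarray(mask_or_idx)
        return replace(
            self,
            X=self.X[idx],
            y=self.y[idx],
            ids=[self.ids[i] for i in np.flatnonzero(idx)]
            if idx.dtype == bool
            else [self.ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        df["label"] = self.y
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, fold_backend: str = "builtin"
    ) -> "LabeledDataset":
        """Build from an (id, <features...>, label) table."""
        feature_cols = [c for c in df.columns if c not in ("id", "label")]
        return cls(
            X=df[feature_cols].to_numpy(dtype=np.float64),
            y=df["label"].to_numpy(dtype=np.int64),
            ids=[str(i) for i in df["id"]],
            feature_names=feature_cols,
            fold_backend=fold_backend,
        )


def concatenate(a: LabeledDataset, b: LabeledDataset) -> LabeledDataset:
    if a.feature_names != b.feature_names:
        raise ValueError("feature schemas differ")
    return LabeledDataset(
        X=np.vstack([a.X, b.X]),
        y=np.concatenate([a.y, b.y]),
        ids=a.ids + b.ids,
        feature_names=a.feature_names,
        fold_backend=a.fold_backend,
    )


SmoteProvenance = namedtuple("SmoteProvenance", ["base", "neighbor", "u"])


def smote_balance(
    ds: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    return_provenance: bool = False,
):
    """Balance classes by synthetic minority oversampling (SMOTE).

    Synthetic rows are x_i + u * (x_nn - x_i) with x_i a minority row,
    x_nn one of its k nearest minority neighbours (Euclidean distance on
    features standardized to zero mean / unit variance for the neighbour
    search only; the interpolation happens in the original feature
    space) and u ~ Uniform(0, 1) from the seeded generator.  Original
    rows are retained unchanged; synthetic ids carry a ``smote`` tag.

    Raises on single-class input or a minority class of size 1; k larger
    than minority_size - 1 is clamped with a warning.

    With ``return_provenance=True`` the return value is a
    ``(LabeledDataset, list[SmoteProvenance])`` pair recording, for each
    synthetic row, the minority-row index it interpolates from, the
    neighbour index it interpolates toward (both indices into the
    minority block in dataset order) and the interpolation weight u.
    """
    counts = ds.class_counts
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("SMOTE requires both classes to be present")
    minority_label = 0 if counts[0] < counts[1] else 1
    n_min, n_maj = counts[minority_label], counts[1 - minority_label]
    if n_min == n_maj:
        return (ds, []) if return_provenance else ds
    if n_min < 2:
        raise ValueError("minority class must contain at least 2 rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_min - 1:
        logger.warning("k=%d clamped to minority_size-1=%d", k, n_min - 1)
        k = n_min - 1

    rng = np.random.default_rng(seed)
    minority = ds.X[ds.y == minority_label]

    mu = minority.mean(axis=0)
    sd = minority.std(axis=0)
    sd[sd == 0] = 1.0
    standardized = (minority - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(standardized)
    neighbor_idx = nn.kneighbors(standardized, return_distance=False)[:, 1:]

    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    neighbor = neighbor_idx[base, pick]
    xi = minority[base]
    xn = minority[neighbor]
    synthetic = xi + u[:, None] * (xn - xi)

    balanced = LabeledDataset(
        X=np.vstack([ds.X, synthetic]),
        y=np.concatenate(
            [ds.y, np.full(n_new, minority_label, dtype=np.int64)]
        ),
        ids=ds.ids + [f"smote_{minority_label}_{t}" for t in range(n_new)],
        feature_names=ds.feature_names,
        fold_backend=ds.fold_backend,
    )
    if return_provenance:
        provenance = [
            SmoteProvenance(int(b), int(m), float(w))
            for b, m, w in zip(base, neighbor, u)
        ]
        return balanced, provenance
    return balanced


def _sample_biased_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=n, p=p)])


def _longest_orf_fraction(residues: str) -> float:
    # local import avoids a circular dependency at module load
    from .features import find_orfs

    seq = RnaSequence(id="tmp", residues=residues)
    orfs = find_orfs(seq)
    if not orfs:
        return 0.0
    return max(o.length for o in orfs) / len(residues)


def _make_mrna_like(
    rng: np.random.Generator, length: int, gc: float
) -> str:
    """One long ORF (>= 60% of the sequence) flanked by UTR-like ends."""
    min_orf = max(6, int(np.ceil(0.6 * length / 3)) * 3)
    max_orf = (length // 3) * 3
    orf_len = int(rng.integers(min_orf // 3, max_orf // 3 + 1)) * 3
    n_codons = orf_len // 3 - 2  # interior codons between AUG and stop
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)]
    orf = "AUG" + "".join(codons) + _STOPS[int(rng.integers(0, 3))]
    utr_total = length - len(orf)
    left = int(rng.integers(0, utr_total + 1))
    return (
        _sample_biased_bases(rng, left, gc)
        + orf
        + _sample_biased_bases(rng, utr_total - left, gc)
    )


def _make_lncrna_like(
    rng: np.random.Generator, length: int, gc: float
) -> str:
    """i.i.d. draw, rejected while its longest ORF exceeds 40% of length."""
    while True:
        residues = _sample_biased_bases(rng, length, gc)
        if _longest_orf_fraction(residues) <= 0.40:
            return residues


def simulate_sequences(
    n_pos: int,
    n_neg: int,
    seed: int,
    length_range: tuple[int, int] = (200, 6000),
    gc_target: float = 0.45,
) -> tuple[SequenceSet, SequenceSet]:
    """Generate lncRNA-like (positive) and mRNA-like (negative) transcripts.

    Fully deterministic per seed; every sequence length lies within
    ``length_range`` (inclusive).  Returns (positives, negatives) with
    set labels 1 and 0.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    pos = [
        RnaSequence(
            id=f"lnc_{i}",
            residues=_make_lncrna_like(
                rng, int(rng.integers(lo, hi + 1)), gc_target
            ),
        )
        for i in range(n_pos)
    ]
    neg = [
        RnaSequence(
            id=f"mrna_{i}",
            residues=_make_mrna_like(
                rng, int(rng.integers(lo, hi + 1)), gc_target
            ),
        )
        for i in range(n_neg)
    ]
    return (
        SequenceSet(records=pos, label=1),
        SequenceSet(records=neg, label=0),
    )


def simulate_dataset(
    n_pos: int,
    n_neg: int,
    seed: int,
    length_range: tuple[int, int] = (200, 6000),
    gc_target: float = 0.45,
    fold_backend: str = "builtin",
) -> LabeledDataset:
    """Convenience: simulate transcripts and extract their feature matrix."""
    from .features import extract_matrix

    pos, neg = simulate_sequences(
        n_pos, n_neg, seed, length_range=length_range, gc_target=gc_target
    )
    frames = []
    labels = []
    for sset, lab in ((pos, 1), (neg, 0)):
        if len(sset) == 0:
            continue
        df, skipped = extract_matrix(sset, fold_backend=fold_backend)
        if skipped:
            raise RuntimeError(f"extraction failed for {len(skipped)} sequences")
        df["label"] = lab
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    return LabeledDataset.from_frame(merged, fold_backend=fold_backend)
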