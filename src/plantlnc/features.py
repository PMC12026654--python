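"""The 100-dimensional multi-feature transcript encoding.

Three feature families distinguish long non-coding RNAs from mRNAs:

* biological properties (3): open-reading-frame count, coverage and
  longest length — mRNAs carry one long ORF, lncRNAs are stop-codon
  dense;
* sequence composition (90): length, GC content, the 3 Z-curve axes,
  the AU/GC ratio, and mono-/di-/tri-nucleotide composition vectors
  (4 + 16 + 64);
* secondary structure (7): pair and loop counts plus length-normalized
  minimum free energy (see :mod:`plantlnc.structure`).

The order of the 100 entries is fixed (``FeatureSchema``) and a
fingerprint of (ordered names, fold backend) travels with every trained
model so a model can refuse matrices built under a different encoding.

Normalization convention: di- and tri-nucleotide frequencies divide the
window counts by L-2 and L-3 respectively (not by the window counts
L-1 / L-2), so the 16 dinucleotide entries sum to (L-1)/(L-2) and the
64 trinucleotide entries to (L-2)/(L-3).  This keeps the encoding
directly comparable with published feature tables that use those
denominators.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_io import RnaSequence, SequenceSet, SkipRecord
from .structure import Backend, SecondaryStructure, fold, resolve_backend
from .structure import structure_feature_block

logger = logging.getLogger(__name__)

BASES = "ACGU"  # lexicographic feature order
STOP_CODONS = frozenset(("UAA", "UAG", "UGA"))
START_CODON = "AUG"


@dataclass(frozen=True)
class OrfRegion:
    """A single open reading frame: AUG through stop codon, inclusive.

    Coordinates are 0-based, half-open [start, end); ``end - start`` is a
    positive multiple of 3 and at least 6 (start codon + stop codon).
    """

    frame: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


OrfFeatures = namedtuple("OrfFeatures", ["orf_count", "orf_coverage", "orf_length"])
CompositionFeatures = namedtuple(
    "CompositionFeatures",
    ["seq_length", "gc_content", "z_x", "z_y", "z_z", "augc_ratio", "nac"],
)


def _build_schema() -> tuple[tuple[str, ...], tuple[str, ...]]:
    names: list[str] = ["orf_count", "orf_coverage", "orf_length"]
    cats: list[str] = ["biological"] * 3
    names += ["seq_length", "gc_content", "z_x", "z_y", "z_z", "augc_ratio"]
    names += [f"nac_{b}" for b in BASES]
    names += ["dnc_" + "".join(p) for p in itertools.product(BASES, repeat=2)]
    names += ["tnc_" + "".join(p) for p in itertools.product(BASES, repeat=3)]
    cats += ["sequence"] * (6 + 4 + 16 + 64)
    names += [
        "num_base_pairs",
        "num_au_pairs",
        "num_gc_pairs",
        "num_internal_loops",
        "num_external_loops",
        "num_unpaired_bases",
        "mfe_norm",
    ]
    cats += ["structure"] * 7
    assert len(names) == 100 and len(set(names)) == 100
    return tuple(names), tuple(cats)


class FeatureSchema:
    """The immutable, ordered 100-feature schema with category tags."""

    names: tuple[str, ...]
    categories: tuple[str, ...]

    def __init__(self) -> None:
        self.names, self.categories = _build_schema()

    def __len__(self) -> int:
        return len(self.names)

    def names_in_category(self, category: str) -> list[str]:
        return [
            n for n, c in zip(self.names, self.categories) if c == category
        ]

    def fingerprint(
        self, backend: str = "builtin", names: tuple[str, ...] | None = None
    ) -> str:
        """SHA-256 over the ordered feature names plus the fold-backend tag."""
        return schema_fingerprint(names or self.names, backend)


def schema_fingerprint(names, backend: str) -> str:
    payload = "\n".join(names) + f"\nbackend={backend}"
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


SCHEMA = FeatureSchema()


def find_orfs(seq: RnaSequence) -> list[OrfRegion]:
    """Scan the 3 forward frames for non-overlapping ORFs.

    Per frame, left to right: at the first AUG, take the first in-frame
    stop codon; emit AUG..stop inclusive and resume scanning after the
    stop.  AUGs with no downstream in-frame stop emit nothing.  ORFs
    from different frames may overlap.  Sorted by (start, frame).
    """
    r = seq.residues
    n = seq.length
    orfs: list[OrfRegion] = []
    for frame in range(3):
        pos = frame
        while pos + 3 <= n:
            if r[pos : pos + 3] == START_CODON:
                stop = None
                for q in range(pos + 3, n - 2, 3):
                    if r[q : q + 3] in STOP_CODONS:
                        stop = q
                        break
                if stop is None:
                    break  # no stop downstream in this frame: frame done
                orfs.append(OrfRegion(frame=frame, start=pos, end=stop + 3))
                pos = stop + 3
            else:
                pos += 3
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def orf_features(seq: RnaSequence) -> OrfFeatures:
    """ORF count, coverage (percent of positions in any ORF) and longest length.

    Coverage uses the union of ORF-covered positions across frames, so it
    can never exceed 100%.
    """
    orfs = find_orfs(seq)
    if not orfs:
        return OrfFeatures(0, 0.0, 0)
    covered: set[int] = set()
    for o in orfs:
        covered.update(range(o.start, o.end))
    coverage = 100.0 * len(covered) / seq.length
    return OrfFeatures(len(orfs), coverage, max(o.length for o in orfs))


def sequence_composition(seq: RnaSequence) -> CompositionFeatures:
    """Length, GC%, Z-curve axes, AU/GC ratio and mononucleotide frequencies.

    The Z-curve axes are the raw count differences
    x = (A+G)-(C+U), y = (A+C)-(G+U), z = (A+U)-(G+C).
    When a sequence contains no G or C the AU/GC ratio's denominator is
    clamped to 1 (the ratio degenerates to nA+nU) with a logged warning.
    """
    nA, nC, nG, nU = seq.counts
    L = seq.length
    gc = 100.0 * (nG + nC) / L
    z_x = float((nA + nG) - (nC + nU))
    z_y = float((nA + nC) - (nG + nU))
    z_z = float((nA + nU) - (nG + nC))
    if nG + nC == 0:
        logger.warning(
            "%s: no G/C residues; AU/GC ratio denominator clamped to 1", seq.id
        )
        augc = float(nA + nU)
    else:
        augc = (nA + nU) / (nG + nC)
    nac = (nA / L, nC / L, nG / L, nU / L)
    return CompositionFeatures(L, gc, z_x, z_y, z_z, augc, nac)


_KMER_INDEX = {
    k: {"".join(p): i for i, p in enumerate(itertools.product(BASES, repeat=k))}
    for k in (1, 2, 3)
}


def kmer_frequencies(seq: RnaSequence, k: int) -> np.ndarray:
    """Sliding-window k-mer frequencies in lexicographic order (A<C<G<U).

    Counts come from the L-k+1 windows of width k; frequencies divide by
    L (k=1), L-2 (k=2) or L-3 (k=3).
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    L = seq.length
    min_len = {1: 1, 2: 3, 3: 4}[k]
    if L < min_len:
        raise ValueError(f"sequence {seq.id!r} too short (L={L}) for k={k}")
    index = _KMER_INDEX[k]
    counts = np.zeros(4**k, dtype=np.float64)
    r = seq.residues
    for i in range(L - k + 1):
        counts[index[r[i : i + k]]] += 1
    denom = {1: L, 2: L - 2, 3: L - 3}[k]
    return counts / denom


def assemble_feature_vector(
    seq: RnaSequence, ss: SecondaryStructure
) -> np.ndarray:
    """Concatenate all families into the canonical 100-entry vector."""
    if ss.length != seq.length:
        raise ValueError(
            f"{seq.id}: structure length {ss.length} != sequence "
            f"length {seq.length}"
        )
    orf = orf_features(seq)
    comp = sequence_composition(seq)
    values = [
        float(orf.orf_count),
        orf.orf_coverage,
        float(orf.orf_length),
        float(comp.seq_length),
        comp.gc_content,
        comp.z_x,
        comp.z_y,
        comp.z_z,
        comp.augc_ratio,
        *comp.nac,
        *kmer_frequencies(seq, 2),
        *kmer_frequencies(seq, 3),
        *structure_feature_block(seq, ss).as_tuple(),
    ]
    vec = np.asarray(values, dtype=np.float64)
    assert vec.shape == (100,)
    return vec


def extract_matrix(
    seqs: SequenceSet, fold_backend: Backend = "auto"
) -> tuple[pd.DataFrame, list[SkipRecord]]:
    """Extract the feature matrix for a sequence set.

    Returns a DataFrame with an ``id`` column followed by the 100
    schema-named columns (one row per sequence, input order), plus a skip
    report for sequences whose extraction failed.  The resolved fold
    backend is recorded in ``df.attrs["fold_backend"]``.
    """
    if len(seqs) == 0:
        raise ValueError("cannot extract features from an empty sequence set")
    backend = resolve_backend(fold_backend)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped: list[SkipRecord] = []
    for seq in seqs:
        try:
            ss = fold(seq, backend)
            rows.append(assemble_feature_vector(seq, ss))
            ids.append(seq.id)
        except Exception as exc:  # per-sequence failure -> skip, not abort
            skipped.append(SkipRecord(seq.id, str(exc)))
            logger.warning("feature extraction failed for %s: %s", seq.id, exc)
    df = pd.DataFrame(rows, columns=list(SCHEMA.names))
    df.insert(0, "id", ids)
    df.attrs["fold_backend"] = backend
    return df, skipped
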