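"""RNA secondary structure: folding backends and dot-bracket feature parsing.

The classifier consumes six structural counts plus a length-normalized
minimum free energy (MFE).  Two folding backends produce the dot-bracket
input:

``external``
    ViennaRNA's MFE folder (RNAfold) through its Python bindings, when
    importable.  Energies are thermodynamic, in kcal/mol.

``builtin``
    A deterministic Nussinov-style maximum-weight pairing with pair
    weights GC=3, AU=2, GU=1 and a minimum hairpin loop of 3 unpaired
    bases.  Its "energy" is minus the total pair weight — a unitless
    proxy, not calibrated to kcal/mol.  Models trained with one backend
    must be applied with the same backend; the feature-schema fingerprint
    embeds the backend tag to enforce this.

The feature *parser* (pair counting, loop decomposition) is backend
agnostic and is where the classifier's structural encoding is defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from .sequence_io import RnaSequence

logger = logging.getLogger(__name__)

try:  # ViennaRNA bindings are optional
    import RNA as _vienna_rna
except ImportError:  # pragma: no cover - environment dependent
    _vienna_rna = None

MIN_HAIRPIN = 3  # unpaired bases enclosed by the innermost pair

Backend = Literal["auto", "external", "builtin"]


class DotBracketError(ValueError):
    """Unbalanced dot-bracket string; ``index`` locates the offending char."""

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket structure plus free energy for one sequence."""

    dot_bracket: str
    energy: float  # kcal/mol (external) or -total pair weight (builtin)
    pairs: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.pairs and "(" in self.dot_bracket:
            object.__setattr__(
                self, "pairs", tuple(parse_dotbracket(self.dot_bracket)[0])
            )

    @property
    def length(self) -> int:
        return len(self.dot_bracket)

    @property
    def n_unpaired(self) -> int:
        return self.dot_bracket.count(".")


@dataclass(frozen=True)
class StructureFeatureBlock:
    """The 7 structural features: 6 counts + normalized MFE."""

    num_base_pairs: int
    num_au_pairs: int
    num_gc_pairs: int
    num_internal_loops: int
    num_external_loops: int
    num_unpaired_bases: int
    mfe_norm: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            float(self.num_base_pairs),
            float(self.num_au_pairs),
            float(self.num_gc_pairs),
            float(self.num_internal_loops),
            float(self.num_external_loops),
            float(self.num_unpaired_bases),
            self.mfe_norm,
        )


def parse_dotbracket(db: str) -> tuple[list[tuple[int, int]], set[int]]:
    """Stack-match a dot-bracket string into pairs and unpaired indices.

    Raises :class:`DotBracketError` (carrying the offending index) on
    unbalanced parentheses or foreign characters.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    unpaired: set[int] = set()
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at index {i}", i)
            pairs.append((stack.pop(), i))
        elif ch == ".":
            unpaired.add(i)
        else:
            raise DotBracketError(f"invalid character {ch!r} at index {i}", i)
    if stack:
        raise DotBracketError(f"unmatched '(' at index {stack[0]}", stack[0])
    pairs.sort()
    return pairs, unpaired


def render_dotbracket(pairs: list[tuple[int, int]], length: int) -> str:
    """Inverse of :func:`parse_dotbracket` for non-crossing pair sets."""
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def loop_counts(
    pairs: list[tuple[int, int]], length: int
) -> tuple[int, int]:
    """Count internal and external loops of a non-crossing structure.

    Standard loop decomposition: each pair (i, j) closes a region
    classified by its number of directly nested pairs k and enclosed
    unpaired bases u — k=0 is a hairpin, k=1 with u>0 an internal loop
    (bulges included), k>=2 a multiloop.  Only internal loops are
    reported.  "External loops" is taken as the number of maximal runs
    of unpaired bases in the exterior region (outside every pair); a
    structure with no pairs at all has no loops, so both counts are 0.
    """
    if not pairs:
        return 0, 0
    paired_at = {}
    for i, j in pairs:
        paired_at[i] = j
        paired_at[j] = i

    internal = 0
    for i, j in sorted(pairs):
        # walk the region directly enclosed by (i, j)
        nested = 0
        unpaired_inside = 0
        p = i + 1
        while p < j:
            if p in paired_at and paired_at[p] > p:
                nested += 1
                p = paired_at[p] + 1
            else:
                unpaired_inside += 1
                p += 1
        if nested == 1 and unpaired_inside > 0:
            internal += 1

    # exterior region: unpaired positions not enclosed by any top-level pair
    enclosed_until = -1
    ext_positions: list[int] = []
    for i, j in sorted(pairs):
        if i > enclosed_until:
            ext_positions.extend(range(enclosed_until + 1, i))
            enclosed_until = j
    ext_positions.extend(range(enclosed_until + 1, length))
    external = 0
    prev = None
    for p in ext_positions:
        if prev is None or p != prev + 1:
            external += 1
        prev = p
    return internal, external


# nucleotide codes for the numba kernel: A=0, C=1, G=2, U=3
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# pair weights, symmetric: GC=3, AU=2, GU=1
_W = np.zeros((4, 4), dtype=np.int32)
_W[2, 1] = _W[1, 2] = 3
_W[0, 3] = _W[3, 0] = 2
_W[2, 3] = _W[3, 2] = 1


@njit(cache=True)
def _nussinov_dp(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(n - d):
            j = i + d
            best = dp[i + 1, j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                w = weights[codes[i], codes[k]]
                if w > 0:
                    v = w + dp[i + 1, k - 1] + dp[k + 1, j] if k + 1 <= j else w + dp[i + 1, k - 1]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _nussinov_traceback(
    codes: np.ndarray, dp: np.ndarray
) -> list[tuple[int, int]]:
    """Deterministic traceback: at each (i, j), pair i with the smallest
    optimal partner k; otherwise leave i unpaired."""
    n = codes.shape[0]
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_HAIRPIN:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            w = _W[codes[i], codes[k]]
            if w == 0:
                continue
            right = dp[k + 1, j] if k + 1 <= j else 0
            if w + dp[i + 1, k - 1] + right == target:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    pairs.sort()
    return pairs


def fold_builtin(seq: RnaSequence) -> SecondaryStructure:
    """Maximum-weight non-crossing pairing (Nussinov-style) of a sequence.

    Energy proxy is minus the total pair weight; deterministic.
    """
    n = seq.length
    codes = np.array([_CODE[c] for c in seq.residues], dtype=np.int8)
    if n <= MIN_HAIRPIN + 1:
        return SecondaryStructure("." * n, 0.0, ())
    dp = _nussinov_dp(codes, _W)
    pairs = _nussinov_traceback(codes, dp)
    energy = -float(sum(_W[codes[i], codes[j]] for i, j in pairs))
    return SecondaryStructure(
        render_dotbracket(pairs, n), energy, tuple(pairs)
    )


def fold_external(seq: RnaSequence) -> SecondaryStructure:
    """MFE fold via ViennaRNA's bindings (kcal/mol energies)."""
    if _vienna_rna is None:
        raise RuntimeError(
            "external folding backend requested but the ViennaRNA Python "
            "bindings are not importable; use backend='builtin'"
        )
    db, mfe = _vienna_rna.fold(seq.residues)
    pairs, _ = parse_dotbracket(db)
    return SecondaryStructure(db, float(mfe), tuple(pairs))


def resolve_backend(backend: Backend = "auto") -> str:
    """Map 'auto' to 'external' when ViennaRNA is importable, else 'builtin'."""
    if backend == "auto":
        chosen = "external" if _vienna_rna is not None else "builtin"
        logger.info("fold backend 'auto' resolved to %r", chosen)
        return chosen
    if backend not in ("external", "builtin"):
        raise ValueError(f"unknown fold backend {backend!r}")
    return backend


def fold(seq: RnaSequence, backend: Backend = "auto") -> SecondaryStructure:
    """Fold one sequence with the requested backend."""
    resolved = resolve_backend(backend)
    if resolved == "external":
        return fold_external(seq)
    return fold_builtin(seq)


def structure_feature_block(
    seq: RnaSequence, ss: SecondaryStructure
) -> StructureFeatureBlock:
    """Count pair types, loops and unpaired bases; normalize the energy.

    AU and GC pair counts are typed from the residues at paired indices;
    GU wobble pairs count toward the total only.  ``mfe_norm`` is the
    structure's energy divided by sequence length.
    """
    if ss.length != seq.length:
        raise ValueError(
            f"structure length {ss.length} != sequence length {seq.length}"
        )
    au = gc = 0
    for i, j in ss.pairs:
        duo = frozenset((seq.residues[i], seq.residues[j]))
        if duo == frozenset("AU"):
            au += 1
        elif duo == frozenset("GC"):
            gc += 1
    internal, external = loop_counts(list(ss.pairs), ss.length)
    return StructureFeatureBlock(
        num_base_pairs=len(ss.pairs),
        num_au_pairs=au,
        num_gc_pairs=gc,
        num_internal_loops=internal,
        num_external_loops=external,
        num_unpaired_bases=ss.n_unpaired,
        mfe_norm=ss.energy / seq.length,
    )
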