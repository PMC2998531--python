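"""Scoring matrices from positional-scanning combinatorial peptide libraries.

A combinatorial library panel characterizes one MHC class II molecule
with 180 peptide mixtures.  Each mixture is a pool of 13-mers with
alanine at positions 1, 2, 12 and 13; the central nine positions
(peptide positions 3-11, core positions 1-9) are equimolar mixtures of
all 20 residues except for a single fixed residue in one position.
Measuring the IC50 of all 9 x 20 = 180 mixtures gives an unbiased
profile of the molecule's core binding specificity.

Matrix derivation from a panel:

1. standardize: ``r[p][a] = IC50[p][a] / G`` with G the geometric mean
   of all 180 mixture IC50s;
2. normalize per position so the optimal (lowest, strongest-binding)
   value is 1: ``n[p][a] = r[p][a] / min_a r[p][a]``;
3. position weighting by average relative binding (ARB): with
   ``ARB_p`` the geometric mean of ``n[p][.]`` and ``ARB_all`` the
   geometric mean over all 180 normalized values, each position is
   weighted by ``w_p = ARB_all / ARB_p``, so positions whose residue
   choice barely moves the affinity count less.

The resulting 9 x 20 matrix predicts binding of a novel peptide by
multiplying the matrix values along each 9-mer core window; the
peptide's score is the best (minimum) product over windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    ALPHABET,
    CORE_LENGTH,
    N_POSITIONS,
    N_RESIDUES,
    LibraryPanel,
    PredictionRecord,
    ScoringMatrix,
    ValidationError,
    encode_peptide,
)

#: 13-mer library template constants: alanine-flanked, core at positions 3-11.
TEMPLATE_LENGTH = 13
FLANK_POSITIONS = (1, 2, 12, 13)
CORE_TEMPLATE_OFFSET = 2  # core position 1 sits at template position 3 (1-based)

#: Assay-sensitivity ceiling (nM) callers should clamp panel IC50s to.
DEFAULT_IC50_CEILING = 50_000.0


@dataclass(frozen=True)
class LibraryMixture:
    """Descriptor of one positional-scanning mixture."""

    core_position: int  # 1-9
    residue: str
    template: str  # 13-mer pattern, X = equimolar mixture position

    @property
    def template_position(self) -> int:
        """1-based position of the fixed residue within the 13-mer."""
        return self.core_position + CORE_TEMPLATE_OFFSET


def library_design() -> list[LibraryMixture]:
    """Enumerate the 180 mixtures of the standard panel design."""
    mixtures = []
    for pos in range(1, N_POSITIONS + 1):
        for residue in ALPHABET:
            core = ["X"] * N_POSITIONS
            core[pos - 1] = residue
            template = "AA" + "".join(core) + "AA"
            mixtures.append(LibraryMixture(core_position=pos, residue=residue, template=template))
    return mixtures


@dataclass
class DerivationTrace:
    """Intermediate quantities of a matrix derivation, for audit.

    All arrays are 9 x 20 (position x residue) on the linear scale.
    """

    geometric_mean: float  # G, geometric mean of the 180 panel IC50s (nM)
    relative: np.ndarray  # r = IC50 / G
    normalized: np.ndarray  # n, per-position optimum scaled to 1
    arb_per_position: np.ndarray  # ARB_p, geometric mean of n[p][.]
    arb_all: float  # geometric mean over all 180 n values
    weights: np.ndarray  # w_p = ARB_all / ARB_p


def derive_matrix(
    panel: LibraryPanel, weighting: bool = True
) -> tuple[ScoringMatrix, DerivationTrace]:
    """Derive the 9 x 20 scoring matrix from a complete library panel.

    With ``weighting`` the normalized values are multiplied by the
    per-position ARB weight ``w_p``; without it the matrix is the
    normalized values themselves.  Scale-invariant: multiplying every
    panel IC50 by a constant leaves the matrix unchanged.
    """
    log_ic50 = np.log(panel.ic50)
    log_g = log_ic50.mean()
    log_r = log_ic50 - log_g
    log_n = log_r - log_r.min(axis=1, keepdims=True)
    log_arb_p = log_n.mean(axis=1)
    log_arb_all = log_n.mean()
    log_w = log_arb_all - log_arb_p
    log_m = log_n + log_w[:, None] if weighting else log_n
    trace = DerivationTrace(
        geometric_mean=float(np.exp(log_g)),
        relative=np.exp(log_r),
        normalized=np.exp(log_n),
        arb_per_position=np.exp(log_arb_p),
        arb_all=float(np.exp(log_arb_all)),
        weights=np.exp(log_w),
    )
    matrix = ScoringMatrix(allele=panel.allele, values=np.exp(log_m), source="comblib")
    return matrix, trace


def score_core(matrix: ScoringMatrix, core: str) -> float:
    """Product of the nine matrix entries along a 9-mer core (lower = stronger)."""
    if len(core) != CORE_LENGTH:
        raise ValidationError(f"core must be exactly {CORE_LENGTH} residues, got {len(core)}")
    idx = encode_peptide(core)
    return float(np.prod(matrix.values[np.arange(CORE_LENGTH), idx]))


def window_scores(matrix: ScoringMatrix, peptide: str) -> np.ndarray:
    """Scores of every 9-mer window of a peptide, left to right."""
    idx = encode_peptide(peptide)
    if idx.size < CORE_LENGTH:
        raise ValidationError(
            f"peptide must be at least {CORE_LENGTH} residues, got {idx.size}"
        )
    n_windows = idx.size - CORE_LENGTH + 1
    offsets = np.arange(n_windows)[:, None] + np.arange(CORE_LENGTH)[None, :]
    log_scores = matrix.log_values[np.arange(CORE_LENGTH)[None, :], idx[offsets]].sum(axis=1)
    return np.exp(log_scores)


def predict_peptide(matrix: ScoringMatrix, peptide: str, method: str = "comblib") -> PredictionRecord:
    """Best-core prediction: minimum window score, leftmost window on ties."""
    scores = window_scores(matrix, peptide)
    offset = int(np.argmin(scores))  # argmin returns the first minimum
    return PredictionRecord(
        sequence=peptide, score=float(scores[offset]), core_offset=offset, method=method
    )
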