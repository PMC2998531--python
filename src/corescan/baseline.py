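"""A trainable best-core matrix predictor and the predictor interface.

This module supplies the machine-learning leg of the benchmarking
harness: an iterative estimator in the spirit of average-relative-
binding matrix methods.  It alternates (E) assigning each training
peptide its current best-scoring 9-mer core with (M) re-estimating the
matrix cells from geometric means of the assigned cores' IC50s,
relative to the dataset geometric mean, with one pseudocount
observation at the dataset mean so unobserved cells stay neutral
(ratio 1).  The M-step is residual-corrected: each cell's geometric
mean is taken over the peptides' IC50s divided by the contribution the
current matrix assigns to the *other* eight core positions
(coordinate-descent backfitting of the log-additive model).  A naive
marginal geometric mean would fold the other positions' signal into
every cell and badly blur strong anchor preferences; the residual form
fits the same product model consistently.  All averaging is done in
log space.  Training is deterministic: the initial assignment is the
leftmost window and every subsequent step is a pure function of the
data.

It also fixes the contract every prediction method in the harness
(library-derived matrices, trained matrices, external predictors) must
satisfy: ``predict_many(peptides)`` returning one record per peptide in
stable order, with per-record error entries for unscorable peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .comblib import predict_peptide
from .data_model import (
    CORE_LENGTH,
    N_POSITIONS,
    N_RESIDUES,
    AffinityDataset,
    PredictionError,
    PredictionRecord,
    ScoringMatrix,
    ValidationError,
    encode_peptide,
)

MIN_TRAINING_RECORDS = 20


@dataclass
class TrainerConfig:
    """Training knobs for the iterative best-core estimator."""

    max_iterations: int = 50
    pseudocount: float = 1.0  # virtual observations at the dataset geometric mean
    convergence: str = "core-assignments-stable"  # or "max-iter"
    seed: int = 0  # reserved; initial assignment is the deterministic leftmost window
    m_step_sweeps: int = 10  # backfitting sweeps per M-step

    def __post_init__(self) -> None:
        if self.max_iterations < 0:
            raise ValidationError("max_iterations must be >= 0")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.m_step_sweeps < 1:
            raise ValidationError("m_step_sweeps must be >= 1")
        if self.convergence not in ("core-assignments-stable", "max-iter"):
            raise ValidationError(f"unknown convergence mode {self.convergence!r}")


@runtime_checkable
class Predictor(Protocol):
    """Anything that can score peptides (lower score = stronger binding)."""

    method: str

    def predict_many(
        self, peptides: Sequence[str]
    ) -> list[PredictionRecord | PredictionError]: ...


def train_core_matrix(train: AffinityDataset, config: TrainerConfig | None = None) -> ScoringMatrix:
    """Fit a 9 x 20 scoring matrix to an affinity dataset.

    With ``max_iterations=0`` the matrix comes from a single M-step on
    leftmost cores.  Otherwise E/M alternation runs until core
    assignments are stable or the iteration cap is hit.
    """
    config = config or TrainerConfig()
    if len(train) < MIN_TRAINING_RECORDS:
        raise ValidationError(
            f"need at least {MIN_TRAINING_RECORDS} training records, got {len(train)}"
        )
    encoded = []
    for rec in train:
        if len(rec.sequence) < CORE_LENGTH:
            raise ValidationError(
                f"training sequence {rec.sequence!r} shorter than {CORE_LENGTH}"
            )
        encoded.append(encode_peptide(rec.sequence))
    log_ic50 = np.log(train.ic50s)
    log_g = log_ic50.mean()
    log_rel = log_ic50 - log_g  # per-peptide log relative affinity

    n = len(encoded)
    n_windows = np.array([e.size - CORE_LENGTH + 1 for e in encoded])
    # window residue index tensor per peptide, ragged -> list of (w, 9) arrays
    windows = [
        e[np.arange(w)[:, None] + np.arange(CORE_LENGTH)[None, :]]
        for e, w in zip(encoded, n_windows)
    ]
    pos_idx = np.arange(CORE_LENGTH)

    def m_step(assignment: np.ndarray, log_m: np.ndarray) -> np.ndarray:
        # backfitting sweeps: each cell is the geometric mean of the
        # assigned cores' residual affinities (other positions' current
        # contribution divided out), pseudocount-smoothed toward ratio 1
        cores = np.stack([windows[i][assignment[i]] for i in range(n)])  # (n, 9)
        log_m = log_m.copy()
        fitted = log_m[pos_idx[None, :], cores].sum(axis=1)
        for _ in range(config.m_step_sweeps):
            for p in range(N_POSITIONS):
                contrib = log_m[p, cores[:, p]]
                residual = log_rel - (fitted - contrib)
                log_sum = np.zeros(N_RESIDUES)
                count = np.full(N_RESIDUES, config.pseudocount)
                np.add.at(log_sum, cores[:, p], residual)
                np.add.at(count, cores[:, p], 1.0)
                new_row = log_sum / count  # pseudocount adds log-ratio 0
                fitted += new_row[cores[:, p]] - contrib
                log_m[p] = new_row
        return log_m

    def e_step(log_m: np.ndarray) -> np.ndarray:
        new = np.empty(n, dtype=np.int64)
        for i in range(n):
            scores = log_m[pos_idx[None, :], windows[i]].sum(axis=1)
            new[i] = int(np.argmin(scores))
        return new

    assignment = np.zeros(n, dtype=np.int64)  # leftmost window
    log_m = m_step(assignment, np.zeros((N_POSITIONS, N_RESIDUES)))
    for _ in range(config.max_iterations):
        new_assignment = e_step(log_m)
        if config.convergence == "core-assignments-stable" and np.array_equal(
            new_assignment, assignment
        ):
            break
        assignment = new_assignment
        log_m = m_step(assignment, log_m)
    return ScoringMatrix(allele=train.allele, values=np.exp(log_m), source="trained")


@dataclass
class MatrixPredictor:
    """Predictor-interface wrapper around any scoring matrix."""

    matrix: ScoringMatrix
    method: str = "matrix"

    def predict_many(
        self, peptides: Sequence[str]
    ) -> list[PredictionRecord | PredictionError]:
        out: list[PredictionRecord | PredictionError] = []
        for pep in peptides:
            try:
                out.append(predict_peptide(self.matrix, pep, method=self.method))
            except ValidationError as exc:
                out.append(PredictionError(sequence=pep, message=str(exc)))
        return out


@dataclass
class BaselineTrainer:
    """Trainable method satisfying the harness trainer contract."""

    config: TrainerConfig | None = None
    method: str = "baseline"

    def fit(self, train: AffinityDataset) -> MatrixPredictor:
        matrix = train_core_matrix(train, self.config)
        return MatrixPredictor(matrix=matrix, method=self.method)
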