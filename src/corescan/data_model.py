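"""Domain types and file formats for MHC class II binding data.

Measured peptide binding affinities are half-maximal inhibitory
concentrations (IC50, nM) from competition assays: lower values mean
stronger binding.  Peptides with IC50 < 1000 nM are classified as
binders, a cutoff chosen for its biological relevance (it captures the
large majority of known DR-restricted epitopes); an IC50 of exactly
1000 nM is a non-binder.

Scoring matrices are 9 positions x 20 residues of positive
multiplicative weights over the 9-mer core that occupies the class II
binding groove.  They share the IC50 orientation: a smaller product
over a core means stronger predicted binding.

All coordinates are 0-based half-open internally; user-facing reports
use 1-based core positions 1-9.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: IC50 threshold (nM) separating binders (strictly below) from non-binders.
BINDER_CUTOFF_NM = 1000.0

#: Length of the MHC class II binding-groove core.
CORE_LENGTH = 9

N_POSITIONS = 9
N_RESIDUES = 20


class ValidationError(ValueError):
    """Raised when domain invariants are violated by input data."""


def classify_binder(ic50: float) -> bool:
    """Classify a measured IC50 (nM) as binder (True) or non-binder.

    Binders have IC50 strictly below 1000 nM; the boundary value
    1000 nM is a non-binder.
    """
    if not isinstance(ic50, (int, float)) or isinstance(ic50, bool):
        raise ValidationError(f"ic50 must be numeric, got {type(ic50).__name__}")
    if math.isnan(ic50) or ic50 <= 0:
        raise ValidationError(f"ic50 must be a positive number of nM, got {ic50!r}")
    return ic50 < BINDER_CUTOFF_NM


def validate_sequence(sequence: str) -> str:
    """Check that a peptide uses only the 20 standard residues."""
    if not sequence:
        raise ValidationError("peptide sequence must be non-empty")
    bad = set(sequence) - set(ALPHABET)
    if bad:
        raise ValidationError(
            f"sequence {sequence!r} contains non-standard residues {sorted(bad)}"
        )
    return sequence


def encode_peptide(sequence: str) -> np.ndarray:
    """Encode a peptide as an int array of residue indices (0-19)."""
    validate_sequence(sequence)
    return np.fromiter((AA_INDEX[a] for a in sequence), dtype=np.int64, count=len(sequence))


@dataclass(frozen=True)
class AffinityRecord:
    """One measured peptide:allele binding affinity.

    The binder flag is derived from the IC50 at construction and is
    always consistent with :func:`classify_binder`.
    """

    allele: str
    sequence: str
    ic50: float
    binder: bool = field(init=False)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        object.__setattr__(self, "binder", classify_binder(self.ic50))


@dataclass
class AffinityDataset:
    """An ordered per-allele collection of affinity measurements.

    Sequence order is stable and reproducible; duplicate sequences are
    not allowed (use :meth:`from_records`, which keeps the first
    occurrence and logs the rest).
    """

    allele: str
    records: list[AffinityRecord]
    provenance: str = "measured"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.allele != self.allele:
                raise ValidationError(
                    f"record allele {rec.allele!r} does not match dataset allele {self.allele!r}"
                )
            if rec.sequence in seen:
                raise ValidationError(f"duplicate sequence {rec.sequence!r} in dataset")
            seen.add(rec.sequence)

    @classmethod
    def from_records(
        cls,
        allele: str,
        records: Iterable[AffinityRecord],
        provenance: str = "measured",
    ) -> "AffinityDataset":
        """Build a dataset, keeping the first occurrence of duplicate sequences."""
        kept: list[AffinityRecord] = []
        seen: set[str] = set()
        for rec in records:
            if rec.sequence in seen:
                logger.warning(
                    "duplicate sequence %s for allele %s: keeping first occurrence",
                    rec.sequence, allele,
                )
                continue
            seen.add(rec.sequence)
            kept.append(rec)
        return cls(allele=allele, records=kept, provenance=provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AffinityRecord]:
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ic50s(self) -> np.ndarray:
        return np.array([r.ic50 for r in self.records], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """Boolean binder labels, dataset order."""
        return np.array([r.binder for r in self.records], dtype=bool)

    def subset(self, sequences: Iterable[str], provenance: str | None = None) -> "AffinityDataset":
        """Records whose sequence is in ``sequences``, original order preserved."""
        wanted = set(sequences)
        recs = [r for r in self.records if r.sequence in wanted]
        return AffinityDataset(
            allele=self.allele,
            records=recs,
            provenance=provenance or self.provenance,
        )


@dataclass
class ScoringMatrix:
    """A 9 x 20 position-specific scoring matrix of positive weights.

    Rows are core positions 1-9, columns the residues ACDEFGHIKLMNPQRSTVWY.
    Orientation is IC50-like: the product over a 9-mer core is smaller
    for stronger predicted binders.
    """

    allele: str
    values: np.ndarray
    source: str = "trained"  # comblib | trained | synthetic-truth

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_POSITIONS, N_RESIDUES):
            raise ValidationError(
                f"matrix must be {N_POSITIONS}x{N_RESIDUES}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValidationError("matrix values must all be finite and > 0")

    def value(self, position: int, residue: str) -> float:
        """Matrix entry for a 1-based core position and residue letter."""
        if not 1 <= position <= N_POSITIONS:
            raise ValidationError(f"core position must be 1-{N_POSITIONS}, got {position}")
        if residue not in AA_INDEX:
            raise ValidationError(f"unknown residue {residue!r}")
        return float(self.values[position - 1, AA_INDEX[residue]])

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.values)


@dataclass
class LibraryPanel:
    """IC50 measurements for the 180 positional-scanning mixtures of one allele.

    ``ic50`` is a 9 x 20 array: entry (p, a) is the measured IC50 of the
    mixture with residue a fixed at core position p+1.
    """

    allele: str
    ic50: np.ndarray

    def __post_init__(self) -> None:
        self.ic50 = np.asarray(self.ic50, dtype=float)
        if self.ic50.shape != (N_POSITIONS, N_RESIDUES):
            raise ValidationError(
                f"panel must have {N_POSITIONS * N_RESIDUES} measurements "
                f"({N_POSITIONS}x{N_RESIDUES}), got shape {self.ic50.shape}"
            )
        if not np.all(np.isfinite(self.ic50)) or np.any(self.ic50 <= 0):
            raise ValidationError("panel IC50s must all be finite and > 0")

    @classmethod
    def from_measurements(
        cls, allele: str, measurements: Iterable[tuple[int, str, float]]
    ) -> "LibraryPanel":
        """Build a panel from (position 1-9, residue, ic50) triples.

        The 180 (position, residue) keys must be exactly the cross
        product of 9 positions and 20 residues, each present once.
        """
        grid = np.full((N_POSITIONS, N_RESIDUES), np.nan)
        for pos, residue, ic50 in measurements:
            if not 1 <= pos <= N_POSITIONS:
                raise ValidationError(f"library position must be 1-{N_POSITIONS}, got {pos}")
            if residue not in AA_INDEX:
                raise ValidationError(f"unknown residue {residue!r} in panel")
            i, j = pos - 1, AA_INDEX[residue]
            if not np.isnan(grid[i, j]):
                raise ValidationError(f"duplicate panel entry for position {pos}, residue {residue}")
            grid[i, j] = ic50
        if np.isnan(grid).any():
            missing = int(np.isnan(grid).sum())
            raise ValidationError(f"panel is incomplete: {missing} of 180 mixtures missing")
        return cls(allele=allele, ic50=grid)

    def measurements(self) -> list[tuple[int, str, float]]:
        """The 180 (position 1-9, residue, ic50) triples in row-major order."""
        return [
            (p + 1, ALPHABET[a], float(self.ic50[p, a]))
            for p in range(N_POSITIONS)
            for a in range(N_RESIDUES)
        ]


@dataclass(frozen=True)
class PredictionRecord:
    """A scored peptide with its best 9-mer core.

    ``score`` is IC50-like (lower = stronger predicted binding);
    ``core_offset`` is the 0-based start of the best core.
    """

    sequence: str
    score: float
    core_offset: int
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.core_offset <= len(self.sequence) - CORE_LENGTH):
            raise ValidationError(
                f"core offset {self.core_offset} out of range for {self.sequence!r}"
            )
        if not self.score > 0:
            raise ValidationError(f"score must be > 0, got {self.score}")

    @property
    def core(self) -> str:
        return self.sequence[self.core_offset : self.core_offset + CORE_LENGTH]


@dataclass(frozen=True)
class PredictionError:
    """Per-peptide failure entry emitted by batch prediction."""

    sequence: str
    message: str


# ---------------------------------------------------------------------------
# File formats (tab-separated dialects)
# ---------------------------------------------------------------------------

AFFINITY_COLUMNS = ("allele", "sequence", "ic50_nM")


def read_affinity_table(path: str | Path, strict: bool = True) -> dict[str, AffinityDataset]:
    """Read an affinity TSV (header ``allele<TAB>sequence<TAB>ic50_nM``).

    Returns one dataset per allele, in order of first appearance, with
    input row order preserved.  Malformed rows raise (strict mode,
    default) or are skipped with a warning (lenient), always naming the
    offending line number.
    """
    path = Path(path)
    errors: list[str] = []
    per_allele: dict[str, list[AffinityRecord]] = {}
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = [c for c in AFFINITY_COLUMNS if c not in header]
        if missing:
            raise ValidationError(f"{path}: missing required columns {missing}")
        idx = {c: header.index(c) for c in AFFINITY_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                allele = row[idx["allele"]].strip()
                sequence = row[idx["sequence"]].strip().upper()
                raw_ic50 = row[idx["ic50_nM"]].strip()
                try:
                    ic50 = float(raw_ic50)
                except ValueError:
                    raise ValidationError(f"non-numeric ic50 {raw_ic50!r}") from None
                record = AffinityRecord(allele=allele, sequence=sequence, ic50=ic50)
            except (ValidationError, IndexError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            per_allele.setdefault(allele, []).append(record)
    if errors:
        msg = f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors)
        if strict:
            raise ValidationError(msg)
        logger.warning("%s (skipped in lenient mode)", msg)
    return {
        allele: AffinityDataset.from_records(allele, records)
        for allele, records in per_allele.items()
    }


def write_affinity_table(datasets: Iterable[AffinityDataset] | AffinityDataset, path: str | Path) -> None:
    """Write one or more datasets in the affinity TSV dialect."""
    if isinstance(datasets, AffinityDataset):
        datasets = [datasets]
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(AFFINITY_COLUMNS)
        for ds in datasets:
            for rec in ds:
                writer.writerow([rec.allele, rec.sequence, _fmt(rec.ic50)])


def _fmt(x: float) -> str:
    """Format a real to 12 significant digits (lossless at that precision)."""
    return f"{x:.12g}"


def read_matrix(path: str | Path, allele: str | None = None, source: str = "comblib") -> ScoringMatrix:
    """Read a scoring matrix TSV.

    Dialect: header row ``residue<TAB>pos1..pos9``; 20 data rows keyed
    by residue letter in alphabetical order; linear (not log) values.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        raise ValidationError(f"{path}: empty matrix file")
    header = [h.strip() for h in rows[0]]
    expected = ["residue"] + [f"pos{i}" for i in range(1, N_POSITIONS + 1)]
    if header != expected:
        raise ValidationError(f"{path}: matrix header must be {expected}, got {header}")
    body = rows[1:]
    if len(body) != N_RESIDUES:
        raise ValidationError(f"{path}: expected {N_RESIDUES} residue rows, got {len(body)}")
    values = np.empty((N_POSITIONS, N_RESIDUES))
    for i, row in enumerate(body):
        residue = row[0].strip()
        if residue != ALPHABET[i]:
            raise ValidationError(
                f"{path}: residue rows must be {ALPHABET} in order; "
                f"row {i + 2} has {residue!r}, expected {ALPHABET[i]!r}"
            )
        if len(row) != N_POSITIONS + 1:
            raise ValidationError(f"{path}: row {i + 2} has {len(row) - 1} positions, expected 9")
        values[:, i] = [float(x) for x in row[1:]]
    return ScoringMatrix(allele=allele or path.stem, values=values, source=source)


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    """Write a scoring matrix in the TSV dialect (12 significant digits)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["residue"] + [f"pos{i}" for i in range(1, N_POSITIONS + 1)])
        for j, residue in enumerate(ALPHABET):
            writer.writerow([residue] + [_fmt(v) for v in matrix.values[:, j]])


def read_panel(path: str | Path, allele: str | None = None) -> LibraryPanel:
    """Read a library panel TSV (header ``position<TAB>residue<TAB>ic50_nM``)."""
    path = Path(path)
    triples: list[tuple[int, str, float]] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = [h.strip() for h in next(reader)]
        if header != ["position", "residue", "ic50_nM"]:
            raise ValidationError(
                f"{path}: panel header must be position/residue/ic50_nM, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                triples.append((int(row[0]), row[1].strip(), float(row[2])))
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return LibraryPanel.from_measurements(allele or path.stem, triples)


def write_panel(panel: LibraryPanel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "residue", "ic50_nM"])
        for pos, residue, ic50 in panel.measurements():
            writer.writerow([pos, residue, _fmt(ic50)])


def read_peptides(path: str | Path) -> list[str]:
    """Read peptides from a plain one-per-line file or FASTA."""
    path = Path(path)
    with path.open() as handle:
        first = handle.readline()
    if first.startswith(">"):
        from Bio import SeqIO

        peptides = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    else:
        with path.open() as handle:
            peptides = [line.strip().upper() for line in handle if line.strip()]
    for pep in peptides:
        validate_sequence(pep)
    return peptides


def write_predictions(
    records: Sequence[PredictionRecord],
    path: str | Path,
    percentile_ranks: Sequence[float] | None = None,
) -> None:
    """Write predictions in the report TSV dialect (1-based core starts)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sequence", "method", "score", "core_start_1based", "core_sequence", "percentile_rank"]
        )
        for i, rec in enumerate(records):
            rank = "" if percentile_ranks is None else _fmt(percentile_ranks[i])
            writer.writerow(
                [rec.sequence, rec.method, _fmt(rec.score), rec.core_offset + 1, rec.core, rank]
            )
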