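"""Peptide similarity and sequence-redundancy reduction.

Epitope-mapping datasets are rich in homologous peptides: overlapping
15-mers tiling a protein, single-residue substitution scans of a
reference ligand, and cross-reactivity variants.  Two peptides are
considered *similar* when they share an identical 9-mer subsequence or
exceed 80% ungapped sequence identity, where identity is the maximum
number of matching residues over all ungapped relative alignments
divided by the shorter length.

Redundancy reduction produces the dataset hierarchy ALL >= SR >= SP:

* **SR** (similarity-reduced): binders and non-binders (1000 nM cutoff)
  are reduced independently with a forward Hobohm-1 selection —
  peptides sorted by their number of similar partners (``N_similarity``,
  ascending) are kept greedily unless similar to an already-kept
  peptide — then merged.  The selection is deterministic and keeps a
  maximal independent set.
* **SP** (singular peptides): peptides with no similar partner anywhere
  in the full set.

A seeded ``random_reduce`` comparator removes one member of each
similar pair in an undefined (shuffled) order; its kept-set size varies
with the seed, which is exactly the instability the deterministic
forward selection avoids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import AA_INDEX, CORE_LENGTH, AffinityDataset, ValidationError

IDENTITY_THRESHOLD = 0.80  # strict: similar requires identity > 0.80


def ungapped_identity(p1: str, p2: str) -> float:
    """Maximum ungapped sequence identity between two peptides.

    Every relative offset with at least one aligned residue is
    examined; M is the largest number of identical aligned residues and
    the identity is M / min(len(p1), len(p2)).  Symmetric, and 1.0 for
    identical peptides.
    """
    if not p1 or not p2:
        raise ValidationError("peptides must be non-empty")
    l1, l2 = len(p1), len(p2)
    best = 0
    for offset in range(-(l2 - 1), l1):
        a = max(0, offset)
        b = max(0, -offset)
        span = min(l1 - a, l2 - b)
        matches = sum(p1[a + i] == p2[b + i] for i in range(span))
        if matches > best:
            best = matches
    return best / min(l1, l2)


def shares_9mer(p1: str, p2: str) -> bool:
    """True iff some identical contiguous 9-residue substring occurs in both."""
    if len(p1) < CORE_LENGTH or len(p2) < CORE_LENGTH:
        return False
    kmers = {p1[i : i + CORE_LENGTH] for i in range(len(p1) - CORE_LENGTH + 1)}
    return any(p2[i : i + CORE_LENGTH] in kmers for i in range(len(p2) - CORE_LENGTH + 1))


def is_similar(p1: str, p2: str) -> bool:
    """Similarity criterion: shared 9-mer OR identity strictly above 80%."""
    return shares_9mer(p1, p2) or ungapped_identity(p1, p2) > IDENTITY_THRESHOLD


def _identity_min_matches(min_len: int) -> int:
    # smallest integer M with M/min_len > 0.80, in exact integer arithmetic
    return (4 * min_len) // 5 + 1


def similar_pairs(peptides: Sequence[str]) -> set[tuple[int, int]]:
    """All index pairs (i < j) of similar peptides.

    Shared 9-mers are found by hashing; the identity condition is
    evaluated with a vectorized match count restricted to offsets whose
    overlap can reach the >80% threshold (shorter overlaps cannot, so
    the result equals the all-pairs brute force).
    """
    n = len(peptides)
    pairs: set[tuple[int, int]] = set()

    # condition 1: shared 9-mer, via k-mer buckets
    buckets: dict[str, list[int]] = {}
    for i, pep in enumerate(peptides):
        for s in range(len(pep) - CORE_LENGTH + 1):
            buckets.setdefault(pep[s : s + CORE_LENGTH], []).append(i)
    for members in buckets.values():
        uniq = sorted(set(members))
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                pairs.add((uniq[a], uniq[b]))

    # condition 2: identity > threshold, grouped by length pair
    by_len: dict[int, list[int]] = {}
    for i, pep in enumerate(peptides):
        by_len.setdefault(len(pep), []).append(i)
    enc = {
        length: np.array(
            [[AA_INDEX[a] for a in peptides[i]] for i in idx], dtype=np.int8
        )
        for length, idx in by_len.items()
    }
    lengths = sorted(by_len)
    for li, l1 in enumerate(lengths):
        for l2 in lengths[li:]:
            idx1, idx2 = by_len[l1], by_len[l2]
            arr1, arr2 = enc[l1], enc[l2]
            need = _identity_min_matches(min(l1, l2))
            hit = np.zeros((len(idx1), len(idx2)), dtype=bool)
            for offset in range(-(l2 - 1), l1):
                a = max(0, offset)
                b = max(0, -offset)
                span = min(l1 - a, l2 - b)
                if span < need:
                    continue
                eq = arr1[:, None, a : a + span] == arr2[None, :, b : b + span]
                hit |= eq.sum(axis=2) >= need
            ii, jj = np.nonzero(hit)
            for x, y in zip(ii, jj):
                gi, gj = idx1[x], idx2[y]
                if gi == gj:
                    continue
                pairs.add((gi, gj) if gi < gj else (gj, gi))
    return pairs


@dataclass
class SimilarityCounts:
    """Per-peptide count of similar partners (``N_similarity``)."""

    peptides: list[str]
    counts: np.ndarray
    pairs: set[tuple[int, int]]

    def __getitem__(self, i: int) -> int:
        return int(self.counts[i])

    def of(self, peptide: str) -> int:
        return int(self.counts[self.peptides.index(peptide)])


def count_similar(peptides: Sequence[str]) -> SimilarityCounts:
    """Count, for each peptide, how many of the others are similar to it."""
    if len(peptides) < 1:
        raise ValidationError("need at least one peptide")
    pairs = similar_pairs(peptides)
    counts = np.zeros(len(peptides), dtype=np.int64)
    for i, j in pairs:
        counts[i] += 1
        counts[j] += 1
    return SimilarityCounts(peptides=list(peptides), counts=counts, pairs=pairs)


@dataclass
class ReductionResult:
    """Outcome of a redundancy-reduction run.

    ``kept`` is ordered (selection order for the forward algorithm);
    kept and discarded partition the input and no kept pair is similar.
    """

    kept: list[str]
    discarded: list[str]
    counts: SimilarityCounts
    algorithm: str
    seed: int | None = None


def hobohm_forward_reduce(
    peptides: Sequence[str], counts: SimilarityCounts | None = None
) -> ReductionResult:
    """Deterministic forward Hobohm-1 redundancy reduction.

    Peptides are sorted by N_similarity ascending (ties broken by
    lexicographic sequence order, then input order) into a work list;
    each is popped in turn and kept unless similar to an already-kept
    peptide.  The kept set is maximal: every discarded peptide is
    similar to at least one kept peptide.
    """
    peptides = list(peptides)
    if counts is None or counts.peptides != peptides:
        counts = count_similar(peptides) if peptides else SimilarityCounts([], np.zeros(0, int), set())
    adjacency: dict[int, set[int]] = {i: set() for i in range(len(peptides))}
    for i, j in counts.pairs:
        adjacency[i].add(j)
        adjacency[j].add(i)
    order = sorted(range(len(peptides)), key=lambda i: (counts[i], peptides[i], i))
    kept_idx: set[int] = set()
    kept: list[str] = []
    discarded: list[str] = []
    for i in order:
        if adjacency[i] & kept_idx:
            discarded.append(peptides[i])
        else:
            kept_idx.add(i)
            kept.append(peptides[i])
    return ReductionResult(kept=kept, discarded=discarded, counts=counts, algorithm="forward_hobohm")


def random_reduce(peptides: Sequence[str], seed: int) -> ReductionResult:
    """Seed-shuffled pair-removal comparator.

    The peptide list is shuffled with the seed and similar pairs are
    visited in that order; the later member of each still-present
    similar pair is removed.  Different seeds can keep different
    numbers of peptides — the instability that motivates the
    deterministic forward selection.
    """
    peptides = list(peptides)
    counts = count_similar(peptides) if peptides else SimilarityCounts([], np.zeros(0, int), set())
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(peptides)))
    position = {idx: pos for pos, idx in enumerate(order)}
    adjacency: dict[int, set[int]] = {i: set() for i in range(len(peptides))}
    for i, j in counts.pairs:
        adjacency[i].add(j)
        adjacency[j].add(i)
    removed: set[int] = set()
    for i in order:
        if i in removed:
            continue
        later = sorted((j for j in adjacency[i] if j not in removed and position[j] > position[i]),
                       key=position.__getitem__)
        removed.update(later)
    kept = [peptides[i] for i in range(len(peptides)) if i not in removed]
    discarded = [peptides[i] for i in sorted(removed)]
    return ReductionResult(
        kept=kept, discarded=discarded, counts=counts, algorithm="random_removal", seed=seed
    )


@dataclass
class DatasetReduction:
    """Similarity reduction of an affinity dataset.

    Binder and non-binder partitions are reduced independently and the
    kept peptides merged, preserving the original dataset order.
    Similar pairs straddling the binder/non-binder boundary may remain
    in the merged SR set by construction.
    """

    binder_result: ReductionResult
    nonbinder_result: ReductionResult
    sr: AffinityDataset

    @property
    def kept_sequences(self) -> list[str]:
        return self.sr.sequences


def similarity_reduce_dataset(
    dataset: AffinityDataset, scope: str = "partition"
) -> DatasetReduction:
    """Build the SR dataset: forward Hobohm-1 within each binder partition.

    ``scope`` controls where N_similarity is counted: ``"partition"``
    (default) counts within the partition being reduced, ``"dataset"``
    counts against the whole dataset (the sort key changes; the
    similarity graph used for rejection is always the partition's).
    """
    if scope not in ("partition", "dataset"):
        raise ValidationError(f"scope must be 'partition' or 'dataset', got {scope!r}")
    labels = dataset.labels
    seqs = dataset.sequences
    binders = [s for s, b in zip(seqs, labels) if b]
    nonbinders = [s for s, b in zip(seqs, labels) if not b]

    if scope == "dataset":
        global_counts = count_similar(seqs) if seqs else None

    def _reduce(part: list[str]) -> ReductionResult:
        if not part:
            return ReductionResult([], [], SimilarityCounts([], np.zeros(0, int), set()), "forward_hobohm")
        counts = count_similar(part)
        if scope == "dataset" and global_counts is not None:
            # keep the partition similarity graph, re-key the sort counts globally
            remap = np.array([global_counts.counts[seqs.index(p)] for p in part])
            counts = SimilarityCounts(peptides=part, counts=remap, pairs=counts.pairs)
        return hobohm_forward_reduce(part, counts)

    binder_result = _reduce(binders)
    nonbinder_result = _reduce(nonbinders)
    kept = set(binder_result.kept) | set(nonbinder_result.kept)
    sr = dataset.subset(kept, provenance=f"{dataset.provenance}:SR")
    return DatasetReduction(binder_result=binder_result, nonbinder_result=nonbinder_result, sr=sr)


def singular_peptides(dataset: AffinityDataset) -> list[str]:
    """Peptides with no similar partner anywhere in the full (ALL) set."""
    seqs = dataset.sequences
    if not seqs:
        return []
    counts = count_similar(seqs)
    return [s for s, c in zip(seqs, counts.counts) if c == 0]


def singular_dataset(dataset: AffinityDataset) -> AffinityDataset:
    """The SP subset of a dataset, original order preserved."""
    return dataset.subset(singular_peptides(dataset), provenance=f"{dataset.provenance}:SP")
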