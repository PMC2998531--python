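"""Synthetic ground-truth worlds for end-to-end testing of the pipeline.

A synthetic world fixes a ground-truth 9 x 20 scoring matrix for a
pretend class II molecule: anchor positions get a wide lognormal spread
of residue preferences (log10 SD = ``strength``), non-anchor positions
are near-flat, and every position is scaled so its best residue has
value 1.  Peptide affinities are generated from the matrix the same way
the predictors read it — IC50 proportional to the best-core product —
times multiplicative lognormal measurement noise, then scaled so a
target fraction of peptides falls under the 1000 nM binder cutoff and
clamped to a typical assay range.

Datasets mix four peptide sources that emulate how real binding data
are collected, and hence carry realistic homolog structure:

* independent random peptides (no similarity),
* 15-mer tiles of a synthetic protein overlapping by 10 residues
  (epitope-mapping scans; consecutive tiles share a 9-mer),
* single-residue substitution scans of a reference peptide
  (motif-mapping; each scan forms one similarity clique),
* 1-2-substitution variants of a base peptide (cross-reactivity
  panels).

Matched library panels are generated from the same truth matrix, so
matrix derivation can be checked as parameter recovery.  Everything is
reproducible from the world's master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .comblib import window_scores
from .data_model import (
    ALPHABET,
    N_POSITIONS,
    N_RESIDUES,
    AffinityDataset,
    AffinityRecord,
    LibraryPanel,
    ScoringMatrix,
    ValidationError,
)

#: Sub-stream tags so dataset, panel and matrix draws never collide.
_MATRIX_STREAM, _DATASET_STREAM, _PANEL_STREAM = 3, 7, 11


@dataclass(frozen=True)
class HomologMix:
    """Proportions of the four peptide sources; must sum to 1."""

    random: float = 0.55
    tiles: float = 0.25
    scan: float = 0.10
    variants: float = 0.10

    def __post_init__(self) -> None:
        parts = (self.random, self.tiles, self.scan, self.variants)
        if any(p < 0 for p in parts):
            raise ValidationError("mix proportions must be non-negative")
        if abs(sum(parts) - 1.0) > 1e-9:
            raise ValidationError(f"mix proportions must sum to 1, got {sum(parts)}")


#: Peptides per substitution-scan cluster (reference + 30 single mutants).
SCAN_CLUSTER_SIZE = 31
#: Peptides per variant cluster (base + 4 close variants).
VARIANT_CLUSTER_SIZE = 5
#: 15-mer tiles per synthetic protein (step 5, overlap 10).
TILES_PER_PROTEIN = 10
TILE_STEP = 5


@dataclass
class SyntheticWorld:
    """Ground truth and generation parameters for one synthetic allele."""

    seed: int = 42
    allele: str = "SYN-DRB1*0101"
    anchors: tuple[int, ...] = (1, 4, 6, 9)
    strength: float = 1.0  # log10 SD of anchor-position values
    noise_sigma: float = 0.3  # lognormal measurement noise, log10 units
    peptide_length: int = 15
    length_jitter: bool = False  # draw lengths uniformly from 13-17
    binder_fraction: float = 0.5  # calibration target when ic50_scale is None
    ic50_scale: float | None = None  # fixed nM scale; None = calibrate
    panel_scale: float = 100.0  # nM scale of library-panel measurements
    clamp: tuple[float, float] = (0.1, 50_000.0)
    mix: HomologMix = field(default_factory=HomologMix)

    def __post_init__(self) -> None:
        if not self.anchors or not all(1 <= a <= N_POSITIONS for a in self.anchors):
            raise ValidationError("anchors must be 1-9 core positions (at least one)")
        if self.noise_sigma < 0 or self.strength < 0:
            raise ValidationError("strength and noise_sigma must be >= 0")

    @property
    def truth(self) -> ScoringMatrix:
        if not hasattr(self, "_truth"):
            self._truth = simulate_matrix(
                [self.seed, _MATRIX_STREAM],
                anchors=self.anchors,
                strength=self.strength,
                allele=self.allele,
            )
        return self._truth


def simulate_matrix(
    seed, anchors: Iterable[int] = (1, 4, 6, 9), strength: float = 1.0,
    allele: str = "SYN-DRB1*0101",
) -> ScoringMatrix:
    """Draw a ground-truth matrix: wide spread at anchors, near-flat elsewhere.

    Per position, values are ``10**Normal(0, sd)`` with sd = strength at
    anchor positions and 0.05 * strength elsewhere, then scaled so the
    position minimum is exactly 1.  ``strength = 0`` gives the all-ones
    matrix; the same seed always gives the same matrix.
    """
    anchors = set(anchors)
    if not anchors or not all(1 <= a <= N_POSITIONS for a in anchors):
        raise ValidationError("anchors must be core positions 1-9 (at least one)")
    rng = np.random.default_rng(seed)
    values = np.empty((N_POSITIONS, N_RESIDUES))
    for pos in range(1, N_POSITIONS + 1):
        sd = strength if pos in anchors else 0.05 * strength
        row = 10.0 ** rng.normal(0.0, sd, N_RESIDUES)
        values[pos - 1] = row / row.min()
    return ScoringMatrix(allele=allele, values=values, source="synthetic-truth")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, N_RESIDUES, length))


def _peptide_length(world: SyntheticWorld, rng: np.random.Generator) -> int:
    if world.length_jitter:
        return int(rng.integers(13, 18))
    return world.peptide_length


def _category_counts(n: int, mix: HomologMix) -> dict[str, int]:
    props = {"random": mix.random, "tiles": mix.tiles, "scan": mix.scan, "variants": mix.variants}
    counts = {k: int(np.floor(p * n)) for k, p in props.items()}
    # largest-remainder apportionment of the leftover slots
    remainders = sorted(
        props, key=lambda k: (props[k] * n - counts[k], k), reverse=True
    )
    for k in remainders[: n - sum(counts.values())]:
        counts[k] += 1
    return counts


def _substitute(rng: np.random.Generator, peptide: str, n_subs: int) -> str:
    positions = rng.choice(len(peptide), size=n_subs, replace=False)
    chars = list(peptide)
    for pos in positions:
        choices = [a for a in ALPHABET if a != chars[pos]]
        chars[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def simulate_dataset(
    world: SyntheticWorld, n: int = 1000, mix: HomologMix | None = None
) -> AffinityDataset:
    """Generate a per-allele affinity dataset with controlled homolog structure.

    IC50 = scale x (best-core product under the truth matrix) x
    lognormal noise, clamped to the world's assay range; binder labels
    follow from the 1000 nM cutoff.  Unless ``ic50_scale`` is fixed,
    the scale is calibrated so the target ``binder_fraction`` of
    peptides sits below 1000 nM.
    """
    if n < 20:
        raise ValidationError(f"need n >= 20, got {n}")
    mix = mix or world.mix
    rng = np.random.default_rng([world.seed, _DATASET_STREAM])
    counts = _category_counts(n, mix)
    seen: set[str] = set()
    peptides: list[str] = []

    def _add_unique(candidate_factory, count: int) -> None:
        added = 0
        attempts = 0
        while added < count:
            attempts += 1
            if attempts > 100 * count + 1000:
                raise ValidationError("could not generate enough unique peptides")
            pep = candidate_factory()
            if pep in seen:
                continue
            seen.add(pep)
            peptides.append(pep)
            added += 1

    # independent random peptides
    _add_unique(lambda: _random_peptide(rng, _peptide_length(world, rng)), counts["random"])

    # overlapping 15-mer tiles of synthetic proteins (step 5, overlap 10)
    remaining = counts["tiles"]
    while remaining > 0:
        n_tiles = min(TILES_PER_PROTEIN, remaining)
        protein = _random_peptide(rng, 15 + TILE_STEP * (n_tiles - 1))
        tiles = [protein[s : s + 15] for s in range(0, TILE_STEP * n_tiles, TILE_STEP)]
        for tile in tiles:
            if tile not in seen:
                seen.add(tile)
                peptides.append(tile)
                remaining -= 1

    # single-substitution scans of reference peptides (cliques of 31)
    remaining = counts["scan"]
    while remaining > 0:
        cluster = min(SCAN_CLUSTER_SIZE, remaining)
        reference = _random_peptide(rng, world.peptide_length)
        if reference in seen:
            continue
        seen.add(reference)
        peptides.append(reference)
        remaining -= 1
        produced = 1
        while produced < cluster:
            pep = _substitute(rng, reference, 1)
            if pep in seen:
                continue
            seen.add(pep)
            peptides.append(pep)
            produced += 1
            remaining -= 1

    # 1-2-substitution variant clusters (cross-reactivity panels)
    remaining = counts["variants"]
    while remaining > 0:
        cluster = min(VARIANT_CLUSTER_SIZE, remaining)
        base = _random_peptide(rng, world.peptide_length)
        if base in seen:
            continue
        seen.add(base)
        peptides.append(base)
        remaining -= 1
        produced = 1
        while produced < cluster:
            pep = _substitute(rng, base, int(rng.integers(1, 3)))
            if pep in seen:
                continue
            seen.add(pep)
            peptides.append(pep)
            produced += 1
            remaining -= 1

    truth = world.truth
    products = np.array([window_scores(truth, pep).min() for pep in peptides])
    noise = 10.0 ** rng.normal(0.0, world.noise_sigma, len(peptides))
    raw = products * noise
    if world.ic50_scale is not None:
        scale = world.ic50_scale
    else:
        scale = 1000.0 / float(np.quantile(raw, world.binder_fraction))
    ic50 = np.clip(scale * raw, world.clamp[0], world.clamp[1])
    records = [
        AffinityRecord(allele=world.allele, sequence=pep, ic50=float(x))
        for pep, x in zip(peptides, ic50)
    ]
    return AffinityDataset.from_records(world.allele, records, provenance="synthetic")


def simulate_library_panel(world: SyntheticWorld, noise_sigma: float | None = None) -> LibraryPanel:
    """Generate the 180-mixture panel implied by the world's truth matrix.

    Mixture IC50 for (position, residue) = panel scale x truth value x
    lognormal noise.  With zero noise, matrix derivation from this
    panel reproduces the truth matrix's per-position rank order.
    """
    sigma = world.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng([world.seed, _PANEL_STREAM])
    noise = 10.0 ** rng.normal(0.0, sigma, (N_POSITIONS, N_RESIDUES))
    ic50 = world.panel_scale * world.truth.values * noise
    return LibraryPanel(allele=world.allele, ic50=ic50)
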