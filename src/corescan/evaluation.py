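"""Cross-validated benchmarking: ROC/AUC, Spearman rho, and homolog impact.

Methods trained on binding data are evaluated by 5-fold cross
validation (each peptide predicted blindly by a model trained on the
other folds, with the same fold assignment reusable across methods);
fixed methods that need no training — library-derived matrices,
published motif matrices — are evaluated by direct prediction over the
entire dataset.

Classification performance is the area under the ROC curve at the
1000 nM binder cutoff: the curve sweeps the score threshold from best
to worst, plotting true-positive rate against false-positive rate, and
equal scores are grouped into a single sweep step, making the
trapezoidal area equal to the Mann-Whitney U statistic with half
credit for ties.  0.5 is random, 1.0 perfect.  Rank agreement with the
measured IC50s is reported alongside as Spearman's rho.

The homolog-impact analysis asks whether training with homologous
peptides hurts prediction of unrelated ones: it cross-validates on the
full (ALL) and similarity-reduced (SR) datasets with shared seeds,
extracts the blinded predictions of the singular peptides (SP, no
similar partner anywhere), and compares the two AUCs per allele with a
paired two-tailed t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import Predictor
from .data_model import AffinityDataset, PredictionRecord, ValidationError
from .similarity import similarity_reduce_dataset, singular_peptides

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Folds and cross validation
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """A k-fold partition of a dataset's peptides, reusable across methods."""

    k: int
    assignment: dict[str, int]  # peptide sequence -> fold index 0..k-1
    seed: int

    def fold_of(self, sequence: str) -> int:
        return self.assignment[sequence]

    def test_sequences(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def make_folds(dataset: AffinityDataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle then round-robin assignment; fold sizes differ by <= 1."""
    n = len(dataset)
    if k < 2 or k > n:
        raise ValidationError(f"k must be between 2 and the dataset size {n}, got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = {dataset.records[idx].sequence: pos % k for pos, idx in enumerate(order)}
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


@dataclass(frozen=True)
class CVPrediction:
    """One blinded cross-validated prediction, tagged with its fold."""

    sequence: str
    ic50: float
    binder: bool
    fold: int
    score: float
    core_offset: int
    method: str


def cross_validate(trainer, dataset: AffinityDataset, folds: FoldAssignment) -> list[CVPrediction]:
    """Predict every peptide once, from a model trained on the other folds.

    ``trainer`` must expose ``fit(dataset) -> predictor`` with the
    predictor satisfying the harness interface.  Output follows the
    dataset order.
    """
    missing = [r.sequence for r in dataset if r.sequence not in folds.assignment]
    if missing:
        raise ValidationError(f"fold assignment does not cover {len(missing)} peptide(s)")
    by_sequence: dict[str, CVPrediction] = {}
    for fold in range(folds.k):
        train_records = [r for r in dataset if folds.fold_of(r.sequence) != fold]
        test_records = [r for r in dataset if folds.fold_of(r.sequence) == fold]
        if not test_records:
            continue
        train_ds = AffinityDataset(
            allele=dataset.allele, records=train_records, provenance=dataset.provenance
        )
        try:
            predictor = trainer.fit(train_ds)
        except ValidationError as exc:
            raise ValidationError(f"training failed on fold {fold}: {exc}") from exc
        results = predictor.predict_many([r.sequence for r in test_records])
        for rec, res in zip(test_records, results):
            if not isinstance(res, PredictionRecord):
                raise ValidationError(
                    f"fold {fold}: prediction failed for {rec.sequence!r}: {res.message}"
                )
            by_sequence[rec.sequence] = CVPrediction(
                sequence=rec.sequence,
                ic50=rec.ic50,
                binder=rec.binder,
                fold=fold,
                score=res.score,
                core_offset=res.core_offset,
                method=res.method,
            )
    return [by_sequence[r.sequence] for r in dataset]


# ---------------------------------------------------------------------------
# ROC / AUC and Spearman
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    """A threshold-sweep ROC curve with its trapezoidal area."""

    points: np.ndarray  # (n, 2) array of (FPR, TPR), from (0,0) to (1,1)
    auc: float


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "lower-is-better":
        return -scores
    if orientation == "higher-is-better":
        return scores
    raise ValidationError(f"unknown orientation {orientation!r}")


def roc_auc(scores, binder_labels, orientation: str = "lower-is-better") -> ROCCurve:
    """ROC curve and AUC from scores and boolean binder labels.

    The sweep runs from the best to the worst score; tied scores form a
    single step, so the trapezoidal area equals the Mann-Whitney U
    statistic with 0.5 credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binder_labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and the same length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC is undefined for single-class label sets")
    x = _oriented(scores, orientation)
    order = np.argsort(-x, kind="stable")  # best first
    x_sorted = x[order]
    labels_sorted = labels[order]
    # group ties: indices where a new distinct score value starts
    boundaries = np.nonzero(np.diff(x_sorted))[0] + 1
    group_ends = np.append(boundaries, x_sorted.size)
    tp = np.cumsum(labels_sorted)[group_ends - 1]
    fp = group_ends - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=np.column_stack([fpr, tpr]), auc=auc)


def spearman_rho(predicted_scores, measured_ic50s, orientation: str = "lower-is-better") -> float:
    """Spearman rank correlation between predictions and measured IC50s.

    The orientation flag aligns the sign so a better predictor gives a
    rho closer to +1 (IC50s themselves are lower-is-stronger).
    Average ranks are used on ties.
    """
    pred = np.asarray(predicted_scores, dtype=float)
    meas = np.asarray(measured_ic50s, dtype=float)
    if pred.size != meas.size or pred.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.unique(pred).size < 2 or np.unique(meas).size < 2:
        raise ValidationError("Spearman rho is undefined for constant vectors")
    aligned = -_oriented(pred, orientation)  # lower-is-better scale, like IC50
    rho = stats.spearmanr(aligned, meas).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Report rows
# ---------------------------------------------------------------------------


@dataclass
class EvalRow:
    """Per-allele, per-method performance entry."""

    allele: str
    method: str
    variant: str  # ALL | SR | SP
    n: int
    auc: float
    rho: float


def evaluate_predictions(
    scores, labels, ic50s, *, allele: str, method: str, variant: str = "ALL"
) -> EvalRow:
    curve = roc_auc(scores, labels)
    try:
        rho = spearman_rho(scores, ic50s)
    except ValidationError as exc:
        # constant predictions still have a (tie-handled) AUC; rho is blank
        logger.warning("allele %s method %s: %s; reporting rho as blank", allele, method, exc)
        rho = float("nan")
    return EvalRow(allele=allele, method=method, variant=variant,
                   n=len(np.asarray(scores)), auc=curve.auc, rho=rho)


def evaluate_fixed_method(
    predictor: Predictor, dataset: AffinityDataset, variant: str = "ALL"
) -> EvalRow:
    """Direct whole-dataset evaluation for methods that need no training."""
    results = predictor.predict_many(dataset.sequences)
    scores = []
    for res in results:
        if not isinstance(res, PredictionRecord):
            raise ValidationError(f"prediction failed for {res.sequence!r}: {res.message}")
        scores.append(res.score)
    return evaluate_predictions(
        scores, dataset.labels, dataset.ic50s,
        allele=dataset.allele, method=predictor.method, variant=variant,
    )


def evaluate_cv(
    trainer, dataset: AffinityDataset, folds: FoldAssignment, variant: str = "ALL"
) -> EvalRow:
    """Cross-validated evaluation for trainable methods."""
    preds = cross_validate(trainer, dataset, folds)
    scores = np.array([p.score for p in preds])
    return evaluate_predictions(
        scores, dataset.labels, dataset.ic50s,
        allele=dataset.allele, method=preds[0].method if preds else trainer.method,
        variant=variant,
    )


def unavailable_row(allele: str, method: str, variant: str = "ALL") -> EvalRow:
    """Report entry for a method not available for an allele (blank, not zero)."""
    return EvalRow(allele=allele, method=method, variant=variant,
                   n=0, auc=float("nan"), rho=float("nan"))


def summarize_report(rows: list[EvalRow]) -> pd.DataFrame:
    """Tabulate rows and append Average/Min/Max summary lines (3 decimals)."""
    df = pd.DataFrame(
        [
            {"allele": r.allele, "method": r.method, "variant": r.variant,
             "n": r.n, "auc": r.auc, "rho": r.rho}
            for r in rows
        ]
    )
    if df.empty:
        return df
    summary = pd.DataFrame(
        {
            "allele": ["Average", "Min", "Max"],
            "method": ["", "", ""],
            "variant": ["", "", ""],
            "n": [df["n"].sum(), df["n"].min(), df["n"].max()],
            "auc": [df["auc"].mean(), df["auc"].min(), df["auc"].max()],
            "rho": [df["rho"].mean(), df["rho"].min(), df["rho"].max()],
        }
    )
    out = pd.concat([df, summary], ignore_index=True)
    out["auc"] = out["auc"].round(3)
    out["rho"] = out["rho"].round(3)
    return out


# ---------------------------------------------------------------------------
# Homolog impact on singular peptides
# ---------------------------------------------------------------------------


@dataclass
class SPImpactResult:
    """Per-allele comparison of SR-trained vs ALL-trained predictions on SP.

    ``table`` columns follow the report layout: AUC with homolog-free
    training (auc_sr), AUC with full training (auc_all), their
    difference auc_all - auc_sr (auc_reduction), the peptide-count
    reduction from ALL down to the singular set and its fraction of
    ALL.  ``p_value`` is the paired two-tailed t-test over alleles on
    the AUC differences (NaN when fewer than two alleles).
    """

    table: pd.DataFrame
    p_value: float
    skipped: list[str] = field(default_factory=list)


def sp_impact_analysis(
    trainer, datasets: dict[str, AffinityDataset] | AffinityDataset,
    k: int = 5, seed: int = 0, scope: str = "partition",
) -> SPImpactResult:
    """Does training with homologs hurt prediction of unrelated peptides?

    For each allele: cross-validate on ALL and on SR with shared seeds,
    extract the blinded predictions of the SP peptides from each run,
    and compare their AUCs.  Alleles whose SP set is single-class are
    skipped with a warning.
    """
    if isinstance(datasets, AffinityDataset):
        datasets = {datasets.allele: datasets}
    rows = []
    skipped: list[str] = []
    for allele, all_ds in datasets.items():
        sp_seqs = singular_peptides(all_ds)
        sp_ds = all_ds.subset(sp_seqs)
        labels = sp_ds.labels
        if len(sp_ds) == 0 or labels.all() or not labels.any():
            logger.warning("allele %s: SP set is empty or single-class, skipped", allele)
            skipped.append(allele)
            continue
        reduction = similarity_reduce_dataset(all_ds, scope=scope)
        sr_ds = reduction.sr

        def _sp_auc(ds: AffinityDataset) -> float:
            folds = make_folds(ds, k=k, seed=seed)
            preds = {p.sequence: p for p in cross_validate(trainer, ds, folds)}
            scores = np.array([preds[s].score for s in sp_ds.sequences])
            return roc_auc(scores, labels).auc

        auc_all = _sp_auc(all_ds)
        auc_sr = _sp_auc(sr_ds)
        n_all, n_sr, n_sp = len(all_ds), len(sr_ds), len(sp_ds)
        rows.append(
            {
                "allele": allele,
                "auc_sr": auc_sr,
                "auc_all": auc_all,
                "auc_reduction": auc_all - auc_sr,
                "n_all": n_all,
                "n_sr": n_sr,
                "n_sp": n_sp,
                "peptide_reduction": n_all - n_sp,
                "pct_peptide_reduction": (n_all - n_sp) / n_all,
            }
        )
    table = pd.DataFrame(rows)
    if len(rows) >= 2:
        p_value = float(stats.ttest_rel(table["auc_all"], table["auc_sr"]).pvalue)
    else:
        p_value = float("nan")
    return SPImpactResult(table=table, p_value=p_value, skipped=skipped)
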