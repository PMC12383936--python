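"""Leave-one-out ablation statistics.

The decision procedure that distils an augmentation pipeline works on
per-fold AUCs from patient-grouped cross-validation:

1. for the full pipeline and every single-omission ablation, per-fold AUC of
   a linear classifier on pluggable image features;
2. a Friedman omnibus test (significance level ``alpha``) across conditions,
   per task;
3. if significant, post-hoc Wilcoxon signed-rank tests of each ablation
   against the baseline, with step-down Holm-Bonferroni control of the
   family-wise error rate;
4. transforms whose omission significantly *lowered* performance on at least
   one task are deemed contributory and compose the distilled pipeline.

Friedman and Wilcoxon are implemented from their rank definitions (with
average-rank tie handling and, for Wilcoxon, exact two-sided enumeration for
up to 12 nonzero differences); ``scipy.stats`` offers the same tests and is
used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import inspect
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ParameterError
from .image import UltrasoundImage
from .phantom import PhantomDataset
from .pipeline import AugmentationPipeline, TransformSpec, ablate, apply_pipeline

logger = logging.getLogger(__name__)

#: exact Wilcoxon enumeration is used up to this many nonzero differences
EXACT_WILCOXON_MAX = 12

#: canonical ordering of a distilled pipeline: ultrasound intensity ops,
#: then standard intensity/jitter ops, then geometric ops, with
#: crop-and-resize last — the convention realised by [B03, A02, B11, A00]
DISTILLED_ORDER = (
    "B02", "B03", "B04", "B05", "B07", "B08", "B09",
    "A02", "A03", "A04", "A05",
    "B00", "B01", "B06", "B10", "B11", "A01",
    "A00",
)


# --------------------------------------------------------------------------
# Splitters
# --------------------------------------------------------------------------

def grouped_kfold(
    patient_ids: Sequence[str], k: int, rng: int | np.random.Generator
) -> list[np.ndarray]:
    """Partition image indices into ``k`` folds with patient-disjoint folds.

    Patients are shuffled under the seed and dealt round-robin, so fold
    patient-counts differ by at most one.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    if patients.size < k:
        raise ParameterError(f"{patients.size} patients but k={k} folds requested")
    order = rng.permutation(patients)
    folds = []
    for i in range(k):
        fold_patients = order[i::k]
        folds.append(np.flatnonzero(np.isin(patient_ids, fold_patients)))
    return folds


def grouped_subsets(
    patient_ids: Sequence[str],
    fraction: float,
    n_subsets: int,
    rng: int | np.random.Generator,
) -> list[np.ndarray]:
    """Pairwise patient-disjoint subsets, each holding ~``fraction`` of patients."""
    if n_subsets * fraction > 1.0 + 1e-9:
        raise ParameterError("n_subsets * fraction must be <= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    target = fraction * patients.size
    boundaries = [int(round(i * target)) for i in range(n_subsets + 1)]
    if any(b1 - b0 < 1 for b0, b1 in zip(boundaries, boundaries[1:])):
        raise ParameterError("fraction too small: a subset would be empty")
    order = rng.permutation(patients)
    return [
        np.flatnonzero(np.isin(patient_ids, order[b0:b1]))
        for b0, b1 in zip(boundaries, boundaries[1:])
    ]


# --------------------------------------------------------------------------
# Metrics and tests
# --------------------------------------------------------------------------

def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve: the probability that a random positive
    outranks a random negative, ties counted half."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ParameterError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def friedman_test(score_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman's chi-square test across the columns of an (n blocks x k
    conditions) matrix, with average-rank ties and the standard tie
    correction.  Returns ``(statistic, p)``; a fully tied matrix yields
    ``(0.0, 1.0)``."""
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ParameterError("need an (n >= 2) x (k >= 2) score matrix")
    n, k = x.shape
    ranks = np.vstack([rankdata(row) for row in x])
    rbar = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * float(np.sum((rbar - (k + 1) / 2.0) ** 2))

    # tie correction: chi2 / (1 - sum(t^3 - t) / (n k (k^2 - 1)))
    tie_sum = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if denom <= 0.0:
        return 0.0, 1.0
    stat /= denom
    return stat, float(chi2.sf(stat, k - 1))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; absolute differences are ranked with
    average-rank ties; the statistic is ``W = min(W+, W-)``.  The p-value is
    exact (enumeration of all sign assignments) for up to
    ``EXACT_WILCOXON_MAX`` nonzero differences and a tie-corrected normal
    approximation with continuity correction beyond that.

    Returns ``(W, p, degenerate)`` where ``degenerate`` marks an all-zero
    difference vector (then ``p = 1``).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size == 0:
        raise ParameterError("empty paired sample")
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0, True
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w = min(w_plus, total - w_plus)
    m = d.size
    if m <= EXACT_WILCOXON_MAX:
        signs = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
        w_plus_all = signs @ ranks
        w_all = np.minimum(w_plus_all, total - w_plus_all)
        p = float(np.mean(w_all <= w + 1e-12))
    else:
        mu = total / 2.0
        sigma = math.sqrt(float(np.sum(ranks**2)) / 4.0)
        z = (w_plus - mu - math.copysign(0.5, w_plus - mu)) / sigma
        p = min(2.0 * float(norm.sf(abs(z))), 1.0)
    return w, p, False


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Step-down Holm-Bonferroni decisions, reported in original order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject.tolist()


# --------------------------------------------------------------------------
# Feature extraction
# --------------------------------------------------------------------------

def default_embed_fn(image: UltrasoundImage) -> np.ndarray:
    """Handcrafted features: 8 row-band means, 8 column-band means, an 8-bin
    in-FOV intensity histogram, and global mean/std (26 dims).

    Row-band means act as a coarse radial intensity profile, which separates
    bright-ray (B-line) from reverberation (A-line) phantoms and detects
    anechoic effusion regions.
    """
    px = image.pixels
    inside = image.mask.astype(bool)
    feats: list[float] = []
    for bands, axis in ((np.array_split(px, 8, axis=0), 1), (np.array_split(px, 8, axis=1), 0)):
        for band in bands:
            feats.append(float(band.mean()))
    vals = px[inside] if inside.any() else px.ravel()
    hist, _ = np.histogram(vals, bins=8, range=(0.0, 1.0))
    feats.extend((hist / max(vals.size, 1)).tolist())
    feats.append(float(vals.mean()))
    feats.append(float(vals.std()))
    # bright-structure cues robust to cropping: bright-pixel fractions and
    # the strongest column response (B-line rays light whole columns)
    for thr in (0.6, 0.75, 0.9):
        feats.append(float((vals > thr).mean()))
    col_means = np.where(
        image.mask.sum(axis=0) > 0,
        px.sum(axis=0) / np.maximum(image.mask.sum(axis=0), 1),
        0.0,
    )
    feats.append(float(col_means.max()))
    feats.append(float(np.sort(col_means)[-max(px.shape[1] // 8, 1):].mean()))
    return np.asarray(feats, dtype=float)


def _call_embed(embed_fn: Callable, image: UltrasoundImage, condition: str) -> np.ndarray:
    try:
        n_pos = len(
            [
                p
                for p in inspect.signature(embed_fn).parameters.values()
                if p.kind
                in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
                and p.default is p.empty
            ]
        )
    except (TypeError, ValueError):
        n_pos = 1
    if n_pos >= 2:
        return np.asarray(embed_fn(image, condition), dtype=float)
    return np.asarray(embed_fn(image), dtype=float)


# --------------------------------------------------------------------------
# Leave-one-out harness
# --------------------------------------------------------------------------

DEFAULT_TASKS = {"AB": ("B", "A"), "PE": ("effusion", "normal")}


@dataclass
class AblationReport:
    """Results of one leave-one-out analysis."""

    pipeline_name: str
    conditions: list[str]
    fold_scores: dict[str, dict[str, list[float]]]  # task -> condition -> scores
    summary: pd.DataFrame  # task, condition, mean, std, median
    friedman: dict[str, tuple[float, float]]  # task -> (stat, p)
    wilcoxon_p: dict[str, dict[str, float]]  # task -> condition -> p
    decisions: dict[str, dict[str, str]]  # task -> condition -> lower/higher/no-difference
    contributory_set: list[str]
    distilled: Optional[AugmentationPipeline]
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "pipeline": self.pipeline_name,
            "alpha": self.alpha,
            "seed": self.seed,
            "conditions": self.conditions,
            "fold_scores": self.fold_scores,
            "summary": self.summary.to_dict(orient="records"),
            "friedman": {t: {"statistic": s, "p": p} for t, (s, p) in self.friedman.items()},
            "wilcoxon_p": self.wilcoxon_p,
            "decisions": self.decisions,
            "contributory_set": self.contributory_set,
            "distilled": self.distilled.to_dict() if self.distilled else None,
        }

    def to_markdown(self) -> str:
        """A per-condition summary table with significance annotations
        (dagger: significantly lower than baseline; section sign: higher)."""
        lines = [
            f"### Leave-one-out ablation of `{self.pipeline_name}`",
            "",
            "| Omitted | " + " | ".join(
                f"{t} mean (std) | {t} median" for t in self.fold_scores
            ) + " |",
            "|" + "---|" * (1 + 2 * len(self.fold_scores)),
        ]
        for cond in self.conditions:
            cells = [cond]
            for task in self.fold_scores:
                s = np.asarray(self.fold_scores[task][cond])
                mark = {"lower": " †", "higher": " §"}.get(
                    self.decisions.get(task, {}).get(cond, ""), ""
                )
                cells.append(f"{s.mean():.3f} ({s.std():.3f})")
                cells.append(f"{np.median(s):.3f}{mark}")
            lines.append("| " + " | ".join(cells) + " |")
        for task, (stat, p) in self.friedman.items():
            lines.append("")
            lines.append(f"Friedman ({task}): chi2 = {stat:.3f}, p = {p:.4g}")
        lines.append("")
        lines.append(f"Contributory set: {self.contributory_set or 'none'}")
        return "\n".join(lines)


def _builtin_probability(transform_id: str) -> float:
    """Application probability of a transform in its source pipeline."""
    from .pipeline import builtin_pipeline

    for name in ("standard_aug", "aug_us_o"):
        pipe = builtin_pipeline(name)
        if transform_id in pipe.ids:
            return pipe.spec(transform_id).probability
    raise ParameterError(f"no source pipeline for transform {transform_id!r}")


def build_distilled(
    contributory: Sequence[str], out_size: tuple[int, int] = (128, 128)
) -> Optional[AugmentationPipeline]:
    """Compose a distilled pipeline from contributory ids in canonical order."""
    if not contributory:
        return None
    ordered = [tid for tid in DISTILLED_ORDER if tid in set(contributory)]
    specs = [
        TransformSpec(id=tid, probability=_builtin_probability(tid)) for tid in ordered
    ]
    return AugmentationPipeline(name="distilled", specs=specs, out_size=out_size)


def run_leave_one_out(
    pipeline: AugmentationPipeline,
    dataset: PhantomDataset,
    embed_fn: Optional[Callable] = None,
    tasks: Optional[dict[str, tuple[str, str]]] = None,
    k: int = 10,
    alpha: float = 0.05,
    rng: int = 0,
) -> AblationReport:
    """Leave-one-out analysis of a pipeline on a labelled dataset.

    For every condition (the full pipeline plus each single-omission
    ablation), each image is augmented once with the condition's pipeline
    under paired sub-seeded draws, embedded with ``embed_fn`` (default:
    handcrafted intensity-profile features), and per-fold AUCs of a logistic
    classifier are computed over patient-grouped folds.  The Friedman /
    Wilcoxon / Holm cascade then flags transforms whose omission
    significantly lowered AUC on at least one task; those compose the
    distilled pipeline.

    ``embed_fn`` may accept ``(image)`` or ``(image, condition_name)``; the
    two-argument form lets harness tests model encoders whose quality depends
    on the pretraining condition.
    """
    if embed_fn is None:
        embed_fn = default_embed_fn
    if tasks is None:
        tasks = {
            name: pair
            for name, pair in DEFAULT_TASKS.items()
            if set(pair) <= set(dataset.manifest["label"].unique())
        }
    if not tasks:
        raise ParameterError("no applicable task for this dataset's labels")
    seed = int(rng)

    conditions = ["baseline"] + [f"minus-{tid}" for tid in pipeline.ids]
    pipelines = {"baseline": pipeline}
    for tid in pipeline.ids:
        pipelines[f"minus-{tid}"] = ablate(pipeline, tid)

    labels = np.asarray([img.class_label for img in dataset.images])
    patients = np.asarray([img.patient_id for img in dataset.images])

    fold_scores: dict[str, dict[str, list[float]]] = {}
    for task, (pos, neg) in tasks.items():
        sel = np.flatnonzero(np.isin(labels, [pos, neg]))
        y = (labels[sel] == pos).astype(int)
        task_patients = patients[sel]
        if np.unique(task_patients).size < k:
            raise ParameterError(
                f"task {task!r} has fewer than k={k} patients with applicable labels"
            )
        folds = grouped_kfold(task_patients, k, np.random.default_rng(seed))

        # features per condition, paired augmentation draws across conditions
        feats: dict[str, np.ndarray] = {}
        for cond in conditions:
            rows = []
            for local_idx, img_idx in enumerate(sel):
                view, _ = apply_pipeline(
                    dataset.images[img_idx],
                    pipelines[cond],
                    seed,
                    image_index=int(img_idx),
                )
                rows.append(_call_embed(embed_fn, view, cond))
            feats[cond] = np.vstack(rows)

        scores: dict[str, list[float]] = {c: [] for c in conditions}
        for f_idx, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(sel.size), test_idx)
            if np.unique(y[test_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
                logger.warning(
                    "task %s: fold %d skipped (single-class); k reduced", task, f_idx
                )
                continue
            for cond in conditions:
                clf = make_pipeline(
                    StandardScaler(), LogisticRegression(max_iter=500)
                )
                clf.fit(feats[cond][train_idx], y[train_idx])
                prob = clf.predict_proba(feats[cond][test_idx])[:, 1]
                scores[cond].append(auroc(prob, y[test_idx]))
        fold_scores[task] = scores

    # ---------------------------------------------------------- statistics
    friedman: dict[str, tuple[float, float]] = {}
    wilcoxon_p: dict[str, dict[str, float]] = {}
    decisions: dict[str, dict[str, str]] = {}
    records = []
    for task, scores in fold_scores.items():
        matrix = np.column_stack([scores[c] for c in conditions])
        friedman[task] = friedman_test(matrix)
        for cond in conditions:
            s = np.asarray(scores[cond])
            records.append(
                {
                    "task": task,
                    "condition": cond,
                    "mean": s.mean(),
                    "std": s.std(ddof=1),
                    "median": float(np.median(s)),
                }
            )
        wilcoxon_p[task] = {}
        decisions[task] = {}
        if friedman[task][1] < alpha:
            ablated = conditions[1:]
            pvals = []
            for cond in ablated:
                _, p, _ = wilcoxon_signed_rank(scores[cond], scores["baseline"])
                wilcoxon_p[task][cond] = p
                pvals.append(p)
            rejects = holm_bonferroni(pvals, alpha)
            base_med = np.median(scores["baseline"])
            for cond, rej in zip(ablated, rejects):
                if not rej:
                    decisions[task][cond] = "no-difference"
                elif np.median(scores[cond]) < base_med:
                    decisions[task][cond] = "lower"
                else:
                    decisions[task][cond] = "higher"

    contributory = [
        tid
        for tid in pipeline.ids
        if any(decisions[t].get(f"minus-{tid}") == "lower" for t in fold_scores)
    ]
    distilled = build_distilled(contributory, out_size=pipeline.out_size)

    return AblationReport(
        pipeline_name=pipeline.name,
        conditions=conditions,
        fold_scores=fold_scores,
        summary=pd.DataFrame(records),
        friedman=friedman,
        wilcoxon_p=wilcoxon_p,
        decisions=decisions,
        contributory_set=contributory,
        distilled=distilled,
        alpha=alpha,
        seed=seed,
    )
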