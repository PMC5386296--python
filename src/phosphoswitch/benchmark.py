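"""Benchmark construction and evaluation.

Positives are phosphosites with a known enabling/disabling effect on an
interaction; negatives are drawn by shuffling each positive to random
S/T/Y positions of the same protein (ten per positive by default),
carrying along interactor and effect and preserving the surface-exposure
class of the site. Predictors are evaluated with ROC/PR curves, the
threshold giving a false positive rate <= 0.05, two-sided Fisher's exact
tests, and a balanced, repeated cross-validated logistic regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

S1_COLUMNS = [
    "set", "protein", "site", "site+-7AA", "interactor", "effect",
    "template", "pdbres", "IE", "f_ID", "f_Cons", "S_switch", "ddG", "kinase",
]


@dataclass
class BenchmarkEntry:
    """One labelled site-interactor pair of the benchmark."""

    set: str
    protein: str
    site: str
    interactor: str
    effect: str
    template: str = ""
    pdbres: str = ""
    site_flank: str = ""
    ie: float = math.nan
    f_id: float = math.nan
    f_cons: float = math.nan
    s_switch: float = math.nan
    ddg: Optional[float] = None
    is_kinase: bool = False

    def __post_init__(self) -> None:
        if self.set not in ("positive", "negative"):
            raise ValueError(f"set must be 'positive' or 'negative', got {self.set!r}")

    @property
    def is_positive(self) -> bool:
        return self.set == "positive"

    def feature(self, name: str) -> float:
        return {
            "IE": self.ie, "f_ID": self.f_id, "f_Cons": self.f_cons,
            "S_switch": self.s_switch,
            "ddG": math.nan if self.ddg is None else self.ddg,
        }[name]


@dataclass
class RocSummary:
    """Confusion statistics at one threshold of a score."""

    auc: float
    threshold: float
    fpr: float
    tpr: float
    tnr: float
    accuracy: float
    ppv: float
    p_value: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass
class RocCurve:
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def load_benchmark_table(path: str | Path) -> list[BenchmarkEntry]:
    """Parse a benchmark TSV with the standard column layout."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("set", "protein", "site", "interactor", "effect") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")

    def num(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v in ("", "NA", "N/A"):
            return math.nan
        return float(v)

    entries = []
    for _, row in frame.iterrows():
        effect = row.get("effect", "unknown")
        if not isinstance(effect, str) or not effect:
            effect = "unknown"
        if effect not in ("enabling", "disabling") and effect != "unknown":
            logger.info("entry %s/%s has non-standard effect %r; kept, flagged unknown-direction",
                        row["protein"], row["site"], effect)
        kinase_raw = str(row.get("kinase", "0")).strip().lower()
        ddg = num(row, "ddG")
        entries.append(
            BenchmarkEntry(
                set=str(row["set"]),
                protein=str(row["protein"]),
                site=str(row["site"]),
                site_flank=str(row.get("site+-7AA", "") or ""),
                interactor=str(row["interactor"]),
                effect=effect,
                template=str(row.get("template", "") or ""),
                pdbres=str(row.get("pdbres", "") or ""),
                ie=num(row, "IE"),
                f_id=num(row, "f_ID"),
                f_cons=num(row, "f_Cons"),
                s_switch=num(row, "S_switch"),
                ddg=None if math.isnan(ddg) else ddg,
                is_kinase=kinase_raw in ("1", "true", "yes", "y"),
            )
        )
    return entries


def entries_to_frame(entries: Sequence[BenchmarkEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append({
            "set": e.set, "protein": e.protein, "site": e.site,
            "site+-7AA": e.site_flank, "interactor": e.interactor,
            "effect": e.effect, "template": e.template, "pdbres": e.pdbres,
            "IE": e.ie, "f_ID": e.f_id, "f_Cons": e.f_cons,
            "S_switch": e.s_switch,
            "ddG": "" if e.ddg is None else e.ddg,
            "kinase": int(e.is_kinase),
        })
    return pd.DataFrame(rows, columns=S1_COLUMNS)


def build_negative_set(
    positives: Sequence[BenchmarkEntry],
    protein_sequences: Mapping[str, str],
    exposure_annotations: Mapping[tuple[str, int], str],
    n_shuffles: int = 10,
    seed: int = 0,
) -> list[BenchmarkEntry]:
    """Shuffled negatives: random same-protein S/T/Y positions per positive.

    Candidate positions share the positive's exposure class
    (buried/exposed); when none do, any S/T/Y of the protein is used (and
    logged); a protein with no alternative S/T/Y skips its positive with a
    warning. Sampling is without replacement and deterministic under the
    seed.
    """
    rng = np.random.default_rng(seed)
    negatives: list[BenchmarkEntry] = []
    for pos_entry in positives:
        seq = protein_sequences.get(pos_entry.protein)
        if seq is None:
            logger.warning("no sequence for %s; positive skipped", pos_entry.protein)
            continue
        site_pos = int("".join(ch for ch in pos_entry.site if ch.isdigit()))
        sty = [i + 1 for i, aa in enumerate(seq) if aa in "STY" and i + 1 != site_pos]
        if not sty:
            logger.warning("no alternative S/T/Y in %s; positive skipped", pos_entry.protein)
            continue
        own_class = exposure_annotations.get((pos_entry.protein, site_pos))
        matched = [
            p for p in sty
            if exposure_annotations.get((pos_entry.protein, p)) == own_class
        ] if own_class is not None else []
        pool = matched
        if not pool:
            pool = sty
            logger.info(
                "no %s-class S/T/Y available in %s; falling back to any S/T/Y",
                own_class, pos_entry.protein,
            )
        k = min(n_shuffles, len(pool))
        if k < n_shuffles:
            logger.info("%s: only %d eligible positions for %d shuffles",
                        pos_entry.protein, k, n_shuffles)
        chosen = rng.choice(pool, size=k, replace=False)
        for p in sorted(int(x) for x in chosen):
            negatives.append(
                BenchmarkEntry(
                    set="negative",
                    protein=pos_entry.protein,
                    site=f"{seq[p - 1]}{p}",
                    interactor=pos_entry.interactor,
                    effect=pos_entry.effect,
                    template=pos_entry.template,
                    is_kinase=pos_entry.is_kinase,
                )
            )
    return negatives


def roc_pr_curves(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "high_positive",
) -> RocCurve:
    """ROC and PR curves with trapezoidal AUC.

    ``direction='absolute'`` ranks by |score| (a strong effect in either
    direction counts), mirroring the unsigned benchmark variant.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if direction == "absolute":
        scores = np.abs(scores)
    elif direction != "high_positive":
        raise ValueError("direction must be 'high_positive' or 'absolute'")
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both a positive and a negative class")
    fpr, tpr, thr = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return RocCurve(
        scores=scores, labels=labels, fpr=fpr, tpr=tpr, thresholds=thr,
        precision=precision, recall=recall, auc=float(_auc(fpr, tpr)),
    )


def fisher_exact_p(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 confusion table."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn + tn == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")[1])


def _confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def threshold_at_fpr(curve: RocCurve, max_fpr: float = 0.05) -> RocSummary:
    """Smallest observed threshold whose FPR does not exceed ``max_fpr``.

    Candidate thresholds are the observed scores (prediction is
    score >= threshold) plus a sentinel above the maximum (the all-negative
    point, which always satisfies the bound).
    """
    scores, labels = curve.scores, curve.labels
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    candidates = np.concatenate((np.unique(scores), [np.inf]))
    best = None
    for t in candidates:  # ascending; keep the smallest admissible
        tp, fp, fn, tn = _confusion_at(scores, labels, t)
        fpr = fp / n_neg
        if fpr <= max_fpr:
            best = (t, tp, fp, fn, tn, fpr)
            break
    t, tp, fp, fn, tn, fpr = best
    ppv = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    return RocSummary(
        auc=curve.auc,
        threshold=float(t),
        fpr=fpr,
        tpr=tp / n_pos,
        tnr=tn / n_neg,
        accuracy=(tp + tn) / (n_pos + n_neg),
        ppv=ppv,
        p_value=fisher_exact_p(tp, fp, fn, tn),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


@dataclass
class LogisticCvResult:
    feature_names: tuple[str, ...]
    coef_mean: dict[str, float]
    coef_sd: dict[str, float]
    intercept_mean: float
    intercept_sd: float
    summary_mean: dict[str, float]
    summary_sd: dict[str, float]
    final_coef: dict[str, float]
    final_intercept: float
    final_summary: RocSummary
    rep_class_counts: list[tuple[int, int]] = field(default_factory=list)


_SIGNED_FEATURES = frozenset({"IE", "S_switch", "ddG"})


def _entries_xy(
    entries: Sequence[BenchmarkEntry],
    features: Sequence[str],
    orient_by_effect: bool = True,
):
    X = np.array([[e.feature(f) for f in features] for e in entries], dtype=float)
    if orient_by_effect:
        flip = np.array([-1.0 if e.effect == "disabling" else 1.0 for e in entries])
        for k, f in enumerate(features):
            if f in _SIGNED_FEATURES:
                X[:, k] *= flip
    y = np.array([1 if e.is_positive else 0 for e in entries], dtype=int)
    if np.isnan(X).any():
        raise ValueError("missing feature values in benchmark entries")
    return X, y


def logistic_cv(
    entries: Sequence[BenchmarkEntry],
    features: Sequence[str] = ("IE", "f_ID", "f_Cons"),
    folds: int = 5,
    reps: int = 100,
    seed: int = 0,
    max_fpr: float = 0.05,
    orient_by_effect: bool = True,
) -> LogisticCvResult:
    """Balanced, repeated cross-validated logistic regression.

    Each repetition undersamples the negatives to the positive count,
    splits into stratified folds, fits an unregularised logistic model on
    the training folds and pools held-out scores; AUC and the
    threshold-at-FPR statistics are averaged over repetitions. A final
    model is fitted on the full (unbalanced) benchmark. Signed features
    (IE, S_switch, ddG) are oriented by the annotated effect direction so
    that a correct prediction is always high-positive, matching the
    signed-score ROC convention.
    """
    features = tuple(features)
    X, y = _entries_xy(entries, features, orient_by_effect)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) < folds or len(neg_idx) < folds:
        raise ValueError("need at least `folds` positives and negatives")
    n_bal = min(len(pos_idx), len(neg_idx))

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(reps)

    coefs, intercepts = [], []
    summaries: list[dict[str, float]] = []
    rep_counts: list[tuple[int, int]] = []
    for rep in range(reps):
        rng = np.random.default_rng(child_seeds[rep])
        neg_sample = rng.choice(neg_idx, size=n_bal, replace=False)
        pos_sample = pos_idx if len(pos_idx) == n_bal else rng.choice(
            pos_idx, size=n_bal, replace=False
        )
        idx = np.concatenate((pos_sample, neg_sample))
        Xb, yb = X[idx], y[idx]
        rep_counts.append((int(yb.sum()), int(len(yb) - yb.sum())))

        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        held_scores = np.empty(len(yb))
        for train, test in skf.split(Xb, yb):
            model = LogisticRegression(C=np.inf, tol=1e-8, max_iter=5000)
            model.fit(Xb[train], yb[train])
            held_scores[test] = model.decision_function(Xb[test])
            coefs.append(model.coef_[0])
            intercepts.append(model.intercept_[0])
        curve = roc_pr_curves(held_scores, yb)
        summ = threshold_at_fpr(curve, max_fpr)
        summaries.append({
            "auc": curve.auc, "cut": summ.threshold, "fpr": summ.fpr,
            "tpr": summ.tpr, "tnr": summ.tnr, "acc": summ.accuracy,
            "ppv": summ.ppv,
        })

    coefs_arr = np.array(coefs)
    stat_names = summaries[0].keys()
    summary_mean = {k: float(np.nanmean([s[k] for s in summaries])) for k in stat_names}
    summary_sd = {k: float(np.nanstd([s[k] for s in summaries], ddof=1)) for k in stat_names}

    final = LogisticRegression(C=np.inf, tol=1e-8, max_iter=5000)
    final.fit(X, y)
    final_scores = final.decision_function(X)
    final_summary = threshold_at_fpr(roc_pr_curves(final_scores, y), max_fpr)

    return LogisticCvResult(
        feature_names=features,
        coef_mean={f: float(m) for f, m in zip(features, coefs_arr.mean(axis=0))},
        coef_sd={f: float(s) for f, s in zip(features, coefs_arr.std(axis=0, ddof=1))},
        intercept_mean=float(np.mean(intercepts)),
        intercept_sd=float(np.std(intercepts, ddof=1)),
        summary_mean=summary_mean,
        summary_sd=summary_sd,
        final_coef={f: float(c) for f, c in zip(features, final.coef_[0])},
        final_intercept=float(final.intercept_[0]),
        final_summary=final_summary,
        rep_class_counts=rep_counts,
    )


def filter_kinase_interactors(entries: Sequence[BenchmarkEntry]) -> list[BenchmarkEntry]:
    """Entries whose interactor is not a kinase (kinase-bias control)."""
    return [e for e in entries if not e.is_kinase]


def filter_high_identity(
    entries: Sequence[BenchmarkEntry], min_f_id: float = 0.99
) -> list[BenchmarkEntry]:
    """Entries scored on near-identical templates (f_ID >= cutoff)."""
    return [e for e in entries if e.f_id >= min_f_id]


def filter_by_effect(entries: Sequence[BenchmarkEntry], effect: str) -> list[BenchmarkEntry]:
    """Effect-stratified sub-benchmark (enabling-only / disabling-only)."""
    return [e for e in entries if e.effect == effect]


def oriented_scores(entries: Sequence[BenchmarkEntry], feature: str = "S_switch") -> np.ndarray:
    """Effect-signed scores: disabling entries flip sign so that a correct
    prediction is always high-positive."""
    out = []
    for e in entries:
        v = e.feature(feature)
        out.append(-v if e.effect == "disabling" else v)
    return np.asarray(out)


def compare_site_properties(
    values_a: Sequence[float],
    values_b: Sequence[float],
    kind: str = "continuous",
) -> tuple[float, float]:
    """Two-group comparison: rank-sum (continuous) or 2x2 chi-square (binary).

    Binary inputs are 0/1 indicators; the chi-square is computed on the
    2x2 category-count table without continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "binary":
        table = np.array([
            [a.sum(), len(a) - a.sum()],
            [b.sum(), len(b) - b.sum()],
        ])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValueError("kind must be 'continuous' or 'binary'")
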