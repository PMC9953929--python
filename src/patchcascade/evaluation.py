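"""Splitting, matched undersampling, classification metrics, repeated-measures stats.

The evaluation protocol this module implements: subjects are stratified
into train/validation/test sets (70/10/20 by default, class proportions
preserved by largest-remainder apportionment within each class); the test
set is balanced by matched undersampling (each disease-class subject keeps
its nearest control under mean voxelwise absolute intensity difference,
greedily, without replacement); performance is summarized by accuracy,
sensitivity, specificity, F1 and AUC; and accuracy across repeated runs of
several conditions is compared by one-way repeated-measures ANOVA with
Mauchly's sphericity test, Greenhouse–Geisser correction, and Tukey
(studentized-range) post hoc pairwise comparisons on the within-subject
error term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectRecord
from .volume import Volume

__all__ = [
    "SplitConfig",
    "MetricsReport",
    "largest_remainder",
    "stratified_split",
    "undersample_match",
    "compute_metrics",
    "class_weights",
    "rm_anova",
    "tukey_posthoc",
    "RMAnovaResult",
]

POSITIVE = "AD"
NEGATIVE = "CN"


@dataclass(frozen=True)
class SplitConfig:
    """Train/validation/test fractions plus the seed that fixes the draw."""

    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    stratified: bool = True
    strict: bool = True  # strict: every fraction in (0,1); relaxed allows zeros

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.fractions)
        object.__setattr__(self, "fractions", f)
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {f}")
        for x in f:
            if self.strict and not (0.0 < x < 1.0):
                raise ValueError(f"each fraction must be in (0,1), got {f}")
            if not self.strict and not (0.0 <= x <= 1.0):
                raise ValueError(f"fractions must be in [0,1], got {f}")


def largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``n`` items to ``fractions`` by the largest-remainder rule.

    Floors of ``n·f`` first; leftover units go to the largest fractional
    parts, ties broken by position order.
    """
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i)
    )
    for i in remainders[:leftover]:
        base[i] += 1
    return base


def stratified_split(
    records: Sequence[SubjectRecord], config: SplitConfig
) -> list[SubjectRecord]:
    """Assign train/val/test within each class by largest-remainder counts.

    Returns new records (input untouched) in the input order; deterministic
    given the seed; in strict mode every class must populate all three
    splits.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5B117)))
    by_class: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_class.setdefault(rec.label, []).append(idx)
    assignment = ["unassigned"] * len(records)
    split_names = ("train", "val", "test")
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        counts = largest_remainder(len(idxs), config.fractions)
        if config.strict and any(c < 1 for c in counts):
            raise ValueError(
                f"class {label!r} ({len(idxs)} subjects) cannot populate all "
                f"three splits with fractions {config.fractions}"
            )
        perm = rng.permutation(len(idxs))
        pos = 0
        for split, c in zip(split_names, counts):
            for i in perm[pos : pos + c]:
                assignment[idxs[i]] = split
            pos += c
    return [
        SubjectRecord(r.subject_id, r.label, r.volume_path, split=assignment[i])
        for i, r in enumerate(records)
    ]


VolumeLike = Volume | np.ndarray


def _as_array(v: VolumeLike) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v)


def undersample_match(
    test_records: Sequence[SubjectRecord],
    volumes: Mapping[str, VolumeLike] | Callable[[SubjectRecord], VolumeLike],
) -> list[SubjectRecord]:
    """Balance the test set by nearest-control matched undersampling.

    For each disease-class (AD) subject, taken in ascending subject-id
    order, keep the not-yet-used control (CN) subject with the smallest mean
    voxelwise absolute intensity difference; repeat until the classes
    balance. All AD test subjects are retained. If controls are not the
    majority the set is returned unchanged with a warning.
    """

    def get(rec: SubjectRecord) -> np.ndarray:
        try:
            v = volumes(rec) if callable(volumes) else volumes[rec.subject_id]
        except KeyError as exc:
            raise FileNotFoundError(
                f"volume missing for subject {rec.subject_id!r}"
            ) from exc
        return _as_array(v)

    ad = sorted(
        (r for r in test_records if r.label == POSITIVE), key=lambda r: r.subject_id
    )
    cn = sorted(
        (r for r in test_records if r.label == NEGATIVE), key=lambda r: r.subject_id
    )
    if len(cn) < len(ad):
        warnings.warn(
            "control class is not the majority in the test set; returning unchanged",
            stacklevel=2,
        )
        return list(test_records)
    if len(cn) == len(ad):
        return list(test_records)
    available = {r.subject_id: get(r).astype(np.float64) for r in cn}
    kept_cn: list[SubjectRecord] = []
    cn_by_id = {r.subject_id: r for r in cn}
    for rec in ad:
        x = get(rec).astype(np.float64)
        best_id, best_d = None, np.inf
        for cid in sorted(available):
            d = float(np.mean(np.abs(x - available[cid])))
            if d < best_d:
                best_id, best_d = cid, d
        kept_cn.append(cn_by_id[best_id])
        del available[best_id]
    keep_ids = {r.subject_id for r in ad} | {r.subject_id for r in kept_cn}
    return [r for r in test_records if r.subject_id in keep_ids]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts at the decision threshold plus the five summary indices.

    ``acc = (TP+TN)/(TP+TN+FP+FN)``, ``sen = TP/(TP+FN)``,
    ``spe = TN/(TN+FP)``, ``f1 = 2TP/(2TP+FP+FN)``; ``auc`` is the
    probability that a random positive scores above a random negative (ties
    counted half), NaN when only one class is present.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    f1: float
    auc: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "acc": self.acc, "sen": self.sen, "spe": self.spe,
            "f1": self.f1, "auc": self.auc,
        }


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank (Mann–Whitney) statistic with ties counted 1/2."""
    pos = labels == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    true_labels: Sequence[str], scores: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Confusion counts and the five indices from positive-class scores.

    ``scores`` are probabilities of the positive (AD) class; a score at or
    above ``threshold`` predicts AD. With a single-class label set the AUC
    is undefined and reported as NaN while the other indices are computed.
    """
    labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    bad = set(labels.tolist()) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected AD/CN")
    pred_pos = scores >= threshold
    is_pos = labels == POSITIVE
    tp = int(np.sum(pred_pos & is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return MetricsReport(tp, tn, fp, fn, acc, sen, spe, f1, rank_auc(labels, scores))


def class_weights(train_labels: Sequence[str]) -> dict[str, float]:
    """Balanced class weights: ``w_c = N_total / (2 · N_c)``."""
    labels = np.asarray(train_labels)
    out = {}
    for c in (POSITIVE, NEGATIVE):
        n_c = int(np.sum(labels == c))
        if n_c == 0:
            raise ValueError(f"class {c} absent from the training labels")
        out[c] = len(labels) / (2.0 * n_c)
    return out


@dataclass(frozen=True)
class RMAnovaResult:
    """One-way repeated-measures ANOVA summary with sphericity diagnostics."""

    f_stat: float
    df_condition: float
    df_error: float
    p_uncorrected: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    p_gg: float
    sphericity_violated: bool
    ms_error: float
    n_subjects: int
    n_conditions: int

    @property
    def p_value(self) -> float:
        """The p-value after applying the correction policy (GG iff violated)."""
        return self.p_gg if self.sphericity_violated else self.p_uncorrected

    def as_dict(self) -> dict:
        return {
            "F": self.f_stat,
            "df": [self.df_condition, self.df_error],
            "p_uncorrected": self.p_uncorrected,
            "Mauchly_W": self.mauchly_w,
            "Mauchly_p": self.mauchly_p,
            "epsilon": self.gg_epsilon,
            "p_gg": self.p_gg,
            "sphericity_violated": self.sphericity_violated,
        }


def _check_table(table: pd.DataFrame) -> np.ndarray:
    data = np.asarray(table, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a complete table with >=2 repetitions and >=2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("repeated-measures table is incomplete (non-finite cells)")
    return data


def rm_anova(table: pd.DataFrame, alpha_sphericity: float = 0.05) -> RMAnovaResult:
    """One-way within-subjects ANOVA on a repetitions × conditions table.

    Standard decomposition: conditions tested against the subject ×
    condition interaction. Mauchly's W tests sphericity; when its p-value
    falls below ``alpha_sphericity`` the Greenhouse–Geisser epsilon is
    applied to both degrees of freedom. All quantities are returned either
    way.
    """
    data = _check_table(table)
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    # guard against float cancellation on (near-)constant tables
    tiny = 1e-12 * (float(np.abs(data).max()) ** 2 * data.size + 1e-300)
    if ms_err <= tiny:
        ms_err = 0.0
        f_stat = 0.0 if ms_cond <= tiny else float("inf")
    else:
        f_stat = ms_cond / ms_err
    p_unc = float(stats.f.sf(f_stat, df_cond, df_err)) if np.isfinite(f_stat) else 0.0

    # orthonormal contrasts of the condition covariance
    helmert = np.linalg.qr(np.vstack([np.ones(k), np.eye(k)[: k - 1]]).T)[0][:, 1:]
    s = np.cov(data, rowvar=False, ddof=1)
    t_mat = helmert.T @ s @ helmert
    tr = float(np.trace(t_mat))
    if tr <= 0:
        eps = 1.0
        w = 1.0
        mauchly_p = 1.0
    else:
        eps = tr**2 / (df_cond * float(np.trace(t_mat @ t_mat)))
        eps = min(max(eps, 1.0 / df_cond), 1.0)
        det = float(np.linalg.det(t_mat))
        w = det / (tr / df_cond) ** df_cond if det > 0 else 0.0
        if k == 2:
            mauchly_p = 1.0  # sphericity is vacuous with two conditions
            w = 1.0
        else:
            df_chi = k * (k - 1) // 2 - 1
            corr = (2 * df_cond**2 + df_cond + 2) / (6.0 * df_cond * (n - 1))
            chi2 = -(n - 1) * (1 - corr) * np.log(max(w, 1e-300))
            mauchly_p = float(stats.chi2.sf(chi2, df_chi))
    violated = mauchly_p < alpha_sphericity
    p_gg = (
        float(stats.f.sf(f_stat, df_cond * eps, df_err * eps))
        if np.isfinite(f_stat)
        else 0.0
    )
    return RMAnovaResult(
        f_stat=f_stat,
        df_condition=float(df_cond),
        df_error=float(df_err),
        p_uncorrected=p_unc,
        mauchly_w=w,
        mauchly_p=mauchly_p,
        gg_epsilon=float(eps),
        p_gg=p_gg,
        sphericity_violated=violated,
        ms_error=ms_err,
        n_subjects=n,
        n_conditions=k,
    )


def tukey_posthoc(table: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Tukey comparisons on the within-subject error term.

    ``q = |mean_a − mean_b| / sqrt(MS_error / n)`` referred to the
    studentized-range distribution with ``k`` groups and the ANOVA error
    degrees of freedom. Symmetric in pair order. With two conditions the
    adjusted p equals the paired t-test's two-sided p.
    """
    data = _check_table(table)
    res = rm_anova(table)
    n, k = data.shape
    names = list(table.columns) if isinstance(table, pd.DataFrame) else list(range(k))
    means = data.mean(axis=0)
    se = np.sqrt(max(res.ms_error, 0.0) / n)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = means[a] - means[b]
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, res.df_error)) if np.isfinite(q) else 0.0
            rows.append(
                {"A": names[a], "B": names[b], "mean_diff": diff, "q": q, "p_adj": p}
            )
    return pd.DataFrame(rows)
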