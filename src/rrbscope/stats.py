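"""Group comparisons, Pearson/BH-FDR correlation screens, and ROC analysis.

These are the reporting-layer kernels: Welch t from printed summary
statistics (mean +/- SEM), raw two-sample and paired t tests, a
Pearson-correlation screen with Benjamini-Hochberg adjustment across the
family submitted in one call, and an empirical ROC with rank-based
(Mann-Whitney, midranks for ties) AUC, percentile-bootstrap CI and the
Youden-optimal cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "two_sample_t_summary",
    "two_sample_t",
    "paired_t",
    "pearson_fdr",
    "rank_auc",
    "roc_analysis",
    "ROCResult",
    "build_report",
    "load_report",
]


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def two_sample_t_summary(
    m1: float, se1: float, n1: int, m2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t test from group means and standard errors.

    t = (m1 - m2) / sqrt(se1^2 + se2^2), Welch-Satterthwaite df.  This is the
    form needed to check a published group comparison reported as mean +/- SEM.
    """
    if se1 < 0 or se2 < 0 or min(n1, n2) < 2:
        raise ValueError("standard errors must be >= 0 and group sizes >= 2")
    v1, v2 = se1 ** 2, se2 ** 2
    if v1 + v2 == 0:
        raise ValueError("both standard errors are zero: t undefined")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def two_sample_t(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t (pooled variance by default) with two-tailed p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if min(a.size, b.size) < 2:
        raise ValueError("need >= 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = a.size + b.size - 2 if not welch else res.df
    return float(res.statistic), float(df), float(res.pvalue)


def paired_t(a, b) -> tuple[float, float, float]:
    """Paired t test on per-subject differences; all-zero differences give t=0, p=1."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    if d.size < 2:
        raise ValueError("need >= 2 pairs")
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, float(d.size - 1), 1.0
        # constant nonzero difference: zero variance, evidence is maximal
        return float(np.sign(d[0]) * np.inf), float(d.size - 1), float(np.finfo(float).tiny)
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(d.size - 1), float(res.pvalue)


# ---------------------------------------------------------------------------
# correlation screen with FDR
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def pearson_fdr(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r with two-tailed p per variable pair, BH-adjusted across the call.

    The FDR family is exactly the set of pairs submitted in one call.  Pairs
    with a constant variable are flagged and excluded from the family
    (r, p, p_fdr all NaN).  Each pair uses its complete cases; n >= 3 required.
    """
    rows = []
    for x, y in pairs:
        sub = table[[x, y]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"pair ({x}, {y}) has only {n} complete cases; >= 3 required")
        xv = sub[x].to_numpy(float)
        yv = sub[y].to_numpy(float)
        if np.all(xv == xv[0]) or np.all(yv == yv[0]):
            rows.append(dict(var_x=x, var_y=y, n=n, r=np.nan, p=np.nan, flagged=True))
            continue
        r, p = sps.pearsonr(xv, yv)
        rows.append(dict(var_x=x, var_y=y, n=n, r=float(r), p=float(p), flagged=False))
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    ok = ~out["flagged"]
    if ok.any():
        out.loc[ok, "p_fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def rank_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney rank formulation with midranks for ties.

    Equals the trapezoidal area under the empirical ROC exactly.  ``labels``
    is 0/1 (1 = positive); higher scores are assumed to indicate positives.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int | None
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    n_pos: int = 0
    n_neg: int = 0

    @property
    def youden_j(self) -> float:
        return self.cutoff_sensitivity + self.cutoff_specificity - 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(threshold=self.thresholds,
                                 sensitivity=self.sensitivity,
                                 specificity=self.specificity))


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sens/spec at every unique threshold, rule: positive iff score >= threshold."""
    thr = np.unique(scores)[::-1]  # descending: sens non-decreasing along the array
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    return thr, sens, spec


def roc_analysis(scores, labels, n_boot: int = 2000, seed: int | None = 0,
                 ci_level: float = 0.95) -> ROCResult:
    """Empirical ROC with rank AUC, stratified percentile-bootstrap CI and
    the Youden-optimal cutoff (ties broken toward higher sensitivity)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos_mask = labels == 1
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("both classes must be present")
    auc = rank_auc(scores, labels)
    thr, sens, spec = _roc_points(scores, labels)
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    # thresholds are descending, so the last tied index has the highest sensitivity
    pick = best[np.argmax(sens[best])]
    rng = np.random.default_rng(seed)
    pos = scores[pos_mask]
    neg = scores[~pos_mask]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boots[b] = rank_auc(np.concatenate([bp, bn]),
                            np.concatenate([np.ones(pos.size), np.zeros(neg.size)]))
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ROCResult(
        thresholds=thr, sensitivity=sens, specificity=spec,
        auc=auc, ci_level=ci_level, ci_lower=float(lo), ci_upper=float(hi),
        n_boot=n_boot, seed=seed,
        cutoff=float(thr[pick]),
        cutoff_sensitivity=float(sens[pick]),
        cutoff_specificity=float(spec[pick]),
        n_pos=int(pos.size), n_neg=int(neg.size),
    )


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

_SECTIONS = ("group_tests", "correlations", "roc")


def build_report(out_dir, group_tests: pd.DataFrame | None = None,
                 correlations: pd.DataFrame | None = None,
                 roc: pd.DataFrame | None = None,
                 meta: dict | None = None) -> dict:
    """Write the results bundle (CSV per section + report.json summary).

    Absent sections (e.g. no ADOS scores available) are recorded as absent in
    report.json rather than failing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sections = dict(group_tests=group_tests, correlations=correlations, roc=roc)
    summary: dict = {"sections": {}, "meta": meta or {}}
    for name, frame in sections.items():
        if frame is None:
            summary["sections"][name] = {"present": False}
            continue
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        summary["sections"][name] = {"present": True, "rows": int(len(frame)),
                                     "file": path.name}
    (out_dir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def load_report(out_dir) -> dict:
    """Round-trip loader for a bundle written by :func:`build_report`."""
    out_dir = Path(out_dir)
    summary = json.loads((out_dir / "report.json").read_text())
    out = {"summary": summary}
    for name, info in summary["sections"].items():
        out[name] = pd.read_csv(out_dir / info["file"]) if info["present"] else None
    return out
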