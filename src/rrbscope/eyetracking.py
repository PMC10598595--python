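"""Fixation-report parsing, QC, and eye-tracking features.

Feature definitions: a trial's total fixation time (TFT) is the sum of its
retained fixation durations (only fixations strictly longer than 100 ms are
retained); the subject x condition TFT is the mean over trials; pupil size is
the mean over all retained fixations (pooled, not per-trial-then-averaged).

QC: a trial with no retained fixation is *missing*.  If more than 30% of a
subject x condition's trials are missing the whole cell is discarded;
otherwise the missing trials' TFT values are imputed with the mean of the
observed trials when their distribution is symmetric (|sample skewness| <=
1), with the median otherwise.  A missing fraction of exactly 30% is
retained (the discard rule reads "more than 30%").
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "parse_fixation_report",
    "qc_and_impute",
    "compute_et_features",
    "REQUIRED_COLUMNS",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "trial", "condition", "fix_onset_ms", "fix_dur_ms", "pupil_um")
MIN_FT_MS = 100.0
MISSING_THRESHOLD = 0.30
SKEW_BOUND = 1.0


class FixationParseError(ValueError):
    """Raised when a fixation report lacks a required column."""


def parse_fixation_report(path_or_frame) -> pd.DataFrame:
    """Read a tab-separated fixation report into typed records.

    Parsing is header-driven (column order is irrelevant; extra columns are
    preserved).  Rows whose numeric fields do not parse are kept with
    ``valid=False`` — downstream they count toward missingness — and their
    count is logged.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        raw = path_or_frame.copy()
    else:
        raw = pd.read_csv(Path(path_or_frame), sep="\t", dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise FixationParseError(f"fixation report is missing required column {col!r}")
    out = raw.copy()
    numeric = {}
    for col in ("trial", "fix_onset_ms", "fix_dur_ms", "pupil_um"):
        numeric[col] = pd.to_numeric(out[col], errors="coerce")
    valid = pd.Series(True, index=out.index)
    for col in ("fix_onset_ms", "fix_dur_ms", "pupil_um"):
        valid &= numeric[col].notna()
    valid &= numeric["fix_dur_ms"] > 0
    valid &= numeric["pupil_um"] > 0
    structural = numeric["trial"].notna() & out["subject_id"].notna() & out["condition"].notna()
    n_dropped = int((~structural).sum())
    if n_dropped:
        logger.warning("fixation report: skipped %d row(s) without subject/trial/condition", n_dropped)
    out = out[structural].copy()
    for col in ("fix_onset_ms", "fix_dur_ms", "pupil_um"):
        out[col] = numeric[col][structural]
    out["trial"] = numeric["trial"][structural].astype(int)
    out["subject_id"] = out["subject_id"].astype(str)
    out["condition"] = out["condition"].astype(str)
    out["valid"] = valid[structural].to_numpy()
    n_invalid = int((~out["valid"]).sum())
    if n_invalid:
        logger.info("fixation report: %d row(s) flagged invalid (malformed numeric fields)", n_invalid)
    return out.reset_index(drop=True)


def _sample_skewness(x: np.ndarray) -> float:
    """Biased sample skewness m3 / m2^(3/2); 0 for < 3 values or zero spread."""
    if x.size < 3:
        return 0.0
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 <= (1e-12 * max(abs(x).max(), 1.0)) ** 2:
        return 0.0
    return float(np.mean(d ** 3) / m2 ** 1.5)


def _trial_metrics(records: pd.DataFrame, min_ft: float) -> pd.DataFrame:
    """Per subject x condition x trial sums over retained (> min_ft) fixations."""
    rec = records.copy()
    if "valid" not in rec.columns:
        rec["valid"] = True
    retained = rec[rec["valid"] & (rec["fix_dur_ms"] > min_ft)]
    grouped = retained.groupby(["subject_id", "condition", "trial"]).agg(
        tft_ms=("fix_dur_ms", "sum"),
        pupil_sum=("pupil_um", "sum"),
        n_fix=("pupil_um", "size"),
    ).reset_index()
    return grouped


def qc_and_impute(
    records: pd.DataFrame,
    missing_threshold: float = MISSING_THRESHOLD,
    skew_bound: float = SKEW_BOUND,
    min_ft: float = MIN_FT_MS,
    n_trials: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the missingness rule and impute retained cells.

    Returns ``(trial_table, qc_table)``.  ``trial_table`` holds one row per
    subject x condition x trial (imputed trials flagged, with no fixation
    counts); only QC-passing cells appear.  ``qc_table`` has one row per
    subject x condition with the missing fraction, the pass flag and the
    imputation method used.  ``n_trials`` is the expected per-condition trial
    count; by default the maximum trial index observed anywhere in the report.
    """
    observed = _trial_metrics(records, min_ft)
    if n_trials is None:
        n_trials = int(records["trial"].max())
    cells = records[["subject_id", "condition"]].drop_duplicates()
    qc_rows = []
    trial_rows = []
    for subject_id, condition in cells.itertuples(index=False):
        obs = observed[(observed["subject_id"] == subject_id)
                       & (observed["condition"] == condition)]
        present = set(obs["trial"])
        missing = [t for t in range(1, n_trials + 1) if t not in present]
        frac = len(missing) / n_trials
        qc_pass = frac <= missing_threshold and len(present) > 0
        method = "none"
        skew = np.nan
        if not qc_pass:
            logger.info("ET QC: %s/%s discarded (%.0f%% trials missing)",
                        subject_id, condition, 100 * frac)
        else:
            tfts = obs["tft_ms"].to_numpy(float)
            if missing:
                skew = _sample_skewness(tfts)
                method = "mean" if abs(skew) <= skew_bound else "median"
                fill_tft = float(np.mean(tfts) if method == "mean" else np.median(tfts))
                pupil_means = (obs["pupil_sum"] / obs["n_fix"]).to_numpy(float)
                fill_pupil = float(np.mean(pupil_means) if method == "mean"
                                   else np.median(pupil_means))
            for _, row in obs.iterrows():
                trial_rows.append((subject_id, condition, int(row["trial"]),
                                   float(row["tft_ms"]), float(row["pupil_sum"]),
                                   int(row["n_fix"]), False))
            for t in missing:
                trial_rows.append((subject_id, condition, t,
                                   fill_tft, fill_pupil, 0, True))
        qc_rows.append((subject_id, condition, n_trials, len(missing), frac,
                        qc_pass, method, skew))
    trial_table = pd.DataFrame(
        trial_rows,
        columns=["subject_id", "condition", "trial", "tft_ms", "pupil_sum", "n_fix", "imputed"],
    )
    qc_table = pd.DataFrame(
        qc_rows,
        columns=["subject_id", "condition", "n_trials_expected", "n_missing",
                 "missing_fraction", "qc_pass", "imputation", "skewness"],
    )
    return trial_table, qc_table


def compute_et_features(
    records: pd.DataFrame,
    missing_threshold: float = MISSING_THRESHOLD,
    skew_bound: float = SKEW_BOUND,
    min_ft: float = MIN_FT_MS,
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Per subject x condition TFT and pupil features after QC.

    TFT = mean over trials of the per-trial summed retained durations
    (imputed trials included); pupil = pooled mean over retained fixations
    (imputed trials carry no fixations and do not enter the pooled pupil
    mean).  Discarded cells appear with ``qc_pass=False`` and NaN features.
    """
    trial_table, qc_table = qc_and_impute(
        records, missing_threshold=missing_threshold,
        skew_bound=skew_bound, min_ft=min_ft, n_trials=n_trials)
    rows = []
    for _, qc in qc_table.iterrows():
        key = (qc["subject_id"], qc["condition"])
        if not qc["qc_pass"]:
            rows.append((*key, np.nan, np.nan, qc["missing_fraction"], False))
            continue
        sub = trial_table[(trial_table["subject_id"] == key[0])
                          & (trial_table["condition"] == key[1])]
        tft = float(sub["tft_ms"].mean())
        n_fix = sub["n_fix"].sum()
        pupil = float(sub["pupil_sum"].sum() / n_fix) if n_fix > 0 else np.nan
        rows.append((*key, tft, pupil, qc["missing_fraction"], True))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "condition", "tft_ms", "pupil_um", "missing_fraction", "qc_pass"],
    )
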