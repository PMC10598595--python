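"""Synthetic data with the statistical structure the analysis assumes.

Three generators share one :class:`SimulationConfig`:

* ``simulate_eeg`` — epoched alpha-band EEG (two groups ASD/TD, two stimulus
  conditions HRIS/LRIS) in which a planted set of channel pairs is
  phase-locked at a fixed lag on a Bernoulli(kappa) fraction of trials, on a
  1/f^beta pink-noise background, with post-stimulus alpha amplitude scaled
  down to induce event-related desynchronization.
* ``simulate_eyetracking`` — per-trial fixation streams whose summed duration
  (total fixation time, TFT) and pupil sizes follow configured group x
  condition means of the magnitude observed in the restricted-interest
  paradigm; a configurable fraction of subjects carries >30% missing trials
  to exercise the QC rule.
* ``simulate_clinical`` — ADOS-2-like scores in which the
  restricted/repetitive-behavior (RRB) sub-score is an affine function of a
  subject's planted-edge connectivity plus Gaussian noise calibrated
  analytically to a target Pearson correlation.

The per-trial Bernoulli phase-locking model is deliberately simple: its
expected WPLI response is monotone in kappa and a brute-force oracle exists,
which is what the calibration tests need.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .montage import DEFAULT_CHANNELS
from .spectral import morlet_transform, compute_wpli

__all__ = [
    "ETParams",
    "AdosLink",
    "SimulationConfig",
    "SubjectRecord",
    "simulate_eeg",
    "simulate_eyetracking",
    "simulate_clinical",
    "planted_edge_wpli",
    "subjects_to_frame",
]

logger = logging.getLogger(__name__)

TRIAL_LENGTH_MS = 10_000.0  # each stimulus is shown for 10 s
MIN_FIXATION_MS = 150.0  # generated fixations stay above the 100 ms analysis filter


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ETParams:
    """Eye-tracking generator cell for one group x condition.

    ``tft_mean``/``pupil_mean`` are the group-level means; ``*_between_sd``
    spread subject means around them (this is what drives group-level t
    statistics), ``*_within_sd`` spreads trials (fixations, for pupil) around
    the subject mean.  All units ms / um.
    """

    tft_mean: float
    tft_between_sd: float
    tft_within_sd: float
    pupil_mean: float
    pupil_between_sd: float
    pupil_within_sd: float
    n_fix_mean: float = 8.0


@dataclass(frozen=True)
class AdosLink:
    """Calibration of the RRB sub-score to planted connectivity.

    ``rrb_noise_sd=None`` derives the noise SD analytically from ``target_r``
    and the empirical variance of the connectivity summary; an explicit value
    overrides it (0 gives a deterministic affine relation, r = 1).
    """

    target_r: float = 0.77
    rrb_noise_sd: float | None = None
    rrb_mean: float = 4.25
    rrb_sd: float = 2.16
    sa_mean: float = 9.84
    sa_sd: float = 3.06


def _default_coupling() -> dict:
    # ASD couples more strongly under high restricted-interest stimuli,
    # TD under low — the group x condition interaction the inference stages
    # are meant to detect.
    return {
        ("ASD", "HRIS"): 0.80,
        ("ASD", "LRIS"): 0.45,
        ("TD", "HRIS"): 0.35,
        ("TD", "LRIS"): 0.60,
    }


def _default_et_params() -> dict:
    # Group-level means match the reported restricted-interest magnitudes;
    # between-subject SDs are the printed SEMs scaled by sqrt(group n).
    return {
        ("ASD", "HRIS"): ETParams(4853.30, 1286.5, 300.0, 4991.67, 878.5, 200.0),
        ("TD", "HRIS"): ETParams(2628.98, 1058.0, 300.0, 2520.87, 1820.5, 200.0),
        ("ASD", "LRIS"): ETParams(2205.51, 1021.2, 300.0, 2896.35, 323.6, 200.0),
        ("TD", "LRIS"): ETParams(5914.00, 2014.7, 300.0, 4687.56, 1082.8, 200.0),
    }


def _default_planted_edges() -> tuple:
    # Parieto-occipital star around Pz, 5 edges.  A star keeps the planted
    # lag exact on every edge: each coupled partner inherits the hub phase
    # plus the lag.  Chained edge sets (a->b->c) would compound the lag (a
    # two-step chain at lag pi/2 lands at pi, which WPLI cannot see).
    return (("Pz", "Oz"), ("Pz", "P3"), ("Pz", "P4"), ("Pz", "O1"), ("Pz", "P7"))


@dataclass(frozen=True)
class SimulationConfig:
    n_asd: int = 32
    n_td: int = 27
    n_trials_per_condition: int = 12
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sample_rate: float = 250.0
    epoch_window_ms: tuple[float, float] = (-1000.0, 2000.0)
    carrier_freq: float = 10.0
    planted_edges: tuple[tuple[str, str], ...] = field(default_factory=_default_planted_edges)
    coupling: dict = field(default_factory=_default_coupling)
    phase_lag: float = np.pi / 4
    alpha_amp: float = 5.0  # uV carrier amplitude in the baseline window
    erd_scale: float = 0.7  # post-stimulus amplitude factor (power x0.49)
    noise_sd: float = 2.0  # uV pink-noise SD per channel
    pink_noise_exponent: float = 1.0
    et_params: dict = field(default_factory=_default_et_params)
    ados_link: AdosLink = field(default_factory=AdosLink)
    missing_subject_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, kappa in self.coupling.items():
            if not 0.0 <= kappa <= 1.0:
                raise ConfigurationError(f"coupling kappa for {cell} must lie in [0, 1]")
        chan = set(self.channels)
        for a, b in self.planted_edges:
            if a not in chan or b not in chan:
                raise ConfigurationError(f"planted edge ({a}, {b}) names a channel outside the montage")
        for cell, p in self.et_params.items():
            if min(p.tft_mean, p.tft_between_sd, p.tft_within_sd,
                   p.pupil_mean, p.pupil_between_sd, p.pupil_within_sd) < 0:
                raise ConfigurationError(f"negative eye-tracking mean/SD for {cell}")
        if not -1.0 < self.ados_link.target_r < 1.0:
            raise ConfigurationError("ados_link.target_r must lie in (-1, 1)")
        if not 0.0 <= self.missing_subject_fraction <= 1.0:
            raise ConfigurationError("missing_subject_fraction must lie in [0, 1]")
        lag = np.mod(self.phase_lag, np.pi)
        if np.isclose(lag, 0.0, atol=1e-9):
            warnings.warn(
                "phase_lag is 0 or pi: WPLI is blind to zero-lag coupling, "
                "planted effects will be invisible",
                stacklevel=2,
            )

    # ---- derived -------------------------------------------------------
    @property
    def asd_ids(self) -> list[str]:
        return [f"ASD{i:03d}" for i in range(1, self.n_asd + 1)]

    @property
    def td_ids(self) -> list[str]:
        return [f"TD{i:03d}" for i in range(1, self.n_td + 1)]

    @property
    def subject_ids(self) -> list[str]:
        return self.asd_ids + self.td_ids

    def group_of(self, subject_id: str) -> str:
        return "ASD" if subject_id.startswith("ASD") else "TD"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupling"] = {f"{g}/{c}": v for (g, c), v in self.coupling.items()}
        d["et_params"] = {f"{g}/{c}": asdict(p) for (g, c), p in self.et_params.items()}
        return d


@dataclass
class SubjectRecord:
    """Group membership, demographics and ADOS-2 scores (absent for TD)."""

    subject_id: str
    group: str
    age: float
    sex: str
    ados_total: float = np.nan
    sa_score: float = np.nan
    rrb_score: float = np.nan


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int, beta: float) -> np.ndarray:
    """1/f^beta noise along the last axis, unit SD per series."""
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (rng.standard_normal(shape + (freqs.size,))
            + 1j * rng.standard_normal(shape + (freqs.size,))) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_eeg(config: SimulationConfig) -> dict[str, EpochSet]:
    """Generate epoched EEG for every subject.

    Each channel carries an alpha carrier with a per-trial random phase plus
    pink noise; on a Bernoulli(kappa) subset of trials the second channel of
    each planted edge inherits the first channel's phase shifted by
    ``phase_lag``.  Edges are processed in their listed order against the
    current phases, so edge sets that chain or fan into a channel compound
    or overwrite lags — use star-shaped sets (as the default does) when every
    edge must carry the exact configured lag.  Post-stimulus carrier amplitude is scaled by
    ``erd_scale`` so alpha power drops below baseline (the ERD convention).
    """
    tmin, tmax = config.epoch_window_ms
    n_samples = int(round((tmax - tmin) / 1000.0 * config.sample_rate))
    t = (tmin + 1000.0 * np.arange(n_samples) / config.sample_rate) / 1000.0  # seconds
    envelope = np.where(t < 0, config.alpha_amp, config.alpha_amp * config.erd_scale)
    ch_index = {c: i for i, c in enumerate(config.channels)}
    n_ch = len(config.channels)
    n_trials = 2 * config.n_trials_per_condition
    conditions = np.array(
        ["HRIS"] * config.n_trials_per_condition + ["LRIS"] * config.n_trials_per_condition,
        dtype=object,
    )
    root = np.random.SeedSequence(config.seed)
    out: dict[str, EpochSet] = {}
    for subject_id, child in zip(config.subject_ids, root.spawn(len(config.subject_ids))):
        rng = np.random.default_rng(child)
        group = config.group_of(subject_id)
        phases = rng.uniform(0, 2 * np.pi, size=(n_trials, n_ch))
        for trial in range(n_trials):
            kappa = config.coupling[(group, str(conditions[trial]))]
            for a, b in config.planted_edges:
                if rng.random() < kappa:
                    phases[trial, ch_index[b]] = phases[trial, ch_index[a]] + config.phase_lag
        carrier = envelope * np.cos(
            2 * np.pi * config.carrier_freq * t + phases[:, :, None]
        )
        data = carrier
        if config.noise_sd > 0:
            data = data + config.noise_sd * _pink_noise(
                rng, (n_trials, n_ch), n_samples, config.pink_noise_exponent
            )
        out[subject_id] = EpochSet(
            subject_id=subject_id,
            data=data,
            sample_rate=config.sample_rate,
            tmin_ms=tmin,
            channels=config.channels,
            conditions=conditions.copy(),
        )
    return out


def planted_edge_wpli(
    epochs_map: dict[str, EpochSet],
    config: SimulationConfig,
    condition: str = "HRIS",
    band: tuple[float, float] = (8.0, 13.0),
) -> dict[str, float]:
    """Mean alpha WPLI over the planted edges, per subject.

    Restricted to the channels the planted edges touch, so it is cheap enough
    to serve as the connectivity summary that calibrates the clinical scores.
    """
    involved = sorted({c for e in config.planted_edges for c in e})
    freqs = np.arange(np.floor(band[0]), np.ceil(band[1]) + 1.0)
    out = {}
    for subject_id, ep in epochs_map.items():
        idx = [ep.channels.index(c) for c in involved]
        sub = EpochSet(
            subject_id=ep.subject_id,
            data=ep.data[:, idx, :],
            sample_rate=ep.sample_rate,
            tmin_ms=ep.tmin_ms,
            channels=tuple(involved),
            conditions=ep.conditions,
            rejected=ep.rejected,
        )
        tf = morlet_transform(sub, freqs=freqs, condition=condition)
        mat = compute_wpli(tf, band=band)
        out[subject_id] = float(np.mean([mat.edge(a, b) for a, b in config.planted_edges]))
    return out


# ---------------------------------------------------------------------------
# eye tracking
# ---------------------------------------------------------------------------

def simulate_eyetracking(config: SimulationConfig) -> pd.DataFrame:
    """Fixation report: one row per fixation.

    Columns: subject_id, trial, condition, fix_onset_ms, fix_dur_ms, pupil_um.
    Per-trial summed duration equals the drawn trial TFT exactly (durations
    are lognormal weights rescaled above a floor).  A
    ``missing_subject_fraction`` of subjects gets >30% of trials removed in
    both conditions, which the downstream QC rule must discard.
    """
    root = np.random.SeedSequence((config.seed, 1))
    rng = np.random.default_rng(root)
    subjects = config.subject_ids
    n_flagged = int(round(config.missing_subject_fraction * len(subjects)))
    flagged = set(rng.choice(subjects, size=n_flagged, replace=False)) if n_flagged else set()
    n_trials = config.n_trials_per_condition
    # smallest count that strictly exceeds the 30% missingness threshold
    n_missing = int(np.floor(0.30 * n_trials)) + 1
    rows = []
    for subject_id in subjects:
        group = config.group_of(subject_id)
        for condition in ("HRIS", "LRIS"):
            p = config.et_params[(group, condition)]
            tft_subject = max(rng.normal(p.tft_mean, p.tft_between_sd), 2 * MIN_FIXATION_MS)
            pupil_subject = max(rng.normal(p.pupil_mean, p.pupil_between_sd), 100.0)
            missing = set()
            if subject_id in flagged:
                missing = set(rng.choice(n_trials, size=min(n_missing, n_trials), replace=False))
            for trial in range(1, n_trials + 1):
                if (trial - 1) in missing:
                    continue
                tft = tft_subject
                if p.tft_within_sd > 0:
                    tft = rng.normal(tft_subject, p.tft_within_sd)
                tft = float(np.clip(tft, 2 * MIN_FIXATION_MS, TRIAL_LENGTH_MS - 500.0))
                n_fix = max(1, int(rng.poisson(p.n_fix_mean)))
                n_fix = max(1, min(n_fix, int(tft // (2 * MIN_FIXATION_MS))))
                w = rng.lognormal(0.0, 0.6, size=n_fix)
                durations = MIN_FIXATION_MS + (tft - MIN_FIXATION_MS * n_fix) * w / w.sum()
                gaps = rng.uniform(30.0, 150.0, size=n_fix)  # gap before each fixation
                slack = TRIAL_LENGTH_MS - durations.sum()
                if gaps.sum() > slack:
                    gaps *= slack / gaps.sum()
                onset = 0.0
                for d, g in zip(durations, gaps):
                    onset += g
                    pupil = max(rng.normal(pupil_subject, p.pupil_within_sd), 50.0)
                    rows.append((subject_id, trial, condition,
                                 round(onset, 3), round(float(d), 3), round(pupil, 2)))
                    onset += d
    frame = pd.DataFrame(
        rows,
        columns=["subject_id", "trial", "condition", "fix_onset_ms", "fix_dur_ms", "pupil_um"],
    )
    if flagged:
        logger.info("eye tracking: %d subject(s) seeded with >30%% missing trials", len(flagged))
    return frame


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def simulate_clinical(
    config: SimulationConfig,
    subject_connectivity: dict[str, float],
) -> list[SubjectRecord]:
    """ADOS-2-like records; RRB is calibrated to planted connectivity.

    RRB = mean + b * (wpli - mean(wpli)) + eps with the slope matched to the
    configured RRB spread and eps solved from ``target_r``
    (sd_eps = rrb_sd * sqrt(1 - r^2)); if any score would fall below zero the
    whole RRB vector is shifted up, which leaves the correlation untouched.
    SA is independent; total = SA + RRB; TD records carry no scores.
    """
    link = config.ados_link
    missing = [s for s in config.asd_ids if s not in subject_connectivity]
    if missing:
        raise ConfigurationError(f"connectivity summaries missing for ASD subjects {missing[:3]}...")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    x = np.array([subject_connectivity[s] for s in config.asd_ids], dtype=float)
    sd_x = x.std(ddof=0)
    if link.rrb_noise_sd is not None:
        slope = (link.rrb_sd / sd_x) if sd_x > 0 else 0.0
        noise_sd = link.rrb_noise_sd
    else:
        slope = (link.target_r * link.rrb_sd / sd_x) if sd_x > 0 else 0.0
        noise_sd = link.rrb_sd * np.sqrt(1.0 - link.target_r ** 2)
    rrb = link.rrb_mean + slope * (x - x.mean())
    if noise_sd > 0:
        rrb = rrb + rng.normal(0.0, noise_sd, size=x.size)
    if rrb.min() < 0:  # affine shift preserves Pearson correlation exactly
        rrb = rrb - rrb.min()
    sa = np.clip(rng.normal(link.sa_mean, link.sa_sd, size=x.size), 0.0, None)
    records = []
    for i, subject_id in enumerate(config.asd_ids):
        records.append(SubjectRecord(
            subject_id=subject_id,
            group="ASD",
            age=float(np.clip(rng.normal(3.1, 0.51), 2.0, 4.5)),
            sex="M" if rng.random() < 25 / 32 else "F",
            ados_total=float(sa[i] + rrb[i]),
            sa_score=float(sa[i]),
            rrb_score=float(rrb[i]),
        ))
    for subject_id in config.td_ids:
        records.append(SubjectRecord(
            subject_id=subject_id,
            group="TD",
            age=float(np.clip(rng.normal(2.9, 0.52), 2.0, 4.5)),
            sex="M" if rng.random() < 20 / 27 else "F",
        ))
    return records


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
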