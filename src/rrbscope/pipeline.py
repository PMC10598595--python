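"""End-to-end orchestration: simulate -> preprocess -> connectivity -> NBS ->
NBS-Predict -> ET features -> stats, with a reproducibility manifest.

All stage parameters default to the analysis' canonical settings (0.1-30 Hz
band-pass, 50 Hz line removal, +/-100 uV rejection, 3-cycle Morlet wavelets
at 4-30 Hz, alpha 8-13 Hz x 500-1400 ms WPLI, ERD baseline -624..-376 ms,
NBS edge alpha 0.005 / component alpha 0.05 / 10,000 permutations, 5-fold x
10-repeat CV with selection p 0.01 and 5,000 prediction permutations, 100 ms
fixation filter, 30% missingness rule).  A single global seed fans out to
per-stage child seeds through a fixed derivation, so each stage is
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .epochs import load_epochs, save_epochs
from .eyetracking import compute_et_features
from .montage import Montage, standard_1020
from .nbs import nbs_test, node_degrees, paired_differences
from .predict import nbs_predict_run, permutation_significance, weighted_network
from .preprocess import preprocess
from .simulate import (SimulationConfig, planted_edge_wpli, simulate_clinical,
                       simulate_eeg, simulate_eyetracking, subjects_to_frame)
from .spectral import compute_erd, compute_wpli, morlet_transform
from .stats import build_report, pearson_fdr, roc_analysis, two_sample_t

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "connectivity", "nbs", "nbs_predict",
          "et_features", "stats")


@dataclass
class RunConfig:
    seed: int = 7
    stages: tuple[str, ...] = STAGES
    # --- preprocessing ---
    hp: float = 0.1
    lp: float = 30.0
    line_freq: float = 50.0
    n_harmonics: int = 2
    baseline_ms: tuple[float, float] = (-1000.0, 0.0)
    reject_uv: float = 100.0
    # --- time-frequency / connectivity ---
    n_cycles: float = 3.0
    freq_lo: float = 4.0
    freq_hi: float = 30.0
    band: tuple[float, float] = (8.0, 13.0)
    window_ms: tuple[float, float] = (500.0, 1400.0)
    erd_baseline_ms: tuple[float, float] = (-624.0, -376.0)
    # --- NBS ---
    edge_alpha: float = 0.005
    comp_alpha: float = 0.05
    nbs_perms: int = 10_000
    # --- NBS-Predict ---
    cv_k: int = 5
    cv_repeats: int = 10
    select_p: float = 0.01
    predict_perms: int = 5000
    predict_perm_repeats: int = 1
    # --- eye tracking ---
    min_ft_ms: float = 100.0
    missing_threshold: float = 0.30
    # --- synthetic data ---
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig

    def validate(self) -> None:
        sim = self.sim_config(0)
        nyq = sim.sample_rate / 2.0
        if self.lp >= nyq:
            raise ValueError(f"low-pass {self.lp} Hz is not below Nyquist {nyq} Hz")
        if self.hp >= self.lp:
            raise ValueError("high-pass must lie below low-pass")
        if not (self.freq_lo <= self.band[0] and self.band[1] <= self.freq_hi):
            raise ValueError("analysis band must lie within the decomposition range")

    def sim_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.sim)

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("baseline_ms", "window_ms", "erd_baseline_ms", "band", "stages"):
            if key in payload:
                payload[key] = tuple(payload[key])
        if "sim" in payload and "planted_edges" in payload["sim"]:
            payload["sim"]["planted_edges"] = tuple(
                tuple(e) for e in payload["sim"]["planted_edges"])
        if "sim" in payload and "channels" in payload["sim"]:
            payload["sim"]["channels"] = tuple(payload["sim"]["channels"])
        return cls(**payload)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Fixed fan-out of the global seed to per-stage child seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES), dtype=np.uint64)
    return {stage: int(s % (2 ** 31)) for stage, s in zip(STAGES, state)}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, seed: int) -> None:
    sim = cfg.sim_config(seed)
    eeg_dir = out / "eeg"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    epochs = simulate_eeg(sim)
    for sid, ep in epochs.items():
        save_epochs(ep, eeg_dir / f"{sid}.npz")
    standard_1020(sim.channels).to_json(out / "montage.json")
    simulate_eyetracking(sim).to_csv(out / "fixations.tsv", sep="\t", index=False)
    wpli = planted_edge_wpli(epochs, sim, condition="HRIS", band=cfg.band)
    subjects = subjects_to_frame(simulate_clinical(sim, wpli))
    subjects.to_csv(out / "subjects.csv", index=False)
    pd.DataFrame(sorted(wpli.items()), columns=["subject_id", "planted_edge_wpli"]).to_csv(
        out / "planted_edge_wpli.csv", index=False)


def _stage_preprocess(cfg: RunConfig, out: Path, seed: int) -> None:
    montage = Montage.from_json(out / "montage.json")
    pre_dir = out / "preproc"
    pre_dir.mkdir(exist_ok=True)
    for path in sorted((out / "eeg").glob("*.npz")):
        ep = load_epochs(path)
        clean = preprocess(
            ep, montage, hp=cfg.hp, lp=cfg.lp, line=cfg.line_freq,
            n_harmonics=cfg.n_harmonics, baseline=cfg.baseline_ms,
            reject_uv=cfg.reject_uv)
        save_epochs(clean, pre_dir / path.name)


def _stage_connectivity(cfg: RunConfig, out: Path, seed: int) -> None:
    matrices = []
    erd_rows = []
    for path in sorted((out / "preproc").glob("*.npz")):
        ep = load_epochs(path)
        for condition in ("HRIS", "LRIS"):
            tf = morlet_transform(ep, freqs=cfg.freqs, n_cycles=cfg.n_cycles,
                                  condition=condition)
            matrices.append(compute_wpli(tf, band=cfg.band, window_ms=cfg.window_ms))
            erd = compute_erd(tf, baseline_ms=cfg.erd_baseline_ms)
            alpha = erd.band_mean(cfg.band, cfg.window_ms)
            erd_rows.append((ep.subject_id, condition, float(alpha.mean())))
    rio.write_connectivity_dir(matrices, out / "connectivity")
    pd.DataFrame(erd_rows, columns=["subject_id", "condition", "alpha_erd_pct"]).to_csv(
        out / "connectivity" / "erd.csv", index=False)


def _load_groups(out: Path) -> dict[str, str]:
    subjects = pd.read_csv(out / "subjects.csv")
    return dict(zip(subjects["subject_id"].astype(str), subjects["group"].astype(str)))


def _stage_nbs(cfg: RunConfig, out: Path, seed: int) -> None:
    matrices = rio.read_connectivity_dir(out / "connectivity")
    groups = _load_groups(out)
    nbs_dir = out / "nbs"
    nbs_dir.mkdir(exist_ok=True)
    runs = []
    for condition in ("HRIS", "LRIS"):
        sub = [m for m in matrices if m.condition == condition]
        labels = [groups[m.subject_id] for m in sub]
        for direction, tag in ((1, "ASD_gt_TD"), (-1, "ASD_lt_TD")):
            runs.append((f"two_sample_{condition}_{tag}",
                         nbs_test(sub, "two_sample", groups=labels, direction=direction,
                                  edge_alpha=cfg.edge_alpha, comp_alpha=cfg.comp_alpha,
                                  n_perm=cfg.nbs_perms, seed=seed)))
    for group in ("ASD", "TD"):
        sub = [m for m in matrices if groups[m.subject_id] == group]
        paired = paired_differences(sub)
        for direction, tag in ((1, "HRIS_gt_LRIS"), (-1, "HRIS_lt_LRIS")):
            runs.append((f"paired_{group}_{tag}",
                         nbs_test(paired, "paired", direction=direction,
                                  edge_alpha=cfg.edge_alpha, comp_alpha=cfg.comp_alpha,
                                  n_perm=cfg.nbs_perms, seed=seed)))
    summary = {}
    for name, res in runs:
        edge_idx = {frozenset(e): i for i, e in enumerate(res.stats.edges)}
        rows = []
        for ci, comp in enumerate(res.components):
            for a, b in comp:
                e = edge_idx[frozenset((a, b))]
                rows.append((ci, a, b, res.stats.t[e], res.stats.p[e],
                             float(res.component_p[ci])))
        pd.DataFrame(rows, columns=["component", "channel_i", "channel_j",
                                    "t", "p", "component_p"]).to_csv(
            nbs_dir / f"{name}_components.csv", index=False)
        np.savetxt(nbs_dir / f"{name}_null.csv", res.null_max_sizes, fmt="%d")
        summary[name] = {
            "observed_max_size": res.observed_max_size,
            "largest_component_degrees": node_degrees(res.components[0]) if res.components else {},
            "component_sizes": [len(c) for c in res.components],
            "component_p": [float(p) for p in res.component_p],
            "n_significant": len(res.significant),
            "n_perm": res.n_perm, "exact": res.exact,
            "edge_alpha": cfg.edge_alpha, "comp_alpha": cfg.comp_alpha,
            "seed": seed,
        }
    rio.write_json(summary, nbs_dir / "summary.json")


def _stage_nbs_predict(cfg: RunConfig, out: Path, seed: int) -> None:
    matrices = [m for m in rio.read_connectivity_dir(out / "connectivity")
                if m.condition == "HRIS"]
    groups = [_load_groups(out)[m.subject_id] for m in matrices]
    result = nbs_predict_run(matrices, groups, k=cfg.cv_k, repeats=cfg.cv_repeats,
                             p_thresh=cfg.select_p, seed=seed)
    result = permutation_significance(matrices, groups, result,
                                      n_perm=cfg.predict_perms, seed=seed,
                                      repeats=cfg.predict_perm_repeats)
    pred_dir = out / "nbs_predict"
    pred_dir.mkdir(exist_ok=True)
    result.fold_metrics.to_csv(pred_dir / "metrics.csv", index=False)
    weighted_network(result).to_csv(pred_dir / "weighted_adjacency.tsv", sep="\t",
                                    float_format=rio.FLOAT_FMT)
    means = result.mean_metrics()
    rio.write_json({
        "best_model": result.best_model,
        "mean_auc": result.mean_auc,
        "mean_metrics": {m: {k: float(v) for k, v in row.items()}
                         for m, row in means.iterrows()},
        "null_mean_auc": result.null_mean_auc,
        "p_value": result.p_value,
        "params": result.params,
        "n_perm": int(result.null_auc.size),
    }, pred_dir / "summary.json")


def _stage_et_features(cfg: RunConfig, out: Path, seed: int) -> None:
    from .eyetracking import parse_fixation_report
    records = parse_fixation_report(out / "fixations.tsv")
    features = compute_et_features(records, missing_threshold=cfg.missing_threshold,
                                   min_ft=cfg.min_ft_ms)
    features.to_csv(out / "et_features.csv", index=False)


def _stage_stats(cfg: RunConfig, out: Path, seed: int) -> None:
    features = pd.read_csv(out / "et_features.csv")
    subjects = pd.read_csv(out / "subjects.csv")
    groups = dict(zip(subjects["subject_id"].astype(str), subjects["group"].astype(str)))
    features["group"] = features["subject_id"].map(groups)
    # --- group comparisons of ET features per condition ---
    g_rows = []
    for condition in ("HRIS", "LRIS"):
        for feat in ("tft_ms", "pupil_um"):
            sub = features[(features["condition"] == condition) & features["qc_pass"]]
            a = sub.loc[sub["group"] == "ASD", feat].dropna()
            b = sub.loc[sub["group"] == "TD", feat].dropna()
            t, df, p = two_sample_t(a, b)
            g_rows.append((condition, feat, len(a), len(b),
                           float(a.mean()), float(b.mean()), t, df, p))
    group_tests = pd.DataFrame(
        g_rows, columns=["condition", "feature", "n_asd", "n_td",
                         "mean_asd", "mean_td", "t", "df", "p"])
    # --- correlations (ASD group, HRIS): connectivity x ET x ADOS ---
    wpli = pd.read_csv(out / "planted_edge_wpli.csv")
    wide = features[features["condition"] == "HRIS"].merge(wpli, on="subject_id")
    wide = wide.merge(subjects, on="subject_id", suffixes=("", "_s"))
    asd = wide[wide["group"] == "ASD"].rename(columns={"planted_edge_wpli": "wpli"})
    pairs = [("wpli", "tft_ms"), ("wpli", "pupil_um"),
             ("wpli", "ados_total"), ("wpli", "rrb_score"), ("wpli", "sa_score"),
             ("tft_ms", "ados_total"), ("tft_ms", "rrb_score")]
    have_ados = asd["ados_total"].notna().sum() >= 3
    if not have_ados:
        pairs = [p for p in pairs if "ados" not in p[1] and "score" not in p[1]]
    correlations = pearson_fdr(asd, pairs) if len(asd) >= 3 else None
    # --- ROC: ET features separating ASD from TD under HRIS ---
    roc_rows = []
    hris = features[(features["condition"] == "HRIS") & features["qc_pass"]]
    for feat in ("tft_ms", "pupil_um"):
        sub = hris.dropna(subset=[feat])
        y = (sub["group"] == "ASD").astype(int).to_numpy()
        if 0 < y.sum() < y.size:
            r = roc_analysis(sub[feat].to_numpy(), y, seed=seed)
            roc_rows.append((feat, r.auc, r.ci_lower, r.ci_upper, r.cutoff,
                             r.cutoff_sensitivity, r.cutoff_specificity))
    roc = pd.DataFrame(roc_rows, columns=["feature", "auc", "ci_lower", "ci_upper",
                                          "cutoff", "sensitivity", "specificity"])
    build_report(out / "report", group_tests=group_tests,
                 correlations=correlations, roc=roc,
                 meta={"seed": seed, "ados_available": bool(have_ados)})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "connectivity": _stage_connectivity,
    "nbs": _stage_nbs,
    "nbs_predict": _stage_nbs_predict,
    "et_features": _stage_et_features,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the enabled stages in order and write a manifest.

    The manifest records the config hash, the seed fan-out and a checksum per
    output file; rerunning with the same config reproduces it bit for bit.
    A stage failure halts the run with the stage named; outputs of completed
    stages are retained.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    for stage in config.stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("stage %s (seed %d)", stage, seeds[stage])
        try:
            _STAGE_FUNCS[stage](config, out, seeds[stage])
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(config.stages),
        "checksums": rio.checksum_tree(out),
    }
    rio.write_json(manifest, out / "manifest.json")
    return out
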