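"""End-to-end driver: preprocess -> microstates + spectra -> merge -> stats.

`run_pipeline` is a pure function of (recordings, clinical table, config,
seed): given the same inputs it writes byte-identical outputs. Clustering is
group-level — every subject's retained GFP-peak maps are pooled and one
template set is fitted for the whole sample, then back-fitted per subject.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core import EEGRecording, EpochSet
from .microstate import (
    MicrostateModel,
    backfit,
    collect_peak_maps,
    compute_gev,
    compute_gfp,
    microstate_metrics,
    modified_kmeans,
    select_k,
    transition_matrix,
)
from .preprocess import preprocess_pipeline
from .spectral import SpectralSettings, subject_spectral_fit
from .stats import build_report
from .synth import ABC_SUBSCALES, SRS_SUBSCALES, Cohort, CohortSpec, simulate_cohort

__all__ = ["PipelineResult", "run_pipeline", "preprocess_cohort", "fit_group_model",
           "subject_features", "simulate_from_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    model: MicrostateModel
    k_table: pd.DataFrame | None
    features: pd.DataFrame
    report: dict[str, pd.DataFrame]
    manifest: dict


def simulate_from_config(cfg: RunConfig) -> Cohort:
    spec = CohortSpec(
        n_per_group=cfg.simulate.n_per_group,
        n_channels=cfg.simulate.n_channels,
        fs=cfg.simulate.fs,
        duration_s=cfg.simulate.duration_s,
        k=cfg.simulate.k,
        snr=cfg.simulate.snr,
        seed=cfg.seed,
    )
    return simulate_cohort(spec, with_eeg=True)


def preprocess_cohort(
    recordings: dict[str, EEGRecording], cfg: RunConfig,
    neighbor_map: dict[str, list[str]] | None = None,
) -> dict[str, EpochSet]:
    p = cfg.preprocess
    out = {}
    for sid, rec in recordings.items():
        out[sid] = preprocess_pipeline(
            rec,
            neighbor_map=neighbor_map,
            notch_hz=p.notch_hz if p.notch_hz > 0 else None,
            band=(p.band_low, p.band_high),
            epoch_length_s=p.epoch_length_s,
            bad_channel_uv=p.bad_channel_uv,
            artifact_amplitude_uv=p.artifact_amplitude_uv,
            artifact_gradient_uv_per_ms=p.artifact_gradient_uv_per_ms,
        )
    return out


def fit_group_model(
    epoch_sets: dict[str, EpochSet], cfg: RunConfig
) -> tuple[MicrostateModel, pd.DataFrame | None, np.ndarray]:
    """Pool per-subject GFP-peak maps and fit one model for the sample.

    Fits every k in the configured range and selects by the normalized
    GEV/CV table unless ``fixed_k`` pins the solution. Templates are ordered
    by descending per-state GEV on the pooled peak maps and named A, B, ...
    """
    m = cfg.microstate
    pooled = []
    for sid in sorted(epoch_sets):
        pooled.append(
            collect_peak_maps(
                epoch_sets[sid],
                min_interval_ms=m.min_interval_ms,
                min_peak_uv=m.min_peak_uv,
                sd_band=m.sd_band,
                max_peaks=m.n_peaks,
                seed=cfg.seed,
            )
        )
    peak_maps = np.concatenate(pooled, axis=0)

    models = {}
    for k in range(m.k_min, m.k_max + 1):
        models[k] = modified_kmeans(
            peak_maps, k, n_init=m.n_init, max_iter=m.max_iter, seed=cfg.seed + k
        )
    k_table = None
    if m.fixed_k:
        chosen = m.fixed_k
        if chosen not in models:
            models[chosen] = modified_kmeans(
                peak_maps, chosen, n_init=m.n_init, max_iter=m.max_iter, seed=cfg.seed + chosen
            )
    else:
        chosen, k_table = select_k(models)
    model = models[chosen]

    # deterministic ordering: descending per-state GEV on the pooled maps
    A = (peak_maps - peak_maps.mean(axis=1, keepdims=True)) @ model.templates.T
    labels = np.argmax(A**2, axis=1)
    _, per_state = compute_gev(model.templates, peak_maps, labels)
    order = np.argsort(-per_state)
    model = MicrostateModel(
        templates=model.templates[order], gev=model.gev, cv=model.cv
    )
    return model, k_table, peak_maps


def subject_features(
    sid: str,
    epochs: EpochSet,
    model: MicrostateModel,
    cfg: RunConfig,
) -> dict[str, float]:
    """Back-fit + temporal parameters + TP entries + spectral fit for one subject."""
    m = cfg.microstate
    s = cfg.spectral
    labels = backfit(model, epochs, min_segment_ms=m.min_segment_ms)
    gfps = [compute_gfp(e) for e in epochs]
    all_maps = epochs.concatenated()
    all_labels = np.concatenate(labels)
    all_gfp = np.concatenate(gfps)
    total_gev, per_state = compute_gev(model.templates, all_maps, all_labels, all_gfp)
    metrics = microstate_metrics(
        labels, gfps, epochs.fs, model.k, per_state_gev=per_state,
        state_names=model.label_names,
    )
    tp, _ = transition_matrix(labels, model.k)

    row: dict[str, float] = {"id": sid}
    for state in metrics.index:
        for col in ("coverage", "occurrence", "duration", "mean_gfp", "gev"):
            row[f"{col}_{state}"] = float(metrics.loc[state, col])
    row["gev_total"] = total_gev
    names = model.label_names
    for i in range(model.k):
        for j in range(model.k):
            if i != j:
                row[f"tp_{names[i]}_{names[j]}"] = float(tp[i, j])

    settings = SpectralSettings(
        fit_range=(s.fit_lo, s.fit_hi),
        peak_width_limits=(s.peak_width_lo, s.peak_width_hi),
        max_n_peaks=s.max_n_peaks,
        peak_threshold=s.peak_threshold,
        min_peak_height=s.min_peak_height,
        alpha_band=(s.alpha_lo, s.alpha_hi),
        welch_window_s=s.welch_window_s,
        welch_overlap=s.welch_overlap,
    )
    fit, alpha = subject_spectral_fit(epochs, settings)
    row.update(
        {
            "alpha_power": alpha.alpha_power,
            "alpha_cf": alpha.alpha_cf,
            "aperiodic_offset": fit.offset,
            "aperiodic_exponent": fit.exponent,
            "spectral_r2": fit.r_squared,
            "spectral_residual": fit.residual_error,
        }
    )
    return row


def run_pipeline(
    cfg: RunConfig,
    cohort: Cohort | None = None,
    out_dir: str | Path | None = None,
    neighbor_map: dict[str, list[str]] | None = None,
) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle."""
    if cohort is None:
        cohort = simulate_from_config(cfg)
    if not cohort.recordings:
        raise ValueError("cohort has no recordings; nothing to analyze")

    epoch_sets = preprocess_cohort(cohort.recordings, cfg, neighbor_map)
    empty = [sid for sid, es in epoch_sets.items() if len(es) == 0]
    for sid in empty:
        logger.warning("subject %s lost all epochs; dropped", sid)
        del epoch_sets[sid]
    if not epoch_sets:
        raise ValueError("no subject retained any epochs")

    model, k_table, _ = fit_group_model(epoch_sets, cfg)

    rows = [subject_features(sid, epoch_sets[sid], model, cfg) for sid in sorted(epoch_sets)]
    features = pd.DataFrame(rows)
    features = features.merge(cohort.subjects, on="id", how="left")
    if not cohort.clinical.empty:
        features = features.merge(cohort.clinical, on="id", how="left")
    features = features.set_index("id")

    clinical_scores = [
        c for c in features.columns if c.startswith(("abc_", "srs_"))
    ]
    report = build_report(
        features,
        states=model.label_names,
        clinical_scores=clinical_scores,
        fdr_family_size=cfg.stats.fdr_family_size,
        ms_instance_limit=cfg.stats.ms_instance_limit,
        tp_instance_limit=cfg.stats.tp_instance_limit,
    )

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "n_subjects": len(epoch_sets),
        "k": model.k,
        "gev": model.gev,
        "epochs_kept": {sid: len(es) for sid, es in sorted(epoch_sets.items())},
        "epochs_rejected": {sid: es.rejected_count for sid, es in sorted(epoch_sets.items())},
        "ms_excluded": int(report["exclusions"]["ms_excluded"].sum()),
        "tp_excluded": int(report["exclusions"]["tp_excluded"].sum()),
    }

    result = PipelineResult(
        model=model, k_table=k_table, features=features, report=report, manifest=manifest
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "templates.tsv", result.model.templates, delimiter="\t")
    result.features.to_csv(out_dir / "features.tsv", sep="\t")
    for name, df in result.report.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t")
    if result.k_table is not None:
        result.k_table.to_csv(out_dir / "k_selection.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
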