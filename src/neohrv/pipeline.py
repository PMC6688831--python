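"""Pipeline orchestration: configuration, feature extraction, analysis.

``extract_features`` turns one screened recording into long-format feature
rows for all four window-length classes; ``run_extract`` does so for a whole
cohort (from a manifest of RR CSV files or an in-memory collection);
``run_analyze`` computes the robustness and structure statistics from the
feature table.  Per-window feature failures become explicit missing values
and are recorded in an error manifest — a run never aborts because one
window was degenerate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import hvg, linear, nonlinear, robustness, structure
from .errors import InsufficientDataError, NeoHRVError
from .rr import (
    LENGTH_CLASSES,
    WINDOW_SPECS,
    RRSeries,
    extract_windows,
    pma_class,
    read_rr_series,
    screen_rr,
)

__all__ = [
    "FEATURE_NAMES",
    "PipelineConfig",
    "compute_window_features",
    "extract_features",
    "run_extract",
    "run_analyze",
]

log = logging.getLogger("neohrv")

#: The 20 HRV features, in canonical column order.
FEATURE_NAMES = (
    "mean",
    "sd",
    "rmssd",
    "lf",
    "hf",
    "lf_hf",
    "sd1",
    "sd2",
    "sd2_sd1",
    "sampen",
    "alpha1",
    "alpha2",
    "dc",
    "ac",
    "z1",
    "z2",
    "z3",
    "z4",
    "z5",
    "z6",
)

#: Features indexing short-term (beat-to-beat) variability.
SHORT_TERM_FEATURES = ("rmssd", "sd1", "hf")

_MIN_WINDOW_BEATS = 20


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, loadable from YAML."""

    outdir: str = "neohrv_out"
    manifest: str | None = None  # cohort manifest CSV (extract from files)
    seed: int = 0
    # screening
    screen: bool = True
    low_ms: float = 200.0
    high_ms: float = 750.0
    max_rel_jump: float = 0.5
    max_bad_frac: float = 0.2
    # windowing / features
    length_classes: tuple[str, ...] = LENGTH_CLASSES
    features: tuple[str, ...] = FEATURE_NAMES
    ar_order: int = 12
    ar_method: str = "burg"
    resample_hz: float = 4.0
    sampen_m: int = 3
    sampen_r: float = 0.25
    # statistics
    bias_reference: str = "mean"
    boxcox_policy: str = "auto"
    k_range: tuple[int, ...] = tuple(range(2, 11))
    pca_per_length: bool = True
    # simulation (used by the `simulate` subcommand)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise NeoHRVError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for name in ("length_classes", "features", "k_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def compute_window_features(
    window: RRSeries, config: PipelineConfig | None = None
) -> dict[str, float]:
    """All requested features of one window; failures map to NaN."""
    cfg = config or PipelineConfig()
    out: dict[str, float] = {f: float("nan") for f in cfg.features}
    if window.n_beats < _MIN_WINDOW_BEATS:
        raise InsufficientDataError(
            f"window has {window.n_beats} beats (< {_MIN_WINDOW_BEATS})"
        )

    def _try(names, fn):
        wanted = [n for n in names if n in out]
        if not wanted:
            return
        try:
            vals = fn()
        except (NeoHRVError, ArithmeticError, np.linalg.LinAlgError) as exc:
            log.debug("feature(s) %s failed: %s", wanted, exc)
            return
        out.update({n: vals[n] for n in wanted})

    def _linear():
        td = linear.time_domain(window)
        return {"mean": td.mean_ms, "sd": td.sd_ms, "rmssd": td.rmssd_ms}

    def _spectral():
        uni = linear.resample_tachogram(window, cfg.resample_hz)
        sp = linear.ar_band_powers(uni, order=cfg.ar_order, method=cfg.ar_method)
        return {"lf": sp.lf_ms2, "hf": sp.hf_ms2, "lf_hf": sp.lf_hf}

    def _poincare():
        pc = nonlinear.poincare(window)
        return {"sd1": pc.sd1_ms, "sd2": pc.sd2_ms, "sd2_sd1": pc.ratio}

    def _sampen():
        se = nonlinear.sample_entropy(window, m=cfg.sampen_m, r_frac=cfg.sampen_r)
        return {"sampen": se.sampen}

    def _dfa():
        d = nonlinear.dfa(window)
        return {"alpha1": d.alpha1, "alpha2": d.alpha2}

    def _prsa():
        p = nonlinear.prsa(window)
        return {"dc": p.dc_ms, "ac": p.ac_ms}

    def _motifs():
        prof = hvg.motif_profile_4(window)
        return dict(zip(hvg.MOTIF_NAMES, prof.z))

    _try(("mean", "sd", "rmssd"), _linear)
    _try(("lf", "hf", "lf_hf"), _spectral)
    _try(("sd1", "sd2", "sd2_sd1"), _poincare)
    _try(("sampen",), _sampen)
    _try(("alpha1", "alpha2"), _dfa)
    _try(("dc", "ac"), _prsa)
    _try(hvg.MOTIF_NAMES, _motifs)
    return out


def extract_features(
    recording: RRSeries,
    recording_id: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Long-format feature rows of one recording at every length class."""
    cfg = config or PipelineConfig()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-recording warnings -> log
        for lc in cfg.length_classes:
            wins = extract_windows(recording, WINDOW_SPECS[lc])
            if not wins:
                log.warning("%s: recording too short for %s windows", recording_id, lc)
                continue
            for w in wins:
                try:
                    feats = compute_window_features(w, cfg)
                except InsufficientDataError as exc:
                    log.warning("%s %s[%s]: %s", recording_id, lc, w.window_index, exc)
                    continue
                for name, value in feats.items():
                    rows.append(
                        {
                            "subject_id": recording.subject_id,
                            "ga_weeks": recording.ga_weeks,
                            "pma_weeks": recording.pma_weeks,
                            "pma_class": pma_class(recording.pma_weeks),
                            "recording_id": recording_id,
                            "length_class": lc,
                            "window_index": w.window_index,
                            "feature": name,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows, columns=robustness.FEATURE_TABLE_COLUMNS)


def run_extract(
    recordings: Mapping[str, RRSeries] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Screen and extract the full cohort into one feature table.

    ``recordings`` maps recording id to series; alternatively
    ``config.manifest`` names a cohort manifest CSV with columns
    ``subject_id, ga_weeks, recording_week, pma_weeks, rr_file`` whose RR
    files are loaded relative to the manifest's directory.
    """
    cfg = config or PipelineConfig()
    if recordings is None:
        if cfg.manifest is None:
            raise NeoHRVError("run_extract needs recordings or config.manifest")
        mpath = Path(cfg.manifest)
        manifest = pd.read_csv(mpath)
        recordings = {}
        for _, row in manifest.iterrows():
            rec_id = Path(str(row["rr_file"])).stem
            recordings[rec_id] = read_rr_series(
                mpath.parent / str(row["rr_file"]),
                subject_id=str(row["subject_id"]),
                ga_weeks=float(row["ga_weeks"]),
                pma_weeks=float(row["pma_weeks"]),
            )
    tables = []
    for rec_id, rec in recordings.items():
        if cfg.screen:
            try:
                rec, report = screen_rr(
                    rec, cfg.low_ms, cfg.high_ms, cfg.max_rel_jump, cfg.max_bad_frac
                )
                if report.n_flagged:
                    log.info(
                        "%s: %d/%d beats interpolated",
                        rec_id, report.n_flagged, report.n_beats,
                    )
            except NeoHRVError as exc:
                log.error("%s excluded by screening: %s", rec_id, exc)
                continue
        tables.append(extract_features(rec, rec_id, cfg))
    if not tables:
        raise NeoHRVError("no recordings survived extraction")
    return pd.concat(tables, ignore_index=True)


def _feature_matrix(table: pd.DataFrame, length_class: str | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot the long table to (recording × feature), window replicates
    averaged; returns the matrix and matching GA/PMA supplementary frame."""
    df = table if length_class is None else table[table["length_class"] == length_class]
    wide = (
        df.pivot_table(
            index="recording_id", columns="feature", values="value", aggfunc="mean"
        )
        .reindex(columns=[f for f in FEATURE_NAMES if f in set(df["feature"])])
    )
    meta = (
        df.groupby("recording_id")[["ga_weeks", "pma_weeks"]].first().loc[wide.index]
    )
    meta.columns = ["GA", "PMA"]
    return wide, meta


def run_analyze(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Full statistics bundle from a feature table.

    Returns a dict with keys ``mad`` (MADTable), ``lme`` (feature ->
    LMEResult), ``bias_loa`` (table), ``pca`` (length class -> PCAResult),
    ``clusters`` (length class -> ClusterResult) and ``errors`` (stage
    failures; the bundle is partial rather than the run aborting).
    """
    cfg = config or PipelineConfig()
    robustness.validate_feature_table(table)
    bundle: dict = {"errors": []}
    features = [f for f in FEATURE_NAMES if f in set(table["feature"])]

    def _stage(key, fn):
        try:
            bundle[key] = fn()
        except Exception as exc:  # noqa: BLE001 - collected in error manifest
            log.error("analysis stage %s failed: %s", key, exc)
            bundle["errors"].append({"stage": key, "error": str(exc)})

    _stage("mad", lambda: robustness.mad_profile(table))

    def _lmes():
        out = {}
        for f in features:
            try:
                out[f] = robustness.lme_length_effect(
                    table, f, transform=cfg.boxcox_policy
                )
            except (NeoHRVError, np.linalg.LinAlgError) as exc:
                log.warning("LME failed for %s: %s", f, exc)
                bundle["errors"].append({"stage": f"lme:{f}", "error": str(exc)})
        return out

    _stage("lme", _lmes)

    def _bias():
        parts = []
        for f in features:
            try:
                parts.append(
                    robustness.bias_loa(table, f, reference=cfg.bias_reference)
                )
            except (NeoHRVError, np.linalg.LinAlgError) as exc:
                log.warning("bias/LoA failed for %s: %s", f, exc)
                bundle["errors"].append({"stage": f"bias:{f}", "error": str(exc)})
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    _stage("bias_loa", _bias)

    lengths = (
        [lc for lc in LENGTH_CLASSES if lc in set(table["length_class"])]
        if cfg.pca_per_length
        else [None]
    )
    pcas, clusters = {}, {}
    for lc in lengths:
        key = lc or "all"
        try:
            wide, meta = _feature_matrix(table, lc)
            pcas[key] = structure.pca_features(wide, supplementary=meta)
            clusters[key] = structure.cluster_features(
                wide, k_range=cfg.k_range, seed=cfg.seed
            )
        except Exception as exc:  # noqa: BLE001
            log.warning("structure analysis failed for %s: %s", key, exc)
            bundle["errors"].append({"stage": f"structure:{key}", "error": str(exc)})
    bundle["pca"] = pcas
    bundle["clusters"] = clusters
    return bundle
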