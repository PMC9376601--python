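"""Cohort-level statistics: group separation, severity correlation, and
the sensor peak-over-background comparison.

ROC/AUC here is the probability that a randomly chosen patient outscores a
randomly chosen control (ties counted 1/2), computed from ranks — the
Mann-Whitney form — which is exactly equal to the trapezoidal area under
the empirical ROC curve.  Severity correlation is an ordinary Pearson r
(with the least-squares line for plotting).  The peak-over-background
ratio summarizes a sensor's in-band SNR: the spectral peak divided by the
median in-band level away from the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import DataError, ParameterError
from .index import IndexConfig, score_recording, to_decibel
from .io import ControlReference, write_control_reference
from .spectral import SpectralConfig, Spectrum, segment_windows, window_ratio

__all__ = [
    "RocResult",
    "CorrelationResult",
    "roc_auc",
    "correlate_severity",
    "peak_over_background",
    "score_cohort",
    "cohort_report",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    slope: float
    intercept: float


def roc_auc(scores_pos, scores_neg) -> RocResult:
    """Rank-based AUC (ties 1/2) with the empirical ROC curve.

    The rank form equals brute-force pair counting exactly and the
    trapezoidal area under the returned curve to float precision.
    """
    pos = np.asarray(list(scores_pos), dtype=float)
    neg = np.asarray(list(scores_neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ParameterError("both score lists must be nonempty")
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[: pos.size].sum()
    auc = (rank_sum_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, thresholds = _sk_roc_curve(labels, combined)
    return RocResult(
        auc=float(auc),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        n_pos=pos.size,
        n_neg=neg.size,
    )


def correlate_severity(scores, severities) -> CorrelationResult:
    """Pearson correlation of tremor scores against clinical severity."""
    x = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(severities), dtype=float)
    if x.size != y.size:
        raise ParameterError("scores and severities must have equal length")
    if x.size < 3:
        raise ParameterError("need at least three paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined: zero variance in an input")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def peak_over_background(
    spectrum: Spectrum,
    band: tuple[float, float] = (3.5, 10.0),
    exclude_hz: float = 1.0,
) -> float:
    """In-band peak divided by the in-band background level.

    Background = median of in-band values excluding bins within
    ``exclude_hz`` of the peak; at least 5 bins must remain outside the
    exclusion zone.  Being a ratio of two values of one spectrum, the
    statistic is invariant to spectrum scaling.
    """
    lo, hi = band
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ParameterError("band lies outside the frequency grid")
    freqs = spectrum.freqs[mask]
    values = spectrum.values[mask]
    k = int(np.argmax(values))
    peak_freq = freqs[k]
    bg_mask = np.abs(freqs - peak_freq) > exclude_hz
    if bg_mask.sum() < 5:
        raise ParameterError(
            "band too narrow: fewer than 5 background bins outside the "
            f"±{exclude_hz} Hz exclusion zone"
        )
    background = float(np.median(values[bg_mask]))
    if background <= 0:
        raise DataError("background level is zero; ratio undefined")
    return float(values[k] / background)


def mean_ratio_spectrum(
    recording,
    channel: str = "la_x",
    spectral_config: SpectralConfig | None = None,
) -> Spectrum:
    """Average oscillatory-ratio spectrum of one channel across windows.

    Summarizes a whole recording in one spectrum for sensor-to-sensor
    comparisons (peak-over-background, spectral-shape correlation).
    """
    spectral_config = spectral_config or SpectralConfig()
    blocks = segment_windows(
        recording.channels[channel], recording.rate, spectral_config
    )
    ratios = [window_ratio(b, recording.rate, spectral_config) for _, b in blocks]
    return Spectrum(
        ratios[0].freqs,
        np.mean([r.values for r in ratios], axis=0),
        "ratio",
        channel=channel,
    )


def score_cohort(
    cohort,
    spectral_config: SpectralConfig | None = None,
    index_config: IndexConfig | None = None,
) -> pd.DataFrame:
    """Run the scoring pipeline on every recording of a simulated cohort.

    Returns one row per subject with a ``score_<sensor>_<position>``
    column per recording condition (raw index scale, not dB).
    """
    rows = {}
    for params in cohort.subjects:
        rows[params.subject_id] = {
            "subject_id": params.subject_id,
            "group": params.group,
            "severity": params.severity,
        }
    for (subject_id, sensor, position), rec in cohort.recordings.items():
        score = score_recording(rec, spectral_config, index_config)
        rows[subject_id][f"score_{sensor}_{position}"] = score.index
    return pd.DataFrame(list(rows.values()))


def _score_columns(table: pd.DataFrame) -> list[tuple[str, str, str]]:
    cols = []
    for col in table.columns:
        if col.startswith("score_"):
            _, sensor, position = col.split("_", 2)
            cols.append((col, sensor, position))
    return cols


def cohort_report(
    table: pd.DataFrame,
    control_ref: ControlReference | None = None,
    config_hash: str = "",
) -> dict:
    """Assemble per-condition separation and correlation statistics.

    For each score column (sensor x position): AUC of each patient group
    against controls and Pearson r² of patient scores against severity;
    plus every subject's dB-normalized score and, when both sensors are
    present, a Wilcoxon signed-rank comparison of paired finger/phone
    scores per position.
    """
    cols = _score_columns(table)
    if not cols:
        raise DataError("table has no score columns")
    groups = set(table["group"])
    if "CTRL" not in groups:
        raise DataError("cohort report requires at least one control subject")
    if not groups - {"CTRL"}:
        raise DataError("cohort report requires at least one patient")
    ctrl = table[table["group"] == "CTRL"]
    report: dict = {"auc": {}, "r2": {}, "scores_db": []}
    control_means = {}
    for col, sensor, position in cols:
        control_means[col] = (
            control_ref.mean_index if control_ref is not None else float(ctrl[col].mean())
        )
    for group in sorted(groups - {"CTRL"}):
        sub = table[table["group"] == group]
        report["auc"][group] = {}
        for col, sensor, position in cols:
            report["auc"][group].setdefault(sensor, {})[position] = roc_auc(
                sub[col], ctrl[col]
            ).auc
    # severity is correlated against dB (log) scores, the scale on which
    # tremor indices are compared across subjects
    patients = table[table["group"] != "CTRL"]
    for col, sensor, position in cols:
        db_scores = 10.0 * np.log10(patients[col] / control_means[col])
        try:
            r2 = correlate_severity(db_scores, patients["severity"]).r2
        except (ParameterError, DataError):
            r2 = None  # fewer than 3 patients, or degenerate severities
        report["r2"].setdefault(sensor, {})[position] = r2
    for _, row in table.iterrows():
        for col, sensor, position in cols:
            db = 10.0 * np.log10(row[col] / control_means[col])
            report["scores_db"].append(
                {
                    "subject_id": row["subject_id"],
                    "group": row["group"],
                    "sensor": sensor,
                    "position": position,
                    "db": float(db),
                }
            )
    sensors = sorted({s for _, s, _ in cols})
    if sensors == ["finger", "phone"]:
        report["wilcoxon_finger_vs_phone"] = {}
        for position in sorted({p for _, _, p in cols}):
            a = table[f"score_finger_{position}"]
            b = table[f"score_phone_{position}"]
            if len(a) >= 5 and not np.allclose(a, b):
                stat = stats.wilcoxon(a, b)
                report["wilcoxon_finger_vs_phone"][position] = float(stat.pvalue)
    if config_hash:
        report["pipeline_config_hash"] = config_hash
    return report


def control_reference_from_table(
    table: pd.DataFrame,
    sensor: str = "phone",
    position: str = "P1",
    band: tuple[float, float] = (3.5, 10.0),
    config_hash: str = "",
) -> ControlReference:
    """Build a control reference from a scored cohort's control rows."""
    ctrl = table[table["group"] == "CTRL"]
    if ctrl.empty:
        raise DataError("no control subjects in table")
    return write_control_reference(
        ctrl[f"score_{sensor}_{position}"].tolist(),
        band=band,
        pipeline_config_hash=config_hash,
    )
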