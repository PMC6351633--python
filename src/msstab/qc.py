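"""Artifact-scan detection and consensus-spectrum construction.

Ambient-ionization sources (electrospray from tissue in particular) emit
occasional unreliable scans — spray instabilities show up as anomalous
local maxima or minima of the total ion current, and such scans corrupt
any profile obtained by blindly summing a whole measurement.  The filter
here scores every scan by its cosine similarity to a robust reference —
the mean of the median-smoothed series, which individual artifact scans
cannot pull — applies a significance threshold, and aggregates only the
surviving scans into the measurement's consensus spectrum.

Thresholding
------------
A fixed cutoff in [0, 1] can be given.  The default ``"auto"`` rule is a
detached-gap rule on the log-deviation scale.  With ``d_i = 1 − score_i``
over the non-degenerate scans and ``m = median(log d)``, the sorted
``log d`` values are scanned upward for the lowest gap such that

* everything above the gap has ``log d > m/3`` — the scan has lost at
  least two-thirds of the log-distance between the typical deviation and
  total dissimilarity (``d = 1``), so it is far closer to "unrelated
  spectrum" than to the measurement's own score mass; and
* the gap itself exceeds ``ln 2`` — the rejected scans are detached from
  the better-scoring scans by at least a factor-of-two jump in deviation,
  not merely the tail of their distribution.

If such a gap exists the threshold is the gap midpoint mapped back to the
score scale (``1 − exp(cut)``); otherwise no scan is score-rejected
(threshold 0).  The keep rule is ``score >= threshold``; degenerate
(all-zero) scans are always rejected.

The gap condition is what makes the rule safe on both kinds of good-scan
score distributions this metric produces: tightly clustered chi-square-
like deviations (strongly right-skewed, so a plain location–scale fence
clips the tail) and bimodal ones (a dominant peak sitting near a bin edge
hops bins scan to scan under m/z jitter, splitting good scans into two
detached clusters — which still share their remaining peaks with the
reference and so stay far below the ``m/3`` line).  Genuine foreign scans
sit near total dissimilarity, beyond both conditions.  A scan whose only
anomaly is its overall intensity scale (a TIC spike or dropout with an
intact profile) is invisible to any scale-invariant score by
construction; screen the TIC trace for those.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, OutlierMixin

from .binning import BinnedSeries, BinnedSpectrum
from .similarity import cosine
from .smoothing import SmoothingConfig, aggregate_spectrum, moving_median

__all__ = [
    "ScanQCResult",
    "ArtifactScanFilter",
    "score_scans",
    "auto_threshold",
    "apply_threshold",
    "consensus_spectrum",
    "write_qc_report",
    "write_consensus",
]

_LOG_FLOOR = 1e-15  # deviations below this are numerically "identical scans"
_MIN_GAP = float(np.log(2.0))  # rejected scans must be a factor >=2 away in deviation


@dataclasses.dataclass
class ScanQCResult:
    """Per-scan QC scores and keep/reject decision for one measurement.

    ``scores[i]`` is the cosine similarity of scan i to the smoothed
    reference; ``degenerate_flags`` marks all-zero scans (score 0 by
    convention, always rejected).  ``threshold`` is None until a threshold
    has been applied; afterwards ``keep_mask[i] = scores[i] >= threshold
    and not degenerate_flags[i]``.
    """

    scores: np.ndarray
    degenerate_flags: np.ndarray
    reference: BinnedSpectrum
    smoothing: SmoothingConfig
    threshold: float | None = None
    threshold_rule: str | None = None
    keep_mask: np.ndarray | None = None

    @property
    def n_scans(self) -> int:
        return int(self.scores.size)

    @property
    def n_kept(self) -> int:
        if self.keep_mask is None:
            raise ValueError("no threshold applied yet")
        return int(self.keep_mask.sum())

    @property
    def rejected_indices(self) -> np.ndarray:
        if self.keep_mask is None:
            raise ValueError("no threshold applied yet")
        return np.flatnonzero(~self.keep_mask)


def score_scans(series: BinnedSeries, smoothing: SmoothingConfig | None = None) -> ScanQCResult:
    """Score every scan against the measurement's smoothed reference.

    The reference is the mean of the moving-median-smoothed series; the
    score is the cosine measure of the raw binned scan against it.  No
    threshold is applied here (see :func:`apply_threshold`).
    """
    smoothing = smoothing or SmoothingConfig()
    smoothed = moving_median(series, smoothing)
    reference = aggregate_spectrum(smoothed, mode="mean")
    scores = np.empty(len(series))
    degenerate = np.zeros(len(series), dtype=bool)
    for i, spec in enumerate(series):
        if spec.nnz == 0:
            scores[i] = 0.0
            degenerate[i] = True
        else:
            scores[i] = cosine(spec, reference)
    return ScanQCResult(
        scores=scores,
        degenerate_flags=degenerate,
        reference=reference,
        smoothing=smoothing,
    )


def auto_threshold(scores: np.ndarray, degenerate_flags: np.ndarray | None = None) -> float:
    """Automatic score cutoff by the detached-gap rule (see module
    docstring), in [0, 1]; 0 when no detached high-deviation group exists."""
    scores = np.asarray(scores, dtype=float)
    if degenerate_flags is not None:
        scores = scores[~np.asarray(degenerate_flags, dtype=bool)]
    if scores.size == 0:
        return 0.0
    log_dev = np.sort(np.log(np.clip(1.0 - scores, _LOG_FLOOR, None)))
    med = np.median(log_dev)
    for j in range(1, log_dev.size):
        if log_dev[j] > med / 3.0 and log_dev[j] - log_dev[j - 1] > _MIN_GAP:
            cut = (log_dev[j] + log_dev[j - 1]) / 2.0
            return float(np.clip(1.0 - np.exp(cut), 0.0, 1.0))
    return 0.0


def apply_threshold(r: ScanQCResult, threshold: float | str = "auto") -> ScanQCResult:
    """Apply a significance threshold to computed scores.

    ``threshold`` is either a fixed value in [0, 1] or ``"auto"`` for the
    robust rule.  Returns a new :class:`ScanQCResult` with ``keep_mask``
    set; degenerate scans are rejected regardless of the threshold.
    """
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"threshold must be a float or 'auto', got {threshold!r}")
        value = auto_threshold(r.scores, r.degenerate_flags)
        rule = "auto"
    else:
        value = float(threshold)
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {value}")
        rule = "fixed"
    keep = (r.scores >= value) & ~r.degenerate_flags
    return dataclasses.replace(
        r, threshold=value, threshold_rule=rule, keep_mask=keep
    )


def consensus_spectrum(series: BinnedSeries, r: ScanQCResult, mode: str = "mean") -> BinnedSpectrum:
    """Aggregate the kept scans only into the measurement's consensus
    profile (sum or mean over surviving scans)."""
    if r.keep_mask is None:
        raise ValueError("apply a threshold before building a consensus")
    if r.keep_mask.size != len(series):
        raise ValueError("QC result does not match series length")
    if not r.keep_mask.any():
        raise ValueError("all scans rejected")
    kept = BinnedSeries(
        series.label, series.config, series.matrix[np.flatnonzero(r.keep_mask)]
    )
    return aggregate_spectrum(kept, mode=mode)


def write_qc_report(r: ScanQCResult, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write the per-scan QC table (scan_index, score, degenerate, kept)
    and a JSON summary of the thresholding parameters and counts."""
    csv_path = Path(csv_path)
    kept = r.keep_mask if r.keep_mask is not None else np.ones(r.n_scans, dtype=bool)
    pd.DataFrame(
        {
            "scan_index": np.arange(r.n_scans),
            "score": r.scores,
            "degenerate": r.degenerate_flags.astype(int),
            "kept": kept.astype(int),
        }
    ).to_csv(csv_path, index=False)
    summary = {
        "threshold": r.threshold,
        "rule": r.threshold_rule,
        "window": r.smoothing.window,
        "step": r.smoothing.step,
        "n_scans": r.n_scans,
        "n_kept": int(kept.sum()),
        "n_rejected": int((~kept).sum()),
        "n_degenerate": int(r.degenerate_flags.sum()),
    }
    jp = Path(json_path) if json_path else csv_path.with_suffix(".json")
    jp.write_text(json.dumps(summary, indent=2))


def write_consensus(spec: BinnedSpectrum, path: str | Path) -> None:
    """Write a consensus spectrum as a two-column peak list
    (bin-center m/z, intensity)."""
    pd.DataFrame(
        {
            "mz": spec.config.bin_center(spec.indices),
            "intensity": spec.data,
        }
    ).to_csv(path, index=False)


class ArtifactScanFilter(OutlierMixin, BaseEstimator):
    """Outlier-scan detector in the scikit-learn idiom.

    Parameters
    ----------
    window, step : int
        Moving-median parameters for the reference spectrum.
    threshold : float or "auto"
        Significance threshold on the cosine score.

    After ``fit(series)`` (a :class:`BinnedSeries`):

    Attributes
    ----------
    scores_ : ndarray
        Per-scan cosine similarity to the smoothed reference.
    threshold_ : float
        The applied cutoff.
    keep_mask_ : ndarray of bool
        True for scans retained.
    degenerate_flags_ : ndarray of bool
    reference_ : BinnedSpectrum
    result_ : ScanQCResult
    """

    def __init__(self, window: int = 51, step: int = 51, threshold: float | str = "auto"):
        self.window = window
        self.step = step
        self.threshold = threshold

    def fit(self, X: BinnedSeries, y=None) -> "ArtifactScanFilter":
        if not isinstance(X, BinnedSeries):
            raise TypeError("ArtifactScanFilter expects a BinnedSeries")
        res = score_scans(X, SmoothingConfig(self.window, self.step))
        res = apply_threshold(res, self.threshold)
        self.result_ = res
        self.scores_ = res.scores
        self.threshold_ = res.threshold
        self.keep_mask_ = res.keep_mask
        self.degenerate_flags_ = res.degenerate_flags
        self.reference_ = res.reference
        return self

    def predict(self, X: BinnedSeries | None = None) -> np.ndarray:
        """+1 for kept scans, −1 for rejected, sklearn outlier convention.

        With no argument, returns the decision for the fitted series; with
        a series, scans are scored against the fitted reference and the
        fitted threshold is applied.
        """
        if not hasattr(self, "result_"):
            raise ValueError("fit the filter first")
        if X is None:
            keep = self.keep_mask_
        else:
            scores = np.array(
                [0.0 if s.nnz == 0 else cosine(s, self.reference_) for s in X]
            )
            degenerate = np.array([s.nnz == 0 for s in X])
            keep = (scores >= self.threshold_) & ~degenerate
        return np.where(keep, 1, -1)

    def consensus(self, X: BinnedSeries, mode: str = "mean") -> BinnedSpectrum:
        if not hasattr(self, "result_"):
            raise ValueError("fit the filter first")
        return consensus_spectrum(X, self.result_, mode=mode)
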