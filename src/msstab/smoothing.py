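"""Moving-median smoothing of a binned scan series along the time axis.

Each output spectrum replaces every bin with the median of that bin's
values over a window of consecutive scans.  Unlike a moving average, the
median rejects outliers outright: an artifact affecting at most
⌊window/2⌋ consecutive scans leaves the smoothed output untouched,
because the clean scans still hold the majority in every window.

Windows are leading (anchored at ``k·step``, not centered) and only full
windows are emitted, so output k covers input scans
``[k·step, k·step + window)`` and the output length is
``⌊(n − window)/step⌋ + 1``.  Edge windows over fewer than ``window``
scans would have different breakdown properties and are not produced.
Windows must be odd, which keeps the median a single order statistic.

Absent sparse entries count as zeros in the per-bin median: a bin present
in fewer than half of a window's scans has median 0 there (intensities
are nonnegative), so zeros never need to be materialized.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .binning import BinnedSeries, BinnedSpectrum

__all__ = [
    "SmoothingConfig",
    "MovingMedianSmoother",
    "moving_median",
    "n_windows",
    "window_spans",
    "aggregate_spectrum",
    "write_smoothed",
]


@dataclasses.dataclass(frozen=True)
class SmoothingConfig:
    """Moving-median parameters.

    window
        Odd number of consecutive scans per median (default 51, roughly one
        minute of acquisition at ~1 scan/s; 5, 7 and 21 are the other
        commonly useful sizes).
    step
        Shift between successive windows, in scans.  1 keeps maximal time
        detail; ``window`` (the default, paired with window 51) gives
        non-overlapping windows for sample-level profiling; ``window // 2 + 1``
        is the half-window compromise.
    """

    window: int = 51
    step: int = 51

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def n_windows(n_scans: int, cfg: SmoothingConfig) -> int:
    """Number of full windows: ⌊(n − window)/step⌋ + 1."""
    if n_scans < cfg.window:
        raise ValueError(
            f"series shorter than window ({n_scans} scans < window {cfg.window})"
        )
    return (n_scans - cfg.window) // cfg.step + 1


def window_spans(n_scans: int, cfg: SmoothingConfig) -> list[tuple[int, int]]:
    """Half-open source-scan span [k·step, k·step + window) per output."""
    return [
        (k * cfg.step, k * cfg.step + cfg.window)
        for k in range(n_windows(n_scans, cfg))
    ]


def _window_median(X: sp.csr_matrix, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin median of rows [lo, hi), zeros implicit.

    Only columns occupied somewhere in the window can have a nonzero
    median, so the dense median is taken over that column subset only.
    """
    sub = X[lo:hi]
    cols = np.unique(sub.indices)
    if cols.size == 0:
        return cols, np.empty(0)
    dense = np.asarray(sub[:, cols].todense())
    med = np.median(dense, axis=0)
    keep = med != 0
    return cols[keep], med[keep]


def moving_median(series: BinnedSeries, cfg: SmoothingConfig | None = None) -> BinnedSeries:
    """Median-smooth a binned series over time.

    Raises ``ValueError`` when the series is shorter than the window.
    """
    cfg = cfg or SmoothingConfig()
    spans = window_spans(len(series), cfg)
    spectra = []
    for lo, hi in spans:
        idx, dat = _window_median(series.matrix, lo, hi)
        spectra.append(BinnedSpectrum(series.config, idx, dat))
    return BinnedSeries.from_spectra(series.label, spectra)


def aggregate_spectrum(series: BinnedSeries, mode: str = "sum") -> BinnedSpectrum:
    """Per-bin sum or mean over all scans of a series.

    The summed aggregate is the conventional single profile assigned to a
    measurement; the mean differs from it only by a scale factor, which
    neither similarity metric sees.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    total = np.asarray(series.matrix.sum(axis=0)).ravel()
    if mode == "mean":
        total = total / len(series)
    idx = np.flatnonzero(total)
    return BinnedSpectrum(series.config, idx, total[idx])


def write_smoothed(
    smoothed: BinnedSeries,
    cfg: SmoothingConfig,
    n_source_scans: int,
    csv_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write a smoothed series as sparse triplets plus a JSON sidecar
    recording the window, step and source-scan span of each output."""
    csv_path = Path(csv_path)
    smoothed.write_triplets(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "window": cfg.window,
                "step": cfg.step,
                "spans": [
                    {"output_index": k, "start": a, "end": b}
                    for k, (a, b) in enumerate(window_spans(n_source_scans, cfg))
                ],
            },
            indent=2,
        )
    )


class MovingMedianSmoother(TransformerMixin, BaseEstimator):
    """Transformer applying the moving median to a sparse scan×bin matrix.

    ``transform`` accepts a :class:`BinnedSeries` or a csr matrix and
    returns the same kind of object, one row per full window.
    """

    def __init__(self, window: int = 51, step: int = 51):
        self.window = window
        self.step = step

    def _config(self) -> SmoothingConfig:
        return SmoothingConfig(self.window, self.step)

    def fit(self, X=None, y=None) -> "MovingMedianSmoother":
        self.config_ = self._config()
        return self

    def transform(self, X: BinnedSeries | sp.spmatrix):
        if not hasattr(self, "config_"):
            self.fit()
        if isinstance(X, BinnedSeries):
            return moving_median(X, self.config_)
        X = sp.csr_matrix(X)
        cfg = self.config_
        rows = []
        for lo, hi in window_spans(X.shape[0], cfg):
            idx, dat = _window_median(X, lo, hi)
            rows.append(
                sp.csr_matrix((dat, idx, [0, dat.size]), shape=(1, X.shape[1]))
            )
        return sp.vstack(rows, format="csr")
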