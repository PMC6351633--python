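"""Pairwise similarity between binned spectra.

Two scan-similarity metrics are provided, both over the full dense bin
dimension N (zeros included):

* **Pearson's r** — the centered correlation
  ``r = Σ(X−X̄)(Y−Ȳ) / (√Σ(X−X̄)² · √Σ(Y−Ȳ)²)`` with ``X̄ = ΣX/N``;
* **cosine measure** — the cosine of the angle between the vectors,
  ``c = ΣXY / (√ΣX² · √ΣY²)``.

Because binned spectra are sparse and nonnegative with N ≈ 1.2·10⁵, the
vector means are close to zero and the two metrics nearly coincide; they
are exactly equal for mean-zero vectors.  Both are invariant to positive
rescaling of either vector, hence to TIC normalization.  Cosine on
nonnegative vectors lies in [0, 1] and is the cheaper of the two, so it is
the default for pipelines.

Sparse evaluation reproduces dense semantics exactly via
``Σ(X−X̄)(Y−Ȳ) = ΣXY − N·X̄·Ȳ``.

Degenerate vectors (all-zero; for Pearson also any vector constant over
all N coordinates) have no defined similarity; by convention the result is
0 rather than NaN, so matrices stay renderable and degenerate scans show
up as low-similarity bands.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .binning import BinnedSeries, BinnedSpectrum

__all__ = [
    "SimilarityMatrix",
    "pearson_r",
    "cosine",
    "similarity_matrix",
    "block_summary",
]

METRICS = ("pearson", "cosine")

# relative tolerance below which a vector's variance (or squared norm)
# counts as zero
_DEGENERATE_RTOL = 1e-12


def _pair_stats(x: BinnedSpectrum, y: BinnedSpectrum) -> tuple[float, float, float, float, float, int]:
    if x.config != y.config:
        raise ValueError("spectra do not share a BinConfig")
    n = x.config.n_bins
    sx = float(x.data.sum())
    sy = float(y.data.sum())
    sxx = float(np.dot(x.data, x.data))
    syy = float(np.dot(y.data, y.data))
    # intersection of sparse supports
    common, ix, iy = np.intersect1d(x.indices, y.indices, return_indices=True)
    sxy = float(np.dot(x.data[ix], y.data[iy])) if common.size else 0.0
    return sx, sy, sxx, syy, sxy, n


def cosine(x: BinnedSpectrum, y: BinnedSpectrum) -> float:
    """Cosine of the angle between two binned spectra.

    Returns 0.0 when either vector is all-zero (degenerate convention).
    """
    sx, sy, sxx, syy, sxy, _ = _pair_stats(x, y)
    if sxx <= 0.0 or syy <= 0.0:
        return 0.0
    return float(sxy / (np.sqrt(sxx) * np.sqrt(syy)))


def pearson_r(x: BinnedSpectrum, y: BinnedSpectrum) -> float:
    """Pearson correlation between two binned spectra over the full dense
    dimension (zeros included in the means).

    Returns 0.0 when either vector is constant over all N coordinates
    (zero variance — in particular all-zero), the degenerate convention.
    """
    sx, sy, sxx, syy, sxy, n = _pair_stats(x, y)
    if n < 2:
        raise ValueError("dense dimension must be >= 2")
    varx = sxx - sx * sx / n
    vary = syy - sy * sy / n
    if varx <= _DEGENERATE_RTOL * max(sxx, 1.0e-300) or vary <= _DEGENERATE_RTOL * max(syy, 1.0e-300):
        return 0.0
    cov = sxy - sx * sy / n
    r = cov / (np.sqrt(varx) * np.sqrt(vary))
    return float(np.clip(r, -1.0, 1.0))


@dataclasses.dataclass
class SimilarityMatrix:
    """Square matrix of pairwise scan similarities with group structure.

    ``group_labels`` holds one ``(label, start, end)`` half-open span per
    measurement, covering [0, n) in order.  ``degenerate`` flags rows whose
    spectrum was degenerate for the metric (their entries are 0).
    """

    metric: str
    values: np.ndarray
    group_labels: list[tuple[str, int, int]]
    degenerate: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def group_span(self, label: str) -> tuple[int, int]:
        for lab, a, b in self.group_labels:
            if lab == label:
                return a, b
        raise KeyError(label)

    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the matrix as a plain n×n CSV plus a JSON sidecar with the
        metric and group spans."""
        csv_path = Path(csv_path)
        pd.DataFrame(self.values).to_csv(csv_path, index=False, header=False)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "metric": self.metric,
                    "n": self.n,
                    "groups": [
                        {"label": lab, "start": a, "end": b}
                        for lab, a, b in self.group_labels
                    ],
                    "degenerate_rows": np.flatnonzero(self.degenerate).tolist(),
                },
                indent=2,
            )
        )


def _metric_matrix(X: sp.csr_matrix, metric: str) -> tuple[np.ndarray, np.ndarray]:
    n_scans, n_bins = X.shape
    G = np.asarray((X @ X.T).todense(), dtype=float)
    if metric == "cosine":
        sq = G.diagonal().copy()
        degenerate = sq <= 0.0
        num = G
        scale = np.sqrt(sq)
    elif metric == "pearson":
        s = np.asarray(X.sum(axis=1)).ravel()
        sq = G.diagonal().copy()
        var = sq - s * s / n_bins
        degenerate = var <= _DEGENERATE_RTOL * np.maximum(sq, 1.0e-300)
        num = G - np.outer(s, s) / n_bins
        scale = np.sqrt(np.maximum(var, 0.0))
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    scale[degenerate] = 1.0  # avoid division warnings; rows zeroed below
    V = num / np.outer(scale, scale)
    V[degenerate, :] = 0.0
    V[:, degenerate] = 0.0
    V = (V + V.T) / 2.0  # enforce exact symmetry of the float result
    np.clip(V, -1.0, 1.0, out=V)
    idx = np.flatnonzero(~degenerate)
    V[idx, idx] = 1.0
    return V, degenerate


def similarity_matrix(
    series: BinnedSeries | Sequence[BinnedSeries], metric: str = "cosine"
) -> SimilarityMatrix:
    """Pairwise similarity between all scans of one or more measurements.

    Measurements are concatenated in the given order into a global scan
    index; ``group_labels`` records each measurement's span, so the matrix
    carries the block structure (within- vs between-measurement) used for
    reproducibility assessment.
    """
    if isinstance(series, BinnedSeries):
        series = [series]
    series = list(series)
    if not series:
        raise ValueError("no series given")
    cfg = series[0].config
    if any(s.config != cfg for s in series):
        raise ValueError("all series must share one BinConfig")
    X = sp.vstack([s.matrix for s in series], format="csr")
    V, degenerate = _metric_matrix(X, metric)
    groups = []
    start = 0
    for s in series:
        groups.append((s.label, start, start + len(s)))
        start += len(s)
    return SimilarityMatrix(metric=metric, values=V, group_labels=groups, degenerate=degenerate)


def block_summary(m: SimilarityMatrix) -> pd.DataFrame:
    """Per-block mean/min/max of a grouped similarity matrix.

    One row per ordered pair of measurement groups; for the diagonal blocks
    (a group against itself) the matrix diagonal is excluded, so the
    within-group mean of identical spectra is exactly 1.
    """
    spans = sorted(m.group_labels, key=lambda g: g[1])
    covered = 0
    for lab, a, b in spans:
        if a != covered or b <= a:
            raise ValueError("group labels must partition [0, n) without overlap")
        covered = b
    if covered != m.n:
        raise ValueError("group labels must cover [0, n)")
    rows = []
    for glab, ga, gb in m.group_labels:
        for hlab, ha, hb in m.group_labels:
            block = m.values[ga:gb, ha:hb]
            if glab == hlab and ga == ha:
                k = block.shape[0]
                if k == 1:
                    continue  # single scan: no off-diagonal entries
                mask = ~np.eye(k, dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            rows.append(
                {
                    "group_row": glab,
                    "group_col": hlab,
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n_pairs": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
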