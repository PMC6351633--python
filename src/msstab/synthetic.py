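"""Seeded synthetic measurements with known ground truth.

Emulates direct spray-from-tissue (NESI-style) acquisitions: one
measurement is ~300 scans over ~5 minutes in m/z 100–1300, each scan a
lipid-like multi-peak profile whose peak-intensity ratios fluctuate
multiplicatively scan to scan, with an overall per-scan TIC scale factor,
optional slow drift of the profile over the run, m/z jitter at the
instrument's ~2 ppm precision, and occasional artifact scans.

Artifact scans come in three kinds covering the failure modes of an
unstable spray:

* ``tic_spike`` — anomalous TIC maximum: the scan is scaled ×10 and
  gains extra spurious peaks;
* ``tic_dropout`` — anomalous TIC minimum: the scan is scaled ×0.01;
* ``foreign_profile`` — the scan carries an unrelated random profile
  (e.g. solvent-only or contamination), same overall TIC.

Everything is drawn from a single seeded ``numpy.random.default_rng``
stream, so a config is fully reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .binning import BinConfig, BinnedSpectrum, bin_scan
from .io import Measurement, Scan

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_measurement",
    "generate_study",
    "write_ground_truth",
]

ARTIFACT_KINDS = ("tic_spike", "tic_dropout", "foreign_profile")


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic measurement.

    Defaults reflect the emulated acquisition: 300 scans, 50 lipid-like
    peaks spanning two decades of intensity, 10% multiplicative per-peak
    noise, 20% per-scan TIC scale noise, 2 ppm m/z jitter, no drift and no
    artifacts unless requested.
    """

    n_scans: int = 300
    n_peaks: int = 50
    mz_min: float = 100.0
    mz_max: float = 1300.0
    base_mzs: tuple[float, ...] | None = None
    base_intensities: tuple[float, ...] | None = None
    intensity_decades: float = 2.0
    noise_sigma: float = 0.1
    scale_sigma: float = 0.2
    drift_rate: float = 0.0
    artifact_indices: tuple[int, ...] = ()
    artifact_kind: str = "foreign_profile"
    mz_jitter_ppm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1 or self.n_peaks < 1:
            raise ValueError("n_scans and n_peaks must be >= 1")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.noise_sigma < 0 or self.scale_sigma < 0 or self.drift_rate < 0:
            raise ValueError("noise_sigma, scale_sigma and drift_rate must be >= 0")
        if self.artifact_kind not in ARTIFACT_KINDS:
            raise ValueError(f"artifact_kind must be one of {ARTIFACT_KINDS}")
        bad = [i for i in self.artifact_indices if not 0 <= i < self.n_scans]
        if bad:
            raise ValueError(f"artifact indices out of range: {bad}")
        if self.base_intensities is not None and any(
            v <= 0 for v in self.base_intensities
        ):
            raise ValueError("base intensities must be positive")
        object.__setattr__(self, "artifact_indices", tuple(sorted(self.artifact_indices)))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for use as a test oracle.

    ``profiles[s]`` is the clean (drifted, noise-free) peak-intensity
    profile scan s would have had; artifact scans keep their clean profile
    here so that recovery can be measured against it.
    """

    mzs: np.ndarray
    profiles: np.ndarray  # (n_scans, n_peaks)
    scale_factors: np.ndarray  # (n_scans,)
    artifact_indices: tuple[int, ...]
    artifact_kind: str

    def base_profile_spectrum(self, cfg: BinConfig | None = None) -> BinnedSpectrum:
        """The scan-0 clean profile, binned — the measurement's true
        molecular profile in vector form."""
        return bin_scan(
            Scan(mz=self.mzs, intensity=self.profiles[0], scan_index=0),
            cfg or BinConfig(),
        )

    def mean_profile_spectrum(self, cfg: BinConfig | None = None) -> BinnedSpectrum:
        """The mean clean profile over all scans, binned; equals the base
        profile when there is no drift."""
        return bin_scan(
            Scan(mz=self.mzs, intensity=self.profiles.mean(axis=0), scan_index=0),
            cfg or BinConfig(),
        )


def _draw_profile(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    mzs = np.sort(rng.uniform(cfg.mz_min, cfg.mz_max, cfg.n_peaks))
    intensities = 10.0 ** rng.uniform(0.0, cfg.intensity_decades, cfg.n_peaks)
    return mzs, intensities


def generate_measurement(
    cfg: GeneratorConfig, label: str = "synthetic"
) -> tuple[Measurement, GroundTruth]:
    """Generate one measurement plus its ground truth, deterministically
    from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    if cfg.base_mzs is not None:
        mzs = np.asarray(cfg.base_mzs, dtype=float)
        base = np.asarray(cfg.base_intensities, dtype=float)
        if mzs.shape != base.shape:
            raise ValueError("base_mzs and base_intensities must align")
    else:
        mzs, base = _draw_profile(rng, cfg)
    # drift morphs the profile linearly toward an independent target
    _, drift_target = _draw_profile(rng, cfg)

    n = cfg.n_scans
    artifacts = set(cfg.artifact_indices)
    profiles = np.empty((n, mzs.size))
    scales = np.empty(n)
    scans: list[Scan] = []
    for s in range(n):
        alpha = min(1.0, cfg.drift_rate * s)
        clean = (1.0 - alpha) * base + alpha * drift_target
        profiles[s] = clean
        scale = float(np.exp(rng.normal(0.0, cfg.scale_sigma)))
        scales[s] = scale
        noise = np.exp(rng.normal(0.0, cfg.noise_sigma, clean.size))
        scan_mz = mzs
        inten = clean * noise * scale
        if s in artifacts:
            if cfg.artifact_kind == "tic_spike":
                inten = inten * 10.0
                extra_mz = rng.uniform(cfg.mz_min, cfg.mz_max, max(1, cfg.n_peaks // 2))
                extra_int = 10.0 ** rng.uniform(0.0, cfg.intensity_decades, extra_mz.size)
                scan_mz = np.concatenate([scan_mz, extra_mz])
                inten = np.concatenate([inten, extra_int * 10.0 * scale])
            elif cfg.artifact_kind == "tic_dropout":
                inten = inten * 0.01
            else:  # foreign_profile
                scan_mz, foreign = _draw_profile(rng, cfg)
                # match the clean scan's TIC so only the profile is foreign
                foreign = foreign * (inten.sum() / foreign.sum())
                inten = foreign
        jitter = rng.uniform(-1.0, 1.0, scan_mz.size) * cfg.mz_jitter_ppm * 1e-6
        scans.append(
            Scan(mz=scan_mz * (1.0 + jitter), intensity=inten, scan_index=s)
        )
    gt = GroundTruth(
        mzs=mzs,
        profiles=profiles,
        scale_factors=scales,
        artifact_indices=cfg.artifact_indices,
        artifact_kind=cfg.artifact_kind,
    )
    return Measurement(label=label, scans=tuple(scans)), gt


def generate_study(
    sample_specs: Sequence[Sequence[GeneratorConfig]],
    sample_labels: Sequence[str] | None = None,
    return_ground_truth: bool = False,
):
    """Generate a multi-sample, multi-fragment study.

    ``sample_specs[i]`` holds one :class:`GeneratorConfig` per fragment of
    sample i.  All fragments of a sample share one base profile (drawn
    from the sample's first config) with fresh per-fragment noise; distinct
    samples get distinct profiles.  Fragment configs should carry distinct
    seeds so fragments differ by noise.

    Returns a list of measurements labelled ``"S{i}-F{j}"`` (or from
    ``sample_labels``), optionally with the ground truths.
    """
    measurements: list[Measurement] = []
    truths: list[GroundTruth] = []
    for i, fragments in enumerate(sample_specs):
        fragments = list(fragments)
        if not fragments:
            continue
        head = fragments[0]
        if head.base_mzs is None:
            rng = np.random.default_rng(head.seed)
            mzs, base = _draw_profile(rng, head)
            shared = (tuple(mzs.tolist()), tuple(base.tolist()))
        else:
            shared = (head.base_mzs, head.base_intensities)
        slab = sample_labels[i] if sample_labels else f"S{i + 1}"
        for j, frag_cfg in enumerate(fragments):
            frag_cfg = dataclasses.replace(
                frag_cfg, base_mzs=shared[0], base_intensities=shared[1]
            )
            m, gt = generate_measurement(frag_cfg, label=f"{slab}-F{j + 1}")
            measurements.append(m)
            truths.append(gt)
    if return_ground_truth:
        return measurements, truths
    return measurements


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Dump a ground truth as JSON (peak m/z, clean profiles, scales,
    artifact bookkeeping)."""
    Path(path).write_text(
        json.dumps(
            {
                "mzs": gt.mzs.tolist(),
                "profiles": gt.profiles.tolist(),
                "scale_factors": gt.scale_factors.tolist(),
                "artifact_indices": list(gt.artifact_indices),
                "artifact_kind": gt.artifact_kind,
            }
        )
    )
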