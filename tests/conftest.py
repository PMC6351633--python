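"""Shared fixtures: toy bin grids, spectrum builders, and a minimal mzML
writer so I/O tests need no stored data files."""

from __future__ import annotations

import base64

import numpy as np
import pytest

from msstab import BinConfig, BinnedSeries, BinnedSpectrum


@pytest.fixture
def toy_config() -> BinConfig:
    """A 4-bin unit-width grid for hand-checkable vectors."""
    return BinConfig(mz_min=0.0, mz_max=4.0, bin_width=1.0)


def make_spectrum(values, cfg: BinConfig | None = None) -> BinnedSpectrum:
    values = np.asarray(values, dtype=float)
    cfg = cfg or BinConfig(0.0, float(values.size), 1.0)
    return BinnedSpectrum.from_dense(values, cfg)


def make_series(rows, cfg: BinConfig | None = None, label: str = "m") -> BinnedSeries:
    rows = np.asarray(rows, dtype=float)
    cfg = cfg or BinConfig(0.0, float(rows.shape[1]), 1.0)
    return BinnedSeries.from_spectra(label, [make_spectrum(r, cfg) for r in rows])


def random_sparse_rows(rng, n_rows: int, n_bins: int, density: float = 0.2) -> np.ndarray:
    """Dense array of nonnegative sparse rows, at least one positive entry
    per row."""
    rows = rng.random((n_rows, n_bins)) * (rng.random((n_rows, n_bins)) < density)
    for i in range(n_rows):
        if not rows[i].any():
            rows[i, rng.integers(n_bins)] = rng.random() + 0.1
    return rows


def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _spectrum_xml(index: int, mz, intensity, mode: str = "centroid", time_min: float | None = None) -> str:
    acc = {"centroid": "MS:1000127", "profile": "MS:1000128"}[mode]
    time_xml = ""
    if time_min is not None:
        time_xml = (
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{time_min}" unitName="minute"/>'
            "</scan></scanList>"
        )
    arrays = ""
    for kind_acc, kind_name, data in (
        ("MS:1000514", "m/z array", mz),
        ("MS:1000515", "intensity array", intensity),
    ):
        enc = _b64(data)
        arrays += f"""
          <binaryDataArray encodedLength="{len(enc)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="{kind_acc}" name="{kind_name}" value=""/>
            <binary>{enc}</binary>
          </binaryDataArray>"""
    return f"""
      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="{acc}" name="{mode} spectrum" value=""/>
        {time_xml}
        <binaryDataArrayList count="2">{arrays}
        </binaryDataArrayList>
      </spectrum>"""


def write_mzml(path, spectra) -> None:
    """Write a minimal mzML file.

    ``spectra`` is a list of dicts with keys ``mz``, ``intensity`` and
    optionally ``mode`` ("centroid"/"profile") and ``time_min``.
    """
    body = "".join(
        _spectrum_xml(
            i,
            s["mz"],
            s["intensity"],
            mode=s.get("mode", "centroid"),
            time_min=s.get("time_min"),
        )
        for i, s in enumerate(spectra)
    )
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1">
    <spectrumList count="{len(spectra)}">{body}
    </spectrumList>
  </run>
</mzML>"""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)
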