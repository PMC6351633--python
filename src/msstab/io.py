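"""Reading and writing scan series.

A *measurement* is one continuous acquisition from one sample (here
typically ~5 minutes, ~300 scans); each *scan* is a single centroided
mass spectrum.  Two on-disk forms are supported:

* mzML (read-only, centroided spectra only), via a small lxml-based
  reader covering the common encodings (32/64-bit float arrays, plain or
  zlib-compressed);
* a plain delimited peak table with header ``scan_index,mz,intensity``
  (comma- or tab-separated, UTF-8), read and written here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scan",
    "Measurement",
    "read_mzml",
    "read_peaktable",
    "write_peaktable",
    "tic_trace",
    "write_tic_trace",
]

PEAKTABLE_COLUMNS = ("scan_index", "mz", "intensity")


@dataclasses.dataclass(frozen=True)
class Scan:
    """One centroided mass spectrum.

    Parameters
    ----------
    mz : ndarray
        Peak positions in Da, sorted ascending.
    intensity : ndarray
        Nonnegative peak intensities (arbitrary counts), aligned with `mz`.
    scan_index : int
        Position of the scan within its measurement (0-based).
    time : float or None
        Acquisition time in seconds, if known.
    """

    mz: np.ndarray
    intensity: np.ndarray
    scan_index: int
    time: float | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.ndim != 1 or mz.shape != inten.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", np.ascontiguousarray(mz[order]))
        object.__setattr__(self, "intensity", np.ascontiguousarray(inten[order]))
        if self.scan_index < 0:
            raise ValueError("scan_index must be >= 0")

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all peak intensities."""
        return float(self.intensity.sum())

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        """Peaks as (m/z, intensity) pairs, sorted by m/z."""
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclasses.dataclass(frozen=True)
class Measurement:
    """A time-ordered series of scans from one acquisition."""

    label: str
    scans: tuple[Scan, ...]

    def __post_init__(self) -> None:
        scans = tuple(self.scans)
        if not scans:
            raise ValueError(f"measurement {self.label!r}: no scans")
        idx = [s.scan_index for s in scans]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"measurement {self.label!r}: scans not strictly ordered by scan_index"
            )
        object.__setattr__(self, "scans", scans)

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self) -> Iterator[Scan]:
        return iter(self.scans)

    def __getitem__(self, i: int) -> Scan:
        return self.scans[i]


# mzML controlled-vocabulary accessions used by the reader
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_SCAN_START = "MS:1000016"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array accession, values)."""
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    kind = None
    text = ""
    for el in bda.iter():
        name = _localname(el.tag)
        if name == "cvParam":
            acc = el.get("accession", "")
            if acc == _CV_F32:
                dtype = "<f4"
            elif acc == _CV_ZLIB:
                compressed = True
            elif acc in (_CV_MZ_ARRAY, _CV_INT_ARRAY):
                kind = acc
        elif name == "binary":
            text = el.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path, label: str | None = None, *, drop_empty_scans: bool = False) -> Measurement:
    """Read a centroided mzML file into a :class:`Measurement`.

    Spectra are taken in file order and re-indexed 0, 1, 2, ….  Profile-mode
    spectra are rejected: centroiding is out of scope, so a spectrum flagged
    ``profile spectrum`` (or lacking the ``centroid spectrum`` flag) raises
    ``ValueError`` naming the offending spectrum.

    Parameters
    ----------
    path : path
        mzML file.
    label : str, optional
        Measurement label; defaults to the file stem.
    drop_empty_scans : bool
        If True, scans with zero peaks are skipped; by default they are
        retained (and flagged downstream by QC scoring).
    """
    from lxml import etree

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: list[Scan] = []
    try:
        context = etree.iterparse(str(path), events=("end",))
        for _, el in context:
            if _localname(el.tag) != "spectrum":
                continue
            sid = el.get("id") or f"index={el.get('index', len(scans))}"
            centroided = False
            time = None
            mz = inten = None
            for sub in el.iter():
                name = _localname(sub.tag)
                if name == "cvParam":
                    acc = sub.get("accession", "")
                    if acc == _CV_CENTROID:
                        centroided = True
                    elif acc == _CV_PROFILE:
                        raise ValueError(
                            f"{path.name}: spectrum {sid!r} is profile-mode; "
                            "centroided data required"
                        )
                    elif acc == _CV_SCAN_START:
                        t = float(sub.get("value", "nan"))
                        unit = (sub.get("unitName") or "").lower()
                        time = t * 60.0 if unit.startswith("min") else t
                elif name == "binaryDataArray":
                    kind, values = _decode_binary_array(sub)
                    if kind == _CV_MZ_ARRAY:
                        mz = values
                    elif kind == _CV_INT_ARRAY:
                        inten = values
            if not centroided:
                raise ValueError(
                    f"{path.name}: spectrum {sid!r} is not flagged as a "
                    "centroid spectrum; profile-mode data is not supported"
                )
            if mz is None or inten is None:
                raise ValueError(f"{path.name}: spectrum {sid!r} lacks m/z or intensity array")
            if not (drop_empty_scans and mz.size == 0):
                scans.append(
                    Scan(mz=mz, intensity=inten, scan_index=len(scans), time=time)
                )
            el.clear()
    except etree.XMLSyntaxError as err:
        raise OSError(f"{path.name}: corrupt mzML ({err})") from err
    if not scans:
        raise ValueError(f"{path.name}: no scans")
    return Measurement(label=label or path.stem, scans=tuple(scans))


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_peaktable(path: str | Path, label: str | None = None, *, drop_empty_scans: bool = False) -> Measurement:
    """Read a delimited peak table into a :class:`Measurement`.

    The table must have a header ``scan_index,mz,intensity`` (comma- or
    tab-delimited).  Rows are grouped by ``scan_index`` into scans, sorted
    by scan_index; duplicate (scan, m/z) rows have their intensities summed,
    consistent with downstream binning semantics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in PEAKTABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path.name}: no scans")
    parsed = {}
    for col in PEAKTABLE_COLUMNS:
        raw = df[col].to_numpy(dtype=object)
        try:
            # numpy's parser is correctly rounded (pandas' fast parser is not)
            vals = raw.astype(float)
            if np.isnan(vals).any():
                raise ValueError
        except (TypeError, ValueError):
            for i, v in enumerate(raw):
                try:
                    if np.isnan(float(v)):
                        raise ValueError
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path.name}: non-numeric {col!r} value at line {i + 2}"
                    ) from None
            raise  # pragma: no cover - unreachable
        parsed[col] = vals
    if np.any(parsed["intensity"] < 0):
        row = int(np.flatnonzero(parsed["intensity"] < 0)[0])
        raise ValueError(f"{path.name}: negative intensity at line {row + 2}")
    scan_idx = parsed["scan_index"].astype(int)
    if np.any(scan_idx != parsed["scan_index"]) or np.any(scan_idx < 0):
        raise ValueError(f"{path.name}: scan_index must be a nonnegative integer")

    scans: list[Scan] = []
    for si in np.unique(scan_idx):  # np.unique sorts -> scans ordered by index
        sel = scan_idx == si
        mz = parsed["mz"][sel]
        inten = parsed["intensity"][sel]
        # sum duplicate m/z within the scan
        umz, inv = np.unique(mz, return_inverse=True)
        uint = np.zeros_like(umz)
        np.add.at(uint, inv, inten)
        if drop_empty_scans and umz.size == 0:
            continue
        scans.append(Scan(mz=umz, intensity=uint, scan_index=int(si)))
    if not scans:
        raise ValueError(f"{path.name}: no scans")
    return Measurement(label=label or path.stem, scans=tuple(scans))


def write_peaktable(m: Measurement, path: str | Path, *, sep: str = ",") -> None:
    """Write a measurement as a delimited peak table (the dialect read back
    by :func:`read_peaktable`)."""
    rows = []
    for s in m.scans:
        for mz, inten in zip(s.mz, s.intensity):
            rows.append((s.scan_index, mz, inten))
    df = pd.DataFrame(rows, columns=list(PEAKTABLE_COLUMNS))
    # %.17g round-trips doubles exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def tic_trace(m: Measurement) -> pd.DataFrame:
    """Total ion current per scan, in scan order.

    Returns a DataFrame with columns ``scan_index`` and ``tic``.
    """
    return pd.DataFrame(
        {
            "scan_index": [s.scan_index for s in m.scans],
            "tic": [s.tic for s in m.scans],
        }
    )


def write_tic_trace(m: Measurement, path: str | Path) -> None:
    tic_trace(m).to_csv(path, index=False)
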