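"""Spectra and feature-table I/O.

Canonical in-memory model shared by every pipeline stage:

* :class:`MsSpectrum` — one MS² scan (precursor m/z, adduct, retention
  time, fragment peak list).
* :class:`FeatureTable` — features × samples peak-area matrix plus
  per-feature metadata (precursor m/z, adduct, retention time) and
  per-sample metadata (group, timepoint, replicate).

MGF parsing/writing is delegated to :mod:`pyteomics.mgf`; this module
adds validation and the GNPS-dialect conveniences (``FEATURE_ID=``,
``SCANS=`` keyed blocks in addition to generic ``TITLE``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

__all__ = [
    "MsSpectrum",
    "FeatureTable",
    "MgfParseError",
    "ValidationError",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
]

#: Adduct labels the pipeline understands; anything else maps to "unknown".
KNOWN_ADDUCTS = ("M+H", "M+NH4")

#: m/z overshoot tolerated for fragment ions above the precursor (isotopes).
_PRECURSOR_OVERSHOOT = 1.0


class MgfParseError(ValueError):
    """Raised for malformed MGF blocks (e.g. missing PEPMASS)."""


class ValidationError(ValueError):
    """Raised when tabular inputs violate the data-model invariants."""


def _normalize_adduct(raw: str | None) -> str:
    if raw is None:
        return "unknown"
    text = str(raw).strip().strip("[]").replace(" ", "")
    # tolerate charge suffixes like "M+H]+" / "M+H+" / "M+NH4]1+"
    for label in KNOWN_ADDUCTS:
        if text.startswith(label) or text.startswith(label.replace("+", "")):
            return label
    return "unknown"


@dataclass
class MsSpectrum:
    """A single MS² spectrum.

    Peaks are stored as an ``(n, 2)`` float64 array of
    ``(fragment_mz, intensity)`` rows, sorted ascending by m/z.
    Intensities must be finite and non-negative; fragment m/z must stay
    below ``precursor_mz + 1.0`` (tolerated isotope overshoot).
    """

    feature_id: str
    precursor_mz: float
    peaks: np.ndarray
    charge: int = 1
    retention_time: float = 0.0
    adduct: str = "unknown"

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=np.float64)
        if peaks.size == 0:
            peaks = peaks.reshape(0, 2)
        if peaks.ndim != 2 or peaks.shape[1] != 2:
            raise ValidationError(
                f"spectrum {self.feature_id!r}: peaks must be an (n, 2) array"
            )
        if not np.all(np.isfinite(peaks)):
            raise ValidationError(f"spectrum {self.feature_id!r}: non-finite peak values")
        if np.any(peaks[:, 1] < 0):
            raise ValidationError(f"spectrum {self.feature_id!r}: negative intensity")
        if self.precursor_mz <= 0:
            raise ValidationError(f"spectrum {self.feature_id!r}: non-positive precursor m/z")
        if self.charge < 1:
            raise ValidationError(f"spectrum {self.feature_id!r}: charge must be >= 1")
        if self.retention_time < 0:
            raise ValidationError(f"spectrum {self.feature_id!r}: negative retention time")
        limit = self.precursor_mz + _PRECURSOR_OVERSHOOT
        if np.any(peaks[:, 0] >= limit):
            raise ValidationError(
                f"spectrum {self.feature_id!r}: fragment m/z above precursor + "
                f"{_PRECURSOR_OVERSHOOT}"
            )
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]
        self.adduct = _normalize_adduct(self.adduct) if self.adduct != "unknown" else "unknown"

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.shape[0])

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


def read_mgf(path: str | Path) -> list[MsSpectrum]:
    """Read an MGF file into a list of :class:`MsSpectrum`.

    Accepts both GNPS-style blocks (``FEATURE_ID=``/``SCANS=``) and
    generic ``TITLE``-keyed blocks. A block lacking ``PEPMASS`` raises
    :class:`MgfParseError` naming the 1-based block index. Missing
    charge defaults to 1; missing feature id falls back to the running
    block index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[MsSpectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, entry in enumerate(reader, start=1):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MgfParseError(f"MGF block {idx}: missing PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge_field = params.get("charge")
            if charge_field:
                first = charge_field[0] if isinstance(charge_field, (tuple, list)) else charge_field
                charge = abs(int(first))
            else:
                charge = 1
            fid = (
                params.get("feature_id")
                or params.get("title")
                or params.get("scans")
                or str(idx)
            )
            rt = float(params.get("rtinseconds", 0.0))
            adduct = params.get("adduct") or params.get("ion") or params.get("iontype")
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(
                MsSpectrum(
                    feature_id=str(fid),
                    precursor_mz=precursor,
                    peaks=peaks,
                    charge=charge,
                    retention_time=rt,
                    adduct=_normalize_adduct(adduct),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[MsSpectrum], path: str | Path) -> None:
    """Write spectra to MGF (GNPS-style FEATURE_ID blocks)."""
    records = []
    for spec in spectra:
        params = {
            "feature_id": spec.feature_id,
            "pepmass": spec.precursor_mz,
            "charge": spec.charge,
            "rtinseconds": spec.retention_time,
        }
        if spec.adduct != "unknown":
            params["adduct"] = spec.adduct
        records.append(
            {
                "params": params,
                "m/z array": spec.mz,
                "intensity array": spec.intensity,
            }
        )
    _pymgf.write(records, str(path), file_mode="w")


@dataclass
class FeatureTable:
    """Features × samples abundance matrix with aligned metadata.

    ``abundance`` rows are features, columns are samples.  ``feature_meta``
    (indexed by feature id) carries at least ``precursor_mz`` and ``adduct``
    where known; ``sample_meta`` (indexed by sample id) carries ``group``,
    ``timepoint_h`` and ``replicate``.
    """

    abundance: pd.DataFrame
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.shape[0] < 1 or ab.shape[1] < 1:
            raise ValidationError("feature table must have >= 1 feature and >= 1 sample")
        if ab.index.duplicated().any():
            dupes = ab.index[ab.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if ab.columns.duplicated().any():
            dupes = ab.columns[ab.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = ab.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("feature table contains non-finite abundances")
        if np.any(values < 0):
            bad = ab.index[np.any(values < 0, axis=1)].tolist()
            raise ValidationError(f"negative abundances for features: {bad[:5]}")
        self.abundance = ab.astype(float)
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=ab.index)
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=ab.columns)
        self.feature_meta = self.feature_meta.reindex(ab.index)
        if len(self.sample_meta):
            missing = [s for s in ab.columns if s not in self.sample_meta.index]
            if missing:
                raise ValidationError(f"samples missing from metadata: {missing}")
            self.sample_meta = self.sample_meta.loc[list(ab.columns)]
        else:
            self.sample_meta = pd.DataFrame(index=ab.columns)

    @property
    def n_features(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def groups(self) -> Mapping[str, list[str]]:
        """Sample ids keyed by metadata group label (insertion-ordered)."""
        if "group" not in self.sample_meta.columns:
            raise ValidationError("sample metadata lacks a 'group' column")
        out: dict[str, list[str]] = {}
        for sample, grp in self.sample_meta["group"].items():
            out.setdefault(str(grp), []).append(sample)
        return out

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            abundance=self.abundance.copy(),
            feature_meta=self.feature_meta.copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def to_csv(self, abundance_path: str | Path, feature_meta_path: str | Path | None = None,
               sample_meta_path: str | Path | None = None) -> None:
        self.abundance.to_csv(abundance_path, index_label="feature_id")
        if feature_meta_path is not None:
            self.feature_meta.to_csv(feature_meta_path, index_label="feature_id")
        if sample_meta_path is not None:
            self.sample_meta.to_csv(sample_meta_path, index_label="sample_id")


def _read_delim(path: Path, **kwargs) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, **kwargs)


def read_feature_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Load a features × samples CSV/TSV plus a sample-metadata table.

    The abundance table's first column holds feature ids; remaining
    columns are sample ids.  The metadata table must have columns
    ``sample_id``, ``group``, ``timepoint_h``, ``replicate`` and must
    cover every sample column.  An optional feature-metadata sidecar
    (``<stem>.feature_meta.csv``) is picked up automatically if present.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    table = _read_delim(path, index_col=0)
    table.index = table.index.astype(str)
    meta = _read_delim(metadata_path)
    if "sample_id" not in meta.columns:
        raise ValidationError("sample metadata must contain a 'sample_id' column")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    table.columns = table.columns.astype(str)
    missing = [s for s in table.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    sidecar = path.with_suffix("")
    feature_meta_path = Path(str(sidecar) + ".feature_meta.csv")
    if feature_meta_path.exists():
        feature_meta = pd.read_csv(feature_meta_path, index_col=0)
        feature_meta.index = feature_meta.index.astype(str)
    else:
        feature_meta = pd.DataFrame(index=table.index)
    return FeatureTable(
        abundance=table,
        feature_meta=feature_meta,
        sample_meta=meta.loc[list(table.columns)],
    )
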