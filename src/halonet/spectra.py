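"""MS/MS spectrum containers and MGF/mzML input.

Spectra are centroided positive-mode MS/MS scans with a precursor m/z
and a retention time, the unit of networking and annotation.  MGF is the
primary interchange format (read through pyteomics, written with fixed
float formatting so a seeded synthetic run is byte-reproducible); mzML
input (MS2 scans only) is supported for converted vendor data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumSet",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "filter_peaks",
]

#: Acquisition scan range in m/z; precursors outside it are rejected.
SCAN_RANGE = (100.0, 1500.0)


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS/MS scan.

    ``mz``/``intensity`` are parallel float arrays sorted by m/z
    ascending with near-duplicate (<1e-6 Da) m/z values merged.
    Retention time is in minutes.  ``extract`` is the source extract
    code (e.g. "LC1").
    """

    id: str
    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1
    extract: str = ""

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be parallel 1-D arrays")
        if not (np.isfinite(mz).all() and np.isfinite(inten).all()):
            raise ValueError("non-finite peak values")
        if (mz <= 0).any() or (inten < 0).any():
            raise ValueError("peaks need positive m/z and non-negative intensity")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if len(mz) > 1:
            dup = np.diff(mz) < 1e-6
            if dup.any():
                keep = np.concatenate(([True], ~dup))
                # merge duplicates by summing intensity into kept peak
                idx = np.cumsum(keep) - 1
                summed = np.zeros(keep.sum())
                np.add.at(summed, idx, inten)
                mz, inten = mz[keep], summed
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not (SCAN_RANGE[0] <= self.precursor_mz <= SCAN_RANGE[1]):
            raise ValueError(
                f"precursor m/z {self.precursor_mz} outside scan range {SCAN_RANGE}"
            )
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return len(self.mz)

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0


@dataclass
class SpectrumSet:
    """A collection of spectra plus per-extract sample metadata."""

    spectra: list[Spectrum] = field(default_factory=list)
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.id for s in self.spectra]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate spectrum ids")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


def _rt_minutes(params: dict) -> float:
    if "rtinminutes" in params:
        return float(params["rtinminutes"])
    if "rtinseconds" in params:
        return float(params["rtinseconds"]) / 60.0
    return 0.0


def read_mgf(path: str | Path) -> SpectrumSet:
    """Read an MGF file into a :class:`SpectrumSet`.

    Every BEGIN/END IONS block becomes one spectrum; RT is normalized to
    minutes; blocks without a PEPMASS are skipped with a warning.  The
    optional EXTRACT local header carries the source extract code.
    """
    spectra: list[Spectrum] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pyteomics warns on local headers
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, block in enumerate(reader):
                params = block["params"]
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    logger.warning("skipping MGF block %d: no PEPMASS", i)
                    continue
                charge = 1
                if params.get("charge"):
                    charge = abs(int(params["charge"][0])) or 1
                spectra.append(
                    Spectrum(
                        id=str(params.get("title", f"scan_{i}")),
                        precursor_mz=float(pepmass[0]),
                        rt=_rt_minutes(params),
                        mz=block["m/z array"],
                        intensity=block["intensity array"],
                        charge=charge,
                        extract=str(params.get("extract", "")),
                    )
                )
    return SpectrumSet(spectra)


def write_mgf(spectra: SpectrumSet | list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed formatting (m/z %.6f, intensity %.4f).

    The fixed formats make output byte-identical across runs for
    identical input, which the seeded synthetic generator relies on.
    """
    items = spectra.spectra if isinstance(spectra, SpectrumSet) else spectra
    with open(path, "w") as fh:
        for s in items:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"RTINSECONDS={s.rt * 60.0:.4f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            if s.extract:
                fh.write(f"EXTRACT={s.extract}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f} {i:.4f}\n")
            fh.write("END IONS\n")


def read_mzml(path: str | Path) -> SpectrumSet:
    """Read MS2 scans from an mzML file (MS1 scans are dropped)."""
    from pyteomics import mzml as _mzml

    spectra: list[Spectrum] = []
    with _mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            if scan.get("ms level") != 2:
                continue
            try:
                precursor = scan["precursorList"]["precursor"][0]
                ion = precursor["selectedIonList"]["selectedIon"][0]
                pep = float(ion["selected ion m/z"])
            except (KeyError, IndexError):
                logger.warning("skipping mzML scan %d: no precursor", i)
                continue
            rt = 0.0
            scan_info = scan.get("scanList", {}).get("scan", [{}])[0]
            if "scan start time" in scan_info:
                t = scan_info["scan start time"]
                rt = float(t)  # pyteomics yields minutes via unitfloat
            spectra.append(
                Spectrum(
                    id=str(scan.get("id", f"scan_{i}")),
                    precursor_mz=pep,
                    rt=rt,
                    mz=scan["m/z array"],
                    intensity=scan["intensity array"],
                    charge=int(ion.get("charge state", 1) or 1),
                )
            )
    return SpectrumSet(spectra)


def filter_peaks(spectrum: Spectrum, min_intensity: float = 50.0) -> Spectrum:
    """Drop fragment peaks below ``min_intensity`` (kept at equality).

    The acquisition-level intensity floor applied before networking; an
    all-peaks-removed spectrum is returned empty (and excluded from
    networking downstream).  Idempotent.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    keep = spectrum.intensity >= min_intensity
    return replace(spectrum, mz=spectrum.mz[keep], intensity=spectrum.intensity[keep])
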