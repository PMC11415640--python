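"""Reading, normalizing and writing experimental MS² data.

MGF and MSP files are read and written through matchms; an additional
reader handles MS-DIAL-style tab-separated alignment exports, where each
row holds precursor m/z, retention time, adduct and an ``MS/MS spectrum``
column of space-separated ``mz:intensity`` pairs.

Intensity normalization is to summed intensity 1 (not base peak 1), so
the structure score S1 = sum of matched intensities is bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from matchms import Spectrum as MatchmsSpectrum
from matchms.exporting import save_as_mgf, save_as_msp
from matchms.importing import load_from_mgf, load_from_msp

from .chem import AdductType, get_adduct
from .errors import ConfigurationError, DegenerateSpectrumError


@dataclass(frozen=True)
class Spectrum:
    """One MS² spectrum: precursor, mode and a peak list sorted by m/z."""

    id: str
    precursor_mz: float
    ion_mode: str  # "positive" | "negative"
    peaks: tuple[tuple[float, float], ...]
    adduct_hint: AdductType | None = None
    retention_time: float | None = None  # minutes
    normalized: bool = False

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ConfigurationError("precursor m/z must be positive")
        object.__setattr__(
            self, "peaks", tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        )

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(sum(i for _, i in self.peaks))


def normalize_spectrum(s: Spectrum, min_relative_intensity: float = 0.0) -> Spectrum:
    """Normalize intensities to sum 1, dropping peaks below a relative floor.

    ``min_relative_intensity`` is a fraction of the total intensity;
    sub-threshold peaks are removed before renormalization.
    """
    if not s.peaks:
        raise DegenerateSpectrumError("spectrum has no peaks")
    total = s.total_intensity
    if total <= 0:
        raise DegenerateSpectrumError("all peak intensities are zero")
    kept = [(m, i) for m, i in s.peaks if i / total >= min_relative_intensity]
    if not kept:
        raise DegenerateSpectrumError("no peaks above the intensity threshold")
    new_total = sum(i for _, i in kept)
    peaks = tuple((m, i / new_total) for m, i in kept)
    return replace(s, peaks=peaks, normalized=True)


# ---------------------------------------------------------------------------
# matchms bridge


def to_matchms(s: Spectrum) -> MatchmsSpectrum:
    meta = {
        "id": s.id,
        "precursor_mz": float(s.precursor_mz),
        "ionmode": s.ion_mode,
    }
    if s.retention_time is not None:
        meta["retention_time"] = float(s.retention_time)
    if s.adduct_hint is not None:
        meta["adduct"] = s.adduct_hint.name
    return MatchmsSpectrum(
        mz=np.array([p[0] for p in s.peaks], dtype=float),
        intensities=np.array([p[1] for p in s.peaks], dtype=float),
        metadata=meta,
        metadata_harmonization=False,
    )


def _mode_from_meta(meta: dict, default: str = "positive") -> str:
    mode = (meta.get("ionmode") or "").lower()
    if mode in ("positive", "negative"):
        return mode
    adduct = meta.get("adduct") or ""
    if adduct.endswith("-"):
        return "negative"
    if adduct.endswith("+"):
        return "positive"
    return default


def from_matchms(ms: MatchmsSpectrum, fallback_id: str = "") -> Spectrum | None:
    meta = ms.metadata
    pmz = meta.get("precursor_mz") or meta.get("pepmass")
    if isinstance(pmz, (tuple, list)):
        pmz = pmz[0]
    if pmz is None or float(pmz) <= 0:
        return None
    adduct = None
    try:
        if meta.get("adduct"):
            adduct = get_adduct(meta["adduct"])
    except ConfigurationError:
        adduct = None
    rt = meta.get("retention_time")
    return Spectrum(
        id=str(meta.get("id") or meta.get("title") or fallback_id),
        precursor_mz=float(pmz),
        ion_mode=_mode_from_meta(meta),
        peaks=tuple(zip(ms.peaks.mz.tolist(), ms.peaks.intensities.tolist())),
        adduct_hint=adduct,
        retention_time=float(rt) if rt is not None else None,
    )


# ---------------------------------------------------------------------------
# Readers


def read_spectra(path, format: str | None = None, min_area: float = 0.0) -> list[Spectrum]:
    """Read spectra from an MGF, MSP or MS-DIAL-style txt file.

    ``format`` is inferred from the file suffix when omitted.  Malformed
    records are skipped.  ``min_area`` applies only to the MS-DIAL dialect
    (rows whose area/height column falls below it are dropped).
    """
    path = str(path)
    if format is None:
        suffix = path.rsplit(".", 1)[-1].lower()
        format = {"mgf": "mgf", "msp": "msp", "txt": "msdial_txt", "tsv": "msdial_txt"}.get(
            suffix
        )
    if format == "mgf":
        loaded = load_from_mgf(path, metadata_harmonization=False)
    elif format == "msp":
        loaded = load_from_msp(path, metadata_harmonization=False)
    elif format == "msdial_txt":
        return _read_msdial(path, min_area)
    else:
        raise ConfigurationError(f"unknown spectrum format {format!r}")
    out = []
    for k, ms in enumerate(loaded):
        if ms is None:
            continue
        s = from_matchms(ms, fallback_id=f"spectrum_{k}")
        if s is not None:
            out.append(s)
    return out


_MZ_COLUMNS = ("precursor m/z", "precursormz", "average mz")
_RT_COLUMNS = ("rt (min)", "average rt(min)", "retention time")
_AREA_COLUMNS = ("area", "height", "peak area")
_ID_COLUMNS = ("alignment id", "id", "title", "metabolite name")


def _find_col(header: list[str], names) -> int | None:
    lowered = [h.strip().lower() for h in header]
    for name in names:
        if name in lowered:
            return lowered.index(name)
    return None


def _read_msdial(path, min_area: float) -> list[Spectrum]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    i_mz = _find_col(header, _MZ_COLUMNS)
    i_rt = _find_col(header, _RT_COLUMNS)
    i_area = _find_col(header, _AREA_COLUMNS)
    i_id = _find_col(header, _ID_COLUMNS)
    i_adduct = _find_col(header, ("adduct type", "adduct"))
    i_ms2 = next(
        (k for k, h in enumerate(header) if "spectrum" in h.strip().lower()), None
    )
    if i_mz is None or i_ms2 is None:
        raise ConfigurationError(
            "MS-DIAL table needs a precursor m/z column and an MS/MS spectrum column"
        )
    out = []
    for row_no, line in enumerate(lines[1:]):
        parts = line.split("\t")
        try:
            pmz = float(parts[i_mz])
            if i_area is not None and parts[i_area] and float(parts[i_area]) < min_area:
                continue
            peaks = []
            for token in parts[i_ms2].split():
                mz_s, int_s = token.split(":")
                peaks.append((float(mz_s), float(int_s)))
            if not peaks:
                continue
            adduct = None
            mode = "positive"
            if i_adduct is not None and parts[i_adduct]:
                name = parts[i_adduct].strip()
                mode = "negative" if name.endswith("-") else "positive"
                try:
                    adduct = get_adduct(name)
                except ConfigurationError:
                    adduct = None
            rt = (
                float(parts[i_rt])
                if i_rt is not None and parts[i_rt]
                else None
            )
            sid = parts[i_id] if i_id is not None else f"row_{row_no}"
            out.append(
                Spectrum(
                    id=sid,
                    precursor_mz=pmz,
                    ion_mode=mode,
                    peaks=tuple(peaks),
                    adduct_hint=adduct,
                    retention_time=rt,
                )
            )
        except (ValueError, IndexError):
            continue
    return out


def write_spectra(spectra: list[Spectrum], path, format: str | None = None) -> None:
    """Write spectra as MGF or MSP (via matchms)."""
    path = str(path)
    if format is None:
        format = path.rsplit(".", 1)[-1].lower()
    ms_list = [to_matchms(s) for s in spectra]
    if format == "mgf":
        save_as_mgf(ms_list, path)
    elif format == "msp":
        save_as_msp(ms_list, path, style="massbank")
    else:
        raise ConfigurationError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# Annotation report


REPORT_COLUMNS = [
    "query_id",
    "rank",
    "candidate_id",
    "smiles",
    "formula",
    "adduct",
    "S0",
    "S1",
    "S2",
    "S3",
    "S4",
    "S5",
    "final_score",
]


def write_annotation_report(rows: list[dict], path) -> None:
    """Write ranked annotation results as a TSV report."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{row.get(c, ''):.4f}" if isinstance(row.get(c), float) else str(row.get(c, ""))
                    for c in REPORT_COLUMNS
                )
                + "\n"
            )
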