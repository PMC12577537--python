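"""Adduct m/z computation and per-compound detection calls from peak lists.

Detection works on centroided (m/z, intensity) peak lists, one per well per
platform per ionization mode. A compound is sought as its singly charged
adducts — protonated [M+H]+ and sodiated [M+Na]+ in positive mode,
deprotonated [M-H]- in negative mode — within a ppm mass tolerance, and a
matched peak counts as detected only when its intensity clears an S/N
threshold against the spectrum's noise floor (median intensity of the
non-matched peaks; unit floor for a one-peak spectrum). Compounds whose
adducts fall outside the instrument's acquisition window (50-650 Da by
default) are not assessable and are excluded from downstream denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEPROTONATION_SHIFT, PROTON_SHIFT, SODIUM_SHIFT

__all__ = [
    "AdductSpec",
    "DEFAULT_ADDUCTS",
    "DetectionConfig",
    "DetectionRecord",
    "PeakList",
    "adduct_mz",
    "adducts_for_mode",
    "call_detection",
    "compound_detected",
    "in_window",
    "match_peak",
]


@dataclass(frozen=True)
class AdductSpec:
    name: str
    polarity: str  # "positive" | "negative"
    mass_shift: float  # Da, signed
    charge: int  # +1 or -1


DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("[M+H]+", "positive", PROTON_SHIFT, +1),
    AdductSpec("[M+Na]+", "positive", SODIUM_SHIFT, +1),
    AdductSpec("[M-H]-", "negative", DEPROTONATION_SHIFT, -1),
)


def adducts_for_mode(mode: str) -> tuple[AdductSpec, ...]:
    return tuple(a for a in DEFAULT_ADDUCTS if a.polarity == mode)


@dataclass
class PeakList:
    """Centroided spectrum for one well on one platform in one mode."""

    platform: str  # "AEMS" | "UPLC-MS"
    mode: str  # "positive" | "negative"
    well: str
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("peaks require mz > 0 and intensity >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def tic(self) -> float:
        """Total ion current: summed intensity of all peaks."""
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class DetectionConfig:
    tol_ppm: float = 10.0
    tol_da: float | None = None  # absolute-tolerance alternative (quad-like)
    snr_min: float = 3.0
    mass_window: tuple[float, float] = (50.0, 650.0)

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.snr_min < 1:
            raise ValueError("snr_min must be >= 1")
        if self.mass_window[0] >= self.mass_window[1]:
            raise ValueError("mass_window must satisfy low < high")


@dataclass(frozen=True)
class DetectionRecord:
    compound_id: str
    platform: str
    mode: str
    adduct: str
    detected: bool
    matched_mz: float | None = None
    mass_error_ppm: float | None = None
    auc: float = 0.0

    def __post_init__(self) -> None:
        if not self.detected and (self.matched_mz is not None or self.auc != 0.0):
            raise ValueError("not-detected records carry no match and zero AUC")


def adduct_mz(M: float, adduct: AdductSpec) -> float:
    """m/z of a singly charged adduct: neutral mass plus the ion shift."""
    if M <= 0:
        raise ValueError("neutral mass must be positive")
    return M + adduct.mass_shift


def in_window(M: float, config: DetectionConfig = DetectionConfig()) -> bool:
    """True iff every default-adduct m/z lies inside the acquisition window."""
    lo, hi = config.mass_window
    return all(lo <= adduct_mz(M, a) <= hi for a in DEFAULT_ADDUCTS)


def match_peak(
    peaks: PeakList, target_mz: float, tol_ppm: float = 10.0,
    tol_da: float | None = None,
) -> int | None:
    """Index of the best in-tolerance peak, or None.

    Best = smallest |ppm error|; exact ties broken by higher intensity,
    then by lower m/z. Tolerance is ppm-based unless ``tol_da`` is given.
    """
    if len(peaks) == 0:
        return None
    tol = tol_da if tol_da is not None else target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(peaks.mz, target_mz - tol, side="left")
    hi = np.searchsorted(peaks.mz, target_mz + tol, side="right")
    if lo == hi:
        return None
    cand = np.arange(lo, hi)
    err = np.abs(peaks.mz[cand] - target_mz)
    in_tol = err <= tol
    if not np.any(in_tol):
        return None
    cand, err = cand[in_tol], err[in_tol]
    # lexicographic: |error| asc, intensity desc, mz asc
    order = np.lexsort((peaks.mz[cand], -peaks.intensity[cand], err))
    return int(cand[order[0]])


def call_detection(
    compound_id: str,
    neutral_mass: float,
    peaks: PeakList,
    config: DetectionConfig = DetectionConfig(),
) -> list[DetectionRecord]:
    """One DetectionRecord per adduct of the peak list's polarity.

    A matched peak is called detected when its intensity reaches
    ``snr_min`` times the noise floor, estimated as the median intensity of
    the non-matched peaks (1 intensity unit when no non-matched peaks
    exist). Peaks matched by *any* adduct of this compound count as signal,
    not background, so a compound's own weaker adduct is never drowned out
    by its stronger one.
    """
    matched_idx: dict[str, int | None] = {}
    for adduct in adducts_for_mode(peaks.mode):
        target = adduct_mz(neutral_mass, adduct)
        matched_idx[adduct.name] = match_peak(
            peaks, target, config.tol_ppm, config.tol_da
        )
    signal = [i for i in matched_idx.values() if i is not None]
    others = np.delete(peaks.intensity, signal)
    noise = float(np.median(others)) if len(others) else 1.0

    records = []
    for adduct in adducts_for_mode(peaks.mode):
        target = adduct_mz(neutral_mass, adduct)
        idx = matched_idx[adduct.name]
        if idx is None:
            records.append(
                DetectionRecord(compound_id, peaks.platform, peaks.mode,
                                adduct.name, detected=False)
            )
            continue
        matched_int = float(peaks.intensity[idx])
        if matched_int >= config.snr_min * noise:
            err_ppm = 1e6 * (peaks.mz[idx] - target) / target
            records.append(
                DetectionRecord(
                    compound_id, peaks.platform, peaks.mode, adduct.name,
                    detected=True, matched_mz=float(peaks.mz[idx]),
                    mass_error_ppm=float(err_ppm), auc=matched_int,
                )
            )
        else:
            records.append(
                DetectionRecord(compound_id, peaks.platform, peaks.mode,
                                adduct.name, detected=False)
            )
    return records


def compound_detected(
    records: Sequence[DetectionRecord], rule: str = "any_adduct"
) -> bool:
    """Aggregate per-adduct records for one compound+platform.

    any_adduct (default): at least one adduct detected across both modes.
    all_adducts: every assessable adduct detected.
    """
    if not records:
        raise ValueError("no detection records supplied")
    if rule == "any_adduct":
        return any(r.detected for r in records)
    if rule == "all_adducts":
        return all(r.detected for r in records)
    raise ValueError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# CSV interfaces

def peaklists_to_frame(peaklists: Iterable[PeakList]) -> pd.DataFrame:
    rows = []
    for pl in peaklists:
        for mz, inten in zip(pl.mz, pl.intensity):
            rows.append(
                {"platform": pl.platform, "mode": pl.mode, "well": pl.well,
                 "mz": mz, "intensity": inten}
            )
    return pd.DataFrame(rows, columns=["platform", "mode", "well", "mz", "intensity"])


def write_peaklists_csv(peaklists: Iterable[PeakList], path) -> None:
    df = peaklists_to_frame(peaklists)
    df["mz"] = df["mz"].map(lambda v: f"{v:.6f}")
    df["intensity"] = df["intensity"].map(lambda v: f"{v:.4f}")
    df.to_csv(path, index=False)


def read_peaklists_csv(path) -> list[PeakList]:
    df = pd.read_csv(path)
    out = []
    for (platform, mode, well), grp in df.groupby(
        ["platform", "mode", "well"], sort=True
    ):
        out.append(
            PeakList(platform=str(platform), mode=str(mode), well=str(well),
                     mz=grp["mz"].to_numpy(), intensity=grp["intensity"].to_numpy())
        )
    return out


def read_peaklists_mzml(path, platform: str, mode: str, well: str) -> list[PeakList]:
    """Read centroided spectra from an mzML file into PeakLists.

    Real-data convenience path (one file per well); each spectrum in the
    file becomes one PeakList with the supplied platform/mode/well labels.
    """
    from pyteomics import mzml as _mzml

    out = []
    with _mzml.read(str(path)) as reader:
        for spectrum in reader:
            out.append(
                PeakList(
                    platform=platform, mode=mode, well=well,
                    mz=np.asarray(spectrum["m/z array"], dtype=float),
                    intensity=np.asarray(spectrum["intensity array"], dtype=float),
                )
            )
    return out


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id, "platform": r.platform,
                "mode": r.mode, "adduct": r.adduct, "detected": r.detected,
                "matched_mz": r.matched_mz, "mass_error_ppm": r.mass_error_ppm,
                "auc": r.auc,
            }
            for r in records
        ],
        columns=["compound_id", "platform", "mode", "adduct", "detected",
                 "matched_mz", "mass_error_ppm", "auc"],
    )
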