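"""Spectrum data model, MGF/MSP I/O, peak matching and cosine similarity.

The :class:`Spectrum` container holds a centroided fragmentation spectrum
with its precursor m/z, adduct and collision energy. Peak matching uses a
deterministic greedy one-to-one assignment (closest mass pairs first)
within a ppm window, the convention used by spectral-library search tools.
The modified cosine here is the plain normalized dot product over matched
peaks — no neutral-loss shifting — with the precursor ion excluded because
its intensity would overshadow fragment peaks.

Pseudo-ramp ("merged") spectra combine acquisitions at several collision
energies into one spectrum: each input is normalized to maximum intensity
1, peaks are clustered within the ppm tolerance, and each cluster becomes
one peak at the intensity-weighted mean mass with summed intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _pt_mgf

__all__ = [
    "Peak",
    "Spectrum",
    "read_mgf",
    "write_mgf",
    "read_msp",
    "match_peaks",
    "cosine_score",
    "merge_spectra",
]


@dataclass(frozen=True)
class Peak:
    """A single centroided peak: m/z in Da, non-negative intensity."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValueError(f"peak mz must be positive, got {self.mz}")
        if not (self.intensity >= 0):
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """A fragmentation spectrum with precursor metadata.

    Peaks are kept sorted by ascending m/z; ``collision_energy`` is either
    a number (eV) or the string ``"merged"`` for pseudo-ramp spectra.
    """

    id: str
    peaks: List[Peak] = field(default_factory=list)
    precursor_mz: float = 0.0
    adduct: str = "[M+H]+"
    collision_energy: float | str | None = None
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        if self.precursor_mz is not None and self.precursor_mz > 0:
            pass
        elif self.precursor_mz not in (0.0, None):
            raise ValueError(f"precursor_mz must be > 0, got {self.precursor_mz}")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        for p in self.peaks:
            if math.isnan(p.mz) or math.isnan(p.intensity):
                raise ValueError("NaN values are not allowed in peaks")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def max_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def __len__(self) -> int:
        return len(self.peaks)

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=list(peaks))

    @classmethod
    def from_arrays(
        cls,
        mz: Sequence[float],
        intensity: Sequence[float],
        **kwargs,
    ) -> "Spectrum":
        peaks = [Peak(float(m), float(i)) for m, i in zip(mz, intensity)]
        return cls(peaks=peaks, **kwargs)


def _parse_energy(value) -> float | str | None:
    if value is None:
        return None
    text = str(value).strip()
    if text.lower() == "merged":
        return "merged"
    # tolerate forms like "20", "20.0", "20 eV", "HCD 20"
    for token in text.replace("eV", " ").split():
        try:
            return float(token)
        except ValueError:
            continue
    return text or None


def read_mgf(path: str | Path) -> List[Spectrum]:
    """Read spectra from an MGF file.

    Recognizes PEPMASS, CHARGE, TITLE, COLLISION_ENERGY and ION_MODE
    headers. Malformed blocks raise a parse error naming the offending
    construct (propagated from the pyteomics reader).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: List[Spectrum] = []
    with _pt_mgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0]) if pepmass and pepmass[0] else 0.0
            charge = params.get("charge")
            ion_mode = "positive"
            if charge:
                try:
                    ion_mode = "negative" if int(charge[0]) < 0 else "positive"
                except (TypeError, ValueError):
                    pass
            spectra.append(
                Spectrum.from_arrays(
                    entry["m/z array"],
                    entry["intensity array"],
                    id=str(params.get("title", f"spectrum_{idx}")),
                    precursor_mz=precursor,
                    adduct=str(params.get("adduct", "[M+H]+")),
                    collision_energy=_parse_energy(params.get("collision_energy")),
                    ion_mode=ion_mode,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF; round-trips with :func:`read_mgf`."""
    entries = []
    for s in spectra:
        params = {
            "title": s.id,
            "pepmass": s.precursor_mz,
            "adduct": s.adduct,
            "charge": "1-" if s.ion_mode == "negative" else "1+",
        }
        if s.collision_energy is not None:
            params["collision_energy"] = s.collision_energy
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": params,
            }
        )
    _pt_mgf.write(entries, str(path), file_mode="w")


def read_msp(path: str | Path) -> List[Spectrum]:
    """Read spectra from an MSP library file (via matchms)."""
    from matchms.importing import load_from_msp

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: List[Spectrum] = []
    for idx, ms in enumerate(load_from_msp(str(path), metadata_harmonization=True)):
        if ms is None:
            continue
        meta = ms.metadata
        spectra.append(
            Spectrum.from_arrays(
                ms.peaks.mz,
                ms.peaks.intensities,
                id=str(meta.get("compound_name") or meta.get("title") or f"spectrum_{idx}"),
                precursor_mz=float(meta.get("precursor_mz") or 0.0),
                adduct=str(meta.get("adduct") or "[M+H]+"),
                collision_energy=_parse_energy(meta.get("collision_energy")),
                ion_mode=str(meta.get("ionmode") or "positive"),
            )
        )
    return spectra


def _ppm_window(mz_a: float, mz_b: float, tol_ppm: float) -> bool:
    return abs(mz_a - mz_b) <= tol_ppm * 1e-6 * max(mz_a, mz_b)


def match_peaks(
    a: Spectrum, b: Spectrum, tol_ppm: float = 7.0
) -> List[Tuple[int, int]]:
    """One-to-one peak matching within a ppm tolerance.

    Candidate pairs within the window are sorted by absolute mass
    difference and assigned greedily (closest pairs first), so the
    matching is deterministic. Returns (index_a, index_b) pairs.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mza, mzb = a.mz, b.mz
    candidates: List[Tuple[float, int, int]] = []
    j_lo = 0
    for i, m in enumerate(mza):
        tol = tol_ppm * 1e-6 * m  # conservative lower bound for scan window
        while j_lo < len(mzb) and mzb[j_lo] < m - 2 * tol:
            j_lo += 1
        j = j_lo
        while j < len(mzb) and mzb[j] <= m + 2 * tol:
            if _ppm_window(m, mzb[j], tol_ppm):
                candidates.append((abs(m - mzb[j]), i, j))
            j += 1
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    pairs: List[Tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs


def _exclude_precursor(s: Spectrum, tol_ppm: float) -> Spectrum:
    if s.precursor_mz <= 0:
        return s
    kept = [
        p for p in s.peaks if not _ppm_window(p.mz, s.precursor_mz, tol_ppm)
    ]
    return s.with_peaks(kept)


def cosine_score(
    a: Spectrum,
    b: Spectrum,
    tol_ppm: float = 7.0,
    sqrt_intensities: bool = False,
    exclude_precursor: bool = True,
) -> float:
    """Normalized dot product over matched peaks, in [0, 1].

    Each spectrum's intensity vector (optionally square-rooted) is
    normalized to unit L2 norm over all its peaks, so unmatched peaks
    count against the score. Precursor ion peaks (within ``tol_ppm`` of
    the precursor m/z) are excluded by default.
    """
    if exclude_precursor:
        a = _exclude_precursor(a, tol_ppm)
        b = _exclude_precursor(b, tol_ppm)
    if len(a) == 0 and len(b) == 0:
        raise ValueError("cosine undefined: both spectra empty after precursor exclusion")
    if len(a) == 0 or len(b) == 0:
        return 0.0
    ia, ib = a.intensity, b.intensity
    if sqrt_intensities:
        ia, ib = np.sqrt(ia), np.sqrt(ib)
    na, nb = np.linalg.norm(ia), np.linalg.norm(ib)
    if na == 0 or nb == 0:
        return 0.0
    ia, ib = ia / na, ib / nb
    score = sum(ia[i] * ib[j] for i, j in match_peaks(a, b, tol_ppm))
    return float(min(1.0, max(0.0, score)))


def merge_spectra(
    spectra: Sequence[Spectrum],
    tol_ppm: float = 7.0,
    precursor_tol_ppm: float = 20.0,
) -> Spectrum:
    """Combine spectra at different collision energies into a pseudo-ramp spectrum.

    All inputs must share the precursor m/z within ``precursor_tol_ppm``.
    Each input is normalized to max intensity 1; peaks across inputs are
    clustered within ``tol_ppm`` and each cluster is collapsed to a single
    peak (intensity-weighted mean mass, summed intensity). The output is
    labelled ``collision_energy="merged"``.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot merge an empty list of spectra")
    p0 = spectra[0].precursor_mz
    for s in spectra[1:]:
        if p0 > 0 and s.precursor_mz > 0 and not _ppm_window(
            s.precursor_mz, p0, precursor_tol_ppm
        ):
            raise ValueError(
                f"precursor mismatch: {s.precursor_mz} vs {p0} beyond "
                f"{precursor_tol_ppm} ppm"
            )
    all_peaks: List[Peak] = []
    for s in spectra:
        mx = s.max_intensity or 1.0
        all_peaks.extend(Peak(p.mz, p.intensity / mx) for p in s.peaks)
    all_peaks.sort(key=lambda p: p.mz)
    merged: List[Peak] = []
    cluster: List[Peak] = []
    for p in all_peaks:
        if cluster and not _ppm_window(p.mz, cluster[0].mz, tol_ppm):
            merged.append(_collapse(cluster))
            cluster = []
        cluster.append(p)
    if cluster:
        merged.append(_collapse(cluster))
    return Spectrum(
        id=spectra[0].id,
        peaks=merged,
        precursor_mz=p0,
        adduct=spectra[0].adduct,
        collision_energy="merged",
        ion_mode=spectra[0].ion_mode,
    )


def _collapse(cluster: List[Peak]) -> Peak:
    total = sum(p.intensity for p in cluster)
    if total == 0:
        return Peak(cluster[0].mz, 0.0)
    mz = sum(p.mz * p.intensity for p in cluster) / total
    return Peak(mz, total)
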