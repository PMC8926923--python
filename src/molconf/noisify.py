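"""Controlled distortion of reference spectra ("noisification").

Library spectra are typically much cleaner than spectra from a biological
LC-MS/MS run. To emulate biological quality, each spectrum is distorted in
four steps:

1. a global relative mass shift (bias) drawn once per spectrum from
   N(0, sigma_mb^2), applied multiplicatively to every peak mass;
2. an individual relative mass deviation per peak, N(0, sigma_md^2);
3. multiplicative intensity distortion per peak with factor ~ N(1,
   sigma_id_sq), then subtraction of ``subtract_frac`` times the maximum
   intensity from every peak, discarding peaks below ``floor_frac`` times
   the maximum;
4. injection of round(alpha * n) realistic "noise peaks" drawn from a pool
   harvested from other spectra — peaks whose mass has no subformula
   decomposition of the donor's precursor formula (uniform random masses
   would be trivially recognisable).

Two presets are provided. Medium noise uses sigma_mb = sigma_md =
(10/3)e-6 (a 3-sigma window of 10 ppm), sigma_id_sq = 1, alpha = 0.2;
high noise uses sigma_mb = (15/3)e-6 (3 sigma = 15 ppm), sigma_md =
(20/3)e-6 (3 sigma = 20 ppm), sigma_id_sq = 2, alpha = 0.4. Both subtract
3% of the maximum intensity and discard peaks below 1/1000 of the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .formula import PROTON_MASS, subformula_decomposable
from .spectra import Peak, Spectrum, cosine_score

__all__ = [
    "NoiseModel",
    "MEDIUM_NOISE",
    "HIGH_NOISE",
    "NoisePeakPool",
    "build_noise_peak_pool",
    "noisify",
    "filter_sparse",
    "calibrate_noise_level",
]


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of the spectral noise model (all mass terms relative)."""

    sigma_mb: float  # std of the global mass bias, relative (unitless)
    sigma_md: float  # std of the per-peak mass deviation, relative
    sigma_id_sq: float  # variance of the multiplicative intensity factor
    subtract_frac: float = 0.03  # fraction of max intensity subtracted
    floor_frac: float = 1e-3  # relative intensity discard threshold
    alpha: float = 0.2  # noise peaks added per existing peak

    def __post_init__(self) -> None:
        if self.sigma_mb < 0 or self.sigma_md < 0 or self.sigma_id_sq < 0:
            raise ValueError("noise std/variance parameters must be >= 0")
        if not (0 <= self.subtract_frac < 1):
            raise ValueError("subtract_frac must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def scaled(self, factor: float) -> "NoiseModel":
        """Scale the intensity-distortion variance and noise-peak rate."""
        return replace(
            self, sigma_id_sq=self.sigma_id_sq * factor, alpha=self.alpha * factor
        )


#: Medium-noise preset: 3*sigma_mb = 10 ppm, 3*sigma_md = 10 ppm.
MEDIUM_NOISE = NoiseModel(
    sigma_mb=(10 / 3) * 1e-6, sigma_md=(10 / 3) * 1e-6, sigma_id_sq=1.0, alpha=0.2
)
#: High-noise preset: 3*sigma_mb = 15 ppm, 3*sigma_md = 20 ppm.
HIGH_NOISE = NoiseModel(
    sigma_mb=(15 / 3) * 1e-6, sigma_md=(20 / 3) * 1e-6, sigma_id_sq=2.0, alpha=0.4
)

PRESETS: Dict[str, NoiseModel] = {"medium": MEDIUM_NOISE, "high": HIGH_NOISE}


@dataclass
class NoisePeakPool:
    """Pool of realistic noise peaks: (mz, intensity relative to donor max)."""

    peaks: List[Tuple[float, float]]

    def __len__(self) -> int:
        return len(self.peaks)


def build_noise_peak_pool(
    spectra: Iterable[Spectrum],
    formulas: Mapping[str, str],
    tol_ppm: float = 10.0,
    adduct_mass: float = PROTON_MASS,
) -> NoisePeakPool:
    """Harvest noise peaks from donor spectra.

    A peak enters the pool iff its mass has no subformula decomposition of
    the donor's precursor formula (within ``tol_ppm``, offset by
    ``adduct_mass``). Intensities are stored relative to the donor
    spectrum's maximum intensity. Donors missing from ``formulas`` raise.
    """
    pool: List[Tuple[float, float]] = []
    for s in spectra:
        if s.id not in formulas:
            raise KeyError(f"no molecular formula provided for spectrum {s.id!r}")
        mx = s.max_intensity or 1.0
        for p in s.peaks:
            if not subformula_decomposable(
                p.mz, formulas[s.id], tol_ppm=tol_ppm, adduct_mass=adduct_mass
            ):
                pool.append((p.mz, p.intensity / mx))
    return NoisePeakPool(pool)


def noisify(
    s: Spectrum,
    model: NoiseModel,
    pool: NoisePeakPool | None = None,
    rng: np.random.Generator | int | None = None,
) -> Spectrum:
    """Apply the four-step noise model to one spectrum.

    ``rng`` may be a Generator or a seed; a fixed seed gives identical
    output across calls. Requires a nonempty spectrum, and a nonempty pool
    whenever round(alpha * n) >= 1 noise peaks are to be injected.
    """
    if len(s) == 0:
        raise ValueError("cannot noisify an empty spectrum")
    rng = np.random.default_rng(rng)

    mz = s.mz.copy()
    inten = s.intensity.copy()

    # (1) global mass bias, one draw per spectrum
    delta_star = rng.normal(0.0, model.sigma_mb)
    mz = mz * (1.0 + delta_star)
    # (2) per-peak mass deviation
    mz = mz * (1.0 + rng.normal(0.0, model.sigma_md, size=mz.shape))
    # (3) intensity distortion: multiply, subtract, floor
    inten = inten * rng.normal(1.0, np.sqrt(model.sigma_id_sq), size=inten.shape)
    inten = np.maximum(inten, 0.0)
    mx = inten.max() if inten.size else 0.0
    inten = inten - model.subtract_frac * mx
    keep = inten >= model.floor_frac * mx
    mz, inten = mz[keep], inten[keep]

    peaks = [Peak(m, i) for m, i in zip(mz, inten) if m > 0]

    # (4) realistic noise peaks from the pool
    n_noise = int(round(model.alpha * len(peaks)))
    if n_noise > 0:
        if pool is None or len(pool) == 0:
            raise ValueError(
                f"noise-peak pool is empty but {n_noise} noise peaks requested"
            )
        receiving_max = max((p.intensity for p in peaks), default=1.0)
        idx = rng.integers(0, len(pool), size=n_noise)
        for k in idx:
            nmz, rel_int = pool.peaks[int(k)]
            peaks.append(Peak(nmz, rel_int * receiving_max))

    return s.with_peaks(peaks)


def filter_sparse(spectra: Iterable[Spectrum], min_peaks: int = 2) -> List[Spectrum]:
    """Drop spectra with fewer than ``min_peaks`` peaks (default: <= 1 peak)."""
    return [s for s in spectra if len(s) >= min_peaks]


def calibrate_noise_level(
    spectra: Sequence[Spectrum],
    base_model: NoiseModel,
    pool: NoisePeakPool,
    target_median_cosine: float,
    seed: int = 0,
    tol_ppm: float = 7.0,
    factor_bounds: Tuple[float, float] = (0.05, 20.0),
    xtol: float = 0.02,
) -> Tuple[NoiseModel, float]:
    """Scale (sigma_id_sq, alpha) so the median original-vs-distorted cosine
    hits a target.

    The median cosine decreases monotonically (in expectation) with the
    scale factor; a bisection on the factor finds the level at which the
    Monte Carlo median (fixed seed, so the objective is deterministic)
    matches ``target_median_cosine``. Returns the scaled model and the
    achieved median.
    """

    def median_cosine(factor: float) -> float:
        model = base_model.scaled(factor)
        scores = []
        for i, s in enumerate(spectra):
            noisy = noisify(s, model, pool, rng=seed + i)
            if len(noisy) == 0:
                scores.append(0.0)
                continue
            scores.append(cosine_score(s, noisy, tol_ppm=tol_ppm))
        return float(np.median(scores))

    lo, hi = factor_bounds
    f_lo, f_hi = median_cosine(lo), median_cosine(hi)
    if not (f_hi <= target_median_cosine <= f_lo):
        raise ValueError(
            f"target median cosine {target_median_cosine} outside achievable "
            f"range [{f_hi:.3f}, {f_lo:.3f}] for factors {factor_bounds}"
        )
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if median_cosine(mid) >= target_median_cosine:
            lo = mid
        else:
            hi = mid
    factor = 0.5 * (lo + hi)
    return base_model.scaled(factor), median_cosine(factor)
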