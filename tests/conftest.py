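"""Shared fixtures: random spectra, synthetic hit data, trained models."""

from __future__ import annotations

import numpy as np
import pytest

from molconf import (
    ConfidenceSVM,
    HitDatasetSpec,
    Spectrum,
    gen_hit_dataset,
)


def random_spectrum(
    rng: np.random.Generator,
    n_peaks: int = 10,
    mz_range: tuple[float, float] = (50.0, 900.0),
    spectrum_id: str = "s",
) -> Spectrum:
    """Random centroided spectrum with well-separated peaks."""
    mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    intensity = rng.exponential(100.0, size=n_peaks) + 1.0
    return Spectrum.from_arrays(
        mz, intensity, id=spectrum_id, precursor_mz=float(mz_range[1] + 50.0),
        collision_energy=20.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240617)


@pytest.fixture(scope="session")
def hit_dataset():
    """Synthetic labeled hit dataset at the default study conditions."""
    return gen_hit_dataset(HitDatasetSpec(n_queries=2000, seed=11))


@pytest.fixture(scope="session")
def trained_model(hit_dataset):
    """Multi-candidate confidence model fitted once per session (fixed C)."""
    multi = hit_dataset[hit_dataset.n_candidates > 1].dropna()
    model = ConfidenceSVM.from_dataframe(
        multi.drop(columns=["query_id", "n_candidates"]),
        collision_energy="merged",
    )
    return model.fit(C=0.01, seed=0)
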