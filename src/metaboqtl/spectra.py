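"""Paired CPMG / JRES-projection spectrum simulation.

Each sample's spectrum is a sum of metabolite signatures (pseudo-Voigt
multiplets) scaled by that sample's concentrations.  The JRES projection
keeps the narrow signature linewidths but carries more noise relative to
signal; the CPMG spectrum re-broadens every peak by a common factor and
adds a polynomial baseline, but is less noisy — the resolution versus
signal-to-noise trade-off the two experiments are combined for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .nmr import MetaboliteSignature, PeakModel, Spectrum, peak_sum


@dataclass(frozen=True)
class SpectrumSet:
    """Paired per-sample CPMG and JRES-projection spectra on one axis."""

    ppm: np.ndarray = field(repr=False)
    cpmg: np.ndarray = field(repr=False)  # samples x points
    jres: np.ndarray = field(repr=False)
    sample_ids: tuple[str, ...]

    def cpmg_spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.ppm, self.cpmg[i], kind="cpmg")

    def jres_spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.ppm, self.jres[i], kind="jres")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def default_axis(lo: float = 0.5, hi: float = 4.5, n_points: int = 4096) -> np.ndarray:
    return np.linspace(lo, hi, n_points)


def make_signature_library(
    n_metabolites: int,
    seed: int,
    ppm_range: tuple[float, float] = (0.7, 4.3),
    width_range: tuple[float, float] = (0.005, 0.009),
) -> list[MetaboliteSignature]:
    """Random but reproducible multiplet library.

    Each metabolite gets 1-3 peaks: a multiplet of lines ~0.015 ppm apart
    with positive relative amplitudes summing to one, and a shared
    Lorentzian fraction.  Multiplet centers are spaced far enough apart
    that distinct metabolites do not sit on top of each other.
    """
    if n_metabolites < 1:
        raise InvalidArgumentError("n_metabolites must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = ppm_range
    centers = np.sort(rng.uniform(lo, hi, n_metabolites))
    # enforce a minimal spacing so signatures stay assignable
    min_gap = (hi - lo) / (3.0 * n_metabolites)
    for i in range(1, n_metabolites):
        if centers[i] - centers[i - 1] < min_gap:
            centers[i] = centers[i - 1] + min_gap
    sigs = []
    for m, c0 in enumerate(centers):
        k = int(rng.integers(1, 4))
        rel = rng.uniform(0.5, 1.0, k)
        rel /= rel.sum()
        width = float(rng.uniform(*width_range))
        eta = float(rng.uniform(0.2, 0.8))
        offsets = (np.arange(k) - (k - 1) / 2.0) * 0.015
        peaks = tuple(
            PeakModel(center=float(c0 + o), width=width, amplitude=float(r), eta=eta)
            for o, r in zip(offsets, rel)
        )
        sigs.append(MetaboliteSignature(name=f"met{m + 1:02d}", peaks=peaks))
    return sigs


def simulate_concentrations(
    n_samples: int,
    signatures: list[MetaboliteSignature],
    seed: int,
    mean: float = 1.0,
    cv: float = 0.3,
) -> pd.DataFrame:
    """Independent lognormal concentration series per metabolite."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2.0
    vals = rng.lognormal(mu, sigma, size=(n_samples, len(signatures)))
    return pd.DataFrame(
        vals,
        index=[f"S{i + 1:04d}" for i in range(n_samples)],
        columns=[s.name for s in signatures],
    )


def simulate_spectra(
    signatures: list[MetaboliteSignature],
    concentrations: pd.DataFrame,
    noise_sd_cpmg: float = 0.01,
    noise_sd_jres: float = 0.03,
    baseline: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    ppm: np.ndarray | None = None,
    cpmg_broadening: float = 2.5,
) -> SpectrumSet:
    """Simulate paired CPMG and JRES-projection spectra.

    ``concentrations`` is samples x metabolites (columns must match the
    signature names).  The CPMG spectrum widens every peak by
    ``cpmg_broadening`` (height preserved) and adds the linear baseline
    ``baseline[0] + baseline[1] * (ppm - ppm_min)``; both spectra get iid
    Gaussian noise with the stated SDs.
    """
    if ppm is None:
        ppm = default_axis()
    conc = concentrations[[s.name for s in signatures]]
    if (conc.to_numpy() < 0).any():
        raise InvalidArgumentError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)

    # per-metabolite component templates, computed once
    jres_tmpl = np.array([peak_sum(ppm, s.peaks) for s in signatures])
    broad = [
        [replace(p, width=p.width * cpmg_broadening) for p in s.peaks]
        for s in signatures
    ]
    cpmg_tmpl = np.array([peak_sum(ppm, pk) for pk in broad])

    C = conc.to_numpy()
    jres = C @ jres_tmpl
    cpmg = C @ cpmg_tmpl + (baseline[0] + baseline[1] * (ppm - ppm[0]))
    if noise_sd_cpmg > 0:
        cpmg = cpmg + rng.normal(0.0, noise_sd_cpmg, cpmg.shape)
    if noise_sd_jres > 0:
        jres = jres + rng.normal(0.0, noise_sd_jres, jres.shape)
    return SpectrumSet(
        ppm=np.asarray(ppm, float),
        cpmg=cpmg,
        jres=jres,
        sample_ids=tuple(conc.index),
    )
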