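"""Synthetic pear-like Vis/NIR reflectance spectra with known SCC linkage.

The study data behind this pipeline are not publicly deposited, so every
downstream stage is exercised against a generator whose ground truth is
known.  The generative model is deliberately simple but targets the features
the pipeline must handle:

* a smooth reflectance envelope over an effective 498-1020 nm window with
  two reflective peaks (near 550 and 750 nm) and two valleys (near 680 and
  980 nm), mimicking pear flesh/skin spectra;
* "informative" bands (default the carbohydrate/water-related 750 and
  980 nm features) whose amplitude is linear in stone cell content with a
  negative slope — stone cell content is inversely related to carbohydrate
  content, so more stone cells means weaker carbohydrate features;
* per-replicate nuisance: multiplicative gain (scatter), a linear additive
  baseline drift, and white channel noise — exactly the corruption family
  MSC/SNV/Savitzky-Golay preprocessing is designed to remove;
* three replicate scans per sample (the instrument rotates each fruit by
  120 degrees between scans), averaged before modeling.

SCC values are drawn uniformly on (0.240, 0.657) %, the range of the
gravimetric measurements the pipeline emulates (mean approximately 0.49 %);
a truncated normal with matching mean/SD is available as an alternative.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .datasets import ReferenceSet, SpectraSet


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model.  Units: nm for wavelengths,
    % mass fraction for SCC, unitless reflectance otherwise."""

    n_samples: int = 120
    replicates_per_sample: int = 3
    grid: tuple[float, float, float] = (498.0, 1020.0, 0.5)  # low, high, step
    scc_range: tuple[float, float] = (0.240, 0.657)
    scc_distribution: str = "uniform"          # or "truncnorm"
    scc_mean: float = 0.486                    # used by truncnorm only
    scc_sd: float = 0.100
    band_centers: tuple[float, ...] = (550.0, 680.0, 750.0, 980.0)
    band_amplitudes: tuple[float, ...] = (0.15, -0.18, 0.35, -0.10)
    band_width_nm: float = 30.0
    informative_slopes: Mapping[float, float] = field(
        default_factory=lambda: {750.0: -0.30, 980.0: -0.20})
    scatter_sd: float = 0.05    # SD of multiplicative gain around 1
    drift_sd: float = 1e-4      # SD of additive baseline slope, per nm
    noise_sd: float = 0.003     # per-channel white noise SD
    band_jitter_sd: float = 0.01  # per-sample band-amplitude variability
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scc_range
        if not (0 < lo < hi < 100):
            raise ValueError("scc_range must satisfy 0 < min < max < 100")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be positive")
        if min(self.scatter_sd, self.drift_sd, self.noise_sd,
               self.band_jitter_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_samples < 1 or self.replicates_per_sample < 1:
            raise ValueError("need at least one sample and one replicate")
        if len(self.band_amplitudes) != len(self.band_centers):
            raise ValueError("one amplitude per band center")
        unknown = set(self.informative_slopes) - set(self.band_centers)
        if unknown:
            raise ValueError(f"informative bands not in band_centers: {unknown}")
        if self.scc_distribution not in ("uniform", "truncnorm"):
            raise ValueError("scc_distribution must be 'uniform' or 'truncnorm'")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(np.floor((hi - lo) / step + 0.5)) + 1
        return lo + step * np.arange(n)


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to recompute the noise-free part of a draw."""

    scc: np.ndarray                      # per sample, %
    gains: np.ndarray                    # (n_samples, replicates)
    drifts: np.ndarray                   # (n_samples, replicates), per nm
    band_jitter: np.ndarray              # (n_samples, n_bands) amplitude wobble
    informative_channels: np.ndarray     # channel indices carrying SCC signal
    replicate_groups: dict[str, str]     # replicate id -> sample id
    config: SyntheticConfig


def _envelope(wl: np.ndarray) -> np.ndarray:
    # broad, featureless backbone of pear flesh reflectance
    return 0.42 + 0.12 * np.exp(-0.5 * ((wl - 760.0) / 260.0) ** 2)


def model_spectrum(config: SyntheticConfig, scc: np.ndarray,
                   band_jitter: np.ndarray | None = None) -> np.ndarray:
    """Deterministic band model: one noise-free spectrum per SCC value.

    Band amplitude is ``a + b * scc`` for informative bands (slope ``b`` from
    ``informative_slopes``) and constant ``a`` otherwise; each band is a
    Gaussian of width ``band_width_nm`` on top of a smooth envelope.
    ``band_jitter`` (samples x bands), if given, adds the per-sample
    amplitude wobble recorded in a :class:`GroundTruth`.
    """
    wl = config.wavelengths
    scc = np.atleast_1d(np.asarray(scc, dtype=float))
    out = np.tile(_envelope(wl), (scc.size, 1))
    for b, (center, amp) in enumerate(zip(config.band_centers,
                                          config.band_amplitudes)):
        shape = np.exp(-0.5 * ((wl - center) / config.band_width_nm) ** 2)
        slope = config.informative_slopes.get(center, 0.0)
        amplitude = amp + slope * scc
        if band_jitter is not None:
            amplitude = amplitude + band_jitter[:, b]
        out += amplitude[:, None] * shape[None, :]
    return out


def _informative_channels(config: SyntheticConfig) -> np.ndarray:
    wl = config.wavelengths
    mask = np.zeros(wl.size, dtype=bool)
    for center, slope in config.informative_slopes.items():
        if slope != 0.0:
            mask |= np.abs(wl - center) <= 3.0 * config.band_width_nm
    return np.flatnonzero(mask)


def _draw_scc(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.scc_range
    if config.scc_distribution == "uniform":
        return rng.uniform(lo, hi, size=config.n_samples)
    a = (lo - config.scc_mean) / config.scc_sd
    b = (hi - config.scc_mean) / config.scc_sd
    u = rng.uniform(0.0, 1.0, size=config.n_samples)
    return stats.truncnorm.ppf(u, a, b, loc=config.scc_mean,
                               scale=config.scc_sd)


def generate(config: SyntheticConfig,
             seed: int | None = None
             ) -> tuple[SpectraSet, ReferenceSet, GroundTruth]:
    """Draw a full synthetic data set.

    Returns the replicate-level spectra (ids ``S001_r1`` etc. when there is
    more than one replicate), the per-sample SCC reference, and the ground
    truth.  Identical ``(config, seed)`` give bit-identical output.
    """
    wl = config.wavelengths
    if wl.size < 10:
        raise ValueError(f"grid yields only {wl.size} channels (< 10)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scc = _draw_scc(config, rng)
    n, reps = config.n_samples, config.replicates_per_sample
    band_jitter = config.band_jitter_sd * rng.standard_normal(
        (n, len(config.band_centers)))
    base = model_spectrum(config, scc, band_jitter)

    gains = 1.0 + config.scatter_sd * rng.standard_normal((n, reps))
    drifts = config.drift_sd * rng.standard_normal((n, reps))
    noise = config.noise_sd * rng.standard_normal((n, reps, wl.size))

    mid = 0.5 * (wl[0] + wl[-1])
    rows = (gains[:, :, None] * base[:, None, :]
            + drifts[:, :, None] * (wl - mid)[None, None, :]
            + noise)

    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    if reps == 1:
        rep_ids = sample_ids
    else:
        rep_ids = tuple(f"{sid}_r{k + 1}" for sid in sample_ids
                        for k in range(reps))
    spectra = SpectraSet(wl, rows.reshape(n * reps, wl.size), rep_ids)
    reference = ReferenceSet(sample_ids, scc)
    groups = {rid: rid.rpartition("_r")[0] if reps > 1 else rid
              for rid in rep_ids}
    truth = GroundTruth(scc=scc, gains=gains, drifts=drifts,
                        band_jitter=band_jitter,
                        informative_channels=_informative_channels(config),
                        replicate_groups=groups, config=config)
    return spectra, reference, truth


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

FIXTURES: dict[str, SyntheticConfig] = {
    # the study-sized data set: 120 fruit, 3 rotational scans each,
    # 0.5 nm grid over the effective window
    "paper-like-120": SyntheticConfig(seed=11_162_391),
    # tiny, noise-free, hand-enumerable (trimmed to 8 channels below)
    "tiny-10x8": SyntheticConfig(
        n_samples=10, replicates_per_sample=1, grid=(500.0, 555.0, 5.0),
        scatter_sd=0.0, drift_sd=0.0, noise_sd=0.0, band_jitter_sd=0.0,
        seed=7),
    # negative control: spectra carry no SCC information at all
    "noise-only": SyntheticConfig(
        n_samples=120, replicates_per_sample=1, grid=(498.0, 1018.0, 4.0),
        informative_slopes={}, seed=13),
}


def make_fixture(name: str, seed: int | None = None
                 ) -> tuple[SpectraSet, ReferenceSet, GroundTruth]:
    """Deterministic named data sets for tests and demos.

    ``seed`` overrides the fixture's data seed (used for seed-replicate
    studies); by default each fixture is fully deterministic.
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    spectra, reference, truth = generate(FIXTURES[name], seed=seed)
    if name == "tiny-10x8":
        # generated on a 12-channel grid (the generator refuses fewer than
        # 10 channels), then trimmed to its advertised 8 channels
        spectra = spectra.select_channels(range(8))
    return spectra, reference, truth
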