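"""Synthetic ATR-FTIR spectra for seven edible oils and camellia/rapeseed blends.

Each oil is modelled as a sum of pseudo-Voigt bands at the canonical
triacylglycerol absorption positions (3006, 2923, 2853, 1744, 1464, 1377,
1240, 1160, 1119, 1096 and 722 cm^-1).  Band amplitudes are calibrated so
that the noise-free template of every oil reproduces the midpoint of that
oil's published I1119/I1096 band-height ratio range, unsaturation-sensitive
bands (3006, 722 cm^-1) scale with the oil's total unsaturated fatty-acid
content, and the remaining fingerprint amplitudes are informed by the
saturated / polyunsaturated fatty-acid totals measured by GC-FID.

The absolute C-O band scale of rapeseed oil relative to camellia oil is set
by the crossover condition: for the blend ratio to fall through 1.000 at a
volume fraction v*, the rapeseed C-O heights must exceed the camellia ones
by k = (1-v*)(r_c-1) / (v*(1-r_r)).  With r_c = 1.064, r_r = 0.971 and
v* = 0.55 (so that the tabulated 50% level stays above 1.000 and the 60%
level falls below it), k ~= 1.806.

Brand-to-brand variability has two components, both multiplicative on band
amplitudes and drawn once per (oil, brand): a global intensity factor
(CV = ``brand_amp_cv``) emulating ATR contact/path variation, and a small
independent per-band composition jitter (CV = ``brand_comp_cv``) that gives
each brand a slightly different band pattern and hence a slightly different
intensity ratio.  Replicate measurements of one brand differ only by white
noise.  All randomness is derived deterministically from the configuration
seed and the (oil, brand, replicate) coordinates, so a generated design is
bitwise reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra import SampleMeta, Spectrum, SpectrumSet

__all__ = [
    "Band",
    "EndmemberModel",
    "GeneratorConfig",
    "BlendDesign",
    "RATIO_MIDPOINTS",
    "FATTY_ACID_TOTALS",
    "BLEND_SERIES_LEVELS",
    "CALIBRATION_LEVELS",
    "SCREEN_LEVELS",
    "crossover_scale",
    "build_endmember_library",
    "endmember_template",
    "synth_spectrum",
    "blend_spectrum",
    "generate_design",
    "generate_pure_set",
    "generate_screen_set",
]

# Published pure-oil I1119/I1096 ranges are 1.045-1.083 (CAO), 0.961-0.981
# (RSO), 0.973-0.988 (PO), 0.935-0.961 (SO), 0.931-0.944 (CO), 0.905-0.922
# (SFO) and 0.905-0.918 (SBO); templates are calibrated to the midpoints.
RATIO_MIDPOINTS: Mapping[str, float] = {
    "CAO": 1.064,
    "RSO": 0.971,
    "PO": 0.9805,
    "SO": 0.948,
    "CO": 0.9375,
    "SFO": 0.9135,
    "SBO": 0.9115,
}

# Saturated / monounsaturated / polyunsaturated fatty-acid totals (% of FAs)
# from GC-FID profiling of the seven oils.
FATTY_ACID_TOTALS: Mapping[str, Mapping[str, float]] = {
    "CAO": {"sat": 13.07, "mono": 76.70, "poly": 10.40},
    "SBO": {"sat": 15.38, "mono": 23.21, "poly": 61.46},
    "CO":  {"sat": 15.69, "mono": 31.90, "poly": 52.80},
    "RSO": {"sat": 7.30,  "mono": 65.46, "poly": 27.45},
    "SFO": {"sat": 12.16, "mono": 23.22, "poly": 64.85},
    "PO":  {"sat": 21.84, "mono": 42.00, "poly": 36.32},
    "SO":  {"sat": 16.05, "mono": 39.03, "poly": 45.45},
}

#: Blend ladder used for the spectral series (plus 0% pure camellia oil).
BLEND_SERIES_LEVELS = (1, 3, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 60, 70, 80, 90)
#: Levels of the quantitative calibration design (12 levels, 0-50% handled
#: by including the pure base oil separately).
CALIBRATION_LEVELS = (1, 3, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
#: Low-level screen groups used for the discriminant analysis.
SCREEN_LEVELS = (0, 1, 3, 5, 10)

_BAND_CENTERS = (3006, 2923, 2853, 1744, 1464, 1377, 1240, 1160, 1119, 1096, 722)
# The two C-O bands share one width so that height-ratio statistics are
# insensitive to the smoothing filter (unequal widths would attenuate the
# two peaks unequally and bias the ratio off its calibrated value).
_FWHM = {3006: 16.0, 2923: 26.0, 2853: 22.0, 1744: 18.0, 1464: 18.0, 1377: 14.0,
         1240: 16.0, 1160: 18.0, 1119: 16.0, 1096: 16.0, 722: 14.0}

# Target windowed height (AU) of the 1096 cm^-1 C-O band per oil; camellia's
# value anchors the scale, rapeseed's is fixed by the crossover factor k, the
# rest increase with polyunsaturated content (C-O ester region grows with
# linoleate-rich triacylglycerols).
_CO_BASE_HEIGHT = {"CAO": 0.115, "SBO": 0.185, "CO": 0.175,
                   "SFO": 0.190, "SO": 0.165, "PO": 0.150}

_CROSSOVER_TARGET = 0.55
_PEAK_HALF_WINDOW = 4.0


@dataclass(frozen=True)
class Band:
    """Pseudo-Voigt absorption band: peak value ``amplitude`` at ``center``,
    full width at half maximum ``fwhm``, Gaussian/Lorentzian mix
    ``gauss_fraction`` (1 = pure Gaussian)."""

    center: float
    fwhm: float
    amplitude: float
    gauss_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValueError("gauss_fraction must lie in [0, 1]")

    def evaluate(self, wn: np.ndarray) -> np.ndarray:
        x = wn - self.center
        g = np.exp(-4.0 * np.log(2.0) * (x / self.fwhm) ** 2)
        l = 1.0 / (1.0 + 4.0 * (x / self.fwhm) ** 2)
        return self.amplitude * (self.gauss_fraction * g + (1.0 - self.gauss_fraction) * l)


@dataclass(frozen=True)
class EndmemberModel:
    """Pure-oil spectral model: band list plus brand-variability parameters."""

    oil_type: str
    bands: tuple
    brand_amp_cv: float = 0.01     # global intensity CV per brand
    brand_comp_cv: float = 0.0015  # per-band composition jitter CV per brand

    def __post_init__(self) -> None:
        centers = {b.center for b in self.bands}
        missing = [c for c in _BAND_CENTERS if c not in centers]
        if missing:
            raise ValueError(f"{self.oil_type}: missing bands at {missing} cm^-1")

    def template(self, wn: np.ndarray) -> np.ndarray:
        """Noise-free, baseline-free band sum on a grid."""
        y = np.zeros_like(wn, dtype=np.float64)
        for b in self.bands:
            y += b.evaluate(wn)
        return y


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition emulation: grid geometry, noise level, additive polynomial
    baseline (coefficients in increasing powers of cm^-1) and master seed."""

    grid_high: float = 4000.0
    grid_low: float = 650.0
    grid_step: float = 2.0
    noise_sd: float = 2e-4
    baseline_coeffs: tuple = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return self.grid_high - self.grid_step * np.arange(n, dtype=np.float64)

    def baseline(self, wn: np.ndarray) -> np.ndarray:
        coeffs = np.asarray(self.baseline_coeffs, dtype=np.float64)
        return np.polynomial.polynomial.polyval(wn, coeffs)


@dataclass(frozen=True)
class BlendDesign:
    """Brand x level x replicate layout of a blend experiment, plus the pure
    endmember brands measured alongside it."""

    cao_brands: tuple
    rso_brands: tuple
    levels: tuple
    replicates: int = 1
    pure_cao_brands: tuple = ()
    pure_rso_brands: tuple = ()

    def __post_init__(self) -> None:
        for v in self.levels:
            if not 0.0 < float(v) < 100.0:
                raise ValueError(f"blend level {v} must lie strictly inside (0, 100) % v/v")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def table5(cls) -> "BlendDesign":
        """The 5 camellia brands x 3 rapeseed brands x 12 levels calibration
        design, measured together with 7 pure brands of each endmember
        (180 blends + 14 pure = 194 samples)."""
        return cls(
            cao_brands=tuple(f"CAO-{i}" for i in range(1, 6)),
            rso_brands=tuple(f"RSO-{i}" for i in range(1, 4)),
            levels=CALIBRATION_LEVELS,
            replicates=1,
            pure_cao_brands=tuple(f"CAO-{i}" for i in range(1, 8)),
            pure_rso_brands=tuple(f"RSO-{i}" for i in range(1, 8)),
        )


# ---------------------------------------------------------------------------
# Deterministic seeding helpers

def _rng(seed: int, *parts) -> np.random.Generator:
    key = zlib.crc32("/".join(str(p) for p in parts).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def _lognormal(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean log-normal draw(s) with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# Endmember calibration

def crossover_scale(r_cao: float, r_rso: float, v_star: float) -> float:
    """Rapeseed/camellia C-O height scale placing the ratio crossover at
    volume fraction ``v_star``: k = (1-v*)(r_c-1) / (v*(1-r_r))."""
    return (1.0 - v_star) * (r_cao - 1.0) / (v_star * (1.0 - r_rso))


def _windowed_height(wn: np.ndarray, y: np.ndarray, center: float,
                     half_window: float = _PEAK_HALF_WINDOW) -> float:
    mask = np.abs(wn - center) <= half_window
    if not mask.any():
        raise ValueError(f"no grid point within {half_window} cm^-1 of {center}")
    return float(y[mask].max())


def _base_amplitudes(oil: str) -> dict:
    fa = FATTY_ACID_TOTALS[oil]
    unsat = fa["mono"] + fa["poly"]
    ref = FATTY_ACID_TOTALS["CAO"]
    unsat_ref = ref["mono"] + ref["poly"]
    return {
        2923: 0.40,
        2853: 0.27,
        1744: 0.50,
        1240: 0.06,
        1464: 0.115 * (0.8 + 0.2 * fa["sat"] / ref["sat"]),
        1377: 0.075 * (0.8 + 0.2 * fa["sat"] / ref["sat"]),
        1160: 0.16 * (0.6 + 0.4 * fa["poly"] / 35.0),
        3006: 0.10 * unsat / unsat_ref,
        722: 0.085 * unsat / unsat_ref,
    }


def build_endmember_library(seed: int = 0) -> dict[str, EndmemberModel]:
    """Calibrated spectral models for the seven oils.

    The 1096/1119 cm^-1 amplitudes of each oil are solved by fixed-point
    iteration so that the windowed heights of the noise-free template equal
    the target base height and ratio-midpoint x base height respectively
    (overlap from neighbouring bands makes this a mildly implicit problem;
    the coupling is a few percent, so the iteration converges to machine
    precision in a handful of steps).  The ``seed`` argument is accepted for
    interface symmetry; the calibration itself is deterministic.
    """
    del seed
    cfg = GeneratorConfig()
    wn = cfg.grid()
    k = crossover_scale(RATIO_MIDPOINTS["CAO"], RATIO_MIDPOINTS["RSO"], _CROSSOVER_TARGET)
    library: dict[str, EndmemberModel] = {}
    for oil in RATIO_MIDPOINTS:
        amps = _base_amplitudes(oil)
        h0 = _CO_BASE_HEIGHT[oil] if oil != "RSO" else k * _CO_BASE_HEIGHT["CAO"]
        r = RATIO_MIDPOINTS[oil]
        amps[1096] = h0
        amps[1119] = r * h0
        for _ in range(200):
            bands = tuple(Band(c, _FWHM[c], amps[c]) for c in _BAND_CENTERS)
            y = np.zeros_like(wn)
            for b in bands:
                y += b.evaluate(wn)
            f96 = h0 / _windowed_height(wn, y, 1096.0)
            f19 = (r * h0) / _windowed_height(wn, y, 1119.0)
            amps[1096] *= f96
            amps[1119] *= f19
            if abs(f96 - 1.0) < 1e-15 and abs(f19 - 1.0) < 1e-15:
                break
        library[oil] = EndmemberModel(
            oil_type=oil,
            bands=tuple(Band(c, _FWHM[c], amps[c]) for c in _BAND_CENTERS),
        )
    return library


def endmember_template(model: EndmemberModel, grid: np.ndarray,
                       oil_type: str | None = None) -> Spectrum:
    """Noise-free, baseline-free, brand-free template spectrum on a grid."""
    oil = oil_type or model.oil_type
    meta = SampleMeta(sample_id=f"{oil}-template", oil_type=oil,
                      blend_fraction_v=100.0 if oil == "RSO" else 0.0)
    return Spectrum(np.asarray(grid, dtype=np.float64).copy(), model.template(np.asarray(grid)), meta)


# ---------------------------------------------------------------------------
# Sample synthesis

def _brand_multipliers(model: EndmemberModel, cfg: GeneratorConfig, brand: str) -> np.ndarray:
    rng = _rng(cfg.seed, "brand", model.oil_type, brand)
    g = _lognormal(rng, model.brand_amp_cv)
    m = _lognormal(rng, model.brand_comp_cv, size=len(model.bands))
    return g * m


def _brand_signal(model: EndmemberModel, cfg: GeneratorConfig, brand: str,
                  wn: np.ndarray) -> np.ndarray:
    mult = _brand_multipliers(model, cfg, brand)
    y = cfg.baseline(wn).astype(np.float64, copy=True)
    if y.shape != wn.shape:
        y = np.broadcast_to(y, wn.shape).copy()
    for b, m in zip(model.bands, mult):
        y += m * b.evaluate(wn)
    return y


def synth_spectrum(model: EndmemberModel, cfg: GeneratorConfig, brand: str,
                   replicate: int = 1) -> Spectrum:
    """One measured pure-oil spectrum: brand-perturbed band sum + baseline +
    white noise.  Identical (seed, oil, brand, replicate) coordinates give
    bitwise-identical output."""
    wn = cfg.grid()
    y = _brand_signal(model, cfg, brand, wn)
    if cfg.noise_sd > 0:
        noise_rng = _rng(cfg.seed, "noise", model.oil_type, brand, replicate)
        y = y + noise_rng.normal(0.0, cfg.noise_sd, size=wn.size)
    meta = SampleMeta(
        sample_id=f"{model.oil_type}-{brand}-r{replicate}",
        oil_type=model.oil_type,
        blend_fraction_v=0.0,
        base_brand=brand,
        replicate=replicate,
    )
    return Spectrum(wn, y, meta)


def blend_spectrum(cao: Spectrum, rso: Spectrum, v: float) -> Spectrum:
    """Ideal Beer-Lambert volume mixing: (1 - v/100) cao + (v/100) rso."""
    if not np.array_equal(cao.wavenumbers, rso.wavenumbers):
        raise ValueError("blend endmembers must share one wavenumber grid")
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"blend level v={v} out of [0, 100] % v/v")
    f = v / 100.0
    ab = (1.0 - f) * cao.absorbance + f * rso.absorbance
    if v == 0.0:
        meta = cao.meta
    elif v == 100.0:
        meta = rso.meta
    else:
        meta = SampleMeta(
            sample_id=f"BLEND-{cao.meta.base_brand or cao.meta.sample_id}"
                      f"-{rso.meta.base_brand or rso.meta.sample_id}-v{v:g}",
            oil_type="BLEND",
            blend_fraction_v=float(v),
            base_brand=cao.meta.base_brand,
            adulterant_brand=rso.meta.base_brand,
            replicate=cao.meta.replicate,
        )
    return Spectrum(cao.wavenumbers.copy(), ab, meta)


def _blend_sample(lib: Mapping[str, EndmemberModel], cfg: GeneratorConfig,
                  cao_brand: str, rso_brand: str, v: float, replicate: int) -> Spectrum:
    """Blend of the two noise-free brand signals plus one measurement noise
    realisation seeded from the blend coordinates."""
    wn = cfg.grid()
    f = v / 100.0
    y = (1.0 - f) * _brand_signal(lib["CAO"], cfg, cao_brand, wn) \
        + f * _brand_signal(lib["RSO"], cfg, rso_brand, wn)
    if cfg.noise_sd > 0:
        noise_rng = _rng(cfg.seed, "noise", "blend", cao_brand, rso_brand, v, replicate)
        y = y + noise_rng.normal(0.0, cfg.noise_sd, size=wn.size)
    meta = SampleMeta(
        sample_id=f"BLEND-{cao_brand}-{rso_brand}-v{v:g}-r{replicate}",
        oil_type="BLEND" if 0.0 < v < 100.0 else ("CAO" if v == 0.0 else "RSO"),
        blend_fraction_v=float(v),
        base_brand=cao_brand,
        adulterant_brand=rso_brand if v > 0 else "",
        replicate=replicate,
    )
    return Spectrum(wn, y, meta)


def generate_design(design: BlendDesign, cfg: GeneratorConfig) -> SpectrumSet:
    """Emit pure endmember spectra followed by every (cao_brand x rso_brand x
    level x replicate) blend.  The standard design yields 7 + 7 pure plus
    5 x 3 x 12 = 180 blends, 194 samples in total."""
    lib = build_endmember_library()
    spectra: list[Spectrum] = []
    for brand in design.pure_cao_brands:
        for rep in range(1, design.replicates + 1):
            spectra.append(synth_spectrum(lib["CAO"], cfg, brand, rep))
    for brand in design.pure_rso_brands:
        for rep in range(1, design.replicates + 1):
            s = synth_spectrum(lib["RSO"], cfg, brand, rep)
            meta = SampleMeta(sample_id=s.meta.sample_id, oil_type="RSO",
                              blend_fraction_v=100.0, base_brand=brand,
                              replicate=rep)
            spectra.append(Spectrum(s.wavenumbers, s.absorbance, meta))
    for cao_brand in design.cao_brands:
        for rso_brand in design.rso_brands:
            for v in design.levels:
                for rep in range(1, design.replicates + 1):
                    spectra.append(_blend_sample(lib, cfg, cao_brand, rso_brand, float(v), rep))
    return SpectrumSet(spectra)


def generate_pure_set(cfg: GeneratorConfig, oils: Sequence[str] | None = None,
                      n_brands: int = 7, replicates: int = 3) -> SpectrumSet:
    """Pure-oil classification set: ``n_brands`` brands x ``replicates``
    replicate measurements for each requested oil type."""
    lib = build_endmember_library()
    oils = list(oils) if oils is not None else list(RATIO_MIDPOINTS)
    spectra = []
    for oil in oils:
        for i in range(1, n_brands + 1):
            for rep in range(1, replicates + 1):
                spectra.append(synth_spectrum(lib[oil], cfg, f"{oil}-{i}", rep))
    return SpectrumSet(spectra)


def generate_screen_set(cfg: GeneratorConfig, levels: Sequence[float] = SCREEN_LEVELS,
                        n_cao_brands: int = 5, rso_brand: str = "RSO-1",
                        replicates: int = 3) -> SpectrumSet:
    """Low-level adulteration screen: for each level (0 = pure camellia oil)
    one group of ``n_cao_brands x replicates`` spectra, every blend built
    against one rapeseed brand."""
    lib = build_endmember_library()
    spectra = []
    for v in levels:
        for i in range(1, n_cao_brands + 1):
            brand = f"CAO-{i}"
            for rep in range(1, replicates + 1):
                if v == 0:
                    spectra.append(synth_spectrum(lib["CAO"], cfg, brand, rep))
                else:
                    spectra.append(_blend_sample(lib, cfg, brand, rso_brand, float(v), rep))
    return SpectrumSet(spectra)
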