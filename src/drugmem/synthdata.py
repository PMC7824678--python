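"""Synthetic raw data for the three assays, with known ground truth.

Each simulator emulates the statistical structure the corresponding
analysis assumes:

* absorbance titrations: a free-drug and a membrane-bound Gaussian band
  mixed by the saturation isotherm ``f_bound = Kp*L/(1 + Kp*L)``, plus a
  smooth lambda^-4 vesicle-scattering background and additive Gaussian
  noise;
* leakage plates: a Hill dose-response for the true released fraction,
  quencher-mixing well intensities, a linear drug-autofluorescence term,
  and additive Gaussian noise;
* SAXS profiles: Lorentzian Bragg peaks on a constant baseline, an optional
  broad diffuse vesicle component over 0.5-2 nm^-1, and counting-like noise
  with standard deviation proportional to sqrt(intensity).

Ground truth travels with every simulated object (``.truth``), so
round-trip recovery can be asserted exactly.  Reference conditions for the
four membrane systems and two drugs (NAP, DIC) are registered in
``fixtures/reference.yaml`` and exposed through :func:`load_fixture` /
:func:`reference_spectra_config`.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import savgol_coeffs

from .leakage import LeakagePlate
from .partition import (
    ANALYTICAL_WAVELENGTHS,
    LIPID_SYSTEMS,
    LipidSystem,
    SpectraTitration,
    Spectrum,
)
from .saxs import SAXSProfile, lorentzian

__all__ = [
    "SpectraSimConfig",
    "LeakageSimConfig",
    "SAXSSimConfig",
    "simulate_spectra_titration",
    "simulate_leakage_plate",
    "simulate_saxs_profile",
    "derivative_noise_gain",
    "series_truth",
    "REFERENCE_LOGD",
    "DRUG_BANDS",
    "reference_spectra_config",
    "load_fixture",
    "list_fixtures",
]

#: Reference log D per (drug, lipid system): the recovery targets the
#: spectra simulator is parameterised against.
REFERENCE_LOGD: dict[tuple[str, str], float] = {
    ("NAP", "POPC"): 3.0,
    ("NAP", "POPC:CHOL (80:20)"): 3.4,
    ("NAP", "POPC:TMCL (85:15)"): 3.1,
    ("NAP", "POPC:PI (85:15)"): 3.6,
    ("DIC", "POPC"): 2.9,
    ("DIC", "POPC:CHOL (80:20)"): 2.8,
    ("DIC", "POPC:TMCL (85:15)"): 2.5,
    ("DIC", "POPC:PI (85:15)"): 2.9,
}

#: Spectral band models per drug: (center nm, sigma nm, peak AU) for the
#: aqueous and membrane-bound species, a working drug concentration, and the
#: analytical wavelength at which the third-derivative series is read.
DRUG_BANDS: dict[str, dict] = {
    "NAP": {
        "aqueous_band": (210.0, 4.0, 0.90),
        "bound_band": (212.0, 4.2, 0.95),
        "drug_conc": 5e-6,
        "wavelength": ANALYTICAL_WAVELENGTHS["NAP"],
    },
    "DIC": {
        "aqueous_band": (318.0, 6.0, 0.55),
        "bound_band": (320.0, 6.3, 0.60),
        "drug_conc": 40e-6,
        "wavelength": ANALYTICAL_WAVELENGTHS["DIC"],
    },
}


def _gaussian_band(wl: np.ndarray, band: tuple[float, float, float]) -> np.ndarray:
    center, sigma, peak = band
    if sigma <= 0:
        raise ValueError("band width must be positive")
    return peak * np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))


# --------------------------------------------------------------------------
# Absorbance titrations
# --------------------------------------------------------------------------

@dataclass
class SpectraSimConfig:
    """Conditions for one simulated absorbance titration.

    Bands are Gaussian (center nm, sigma nm, peak AU).  ``scatter_coeff``
    is the vesicle-scattering absorbance per molar lipid at 400 nm; the
    background scales as (lambda/400)^-4.  ``noise_sd`` is additive
    Gaussian absorbance noise per point.
    """

    kp_true: float
    drug_conc: float = 5e-6
    lipid_concs: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 2e-3, 12)
    )
    aqueous_band: tuple[float, float, float] = (210.0, 4.0, 0.90)
    bound_band: tuple[float, float, float] = (212.0, 4.2, 0.95)
    scatter_coeff: float = 10.0
    noise_sd: float = 0.0
    wavelength_grid: tuple[float, float, float] = (200.0, 400.0, 1.0)
    seed: int = 0
    drug: str | None = None
    lipid_system: LipidSystem | None = None
    analytical_wavelength: float | None = None

    def __post_init__(self) -> None:
        self.lipid_concs = np.asarray(self.lipid_concs, dtype=float)
        if np.any(self.lipid_concs < 0):
            raise ValueError("lipid concentrations must be non-negative")
        if np.any(np.diff(self.lipid_concs) <= 0):
            raise ValueError("lipid concentrations must be strictly increasing")
        if self.lipid_concs[0] != 0:
            raise ValueError("first lipid concentration must be 0")
        if self.kp_true <= 0:
            raise ValueError("kp_true must be positive")
        if self.aqueous_band[1] <= 0 or self.bound_band[1] <= 0:
            raise ValueError("band widths must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi, step = self.wavelength_grid
        return np.arange(lo, hi + step / 2, step)


def derivative_noise_gain(
    window_points: int = 9, poly_order: int = 5, step: float = 1.0
) -> float:
    """White-noise amplification of the Savitzky-Golay third-derivative
    filter: the l2 norm of its coefficient vector.  Multiplying an
    absorbance noise sd by this gain gives the derivative-series noise sd."""
    coeffs = savgol_coeffs(window_points, poly_order, deriv=3, delta=step)
    return float(np.linalg.norm(coeffs))


def series_truth(
    config: SpectraSimConfig,
    wavelength: float | None = None,
    window_points: int = 9,
    poly_order: int = 5,
) -> tuple[float, float]:
    """Noise-free (D_W, b) the derivative pipeline sees at ``wavelength``:
    the smoothed third derivative of the pure aqueous band, and the
    bound-minus-aqueous difference.  Exact because the filter is linear."""
    from .partition import third_derivative

    if wavelength is None:
        wavelength = config.analytical_wavelength
    if wavelength is None:
        raise ValueError("no analytical wavelength available")
    wl = config.wavelengths
    idx = int(np.argmin(np.abs(wl - wavelength)))
    d3_aq = third_derivative(
        Spectrum(wl, _gaussian_band(wl, config.aqueous_band)),
        window_points, poly_order,
    ).absorbance[idx]
    d3_bound = third_derivative(
        Spectrum(wl, _gaussian_band(wl, config.bound_band)),
        window_points, poly_order,
    ).absorbance[idx]
    return float(d3_aq), float(d3_bound - d3_aq)


def simulate_spectra_titration(config: SpectraSimConfig) -> SpectraTitration:
    """Emit one titration: per lipid concentration L,

        A(lambda) = f_free*aqueous + f_bound*bound
                    + scatter_coeff*L*(lambda/400)^-4 + noise

    with f_bound = Kp*L/(1 + Kp*L).  Ground truth (kp_true, implied D_W and
    b at the analytical wavelength, log D when the lipid system is known)
    rides along in ``.truth``.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    aq = _gaussian_band(wl, config.aqueous_band)
    bound = _gaussian_band(wl, config.bound_band)
    scatter_shape = (wl / 400.0) ** -4

    spectra = []
    for L in config.lipid_concs:
        f_bound = config.kp_true * L / (1.0 + config.kp_true * L)
        A = (1.0 - f_bound) * aq + f_bound * bound
        A = A + config.scatter_coeff * L * scatter_shape
        if config.noise_sd > 0:
            A = A + rng.normal(0.0, config.noise_sd, size=wl.size)
        spectra.append(Spectrum(wl.copy(), A))

    wavelength = config.analytical_wavelength
    if wavelength is None and config.drug in ANALYTICAL_WAVELENGTHS:
        wavelength = ANALYTICAL_WAVELENGTHS[config.drug]
    truth = {"kp_true": config.kp_true}
    if wavelength is not None:
        dw, b = series_truth(config, wavelength)
        truth.update({"dw_true": dw, "b_true": b, "wavelength": wavelength})
    if config.lipid_system is not None:
        truth["logd_true"] = math.log10(config.kp_true / config.lipid_system.v_phi)

    return SpectraTitration(
        drug_conc=config.drug_conc,
        lipid_concs=config.lipid_concs.copy(),
        spectra=spectra,
        lipid_system=config.lipid_system,
        drug=config.drug,
        truth=truth,
    )


def reference_spectra_config(
    drug: str,
    system_name: str,
    noise_frac: float = 0.02,
    seed: int = 0,
    window_points: int = 9,
    poly_order: int = 5,
) -> SpectraSimConfig:
    """Titration conditions whose ground-truth log D equals the registered
    reference value for (drug, system): kp_true = V_phi * 10**logD.

    ``noise_frac`` sets the absorbance noise so that the propagated noise on
    the third-derivative series is that fraction of |b| (2% by default).
    """
    system = LIPID_SYSTEMS[system_name]
    logd = REFERENCE_LOGD[(drug, system_name)]
    bands = DRUG_BANDS[drug]
    config = SpectraSimConfig(
        kp_true=system.v_phi * 10.0**logd,
        drug_conc=bands["drug_conc"],
        aqueous_band=bands["aqueous_band"],
        bound_band=bands["bound_band"],
        seed=seed,
        drug=drug,
        lipid_system=system,
        analytical_wavelength=bands["wavelength"],
    )
    if noise_frac > 0:
        _, b = series_truth(config, window_points=window_points,
                            poly_order=poly_order)
        gain = derivative_noise_gain(window_points, poly_order,
                                     config.wavelength_grid[2])
        config.noise_sd = noise_frac * abs(b) / gain
    return config


# --------------------------------------------------------------------------
# Leakage plates
# --------------------------------------------------------------------------

@dataclass
class LeakageSimConfig:
    """Conditions for one simulated leakage plate.

    The true released fraction follows a Hill curve
    ``leak(c) = leak_max * c^h / (ec50^h + c^h)``; intensities carry a
    linear drug-autofluorescence term and additive Gaussian noise.
    """

    drug_concs: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 400e-6, 9)
    )
    lipid_conc: float = 1e-3
    leak_max: float = 0.20
    ec50: float = 150e-6
    hill: float = 1.5
    i0: float = 1000.0
    itot: float = 200.0
    drug_fluor_slope: float = 2e5
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.drug_concs = np.asarray(self.drug_concs, dtype=float)
        if self.itot >= self.i0:
            raise ValueError("itot must be below i0")
        if not 0.0 <= self.leak_max <= 1.0:
            raise ValueError("leak_max must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def leak_fraction(config: LeakageSimConfig, c) -> np.ndarray:
    """Ground-truth Hill released fraction at drug concentration(s) c."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            c > 0,
            config.leak_max * c**config.hill
            / (config.ec50**config.hill + c**config.hill),
            0.0,
        )
    return frac


def simulate_leakage_plate(config: LeakageSimConfig) -> LeakagePlate:
    """Emit one plate: buffer-treated wells
    ``I_t = itot + (i0 - itot)*(1 - leak) + slope*c + noise``, lysed wells
    ``itot + slope*c + noise``, drug-only blanks ``slope*c + noise``.
    Ground-truth leak fractions ride along in ``.truth``."""
    rng = np.random.default_rng(config.seed)
    c = config.drug_concs[:, None]
    shape = (config.drug_concs.size, config.replicates)
    leak = leak_fraction(config, c)
    fluor = config.drug_fluor_slope * c

    def noise():
        return rng.normal(0.0, config.noise_sd, shape) if config.noise_sd > 0 \
            else np.zeros(shape)

    i_t = config.itot + (config.i0 - config.itot) * (1.0 - leak) + fluor + noise()
    i_tot = config.itot + fluor + noise()
    blank = fluor + noise()
    return LeakagePlate(
        drug_concs=config.drug_concs.copy(),
        i_t=np.broadcast_to(i_t, shape).copy(),
        i_tot=np.broadcast_to(i_tot, shape).copy(),
        drug_blank=np.broadcast_to(blank, shape).copy(),
        i_0=config.i0,
        lipid_conc=config.lipid_conc,
        truth={"leak_fraction": leak.ravel().copy(),
               "ratios": config.drug_concs / config.lipid_conc},
    )


# --------------------------------------------------------------------------
# SAXS profiles
# --------------------------------------------------------------------------

@dataclass
class SAXSSimConfig:
    """Conditions for one simulated 1-D SAXS profile.

    ``peaks`` are (center nm^-1, fwhm nm^-1, amplitude) Lorentzians;
    ``diffuse`` an optional broad (center, fwhm, amplitude) vesicle
    background; noise sd is ``noise_scale * sqrt(intensity)``.
    """

    peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(1.0, 0.05, 100.0), (2.0, 0.08, 30.0)]
    )
    diffuse: tuple[float, float, float] | None = None
    baseline: float = 10.0
    q_grid: tuple[float, float, float] = (0.2, 3.0, 0.002)
    noise_scale: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        lo, hi, step = self.q_grid
        if hi <= lo or step <= 0:
            raise ValueError("empty q grid")
        for center, fwhm, amp in self.peaks:
            if not lo <= center <= hi:
                raise ValueError(f"peak center {center} outside q grid")
            if fwhm <= 0:
                raise ValueError("peak fwhm must be positive")
            if amp < 0:
                raise ValueError("peak amplitude must be non-negative")

    @property
    def q(self) -> np.ndarray:
        lo, hi, step = self.q_grid
        return np.arange(lo, hi + step / 2, step)


def simulate_saxs_profile(config: SAXSSimConfig) -> SAXSProfile:
    """Emit one profile: baseline + optional diffuse component + Lorentzian
    Bragg peaks + counting-like noise.  With noise off the emitted profile
    equals the analytic model at machine precision."""
    q = config.q
    model = np.full(q.size, float(config.baseline))
    if config.diffuse is not None:
        model = model + lorentzian(q, *config.diffuse)
    for center, fwhm, amp in config.peaks:
        model = model + lorentzian(q, center, fwhm, amp)
    intensity = model
    if config.noise_scale > 0:
        rng = np.random.default_rng(config.seed)
        intensity = model + rng.normal(
            0.0, config.noise_scale * np.sqrt(np.clip(model, 0, None))
        )
    return SAXSProfile(
        q=q,
        intensity=intensity,
        label=config.label,
        truth={
            "peaks": list(config.peaks),
            "baseline": config.baseline,
            "diffuse": config.diffuse,
        },
    )


# --------------------------------------------------------------------------
# Shipped fixtures
# --------------------------------------------------------------------------

def _fixture_registry() -> dict:
    text = (
        importlib.resources.files("drugmem") / "fixtures" / "reference.yaml"
    ).read_text()
    return yaml.safe_load(text)


def list_fixtures() -> list[str]:
    """Names of the shipped reference fixtures (one per drug and system)."""
    return sorted(_fixture_registry())


def load_fixture(name: str, seed: int = 0) -> dict:
    """Build the simulator configs for one shipped reference fixture.

    Returns a dict with keys ``drug``, ``system``, ``logd_true``,
    ``spectra`` (SpectraSimConfig), ``leakage`` (LeakageSimConfig) and
    ``saxs`` (SAXSSimConfig).
    """
    registry = _fixture_registry()
    if name not in registry:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(registry))}"
        )
    entry = registry[name]
    drug, system = entry["drug"], entry["system"]
    spectra = reference_spectra_config(
        drug, system, noise_frac=entry.get("noise_frac", 0.02), seed=seed
    )
    leak_kwargs = dict(entry.get("leakage", {}))
    leakage = LeakageSimConfig(seed=seed, **leak_kwargs)
    saxs_kwargs = dict(entry.get("saxs", {}))
    if "peaks" in saxs_kwargs:
        saxs_kwargs["peaks"] = [tuple(p) for p in saxs_kwargs["peaks"]]
    if saxs_kwargs.get("diffuse") is not None:
        saxs_kwargs["diffuse"] = tuple(saxs_kwargs["diffuse"])
    saxsconf = SAXSSimConfig(seed=seed, label=name, **saxs_kwargs)
    return {
        "name": name,
        "drug": drug,
        "system": system,
        "logd_true": REFERENCE_LOGD[(drug, system)],
        "spectra": spectra,
        "leakage": leakage,
        "saxs": saxsconf,
    }
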