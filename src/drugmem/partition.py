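"""Liposome/water partition coefficients by third-derivative spectrophotometry.

A drug is titrated with increasing lipid (large unilamellar vesicle)
concentration at fixed drug concentration, and absorbance spectra are
recorded.  Because vesicle suspensions scatter light, raw absorbances are
unusable; the third derivative of the spectrum with respect to wavelength
suppresses the smooth scattering background while amplifying the sharp
spectral shift the drug undergoes on binding the bilayer.  The
third-derivative value ``D_T`` at a drug-specific analytical wavelength then
follows a saturation isotherm in total lipid concentration ``[L]``::

    D_T = D_W + b * Kp * [L] / (1 + Kp * [L])

where ``D_W`` is the derivative value of the fully aqueous drug, ``b`` the
amplitude of the bound-minus-free derivative difference, and ``Kp`` (M^-1)
the partition coefficient.  ``Kp`` is made dimensionless through the lipid
molar volume ``V_phi`` (L/mol) of the membrane system:

    log D = log10(Kp / V_phi)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "LipidSystem",
    "LIPID_SYSTEMS",
    "COMPONENT_MOLAR_VOLUMES",
    "ANALYTICAL_WAVELENGTHS",
    "Spectrum",
    "SpectraTitration",
    "DerivativeSeries",
    "PartitionFit",
    "third_derivative",
    "extract_series",
    "fit_partition_model",
    "logd_from_kp",
    "mixture_molar_volume",
    "estimate_partition",
    "scan_wavelengths",
    "read_titration",
    "write_titration",
]

# Kp search bounds (M^-1) during optimisation; hitting either bound marks the
# fit as non-converged rather than raising.
KP_BOUNDS = (1e-2, 1e8)

#: Default analytical wavelength (nm) per drug: the wavelength at which the
#: third-derivative titration series is read out.
ANALYTICAL_WAVELENGTHS: dict[str, float] = {"NAP": 213.0, "DIC": 321.0}

#: Molar volumes (L/mol) of individual membrane components, consistent with
#: the mole-fraction-weighted system volumes in ``LIPID_SYSTEMS``.
COMPONENT_MOLAR_VOLUMES: dict[str, float] = {
    "POPC": 0.756,
    "CHOL": 0.381,
    "TMCL": 2.296,
    "PI": 0.296,
}


# --------------------------------------------------------------------------
# Lipid systems
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidSystem:
    """A named membrane model: components with mole fractions and its molar
    volume ``V_phi`` in L/mol."""

    name: str
    components: tuple[tuple[str, float], ...]
    v_phi: float

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mole fractions sum to {total}, expected 1")
        if self.v_phi <= 0:
            raise ValueError("v_phi must be positive")


#: The four membrane models used throughout, with their molar volumes.
LIPID_SYSTEMS: dict[str, LipidSystem] = {
    s.name: s
    for s in (
        LipidSystem("POPC", (("POPC", 1.0),), 0.756),
        LipidSystem("POPC:CHOL (80:20)", (("POPC", 0.8), ("CHOL", 0.2)), 0.681),
        LipidSystem("POPC:TMCL (85:15)", (("POPC", 0.85), ("TMCL", 0.15)), 0.987),
        LipidSystem("POPC:PI (85:15)", (("POPC", 0.85), ("PI", 0.15)), 0.687),
    )
}


def mixture_molar_volume(components: list[tuple[float, float]]) -> float:
    """Mole-fraction-weighted mean molar volume of a lipid mixture.

    Parameters
    ----------
    components : list of (mole fraction, molar volume L/mol) pairs.
    """
    fractions = np.array([f for f, _ in components], dtype=float)
    volumes = np.array([v for _, v in components], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError(f"mole fractions sum to {fractions.sum()}, expected 1")
    return float(fractions @ volumes)


# --------------------------------------------------------------------------
# Spectra containers
# --------------------------------------------------------------------------

@dataclass
class Spectrum:
    """An absorbance (or derivative) spectrum on a uniform wavelength grid.

    ``edge_mask`` marks points whose derivative estimate came from one-sided
    polynomial fits at the grid edges; they are excluded from analytical
    readout.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.size != self.absorbance.size:
            raise ValueError("wavelengths and absorbance differ in length")
        if self.wavelengths.size < 7:
            raise ValueError("spectrum needs >= 7 points")
        steps = np.diff(self.wavelengths)
        if np.any(steps <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise ValueError("wavelength grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass
class SpectraTitration:
    """A family of spectra at fixed drug concentration and increasing lipid
    concentration (first concentration must be zero lipid)."""

    drug_conc: float
    lipid_concs: np.ndarray
    spectra: list[Spectrum]
    lipid_system: LipidSystem | None = None
    drug: str | None = None
    truth: dict | None = None  # populated by the simulator

    def __post_init__(self) -> None:
        self.lipid_concs = np.asarray(self.lipid_concs, dtype=float)
        if len(self.spectra) != self.lipid_concs.size:
            raise ValueError("lipid_concs and spectra differ in length")
        if np.any(self.lipid_concs < 0):
            raise ValueError("lipid concentrations must be non-negative")
        if np.any(np.diff(self.lipid_concs) <= 0):
            raise ValueError("lipid concentrations must be strictly increasing")
        if self.lipid_concs[0] != 0:
            raise ValueError("titration must include a zero-lipid point first")


@dataclass
class DerivativeSeries:
    """Third-derivative values D_T at one analytical wavelength, one per
    lipid concentration [L]."""

    wavelength: float
    lipid_concs: np.ndarray
    d3_values: np.ndarray

    def __post_init__(self) -> None:
        self.lipid_concs = np.asarray(self.lipid_concs, dtype=float)
        self.d3_values = np.asarray(self.d3_values, dtype=float)
        if self.lipid_concs.size != self.d3_values.size:
            raise ValueError("lipid_concs and d3_values differ in length")


@dataclass
class PartitionFit:
    """Result of fitting the saturation isotherm, with derived log D."""

    kp: float
    kp_se: float
    dw: float
    b: float
    residual_sse: float
    converged: bool
    logd: float = math.nan
    v_phi: float = math.nan
    dw_se: float = math.nan
    b_se: float = math.nan


# --------------------------------------------------------------------------
# Third-derivative spectrophotometry
# --------------------------------------------------------------------------

def third_derivative(
    spectrum: Spectrum, window_points: int = 9, poly_order: int = 5
) -> Spectrum:
    """Smoothed third derivative d3A/dlambda3 by local polynomial
    (Savitzky-Golay) filtering, in AU nm^-3 on the same grid.

    Edge points (half a window at each end) come from one-sided polynomial
    fits and are flagged in ``edge_mask``.
    """
    if poly_order < 3:
        raise ValueError("poly_order must be >= 3 for a third derivative")
    if window_points % 2 == 0 or window_points <= poly_order:
        raise ValueError("window_points must be odd and > poly_order")
    if spectrum.wavelengths.size < window_points:
        raise ValueError("spectrum shorter than the smoothing window")
    d3 = savgol_filter(
        spectrum.absorbance,
        window_length=window_points,
        polyorder=poly_order,
        deriv=3,
        delta=spectrum.step,
        mode="interp",
    )
    half = window_points // 2
    mask = np.zeros(d3.size, dtype=bool)
    mask[:half] = True
    mask[-half:] = True
    return Spectrum(spectrum.wavelengths.copy(), d3, edge_mask=mask)


def extract_series(
    titration: SpectraTitration,
    wavelength: float,
    window_points: int = 9,
    poly_order: int = 5,
) -> DerivativeSeries:
    """Third-derivative value at the grid point nearest ``wavelength``, one
    per lipid concentration."""
    values = np.empty(titration.lipid_concs.size)
    for i, spectrum in enumerate(titration.spectra):
        wl = spectrum.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]"
            )
        deriv = third_derivative(spectrum, window_points, poly_order)
        idx = int(np.argmin(np.abs(wl - wavelength)))
        if deriv.edge_mask is not None and deriv.edge_mask[idx]:
            raise ValueError(
                f"wavelength {wavelength} nm falls in the flagged edge region"
            )
        values[i] = deriv.absorbance[idx]
    return DerivativeSeries(
        wavelength=float(wavelength),
        lipid_concs=titration.lipid_concs.copy(),
        d3_values=values,
    )


# --------------------------------------------------------------------------
# Saturation-isotherm fit
# --------------------------------------------------------------------------

def partition_model(L: np.ndarray, dw: float, b: float, kp: float) -> np.ndarray:
    """Saturation isotherm D_T(L) = D_W + b*Kp*L/(1 + Kp*L)."""
    L = np.asarray(L, dtype=float)
    return dw + b * kp * L / (1.0 + kp * L)


def fit_partition_model(series: DerivativeSeries) -> PartitionFit:
    """Nonlinear least-squares fit of the saturation isotherm.

    Initialisation: D_W from the zero-lipid point, b from the span to the
    highest lipid concentration, Kp from the reciprocal median positive
    lipid concentration.  Failure to converge or Kp pinned at a bound is
    reported through ``converged=False``, never an exception.
    """
    L = series.lipid_concs
    y = series.d3_values
    if np.unique(L).size < 4:
        raise ValueError("need >= 4 distinct lipid concentrations")
    if 0.0 not in L:
        raise ValueError("series must include the zero-lipid point")
    if not np.all(np.isfinite(y)):
        raise ValueError("d3_values must be finite")

    failed = PartitionFit(
        kp=math.nan, kp_se=math.nan, dw=math.nan, b=math.nan,
        residual_sse=math.nan, converged=False,
    )
    if np.ptp(y) == 0:  # flat series: Kp unidentifiable
        return failed

    dw0 = float(y[L == 0][0])
    b0 = float(y[np.argmax(L)] - dw0)
    kp0 = 1.0 / float(np.median(L[L > 0]))
    kp0 = min(max(kp0, KP_BOUNDS[0] * 10), KP_BOUNDS[1] / 10)
    if b0 == 0:
        b0 = np.ptp(y) or 1.0

    try:
        popt, pcov = curve_fit(
            partition_model, L, y,
            p0=[dw0, b0, kp0],
            bounds=([-np.inf, -np.inf, KP_BOUNDS[0]], [np.inf, np.inf, KP_BOUNDS[1]]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return failed

    dw, b, kp = (float(v) for v in popt)
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    sse = float(np.sum((y - partition_model(L, *popt)) ** 2))
    at_bound = (
        kp <= KP_BOUNDS[0] * (1 + 1e-6) or kp >= KP_BOUNDS[1] * (1 - 1e-6)
    )
    return PartitionFit(
        kp=kp, kp_se=float(ses[2]), dw=dw, b=b,
        dw_se=float(ses[0]), b_se=float(ses[1]),
        residual_sse=sse, converged=not at_bound,
    )


def logd_from_kp(kp: float, system: LipidSystem) -> float:
    """Dimensionless log D = log10(Kp / V_phi), Kp in M^-1 (= L/mol)."""
    if kp <= 0:
        raise ValueError("Kp must be positive")
    if system.v_phi <= 0:
        raise ValueError("V_phi must be positive")
    return math.log10(kp / system.v_phi)


def estimate_partition(
    titration: SpectraTitration,
    wavelength: float | None = None,
    window_points: int = 9,
    poly_order: int = 5,
) -> PartitionFit:
    """Full pipeline: derivative series extraction, isotherm fit, log D.

    ``wavelength`` defaults to the registered analytical wavelength of
    ``titration.drug`` (213 nm NAP, 321 nm DIC).
    """
    if wavelength is None:
        if titration.drug is None or titration.drug not in ANALYTICAL_WAVELENGTHS:
            raise ValueError(
                "no wavelength given and no registered default for drug "
                f"{titration.drug!r}"
            )
        wavelength = ANALYTICAL_WAVELENGTHS[titration.drug]
    series = extract_series(titration, wavelength, window_points, poly_order)
    fit = fit_partition_model(series)
    if fit.converged and titration.lipid_system is not None:
        fit = replace(
            fit,
            logd=logd_from_kp(fit.kp, titration.lipid_system),
            v_phi=titration.lipid_system.v_phi,
        )
    return fit


def scan_wavelengths(
    titration: SpectraTitration,
    window_points: int = 9,
    poly_order: int = 5,
) -> pd.DataFrame:
    """Convenience scan: estimated |b| (span of the derivative series between
    zero and maximal lipid) at every usable wavelength, to help pick an
    analytical wavelength for an unfamiliar drug."""
    first = third_derivative(titration.spectra[0], window_points, poly_order)
    last = third_derivative(titration.spectra[-1], window_points, poly_order)
    usable = ~first.edge_mask
    return pd.DataFrame(
        {
            "wavelength": first.wavelengths[usable],
            "abs_b_estimate": np.abs(last.absorbance - first.absorbance)[usable],
        }
    )


# --------------------------------------------------------------------------
# Text I/O
# --------------------------------------------------------------------------

def write_titration(path, titration: SpectraTitration) -> None:
    """Delimited text: first column wavelength (nm), one absorbance column
    per lipid concentration; lipid molarities in the header row."""
    wl = titration.spectra[0].wavelengths
    data = {"wavelength_nm": wl}
    for conc, spec in zip(titration.lipid_concs, titration.spectra):
        if not np.array_equal(spec.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid")
        data[f"{conc:.10g}"] = spec.absorbance
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_titration(
    path,
    drug_conc: float,
    lipid_system: LipidSystem | None = None,
    drug: str | None = None,
) -> SpectraTitration:
    """Read a titration written by :func:`write_titration`."""
    df = pd.read_csv(path, sep="\t")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    concs = np.array([float(c) for c in df.columns[1:]])
    spectra = [
        Spectrum(wl, df.iloc[:, i + 1].to_numpy(dtype=float))
        for i in range(concs.size)
    ]
    return SpectraTitration(
        drug_conc=drug_conc,
        lipid_concs=concs,
        spectra=spectra,
        lipid_system=lipid_system,
        drug=drug,
    )
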