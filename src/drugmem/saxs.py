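"""Lamellar structure analysis of 1-D SAXS profiles.

Stacked lipid bilayers diffract as a lamellar lattice: Bragg peaks at
q = n*q1 (n = 1, 2, ...).  Each peak is fitted with a Lorentzian

    I(q) = A * gamma^2 / ((q - q0)^2 + gamma^2),    fwhm = 2*gamma

on top of a constant baseline and, optionally, a broad diffuse component
(0.5-2 nm^-1) produced by uncorrelated vesicles when stacking is disrupted.
From the fitted peak the lamellar repeat distance and the correlation
length follow as

    d  = 2*pi / q0          (nm)
    xi = 4*pi^2 / fwhm      (default convention; 2*pi/fwhm also exposed)

Peaks are indexed to diffraction orders against the most intense low-q
(first-order) peak; several peaks within tolerance of q1 are treated as a
split first order.  A per-sample summary reports d and xi of the most
intense first-order peak vs the drug:lipid molar ratio x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model, Parameters
from scipy.signal import find_peaks, medfilt, peak_widths

__all__ = [
    "SAXSProfile",
    "BraggPeak",
    "LamellarFit",
    "StructureSummary",
    "lorentzian",
    "read_profile",
    "write_profile",
    "detect_peaks",
    "fit_lorentzian_peaks",
    "index_lamellar_orders",
    "summarize_series",
]

# Diffuse background is declared present when its fitted amplitude exceeds
# this fraction of the tallest Bragg amplitude.
DIFFUSE_FLAG_FRACTION = 0.2
# Fitting window half-width around each peak guess, in units of fwhm.
WINDOW_FWHM_MULTIPLE = 3.0


def lorentzian(q, center, fwhm, amplitude):
    """Height-parameterised Lorentzian: amplitude at the peak maximum."""
    gamma = fwhm / 2.0
    return amplitude * gamma**2 / ((np.asarray(q, dtype=float) - center) ** 2 + gamma**2)


@dataclass
class SAXSProfile:
    """1-D scattering profile: intensity (arbitrary units) vs q (nm^-1)."""

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""
    truth: dict | None = None  # populated by the simulator

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity differ in length")
        if self.q.size < 50:
            raise ValueError("profile needs >= 50 points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")


@dataclass
class BraggPeak:
    """A fitted Bragg peak with its derived structural parameters.

    ``d`` and ``xi`` are set from ``q0`` and ``fwhm`` at construction:
    d = 2*pi/q0 and xi = 4*pi^2/fwhm (the default convention).
    """

    q0: float
    fwhm: float
    amplitude: float
    order: int | None = None
    converged: bool = True
    d: float = field(init=False)
    xi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.q0 <= 0:
            raise ValueError("q0 must be positive")
        self.d = 2.0 * math.pi / self.q0
        self.xi = 4.0 * math.pi**2 / self.fwhm

    @property
    def xi_2pi(self) -> float:
        """Correlation length under the alternative 2*pi/fwhm convention."""
        return 2.0 * math.pi / self.fwhm


@dataclass
class LamellarFit:
    """Fitted peak list plus background description for one profile."""

    peaks: list[BraggPeak]
    background: dict
    diffuse_flag: bool
    fit_sse: float
    label: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.q0)

    def peak_table(self, xi_convention: str = "4pi2") -> pd.DataFrame:
        rows = [
            {
                "q0": p.q0,
                "fwhm": p.fwhm,
                "amplitude": p.amplitude,
                "order": p.order,
                "d": p.d,
                "xi": p.xi if xi_convention == "4pi2" else p.xi_2pi,
            }
            for p in self.peaks
        ]
        return pd.DataFrame(rows)


@dataclass
class StructureSummary:
    """Per-sample structural parameters vs drug:lipid molar ratio."""

    table: pd.DataFrame  # x, d, xi, diffuse_flag, no_first_order
    peaks: pd.DataFrame  # full peak table across samples


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_profile(source, label: str = "", from_angstrom: bool = False) -> SAXSProfile:
    """Read a two-column (q, intensity) delimited text profile.

    Lines starting with '#' are comments.  ``from_angstrom`` converts q from
    inverse Angstrom to inverse nm (x10) on ingest.
    """
    qs, Is = [], []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            try:
                q, I = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{source}: non-numeric data at line {lineno}") from exc
            qs.append(q)
            Is.append(I)
    q = np.array(qs)
    if from_angstrom:
        q = q * 10.0
    return SAXSProfile(q=q, intensity=np.array(Is), label=label)


def write_profile(path, profile: SAXSProfile) -> None:
    with open(path, "w") as fh:
        fh.write("# q_nm^-1\tintensity_au\n")
        for q, I in zip(profile.q, profile.intensity):
            fh.write(f"{q:.6g}\t{I:.8g}\n")


# --------------------------------------------------------------------------
# Peak detection and fitting
# --------------------------------------------------------------------------

def detect_peaks(
    profile: SAXSProfile,
    prominence_frac: float = 0.05,
    search_window: tuple[float, float] | None = None,
    median_kernel: int = 5,
) -> list[tuple[float, float, float]]:
    """Initial peak guesses: (q_guess, height, fwhm_guess), sorted by q.

    Local maxima of the median-filtered profile with prominence at least
    ``prominence_frac`` of the intensity span; ``search_window`` restricts
    the q range searched.
    """
    q, I = profile.q, profile.intensity
    if search_window is not None:
        sel = (q >= search_window[0]) & (q <= search_window[1])
        q, I = q[sel], I[sel]
    if q.size < max(median_kernel, 5):
        return []
    smooth = medfilt(I, kernel_size=median_kernel)
    span = float(np.ptp(smooth))
    if span == 0:
        return []
    idx, props = find_peaks(smooth, prominence=prominence_frac * span)
    if idx.size == 0:
        return []
    widths = peak_widths(smooth, idx, rel_height=0.5)[0]
    dq = float(np.median(np.diff(q)))
    guesses = [
        (float(q[i]), float(smooth[i]), max(float(w) * dq, 2 * dq))
        for i, w in zip(idx, widths)
    ]
    return sorted(guesses, key=lambda g: g[0])


def _merge_windows(guesses: list[tuple[float, float, float]]):
    """Group guesses whose +/-3*fwhm windows overlap; joint fit per group."""
    windows = [
        (qg - WINDOW_FWHM_MULTIPLE * wg, qg + WINDOW_FWHM_MULTIPLE * wg, i)
        for i, (qg, _, wg) in enumerate(guesses)
    ]
    windows.sort()
    groups, current = [], [windows[0]]
    for win in windows[1:]:
        if win[0] <= max(w[1] for w in current):
            current.append(win)
        else:
            groups.append(current)
            current = [win]
    groups.append(current)
    return [
        (min(w[0] for w in g), max(w[1] for w in g), [w[2] for w in g])
        for g in groups
    ]


def _peak_model(prefixes):
    model = None
    for p in prefixes:
        m = Model(lorentzian, prefix=p)
        model = m if model is None else model + m
    return model


def fit_lorentzian_peaks(
    profile: SAXSProfile,
    guesses: list[tuple[float, float, float]],
    background_model: str = "constant",
) -> LamellarFit:
    """Least-squares Lorentzian fit of the guessed Bragg peaks.

    ``background_model``: 'constant' fits a flat baseline per window group;
    'diffuse' fits the whole profile jointly with a constant baseline plus a
    broad Lorentzian background over the 0.5-2 nm^-1 region and sets
    ``diffuse_flag`` when its amplitude exceeds 20% of the tallest Bragg
    amplitude.  Overlapping peak windows are always fitted jointly.
    """
    if not guesses:
        raise ValueError("need at least one peak guess")
    if background_model not in ("constant", "diffuse"):
        raise ValueError(f"unknown background model {background_model!r}")

    q, I = profile.q, profile.intensity
    peaks: list[BraggPeak] = [None] * len(guesses)
    sse = 0.0
    background: dict = {"baseline": 0.0, "diffuse": None}
    diffuse_flag = False

    def add_peak_params(params, members, qlo, qhi):
        for i in members:
            qg, hg, wg = guesses[i]
            params.add(f"p{i}_center", value=qg, min=qlo, max=qhi)
            params.add(f"p{i}_fwhm", value=wg, min=1e-6, max=(qhi - qlo))
            params.add(f"p{i}_amplitude", value=max(hg, 1e-12), min=0)

    if background_model == "diffuse":
        # Joint full-profile fit: all peaks + constant + broad component.
        prefixes = [f"p{i}_" for i in range(len(guesses))]
        model = _peak_model(prefixes) + Model(lorentzian, prefix="diff_")

        def baseline_fn(q, c):
            return c + 0.0 * np.asarray(q)

        model = model + Model(baseline_fn, prefix="bg_")
        params = Parameters()
        add_peak_params(params, range(len(guesses)), float(q[0]), float(q[-1]))
        params.add("diff_center", value=1.2, min=0.5, max=2.0)
        params.add("diff_fwhm", value=1.0, min=0.3, max=3.0)
        params.add("diff_amplitude", value=float(np.ptp(I)) * 0.05, min=0)
        params.add("bg_c", value=float(np.min(I)))
        result = model.fit(I, params, q=q)
        sse = float(np.sum(result.residual**2))
        for i in range(len(guesses)):
            peaks[i] = BraggPeak(
                q0=float(result.params[f"p{i}_center"].value),
                fwhm=float(result.params[f"p{i}_fwhm"].value),
                amplitude=float(result.params[f"p{i}_amplitude"].value),
                converged=bool(result.success),
            )
        background = {
            "baseline": float(result.params["bg_c"].value),
            "diffuse": {
                "center": float(result.params["diff_center"].value),
                "fwhm": float(result.params["diff_fwhm"].value),
                "amplitude": float(result.params["diff_amplitude"].value),
            },
        }
        tallest = max(p.amplitude for p in peaks)
        diffuse_flag = (
            background["diffuse"]["amplitude"] > DIFFUSE_FLAG_FRACTION * tallest
        )
    else:
        baselines = []
        for qlo, qhi, members in _merge_windows(guesses):
            sel = (q >= qlo) & (q <= qhi)
            qw, Iw = q[sel], I[sel]
            model = _peak_model([f"p{i}_" for i in members])

            def baseline_fn(q, c):
                return c + 0.0 * np.asarray(q)

            model = model + Model(baseline_fn, prefix="bg_")
            params = Parameters()
            add_peak_params(params, members, float(qw[0]), float(qw[-1]))
            params.add("bg_c", value=float(np.min(Iw)))
            result = model.fit(Iw, params, q=qw)
            sse += float(np.sum(result.residual**2))
            baselines.append(float(result.params["bg_c"].value))
            for i in members:
                peaks[i] = BraggPeak(
                    q0=float(result.params[f"p{i}_center"].value),
                    fwhm=float(result.params[f"p{i}_fwhm"].value),
                    amplitude=float(result.params[f"p{i}_amplitude"].value),
                    converged=bool(result.success),
                )
        background = {"baseline": float(np.mean(baselines)), "diffuse": None}

    return LamellarFit(
        peaks=peaks,
        background=background,
        diffuse_flag=diffuse_flag,
        fit_sse=sse,
        label=profile.label,
    )


# --------------------------------------------------------------------------
# Order indexing and series summary
# --------------------------------------------------------------------------

def index_lamellar_orders(fit: LamellarFit, tolerance_frac: float = 0.05) -> LamellarFit:
    """Assign diffraction orders n against the most intense low-q peak.

    q1 is the q0 of the most intense peak in the low-q candidate set (peaks
    within the order-1 tolerance band of the lowest-q peak).  A peak gets
    order n when |q0 - n*q1| <= tolerance_frac*q1; several peaks within
    tolerance of q1 itself all become (split) first order.  Assignment is
    idempotent and independent of input peak ordering.
    """
    if not fit.peaks:
        raise ValueError("fit has no peaks to index")
    peaks = sorted(fit.peaks, key=lambda p: p.q0)
    q_min = peaks[0].q0
    low_q = [p for p in peaks if p.q0 <= q_min * (1 + 2 * tolerance_frac)]
    q1 = max(low_q, key=lambda p: p.amplitude).q0
    for p in peaks:
        n = max(int(round(p.q0 / q1)), 1)
        p.order = n if abs(p.q0 - n * q1) <= tolerance_frac * q1 else None
    fit.peaks = peaks
    return fit


def summarize_series(
    fits: list[tuple[float, LamellarFit]],
    xi_convention: str = "4pi2",
) -> StructureSummary:
    """Per-sample d and xi of the most intense first-order peak vs the
    drug:lipid molar ratio x, plus the full peak table.

    Samples without any order-1 peak get missing d/xi and a flag; the
    diffuse-background flag marks samples where vesicle scattering rather
    than lamellar stacking dominates.
    """
    if xi_convention not in ("4pi2", "2pi"):
        raise ValueError(f"unknown xi convention {xi_convention!r}")
    rows, peak_frames = [], []
    for x, fit in fits:
        first_order = [p for p in fit.peaks if p.order == 1]
        if first_order:
            best = max(first_order, key=lambda p: p.amplitude)
            d = best.d
            xi = best.xi if xi_convention == "4pi2" else best.xi_2pi
            missing = False
        else:
            d = xi = math.nan
            missing = True
        rows.append(
            {
                "x": x,
                "d": d,
                "xi": xi,
                "diffuse_flag": fit.diffuse_flag,
                "no_first_order": missing,
                "label": fit.label,
            }
        )
        pt = fit.peak_table(xi_convention)
        pt.insert(0, "x", x)
        pt.insert(1, "label", fit.label)
        peak_frames.append(pt)
    return StructureSummary(
        table=pd.DataFrame(rows),
        peaks=pd.concat(peak_frames, ignore_index=True),
    )
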