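"""Fluorometric dye-leakage analysis for drug-permeabilized liposomes.

Vesicles loaded with a fluorophore (PTS) sit in a quencher (methyl viologen)
solution; drug-induced membrane leakage mixes the two and quenches the
signal.  With ``I_0`` the intensity without drug, ``I_t`` the intensity at a
given drug concentration, and ``I_tot`` the intensity after full detergent
lysis, the released fraction is

    Leakage % = (I_0 - I_t) / (I_0 - I_tot) * 100

Intensities are corrected for the drug's own fluorescence at the emission
wavelength using drug-only blank wells.  Dose is expressed as the drug:lipid
molar ratio, with the lipid concentration of the vesicle stock determined by
an inorganic-phosphate (molybdenum blue) calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LeakagePlate",
    "LeakageCurve",
    "PhosphateCalibration",
    "correct_drug_fluorescence",
    "leakage_percent",
    "build_leakage_curve",
    "fit_phosphate_calibration",
    "lipid_conc_from_absorbance",
    "read_plate",
    "write_plate",
]

# Reporting range for leakage percentages; raw values are always preserved.
REPORT_RANGE = (-5.0, 105.0)


@dataclass
class LeakagePlate:
    """Raw plate intensities, shaped (n_concentrations, n_replicates).

    ``i_t`` are buffer-treated wells, ``i_tot`` detergent-lysed wells,
    ``i_0`` the zero-drug intensity, ``drug_blank`` optional drug-only wells.
    """

    drug_concs: np.ndarray
    i_t: np.ndarray
    i_tot: np.ndarray
    i_0: float
    lipid_conc: float
    drug_blank: np.ndarray | None = None
    truth: dict | None = None  # populated by the simulator

    def __post_init__(self) -> None:
        self.drug_concs = np.asarray(self.drug_concs, dtype=float)
        self.i_t = np.atleast_2d(np.asarray(self.i_t, dtype=float).T).T
        self.i_tot = np.atleast_2d(np.asarray(self.i_tot, dtype=float).T).T
        if self.drug_blank is not None:
            self.drug_blank = np.atleast_2d(
                np.asarray(self.drug_blank, dtype=float).T
            ).T
            if self.drug_blank.shape[0] != self.drug_concs.size:
                raise ValueError("drug_blank misaligned with drug_concs")
        n = self.drug_concs.size
        if self.i_t.shape[0] != n or self.i_tot.shape[0] != n:
            raise ValueError("intensity arrays misaligned with drug_concs")
        if self.i_0 <= float(np.mean(self.i_tot)):
            raise ValueError(
                "i_0 must exceed the mean lysed intensity (no dynamic range)"
            )

    @property
    def replicates(self) -> int:
        return self.i_t.shape[1]


@dataclass
class LeakageCurve:
    """Leakage percentage vs drug:lipid molar ratio (replicate mean +/- sd).

    ``leakage_pct``/``leakage_sd`` are clipped to the reporting range;
    ``raw_pct`` keeps the unclipped per-replicate values.
    """

    ratios: np.ndarray
    leakage_pct: np.ndarray
    leakage_sd: np.ndarray
    raw_pct: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ratios) < 0):
            raise ValueError("ratios must be ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_lipid_ratio": self.ratios,
                "leakage_pct": self.leakage_pct,
                "leakage_sd": self.leakage_sd,
            }
        )


def leakage_percent(i_0, i_t, i_tot):
    """Dye release as a percentage: (I_0 - I_t)/(I_0 - I_tot) * 100.

    Accepts scalars or broadcastable arrays; rejects I_0 == I_tot (no
    dynamic range).
    """
    i_0 = np.asarray(i_0, dtype=float)
    i_t = np.asarray(i_t, dtype=float)
    i_tot = np.asarray(i_tot, dtype=float)
    if np.any(i_0 == i_tot):
        raise ValueError("I_0 equals I_tot: leakage undefined (no dynamic range)")
    out = (i_0 - i_t) / (i_0 - i_tot) * 100.0
    return float(out) if out.ndim == 0 else out


def correct_drug_fluorescence(plate: LeakagePlate) -> LeakagePlate:
    """Subtract the drug-only blank intensity (replicate mean per drug
    concentration) from the treated and lysed wells.  The zero-drug ``i_0``
    is left untouched.  Without blank wells the plate is returned unchanged
    with a warning."""
    if plate.drug_blank is None:
        warnings.warn(
            "no drug-blank wells: skipping autofluorescence correction",
            stacklevel=2,
        )
        return plate
    blank = plate.drug_blank.mean(axis=1, keepdims=True)
    return replace(
        plate,
        i_t=plate.i_t - blank,
        i_tot=plate.i_tot - blank,
        drug_blank=None,
    )


def build_leakage_curve(
    plate: LeakagePlate, correct: bool = True
) -> LeakageCurve:
    """Leakage curve vs drug:lipid molar ratio.

    Applies the autofluorescence correction (when blank wells exist), then
    Eq.-style leakage per well, then the replicate mean +/- sd.
    """
    if plate.lipid_conc <= 0:
        raise ValueError("lipid_conc must be positive")
    if correct and plate.drug_blank is not None:
        plate = correct_drug_fluorescence(plate)
    raw = leakage_percent(plate.i_0, plate.i_t, plate.i_tot)
    mean = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=1) if plate.replicates > 1 else np.zeros_like(mean)
    lo, hi = REPORT_RANGE
    return LeakageCurve(
        ratios=plate.drug_concs / plate.lipid_conc,
        leakage_pct=np.clip(mean, lo, hi),
        leakage_sd=sd,
        raw_pct=raw,
    )


# --------------------------------------------------------------------------
# Phosphate (molybdenum blue) lipid quantification
# --------------------------------------------------------------------------

@dataclass
class PhosphateCalibration:
    """Linear calibration of absorbance at 797 nm vs phosphate standards."""

    standards_nmol: np.ndarray
    absorbances_797: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def fit_phosphate_calibration(standards_nmol, absorbances) -> PhosphateCalibration:
    """Ordinary least-squares calibration line through the standards."""
    x = np.asarray(standards_nmol, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 calibration standards")
    if np.ptp(x) == 0:
        raise ValueError("standards must span a nonzero range")
    if np.any(np.diff(x) < 0):
        raise ValueError("standards must be ascending")
    res = stats.linregress(x, y)
    return PhosphateCalibration(
        standards_nmol=x,
        absorbances_797=y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def lipid_conc_from_absorbance(
    cal: PhosphateCalibration,
    absorbance: float,
    sample_volume: float,
    phosphates_per_lipid: float = 1.0,
) -> float:
    """Phospholipid concentration (M) from a sample absorbance.

    ``sample_volume`` in litres.  ``phosphates_per_lipid`` handles lipids
    with more than one phosphate per molecule (cardiolipin: 2).
    """
    if cal.slope <= 0:
        raise ValueError("calibration slope must be positive")
    if sample_volume <= 0:
        raise ValueError("sample volume must be positive")
    nmol_phosphate = (absorbance - cal.intercept) / cal.slope
    if nmol_phosphate < 0:
        warnings.warn("absorbance below calibration intercept: clamping to 0",
                      stacklevel=2)
        nmol_phosphate = 0.0
    nmol_lipid = nmol_phosphate / phosphates_per_lipid
    return nmol_lipid * 1e-9 / sample_volume


# --------------------------------------------------------------------------
# Text I/O
# --------------------------------------------------------------------------

def write_plate(path, plate: LeakagePlate) -> None:
    """Long-format delimited text: drug_conc_M, replicate, I_t, I_tot,
    optional I_blank; i_0 and lipid_conc on '#' header lines."""
    rows = []
    for i, c in enumerate(plate.drug_concs):
        for r in range(plate.replicates):
            row = {
                "drug_conc_M": c,
                "replicate": r + 1,
                "I_t": plate.i_t[i, r],
                "I_tot": plate.i_tot[i, r],
            }
            if plate.drug_blank is not None:
                row["I_blank"] = plate.drug_blank[i, r]
            rows.append(row)
    with open(path, "w") as fh:
        fh.write(f"# i_0 = {plate.i_0:.10g}\n")
        fh.write(f"# lipid_conc_M = {plate.lipid_conc:.10g}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_plate(path) -> LeakagePlate:
    """Read a plate written by :func:`write_plate`."""
    i_0 = lipid_conc = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition("=")
            if key.strip() == "i_0":
                i_0 = float(value)
            elif key.strip() == "lipid_conc_M":
                lipid_conc = float(value)
    if i_0 is None or lipid_conc is None:
        raise ValueError(f"{path}: missing '# i_0' or '# lipid_conc_M' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    concs = np.sort(df["drug_conc_M"].unique())
    def pivot(col):
        if col not in df:
            return None
        wide = df.pivot(index="drug_conc_M", columns="replicate", values=col)
        return wide.loc[concs].to_numpy()
    return LeakagePlate(
        drug_concs=concs,
        i_t=pivot("I_t"),
        i_tot=pivot("I_tot"),
        drug_blank=pivot("I_blank"),
        i_0=i_0,
        lipid_conc=lipid_conc,
    )
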