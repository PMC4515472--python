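"""Juvenoid quantification from DART mass spectrometry.

Direct-analysis-in-real-time ionisation of juvenile hormone III and related
sesquiterpenoids produces a protonated molecular ion [M+H]+ and, for
hydroxy/epoxide compounds, a water-loss ion [M-H2O+H]+.  Quantification
proceeds by extracting the signature-ion abundance from each technical
replicate spectrum, averaging replicates, normalising to haemolymph weight,
and inverting a linear calibration curve fitted on authentic standards.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "MolecularFormula",
    "MassSpectrum",
    "HaemolymphSample",
    "CalibrationCurve",
    "QuantResult",
    "JH3",
    "METHYL_FARNESOATE",
    "JH3_BISEPOXIDE",
    "signature_mz",
    "extract_ion_intensity",
    "fit_calibration",
    "quantify_sample",
]

# Monoisotopic atomic masses (u), CODATA/AME values.
MONOISOTOPIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}
PROTON_MASS = 1.007276466812
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition, e.g. ``MolecularFormula.parse("C16H26O3")``."""

    element_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.element_counts or sum(n for _, n in self.element_counts) == 0:
            raise ValueError("formula must contain at least one atom")
        for el, n in self.element_counts:
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"no monoisotopic mass for element {el!r}")
            if n < 0:
                raise ValueError("element counts must be >= 0")

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(tuple(sorted(counts.items())))

    def count(self, element: str) -> int:
        return dict(self.element_counts).get(element, 0)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.element_counts)


#: Juvenile hormone III.
JH3 = MolecularFormula.parse("C16H26O3")
#: Methylfarnesoate.
METHYL_FARNESOATE = MolecularFormula.parse("C16H26O2")
#: Juvenile hormone III bisepoxide.
JH3_BISEPOXIDE = MolecularFormula.parse("C16H26O4")


def signature_mz(
    formula: MolecularFormula,
    mode: Literal["protonated", "protonated_minus_water"] = "protonated",
) -> float:
    """Signature-ion m/z for a singly charged adduct.

    ``protonated`` gives [M+H]+; ``protonated_minus_water`` gives the
    neutral-water-loss ion [M-H2O+H]+, defined only for formulas with at
    least one oxygen and two hydrogens.
    """
    mz = formula.monoisotopic_mass + PROTON_MASS
    if mode == "protonated_minus_water":
        if formula.count("O") < 1 or formula.count("H") < 2:
            raise ValueError("water loss needs at least one O and two H")
        mz -= WATER_MASS
    elif mode != "protonated":
        raise ValueError(f"unknown mode {mode!r}")
    return mz


@dataclass
class MassSpectrum:
    """A centroided or profile spectrum: ascending m/z with intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be matched 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "MassSpectrum":
        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        if "mz" in cols and "intensity" in cols:
            mz = df[df.columns[cols.index("mz")]].to_numpy()
            inten = df[df.columns[cols.index("intensity")]].to_numpy()
        else:  # headerless two-column file
            df = pd.read_csv(path, header=None)
            mz, inten = df[0].to_numpy(), df[1].to_numpy()
        order = np.argsort(mz)
        return cls(mz[order], inten[order])

    @classmethod
    def from_mzml(cls, path, index: int = 0) -> "MassSpectrum":
        """Read one spectrum from an mzML file (requires pyteomics)."""
        try:
            from pyteomics import mzml
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("mzML reading requires the pyteomics package") from exc
        with mzml.read(str(path)) as reader:
            for i, spec in enumerate(reader):
                if i == index:
                    return cls(spec["m/z array"], spec["intensity array"])
        raise IndexError(f"spectrum {index} not found in {path}")


def extract_ion_intensity(
    spec: MassSpectrum, target_mz: float, tol: float = 0.05
) -> float:
    """Peak abundance: maximum intensity within ``target_mz ± tol``.

    The window maximum (not the integral) is used because it is robust to
    the exact window width.  An empty window yields 0 with a warning.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo = np.searchsorted(spec.mz, target_mz - tol, side="left")
    hi = np.searchsorted(spec.mz, target_mz + tol, side="right")
    if hi <= lo:
        warnings.warn(
            f"no data points within {tol} Th of m/z {target_mz:.4f}; returning 0"
        )
        return 0.0
    return float(spec.intensity[lo:hi].max())


@dataclass
class HaemolymphSample:
    """Technical replicate spectra of one pooled haemolymph extract."""

    replicate_spectra: list[MassSpectrum]
    haemolymph_weight_mg: float

    def __post_init__(self) -> None:
        if not self.replicate_spectra:
            raise ValueError("need at least one replicate spectrum")
        if not self.haemolymph_weight_mg > 0:
            raise ValueError("haemolymph weight must be positive")


@dataclass
class CalibrationCurve:
    """Linear intensity-vs-amount calibration fitted on standards."""

    slope: float  # intensity per ng
    intercept: float  # intensity
    r_squared: float
    standards: list[tuple[float, float]] = field(default_factory=list)


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least squares of intensity on amount (free intercept)."""
    standards = [(float(a), float(i)) for a, i in standards]
    amounts = np.array([a for a, _ in standards])
    intens = np.array([i for _, i in standards])
    if len(set(amounts.tolist())) < 2:
        raise ValueError("need at least 2 distinct standard amounts")
    res = sps.linregress(amounts, intens)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        standards=standards,
    )


@dataclass
class QuantResult:
    """Quantified titre of one sample."""

    ng_per_mg: float
    mean_intensity: float
    below_lod: bool = False


def quantify_sample(
    sample: HaemolymphSample,
    curve: CalibrationCurve,
    target_mz: float,
    tol: float = 0.05,
) -> QuantResult:
    """Average replicate signature-ion intensities, invert the calibration,
    normalise to haemolymph weight.

    Amounts below the calibration intercept are clipped to zero and flagged
    as below the limit of detection.
    """
    if curve.slope <= 0:
        raise ValueError("invalid calibration: slope must be positive")
    intensities = [
        extract_ion_intensity(spec, target_mz, tol) for spec in sample.replicate_spectra
    ]
    mean_intensity = float(np.mean(intensities))
    amount_ng = (mean_intensity - curve.intercept) / curve.slope
    below = amount_ng < 0
    amount_ng = max(amount_ng, 0.0)
    return QuantResult(
        ng_per_mg=amount_ng / sample.haemolymph_weight_mg,
        mean_intensity=mean_intensity,
        below_lod=below,
    )
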