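"""Ensemble FRET spectra normalization and quadruplex-unfolding curves.

A quadruplex RNA doubly labelled with a Cy3 donor (emission maximum 566 nm)
and Cy5 acceptor (emission ~670 nm) reports its folding state through FRET:
the folded quadruplex holds the dyes close, transferring donor energy to
the acceptor; unfolding drops the acceptor peak. Spectra are normalized to
the donor maximum at 566 nm (after optional baseline subtraction) and the
unfolding fraction at protein concentration X is

    (F_670nm,0 protein - F_670nm,X protein) / F_670nm,0 protein

computed on normalized intensities. Negative fractions (acceptor gain) are
reported, not clipped — they flag anomalous spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "UnfoldingCurve",
    "normalize_spectrum",
    "unfolding_fraction",
    "build_unfolding_curve",
    "read_spectra_csv",
    "DONOR_REF_NM",
    "ACCEPTOR_REF_NM",
]

DONOR_REF_NM = 566.0
ACCEPTOR_REF_NM = 670.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """A wavelength-intensity table for one titration condition.

    ``condition`` labels the protein/peptide, ``concentration_nm`` its
    concentration in nM, ``salt`` the monovalent cation (label only).
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    condition: str = ""
    concentration_nm: float = 0.0
    salt: str = "K+"

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or w.shape != y.shape:
            raise ValueError("wavelengths and intensities must be equal-length 1-D")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", y)

    def intensity_at(self, nm: float) -> float:
        """Linear interpolation; errors if ``nm`` is outside the grid."""
        w = self.wavelengths
        if nm < w[0] or nm > w[-1]:
            raise ValueError(f"{nm} nm outside spectral grid [{w[0]}, {w[-1]}]")
        return float(np.interp(nm, w, self.intensities))


@dataclass(frozen=True)
class UnfoldingCurve:
    """Unfolding fraction vs protein concentration (nM, ascending)."""

    concentrations_nm: np.ndarray
    fractions: np.ndarray
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "concentration_nM": self.concentrations_nm,
                "unfolding_fraction": self.fractions,
            }
        )


def normalize_spectrum(
    spec: EmissionSpectrum,
    donor_ref_nm: float = DONOR_REF_NM,
    baseline: Optional[Union[EmissionSpectrum, float]] = None,
) -> EmissionSpectrum:
    """Baseline-subtract (optional) and scale so intensity(566 nm) = 1.

    ``baseline`` may be a buffer-only spectrum on the same grid or a flat
    scalar offset. A zero or negative reference intensity is an error: the
    spectrum is uninterpretable.
    """
    y = spec.intensities
    if baseline is not None:
        if isinstance(baseline, EmissionSpectrum):
            if not np.array_equal(baseline.wavelengths, spec.wavelengths):
                raise ValueError("baseline must share the spectral grid")
            y = y - baseline.intensities
        else:
            y = y - float(baseline)
    tmp = replace(spec, intensities=y)
    ref = tmp.intensity_at(donor_ref_nm)
    if ref <= 0:
        raise ValueError(
            f"non-positive reference intensity ({ref:g}) at {donor_ref_nm} nm"
        )
    return replace(spec, intensities=y / ref)


def unfolding_fraction(f0: float, fx: float) -> float:
    """(F0 - FX) / F0 on normalized 670-nm intensities; F0 must be > 0."""
    if f0 <= 0:
        raise ValueError("reference intensity F0 must be positive")
    return (f0 - fx) / f0


def build_unfolding_curve(
    spectra: Iterable[EmissionSpectrum],
    donor_ref_nm: float = DONOR_REF_NM,
    acceptor_ref_nm: float = ACCEPTOR_REF_NM,
    baseline: Optional[Union[EmissionSpectrum, float]] = None,
) -> UnfoldingCurve:
    """Normalize a titration and compute the unfolding fraction per dose.

    Input order is irrelevant; the curve is returned in ascending
    concentration. A spectrum at concentration 0 must be present — it
    supplies the reference acceptor intensity F0.
    """
    specs = sorted(spectra, key=lambda s: s.concentration_nm)
    if not specs:
        raise ValueError("no spectra given")
    if specs[0].concentration_nm != 0:
        raise ValueError("missing zero-concentration reference spectrum")
    normed = [
        normalize_spectrum(s, donor_ref_nm=donor_ref_nm, baseline=baseline)
        for s in specs
    ]
    f0 = normed[0].intensity_at(acceptor_ref_nm)
    fracs = np.array(
        [unfolding_fraction(f0, s.intensity_at(acceptor_ref_nm)) for s in normed]
    )
    return UnfoldingCurve(
        concentrations_nm=np.array([s.concentration_nm for s in specs]),
        fractions=fracs,
        condition=specs[0].condition,
    )


def read_spectra_csv(path: Union[str, Path]) -> list[EmissionSpectrum]:
    """Read long-format CSV (condition, concentration_nM, wavelength_nm,
    intensity[, salt]) into one spectrum per (condition, concentration)."""
    df = pd.read_csv(path)
    required = {"condition", "concentration_nM", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectra CSV needs columns {sorted(required)}")
    out = []
    for (cond, conc), grp in df.groupby(["condition", "concentration_nM"], sort=True):
        grp = grp.sort_values("wavelength_nm")
        salt = str(grp["salt"].iloc[0]) if "salt" in grp.columns else "K+"
        out.append(
            EmissionSpectrum(
                wavelengths=grp["wavelength_nm"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                condition=str(cond),
                concentration_nm=float(conc),
                salt=salt,
            )
        )
    return out
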