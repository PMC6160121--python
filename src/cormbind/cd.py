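"""Far-UV circular dichroism: mean residue molar ellipticity and change tests.

Raw CD signal (mdeg) is normalized to mean residue molar ellipticity
(MRME, deg*cm^2/dmol) so spectra recorded at different protein
concentrations or path lengths are comparable.  An alpha-helical protein
such as serum albumin shows the canonical double minimum at 208 and
222 nm; a ligand that perturbs secondary structure shifts or fills these
bands, which :func:`spectra_change` quantifies against a tolerance on the
spectral dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["CDSpectrum", "to_mrme", "band_minima", "spectra_change"]

# local-minimum search windows around the canonical helix bands (nm)
BAND_WINDOWS = ((204.0, 212.0), (218.0, 226.0))


@dataclass(frozen=True)
class CDSpectrum:
    """A far-UV CD spectrum with the metadata needed for normalization.

    ``conc_m`` is the molar protein concentration, ``path_cm`` the cuvette
    path length and ``n_residues`` the chain length used for the
    per-residue normalization (583 for mature bovine serum albumin).
    """

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    conc_m: float | None = None
    n_residues: int | None = None
    path_cm: float | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        el = np.asarray(self.ellipticity_mdeg, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "ellipticity_mdeg", el)
        if wl.ndim != 1 or el.shape != wl.shape:
            raise ValueError("wavelength and ellipticity must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.conc_m is not None and self.conc_m <= 0:
            raise ValueError("conc_m must be positive")
        if self.path_cm is not None and self.path_cm <= 0:
            raise ValueError("path_cm must be positive")
        if self.n_residues is not None and self.n_residues <= 0:
            raise ValueError("n_residues must be positive")


def to_mrme(spec: CDSpectrum) -> np.ndarray:
    """Convert raw ellipticity (mdeg) to MRME (deg*cm^2/dmol).

    MRME(l) = theta_mdeg(l) / (10 * C * N * d) with molar concentration C,
    residue count N and path d in cm.  Linear in theta, inverse-linear in
    each metadata factor.
    """
    if spec.conc_m is None or spec.n_residues is None or spec.path_cm is None:
        raise ValueError("conc_m, n_residues and path_cm are all required for MRME")
    return spec.ellipticity_mdeg / (10.0 * spec.conc_m * spec.n_residues * spec.path_cm)


def band_minima(
    spec: CDSpectrum,
    smooth_window: int = 7,
    windows: tuple[tuple[float, float], ...] = BAND_WINDOWS,
) -> list[tuple[float, float]]:
    """Locate the helix-band local minima of a spectrum.

    The spectrum is lightly Savitzky-Golay smoothed, local minima are
    found by a strict discrete neighborhood test and only those falling
    in the requested wavelength windows (by default around 208 and
    222 nm) are returned as ``(wavelength, raw ellipticity)`` pairs.  A
    monotone spectrum yields an empty list.
    """
    wl = spec.wavelength_nm
    if wl[0] > 200.0 or wl[-1] < 230.0:
        raise ValueError("spectrum must cover at least 200-230 nm")
    y = spec.ellipticity_mdeg
    if smooth_window and y.size >= smooth_window >= 3:
        ys = savgol_filter(y, smooth_window, polyorder=2)
    else:
        ys = y
    found: list[tuple[float, float]] = []
    for lo, hi in windows:
        candidates = [
            i for i in range(1, len(wl) - 1)
            if lo <= wl[i] <= hi and ys[i] < ys[i - 1] and ys[i] < ys[i + 1]
        ]
        if candidates:
            i = min(candidates, key=lambda i: ys[i])
            found.append((float(wl[i]), float(y[i])))
    return found


def spectra_change(specs: list[CDSpectrum], tol: float = 0.05) -> dict:
    """Test whether spectra differ beyond ``tol`` of the dynamic range.

    The first spectrum is the reference; every other spectrum is linearly
    resampled onto its grid, converted to MRME, and the maximum absolute
    deviation is normalized by the reference's dynamic range
    (max - min of MRME).  ``unchanged`` is True when the worst relative
    deviation stays within ``tol``.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 spectra to compare")
    ref = specs[0]
    ref_mrme = to_mrme(ref)
    dyn = float(ref_mrme.max() - ref_mrme.min())
    if dyn == 0.0:
        raise ValueError("reference spectrum has zero dynamic range")
    max_dev = 0.0
    worst = ref.label
    for s in specs[1:]:
        m = to_mrme(s)
        if not np.array_equal(s.wavelength_nm, ref.wavelength_nm):
            m = np.interp(ref.wavelength_nm, s.wavelength_nm, m)
        dev = float(np.max(np.abs(m - ref_mrme))) / dyn
        if dev >= max_dev:
            max_dev = dev
            worst = s.label
    return {
        "unchanged": bool(max_dev <= tol),
        "max_rel_dev": max_dev,
        "tol": tol,
        "reference": ref.label,
        "worst_spectrum": worst,
        "n_spectra": len(specs),
    }
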