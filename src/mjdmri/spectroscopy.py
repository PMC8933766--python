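"""Linear-combination quantification of single-voxel 1H spectra.

The quantifier models a frequency-domain spectrum as a non-negative linear
combination of per-metabolite basis signatures plus a smooth polynomial
baseline, in the spirit of clinical linear-combination fitters. Reliability
per metabolite is scored as a Cramer-Rao lower bound expressed as a percent
of the fitted concentration, and metabolites whose CRLB exceeds a threshold
(24% by default) are flagged for exclusion from downstream analysis.

The default mouse basis set is synthesized as sums of Lorentzian lines at
literature chemical shifts (see ``data/basis_lines.json``); measured basis
sets may be substituted via the basis-directory format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

__all__ = [
    "Spectrum",
    "BasisSet",
    "FitResult",
    "MOUSE_PANEL",
    "voi_volume_mm3",
    "default_basis",
    "fit_spectrum",
    "apply_crlb_filter",
    "reference_concentrations",
    "compute_ratios",
    "read_spectrum",
    "write_spectrum",
    "read_basis_dir",
    "write_basis_dir",
    "fit_report",
]

#: Default CRLB exclusion threshold in percent ("higher than 24%" excluded).
CRLB_THRESHOLD_PERCENT = 24.0

# Assumed tissue water concentration (mM): ~55.5 M pure water scaled by a
# nominal brain water fraction. Only sets the unit of water-referenced values.
TISSUE_WATER_MM = 43300.0


@dataclass
class Spectrum:
    """Frequency-domain signal on a strictly monotone ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    water_reference: float | None = None
    true_concentrations: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm axis and intensity must be 1D arrays of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")


@dataclass
class BasisSet:
    """Per-metabolite signature spectra sharing one ppm axis."""

    ppm: np.ndarray
    signatures: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        for name, sig in self.signatures.items():
            sig = np.asarray(sig, dtype=float)
            if sig.shape != self.ppm.shape:
                raise ValueError(f"signature {name!r} is not on the shared ppm axis")
            self.signatures[name] = sig

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def matrix(self) -> np.ndarray:
        """Design matrix with one column per metabolite (name order)."""
        return np.column_stack([self.signatures[n] for n in self.names])


@dataclass
class FitResult:
    """Fitted concentrations with CRLB-based reliability flags."""

    concentration: dict[str, float]
    crlb_percent: dict[str, float]
    baseline_coeffs: np.ndarray
    residual_norm: float
    included: dict[str, bool]
    constrained: dict[str, bool]
    noise_sd: float
    crlb_threshold: float = CRLB_THRESHOLD_PERCENT
    reference_mode: str = "raw"
    reference_scale: float = 1.0

    @property
    def raw_concentration(self) -> dict[str, float]:
        """Concentrations on the fitter's native scale (referencing undone)."""
        return {m: c / self.reference_scale for m, c in self.concentration.items()}


def _load_line_catalogue() -> tuple[dict, float]:
    with resources.files("mjdmri.data").joinpath("basis_lines.json").open() as fh:
        cat = json.load(fh)
    return cat["metabolites"], float(cat["default_linewidth_ppm"])


_CAT, _DEFAULT_LW = _load_line_catalogue()

#: The 17-metabolite mouse cerebellum panel quantified by default.
MOUSE_PANEL = tuple(_CAT)


def voi_volume_mm3(dims_mm: tuple[float, float, float]) -> float:
    """Volume of a rectangular spectroscopy voxel from its edge lengths (mm)."""
    if len(dims_mm) != 3 or any(d <= 0 for d in dims_mm):
        raise ValueError(f"VOI needs three positive edge lengths, got {dims_mm}")
    return float(np.prod(dims_mm))


def lorentzian(ppm: np.ndarray, center: float, amplitude: float, hwhm: float) -> np.ndarray:
    """Lorentzian line of peak height ``amplitude`` and half-width ``hwhm``."""
    return amplitude * hwhm**2 / ((ppm - center) ** 2 + hwhm**2)


def default_basis(
    n_points: int = 1024,
    ppm_max: float = 5.0,
    ppm_min: float = 0.2,
    panel: tuple[str, ...] | None = None,
) -> BasisSet:
    """Synthesize the default Lorentzian-line basis set.

    The ppm axis descends from ``ppm_max`` to ``ppm_min`` as spectra are
    conventionally displayed. ``panel`` restricts the metabolite list.
    """
    ppm = np.linspace(ppm_max, ppm_min, n_points)
    names = panel if panel is not None else MOUSE_PANEL
    sigs = {}
    for name in names:
        lines = _CAT[name]
        sig = np.zeros_like(ppm)
        for center, amp, lw in lines:
            sig += lorentzian(ppm, center, amp, lw if lw is not None else _DEFAULT_LW)
        sigs[name] = sig
    return BasisSet(ppm=ppm, signatures=sigs)


def _baseline_design(ppm: np.ndarray, order: int) -> np.ndarray:
    """Legendre polynomial columns on the ppm range, up to ``order``."""
    x = 2 * (ppm - ppm.min()) / (ppm.max() - ppm.min()) - 1
    return np.polynomial.legendre.legvander(x, order)


def _noise_window_mask(ppm: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = min(window), max(window)
    mask = (ppm >= lo) & (ppm <= hi)
    if mask.sum() < 8:
        raise ValueError(f"noise window {window} covers fewer than 8 points")
    return mask


def fit_spectrum(
    spectrum: Spectrum,
    basis: BasisSet,
    baseline_order: int = 2,
    noise_window_ppm: tuple[float, float] = (4.4, 5.0),
    noise_sd: float | None = None,
    crlb_threshold: float = CRLB_THRESHOLD_PERCENT,
) -> FitResult:
    """Fit a spectrum as a non-negative linear combination of basis signatures.

    Concentrations solve ``min ||y - B c - P b||`` subject to ``c >= 0`` with
    a free polynomial baseline ``P b``. CRLB percentages come from the Fisher
    information of the full linear design, with the noise variance estimated
    from fit residuals inside ``noise_window_ppm`` (a signal-free region)
    unless ``noise_sd`` is given explicitly.

    Raises a conditioning error naming the most collinear signature pair if
    the design is numerically rank deficient.
    """
    if not basis.signatures:
        raise ValueError("basis set is empty")
    if spectrum.ppm.shape != basis.ppm.shape or not np.allclose(spectrum.ppm, basis.ppm):
        raise ValueError("spectrum and basis are on different ppm axes")
    if baseline_order < 0:
        raise ValueError("baseline_order must be >= 0")

    names = basis.names
    B = basis.matrix()
    P = _baseline_design(spectrum.ppm, baseline_order)
    D = np.hstack([B, P])
    n_met, n_base = B.shape[1], P.shape[1]

    if np.linalg.matrix_rank(D) < D.shape[1]:
        # diagnose: most collinear pair of basis signatures
        C = np.corrcoef(B, rowvar=False)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient design: basis signatures {names[i]!r} and {names[j]!r} "
            f"are collinear (|r| = {abs(C[i, j]):.4f})"
        )

    lb = np.concatenate([np.zeros(n_met), np.full(n_base, -np.inf)])
    ub = np.full(n_met + n_base, np.inf)
    sol = lsq_linear(D, spectrum.intensity, bounds=(lb, ub), method="bvls")
    coef = sol.x
    resid = spectrum.intensity - D @ coef
    conc = {m: float(coef[k]) for k, m in enumerate(names)}
    # a non-negativity constraint is "active" when the solver pinned c at 0
    constrained = {m: bool(coef[k] <= 1e-12 * max(1.0, np.abs(coef).max())) for k, m in enumerate(names)}

    cov = np.linalg.inv(D.T @ D)
    if noise_sd is None:
        w = _noise_window_mask(spectrum.ppm, noise_window_ppm)
        # unbiased variance: window residuals lose the leverage the design
        # (mostly the baseline) absorbs there, E[RSS_w] = sigma^2 (n_w - tr H_w)
        leverage = float(np.einsum("ij,jk,ik->", D[w], cov, D[w]))
        dof = max(int(w.sum()) - leverage, 1.0)
        sigma = float(np.sqrt(np.sum(resid[w] ** 2) / dof))
    else:
        sigma = float(noise_sd)
    crlb = {}
    for k, m in enumerate(names):
        sd_k = sigma * float(np.sqrt(cov[k, k]))
        if constrained[m] or conc[m] <= 0:
            crlb[m] = float("nan")  # undefined for a zero-pinned metabolite
        else:
            crlb[m] = 100.0 * sd_k / conc[m]

    result = FitResult(
        concentration=conc,
        crlb_percent=crlb,
        baseline_coeffs=coef[n_met:].copy(),
        residual_norm=float(np.linalg.norm(resid)),
        included={m: True for m in names},
        constrained=constrained,
        noise_sd=sigma,
        crlb_threshold=crlb_threshold,
    )
    return apply_crlb_filter(result, crlb_threshold)


def apply_crlb_filter(result: FitResult, threshold_percent: float = CRLB_THRESHOLD_PERCENT) -> FitResult:
    """Flag metabolites whose CRLB exceeds the threshold as excluded.

    Exclusion is downstream masking only: concentrations are preserved.
    A CRLB exactly at the threshold is kept ("higher than" rule); an
    undefined CRLB (zero-constrained metabolite) is excluded.
    """
    included = {}
    for m, crlb in result.crlb_percent.items():
        included[m] = bool(np.isfinite(crlb) and crlb <= threshold_percent)
    return replace(result, included=included, crlb_threshold=threshold_percent)


def reference_concentrations(
    result: FitResult,
    mode: str,
    water_concentration: float = TISSUE_WATER_MM,
    water_area: float | None = None,
) -> FitResult:
    """Re-express concentrations relative to water or to total creatine.

    ``water`` mode multiplies by ``water_concentration / water_area`` (the
    area of the unsuppressed water signal); ``creatine`` mode divides by the
    fitted Cr + PCr. ``raw`` restores the fitter's native scale. Referencing
    is a pure rescaling, so any previously applied mode is undone first and
    ratios between metabolites are invariant to the mode.
    """
    raw = result.raw_concentration
    if mode == "raw":
        scale = 1.0
    elif mode == "water":
        if water_area is None or water_area <= 0:
            raise ValueError("water referencing requires a positive unsuppressed-water area")
        scale = water_concentration / water_area
    elif mode == "creatine":
        for m in ("Cr", "PCr"):
            if m not in raw:
                raise ValueError(f"creatine referencing requires a fitted {m}")
            if not result.included[m]:
                raise ValueError(f"creatine referencing requires {m} to pass the CRLB filter")
        tcr = raw["Cr"] + raw["PCr"]
        if tcr <= 0:
            raise ValueError("total creatine is non-positive; cannot reference")
        scale = 1.0 / tcr
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    conc = {m: c * scale for m, c in raw.items()}
    return replace(result, concentration=conc, reference_mode=mode, reference_scale=scale)


def compute_ratios(result: FitResult) -> dict[str, float | None]:
    """Diagnostic ratios NAA/Ins and NAA/tCho (tCho = PCh + GPC).

    An excluded input propagates a missing value (None) rather than 0; the
    companion ``*_reason`` entry names the excluded metabolite.
    """
    out: dict[str, float | None] = {}

    def _get(m: str) -> tuple[float | None, str | None]:
        if m not in result.concentration:
            return None, f"{m} not fitted"
        if not result.included[m]:
            return None, f"{m} excluded by CRLB filter"
        return result.concentration[m], None

    naa, r_naa = _get("NAA")
    for label, denoms in (("NAA/Ins", ("Ins",)), ("NAA/tCho", ("PCh", "GPC"))):
        reasons = [r for r in (r_naa,) if r]
        total = 0.0
        for d in denoms:
            v, r = _get(d)
            if r:
                reasons.append(r)
            else:
                total += v
        if reasons:
            out[label] = None
            out[label + "_reason"] = "; ".join(reasons)
        else:
            if total <= 0:
                raise ValueError(f"denominator of {label} is non-positive")
            out[label] = naa / total
    return out


# ---------------------------------------------------------------------------
# text I/O: two-column spectra, basis directories, fit reports

def write_spectrum(path, spectrum: Spectrum) -> None:
    np.savetxt(path, np.column_stack([spectrum.ppm, spectrum.intensity]), fmt="%.8g")


def read_spectrum(path, water_reference: float | None = None) -> Spectrum:
    arr = np.loadtxt(path)
    return Spectrum(ppm=arr[:, 0], intensity=arr[:, 1], water_reference=water_reference)


def write_basis_dir(path, basis: BasisSet) -> None:
    """One two-column text file per metabolite plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"metabolites": {}, "n_points": int(basis.ppm.size)}
    for name, sig in basis.signatures.items():
        fname = f"{name}.txt"
        np.savetxt(path / fname, np.column_stack([basis.ppm, sig]), fmt="%.8g")
        manifest["metabolites"][name] = fname
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_basis_dir(path) -> BasisSet:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    ppm = None
    sigs = {}
    for name, fname in manifest["metabolites"].items():
        arr = np.loadtxt(path / fname)
        if ppm is None:
            ppm = arr[:, 0]
        elif not np.allclose(ppm, arr[:, 0]):
            raise ValueError(f"basis file {fname} is on a different ppm axis")
        sigs[name] = arr[:, 1]
    return BasisSet(ppm=ppm, signatures=sigs)


def fit_report(result: FitResult) -> pd.DataFrame:
    """Tidy per-metabolite table (metabolite, concentration, crlb_percent, included)."""
    rows = [
        {
            "metabolite": m,
            "concentration": result.concentration[m],
            "crlb_percent": result.crlb_percent[m],
            "included": result.included[m],
        }
        for m in result.concentration
    ]
    return pd.DataFrame(rows)
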