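"""Synthetic inputs for the full pipeline.

Every input the analysis needs can be generated here with known ground
truth: labeled 3D phantoms with surface-coil bias, homogeneous calibration
volumes, frequency-domain spectra from known concentrations, and mouse /
human cohort tables whose group shifts, covariate slopes and correlation
structure mirror the study design (two-group MJD mouse model across three
ages; a patient/control cohort with collinear clinical covariates).

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import Image3D, LabelMap, LABEL_LEGEND
from .spectroscopy import BasisSet, Spectrum, _baseline_design

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_homogeneous_phantom",
    "bias_field",
    "make_spectrum",
    "make_cohort",
    "mouse_cohort_spec",
    "human_cohort_spec",
    "MOUSE_METABOLITE_MEANS",
]

# Per-metabolite (control_mean, mjd_mean, control_sd, mjd_sd) in
# water-referenced units. Means for NAA, NAAG (via NAA+NAAG), Glu, Tau and
# Ins follow the reported group values for this mouse model; the remaining
# panel members use literature-plausible rodent cerebellum levels with
# little or no group shift.
MOUSE_METABOLITE_MEANS: dict[str, tuple[float, float, float, float]] = {
    "NAA": (1.02, 0.71, 0.25, 0.22),
    "NAAG": (0.22, 0.20, 0.08, 0.08),
    "Cr": (4.00, 4.00, 0.60, 0.60),
    "PCr": (4.20, 4.20, 0.60, 0.60),
    "Glu": (5.80, 4.29, 1.27, 1.25),
    "Gln": (2.50, 2.60, 0.50, 0.50),
    "Ins": (4.95, 6.97, 1.25, 2.32),
    "Tau": (5.73, 4.35, 1.66, 1.22),
    "Cho": (0.06, 0.06, 0.02, 0.02),
    "PCh": (0.15, 0.17, 0.04, 0.04),
    "GPC": (0.13, 0.15, 0.04, 0.04),
    "GSH": (1.00, 1.00, 0.25, 0.25),
    "GABA": (1.50, 1.40, 0.35, 0.35),
    "Lac": (1.00, 1.10, 0.30, 0.30),
    "Ala": (0.40, 0.40, 0.12, 0.12),
    "MM": (5.00, 5.90, 1.20, 1.20),
    "Lip": (2.00, 2.30, 0.70, 0.70),
}


@dataclass
class PhantomSpec:
    """Geometry and signal model of a synthetic cerebellar T2-like stack.

    Defaults emulate the animal acquisition grid (0.0781 mm in-plane,
    0.5 mm slices). The cerebellum is an ellipsoid with semi-axes
    ``(r, 0.85 r, 0.6 r)`` for ``r = cerebellum_radius_mm``; WM is an
    arborized branching tree inside it; the fourth ventricle is a small
    CSF ellipsoid abutting the cerebellum, sized to a target volume.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 24)
    voxel_size_mm: tuple[float, float, float] = (0.0781, 0.0781, 0.5)
    cerebellum_radius_mm: float = 3.0
    wm_fraction: float = 0.25
    ventricle_volume_mm3: float = 2.772
    tissue_means: dict[str, float] = field(
        default_factory=lambda: {"background": 10.0, "GM": 100.0, "WM": 160.0, "CSF": 230.0}
    )
    noise_sd: float = 2.0
    bias_strength: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if self.cerebellum_radius_mm <= 0:
            raise ValueError("cerebellum_radius_mm must be positive")
        if not 0 < self.wm_fraction < 1:
            raise ValueError(f"wm_fraction must be in (0, 1), got {self.wm_fraction}")
        if self.ventricle_volume_mm3 <= 0:
            raise ValueError("ventricle_volume_mm3 must be positive")
        if self.noise_sd < 0 or self.bias_strength <= 0:
            raise ValueError("noise_sd must be >= 0 and bias_strength > 0")
        vals = list(self.tissue_means.values())
        if len(set(vals)) != len(vals):
            raise ValueError("tissue_means must be pairwise distinct")
        self._check_fit()

    # cerebellum semi-axes in mm, per axis
    @property
    def semi_axes_mm(self) -> tuple[float, float, float]:
        r = self.cerebellum_radius_mm
        return (r, 0.85 * r, 0.6 * r)

    def _check_fit(self) -> None:
        axes = ("axis 0", "axis 1", "axis 2")
        half_extent = [0.5 * n * s for n, s in zip(self.grid_shape, self.voxel_size_mm)]
        # ventricle sits beyond the cerebellum along axis 1
        a_v, c_v = _ventricle_semi_axes(self.ventricle_volume_mm3)
        need = list(self.semi_axes_mm)
        need[1] += 2 * a_v + 0.3  # offset for the abutting ventricle
        for name, req, have, vox in zip(axes, need, half_extent, self.voxel_size_mm):
            if req + 2 * vox > have:
                raise ValueError(
                    f"phantom geometry does not fit the grid along {name}: "
                    f"needs {req:.2f} mm half-extent, grid provides {have:.2f} mm"
                )


def _ventricle_semi_axes(volume_mm3: float, c_mm: float = 0.75) -> tuple[float, float]:
    """In-plane and through-plane semi-axes of the ventricle ellipsoid."""
    a = np.sqrt(3.0 * volume_mm3 / (4.0 * np.pi * c_mm))
    return float(a), float(c_mm)


def _grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates (mm) relative to the grid centre, per axis."""
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    return tuple(np.meshgrid(*coords, indexing="ij"))


def bias_field(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth multiplicative coil gain for a spec.

    A smooth strictly positive profile decaying exponentially with depth
    from a virtual surface coil at the low end of axis 1; the peak-to-trough
    ratio equals ``bias_strength``.
    """
    ny = spec.grid_shape[1]
    depth = np.arange(ny) / max(ny - 1, 1)
    profile = np.exp(-np.log(spec.bias_strength) * depth)
    return np.broadcast_to(profile[None, :, None], spec.grid_shape).copy()


def _segment_distance_xy(px, py, ax, ay, bx, by):
    """Distance of points (px, py) to segment (a, b), vectorized."""
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / max(L2, 1e-12), 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def _wm_tree_mask(spec: PhantomSpec, cere: np.ndarray, X, Y, Z) -> np.ndarray:
    """Connected branching WM (arbor-vitae-like) inside the cerebellum.

    A trunk with paired branches in the axial plane is dilated by taking all
    cerebellar voxels whose distance to the skeleton falls below the
    ``wm_fraction`` quantile of that distance, so the WM voxel fraction
    matches the spec exactly up to ties.
    """
    a, b, c = spec.semi_axes_mm
    segs = [(-0.6 * a, 0.0, 0.6 * a, 0.0)]  # trunk along axis 0
    for fx in (-0.4, 0.0, 0.4):
        reach = 0.7 * b * np.sqrt(max(1.0 - fx**2, 0.0))
        segs.append((fx * a, 0.0, (fx + 0.15) * a, reach))
        segs.append((fx * a, 0.0, (fx + 0.15) * a, -reach))

    px, py, pz = X[cere], Y[cere], Z[cere]
    d_xy = np.full(px.shape, np.inf)
    for ax_, ay_, bx_, by_ in segs:
        d_xy = np.minimum(d_xy, _segment_distance_xy(px, py, ax_, ay_, bx_, by_))
    # confine the tree to a central slab through the slices
    dz = np.maximum(np.abs(pz) - 0.45 * c, 0.0)
    d = np.hypot(d_xy, dz)
    thr = np.quantile(d, spec.wm_fraction)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    mask[cere] = d <= thr
    return mask


def make_phantom(spec: PhantomSpec) -> tuple[Image3D, LabelMap]:
    """Generate a labeled cerebellar phantom and its biased intensity volume.

    Returns the intensity image ``tissue_means[label] * bias + noise`` and
    the exact ground-truth label map (0=background, 1=GM, 2=WM, 3=CSF).
    The ventricle voxel count is calibrated so that count x voxel volume
    lands within half a voxel of ``ventricle_volume_mm3``.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = _grid_mm(spec)
    a, b, c = spec.semi_axes_mm

    cere = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[cere] = 1
    labels[_wm_tree_mask(spec, cere, X, Y, Z)] = 2

    # fourth ventricle: CSF ellipsoid abutting the cerebellum along axis 1,
    # trimmed/grown to the exact target voxel count
    a_v, c_v = _ventricle_semi_axes(spec.ventricle_volume_mm3)
    cy = b + a_v + 0.15
    q = (X / a_v) ** 2 + ((Y - cy) / a_v) ** 2 + (Z / c_v) ** 2
    voxvol = float(np.prod(spec.voxel_size_mm))
    n_target = int(round(spec.ventricle_volume_mm3 / voxvol))
    cand = np.flatnonzero((q <= 2.0).ravel() & (labels.ravel() == 0))
    if cand.size < n_target:
        raise ValueError("phantom geometry does not fit the grid along axis 1: ventricle candidates exhausted")
    order = np.argsort(q.ravel()[cand], kind="stable")
    labels.ravel()[cand[order[:n_target]]] = 3

    lut = np.array(
        [spec.tissue_means[LABEL_LEGEND[k]] for k in range(4)], dtype=float
    )
    data = lut[labels] * bias_field(spec)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    image = Image3D(data, spec.voxel_size_mm)
    return image, LabelMap(labels, spec.voxel_size_mm)


def make_homogeneous_phantom(spec: PhantomSpec) -> Image3D:
    """Single-tissue calibration volume modulated only by the coil bias.

    The tissue intensity is the mean of the non-background tissue means (a
    uniform water/agar phantom at mid-range signal); noise is additive.
    """
    rng = np.random.default_rng(spec.seed)
    mean = float(
        np.mean([v for k, v in spec.tissue_means.items() if k != "background"])
    )
    data = mean * bias_field(spec)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    return Image3D(data, spec.voxel_size_mm)


def make_spectrum(
    basis: BasisSet,
    concentrations: dict[str, float],
    baseline_coeffs: np.ndarray | list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """Forward-model a spectrum from known concentrations.

    ``spectrum = sum_m c_m * basis_m + smooth Legendre baseline + noise``.
    The true concentrations are recorded in the spectrum's metadata.
    """
    unknown = set(concentrations) - set(basis.signatures)
    if unknown:
        raise ValueError(f"concentrations name metabolites absent from the basis: {sorted(unknown)}")
    if any(v < 0 for v in concentrations.values()):
        raise ValueError("concentrations must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.zeros_like(basis.ppm)
    for m, conc in concentrations.items():
        y = y + conc * basis.signatures[m]
    if baseline_coeffs is not None:
        bc = np.asarray(baseline_coeffs, dtype=float)
        y = y + _baseline_design(basis.ppm, bc.size - 1) @ bc
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return Spectrum(ppm=basis.ppm.copy(), intensity=y, true_concentrations=dict(concentrations))


# ---------------------------------------------------------------------------
# cohort tables


@dataclass
class CohortSpec:
    """Statistical structure of a synthetic cohort.

    ``group_effects`` holds the MJD-minus-control mean shift per variable on
    top of ``means`` (the control means); ``noise_sds`` the within-group
    SDs (``<var>__mjd`` overrides the MJD-group SD where it differs).
    ``covariate_effects`` holds the slope structure (volume on age per
    group/sex, rotarod latency on metabolites), ``correlation_block`` the
    target correlations among the clinical variables of patients.
    """

    species: str = "mouse"
    n_per_group: int | dict[str, int] = 9
    ages: tuple[float, ...] = (2.0, 4.0, 16.0)
    means: dict[str, float] = field(default_factory=dict)
    group_effects: dict[str, float] = field(default_factory=dict)
    noise_sds: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    correlation_block: dict = field(default_factory=dict)
    seed: int = 0

    def n_for(self, group: str) -> int:
        n = self.n_per_group[group] if isinstance(self.n_per_group, dict) else self.n_per_group
        if n < 2:
            raise ValueError(f"n_per_group must be >= 2 (got {n} for {group}); downstream tests are undefined")
        return int(n)


def mouse_cohort_spec(n_per_group: int = 9, seed: int = 0) -> CohortSpec:
    """Default two-group mouse cohort across ages 2/4/16 months.

    ``n_per_group`` is subjects per (group, age) cell; the default of 9 per
    cell yields 27 animals per group, matching the volumetric comparison's
    sample size. Volume and metabolite group means follow the reported
    values; rotarod latencies depend linearly on NAA with noise sized for a
    weak-to-moderate fit (r^2 near 0.35) at desk-scale n.
    """
    means, shifts, sds = {}, {}, {}
    for var, (wt, mjd, sd_wt, sd_mjd) in MOUSE_METABOLITE_MEANS.items():
        means[var], shifts[var], sds[var] = wt, mjd - wt, sd_wt
        if sd_mjd != sd_wt:
            sds[var + "__mjd"] = sd_mjd
    # volumes in mm^3; SDs are SEM * sqrt(n) from the printed group summaries
    means.update({"cerebellum_volume_mm3": 49.62, "wm_volume_mm3": 25.35, "ventricle_volume_mm3": 1.491})
    shifts.update({"cerebellum_volume_mm3": 20.73 - 49.62, "wm_volume_mm3": 19.03 - 25.35,
                   "ventricle_volume_mm3": 2.772 - 1.491})
    sds.update({"cerebellum_volume_mm3": 3.19, "cerebellum_volume_mm3__mjd": 1.39,
                "wm_volume_mm3": 1.41, "wm_volume_mm3__mjd": 1.69,
                "ventricle_volume_mm3": 0.209, "ventricle_volume_mm3__mjd": 0.393})
    covar = {
        "rotarod_accel_s": {"intercept": 20.0, "NAA": 180.0, "noise_sd": 72.0},
        "rotarod_stationary_s": {"intercept": 60.0, "NAA": 150.0, "noise_sd": 80.0},
        "rotarod_ages": [2.0, 4.0],
    }
    return CohortSpec(
        species="mouse", n_per_group=n_per_group, ages=(2.0, 4.0, 16.0),
        means=means, group_effects=shifts, noise_sds=sds,
        covariate_effects=covar, seed=seed,
    )


def human_cohort_spec(n_per_group: int | dict[str, int] | None = None, seed: int = 0) -> CohortSpec:
    """Default patient/control cohort (18 controls vs 16 MJD).

    Cerebellar GM/WM/CSF volumes (mL) decline with age with steeper slopes
    in patients; CSF growth with age is sex-dependent in patients. The
    clinical block (age of onset, disease duration, CAG repeats, SARA)
    carries the collinearity the screening step must resolve: duration and
    CAG correlate strongly (|r| > 0.7) with onset, while SARA correlates
    only moderately with the rest; GM additionally depends on onset and
    SARA so that onset wins the univariate-AIC contest against its
    correlated partners.
    """
    if n_per_group is None:
        n_per_group = {"control": 18, "MJD": 16}
    covar = {
        "gm": {"intercept": {"control": 110.0, "MJD": 115.0},
               "age_slope": {"control": -0.39, "MJD": -0.72},
               "onset_slope": 0.6, "sara_slope": -0.15, "noise_sd": 2.5},
        "wm": {"intercept": {"control": 32.0, "MJD": 33.0},
               "age_slope": {"control": -0.11, "MJD": -0.28}, "noise_sd": 1.5},
        "csf": {"intercept": {"control": 8.0, "MJD": 9.0},
                "age_slope": {"control": {"M": 0.03, "F": -0.01},
                              "MJD": {"M": 0.15, "F": 0.08}}, "noise_sd": 1.2},
        "age": {"mean": {"control": 33.19, "MJD": 41.15}, "sd": {"control": 10.0, "MJD": 12.2}},
        "male_fraction": {"control": 10 / 18, "MJD": 9 / 16},
    }
    block = {
        "variables": ["age_of_onset", "disease_duration", "cag_repeats", "sara"],
        "means": [38.0, 8.0, 72.0, 15.0],
        "sds": [8.0, 5.0, 3.0, 6.0],
        "correlation": [
            [1.00, -0.85, -0.80, -0.35],
            [-0.85, 1.00, 0.65, 0.20],
            [-0.80, 0.65, 1.00, 0.25],
            [-0.35, 0.20, 0.25, 1.00],
        ],
    }
    return CohortSpec(
        species="human", n_per_group=n_per_group, ages=(),
        covariate_effects=covar, correlation_block=block, seed=seed,
    )


def _group_sd(spec: CohortSpec, var: str, group: str) -> float:
    if group == "MJD" and var + "__mjd" in spec.noise_sds:
        return spec.noise_sds[var + "__mjd"]
    return spec.noise_sds[var]


def _make_mouse_cohort(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sid = 0
    variables = [v for v in spec.means]
    for group in ("control", "MJD"):
        n_cell = spec.n_for(group)
        for age in spec.ages:
            for _ in range(n_cell):
                row = {"subject_id": f"m{sid:03d}", "species": "mouse", "group": group,
                       "age_months": age, "sex": "M" if rng.random() < 0.5 else "F"}
                for var in variables:
                    mu = spec.means[var] + (spec.group_effects.get(var, 0.0) if group == "MJD" else 0.0)
                    row[var] = rng.normal(mu, _group_sd(spec, var, group))
                rows.append(row)
                sid += 1
    df = pd.DataFrame(rows)
    # metabolite concentrations are physically non-negative
    for var in MOUSE_METABOLITE_MEANS:
        df[var] = df[var].clip(lower=0.0)
    rot_ages = spec.covariate_effects.get("rotarod_ages", [])
    for latency in ("rotarod_accel_s", "rotarod_stationary_s"):
        eff = spec.covariate_effects[latency]
        vals = np.full(len(df), np.nan)
        mask = df["age_months"].isin(rot_ages).to_numpy()
        lin = eff["intercept"] + sum(
            slope * df[m].to_numpy() for m, slope in eff.items() if m not in ("intercept", "noise_sd")
        )
        vals[mask] = np.clip(lin[mask] + rng.normal(0.0, eff["noise_sd"], mask.sum()), 0.0, None)
        df[latency] = vals
    return df


def _make_human_cohort(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cov = spec.covariate_effects
    blk = spec.correlation_block
    R = np.asarray(blk["correlation"], dtype=float)
    L = np.linalg.cholesky(R)
    sds, mus = np.asarray(blk["sds"]), np.asarray(blk["means"])

    rows = []
    sid = 0
    for group in ("control", "MJD"):
        n = spec.n_for(group)
        age = rng.normal(cov["age"]["mean"][group], cov["age"]["sd"][group], n).clip(18.0, 75.0)
        sex = np.where(rng.random(n) < cov["male_fraction"][group], "M", "F")
        if group == "MJD":
            z = rng.standard_normal((n, R.shape[0])) @ L.T
            clin = mus + z * sds
            onset = clin[:, 0].clip(15.0, 60.0)
            duration = clin[:, 1].clip(0.5, None)
            cag = np.round(clin[:, 2]).clip(61, 87)
            sara = clin[:, 3].clip(4.0, 40.0)
        else:
            onset = duration = cag = sara = np.full(n, np.nan)

        gm_c = cov["gm"]
        gm = gm_c["intercept"][group] + gm_c["age_slope"][group] * age
        if group == "MJD":
            gm = gm + gm_c["onset_slope"] * (onset - blk["means"][0]) + gm_c["sara_slope"] * (sara - blk["means"][3])
        gm = gm + rng.normal(0.0, gm_c["noise_sd"], n)
        wm_c = cov["wm"]
        wm = wm_c["intercept"][group] + wm_c["age_slope"][group] * age + rng.normal(0.0, wm_c["noise_sd"], n)
        csf_c = cov["csf"]
        csf_slope = np.array([csf_c["age_slope"][group][s] for s in sex])
        csf = csf_c["intercept"][group] + csf_slope * age + rng.normal(0.0, csf_c["noise_sd"], n)

        for i in range(n):
            rows.append({
                "subject_id": f"h{sid:03d}", "species": "human", "group": group,
                "age_years": age[i], "sex": sex[i],
                "gm_volume_ml": gm[i], "wm_volume_ml": wm[i], "csf_volume_ml": csf[i],
                "total_volume_ml": gm[i] + wm[i] + csf[i],
                "sara": sara[i], "age_of_onset": onset[i],
                "disease_duration": duration[i], "cag_repeats": cag[i],
            })
            sid += 1
    return pd.DataFrame(rows)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table (one row per subject) for either species.

    Mouse tables carry tissue volumes, the 17-metabolite panel and rotarod
    latencies (missing for 16-month animals, which were not tested); human
    tables carry GM/WM/CSF/total cerebellar volumes and the clinical block
    (missing for controls). Missingness is explicit NaN, never silent.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.species == "mouse":
        return _make_mouse_cohort(spec, rng)
    if spec.species == "human":
        return _make_human_cohort(spec, rng)
    raise ValueError(f"unknown species {spec.species!r}")
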