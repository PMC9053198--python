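"""Digital breast phantoms, dual-energy forward projection, and a CAD surrogate.

The generator emulates the population structure the downstream analysis
assumes: compressed-breast lipid/water/protein (LWP) thickness maps with mild
low-frequency compositional texture, irregular lesions of four pathology
classes (other-benign BN, fibroadenoma FA, ductal carcinoma in situ DCIS,
invasive ductal carcinoma IDC) carrying class-specific compositional gradients,
hormone-receptor labels on invasive lesions, paired low-/high-energy
attenuation images, and CAD-style region proposals with binormal malignancy
scores, including per-pathology misses and unmatched false proposals.

Lesion compositional gradients are parametrized by the lesion-minus-ring
median signature at the three 2-mm outer rings.  A lesion applies a
piecewise-constant additive offset to each component map: one value inside the
lesion (the "core") and one per 2-mm distance band outside it, zero beyond
6 mm.  With offsets ``core = S_3`` and ``ring_k = S_3 - S_k`` the expected
measured signature at ring k is exactly ``S_k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import ndtr, ndtri

from .decomposition import AttenuationModel
from .exceptions import ConfigurationError, DegenerateModelError

PATHOLOGIES = ("BN", "FA", "DCIS", "IDC")
#: Pathology mix of a diagnostic (biopsy-bound) cohort (BN, FA, DCIS, IDC).
DEFAULT_PATHOLOGY_COUNTS = {"BN": 409, "FA": 116, "DCIS": 61, "IDC": 103}

RECEPTOR_STATUSES = (
    "ER+",
    "PR+",
    "HER2+",
    "ER+/PR+",
    "ER+/PR+/HER2+",
    "triple-negative",
)
#: Receptor mix for invasive lesions (not reported as counts in the source
#: cohort; a typical clinical distribution is assumed).
DEFAULT_RECEPTOR_WEIGHTS = {
    "ER+": 0.20,
    "PR+": 0.05,
    "HER2+": 0.10,
    "ER+/PR+": 0.30,
    "ER+/PR+/HER2+": 0.20,
    "triple-negative": 0.15,
}

COMPONENTS = ("lipid", "water", "protein")

#: Default lesion-minus-ring median signatures (cm) at rings 1/2/3 for the
#: malignant (DCIS+IDC) and benign (BN+FA) classes.  Malignant lesions show a
#: lipid deficit that widens with ring distance and a relative water/protein
#: excess over benign lesions that also widens with distance.
MALIGNANT_SIGNATURES = {
    "lipid": (-2.50e-2, -4.93e-2, -5.56e-2),
    "water": (-9.39e-3, -9.17e-3, -5.17e-3),
    "protein": (1.23e-2, 3.42e-2, 3.99e-2),
}
BENIGN_SIGNATURES = {
    "lipid": (-1.82e-2, -3.74e-2, -4.03e-2),
    "water": (-1.77e-2, -2.21e-2, -2.22e-2),
    "protein": (3.44e-3, 1.89e-2, 2.33e-2),
}


@dataclass(frozen=True)
class EffectProfile:
    """Per-component additive thickness offsets (cm) at the lesion core and in
    the three 2-mm outer bands.  ``offsets[comp] = (core, band1, band2, band3)``.
    """

    offsets: dict

    @classmethod
    def from_signatures(cls, signatures: dict) -> "EffectProfile":
        """Build offsets realizing target lesion-minus-ring signatures.

        ``signatures[comp] = (S1, S2, S3)``; the band at 4-6 mm is anchored at
        zero (taken as normal tissue), so the core offset equals S3.
        """
        offs = {}
        for comp, (s1, s2, s3) in signatures.items():
            offs[comp] = (float(s3), float(s3 - s1), float(s3 - s2), 0.0)
        return cls(offs)

    def signatures(self) -> dict:
        """Expected lesion-minus-ring median signature per component."""
        return {
            comp: tuple(v[0] - v[k] for k in (1, 2, 3))
            for comp, v in self.offsets.items()
        }

    def scaled(self, factor: float) -> "EffectProfile":
        return EffectProfile(
            {c: tuple(factor * x for x in v) for c, v in self.offsets.items()}
        )


def default_effect_profiles() -> dict:
    mal = EffectProfile.from_signatures(MALIGNANT_SIGNATURES)
    ben = EffectProfile.from_signatures(BENIGN_SIGNATURES)
    return {"BN": ben, "FA": ben, "DCIS": mal, "IDC": mal}


@dataclass(frozen=True)
class LesionRecord:
    mask: np.ndarray
    pathology: str
    receptor_status: str  # "none" for non-IDC lesions
    effect_profile: EffectProfile
    center_px: tuple[int, int]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGIES:
            raise ConfigurationError(f"unknown pathology {self.pathology!r}")
        if self.receptor_status != "none" and self.pathology != "IDC":
            raise ConfigurationError("receptor status applies to IDC lesions only")

    @property
    def is_malignant(self) -> bool:
        return self.pathology in ("DCIS", "IDC")

    @property
    def label(self) -> int:
        return int(self.is_malignant)


@dataclass
class Phantom:
    """Ground-truth compressed-breast composition on a 2D pixel grid."""

    lipid_map: np.ndarray
    water_map: np.ndarray
    protein_map: np.ndarray
    breast_mask: np.ndarray
    pixel_spacing: float  # mm per pixel, isotropic
    lesions: list
    patient_id: str
    view: str = "CC"

    @property
    def thickness_map(self) -> np.ndarray:
        return self.lipid_map + self.water_map + self.protein_map

    def component(self, name: str) -> np.ndarray:
        return {"lipid": self.lipid_map, "water": self.water_map,
                "protein": self.protein_map}[name]


@dataclass
class DualEnergyAcquisition:
    attenuation_le: np.ndarray
    attenuation_he: np.ndarray
    thickness_map: np.ndarray
    pixel_spacing: float
    noise_sigma: float


@dataclass
class CadProposal:
    mask: np.ndarray
    kind: str  # "mass" | "calcification-cluster"
    probability: float
    matched_lesion: int | None  # index into phantom.lesions, None for false hits

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError("CAD probability must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Phantom-generator configuration.

    Defaults describe a desk-scale compressed breast: a 256x256 grid at 0.2 mm
    pitch (~5 cm field), ~4.5 cm compressed thickness with an edge taper,
    background composition 40/45/15 % lipid/water/protein with gentle
    low-frequency texture, and one to two irregular lesions per view with the
    pathology mix of a diagnostic cohort.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_spacing_mm: float = 0.2
    mean_thickness_cm: float = 4.5
    thickness_sd_cm: float = 0.5
    background_fractions: tuple[float, float, float] = (0.40, 0.45, 0.15)
    fraction_patient_sd: float = 0.04
    texture_scale_mm: float = 14.0
    texture_sd: float = 0.005
    lesion_count_range: tuple[int, int] = (1, 2)
    lesion_radius_mm_range: tuple[float, float] = (2.0, 4.5)
    ring_margin_mm: float = 6.0
    #: normalized elliptical radius inside which the compressed thickness is
    #: flat; lesions and their rings are confined to this plateau so that ring
    #: statistics are not confounded by the edge taper.
    flat_radius: float = 0.88
    boundary_irregularity: float = 0.35
    pathology_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_PATHOLOGY_COUNTS)
    )
    receptor_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_RECEPTOR_WEIGHTS)
    )
    effect_profiles: dict = field(default_factory=default_effect_profiles)
    #: triple-negative invasive lesions get their lipid gradient deepened by
    #: this factor (stronger peripheral lipid depletion).
    triple_negative_lipid_factor: float = 1.3
    profile_jitter_sd: float = 0.25


def _gaussian_random_field(rng, shape, sigma_px):
    """Unit-variance smooth field: coarse white noise spline-upsampled."""
    coarse = (max(4, int(np.ceil(shape[0] / max(sigma_px, 1.0)) + 3)),
              max(4, int(np.ceil(shape[1] / max(sigma_px, 1.0)) + 3)))
    noise = rng.standard_normal(coarse)
    zoom = (shape[0] / coarse[0], shape[1] / coarse[1])
    f = ndimage.zoom(noise, zoom, order=3, mode="nearest")[: shape[0], : shape[1]]
    sd = f.std()
    return f / sd if sd > 0 else f


def _breast_geometry(shape):
    """Elliptical breast mask and normalized elliptical radius rho in [0, inf)."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = 0.46 * ny, 0.42 * nx
    rho = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    return rho <= 1.0, rho


def _lesion_blob(rng, shape, center, radius_px, irregularity):
    """Irregular 4-connected blob: radial ramp plus smooth noise, thresholded."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(yy - center[0], xx - center[1])
    noise = _gaussian_random_field(rng, shape, sigma_px=max(2.0, radius_px / 1.5))
    fld = (1.0 - d / radius_px) + irregularity * noise
    blob = fld > 0
    # keep only the 4-connected component containing the center
    lab, _ = ndimage.label(blob, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    lab_c = lab[center]
    if lab_c == 0:  # degenerate draw: fall back to a disk
        return d <= radius_px
    return lab == lab_c


def _draw_category(rng, weights: dict) -> str:
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def generate_phantom(
    sim_config: SimConfig,
    seed: int,
    patient_id: str | None = None,
    view: str = "CC",
) -> Phantom:
    """Generate one synthetic compressed-breast view with embedded lesions.

    Identical ``(sim_config, seed)`` pairs reproduce bit-identical phantoms.
    The three component maps are nonnegative, zero outside the breast mask,
    and sum to the total-thickness map by construction.
    """
    cfg = sim_config
    if cfg.pixel_spacing_mm <= 0:
        raise ConfigurationError("pixel spacing must be positive")
    rng = np.random.default_rng(seed)
    shape = tuple(cfg.shape)
    spacing = cfg.pixel_spacing_mm

    mask, rho = _breast_geometry(shape)
    semi_minor_mm = min(0.46 * shape[0], 0.42 * shape[1]) * spacing
    max_radius = cfg.lesion_radius_mm_range[1]
    if (cfg.lesion_count_range[1] > 0
            and max_radius + cfg.ring_margin_mm >= cfg.flat_radius * semi_minor_mm):
        raise ConfigurationError(
            "lesion plus outer rings cannot fit inside the breast region"
        )

    # compressed thickness: flat plateau under the paddle, cosine edge rolloff
    t0 = max(1.0, rng.normal(cfg.mean_thickness_cm, cfg.thickness_sd_cm))
    edge = np.clip((rho - cfg.flat_radius) / (1.0 - cfg.flat_radius), 0.0, 1.0)
    thickness = np.where(mask, t0 * np.sqrt(np.cos(0.5 * np.pi * edge * 0.97)), 0.0)

    # background composition: per-patient base fractions + smooth texture
    sigma_px = cfg.texture_scale_mm / spacing
    base = np.asarray(cfg.background_fractions, dtype=float)
    base = np.clip(base + rng.normal(0.0, cfg.fraction_patient_sd, 3), 0.05, None)
    fracs = []
    for c in range(3):
        f = base[c] + cfg.texture_sd * _gaussian_random_field(rng, shape, sigma_px)
        fracs.append(np.clip(f, 0.02, None))
    fracs = np.stack(fracs)
    fracs /= fracs.sum(axis=0, keepdims=True)
    maps = [fracs[c] * thickness for c in range(3)]

    # lesions
    n_lesions = int(rng.integers(cfg.lesion_count_range[0],
                                 cfg.lesion_count_range[1] + 1))
    lesions: list[LesionRecord] = []
    margin_px = cfg.ring_margin_mm / spacing
    for _ in range(n_lesions):
        pathology = _draw_category(rng, cfg.pathology_weights)
        receptor = (
            _draw_category(rng, cfg.receptor_weights) if pathology == "IDC" else "none"
        )
        radius_mm = rng.uniform(*cfg.lesion_radius_mm_range)
        radius_px = radius_mm / spacing

        # lesion plus its rings must stay on the thickness plateau
        rho_bound = cfg.flat_radius - (radius_mm + cfg.ring_margin_mm) / semi_minor_mm
        center = None
        for _try in range(200):
            cy = int(rng.integers(0, shape[0]))
            cx = int(rng.integers(0, shape[1]))
            if rho[cy, cx] > rho_bound:
                continue
            ok = True
            for prev in lesions:
                dy = cy - prev.center_px[0]
                dx = cx - prev.center_px[1]
                min_sep = (radius_px + prev.radius_mm / spacing) + 2 * margin_px
                if math.hypot(dy, dx) < min_sep:
                    ok = False
                    break
            if ok:
                center = (cy, cx)
                break
        if center is None:
            continue  # crowded view: drop the extra lesion

        blob = _lesion_blob(rng, shape, center, radius_px, cfg.boundary_irregularity)
        blob &= mask
        if not blob.any():
            continue

        profile = cfg.effect_profiles[pathology]
        if receptor == "triple-negative":
            offs = dict(profile.offsets)
            offs["lipid"] = tuple(
                cfg.triple_negative_lipid_factor * x for x in offs["lipid"]
            )
            profile = EffectProfile(offs)
        jitter = max(0.2, rng.normal(1.0, cfg.profile_jitter_sd))
        realized = profile.scaled(jitter)

        dist_mm = ndimage.distance_transform_edt(~blob, sampling=spacing)
        bands = [
            blob,
            (dist_mm > 0) & (dist_mm <= 2.0) & mask,
            (dist_mm > 2.0) & (dist_mm <= 4.0) & mask,
            (dist_mm > 4.0) & (dist_mm <= 6.0) & mask,
        ]
        for c, comp in enumerate(COMPONENTS):
            offs = realized.offsets[comp]
            for b, bandmask in enumerate(bands):
                maps[c][bandmask] += offs[b]

        lesions.append(
            LesionRecord(
                mask=blob,
                pathology=pathology,
                receptor_status=receptor,
                effect_profile=realized,
                center_px=center,
                radius_mm=radius_mm,
            )
        )

    for c in range(3):
        maps[c] = np.where(mask, np.clip(maps[c], 0.0, None), 0.0)

    return Phantom(
        lipid_map=maps[0],
        water_map=maps[1],
        protein_map=maps[2],
        breast_mask=mask,
        pixel_spacing=spacing,
        lesions=lesions,
        patient_id=patient_id or f"P{seed:08d}",
        view=view,
    )


def forward_project(
    phantom: Phantom,
    atten_model: AttenuationModel,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DualEnergyAcquisition:
    """Project a phantom into paired low-/high-energy attenuation images.

    The noiseless output satisfies ``A_E = mu_l,E t_l + mu_w,E t_w + mu_p,E t_p``
    per pixel; independent zero-mean Gaussian noise of the stated sigma is then
    added to each attenuation pixel.  The thickness map is the exact sum of the
    three component maps (the paddle-derived thickness is treated as known).
    """
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be nonnegative")
    if atten_model.energy_rows_proportional():
        raise DegenerateModelError(
            "LE and HE coefficient rows are proportional; energies are degenerate"
        )
    stack = np.stack([phantom.lipid_map, phantom.water_map, phantom.protein_map])
    mu = atten_model.coefficients  # (2, 3)
    atten = np.tensordot(mu, stack, axes=(1, 0))  # (2, ny, nx)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        atten = atten + rng.normal(0.0, noise_sigma, atten.shape)
    return DualEnergyAcquisition(
        attenuation_le=atten[0],
        attenuation_he=atten[1],
        thickness_map=phantom.thickness_map,
        pixel_spacing=phantom.pixel_spacing,
        noise_sigma=float(noise_sigma),
    )


def generate_calibration_set(
    atten_model: AttenuationModel,
    step_design,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Simulate calibration-phantom measurements for a list of LWP triples."""
    from .decomposition import CalibrationSet
    from .exceptions import CalibrationError

    design = np.atleast_2d(np.asarray(step_design, dtype=float))
    if design.shape[0] < 3 or design.shape[1] != 3:
        raise CalibrationError("step design needs >= 3 LWP thickness triples")
    if np.linalg.matrix_rank(design) < 3:
        raise CalibrationError("step design is rank deficient")
    atten = design @ atten_model.coefficients.T  # (n, 2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        atten = atten + rng.normal(0.0, noise_sigma, atten.shape)
    return CalibrationSet(np.hstack([design, atten]))


@dataclass(frozen=True)
class CadConfig:
    """CAD-surrogate operating point.

    The surrogate draws malignancy scores from a binormal model calibrated so
    the expected AUC against the malignancy label equals ``target_auc``: benign
    scores are standard normal, malignant scores are shifted by
    ``sqrt(2) * Phi^-1(AUC)``, and scores map to probabilities through the
    normal CDF.  Per-pathology miss rates default to clinically observed miss
    fractions for DCIS (4/61) and IDC (18/103); benign lesions are never
    missed (only the malignant miss rule is clinically documented).
    """

    target_auc: float = 0.69
    miss_probability: dict = field(
        default_factory=lambda: {
            "BN": 0.0,
            "FA": 0.0,
            "DCIS": 4 / 61,
            "IDC": 18 / 103,
        }
    )
    false_rate_per_image: float = 1.2
    jitter_px: int = 2
    calc_cluster_probability: dict = field(
        default_factory=lambda: {"BN": 0.1, "FA": 0.1, "DCIS": 0.5, "IDC": 0.15}
    )

    def __post_init__(self) -> None:
        if not 0.5 < self.target_auc < 1.0:
            raise ConfigurationError("target AUC must lie strictly in (0.5, 1)")


def binormal_scores(labels, target_auc: float, rng) -> np.ndarray:
    """Binormal malignancy probabilities with expected AUC = target_auc."""
    if not 0.5 < target_auc < 1.0:
        raise ConfigurationError("target AUC must lie strictly in (0.5, 1)")
    labels = np.asarray(labels)
    sep = math.sqrt(2.0) * float(ndtri(target_auc))
    z = rng.standard_normal(labels.shape) + sep * labels
    return ndtr(z)


def _jitter_mask(rng, mask, jitter_px, limit_mask):
    if jitter_px <= 0:
        return mask.copy()
    shift = rng.integers(-jitter_px, jitter_px + 1, size=2)
    out = np.roll(np.roll(mask, shift[0], axis=0), shift[1], axis=1)
    grow = int(rng.integers(-jitter_px, jitter_px + 1))
    if grow > 0:
        out = ndimage.binary_dilation(out, iterations=grow)
    elif grow < 0:
        eroded = ndimage.binary_erosion(out, iterations=-grow)
        if eroded.any():
            out = eroded
    out &= limit_mask
    return out if out.any() else (mask & limit_mask)


def _calc_cluster_mask(rng, lesion_mask, breast_mask):
    """Simulated calcification-cluster ROI: hull of dots within the lesion."""
    from .features import calcification_cluster_hull

    idx = np.argwhere(lesion_mask)
    n_dots = int(rng.integers(3, 7))
    picks = idx[rng.integers(0, len(idx), size=min(n_dots, len(idx)))]
    dots = np.zeros(lesion_mask.shape, dtype=bool)
    dots[picks[:, 0], picks[:, 1]] = True
    hull = calcification_cluster_hull([dots]) & breast_mask
    return hull if hull.any() else (lesion_mask & breast_mask)


def simulate_cad(phantom: Phantom, cad_config: CadConfig, seed: int) -> list:
    """Surrogate CAD: jittered proposals on detected lesions plus false hits."""
    cfg = cad_config
    rng = np.random.default_rng(seed)
    sep = math.sqrt(2.0) * float(ndtri(cfg.target_auc))
    proposals: list[CadProposal] = []
    occupied = np.zeros(phantom.breast_mask.shape, dtype=bool)
    for lesion in phantom.lesions:
        occupied |= lesion.mask

    for idx, lesion in enumerate(phantom.lesions):
        if rng.random() < cfg.miss_probability.get(lesion.pathology, 0.0):
            continue
        kind = (
            "calcification-cluster"
            if rng.random() < cfg.calc_cluster_probability.get(lesion.pathology, 0.1)
            else "mass"
        )
        if kind == "calcification-cluster" and cfg.jitter_px > 0:
            # cluster ROI = convex hull of individual calcification dots
            # (jitter 0 is the identity configuration: masks pass through)
            pmask = _calc_cluster_mask(rng, lesion.mask, phantom.breast_mask)
        else:
            pmask = _jitter_mask(rng, lesion.mask, cfg.jitter_px, phantom.breast_mask)
        z = rng.normal(sep * lesion.label, 1.0)
        proposals.append(
            CadProposal(
                mask=pmask,
                kind=kind,
                probability=float(ndtr(z)),
                matched_lesion=idx,
            )
        )

    n_false = int(rng.poisson(cfg.false_rate_per_image))
    rho = _breast_geometry(phantom.breast_mask.shape)[1]
    for _ in range(n_false):
        for _try in range(100):
            cy = int(rng.integers(0, phantom.breast_mask.shape[0]))
            cx = int(rng.integers(0, phantom.breast_mask.shape[1]))
            if rho[cy, cx] > 0.75 or occupied[cy, cx]:
                continue
            r_px = rng.uniform(1.0, 2.5) / phantom.pixel_spacing
            blob = _lesion_blob(rng, phantom.breast_mask.shape, (cy, cx), r_px, 0.3)
            blob &= phantom.breast_mask & ~occupied
            if not blob.any():
                continue
            z = rng.normal(0.0, 1.0)
            proposals.append(
                CadProposal(
                    mask=blob,
                    kind="mass",
                    probability=float(ndtr(z)),
                    matched_lesion=None,
                )
            )
            break
    return proposals
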