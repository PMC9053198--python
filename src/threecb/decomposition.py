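"""Dual-energy attenuation calibration and per-pixel lipid/water/protein solving.

A dual-energy mammographic acquisition measures two line attenuations per pixel
(low energy ``A_LE`` and high energy ``A_HE``, each the negative log of the
transmitted fraction) plus the local compressed-breast thickness ``T`` (cm).
Under a monoenergetic approximation with one effective linear attenuation
coefficient per material and beam, the three unknown component thicknesses
``(t_l, t_w, t_p)`` satisfy the linear system

    [ mu_l,LE  mu_w,LE  mu_p,LE ] [t_l]   [A_LE]
    [ mu_l,HE  mu_w,HE  mu_p,HE ] [t_w] = [A_HE]
    [    1        1        1    ] [t_p]   [ T  ]

The coefficients are spatially constant, so one 3x3 inverse is precomputed and
applied to every pixel.  The third row makes lipid+water+protein equal the
thickness map exactly on solved pixels, regardless of noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CalibrationError,
    DegenerateModelError,
    IllConditionedError,
    InputError,
)

MATERIALS = ("lipid", "water", "protein")
ENERGIES = ("LE", "HE")

#: Effective monoenergetic linear attenuation coefficients (cm^-1), rows LE/HE,
#: columns lipid/water/protein.  Assembled from standard attenuation tables at
#: effective energies of ~19 keV (clinical mammographic beam) and ~31 keV
#: (39 kVp with 3 mm added Al filtration); protein assumes density 1.35 g/cm^3.
DEFAULT_COEFFICIENTS = np.array(
    [
        [0.511, 0.795, 1.070],
        [0.266, 0.367, 0.456],
    ]
)


@dataclass(frozen=True)
class AttenuationModel:
    """Two-energy, three-material attenuation coefficient matrix.

    Parameters
    ----------
    coefficients
        (2, 3) array of linear attenuation coefficients (cm^-1); rows are
        (LE, HE), columns (lipid, water, protein).
    residual_rms
        Per-energy root-mean-square calibration residual (dimensionless
        attenuation units); zero for models written down directly.
    negative_coefficient_warning
        Set when a calibration fit produced a negative coefficient.
    """

    coefficients: np.ndarray
    residual_rms: tuple[float, float] = (0.0, 0.0)
    negative_coefficient_warning: bool = False

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (2, 3):
            raise InputError(f"coefficients must have shape (2, 3), got {coef.shape}")
        object.__setattr__(self, "coefficients", coef)

    def system_matrix(self) -> np.ndarray:
        """The full 3x3 system: two coefficient rows plus the all-ones row."""
        return np.vstack([self.coefficients, np.ones(3)])

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.system_matrix()))

    def energy_rows_proportional(self, rtol: float = 1e-10) -> bool:
        """True when the LE and HE rows are scalar multiples of each other."""
        le, he = self.coefficients
        cross = np.linalg.norm(np.cross(le, he))
        return cross <= rtol * np.linalg.norm(le) * np.linalg.norm(he)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "materials": list(MATERIALS),
                "energies": list(ENERGIES),
                "residual_rms": list(self.residual_rms),
                "negative_coefficient_warning": self.negative_coefficient_warning,
                "condition_number": self.condition_number,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "AttenuationModel":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            residual_rms=tuple(d.get("residual_rms", (0.0, 0.0))),
            negative_coefficient_warning=bool(
                d.get("negative_coefficient_warning", False)
            ),
        )


def default_attenuation_model() -> AttenuationModel:
    return AttenuationModel(DEFAULT_COEFFICIENTS.copy())


@dataclass(frozen=True)
class CalibrationSet:
    """Calibration-phantom measurements: known LWP steps with their attenuations.

    ``entries`` is an (n, 5) array of rows ``(t_l, t_w, t_p, A_LE, A_HE)`` with
    thicknesses in cm and attenuations dimensionless.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if arr.shape[1] != 5:
            raise InputError("calibration entries must be (t_l, t_w, t_p, A_LE, A_HE)")
        object.__setattr__(self, "entries", arr)

    @property
    def thicknesses(self) -> np.ndarray:
        return self.entries[:, :3]

    @property
    def attenuations(self) -> np.ndarray:
        return self.entries[:, 3:5]

    def design_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.thicknesses))


def fit_attenuation_model(cal: CalibrationSet) -> AttenuationModel:
    """Per-energy ordinary least squares of attenuation on thickness triples.

    No intercept is fitted: zero material implies zero attenuation.  A
    rank-deficient thickness design raises :class:`CalibrationError`; a
    negative fitted coefficient only flags a warning on the returned model.
    """
    if len(cal.entries) < 3:
        raise CalibrationError("need at least 3 calibration entries")
    if cal.design_rank() < 3:
        raise CalibrationError("calibration thickness design is rank deficient")
    X = cal.thicknesses
    coef = np.empty((2, 3))
    resid = []
    for j in range(2):
        y = cal.attenuations[:, j]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coef[j] = beta
        resid.append(float(np.sqrt(np.mean((y - X @ beta) ** 2))))
    return AttenuationModel(
        coefficients=coef,
        residual_rms=(resid[0], resid[1]),
        negative_coefficient_warning=bool((coef < 0).any()),
    )


@dataclass
class LWPMaps:
    """Solved lipid/water/protein thickness maps (cm).

    ``valid_mask`` marks pixels where the solve was performed;
    ``negativity_fraction`` is the fraction of solved pixels with at least one
    negative component (the unconstrained linear solve permits them under
    noise).
    """

    lipid: np.ndarray
    water: np.ndarray
    protein: np.ndarray
    valid_mask: np.ndarray
    negativity_fraction: float

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def total(self) -> np.ndarray:
        return self.lipid + self.water + self.protein


def solve_lwp(
    acq,
    model: AttenuationModel,
    breast_mask: np.ndarray,
    clip_negative: bool = False,
    condition_ceiling: float = 1e8,
) -> LWPMaps:
    """Solve the per-pixel three-equation system inside ``breast_mask``.

    One 3x3 inverse is applied to the stacked right-hand side
    ``(A_LE, A_HE, T)`` of every masked pixel.  With ``clip_negative`` off
    (default) raw solutions are kept and the negativity fraction reported;
    with it on, negative components are zeroed and the remaining components
    rescaled so that their sum still equals the thickness map.
    """
    mask = np.asarray(breast_mask, dtype=bool)
    a_le = np.asarray(acq.attenuation_le, dtype=float)
    a_he = np.asarray(acq.attenuation_he, dtype=float)
    thick = np.asarray(acq.thickness_map, dtype=float)
    if not (a_le.shape == a_he.shape == thick.shape == mask.shape):
        raise InputError("attenuation, thickness and mask grids must share one shape")
    if model.condition_number > condition_ceiling:
        raise IllConditionedError(
            f"system condition number {model.condition_number:.3g} exceeds "
            f"ceiling {condition_ceiling:.3g}"
        )
    minv = np.linalg.inv(model.system_matrix())
    rhs = np.stack([a_le[mask], a_he[mask], thick[mask]])  # (3, n)
    sol = minv @ rhs  # (3, n)

    n = sol.shape[1]
    neg_frac = float((sol < 0).any(axis=0).sum() / n) if n else 0.0

    if clip_negative and n:
        clipped = np.clip(sol, 0.0, None)
        sums = clipped.sum(axis=0)
        target = thick[mask]
        scale = np.where(sums > 0, target / np.where(sums > 0, sums, 1.0), 0.0)
        clipped *= scale
        # all-components-clipped pixels (rare): split the thickness evenly
        dead = sums == 0
        clipped[:, dead] = target[dead] / 3.0
        sol = clipped

    out = []
    for i in range(3):
        grid = np.zeros_like(thick)
        grid[mask] = sol[i]
        out.append(grid)
    return LWPMaps(
        lipid=out[0],
        water=out[1],
        protein=out[2],
        valid_mask=mask,
        negativity_fraction=neg_frac,
    )
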