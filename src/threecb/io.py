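"""File conventions: float32 TIFF maps, 8-bit TIFF masks, JSON ROIs, CSV tables.

A simulated patient directory holds::

    lipid.tif water.tif protein.tif thickness.tif   float32 thickness maps (cm)
    le.tif he.tif                                   float32 attenuation maps
    breast_mask.tif                                 uint8 mask
    lesion_###_mask.tif / proposal_###_mask.tif     uint8 ROI masks
    rois.json                                       lesion + proposal metadata

and a cohort directory a ``manifest.csv`` with one row per patient/view.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .decomposition import LWPMaps
from .phantom_sim import (
    CadProposal,
    DualEnergyAcquisition,
    EffectProfile,
    LesionRecord,
    Phantom,
)


def _write_map(path: Path, arr: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def _write_mask(path: Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool)).astype(np.uint8) * 255)


def read_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def save_patient(
    out_dir,
    phantom: Phantom,
    acquisition: DualEnergyAcquisition | None = None,
    proposals: list | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_map(out / "lipid.tif", phantom.lipid_map)
    _write_map(out / "water.tif", phantom.water_map)
    _write_map(out / "protein.tif", phantom.protein_map)
    _write_map(out / "thickness.tif", phantom.thickness_map)
    _write_mask(out / "breast_mask.tif", phantom.breast_mask)
    meta = {
        "patient_id": phantom.patient_id,
        "view": phantom.view,
        "pixel_spacing_mm": phantom.pixel_spacing,
        "lesions": [],
        "proposals": [],
    }
    for i, lesion in enumerate(phantom.lesions):
        name = f"lesion_{i:03d}_mask.tif"
        _write_mask(out / name, lesion.mask)
        meta["lesions"].append(
            {
                "mask_file": name,
                "pathology": lesion.pathology,
                "receptor_status": lesion.receptor_status,
                "radius_mm": lesion.radius_mm,
                "effect_profile": lesion.effect_profile.offsets,
            }
        )
    if acquisition is not None:
        _write_map(out / "le.tif", acquisition.attenuation_le)
        _write_map(out / "he.tif", acquisition.attenuation_he)
        meta["noise_sigma"] = acquisition.noise_sigma
    for i, prop in enumerate(proposals or []):
        name = f"proposal_{i:03d}_mask.tif"
        _write_mask(out / name, prop.mask)
        meta["proposals"].append(
            {
                "mask_file": name,
                "kind": prop.kind,
                "probability": prop.probability,
                "matched_lesion": prop.matched_lesion,
            }
        )
    (out / "rois.json").write_text(json.dumps(meta, indent=2))
    return out


def load_patient(patient_dir) -> tuple[Phantom, DualEnergyAcquisition | None, list]:
    d = Path(patient_dir)
    meta = json.loads((d / "rois.json").read_text())
    mask = read_mask(d / "breast_mask.tif")
    lesions = []
    for rec in meta["lesions"]:
        lesions.append(
            LesionRecord(
                mask=read_mask(d / rec["mask_file"]),
                pathology=rec["pathology"],
                receptor_status=rec["receptor_status"],
                effect_profile=EffectProfile(
                    {k: tuple(v) for k, v in rec["effect_profile"].items()}
                ),
                center_px=(0, 0),
                radius_mm=rec["radius_mm"],
            )
        )
    phantom = Phantom(
        lipid_map=read_map(d / "lipid.tif"),
        water_map=read_map(d / "water.tif"),
        protein_map=read_map(d / "protein.tif"),
        breast_mask=mask,
        pixel_spacing=meta["pixel_spacing_mm"],
        lesions=lesions,
        patient_id=meta["patient_id"],
        view=meta["view"],
    )
    acq = None
    if (d / "le.tif").exists():
        acq = DualEnergyAcquisition(
            attenuation_le=read_map(d / "le.tif"),
            attenuation_he=read_map(d / "he.tif"),
            thickness_map=read_map(d / "thickness.tif"),
            pixel_spacing=meta["pixel_spacing_mm"],
            noise_sigma=meta.get("noise_sigma", 0.0),
        )
    proposals = [
        CadProposal(
            mask=read_mask(d / rec["mask_file"]),
            kind=rec["kind"],
            probability=rec["probability"],
            matched_lesion=rec["matched_lesion"],
        )
        for rec in meta["proposals"]
    ]
    return phantom, acq, proposals


def save_lwp(out_dir, lwp: LWPMaps) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_map(out / "lwp_lipid.tif", lwp.lipid)
    _write_map(out / "lwp_water.tif", lwp.water)
    _write_map(out / "lwp_protein.tif", lwp.protein)
    _write_mask(out / "lwp_valid_mask.tif", lwp.valid_mask)
    (out / "lwp_meta.json").write_text(
        json.dumps({"negativity_fraction": lwp.negativity_fraction})
    )
    return out


def write_manifest(path, rows: list) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
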