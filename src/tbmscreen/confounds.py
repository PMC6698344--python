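"""Normal-aging confound: voxel-wise age regression on control maps.

Brain volume change happens in healthy aging too, so the annual change
rate at each voxel is regressed on age (the mean age of the scan pair)
using *control* maps only, and the age-dependent part can then be removed
from any map.  The model is ordinary least squares per voxel on centered
age; the stored intercept is the expected map at the mean control age.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .morphometry import JacobianMap

__all__ = ["AgeModel", "fit_age_model", "residualize"]


@dataclass(frozen=True)
class AgeModel:
    """Voxel-wise linear model: value ≈ intercept + slope·(age − age_centering)."""

    intercept: np.ndarray      # annualized-change units, at the mean control age
    slope: np.ndarray          # annualized-change per year of age
    n_fit: int
    age_centering: float       # mean age of the fitting (control) maps, years

    def __post_init__(self) -> None:
        if self.intercept.shape != self.slope.shape:
            raise ValueError("intercept and slope shapes differ")
        if self.n_fit < 3:
            raise ValueError("age model needs >= 3 fitted maps")

    @property
    def shape(self):
        return self.slope.shape


def fit_age_model(control_maps: Sequence[JacobianMap], ages: Sequence[float]) -> AgeModel:
    """Fit the voxel-wise OLS of annualized change on age, controls only."""
    if len(control_maps) < 3:
        raise ValueError(f"need >= 3 control maps, got {len(control_maps)}")
    if len(ages) != len(control_maps):
        raise ValueError("one age per map required")
    shapes = {m.shape for m in control_maps}
    if len(shapes) != 1:
        raise ValueError(f"maps on different grids: {shapes}")
    if not all(m.is_annualized for m in control_maps):
        raise ValueError("age model is fitted on annualized maps")
    ages = np.asarray(ages, dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("constant ages: age slope is unidentifiable")
    Y = np.stack([m.values for m in control_maps])        # (n, nx, ny, nz)
    mean_age = ages.mean()
    a = ages - mean_age
    denom = np.sum(a**2)
    slope = np.tensordot(a, Y - Y.mean(axis=0), axes=(0, 0)) / denom
    intercept = Y.mean(axis=0)
    return AgeModel(
        intercept=intercept, slope=slope, n_fit=len(control_maps), age_centering=float(mean_age)
    )


def residualize(
    jmap: JacobianMap, age: float, model: AgeModel, keep_mean: bool = True
) -> JacobianMap:
    """Remove the age-dependent component from one map.

    With ``keep_mean`` (default) only slope·(age − age_centering) is
    subtracted, leaving the map on its natural scale; with
    ``keep_mean=False`` the intercept is removed as well, producing a
    residual relative to the control expectation.
    """
    if jmap.shape != model.shape:
        raise ValueError(f"grid mismatch: map {jmap.shape}, model {model.shape}")
    vals = jmap.values - model.slope * (age - model.age_centering)
    if not keep_mean:
        vals = vals - model.intercept
    return replace(jmap, values=vals)


def save_age_model(model: AgeModel, path_prefix: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Persist as a 2-volume NIfTI (slope, intercept) + JSON sidecar."""
    import nibabel as nib

    prefix = Path(path_prefix)
    stacked = np.stack([model.slope, model.intercept], axis=-1).astype(np.float32)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(stacked, affine), prefix.with_suffix(".nii.gz"))
    prefix.with_suffix(".json").write_text(
        json.dumps({"n_fit": model.n_fit, "age_centering": model.age_centering})
    )


def load_age_model(path_prefix: str | Path) -> AgeModel:
    import nibabel as nib

    prefix = Path(path_prefix)
    stacked = np.asarray(nib.load(prefix.with_suffix(".nii.gz")).dataobj, dtype=float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return AgeModel(
        intercept=stacked[..., 1],
        slope=stacked[..., 0],
        n_fit=int(meta["n_fit"]),
        age_centering=float(meta["age_centering"]),
    )
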