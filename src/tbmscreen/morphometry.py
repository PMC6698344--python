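"""Jacobian-determinant morphometry on displacement fields.

The deformation that registers a follow-up scan to its reference is a
displacement field u(x) (mm).  The local volume ratio of that mapping is
the Jacobian determinant J(x) = det(I + ∂u/∂x): J > 1 is expansion,
J < 1 contraction.  Pooling maps across pairs with different intervals dt
requires a rate scale, so the default annualization is log J / dt — the
annual log-volume-change rate.  ROI summaries average the map over atlas
regions restricted to a gray-matter mask.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "DeformationField",
    "JacobianMap",
    "FWHM_TO_SIGMA",
    "jacobian_determinant",
    "annualize",
    "smooth_map",
    "roi_means",
    "save_map_nifti",
    "load_map_nifti",
]

#: Gaussian FWHM-to-sigma conversion: sigma = fwhm / sqrt(8 ln 2).
FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass(frozen=True)
class DeformationField:
    """Displacement lattice u(x) with one 3-vector (mm) per voxel.

    ``displacement`` has shape (nx, ny, nz, 3); component c is the
    displacement along axis c.  ``boundary`` selects the finite-difference
    convention at the lattice edges: ``replicate`` (one-sided differences)
    or ``periodic`` (wrap-around central differences, used for simulated
    fields built on a periodic domain).
    """

    displacement: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    boundary: str = "replicate"

    def __post_init__(self) -> None:
        u = np.asarray(self.displacement, dtype=float)
        if u.ndim != 4 or u.shape[-1] != 3:
            raise ValueError(f"displacement must have shape (nx, ny, nz, 3), got {u.shape}")
        if not np.all(np.isfinite(u)):
            raise ValueError("displacement contains non-finite values")
        if self.boundary not in ("replicate", "periodic"):
            raise ValueError(f"unknown boundary convention: {self.boundary!r}")
        object.__setattr__(self, "displacement", u)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]


@dataclass
class JacobianMap:
    """A scalar volumetric-change map.

    ``scale`` records what the values mean:

    - ``raw_det``: determinant J itself (1 = no change);
    - ``log_det``: log J over the full interval;
    - ``annualized_log_det``: log J / dt, the annual log-volume rate;
    - ``annualized_raw``: J / dt (literal division of the determinant,
      kept for strict-reproduction comparisons; note it maps "no change"
      to 1/dt).
    """

    values: np.ndarray
    scale: str = "raw_det"
    dt: Optional[float] = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: number of voxels with J <= 0 found when the map was computed
    n_folded: int = 0

    _SCALES = ("raw_det", "log_det", "annualized_log_det", "annualized_raw")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"values must be a 3-D lattice, got shape {v.shape}")
        if self.scale not in self._SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale.startswith("annualized"):
            if self.dt is None or not self.dt > 0:
                raise ValueError("annualized maps must carry dt > 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("map contains non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_annualized(self) -> bool:
        return self.scale.startswith("annualized")


def _gradient_axis(a: np.ndarray, axis: int, spacing: float, periodic: bool) -> np.ndarray:
    if periodic:
        return (np.roll(a, -1, axis=axis) - np.roll(a, 1, axis=axis)) / (2.0 * spacing)
    return np.gradient(a, spacing, axis=axis)


def jacobian_determinant(fld: DeformationField) -> JacobianMap:
    """Voxel-wise determinant of the deformation gradient I + ∂u/∂x.

    Displacement gradients are estimated by central differences in mm
    (one-sided at the edges under the ``replicate`` convention, wrapped
    under ``periodic``).  Non-positive determinants indicate folding of
    the deformation; they are counted in ``n_folded`` on the returned map
    rather than clipped.
    """
    if min(fld.shape) < 3:
        raise ValueError(f"lattice too small for finite differences: {fld.shape}")
    u = fld.displacement
    periodic = fld.boundary == "periodic"
    # G[i, j] = d u_i / d x_j + identity
    G = np.empty(fld.shape + (3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            G[..., i, j] = _gradient_axis(u[..., i], j, fld.voxel_size[j], periodic)
        G[..., i, i] += 1.0
    det = np.linalg.det(G)
    n_folded = int(np.count_nonzero(det <= 0))
    if n_folded:
        warnings.warn(
            f"deformation folds at {n_folded} voxel(s) (J <= 0)", RuntimeWarning
        )
    return JacobianMap(det, scale="raw_det", voxel_size=fld.voxel_size, n_folded=n_folded)


def annualize(jmap: JacobianMap, dt: float, mode: str = "log_then_divide") -> JacobianMap:
    """Convert a change map over interval ``dt`` into an annual rate.

    ``log_then_divide`` (default) returns log J / dt, the annual
    log-volume-change rate, which puts pairs of differing dt on one
    comparable scale.  ``literal_divide`` returns J / dt.  Maps already on
    a log scale are simply divided by dt in the default mode.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if jmap.is_annualized:
        raise ValueError("map is already annualized")
    if mode == "log_then_divide":
        if jmap.scale == "raw_det":
            if np.any(jmap.values <= 0):
                n = int(np.count_nonzero(jmap.values <= 0))
                raise ValueError(
                    f"cannot take log of non-positive determinants at {n} voxel(s); "
                    "the deformation folds there"
                )
            vals = np.log(jmap.values) / dt
        else:  # log_det
            vals = jmap.values / dt
        scale = "annualized_log_det"
    elif mode == "literal_divide":
        if jmap.scale != "raw_det":
            raise ValueError("literal_divide applies to raw determinant maps")
        vals = jmap.values / dt
        scale = "annualized_raw"
    else:
        raise ValueError(f"unknown annualization mode: {mode!r}")
    return replace(jmap, values=vals, scale=scale, dt=dt)


def smooth_map(jmap: JacobianMap, fwhm_mm: float) -> JacobianMap:
    """Gaussian smoothing with the given FWHM in mm (0 = identity)."""
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return replace(jmap, values=jmap.values.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in jmap.voxel_size]
    vals = ndimage.gaussian_filter(jmap.values, sigma=sigma_vox, mode="nearest")
    return replace(jmap, values=vals)


def smooth_volume(values: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Gaussian-smooth a bare 3-D array (helper shared with the simulator)."""
    if fwhm_mm == 0:
        return np.asarray(values, dtype=float).copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in voxel_size]
    return ndimage.gaussian_filter(np.asarray(values, dtype=float), sigma=sigma_vox, mode="nearest")


def roi_means(jmap: JacobianMap, atlas) -> dict[str, float]:
    """Mean map value per atlas region, restricted to the gray-matter mask.

    Returns a mapping region name -> mean; regions whose intersection with
    the GM mask is empty map to NaN (flagged missing).
    """
    labels = np.asarray(atlas.labels)
    gm = np.asarray(atlas.gm_mask, dtype=bool)
    if labels.shape != jmap.shape or gm.shape != jmap.shape:
        raise ValueError(
            f"shape mismatch: map {jmap.shape}, atlas {labels.shape}, gm {gm.shape}"
        )
    out: dict[str, float] = {}
    for label, name in atlas.region_names.items():
        sel = (labels == label) & gm
        out[name] = float(jmap.values[sel].mean()) if sel.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O with a JSON sidecar carrying scale and dt (the NIfTI header's
# free-text fields are not relied upon).

def save_map_nifti(jmap: JacobianMap, path: str | Path) -> None:
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(jmap.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(jmap.values.astype(np.float32), affine), path)
    sidecar = {
        "scale": jmap.scale,
        "dt": jmap.dt,
        "voxel_size": list(jmap.voxel_size),
        "n_folded": jmap.n_folded,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_map_nifti(path: str | Path) -> JacobianMap:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    vox = tuple(meta.get("voxel_size") or img.header.get_zooms()[:3])
    return JacobianMap(
        values=np.asarray(img.dataobj, dtype=float),
        scale=meta.get("scale", "raw_det"),
        dt=meta.get("dt"),
        voxel_size=tuple(float(v) for v in vox),
        n_folded=int(meta.get("n_folded", 0)),
    )
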