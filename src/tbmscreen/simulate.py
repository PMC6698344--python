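"""Synthetic longitudinal cohort generator.

Generates a fully synthetic stand-in for a longitudinal amyloid study:
subject metadata (ages, visit schedules, CSF amyloid-beta on the correct
side of the positivity cutoff per group), a toy atlas with the regions the
analysis cares about, and per-visit-pair volumetric-change maps (or
displacement fields) with a known ground truth.

The generative model for the raw (full-interval) log-Jacobian of a pair
with interval dt and mean age a is, per voxel,

    dt * ( rate[group, region] + aging_slope[region] * (a - age_center) )
    + noise,    noise ~ N(0, scan_noise_sd) i.i.d. per voxel,

followed by Gaussian smoothing.  Two structural choices matter downstream:

- the additive noise is applied to the *raw* map, independent of dt, so
  after annualization (divide by dt) longer intervals carry less noise —
  which is why discrimination improves when only long-interval pairs are
  evaluated;
- smoothing makes strong ventricular expansion bleed ("spill over") into
  the adjacent caudate head, an artifact the statistical maps should
  reproduce when smoothing is on and lose when it is off.

Default effect rates are calibration choices of this package (they place
the end-to-end classifier in a realistic performance regime); they are not
measured values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .cohort import (
    CohortTable,
    Group,
    SubjectRecord,
    Visit,
    VisitPair,
    enumerate_visit_pairs,
    write_cohort_csv,
)
from .morphometry import DeformationField, JacobianMap, smooth_volume

__all__ = [
    "ToyAtlas",
    "EffectModel",
    "GroundTruth",
    "SimulatedDataset",
    "default_atlas",
    "simulate_cohort",
    "synthesize_pair_change",
    "synthesize_displacement_field",
]

REGION_NAMES = (
    "ventricles",
    "caudate_head",
    "parahippocampal_fusiform",
    "middle_temporal",
    "posterior_cingulate_precuneus",
    "basal_ganglia",
    "other_gm",
)


@dataclass(frozen=True)
class ToyAtlas:
    """Toy label volume + gray-matter mask on a small regular grid."""

    labels: np.ndarray                    # int, 0 = background
    region_names: dict[int, str]          # label -> name
    gm_mask: np.ndarray                   # bool, same shape
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        gm = np.asarray(self.gm_mask, dtype=bool)
        if labels.shape != gm.shape:
            raise ValueError("gm_mask shape must equal labels shape")
        if labels.min() < 0:
            raise ValueError("labels must be >= 0")
        for label, name in self.region_names.items():
            if not (labels == label).any():
                raise ValueError(f"region {name!r} (label {label}) is empty")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gm_mask", gm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def label_of(self, name: str) -> int:
        for label, n in self.region_names.items():
            if n == name:
                return label
        raise KeyError(name)

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)


def default_atlas(
    shape: tuple[int, int, int] = (32, 38, 32),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> ToyAtlas:
    """Build the default toy atlas.

    A brain-shaped ellipsoid holds seven regions: central CSF-filled
    ventricles, caudate heads hugging the ventricular walls, inferior
    medial temporal cortex (parahippocampal/fusiform), lateral middle
    temporal cortex, posterior cingulate/precuneus, basal ganglia, and the
    remaining gray matter.  Axes follow the usual (x = left-right,
    y = posterior-anterior, z = inferior-superior) convention.
    """
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    brain = ((x - cx) / (0.44 * nx)) ** 2 + ((y - cy) / (0.46 * ny)) ** 2 + (
        (z - cz) / (0.44 * nz)
    ) ** 2 <= 1.0

    ax = np.abs(x - cx)
    labels = np.zeros(shape, dtype=np.int16)

    ventricles = (ax >= 2) & (ax <= 4) & (np.abs(y - cy) <= 6) & (z >= cz - 2) & (z <= cz + 3)
    caudate = (ax >= 4) & (ax <= 6) & (y >= cy - 1) & (y <= cy + 5) & (z >= cz - 1) & (z <= cz + 3)
    parahipp = (ax >= 4) & (ax <= 9) & (np.abs(y - cy) <= 4) & (z >= cz - 9) & (z <= cz - 5)
    mid_temp = (ax >= 10) & (ax <= 12) & (np.abs(y - cy) <= 5) & (z >= cz - 5) & (z <= cz + 1)
    pcc = (ax <= 3) & (y <= cy - 7) & (y >= cy - 11) & (z >= cz + 1) & (z <= cz + 6)
    basal = (ax >= 7) & (ax <= 9) & (np.abs(y - cy) <= 4) & (z >= cz - 2) & (z <= cz + 2)

    # later assignments never overwrite earlier ones
    for lab, mask in enumerate(
        (ventricles, caudate, parahipp, mid_temp, pcc, basal), start=1
    ):
        labels[brain & mask & (labels == 0)] = lab
    labels[brain & (labels == 0)] = 7  # other_gm

    region_names = dict(enumerate(REGION_NAMES, start=1))
    gm_mask = (labels > 1)  # everything but background and ventricles
    return ToyAtlas(labels=labels, region_names=region_names, gm_mask=gm_mask, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# Effect model

#: Default group-specific annual log-volume-change rates (per year).
#: Calibration choices of this package, not measured values: the
#: preclinical pattern is mild medial-temporal atrophy plus ventricular
#: expansion; the symptomatic pattern is stronger and anatomically broader.
DEFAULT_RATES: dict[tuple[str, str], float] = {
    ("PreAD", "parahippocampal_fusiform"): -0.010,
    ("PreAD", "middle_temporal"): -0.004,
    ("PreAD", "ventricles"): 0.020,
    ("MCI_AD", "parahippocampal_fusiform"): -0.025,
    ("MCI_AD", "middle_temporal"): -0.015,
    ("MCI_AD", "posterior_cingulate_precuneus"): -0.015,
    ("MCI_AD", "basal_ganglia"): -0.010,
    ("MCI_AD", "ventricles"): 0.045,
}

#: Default normal-aging slopes: change of the annual log-volume rate per
#: year of age (applies to every group).
DEFAULT_AGING_SLOPES: dict[str, float] = {
    "ventricles": 4.0e-4,
    "caudate_head": -1.5e-4,
    "parahippocampal_fusiform": -1.5e-4,
    "middle_temporal": -1.5e-4,
    "posterior_cingulate_precuneus": -1.5e-4,
    "basal_ganglia": -1.5e-4,
    "other_gm": -1.5e-4,
}


@dataclass
class EffectModel:
    """Parameters of the synthetic generative model.

    ``scan_noise_sd`` is the per-voxel s.d. of the additive noise on the
    raw (non-annualized) log-Jacobian; it does not scale with dt.
    ``dt_distribution`` is a dict spec: ``{"family": "lognormal",
    "median": 2.0, "sigma": 0.45, "min": 0.5}``, ``{"family": "point",
    "value": v}`` or ``{"family": "uniform", "low": a, "high": b}``.
    """

    annual_log_volume_change: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    aging_slope: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGING_SLOPES))
    age_center: float = 74.0
    scan_noise_sd: float = 0.30
    #: "raw" (default): noise s.d. is per scan pair, independent of dt, so
    #: annualized maps from longer intervals are cleaner.  "annualized":
    #: the control condition where the noise scales with dt and the
    #: annualized SNR is flat in dt.
    noise_stage: str = "raw"
    smoothing_fwhm: float = 8.0
    dt_distribution: dict = field(
        default_factory=lambda: {"family": "lognormal", "median": 2.0, "sigma": 0.55, "min": 0.5}
    )
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"Ctrl": 30, "PreAD": 18, "MCI_AD": 12}
    )
    visits_per_subject: dict[int, float] = field(
        default_factory=lambda: {2: 0.35, 3: 0.4, 4: 0.25}
    )
    age_mean: float = 74.0
    age_sd: float = 6.0
    age_range: tuple[float, float] = (55.0, 90.0)
    csf_ctrl: tuple[float, float] = (230.0, 25.0)     # mean, sd; truncated > cutoff
    csf_positive: tuple[float, float] = (150.0, 25.0)  # mean, sd; truncated <= cutoff
    amyloid_cutoff: float = 192.0
    pair_mode: str = "consecutive"
    mode: str = "map"          # "map" or "field"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_noise_sd < 0:
            raise ValueError("scan_noise_sd must be >= 0")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")
        if self.mode not in ("map", "field"):
            raise ValueError(f"unknown simulator mode {self.mode!r}")
        if self.noise_stage not in ("raw", "annualized"):
            raise ValueError(f"unknown noise_stage {self.noise_stage!r}")
        if not all(np.isfinite(list(self.annual_log_volume_change.values()) or [0.0])):
            raise ValueError("rates must be finite")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("impossible age truncation bounds")

    def rate_volume(self, group: str, atlas: ToyAtlas) -> np.ndarray:
        """Per-voxel annual log-volume-change rate field for a group."""
        out = np.zeros(atlas.shape)
        for (g, region), rate in self.annual_log_volume_change.items():
            if g == str(getattr(group, "value", group)):
                out[atlas.region_mask(region)] = rate
        return out

    def aging_volume(self, atlas: ToyAtlas) -> np.ndarray:
        """Per-voxel aging coefficient field (rate change per year of age)."""
        out = np.zeros(atlas.shape)
        for region, slope in self.aging_slope.items():
            out[atlas.region_mask(region)] = slope
        return out


@dataclass
class GroundTruth:
    """What the simulator actually implanted, for recovery tests."""

    atlas: ToyAtlas
    rates: dict[tuple[str, str], float]
    aging_coeff: np.ndarray                    # per-voxel, rate per year of age
    #: smoothed noiseless annual log-Jacobian per pair, keyed by scan_ref
    noiseless_annual: dict[str, np.ndarray] = field(default_factory=dict)
    #: smoothed per-voxel rate field per group (the effect as it appears in
    #: the emitted maps, smoothing halo included)
    smoothed_rates: dict[str, np.ndarray] = field(default_factory=dict)

    def effect_mask(self, group: str, sign: Optional[int] = None) -> np.ndarray:
        """Voxels whose implanted rate differs from the control group.

        ``sign`` restricts to atrophy (-1, rate < 0) or expansion (+1).
        Masks are the pre-smoothing region supports.
        """
        out = np.zeros(self.atlas.shape, dtype=bool)
        for (g, region), rate in self.rates.items():
            if g != group or rate == 0:
                continue
            if sign is not None and np.sign(rate) != sign:
                continue
            out |= self.atlas.region_mask(region)
        return out

    def smoothed_effect_mask(self, group: str, rel_threshold: float = 0.05) -> np.ndarray:
        """Support of the implanted effect as expressed in the emitted maps.

        Smoothing redistributes the implanted rates beyond the nominal
        region boundaries (the same mechanism that produces the caudate
        spillover), so the effect present in the data occupies the
        smoothed support: voxels where the smoothed rate field exceeds
        ``rel_threshold`` times its maximum magnitude.
        """
        sm = self.smoothed_rates.get(group)
        if sm is None:
            raise KeyError(f"no smoothed rate field recorded for group {group!r}")
        peak = np.abs(sm).max()
        if peak == 0:
            return np.zeros(self.atlas.shape, dtype=bool)
        return np.abs(sm) > rel_threshold * peak


@dataclass
class SimulatedDataset:
    """Everything a downstream stage needs, in memory."""

    cohort: CohortTable
    atlas: ToyAtlas
    ground_truth: GroundTruth
    pairs: list[VisitPair]
    pair_groups: list[Group]
    #: raw (full-interval) log-Jacobian maps, aligned with ``pairs``
    maps: list[JacobianMap]
    #: displacement fields, present only in field mode
    fields: Optional[list[DeformationField]] = None
    effect_model: Optional[EffectModel] = None

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Sampling helpers

def _truncnorm_rvs(mean, sd, lo, hi, rng, size=None):
    if not lo < hi:
        raise ValueError(f"impossible truncation bounds ({lo}, {hi})")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    out = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    if not np.all(np.isfinite(out)):
        raise ValueError(
            f"impossible truncation bounds ({lo}, {hi}) for N({mean}, {sd}^2)"
        )
    return out


def _draw_dt(spec: dict, rng) -> float:
    family = spec.get("family", "lognormal")
    if family == "point":
        return float(spec["value"])
    if family == "uniform":
        return float(rng.uniform(spec["low"], spec["high"]))
    if family == "lognormal":
        lo = float(spec.get("min", 0.5))
        mu = float(np.log(spec.get("median", 2.0)))
        sigma = float(spec.get("sigma", 0.45))
        for _ in range(1000):
            v = float(np.exp(rng.normal(mu, sigma)))
            if v >= lo:
                return v
        raise RuntimeError("dt rejection sampling failed; check dt_distribution")
    raise ValueError(f"unknown dt family {family!r}")


def _draw_n_visits(dist: dict[int, float], rng) -> int:
    ks = sorted(dist)
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps /= ps.sum()
    return int(rng.choice(ks, p=ps))


# ---------------------------------------------------------------------------
# Map / field synthesis

def synthesize_pair_change(
    pair: VisitPair,
    group: Group | str,
    effect_model: EffectModel,
    atlas: ToyAtlas,
    rng: np.random.Generator,
    ground_truth: Optional[GroundTruth] = None,
) -> np.ndarray:
    """Raw (full-interval) log-Jacobian volume for one visit pair.

    Signal = dt * (group rate + aging slope * centered mean age) per voxel;
    noise is added once (s.d. ``scan_noise_sd``, independent of dt); the
    noisy map is then Gaussian-smoothed.  If ``ground_truth`` is given,
    the smoothed noiseless annualized signal is recorded under the pair's
    ``scan_ref``.
    """
    gname = str(getattr(group, "value", group))
    known = {g for g, _ in effect_model.annual_log_volume_change} | {"Ctrl", "PreAD", "MCI_AD"}
    if gname not in known:
        raise ValueError(f"unknown group {gname!r}")
    annual = effect_model.rate_volume(gname, atlas) + effect_model.aging_volume(atlas) * (
        pair.mean_age - effect_model.age_center
    )
    raw = pair.dt * annual
    if effect_model.scan_noise_sd > 0:
        sd = effect_model.scan_noise_sd
        if effect_model.noise_stage == "annualized":
            sd = sd * pair.dt  # constant annualized noise regardless of dt
        raw = raw + rng.normal(0.0, sd, size=atlas.shape)
    raw = smooth_volume(raw, effect_model.smoothing_fwhm, atlas.voxel_size)
    if ground_truth is not None:
        key = f"{pair.subject_id}_{pair.reference.visit_id}_{pair.followup.visit_id}"
        ground_truth.noiseless_annual[key] = smooth_volume(
            annual, effect_model.smoothing_fwhm, atlas.voxel_size
        )
    return raw


def synthesize_displacement_field(
    target_logj: np.ndarray,
    voxel_size: tuple[float, float, float],
    amplitude_scale: float = 1.0,
    mean_tol: float = 1e-9,
) -> DeformationField:
    """Displacement field whose divergence equals a target log-Jacobian.

    Solves the potential-flow problem ∇²φ = target on a periodic domain by
    FFT and returns u = ∇φ.  For small amplitudes log det(I + ∇u) ≈ div u,
    so the Jacobian map of the returned field matches the target to second
    order.  A constant nonzero divergence is incompatible with periodic
    boundaries; a nonzero target mean is removed with a warning.
    """
    import warnings

    t = np.asarray(target_logj, dtype=float) * amplitude_scale
    if not np.all(np.isfinite(t)):
        raise ValueError("target contains non-finite values")
    mean = t.mean()
    if abs(mean) > mean_tol:
        warnings.warn(
            f"target divergence has nonzero mean {mean:.3g}; removing it "
            "(incompatible with periodic boundaries)",
            RuntimeWarning,
        )
    t = t - mean
    shape = t.shape
    ks = [2.0 * np.pi * np.fft.fftfreq(n, d=vs) for n, vs in zip(shape, voxel_size)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx**2 + ky**2 + kz**2
    t_hat = np.fft.fftn(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = np.where(k2 > 0, -t_hat / k2, 0.0)
    u = np.empty(shape + (3,), dtype=float)
    for c, kc in enumerate((kx, ky, kz)):
        u[..., c] = np.real(np.fft.ifftn(1j * kc * phi_hat))
    return DeformationField(displacement=u, voxel_size=voxel_size, boundary="periodic")


# ---------------------------------------------------------------------------
# Cohort synthesis

def _map_rng(seed: int, index: int) -> np.random.Generator:
    # independent, reproducible per-map stream
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, index)))


def simulate_cohort(
    effect_model: EffectModel,
    atlas: Optional[ToyAtlas] = None,
    out_dir: Optional[str | Path] = None,
) -> SimulatedDataset:
    """Generate a full synthetic dataset (metadata + change maps/fields).

    Deterministic: the same ``effect_model.seed`` reproduces the dataset
    byte for byte.  With ``out_dir`` set, the cohort CSV, atlas, GM mask,
    per-pair NIfTI volumes and a manifest JSON (seed + SHA-256 checksums)
    are written to disk.
    """
    atlas = atlas or default_atlas()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=effect_model.seed, spawn_key=(0,)))

    subjects: list[SubjectRecord] = []
    start_date = _date(2010, 1, 1)
    for gname in ("Ctrl", "PreAD", "MCI_AD"):
        n = int(effect_model.n_per_group.get(gname, 0))
        for i in range(n):
            sid = f"{gname}{i:03d}"
            sex = "F" if rng.random() < 0.5 else "M"
            age0 = float(
                _truncnorm_rvs(
                    effect_model.age_mean,
                    effect_model.age_sd,
                    *effect_model.age_range,
                    rng,
                )
            )
            n_visits = _draw_n_visits(effect_model.visits_per_subject, rng)
            gaps = [_draw_dt(effect_model.dt_distribution, rng) for _ in range(n_visits - 1)]
            ages = np.concatenate([[age0], age0 + np.cumsum(gaps)])
            if gname == "Ctrl":
                mean, sd = effect_model.csf_ctrl
                lo, hi = effect_model.amyloid_cutoff + 1e-9, np.inf
            else:
                mean, sd = effect_model.csf_positive
                lo, hi = 1e-9, effect_model.amyloid_cutoff
            csf = _truncnorm_rvs(mean, sd, lo, hi, rng, size=n_visits)
            visits = []
            for k, (a, c) in enumerate(zip(ages, csf)):
                d = start_date + timedelta(days=int(round((a - age0) * 365.25)))
                visits.append(
                    Visit(
                        visit_id=f"v{k}",
                        age=float(a),
                        date=d,
                        csf_abeta=float(c),
                        scan_ref=f"{sid}_v{k}",
                    )
                )
            subjects.append(
                SubjectRecord(subject_id=sid, sex=sex, group=Group(gname), visits=tuple(visits))
            )

    cohort = CohortTable(
        subjects=subjects,
        provenance=f"tbmscreen synthetic cohort, seed={effect_model.seed}",
        amyloid_cutoff=effect_model.amyloid_cutoff,
    )

    ground_truth = GroundTruth(
        atlas=atlas,
        rates=dict(effect_model.annual_log_volume_change),
        aging_coeff=effect_model.aging_volume(atlas),
        smoothed_rates={
            g: smooth_volume(
                effect_model.rate_volume(g, atlas),
                effect_model.smoothing_fwhm,
                atlas.voxel_size,
            )
            for g in ("Ctrl", "PreAD", "MCI_AD")
        },
    )

    pairs: list[VisitPair] = []
    pair_groups: list[Group] = []
    for subj in cohort:
        for p in enumerate_visit_pairs(subj, mode=effect_model.pair_mode):
            pairs.append(p)
            pair_groups.append(subj.group)

    maps: list[JacobianMap] = []
    fields: Optional[list[DeformationField]] = [] if effect_model.mode == "field" else None
    for idx, (pair, group) in enumerate(zip(pairs, pair_groups)):
        map_rng = _map_rng(effect_model.seed, idx)
        raw = synthesize_pair_change(pair, group, effect_model, atlas, map_rng, ground_truth)
        if effect_model.mode == "field":
            fld = synthesize_displacement_field(raw, atlas.voxel_size)
            fields.append(fld)
            from .morphometry import jacobian_determinant

            det = jacobian_determinant(fld)
            logj = np.log(det.values)
            maps.append(
                JacobianMap(logj, scale="log_det", dt=pair.dt, voxel_size=atlas.voxel_size)
            )
        else:
            maps.append(
                JacobianMap(raw, scale="log_det", dt=pair.dt, voxel_size=atlas.voxel_size)
            )

    dataset = SimulatedDataset(
        cohort=cohort,
        atlas=atlas,
        ground_truth=ground_truth,
        pairs=pairs,
        pair_groups=pair_groups,
        maps=maps,
        fields=fields,
        effect_model=effect_model,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_dataset(ds: SimulatedDataset, out_dir: Path) -> None:
    import gzip

    import nibabel as nib

    def save_nii(arr, path, dtype=np.float32):
        affine = np.diag(list(ds.atlas.voxel_size) + [1.0])
        img = nib.Nifti1Image(np.asarray(arr).astype(dtype), affine)
        # fixed mtime so identical data gives identical bytes
        with gzip.GzipFile(path, "wb", mtime=0) as f:
            f.write(img.to_bytes())

    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(ds.cohort, out_dir / "cohort.csv")
    save_nii(ds.atlas.labels, out_dir / "atlas.nii.gz", dtype=np.int16)
    save_nii(ds.atlas.gm_mask, out_dir / "gm_mask.nii.gz", dtype=np.uint8)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    pair_rows = []
    for pair, group, jmap in zip(ds.pairs, ds.pair_groups, ds.maps):
        ref = f"{pair.subject_id}_{pair.reference.visit_id}_{pair.followup.visit_id}"
        save_nii(jmap.values, maps_dir / f"{ref}.nii.gz")
        pair_rows.append(
            {
                "scan_ref": ref,
                "subject_id": pair.subject_id,
                "group": group.value,
                "dt": pair.dt,
                "mean_age": pair.mean_age,
                "scale": jmap.scale,
            }
        )
    if ds.fields is not None:
        fields_dir = out_dir / "fields"
        fields_dir.mkdir(exist_ok=True)
        for pair, fld in zip(ds.pairs, ds.fields):
            ref = f"{pair.subject_id}_{pair.reference.visit_id}_{pair.followup.visit_id}"
            save_nii(fld.displacement, fields_dir / f"{ref}.nii.gz")
    import pandas as pd

    pd.DataFrame(pair_rows).to_csv(out_dir / "pairs.csv", index=False)
    checksums = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "seed": ds.effect_model.seed if ds.effect_model else None,
        "n_subjects": len(ds.cohort),
        "n_maps": len(ds.maps),
        "mode": ds.effect_model.mode if ds.effect_model else "map",
        "checksums": checksums,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
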