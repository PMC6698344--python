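"""End-to-end orchestration: simulate -> morphometry -> confounds -> analyses.

One master seed drives the whole run; each stage derives its own child
seed with a counter-based scheme, so any stage can be rerun independently
yet reproducibly.  Every stage directory receives a manifest JSON with
the config hash, the stage seed and SHA-256 checksums of its outputs:
rerunning with the same config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import read_cohort_csv
from .ml import NestedCVConfig, build_feature_matrix, evaluate_vs_dt, run_nested_cv, selection_frequency_map
from .morphometry import JacobianMap
from .savings import SavingsParams, pr_savings_surface
from .simulate import EffectModel, SimulatedDataset, ToyAtlas, simulate_cohort
from .statmaps import ContrastSpec, signature_contrasts

__all__ = ["PipelineConfig", "run_pipeline", "load_simulated_dataset", "stage_seed"]

STAGES = ("simulate", "morphometry", "confounds", "ml", "eval_dt", "statmaps", "savings")


def stage_seed(master_seed: int, stage: str) -> int:
    """Counter-derived child seed for a stage (stable, < 2^31)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    out_root: Path = Path("tbmscreen_out")
    seed: int = 0
    effect_model: EffectModel = field(default_factory=EffectModel)
    cv: NestedCVConfig = field(default_factory=NestedCVConfig)
    contrast: ContrastSpec = field(default_factory=lambda: ContrastSpec("PreAD", "Ctrl"))
    savings: SavingsParams = field(default_factory=SavingsParams)
    dt_thresholds: tuple[float, ...] = (0.0, 1.0, 1.5, 2.0, 2.5)
    eval_window: Optional[tuple[float, float]] = (2.5, 3.5)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "out_root" in raw:
            kwargs["out_root"] = Path(raw["out_root"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "effect_model" in raw:
            em = dict(raw["effect_model"])
            if "annual_log_volume_change" in em:
                em["annual_log_volume_change"] = {
                    (g, r): v for (g, r, v) in (tuple(item) for item in em["annual_log_volume_change"])
                }
            kwargs["effect_model"] = EffectModel(**em)
        if "cv" in raw:
            cv = dict(raw["cv"])
            if "C_grid" in cv:
                cv["C_grid"] = tuple(cv["C_grid"])
            kwargs["cv"] = NestedCVConfig(**cv)
        if "contrast" in raw:
            kwargs["contrast"] = ContrastSpec(**raw["contrast"])
        if "savings" in raw:
            kwargs["savings"] = SavingsParams(**raw["savings"])
        if "dt_thresholds" in raw:
            kwargs["dt_thresholds"] = tuple(raw["dt_thresholds"])
        if "eval_window" in raw:
            w = raw["eval_window"]
            kwargs["eval_window"] = tuple(w) if w else None
        return cls(**kwargs)

    def config_hash(self) -> str:
        def normalize(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                o = dataclasses.asdict(o)
            if isinstance(o, dict):
                return {str(k): normalize(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [normalize(v) for v in o]
            if isinstance(o, (Path, np.floating, np.integer)):
                return str(o)
            return o

        payload = json.dumps(normalize(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class MissingStageError(RuntimeError):
    """Raised when a requested stage needs outputs of a stage not yet run."""


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, config: PipelineConfig, stage: str, extra: dict, t0: float) -> dict:
    checksums = {
        str(p.relative_to(stage_dir)): _sha256_file(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seed": stage_seed(config.seed, stage),
        "wall_time_s": round(time.time() - t0, 3),
        "checksums": checksums,
        **extra,
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_simulated_dataset(sim_dir: str | Path) -> SimulatedDataset:
    """Reload a simulated dataset written by the simulate stage.

    Ground truth is not persisted; the reloaded dataset supports the ML
    and statistical stages (which only need maps, pairs and the atlas).
    """
    import nibabel as nib

    from .cohort import VisitPair
    from .simulate import REGION_NAMES, GroundTruth

    sim_dir = Path(sim_dir)
    cohort = read_cohort_csv(sim_dir / "cohort.csv")
    labels = np.asarray(nib.load(sim_dir / "atlas.nii.gz").dataobj).astype(int)
    gm = np.asarray(nib.load(sim_dir / "gm_mask.nii.gz").dataobj).astype(bool)
    zooms = nib.load(sim_dir / "atlas.nii.gz").header.get_zooms()[:3]
    atlas = ToyAtlas(
        labels=labels,
        region_names=dict(enumerate(REGION_NAMES, start=1)),
        gm_mask=gm,
        voxel_size=tuple(float(z) for z in zooms),
    )
    pairs_df = pd.read_csv(sim_dir / "pairs.csv")
    pairs, groups, maps = [], [], []
    from .cohort import Group

    for row in pairs_df.itertuples():
        subj = cohort.subject(row.subject_id)
        _, ref_vid, fu_vid = row.scan_ref.rsplit("_", 2)
        by_id = {v.visit_id: v for v in subj.visits}
        pair = VisitPair.from_visits(subj.subject_id, by_id[ref_vid], by_id[fu_vid])
        vol = np.asarray(nib.load(sim_dir / "maps" / f"{row.scan_ref}.nii.gz").dataobj, dtype=float)
        pairs.append(pair)
        groups.append(Group(row.group))
        maps.append(JacobianMap(vol, scale=row.scale, dt=pair.dt, voxel_size=atlas.voxel_size))
    gt = GroundTruth(atlas=atlas, rates={}, aging_coeff=np.zeros(atlas.shape))
    return SimulatedDataset(
        cohort=cohort, atlas=atlas, ground_truth=gt, pairs=pairs, pair_groups=groups, maps=maps
    )


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] = STAGES
) -> dict[str, dict]:
    """Execute the requested stages in dependency order; return manifests.

    Stages not requested must already have their outputs on disk when a
    downstream stage needs them, otherwise a :class:`MissingStageError`
    names the stage to run first.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    root = Path(config.out_root)
    root.mkdir(parents=True, exist_ok=True)
    manifests: dict[str, dict] = {}
    dataset: Optional[SimulatedDataset] = None

    def need_dataset(for_stage: str) -> SimulatedDataset:
        nonlocal dataset
        if dataset is None:
            sim_dir = root / "simulate"
            if not (sim_dir / "manifest.json").exists():
                raise MissingStageError(
                    f"stage '{for_stage}' needs the simulated dataset; run stage 'simulate' first"
                )
            dataset = load_simulated_dataset(sim_dir)
        return dataset

    if "simulate" in stages:
        t0 = time.time()
        em = dataclasses.replace(config.effect_model, seed=stage_seed(config.seed, "simulate"))
        sim_dir = root / "simulate"
        dataset = simulate_cohort(em, out_dir=sim_dir)
        manifests["simulate"] = _write_manifest(
            sim_dir, config, "simulate", {"n_subjects": len(dataset.cohort), "n_maps": len(dataset)}, t0
        )

    if "morphometry" in stages:
        t0 = time.time()
        ds = need_dataset("morphometry")
        stage_dir = root / "morphometry"
        stage_dir.mkdir(exist_ok=True)
        from .morphometry import annualize, roi_means

        rows = []
        for pair, jmap, grp in zip(ds.pairs, ds.maps, ds.pair_groups):
            ann = annualize(jmap, pair.dt) if not jmap.is_annualized else jmap
            means = roi_means(ann, ds.atlas)
            rows.append(
                {"subject_id": pair.subject_id, "group": grp.value, "dt": pair.dt, **means}
            )
        pd.DataFrame(rows).to_csv(stage_dir / "roi_annual_rates.csv", index=False)
        manifests["morphometry"] = _write_manifest(stage_dir, config, "morphometry", {"n_maps": len(rows)}, t0)

    if "confounds" in stages:
        t0 = time.time()
        ds = need_dataset("confounds")
        stage_dir = root / "confounds"
        stage_dir.mkdir(exist_ok=True)
        from .confounds import fit_age_model, save_age_model
        from .morphometry import annualize

        ctrl = [
            (annualize(m, p.dt) if not m.is_annualized else m, p.mean_age)
            for m, p, g in zip(ds.maps, ds.pairs, ds.pair_groups)
            if g.value == "Ctrl"
        ]
        model = fit_age_model([m for m, _ in ctrl], [a for _, a in ctrl])
        save_age_model(model, stage_dir / "age_model", voxel_size=ds.atlas.voxel_size)
        manifests["confounds"] = _write_manifest(
            stage_dir, config, "confounds", {"n_fit": model.n_fit, "age_centering": model.age_centering}, t0
        )

    if "ml" in stages:
        t0 = time.time()
        ds = need_dataset("ml")
        stage_dir = root / "ml"
        stage_dir.mkdir(exist_ok=True)
        fm = build_feature_matrix(ds)
        cv = dataclasses.replace(
            config.cv, seed=stage_seed(config.seed, "ml"), dt_eval_window=config.eval_window
        )
        result = run_nested_cv(fm, cv)
        result.metrics.to_csv(stage_dir / "metrics_per_repeat.csv", index=False)
        result.scores.to_csv(stage_dir / "scores_per_map.csv", index=False)
        summary = result.summary()
        summary.to_csv(stage_dir / "metrics_summary.csv")
        freq = selection_frequency_map(result, fm.mask)
        import gzip

        import nibabel as nib

        affine = np.diag(list(ds.atlas.voxel_size) + [1.0])
        with gzip.GzipFile(stage_dir / "selection_frequency.nii.gz", "wb", mtime=0) as f:
            f.write(nib.Nifti1Image(freq.astype(np.float32), affine).to_bytes())
        (stage_dir / "cv_result.json").write_text(
            json.dumps(
                {
                    "chosen_C": result.chosen_C,
                    "n_repeats_valid": result.n_repeats_valid,
                    "summary": {m: dict(summary.loc[m]) for m in summary.index},
                },
                indent=1,
                sort_keys=True,
            )
        )
        manifests["ml"] = _write_manifest(
            stage_dir, config, "ml", {"n_repeats_valid": result.n_repeats_valid}, t0
        )

    if "eval_dt" in stages:
        t0 = time.time()
        ds = need_dataset("eval_dt")
        stage_dir = root / "eval_dt"
        stage_dir.mkdir(exist_ok=True)
        fm = build_feature_matrix(ds)
        cv = dataclasses.replace(config.cv, seed=stage_seed(config.seed, "eval_dt"))
        curves = evaluate_vs_dt(fm, cv, list(config.dt_thresholds), savings_params=config.savings)
        curves.to_csv(stage_dir / "metrics_vs_dt.csv", index=False)
        manifests["eval_dt"] = _write_manifest(stage_dir, config, "eval_dt", {"n_thresholds": len(curves)}, t0)

    if "statmaps" in stages:
        t0 = time.time()
        ds = need_dataset("statmaps")
        stage_dir = root / "statmaps"
        stage_dir.mkdir(exist_ok=True)
        results = signature_contrasts(ds, spec=config.contrast)
        import gzip

        import nibabel as nib

        affine = np.diag(list(ds.atlas.voxel_size) + [1.0])
        for (ga, gb), stat in results.items():
            tag = f"{ga}_vs_{gb}"
            signed_mask = stat.sig_mask_pos.astype(np.int8) - stat.sig_mask_neg.astype(np.int8)
            for name, arr, dtype in (
                (f"t_{tag}", stat.t_values, np.float32),
                (f"neglog10p_pos_{tag}", -np.log10(np.maximum(stat.p_pos, 1e-300)), np.float32),
                (f"cluster_mask_{tag}", signed_mask, np.int8),
            ):
                with gzip.GzipFile(stage_dir / f"{name}.nii.gz", "wb", mtime=0) as f:
                    f.write(nib.Nifti1Image(np.asarray(arr).astype(dtype), affine).to_bytes())
            stat.clusters.to_csv(stage_dir / f"clusters_{tag}.csv", index=False)
        manifests["statmaps"] = _write_manifest(
            stage_dir, config, "statmaps", {"contrasts": [f"{a}_vs_{b}" for a, b in results]}, t0
        )

    if "savings" in stages:
        t0 = time.time()
        stage_dir = root / "savings"
        stage_dir.mkdir(exist_ok=True)
        surf = pr_savings_surface(config.savings)
        pd.DataFrame(surf.values, index=surf.recall, columns=surf.precision).to_csv(
            stage_dir / "savings_surface.csv"
        )
        (stage_dir / "iso_contours.json").write_text(
            json.dumps(
                {str(lvl): [line.tolist() for line in lines] for lvl, lines in surf.contours.items()},
                sort_keys=True,
            )
        )
        manifests["savings"] = _write_manifest(stage_dir, config, "savings", {}, t0)

    return manifests
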