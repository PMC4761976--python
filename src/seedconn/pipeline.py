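"""End-to-end orchestration: simulate two cohorts, run the full analysis.

``run_pipeline`` chains simulate -> preprocess -> seed DMN -> group stats ->
ROI network for each configured group and writes a structured results
bundle (NIfTI maps, TSV tables, JSON summary). Everything is a pure
function of the configuration and master seed, so re-runs are
byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .connectivity import corr_map, roi_timecourse
from .core import AcquisitionSpec
from .group import SeedDMN, compare_strength, dmn_histogram, reported_threshold
from .network import EdgeNetwork, export_graph, subject_conn_matrix
from .preprocess import PreprocConfig, preprocess_subject
from .synthetic import (
    StrainProfile,
    _roi_names,
    build_target_matrix,
    get_profile,
    iter_cohort,
    make_toy_atlas,
)

log = logging.getLogger("seedconn")

__all__ = ["GroupSpec", "RunConfig", "validate_config", "run_pipeline"]


@dataclass(frozen=True)
class GroupSpec:
    name: str
    profile: StrainProfile
    n_subjects: int = 9

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"group {self.name!r}: n_subjects must be >= 2")


def _default_groups() -> tuple[GroupSpec, ...]:
    return (
        GroupSpec("SHR-like", get_profile("shr"), 9),
        GroupSpec("WKY-like", get_profile("wky"), 9),
    )


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration with every default filled in."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    seed_roi: str = "RSC"
    r0: float = 0.3
    alpha: float = 0.05
    n_rois: int = 25
    family_size: int | None = None  # None -> group size
    edge_family: int | str | None = None  # None -> group size, "edges" -> K(K-1)/2
    master_seed: int = 0
    write_images: bool = False

    def __post_init__(self) -> None:
        self.preproc.validate_band(self.acquisition.tr)
        names = _roi_names(self.n_rois)
        if self.seed_roi not in names:
            raise ValueError(
                f"seed ROI {self.seed_roi!r} not in the {self.n_rois}-ROI atlas "
                f"(known: {', '.join(names)})"
            )
        for g in self.groups:
            for a, b, _ in g.profile.couplings:
                for roi in (a, b):
                    if roi not in names:
                        raise ValueError(
                            f"group {g.name!r}: coupling ROI {roi!r} not in atlas"
                        )

    def to_dict(self) -> dict:
        acq = self.acquisition
        return {
            "acquisition": {
                "nx": acq.nx, "ny": acq.ny, "nz": acq.nz,
                "n_volumes": acq.n_volumes, "tr": acq.tr,
                "voxel_dims": list(acq.voxel_dims),
            },
            "preproc": {
                "band": list(self.preproc.band),
                "fwhm_mm": self.preproc.fwhm_mm,
                "detrend_order": self.preproc.detrend_order,
                "mask_fraction": self.preproc.mask_fraction,
                "order": list(self.preproc.order),
            },
            "groups": [
                {"name": g.name, "n_subjects": g.n_subjects,
                 "profile": g.profile.to_dict()}
                for g in self.groups
            ],
            "seed_roi": self.seed_roi,
            "r0": self.r0,
            "alpha": self.alpha,
            "n_rois": self.n_rois,
            "family_size": self.family_size,
            "edge_family": self.edge_family,
            "master_seed": self.master_seed,
            "write_images": self.write_images,
        }


_TOP_KEYS = {
    "acquisition", "preproc", "groups", "seed_roi", "r0", "alpha", "n_rois",
    "family_size", "edge_family", "master_seed", "write_images",
}
_ACQ_KEYS = {"nx", "ny", "nz", "n_volumes", "tr", "voxel_dims"}
_PRE_KEYS = {"band", "fwhm_mm", "detrend_order", "mask_fraction", "order"}
_GROUP_KEYS = {"name", "profile", "n_subjects"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}"
        )


def _parse_profile(raw) -> StrainProfile:
    if isinstance(raw, str):
        return get_profile(raw)
    if isinstance(raw, dict):
        return StrainProfile.from_dict(raw)
    raise ValueError(f"profile must be 'shr', 'wky' or a mapping, got {raw!r}")


def validate_config(text: str | None = None, raw: dict | None = None) -> RunConfig:
    """Parse a YAML configuration and fill every default.

    An empty document yields the all-defaults configuration. Unknown keys,
    bands beyond Nyquist and missing ROI references raise with actionable
    messages.
    """
    if raw is None:
        raw = yaml.safe_load(text) if text else None
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "configuration")

    acq_raw = dict(raw.get("acquisition") or {})
    _check_keys(acq_raw, _ACQ_KEYS, "acquisition")
    if "voxel_dims" in acq_raw:
        acq_raw["voxel_dims"] = tuple(acq_raw["voxel_dims"])
    acquisition = AcquisitionSpec(**acq_raw)

    pre_raw = dict(raw.get("preproc") or {})
    _check_keys(pre_raw, _PRE_KEYS, "preproc")
    for key in ("band", "order"):
        if key in pre_raw:
            pre_raw[key] = tuple(pre_raw[key])
    preproc = PreprocConfig(**pre_raw)

    groups = []
    for g in raw.get("groups") or []:
        _check_keys(g, _GROUP_KEYS, f"group {g.get('name', '?')!r}")
        groups.append(
            GroupSpec(
                name=str(g.get("name", f"group{len(groups)}")),
                profile=_parse_profile(g.get("profile", "shr")),
                n_subjects=int(g.get("n_subjects", 9)),
            )
        )

    kwargs = {k: raw[k] for k in
              ("seed_roi", "r0", "alpha", "n_rois", "family_size",
               "edge_family", "master_seed", "write_images") if k in raw}
    return RunConfig(
        acquisition=acquisition,
        preproc=preproc,
        groups=tuple(groups) if groups else _default_groups(),
        **kwargs,
    )


def _analyze_group(cfg: RunConfig, atlas, group: GroupSpec, group_seed: int,
                   out_dir: Path | None):
    """Simulate and analyze one cohort, one subject in memory at a time."""
    truth = build_target_matrix(atlas, group.profile, cfg.acquisition)
    maps, mats, seeds = [], [], []
    for i, (seed, img) in enumerate(
        iter_cohort(truth, group.n_subjects, group_seed)
    ):
        sid = f"{group.name}_sub{i:02d}"
        stage = "simulate"
        try:
            stage = "preprocess"
            proc, mask = preprocess_subject(img, cfg.preproc)
            stage = "seed-correlation"
            seed_ts = roi_timecourse(proc, atlas, cfg.seed_roi, mask)
            smap = corr_map(proc, seed_ts, mask, cfg.seed_roi, sid)
            stage = "roi-network"
            mats.append(subject_conn_matrix(proc, atlas, mask, sid))
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed for subject {sid}: {exc}"
            ) from exc
        maps.append(smap)
        seeds.append(seed)
        if out_dir is not None and cfg.write_images:
            img.save(out_dir / f"{sid}.nii.gz")
        log.info("group %s subject %s done (seed %d)", group.name, sid, seed)
    return truth, seeds, maps, mats


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the whole study for every configured group.

    Returns the results bundle as a dict (also written as ``summary.json``
    together with maps and tables when ``out_dir`` is given). The summary
    echoes the effective configuration and every threshold applied.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    atlas = make_toy_atlas(cfg.acquisition, cfg.n_rois)
    if out is not None:
        atlas.save(out / "atlas.nii.gz")

    per_group: dict[str, dict] = {}
    group_objects = {}
    for gi, group in enumerate(cfg.groups):
        group_seed = int(
            np.random.SeedSequence([cfg.master_seed, 1000 + gi]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        gdir = out / group.name if out is not None else None
        if gdir is not None:
            gdir.mkdir(exist_ok=True)
        truth, seeds, maps, mats = _analyze_group(cfg, atlas, group, group_seed, gdir)
        results = SeedDMN(
            maps, r0=cfg.r0, alpha=cfg.alpha, family_size=cfg.family_size
        ).fit()
        counts, edges_ = results.histogram()
        per_group[group.name] = {
            "n_subjects": group.n_subjects,
            "group_seed": group_seed,
            "subject_seeds": seeds,
            "pixel_count": results.pixel_count,
            "per_test_alpha": results.group_map.per_test_alpha,
            "reported_alpha": results.group_map.reported_alpha,
            "dmn_mean_r": float(
                results.mean_r_map[results.dmn_mask].mean()
            ) if results.pixel_count else None,
            "histogram": {
                "bin_edges": [round(float(e), 6) for e in edges_],
                "counts": [int(c) for c in counts],
            },
            "repair_distance": truth.repair_distance,
        }
        group_objects[group.name] = (truth, maps, mats, results)
        if gdir is not None:
            results.save(gdir, prefix="group", voxel_dims=cfg.acquisition.voxel_dims)
            truth.save(gdir / "ground_truth.json")
            for m in mats:
                m.save(gdir / f"{m.subject_id}_connmatrix.tsv")
            if cfg.write_images:
                for smap in maps:
                    smap.save(gdir, cfg.acquisition.voxel_dims)
        log.info("group %s: DMN pixel count %d", group.name, results.pixel_count)

    summary: dict = {
        "config": cfg.to_dict(),
        "roi_names": atlas.names,
        "groups": per_group,
    }

    names = [g.name for g in cfg.groups]
    if len(names) >= 2:
        a, b = names[0], names[1]
        (_, maps_a, mats_a, res_a) = group_objects[a]
        (_, maps_b, mats_b, res_b) = group_objects[b]
        strength = compare_strength(
            maps_a, maps_b, res_a.dmn_mask, res_b.dmn_mask,
            group_a=a, group_b=b,
        )
        # variant with the seed ROI removed from both masks: the seed's
        # near-unit self-correlation voxels otherwise dominate small masks
        try:
            strength_excl = compare_strength(
                maps_a, maps_b, res_a.dmn_mask, res_b.dmn_mask,
                exclude_roi=cfg.seed_roi, atlas=atlas, group_a=a, group_b=b,
            )
            summary["strength_comparison_excluding_seed"] = strength_excl.to_dict()
        except ValueError:
            summary["strength_comparison_excluding_seed"] = None
        net = EdgeNetwork(
            mats_a, mats_b, alpha=cfg.alpha, family_size=cfg.edge_family,
            group_a=a, group_b=b,
        ).fit()
        sig = net.significant_edges
        summary["strength_comparison"] = strength.to_dict()
        summary["edge_network"] = {
            "per_test_alpha": net.graph.per_test_alpha,
            "family_size": net.graph.family_size,
            "n_edges": net.graph.n_edges,
            "n_significant": int(len(sig)),
            "n_stronger_a": int((sig["direction"] == a).sum()),
            "n_stronger_b": int((sig["direction"] == b).sum()),
            "significant_edges": [
                {
                    "roi_a": r.roi_a, "roi_b": r.roi_b,
                    "t_stat": float(r.t_stat), "p_value": float(r.p_value),
                    "direction": r.direction,
                }
                for r in sig.itertuples()
            ],
        }
        if out is not None:
            export_graph(net.graph, out, prefix="edges")

    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
    return summary
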