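"""End-to-end orchestration: simulate (or load) -> FC store -> association ->
clinical correlates -> report, with one master seed and a machine-readable
summary."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import clinical as clinical_mod
from . import fc as fc_mod
from . import io_atlas, synth

__all__ = [
    "RunConfig",
    "AssociationResult",
    "associate",
    "save_association",
    "load_cluster_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Inputs are either a bundled simulation (``synth``) or paths to an atlas
    volume, region-name TSV, scan NIfTIs and a phenotype TSV.
    """

    seed: int
    roi_id: int
    contrast: tuple[str, str, str] = ("group", "control", "patient")
    covariates: tuple[str, ...] = ("age", "sex", "education", "mean_fd")
    threshold: str = "fdr:0.05"
    chunk_size: int = 200_000
    min_cluster_table_voxels: int = 10
    clinical_scores: tuple[str, ...] = clinical_mod.DEFAULT_SCORES
    clinical_covariates: tuple[str, ...] = clinical_mod.DEFAULT_COVARIATES
    run_clinical: bool = True
    synth: synth.SimulationConfig | None = None
    atlas_path: str | None = None
    names_path: str | None = None
    scan_paths: tuple[str, ...] = ()
    phenotype_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synth" in raw and raw["synth"] is not None:
            s = raw["synth"]
            s["sites"] = [synth.SiteSpec(**x) for x in s["sites"]]
            s["regions"] = [
                synth.RegionSpec(
                    region_id=r["region_id"], name=r["name"],
                    origin=tuple(r["origin"]), shape=tuple(r["shape"]),
                )
                for r in s["regions"]
            ]
            s["effects"] = [synth.EffectSpec(**e) for e in s.get("effects", [])]
            s["clinical_couplings"] = [
                synth.ClinicalCoupling(**c) for c in s.get("clinical_couplings", [])
            ]
            s["grid_dims"] = tuple(s["grid_dims"])
            raw["synth"] = synth.SimulationConfig(**s)
        for key in ("contrast", "covariates", "clinical_scores",
                    "clinical_covariates", "scan_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclasses.dataclass
class AssociationResult:
    """Combined statistics, significance mask and spatial summaries."""

    combined_z: np.ndarray
    combined_p: np.ndarray
    mask: np.ndarray
    p_star: float | None
    mode: assoc_mod.ThresholdMode
    site_stats: list[assoc_mod.SiteLinkStats]
    ma: np.ndarray
    s_abs: np.ndarray
    sign: np.ndarray
    clusters: assoc_mod.ClusterTable


def associate(
    store: fc_mod.PairFCStore,
    phenotypes: pd.DataFrame,
    atlas: io_atlas.Atlas,
    contrast: tuple[str, str, str] = ("group", "control", "patient"),
    covariates: tuple[str, ...] = (),
    mode: assoc_mod.ThresholdMode | str = "fdr:0.05",
    min_cluster_table_voxels: int = 10,
) -> AssociationResult:
    """Per-site link tests, cross-site combination, thresholding and summaries.

    Sites where either contrast group has fewer than 2 subjects are skipped
    with a log note (single-site contrasts then reduce to that site's own
    statistics through the single-site combination identity).
    """
    if isinstance(mode, str):
        mode = assoc_mod.ThresholdMode.parse(mode)
    col, level_a, level_b = contrast
    usable = phenotypes[phenotypes[col].isin([level_a, level_b])]
    site_stats: list[assoc_mod.SiteLinkStats] = []
    for site, sub in usable.groupby("site", sort=True):
        counts = sub[col].value_counts()
        if counts.get(level_a, 0) < 2 or counts.get(level_b, 0) < 2:
            logger.info("site %r lacks both contrast groups; skipped", site)
            continue
        rows = store.subject_rows(list(sub["subject_id"]))
        stats_k = assoc_mod.site_link_test(
            store.z[rows].astype(np.float64),
            sub.reset_index(drop=True),
            contrast=contrast,
            covariates=covariates,
            site=str(site),
        )
        site_stats.append(stats_k)
    if not site_stats:
        raise ValueError("no site has >= 2 subjects in both contrast groups")

    z_sites = np.stack([s.z_signed for s in site_stats])
    n_sites = np.array([s.n for s in site_stats])
    combined_z, combined_p = assoc_mod.liptak_combine(z_sites, n_sites)
    mask, p_star = assoc_mod.apply_threshold(
        combined_p, mode, pair_index=store.pair_index, atlas=atlas
    )
    ma = assoc_mod.ma_score(mask, store.pair_index)
    s_abs, sign = assoc_mod.voxel_signed_summary(combined_z, mask, store.pair_index)
    clusters = assoc_mod.region_cluster_table(
        mask, combined_z, atlas, store.pair_index,
        min_cluster_voxels=min_cluster_table_voxels,
    )
    return AssociationResult(
        combined_z=combined_z, combined_p=combined_p, mask=mask, p_star=p_star,
        mode=mode, site_stats=site_stats, ma=ma, s_abs=s_abs, sign=sign,
        clusters=clusters,
    )


def _voxel_map_volume(values: np.ndarray, atlas: io_atlas.Atlas) -> np.ndarray:
    vol = np.zeros(atlas.labels.shape, dtype=np.float32)
    c = atlas.voxel_coords
    vol[c[:, 0], c[:, 1], c[:, 2]] = values
    return vol


def save_association(
    result: AssociationResult, atlas: io_atlas.Atlas, out_dir: str | Path
) -> None:
    """Write pair-level statistics (HDF5), voxel maps (NIfTI) and the cluster
    table (TSV) of one association run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "assoc.h5", "w") as f:
        f.create_dataset("Z", data=result.combined_z, dtype="f8")
        f.create_dataset("p", data=result.combined_p, dtype="f8")
        f.create_dataset("mask", data=result.mask)
        f.attrs["mode"] = str(result.mode)
        if result.p_star is not None:
            f.attrs["p_star"] = result.p_star
        links = result.clusters.row_links
        flat = np.concatenate(links) if links else np.empty(0, dtype=np.int64)
        offsets = np.cumsum([0] + [len(x) for x in links])
        f.create_dataset("cluster_links", data=flat.astype(np.int64))
        f.create_dataset("cluster_offsets", data=offsets.astype(np.int64))
    result.clusters.table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    nib.save(
        nib.Nifti1Image(_voxel_map_volume(result.ma, atlas), atlas.affine),
        out / "ma.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(
            _voxel_map_volume(result.s_abs * result.sign, atlas), atlas.affine
        ),
        out / "signed_sum_abs_z.nii.gz",
    )


def load_cluster_table(out_dir: str | Path) -> assoc_mod.ClusterTable:
    """Reload the cluster table and link membership written by
    :func:`save_association` (voxel membership is not persisted)."""
    out = Path(out_dir)
    table = pd.read_csv(out / "clusters.tsv", sep="\t")
    with h5py.File(out / "assoc.h5", "r") as f:
        flat = f["cluster_links"][()]
        offsets = f["cluster_offsets"][()]
    links = [flat[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)]
    return assoc_mod.ClusterTable(table=table, row_links=links, row_voxels=[])


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all artifacts plus ``summary.json``.

    Deterministic given the config (seed included); re-running overwrites the
    run directory with identical contents.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("voxelfc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, out)
    except Exception as err:  # noqa: BLE001 - re-raise with stage tag
        raise RuntimeError(f"pipeline failed: {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline(config: RunConfig, out: Path) -> dict:
    # stage: inputs
    try:
        if config.synth is not None:
            atlas, scans, phen, truth = synth.generate_cohort(config.synth)
            io_atlas.save_atlas(atlas, out / "atlas.nii.gz", out / "regions.tsv")
            phen.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
            truth.save(out / "ground_truth.json")
        else:
            if not (config.atlas_path and config.names_path and config.phenotype_path):
                raise ValueError("either synth or atlas/names/phenotype paths required")
            atlas = io_atlas.load_atlas(config.atlas_path, config.names_path)
            phen = io_atlas.load_phenotypes(config.phenotype_path)
            scans = [io_atlas.load_scan(p, atlas) for p in config.scan_paths]
            truth = None
        logger.info("inputs: %d scans, %d brain voxels", len(scans), atlas.n_voxels)
    except Exception as err:
        raise RuntimeError(f"[inputs] {err}") from err

    # stage: fc
    try:
        atlas.validate_roi(config.roi_id)
        pair_index = fc_mod.enumerate_pairs(atlas, config.roi_id)
        store = fc_mod.compute_store(scans, pair_index, chunk_size=config.chunk_size)
        store.save(out / "store.h5")
        logger.info(
            "fc: %d pairs, %d zero-variance voxel records",
            pair_index.n_pairs, len(store.zero_variance),
        )
    except Exception as err:
        raise RuntimeError(f"[fc] {err}") from err

    # stage: associate
    try:
        result = associate(
            store, phen, atlas,
            contrast=config.contrast,
            covariates=config.covariates,
            mode=config.threshold,
            min_cluster_table_voxels=config.min_cluster_table_voxels,
        )
        save_association(result, atlas, out)
        logger.info(
            "associate: %d significant links, p_star=%s",
            int(result.mask.sum()), result.p_star,
        )
    except Exception as err:
        raise RuntimeError(f"[associate] {err}") from err

    # stage: clinical
    clinical_table = None
    if config.run_clinical and len(result.clusters.row_links) > 0:
        try:
            profile = clinical_mod.roiwise_mean_fc(store, result.clusters)
            clinical_table = clinical_mod.clinical_correlates(
                profile, phen,
                scores=config.clinical_scores,
                covariates=config.clinical_covariates,
            )
            clinical_table.to_csv(out / "clinical.tsv", sep="\t", index=False)
            logger.info("clinical: %d correlate rows", len(clinical_table))
        except Exception as err:
            raise RuntimeError(f"[clinical] {err}") from err

    # stage: report
    counts = (
        phen.groupby(["site", "group"]).size().reset_index(name="n")
        .to_dict(orient="records")
    )
    top = result.clusters.table.head(5).to_dict(orient="records")
    summary = {
        "seed": int(config.seed),
        "subjects": counts,
        "n_pairs": int(pair_index.n_pairs),
        "threshold": str(result.mode),
        "fdr_p_star": result.p_star,
        "n_significant_links": int(result.mask.sum()),
        "n_zero_variance_records": int(len(store.zero_variance)),
        "n_cluster_rows": int(len(result.clusters.table)),
        "top_clusters": top,
        "n_clinical_rows": None if clinical_table is None else int(len(clinical_table)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
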