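"""Synthetic multi-site BOLD cohort generator with known injected effects.

Generative model
----------------
Each region ``r`` carries a latent signal ``u_r(t)``, a stationary AR(1)
Gaussian process with unit variance and lag-1 autocorrelation ``phi``.
Voxel ``i`` inside region ``r`` observes

    x_i(t) = sqrt(c) * u_r(t) + sqrt(1 - c) * eps_i(t)

with white Gaussian ``eps`` and within-region coherence ``c`` in [0, 1], so
two voxels of the same region correlate at ``c`` and a voxel pair spanning
regions ``a, b`` correlates at ``c * corr(u_a, u_b)``.

Group differences, site shifts and covariate effects act on a per-subject
*coupling parameter* ``zeta`` for each declared region pair:

    zeta = zeta_base + site_offset + delta_z * 1[patient]
           + sum_j beta_j * covariate_j(standardized) + eta

where ``eta`` is subject-level coupling noise, Gaussian with SD
``subject_sd`` clipped at +/-2.5 SD (the clipping keeps the joint
latent-correlation matrix feasible in the far tails for the default
multi-effect layouts).

and the latents are mixed so that the expected voxel-pair correlation
between the two regions is exactly ``tanh(zeta)`` — i.e. the injected group
difference is ``delta_z`` on the Fisher-z scale, the scale on which the
pipeline tests. The latent correlation needed is ``rho = tanh(zeta) / c``.
All requested latent correlations are realized jointly: the target
correlation matrix ``S`` (identity with ``rho_e`` on each effect's region
pair) is factored as ``S = L L^T`` through its eigendecomposition and the
region latents are ``u = L v`` for independent AR(1) processes ``v``. This
gives ``corr(u_a, u_b) = rho_e`` exactly, zero correlation for undeclared
region pairs, and a clean error when the couplings are not jointly
realizable (``S`` not positive semidefinite). The mixing is unit-tested
against a Monte-Carlo oracle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .io_atlas import Atlas, SubjectScan

__all__ = [
    "RegionSpec",
    "SiteSpec",
    "EffectSpec",
    "ClinicalCoupling",
    "SimulationConfig",
    "GroundTruth",
    "make_toy_atlas",
    "generate_subject",
    "generate_cohort",
    "demo_config",
    "study_config",
    "null_calibration_config",
    "small_study_regions",
    "calibration_regions",
]

#: Theoretical moments used to standardize covariates inside the generator,
#: matching the sampling distributions in ``_draw_phenotype``.
COVARIATE_MOMENTS = {
    "age": (39.0, 42.0 / math.sqrt(12.0)),
    "sex": (0.5, 0.5),
    "education": (13.0, 14.0 / math.sqrt(12.0)),
    "mean_fd": (
        0.12 * math.exp(0.08),
        0.12 * math.exp(0.08) * math.sqrt(math.exp(0.16) - 1.0),
    ),
}


@dataclasses.dataclass
class RegionSpec:
    """A cuboid region: ``shape`` voxels starting at ``origin`` (0-based)."""

    region_id: int
    name: str
    origin: tuple[int, int, int]
    shape: tuple[int, int, int]


@dataclasses.dataclass
class SiteSpec:
    """One imaging site of the cohort.

    ``baseline_coupling_offset`` shifts every effect's coupling parameter at
    this site (a site batch effect on FC); ``noise_scale`` scales signal
    amplitude (correlations are scale invariant, so it exercises I/O paths
    without changing statistics). ``medicated_fraction`` applies to patients;
    ``all_medicated`` forces it to 1.
    """

    name: str
    n_controls: int
    n_patients: int
    noise_scale: float = 1.0
    baseline_coupling_offset: float = 0.0
    all_medicated: bool = False
    medicated_fraction: float = 0.5


@dataclasses.dataclass
class EffectSpec:
    """Injected coupling between two regions; ``delta_z`` is the
    patient-minus-control difference on the Fisher-z scale."""

    region_a: int
    region_b: int
    delta_z: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_z):
            raise ValueError("delta_z must be finite")


@dataclasses.dataclass
class ClinicalCoupling:
    """Correlate a clinical score with a subject's coupling deviation.

    ``r`` is the target correlation between the score and the subject-level
    coupling noise ``eta`` of effect ``effect_index`` (patients only).
    """

    score: str
    effect_index: int
    r: float


@dataclasses.dataclass
class SimulationConfig:
    seed: int
    sites: list[SiteSpec]
    regions: list[RegionSpec]
    grid_dims: tuple[int, int, int]
    roi_id: int
    effects: list[EffectSpec] = dataclasses.field(default_factory=list)
    n_timepoints: int = 230
    covariate_betas: dict[str, float] = dataclasses.field(default_factory=dict)
    ar_coefficient: float = 0.4
    coherence: float = 0.75
    base_coupling: float = 0.15
    subject_sd: float = 0.05
    clinical_couplings: list[ClinicalCoupling] = dataclasses.field(default_factory=list)
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 30:
            raise ValueError("n_timepoints must be >= 30")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must be in [0, 1]")
        unknown = set(self.covariate_betas) - set(COVARIATE_MOMENTS)
        if unknown:
            raise ValueError(f"unknown covariates in betas: {sorted(unknown)}")

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["sites"] = [SiteSpec(**s) for s in raw["sites"]]
        raw["regions"] = [
            RegionSpec(
                region_id=r["region_id"],
                name=r["name"],
                origin=tuple(r["origin"]),
                shape=tuple(r["shape"]),
            )
            for r in raw["regions"]
        ]
        raw["effects"] = [EffectSpec(**e) for e in raw.get("effects", [])]
        raw["clinical_couplings"] = [
            ClinicalCoupling(**c) for c in raw.get("clinical_couplings", [])
        ]
        raw["grid_dims"] = tuple(raw["grid_dims"])
        return cls(**raw)


@dataclasses.dataclass
class GroundTruth:
    """What the generator injected, for validating the pipeline against."""

    effects: list[EffectSpec]
    #: rows: region_a, region_b, site, group, expected Fisher-z coupling
    expected_z: pd.DataFrame
    #: realized coupling parameter per subject (rows) and effect (columns)
    subject_zetas: pd.DataFrame

    def effect_pair_mask(self, atlas: Atlas, pairs: np.ndarray) -> np.ndarray:
        """Boolean mask over voxel pairs: True where a nonzero group
        difference was injected (pair spans an effect's two regions)."""
        la = atlas.voxel_labels[pairs[:, 0]]
        lb = atlas.voxel_labels[pairs[:, 1]]
        mask = np.zeros(len(pairs), dtype=bool)
        for eff in self.effects:
            if eff.delta_z == 0:
                continue
            mask |= (la == eff.region_a) & (lb == eff.region_b)
            mask |= (la == eff.region_b) & (lb == eff.region_a)
        return mask

    def save(self, path: str | Path) -> None:
        payload = {
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "expected_z": self.expected_z.to_dict(orient="list"),
            "subject_zetas": {
                "index": list(self.subject_zetas.index),
                "columns": list(self.subject_zetas.columns),
                "values": self.subject_zetas.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def make_toy_atlas(
    grid_dims: tuple[int, int, int],
    regions: list[RegionSpec],
    voxel_size_mm: float = 3.0,
) -> Atlas:
    """Build a labelled volume of non-overlapping cuboid regions."""
    labels = np.zeros(tuple(grid_dims), dtype=np.int32)
    names: dict[int, str] = {}
    for reg in regions:
        if reg.region_id <= 0:
            raise ValueError("region ids must be positive")
        if reg.region_id in names:
            raise ValueError(f"duplicate region id {reg.region_id}")
        sl = tuple(slice(o, o + s) for o, s in zip(reg.origin, reg.shape))
        block = labels[sl]
        if block.shape != tuple(reg.shape):
            raise ValueError(f"region {reg.region_id} does not fit in the grid")
        if np.any(block != 0):
            raise ValueError(f"region {reg.region_id} overlaps an earlier region")
        labels[sl] = reg.region_id
        names[reg.region_id] = reg.name
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return Atlas(labels=labels, affine=affine, region_names=names)


def _ar1(white: np.ndarray, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) from white noise rows."""
    if phi == 0.0:
        return white
    innov = white * math.sqrt(1.0 - phi * phi)
    innov[..., 0] = white[..., 0]
    return lfilter([1.0], [1.0, -phi], innov, axis=-1)


def _latent_mixing(rho: np.ndarray, effects: list[EffectSpec],
                   region_ids: list[int]) -> np.ndarray:
    """Factor the target latent correlation matrix.

    Builds S = I with ``rho[e]`` on each effect's (region_a, region_b) entry
    and returns L with ``L @ L.T = S`` via the (deterministic) symmetric
    eigendecomposition; raises if S is not positive semidefinite, i.e. the
    requested couplings cannot coexist.
    """
    pos = {rid: k for k, rid in enumerate(region_ids)}
    s = np.eye(len(region_ids))
    for j, eff in enumerate(effects):
        a, b = pos[eff.region_a], pos[eff.region_b]
        if a == b:
            raise ValueError("an effect must couple two distinct regions")
        s[a, b] = s[b, a] = rho[j]
    w, vec = np.linalg.eigh(s)
    if np.min(w) < -1e-8:
        raise ValueError("requested couplings are not jointly realizable")
    return vec * np.sqrt(np.clip(w, 0.0, None))


def _standardized_covariates(row: pd.Series) -> dict[str, float]:
    out = {}
    for name, (mu, sd) in COVARIATE_MOMENTS.items():
        out[name] = (float(row[name]) - mu) / sd
    return out


def _draw_eta(
    rng: np.random.Generator, config: SimulationConfig, n_eff: int
) -> np.ndarray:
    """Subject-level coupling noise: Gaussian clipped at +/-2.5 SD."""
    if n_eff == 0:
        return np.empty(0)
    sd = config.subject_sd
    return np.clip(rng.normal(0.0, sd, size=n_eff), -2.5 * sd, 2.5 * sd)


def _subject_zetas(
    config: SimulationConfig,
    site: SiteSpec,
    row: pd.Series,
    eta: np.ndarray,
) -> np.ndarray:
    """Per-effect coupling parameter for one subject."""
    cov = _standardized_covariates(row)
    shift = sum(config.covariate_betas.get(k, 0.0) * v for k, v in cov.items())
    is_patient = 1.0 if row["group"] == "patient" else 0.0
    zetas = np.array(
        [
            config.base_coupling
            + site.baseline_coupling_offset
            + eff.delta_z * is_patient
            + shift
            + eta[j]
            for j, eff in enumerate(config.effects)
        ]
    )
    return zetas


def generate_subject(
    config: SimulationConfig,
    phenotype_row: pd.Series,
    rng: np.random.Generator,
    atlas: Atlas | None = None,
    eta: np.ndarray | None = None,
) -> tuple[SubjectScan, np.ndarray]:
    """Simulate one subject's masked BOLD matrix.

    Returns the scan and the realized per-effect coupling parameters. ``eta``
    (subject-level coupling noise) may be supplied; otherwise it is drawn
    from ``rng`` first, keeping the draw order deterministic.
    """
    if atlas is None:
        atlas = make_toy_atlas(config.grid_dims, config.regions, config.voxel_size_mm)
    site = next(s for s in config.sites if s.name == phenotype_row["site"])
    n_eff = len(config.effects)
    if eta is None:
        eta = _draw_eta(rng, config, n_eff)
    zetas = _subject_zetas(config, site, phenotype_row, eta)

    c = config.coherence
    target_rho = np.tanh(zetas)
    if np.any(target_rho != 0) and c == 0.0:
        raise ValueError("nonzero coupling requested with coherence 0")
    rho_latent = target_rho / c if c > 0 else np.zeros_like(target_rho)
    if np.any(np.abs(rho_latent) > 1.0):
        raise ValueError(
            "requested voxel-pair correlation exceeds the within-region "
            f"coherence (|tanh(zeta)| >= c = {c})"
        )
    region_ids = [r.region_id for r in config.regions]
    mixing = _latent_mixing(rho_latent, config.effects, region_ids)
    pos = {rid: k for k, rid in enumerate(region_ids)}

    n_t = config.n_timepoints
    white = rng.standard_normal((len(region_ids), n_t))
    u = mixing @ _ar1(white, config.ar_coefficient)

    noise = rng.standard_normal((atlas.n_voxels, n_t))
    data = math.sqrt(1.0 - c) * noise
    if c > 0:
        for rid in region_ids:
            idx = atlas.voxel_indices(rid)
            data[idx] += math.sqrt(c) * u[pos[rid]]
    data *= site.noise_scale
    scan = SubjectScan(data=data, subject_id=str(phenotype_row["subject_id"]))
    return scan, zetas


def _draw_phenotype(
    rng: np.random.Generator,
    site: SiteSpec,
    group: str,
    subject_id: str,
) -> dict:
    age = rng.uniform(18.0, 60.0)
    sex = float(rng.random() < 0.5)
    education = rng.uniform(6.0, 20.0)
    mean_fd = float(np.exp(rng.normal(math.log(0.12), 0.4)))
    med_draw = rng.random()  # drawn for every subject to keep stream order fixed
    if group == "patient":
        medicated = 1.0 if site.all_medicated else float(med_draw < site.medicated_fraction)
    else:
        medicated = np.nan
    return {
        "subject_id": subject_id,
        "site": site.name,
        "group": group,
        "age": age,
        "sex": sex,
        "education": education,
        "mean_fd": mean_fd,
        "medicated": medicated,
    }


def _draw_scores(
    rng: np.random.Generator,
    config: SimulationConfig,
    group: str,
    eta: np.ndarray,
) -> dict:
    g = {name: rng.standard_normal() for name in ("hamd", "bdi", "illness_duration")}
    if group == "patient":
        for cpl in config.clinical_couplings:
            if config.subject_sd <= 0:
                raise ValueError("clinical coupling requires subject_sd > 0")
            eta_std = eta[cpl.effect_index] / config.subject_sd
            g[cpl.score] = cpl.r * eta_std + math.sqrt(1.0 - cpl.r**2) * g[cpl.score]
        return {
            "hamd": float(np.clip(20.0 + 4.0 * g["hamd"], 0.0, 52.0)),
            "bdi": float(np.clip(25.0 + 6.0 * g["bdi"], 0.0, 63.0)),
            "illness_duration": float(
                np.exp(math.log(24.0) + 0.6 * g["illness_duration"])
            ),
        }
    return {
        "hamd": float(np.clip(2.0 + 1.5 * g["hamd"], 0.0, 52.0)),
        "bdi": float(np.clip(3.0 + 2.0 * g["bdi"], 0.0, 63.0)),
        "illness_duration": np.nan,
    }


def generate_cohort(
    config: SimulationConfig,
) -> tuple[Atlas, list[SubjectScan], pd.DataFrame, GroundTruth]:
    """Simulate the whole multi-site cohort.

    Each subject uses an RNG stream keyed by (master seed, global subject
    index), so cohorts are bit-reproducible and a subject's data does not
    depend on the other subjects.
    """
    atlas = make_toy_atlas(config.grid_dims, config.regions, config.voxel_size_mm)
    atlas.validate_roi(config.roi_id)
    scans: list[SubjectScan] = []
    rows: list[dict] = []
    zeta_rows: list[np.ndarray] = []
    gidx = 0
    for site in config.sites:
        for group, count in (("control", site.n_controls), ("patient", site.n_patients)):
            for i in range(count):
                rng = np.random.default_rng([int(config.seed), gidx])
                sid = f"{site.name}-{group[0]}{i:03d}"
                row = _draw_phenotype(rng, site, group, sid)
                eta = _draw_eta(rng, config, len(config.effects))
                row.update(_draw_scores(rng, config, group, eta))
                scan, zetas = generate_subject(
                    config, pd.Series(row), rng, atlas=atlas, eta=eta
                )
                scans.append(scan)
                rows.append(row)
                zeta_rows.append(zetas)
                gidx += 1
    phen = pd.DataFrame(rows)
    cols = [
        "subject_id", "site", "group", "age", "sex", "education",
        "mean_fd", "medicated", "hamd", "bdi", "illness_duration",
    ]
    phen = phen[cols]

    exp_rows = []
    for eff in config.effects:
        for site in config.sites:
            for group in ("control", "patient"):
                exp_rows.append(
                    {
                        "region_a": eff.region_a,
                        "region_b": eff.region_b,
                        "site": site.name,
                        "group": group,
                        "expected_z": config.base_coupling
                        + site.baseline_coupling_offset
                        + (eff.delta_z if group == "patient" else 0.0),
                    }
                )
    expected = pd.DataFrame(
        exp_rows, columns=["region_a", "region_b", "site", "group", "expected_z"]
    )
    zeta_df = pd.DataFrame(
        np.array(zeta_rows) if zeta_rows else np.empty((len(rows), 0)),
        index=phen["subject_id"],
        columns=[f"{e.region_a}-{e.region_b}" for e in config.effects],
    )
    truth = GroundTruth(
        effects=list(config.effects), expected_z=expected, subject_zetas=zeta_df
    )
    return atlas, scans, phen, truth


# -- standard layouts ----------------------------------------------------


def small_study_regions() -> tuple[tuple[int, int, int], list[RegionSpec]]:
    """Desk-scale atlas: 27-voxel seed + 3 target regions + 7 filler blocks,
    983 brain voxels on a 15^3 grid."""
    regions = [
        RegionSpec(1, "PCC-like", (1, 1, 1), (3, 3, 3)),
        RegionSpec(2, "lOFC-like", (11, 1, 1), (3, 3, 3)),
        RegionSpec(3, "IFG-like", (1, 11, 1), (3, 3, 3)),
        RegionSpec(4, "ACC-like", (11, 11, 1), (3, 3, 3)),
    ]
    fillers = [(0, 0), (0, 5), (0, 10), (5, 0), (5, 5), (5, 10), (10, 0)]
    for k, (i, j) in enumerate(fillers, start=5):
        regions.append(RegionSpec(k, f"filler-{k:02d}", (i, j, 9), (5, 5, 5)))
    return (15, 15, 15), regions


def calibration_regions() -> tuple[tuple[int, int, int], list[RegionSpec]]:
    """Large null atlas: 27-voxel seed + 30 filler blocks, 3777 brain voxels
    (101,601 seed-anchored pairs) on a 20^3 grid."""
    regions = [RegionSpec(1, "PCC-like", (0, 0, 12), (3, 3, 3))]
    rid = 2
    for k in (0, 5):
        for i in (0, 5, 10, 15):
            for j in (0, 5, 10, 15):
                if rid > 31:  # 30 fillers
                    break
                regions.append(RegionSpec(rid, f"filler-{rid:02d}", (i, j, k), (5, 5, 5)))
                rid += 1
    return (20, 20, 20), regions


def demo_config(
    seed: int,
    n_controls: int = 20,
    n_patients: int = 20,
    n_timepoints: int = 120,
    effects: list[EffectSpec] | None = None,
    covariate_betas: dict[str, float] | None = None,
    clinical_couplings: list[ClinicalCoupling] | None = None,
    subject_sd: float = 0.05,
) -> SimulationConfig:
    """Two-site desk-scale cohort on the small study atlas.

    Default effects mirror the study pattern: elevated patient coupling of
    the seed with two frontal-like targets and reduced coupling with an
    anterior-cingulate-like region.
    """
    grid, regions = small_study_regions()
    if effects is None:
        effects = [
            EffectSpec(1, 2, 0.25),
            EffectSpec(1, 3, 0.20),
            EffectSpec(1, 4, -0.15),
        ]
    return SimulationConfig(
        seed=seed,
        sites=[
            SiteSpec("siteA", n_controls, n_patients, baseline_coupling_offset=0.03,
                     all_medicated=True),
            SiteSpec("siteB", n_controls, n_patients, baseline_coupling_offset=-0.03,
                     medicated_fraction=0.55),
        ],
        regions=regions,
        grid_dims=grid,
        roi_id=1,
        effects=effects,
        n_timepoints=n_timepoints,
        covariate_betas=covariate_betas or {},
        subject_sd=subject_sd,
        clinical_couplings=clinical_couplings or [],
    )


def study_config(seed: int) -> SimulationConfig:
    """Full-scale two-site cohort emulating the study structure: one smaller
    site with all patients medicated, one larger mixed site (686 subjects)."""
    grid, regions = small_study_regions()
    return SimulationConfig(
        seed=seed,
        sites=[
            SiteSpec("siteA", 96, 54, baseline_coupling_offset=0.03, all_medicated=True),
            SiteSpec("siteB", 254, 282, baseline_coupling_offset=-0.03,
                     medicated_fraction=157.0 / 282.0),
        ],
        regions=regions,
        grid_dims=grid,
        roi_id=1,
        effects=[
            EffectSpec(1, 2, 0.25),
            EffectSpec(1, 3, 0.20),
            EffectSpec(1, 4, -0.15),
        ],
        n_timepoints=230,
    )


def null_calibration_config(
    seed: int, n_controls: int = 20, n_patients: int = 20, n_timepoints: int = 120
) -> SimulationConfig:
    """Global-null cohort for distributional calibration of the pipeline.

    No effects, no covariate slopes and coherence 0, so every voxel series is
    independent white-in-space noise and the combined statistics of distinct
    pairs are (asymptotically) independent — the regime where an iid
    goodness-of-fit test of the combined Z against N(0,1) is valid.
    """
    grid, regions = calibration_regions()
    return SimulationConfig(
        seed=seed,
        sites=[
            SiteSpec("siteA", n_controls, n_patients),
            SiteSpec("siteB", n_controls, n_patients),
        ],
        regions=regions,
        grid_dims=grid,
        roi_id=1,
        effects=[],
        n_timepoints=n_timepoints,
        coherence=0.0,
        base_coupling=0.0,
        subject_sd=0.0,
    )
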