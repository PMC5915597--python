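"""Group association testing over voxel-pair FC and its spatial summaries.

Pipeline per contrast:

1. Per site, fit one linear model per pair, ``z ~ intercept + group +
   covariates``, and take the t statistic (and two-tailed p) of the group
   coefficient. With no covariates this reduces exactly to the
   pooled-variance two-sample t-test.
2. Convert each site's p to a signed normal deviate
   ``z' = sign(t) * Phi^{-1}(1 - p/2)`` and combine sites with the weighted
   Stouffer (Liptak) statistic ``Z = sum(w_k z'_k) / sqrt(sum(w_k^2))``,
   ``w_k = sqrt(n_k)``, which is N(0,1) under the null.
3. Threshold the combined two-tailed p: Benjamini-Hochberg FDR, an
   uncorrected alpha, or an uncorrected alpha plus cluster-extent filter.
4. Summarize per voxel (MA link counts, signed sum of |Z|) and per
   connected component (region cluster table).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fc import PairIndex
from .io_atlas import Atlas

__all__ = [
    "SiteLinkStats",
    "ThresholdMode",
    "ClusterTable",
    "site_link_test",
    "p_to_signed_z",
    "liptak_combine",
    "bh_fdr",
    "apply_threshold",
    "ma_score",
    "voxel_signed_summary",
    "cluster_filter",
    "region_cluster_table",
]

P_FLOOR = 1e-300
#: 26-connectivity in 3D (vertex/edge/face neighbours all adjacent)
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class SiteLinkStats:
    """Per-pair group statistics from one site's linear models."""

    t: np.ndarray
    p: np.ndarray
    z_signed: np.ndarray
    effect: np.ndarray  # group coefficient: mean adjusted z difference (B - A)
    n: int
    df: int
    site: str = ""

    @property
    def weight(self) -> float:
        return float(np.sqrt(self.n))


def site_link_test(
    z: np.ndarray,
    phenotypes: pd.DataFrame,
    contrast: tuple[str, str, str] = ("group", "control", "patient"),
    covariates: tuple[str, ...] = (),
    site: str = "",
) -> SiteLinkStats:
    """Covariate-adjusted group test per pair within one site.

    Parameters
    ----------
    z
        Subjects x pairs Fisher-z matrix for the site's subjects, row order
        matching ``phenotypes``.
    phenotypes
        One row per subject; must contain the contrast column and covariates.
    contrast
        ``(column, level_A, level_B)``; positive t means level B > level A.
    covariates
        Phenotype columns regressed out jointly with the group term.

    Pairs with any missing z among the site's subjects get NaN statistics.
    """
    col, level_a, level_b = contrast
    z = np.asarray(z, dtype=np.float64)
    if z.shape[0] != len(phenotypes):
        raise ValueError("z rows and phenotype rows disagree")
    values = phenotypes[col].to_numpy()
    is_b = values == level_b
    is_a = values == level_a
    if not (is_a | is_b).all():
        raise ValueError(f"contrast column {col} has levels outside {level_a}/{level_b}")
    if is_a.sum() < 2 or is_b.sum() < 2:
        raise ValueError("need >= 2 subjects in each contrast group")

    cov_mat = phenotypes[list(covariates)].to_numpy(dtype=np.float64) if covariates else \
        np.empty((len(phenotypes), 0))
    if np.isnan(cov_mat).any():
        raise ValueError("covariates contain missing values")
    x = np.column_stack([np.ones(len(phenotypes)), is_b.astype(np.float64), cov_mat])
    n, n_par = x.shape
    if np.linalg.matrix_rank(x) < n_par:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    df = n - n_par
    if df < 1:
        raise ValueError("not enough subjects for the requested covariates")

    n_pairs = z.shape[1]
    t_stat = np.full(n_pairs, np.nan)
    p_val = np.full(n_pairs, np.nan)
    effect = np.full(n_pairs, np.nan)
    ok = ~np.isnan(z).any(axis=0)
    if ok.any():
        zz = z[:, ok]
        xtx_inv = np.linalg.inv(x.T @ x)
        coef = xtx_inv @ (x.T @ zz)
        resid = zz - x @ coef
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ok = np.where(se > 0, coef[1] / se, 0.0)
        p_ok = np.minimum(2.0 * stats.t.sf(np.abs(t_ok), df), 1.0)
        t_stat[ok] = t_ok
        p_val[ok] = p_ok
        effect[ok] = coef[1]
    z_signed = p_to_signed_z(p_val, np.sign(t_stat))
    return SiteLinkStats(
        t=t_stat, p=p_val, z_signed=z_signed, effect=effect, n=n, df=df, site=site
    )


def p_to_signed_z(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed normal deviate of a two-tailed p: ``sign * Phi^{-1}(1 - p/2)``.

    p is floored at 1e-300 so the deviate stays finite; p = 1 maps to 0 for
    either sign. NaN propagates.
    """
    p = np.asarray(p, dtype=np.float64)
    sign = np.asarray(sign, dtype=np.float64)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    mag = stats.norm.isf(np.clip(p, P_FLOOR, 1.0) / 2.0)
    return sign * mag


def liptak_combine(
    z_sites: np.ndarray, n_sites: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Stouffer combination across sites.

    ``z_sites`` is (sites, pairs); weights are sqrt of the per-site sample
    sizes, and the sum is normalized by sqrt(sum of squared weights) so the
    combined Z is N(0,1) under the null. Sites with a missing z' for a pair
    drop out of both sums; all-missing pairs stay NaN.
    """
    z_sites = np.atleast_2d(np.asarray(z_sites, dtype=np.float64))
    w = np.sqrt(np.asarray(n_sites, dtype=np.float64)).reshape(-1, 1)
    if np.any(w <= 0):
        raise ValueError("site sample sizes must be positive")
    if w.shape[0] != z_sites.shape[0]:
        raise ValueError("one weight per site required")
    finite = np.isfinite(z_sites)
    num = np.where(finite, w * z_sites, 0.0).sum(axis=0)
    den = np.sqrt(np.where(finite, w**2, 0.0).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.where(den > 0, num / den, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(combined))
    return combined, p


def bh_fdr(pvals: np.ndarray, q: float) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up.

    Returns ``(p_star, mask)``: the largest rejected p (0.0 if none) and the
    rejection mask aligned to the input (NaN p excluded, never rejected).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    pvals = np.asarray(pvals, dtype=np.float64)
    finite = np.isfinite(pvals)
    m = int(finite.sum())
    if m == 0:
        raise ValueError("no finite p-values to correct")
    ps = np.sort(pvals[finite])
    crit = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(ps <= crit)
    if below.size == 0:
        return 0.0, np.zeros_like(pvals, dtype=bool)
    p_star = float(ps[below[-1]])
    mask = finite & (pvals <= p_star)
    return p_star, mask


@dataclasses.dataclass
class ThresholdMode:
    """How pair significance is declared: ``fdr(q)``, ``uncorrected(alpha)``
    or ``uncorrected_cluster(alpha, min_cluster_voxels)``."""

    kind: str
    alpha: float
    min_cluster_voxels: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fdr", "uncorrected", "uncorrected_cluster"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha/q must be in (0, 1)")
        if self.kind == "uncorrected_cluster" and self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "ThresholdMode":
        """Parse ``fdr:0.05``, ``unc:1e-4`` or ``unc-cluster:1e-3:20``."""
        parts = text.split(":")
        if parts[0] == "fdr" and len(parts) == 2:
            return cls("fdr", float(parts[1]))
        if parts[0] == "unc" and len(parts) == 2:
            return cls("uncorrected", float(parts[1]))
        if parts[0] == "unc-cluster" and len(parts) == 3:
            return cls("uncorrected_cluster", float(parts[1]), int(parts[2]))
        raise ValueError(f"cannot parse threshold mode {text!r}")

    def __str__(self) -> str:
        if self.kind == "fdr":
            return f"fdr:{self.alpha:g}"
        if self.kind == "uncorrected":
            return f"unc:{self.alpha:g}"
        return f"unc-cluster:{self.alpha:g}:{self.min_cluster_voxels}"


def apply_threshold(
    p: np.ndarray,
    mode: ThresholdMode,
    pair_index: PairIndex | None = None,
    atlas: Atlas | None = None,
) -> tuple[np.ndarray, float | None]:
    """Significance mask for combined p-values under a threshold mode.

    Returns ``(mask, p_star)``; ``p_star`` is the attained FDR threshold for
    the fdr mode, else None. Cluster mode needs the pair index and atlas.
    """
    if mode.kind == "fdr":
        p_star, mask = bh_fdr(p, mode.alpha)
        return mask, p_star
    mask = np.isfinite(p) & (p < mode.alpha)
    if mode.kind == "uncorrected_cluster":
        if pair_index is None or atlas is None:
            raise ValueError("cluster threshold requires pair index and atlas")
        mask = cluster_filter(mask, pair_index, atlas, mode.min_cluster_voxels)
    return mask, None


def ma_score(mask: np.ndarray, pair_index: PairIndex) -> np.ndarray:
    """Per-voxel measure of association: the number of significant links
    incident to each voxel (defined for seed and non-seed voxels alike)."""
    mask = np.asarray(mask, dtype=bool)
    endpoints = pair_index.pairs[mask].ravel()
    return np.bincount(endpoints, minlength=pair_index.n_brain).astype(np.int64)


def voxel_signed_summary(
    combined_z: np.ndarray, mask: np.ndarray, pair_index: PairIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel signed link-evidence summary.

    ``S_v`` is the sum of |Z| over significant links at voxel v and the sign
    is that of the signed sum of Z over the same links (0 when no links).
    """
    mask = np.asarray(mask, dtype=bool)
    pairs = pair_index.pairs[mask]
    zz = np.asarray(combined_z, dtype=np.float64)[mask]
    n = pair_index.n_brain
    endpoints = pairs.ravel()
    s_abs = np.bincount(endpoints, weights=np.repeat(np.abs(zz), 2), minlength=n)
    s_signed = np.bincount(endpoints, weights=np.repeat(zz, 2), minlength=n)
    sign = np.sign(s_signed)
    sign[s_abs == 0.0] = 0.0
    return s_abs, sign


def _component_labels(
    voxel_mask_1d: np.ndarray, atlas: Atlas
) -> tuple[np.ndarray, int]:
    """26-connected components of a set of enumerated voxels.

    Returns per-enumerated-voxel component labels (0 outside the set) and the
    number of components.
    """
    vol = np.zeros(atlas.labels.shape, dtype=bool)
    coords = atlas.voxel_coords[voxel_mask_1d]
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    labelled, n_comp = ndimage.label(vol, structure=CONNECTIVITY_26)
    all_coords = atlas.voxel_coords
    per_voxel = labelled[all_coords[:, 0], all_coords[:, 1], all_coords[:, 2]]
    return per_voxel, int(n_comp)


def cluster_filter(
    mask: np.ndarray,
    pair_index: PairIndex,
    atlas: Atlas,
    min_cluster_voxels: int,
) -> np.ndarray:
    """Cluster-extent filter on a pair significance mask.

    Voxels with at least one significant link form 26-connected components;
    components of ``min_cluster_voxels`` or fewer voxels have all their
    incident links removed from the mask (i.e. only clusters strictly larger
    than the minimum survive).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    incident = ma_score(mask, pair_index) > 0
    comp, n_comp = _component_labels(incident, atlas)
    sizes = np.bincount(comp, minlength=n_comp + 1)
    small = np.flatnonzero(sizes <= min_cluster_voxels)
    small = small[small > 0]
    bad_voxel = np.isin(comp, small)
    pairs = pair_index.pairs
    keep = mask & ~(bad_voxel[pairs[:, 0]] | bad_voxel[pairs[:, 1]])
    return keep


@dataclasses.dataclass
class ClusterTable:
    """Region cluster table plus per-row link and voxel membership."""

    table: pd.DataFrame
    row_links: list[np.ndarray]  # significant-pair indices per row
    row_voxels: list[np.ndarray]  # enumerated voxel indices per row


def region_cluster_table(
    mask: np.ndarray,
    combined_z: np.ndarray,
    atlas: Atlas,
    pair_index: PairIndex,
    min_cluster_voxels: int = 10,
) -> ClusterTable:
    """Tabulate 26-connected components of significant voxels.

    Every voxel incident to a significant link enters the component map (so
    the seed region reports its own row, as in published cluster tables).
    Each row gives the set of region names the component occupies, its voxel
    count, the sum of |Z| over all significant links incident to it (a link
    joining two components contributes to both rows), and the world
    coordinate of the peak voxel (largest per-voxel sum of |Z|). Components
    with ``min_cluster_voxels`` voxels or fewer are suppressed.
    """
    mask = np.asarray(mask, dtype=bool)
    zz = np.asarray(combined_z, dtype=np.float64)
    columns = ["regions", "n_voxels", "sum_abs_z", "peak_x", "peak_y", "peak_z"]
    empty = ClusterTable(pd.DataFrame(columns=columns), [], [])
    if not mask.any():
        return empty
    s_abs, _ = voxel_signed_summary(zz, mask, pair_index)
    incident = s_abs > 0.0
    comp, n_comp = _component_labels(incident, atlas)
    pairs = pair_index.pairs
    sig_idx = np.flatnonzero(mask)
    comp_i = comp[pairs[sig_idx, 0]]
    comp_j = comp[pairs[sig_idx, 1]]
    rows = []
    links_out: list[np.ndarray] = []
    voxels_out: list[np.ndarray] = []
    for k in range(1, n_comp + 1):
        voxels = np.flatnonzero(comp == k)
        if voxels.size <= min_cluster_voxels:
            continue
        link_sel = sig_idx[(comp_i == k) | (comp_j == k)]
        names = sorted({atlas.region_names[int(r)] for r in atlas.voxel_labels[voxels]})
        peak = voxels[int(np.argmax(s_abs[voxels]))]
        world = atlas.voxel_to_world(peak)
        rows.append(
            {
                "regions": ", ".join(names),
                "n_voxels": int(voxels.size),
                "sum_abs_z": float(np.abs(zz[link_sel]).sum()),
                "peak_x": float(world[0]),
                "peak_y": float(world[1]),
                "peak_z": float(world[2]),
            }
        )
        links_out.append(link_sel)
        voxels_out.append(voxels)
    if not rows:
        return empty
    table = pd.DataFrame(rows, columns=columns)
    order = np.lexsort((table["regions"].to_numpy(), -table["sum_abs_z"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    return ClusterTable(
        table=table,
        row_links=[links_out[i] for i in order],
        row_voxels=[voxels_out[i] for i in order],
    )
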