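"""ROI-wise FC summaries over significant clusters and clinical correlates.

The cluster table of the primary association run defines one region-set per
row. For each patient, the mean Fisher-z FC over that row's significant
links is a scalar "ROI-wise FC"; its partial correlation with each clinical
score (covariate-adjusted within site) is combined across sites with the
same weighted Stouffer statistic used for the link tests. Only patients
enter: the scores and the medication covariate are patient measures.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import ClusterTable, liptak_combine, p_to_signed_z
from .fc import PairFCStore

__all__ = [
    "roiwise_mean_fc",
    "partial_corr",
    "combine_correlation_sites",
    "clinical_correlates",
]

logger = logging.getLogger(__name__)

DEFAULT_SCORES = ("hamd", "bdi", "illness_duration")
DEFAULT_COVARIATES = ("mean_fd", "education", "sex", "age", "medicated")


def roiwise_mean_fc(store: PairFCStore, clusters: ClusterTable) -> pd.DataFrame:
    """Per-subject mean Fisher-z FC over each cluster row's significant links.

    Returns subjects x region-sets; an entry is NaN when a subject has no
    finite z on any of the row's links. Rows with an empty link set are
    dropped with a warning.
    """
    data = {}
    for row_idx, links in enumerate(clusters.row_links):
        label = clusters.table.iloc[row_idx]["regions"]
        if links.size == 0:
            logger.warning("region-set %r has no significant links; dropped", label)
            continue
        sub = store.z[:, links].astype(np.float64)
        finite = np.isfinite(sub)
        counts = finite.sum(axis=1)
        sums = np.where(finite, sub, 0.0).sum(axis=1)
        data[label] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(data, index=pd.Index(store.subject_ids, name="subject_id"))


def partial_corr(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus intercept) and
    the residuals correlated; the two-tailed p uses
    ``t = r * sqrt((n - k - 2) / (1 - r^2))`` on n - k - 2 degrees of freedom
    with k covariates.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} samples for {k} covariates")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    res = np.column_stack([x, y]) - design @ coef
    rx, ry = res[:, 0], res[:, 1]
    # a variable explained (numerically) exactly by the covariates has no
    # residual association left: r = 0 by convention
    ss_x, ss_y = float(rx @ rx), float(ry @ ry)
    tol_x = 1e-24 * max(float(x @ x), 1e-300)
    tol_y = 1e-24 * max(float(y @ y), 1e-300)
    if ss_x <= tol_x or ss_y <= tol_y:
        return 0.0, 1.0
    denom = np.sqrt(ss_x * ss_y)
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(min(2.0 * stats.t.sf(abs(t), df), 1.0))
    return r, p


def combine_correlation_sites(
    r_sites: np.ndarray, p_sites: np.ndarray, n_sites: np.ndarray
) -> tuple[float, float]:
    """Combine per-site (r, p) partial correlations across sites.

    Each site contributes a signed deviate z' = sign(r) * Phi^{-1}(1 - p/2);
    sites are weighted by sqrt(n) as in the link combination.
    """
    r_sites = np.asarray(r_sites, dtype=np.float64)
    p_sites = np.asarray(p_sites, dtype=np.float64)
    z = p_to_signed_z(p_sites, np.sign(r_sites))
    combined, p = liptak_combine(z[:, None], np.asarray(n_sites))
    return float(combined[0]), float(p[0])


def _site_covariate_matrix(
    sub: pd.DataFrame, covariates: tuple[str, ...]
) -> np.ndarray:
    """Covariate matrix for one site, dropping within-site constants.

    A covariate that is constant within a site (e.g. medication at an
    all-medicated site) carries no information there and would make the
    design rank deficient; it is dropped with a log note.
    """
    cols = []
    for name in covariates:
        v = sub[name].to_numpy(dtype=np.float64)
        if np.unique(v).size < 2:
            logger.info(
                "covariate %r constant within site %r; dropped for this site",
                name, sub["site"].iloc[0],
            )
            continue
        cols.append(v)
    return np.column_stack(cols) if cols else np.empty((len(sub), 0))


def clinical_correlates(
    profile: pd.DataFrame,
    phenotypes: pd.DataFrame,
    scores: tuple[str, ...] = DEFAULT_SCORES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Partial correlations of ROI-wise FC with clinical scores, by site,
    combined across sites.

    Returns a long table: region_set, score, site, n, r, p plus the
    cross-site combined_Z and combined_p repeated on each site row. Patients
    only; subjects with a missing score or FC value are excluded pairwise.
    """
    patients = phenotypes[phenotypes["group"] == "patient"]
    out_rows = []
    for region_set in profile.columns:
        fc_all = profile[region_set]
        for score in scores:
            site_stats = []
            for site, sub in patients.groupby("site", sort=True):
                fc = fc_all.reindex(sub["subject_id"]).to_numpy(dtype=np.float64)
                y = sub[score].to_numpy(dtype=np.float64)
                cov = _site_covariate_matrix(sub, covariates)
                keep = np.isfinite(fc) & np.isfinite(y)
                if cov.shape[1]:
                    keep &= np.isfinite(cov).all(axis=1)
                n = int(keep.sum())
                if n <= cov.shape[1] + 2:
                    logger.warning(
                        "site %r: too few patients (%d) for %r ~ %r; skipped",
                        site, n, region_set, score,
                    )
                    continue
                r, p = partial_corr(fc[keep], y[keep], cov[keep])
                site_stats.append({"site": site, "n": n, "r": r, "p": p})
            if not site_stats:
                continue
            comb_z, comb_p = combine_correlation_sites(
                np.array([s["r"] for s in site_stats]),
                np.array([s["p"] for s in site_stats]),
                np.array([s["n"] for s in site_stats]),
            )
            for s in site_stats:
                out_rows.append(
                    {
                        "region_set": region_set,
                        "score": score,
                        "site": s["site"],
                        "n": s["n"],
                        "r": s["r"],
                        "p": s["p"],
                        "combined_Z": comb_z,
                        "combined_p": comb_p,
                    }
                )
    columns = ["region_set", "score", "site", "n", "r", "p", "combined_Z", "combined_p"]
    return pd.DataFrame(out_rows, columns=columns)
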