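"""Genome-wide association scan and LD-decay estimation.

The scan is a PC-adjusted ordinary-least-squares single-marker test:
for each polymorphic marker, ``value = intercept + PCs + dosage`` is fit
and the dosage effect is tested with a two-sided t-test.  This is a
deliberate, documented substitute for the multi-locus FarmCPU/MLM
machinery of GWAS toolkits — the focus of this package is the phenotype
derivation, not the association solver.  Population structure enters as
the top principal components of the standardized dosage matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .genotypes import GenotypeMatrix, read_genotypes  # re-export read_genotypes

__all__ = [
    "AssociationResult",
    "LDDecayCurve",
    "read_genotypes",
    "compute_pcs",
    "scan",
    "bonferroni_threshold",
    "ld_decay",
    "select_window",
]

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # p-values below this are reported at the floor


@dataclass(frozen=True)
class AssociationResult:
    """Per-marker scan results.

    ``table`` columns: marker, chrom, pos, effect, se, p, neg_log10_p,
    significant, skipped.  Monomorphic or mostly-missing markers are
    flagged ``skipped`` with NaN statistics, never p = 0.
    """

    table: pd.DataFrame
    n_taxa: int
    n_tested: int
    threshold_neg_log10: float | None = None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LDDecayCurve:
    """Mean r-squared per physical-distance bin."""

    table: pd.DataFrame  # columns: dist_mid, mean_r2, n_pairs

    def __post_init__(self):
        t = self.table
        if not t["dist_mid"].is_monotonic_increasing:
            raise ValueError("distance bins must be ordered")


def compute_pcs(genotypes: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k principal-component scores of the standardized dosages.

    Missing dosages are imputed to the marker mean; markers are centered
    at 2*p and scaled by sqrt(2*p*(1-p)); monomorphic markers are
    dropped.  The sign of each component is fixed so its
    largest-magnitude marker loading is positive, making the scores
    deterministic.  Returns a taxa-indexed DataFrame (PC1..PCk).
    """
    if genotypes.n_taxa < k + 1:
        raise ValueError(f"need >= {k + 1} taxa for {k} PCs")
    D = genotypes.dosages.copy()
    mean = np.nanmean(D, axis=0)
    idx = np.where(np.isnan(D))
    D[idx] = mean[idx[1]]
    p = mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; PCA undefined")
    Z = (D[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    Z = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(scores.shape[1]):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=pd.Index(genotypes.taxa, name="taxon"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )


def scan(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    max_missing: float = 0.5,
    chrom: str | None = None,
    min_overlap: int = 30,
) -> AssociationResult:
    """PC-adjusted OLS single-marker association scan.

    ``phenotype`` is taxon-indexed; only taxa present in both phenotype
    and genotypes are used (>= ``min_overlap`` required).  Markers that
    are monomorphic among the analyzed taxa or missing in more than
    ``max_missing`` of them are skipped.  ``chrom`` restricts the scan
    to one chromosome so chromosomes can be run individually; the
    returned Bonferroni threshold always uses the count of markers
    actually tested in this call.
    """
    common = [t for t in genotypes.taxa if t in phenotype.index]
    if len(common) < min_overlap:
        raise ValueError(
            f"only {len(common)} taxa overlap phenotype and genotypes "
            f"(need >= {min_overlap})"
        )
    geno = genotypes.subset_taxa(common)
    y = phenotype.loc[common].to_numpy(dtype=float)
    n = len(common)
    if covariates is not None:
        C = covariates.loc[common].to_numpy(dtype=float)
        X0 = np.column_stack([np.ones(n), C])
    else:
        X0 = np.ones((n, 1))
    # residualize y on the null design once; an orthonormal basis of the
    # column space (SVD-based) keeps redundant covariate columns harmless
    Q = scipy.linalg.orth(X0)
    k0 = Q.shape[1]
    y_res = y - Q @ (Q.T @ y)

    markers = geno.markers
    sel = np.ones(len(markers), dtype=bool) if chrom is None else (
        markers["chrom"].astype(str) == str(chrom)
    ).to_numpy()
    D = geno.dosages
    eff = np.full(len(markers), np.nan)
    se = np.full(len(markers), np.nan)
    pval = np.full(len(markers), np.nan)
    skipped = np.ones(len(markers), dtype=bool)
    df = n - k0 - 1
    for j in np.where(sel)[0]:
        g = D[:, j]
        miss = np.isnan(g)
        if miss.mean() > max_missing:
            continue
        if miss.any():
            m = ~miss
            Qm = scipy.linalg.orth(X0[m])
            ym = y[m] - Qm @ (Qm.T @ y[m])
            gm = g[m] - Qm @ (Qm.T @ g[m])
            dfm = m.sum() - Qm.shape[1] - 1
        else:
            ym = y_res
            gm = g - Q @ (Q.T @ g)
            dfm = df
        gss = float(gm @ gm)
        if gss < 1e-12 or dfm <= 0:
            continue  # monomorphic (after projection) or underdetermined
        b = float(gm @ ym) / gss
        resid = ym - b * gm
        sigma2 = float(resid @ resid) / dfm
        sej = np.sqrt(sigma2 / gss)
        if sej == 0.0:
            pj = P_FLOOR
        else:
            tstat = b / sej
            pj = 2.0 * scipy.stats.t.sf(abs(tstat), dfm)
            pj = max(pj, P_FLOOR)
        eff[j], se[j], pval[j], skipped[j] = b, sej, pj, False
    tested = int((~skipped).sum())
    if tested == 0:
        raise ValueError("no polymorphic markers to test")
    thr = bonferroni_threshold(tested, alpha)
    neglog = -np.log10(pval)
    out = markers[["marker", "chrom", "pos"]].copy()
    out["effect"] = eff
    out["se"] = se
    out["p"] = pval
    out["neg_log10_p"] = neglog
    out["significant"] = (~skipped) & (neglog > thr)
    out["skipped"] = skipped
    out = out[sel].reset_index(drop=True)
    log.info("scan: %d markers tested, %d significant (threshold %.4f)",
             tested, int(out["significant"].sum()), thr)
    return AssociationResult(
        table=out, n_taxa=n, n_tested=tested, threshold_neg_log10=thr
    )


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Genome-wide -log10 significance line, -log10(alpha / m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / m))


def ld_decay(
    genotypes: GenotypeMatrix,
    max_dist: int = 1_000_000,
    bin_width: int = 50_000,
) -> LDDecayCurve:
    """Mean r² between same-chromosome marker pairs, binned by distance.

    r² is the squared Pearson correlation of dosage vectors over
    pairwise-complete taxa.  Pairs farther apart than ``max_dist`` are
    ignored.
    """
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    D = genotypes.dosages
    markers = genotypes.markers
    for chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        if len(idx) < 2:
            continue
        for a_i in range(len(idx)):
            j = a_i + 1
            while j < len(idx) and pos[j] - pos[a_i] <= max_dist:
                x, z = D[:, idx[a_i]], D[:, idx[j]]
                m = ~(np.isnan(x) | np.isnan(z))
                if m.sum() >= 3:
                    xs, zs = x[m] - x[m].mean(), z[m] - z[m].mean()
                    vx, vz = float(xs @ xs), float(zs @ zs)
                    if vx > 0 and vz > 0:
                        r2 = float(xs @ zs) ** 2 / (vx * vz)
                        b = min(int((pos[j] - pos[a_i]) // bin_width), n_bins - 1)
                        sums[b] += r2
                        counts[b] += 1
                j += 1
    if counts.sum() == 0:
        raise ValueError("no qualifying marker pairs for LD decay")
    mids = (np.arange(n_bins) + 0.5) * bin_width
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    tab = pd.DataFrame({"dist_mid": mids, "mean_r2": mean_r2, "n_pairs": counts})
    return LDDecayCurve(tab[tab["n_pairs"] > 0].reset_index(drop=True))


def select_window(
    curve: LDDecayCurve, r2_threshold: float = 0.2, fallback: int = 300_000
) -> int:
    """Candidate-window halfwidth from the LD-decay curve.

    The smallest bin midpoint at which mean r² drops below the
    threshold, rounded up to the next 50 kb; if the curve never crosses,
    the fallback (default ±300 kb) is returned.
    """
    below = curve.table[curve.table["mean_r2"] < r2_threshold]
    if below.empty:
        log.warning("LD curve never crosses r2 = %.2f; using fallback %d bp",
                    r2_threshold, fallback)
        return fallback
    d = float(below["dist_mid"].iloc[0])
    return int(np.ceil(d / 50_000) * 50_000)
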