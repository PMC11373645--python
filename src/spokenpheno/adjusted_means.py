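"""Per-taxon adjusted means: BLUE, BLUP, and multinomial expected bins.

Collapses per-row phenotype signals (measured heights, similarity
scores, or ordinal bins) to one value per taxon, ready for association:

* **BLUE** — fixed-effects least squares ``value ~ taxon + replicate``;
  the per-taxon value is the estimated marginal mean (taxon effect plus
  the unweighted average over replicate effects).
* **BLUP** — REML fit of ``value ~ 1 + taxon(r) + replicate(r) + row(r)``
  with all grouping factors random; the per-taxon value is the grand
  mean plus the taxon BLUP (conditional mode), which shrinks toward the
  mean relative to raw taxon means.
* **multinomial** — ridge-stabilized multinomial logit of the bin on
  taxon and replicate; the per-taxon value is the expected bin
  ``sum_b b * P(b | taxon)`` averaged over replicates.

The REML solver works on Henderson's mixed-model equations with the
residual variance profiled out, which keeps the crossed
taxa x replicate x row design fast at field-trial size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp

__all__ = ["PhenotypeTable", "fit_blue", "fit_blup", "fit_multinomial", "reml_crossed"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenotypeTable:
    """One adjusted value per taxon, plus fit diagnostics."""

    values: pd.Series  # index: taxon
    method: str
    variance_components: dict[str, float] = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None  # per-observation fitted/residual

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("non-finite adjusted values")

    def to_tsv(self, path) -> None:
        df = self.values.rename("value").rename_axis("taxon").reset_index()
        df["method"] = self.method
        df.to_csv(path, sep="\t", index=False)


def _check_table(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    req = {"taxon", "replicate", value_col}
    if missing := req - set(table.columns):
        raise ValueError(f"observation table missing columns {sorted(missing)}")
    t = table.dropna(subset=[value_col])
    if t["taxon"].nunique() < 2:
        raise ValueError("need >= 2 taxa")
    return t


def _indicator(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def fit_blue(table: pd.DataFrame, value_col: str = "value") -> PhenotypeTable:
    """Estimated marginal means from ``value ~ taxon + replicate`` (fixed).

    Uses treatment-coded least squares; the EMM for a taxon is its
    effect plus the unweighted average of the replicate effects, which
    is invariant to the factor coding.  Requires a connected design;
    rank deficiency beyond the usual one-per-factor aliasing raises an
    error naming the factors.
    """
    t = _check_table(table, value_col)
    y = t[value_col].to_numpy(dtype=float)
    taxa, tx = np.unique(t["taxon"].to_numpy(), return_inverse=True)
    reps, rx = np.unique(t["replicate"].to_numpy(), return_inverse=True)
    n, a, r = len(y), len(taxa), len(reps)
    # treatment coding: intercept + (a-1) taxon dummies + (r-1) rep dummies
    X = np.zeros((n, 1 + (a - 1) + (r - 1)))
    X[:, 0] = 1.0
    for j in range(1, a):
        X[tx == j, j] = 1.0
    for j in range(1, r):
        X[rx == j, a - 1 + j] = 1.0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient design beyond standard aliasing: taxon and "
            "replicate are confounded (design not connected)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = beta[0]
    taxon_eff = np.concatenate([[0.0], beta[1:a]])
    rep_eff = np.concatenate([[0.0], beta[a : a + r - 1]])
    emm = mu + taxon_eff + rep_eff.mean()
    fitted = X @ beta
    diag = t[["taxon", "replicate"]].copy()
    diag["fitted"] = fitted
    diag["residual"] = y - fitted
    return PhenotypeTable(
        values=pd.Series(emm, index=taxa, name="blue"),
        method="BLUE",
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# REML for the crossed random-effects model
# ---------------------------------------------------------------------------


class RemlError(RuntimeError):
    """REML failed to converge; carries the last variance components."""

    def __init__(self, msg: str, components: dict[str, float]):
        super().__init__(msg)
        self.components = components


def reml_crossed(
    y: np.ndarray,
    factors: dict[str, np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 200,
    fixed_gammas: dict[str, float] | None = None,
):
    """REML variance components for ``y = mu + sum_f u_f + e``.

    ``factors`` maps factor name -> integer level codes per observation;
    every factor is random with its own variance.  Returns
    ``(components, mu, blups, loglik)`` where ``components`` includes
    "resid" and ``blups`` maps factor name -> per-level BLUP array.

    The profiled REML criterion is evaluated through Henderson's
    mixed-model equations: with variance ratios g_f = s2_f / s2_e and
    M the MME coefficient matrix,

        -2 lR = (n-1) log(y'Py) + log|M| + sum_f q_f log g_f + const.

    ``fixed_gammas`` pins chosen ratios (used by the closed-form
    shrinkage tests); remaining ratios are optimized by Nelder-Mead on
    the log scale.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    names = list(factors)
    Zs = []
    q = []
    for name in names:
        codes = np.asarray(factors[name])
        q.append(codes.max() + 1)
        Zs.append(_indicator(codes, q[-1]))
    Z = sp.hstack(Zs, format="csr")
    qtot = Z.shape[1]
    X = np.ones((n, 1))
    XtX = np.full((1, 1), float(n))
    XtZ = np.asarray(Z.sum(axis=0), dtype=float).reshape(1, -1)
    ZtZ = (Z.T @ Z).toarray()
    Xty = np.array([y.sum()])
    Zty = Z.T @ y
    yty = float(y @ y)
    bounds = np.array([[-12.0, 12.0]] * len(names))

    def mme(gammas: np.ndarray):
        ginv = np.concatenate([np.full(qi, 1.0 / g) for qi, g in zip(q, gammas)])
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(ginv)]])
        rhs = np.concatenate([Xty, Zty])
        cho = scipy.linalg.cho_factor(M, lower=True, check_finite=False)
        sol = scipy.linalg.cho_solve(cho, rhs, check_finite=False)
        logdetM = 2.0 * np.sum(np.log(np.diag(cho[0])))
        ypy = yty - float(rhs @ sol)
        return sol, logdetM, max(ypy, 1e-300)

    fixed_gammas = fixed_gammas or {}
    free = [i for i, nm in enumerate(names) if nm not in fixed_gammas]

    def full_gammas(theta_free: np.ndarray) -> np.ndarray:
        g = np.empty(len(names))
        for i, nm in enumerate(names):
            if nm in fixed_gammas:
                g[i] = fixed_gammas[nm]
            else:
                g[i] = np.exp(theta_free[free.index(i)])
        return np.maximum(g, 1e-12)

    neval = 0

    def neg2_reml(theta_free: np.ndarray) -> float:
        nonlocal neval
        neval += 1
        g = full_gammas(np.clip(theta_free, bounds[free, 0], bounds[free, 1]))
        try:
            _, logdetM, ypy = mme(g)
        except np.linalg.LinAlgError:
            return np.inf
        p = 1
        crit = (n - p) * np.log(ypy) + logdetM
        crit += sum(qi * np.log(gi) for qi, gi in zip(q, g))
        return crit

    if free:
        x0 = np.zeros(len(free))
        res = scipy.optimize.minimize(
            neg2_reml,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": max_iter * len(free) * 20},
        )
        theta = np.clip(res.x, bounds[free, 0], bounds[free, 1])
        gam = full_gammas(theta)
        if not res.success and not np.isfinite(res.fun):
            comps = {nm: float(g) for nm, g in zip(names, gam)}
            raise RemlError(f"REML did not converge: {res.message}", comps)
        converged = res.success or np.isfinite(res.fun)
    else:
        gam = full_gammas(np.array([]))
        converged = True

    sol, logdetM, ypy = mme(gam)
    sigma2_e = ypy / (n - 1)
    mu = float(sol[0])
    blups, off = {}, 1
    for nm, qi in zip(names, q):
        blups[nm] = sol[off : off + qi]
        off += qi
    components = {nm: float(g * sigma2_e) for nm, g in zip(names, gam)}
    components["resid"] = float(sigma2_e)
    # constant-data degenerate case: everything collapses to the mean
    if yty - n * (y.mean() ** 2) < 1e-12 * max(1.0, yty):
        components = {k: 0.0 for k in components}
        for nm in blups:
            blups[nm] = np.zeros_like(blups[nm])
    loglik = -0.5 * neg2_reml(np.log(np.maximum(gam[free], 1e-300))) if free else np.nan
    if not converged:
        raise RemlError("REML did not converge", components)
    return components, mu, blups, loglik


def fit_blup(
    table: pd.DataFrame,
    value_col: str = "value",
    tol: float = 1e-8,
    max_iter: int = 200,
    fixed_gammas: dict[str, float] | None = None,
) -> PhenotypeTable:
    """REML BLUPs from ``value ~ 1 + taxon(r) + replicate(r) + row(r)``.

    Per-taxon value = grand mean + taxon BLUP.  Variance components are
    constrained non-negative; BLUP deviations shrink toward zero
    relative to raw-mean deviations whenever residual variance is
    positive.
    """
    t = _check_table(table, value_col)
    counts = t.groupby("taxon").size()
    if (counts < 2).all():
        # still fit, but components may be weakly identified
        log.warning("no taxon has >= 2 observations; variance components weakly identified")
    y = t[value_col].to_numpy(dtype=float)
    factors = {}
    taxa, factors["taxon"] = np.unique(t["taxon"].to_numpy(), return_inverse=True)
    _, factors["replicate"] = np.unique(t["replicate"].to_numpy(), return_inverse=True)
    if "row" in t.columns:
        _, factors["row"] = np.unique(t["row"].to_numpy(), return_inverse=True)
    components, mu, blups, _ = reml_crossed(
        y, factors, tol=tol, max_iter=max_iter, fixed_gammas=fixed_gammas
    )
    values = pd.Series(mu + blups["taxon"], index=taxa, name="blup")
    return PhenotypeTable(values=values, method="BLUP", variance_components=components)


def fit_multinomial(
    table: pd.DataFrame,
    value_col: str = "bin",
    ridge: float = 1e-4,
    mode: str = "expected",
) -> PhenotypeTable:
    """Multinomial logit of the bin on taxon + replicate, per-taxon summary.

    ``mode="expected"`` returns the expected bin sum_b b * P(b | taxon)
    averaged over replicate levels (a real value in [0, 7]);
    ``mode="modal"`` returns the most probable bin instead.  A small
    ridge penalty (default 1e-4) keeps the per-taxon parameters finite
    under separation.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import OneHotEncoder

    t = _check_table(table, value_col)
    bins = t[value_col].to_numpy(dtype=int)
    classes = np.unique(bins)
    taxa = np.unique(t["taxon"].to_numpy())
    if len(classes) < 2:
        warnings.warn("single observed bin; returning that bin for all taxa")
        return PhenotypeTable(
            values=pd.Series(float(classes[0]), index=taxa, name="multinomial"),
            method="multinomial-expected-bin",
        )
    enc = OneHotEncoder(sparse_output=False, handle_unknown="error")
    X = enc.fit_transform(t[["taxon", "replicate"]])
    clf = LogisticRegression(C=1.0 / ridge, max_iter=5000, tol=1e-7)
    clf.fit(X, bins)
    reps = np.unique(t["replicate"].to_numpy())
    grid = pd.DataFrame(
        [(tx, rp) for tx in taxa for rp in reps], columns=["taxon", "replicate"]
    )
    P = clf.predict_proba(enc.transform(grid))  # (a*r) x classes
    P = P.reshape(len(taxa), len(reps), -1).mean(axis=1)  # average over reps
    if mode == "expected":
        vals = P @ clf.classes_.astype(float)
    elif mode == "modal":
        vals = clf.classes_[np.argmax(P, axis=1)].astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PhenotypeTable(
        values=pd.Series(vals, index=taxa, name="multinomial"),
        method="multinomial-expected-bin",
    )
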