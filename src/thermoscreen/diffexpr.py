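"""Temperature-only differential expression under a nested NB log-linear model.

The model for gene counts is log mu_ijk = l_i + d_ij + t_ik: a per-locality
intercept, a developmental-stage effect nested in locality, and a
temperature effect nested in locality, with reference-level constraints
(d_{i,36} = 0, t_{i,20} = 0) so t_{i,25} is the within-locality temperature
contrast. Counts are negative binomial with per-gene dispersion phi
(variance mu + phi mu^2). Per gene and locality, a 1-df likelihood-ratio
test compares the full model against the model with that locality's
temperature term removed, and Benjamini-Hochberg adjustment is applied
within locality.

Fitting is an in-house iteratively reweighted least squares, vectorized
across genes (all genes share one design matrix); dispersion is estimated
by maximizing the Cox-Reid adjusted profile likelihood, first jointly
(common dispersion), then per gene with shrinkage toward the common curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ModelSpec

_MIN_PHI = 1e-6
_MAX_PHI = 10.0


# ---------------------------------------------------------------- CPM & filters

def cpm(counts, lib_sizes) -> np.ndarray:
    """Counts per million: count * 1e6 / library size."""
    counts = np.asarray(counts, dtype=float)
    lib = np.asarray(lib_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e6 / lib


def filter_low_expression(
    cm: CountMatrix, min_cpm: float = 0.25, min_samples: int = 6
) -> pd.Index:
    """Genes with CPM >= min_cpm in at least min_samples samples (inclusive).

    The default keeps genes represented in at least two experimental
    conditions (3 replicates each) at a minimal expression level.
    """
    mat = cpm(cm.counts.to_numpy(), cm.lib_sizes.to_numpy())
    keep = (mat >= min_cpm).sum(axis=1) >= min_samples
    return cm.counts.index[keep]


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Relative-log-expression (median-of-ratios) size factors.

    The reference expression of a gene is its geometric mean across
    samples, computed over genes positive in every sample; each sample's
    factor is the median ratio of its counts to the reference. Factors
    absorb sequencing depth: scaling one sample's counts scales its factor.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    sub = mat[positive]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def offset_from_size_factors(lib_sizes, size_factors=None) -> np.ndarray:
    """Log effective library size used as the GLM offset.

    RLE factors already absorb depth, so the offset is log(size_factor)
    plus the log geometric-mean library size (a constant that keeps the
    intercepts on the scale of raw counts). Without size factors the raw
    library sizes are used.
    """
    lib = np.asarray(lib_sizes, dtype=float)
    if size_factors is None:
        return np.log(lib)
    sf = np.asarray(size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log(sf) + np.mean(np.log(lib))


# ---------------------------------------------------------------- NB GLM core

def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Negative binomial deviance per gene (rows of y/mu)."""
    y = np.atleast_2d(y)
    mu = np.atleast_2d(mu)
    phi = np.broadcast_to(np.atleast_1d(np.maximum(phi, _MIN_PHI))[:, None], y.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        term2 = (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """NB log-likelihood per gene."""
    y = np.atleast_2d(y)
    mu = np.atleast_2d(mu)
    phi = np.broadcast_to(np.atleast_1d(np.maximum(phi, _MIN_PHI))[:, None], y.shape)
    r = 1.0 / phi
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    ).sum(axis=1)


@dataclass
class GlmFit:
    """Vectorized NB GLM fit: per-gene coefficients over a shared design."""

    coef: pd.DataFrame          # genes x coefficients
    mu: np.ndarray              # genes x samples fitted means
    deviance: np.ndarray        # per gene
    phi: np.ndarray             # per-gene dispersion used
    converged: np.ndarray       # per-gene bool
    ok: np.ndarray              # finite, usable fits
    design: pd.DataFrame
    offset: np.ndarray


def _irls(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
    tol: float = 1e-8, max_iter: int = 100,
):
    """IRLS for the NB log-link GLM, all genes at once.

    Stops when the relative deviance change drops below ``tol``.
    Returns (beta, mu, deviance, converged).
    """
    G, n = Y.shape
    p = X.shape[1]
    phi = np.maximum(np.broadcast_to(phi, (G,)).astype(float), _MIN_PHI)
    mu = np.maximum(Y, 0.0) + np.mean(Y, axis=1, keepdims=True) * 0.1 + 0.1
    eta = np.log(mu)
    beta = np.zeros((G, p))
    dev = nb_deviance(Y, mu, phi)
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        W = mu[active] / (1.0 + phi[active, None] * mu[active])  # working weights
        z = eta[active] - offset[None, :] + (Y[active] - mu[active]) / mu[active]
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + ridge
        XtWz = np.einsum("ni,gn->gi", X, W * z)
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack([np.linalg.lstsq(A, b, rcond=None)[0] for A, b in zip(XtWX, XtWz)])
        beta[active] = beta_new
        eta_new = np.clip(beta_new @ X.T + offset[None, :], -30, 30)
        mu_new = np.exp(eta_new)
        dev_new = nb_deviance(Y[active], mu_new, phi[active])
        rel = np.abs(dev[active] - dev_new) / (np.abs(dev_new) + 0.1)
        eta[active] = eta_new
        mu[active] = mu_new
        dev[active] = dev_new
        done = np.zeros(G, dtype=bool)
        done[np.flatnonzero(active)[rel < tol]] = True
        converged |= done
    return beta, mu, dev, converged


def fit_nested_model(
    counts: pd.DataFrame,
    model: ModelSpec,
    samples: pd.DataFrame,
    size_factors: pd.Series | None = None,
    dispersions=0.1,
    design: pd.DataFrame | None = None,
) -> GlmFit:
    """Fit the nested NB model to every gene.

    ``dispersions`` is a scalar or per-gene array of NB dispersions.
    Genes whose fit is non-finite are flagged (``ok`` False) and excluded
    from downstream testing.
    """
    X_df = model.design_matrix(samples) if design is None else design
    if np.linalg.matrix_rank(X_df.to_numpy()) < X_df.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = counts.to_numpy(dtype=float)
    offset = offset_from_size_factors(
        counts.sum(axis=0).to_numpy(),
        None if size_factors is None else size_factors.loc[counts.columns].to_numpy(),
    )
    phi = np.broadcast_to(np.asarray(dispersions, dtype=float), (Y.shape[0],))
    beta, mu, dev, converged = _irls(Y, X_df.to_numpy(), offset, phi)
    ok = np.isfinite(beta).all(axis=1) & np.isfinite(dev)
    coef = pd.DataFrame(beta, index=counts.index, columns=X_df.columns)
    return GlmFit(coef, mu, dev, np.asarray(phi), converged, ok, X_df, offset)


# ---------------------------------------------------------------- dispersion

def _apl(Y, X, offset, phi_scalar) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at a common phi."""
    G = Y.shape[0]
    phi = np.full(G, max(phi_scalar, _MIN_PHI))
    beta, mu, _, _ = _irls(Y, X, offset, phi)
    ll = nb_loglik(Y, mu, phi)
    W = mu / (1.0 + phi[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-10 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet


def estimate_dispersion(
    counts: pd.DataFrame,
    model: ModelSpec,
    samples: pd.DataFrame,
    size_factors: pd.Series | None = None,
    prior_df: float = 10.0,
    grid_size: int = 49,
) -> tuple[float, pd.Series]:
    """Common and tagwise NB dispersions.

    The common dispersion maximizes the summed Cox-Reid adjusted profile
    likelihood over genes. Tagwise values maximize, per gene on a log-phi
    grid, APL_g(phi) + prior_df * mean-gene APL(phi): a weighted compromise
    between the gene's own likelihood and the common curve, with
    ``prior_df`` playing the role of prior genes'-worth of information.
    prior_df = inf returns the common value for every gene.
    """
    X = model.design_matrix(samples).to_numpy()
    Y = counts.to_numpy(dtype=float)
    offset = offset_from_size_factors(
        counts.sum(axis=0).to_numpy(),
        None if size_factors is None else size_factors.loc[counts.columns].to_numpy(),
    )

    res = minimize_scalar(
        lambda lp: -float(_apl(Y, X, offset, np.exp(lp)).sum()),
        bounds=(np.log(_MIN_PHI), np.log(_MAX_PHI)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    common = float(np.exp(res.x))

    if np.isinf(prior_df):
        tagwise = np.full(Y.shape[0], common)
        return common, pd.Series(tagwise, index=counts.index, name="dispersion")

    log_grid = np.linspace(np.log(_MIN_PHI), np.log(_MAX_PHI), grid_size)
    apl_grid = np.stack([_apl(Y, X, offset, g) for g in np.exp(log_grid)], axis=1)
    score = apl_grid + prior_df * apl_grid.mean(axis=0)[None, :]
    best = np.argmax(score, axis=1)
    # parabolic refinement of the grid argmax on the log-phi scale
    log_phi = log_grid[best].copy()
    interior = (best > 0) & (best < grid_size - 1)
    idx = np.flatnonzero(interior)
    k = best[idx]
    y0, y1, y2 = score[idx, k - 1], score[idx, k], score[idx, k + 1]
    denom = y0 - 2 * y1 + y2
    step = log_grid[1] - log_grid[0]
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    log_phi[idx] = log_grid[k] + np.clip(shift, -1, 1) * step
    tagwise = np.exp(log_phi)
    return common, pd.Series(tagwise, index=counts.index, name="dispersion")


# ---------------------------------------------------------------- testing

def test_temperature_effect(
    counts: pd.DataFrame,
    model: ModelSpec,
    samples: pd.DataFrame,
    locality: str,
    size_factors: pd.Series | None = None,
    dispersions=0.1,
    alpha: float = 0.05,
    full_fit: GlmFit | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of the temperature effect within one locality.

    Compares the full nested model against the reduced model with
    t_{locality,.} removed (1 df for two temperatures); BH adjustment is
    applied across genes within the locality. Returns a DataFrame indexed
    by gene with log2FC (25 vs 20), LR statistic, p, padj and the DE flag.
    Genes with unusable fits carry NaN statistics and a False flag.
    """
    if full_fit is None:
        full_fit = fit_nested_model(counts, model, samples, size_factors, dispersions)
    drop = model.temperature_coefs(locality)
    reduced_design = full_fit.design.drop(columns=drop)
    reduced = fit_nested_model(
        counts, model, samples, size_factors, dispersions, design=reduced_design
    )
    lr = np.maximum(reduced.deviance - full_fit.deviance, 0.0)
    df = len(drop)
    ok = full_fit.ok & reduced.ok
    pvals = np.where(ok, chi2.sf(lr, df), np.nan)
    padj = np.full_like(pvals, np.nan)
    if ok.any():
        padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    tcoef = [c for c in drop if c.endswith("25")]
    log2fc = full_fit.coef[tcoef[0]].to_numpy() / np.log(2.0) if tcoef else np.nan
    out = pd.DataFrame(
        {
            "locality": locality,
            "log2fc": log2fc,
            "lr_stat": np.where(ok, lr, np.nan),
            "pvalue": pvals,
            "padj": padj,
            "de": np.where(ok, padj <= alpha, False).astype(bool),
        },
        index=counts.index,
    )
    out.index.name = "gene"
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------- MDS

def classical_mds(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top-k coordinates (eigenvalues clipped at zero). Sign convention: each
    dimension is flipped so its first non-zero coordinate is positive.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)[None, :]
    for dim in range(coords.shape[1]):
        col = coords[:, dim]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, dim] = -col
    return coords


def log_cpm(counts: pd.DataFrame, size_factors: pd.Series | None = None, prior: float = 2.0):
    """log2 CPM with a prior count, on effective (size-factor) library sizes."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if size_factors is not None:
        sf = size_factors.loc[counts.columns].to_numpy()
        lib = sf * np.exp(np.mean(np.log(lib)))
    mat = counts.to_numpy(dtype=float)
    return np.log2((mat + prior) * 1e6 / (lib[None, :] + 2 * prior))


def mds_logfc(
    counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
    top_k: int = 500,
    prior: float = 2.0,
) -> pd.DataFrame:
    """2-D MDS of samples on leading pairwise log-fold-changes.

    The distance between two samples is the root-mean-square of the top_k
    largest absolute log2 differences of normalized log-CPM between them
    (the genes driving each comparison are chosen pairwise), embedded by
    classical MDS.
    """
    if counts.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    lc = log_cpm(counts, size_factors, prior)
    k = min(top_k, lc.shape[0])
    n = lc.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (lc[:, i] - lc[:, j]) ** 2
            top = np.partition(diff2, len(diff2) - k)[len(diff2) - k:]
            D[i, j] = D[j, i] = np.sqrt(top.mean())
    coords = classical_mds(D, k=2)
    return pd.DataFrame(coords, index=counts.columns, columns=["dim1", "dim2"])
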