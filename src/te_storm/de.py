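"""Negative-binomial differential expression for paired and unpaired contrasts.

Per-locus counts are modeled as NB with a log link and offsets
``log(N_k * f_k)`` (library size times TMM factor).  The paired contrast
uses a subject blocking factor plus a condition term (no interaction); the
unpaired contrasts use a two-group model.  Dispersion is estimated on an
adjusted profile likelihood (Cox-Reid correction for the fitted
coefficients) over a log-grid, with per-locus (tagwise) values shrunk
toward the common value by a prior weight.  Condition effects are tested
by likelihood ratio against the nested reduced model, chi-square reference,
BH-adjusted across retained loci.

All model fitting is vectorized across loci: one IRLS sweep updates every
locus simultaneously against the shared design matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TEStormError, UsageError
from .normalize import ExpressionMatrix, expression_filter, logcpm, tmm_factors

LN2 = np.log(2.0)

CONTRAST_CONDITIONS = {
    "pre_vs_post": ("Converter_pre", "Converter_post"),
    "pre_vs_nc": ("Converter_pre", "NC"),
    "nc_vs_post": ("NC", "Converter_post"),
}

PAIRED_DEFAULT = {"pre_vs_post": True, "pre_vs_nc": False, "nc_vs_post": False}


@dataclass
class DesignSpec:
    """Contrast definition: which conditions, and whether subjects block."""

    contrast: str
    paired: bool
    conditions: tuple[str, str]
    covariates: tuple[str, ...] = ()

    @classmethod
    def for_contrast(cls, contrast: str, paired: bool | None = None,
                     covariates: tuple[str, ...] = ()) -> "DesignSpec":
        if contrast not in CONTRAST_CONDITIONS:
            raise UsageError(f"unknown contrast {contrast!r}")
        if paired is None:
            paired = PAIRED_DEFAULT[contrast]
        return cls(contrast=contrast, paired=paired,
                   conditions=CONTRAST_CONDITIONS[contrast], covariates=covariates)


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    prior_df: float


@dataclass
class NBFit:
    """Vectorized NB GLM fit: one row of coefficients per locus."""

    beta: np.ndarray        # (G, p)
    mu: np.ndarray          # (G, n)
    loglik: np.ndarray      # (G,)
    converged: np.ndarray   # (G,) bool
    degenerate: np.ndarray  # (G,) bool, all-zero loci
    design: np.ndarray      # (n, p)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row sums of the NB log-pmf; Poisson limit below phi = 1e-8."""
    mu = np.maximum(mu, 1e-10)
    phi_arr = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)),
                              (y.shape[0],)).copy()
    out = np.empty(y.shape[0])
    pois = phi_arr < 1e-8
    if pois.any():
        out[pois] = stats.poisson.logpmf(y[pois], mu[pois]).sum(axis=1)
    if (~pois).any():
        r = 1.0 / phi_arr[~pois][:, None]
        p = r / (r + mu[~pois])
        out[~pois] = stats.nbinom.logpmf(y[~pois], r, p).sum(axis=1)
    return out


def fit_nb_glm(
    counts: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    dispersion,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NBFit:
    """IRLS fit of a per-locus NB log-linear model with shared design.

    ``counts`` is loci x samples, ``design`` samples x coefficients,
    ``offset`` per sample (log effective library size).  Iterates until the
    per-locus score norm falls below ``tol`` or ``max_iter`` sweeps.
    All-zero loci are flagged degenerate with zero coefficients.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise UsageError("design matrix is not full rank")
    phi = np.broadcast_to(np.atleast_1d(np.asarray(dispersion, dtype=float)),
                          (G,)).copy()
    degenerate = y.sum(axis=1) == 0

    beta = np.zeros((G, p))
    mu = np.maximum(y, 0.0) + np.maximum(y.mean(axis=1, keepdims=True), 0.5) / 2.0
    eta = np.log(mu) - offset[None, :]
    converged = np.zeros(G, dtype=bool)
    active = ~degenerate
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        mu_a = np.exp(np.clip(eta[idx] + offset[None, :], -30, 30))
        W = mu_a / (1.0 + phi[idx, None] * mu_a)
        z = eta[idx] + (y[idx] - mu_a) / mu_a
        XtWX = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True) + ridge
        XtWz = np.einsum("gn,np,gn->gp", W, X, z, optimize=True)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        # step-halving to keep the likelihood finite
        step = beta_new - beta[idx]
        beta[idx] = beta[idx] + step
        eta[idx] = beta[idx] @ X.T
        mu_a = np.exp(np.clip(eta[idx] + offset[None, :], -30, 30))
        grad = np.einsum("gn,np->gp", (y[idx] - mu_a) / (1.0 + phi[idx, None] * mu_a),
                         X, optimize=True)
        done = np.max(np.abs(grad), axis=1) < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    mu = np.exp(np.clip(eta + offset[None, :], -30, 30))
    mu[degenerate] = 1e-10
    beta[degenerate] = 0.0
    ll = nb_loglik(y, mu, phi)
    return NBFit(beta=beta, mu=mu, loglik=ll,
                 converged=converged | degenerate, degenerate=degenerate,
                 design=X)


def _apl_matrix(
    y: np.ndarray, mu: np.ndarray, X: np.ndarray, phi_grid: np.ndarray
) -> np.ndarray:
    """Adjusted profile log-likelihood, loci x grid, at fixed fitted means."""
    G, n = y.shape
    p = X.shape[1]
    X2 = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    apl = np.empty((G, len(phi_grid)))
    for j, phi in enumerate(phi_grid):
        ll = nb_loglik(y, mu, phi)
        W = mu / (1.0 + phi * mu)
        A = (W @ X2).reshape(G, p, p) + 1e-10 * np.eye(p)
        _, logdet = np.linalg.slogdet(A)
        apl[:, j] = ll - 0.5 * logdet
    return apl


def estimate_dispersion(
    counts: np.ndarray | pd.DataFrame,
    design: np.ndarray,
    offset: np.ndarray,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> DispersionEstimate:
    """Common and tagwise NB dispersion by adjusted profile likelihood.

    The common value maximizes the summed Cox-Reid adjusted profile
    likelihood over a log-grid spanning 1e-4 to 4, given means fitted
    under the full design (two rounds: Poisson means, then means refit at
    the first-round common value).  Tagwise values maximize the per-locus
    adjusted likelihood penalized toward the common curve with weight
    ``prior_df``.
    """
    index = counts.index if isinstance(counts, pd.DataFrame) else None
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n - p < 2:
        raise UsageError(
            f"only {n - p} residual degrees of freedom; at least 2 are needed — "
            "reduce the model or add samples"
        )
    if grid is None:
        grid = np.logspace(-4, np.log10(4.0), 61)
    keep = y.sum(axis=1) > 0
    common = grid[0]
    apl = np.full((y.shape[0], len(grid)), 0.0)
    mu = None
    for _ in range(2):
        fit = fit_nb_glm(y[keep], X, offset, common, max_iter=50)
        mu = fit.mu
        apl_k = _apl_matrix(y[keep], mu, X, grid)
        common = float(grid[np.argmax(apl_k.sum(axis=0))])
    apl[keep] = apl_k
    apl_bar = apl_k.mean(axis=0)
    score = apl + prior_df * apl_bar[None, :]
    tag = grid[np.argmax(score, axis=1)]
    tag[~keep] = common
    tagwise = pd.Series(tag, index=index, name="dispersion")
    return DispersionEstimate(common=common, tagwise=tagwise, prior_df=prior_df)


def lrt(
    full: NBFit,
    reduced: NBFit,
) -> pd.DataFrame:
    """Likelihood-ratio test of nested NB GLM fits, chi-square reference."""
    df = full.beta.shape[1] - reduced.beta.shape[1]
    if df <= 0:
        raise UsageError("reduced model must be nested in (smaller than) full")
    lr = 2.0 * (full.loglik - reduced.loglik)
    if (lr < -1e-6).any():
        worst = float(lr.min())
        raise TEStormError(
            f"negative likelihood ratio ({worst:.3g}): fits did not converge"
        )
    lr = np.clip(lr, 0.0, None)
    p = stats.chi2.sf(lr, df)
    p[~(full.converged & reduced.converged)] = np.nan
    return pd.DataFrame({"LR": lr, "p": p})


def bh_adjust(p: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg, NaN-safe (NaNs stay NaN, excluded from ranking)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def build_design(
    meta: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Full and reduced design matrices for the contrast's samples.

    Returns (X_full, X_reduced, meta_subset).  The condition indicator is 1
    for the contrast's *second* condition, so the tested coefficient is the
    log fold-change of second over first.  For a paired design every
    retained subject contributes exactly one sample per condition; subjects
    with a missing condition are dropped with a warning.
    """
    first, second = spec.conditions
    sub = meta[meta["group"].isin([first, second])].copy()
    if spec.paired:
        ok_subjects = []
        for subj, grp in sub.groupby("subject_id"):
            conds = set(grp["group"])
            if conds == {first, second} and len(grp) == 2:
                ok_subjects.append(subj)
            else:
                warnings.warn(f"subject {subj} lacks a complete pair; dropped")
        sub = sub[sub["subject_id"].isin(ok_subjects)]
    sub = sub.sort_values(["subject_id", "group"]).reset_index(drop=True)
    if sub.empty or sub["group"].nunique() < 2:
        raise UsageError(f"contrast {spec.contrast}: need samples of both conditions")
    cond = (sub["group"] == second).astype(float).to_numpy()
    cols = [np.ones(len(sub))]
    if spec.paired:
        subjects = sorted(sub["subject_id"].unique())
        for s in subjects[1:]:
            cols.append((sub["subject_id"] == s).astype(float).to_numpy())
    for cov in spec.covariates:
        v = sub[cov]
        if v.dtype.kind in "if":
            cols.append(((v - v.mean()) / (v.std() or 1.0)).to_numpy())
        else:
            for level in sorted(v.unique())[1:]:
                cols.append((v == level).astype(float).to_numpy())
    X_red = np.column_stack(cols)
    X_full = np.column_stack(cols + [cond])
    return X_full, X_red, sub


def classify_de(
    results: pd.DataFrame,
    p_max: float = 0.01,
    lfc_min: float = 1.5,
    two_sided: bool = True,
) -> tuple[set[str], set[str]]:
    """Up/down calls at nominal p < p_max and |log2FC| >= lfc_min.

    ``two_sided=False`` restricts calls to the up direction only.  A
    ``direction`` column (up/down/ns) is written onto ``results`` in place.
    """
    p = results["p"]
    lfc = results["logFC"]
    up = set(results.index[(p < p_max) & (lfc >= lfc_min)])
    down = set(results.index[(p < p_max) & (lfc <= -lfc_min)]) if two_sided else set()
    results["direction"] = "ns"
    results.loc[sorted(up), "direction"] = "up"
    results.loc[sorted(down), "direction"] = "down"
    return up, down


def run_de(
    em: ExpressionMatrix,
    contrast: str,
    paired: bool | None = None,
    covariates: tuple[str, ...] = (),
    min_cpm: float = 1.0,
    min_samples: int = 2,
    prior_df: float = 10.0,
    common_dispersion: bool = False,
    p_max: float = 0.01,
    lfc_min: float = 1.5,
) -> dict:
    """Full DE analysis of one contrast; the pipeline's central computation.

    Filters to expressed loci, computes TMM offsets, estimates dispersion,
    fits full/reduced NB GLMs, and returns the per-locus results table
    (logFC, logCPM, LR, p, fdr, direction) with the supporting objects.
    """
    spec = DesignSpec.for_contrast(contrast, paired, covariates)
    X_full, X_red, sub = build_design(em.meta, spec)
    counts = em.counts[sub["sample_id"].tolist()]
    retained = expression_filter(counts, min_cpm, min_samples)
    counts = counts.loc[retained]
    norm = tmm_factors(counts)
    offset = np.log(counts.sum(axis=0).to_numpy() *
                    norm.factors[counts.columns].to_numpy())
    disp = estimate_dispersion(counts, X_full, offset, prior_df=prior_df)
    phi = (np.full(len(counts), disp.common)
           if common_dispersion else disp.tagwise.to_numpy())
    full = fit_nb_glm(counts.to_numpy(), X_full, offset, phi)
    red = fit_nb_glm(counts.to_numpy(), X_red, offset, phi)
    stats_df = lrt(full, red)
    lc = logcpm(counts, norm)
    results = pd.DataFrame({
        "logFC": full.beta[:, -1] / LN2,
        "logCPM": lc.mean(axis=1).to_numpy(),
        "LR": stats_df["LR"].to_numpy(),
        "p": stats_df["p"].to_numpy(),
    }, index=counts.index)
    results["fdr"] = bh_adjust(results["p"])
    up, down = classify_de(results, p_max=p_max, lfc_min=lfc_min)
    return {
        "results": results, "up": up, "down": down, "design": spec,
        "dispersion": disp, "norm": norm, "retained": retained,
        "samples": sub, "n_converged": int(full.converged.sum()),
    }


# ---------------------------------------------------------------------------
# PCA-based QC

def pca_qc(
    logcpm_matrix: pd.DataFrame,
    groups: pd.Series,
    n_components: int = 2,
    scale: bool = False,
) -> dict:
    """PCA of samples over the given loci, with a group-separation score.

    Returns component scores (samples x components), explained variance
    ratios, and a silhouette-style separation score; no decision is made.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    Xs = logcpm_matrix.T  # samples x loci
    if Xs.shape[0] < 3:
        raise UsageError("PCA QC needs at least 3 samples")
    vals = Xs.to_numpy(dtype=float)
    if np.allclose(vals.std(axis=0), 0):
        warnings.warn("constant matrix: all PCA scores are zero")
        scores = np.zeros((Xs.shape[0], n_components))
        return {"scores": pd.DataFrame(scores, index=Xs.index),
                "explained_variance_ratio": np.zeros(n_components),
                "separation": 0.0}
    if scale:
        sd = vals.std(axis=0)
        vals = (vals - vals.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    k = min(n_components, min(vals.shape) - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(vals)
    groups = groups.loc[Xs.index]
    sep = np.nan
    if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
        sep = float(silhouette_score(scores, groups.to_numpy()))
    frame = pd.DataFrame(scores, index=Xs.index,
                         columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    return {"scores": frame,
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "separation": sep}


def age_association(scores: pd.DataFrame, age: pd.Series) -> pd.DataFrame:
    """Linear regression of each component on age (the null-covariate check)."""
    rows = []
    age = age.loc[scores.index].astype(float)
    for col in scores.columns:
        res = stats.linregress(age.to_numpy(), scores[col].to_numpy())
        rows.append({"component": col, "slope": res.slope,
                     "r": res.rvalue, "p": res.pvalue})
    return pd.DataFrame(rows)
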