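"""Whole-genome prediction models.

Covers the model battery used to rank clonal candidates from marker data:

* :func:`gblup_fit` — kernel BLUP with any combination of additive (G),
  dominance (D), epistatic (GG, GD) and single-step (H) relationship
  matrices, plus optional fixed covariates (genome-wide heterozygosity,
  GWAS-selected SNP dosages),
* :func:`rrblup_fit` — ridge-regression BLUP with the shrinkage level from
  an exact spectral REML (an independent route from :func:`gblup_fit`,
  related to it by the GBLUP–rrBLUP equivalence theorem),
* :func:`bayes_fit` — single-site Gibbs samplers for the Bayesian alphabet
  (BRR, Bayesian Lasso, BayesA, BayesB, BayesC),
* :func:`rkhs_fit` — Gaussian-kernel reproducing kernel Hilbert space
  regression fitted as a Bayesian kernel BLUP,
* :func:`ml_fit` — random-forest and radial-kernel support-vector
  adapters (scikit-learn),
* :func:`gwas_scan` / :func:`gs_with_fixed_snps` — EMMA-style single-locus
  mixed linear model scan and the GBLUP + fixed-SNP ("G+S") model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genorel import GenotypeMatrix, RelationshipMatrix
from .mixedmodel import reml_core, spectral_reml

__all__ = [
    "KernelSet",
    "GEBVResult",
    "GwasScan",
    "gblup_fit",
    "rrblup_fit",
    "bayes_fit",
    "rkhs_fit",
    "ml_fit",
    "gwas_scan",
    "gs_with_fixed_snps",
    "centered_dosages",
]

BAYES_METHODS = ("BRR", "BL", "BayesA", "BayesB", "BayesC")


@dataclass
class KernelSet:
    """Ordered kernels sharing one id universe, plus optional fixed covariates."""

    kernels: list[tuple[str, RelationshipMatrix]]
    fixed_covariates: pd.DataFrame | None = None  # indexed by genotype id

    def __post_init__(self) -> None:
        labels = [lb for lb, _ in self.kernels]
        if len(set(labels)) != len(labels):
            raise ValueError("kernel labels must be unique")
        ids0 = self.kernels[0][1].ids
        for lb, K in self.kernels[1:]:
            if not np.array_equal(K.ids, ids0):
                raise ValueError(f"kernel {lb!r} has a different id universe")

    @property
    def ids(self) -> np.ndarray:
        return self.kernels[0][1].ids


@dataclass
class GEBVResult:
    model_label: str
    gebv: pd.Series
    kernel_blups: dict[str, pd.Series] = field(default_factory=dict)
    varcomps: dict[str, float] = field(default_factory=dict)
    fixed_effects: pd.Series | None = None
    marker_effects: pd.Series | None = None
    posterior_sd: pd.Series | None = None
    n_retained: int | None = None
    loglik: float | None = None
    converged: bool = True


@dataclass
class GwasScan:
    table: pd.DataFrame  # marker_id, chrom, pos, effect, se, p
    p_threshold: float

    @property
    def selected(self) -> np.ndarray:
        return self.table.loc[self.table["p"] < self.p_threshold, "marker_id"].to_numpy()


def _as_series(blues) -> pd.Series:
    if isinstance(blues, pd.DataFrame):
        if {"genotype", "blue"} <= set(blues.columns):
            s = blues.set_index("genotype")["blue"]
        else:
            raise ValueError("blues DataFrame needs 'genotype' and 'blue' columns")
    else:
        s = pd.Series(blues)
    return s.dropna().astype(float)


def centered_dosages(G: GenotypeMatrix) -> np.ndarray:
    """VanRaden-centered dosages W = X − 2p (panel allele frequencies)."""
    if np.isnan(G.dosages).any():
        raise ValueError("impute missing dosages first")
    return G.dosages - G.dosages.mean(axis=0)


# ---------------------------------------------------------------------------
# kernel BLUP
# ---------------------------------------------------------------------------


def gblup_fit(
    blues,
    kernels: KernelSet,
    tol: float = 1e-6,
    max_iter: int = 200,
    psd_tol: float = 1e-6,
) -> GEBVResult:
    """Extended GBLUP: one REML variance component per kernel.

    Training ids are the phenotyped ids present in the kernel universe;
    every id in the universe receives a GEBV (unphenotyped ids through
    their covariance with the training set). The GEBV is the sum of all
    kernel BLUPs plus any fixed-covariate contribution.
    """
    y_all = _as_series(blues)
    universe = kernels.ids
    upos = {g: i for i, g in enumerate(universe)}
    train = [g for g in y_all.index if g in upos]
    if not train:
        raise ValueError("no phenotyped ids found in the kernel universe")
    tr_idx = np.array([upos[g] for g in train])
    y = y_all.loc[train].to_numpy()
    n = len(train)
    for lb, K in kernels.kernels:
        lam = np.linalg.eigvalsh(K.values)[0]
        if lam < -psd_tol * max(1.0, np.abs(K.values).max()):
            raise ValueError(f"kernel {lb!r} is not PSD (min eigenvalue {lam:.3e})")
    Xcols = [np.ones(n)]
    labels = ["intercept"]
    C_all = None
    if kernels.fixed_covariates is not None:
        C = kernels.fixed_covariates
        missing = [g for g in train if g not in C.index]
        if missing:
            raise KeyError(f"fixed covariates missing for ids {missing[:5]}")
        Xc = C.loc[train].to_numpy(dtype=float)
        # drop collinear covariates (QR pivoting)
        full = np.column_stack([np.ones(n), Xc])
        from scipy.linalg import qr

        _, r, piv = qr(full, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        rank = int(np.sum(d > 1e-8 * d.max()))
        keep = sorted(piv[:rank])
        dropped = [i for i in range(full.shape[1]) if i not in keep]
        if dropped:
            warnings.warn(f"dropped {len(dropped)} collinear fixed covariates")
        keep_cov = [i - 1 for i in keep if i >= 1]
        Xcols = [np.ones(n)] + [Xc[:, j] for j in keep_cov]
        labels = ["intercept"] + [str(C.columns[j]) for j in keep_cov]
        C_all = C.reindex(universe).to_numpy(dtype=float)[:, keep_cov]
    X = np.column_stack(Xcols)
    terms = [
        (lb, K.values[np.ix_(tr_idx, tr_idx)], len(universe))
        for lb, K in kernels.kernels
    ]
    out = reml_core(y, X, terms, method="AI", tol=tol, max_iter=max_iter)
    Py = out["Py"]
    kernel_blups: dict[str, pd.Series] = {}
    gebv = np.zeros(len(universe))
    for lb, K in kernels.kernels:
        u = out["varcomps"][lb] * (K.values[:, tr_idx] @ Py)
        kernel_blups[lb] = pd.Series(u, index=universe, name=lb)
        gebv = gebv + u
    fixed = pd.Series(out["beta"], index=labels)
    if C_all is not None and C_all.shape[1] > 0:
        contrib = np.where(np.isnan(C_all), 0.0, C_all) @ out["beta"][1:]
        gebv = gebv + contrib
    return GEBVResult(
        model_label="+".join(lb for lb, _ in kernels.kernels),
        gebv=pd.Series(gebv, index=universe),
        kernel_blups=kernel_blups,
        varcomps=out["varcomps"],
        fixed_effects=fixed,
        loglik=out["loglik"],
        converged=out["converged"],
    )


def rrblup_fit(blues, G: GenotypeMatrix) -> GEBVResult:
    """Ridge-regression BLUP with REML shrinkage (spectral route).

    Marker effects β̂ = σ²_β W' V⁻¹ (y − X b̂); GEBV = W β̂ for every
    genotyped id.
    """
    if G.m == 0:
        raise ValueError("no markers")
    y_all = _as_series(blues)
    ids = list(G.ids)
    pos = {g: i for i, g in enumerate(ids)}
    train = [g for g in y_all.index if g in pos]
    tr = np.array([pos[g] for g in train])
    y = y_all.loc[train].to_numpy()
    W = centered_dosages(G)
    p = G.dosages.mean(axis=0) / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    Ktr = (W[tr] @ W[tr].T) / c
    out = spectral_reml(y, np.ones((len(y), 1)), Ktr)
    # V⁻¹(y−Xb) comes back scaled by 1/σ²_g; marker variance σ²_β = σ²_g / c
    beta = (W[tr].T @ out["Vinv_resid"]) / c
    gebv = W @ beta
    return GEBVResult(
        model_label="rrBLUP",
        gebv=pd.Series(gebv, index=ids),
        varcomps={
            "G": out["sigma_g"],
            "marker": out["sigma_g"] / c,
            "residual": out["sigma_e"],
        },
        fixed_effects=pd.Series(out["beta"], index=["intercept"]),
        marker_effects=pd.Series(beta, index=G.marker_ids),
        loglik=out["loglik"],
    )


# ---------------------------------------------------------------------------
# Bayesian alphabet (single-site Gibbs)
# ---------------------------------------------------------------------------


def _bayes_hyper(y: np.ndarray, W: np.ndarray, R2: float = 0.5):
    """Prior scales following the BGLR convention: each term's prior mode
    explains R² of the phenotypic variance."""
    vy = float(np.var(y)) or 1.0
    df0 = 5.0
    S_e = vy * (1.0 - R2) * (df0 + 2.0)
    msx = float(np.sum(W.var(axis=0))) or 1.0
    S_b = vy * R2 / msx * (df0 + 2.0)
    return df0, S_e, S_b, msx


def bayes_fit(
    blues,
    G: GenotypeMatrix,
    method: str = "BRR",
    n_iter: int = 12000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: int = 0,
    R2: float = 0.5,
) -> GEBVResult:
    """Whole-genome regression by single-site Gibbs sampling.

    Marker-effect priors: BRR — common normal variance; BayesA —
    marker-specific scaled-inverse-χ² variances; BayesB/BayesC —
    spike-and-slab with inclusion probability π (Beta(5,5) prior, prior
    mean 0.5); BL — double-exponential via the Park–Casella normal scale
    mixture. Retained draws = (n_iter − burn_in) / thin.
    """
    if method not in BAYES_METHODS:
        raise ValueError(f"method must be one of {BAYES_METHODS}, got {method!r}")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    y_all = _as_series(blues)
    pos = {g: i for i, g in enumerate(G.ids)}
    train = [g for g in y_all.index if g in pos]
    tr = np.array([pos[g] for g in train])
    y = y_all.loc[train].to_numpy()
    Wall = centered_dosages(G)
    W = np.ascontiguousarray(Wall[tr])
    n, m = W.shape
    xtx = (W**2).sum(axis=0)
    df0, S_e, S_b, msx = _bayes_hyper(y, W, R2)

    mu = float(y.mean())
    beta = np.zeros(m)
    resid = y - mu
    sig_e = float(np.var(y)) * (1.0 - R2) + 1e-12
    sig_b = np.full(m, float(np.var(y)) * R2 / msx + 1e-12)  # per-marker slab var
    common_sb = float(sig_b[0])
    delta = np.ones(m, dtype=bool)
    pi = 0.5
    lam2 = 1.0  # BL penalty²
    tau2 = np.full(m, 1.0)

    spike = method in ("BayesB", "BayesC")
    n_keep = (n_iter - burn_in) // thin
    g_sum = np.zeros(G.n)
    g_sumsq = np.zeros(G.n)
    se_sum = 0.0
    sb_sum = 0.0
    kept = 0

    for it in range(1, n_iter + 1):
        # --- marker effects
        if method == "BRR":
            sb = np.full(m, common_sb)
        elif method == "BayesA":
            sb = sig_b
        elif method == "BayesB":
            sb = sig_b
        elif method == "BayesC":
            sb = np.full(m, common_sb)
        else:  # BL: conditional variance σ²_e τ²_j
            sb = sig_e * tau2
        log_odds_prior = np.log(pi / (1.0 - pi)) if spike else 0.0
        z = rng.standard_normal(m)
        u_inc = rng.random(m) if spike else None
        for j in range(m):
            bj = beta[j]
            wj = W[:, j]
            if xtx[j] <= 1e-12:
                if bj != 0.0:
                    resid += wj * bj
                    beta[j] = 0.0
                if spike:
                    delta[j] = False
                continue
            cj = wj @ resid + xtx[j] * bj  # w_j' resid_without_j
            if spike:
                v0 = xtx[j] * sig_e
                v1 = v0 + xtx[j] ** 2 * sb[j]
                logbf = 0.5 * (np.log(v0 / v1) + cj * cj * (1.0 / v0 - 1.0 / v1))
                pin = 1.0 / (1.0 + np.exp(-(log_odds_prior + logbf)))
                inc = u_inc[j] < pin
            else:
                inc = True
            if inc:
                prec = xtx[j] + sig_e / sb[j]
                mean = cj / prec
                bnew = mean + z[j] * np.sqrt(sig_e / prec)
            else:
                bnew = 0.0
            if bnew != bj:
                resid += wj * (bj - bnew)
                beta[j] = bnew
            if spike:
                delta[j] = inc
        # --- variance of effects
        ss = float(beta @ beta)
        if method == "BRR":
            common_sb = (ss + S_b) / rng.chisquare(df0 + m)
        elif method == "BayesA":
            sig_b = (beta**2 + S_b) / rng.chisquare(df0 + 1.0, size=m)
        elif method == "BayesB":
            b2 = np.where(delta, beta**2, 0.0)
            draw = rng.chisquare(df0 + delta.astype(float))
            sig_b = (b2 + S_b) / draw
        elif method == "BayesC":
            m_in = int(delta.sum())
            ss_in = float(beta[delta] @ beta[delta]) if m_in else 0.0
            common_sb = (ss_in + S_b) / rng.chisquare(df0 + m_in)
        else:  # BL
            babs2 = np.maximum(beta**2, 1e-12)
            mu_ig = np.sqrt(lam2 * sig_e / babs2)
            inv_tau2 = rng.wald(np.minimum(mu_ig, 1e8), lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            lam2 = rng.gamma(shape=m + 1.2, scale=1.0 / (0.5 * tau2.sum() + 1e-4))
        if spike:
            m_in = int(delta.sum())
            pi = rng.beta(5.0 + m_in, 5.0 + m - m_in)
            pi = min(max(pi, 1e-4), 1.0 - 1e-4)
        # --- intercept and residual variance
        rbar = float(resid.mean())
        mu_new = rbar + mu + rng.standard_normal() * np.sqrt(sig_e / n)
        resid += mu - mu_new
        mu = mu_new
        sig_e = (float(resid @ resid) + S_e) / rng.chisquare(df0 + n)
        if not np.isfinite(resid).all() or not np.isfinite(sig_e):
            raise FloatingPointError(f"divergent chain at iteration {it}")
        # --- bookkeeping
        if it > burn_in and (it - burn_in) % thin == 0:
            g = Wall @ beta
            g_sum += g
            g_sumsq += g * g
            se_sum += sig_e
            if method in ("BRR", "BayesC"):
                sb_sum += common_sb
            elif method == "BL":
                sb_sum += sig_e * float(tau2.mean())
            else:
                sb_sum += float(sig_b.mean())
            kept += 1
    assert kept == n_keep
    g_mean = g_sum / kept
    g_var = np.maximum(g_sumsq / kept - g_mean**2, 0.0)
    return GEBVResult(
        model_label=method,
        gebv=pd.Series(g_mean, index=G.ids),
        posterior_sd=pd.Series(np.sqrt(g_var), index=G.ids),
        varcomps={"residual": se_sum / kept, "marker": sb_sum / kept},
        n_retained=kept,
    )


def rkhs_fit(
    blues,
    G: GenotypeMatrix,
    bandwidth: float | str = 1.0,
    n_iter: int = 12000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: int = 0,
) -> GEBVResult:
    """Gaussian-kernel RKHS regression fitted as a Bayesian kernel BLUP.

    K = exp(−h · D²) with D² the squared-Euclidean marker distance scaled
    to mean 1; the kernel is eigendecomposed and the regression on the
    scaled eigenvectors is sampled exactly like Bayesian ridge.
    """
    h = 1.0 if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    W = centered_dosages(G)
    sq = (W**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (W @ W.T)
    D2 = np.maximum(D2, 0.0)
    mean_d2 = float(D2[np.triu_indices_from(D2, k=1)].mean())
    if mean_d2 <= 0:
        raise ValueError("degenerate marker distances; all genotypes identical")
    K = np.exp(-h * D2 / mean_d2)
    if K.min() > 1.0 - 1e-6:
        raise ValueError("kernel is degenerate (all entries ≈ 1); increase bandwidth h")
    s, U = np.linalg.eigh(K)
    keep = s > 1e-8 * s.max()
    Phi = U[:, keep] * np.sqrt(s[keep])
    ids = np.asarray(G.ids, dtype=object)
    phi_G = GenotypeMatrix(
        ids=ids,
        marker_ids=np.array([f"eig{i}" for i in range(Phi.shape[1])], dtype=object),
        chrom=np.array(["1"] * Phi.shape[1], dtype=object),
        pos=np.arange(1, Phi.shape[1] + 1),
        dosages=Phi,
        imputed=True,
    )
    res = bayes_fit(
        blues, phi_G, method="BRR", n_iter=n_iter, burn_in=burn_in, thin=thin,
        seed=seed,
    )
    res.model_label = "RKHS"
    return res


# ---------------------------------------------------------------------------
# machine-learning adapters
# ---------------------------------------------------------------------------


def ml_fit(
    blues,
    G: GenotypeMatrix,
    method: str = "random_forest",
    hyper: dict | None = None,
    seed: int = 0,
) -> GEBVResult:
    """Random-forest or radial-kernel SVR on dosage features."""
    hyper = dict(hyper or {})
    y_all = _as_series(blues)
    pos = {g: i for i, g in enumerate(G.ids)}
    train = [g for g in y_all.index if g in pos]
    tr = np.array([pos[g] for g in train])
    y = y_all.loc[train].to_numpy()
    if np.ptp(y) == 0:
        raise ValueError("constant response; predictive ability undefined")
    X = centered_dosages(G)
    if method == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(
            n_estimators=hyper.pop("n_estimators", 300),
            random_state=seed,
            n_jobs=1,
            **hyper,
        )
    elif method == "svr_radial":
        from sklearn.svm import SVR

        model = SVR(kernel="rbf", **hyper)
    else:
        raise ValueError("method must be 'random_forest' or 'svr_radial'")
    model.fit(X[tr], y)
    pred = model.predict(X)
    return GEBVResult(
        model_label={"random_forest": "RF", "svr_radial": "SVM"}[method],
        gebv=pd.Series(pred - pred.mean(), index=G.ids),
    )


# ---------------------------------------------------------------------------
# GWAS and the G+S model
# ---------------------------------------------------------------------------


def gwas_scan(
    blues,
    G: GenotypeMatrix,
    K: RelationshipMatrix | None = None,
    p_threshold: float = 0.001,
) -> GwasScan:
    """Single-locus mixed linear model scan (EMMA-style).

    The polygenic variance ratio is estimated once from the null model on
    the kinship spectrum, then every marker is tested by GLS in the rotated
    basis (P3D). Monomorphic markers get p = 1 by convention.
    """
    y_all = _as_series(blues)
    pos = {g: i for i, g in enumerate(G.ids)}
    train = [g for g in y_all.index if g in pos]
    tr = np.array([pos[g] for g in train])
    y = y_all.loc[train].to_numpy()
    n = len(y)
    W = G.dosages[tr]
    if K is not None:
        Kt = K.align(train)
        s, U = np.linalg.eigh(Kt)
        s = np.maximum(s, 0.0)
        null = spectral_reml(y, np.ones((n, 1)), Kt)
        d = null["delta"]
        w = s + d
    else:
        U = np.eye(n)
        w = np.ones(n)
    yt = U.T @ y
    ot = U.T @ np.ones(n)
    Xt = U.T @ W
    iw = 1.0 / w
    a11 = float(ot @ (iw * ot))
    a12 = Xt.T @ (iw * ot)
    a22 = np.einsum("ij,i,ij->j", Xt, iw, Xt)
    b1 = float(ot @ (iw * yt))
    b2 = Xt.T @ (iw * yt)
    yty = float(yt @ (iw * yt))
    det = a11 * a22 - a12**2
    mono = det <= 1e-10 * max(a11, 1.0)
    det_safe = np.where(mono, 1.0, det)
    beta = (a11 * b2 - a12 * b1) / det_safe
    alpha = (a22 * b1 - a12 * b2) / det_safe
    rss = np.maximum(yty - (alpha * b1 + beta * b2), 1e-300)
    dof = n - 2
    sig2 = rss / dof
    se = np.sqrt(sig2 * a11 / det_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(mono, 1.0, p)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.inf, se)
    table = pd.DataFrame(
        {
            "marker_id": G.marker_ids,
            "chrom": G.chrom,
            "pos": G.pos,
            "effect": beta,
            "se": se,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
        }
    )
    return GwasScan(table=table, p_threshold=p_threshold)


def gs_with_fixed_snps(
    blues,
    kernels: KernelSet,
    scan: GwasScan,
    G: GenotypeMatrix,
    max_snps: int = 50,
) -> GEBVResult:
    """GBLUP with GWAS-selected SNP dosages as fixed covariates (G+S).

    Falls back to plain GBLUP with a notice when the scan selected nothing.
    The caller is responsible for running the scan on training data only;
    :func:`canegps.evaluate.run_scheme` enforces this.
    """
    sel = list(scan.selected)
    if not sel:
        warnings.warn("no SNPs below the scan threshold; fitting plain GBLUP")
        return gblup_fit(blues, kernels)
    if len(sel) > max_snps:
        order = scan.table.set_index("marker_id").loc[sel, "p"].sort_values()
        sel = list(order.index[:max_snps])
    mpos = {mid: j for j, mid in enumerate(G.marker_ids)}
    cols = np.array([mpos[mid] for mid in sel])
    X = centered_dosages(G)[:, cols]
    cov = pd.DataFrame(X, index=G.ids, columns=sel)
    if kernels.fixed_covariates is not None:
        cov = kernels.fixed_covariates.join(cov, how="outer")
    ks = KernelSet(kernels=kernels.kernels, fixed_covariates=cov)
    res = gblup_fit(blues, ks)
    res.model_label = res.model_label + "+S"
    return res
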