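"""REML engine for Gaussian mixed models with known covariance structures.

The model is

    y = X b + Σ_k Z_k u_k + e,   u_k ~ N(0, K_k σ²_k),   e ~ N(0, I σ²_e)

with each K_k a known relationship (or identity) matrix. Variance
components are estimated by EM-REML with optional average-information
(AI) acceleration; BLUEs and BLUPs come from the mixed-model equations at
the REML estimates.

On top of the engine sit the trial-analysis conveniences:

* :func:`compute_blues` — adjusted genotype means from the multi-environment
  trial model (genotype fixed; environment, rep-within-environment, crop
  and all interactions random),
* :func:`harmonic_means` / :func:`holland_h2` — broad-sense heritability on
  an entry-mean basis with interaction variances scaled by harmonic means
  of per-genotype counts,
* :func:`narrow_h2` — narrow-sense heritability under a pedigree (A) or
  marker (G_A) covariance,
* :func:`spectral_reml` — fast exact single-kernel REML via one
  eigendecomposition (used by ridge/GWAS style fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genorel import RelationshipMatrix

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "MixedModelFit",
    "HarmonicMeans",
    "reml_fit",
    "reml_core",
    "spectral_reml",
    "compute_blues",
    "harmonic_means",
    "holland_h2",
    "narrow_h2",
]

VAR_FLOOR_FRAC = 1e-8  # variance floor as a fraction of var(y)


@dataclass
class RandomTerm:
    """One random effect: levels = combinations of ``factors`` in the table."""

    name: str
    factors: tuple[str, ...]
    covariance: RelationshipMatrix | None = None  # None = identity


@dataclass
class ModelSpec:
    response: str
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[RandomTerm, ...] = ()
    cell_means_factor: str | None = None  # factor fitted without intercept


@dataclass
class MixedModelFit:
    varcomps: dict[str, float]
    blues: pd.DataFrame  # columns: term, level, estimate, se
    blups: dict[str, pd.Series]
    loglik: float
    converged: bool
    n_iter: int
    spec: ModelSpec | None = None
    _Py: np.ndarray | None = field(default=None, repr=False)


@dataclass
class HarmonicMeans:
    nE: float
    nC: float
    nEC: float
    nECr: float


# ---------------------------------------------------------------------------
# core solver (numeric interface)
# ---------------------------------------------------------------------------


def _project(Vinv: np.ndarray, X: np.ndarray, y: np.ndarray):
    A = Vinv @ X
    XtViX = X.T @ A
    cf = linalg.cho_factor(XtViX + 1e-12 * np.eye(X.shape[1]))
    beta = linalg.cho_solve(cf, A.T @ y)
    P = Vinv - A @ linalg.cho_solve(cf, A.T)
    _, ld = np.linalg.slogdet(XtViX)
    return P, beta, cf, ld


def reml_core(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[tuple[str, np.ndarray | None]],
    method: str = "AI",
    tol: float = 1e-6,
    max_iter: int = 200,
    start: dict[str, float] | None = None,
):
    """Fit the variance components for covariance structures ``B_k = Z_k K_k Z_k'``.

    ``terms`` is a list of (name, B, q) with B an n×n covariance
    contribution per unit variance (already folded through the incidence
    matrix) and q the number of levels of the term (dimension of u_k, used
    by the EM step); the residual term is added automatically. Returns a
    dict with varcomps, beta, beta covariance factor, P·y, P, loglik,
    converged, n_iter and the EM/AI trajectory of log-likelihoods.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = [t[0] for t in terms] + ["residual"]
    Bs = [np.asarray(t[1], dtype=float) for t in terms]
    qs = np.array([float(t[2]) for t in terms] + [float(n)])
    vary = float(np.var(y)) or 1.0
    floor = VAR_FLOOR_FRAC * vary
    k = len(names)
    if start:
        sig = np.array([max(start.get(nm, vary / k), floor) for nm in names])
    else:
        sig = np.full(k, vary / k)
    loglik_path: list[float] = []
    converged = False
    it = 0
    I = np.eye(n)

    def build(sig):
        V = sig[-1] * I
        for s, B in zip(sig[:-1], Bs):
            V = V + s * B
        cf = linalg.cho_factor(V)
        Vinv = linalg.cho_solve(cf, I)
        ldV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return Vinv, ldV

    def loglik_of(sig):
        Vinv, ldV = build(sig)
        P, beta, cfx, ldX = _project(Vinv, X, y)
        Py = P @ y
        ll = -0.5 * (ldV + ldX + float(y @ Py))
        return ll, P, Py, beta, cfx

    ll, P, Py, beta, cfx = loglik_of(sig)
    loglik_path.append(ll)
    for it in range(1, max_iter + 1):
        trPB = np.empty(k)
        yPBPy = np.empty(k)
        Ws = []
        for j in range(k):
            B = Bs[j] if j < k - 1 else I
            trPB[j] = float(np.sum(P * B)) if j < k - 1 else float(np.trace(P))
            w = B @ Py if j < k - 1 else Py.copy()
            Ws.append(w)
            yPBPy[j] = float(Py @ w)
        score = 0.5 * (yPBPy - trPB)
        use_ai = method.upper() == "AI" and it > 2
        new = None
        if use_ai:
            PW = [P @ w for w in Ws]
            AI = 0.5 * np.array(
                [[float(Ws[i] @ PW[j]) for j in range(k)] for i in range(k)]
            )
            try:
                delta = np.linalg.solve(AI + 1e-10 * np.eye(k), score)
                step = 1.0
                for _ in range(6):
                    cand = np.maximum(sig + step * delta, floor)
                    try:
                        ll_c = loglik_of(cand)[0]
                    except np.linalg.LinAlgError:
                        ll_c = -np.inf
                    if ll_c >= ll - 1e-10:
                        new = cand
                        break
                    step *= 0.5
            except np.linalg.LinAlgError:
                new = None
        if new is None:  # EM step (guaranteed ascent)
            new = np.maximum(sig + (sig**2 / qs) * (yPBPy - trPB), floor)
        rel = np.max(np.abs(new - sig) / np.maximum(sig, floor))
        sig = new
        ll, P, Py, beta, cfx = loglik_of(sig)
        loglik_path.append(ll)
        if rel < tol:
            converged = True
            break
    return {
        "varcomps": dict(zip(names, sig)),
        "beta": beta,
        "beta_cov_factor": cfx,
        "P": P,
        "Py": Py,
        "loglik": ll,
        "loglik_path": loglik_path,
        "converged": converged,
        "n_iter": it,
    }


def spectral_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Exact single-kernel REML via eigendecomposition of K.

    Profiles the likelihood over the ratio δ = σ²_e/σ²_g with Brent's
    method; returns varcomps, beta and the residual projection needed for
    BLUP. Independent of :func:`reml_core` (distinct computational route).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    s, U = np.linalg.eigh(K)
    s = np.maximum(s, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        w = s + d
        Xw = Xt / w[:, None]
        XtViX = Xt.T @ Xw
        try:
            cf = linalg.cho_factor(XtViX)
        except np.linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(cf, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / w))
        sig_g = rss / (n - p)
        ld_logs = float(np.sum(np.log(w)))
        ld_x = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * ((n - p) * np.log(sig_g) + ld_logs + ld_x + (n - p))
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    d = float(np.exp(res.x))
    w = s + d
    Xw = Xt / w[:, None]
    XtViX = Xt.T @ Xw
    cf = linalg.cho_factor(XtViX)
    beta = linalg.cho_solve(cf, Xw.T @ yt)
    r = yt - Xt @ beta
    sig_g = float(r @ (r / w)) / (n - p)
    sig_e = sig_g * d
    # BLUP of u over the K id universe: u = σ²_g K V⁻¹ (y − Xβ)
    Vinv_r = U @ (r / w)          # V⁻¹(y−Xβ) up to 1/σ²_g cancelling with σ²_g
    u = K @ Vinv_r
    return {
        "sigma_g": sig_g,
        "sigma_e": sig_e,
        "delta": d,
        "beta": beta,
        "u": u,
        "Vinv_resid": Vinv_r,
        "loglik": -res.fun,
    }


# ---------------------------------------------------------------------------
# table interface
# ---------------------------------------------------------------------------


def _design_fixed(table: pd.DataFrame, spec: ModelSpec):
    n = len(table)
    cols: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    if spec.cell_means_factor:
        fac = table[spec.cell_means_factor].astype(str)
        levels = list(dict.fromkeys(fac))
        for lv in levels:
            cols.append((fac == lv).to_numpy(dtype=float))
            labels.append((spec.cell_means_factor, lv))
    else:
        cols.append(np.ones(n))
        labels.append(("intercept", ""))
    for term in spec.fixed_terms:
        col = table[term]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            labels.append((term, "covariate"))
        else:
            fac = col.astype(str)
            levels = list(dict.fromkeys(fac))
            for lv in levels[1:]:  # first level = reference
                cols.append((fac == lv).to_numpy(dtype=float))
                labels.append((term, lv))
    X = np.column_stack(cols)
    # drop exactly collinear columns by QR pivoting, keep record
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > 1e-8 * diag.max()))
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        X = X[:, keep]
        labels = [labels[i] for i in keep]
    return X, labels


def _incidence(table: pd.DataFrame, factors) -> tuple[np.ndarray, list[str]]:
    key = table[list(factors)].astype(str).agg(":".join, axis=1)
    levels = list(dict.fromkeys(key))
    pos = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(table), len(levels)))
    Z[np.arange(len(table)), key.map(pos).to_numpy()] = 1.0
    return Z, levels


def reml_fit(
    table: pd.DataFrame,
    spec: ModelSpec,
    method: str = "AI",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MixedModelFit:
    """Fit ``spec`` on a long-format table by REML.

    Random terms with a RelationshipMatrix covariance receive BLUPs for
    every id in the matrix, including ids with no records (genomic
    prediction of unphenotyped genotypes).
    """
    tab = table.dropna(subset=[spec.response]).reset_index(drop=True)
    if len(tab) == 0:
        raise ValueError(f"no non-missing records for {spec.response!r}")
    y = tab[spec.response].to_numpy(dtype=float)
    X, labels = _design_fixed(tab, spec)
    terms = []
    meta = []
    for rt in spec.random_terms:
        Z, levels = _incidence(tab, rt.factors)
        if rt.covariance is None:
            B = Z @ Z.T
            meta.append((rt.name, Z, levels, None))
        else:
            # align K to the full id universe; incidence maps to that universe
            K = rt.covariance.values
            kidx = {g: i for i, g in enumerate(rt.covariance.ids)}
            missing = [lv for lv in levels if lv not in kidx]
            if missing:
                raise KeyError(
                    f"levels of term {rt.name!r} absent from its covariance: "
                    f"{missing[:5]}"
                )
            Zfull = np.zeros((len(tab), K.shape[0]))
            rows = np.arange(len(tab))
            colmap = np.array([kidx[lv] for lv in levels])
            Zfull[rows, colmap[np.argmax(Z, axis=1)]] = 1.0
            B = Zfull @ K @ Zfull.T
            meta.append((rt.name, Zfull, list(rt.covariance.ids), K))
        q = Z.shape[1] if rt.covariance is None else rt.covariance.values.shape[0]
        terms.append((rt.name, B, q))
    out = reml_core(y, X, terms, method=method, tol=tol, max_iter=max_iter)
    Py = out["Py"]
    blups: dict[str, pd.Series] = {}
    for nm, Z, levels, K in meta:
        s2 = out["varcomps"][nm]
        if K is None:
            u = s2 * (Z.T @ Py)
        else:
            u = s2 * (K @ (Z.T @ Py))
        blups[nm] = pd.Series(u, index=levels, name=nm)
    se = np.sqrt(np.diag(linalg.cho_solve(out["beta_cov_factor"],
                                          np.eye(X.shape[1]))))
    blues = pd.DataFrame(
        {
            "term": [t for t, _ in labels],
            "level": [l for _, l in labels],
            "estimate": out["beta"],
            "se": se,
        }
    )
    return MixedModelFit(
        varcomps=out["varcomps"],
        blues=blues,
        blups=blups,
        loglik=out["loglik"],
        converged=out["converged"],
        n_iter=out["n_iter"],
        spec=spec,
        _Py=Py,
    )


def eq1_random_terms(
    table: pd.DataFrame, include_genotype: bool = False
) -> tuple[RandomTerm, ...]:
    """The multi-environment trial terms present in a table subset.

    Builds E, R(E), C, EC, GE, GC, GCE (plus G when ``include_genotype``),
    dropping any term whose factor has fewer than two levels in the subset
    (e.g. the crop terms in a single-crop stratum, or the rep term in an
    unreplicated stage-2-style trial).
    """
    has = lambda c: c in table.columns and table[c].nunique() > 1
    terms: list[RandomTerm] = []
    if include_genotype and has("genotype"):
        terms.append(RandomTerm("G", ("genotype",)))
    if has("env"):
        terms.append(RandomTerm("E", ("env",)))
        if has("rep"):
            terms.append(RandomTerm("R", ("env", "rep")))
    if has("crop"):
        terms.append(RandomTerm("C", ("crop",)))
        if has("env"):
            terms.append(RandomTerm("EC", ("env", "crop")))
    if has("env"):
        terms.append(RandomTerm("GE", ("genotype", "env")))
    if has("crop"):
        terms.append(RandomTerm("GC", ("genotype", "crop")))
        if has("env"):
            terms.append(RandomTerm("GCE", ("genotype", "env", "crop")))
    return tuple(terms)


def compute_blues(
    table: pd.DataFrame,
    trait: str,
    method: str = "AI",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Adjusted phenotypic means (BLUEs) per genotype.

    Genotype is fitted as fixed (cell means, no intercept); all other trial
    terms present in the table are random. Returns columns
    genotype, trait, blue, se.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    if table[trait].notna().sum() == 0:
        raise ValueError(f"trait {trait!r} entirely missing")
    spec = ModelSpec(
        response=trait,
        cell_means_factor="genotype",
        random_terms=eq1_random_terms(table, include_genotype=False),
    )
    fit = reml_fit(table, spec, method=method, tol=tol, max_iter=max_iter)
    sel = fit.blues[fit.blues["term"] == "genotype"]
    return pd.DataFrame(
        {
            "genotype": sel["level"].to_numpy(),
            "trait": trait,
            "blue": sel["estimate"].to_numpy(),
            "se": sel["se"].to_numpy(),
        }
    )


def harmonic_means(table: pd.DataFrame) -> HarmonicMeans:
    """Harmonic means across genotypes of per-genotype factor counts."""

    def hmean(x: pd.Series) -> float:
        x = x[x > 0]
        return float(len(x) / np.sum(1.0 / x))

    g = table.groupby("genotype", sort=False)
    nE = hmean(g["env"].nunique()) if "env" in table else 1.0
    nC = hmean(g["crop"].nunique()) if "crop" in table else 1.0
    if {"env", "crop"} <= set(table.columns):
        nEC = hmean(
            table.groupby("genotype", sort=False)
            .apply(lambda d: d[["env", "crop"]].drop_duplicates().shape[0],
                   include_groups=False)
        )
    else:
        nEC = max(nE, nC)
    nECr = hmean(g.size())
    return HarmonicMeans(nE=nE, nC=nC, nEC=nEC, nECr=nECr)


def holland_h2(varcomps: dict[str, float], hm: HarmonicMeans) -> float:
    """Broad-sense heritability on an entry-mean basis.

    H² = σ²_G / (σ²_G + σ²_GE/ñE + σ²_GC/ñC + σ²_GEC/ñEC + σ²_e/ñECr),
    with missing interaction components treated as zero.
    """
    sG = varcomps.get("G", varcomps.get("genotype"))
    if sG is None:
        raise KeyError("varcomps must contain a genotype component 'G'")
    denom = (
        sG
        + varcomps.get("GE", 0.0) / hm.nE
        + varcomps.get("GC", 0.0) / hm.nC
        + varcomps.get("GEC", varcomps.get("GCE", 0.0)) / hm.nEC
        + varcomps.get("residual", varcomps.get("e", 0.0)) / hm.nECr
    )
    if denom <= 0:
        raise ValueError("all variance components are zero; H² undefined")
    return float(sG / denom)


def narrow_h2(
    table: pd.DataFrame,
    trait: str,
    K: RelationshipMatrix,
    fixed_terms: tuple[str, ...] = (),
) -> float:
    """Narrow-sense heritability h² = σ²_A / (σ²_A + σ²_e) under covariance K."""
    if K.kind not in ("A", "G_A", "K"):
        raise ValueError(f"K must be an additive relationship matrix, got {K.kind}")
    tab = table.dropna(subset=[trait]).reset_index(drop=True)
    one_rec = tab["genotype"].is_unique
    if one_rec and not fixed_terms:
        y = tab[trait].to_numpy(dtype=float)
        Ksub = K.align(tab["genotype"])
        out = spectral_reml(y, np.ones((len(y), 1)), Ksub)
        sA, sE = out["sigma_g"], out["sigma_e"]
    else:
        spec = ModelSpec(
            response=trait,
            fixed_terms=tuple(fixed_terms),
            random_terms=(RandomTerm("G", ("genotype",), covariance=K),),
        )
        fit = reml_fit(tab, spec)
        sA, sE = fit.varcomps["G"], fit.varcomps["residual"]
    return float(sA / (sA + sE))
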