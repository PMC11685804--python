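"""Multi-trait genomic prediction with a Kronecker-structured mixed model.

The model for t traits on n genotypes is

    y = μ + Z α + ε,   α ~ MVN(0, Σ ⊗ K),   ε ~ MVN(0, R ⊗ I)

with K a known additive relationship matrix, Σ an unstructured t×t genetic
covariance and R a diagonal residual covariance. Phenotype cells may be
missing — in particular the target trait can be hidden in a validation set
while correlated secondary traits stay observed, which is how a compound
trait such as sucrose yield is predicted from its component traits.

Two fitting routes are provided: expectation–maximisation REML
(:func:`mvgblup_fit`) and a Gibbs sampler with inverse-Wishart prior on Σ
(:func:`bmtm_fit`); :func:`predict_hidden_trait` wraps either for the
hidden-trait validation design and always reports the single-trait
baseline alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genorel import RelationshipMatrix
from .mixedmodel import spectral_reml

__all__ = ["MultiTraitFit", "mvgblup_fit", "bmtm_fit", "predict_hidden_trait"]


@dataclass
class MultiTraitFit:
    method: str
    traits: list[str]
    ids: np.ndarray
    Sigma: np.ndarray          # t×t genetic covariance (original trait scales)
    R: np.ndarray              # t-vector of residual variances
    mu: np.ndarray             # t-vector of trait means
    gebv_matrix: pd.DataFrame  # genotype × trait genetic values
    converged: bool = True
    n_iter: int = 0
    n_retained: int | None = None
    n_psd_repairs: int = 0

    def genetic_correlations(self) -> np.ndarray:
        d = np.sqrt(np.maximum(np.diag(self.Sigma), 1e-300))
        return self.Sigma / np.outer(d, d)

    def predictions(self) -> pd.DataFrame:
        """Phenotype-scale predictions μ_t + genetic value."""
        return self.gebv_matrix + self.mu


def _prepare(blues_matrix: pd.DataFrame, K: RelationshipMatrix):
    Y = blues_matrix.astype(float)
    traits = list(Y.columns)
    ids = Y.index.to_numpy(dtype=object)
    if len(traits) < 1:
        raise ValueError("need at least one trait column")
    missing = [g for g in ids if g not in set(K.ids)]
    if missing:
        raise KeyError(f"ids absent from K: {missing[:5]}")
    Kv = K.align(ids)
    obs = Y.notna().to_numpy()
    if not obs.any(axis=1).all():
        warnings.warn("some genotypes have no observed trait; they are predicted "
                      "purely from relatives")
    # per-trait standardisation for numerical conditioning
    mu0 = np.nanmean(Y.to_numpy(), axis=0)
    sd0 = np.nanstd(Y.to_numpy(), axis=0)
    sd0 = np.where(sd0 > 0, sd0, 1.0)
    Ys = (Y.to_numpy() - mu0) / sd0
    return Ys, obs, traits, ids, Kv, mu0, sd0


def _nearest_psd(S: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    w, V = np.linalg.eigh(S)
    if w[0] >= eps:
        return S, False
    w = np.maximum(w, eps)
    return (V * w) @ V.T, True


def mvgblup_fit(
    blues_matrix: pd.DataFrame,
    K: RelationshipMatrix,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> MultiTraitFit:
    """Multivariate GBLUP by EM-REML with missing-cell updates.

    The E-step computes the exact posterior of the nt genetic values given
    the observed cells; the M-step updates Σ (unstructured), the diagonal
    R and the trait means. Σ is repaired to the nearest PSD matrix if an
    update leaves the cone (counted in ``n_psd_repairs``).
    """
    Ys, obs, traits, ids, Kv, mu0, sd0 = _prepare(blues_matrix, K)
    n, t = Ys.shape
    Kreg = Kv + 1e-8 * np.eye(n)
    Kinv = np.linalg.inv(Kreg)
    Sigma = 0.5 * np.eye(t)
    r = np.full(t, 0.5)
    obs_flat = obs.T.reshape(-1)  # trait-major stacking: a = [A[:,0]; A[:,1]; ...]
    oi = np.flatnonzero(obs_flat)
    y_o = np.where(obs, Ys, 0.0).T.reshape(-1)[oi]
    trait_of_obs = oi // n
    # fixed design: one intercept per trait
    X = np.zeros((len(oi), t))
    X[np.arange(len(oi)), trait_of_obs] = 1.0
    n_obs_t = np.array([(trait_of_obs == s).sum() for s in range(t)], dtype=float)
    repairs = 0
    converged = False
    it = 0
    A_hat = np.zeros((n, t))
    mu = np.zeros(t)
    for it in range(1, max_iter + 1):
        C = np.kron(Sigma, Kreg)
        Co = C[np.ix_(oi, oi)]
        V = Co + np.diag(r[trait_of_obs])
        Vinv = np.linalg.inv(V)
        VX = Vinv @ X
        XtViX = X.T @ VX
        mu = np.linalg.solve(XtViX, VX.T @ y_o)
        P = Vinv - VX @ np.linalg.solve(XtViX, VX.T)
        Py = P @ y_o
        # REML E-step: â = C Z' P y;  E[aa'] − ââ' = C − C Z' P Z C
        Czp = C[:, oi]
        a = Czp @ Py
        A_hat = a.reshape(t, n).T
        CPC = Czp @ (P @ Czp.T)
        # M-step: Σ_su = (Â_s' K⁻¹ Â_u + tr(K⁻¹ Cov_su)) / n
        newS = np.empty((t, t))
        for s in range(t):
            KiA_s = Kinv @ A_hat[:, s]
            for u in range(s, t):
                cov_blk = (C[s * n:(s + 1) * n, u * n:(u + 1) * n]
                           - CPC[s * n:(s + 1) * n, u * n:(u + 1) * n])
                val = (float(A_hat[:, u] @ KiA_s)
                       + float(np.sum(Kinv * cov_blk))) / n
                newS[s, u] = newS[u, s] = val
        newS, rep = _nearest_psd(newS)
        repairs += int(rep)
        # M-step: r_t ← r_t + r_t²(y'P D_t P y − tr(P D_t)) / n_t
        newr = np.empty(t)
        Pd = np.diag(P)
        for s in range(t):
            sel = trait_of_obs == s
            if not sel.any():
                newr[s] = r[s]
                continue
            newr[s] = r[s] + r[s] ** 2 * (
                float(Py[sel] @ Py[sel]) - float(Pd[sel].sum())
            ) / n_obs_t[s]
        newr = np.maximum(newr, 1e-8)
        rel = max(
            np.max(np.abs(newS - Sigma)) / max(np.max(np.abs(Sigma)), 1e-8),
            np.max(np.abs(newr - r)) / max(np.max(r), 1e-8),
        )
        Sigma, r = newS, newr
        if rel < tol:
            converged = True
            break
    # back-transform to original scales
    S_out = Sigma * np.outer(sd0, sd0)
    r_out = r * sd0**2
    mu_out = mu * sd0 + mu0
    gebv = pd.DataFrame(A_hat * sd0, index=ids, columns=traits)
    return MultiTraitFit(
        method="MVGBLUP",
        traits=traits,
        ids=ids,
        Sigma=S_out,
        R=r_out,
        mu=mu_out,
        gebv_matrix=gebv,
        converged=converged,
        n_iter=it,
        n_psd_repairs=repairs,
    )


def bmtm_fit(
    blues_matrix: pd.DataFrame,
    K: RelationshipMatrix,
    n_iter: int = 6000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
) -> MultiTraitFit:
    """Bayesian multi-trait model: Gibbs sampler with inverse-Wishart Σ prior.

    Missing cells are handled by data augmentation. The genetic values are
    sampled in the eigenbasis of K, where their full conditional factorises
    into n independent t×t Gaussians.
    """
    rng = np.random.default_rng(seed)
    Ys, obs, traits, ids, Kv, mu0, sd0 = _prepare(blues_matrix, K)
    n, t = Ys.shape
    s_eig, U = np.linalg.eigh(Kv)
    s_eig = np.maximum(s_eig, 1e-8)
    nu0 = t + 2.0
    S0 = 0.5 * (nu0 + t + 1.0) * np.eye(t)  # prior mode 0.5·I on standardised scale
    df_r0 = 5.0
    Se0 = 0.5 * (df_r0 + 2.0)

    Sigma = 0.5 * np.eye(t)
    r = np.full(t, 0.5)
    mu = np.zeros(t)
    A = np.zeros((n, t))
    Y = np.where(obs, Ys, 0.0)

    kept = 0
    A_sum = np.zeros((n, t))
    S_sum = np.zeros((t, t))
    r_sum = np.zeros(t)
    mu_sum = np.zeros(t)
    for it in range(1, n_iter + 1):
        # impute missing cells
        if (~obs).any():
            noise = rng.standard_normal((n, t)) * np.sqrt(r)
            Y = np.where(obs, Ys, mu + A + noise)
        # sample genetic values in the eigenbasis of K
        Sinv = np.linalg.inv(Sigma + 1e-10 * np.eye(t))
        Rinv = np.diag(1.0 / r)
        Yt = U.T @ (Y - mu)
        At = np.empty((n, t))
        z = rng.standard_normal((n, t))
        for i in range(n):
            M = Sinv / s_eig[i] + Rinv
            L = np.linalg.cholesky(M)
            mean = np.linalg.solve(M, Rinv @ Yt[i])
            At[i] = mean + np.linalg.solve(L.T, z[i])
        A = U @ At
        # Σ | A  ~ inverse-Wishart
        SA = At.T @ (At / s_eig[:, None])  # = A' K⁻¹ A
        Sigma = stats.invwishart.rvs(df=nu0 + n, scale=S0 + SA, random_state=rng)
        Sigma = np.atleast_2d(Sigma)
        # R diagonal and μ
        res = Y - mu - A
        for s in range(t):
            sse = float(res[:, s] @ res[:, s])
            r[s] = (sse + Se0) / rng.chisquare(df_r0 + n)
            mu[s] = float(np.mean(Y[:, s] - A[:, s])) + rng.standard_normal() * np.sqrt(
                r[s] / n
            )
        res = None
        if it > burn_in and (it - burn_in) % thin == 0:
            kept += 1
            A_sum += A
            S_sum += Sigma
            r_sum += r
            mu_sum += mu
    A_mean = A_sum / kept
    S_mean = S_sum / kept
    return MultiTraitFit(
        method="BMTM",
        traits=traits,
        ids=ids,
        Sigma=S_mean * np.outer(sd0, sd0),
        R=(r_sum / kept) * sd0**2,
        mu=(mu_sum / kept) * sd0 + mu0,
        gebv_matrix=pd.DataFrame(A_mean * sd0, index=ids, columns=traits),
        n_iter=n_iter,
        n_retained=kept,
    )


def predict_hidden_trait(
    blues_matrix: pd.DataFrame,
    K: RelationshipMatrix,
    target: str,
    secondary,
    validation_ids,
    method: str = "MVGBLUP",
    **fit_kwargs,
) -> dict:
    """Hidden-trait validation: mask the target on ``validation_ids``, keep
    the secondary traits observed, fit the multi-trait model and return the
    target predictions together with the single-trait baseline.
    """
    secondary = [s for s in secondary if s != target]
    validation_ids = list(validation_ids)
    cols = [target] + secondary
    missing_cols = [c for c in cols if c not in blues_matrix.columns]
    if missing_cols:
        raise KeyError(f"traits not in blues matrix: {missing_cols}")
    masked = blues_matrix[cols].copy()
    masked.loc[masked.index.isin(validation_ids), target] = np.nan

    # single-trait baseline: GBLUP on the training portion of the target
    y_train = blues_matrix[target].drop(index=validation_ids, errors="ignore").dropna()
    Kv = K.align(list(y_train.index) + validation_ids)
    out = spectral_reml(
        y_train.to_numpy(), np.ones((len(y_train), 1)), Kv[: len(y_train), : len(y_train)]
    )
    u_val = Kv[len(y_train):, : len(y_train)] @ out["Vinv_resid"]
    single = pd.Series(u_val + out["beta"][0], index=validation_ids, name="single")

    if not secondary:
        warnings.warn("no secondary traits; degenerating to single-trait prediction")
        return {"multi": single.copy(), "single": single, "fit": None}

    if method.upper() == "MVGBLUP":
        fit = mvgblup_fit(masked, K, **fit_kwargs)
    elif method.upper() == "BMTM":
        fit = bmtm_fit(masked, K, **fit_kwargs)
    else:
        raise ValueError("method must be 'MVGBLUP' or 'BMTM'")
    preds = fit.predictions()
    multi = preds.loc[validation_ids, target].rename("multi")
    return {"multi": multi, "single": single, "fit": fit}
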