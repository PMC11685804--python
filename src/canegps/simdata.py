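"""Synthetic staged-trial data generator.

Emulates the data structure of a clonal (sugarcane-style) variety
development program: a panel of genotypes scored at biallelic SNPs with
block-wise linkage disequilibrium, a shallow pedigree of founders and
crosses, four correlated latent traits (TRS, NS, SW, Fiber) with additive,
dominance and pairwise-epistatic architecture, the compound traits
CY = NS·SW and SY = CY·TRS, and multi-environment trials organised in a
selection funnel of stages with plant-cane/ratoon crop types, heavy/light
soils, replicates and a full set of genotype × environment × crop
interaction effects plus plot residuals.

Everything is driven by :class:`SimConfig` and a single integer seed; all
generators are deterministic given the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genorel import GenotypeMatrix, Pedigree

__all__ = [
    "StageSpec",
    "SimConfig",
    "TrueValues",
    "LATENT_TRAITS",
    "TRAITS",
    "simulate_genotypes",
    "simulate_pedigree",
    "simulate_trait_set",
    "simulate_trials",
    "write_trial_csv",
]

LATENT_TRAITS = ("TRS", "NS", "SW", "Fiber")
TRAITS = ("TRS", "NS", "SW", "CY", "SY", "Fiber")

# natural-scale trait means and genetic coefficients of variation;
# TRS in Mg sucrose per Mg cane, NS in thousand stalks/ha, SW in kg,
# CY and SY in Mg/ha, Fiber in %
_TRAIT_MEAN = {"TRS": 0.110, "NS": 60.0, "SW": 1.10, "Fiber": 12.0}
_TRAIT_GCV = {"TRS": 0.05, "NS": 0.10, "SW": 0.08, "Fiber": 0.06}


@dataclass(frozen=True)
class StageSpec:
    """One stage of the selection funnel."""

    stage: int
    n_environments: int
    n_crop_types: int
    n_reps: int
    soils: tuple[str, ...] = ("H", "L")
    fraction: float = 1.0  # fraction of the panel entering this stage


def _default_stage_plan() -> tuple[StageSpec, ...]:
    # mirrors a four-stage clonal program: an unreplicated second-line
    # stage, replicated nursery and infield stages, and a multi-location
    # replicated outfield stage; funnel fractions are free parameters
    return (
        StageSpec(2, n_environments=2, n_crop_types=3, n_reps=1, fraction=1.0),
        StageSpec(3, n_environments=4, n_crop_types=3, n_reps=2, fraction=0.5),
        StageSpec(4, n_environments=4, n_crop_types=3, n_reps=2, fraction=0.25),
        StageSpec(5, n_environments=6, n_crop_types=3, n_reps=3, fraction=0.1),
    )


def _default_corr() -> np.ndarray:
    # mild genetic correlations among the latent traits
    c = np.array(
        [
            [1.0, -0.1, 0.1, -0.2],
            [-0.1, 1.0, -0.3, 0.1],
            [0.1, -0.3, 1.0, 0.1],
            [-0.2, 0.1, 0.1, 1.0],
        ]
    )
    return c


@dataclass
class SimConfig:
    """Knobs of the synthetic breeding program.

    Variance fractions apply per latent trait and must satisfy
    additive + dominance + epistasis ≤ 1 (the remainder is unused
    micro-environmental slack at the genotypic level: components are
    rescaled so the three fractions are realised exactly).
    """

    n_genotypes: int = 567
    n_markers: int = 2000
    n_chromosomes: int = 10
    ld_block_size: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    h2_additive: float = 0.7          # additive fraction of genotypic variance
    var_dominance_frac: float = 0.2
    var_epistasis_frac: float = 0.1
    trait_genetic_corr: np.ndarray = field(default_factory=_default_corr)
    ld_mix: float = 0.85              # within-block haplotype mixing weight
    stage_plan: tuple[StageSpec, ...] = field(default_factory=_default_stage_plan)
    # non-genetic variance components of the trial model, as multiples of
    # the genotypic variance of each trait
    env_var_frac: float = 1.0
    rep_var_frac: float = 0.1
    crop_var_frac: float = 0.3
    env_crop_var_frac: float = 0.2
    gxe_var_frac: float = 0.4
    gxc_var_frac: float = 0.2
    gxec_var_frac: float = 0.2
    resid_var_frac: float = 1.0
    selection_trait: str = "CY"
    pedigree_founder_frac: float = 0.3
    pedigree_genotyped_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_markers", "n_chromosomes", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        fr = (self.h2_additive, self.var_dominance_frac, self.var_epistasis_frac)
        if any(not 0.0 <= f <= 1.0 for f in fr) or sum(fr) > 1.0 + 1e-12:
            raise ValueError(
                "variance fractions must be in [0,1] with "
                f"additive+dominance+epistasis ≤ 1, got {fr}"
            )
        C = np.asarray(self.trait_genetic_corr, dtype=float)
        if C.shape != (len(LATENT_TRAITS), len(LATENT_TRAITS)):
            raise ValueError("trait_genetic_corr must be 4×4 over the latent traits")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("trait_genetic_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C)[0] < -1e-10:
            raise ValueError("trait_genetic_corr must be positive semidefinite")
        fracs = [s.fraction for s in self.stage_plan]
        if any(f > 1.0 for f in fracs):
            raise ValueError("stage fractions must be ≤ 1")
        if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("stage fractions must be non-increasing (selection funnel)")


@dataclass
class TrueValues:
    """Simulated genotypic values per genotype × trait (columns of TRAITS)."""

    ids: np.ndarray
    breeding_values: pd.DataFrame
    dominance_deviations: pd.DataFrame
    epistatic_deviations: pd.DataFrame
    total_genotypic: pd.DataFrame


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw dosages {0,1,2} with LD blocks.

    Within each block of ``ld_block_size`` markers a latent per-gamete
    signal is mixed into every marker (weight ``ld_mix``), so pairwise r²
    is high within a block and decays to ~0 across blocks. MAF is drawn
    uniformly from ``maf_range`` per marker before missing injection.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genotypes, config.n_markers
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    per_chr = int(np.ceil(m / config.n_chromosomes))
    chrom = np.array(
        [str(1 + j // per_chr) for j in range(m)], dtype=object
    )
    pos = np.array([1 + j % per_chr for j in range(m)], dtype=np.int64)
    block = np.arange(m) // config.ld_block_size
    n_blocks = int(block.max()) + 1
    w = config.ld_mix if config.ld_block_size > 1 else 0.0
    dosages = np.empty((n, m))
    # liability has unit marginal variance, so the Gaussian quantile gives
    # P(allele) = p_j exactly in expectation
    from scipy.stats import norm

    thresh = norm.ppf(1.0 - p)
    for gamete in range(2):
        latent = rng.standard_normal((n, n_blocks))
        noise = rng.standard_normal((n, m))
        liab = np.sqrt(w) * latent[:, block] + np.sqrt(1.0 - w) * noise
        allele = liab > thresh[None, :]
        if gamete == 0:
            dosages = allele.astype(float)
        else:
            dosages += allele
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages = np.where(mask, np.nan, dosages)
    ids = np.array([f"G{i:04d}" for i in range(n)], dtype=object)
    mids = np.array([f"M{j:05d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(ids=ids, marker_ids=mids, chrom=chrom, pos=pos, dosages=dosages)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Founders plus biparental crosses; parents always precede offspring."""
    if config.n_genotypes < 4:
        raise ValueError("n_genotypes must be ≥ 4 to build a pedigree")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_genotypes
    n_found = max(2, int(round(config.pedigree_founder_frac * n)))
    ids = np.array([f"G{i:04d}" for i in range(n)], dtype=object)
    sire = np.empty(n, dtype=object)
    dam = np.empty(n, dtype=object)
    sire[:n_found] = None
    dam[:n_found] = None
    for i in range(n_found, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = ids[s], ids[d]
    genotyped = rng.random(n) < config.pedigree_genotyped_frac
    return Pedigree(id=ids, sire=sire, dam=dam, genotyped=genotyped)


# ---------------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------------


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        return x
    return x * np.sqrt(target_var) / sd


def simulate_trait_set(G: GenotypeMatrix, config: SimConfig) -> TrueValues:
    """Latent genotypic values from marker effects, then the compound traits.

    For each latent trait (TRS, NS, SW, Fiber) additive values come from
    correlated marker effects on centered dosages, dominance values from
    heterozygosity-coded effects, and epistatic values from products of
    random marker pairs. Components are rescaled so the realised variance
    fractions equal the configured ones, then shifted to the trait's
    natural scale. CY = NS·SW and SY = CY·TRS hold exactly at the
    genotypic level.
    """
    if np.isnan(G.dosages).any():
        raise ValueError("trait simulation needs complete (or imputed) genotypes")
    C = np.asarray(config.trait_genetic_corr, dtype=float)
    if np.linalg.eigvalsh(C)[0] < -1e-10:
        raise ValueError("trait_genetic_corr must be positive semidefinite")
    rng = np.random.default_rng(config.seed + 2)
    n, m = G.n, G.m
    t = len(LATENT_TRAITS)
    # correlated additive marker effects: rows iid MVN(0, C)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(t))
    beta = rng.standard_normal((m, t)) @ L.T
    Wc = G.dosages - G.dosages.mean(axis=0)
    A = Wc @ beta
    # dominance: effects on centered heterozygote indicator
    Hc = (G.dosages == 1.0).astype(float)
    Hc = Hc - Hc.mean(axis=0)
    D = Hc @ (rng.standard_normal((m, t)) @ L.T)
    # epistasis: products of random marker pairs
    n_pairs = min(2 * m, 2000)
    i1 = rng.integers(0, m, n_pairs)
    i2 = rng.integers(0, m, n_pairs)
    P = Wc[:, i1] * Wc[:, i2]
    P = P - P.mean(axis=0)
    E = P @ (rng.standard_normal((n_pairs, t)) @ L.T)

    fa, fd, fe = config.h2_additive, config.var_dominance_frac, config.var_epistasis_frac
    tot = fa + fd + fe
    if tot <= 0:
        raise ValueError("at least one genetic variance fraction must be positive")
    fa, fd, fe = fa / tot, fd / tot, fe / tot

    bv = pd.DataFrame(index=G.ids, columns=list(TRAITS), dtype=float)
    dd = pd.DataFrame(0.0, index=G.ids, columns=list(TRAITS))
    ee = pd.DataFrame(0.0, index=G.ids, columns=list(TRAITS))
    tg = pd.DataFrame(index=G.ids, columns=list(TRAITS), dtype=float)
    for k, trait in enumerate(LATENT_TRAITS):
        gvar = (_TRAIT_MEAN[trait] * _TRAIT_GCV[trait]) ** 2
        a = _scale_to_var(A[:, k], fa * gvar)
        d = _scale_to_var(D[:, k], fd * gvar) if fd > 0 else np.zeros(n)
        e = _scale_to_var(E[:, k], fe * gvar) if fe > 0 else np.zeros(n)
        bv[trait], dd[trait], ee[trait] = a, d, e
        tg[trait] = a + d + e

    # compound traits on natural scales
    ns = tg["NS"] + _TRAIT_MEAN["NS"]
    sw = tg["SW"] + _TRAIT_MEAN["SW"]
    trs = tg["TRS"] + _TRAIT_MEAN["TRS"]
    cy = ns * sw
    sy = cy * trs
    tg["CY"] = cy - cy.mean()
    tg["SY"] = sy - sy.mean()
    # first-order additive parts of the products; the nonlinear remainder is
    # booked as epistatic deviation
    cy_a = _TRAIT_MEAN["SW"] * bv["NS"] + _TRAIT_MEAN["NS"] * bv["SW"]
    sy_a = _TRAIT_MEAN["TRS"] * cy_a + (_TRAIT_MEAN["NS"] * _TRAIT_MEAN["SW"]) * bv["TRS"]
    bv["CY"] = cy_a - cy_a.mean()
    bv["SY"] = sy_a - sy_a.mean()
    dd["CY"] = 0.0
    dd["SY"] = 0.0
    ee["CY"] = tg["CY"] - bv["CY"]
    ee["SY"] = tg["SY"] - bv["SY"]
    return TrueValues(
        ids=G.ids,
        breeding_values=bv,
        dominance_deviations=dd,
        epistatic_deviations=ee,
        total_genotypic=tg,
    )


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

_CROPS = ("P", "R1", "R2")


def simulate_trials(true: TrueValues, config: SimConfig) -> pd.DataFrame:
    """Long-format trial records for every stage of the funnel.

    phenotype = trait mean + genotypic value + environment + rep(environment)
    + crop + env×crop + G×E + G×C + G×E×C + residual, each component drawn
    with variance ``*_var_frac`` × the trait's genotypic variance. Later
    stages keep the top ``fraction`` of genotypes ranked on the previous
    stage's phenotypic mean of ``selection_trait``.
    """
    if not config.stage_plan:
        raise ValueError("stage_plan must be non-empty")
    rng = np.random.default_rng(config.seed + 3)
    ids = np.asarray(true.ids, dtype=object)
    n = len(ids)
    records: list[pd.DataFrame] = []
    current = np.arange(n)  # indices of genotypes in the current stage
    gvar = {
        tr: max(float(true.total_genotypic[tr].var(ddof=0)), 1e-12) for tr in TRAITS
    }
    mean = {
        "TRS": _TRAIT_MEAN["TRS"],
        "NS": _TRAIT_MEAN["NS"],
        "SW": _TRAIT_MEAN["SW"],
        "Fiber": _TRAIT_MEAN["Fiber"],
        "CY": _TRAIT_MEAN["NS"] * _TRAIT_MEAN["SW"],
        "SY": _TRAIT_MEAN["NS"] * _TRAIT_MEAN["SW"] * _TRAIT_MEAN["TRS"],
    }
    year0 = 2010
    for si, st in enumerate(config.stage_plan):
        if st.fraction > 1.0:
            raise ValueError(f"stage {st.stage} fraction {st.fraction} > 1")
        n_keep = max(1, int(round(st.fraction * n)))
        if si > 0 and n_keep < len(current):
            # truncation selection on the previous stage's phenotypic means
            prev = records[-1]
            sel = (
                prev.groupby("genotype", sort=False)[config.selection_trait]
                .mean()
                .sort_values(ascending=False, kind="stable")
            )
            top = sel.index[:n_keep]
            pos = {g: i for i, g in enumerate(ids)}
            current = np.array(sorted(pos[g] for g in top), dtype=int)
        g_ids = ids[current]
        crops = _CROPS[: st.n_crop_types]
        envs = [f"S{st.stage}E{e}" for e in range(st.n_environments)]
        soils = [st.soils[e % len(st.soils)] for e in range(st.n_environments)]
        locs = [f"L{e}" for e in range(st.n_environments)]
        years = [year0 + si * 2 + (e % 2) for e in range(st.n_environments)]
        reps = range(1, st.n_reps + 1)
        idx = pd.MultiIndex.from_product(
            [g_ids, range(st.n_environments), crops, list(reps)],
            names=["genotype", "env_i", "crop", "rep"],
        )
        df = idx.to_frame(index=False)
        df["stage"] = st.stage
        df["location"] = [locs[e] for e in df["env_i"]]
        df["year"] = [years[e] for e in df["env_i"]]
        df["soil"] = [soils[e] for e in df["env_i"]]
        df["env"] = [envs[e] for e in df["env_i"]]
        gpos = {g: i for i, g in enumerate(g_ids)}
        gi = df["genotype"].map(gpos).to_numpy()
        ei = df["env_i"].to_numpy()
        ci = df["crop"].map({c: i for i, c in enumerate(crops)}).to_numpy()
        ri = df["rep"].to_numpy() - 1
        ng, ne, nc, nr = len(g_ids), st.n_environments, len(crops), st.n_reps
        for tr in TRAITS:
            v = gvar[tr]
            eff_E = rng.normal(0, np.sqrt(config.env_var_frac * v), ne)
            eff_R = rng.normal(0, np.sqrt(config.rep_var_frac * v), (ne, nr))
            eff_C = rng.normal(0, np.sqrt(config.crop_var_frac * v), nc)
            eff_EC = rng.normal(0, np.sqrt(config.env_crop_var_frac * v), (ne, nc))
            eff_GE = rng.normal(0, np.sqrt(config.gxe_var_frac * v), (ng, ne))
            eff_GC = rng.normal(0, np.sqrt(config.gxc_var_frac * v), (ng, nc))
            eff_GEC = rng.normal(
                0, np.sqrt(config.gxec_var_frac * v), (ng, ne, nc)
            )
            resid = rng.normal(0, np.sqrt(config.resid_var_frac * v), len(df))
            gval = true.total_genotypic[tr].to_numpy()[current][gi]
            df[tr] = (
                mean[tr]
                + gval
                + eff_E[ei]
                + eff_R[ei, ri]
                + eff_C[ci]
                + eff_EC[ei, ci]
                + eff_GE[gi, ei]
                + eff_GC[gi, ci]
                + eff_GEC[gi, ei, ci]
                + resid
            )
        records.append(
            df[
                ["genotype", "stage", "location", "year", "crop", "soil", "rep", "env"]
                + list(TRAITS)
            ]
        )
    out = pd.concat(records, ignore_index=True)
    return out


def write_trial_csv(table: pd.DataFrame, path) -> None:
    cols = ["genotype", "stage", "location", "year", "crop", "soil", "rep"] + list(TRAITS)
    table[cols].to_csv(path, index=False)
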