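"""Validation schemes and metrics for genomic prediction.

Implements fivefold cross-validation within a stage and cross-stage
validation (train on an early-stage subset, predict an advanced stage),
with three metrics throughout: predictive ability (Pearson correlation of
GEBVs with phenotypic BLUEs), and the top/bottom coincidence indices (the
fraction of the observed best/worst 20% of clones recovered by the
predicted ranking). A marker-density sweep re-runs a scheme after greedy
LD pruning at a ladder of r² thresholds.

Models are threaded through as factories built by :func:`make_model`, so
every training-data-only contract (GWAS scans for the G+S model in
particular) is enforced inside the fold loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genorel import (
    GenotypeMatrix,
    Pedigree,
    RelationshipMatrix,
    amatrix,
    build_grm,
    hadamard_kernels,
    heterozygosity,
    hmatrix,
    ld_prune,
)
from .predict import (
    KernelSet,
    bayes_fit,
    gblup_fit,
    gs_with_fixed_snps,
    gwas_scan,
    ml_fit,
    rkhs_fit,
    rrblup_fit,
)

__all__ = [
    "CvScheme",
    "EvaluationResult",
    "DataBundle",
    "kfold_split",
    "predictive_ability",
    "coincidence_index",
    "make_model",
    "run_scheme",
    "marker_density_sweep",
]


@dataclass
class CvScheme:
    kind: str = "kfold"  # or "cross_stage"
    k: int = 5
    seed: int = 0
    train_filter: dict = field(default_factory=dict)  # e.g. {"stage": 2, "crop": "P"}
    test_filter: dict = field(default_factory=dict)
    drop_shared_genotypes: bool = True  # cross-stage leakage guard


@dataclass
class EvaluationResult:
    model_label: str
    trait: str
    scheme: str
    pa: float
    tci: float
    bci: float
    per_fold: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.pa <= 1.0 + 1e-9:
            raise ValueError("predictive ability outside [-1, 1]")


@dataclass
class DataBundle:
    """Everything a validation scheme needs.

    ``blues`` is a long table with columns genotype, trait, blue and any of
    stage/crop/soil used by scheme filters. Kernel construction from the
    genotype panel is cached on first use.
    """

    genotypes: GenotypeMatrix
    blues: pd.DataFrame
    pedigree: Pedigree | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def kernel(self, name: str) -> RelationshipMatrix:
        if name in self._cache:
            return self._cache[name]
        if name == "G_A":
            K = build_grm(self.genotypes, "additive")
        elif name == "G_D":
            K = build_grm(self.genotypes, "dominance")
        elif name in ("G_AA", "G_AD"):
            gaa, gad = hadamard_kernels(self.kernel("G_A"), self.kernel("G_D"))
            self._cache["G_AA"], self._cache["G_AD"] = gaa, gad
            return self._cache[name]
        elif name == "A":
            if self.pedigree is None:
                raise ValueError("bundle has no pedigree")
            K = amatrix(self.pedigree)
        elif name == "H":
            genotyped = [g for g in self.genotypes.ids]
            K = hmatrix(self.kernel("A"), self.kernel("G_A"), genotyped)
        else:
            raise KeyError(f"unknown kernel {name!r}")
        self._cache[name] = K
        return K

    def het_covariate(self) -> pd.DataFrame:
        if "het" not in self._cache:
            hv = heterozygosity(self.genotypes)
            het = hv.het - hv.het.mean()  # centered before inclusion
            self._cache["het"] = pd.DataFrame({"het": het}, index=hv.ids)
        return self._cache["het"]

    def subset_blues(self, trait: str, filt: dict) -> pd.Series:
        df = self.blues
        df = df[df["trait"] == trait] if "trait" in df.columns else df
        for col, val in filt.items():
            if col in df.columns:
                df = df[df[col] == val]
        s = df.groupby("genotype", sort=False)["blue"].mean()
        return s.dropna()


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def kfold_split(ids, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Disjoint random folds covering ``ids``; sizes differ by at most one."""
    ids = np.asarray(list(ids), dtype=object)
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def _aligned(gebv, blues) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = pd.Series(gebv).dropna()
    b = pd.Series(blues).dropna()
    common = g.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired values")
    return common.to_numpy(), g.loc[common].to_numpy(), b.loc[common].to_numpy()


def predictive_ability(gebv, blues) -> float:
    """Pearson correlation between GEBVs and observed BLUEs."""
    _, g, b = _aligned(gebv, blues)
    if np.ptp(g) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector; correlation undefined")
    return float(np.corrcoef(g, b)[0, 1])


def coincidence_index(
    gebv, blues, fraction: float = 0.2, side: str = "top"
) -> float:
    """Overlap of the predicted and observed selected tails.

    |top-s by GEBV ∩ top-s by BLUE| / s with s = ⌈n·fraction⌉; ties are
    broken by stable genotype-id order.
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    ids, g, b = _aligned(gebv, blues)
    n = len(ids)
    s = math.ceil(n * fraction)
    if s < 1:
        raise ValueError("n·fraction must be ≥ 1")
    # lexsort: primary key = value, secondary = id order (stable tie-break)
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    sign = 1.0 if side == "bottom" else -1.0

    def tail(values) -> set:
        order = np.lexsort((id_rank, sign * values))
        return set(order[:s])

    return len(tail(g) & tail(b)) / s


# ---------------------------------------------------------------------------
# model factory
# ---------------------------------------------------------------------------

_EGBLUP_COMBOS = {
    "G": ("G_A",),
    "G+D": ("G_A", "G_D"),
    "G+D+GG": ("G_A", "G_D", "G_AA"),
    "G+D+GD": ("G_A", "G_D", "G_AD"),
    "G+D+GD+GG": ("G_A", "G_D", "G_AD", "G_AA"),
}


def make_model(label: str, bundle: DataBundle, seed: int = 0, **opts):
    """Build a model adapter ``fit(y_train) -> gebv Series over all ids``.

    Labels: the eGBLUP family ("G", "G+D", "G+D+GG", "G+D+GD",
    "G+D+GD+GG", each optionally "+H" for the heterozygosity fixed
    effect), "HBLUP", "rrBLUP", the Bayesian alphabet ("BRR", "BL",
    "BayesA", "BayesB", "BayesC"), "RKHS", "RF", "SVM" and "G+S". All
    adapters see training phenotypes only; predictions cover every
    genotyped id.
    """
    base = label
    with_het = False
    if base.endswith("+H") and base not in ("G+S",):
        base, with_het = base[:-2], True

    if base in _EGBLUP_COMBOS:
        kernel_names = _EGBLUP_COMBOS[base]

        def fit(y_train: pd.Series) -> pd.Series:
            ks = KernelSet(
                kernels=[(nm, bundle.kernel(nm)) for nm in kernel_names],
                fixed_covariates=bundle.het_covariate() if with_het else None,
            )
            return gblup_fit(y_train, ks, **opts).gebv

    elif base == "HBLUP":

        def fit(y_train: pd.Series) -> pd.Series:
            ks = KernelSet(kernels=[("H", bundle.kernel("H"))])
            return gblup_fit(y_train, ks, **opts).gebv

    elif base == "rrBLUP":

        def fit(y_train: pd.Series) -> pd.Series:
            return rrblup_fit(y_train, bundle.genotypes).gebv

    elif base in ("BRR", "BL", "BayesA", "BayesB", "BayesC"):

        def fit(y_train: pd.Series) -> pd.Series:
            return bayes_fit(
                y_train, bundle.genotypes, method=base, seed=seed, **opts
            ).gebv

    elif base == "RKHS":

        def fit(y_train: pd.Series) -> pd.Series:
            return rkhs_fit(y_train, bundle.genotypes, seed=seed, **opts).gebv

    elif base in ("RF", "SVM"):
        method = {"RF": "random_forest", "SVM": "svr_radial"}[base]

        def fit(y_train: pd.Series) -> pd.Series:
            return ml_fit(
                y_train, bundle.genotypes, method=method, seed=seed,
                hyper=opts.get("hyper"),
            ).gebv

    elif base == "G+S":
        p_threshold = opts.pop("p_threshold", 0.001)
        allow_full_data_scan = opts.pop("allow_full_data_scan", False)
        full_blues = opts.pop("full_blues", None)

        def fit(y_train: pd.Series) -> pd.Series:
            ks = KernelSet(kernels=[("G", bundle.kernel("G_A"))])
            scan_y = (
                full_blues if (allow_full_data_scan and full_blues is not None)
                else y_train
            )
            scan = gwas_scan(
                scan_y, bundle.genotypes, bundle.kernel("G_A"),
                p_threshold=p_threshold,
            )
            return gs_with_fixed_snps(
                y_train, ks, scan, bundle.genotypes, **opts
            ).gebv

    else:
        raise KeyError(f"unknown model label {label!r}")

    fit.label = label  # type: ignore[attr-defined]
    return fit


# ---------------------------------------------------------------------------
# schemes
# ---------------------------------------------------------------------------


def _metrics(pred: pd.Series, obs: pd.Series, fraction: float = 0.2):
    pa = predictive_ability(pred, obs)
    tci = coincidence_index(pred, obs, fraction, "top")
    bci = coincidence_index(pred, obs, fraction, "bottom")
    return pa, tci, bci


def run_scheme(
    scheme: CvScheme,
    model,
    trait: str,
    bundle: DataBundle,
    fraction: float = 0.2,
) -> EvaluationResult:
    """Run a validation scheme with a model adapter from :func:`make_model`.

    kfold: fit on k−1 folds, predict the held-out fold; metrics are
    computed per fold and averaged. cross_stage: fit on the training
    subset's BLUEs, predict the test genotypes from genomic data alone and
    score against their BLUEs; genotypes present in both subsets stay in
    training only unless ``scheme.drop_shared_genotypes`` is switched off.
    """
    label = getattr(model, "label", "model")
    if scheme.kind == "kfold":
        y = bundle.subset_blues(trait, scheme.train_filter)
        if y.empty:
            raise ValueError(f"train filter {scheme.train_filter} selects no records")
        folds = kfold_split(y.index, k=scheme.k, seed=scheme.seed)
        rows = []
        for fi, test_ids in enumerate(folds):
            train_y = y.drop(index=test_ids)
            pred = model(train_y)
            pa, tci, bci = _metrics(pred.loc[test_ids], y.loc[test_ids], fraction)
            rows.append({"fold": fi, "pa": pa, "tci": tci, "bci": bci})
        per_fold = pd.DataFrame(rows)
        return EvaluationResult(
            model_label=label,
            trait=trait,
            scheme="kfold",
            pa=float(per_fold["pa"].mean()),
            tci=float(per_fold["tci"].mean()),
            bci=float(per_fold["bci"].mean()),
            per_fold=per_fold,
        )
    if scheme.kind == "cross_stage":
        y_train = bundle.subset_blues(trait, scheme.train_filter)
        y_test = bundle.subset_blues(trait, scheme.test_filter)
        if y_train.empty:
            raise ValueError(f"train filter {scheme.train_filter} selects no records")
        if y_test.empty:
            raise ValueError(f"test filter {scheme.test_filter} selects no records")
        if scheme.drop_shared_genotypes:
            y_test = y_test.drop(index=y_train.index, errors="ignore")
        if y_test.empty:
            raise ValueError("test set empty after removing shared genotypes")
        pred = model(y_train)
        pa, tci, bci = _metrics(pred.loc[y_test.index], y_test, fraction)
        return EvaluationResult(
            model_label=label, trait=trait, scheme="cross_stage",
            pa=pa, tci=tci, bci=bci,
        )
    raise ValueError(f"unknown scheme kind {scheme.kind!r}")


DEFAULT_THRESHOLDS = (0.1, 0.15, 0.2, 0.3, 0.4, 0.6, 0.8, 0.99)


def marker_density_sweep(
    bundle: DataBundle,
    trait: str,
    scheme: CvScheme,
    model_labels=("G",),
    thresholds=DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run a scheme after LD pruning at each r² threshold.

    LD pruning uses genotype data only (no phenotypes), so it is computed
    once per threshold on the panel. Returns threshold, n_markers, model,
    pa, tci, bci.
    """
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    rows = []
    for thr in thresholds:
        pruned = ld_prune(bundle.genotypes, thr)
        sub = DataBundle(
            genotypes=pruned, blues=bundle.blues, pedigree=bundle.pedigree
        )
        for lbl in model_labels:
            model = make_model(lbl, sub, seed=seed)
            res = run_scheme(scheme, model, trait, sub)
            rows.append(
                {
                    "threshold": thr,
                    "n_markers": pruned.m,
                    "model": lbl,
                    "pa": res.pa,
                    "tci": res.tci,
                    "bci": res.bci,
                }
            )
    return pd.DataFrame(rows)
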