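"""Genotype containers, marker QC and relationship matrices.

Implements the marker-filtering rules used for clonal breeding panels
(missing-rate and minor-allele-frequency thresholds, complete-LD
deduplication, greedy LD pruning) and the covariance structures of
whole-genome prediction:

* pedigree numerator relationship matrix ``A`` (Henderson's tabular method),
* VanRaden additive genomic relationship matrix ``G_A``,
* Vitezica dominance genomic relationship matrix ``G_D``,
* epistatic kernels ``G_AA = G_A ∘ G_A`` and ``G_AD = G_A ∘ G_D``
  (Hadamard products, PSD by the Schur product theorem),
* the Legarra single-step hybrid matrix ``H`` blending ``A`` and ``G``,
* the per-genotype genome-wide heterozygosity covariate.

Genotypes are diploid allele dosages in {0, 1, 2}; missing calls are
carried as NaN in the dosage array.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "RelationshipMatrix",
    "HeterozygosityVector",
    "EmptyPanelError",
    "filter_markers",
    "dedup_complete_ld",
    "ld_prune",
    "impute_mean",
    "build_grm",
    "amatrix",
    "hmatrix",
    "hadamard_kernels",
    "heterozygosity",
    "pairwise_r2",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_pedigree_csv",
    "write_pedigree_csv",
]


class EmptyPanelError(ValueError):
    """Raised when a filter removes every marker from the panel."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals × biallelic markers, dosage coded {0,1,2}, NaN = missing."""

    ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray  # float (n, m), NaN where missing

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.ids) != n:
            raise ValueError(f"ids length {len(self.ids)} != {n} rows")
        if not (len(self.marker_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("marker map length does not match dosage columns")
        if len(set(self.ids)) != n:
            raise ValueError("genotype ids must be unique")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)) \
            | self._imputed_flag()
        if not ok.all():
            bad = self.dosages[~ok]
            raise ValueError(f"dosages must be in {{0,1,2}} or NaN; found {bad[:5]}")

    def _imputed_flag(self) -> bool:
        # fractional dosages are legal only after mean imputation
        return bool(getattr(self, "imputed", False))

    imputed: bool = field(default=False)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency p of the dosage-counted allele (non-missing calls)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            marker_ids=self.marker_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosages=self.dosages[:, idx],
        )

    def take_ids(self, ids) -> "GenotypeMatrix":
        order = {g: i for i, g in enumerate(self.ids)}
        idx = np.array([order[g] for g in ids], dtype=int)
        return replace(self, ids=self.ids[idx], dosages=self.dosages[idx, :])


@dataclass
class Pedigree:
    """Three-column pedigree; unknown parent is None. Parents precede offspring."""

    id: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    genotyped: np.ndarray  # bool per individual

    def __post_init__(self) -> None:
        self.id = np.asarray(self.id, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.dam = np.asarray(self.dam, dtype=object)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        if len(set(self.id)) != len(self.id):
            raise ValueError("pedigree ids must be unique")
        seen = set()
        for i, s, d in zip(self.id, self.sire, self.dam):
            for p in (s, d):
                if p is not None and p not in seen:
                    raise ValueError(
                        f"parent {p!r} of {i!r} does not precede it; "
                        "sort the pedigree topologically first"
                    )
            seen.add(i)

    def __len__(self) -> int:
        return len(self.id)


@dataclass
class RelationshipMatrix:
    """Symmetric kinship-like matrix tagged by kind (A, G_A, G_D, G_AA, G_AD, H)."""

    kind: str
    ids: np.ndarray
    values: np.ndarray

    _KINDS = ("A", "G_A", "G_D", "G_AA", "G_AD", "H", "K")

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over ids")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.2e})")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def align(self, ids) -> np.ndarray:
        """Submatrix over ``ids`` in that order; KeyError if an id is absent."""
        order = {g: i for i, g in enumerate(self.ids)}
        idx = np.array([order[g] for g in ids], dtype=int)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class HeterozygosityVector:
    ids: np.ndarray
    het: np.ndarray

    def __post_init__(self) -> None:
        self.het = np.asarray(self.het, dtype=float)
        if np.any((self.het < 0) | (self.het > 1)):
            raise ValueError("heterozygosity must lie in [0, 1]")


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


def filter_markers(
    G: GenotypeMatrix, max_missing: float = 0.2, min_maf: float = 0.1
) -> GenotypeMatrix:
    """Retain markers with missing fraction ≤ ``max_missing`` and MAF ≥ ``min_maf``.

    MAF is computed on non-missing calls only. Marker order is preserved.
    """
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    miss = np.isnan(G.dosages).mean(axis=0)
    p = G.allele_freq
    maf = np.minimum(p, 1.0 - p)
    keep = (miss <= max_missing) & (maf >= min_maf) & ~np.isnan(maf)
    if not keep.any():
        raise EmptyPanelError(
            f"no markers survive max_missing={max_missing}, min_maf={min_maf}"
        )
    return G.take_markers(np.flatnonzero(keep))


def _corr_with_kept(col: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of one centered column against centered columns."""
    num = block.T @ col
    den = np.sqrt((block**2).sum(axis=0) * (col**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r**2


def pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """All-pairs composite-LD r² on (imputed) dosage columns.

    Monomorphic columns get r² = 0 against everything.
    """
    X = dosages - dosages.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xs = np.where(sd > 0, X / sd, 0.0)
    r = (Xs.T @ Xs) / dosages.shape[0]
    return r**2


def dedup_complete_ld(G: GenotypeMatrix, tol: float = 1e-12) -> GenotypeMatrix:
    """Among markers in complete LD (r² = 1 on imputed dosages) keep the first by map order."""
    X = np.where(np.isnan(G.dosages), np.nanmean(G.dosages, axis=0), G.dosages)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xs = np.where(sd > 0, X / sd, 0.0)
    # markers in complete LD share the same normalized profile up to sign
    keep: list[int] = []
    kept_cols: list[np.ndarray] = []
    n = G.n
    for j in range(G.m):
        col = Xs[:, j]
        dup = False
        for kc in kept_cols:
            r = float(kc @ col) / n
            if 1.0 - r * r <= tol:
                dup = True
                break
        if not dup:
            keep.append(j)
            kept_cols.append(col)
    return G.take_markers(np.array(keep, dtype=int))


def ld_prune(
    G: GenotypeMatrix, r2_threshold: float, window: int = 100
) -> GenotypeMatrix:
    """Greedy LD pruning in map order.

    A marker is kept iff its r² with every previously kept marker on the same
    chromosome within ``window`` kept positions is below ``r2_threshold``.
    Deterministic; kept-marker count is non-decreasing in the threshold.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    X = np.where(np.isnan(G.dosages), np.nanmean(G.dosages, axis=0), G.dosages)
    X = X - X.mean(axis=0)
    keep: list[int] = []
    kept_by_chrom: dict[object, list[int]] = {}
    for j in range(G.m):
        c = G.chrom[j]
        prior = kept_by_chrom.get(c, [])[-window:]
        ok = True
        if prior:
            r2 = _corr_with_kept(X[:, j], X[:, prior])
            ok = bool(np.all(r2 < r2_threshold))
        if ok:
            keep.append(j)
            kept_by_chrom.setdefault(c, []).append(j)
    return G.take_markers(np.array(keep, dtype=int))


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean over non-missing calls."""
    if not np.isnan(G.dosages).any():
        return replace(G, imputed=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(G.dosages, axis=0)
    if np.isnan(means).any():
        bad = G.marker_ids[np.isnan(means)][:5]
        raise ValueError(f"markers entirely missing (filter first): {list(bad)}")
    filled = np.where(np.isnan(G.dosages), means, G.dosages)
    return replace(G, dosages=filled, imputed=True)


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------


def build_grm(G: GenotypeMatrix, kind: str = "additive") -> RelationshipMatrix:
    """Genomic relationship matrix from imputed dosages.

    additive (VanRaden): W = dosage − 2p,  G_A = W W' / Σ 2p(1−p)
    dominance (Vitezica): per-marker coding (−2p², 2pq, −2q²) for dosages
    (0, 1, 2), G_D = H H' / Σ (2pq)².

    Monomorphic markers (p ∈ {0,1}) contribute nothing and are excluded with
    a warning count.
    """
    if np.isnan(G.dosages).any():
        raise ValueError("impute missing dosages before building a GRM")
    p = G.dosages.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        warnings.warn(f"{n_mono} monomorphic markers excluded from GRM")
    if not poly.any():
        raise EmptyPanelError("no polymorphic markers left for the GRM")
    X = G.dosages[:, poly]
    p = p[poly]
    q = 1.0 - p
    if kind == "additive":
        W = X - 2.0 * p
        denom = float(np.sum(2.0 * p * q))
        values = (W @ W.T) / denom
        tag = "G_A"
    elif kind == "dominance":
        # dosage 0 → −2p², 1 → 2pq, 2 → −2q²
        H0, H1, H2 = -2.0 * p**2, 2.0 * p * q, -2.0 * q**2
        # linear-in-dosage-indicator expansion works for fractional (imputed)
        # dosages too: interpolate the three codings piecewise-linearly
        lo = np.clip(X, 0.0, 1.0)          # weight along 0→1 segment
        hi = np.clip(X - 1.0, 0.0, 1.0)    # weight along 1→2 segment
        Hm = H0 + (H1 - H0) * lo + (H2 - H1) * hi
        Hm = Hm - Hm.mean(axis=0)
        denom = float(np.sum((2.0 * p * q) ** 2))
        values = (Hm @ Hm.T) / denom
        tag = "G_D"
    else:
        raise ValueError(f"kind must be 'additive' or 'dominance', got {kind!r}")
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(kind=tag, ids=G.ids, values=values)


def amatrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by Henderson's tabular method.

    a_ii = 1 + 0.5·a(sire_i, dam_i); a_ij = 0.5·(a(j, sire_i) + a(j, dam_i));
    founders have diagonal 1 and zero relationship to earlier individuals.
    """
    n = len(ped)
    pos = {g: i for i, g in enumerate(ped.id)}
    A = np.zeros((n, n))
    for i in range(n):
        s = pos.get(ped.sire[i]) if ped.sire[i] is not None else None
        d = pos.get(ped.dam[i]) if ped.dam[i] is not None else None
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        row = np.zeros(i)
        if s is not None:
            row += 0.5 * A[s, :i]
        if d is not None:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(kind="A", ids=ped.id, values=A)


def hmatrix(
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    genotyped,
    tau_blend: float = 0.05,
) -> RelationshipMatrix:
    """Single-step hybrid relationship matrix (Legarra construction).

    With individuals partitioned into non-genotyped (1) and genotyped (2):

        H22 = G*,   H12 = A12 A22⁻¹ G*,
        H11 = A11 + A12 A22⁻¹ (G* − A22) A22⁻¹ A21,

    where G* = (1 − tau_blend)·G + tau_blend·A22 blends in the pedigree
    matrix for invertibility. ``genotyped`` lists the ids covered by G.
    """
    genotyped = list(genotyped)
    id_set = set(A.ids)
    missing = [g for g in genotyped if g not in id_set]
    if missing:
        raise ValueError(f"genotyped ids not in A: {missing[:5]}")
    if not genotyped:
        return RelationshipMatrix(kind="H", ids=A.ids, values=A.values.copy())
    gset = set(genotyped)
    nong = [g for g in A.ids if g not in gset]
    order = nong + genotyped
    A11 = A.align(nong) if nong else np.zeros((0, 0))
    A22 = A.align(genotyped)
    idx = {g: i for i, g in enumerate(A.ids)}
    A12 = A.values[np.ix_([idx[g] for g in nong], [idx[g] for g in genotyped])]
    Gs = (1.0 - tau_blend) * G.align(genotyped) + tau_blend * A22
    try:
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "A22 is singular; consider blending (tau_blend > 0)"
        ) from exc
    T = A12 @ A22_inv
    n = len(order)
    H = np.zeros((n, n))
    k = len(nong)
    H[k:, k:] = Gs
    if k:
        H[:k, :k] = A11 + T @ (Gs - A22) @ T.T
        H[:k, k:] = T @ Gs
        H[k:, :k] = H[:k, k:].T
    H = 0.5 * (H + H.T)
    # return in A's original id order
    back = {g: i for i, g in enumerate(order)}
    perm = np.array([back[g] for g in A.ids], dtype=int)
    return RelationshipMatrix(kind="H", ids=A.ids, values=H[np.ix_(perm, perm)])


def hadamard_kernels(
    G_A: RelationshipMatrix, G_D: RelationshipMatrix, rescale: bool = True
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Epistatic kernels G_AA = G_A∘G_A and G_AD = G_A∘G_D.

    With ``rescale`` each kernel is divided by its mean diagonal so variance
    components are comparable across kernels.
    """
    if len(G_A.ids) != len(G_D.ids) or not np.array_equal(G_A.ids, G_D.ids):
        raise ValueError("G_A and G_D must share the same ids in the same order")
    gaa = G_A.values * G_A.values
    gad = G_A.values * G_D.values
    if rescale:
        for mat in (gaa, gad):
            md = float(np.mean(np.diag(mat)))
            if md > 0:
                mat /= md
    return (
        RelationshipMatrix(kind="G_AA", ids=G_A.ids, values=gaa),
        RelationshipMatrix(kind="G_AD", ids=G_A.ids, values=gad),
    )


def heterozygosity(G: GenotypeMatrix) -> HeterozygosityVector:
    """Per-genotype fraction of markers with dosage exactly 1 (missing skipped)."""
    het_calls = (G.dosages == 1.0).sum(axis=1)
    n_obs = (~np.isnan(G.dosages)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.where(n_obs > 0, het_calls / n_obs, 0.0)
    return HeterozygosityVector(ids=G.ids, het=het)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.dosages, index=G.ids, columns=G.marker_ids)
    df.index.name = "genotype"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, chrom=None, pos=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    m = df.shape[1]
    return GenotypeMatrix(
        ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        chrom=np.asarray(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1)),
        dosages=df.to_numpy(dtype=float),
        imputed=bool(np.nanmax(df.to_numpy() % 1, initial=0) > 0),
    )


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal unphased VCF with GT only; dosage counts the ALT allele."""
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(str(g) for g in G.ids) + "\n")
    for j in range(G.m):
        calls = [
            "./." if np.isnan(x) else gt_code[float(x)] for x in G.dosages[:, j]
        ]
        buf.write(
            f"{G.chrom[j]}\t{int(G.pos[j])}\t{G.marker_ids[j]}\tA\tT\t.\t.\t.\tGT\t"
            + "\t".join(calls)
            + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into ALT-dosage coding via cyvcf2 (biallelic sites only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.asarray(vcf.samples, dtype=object)
    marker_ids, chrom, pos, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unk,3 hom-alt
        dos = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts))
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        rows.append(dos)
    return GenotypeMatrix(
        ids=ids,
        marker_ids=np.asarray(marker_ids, dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        dosages=np.asarray(rows).T,
    )


def write_pedigree_csv(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        {
            "id": ped.id,
            "sire": [s if s is not None else 0 for s in ped.sire],
            "dam": [d if d is not None else 0 for d in ped.dam],
            "genotyped": ped.genotyped.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    sent = {"0", "NA", "", "nan"}
    sire = [None if str(s) in sent else s for s in df["sire"]]
    dam = [None if str(d) in sent else d for d in df["dam"]]
    genotyped = (
        df["genotyped"].astype(bool).to_numpy()
        if "genotyped" in df
        else np.ones(len(df), dtype=bool)
    )
    return Pedigree(
        id=df["id"].to_numpy(dtype=object),
        sire=np.asarray(sire, dtype=object),
        dam=np.asarray(dam, dtype=object),
        genotyped=genotyped,
    )
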