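"""PC-Relate-style kinship estimation from individual-specific allele
frequencies.

The estimator regresses population structure out of the genotypes with
principal components, giving each sample its own expected allele frequency
mu_si per marker, and then measures the residual genotype covariance between
samples:

    phi_ij = sum_s (g_si - 2 mu_si)(g_sj - 2 mu_sj)
             / (4 sum_s sqrt(mu_si (1 - mu_si) mu_sj (1 - mu_sj)))

with minor-allele dosages g in {0, 1, 2} (pseudo-haploid calls contribute
{0, 2}).  Missing genotypes contribute a zero residual to the numerator while
the denominator sums over all kept markers — the mean-imputation convention
that makes the raw coefficient scale linearly with the pairwise overlapping
marker fraction, which is exactly what the downstream correction divides out.

Markers are pruned at a cohort minor-allele-frequency threshold (default
0.05) before estimation, mirroring the default pruning of the upstream
PCA-based genotype tools this workflow interoperates with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset

log = logging.getLogger(__name__)


@dataclass
class IndividualAF:
    """Per-sample, per-marker individual-specific allele frequencies."""

    mu: np.ndarray  # (n_samples, n_kept) in [eps, 1-eps]
    kept_idx: np.ndarray  # marker indices retained after MAF pruning
    K: int
    maf_min: float
    eps: float
    components: np.ndarray  # (n_samples, K) PC basis used for the regression
    eigenvalues: np.ndarray  # full spectrum of the (rescaled) Gram matrix
    inbreeding: np.ndarray | None = None


@dataclass
class KinshipResult:
    """Raw (uncorrected) pairwise kinship matrix with its settings."""

    phi: np.ndarray  # (n, n) symmetric; diagonal = self-kinship
    sample_ids: list
    inbreeding: np.ndarray | None = None
    settings: dict = field(default_factory=dict)


def _missingness_rescaled(X: np.ndarray, typed: np.ndarray) -> np.ndarray:
    """Rescale rows so per-sample typedness does not masquerade as structure.

    Mean-imputed standardized rows of sparsely typed samples have shrunken
    norms, which spreads the bulk eigenvalue spectrum and would confuse any
    bulk-edge criterion.  Dividing each row by the square root of its typed
    fraction restores an approximately flat bulk.
    """
    frac = typed.mean(axis=1)
    frac = np.maximum(frac, 1e-6)
    return X / np.sqrt(frac)[:, None]


def _select_components(eigvals, U, n, m, margin=1.25, localization=0.5):
    """Indices of eigenvectors carrying population structure.

    A component is retained when its eigenvalue exceeds the Marchenko-Pastur
    bulk edge (noise scale from the median eigenvalue, with a safety margin)
    AND its loadings are not concentrated on one or two samples.  Localized
    components are relative-pair or single-outlier directions; regressing on
    them would absorb the very relatedness signal the estimator measures.
    """
    sigma2 = float(np.median(eigvals)) if len(eigvals) else 0.0
    edge = sigma2 * (1.0 + np.sqrt(n / m)) ** 2 * margin
    selected = []
    for k in range(len(eigvals)):
        if eigvals[k] <= edge:
            break  # eigenvalues sorted descending
        loadings2 = np.sort(U[:, k] ** 2)[::-1]
        if loadings2[:2].sum() >= localization:
            continue
        selected.append(k)
    return selected, edge


def individual_af(
    ds: GenotypeDataset,
    K: int | str = "auto",
    maf_min: float = 0.05,
    inbreed: bool = True,
    eps: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> IndividualAF:
    """Estimate individual-specific allele frequencies from K principal
    components of the standardized, mean-imputed genotype matrix.

    ``K="auto"`` keeps the components above the Marchenko-Pastur bulk edge of
    the missingness-rescaled spectrum, skipping components localized on <= 2
    samples (relative pairs). ``K=0`` reduces mu to the cohort frequency.
    With ``inbreed=True`` a per-sample inbreeding coefficient is estimated
    from the excess residual variance (alternating mu/F update; for
    pseudo-haploid data F converges to ~1 by construction, reflecting the
    single sampled allele).
    """
    n = ds.n_samples
    if n < 2:
        raise ValueError("individual_af requires at least 2 samples")
    if isinstance(K, str) and K != "auto":
        raise ValueError(f"K must be an integer or 'auto', got {K!r}")
    if not isinstance(K, str) and K >= n:
        raise ValueError(f"K={K} must be smaller than the sample count {n}")

    typed = ds.calls != 3  # MISSING
    Gz = np.where(typed, ds.calls, 0).astype(np.float64)  # zeros at missing
    cnt = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = Gz.sum(axis=0) / (2.0 * cnt)
    p = np.where(cnt > 0, p, 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = (maf >= maf_min) & (maf > 0)  # monomorphic markers carry no signal
    if not keep.any():
        raise ValueError(f"all markers pruned at maf_min={maf_min}")
    kept_idx = np.flatnonzero(keep)
    tk = np.ascontiguousarray(typed[:, kept_idx], dtype=np.float64)
    Gk = np.ascontiguousarray(Gz[:, kept_idx])  # zero where untyped
    pk = p[kept_idx]
    m = len(kept_idx)

    if eps is None:
        eps = float(np.clip(1.0 / (2.0 * n), 1e-4, 0.01))

    # standardized, mean-imputed matrix for the PCA; the sample-space Gram
    # matrix is all we need (right singular vectors are never used).
    # Untyped entries of Gk are zero, so subtracting 2*pk*tk zeroes them.
    denom = np.sqrt(2.0 * pk * (1.0 - pk))
    X = (Gk - (2.0 * pk) * tk) / denom
    Xs = _missingness_rescaled(X, tk)
    gram = (Xs @ Xs.T) / m
    w, V = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    eigvals = np.maximum(w[order], 0.0)
    U = V[:, order]

    if K == "auto":
        selected, edge = _select_components(eigvals, U, n, m)
        log.info(
            "auto K selection: %d components above bulk edge %.4g", len(selected), edge
        )
    else:
        selected = list(range(int(K)))
    K_used = len(selected)

    # affine regression of each marker's (half-)dosage on the PC basis
    D = np.empty((n, K_used + 1))
    D[:, 0] = 1.0
    if K_used:
        D[:, 1:] = U[:, selected]
    Himp = Gk / 2.0 + pk * (1.0 - tk)  # mean-imputed half-dosage
    B = np.linalg.solve(D.T @ D, D.T @ Himp)
    mu = np.clip(D @ B, eps, 1.0 - eps)

    F = None
    if inbreed:
        F = np.zeros(n)
        for _ in range(max_iter):
            het_typed = 2.0 * mu * (1.0 - mu) * tk
            resid = Gk - 2.0 * mu * tk  # zero at untyped sites
            num = (resid**2 - het_typed).sum(axis=1)
            den = het_typed.sum(axis=1)
            F_new = np.clip(np.divide(num, den, out=np.zeros(n), where=den > 0), -1.0, 1.0)
            if np.max(np.abs(F_new - F)) < tol:
                F = F_new
                break
            F = F_new

    return IndividualAF(
        mu=mu,
        kept_idx=kept_idx,
        K=K_used,
        maf_min=maf_min,
        eps=eps,
        components=U[:, selected] if K_used else np.empty((n, 0)),
        eigenvalues=eigvals,
        inbreeding=F,
    )


def kinship_matrix(ds: GenotypeDataset, iaf: IndividualAF) -> KinshipResult:
    """Raw pairwise kinship from residual genotype covariance.

    Missing genotypes contribute zero to the numerator while the denominator
    runs over all kept markers (mean-imputation convention); consequently the
    raw coefficient of a partially typed pair scales linearly with its
    overlapping-marker fraction, by design.
    """
    calls = ds.calls[:, iaf.kept_idx]
    typed = (calls != 3).astype(np.float64)
    G = np.where(calls != 3, calls, 0).astype(np.float64)
    mu = iaf.mu
    if mu.shape != G.shape:
        raise ValueError("iaf was not computed on this dataset (shape mismatch)")
    R = G - 2.0 * mu * typed  # zero residual at untyped sites
    S = np.sqrt(mu * (1.0 - mu))
    den = 4.0 * (S @ S.T)
    if np.any(den <= 0):
        raise ValueError("degenerate denominator: all mu at the clip bounds")
    phi = (R @ R.T) / den
    phi = (phi + phi.T) / 2.0
    return KinshipResult(
        phi=phi,
        sample_ids=ds.sample_ids,
        inbreeding=iaf.inbreeding,
        settings={
            "K": iaf.K,
            "maf_min": iaf.maf_min,
            "eps": iaf.eps,
            "n_markers_kept": int(len(iaf.kept_idx)),
            "external": False,
        },
    )


def estimate_kinship(ds: GenotypeDataset, K="auto", maf_min=0.05, inbreed=True):
    """Convenience wrapper: individual_af followed by kinship_matrix."""
    iaf = individual_af(ds, K=K, maf_min=maf_min, inbreed=inbreed)
    return kinship_matrix(ds, iaf)


def write_kinship_tsv(result: KinshipResult, path: str) -> None:
    df = pd.DataFrame(result.phi, index=result.sample_ids, columns=result.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_kinship_tsv(path: str) -> KinshipResult:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipResult(
        phi=df.to_numpy(dtype=float),
        sample_ids=[str(c) for c in df.columns],
        settings={"external": False},
    )


def read_external_kinship(path: str, sample_ids: list) -> KinshipResult:
    """Wrap a dense kinship matrix computed by an external tool.

    Accepts either a bare whitespace-separated numeric matrix or a
    tab-separated matrix with a sample-id header row/column; the dimension
    must equal the cohort size.
    """
    with open(path) as fh:
        first = fh.readline()
    try:
        [float(x) for x in first.split()]
        header = False
    except ValueError:
        header = True
    if header:
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = df.to_numpy(dtype=float)
    else:
        mat = np.loadtxt(path)
        if mat.ndim == 0:
            mat = mat.reshape(1, 1)
        elif mat.ndim == 1:
            mat = mat.reshape(1, -1)
    n = len(sample_ids)
    if mat.shape != (n, n):
        raise ValueError(
            f"external kinship matrix is {mat.shape}, cohort has {n} samples"
        )
    return KinshipResult(phi=mat, sample_ids=list(sample_ids), settings={"external": True})
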