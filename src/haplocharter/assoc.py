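"""PC-adjusted linear-model association scan and Welch group contrasts.

The scan is a deliberate methodological substitution: the original locus
discovery used FarmCPU and kinship MLM models, which are out of scope here.
An ordinary-least-squares scan of phenotype on per-site alternate-allele
dosage, adjusted for the leading principal components of the dosage matrix
and thresholded by Bonferroni (alpha / number of tested sites), is enough to
make the pipeline end-to-end runnable and its focal-SNP discovery testable on
synthetic cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .variants import GenotypeMatrix


@dataclass(frozen=True)
class AssocResult:
    position: int
    effect: float      # g per 100 g per alternate allele
    p_value: float
    n_used: int


@dataclass(frozen=True)
class ScanResult:
    results: list[AssocResult]
    threshold: float          # Bonferroni: alpha / n tested sites
    alpha: float
    n_tested: int
    skipped_positions: tuple[int, ...]  # monomorphic sites

    def top_hit(self) -> AssocResult:
        return min(self.results, key=lambda r: r.p_value)


@dataclass(frozen=True)
class WelchResult:
    mean_a: float
    mean_b: float
    diff: float       # mean_a - mean_b
    t_stat: float
    df: float         # Welch–Satterthwaite
    p_value: float
    n_a: int
    n_b: int


def bonferroni_threshold(alpha: float, n_markers: int) -> float:
    """Family-wise significance threshold alpha / marker count."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return alpha / n_markers


def pca_covariates(m: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Leading principal components of the centred dosage matrix.

    Missing dosages are imputed to the per-site mean before centring.  Returns
    an (n_samples, k) score matrix ordered by explained variance; if the
    matrix rank is below ``k`` the surplus columns are dropped with a warning.
    Sites contribute alternate-allele counts 0/1/2.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    n = m.n_samples
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, have {n}")
    if k == 0 or m.n_sites == 0:
        return np.empty((n, 0))
    d = m.dosage(mean_impute=True)          # (N, S)
    d = d - d.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(d, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-9)) if s.size and s[0] > 0 else 0
    if rank < k:
        warnings.warn(
            f"dosage matrix rank {rank} < requested k={k}; returning {rank} PCs",
            stacklevel=2,
        )
        k = rank
    return u[:, :k] * s[:k]


def scan(
    m: GenotypeMatrix,
    phenotype: Sequence[float],
    covariates: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> ScanResult:
    """OLS scan of phenotype ~ dosage + covariates at every site.

    Samples with missing phenotype are dropped; missing dosages are mean
    imputed per site (scan only — LD and haplotyping never impute).
    Monomorphic sites are skipped and recorded.  Two-sided p-values for the
    dosage coefficient; Bonferroni threshold = alpha / tested sites.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != m.n_samples:
        raise ValueError("phenotype length does not match sample count")
    keep = ~np.isnan(y)
    y = y[keep]
    n = int(keep.sum())
    if covariates is None:
        covariates = np.empty((m.n_samples, 0))
    X0 = np.column_stack([np.ones(m.n_samples), np.asarray(covariates, float)])[keep]
    p0 = X0.shape[1]
    if n <= p0 + 1:
        raise ValueError("too few phenotyped samples for the model")

    D = m.dosage(mean_impute=True)[keep]            # (n, S)
    called = ~np.isnan(m.dosage(mean_impute=False))[keep]  # pre-imputation calls

    # Frisch–Waugh: residualise y and every dosage column on [1, covariates]
    Q, _r = np.linalg.qr(X0)
    y_r = y - Q @ (Q.T @ y)
    D_r = D - Q @ (Q.T @ D)

    ss_d = np.einsum("ij,ij->j", D_r, D_r)
    results: list[AssocResult] = []
    skipped: list[int] = []
    df = n - p0 - 1
    yy = float(y_r @ y_r)
    for j, site in enumerate(m.sites):
        col = D[:, j]
        if np.nanstd(col) == 0 or ss_d[j] <= 1e-12:
            skipped.append(site.pos)
            continue
        beta = float(D_r[:, j] @ y_r) / ss_d[j]
        rss = yy - beta * beta * ss_d[j]
        rss = max(rss, 0.0)
        se = math.sqrt(rss / df / ss_d[j]) if df > 0 else float("nan")
        if se == 0 or math.isnan(se):
            p = 1.0 if beta == 0 else 0.0
            t = float("inf") if p == 0 else 0.0
        else:
            t = beta / se
            p = float(2 * stats.t.sf(abs(t), df))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        results.append(
            AssocResult(
                position=site.pos,
                effect=beta,
                p_value=p,
                n_used=int(called[:, j].sum()),
            )
        )
    n_tested = len(results)
    threshold = bonferroni_threshold(alpha, n_tested) if n_tested else float("nan")
    return ScanResult(
        results=results,
        threshold=threshold,
        alpha=alpha,
        n_tested=n_tested,
        skipped_positions=tuple(skipped),
    )


def permutation_fwer(
    m: GenotypeMatrix,
    phenotype: Sequence[float],
    n_perm: int = 200,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Empirical family-wise error of the Bonferroni-thresholded scan.

    Permutes the phenotype ``n_perm`` times and returns the fraction of
    permutations in which any site's p-value falls below alpha / n_sites.
    Vectorised (no covariates; the null is exchangeable by construction).
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    n = y.size
    D = m.dosage(mean_impute=True)[keep]
    D = D - D.mean(axis=0, keepdims=True)
    ss_d = np.einsum("ij,ij->j", D, D)
    poly = ss_d > 1e-12
    D = D[:, poly]
    ss_d = ss_d[poly]
    S = D.shape[1]
    if S == 0:
        raise ValueError("no polymorphic sites")
    thr = bonferroni_threshold(alpha, S)
    df = n - 2
    Y = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    Y = Y - Y.mean(axis=0, keepdims=True)
    B = (D.T @ Y) / ss_d[:, None]                     # (S, P) slopes
    yy = np.einsum("ij,ij->j", Y, Y)                  # (P,)
    rss = np.clip(yy[None, :] - B * B * ss_d[:, None], 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / ss_d[:, None])
        t = np.where(se > 0, B / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    return float((p.min(axis=0) < thr).mean())


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    Implements the textbook statistic and Welch–Satterthwaite degrees of
    freedom directly; requires n >= 2 per group and positive variance in at
    least one group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"need >=2 observations per group (got {na}, {nb})")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if va == 0 and vb == 0:
        ma, mb = float(a.mean()), float(b.mean())
        if ma == mb:
            return WelchResult(ma, mb, 0.0, 0.0, float(na + nb - 2), 1.0, na, nb)
        raise ValueError("zero variance in both groups with unequal means")
    ma, mb = float(a.mean()), float(b.mean())
    sa, sb = va / na, vb / nb
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        (sa ** 2 / (na - 1) if na > 1 else 0.0)
        + (sb ** 2 / (nb - 1) if nb > 1 else 0.0)
    )
    p = float(2 * stats.t.sf(abs(t), df))
    return WelchResult(ma, mb, ma - mb, float(t), float(df), p, na, nb)
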