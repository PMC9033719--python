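"""Pairwise linkage disequilibrium, tag sites, Gabriel blocks, region delimitation.

All statistics are computed on phased haplotypes coded {0 ref, 1 alt, -1
missing}; half-missing diploids contribute their one called haplotype.  For a
pair of biallelic sites with haplotype frequencies pA, pB and joint pAB over
jointly non-missing haplotypes:

    D   = pAB - pA*pB
    D'  = |D| / Dmax,  Dmax = min(pA*(1-pB), (1-pA)*pB)        if D > 0
                        Dmax = min(pA*pB, (1-pA)*(1-pB))        if D < 0
    r^2 = D^2 / (pA*(1-pA)*pB*(1-pB))

Gabriel-style haplotype blocks use a 90% confidence interval on D' obtained by
profiling the multinomial likelihood of the four gamete counts over a fixed
101-point D' grid, the approach popularised by Haploview/PLINK.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .variants import GenotypeMatrix, MISSING


@dataclass(frozen=True)
class LDPair:
    """LD between two sites; statistics are NaN when undefined."""

    site_a: int
    site_b: int
    r2: float
    dprime: float
    n_haplotypes: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r2)


@dataclass(frozen=True)
class LDRegion:
    """Contiguous stretch of sites in strong LD with a focal site."""

    focal_pos: int
    threshold: float
    start: int
    end: int  # 1-based half-open
    n_supporting_sites: int
    max_gap: int

    def __post_init__(self) -> None:
        if not (self.start <= self.focal_pos < self.end):
            raise ValueError("focal position must lie inside the region")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HaploBlock:
    start: int
    end: int  # 1-based half-open
    member_positions: tuple[int, ...]
    fraction_strong_pairs: float

    def __post_init__(self) -> None:
        if len(self.member_positions) < 2:
            raise ValueError("a block needs at least two member sites")


def _pair_counts(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[int, int, int, int]:
    """Gamete counts (n11, n10, n01, n00) over jointly called haplotypes."""
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok]
    b = b[ok]
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return n11, n10, n01, n00


def ld_pair(hap_a: np.ndarray, hap_b: np.ndarray,
            pos_a: int = 0, pos_b: int = 0) -> LDPair:
    """r² and D' for two binary haplotype vectors.

    Monomorphism among jointly called haplotypes leaves both statistics
    undefined (NaN); such pairs are excluded downstream.
    """
    n11, n10, n01, n00 = _pair_counts(hap_a, hap_b)
    n = n11 + n10 + n01 + n00
    if n == 0:
        return LDPair(pos_a, pos_b, float("nan"), float("nan"), 0)
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDPair(pos_a, pos_b, float("nan"), float("nan"), n)
    pAB = n11 / n
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDPair(pos_a, pos_b, float(r2), float(min(dprime, 1.0)), n)


def r2_matrix(haps: np.ndarray) -> np.ndarray:
    """All-pairs r² for a (n_sites, n_haplotypes) binary matrix with missing.

    Vectorised via indicator matrix products; undefined pairs are NaN.
    """
    H = np.asarray(haps)
    A = (H == 1).astype(np.float64)
    C = (H != MISSING).astype(np.float64)
    n = C @ C.T
    nA = A @ C.T          # site i alt, site j called
    nAB = A @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = nA / n
        pB = nA.T / n
        pAB = nAB / n
        D = pAB - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, D * D / denom, np.nan)
        r2 = np.where(n > 0, r2, np.nan)
    return r2


def r2_to_focal(m: GenotypeMatrix, focal_pos: int) -> np.ndarray:
    """r² of every site against the focal site (NaN where undefined)."""
    haps = m.binary_haplotypes()
    fi = m.site_index(focal_pos)
    focal = haps[fi]
    out = np.empty(m.n_sites)
    for i in range(m.n_sites):
        out[i] = ld_pair(haps[i], focal).r2
    return out


def tag_sites(m: GenotypeMatrix, focal_pos: int, tag_r2: float = 0.9) -> list[int]:
    """Positions of all sites with r² >= ``tag_r2`` to the focal site.

    The focal site itself is always included.  Raises if the focal site is
    monomorphic (no LD is defined against it).
    """
    haps = m.binary_haplotypes()
    fi = m.site_index(focal_pos)
    focal = haps[fi]
    called = focal[focal != MISSING]
    if called.size == 0 or len(set(called.tolist())) < 2:
        raise ValueError(f"focal site {focal_pos} is monomorphic")
    out = []
    for i, site in enumerate(m.sites):
        if i == fi:
            out.append(site.pos)
            continue
        pair = ld_pair(haps[i], focal)
        if pair.defined and pair.r2 >= tag_r2:
            out.append(site.pos)
    return sorted(out)


def delimit_region(
    m: GenotypeMatrix,
    focal_pos: int,
    r2_threshold: float = 0.91,
    max_gap: int = 50_000,
) -> LDRegion:
    """Delimit the trait region by LD decay around a focal site.

    Scanning outward from the focal site, supporting sites (r² >= threshold
    with the focal) are chained as long as no gap between consecutive
    supporting sites exceeds ``max_gap``.  The region start is the leftmost
    chained site; the end is one past the rightmost (half-open).  A focal site
    with no linked neighbours yields the degenerate single-site region.
    """
    r2 = r2_to_focal(m, focal_pos)
    pos = m.positions
    fi = m.site_index(focal_pos)
    support = np.where(np.nan_to_num(r2, nan=-1.0) >= r2_threshold)[0]
    support = set(support.tolist()) | {fi}
    sup_pos = sorted(pos[i] for i in support)

    k = sup_pos.index(focal_pos)
    left = k
    while left > 0 and sup_pos[left] - sup_pos[left - 1] <= max_gap:
        left -= 1
    right = k
    while right < len(sup_pos) - 1 and sup_pos[right + 1] - sup_pos[right] <= max_gap:
        right += 1
    chained = sup_pos[left:right + 1]
    return LDRegion(
        focal_pos=focal_pos,
        threshold=r2_threshold,
        start=int(chained[0]),
        end=int(chained[-1]) + 1,
        n_supporting_sites=len(chained),
        max_gap=max_gap,
    )


# ---------------------------------------------------------------------------
# Gabriel confidence-interval blocks
# ---------------------------------------------------------------------------

_DPRIME_GRID = np.linspace(0.0, 1.0, 101)  # fixed resolution for reproducibility


def dprime_ci(hap_a: np.ndarray, hap_b: np.ndarray,
              conf: float = 0.90) -> tuple[float, float]:
    """90% confidence bounds on |D'| from the multinomial likelihood.

    Allele frequencies are fixed at their sample estimates and the likelihood
    of the four observed gamete counts is profiled over |D'| on a fixed
    101-point grid in the direction of the observed D.  Returns (lower, upper);
    NaN bounds for monomorphic pairs.
    """
    n11, n10, n01, n00 = _pair_counts(hap_a, hap_b)
    n = n11 + n10 + n01 + n00
    if n == 0:
        return float("nan"), float("nan")
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return float("nan"), float("nan")
    D = n11 / n - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        sign = 1.0
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        sign = -1.0
    if dmax == 0:
        return float("nan"), float("nan")
    d_abs = _DPRIME_GRID * dmax
    p11 = np.clip(pA * pB + sign * d_abs, 1e-12, 1.0)
    p10 = np.clip(pA - p11, 1e-12, 1.0)
    p01 = np.clip(pB - p11, 1e-12, 1.0)
    p00 = np.clip(1 - pA - pB + p11, 1e-12, 1.0)
    ll = (
        n11 * np.log(p11) + n10 * np.log(p10)
        + n01 * np.log(p01) + n00 * np.log(p00)
    )
    w = np.exp(ll - ll.max())
    cdf = np.cumsum(w) / w.sum()
    tail = (1.0 - conf) / 2.0
    lower = float(_DPRIME_GRID[int(np.searchsorted(cdf, tail))])
    upper = float(_DPRIME_GRID[min(int(np.searchsorted(cdf, 1.0 - tail)), 100)])
    return lower, upper


def gabriel_blocks(
    m: GenotypeMatrix,
    ci_low: float = 0.70,
    ci_high: float = 0.98,
    recomb_high: float = 0.90,
    frac_strong: float = 0.95,
) -> list[HaploBlock]:
    """Haplotype blocks by the D' confidence-interval definition.

    A pair is "strong LD" when the 90% CI of D' has lower bound >= ``ci_low``
    and upper bound >= ``ci_high``; "strong recombination" when the upper
    bound < ``recomb_high``; other pairs are uninformative.  A candidate block
    is a site interval whose outermost pair is strong LD and in which at least
    ``frac_strong`` of informative pairs are strong LD.  Non-overlapping
    blocks are selected greedily by descending bp span (ties: leftmost start).
    """
    S = m.n_sites
    if S < 2:
        return []
    haps = m.binary_haplotypes()
    pos = m.positions
    order = np.argsort(pos, kind="stable")
    haps = haps[order]
    pos = pos[order]

    strong = np.zeros((S, S), dtype=bool)
    informative = np.zeros((S, S), dtype=bool)
    for i in range(S):
        for j in range(i + 1, S):
            lo, hi = dprime_ci(haps[i], haps[j])
            if math.isnan(lo):
                continue
            if lo >= ci_low and hi >= ci_high:
                strong[i, j] = True
                informative[i, j] = True
            elif hi < recomb_high:
                informative[i, j] = True

    # 2-D prefix sums for O(1) window pair counts
    cs = strong.astype(np.int64).cumsum(0).cumsum(1)
    ci_ = informative.astype(np.int64).cumsum(0).cumsum(1)

    def window_count(prefix: np.ndarray, i: int, j: int) -> int:
        # pairs (a, b) with i <= a < b <= j
        total = prefix[j, j]
        if i > 0:
            total -= prefix[i - 1, j]
        return int(total)

    candidates = []
    for i in range(S):
        for j in range(i + 1, S):
            if not strong[i, j]:
                continue
            n_inf = window_count(ci_, i, j)
            n_str = window_count(cs, i, j)
            if n_inf == 0 or n_str / n_inf < frac_strong:
                continue
            candidates.append((int(pos[j] - pos[i]), int(pos[i]), i, j, n_str / n_inf))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    used = np.zeros(S, dtype=bool)
    blocks: list[HaploBlock] = []
    for _span, _start, i, j, frac in candidates:
        if used[i:j + 1].any():
            continue
        used[i:j + 1] = True
        blocks.append(
            HaploBlock(
                start=int(pos[i]),
                end=int(pos[j]) + 1,
                member_positions=tuple(int(p) for p in pos[i:j + 1]),
                fraction_strong_pairs=float(frac),
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


# ---------------------------------------------------------------------------
# Missingness profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingnessProfile:
    positions: np.ndarray
    fractions: np.ndarray
    flagged_windows: tuple[tuple[int, int, float], ...]  # (start, end, mean)


def missingness_profile(
    m: GenotypeMatrix, window_bp: int = 10_000, flag_mean: float = 0.05
) -> MissingnessProfile:
    """Per-site missing-allele fractions plus windows whose mean exceeds a flag.

    Windows tile the observed position range in non-overlapping ``window_bp``
    steps; empty windows are skipped.
    """
    frac = m.missing_allele_fraction()
    pos = m.positions
    flagged: list[tuple[int, int, float]] = []
    if len(pos):
        lo = int(pos.min())
        hi = int(pos.max()) + 1
        for w_start in range(lo, hi, window_bp):
            w_end = w_start + window_bp
            in_w = (pos >= w_start) & (pos < w_end)
            if not in_w.any():
                continue
            mean = float(frac[in_w].mean())
            if mean > flag_mean:
                flagged.append((w_start, w_end, mean))
    return MissingnessProfile(
        positions=pos, fractions=frac, flagged_windows=tuple(flagged)
    )


def ld_heatmap(m: GenotypeMatrix, path, max_sites: int = 300):
    """Basic r² matrix heatmap (PNG); a stand-in for triangle LD plots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = np.argsort(m.positions)[:max_sites]
    r2 = r2_matrix(m.binary_haplotypes()[idx])
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(r2, cmap="Reds", vmin=0, vmax=1, interpolation="nearest")
    ax.set_title("pairwise r²")
    ax.set_xlabel("site index (by position)")
    fig.colorbar(im, ax=ax, label="r²")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
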