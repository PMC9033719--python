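"""Marker-group clustering, pruning, haplotype combinations, diversity.

The site-centric haplotyping view: region markers are filtered (heterozygotes
masked to missing first), clustered into marker groups by single-linkage on
the r² >= threshold graph, pruned by three redundancy rules, and each sample
is then described by its five-state vector (REF/HET/ALT/HETMISS/MISS) at the
groups' representative sites.  Samples sharing a vector form a haplotype
combination, labelled A, B, ... in descending membership order.

Groups are numbered M01, M02, ... by descending absolute protein contrast
between homozygous-alternate and homozygous-reference carriers, so M01 is the
most protein-associated group; this ordering is this package's convention and
is recorded in all outputs.

Nucleotide diversity (π) and divergence (dXY) follow the invariant-site-aware
estimators (pixy-style): invariant sites contribute comparison denominators
but no mismatches, so π is a true per-site rate over the region rather than a
rate over variant sites only.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assoc import WelchResult, welch_t
from .ld import r2_matrix
from .variants import GenotypeMatrix, MISSING

STATE_REF = "REF"
STATE_HET = "HET"
STATE_ALT = "ALT"
STATE_HETMISS = "HETMISS"
STATE_MISS = "MISS"
STATES = (STATE_REF, STATE_HET, STATE_ALT, STATE_HETMISS, STATE_MISS)


@dataclass
class MarkerGroup:
    group_id: str                      # "M01", ...
    representative_pos: int
    member_positions: tuple[int, ...]
    protein_contrast: float            # |ALT - REF| mean protein at build time

    def __post_init__(self) -> None:
        if self.representative_pos not in self.member_positions:
            raise ValueError("representative must be a member site")

    @property
    def n_members(self) -> int:
        return len(self.member_positions)


@dataclass
class HaplotypeCombo:
    label: str                         # "A", "B", ...
    state_vector: tuple[str, ...]      # one state per marker group
    members: tuple[str, ...]           # sample ids

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DiversityStat:
    pi: dict                 # group name -> per-site nucleotide diversity
    dxy: dict                # frozenset({a, b}) -> divergence
    n_sites_used: int
    n_invariant: int


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def mask_heterozygotes(m: GenotypeMatrix) -> GenotypeMatrix:
    """Set heterozygous diploid genotypes (two different called alleles) to missing."""
    g = m.genotypes.copy()
    both = (g[..., 0] != MISSING) & (g[..., 1] != MISSING)
    het = both & (g[..., 0] != g[..., 1])
    g[het] = MISSING
    return GenotypeMatrix(
        samples=list(m.samples), sites=list(m.sites), genotypes=g,
        phased=m.phased, region=m.region,
    )


def filter_markers(
    m: GenotypeMatrix,
    max_missing: float = 0.6,
    max_het: float = 0.3,
    min_alt: float = 0.01,
    min_allele_count: int = 4,
) -> GenotypeMatrix:
    """Marker filter for haplotyping (heterozygotes masked to missing first).

    Per site, computed on the masked matrix except for the heterozygosity rate
    (measured before masking): missing-allele fraction <= ``max_missing``,
    heterozygous-genotype fraction <= ``max_het``, non-reference allele
    frequency >= ``min_alt`` and non-reference allele count >=
    ``min_allele_count``.
    """
    g = m.genotypes
    both = (g[..., 0] != MISSING) & (g[..., 1] != MISSING)
    het = both & (g[..., 0] != g[..., 1])
    with np.errstate(invalid="ignore"):
        het_rate = np.where(
            both.sum(axis=1) > 0, het.sum(axis=1) / np.maximum(both.sum(axis=1), 1), 0.0
        )
    masked = mask_heterozygotes(m)
    gm = masked.genotypes
    keep = []
    for i in range(m.n_sites):
        if het_rate[i] > max_het:
            continue
        alleles = gm[i].ravel()
        called = alleles[alleles != MISSING]
        miss_frac = 1.0 - called.size / alleles.size
        if miss_frac > max_missing:
            continue
        alt_count = int((called > 0).sum())
        alt_freq = alt_count / called.size if called.size else 0.0
        if alt_count < min_allele_count or alt_freq < min_alt:
            continue
        keep.append(i)
    return masked.take_sites(keep)


# ---------------------------------------------------------------------------
# Clustering into marker groups
# ---------------------------------------------------------------------------

def representative_states(
    m: GenotypeMatrix, pos: int
) -> np.ndarray:
    """Five-state classification of every sample at one site."""
    i = m.site_index(pos)
    g = m.genotypes[i]
    out = np.empty(m.n_samples, dtype=object)
    for j, (a, b) in enumerate(g):
        called = [x for x in (a, b) if x != MISSING]
        if len(called) == 0:
            out[j] = STATE_MISS
        elif len(called) == 1:
            out[j] = STATE_HETMISS
        elif a != b:
            out[j] = STATE_HET
        elif a == 0:
            out[j] = STATE_REF
        else:
            out[j] = STATE_ALT
    return out


def _alt_ref_contrast(states: np.ndarray, values: np.ndarray) -> float:
    alt = values[(states == STATE_ALT) & ~np.isnan(values)]
    ref = values[(states == STATE_REF) & ~np.isnan(values)]
    if alt.size == 0 or ref.size == 0:
        return 0.0
    return float(alt.mean() - ref.mean())


def cluster_markers(
    m: GenotypeMatrix,
    phenotypes: Optional[pd.DataFrame] = None,
    independence_r2: float = 0.9,
) -> list[MarkerGroup]:
    """Single-linkage clustering of markers on the r² >= threshold graph.

    Each connected component becomes a group.  Representative site: lowest
    missingness, ties broken by highest minor allele frequency, then lowest
    position.  When a phenotype table (with ``protein`` column aligned to the
    matrix samples) is supplied, groups are ordered by descending absolute
    protein contrast between homozygous-ALT and homozygous-REF samples at the
    representative site; otherwise by position.
    """
    if m.n_sites == 0:
        raise ValueError("no sites to cluster")
    r2 = r2_matrix(m.binary_haplotypes())
    S = m.n_sites
    parent = list(range(S))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(S):
        for j in range(i + 1, S):
            if not np.isnan(r2[i, j]) and r2[i, j] >= independence_r2:
                union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(S):
        comps.setdefault(find(i), []).append(i)

    missing = m.missing_allele_fraction()
    protein = None
    if phenotypes is not None:
        protein = _aligned_column(phenotypes, m.samples, "protein")

    groups: list[tuple[float, int, list[int], int]] = []
    for members in comps.values():
        rep = min(
            members,
            key=lambda i: (missing[i], -m.minor_allele_frequency(i), m.sites[i].pos),
        )
        contrast = 0.0
        if protein is not None:
            states = representative_states(m, m.sites[rep].pos)
            contrast = _alt_ref_contrast(states, protein)
        groups.append((abs(contrast), contrast, members, rep))

    if protein is not None:
        groups.sort(key=lambda g: (-g[0], m.sites[g[3]].pos))
    else:
        groups.sort(key=lambda g: m.sites[g[3]].pos)

    out = []
    for k, (_abs_c, contrast, members, rep) in enumerate(groups, start=1):
        out.append(
            MarkerGroup(
                group_id=f"M{k:02d}",
                representative_pos=int(m.sites[rep].pos),
                member_positions=tuple(sorted(int(m.sites[i].pos) for i in members)),
                protein_contrast=float(contrast),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_groups(
    groups: Sequence[MarkerGroup], combos: Sequence[HaplotypeCombo],
    min_members: int = 6,
) -> list[MarkerGroup]:
    """Remove redundant marker groups, preserving contrast order.

    Three rules, applied in order: (1) among groups whose representative-state
    vectors over the provisional haplotype combinations are identical, keep
    the one with the most member SNPs (ties: lowest representative position);
    (2) drop groups with fewer than ``min_members`` member SNPs (i.e. five or
    fewer at the default); (3) for any pair whose member-position sets differ
    by exactly one SNP, drop the smaller.  Surviving groups are relabelled
    M01, M02, ... in their incoming order.
    """
    groups = list(groups)
    order = {g.group_id: k for k, g in enumerate(groups)}

    # Rule 1: identical state vectors across combos
    by_vector: dict[tuple, list[MarkerGroup]] = {}
    for k, g in enumerate(groups):
        vec = tuple(c.state_vector[k] for c in combos) if combos else (k,)
        by_vector.setdefault(vec, []).append(g)
    kept: list[MarkerGroup] = []
    for dupes in by_vector.values():
        best = max(dupes, key=lambda g: (g.n_members, -g.representative_pos))
        kept.append(best)

    # Rule 2: tiny groups
    kept = [g for g in kept if g.n_members >= min_members]

    # Rule 3: near-identical member sets (symmetric difference of one site)
    drop: set[str] = set()
    for a, b in itertools.combinations(kept, 2):
        sa, sb = set(a.member_positions), set(b.member_positions)
        if len(sa ^ sb) == 1:
            smaller = a if a.n_members < b.n_members else b
            drop.add(smaller.group_id)
    kept = [g for g in kept if g.group_id not in drop]

    if not kept:
        raise ValueError(
            "all marker groups pruned; relax the clustering or pruning thresholds"
        )
    kept.sort(key=lambda g: order[g.group_id])
    return [
        MarkerGroup(
            group_id=f"M{k:02d}",
            representative_pos=g.representative_pos,
            member_positions=g.member_positions,
            protein_contrast=g.protein_contrast,
        )
        for k, g in enumerate(kept, start=1)
    ]


# ---------------------------------------------------------------------------
# Haplotype combinations
# ---------------------------------------------------------------------------

def _combo_labels():
    letters = string.ascii_uppercase
    for size in range(1, 3):
        for tup in itertools.product(letters, repeat=size):
            yield "".join(tup)


def assign_combos(
    groups: Sequence[MarkerGroup], m: GenotypeMatrix
) -> tuple[list[HaplotypeCombo], list[str]]:
    """Group samples by their representative-state vectors.

    States are read from the (unmasked) matrix supplied, so HET and HETMISS
    survive as distinct states.  Samples with a fully missing state (MISS) at
    any group are set aside as unassigned and returned separately.  Combos are
    labelled A, B, ... in descending membership order (ties broken by state
    vector for determinism).
    """
    state_mat = np.stack(
        [representative_states(m, g.representative_pos) for g in groups]
    )  # (G, N)
    combos: dict[tuple[str, ...], list[str]] = {}
    unassigned: list[str] = []
    for j, sample in enumerate(m.samples):
        vec = tuple(state_mat[:, j])
        if STATE_MISS in vec:
            unassigned.append(sample)
            continue
        combos.setdefault(vec, []).append(sample)
    ordered = sorted(combos.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    out = [
        HaplotypeCombo(label=label, state_vector=vec, members=tuple(members))
        for label, (vec, members) in zip(_combo_labels(), ordered)
    ]
    return out, unassigned


def mine_haplotypes(
    m: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    independence_r2: float = 0.9,
    **marker_filter_kwargs,
) -> tuple[list[MarkerGroup], list[HaplotypeCombo], list[str]]:
    """Full marker-group workflow: filter → cluster → prune → assign.

    Returns the pruned groups (M01 = strongest protein contrast), final
    combos, and the unassigned sample ids.  ``m`` should already be
    site-filtered and region-restricted as appropriate.
    """
    markers = filter_markers(m, **marker_filter_kwargs)
    provisional = cluster_markers(markers, phenotypes,
                                  independence_r2=independence_r2)
    prov_combos, _ = assign_combos(provisional, m)
    groups = prune_groups(provisional, prov_combos)
    combos, unassigned = assign_combos(groups, m)
    return groups, combos, unassigned


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def pi_dxy(
    m: GenotypeMatrix,
    partition: dict[str, Sequence[int]],
    region_length: Optional[int] = None,
    n_invariant: Optional[int] = None,
) -> DiversityStat:
    """π per group and dXY per group pair, with invariant-site denominators.

    ``partition`` maps group name to sample indices.  Invariant sites
    contribute only denominators and are assumed fully genotyped; their count
    is ``n_invariant`` or, when ``region_length`` is given, region length
    minus the number of variant sites in the matrix.

    Per site s with allele counts {c_a} over a group's called alleles
    (n_s = sum c_a):  mismatches  = C(n_s,2) - sum_a C(c_a,2), and
    π = Σ_s mismatches / (Σ_s C(n_s,2) + n_invariant * C(2N,2)).
    dXY uses cross-group pairs: n1*n2 - Σ_a c1_a*c2_a per site.
    """
    if n_invariant is None:
        if region_length is None:
            if m.region is not None:
                region_length = len(m.region)
            else:
                raise ValueError("provide region_length or n_invariant")
        n_invariant = region_length - m.n_sites
    if n_invariant < 0:
        raise ValueError("more variant sites than region length")

    def site_counts(idx: np.ndarray) -> list[np.ndarray]:
        out = []
        for i in range(m.n_sites):
            g = m.genotypes[i][idx].ravel()
            g = g[g != MISSING]
            out.append(np.bincount(g, minlength=m.sites[i].n_alleles))
        return out

    counts = {name: site_counts(np.asarray(list(idx), dtype=int))
              for name, idx in partition.items()}

    def c2(x):
        return x * (x - 1) / 2.0

    pi: dict[str, float] = {}
    for name, idx in partition.items():
        n_hap_full = 2 * len(list(idx))
        num = 0.0
        den = 0.0
        any_pairs = False
        for c in counts[name]:
            n_s = int(c.sum())
            if n_s < 2:
                continue
            any_pairs = True
            num += c2(n_s) - c2(c.astype(float)).sum()
            den += c2(n_s)
        den += n_invariant * c2(float(n_hap_full))
        if not any_pairs and n_invariant == 0:
            pi[name] = float("nan")
        else:
            pi[name] = num / den if den > 0 else float("nan")

    dxy: dict[frozenset, float] = {}
    for a, b in itertools.combinations(partition.keys(), 2):
        num = 0.0
        den = 0.0
        for ca, cb in zip(counts[a], counts[b]):
            n1 = float(ca.sum())
            n2 = float(cb.sum())
            if n1 == 0 or n2 == 0:
                continue
            num += n1 * n2 - float(ca.astype(float) @ cb.astype(float))
            den += n1 * n2
        den += n_invariant * (2.0 * len(list(partition[a]))) * (2.0 * len(list(partition[b])))
        dxy[frozenset((a, b))] = num / den if den > 0 else float("nan")

    return DiversityStat(
        pi=pi, dxy=dxy, n_sites_used=m.n_sites, n_invariant=int(n_invariant)
    )


# ---------------------------------------------------------------------------
# Phenotype summaries
# ---------------------------------------------------------------------------

def _aligned_column(
    phenotypes: pd.DataFrame, samples: Sequence[str], column: str
) -> np.ndarray:
    tbl = phenotypes.set_index("sample_id") if "sample_id" in phenotypes else phenotypes
    missing = [s for s in samples if s not in tbl.index]
    if missing:
        raise ValueError(f"phenotype table lacks samples: {missing[:5]} ...")
    return tbl.loc[list(samples), column].to_numpy(dtype=float)


def group_phenotype_summary(
    combos: Sequence[HaplotypeCombo],
    groups: Sequence[MarkerGroup],
    m: GenotypeMatrix,
    phenotypes: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Phenotype means per combo and per marker-group ALT/REF partition.

    Returns a tidy table (scope, name, dclass, trait, state, n, mean, var) and
    a dict of Welch ALT-vs-REF tests keyed ``(group_id, trait, dclass)``;
    contrasts with fewer than two samples on either side are summarised
    without a test.
    """
    tbl = phenotypes.set_index("sample_id") if "sample_id" in phenotypes else phenotypes
    classes = ["all"] + sorted(tbl["dclass"].unique().tolist())
    traits = ["protein", "oil"]
    rows = []
    tests: dict[tuple, WelchResult] = {}

    sample_class = {s: tbl.loc[s, "dclass"] for s in m.samples if s in tbl.index}

    def class_mask(samples: Sequence[str], dclass: str) -> list[str]:
        if dclass == "all":
            return list(samples)
        return [s for s in samples if sample_class.get(s) == dclass]

    def values(samples: Sequence[str], trait: str) -> np.ndarray:
        present = [s for s in samples if s in tbl.index]
        v = tbl.loc[present, trait].to_numpy(dtype=float)
        return v[~np.isnan(v)]

    for combo in combos:
        for dclass in classes:
            members = class_mask(combo.members, dclass)
            for trait in traits:
                v = values(members, trait)
                rows.append(
                    dict(scope="combo", name=combo.label, dclass=dclass,
                         trait=trait, state="", n=len(v),
                         mean=float(v.mean()) if v.size else float("nan"),
                         var=float(v.var(ddof=1)) if v.size > 1 else float("nan"))
                )

    for group in groups:
        states = representative_states(m, group.representative_pos)
        by_state = {st: [s for s, x in zip(m.samples, states) if x == st]
                    for st in (STATE_ALT, STATE_REF)}
        for dclass in classes:
            for trait in traits:
                vals = {}
                for st, samples in by_state.items():
                    v = values(class_mask(samples, dclass), trait)
                    vals[st] = v
                    rows.append(
                        dict(scope="group", name=group.group_id, dclass=dclass,
                             trait=trait, state=st, n=len(v),
                             mean=float(v.mean()) if v.size else float("nan"),
                             var=float(v.var(ddof=1)) if v.size > 1 else float("nan"))
                    )
                if vals[STATE_ALT].size >= 2 and vals[STATE_REF].size >= 2:
                    try:
                        tests[(group.group_id, trait, dclass)] = welch_t(
                            vals[STATE_ALT], vals[STATE_REF]
                        )
                    except ValueError:
                        pass
    return pd.DataFrame(rows), tests
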