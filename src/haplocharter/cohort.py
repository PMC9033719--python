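"""Synthetic cohort generator for the cqProt-003 haplotype analysis.

Emulates the statistical structure of the 985-accession soybean panel around
the chromosome-20 seed-protein locus so that every downstream stage — site
filtering, LD delimitation, marker-group haplotyping, repeat genotyping and
coverage-based deletion calling — is testable without external data:

* four domestication classes (wild / landrace / old cultivar / modern
  cultivar) with class-specific frequencies of the high-protein haplotype
  (defaults 94.7% / 10.6% / 4.1% / 4.1% per haplotype copy);
* six marker groups of mutually linked SNPs inside a 173 kb linked region;
  the focal group (the one carrying the phenotype effect) marks carrier
  haplotypes exactly, the secondary groups are planted on partially
  overlapping subsets of carrier haplotypes so that at least seven distinct
  diploid combination vectors arise;
* a CAA tandem-repeat insertion locus (6–14 total copies among carriers, five
  invariant copies in everyone) and a 304 bp deletion co-inherited with the
  expansion; the deletion is visible only as a per-base coverage drop;
* dosage-additive protein and oil effects (defaults +3.32 / −2.66 g per 100 g
  per homozygous carrier) on class-specific baselines with Gaussian noise.

Identical config + seed produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .coords import GenomicInterval
from .repeats import DepthTrack, write_depth_bed
from .variants import GenotypeMatrix, MISSING, VariantSite, write_vcf

CLASSES = ("wild", "landrace", "old_cultivar", "modern_cultivar")
_CLASS_PREFIX = {"wild": "W", "landrace": "L",
                 "old_cultivar": "OC", "modern_cultivar": "MC"}

# Carrier-haplotype patterns over the secondary marker groups (M02..M06 when
# six groups are configured).  Distinct columns keep cross-group r² well below
# the 0.9 clustering threshold while guaranteeing >= 7 distinct diploid
# combination vectors at the defaults.
_NESTED_PATTERNS = np.array(
    [
        (1, 1, 1, 1, 1),
        (1, 1, 1, 1, 0),
        (1, 1, 0, 0, 0),
        (1, 0, 1, 0, 0),
        (0, 1, 0, 1, 0),
        (0, 0, 0, 0, 1),
        (0, 0, 0, 0, 0),
    ],
    dtype=np.int8,
)
_PATTERN_PROBS = np.array([0.30, 0.15, 0.15, 0.10, 0.10, 0.10, 0.10])


def _default_repeat_distribution() -> dict[int, float]:
    # Total-copy distribution among carrier haplotypes, proportional to the
    # homozygous copy-class counts observed in the published reference panel.
    counts = {6: 2, 7: 10, 8: 8, 9: 21, 10: 13, 11: 24, 12: 46, 13: 30, 14: 1}
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Class sizes default to the reference panel's composition (131 wild, 708
    landraces, 44 old and 102 modern cultivars).  Baselines are plumbing
    choices (wild seeds are protein-rich and oil-poor); effects, frequencies,
    the repeat distribution and the deletion interval default to the reported
    locus characterisation.
    """

    n_wild: int = 131
    n_landrace: int = 708
    n_old_cultivar: int = 44
    n_modern_cultivar: int = 102

    chrom: str = "Gm20"
    region_start: int = 31_550_000
    region_end: int = 32_000_000
    linked_region_start: int = 31_604_127
    linked_region_end: int = 31_777_346
    focal_pos: int = 31_632_556

    hap_freq_by_class: dict = field(
        default_factory=lambda: {
            "wild": 0.947, "landrace": 0.106,
            "old_cultivar": 0.041, "modern_cultivar": 0.041,
        }
    )
    protein_effect: float = 3.32
    oil_effect: float = -2.66
    baseline_protein: dict = field(
        default_factory=lambda: {
            "wild": 46.0, "landrace": 43.0,
            "old_cultivar": 42.0, "modern_cultivar": 42.0,
        }
    )
    baseline_oil: dict = field(
        default_factory=lambda: {
            "wild": 12.0, "landrace": 19.0,
            "old_cultivar": 20.0, "modern_cultivar": 20.0,
        }
    )
    noise_sd_protein: float = 0.4
    noise_sd_oil: float = 0.4

    repeat_locus: int = 31_727_019
    repeat_unit: str = "CAA"
    invariant_repeat_copies: int = 5
    repeat_copy_distribution: dict = field(
        default_factory=_default_repeat_distribution
    )
    repeat_resample_rate: float = 0.05
    deletion_start: int = 31_728_619
    deletion_end: int = 31_728_923     # 1-based half-open; length 304 bp
    sv_decouple_rate: float = 0.0
    nested_insertion_prob: float = 30 / 194
    nested_insertion_seq: str = "TTGACCAGTGCAATCGGATTCAAGA"  # 25 bp

    n_marker_groups: int = 6
    snps_per_group: int = 12
    ld_leak: float = 0.002
    group_layout: str = "nested"       # "nested" | "independent"
    independent_group_freq: float = 0.3
    background_snp_count: int = 200
    background_fst: float = 0.05
    missing_rate: float = 0.02
    half_missing_fraction: float = 0.2
    depth_flank: int = 1500
    seed: int = 0

    # -- derived ---------------------------------------------------------

    @property
    def class_sizes(self) -> dict[str, int]:
        return {
            "wild": self.n_wild,
            "landrace": self.n_landrace,
            "old_cultivar": self.n_old_cultivar,
            "modern_cultivar": self.n_modern_cultivar,
        }

    @property
    def n_samples(self) -> int:
        return sum(self.class_sizes.values())

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.region_start, self.region_end)

    @property
    def deletion_interval(self) -> tuple[int, int]:
        return self.deletion_start, self.deletion_end

    def validate(self) -> None:
        if self.n_samples == 0:
            raise ValueError("cohort has zero samples")
        if any(n < 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be non-negative")
        if self.region_end <= self.region_start:
            raise ValueError("region_end must exceed region_start")
        for c, p in self.hap_freq_by_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"haplotype frequency for {c} outside [0,1]")
        for p in (self.ld_leak, self.missing_rate, self.sv_decouple_rate,
                  self.nested_insertion_prob, self.half_missing_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        dist_total = sum(self.repeat_copy_distribution.values())
        if abs(dist_total - 1.0) > 1e-9:
            raise ValueError("repeat_copy_distribution must sum to 1")
        if min(self.repeat_copy_distribution) <= self.invariant_repeat_copies:
            raise ValueError(
                "repeat distribution totals must exceed the invariant copies"
            )
        if not (
            self.region_start <= self.deletion_start
            and self.deletion_end <= self.region_end
        ):
            raise ValueError("deletion interval outside the region")
        if self.deletion_end <= self.deletion_start:
            raise ValueError("empty deletion interval")
        if self.group_layout not in ("nested", "independent"):
            raise ValueError(f"unknown group_layout {self.group_layout!r}")
        if not 2 <= self.n_marker_groups <= 6:
            raise ValueError("n_marker_groups must be between 2 and 6")


@dataclass
class TruthSet:
    """Ground truth recorded during generation.

    ``carrier`` is the per-haplotype-copy carrier flag; by construction it
    equals the alternate-allele indicator at the focal site of the top marker
    group.  ``group_alleles`` holds the planted (pre-leak) group indicator per
    haplotype, ``site_labels`` maps every emitted VCF site to its generating
    group or "background"/"repeat"/"nested_insertion".
    """

    samples: list[str]
    classes: list[str]
    carrier: np.ndarray            # (N, 2) bool
    group_alleles: np.ndarray      # (G, N, 2) int8
    repeat_copies: np.ndarray      # (N, 2) total copies; 0 for non-insertion
    deletion_present: np.ndarray   # (N,) bool
    nested_insertion: np.ndarray   # (N,) bool
    site_labels: list[str]
    group_ids: list[str]

    def carrier_dosage(self) -> np.ndarray:
        return self.carrier.sum(axis=1)

    def combo_vectors(self) -> set[tuple[int, ...]]:
        """Distinct diploid group-dosage vectors among the samples."""
        dos = self.group_alleles.sum(axis=2)  # (G, N)
        return {tuple(int(x) for x in dos[:, j]) for j in range(dos.shape[1])}


@dataclass
class CohortResult:
    config: CohortConfig
    matrix: GenotypeMatrix
    phenotypes: pd.DataFrame       # sample_id, protein, oil, dclass
    depth: list[DepthTrack]
    truth: TruthSet


def _draw_positions(rng: np.random.Generator, cfg: CohortConfig) -> dict:
    """Deterministic site positions: contiguous group territories inside the
    linked region, background sites across the rest of the region."""
    g = cfg.n_marker_groups
    span = cfg.linked_region_end - cfg.linked_region_start
    bounds = [cfg.linked_region_start + round(span * k / g) for k in range(g + 1)]
    reserved = {cfg.repeat_locus, cfg.deletion_start - 1, cfg.focal_pos}
    group_pos: list[np.ndarray] = []
    for k in range(g):
        lo, hi = bounds[k], bounds[k + 1]
        need = cfg.snps_per_group
        if k == 0:
            need -= 1  # focal site occupies one slot
        pool = rng.choice(
            np.arange(lo, hi), size=min(need * 4, hi - lo), replace=False
        )
        pool = [int(p) for p in pool if p not in reserved][:need]
        if len(pool) < need:
            raise ValueError("territory too narrow for requested snps_per_group")
        if k == 0:
            pool.append(cfg.focal_pos)
        reserved.update(pool)
        group_pos.append(np.array(sorted(pool)))
    n_bg = cfg.background_snp_count
    bg = []
    candidates = rng.choice(
        np.arange(cfg.region_start, cfg.region_end),
        size=min(n_bg * 4 + 8, cfg.region_end - cfg.region_start),
        replace=False,
    )
    for p in candidates:
        if int(p) not in reserved:
            bg.append(int(p))
            reserved.add(int(p))
        if len(bg) == n_bg:
            break
    return {"groups": group_pos, "background": np.array(sorted(bg))}


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Generate the phased VCF matrix, phenotypes, depth tracks and truth set."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples: list[str] = []
    classes: list[str] = []
    for cls in CLASSES:
        for i in range(config.class_sizes[cls]):
            samples.append(f"{_CLASS_PREFIX[cls]}{i + 1:04d}")
            classes.append(cls)
    N = len(samples)
    G = config.n_marker_groups

    # Per-haplotype carrier status from the class frequency
    p_carrier = np.array([config.hap_freq_by_class[c] for c in classes])
    carrier = rng.random((N, 2)) < p_carrier[:, None]

    # Planted group indicator per haplotype.  The secondary-group background
    # pattern is drawn once per sample and shared by both carrier haplotype
    # copies: these are essentially inbred lines whose two haplotypes descend
    # from the same background, and a shared pattern keeps the
    # homozygote-conditioned r² between different groups (what the marker
    # clustering sees after heterozygote masking) at the planted level.
    group_alleles = np.zeros((G, N, 2), dtype=np.int8)
    group_alleles[0] = carrier
    if config.group_layout == "nested":
        pat_idx = rng.choice(len(_NESTED_PATTERNS), size=N, p=_PATTERN_PROBS)
        sub = _NESTED_PATTERNS[pat_idx][:, : G - 1]     # (N, G-1)
        for k in range(1, G):
            group_alleles[k] = carrier & (sub[:, None, k - 1] == 1)
    else:
        for k in range(1, G):
            ind = rng.random(N) < config.independent_group_freq
            group_alleles[k] = np.repeat(ind[:, None], 2, axis=1)

    positions = _draw_positions(rng, config)

    # Site-level alleles: planted indicator with one-directional leak (a
    # carrier haplotype loses the group allele with probability ld_leak; the
    # focal site of the top group is emitted leak-free so the truth invariant
    # "carrier flag <=> focal alternate allele" is exact).
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    labels: list[str] = []
    bases = np.array(list("ACGT"))

    def snp_alleles(pos_seed: int) -> tuple[str, str]:
        r, a = rng.choice(4, size=2, replace=False)
        return str(bases[r]), str(bases[a])

    for k in range(G):
        gid = f"G{k + 1:02d}"
        for pos in positions["groups"][k]:
            ref, alt = snp_alleles(pos)
            planted = group_alleles[k]
            if pos == config.focal_pos and k == 0:
                hap = planted.astype(np.int16)
            else:
                leak = rng.random((N, 2)) < config.ld_leak
                hap = (planted.astype(bool) & ~leak).astype(np.int16)
            sites.append(
                VariantSite(
                    chrom=config.chrom, pos=int(pos), ref=ref, alts=(alt,),
                    qual=float(np.round(rng.uniform(40, 200), 1)),
                    info={"TRUTH_GROUP": gid},
                )
            )
            rows.append(hap)
            labels.append(gid)

    # Background SNPs: class-structured frequencies (Balding–Nichols drift)
    F = config.background_fst
    for pos in positions["background"]:
        ref, alt = snp_alleles(pos)
        q = rng.uniform(0.05, 0.5)
        if F > 0:
            a, b = q * (1 - F) / F, (1 - q) * (1 - F) / F
            class_freq = {c: rng.beta(a, b) for c in CLASSES}
        else:
            class_freq = {c: q for c in CLASSES}
        p = np.array([class_freq[c] for c in classes])
        hap = (rng.random((N, 2)) < p[:, None]).astype(np.int16)
        sites.append(
            VariantSite(
                chrom=config.chrom, pos=int(pos), ref=ref, alts=(alt,),
                qual=float(np.round(rng.uniform(40, 200), 1)),
                info={"TRUTH_GROUP": "background"},
            )
        )
        rows.append(hap)
        labels.append("background")

    # Repeat locus: a carrier sample draws one total copy number shared by
    # both carrier haplotype copies (inbred lines are homozygous at the
    # locus); each carrier haplotype independently re-draws with a small
    # probability, emulating the hypermutability of tandem repeats and
    # populating the heterozygous-repeats category.
    copy_vals = np.array(sorted(config.repeat_copy_distribution))
    copy_probs = np.array(
        [config.repeat_copy_distribution[int(v)] for v in copy_vals]
    )
    repeat_copies = np.zeros((N, 2), dtype=np.int16)
    shared = copy_vals[rng.choice(len(copy_vals), size=N, p=copy_probs)]
    redraw = copy_vals[rng.choice(len(copy_vals), size=(N, 2), p=copy_probs)]
    mutate = rng.random((N, 2)) < config.repeat_resample_rate
    per_hap = np.where(mutate, redraw, shared[:, None])
    repeat_copies[carrier] = per_hap[carrier]
    present_copies = sorted({int(c) for c in repeat_copies.ravel() if c > 0})
    if present_copies:
        anchor = "A"
        alts = tuple(
            anchor + config.repeat_unit * (c - config.invariant_repeat_copies)
            for c in present_copies
        )
        allele_of = {c: i + 1 for i, c in enumerate(present_copies)}
        hap = np.zeros((N, 2), dtype=np.int16)
        for c, ai in allele_of.items():
            hap[repeat_copies == c] = ai
        sites.append(
            VariantSite(
                chrom=config.chrom, pos=config.repeat_locus, ref=anchor,
                alts=alts, qual=float(np.round(rng.uniform(40, 200), 1)),
                info={"TRUTH_GROUP": "repeat"},
            )
        )
        rows.append(hap)
        labels.append("repeat")

    # Deletion presence: both haplotype copies must carry the high-protein
    # haplotype (an intact copy masks the coverage drop); an optional
    # decoupling rate flips the flag to emulate imperfect co-inheritance.
    deletion_present = carrier.all(axis=1)
    if config.sv_decouple_rate > 0:
        flip = rng.random(N) < config.sv_decouple_rate
        deletion_present = deletion_present ^ flip

    # Nested 25 bp insertion at the deletion start, in a subset of deletion
    # carriers (planted homozygous; it rides the same haplotype background).
    nested = deletion_present & (rng.random(N) < config.nested_insertion_prob)
    if nested.any():
        hap = np.repeat(nested[:, None], 2, axis=1).astype(np.int16)
        sites.append(
            VariantSite(
                chrom=config.chrom, pos=config.deletion_start - 1, ref="C",
                alts=("C" + config.nested_insertion_seq,),
                qual=float(np.round(rng.uniform(40, 200), 1)),
                info={"TRUTH_GROUP": "nested_insertion"},
            )
        )
        rows.append(hap)
        labels.append("nested_insertion")

    # Sort records by position
    order = np.argsort([s.pos for s in sites], kind="stable")
    sites = [sites[i] for i in order]
    rows = [rows[i] for i in order]
    labels = [labels[i] for i in order]
    genotypes = np.stack(rows)  # (S, N, 2)

    # Inject missingness (a slice of it half-missing, to exercise HETMISS)
    miss = rng.random(genotypes.shape[:2]) < config.missing_rate
    half = rng.random(genotypes.shape[:2]) < config.half_missing_fraction
    which_allele = rng.integers(0, 2, size=genotypes.shape[:2])
    full_mask = miss & ~half
    genotypes[full_mask] = MISSING
    half_mask = miss & half
    idx = np.where(half_mask)
    genotypes[idx[0], idx[1], which_allele[idx]] = MISSING

    matrix = GenotypeMatrix(
        samples=samples, sites=sites, genotypes=genotypes,
        phased=True, region=config.region,
    )

    # Phenotypes: class baseline + effect * dosage/2 + noise
    dosage = carrier.sum(axis=1)
    base_p = np.array([config.baseline_protein[c] for c in classes])
    base_o = np.array([config.baseline_oil[c] for c in classes])
    protein = base_p + config.protein_effect * dosage / 2.0
    oil = base_o + config.oil_effect * dosage / 2.0
    if config.noise_sd_protein > 0:
        protein = protein + rng.normal(0, config.noise_sd_protein, N)
    if config.noise_sd_oil > 0:
        oil = oil + rng.normal(0, config.noise_sd_oil, N)
    phenotypes = pd.DataFrame(
        {
            "sample_id": samples,
            "protein": np.round(protein, 4),
            "oil": np.round(oil, 4),
            "dclass": classes,
        }
    )

    # Depth tracks over the deletion neighbourhood: per-sample background
    # depth U(8,50), Poisson-jittered per base; inside the deletion, present
    # samples drop to per-base Bernoulli(u), u ~ U(0,1), so every base is 0/1.
    win_start = config.deletion_start - config.depth_flank
    win_end = config.deletion_end + config.depth_flank
    L = win_end - win_start
    del_off = config.deletion_start - win_start
    del_len = config.deletion_end - config.deletion_start
    depth_tracks: list[DepthTrack] = []
    bg_levels = rng.uniform(8, 50, N)
    for j, sample in enumerate(samples):
        d = rng.poisson(bg_levels[j], L).astype(np.int32)
        if deletion_present[j]:
            u = rng.uniform(0, 1)
            d[del_off:del_off + del_len] = (
                rng.random(del_len) < u
            ).astype(np.int32)
        depth_tracks.append(
            DepthTrack(sample=sample, chrom=config.chrom,
                       start=win_start, depth=d)
        )

    truth = TruthSet(
        samples=samples,
        classes=classes,
        carrier=carrier,
        group_alleles=group_alleles,
        repeat_copies=repeat_copies,
        deletion_present=deletion_present,
        nested_insertion=nested,
        site_labels=labels,
        group_ids=[f"G{k + 1:02d}" for k in range(G)],
    )
    return CohortResult(
        config=config, matrix=matrix, phenotypes=phenotypes,
        depth=depth_tracks, truth=truth,
    )


def write_fixture_bundle(result: CohortResult, directory: str | Path) -> dict:
    """Write VCF / phenotype TSV / depth BED / truth JSON; returns the paths.

    Re-reading the VCF through :func:`haplocharter.variants.load_vcf` yields
    an identical genotype matrix; the phenotype row order matches the VCF
    header sample order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "cohort.vcf",
        "phenotypes": directory / "phenotypes.tsv",
        "depth": directory / "depth.bed",
        "truth": directory / "truth.json",
    }
    write_vcf(result.matrix, paths["vcf"])
    result.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    write_depth_bed(result.depth, paths["depth"])
    t = result.truth
    truth_json = {
        "samples": t.samples,
        "classes": t.classes,
        "carrier": t.carrier.astype(int).tolist(),
        "group_alleles": t.group_alleles.astype(int).tolist(),
        "repeat_copies": t.repeat_copies.astype(int).tolist(),
        "deletion_present": t.deletion_present.astype(int).tolist(),
        "nested_insertion": t.nested_insertion.astype(int).tolist(),
        "site_labels": t.site_labels,
        "group_ids": t.group_ids,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=0, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def load_truth(path: str | Path) -> TruthSet:
    with open(path) as fh:
        d = json.load(fh)
    return TruthSet(
        samples=d["samples"],
        classes=d["classes"],
        carrier=np.array(d["carrier"], dtype=bool),
        group_alleles=np.array(d["group_alleles"], dtype=np.int8),
        repeat_copies=np.array(d["repeat_copies"], dtype=np.int16),
        deletion_present=np.array(d["deletion_present"], dtype=bool),
        nested_insertion=np.array(d["nested_insertion"], dtype=bool),
        site_labels=d["site_labels"],
        group_ids=d["group_ids"],
    )
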