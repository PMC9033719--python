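"""VCF-backed genotype container, site filters, and InDel proxy recoding.

The container keeps per-haplotype allele indices (``-1`` = missing allele), so
half-missing diploid calls like ``./1`` survive every transformation: the one
called allele keeps contributing to allele frequencies and, downstream, to the
HETMISS state tallies of the haplotyping stage.

InDel handling mirrors the standard pan-genome workflow: multiallelic records
are split into an insertion stream and a deletion stream by comparing each
alternate allele's length to the reference, each stream is collapsed to a
presence/absence proxy site (REF=T / ALT=A), and the streams are re-merged so
that linkage with SNPs tests "any insertion (or deletion) versus reference"
rather than specific alleles.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .coords import GenomicInterval

MISSING = -1

_ALLELE_RE = re.compile(r"^[ACGTN]+$")

PROXY_REF = "T"
PROXY_ALT = "A"


class VCFParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True)
class VariantSite:
    """One VCF record's site-level fields (genotypes live in the matrix)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float = float("nan")
    vid: str = "."
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or not _ALLELE_RE.match(allele):
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class GenotypeMatrix:
    """Samples x variant sites with per-haplotype allele indices.

    ``genotypes`` has shape (n_sites, n_samples, 2), dtype int16, with
    ``MISSING`` (-1) for uncalled alleles.  Sample order is fixed at load time
    and must stay stable across all downstream stages.
    """

    samples: list[str]
    sites: list[VariantSite]
    genotypes: np.ndarray
    phased: bool = True
    region: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        expected = (len(self.sites), len(self.samples), 2)
        if self.genotypes.shape != expected:
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} != {expected}"
            )
        for site, gt in zip(self.sites, self.genotypes):
            hi = int(gt.max(initial=MISSING))
            if hi >= site.n_alleles:
                raise ValueError(
                    f"allele index {hi} out of range at {site.chrom}:{site.pos}"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def site_index(self, pos: int) -> int:
        for i, s in enumerate(self.sites):
            if s.pos == pos:
                return i
        raise KeyError(f"no site at position {pos}")

    def take_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            genotypes=self.genotypes[idx] if idx else np.empty((0, self.n_samples, 2), dtype=np.int16),
            phased=self.phased,
            region=self.region,
        )

    def restrict(self, interval: GenomicInterval) -> "GenotypeMatrix":
        keep = [i for i, s in enumerate(self.sites)
                if s.chrom == interval.chrom and interval.contains(s.pos)]
        out = self.take_sites(keep)
        out.region = interval
        return out

    # -- derived views --------------------------------------------------

    def haplotypes(self) -> np.ndarray:
        """(n_sites, 2*n_samples) allele indices, sample-major haplotype order."""
        return self.genotypes.reshape(self.n_sites, 2 * self.n_samples)

    def binary_haplotypes(self) -> np.ndarray:
        """Haplotype matrix collapsed to {0 ref, 1 any-alt, -1 missing}.

        Multiallelic sites are binarised to presence of any non-reference
        allele, consistent with the proxy-recoding philosophy used for LD.
        """
        h = self.haplotypes()
        out = np.where(h > 0, 1, h).astype(np.int8)
        return out

    def dosage(self, mean_impute: bool = False) -> np.ndarray:
        """(n_samples, n_sites) count of non-reference alleles per sample.

        Half-missing genotypes contribute their called allele; fully missing
        genotypes are NaN unless ``mean_impute`` (per-site mean of called
        dosages; used only by the association scan).
        """
        g = self.genotypes  # (S, N, 2)
        called = g != MISSING
        alt = (g > 0) & called
        n_called = called.sum(axis=2).astype(float)  # (S, N)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(n_called > 0, alt.sum(axis=2) * (2.0 / n_called), np.nan)
        if mean_impute:
            site_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
            site_mean = np.where(np.isnan(site_mean), 0.0, site_mean)
            d = np.where(np.isnan(d), site_mean[:, None], d)
        return d.T

    def missing_allele_fraction(self) -> np.ndarray:
        """Per-site fraction of missing alleles (half-missing counts 0.5)."""
        return (self.genotypes == MISSING).mean(axis=(1, 2))

    def allele_frequencies(self, i: int) -> np.ndarray:
        """Frequencies of all alleles at site ``i`` over non-missing alleles."""
        g = self.genotypes[i].ravel()
        g = g[g != MISSING]
        n_alleles = self.sites[i].n_alleles
        if g.size == 0:
            return np.zeros(n_alleles)
        counts = np.bincount(g, minlength=n_alleles).astype(float)
        return counts / g.size

    def minor_allele_frequency(self, i: int) -> float:
        """Second-largest allele frequency (0 for monomorphic sites)."""
        freqs = np.sort(self.allele_frequencies(i))[::-1]
        return float(freqs[1]) if freqs.size > 1 else 0.0


def empty_like(m: GenotypeMatrix) -> GenotypeMatrix:
    return m.take_sites([])


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_REGION_TAG = "haplocharter_region"


def load_vcf(path: str | Path, region: Optional[GenomicInterval] = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    ``region`` restricts to records whose POS falls in the 1-based half-open
    interval; a region containing no sites yields an empty matrix.  The
    generator's ``##haplocharter_region`` header tag (used for invariant-site
    accounting in diversity estimates) is recovered when present.
    """
    from cyvcf2 import VCF  # deferred: keeps import cost out of light paths

    reader = VCF(str(path), gts012=False)
    samples = list(reader.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    phased = True
    header_region = _parse_region_tag(reader.raw_header)

    for rec_no, var in enumerate(reader, start=1):
        try:
            pos = var.POS
            if region is not None and not (
                var.CHROM == region.chrom and region.contains(pos)
            ):
                continue
            alts = tuple(var.ALT) if var.ALT else ()
            qual = float(var.QUAL) if var.QUAL is not None else float("nan")
            info = dict(var.INFO) if var.INFO else {}
            site = VariantSite(
                chrom=var.CHROM, pos=pos, ref=var.REF, alts=alts,
                qual=qual, vid=var.ID or ".", info=info,
            )
            gts = np.full((len(samples), 2), MISSING, dtype=np.int16)
            for j, g in enumerate(var.genotypes):
                # cyvcf2 genotype row: [allele0, allele1, ..., phased_flag]
                alleles = g[:-1]
                if len(alleles) == 1:  # haploid call; duplicate
                    alleles = [alleles[0], alleles[0]]
                gts[j, 0] = alleles[0]
                gts[j, 1] = alleles[1]
                if not g[-1] and not all(a < 0 for a in alleles):
                    phased = False
            sites.append(site)
            rows.append(gts)
        except Exception as exc:  # pragma: no cover - defensive
            raise VCFParseError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc

    gt = (
        np.stack(rows)
        if rows
        else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        genotypes=gt,
        phased=phased if rows else True,
        region=region or header_region,
    )


def _parse_region_tag(raw_header: str) -> Optional[GenomicInterval]:
    for line in raw_header.splitlines():
        if line.startswith(f"##{_REGION_TAG}="):
            spec = line.split("=", 1)[1]
            chrom, span = spec.split(":")
            start, end = span.split("-")
            return GenomicInterval(chrom, int(start), int(end))
    return None


def write_vcf(m: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as an uncompressed VCF 4.2 file."""
    path = Path(path)
    sep = "|" if m.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplocharter\n")
        if m.region is not None:
            fh.write(
                f"##{_REGION_TAG}={m.region.chrom}:{m.region.start}-{m.region.end}\n"
            )
        for chrom in dict.fromkeys(s.chrom for s in m.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##INFO=<ID=PROXY_TYPE,Number=1,Type=String,'
            'Description="InDel presence/absence proxy stream (ins or del)">\n'
        )
        fh.write(
            '##INFO=<ID=TRUTH_GROUP,Number=1,Type=String,'
            'Description="Synthetic-cohort generating label">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(m.samples) + "\n")
        for site, row in zip(m.sites, m.genotypes):
            alt = ",".join(site.alts) if site.alts else "."
            qual = "." if np.isnan(site.qual) else f"{site.qual:g}"
            info = (
                ";".join(f"{k}={v}" for k, v in site.info.items())
                if site.info
                else "."
            )
            gts = "\t".join(
                sep.join("." if a == MISSING else str(int(a)) for a in pair)
                for pair in row
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.vid}\t{site.ref}\t{alt}\t"
                f"{qual}\tPASS\t{info}\tGT\t{gts}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def filter_sites(
    m: GenotypeMatrix,
    min_qual: float = 30.0,
    max_missing: float = 0.10,
    min_maf: float = 0.01,
    af_mode: str = "minor",
) -> GenotypeMatrix:
    """Quality / missingness / frequency site filter.

    Retains sites with QUAL >= ``min_qual`` (NaN QUAL passes), missing-allele
    fraction <= ``max_missing`` and allele frequency >= ``min_maf``.  With
    ``af_mode="minor"`` the frequency tested is the minor (second most common)
    allele frequency; ``af_mode="nonref_any"`` instead keeps a site if *any*
    single non-reference allele reaches the threshold, the convention used for
    the InDel streams.  Idempotent; order preserved.
    """
    if af_mode not in ("minor", "nonref_any"):
        raise ValueError(f"unknown af_mode {af_mode!r}")
    missing = m.missing_allele_fraction()
    keep = []
    for i, site in enumerate(m.sites):
        if not np.isnan(site.qual) and site.qual < min_qual:
            continue
        if missing[i] > max_missing:
            continue
        freqs = m.allele_frequencies(i)
        if af_mode == "minor":
            af = np.sort(freqs)[::-1][1] if freqs.size > 1 else 0.0
        else:
            af = freqs[1:].max() if freqs.size > 1 else 0.0
        if af < min_maf:
            continue
        keep.append(i)
    return m.take_sites(keep)


# ---------------------------------------------------------------------------
# InDel splitting and proxy recoding
# ---------------------------------------------------------------------------

def split_indels(m: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split records into insertion and deletion streams by allele length.

    Per record, alternate alleles longer than REF route to the insertion
    stream and shorter ones to the deletion stream; equal-length non-SNP
    alleles are dropped with a warning count.  Genotypes referencing an allele
    routed to the other stream become missing in this stream, so each stream
    sees only "this type of variant vs reference".
    """
    ins_idx: list[tuple[int, VariantSite, dict]] = []
    del_idx: list[tuple[int, VariantSite, dict]] = []
    n_equal_dropped = 0

    for i, site in enumerate(m.sites):
        routed: dict[str, list[int]] = {"ins": [], "del": []}
        for ai, alt in enumerate(site.alts, start=1):
            if len(alt) > len(site.ref):
                routed["ins"].append(ai)
            elif len(alt) < len(site.ref):
                routed["del"].append(ai)
            elif len(alt) != 1 or len(site.ref) != 1:
                n_equal_dropped += 1
            # equal-length single-base = SNP allele: belongs to neither stream
        for kind, target in (("ins", ins_idx), ("del", del_idx)):
            kept = routed[kind]
            if not kept:
                continue
            new_alts = tuple(site.alts[ai - 1] for ai in kept)
            remap = {0: 0, MISSING: MISSING}
            remap.update({old: new for new, old in enumerate(kept, start=1)})
            new_site = replace(site, alts=new_alts)
            target.append((i, new_site, remap))

    if n_equal_dropped:
        warnings.warn(
            f"dropped {n_equal_dropped} equal-length non-SNP alleles during "
            "insertion/deletion splitting",
            stacklevel=2,
        )

    def build(entries: list[tuple[int, VariantSite, dict]]) -> GenotypeMatrix:
        if not entries:
            return empty_like(m)
        sites = [e[1] for e in entries]
        gt = np.empty((len(entries), m.n_samples, 2), dtype=np.int16)
        for row, (i, _site, remap) in enumerate(entries):
            src = m.genotypes[i]
            gt[row] = np.vectorize(lambda a: remap.get(int(a), MISSING))(src)
        return GenotypeMatrix(
            samples=list(m.samples), sites=sites, genotypes=gt,
            phased=m.phased, region=m.region,
        )

    return build(ins_idx), build(del_idx)


def recode_biallelic_proxy(m: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse an insertion-only or deletion-only stream to proxy biallelics.

    Every site becomes REF=T / ALT=A: any non-reference allele maps to the
    proxy alternate, the reference maps to the proxy reference, missing stays
    missing.  The recoded site therefore tests presence of a variant of that
    type, of any length, against the reference.
    """
    new_sites = []
    for site in m.sites:
        if site.is_snp():
            raise ValueError(
                f"site {site.chrom}:{site.pos} is a plain SNP; proxy recoding "
                "applies only to insertion/deletion streams"
            )
        kind = "ins" if all(len(a) > len(site.ref) for a in site.alts) else "del"
        info = dict(site.info)
        info["PROXY_TYPE"] = kind
        new_sites.append(
            VariantSite(
                chrom=site.chrom, pos=site.pos, ref=PROXY_REF,
                alts=(PROXY_ALT,), qual=site.qual, vid=site.vid, info=info,
            )
        )
    gt = np.where(m.genotypes > 0, 1, m.genotypes).astype(np.int16)
    return GenotypeMatrix(
        samples=list(m.samples), sites=new_sites, genotypes=gt,
        phased=m.phased, region=m.region,
    )


def merge_streams(
    insertions: GenotypeMatrix, deletions: GenotypeMatrix
) -> GenotypeMatrix:
    """Position-sorted union of the two recoded proxy streams.

    A position present in both streams yields two proxy sites distinguished by
    their PROXY_TYPE tag; a duplicate (position, type) is an error.
    """
    if insertions.samples != deletions.samples and insertions.n_sites and deletions.n_sites:
        raise ValueError("streams carry different sample sets")
    entries: list[tuple[int, int, VariantSite, np.ndarray]] = []
    type_rank = {"ins": 0, "del": 1}
    seen: set[tuple[int, str]] = set()
    for src in (insertions, deletions):
        for site, row in zip(src.sites, src.genotypes):
            kind = site.info.get("PROXY_TYPE")
            if kind not in type_rank:
                raise ValueError(
                    f"site {site.chrom}:{site.pos} lacks a PROXY_TYPE tag; "
                    "recode streams before merging"
                )
            key = (site.pos, kind)
            if key in seen:
                raise ValueError(f"duplicate proxy site {key}")
            seen.add(key)
            entries.append((site.pos, type_rank[kind], site, row))
    entries.sort(key=lambda e: (e[0], e[1]))
    samples = insertions.samples if insertions.n_sites else deletions.samples
    if not entries:
        return empty_like(insertions)
    gt = np.stack([e[3] for e in entries])
    return GenotypeMatrix(
        samples=list(samples),
        sites=[e[2] for e in entries],
        genotypes=gt,
        phased=insertions.phased and deletions.phased,
        region=insertions.region or deletions.region,
    )
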