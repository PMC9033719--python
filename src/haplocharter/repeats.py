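"""Trinucleotide-repeat genotyping, frame annotation, and depth-based SV calls.

The repeat locus is a multiallelic VCF insertion record: REF is the anchor
base and each ALT is the anchor plus an inserted sequence.  Five invariant
CAA copies immediately downstream are shared by every individual, so an
allele's total copy number is ``invariant_copies + inserted copies`` when the
insertion is a pure whole-number concatenation of the repeat unit.  Frame
annotation: a pure unit multiple is a conservative in-frame insertion (CIF);
any other insertion with length divisible by three is a disruptive in-frame
insertion (DIF); anything else shifts the reading frame (FSV).

The larger deletion is not genotyped from the VCF at all: it is classified
from per-base coverage, as a maximal run of near-zero depth inside a
candidate interval flanked by normal background coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ld import LDPair, ld_pair
from .variants import GenotypeMatrix, MISSING

ANNOT_CIF = "CIF"
ANNOT_DIF = "DIF"
ANNOT_FSV = "FSV"
ANNOT_REFLIKE = "REFLIKE"

CAT_REFERENCE = "reference"
CAT_HOM_REPEAT = "hom_repeat"
CAT_HET_REPEATS = "heterozygous_repeats"
CAT_SINGLE_REPEAT = "single_repeat"
CAT_OTHER = "other"
CAT_MISSING = "missing"


@dataclass(frozen=True)
class RepeatAllele:
    inserted_seq: str
    caa_copies_inserted: int      # 0 unless a pure repeat concatenation
    total_copies: Optional[int]   # invariant + inserted; None if not pure
    annotation: str

    @property
    def inserted_len(self) -> int:
        return len(self.inserted_seq)

    @property
    def is_pure_repeat(self) -> bool:
        return self.caa_copies_inserted > 0


@dataclass(frozen=True)
class RepeatGenotype:
    sample: str
    alleles: tuple[Optional[RepeatAllele], ...]  # None = reference allele
    category: str
    hom_copies: Optional[int] = None  # total copies when category is hom_repeat


@dataclass
class SVCall:
    """A coverage-drop deletion call: consensus interval + per-sample flags."""

    start: int                   # 1-based half-open consensus interval
    end: int
    presence: dict               # sample -> True / False / None (uncallable)
    background_depth: dict       # sample -> flanking mean depth
    interval_depth: dict         # sample -> mean depth inside candidate region

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def called_samples(self) -> list[str]:
        return [s for s, p in self.presence.items() if p is not None]


@dataclass(frozen=True)
class DepthTrack:
    """Per-base depth for one sample; ``start`` is the 1-based first position."""

    sample: str
    chrom: str
    start: int
    depth: np.ndarray

    @property
    def end(self) -> int:  # 1-based half-open
        return self.start + len(self.depth)


# ---------------------------------------------------------------------------
# Repeat genotyping
# ---------------------------------------------------------------------------

def classify_insertion(inserted_seq: str, unit: str = "CAA",
                       invariant_copies: int = 5) -> RepeatAllele:
    """Annotate one inserted sequence (total function over insertions)."""
    L = len(inserted_seq)
    if L == 0:
        return RepeatAllele("", 0, invariant_copies, ANNOT_REFLIKE)
    k, rem = divmod(L, len(unit))
    pure = rem == 0 and inserted_seq == unit * k
    if pure:
        return RepeatAllele(inserted_seq, k, invariant_copies + k, ANNOT_CIF)
    if L % 3 == 0:
        return RepeatAllele(inserted_seq, 0, None, ANNOT_DIF)
    return RepeatAllele(inserted_seq, 0, None, ANNOT_FSV)


def genotype_repeat(
    m: GenotypeMatrix,
    locus_pos: int,
    unit: str = "CAA",
    invariant_copies: int = 5,
) -> list[RepeatGenotype]:
    """Genotype the tandem-repeat locus for every sample.

    The record's ALTs must share the REF as an anchor prefix; the inserted
    sequence is the ALT with that prefix removed.  Categories follow the
    locus-summary convention: homozygous pure-repeat (by total copies),
    heterozygous with two different insertions, heterozygous with one
    insertion and one reference allele ("single repeat"), homozygous for a
    non-repeat insertion ("other"), and missing when either allele is uncalled.
    """
    try:
        i = m.site_index(locus_pos)
    except KeyError:
        raise ValueError(f"repeat locus {locus_pos} absent from the matrix")
    site = m.sites[i]
    alleles: list[Optional[RepeatAllele]] = [None]  # index 0 = reference
    for alt in site.alts:
        if not alt.startswith(site.ref):
            raise ValueError(
                f"ALT {alt!r} at {locus_pos} does not share the REF anchor "
                f"{site.ref!r}"
            )
        alleles.append(
            classify_insertion(alt[len(site.ref):], unit, invariant_copies)
        )

    out: list[RepeatGenotype] = []
    for j, sample in enumerate(m.samples):
        a, b = (int(x) for x in m.genotypes[i, j])
        if a == MISSING or b == MISSING:
            out.append(RepeatGenotype(sample, (), CAT_MISSING))
            continue
        ra, rb = alleles[a], alleles[b]
        if ra is None and rb is None:
            out.append(RepeatGenotype(sample, (None, None), CAT_REFERENCE))
        elif ra is None or rb is None:
            out.append(RepeatGenotype(sample, (ra, rb), CAT_SINGLE_REPEAT))
        elif a == b:
            if ra.is_pure_repeat:
                out.append(
                    RepeatGenotype(sample, (ra, rb), CAT_HOM_REPEAT,
                                   hom_copies=ra.total_copies)
                )
            else:
                out.append(RepeatGenotype(sample, (ra, rb), CAT_OTHER))
        else:
            out.append(RepeatGenotype(sample, (ra, rb), CAT_HET_REPEATS))
    return out


# ---------------------------------------------------------------------------
# Locus summary table (Table-1 style)
# ---------------------------------------------------------------------------

# Published class rows for the 985-accession reference panel at this locus:
# (row label, annotation, n individuals, mean protein g/100g).  Used as a
# worked example and as direct input to the re-aggregation routines.
REFERENCE_PANEL_REPEAT_ROWS: tuple[tuple[str, str, int, float], ...] = (
    ("5", "reference", 787, 43.86),
    ("6", ANNOT_CIF, 2, 49.85),
    ("7", ANNOT_CIF, 10, 46.67),
    ("8", ANNOT_CIF, 8, 45.64),
    ("9", ANNOT_CIF, 21, 46.75),
    ("10", ANNOT_CIF, 13, 48.19),
    ("11", ANNOT_CIF, 24, 47.19),
    ("12", ANNOT_CIF, 46, 46.68),
    ("13", ANNOT_CIF, 30, 48.97),
    ("14", ANNOT_CIF, 1, 50.20),
    ("other", "2xDIF; 2xFSV", 4, 44.78),
    ("heterozygous_repeats", "N/A", 11, 47.09),
    ("single_repeat", "N/A", 15, 47.03),
    ("missing", "N/A", 13, 46.92),
)


@dataclass(frozen=True)
class RepeatSummary:
    table: pd.DataFrame           # label, annotation, n, mean_protein
    total_n: int
    total_mean: float             # count-weighted, 2 dp
    pct_increase: Optional[float]  # hom pure-repeat vs reference, percent


def aggregate_repeat_rows(
    rows: Sequence[tuple[str, str, int, float]],
    include_other_in_increase: bool = False,
) -> RepeatSummary:
    """Re-aggregate per-class (label, annotation, n, mean) rows.

    Total mean is the count-weighted mean over all rows (2 dp).  The percent
    increase contrasts the weighted mean of the homozygous pure-repeat (CIF)
    copy-number rows against the reference row; the four individuals
    homozygous for atypical insertions are excluded unless
    ``include_other_in_increase`` is set (a documented toggle).
    """
    df = pd.DataFrame(rows, columns=["label", "annotation", "n", "mean_protein"])
    total_n = int(df["n"].sum())
    total_mean = round(
        float((df["n"] * df["mean_protein"]).sum() / total_n), 2
    ) if total_n else float("nan")

    ref = df[df["annotation"] == "reference"]
    hom_mask = df["annotation"] == ANNOT_CIF
    if include_other_in_increase:
        hom_mask |= df["label"] == "other"
    hom = df[hom_mask]
    pct: Optional[float] = None
    if len(ref) and ref["n"].sum() > 0:
        ref_mean = float(
            (ref["n"] * ref["mean_protein"]).sum() / ref["n"].sum()
        )
        if hom["n"].sum() > 0 and ref_mean != 0:
            hom_mean = float(
                (hom["n"] * hom["mean_protein"]).sum() / hom["n"].sum()
            )
            pct = 100.0 * (hom_mean - ref_mean) / ref_mean
    else:
        warnings.warn("empty reference class; percent increase undefined",
                      stacklevel=2)
    return RepeatSummary(table=df, total_n=total_n, total_mean=total_mean,
                         pct_increase=pct)


def repeat_summary(
    genotypes: Sequence[RepeatGenotype],
    phenotypes: pd.DataFrame,
    include_other_in_increase: bool = False,
) -> RepeatSummary:
    """Summarise repeat genotypes into the per-category table.

    One row per homozygous total-copy class, plus reference, other,
    heterozygous-repeats, single-repeat and missing rows; means to 2 dp.
    """
    tbl = phenotypes.set_index("sample_id") if "sample_id" in phenotypes else phenotypes

    def mean_protein(samples: list[str]) -> tuple[int, float]:
        present = [s for s in samples if s in tbl.index]
        v = tbl.loc[present, "protein"].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        return len(v), round(float(v.mean()), 2) if v.size else float("nan")

    buckets: dict[tuple[str, str], list[str]] = {}
    for g in genotypes:
        if g.category == CAT_HOM_REPEAT:
            key = (str(g.hom_copies), ANNOT_CIF)
        elif g.category == CAT_REFERENCE:
            key = ("5", "reference")
        else:
            key = (g.category, "N/A")
        buckets.setdefault(key, []).append(g.sample)

    def sort_key(key: tuple[str, str]):
        label = key[0]
        return (0, int(label)) if label.isdigit() else (1, label)

    rows = []
    for key in sorted(buckets, key=sort_key):
        n, mean = mean_protein(buckets[key])
        rows.append((key[0], key[1], n, mean))
    return aggregate_repeat_rows(rows, include_other_in_increase)


# ---------------------------------------------------------------------------
# Coverage-drop SV calling
# ---------------------------------------------------------------------------

def call_sv_from_depth(
    tracks: Sequence[DepthTrack],
    candidate_region: tuple[int, int],
    low_max: float = 1.0,
    bg_min: float = 8.0,
    min_len: int = 50,
    flank_bp: int = 1000,
) -> SVCall:
    """Classify a deletion from per-base coverage inside a candidate region.

    Per sample, the longest run of bases with depth <= ``low_max`` inside the
    candidate interval is located; the deletion is present when that run is at
    least ``min_len`` bp long and the mean depth over up to ``flank_bp`` bases
    on each side of the run is >= ``bg_min``.  Samples whose track mean is
    below ``bg_min`` with no qualifying run are uncallable (None), not absent.
    The reported interval is the consensus (median run start / end over
    presence samples).
    """
    r_start, r_end = candidate_region
    if r_end <= r_start:
        raise ValueError("empty candidate region")
    presence: dict[str, Optional[bool]] = {}
    background: dict[str, float] = {}
    interval_depth: dict[str, float] = {}
    starts: list[int] = []
    ends: list[int] = []

    for track in tracks:
        if track.start > r_start or track.end < r_end:
            raise ValueError(
                f"depth track for {track.sample} does not cover the candidate "
                f"region {r_start}-{r_end}"
            )
        d = track.depth
        off = r_start - track.start
        win = d[off:off + (r_end - r_start)]
        interval_depth[track.sample] = float(win.mean())

        low = win <= low_max
        best_len, best_s = 0, -1
        run_s = None
        for i, flag in enumerate(np.append(low, False)):
            if flag and run_s is None:
                run_s = i
            elif not flag and run_s is not None:
                if i - run_s > best_len:
                    best_len, best_s = i - run_s, run_s
                run_s = None

        if best_len >= min_len:
            abs_s = r_start + best_s
            abs_e = abs_s + best_len
            lf = d[max(abs_s - track.start - flank_bp, 0):abs_s - track.start]
            rf = d[abs_e - track.start:abs_e - track.start + flank_bp]
            flanks = np.concatenate([lf, rf])
            bg = float(flanks.mean()) if flanks.size else 0.0
            background[track.sample] = bg
            if bg >= bg_min:
                presence[track.sample] = True
                starts.append(abs_s)
                ends.append(abs_e)
            else:
                presence[track.sample] = None
        else:
            bg = float(d.mean())
            background[track.sample] = bg
            presence[track.sample] = False if bg >= bg_min else None

    if starts:
        c_start = int(np.median(starts))
        c_end = int(np.median(ends))
    else:  # no carriers: report the candidate region itself, zero-present
        c_start, c_end = r_start, r_end
    return SVCall(
        start=c_start, end=c_end, presence=presence,
        background_depth=background, interval_depth=interval_depth,
    )


# ---------------------------------------------------------------------------
# Concordance and SV–SNP linkage
# ---------------------------------------------------------------------------

def concordance(
    genotypes: Sequence[RepeatGenotype], sv: SVCall
) -> tuple[pd.DataFrame, Optional[float]]:
    """Cross-tabulate deletion presence against repeat category.

    Returns the margins-included table and the fraction of
    homozygous-pure-repeat samples that carry the deletion (None when there
    are no such samples).  Uncallable SV samples are excluded.
    """
    by_sample = {g.sample: g.category for g in genotypes}
    shared = [s for s in sv.presence
              if sv.presence[s] is not None and s in by_sample]
    if not shared:
        warnings.warn("no samples shared between repeat genotypes and SV call",
                      stacklevel=2)
        return pd.DataFrame(), None
    df = pd.DataFrame(
        {
            "deletion": ["present" if sv.presence[s] else "absent" for s in shared],
            "category": [by_sample[s] for s in shared],
        }
    )
    table = pd.crosstab(df["category"], df["deletion"], margins=True)
    hom = df[df["category"] == CAT_HOM_REPEAT]
    frac = float((hom["deletion"] == "present").mean()) if len(hom) else None
    return table, frac


def sv_presence_haplotypes(sv: SVCall, samples: Sequence[str]) -> np.ndarray:
    """Proxy-recode per-sample presence onto both haplotypes (biallelic)."""
    out = np.empty(2 * len(samples), dtype=np.int8)
    for j, s in enumerate(samples):
        p = sv.presence.get(s)
        code = MISSING if p is None else (1 if p else 0)
        out[2 * j] = code
        out[2 * j + 1] = code
    return out


def sv_linkage(sv: SVCall, m: GenotypeMatrix, focal_pos: int) -> LDPair:
    """LD between the deletion (proxy-recoded presence) and a focal SNP."""
    sv_hap = sv_presence_haplotypes(sv, m.samples)
    called = sv_hap[sv_hap != MISSING]
    if called.size == 0 or len(set(called.tolist())) < 2:
        raise ValueError("SV presence is monomorphic; linkage undefined")
    focal = m.binary_haplotypes()[m.site_index(focal_pos)]
    pair = ld_pair(sv_hap, focal, pos_a=sv.start, pos_b=focal_pos)
    if not pair.defined:
        raise ValueError("LD undefined between SV and focal site")
    return pair


# ---------------------------------------------------------------------------
# Depth BED I/O (0-based half-open, mosdepth-style, plus a sample column)
# ---------------------------------------------------------------------------

def write_depth_bed(tracks: Sequence[DepthTrack], path: str | Path) -> Path:
    """Write tracks as a 5-column BED: chrom, start0, end0, depth, sample.

    Runs of equal depth are merged into single rows, as per-base coverage
    tools do.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for t in tracks:
            d = t.depth
            i = 0
            while i < len(d):
                j = i
                while j + 1 < len(d) and d[j + 1] == d[i]:
                    j += 1
                # 1-based position p covers BED [p-1, p); run end exclusive
                fh.write(
                    f"{t.chrom}\t{t.start - 1 + i}\t{t.start + j}\t"
                    f"{int(d[i])}\t{t.sample}\n"
                )
                i = j + 1
    return path


def read_depth_bed(path: str | Path) -> list[DepthTrack]:
    """Read tracks written by :func:`write_depth_bed` (contiguous per sample)."""
    rows = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start0", "end0", "depth", "sample"],
    )
    tracks = []
    for (sample, chrom), grp in rows.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("start0")
        start0 = int(grp["start0"].iloc[0])
        end0 = int(grp["end0"].iloc[-1])
        depth = np.zeros(end0 - start0, dtype=np.int32)
        for s0, e0, d in zip(grp["start0"], grp["end0"], grp["depth"]):
            depth[int(s0) - start0:int(e0) - start0] = int(d)
        tracks.append(
            DepthTrack(sample=str(sample), chrom=str(chrom),
                       start=start0 + 1, depth=depth)
        )
    return tracks


def write_sv_vcf(sv: SVCall, chrom: str, path: str | Path) -> Path:
    """Write the consensus deletion as a symbolic <DEL> record with END info."""
    path = Path(path)
    samples = list(sv.presence)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=haplocharter-sv\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        gts = []
        for s in samples:
            p = sv.presence[s]
            gts.append("./." if p is None else ("1/1" if p else "0/0"))
        fh.write(
            f"{chrom}\t{sv.start}\t.\tN\t<DEL>\t.\tPASS\t"
            f"END={sv.end - 1};SVLEN=-{sv.length_bp}\tGT\t" + "\t".join(gts) + "\n"
        )
    return path
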