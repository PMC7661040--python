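"""Genomic context of CpGs: TSS distance, region category, CpG density, and
region-set enrichment of modules against a fixed CpG background.

Gene models come from GFF3 (1-based inclusive); region sets from BED
(0-based half-open, converted on read and merged).  Enrichment is a 2x2
Fisher exact test of module membership against region overlap, with the
fold change computed from module-vs-rest proportions and BH adjustment
across sets within a module.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matrix import GenomicSite

__all__ = [
    "GeneModel",
    "read_gff_genes",
    "RegionSet",
    "read_bed",
    "scan_cpgs",
    "cpg_density",
    "tss_distance",
    "TSS_BINS",
    "classify_region",
    "EnrichmentResult",
    "region_enrichment",
]


# ------------------------------------------------------------------- genes
@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive gene span
    end: int
    exons: list = field(default_factory=list)  # (start, end) 1-based inclusive

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gff_genes(path) -> list[GeneModel]:
    """Read gene and exon features from a GFF3 file (1-based inclusive)."""
    genes: dict[str, GeneModel] = {}
    exon_rows: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", attr.get("gene_id", f"{chrom}:{start}"))
                genes[gid] = GeneModel(
                    gene_id=gid, chrom=chrom, strand=strand,
                    start=int(start), end=int(end),
                )
            elif ftype == "exon":
                parent = attr.get("Parent", attr.get("gene_id", ""))
                exon_rows.append((parent.split(":")[-1], int(start), int(end)))
    for parent, s, e in exon_rows:
        for gid, g in genes.items():
            if gid == parent or gid.endswith(parent):
                g.exons.append((s, e))
                break
    return list(genes.values())


# ----------------------------------------------------------------- regions
@dataclass
class RegionSet:
    """Named set of merged intervals, 0-based half-open."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end (sorted, merged)

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based position membership."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if sub.empty:
            return False
        p0 = pos - 1
        idx = np.searchsorted(sub["start"].to_numpy(), p0, side="right") - 1
        return idx >= 0 and p0 < int(sub["end"].iloc[idx])

    def contains_sites(self, sites: Sequence[GenomicSite]) -> np.ndarray:
        return np.array([self.contains(s.chrom, s.pos) for s in sites], dtype=bool)


def read_bed(path, name: str | None = None) -> RegionSet:
    """Read a BED file; overlapping or adjacent intervals are merged."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    merged = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    if name is None:
        base = str(path).rsplit("/", 1)[-1]
        name = base[:-4] if base.endswith(".bed") else base
    return RegionSet(name=name, intervals=out)


# --------------------------------------------------------------- CpG sites
def scan_cpgs(fasta_path) -> list[GenomicSite]:
    """One site per CG dinucleotide (position of the C, forward strand)."""
    sites: list[GenomicSite] = []
    name = None
    tail = ""
    offset = 0

    def _scan(chunk: str, chrom: str, base: int):
        start = 0
        while True:
            i = chunk.find("CG", start)
            if i < 0:
                return
            sites.append(GenomicSite(chrom=chrom, pos=base + i + 1))
            start = i + 1

    with _open_text(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                tail = ""
                offset = 0
            elif line and name is not None:
                seq = (tail + line.upper())
                _scan(seq, name, offset - len(tail))
                tail = seq[-1]
                offset += len(line)
    return sites


def cpg_density(site: GenomicSite, catalogue: Sequence[GenomicSite],
                window_bp: int = 100) -> int:
    """CpGs within ``window_bp`` centred on the site (inclusive of itself)."""
    half = window_bp // 2
    positions = np.array([c.pos for c in catalogue if c.chrom == site.chrom])
    positions.sort()
    lo = np.searchsorted(positions, max(site.pos - half, 1), side="left")
    hi = np.searchsorted(positions, site.pos + half, side="right")
    return int(hi - lo)


# ----------------------------------------------------------- TSS distance
TSS_BINS = ["<1e3", "1e3-1e4", "1e4-1e5", "1e5-1e6", ">1e6"]


def _bin_distance(d: float) -> str:
    a = abs(d)
    if a < 1e3:
        return TSS_BINS[0]
    if a < 1e4:
        return TSS_BINS[1]
    if a < 1e5:
        return TSS_BINS[2]
    if a <= 1e6:
        return TSS_BINS[3]
    return TSS_BINS[4]


def tss_distance(site: GenomicSite, genes: Sequence[GeneModel]):
    """Signed distance to the nearest TSS (positive = downstream of that
    gene's TSS, strand-aware) and its decade bin label."""
    best = None
    for g in genes:
        if g.chrom != site.chrom:
            continue
        raw = site.pos - g.tss
        signed = raw if g.strand == "+" else -raw
        if best is None or abs(signed) < abs(best):
            best = signed
    if best is None:
        return None, "no-gene"
    return int(best), _bin_distance(best)


def classify_region(site: GenomicSite, genes: Sequence[GeneModel],
                    flank_bp: int = 1000) -> str:
    """Category with precedence promoter > exon > intron > TTS > intergenic.

    Promoter and TTS are the TSS/TES +- ``flank_bp``; intron is the gene body
    outside exons.
    """
    in_promoter = in_exon = in_intron = in_tts = False
    for g in genes:
        if g.chrom != site.chrom:
            continue
        if abs(site.pos - g.tss) <= flank_bp:
            in_promoter = True
        if abs(site.pos - g.tes) <= flank_bp:
            in_tts = True
        if g.start <= site.pos <= g.end:
            if any(s <= site.pos <= e for s, e in g.exons):
                in_exon = True
            else:
                in_intron = True
    for flag, label in ((in_promoter, "promoter"), (in_exon, "exon"),
                        (in_intron, "intron"), (in_tts, "TTS")):
        if flag:
            return label
    return "intergenic"


# -------------------------------------------------------------- enrichment
@dataclass
class EnrichmentResult:
    set_name: str
    a: int  # module & in region
    b: int  # module & not in region
    c: int  # rest of background & in region
    d: int  # rest of background & not in region
    fold: float
    p: float
    q: float = float("nan")


def region_enrichment(module_sites: Sequence[GenomicSite],
                      background_sites: Sequence[GenomicSite],
                      sets: Sequence[RegionSet]) -> list[EnrichmentResult]:
    """Two-sided Fisher exact enrichment of a module against region sets.

    The 2x2 table crosses module membership (module vs background-minus-
    module) with region overlap; fold = (a/(a+b)) / (c/(c+d)); q-values are
    BH-adjusted across the supplied sets.
    """
    if not module_sites:
        raise ValueError("module is empty")
    module_ids = {s.site_id for s in module_sites}
    bg_ids = {s.site_id for s in background_sites}
    if not module_ids <= bg_ids:
        raise ValueError("module sites must be a subset of the background")
    rest = [s for s in background_sites if s.site_id not in module_ids]

    results = []
    for rs in sets:
        in_mod = rs.contains_sites(list(module_sites))
        in_rest = rs.contains_sites(rest)
        a = int(in_mod.sum())
        b = len(module_sites) - a
        c = int(in_rest.sum())
        d = len(rest) - c
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p_mod = a / (a + b)
        p_rest = c / (c + d) if (c + d) else math.nan
        fold = math.inf if p_rest == 0 and p_mod > 0 else \
            (0.0 if p_mod == 0 else p_mod / p_rest)
        results.append(EnrichmentResult(set_name=rs.name, a=a, b=b, c=c, d=d,
                                        fold=fold, p=float(p)))
    if results:
        _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q = float(qv)
    return results
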