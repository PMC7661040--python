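"""Chain-file coordinate mapping and cross-species clock transfer.

Parses UCSC chain files and lifts single CpG positions from a source genome
to a target genome.  In chain-file nomenclature the "t" (target) fields are
the assembly being lifted FROM and the "q" (query) fields the assembly being
lifted TO; here they are called source and dest throughout to avoid the trap.

Coordinates are 1-based internally; chain files are 0-based half-open.  The
conversion happens in exactly one place (:func:`liftover_site`).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clocks import PCClock, fit_pc_clock
from .matrix import BetaMatrix, GenomicSite

__all__ = [
    "ChainBlock",
    "Chain",
    "ChainAlignment",
    "read_chain",
    "write_chain",
    "liftover_site",
    "liftover_sites",
    "MappedSite",
    "intersect_sites",
    "TransferredClock",
    "transfer_clock",
]


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped block, 0-based half-open on both genomes (strand coords)."""

    src_start: int
    src_end: int
    dst_start: int
    dst_end: int


@dataclass
class Chain:
    score: float
    src_chrom: str
    src_size: int
    dst_chrom: str
    dst_size: int
    dst_strand: str  # '+' or '-'
    blocks: list = field(default_factory=list)


class ChainAlignment:
    """A parsed chain file, indexed by source chromosome for block lookup."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains = list(chains)
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        per_chrom: dict[str, list] = {}
        for ci, chain in enumerate(self.chains):
            for b in chain.blocks:
                per_chrom.setdefault(chain.src_chrom, []).append((b.src_start, b.src_end, ci, b))
        for chrom, entries in per_chrom.items():
            entries.sort(key=lambda e: (e[0], e[1]))
            starts = np.array([e[0] for e in entries], dtype=np.int64)
            ends = np.array([e[1] for e in entries], dtype=np.int64)
            self._index[chrom] = (starts, ends, entries)

    def blocks_at(self, chrom: str, pos0: int):
        """All (chain_index, block) whose source interval contains pos0."""
        if chrom not in self._index:
            return []
        starts, ends, entries = self._index[chrom]
        hi = np.searchsorted(starts, pos0, side="right")
        return [(e[2], e[3]) for e in entries[:hi] if e[1] > pos0]


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_chain(path) -> ChainAlignment:
    """Parse a UCSC chain file, validating block arithmetic per chain."""
    chains: list[Chain] = []
    current: Chain | None = None
    src_cursor = dst_cursor = 0
    src_end_decl = dst_end_decl = 0
    chain_id = "?"

    def _finish():
        if current is None:
            return
        if src_cursor != src_end_decl or dst_cursor != dst_end_decl:
            raise ValueError(
                f"chain {chain_id}: block arithmetic inconsistent "
                f"(source ends at {src_cursor}, declared {src_end_decl}; "
                f"dest ends at {dst_cursor}, declared {dst_end_decl})"
            )
        chains.append(current)

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "chain":
                _finish()
                (_tag, score, s_chrom, s_size, s_strand, s_start, s_end,
                 d_chrom, d_size, d_strand, d_start, d_end) = fields[:12]
                chain_id = fields[12] if len(fields) > 12 else str(len(chains) + 1)
                if s_strand != "+":
                    raise ValueError(f"chain {chain_id}: source strand must be +")
                current = Chain(
                    score=float(score), src_chrom=s_chrom, src_size=int(s_size),
                    dst_chrom=d_chrom, dst_size=int(d_size), dst_strand=d_strand,
                )
                src_cursor, dst_cursor = int(s_start), int(d_start)
                src_end_decl, dst_end_decl = int(s_end), int(d_end)
            else:
                if current is None:
                    raise ValueError("alignment line before any chain header")
                size = int(fields[0])
                current.blocks.append(ChainBlock(
                    src_start=src_cursor, src_end=src_cursor + size,
                    dst_start=dst_cursor, dst_end=dst_cursor + size,
                ))
                if len(fields) >= 3:
                    src_cursor += size + int(fields[1])
                    dst_cursor += size + int(fields[2])
                else:  # terminal line
                    src_cursor += size
                    dst_cursor += size
    _finish()
    return ChainAlignment(chains)


def write_chain(chains: Sequence[Chain], path) -> None:
    """Serialise chains in UCSC chain format (inverse of :func:`read_chain`)."""
    with open(path, "w") as fh:
        for i, c in enumerate(chains, start=1):
            b0, bn = c.blocks[0], c.blocks[-1]
            fh.write(
                f"chain {c.score:g} {c.src_chrom} {c.src_size} + "
                f"{b0.src_start} {bn.src_end} {c.dst_chrom} {c.dst_size} "
                f"{c.dst_strand} {b0.dst_start} {bn.dst_end} {i}\n"
            )
            for b, nxt in zip(c.blocks, c.blocks[1:]):
                size = b.src_end - b.src_start
                fh.write(f"{size}\t{nxt.src_start - b.src_end}\t{nxt.dst_start - b.dst_end}\n")
            fh.write(f"{bn.src_end - bn.src_start}\n\n")


@dataclass(frozen=True)
class MappedSite:
    source: GenomicSite
    target: GenomicSite | None
    chain_score: float | None

    @property
    def mapped(self) -> bool:
        return self.target is not None


def liftover_site(alignment: ChainAlignment, site: GenomicSite) -> MappedSite:
    """Map a single 1-based site through the highest-scoring covering block.

    Minus-strand targets use ``target_pos0 = dst_size - strand_pos0 - 1`` to
    express the position on the forward strand of the target assembly.
    """
    pos0 = site.pos - 1  # the single 1-based <-> 0-based conversion
    hits = alignment.blocks_at(site.chrom, pos0)
    if not hits:
        return MappedSite(source=site, target=None, chain_score=None)
    # highest score wins; ties broken by chain order in the file
    ci, block = max(hits, key=lambda h: (alignment.chains[h[0]].score, -h[0]))
    chain = alignment.chains[ci]
    offset = pos0 - block.src_start
    strand_pos0 = block.dst_start + offset
    if chain.dst_strand == "+":
        tgt0 = strand_pos0
        tgt_strand = site.strand
    else:
        tgt0 = chain.dst_size - strand_pos0 - 1
        tgt_strand = {"+": "-", "-": "+", ".": "."}[site.strand]
    target = GenomicSite(chrom=chain.dst_chrom, pos=tgt0 + 1, strand=tgt_strand)
    return MappedSite(source=site, target=target, chain_score=chain.score)


def liftover_sites(alignment: ChainAlignment, sites) -> list:
    """Map an iterable of sites (GenomicSite or a BetaMatrix sites frame)."""
    if isinstance(sites, pd.DataFrame):
        sites = [GenomicSite(r.chrom, int(r.pos), r.strand) for r in sites.itertuples()]
    return [liftover_site(alignment, s) for s in sites]


def intersect_sites(mapped: Sequence[MappedSite], other_site_ids) -> pd.DataFrame:
    """Pair mapped sources with sites present in the other species' matrix.

    If two sources map to the same target the one with the higher chain score
    is kept (ties: first in input order); the other is dropped.
    Returns a DataFrame with columns source_id, target_id, chain_score.
    """
    other = set(other_site_ids)
    best: dict[str, tuple[float, int, MappedSite]] = {}
    for i, m in enumerate(mapped):
        if not m.mapped or m.target.site_id not in other:
            continue
        key = m.target.site_id
        entry = (m.chain_score, -i, m)
        if key not in best or entry > best[key]:
            best[key] = entry
    rows = sorted(
        ((m.source.chrom, m.source.pos, m.source.site_id, m.target.site_id, m.chain_score)
         for _, _, m in best.values())
    )
    return pd.DataFrame(
        [(r[2], r[3], r[4]) for r in rows],
        columns=["source_id", "target_id", "chain_score"],
    )


class TransferredClock:
    """A PC clock trained on source-species CpGs, applicable across species.

    Carries the source->target site pairing so that prediction can consume a
    target-species beta matrix directly.
    """

    def __init__(self, clock: PCClock, pairs: pd.DataFrame):
        self.clock = clock
        self.pairs = pairs.reset_index(drop=True)

    def predict_source(self, matrix: BetaMatrix) -> pd.Series:
        X = _aligned(matrix, self.pairs["source_id"])
        return pd.Series(self.clock.predict(X), index=matrix.samples, name="dnam_age_months")

    def predict_target(self, matrix: BetaMatrix) -> pd.Series:
        X = _aligned(matrix, self.pairs["target_id"])
        return pd.Series(self.clock.predict(X), index=matrix.samples, name="dnam_age_months")


def _aligned(matrix: BetaMatrix, site_ids) -> np.ndarray:
    idx = matrix.site_ids.get_indexer(pd.Index(site_ids))
    if (idx < 0).any():
        n = int((idx < 0).sum())
        raise KeyError(f"matrix lacks {n} paired sites")
    return matrix.values[idx].T


def transfer_clock(matrix_src: BetaMatrix, train_ids, ages, pairs: pd.DataFrame,
                   components=(1,)) -> TransferredClock:
    """Refit the PC clock on the source training split restricted to paired sites."""
    if len(pairs) < 2:
        raise ValueError("site pairing must cover at least 2 sites")
    train = matrix_src.subset_samples(list(train_ids))
    X = _aligned(train, pairs["source_id"])
    clock = fit_pc_clock(X, np.asarray(ages, dtype=float), components=components,
                         sites=pd.Index(pairs["source_id"]))
    return TransferredClock(clock, pairs)
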