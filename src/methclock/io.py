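"""Reading methylation call tables and assembling the cohort beta matrix.

Two input dialects are supported:

* ``cgmap`` — CGmap-style TSV: chrom, nucleotide, pos (1-based), context,
  dinucleotide, beta, methylated count, total count.  Only CpG-context rows
  are ingested; CHG/CHH rows are skipped (counted).
* ``cov`` — bismark coverage-style TSV: chrom, start, end, percent
  methylation, methylated count, unmethylated count.  Percentages are divided
  by 100 and positions normalised to 1-based.

Coverage filtering follows the strict reading of "greater than 10x": an entry
is kept only when its coverage is strictly above ``min_coverage``.
"""

from __future__ import annotations

import gzip
import logging
import math
import os
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, MethylationCallSet, _sites_frame

logger = logging.getLogger(__name__)

__all__ = ["read_calls", "assemble_matrix", "filter_sites"]

_CPG_CONTEXTS = {"CG", "CpG"}


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_calls(path, dialect: str = "cov", sample_id: str | None = None) -> MethylationCallSet:
    """Parse a per-sample methylation call file into a :class:`MethylationCallSet`.

    Parameters
    ----------
    path : file path (plain or ``.gz``).
    dialect : ``"cgmap"`` or ``"cov"``.
    sample_id : defaults to the file's base name without extensions.
    """
    if dialect not in {"cgmap", "cov"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if sample_id is None:
        base = os.path.basename(str(path))
        for suffix in (".gz", ".tsv", ".cov", ".CGmap", ".cgmap", ".txt"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        sample_id = base

    chroms: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    betas: list[float] = []
    coverages: list[int] = []
    skipped_non_cpg = 0

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "cgmap":
                    chrom, nucleotide, pos, context, _dinuc, beta, meth, total = fields[:8]
                    if context not in _CPG_CONTEXTS:
                        skipped_non_cpg += 1
                        continue
                    pos = int(pos)
                    meth, total = int(meth), int(total)
                    beta = float(beta) if total == 0 else meth / total
                    coverage = total
                    strand = "+" if nucleotide.upper() == "C" else "-"
                else:  # cov
                    chrom, start, end, pct, meth, unmeth = fields[:6]
                    meth, unmeth = int(meth), int(unmeth)
                    coverage = meth + unmeth
                    beta = float(pct) / 100.0
                    start, end = int(start), int(end)
                    # bismark cov files are 1-based inclusive when start==end,
                    # 0-based half-open when end==start+1; normalise to 1-based
                    pos = start if end == start else start + 1
                    strand = "+"
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed {dialect} row at line {lineno}: {exc}") from None
            if not (0.0 <= beta <= 1.0):
                raise ValueError(f"{path}: beta {beta} outside [0,1] at line {lineno}")
            chroms.append(chrom)
            positions.append(pos)
            strands.append(strand)
            betas.append(beta)
            coverages.append(coverage)

    if skipped_non_cpg:
        logger.info("%s: skipped %d non-CpG rows", path, skipped_non_cpg)
    records = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": strands,
            "beta": np.asarray(betas, dtype=float),
            "coverage": np.asarray(coverages, dtype=np.int64),
        }
    )
    return MethylationCallSet(sample_id=sample_id, records=records)


def assemble_matrix(callsets: Sequence[MethylationCallSet], min_coverage: int = 10) -> BetaMatrix:
    """Union sites across samples; mask entries with coverage <= ``min_coverage``.

    An entry is present only when the sample observed the site with strictly
    more than ``min_coverage`` reads ("greater than 10x").
    """
    if not callsets:
        raise ValueError("need at least one call set")
    ids = [cs.sample_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among call sets")

    # union of sites comes from *all* records, not only high-coverage ones
    all_sites = pd.concat([cs.records[["chrom", "pos", "strand"]] for cs in callsets])
    all_sites = all_sites.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])
    sites = _sites_frame(all_sites["chrom"], all_sites["pos"], all_sites["strand"])

    values = np.full((len(sites), len(ids)), np.nan)
    for j, cs in enumerate(callsets):
        rec = cs.records
        keep = (rec["coverage"] > min_coverage).to_numpy()
        site_ids = rec["chrom"].astype(str) + ":" + rec["pos"].astype(str)
        rows = sites.index.get_indexer(site_ids[keep])
        values[rows, j] = rec["beta"].to_numpy()[keep]
    return BetaMatrix(sites, values, ids)


def filter_sites(matrix: BetaMatrix, min_fraction: float = 0.8) -> BetaMatrix:
    """Keep sites present (post coverage mask) in at least ``min_fraction`` of samples.

    The required count is ``ceil(min_fraction * n_samples)`` — "at least 80%"
    is a lower bound.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    required = math.ceil(min_fraction * matrix.n_samples)
    keep = matrix.presence_counts() >= required
    if not keep.any():
        warnings.warn("no sites survive the completeness filter", stacklevel=2)
    return BetaMatrix(matrix.sites.iloc[keep], matrix.values[keep], matrix.samples)
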