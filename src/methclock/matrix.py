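"""Core containers: genomic sites, per-sample call sets, and the beta matrix.

The beta matrix is the central object of the pipeline: a sites x samples grid
of methylation fractions in [0, 1] with explicit missingness (NaN).  Sites are
kept sorted by (chrom, pos) and identified by the string ``"chrom:pos"``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenomicSite", "MethylationCallSet", "BetaMatrix", "read_sample_table"]


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A 1-based genomic position, optionally stranded."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class MethylationCallSet:
    """Per-sample CpG methylation calls: (site, beta, coverage) records."""

    sample_id: str
    records: pd.DataFrame  # columns: chrom, pos, strand, beta, coverage

    REQUIRED = ("chrom", "pos", "strand", "beta", "coverage")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"call set missing columns: {missing}")
        bad = df["beta"].lt(0) | df["beta"].gt(1)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"beta outside [0,1] in sample {self.sample_id} at row {i}: "
                f"{df['beta'].iloc[i]}"
            )
        if (df["coverage"] < 0).any():
            raise ValueError(f"negative coverage in sample {self.sample_id}")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"duplicate sites in sample {self.sample_id}")
        object.__setattr__(self, "records", df)

    def __len__(self) -> int:
        return len(self.records)


def _sites_frame(chroms, positions, strands=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": "+" if strands is None else np.asarray(strands, dtype=object),
        }
    )
    df.index = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    return df


class BetaMatrix:
    """Sites x samples methylation fractions with explicit missingness.

    Parameters
    ----------
    sites : DataFrame with columns chrom, pos, strand, indexed by "chrom:pos".
    values : float array, shape (n_sites, n_samples); NaN encodes missing.
    samples : sequence of sample ids (columns).
    """

    def __init__(self, sites: pd.DataFrame, values: np.ndarray, samples: Sequence[str]):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sites), len(samples)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(sites)} sites x {len(samples)} samples"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        present = values[~np.isnan(values)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("present beta values must lie in [0, 1]")
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        self.sites = sites.iloc[order].copy()
        self.values = values[order]
        self.samples = list(samples)

    # ------------------------------------------------------------------ info
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def site_ids(self) -> pd.Index:
        return self.sites.index

    def presence_counts(self) -> np.ndarray:
        """Number of non-missing samples per site."""
        return (~np.isnan(self.values)).sum(axis=1)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    # -------------------------------------------------------------- subsets
    def subset_sites(self, site_ids: Iterable[str]) -> "BetaMatrix":
        idx = self.sites.index.get_indexer(pd.Index(site_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(site_ids, idx) if i < 0]
            raise KeyError(f"sites not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return BetaMatrix(self.sites.iloc[idx], self.values[idx], self.samples)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"sample not in matrix: {e}") from None
        return BetaMatrix(self.sites, self.values[:, idx], list(sample_ids))

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.sites.copy(), self.values.copy(), list(self.samples))

    # ---------------------------------------------------------------- views
    def to_frame(self) -> pd.DataFrame:
        """Sites x samples DataFrame (index "chrom:pos")."""
        return pd.DataFrame(self.values, index=self.sites.index, columns=self.samples)

    @property
    def X(self) -> np.ndarray:
        """Samples x sites array — the scikit-learn orientation."""
        return self.values.T

    # ------------------------------------------------------------------ I/O
    def write_tsv(self, path) -> None:
        df = self.to_frame().round(6)
        df.insert(0, "strand", self.sites["strand"].to_numpy())
        df.to_csv(path, sep="\t", index_label="site", float_format="%.6f")

    @classmethod
    def read_tsv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site")
        strands = df.pop("strand").to_numpy() if "strand" in df.columns else None
        parts = df.index.str.rsplit(":", n=1)
        chroms = [p[0] for p in parts]
        positions = [int(p[1]) for p in parts]
        sites = _sites_frame(chroms, positions, strands)
        return cls(sites, df.to_numpy(dtype=float), list(df.columns))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strands=None) -> "BetaMatrix":
        parts = df.index.str.rsplit(":", n=1)
        sites = _sites_frame([p[0] for p in parts], [int(p[1]) for p in parts], strands)
        return cls(sites, df.to_numpy(dtype=float), list(df.columns))

    def __repr__(self) -> str:
        miss = float(np.isnan(self.values).mean()) if self.values.size else 0.0
        return (
            f"BetaMatrix({self.n_sites} sites x {self.n_samples} samples, "
            f"{100 * miss:.1f}% missing)"
        )


SAMPLE_COLUMNS = ["sample_id", "species", "age_months", "diet", "cr_duration_months", "tissue", "split"]


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample metadata TSV and validate its invariants."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if (df["age_months"] <= 0).any():
        raise ValueError("age_months must be positive")
    al = df["diet"] == "AL"
    if (df.loc[al, "cr_duration_months"] != 0).any():
        raise ValueError("cr_duration_months must be 0 for AL animals")
    return df.set_index("sample_id", drop=False)
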