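"""Core in-memory containers: methylation count matrix, sample sheet, annotation.

Coordinates are 1-based inclusive throughout (the Bismark-coverage and GFF3
convention); conversion to 0-based half-open happens only at BED boundaries.
CpGs are strandless merged units keyed by (chrom, position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SiteKey = tuple[str, int]


@dataclass
class MethylationMatrix:
    """Per-CpG, per-sample (methylated, total) read counts.

    ``sites`` is a DataFrame with columns ``chrom`` and ``pos`` sorted by
    (chrom, pos); ``meth`` and ``total`` are int arrays of shape
    (n_sites, n_samples), column order matching ``samples``.
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        n, s = self.meth.shape
        if self.total.shape != (n, s) or len(self.sites) != n or len(self.samples) != s:
            raise ValueError("inconsistent matrix dimensions")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.meth > self.total):
            raise ValueError("methylated count exceeds total")

    @property
    def n_sites(self) -> int:
        return self.meth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def site_keys(self) -> list[SiteKey]:
        return list(zip(self.sites["chrom"].tolist(), self.sites["pos"].tolist()))

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        idx = self.sample_index(sample_ids)
        return MethylationMatrix(self.sites.reset_index(drop=True),
                                 list(sample_ids),
                                 self.meth[:, idx].copy(), self.total[:, idx].copy())

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(self.sites.loc[mask].reset_index(drop=True),
                                 list(self.samples),
                                 self.meth[mask].copy(), self.total[mask].copy())

    def fraction(self) -> np.ndarray:
        """Methylated fraction per cell; NaN where total is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)


@dataclass
class SampleSheet:
    """Maps samples to experiment (T1/T2), treatment, generation and clone line."""

    frame: pd.DataFrame  # sample_id, experiment, treatment, generation, clone_line[, path]

    REQUIRED = ("sample_id", "experiment", "treatment", "generation", "clone_line")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in sample sheet")

    def samples_for(self, *, treatment: str | None = None,
                    generation: str | None = None,
                    experiment: str | None = None) -> list[str]:
        f = self.frame
        if treatment is not None:
            f = f[f["treatment"] == treatment]
        if generation is not None:
            f = f[f["generation"] == generation]
        if experiment is not None:
            f = f[f["experiment"] == experiment]
        return f["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")


@dataclass
class GenomeAnnotation:
    genes: list[Gene]
    go_map: dict[str, set[str]] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.gene_id))
        return out


def _sort_sites(sites: pd.DataFrame) -> pd.DataFrame:
    return sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def assemble_matrix(records: dict[str, pd.DataFrame], sheet: SampleSheet,
                    site_policy: str = "union") -> MethylationMatrix:
    """Assemble per-sample coverage records into one matrix.

    ``records`` maps sample_id to a DataFrame with columns
    (chrom, pos, meth, unmeth).  Under the ``union`` policy sites absent from
    a sample get total 0; ``intersection`` keeps sites present in every sample.
    """
    if site_policy not in ("union", "intersection"):
        raise ValueError("site_policy must be 'union' or 'intersection'")
    sample_ids = sheet.frame["sample_id"].tolist()
    missing = [s for s in sample_ids if s not in records]
    if missing:
        raise ValueError(f"no coverage records for samples: {missing}")

    keysets = []
    for sid in sample_ids:
        df = records[sid]
        keys = list(zip(df["chrom"].tolist(), df["pos"].tolist()))
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate (chrom, position) rows in sample {sid}")
        keysets.append(set(keys))
    if site_policy == "union":
        allkeys = set().union(*keysets) if keysets else set()
    else:
        allkeys = set.intersection(*keysets) if keysets else set()
    sites = _sort_sites(pd.DataFrame(sorted(allkeys), columns=["chrom", "pos"]))
    index = {k: i for i, k in enumerate(zip(sites["chrom"], sites["pos"]))}

    n, s = len(sites), len(sample_ids)
    meth = np.zeros((n, s), dtype=np.int64)
    total = np.zeros((n, s), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        df = records[sid]
        for chrom, pos, m, u in zip(df["chrom"], df["pos"], df["meth"], df["unmeth"]):
            i = index.get((chrom, pos))
            if i is not None:
                meth[i, j] = m
                total[i, j] = m + u
    return MethylationMatrix(sites, sample_ids, meth, total)
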