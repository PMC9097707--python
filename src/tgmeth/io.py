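"""Readers and writers for the formats the pipeline touches.

Bismark coverage TSV (chrom, 1-based start, end, %methylation, methylated
count, unmethylated count), GFF3 gene/exon annotation, sample-sheet CSV,
gene->GO TSV, DMP tables and JSON reports.  The %methylation column of
coverage files is ignored on input and recomputed from the counts.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from pathlib import Path
from typing import IO

import gffutils
import numpy as np
import pandas as pd

from .matrix import Gene, GenomeAnnotation, MethylationMatrix, SampleSheet

log = logging.getLogger(__name__)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# Bismark coverage files
# --------------------------------------------------------------------------

def read_bismark_coverage(path: str | Path) -> pd.DataFrame:
    """Parse one Bismark coverage file into (chrom, pos, meth, unmeth) records.

    Rows with meth + unmeth == 0 are kept (total 0).  A malformed row raises
    with its 1-based line number.
    """
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated columns, "
                    f"got {len(parts)}")
            try:
                chrom = parts[0]
                pos = int(parts[1])
                m = int(parts[4])
                u = int(parts[5])
            except ValueError as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from None
            if pos < 1 or m < 0 or u < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative count or position < 1")
            chroms.append(chrom)
            poss.append(pos)
            meths.append(m)
            unmeths.append(u)
    if not chroms:
        warnings.warn(f"{path}: empty coverage file", stacklevel=2)
    return pd.DataFrame({"chrom": chroms, "pos": poss,
                         "meth": meths, "unmeth": unmeths})


def write_bismark_coverage(matrix: MethylationMatrix, sample_id: str,
                           path: str | Path) -> None:
    """Write one sample's counts as a Bismark coverage file (start == end)."""
    j = matrix.samples.index(sample_id)
    m = matrix.meth[:, j]
    t = matrix.total[:, j]
    u = t - m
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(t > 0, 100.0 * m / np.maximum(t, 1), 0.0)
    with _open_text(path, "wt") as fh:
        for chrom, pos, mi, ui, p in zip(matrix.sites["chrom"], matrix.sites["pos"],
                                         m, u, pct):
            fh.write(f"{chrom}\t{pos}\t{pos}\t{p:.6g}\t{mi}\t{ui}\n")


# --------------------------------------------------------------------------
# Sample sheets
# --------------------------------------------------------------------------

def read_samplesheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, dtype=str)
    return SampleSheet(frame)


def write_samplesheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


# --------------------------------------------------------------------------
# GFF3 annotation and GO map
# --------------------------------------------------------------------------

def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene/exon features from GFF3, resolving exons to parent genes.

    Orphan exons (no resolvable gene parent) are dropped with a warning.
    Chromosome sizes are taken from ``##sequence-region`` pragmas if present.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: dict[str, Gene] = {}
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("ID", [f.id])[0]
        genes[gid] = Gene(gene_id=gid, chrom=f.seqid, start=f.start, end=f.end,
                          strand=f.strand or "+")
    n_orphans = 0
    for f in db.features_of_type("exon"):
        parents = f.attributes.get("Parent", [])
        hit = next((p for p in parents if p in genes), None)
        if hit is None:
            # attach to an enclosing gene if one exists, otherwise drop
            hit = next((gid for gid, g in genes.items()
                        if g.chrom == f.seqid and g.start <= f.start
                        and f.end <= g.end), None)
        if hit is None:
            n_orphans += 1
            continue
        genes[hit].exons.append((f.start, f.end))
    if n_orphans:
        warnings.warn(f"{path}: dropped {n_orphans} orphan exon(s)", stacklevel=2)
    for g in genes.values():
        g.exons.sort()
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    ordered = sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))
    return GenomeAnnotation(genes=ordered, chrom_sizes=sizes)


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_sizes[chrom]}\n")
        for g in sorted(ann.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t."
                         f"\tID={g.gene_id}.exon{k};Parent={g.gene_id}\n")


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO-term TSV (gene_id, comma-separated GO IDs)."""
    out: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, _, terms = line.partition("\t")
            out[gene] = {t for t in terms.split(",") if t}
    return out


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for gene in sorted(go_map):
            fh.write(f"{gene}\t{','.join(sorted(go_map[gene]))}\n")


# --------------------------------------------------------------------------
# Result tables and reports
# --------------------------------------------------------------------------

def write_dmp_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_dmp_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(summary: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
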