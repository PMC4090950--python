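"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED6 (tab-separated, track lines ignored, '#' comments skipped),
two-column chromosome-sizes tables, enhancer-anchor tables, bedGraph,
genes-by-tissues expression TSV, GMT gene sets, JASPAR-style PWMs and FASTA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Annotation, GenomeLayout, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_annotations",
    "write_annotations",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_anchors",
    "write_anchors",
    "read_bedgraph",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
]

# BED name fields are written as "family|id" so both survive a round trip.
_FAMILY_SEP = "|"


def _data_lines(path: str | Path) -> Iterable[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            yield line.split("\t")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (strand taken from column 6 when present)."""
    out = []
    for fields in _data_lines(path):
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_annotations(path: str | Path, family: str | None = None) -> list[Annotation]:
    """Read BED6 annotations; the name field is ``family|id`` or a bare family.

    ``family`` filters to a single family (e.g. "MIR"). Rows without an
    explicit id get sequential ones.
    """
    out = []
    for i, fields in enumerate(_data_lines(path)):
        name = fields[3] if len(fields) >= 4 else f"feat{i:06d}"
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        if _FAMILY_SEP in name:
            fam, uid = name.split(_FAMILY_SEP, 1)
        else:
            fam, uid = name, f"{name}.{i:06d}"
        if family is not None and fam != family:
            continue
        iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
        out.append(Annotation(iv, fam, uid))
    ids = [a.id for a in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate annotation ids in {path}")
    return out


def write_annotations(path: str | Path, annotations: Sequence[Annotation]) -> None:
    """Write BED6 with name ``family|id`` and score 0."""
    with open(path, "w") as fh:
        for a in annotations:
            iv = a.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{a.family}{_FAMILY_SEP}{a.id}"
                f"\t0\t{iv.strand if iv.strand != '.' else '+'}\n"
            )


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    sizes = {}
    for fields in _data_lines(path):
        sizes[fields[0]] = int(fields[1])
    return GenomeLayout(sizes)


def write_chrom_sizes(path: str | Path, layout: GenomeLayout) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_anchors(path: str | Path) -> list[tuple[str, int]]:
    """Enhancer anchors as (chrom, position).

    Accepts either a 2-column ``chrom<TAB>anchor`` table or BED rows; for BED
    rows the anchor is the interval midpoint (a length-1 interval's basepair).
    """
    out = []
    for fields in _data_lines(path):
        if len(fields) >= 3:
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"malformed anchor row: {fields}")
            out.append((fields[0], (start + end) // 2))
        else:
            out.append((fields[0], int(fields[1])))
    return out


def write_anchors(path: str | Path, anchors: Sequence[tuple[str, int]]) -> None:
    """Write anchors as BED intervals of length 1."""
    with open(path, "w") as fh:
        for chrom, pos in anchors:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read bedGraph (or 3-column tag BED) rows into per-chromosome
    (interval starts, values).

    Values are interpreted as tag counts attributed to the interval start
    (point model), matching how tag-position tracks are binned; rows without
    a value column count as one tag each.
    """
    pos: dict[str, list[int]] = {}
    val: dict[str, list[float]] = {}
    for fields in _data_lines(path):
        chrom, start = fields[0], int(fields[1])
        value = float(fields[3]) if len(fields) >= 4 else 1.0
        pos.setdefault(chrom, []).append(start)
        val.setdefault(chrom, []).append(value)
    out = {}
    for chrom in pos:
        p = np.array(pos[chrom], dtype=np.int64)
        v = np.array(val[chrom], dtype=float)
        order = np.argsort(p, kind="stable")
        out[chrom] = (p[order], v[order])
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x tissues intensity matrix: first column gene id, header row tissues."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression matrix contains negative intensities")
    return df


def write_expression_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path: str | Path) -> dict[str, dict]:
    """GMT gene sets: name, description, tab-separated members."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {
                "description": fields[1],
                "genes": set(g for g in fields[2:] if g),
            }
    return sets


def write_gmt(path: str | Path, sets: dict[str, dict]) -> None:
    with open(path, "w") as fh:
        for name, rec in sets.items():
            genes = "\t".join(sorted(rec["genes"]))
            fh.write(f"{name}\t{rec.get('description', '')}\t{genes}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
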