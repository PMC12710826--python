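"""Readers and writers for the standard formats at the package boundary.

All internal coordinates are 0-based half-open; VCF POS (1-based) is
converted on the way in and out.  For deletions ``end = start + |SVLEN|``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import ConservationTrack, IntervalSet, PointSet, SVRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path):
    """Open an indexed FASTA; slicing returns plain uppercase strings."""
    import pyfaidx
    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_fasta(path, sequences: Mapping[str, str], line_width: int = 70) -> None:
    import pyfaidx
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
    pyfaidx.Faidx(str(path))  # build the .fai sidecar


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

_SV_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">
##INFO=<ID=RCLASS,Number=1,Type=String,Description="Repeat class of the variant">
"""


def write_sv_vcf(path, records: Sequence[SVRecord], contigs: Mapping[str, int],
                 reference=None) -> None:
    """Emit SV records as VCF 4.2 with SVTYPE/SVLEN/END (+AF, RCLASS)."""
    lines = [_SV_HEADER]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for r in sorted(records, key=lambda x: (x.chrom, x.start)):
        pos = r.start + 1
        ref_base = "N"
        if reference is not None:
            ref_base = str(reference[r.chrom][r.start:r.start + 1]).upper() or "N"
        svlen = -r.length if r.svtype == "DEL" else r.length
        end = pos if r.svtype == "INS" else r.start + r.length
        info = f"SVTYPE={r.svtype};SVLEN={svlen};END={end}"
        if r.allele_frequency is not None:
            info += f";AF={r.allele_frequency:.6g}"
        if r.repeat_class != "unlabeled":
            info += f";RCLASS={r.repeat_class.replace(';', '_')}"
        lines.append(f"{r.chrom}\t{pos}\t{r.id}\t{ref_base}\t<{r.svtype}>\t.\tPASS\t{info}\n")
    Path(path).write_text("".join(lines))


def read_sv_vcf(path) -> list[SVRecord]:
    """Read an SV callset; records without a recognised SVTYPE are skipped
    (with a logged count)."""
    from cyvcf2 import VCF
    records = []
    skipped = 0
    for v in VCF(str(path)):
        svtype = v.INFO.get("SVTYPE")
        if svtype not in ("INS", "DEL", "INV"):
            skipped += 1
            continue
        start = v.POS - 1
        svlen = v.INFO.get("SVLEN")
        end_info = v.INFO.get("END")
        if svlen is not None:
            length = abs(int(svlen))
        elif end_info is not None and svtype != "INS":
            length = int(end_info) - start
        else:
            skipped += 1
            continue
        end = start if svtype == "INS" else start + length
        rclass = v.INFO.get("RCLASS")
        records.append(SVRecord(
            chrom=v.CHROM, start=start, end=end, svtype=svtype, length=length,
            id=v.ID or f"sv_{len(records)}",
            allele_frequency=(float(v.INFO.get("AF"))
                              if v.INFO.get("AF") is not None else None),
            repeat_class=rclass if rclass else "unlabeled"))
    if skipped:
        logger.warning("skipped %d VCF records without usable SVTYPE/SVLEN", skipped)
    return records


# ---------------------------------------------------------------------------
# Small-variant VCF (SNPs + small indels as point sets)
# ---------------------------------------------------------------------------

_SMALL_HEADER = """##fileformat=VCFv4.2
"""


def write_small_variant_vcf(path, snps: Mapping[str, Sequence[int]],
                            small_ins: Mapping[str, Sequence[int]],
                            small_del: Mapping[str, Sequence[int]],
                            reference, contigs: Mapping[str, int]) -> None:
    """Serialize small-variant position sets as a minimal VCF.

    SNPs get a substituted ALT base, insertions a 2 bp ALT, deletions a
    2 bp REF, so the variant kind round-trips through REF/ALT lengths.
    """
    _alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
    rows = []
    for chrom in contigs:
        for p in sorted(set(snps.get(chrom, ()))):
            ref = str(reference[chrom][p:p + 1]).upper()
            rows.append((chrom, p + 1, ref, _alt.get(ref, "A")))
        for p in sorted(set(small_ins.get(chrom, ()))):
            ref = str(reference[chrom][p:p + 1]).upper()
            rows.append((chrom, p + 1, ref, ref + "A"))
        for p in sorted(set(small_del.get(chrom, ()))):
            ref2 = str(reference[chrom][p:p + 2]).upper()
            if len(ref2) < 2:
                continue
            rows.append((chrom, p + 1, ref2, ref2[0]))
    rows.sort(key=lambda r: (r[0], r[1]))
    lines = [_SMALL_HEADER]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for chrom, pos, ref, alt in rows:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    Path(path).write_text("".join(lines))


def read_small_variant_vcf(path) -> dict[str, PointSet]:
    """Read a small-variant VCF into SNP / small-insertion / small-deletion
    point sets keyed ``snp``, ``small_ins``, ``small_del``."""
    from cyvcf2 import VCF
    sets: dict[str, dict[str, list[int]]] = {"snp": {}, "small_ins": {}, "small_del": {}}
    for v in VCF(str(path)):
        alt = v.ALT[0] if v.ALT else ""
        if len(v.REF) == 1 and len(alt) == 1:
            kind = "snp"
        elif len(alt) > len(v.REF):
            kind = "small_ins"
        elif len(v.REF) > len(alt):
            kind = "small_del"
        else:
            continue
        sets[kind].setdefault(v.CHROM, []).append(v.POS - 1)
    return {k: PointSet(v) for k, v in sets.items()}


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV
# ---------------------------------------------------------------------------

def write_bed(path, intervals: IntervalSet, name: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals.chroms()):
            for s, e in intervals.intervals(chrom):
                if name:
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
    return IntervalSet(out)


def write_bedgraph(path, track: ConservationTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms()):
            for s, e, v in track.segments(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path) -> ConservationTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    out: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = list(zip(sub["start"].astype(int),
                                   sub["end"].astype(int),
                                   sub["value"].astype(float)))
    return ConservationTrack(out)


def read_bigwig_track(path, chroms: Sequence[str]) -> ConservationTrack:
    """Optional bigWig backend for conservation signal."""
    import pyBigWig
    bw = pyBigWig.open(str(path))
    out = {}
    for chrom in chroms:
        ivs = bw.intervals(chrom) or []
        out[chrom] = [(s, e, float(v)) for s, e, v in ivs]
    bw.close()
    return ConservationTrack(out)


def write_gene_scores(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
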