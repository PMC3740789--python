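"""Readers and writers for the external tables and sequence formats.

All delimited outputs are tab-separated UTF-8 with a header row; BED output
follows BED6 with 0-based half-open coordinates.  The dbSNP-style table is
expected in the UCSC dump convention (0-based half-open chromStart/chromEnd)
and converted to 1-based single-base positions on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, ProbeRecord

log = logging.getLogger(__name__)

#: column names of the merged per-probe annotation table
ANNOTATION_COLUMNS = [
    "probe_id",
    "target CpG SNP",
    "n_target CpG SNP",
    "AlleleA_Hits",
    "AlleleB_Hits",
    "XY_Hits",
    "Autosomal_Hits",
    "n_bp_repetitive",
    "HIL_CpG_class",
    "HIL_CpG_Island_Name",
    "UCSC_CpG_class",
    "Closest_TSS",
    "Distance_closest_TSS",
    "Closest_TSS_gene_name",
    "Closest_TSS_Transcript",
    "5'UTR first exon",
    "5'UTR exon",
    "5'UTR intron",
    "body first exon",
    "body exon",
    "body intron",
    "3'UTR first exon",
    "3'UTR exon",
    "3'UTR intron",
]


class DuplicateHeaderError(ValueError):
    """Raised when a FASTA file contains repeated record names."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a case-preserving {name: sequence} store.

    Lowercase (soft-masked / repetitive) bases are kept as-is.
    """
    store: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in store:
            raise DuplicateHeaderError(f"duplicate FASTA header: {record.id}")
        store[record.id] = str(record.seq)
    return store


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w", encoding="utf-8") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = {
    "ilmnid": "probe_id",
    "name": "probe_id",
    "infinium_design_type": "assay_type",
    "strand": "design_strand",
    "chr": "chrom",
    "mapinfo": "mapinfo",
    "allelea_probeseq": "probe_seq_A",
    "alleleb_probeseq": "probe_seq_B",
}


def read_manifest(path: str | Path) -> list[ProbeRecord]:
    """Read a GenomeStudio-style manifest (tab- or comma-delimited)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _MANIFEST_REQUIRED:
            colmap[_MANIFEST_REQUIRED[key]] = col
    missing = {"probe_id", "assay_type", "design_strand", "chrom", "mapinfo",
               "probe_seq_A"} - set(colmap)
    if missing:
        raise ValueError(f"manifest is missing required columns: {sorted(missing)}")
    probes = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        seq_b = row.get(colmap.get("probe_seq_B", ""), "") if "probe_seq_B" in colmap else ""
        seq_b = seq_b.strip() or None
        probes.append(
            ProbeRecord(
                probe_id=row[colmap["probe_id"]].strip(),
                assay_type=row[colmap["assay_type"]].strip(),
                design_strand=row[colmap["design_strand"]].strip(),
                chrom=row[colmap["chrom"]].strip(),
                mapinfo=int(row[colmap["mapinfo"]]),
                probe_seq_A=row[colmap["probe_seq_A"]].strip(),
                probe_seq_B=seq_b,
            )
        )
    return probes


def write_manifest(probes: Iterable[ProbeRecord], path: str | Path) -> None:
    rows = [
        {
            "IlmnID": p.probe_id,
            "Infinium_Design_Type": p.assay_type,
            "Strand": p.design_strand,
            "CHR": p.chrom,
            "MAPINFO": p.mapinfo,
            "AlleleA_ProbeSeq": p.probe_seq_A,
            "AlleleB_ProbeSeq": p.probe_seq_B or "",
        }
        for p in probes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """A single-base polymorphism of the highest dbSNP quality class."""

    rs_id: str
    chrom: str
    pos: int  # 1-based single base
    weight: int
    heterozygosity: float | None


@dataclass
class SnpReadStats:
    kept: int = 0
    dropped_length: int = 0
    dropped_weight: int = 0
    dropped_malformed: int = 0


def read_snp_table(
    path: str | Path,
    het_column: str = "avHet",
    return_stats: bool = False,
):
    """Read a UCSC-style SNP dump, keeping only 1-bp, weight=1 records.

    Coordinates in the file are 0-based half-open; returned positions are
    1-based.  Records of other lengths or weights are dropped and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    stats = SnpReadStats()
    records: list[SnpRecord] = []

    def col(*names: str) -> str:
        for n in names:
            if n.lower() in cols:
                return cols[n.lower()]
        raise ValueError(f"SNP table is missing a column among {names}")

    c_chrom = col("chrom", "chr")
    c_start = col("chromStart", "start")
    c_end = col("chromEnd", "end")
    c_name = col("name", "rs_id")
    c_weight = col("weight")
    c_het = cols.get(het_column.lower())

    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        try:
            start = int(d[c_start])
            end = int(d[c_end])
            weight = int(d[c_weight])
        except (ValueError, TypeError):
            stats.dropped_malformed += 1
            log.warning("skipping malformed SNP row: %r", d)
            continue
        if end - start != 1:
            stats.dropped_length += 1
            continue
        if weight != 1:
            stats.dropped_weight += 1
            continue
        het: float | None = None
        if c_het is not None and str(d[c_het]).strip() not in ("", "NA", "nan"):
            try:
                het = float(d[c_het])
            except ValueError:
                het = None
        records.append(
            SnpRecord(
                rs_id=str(d[c_name]).strip(),
                chrom=str(d[c_chrom]).strip(),
                pos=start + 1,
                weight=weight,
                heterozygosity=het,
            )
        )
        stats.kept += 1
    if return_stats:
        return records, stats
    return records


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "chromStart": s.pos - 1,
            "chromEnd": s.pos,
            "name": s.rs_id,
            "weight": s.weight,
            "avHet": "" if s.heterozygosity is None else s.heterozygosity,
        }
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A refGene-style transcript model (0-based half-open coordinates)."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.transcript_id}: exon start/end count mismatch")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.transcript_id}: cds outside transcript span")
        prev_end = -1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.transcript_id}: exon [{s},{e}) out of bounds")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (0-based base position)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def exons(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, s, e, self.strand)
            for s, e in zip(self.exon_starts, self.exon_ends)
        ]

    def introns(self) -> list[GenomicInterval]:
        out = []
        for e_prev, s_next in zip(self.exon_ends, self.exon_starts[1:]):
            if s_next > e_prev:
                out.append(GenomicInterval(self.chrom, e_prev, s_next, self.strand))
        return out


def _parse_int_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in str(text).strip().rstrip(",").split(",") if x != "")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a refGene-style table; malformed transcripts are rejected with a diagnostic."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}

    def col(*names: str) -> str:
        for n in names:
            if n.lower() in cols:
                return cols[n.lower()]
        raise ValueError(f"gene table is missing a column among {names}")

    c_tx = col("name", "transcript_id")
    c_gene = col("name2", "gene_name")
    models = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        tx_id = str(d[c_tx]).strip()
        try:
            model = GeneModel(
                gene_name=str(d[c_gene]).strip(),
                transcript_id=tx_id,
                chrom=str(d[col("chrom")]).strip(),
                strand=str(d[col("strand")]).strip(),
                tx_start=int(d[col("txStart")]),
                tx_end=int(d[col("txEnd")]),
                cds_start=int(d[col("cdsStart")]),
                cds_end=int(d[col("cdsEnd")]),
                exon_starts=_parse_int_list(d[col("exonStarts")]),
                exon_ends=_parse_int_list(d[col("exonEnds")]),
            )
        except ValueError as exc:
            raise ValueError(f"rejected transcript {tx_id}: {exc}") from exc
        models.append(model)
    return models


def write_gene_table(models: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "name": m.transcript_id,
            "name2": m.gene_name,
            "chrom": m.chrom,
            "strand": m.strand,
            "txStart": m.tx_start,
            "txEnd": m.tx_end,
            "cdsStart": m.cds_start,
            "cdsEnd": m.cds_end,
            "exonCount": len(m.exon_starts),
            "exonStarts": ",".join(map(str, m.exon_starts)) + ",",
            "exonEnds": ",".join(map(str, m.exon_ends)) + ",",
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[int] | None = None,
) -> None:
    """Write BED6 records (0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


# ---------------------------------------------------------------------------
# merged annotation table
# ---------------------------------------------------------------------------

def write_annotation_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the merged per-probe annotation table as TSV."""
    if "probe_id" not in table.columns:
        raise ValueError("annotation table must carry a probe_id column")
    if table["probe_id"].isna().any() or (table["probe_id"] == "").any():
        raise ValueError("annotation table contains missing probe ids")
    cols = [c for c in ANNOTATION_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
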