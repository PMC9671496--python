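"""Readers and writers for the standard formats the pipeline consumes.

Formats: GFF3 + FASTA for the genome, a wide TSV (contig, position, strand,
one column per sample) or variableStep genome-track text for insertion
counts, and plain TSV sample sheets / truth tables.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneRecord, GenomeAnnotation, InsertionCountTable

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_varstep_track",
    "write_varstep_track",
    "read_sample_sheet",
    "write_sample_sheet",
]


class AnnotationError(ValueError):
    pass


def read_annotation(
    path: str | os.PathLike,
    *,
    feature_type: str = "gene",
    contig_length: int | None = None,
) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3 coordinates are 1-based inclusive and are used verbatim.  Features
    of ``feature_type`` become genes, ordered by (start, gene_id).  The
    contig length is taken from a ``##sequence-region`` pragma when present,
    else from ``contig_length``, else from the maximum feature end.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
            id_spec=["ID", "gene_id", "Name"],
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"malformed GFF3 {path}: {exc}") from exc

    # sequence-region pragma gives the contig length when present
    region_len: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    region_len[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break

    genes: list[GeneRecord] = []
    contig = ""
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise AnnotationError(f"duplicate gene id {gid!r} in {path}")
        seen.add(gid)
        contig = contig or feat.seqid
        name = feat.attributes.get("Name", [""])[0]
        genes.append(
            GeneRecord(
                gene_id=gid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                name=name,
            )
        )
    if not genes:
        raise AnnotationError(
            f"no features of type {feature_type!r} found in {path}"
        )
    length = region_len.get(contig) or contig_length or max(g.end for g in genes)
    return GenomeAnnotation(contig_id=contig, contig_length=length, genes=genes)


def write_annotation(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write a GenomeAnnotation as GFF3 (gene features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {annotation.contig_id} 1 "
            f"{annotation.contig_length}\n"
        )
        for g in annotation:
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                f"{annotation.contig_id}\ttnselect\tgene\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Insertion count tables


def write_counts_tsv(
    tables: list[InsertionCountTable], path: str | os.PathLike
) -> None:
    """Write tables as a wide TSV: contig, position, strand, <sample>...

    Collapsed tables use '.' in the strand column.
    """
    all_sites: set = set()
    for t in tables:
        all_sites.update(t.counts)

    def site_key(site):
        return site if isinstance(site, tuple) else (site, ".")

    rows = []
    for site in sorted(all_sites, key=site_key):
        pos, strand = site_key(site)
        row = {"contig": tables[0].contig_id or ".", "position": pos, "strand": strand}
        for t in tables:
            row[t.sample_id] = t.counts.get(site, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path: str | os.PathLike,
    *,
    collapse_strands: bool = True,
    sample_meta: dict[str, dict] | None = None,
) -> list[InsertionCountTable]:
    """Read a wide counts TSV back into one table per sample column.

    ``sample_meta`` maps sample_id -> metadata fields (condition, replicate,
    phage_label, paired_control_id); samples without metadata default to
    condition="control".
    """
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "position", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts TSV {path} lacks columns {required - set(df.columns)}")
    sample_cols = [c for c in df.columns if c not in required]
    contig = str(df["contig"].iloc[0]) if len(df) else ""
    tables = []
    for col in sample_cols:
        meta = dict(sample_meta.get(col, {})) if sample_meta else {}
        meta.setdefault("condition", "control")
        records = [
            (int(p), str(s), c)
            for p, s, c in zip(df["position"], df["strand"], df[col])
            if c > 0
        ]
        tables.append(
            InsertionCountTable.from_records(
                records,
                collapse_strands=collapse_strands,
                sample_id=col,
                contig_id="" if contig == "." else contig,
                **meta,
            )
        )
    return tables


def write_varstep_track(
    table: InsertionCountTable, path: str | os.PathLike
) -> None:
    """Write one sample as variableStep genome-track text (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(f"track type=wiggle_0 name={table.sample_id}\n")
        fh.write(f"variableStep chrom={table.contig_id or 'chr'}\n")
        for pos, count in sorted(table.collapsed_counts().items()):
            if float(count).is_integer():
                count = int(count)
            fh.write(f"{pos}\t{count}\n")


def read_varstep_track(
    path: str | os.PathLike, *, sample_id: str = "", condition: str = "control", **meta
) -> InsertionCountTable:
    """Read a variableStep track (positions are 1-based, per the dialect)."""
    counts: dict[int, float] = {}
    contig = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                for tok in line.split():
                    if tok.startswith("chrom="):
                        contig = tok.split("=", 1)[1]
                continue
            pos_s, count_s = line.split()
            count = float(count_s)
            counts[int(pos_s)] = int(count) if count.is_integer() else count
    return InsertionCountTable(
        sample_id=sample_id or Path(path).stem,
        condition=condition,
        counts=counts,
        contig_id=contig,
        **meta,
    )


# ---------------------------------------------------------------------------
# Sample sheets

SHEET_COLUMNS = ["sample_id", "condition", "phage_label", "replicate", "paired_control_id"]


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.to_csv(path, sep="\t", index=False, columns=SHEET_COLUMNS)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"phage_label": str, "paired_control_id": str})
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {sorted(missing)}")
    sheet["phage_label"] = sheet["phage_label"].fillna("")
    sheet["paired_control_id"] = sheet["paired_control_id"].fillna("")
    return sheet
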