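"""FASTA and GFF3 plumbing.

FASTA goes through Biopython.  GFF3 is written as plain 9-column text
carrying ``ID``, ``product``, ``module_category`` (and ``disrupted``)
attributes, and read back with a small tolerant reader for that
documented subset.
"""

from __future__ import annotations

from pathlib import Path
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import GeneFeature

__all__ = ["read_fasta", "write_fasta", "read_gff3", "write_gff3"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


_GFF_TYPE = {"tRNA": "tRNA"}


def write_gff3(features: list[GeneFeature], path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for f in sorted(features, key=lambda x: (x.contig, x.start, x.id)):
            attrs = [f"ID={quote(f.id)}"]
            if f.product:
                attrs.append(f"product={quote(f.product)}")
            attrs.append(f"module_category={f.module_category}")
            if f.disrupted:
                attrs.append("disrupted=true")
            fh.write(
                "\t".join(
                    (
                        f.contig, "paravirome", _GFF_TYPE.get(f.feature_type, "CDS"),
                        str(f.start), str(f.end), ".", f.strand, ".", ";".join(attrs),
                    )
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
            contig, _, ftype, start, end, _, strand, _, attr_col = cols
            attrs = {}
            for item in attr_col.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = unquote(v.strip())
            features.append(
                GeneFeature(
                    id=attrs.get("ID", f"feature_{lineno}"),
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in {"+", "-"} else "+",
                    feature_type="tRNA" if ftype == "tRNA" else "CDS",
                    module_category=attrs.get("module_category", "other"),
                    product=attrs.get("product", ""),
                    disrupted=attrs.get("disrupted", "").lower() == "true",
                )
            )
    return features
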