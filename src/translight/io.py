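"""Readers and writers for the standard interchange formats.

FASTA handling goes through Biopython; GTF is written with 1-based closed
coordinates (gene/transcript/exon/CDS/five_prime_utr/three_prime_utr
features) and read back via gffutils in :mod:`translight.enrichment`; BED6
is 0-based half-open with the RBP name in column 4.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import BindingSite, GeneModel
from .signature import TranscriptRecord

__all__ = [
    "write_fasta",
    "read_transcripts",
    "write_expression",
    "write_gtf",
    "write_bed",
]


def write_fasta(records: Sequence[TranscriptRecord], path: str) -> None:
    """Write CDS sequences as 60-column-wrapped FASTA."""
    seqs = [
        SeqRecord(Seq(rec.cds), id=rec.transcript_id, description="")
        for rec in records
    ]
    SeqIO.write(seqs, path, "fasta")


def write_expression(records: Sequence[TranscriptRecord], path: str) -> None:
    """Abundance / ribosome-density TSV companion to the CDS FASTA."""
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "abundance": [r.abundance for r in records],
            "ribo_density": [r.ribo_density for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_transcripts(fasta_path: str, expression_path: str | None = None) -> list[TranscriptRecord]:
    """Load CDS FASTA plus optional expression TSV into TranscriptRecords.

    Transcripts absent from the expression table default to abundance and
    density 1.0.
    """
    expr: dict[str, tuple[float, float]] = {}
    if expression_path is not None:
        df = pd.read_csv(expression_path, sep="\t")
        expr = {
            str(r.transcript_id): (float(r.abundance), float(r.ribo_density))
            for r in df.itertuples(index=False)
        }
    records = []
    for seq in SeqIO.parse(fasta_path, "fasta"):
        a, r = expr.get(seq.id, (1.0, 1.0))
        records.append(
            TranscriptRecord(seq.id, str(seq.seq), abundance=a, ribo_density=r)
        )
    return records


_GTF_REGION_FEATURE = {
    "five_prime_utr": "five_prime_utr",
    "cds": "CDS",
    "three_prime_utr": "three_prime_utr",
}


def write_gtf(models: Mapping[str, GeneModel], path: str, source: str = "translight") -> None:
    """Write gene models as GTF (1-based closed coordinates).

    Exons are emitted as the union of UTR and CDS intervals; introns are
    implicit (gaps between exons) and re-derived on read.
    """
    lines = []
    for gene_id in sorted(models):
        gm = models[gene_id]
        attrs = f'gene_id "{gm.gene_id}"; transcript_id "{gm.transcript_id}";'
        pieces: list[tuple[int, int, str]] = []
        for region, ivs in gm.regions.items():
            if region == "intron":
                continue
            for s, e in ivs:
                pieces.append((s, e, _GTF_REGION_FEATURE[region]))
        pieces.sort()
        span = (min(s for s, _, _ in pieces), max(e for _, e, _ in pieces))

        def row(feature: str, start: int, end: int) -> str:
            return "\t".join(
                [gm.chrom, source, feature, str(start + 1), str(end), ".",
                 gm.strand, ".", attrs]
            )

        lines.append(row("gene", *span))
        lines.append(row("transcript", *span))
        for s, e, feature in pieces:
            lines.append(row("exon", s, e))
            if feature != "exon":
                lines.append(row(feature, s, e))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_bed(sites: Sequence[BindingSite], path: str) -> None:
    """Write binding sites as BED6 (name column = RBP)."""
    with open(path, "w") as fh:
        for s in sites:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.rbp}\t{s.score:g}\t{iv.strand}\n"
            )
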