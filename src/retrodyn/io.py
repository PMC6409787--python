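"""File-format helpers: FASTA/FASTQ via Biopython, tables via pandas.

All genomic coordinates written by the package are 0-based, half-open, BED
style.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq_pairs(pairs: list[tuple[str, str, str]],
                      path1, path2) -> None:
    """Write (pair_id, read1, read2) triples as two mate FASTQ files."""
    def recs(mate_idx, suffix):
        for pid, r1, r2 in pairs:
            seq = r1 if mate_idx == 1 else r2
            rec = SeqRecord(Seq(seq), id=f"{pid}/{suffix}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    SeqIO.write(recs(1, "1"), str(path1), "fastq")
    SeqIO.write(recs(2, "2"), str(path2), "fastq")


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def truth_to_frame(truth) -> pd.DataFrame:
    return pd.DataFrame(truth.to_rows())


def write_truth(truth, tsv_path, bed_path) -> None:
    df = truth_to_frame(truth)
    write_tsv(df, tsv_path, index=False)
    if len(df):
        bed = df[["contig", "start", "end", "copy_id", "subfamily", "strand"]]
    else:
        bed = pd.DataFrame(
            columns=["contig", "start", "end", "copy_id", "subfamily",
                     "strand"])
    bed.to_csv(bed_path, sep="\t", index=False, header=False)


def candidates_to_frame(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {k: v for k, v in vars(c).items()
               if k not in ("sequence", "domains_found")}
        if hasattr(c, "domains_found"):
            row["domains_found"] = ",".join(sorted(c.domains_found))
        rows.append(row)
    return pd.DataFrame(rows)


def loci_to_bed(loci) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contig": l.contig, "start": l.start, "end": l.end,
          "name": l.query, "score": round(l.identity, 1), "strand": l.strand}
         for l in loci]
    )
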