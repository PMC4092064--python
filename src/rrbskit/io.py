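"""Readers and writers for the plain-text interchange formats.

FASTA and FASTQ go through Biopython; BED output follows BED6 (0-based
half-open, name = gene id, score = expression count, strand column used).
The cytosine report is 1-based in the file only, matching the de-facto
dialect; everything in memory stays 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import PairedAlignment, Rejection
from .calls import CpGCallTable
from .genome import ExpressionTable, Gene, Genome, MethylomeTruth
from .library import ReadPair


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> Genome:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(genome[contig]), id=contig, description="")
        for contig in sorted(genome)
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# -- genes (BED6) -----------------------------------------------------------

def write_genes_bed(genes: Iterable[Gene], path,
                    expression: Optional[ExpressionTable] = None) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            score = expression.counts.get(gene.gene_id, 0) if expression else 0
            fh.write(
                f"{gene.contig}\t{gene.start}\t{gene.end}\t{gene.gene_id}"
                f"\t{score}\t{gene.strand}\n"
            )


def read_genes_bed(path) -> List[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            contig, start, end, name, _score, strand = fields[:6]
            genes.append(Gene(name, contig, strand, int(start), int(end)))
    return genes


# -- truth methylome --------------------------------------------------------

def write_truth_tsv(truth: MethylomeTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tm\n")
        for (contig, pos), m in truth.items():
            fh.write(f"{contig}\t{pos}\t{m:.6f}\n")


def read_truth_tsv(path) -> MethylomeTruth:
    df = pd.read_csv(path, sep="\t")
    sites = {}
    for contig, sub in df.groupby("contig", sort=True):
        sub = sub.sort_values("pos")
        sites[str(contig)] = (
            sub["pos"].to_numpy(dtype=np.int64),
            sub["m"].to_numpy(dtype=float),
        )
    return MethylomeTruth(sites)


# -- expression -------------------------------------------------------------

def write_expression_tsv(table: ExpressionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcount\tclass\n")
        for gid in table.counts:
            fh.write(f"{gid}\t{table.counts[gid]}\t{table.classes.get(gid, '')}\n")


def read_expression_tsv(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    counts = dict(zip(df["gene_id"].astype(str), df["count"].astype(int)))
    classes = (
        dict(zip(df["gene_id"].astype(str), df["class"].astype(str)))
        if "class" in df else {}
    )
    return ExpressionTable(counts=counts, classes=classes)


# -- FASTQ + truth tags -----------------------------------------------------

def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path,
                      tags_path=None) -> int:
    """Write paired FASTQ (Phred+33) and optionally a truth-tag TSV."""
    n = 0
    tag_fh = open(tags_path, "w") if tags_path else None
    if tag_fh:
        tag_fh.write("read_id\tcontig\tstart\tend\tstrand\n")
    with open(r1_path, "w") as fh1, open(r2_path, "w") as fh2:
        for rp in pairs:
            fh1.write(f"@{rp.name}/1\n{rp.read1_seq}\n+\n{rp.read1_qual}\n")
            fh2.write(f"@{rp.name}/2\n{rp.read2_seq}\n+\n{rp.read2_qual}\n")
            if tag_fh:
                tag_fh.write(
                    f"{rp.name}\t{rp.contig}\t{rp.frag_start}\t{rp.frag_end}"
                    f"\t{rp.strand}\n"
                )
            n += 1
    if tag_fh:
        tag_fh.close()
    return n


def read_fastq_pairs(r1_path, r2_path) -> List[ReadPair]:
    out = []
    r1 = SeqIO.parse(str(r1_path), "fastq")
    r2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(r1, r2):
        name = rec1.id.rsplit("/", 1)[0]
        out.append(ReadPair(
            name=name,
            read1_seq=str(rec1.seq),
            read1_qual="".join(
                chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
            ),
            read2_seq=str(rec2.seq),
            read2_qual="".join(
                chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
            ),
            contig="", frag_start=0, frag_end=0, strand=".",
        ))
    return out


# -- alignments -------------------------------------------------------------

_ALN_COLUMNS = ["read_id", "contig", "start", "end", "strand", "mm1", "mm2",
                "status", "reason", "read1_seq", "read2_seq"]


def write_alignments_tsv(accepted: Iterable[PairedAlignment],
                         rejected: Iterable[Rejection], path) -> None:
    """Minimal alignment dialect; trimmed read sequences are carried so the
    caller can extract methylation without the FASTQ."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLUMNS) + "\n")
        for a in accepted:
            fh.write(
                f"{a.name}\t{a.contig}\t{a.start}\t{a.end}\t{a.strand}"
                f"\t{a.mm1}\t{a.mm2}\taccepted\t.\t{a.read1_seq}\t{a.read2_seq}\n"
            )
        for r in rejected:
            fh.write(f"{r.name}\t.\t-1\t-1\t.\t-1\t-1\trejected\t{r.reason}\t.\t.\n")


def read_alignments_tsv(path) -> Tuple[List[PairedAlignment], List[Rejection]]:
    accepted, rejected = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[idx["status"]] == "accepted":
                accepted.append(PairedAlignment(
                    name=f[idx["read_id"]], contig=f[idx["contig"]],
                    start=int(f[idx["start"]]), end=int(f[idx["end"]]),
                    strand=f[idx["strand"]], mm1=int(f[idx["mm1"]]),
                    mm2=int(f[idx["mm2"]]), read1_seq=f[idx["read1_seq"]],
                    read2_seq=f[idx["read2_seq"]],
                ))
            else:
                rejected.append(Rejection(f[idx["read_id"]], f[idx["reason"]]))
    return accepted, rejected


# -- cytosine report --------------------------------------------------------

def write_cytosine_report(table: CpGCallTable, path) -> None:
    """Cytosine-report-style TSV: contig, 1-based position of the forward C,
    strand '+', methylated count, unmethylated count, context 'CpG'."""
    with open(path, "w") as fh:
        for (contig, pos), (meth, unmeth) in sorted(table.data.items()):
            fh.write(f"{contig}\t{pos + 1}\t+\t{meth}\t{unmeth}\tCpG\n")


def read_cytosine_report(path) -> CpGCallTable:
    data = {}
    with open(path) as fh:
        for line in fh:
            contig, pos1, _strand, meth, unmeth, _ctx = \
                line.rstrip("\n").split("\t")
            data[(contig, int(pos1) - 1)] = [int(meth), int(unmeth)]
    return CpGCallTable(data)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
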