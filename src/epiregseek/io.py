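"""Readers and writers for the pipeline's on-disk formats.

Coordinates are 0-based half-open in memory.  On disk: cytosine reports are
1-based TSV in the Bismark cytosine-report dialect (chrom, pos, strand,
count_methylated, count_unmethylated, context); GFF3 is 1-based inclusive
(converted on read/write); BED is 0-based half-open.
"""

from __future__ import annotations

import os

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import GeneModel, TEModel

REPORT_FILE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
]


def write_fasta(genome: dict, path):
    records = [
        SeqRecord(Seq(genome[c]), id=c, description="") for c in sorted(genome)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_cytosine_report(report: pd.DataFrame, path):
    """Write a per-cytosine report (1-based positions on disk)."""
    out = pd.DataFrame(
        {
            "chrom": report["chrom"],
            "pos": report["pos"] + 1,
            "strand": report["strand"],
            "count_methylated": report["meth"],
            "count_unmethylated": report["total"] - report["meth"],
            "context": report["context"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_cytosine_report(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "pos": raw["pos"] - 1,
            "strand": raw["strand"],
            "context": raw["context"],
            "meth": raw["count_methylated"],
            "total": raw["count_methylated"] + raw["count_unmethylated"],
        }
    )


def write_gff3(genes: list[GeneModel], tes: list[TEModel], path):
    """Genes as gene/mRNA/CDS features, TEs as repeat_region with a class
    attribute; 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            base = f"{g.chrom}\tsim\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(
                f"{base}gene\t{g.start + 1}\t{g.end}{tail}\tID={g.id}\n"
            )
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}\t"
                f"ID={g.id}.1;Parent={g.id}\n"
            )
            for j, (s, e) in enumerate(g.cds, start=1):
                fh.write(
                    f"{base}CDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.id}.1.cds{j};Parent={g.id}.1\n"
                )
        for t in sorted(tes, key=lambda t: (t.chrom, t.start)):
            fh.write(
                f"{t.chrom}\tsim\trepeat_region\t{t.start + 1}\t{t.end}\t.\t+\t.\t"
                f"ID={t.id};te_class={t.te_class}\n"
            )


def read_gff3(path) -> tuple[list[GeneModel], list[TEModel]]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = []
        for mrna in db.children(g, featuretype="mRNA"):
            for c in db.children(mrna, featuretype="CDS"):
                cds.append((c.start - 1, c.end))
        genes.append(
            GeneModel(
                id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                cds=tuple(sorted(cds)),
            )
        )
    tes = [
        TEModel(
            id=t.id,
            chrom=t.seqid,
            start=t.start - 1,
            end=t.end,
            te_class=t.attributes.get("te_class", ["unknown"])[0],
        )
        for t in db.features_of_type("repeat_region")
    ]
    return genes, tes


def write_dmr_bed(dmr_frame: pd.DataFrame, path):
    """BED6: name = context:direction, score = round(1000*|delta|)."""
    bed = pd.DataFrame(
        {
            "chrom": dmr_frame["chrom"],
            "start": dmr_frame["start"],
            "end": dmr_frame["end"],
            "name": dmr_frame["context"] + ":" + dmr_frame["direction"],
            "score": (1000 * dmr_frame["delta"].abs()).round().astype(int).clip(0, 1000),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_expression(matrix: pd.DataFrame, path):
    matrix.rename_axis("feature_id").to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(samples: pd.DataFrame, path):
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_simulation(result, outdir):
    """Write every artifact of a :class:`~epiregseek.simulate.SimulationResult`
    (FASTA, GFF3, cytosine reports, expression + sample sheet, phenotype CSV
    and the truth tables)."""
    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)  # noqa: E731
    write_fasta(result.genome, join("genome.fa"))
    write_gff3(result.genes, result.tes, join("annotation.gff3"))
    for cond, report in result.methylomes.items():
        write_cytosine_report(report, join(f"methylome_{cond}.tsv"))
    write_expression(result.counts, join("gene_counts.tsv"))
    write_expression(result.fpkm, join("gene_fpkm.tsv"))
    write_expression(result.te_counts, join("te_counts.tsv"))
    result.gene_lengths.rename_axis("feature_id").to_csv(
        join("gene_lengths.tsv"), sep="\t"
    )
    result.te_lengths.rename_axis("feature_id").to_csv(
        join("te_lengths.tsv"), sep="\t"
    )
    write_sample_sheet(result.samples, join("samples.tsv"))
    result.phenotype.to_csv(join("phenotype.csv"), index=False)
    truth = result.truth
    truth.planted_dmrs.to_csv(join("truth_dmrs.tsv"), sep="\t", index=False)
    truth.planted_degs.to_csv(join("truth_degs.tsv"), sep="\t", index=False)
    truth.planted_dets.to_csv(join("truth_dets.tsv"), sep="\t", index=False)
    truth.planted_epiregs.to_csv(join("truth_epiregs.tsv"), sep="\t", index=False)
    pd.Series(truth.variance_components).rename_axis("source").rename("variance").to_csv(
        join("truth_variance_components.tsv"), sep="\t"
    )
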