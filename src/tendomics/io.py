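"""Readers and writers for the plain-text formats used throughout the pipeline.

Coordinate conventions: narrowPeak/BED are 0-based half-open; GTF-lite is
1-based inclusive and converted to 0-based half-open on read.
"""

from __future__ import annotations

import pandas as pd

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal", "pvalue", "qvalue", "summit_offset",
]


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a feature x sample count matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample, timepoint, RIN, sex, pool (indexed by sample)."""
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_narrowpeak(path) -> pd.DataFrame:
    """Read ENCODE narrowPeak; adds an absolute ``summit`` column."""
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS)
    df["summit"] = df["start"] + df["summit_offset"]
    return df


def write_narrowpeak(peaks: pd.DataFrame, path, extra_cols=()) -> None:
    """Write narrowPeak; ``extra_cols`` append beyond the 10 standard fields."""
    out = peaks.copy()
    if "summit_offset" not in out.columns:
        out["summit_offset"] = out["summit"] - out["start"]
    for col in ("name", "strand"):
        if col not in out.columns:
            out[col] = "." if col == "strand" else [f"peak_{i}" for i in range(len(out))]
    for col in ("score", "signal", "pvalue", "qvalue"):
        if col not in out.columns:
            out[col] = 0
    cols = NARROWPEAK_COLUMNS + [c for c in extra_cols if c in out.columns]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a minimal BED3+ file (chrom, start, end, extra columns kept)."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


def write_bed(intervals: pd.DataFrame, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gtf_lite(path) -> pd.DataFrame:
    """Read gene/exon/UTR lines from a GTF-lite file.

    Returns a frame with columns chrom, source, feature, start, end (converted
    to 0-based half-open), strand, gene_id.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, source, feature, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            gene_id = None
            for field in attrs.split(";"):
                field = field.strip()
                if field.startswith("gene_id"):
                    gene_id = field.split(None, 1)[1].strip('"')
            rows.append({
                "chrom": chrom, "source": source, "feature": feature,
                "start": int(start) - 1, "end": int(end),
                "strand": strand, "gene_id": gene_id,
            })
    return pd.DataFrame(rows)


def write_gtf_lite(features: pd.DataFrame, path) -> None:
    """Write gene/exon rows (0-based half-open in memory) as 1-based GTF."""
    with open(path, "w") as fh:
        for _, row in features.iterrows():
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\t{row.get('source', 'tendomics')}\t{row.feature}\t"
                f"{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path) -> dict:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")
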