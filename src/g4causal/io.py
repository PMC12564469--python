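"""Readers and writers for the plain-text genomic formats the pipeline uses.

All in-memory coordinates are 0-based half-open.  BED and bedGraph are
already half-open and pass through unchanged; GFF3 is 1-based closed and is
converted on read (start-1, end) and back on write.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6(+score); returns chrom/start/end [, name, score, strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[:df.shape[1]] + \
        [f"extra_{i}" for i in range(max(0, df.shape[1] - 6))]
    return df


def write_bed(frame: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in BED6_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, stranded: bool = False) -> pd.DataFrame:
    """Read a bedGraph track: chrom start end value [strand in column 5]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "value"]
    if stranded:
        names.append("strand")
    df.columns = names[:df.shape[1]]
    if stranded and "strand" not in df.columns:
        raise ValueError("expected a 5th strand column in stranded bedGraph")
    return df


def write_bedgraph(frame: pd.DataFrame, path, stranded: bool = False) -> None:
    cols = ["chrom", "start", "end", "value"]
    if stranded:
        cols.append("strand")
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


def write_stranded_bedgraph_pair(frame: pd.DataFrame, plus_path,
                                 minus_path) -> None:
    """MM% convention: one bedGraph per strand."""
    write_bedgraph(frame[frame.strand == "+"], plus_path)
    write_bedgraph(frame[frame.strand == "-"], minus_path)


def read_stranded_bedgraph_pair(plus_path, minus_path) -> pd.DataFrame:
    plus = read_bedgraph(plus_path)
    plus["strand"] = "+"
    minus = read_bedgraph(minus_path)
    minus["strand"] = "-"
    return pd.concat([plus, minus], ignore_index=True)


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 loci into half-open coordinates.

    Returns chrom/start/end/strand plus source/type/score columns; the
    1-based closed [start, end] becomes [start-1, end).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"chrom": str})
    out = df[["chrom", "source", "type", "score", "strand"]].copy()
    out.insert(1, "start", df["start"].astype(int) - 1)
    out.insert(2, "end", df["end"].astype(int))
    return out


def write_gff3(frame: pd.DataFrame, path, source: str = "g4causal",
               feature_type: str = "pG4") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in frame.itertuples():
            score = getattr(row, "score", ".")
            fh.write("\t".join([
                str(row.chrom), source, feature_type,
                str(int(row.start) + 1), str(int(row.end)),
                str(score), str(row.strand), ".", ".",
            ]) + "\n")


def read_tss(path) -> pd.DataFrame:
    """Read a TSS list TSV: chrom, pos [, gene_id, strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "pos", "gene_id", "strand"][:df.shape[1]]
    df.columns = names
    if "gene_id" not in df.columns:
        df["gene_id"] = [f"gene_{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a metric/region/discrete table as headered TSV."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def export_fixture(fixture, outdir) -> dict[str, Path]:
    """Write every track of a genome fixture as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "regions": outdir / "eg4_regions.bed",
        "pg4s": outdir / "pg4_loci.gff3",
        "mm_plus": outdir / "mm_percent.plus.bedGraph",
        "mm_minus": outdir / "mm_percent.minus.bedGraph",
        "phylop": outdir / "phylop.bedGraph",
        "segmentation": outdir / "chromatin_states.bed",
        "atac": outdir / "atac_fragments.bed",
        "tf_peaks": outdir / "tf_peaks.bed",
        "tss": outdir / "tss.tsv",
        "chrom_sizes": outdir / "chrom.sizes",
    }
    regions = fixture.regions.rename(columns={"region_id": "name",
                                              "eg4_signal": "score"})
    write_bed(regions, paths["regions"],
              columns=["chrom", "start", "end", "name", "score"])
    write_gff3(fixture.pg4s, paths["pg4s"])
    write_stranded_bedgraph_pair(fixture.mm_track, paths["mm_plus"],
                                 paths["mm_minus"])
    write_bedgraph(fixture.phylop_track, paths["phylop"])
    seg = fixture.segmentation.rename(columns={"state": "name"})
    write_bed(seg, paths["segmentation"],
              columns=["chrom", "start", "end", "name"])
    write_bed(fixture.atac_fragments, paths["atac"])
    peaks = fixture.tf_peaks.rename(columns={"tf": "name"})
    write_bed(peaks, paths["tf_peaks"],
              columns=["chrom", "start", "end", "name"])
    fixture.tss.to_csv(paths["tss"], sep="\t", header=False, index=False)
    pd.Series(fixture.chrom_sizes).to_csv(paths["chrom_sizes"], sep="\t",
                                          header=False)
    return paths
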