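"""Readers and writers for the pipeline's plain-text formats.

Counts tables follow the GATK ASEReadCounter column convention (contig,
position, refCount, altCount) with an added ``sample`` column; coordinates
are 1-based.  Gene models come from GFF3 (1-based inclusive), parsed with
gffutils into per-chromosome gene and exon interval frames.  Epireads are
one record per line: chrom TAB first-CpG index (0-based within the
chromosome's ordered CpG list) TAB state string over {C, T}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "GeneModels",
    "read_counts_table",
    "read_samples_sheet",
    "read_gff",
    "read_epireads",
    "read_cytosine_report",
    "cpg_positions_from_report",
    "read_gene_list",
    "read_go_map",
    "write_results_tsv",
    "write_bed",
]

_COUNT_COLUMNS = {"contig", "position", "refCount", "altCount"}


def read_counts_table(path, sample: str = None) -> pd.DataFrame:
    """Read an ASEReadCounter-style TSV into a typed SNP count table.

    Malformed rows (non-numeric or negative counts, position < 1) are
    rejected with a warning naming their line numbers; a missing required
    header is a hard error.  ``sample`` supplies the sample id when the file
    has no ``sample`` column (one file per sample, as ASEReadCounter writes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = _COUNT_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} lacks column(s): {sorted(missing)}")
    if "sample" not in df.columns:
        if sample is None:
            raise ValueError("counts table has no 'sample' column and no sample id given")
        df["sample"] = sample
    pos = pd.to_numeric(df["position"], errors="coerce")
    ref = pd.to_numeric(df["refCount"], errors="coerce")
    alt = pd.to_numeric(df["altCount"], errors="coerce")
    good = pos.notna() & ref.notna() & alt.notna() & (pos >= 1) & (ref >= 0) & (alt >= 0)
    if not good.all():
        bad_lines = [int(i) + 2 for i in df.index[~good]]  # +2: header + 1-based
        warnings.warn(f"rejected {len(bad_lines)} malformed row(s) at line(s) {bad_lines}")
    out = pd.DataFrame(
        {
            "sample": df.loc[good, "sample"],
            "chrom": df.loc[good, "contig"],
            "pos": pos[good].astype(int),
            "ref_count": ref[good].astype(int),
            "alt_count": alt[good].astype(int),
        }
    )
    return out.reset_index(drop=True)


def read_samples_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample, colony, status."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "colony", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet lacks column(s): {sorted(missing)}")
    return df[["sample", "colony", "status"]]


@dataclass
class GeneModels:
    """Gene and exon intervals (1-based inclusive), indexed per chromosome."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    exons: pd.DataFrame  # gene_id, chrom, start, end

    def introns(self) -> pd.DataFrame:
        """Intron intervals derived as gaps between a gene's sorted exons."""
        rows = []
        for gene_id, grp in self.exons.groupby("gene_id"):
            grp = grp.sort_values("start")
            prev_end = None
            for ex in grp.itertuples(index=False):
                if prev_end is not None and ex.start > prev_end + 1:
                    rows.append((gene_id, ex.chrom, prev_end + 1, ex.start - 1))
                prev_end = max(prev_end or 0, ex.end)
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def read_gff(path) -> GeneModels:
    """Parse gene and exon features from GFF3 via an in-memory gffutils DB.

    Exons are attached to their ancestor gene through the Parent chain; an
    exon outside its gene's span is a validation error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gene_rows: List[tuple] = []
    exon_rows: List[tuple] = []
    for gene in db.features_of_type("gene"):
        gene_rows.append((gene.id, gene.seqid, gene.start, gene.end, gene.strand))
        for exon in db.children(gene, featuretype="exon"):
            if exon.start < gene.start or exon.end > gene.end:
                raise ValueError(
                    f"exon {exon.id} ({exon.start}-{exon.end}) outside gene "
                    f"{gene.id} span ({gene.start}-{gene.end})"
                )
            exon_rows.append((gene.id, exon.seqid, exon.start, exon.end))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneModels(genes=genes, exons=exons)


def read_epireads(path) -> pd.DataFrame:
    """Epiread text: chrom TAB first-CpG-index TAB C/T state string."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "states"], dtype=str
    )
    df["start"] = df["start"].astype(int)
    if (df["start"] < 0).any():
        raise ValueError("epiread start indices must be >= 0")
    bad = ~df["states"].str.fullmatch(r"[CT]+")
    if bad.any():
        raise ValueError(f"invalid epiread state string at line(s) {list(df.index[bad] + 1)}")
    return df


def read_cytosine_report(path) -> pd.DataFrame:
    """Cytosine report TSV: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "count_methylated", "count_unmethylated"} - set(df.columns)
    if missing:
        raise ValueError(f"cytosine report lacks column(s): {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


def cpg_positions_from_report(cytosine: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Ordered CpG position list per chromosome, from a cytosine report."""
    return {
        chrom: np.sort(grp["pos"].unique())
        for chrom, grp in cytosine.groupby("chrom")
    }


def read_gene_list(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_go_map(path) -> Dict[str, set]:
    """GO map TSV: gene_id TAB term[;term...]."""
    mapping: Dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GO map line: {line!r}")
            gene, terms = parts[0], parts[1]
            mapping.setdefault(gene, set()).update(
                t for t in terms.split(";") if t
            )
    return mapping


def write_results_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(regions: pd.DataFrame, path, score_cap: float = 1000.0) -> None:
    """Write AMR regions as BED6+ (score = −10·log10 q, capped)."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            q = max(row.q_value, 1e-300)
            score = min(-10.0 * np.log10(q), score_cap)
            extras = [f"{row.p_value:.6g}", f"{row.q_value:.6g}"]
            for col in ("gene_ids", "feature"):
                if hasattr(row, col):
                    extras.append(str(getattr(row, col)))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.region_id}\t"
                f"{score:.1f}\t.\t" + "\t".join(extras) + "\n"
            )
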