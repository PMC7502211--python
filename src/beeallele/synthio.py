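"""Synthetic allelic-count and epiread generators with known truth.

The generators emulate the statistical structure the downstream analysis
assumes, not raw sequencing: heterozygous-SNP read counts with beta-binomial
overdispersion across colonies and reproductive statuses, and bisulfite
epireads drawn from one- or two-epiallele mixtures with a bisulfite
conversion-error floor.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AseSimConfig",
    "MethSimConfig",
    "simulate_ase_counts",
    "simulate_epireads",
    "gene_models_frame",
    "write_counts_tsv",
    "write_samples_tsv",
    "write_epireads",
    "write_cytosine_report",
    "write_gff",
]

STATUSES = ("reproductive", "sterile")


@dataclass
class AseSimConfig:
    """Configuration for the allelic read-count generator.

    ``true_prop`` is the per-gene truth: the fraction of reads carried by the
    more-expressed physical allele (π). ``overdispersion_rho`` is the
    beta-binomial intra-class correlation; 0 gives plain binomial counts.
    The default design mirrors a 3-colony × 2-status study with 3 RNA
    replicates per (colony, status) group.
    """

    n_genes: int = 100
    snps_per_gene: Union[int, tuple] = 3
    n_colonies: int = 3
    statuses: tuple = STATUSES
    replicates_per_group: int = 3
    coverage_mean: float = 30.0
    coverage_dist: str = "poisson"  # "poisson" | "fixed"
    true_prop: Union[float, Sequence[float]] = 0.5
    overdispersion_rho: float = 0.0
    missing_colony_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        pi = np.atleast_1d(np.asarray(self.true_prop, dtype=float))
        if pi.size not in (1, self.n_genes):
            raise ValueError("true_prop must be scalar or length n_genes")
        if np.any(~np.isfinite(pi)) or np.any((pi < 0.0) | (pi > 1.0)):
            raise ValueError("true_prop must be finite and within [0, 1]")
        if not np.isfinite(self.coverage_mean) or self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if not (0.0 <= self.missing_colony_rate <= 1.0):
            raise ValueError("missing_colony_rate must be in [0, 1]")
        if self.coverage_dist not in ("poisson", "fixed"):
            raise ValueError("coverage_dist must be 'poisson' or 'fixed'")
        if self.n_genes < 1 or self.n_colonies < 1 or self.replicates_per_group < 1:
            raise ValueError("n_genes, n_colonies, replicates_per_group must be >= 1")
        if isinstance(self.snps_per_gene, int):
            if self.snps_per_gene < 1:
                raise ValueError("snps_per_gene must be >= 1")
        else:
            lo, hi = self.snps_per_gene
            if lo < 1 or hi < lo:
                raise ValueError("snps_per_gene range must satisfy 1 <= lo <= hi")


# synthetic genome layout: genes tiled over 18 linkage-group-like chromosomes
_GENE_SPAN = 5_000
_GENE_PITCH = 10_000
_N_CHROMS = 18


def _gene_coords(i: int) -> tuple:
    chrom = f"LG{(i % _N_CHROMS) + 1}"
    start = 1 + (i // _N_CHROMS) * _GENE_PITCH
    return chrom, start, start + _GENE_SPAN - 1


def gene_models_frame(cfg: AseSimConfig) -> pd.DataFrame:
    """Gene models (gene_id, chrom, start, end; 1-based inclusive) matching
    the coordinates at which :func:`simulate_ase_counts` places its SNPs."""
    rows = []
    for i in range(cfg.n_genes):
        chrom, start, end = _gene_coords(i)
        rows.append((f"gene{i:05d}", chrom, start, end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def simulate_ase_counts(cfg: AseSimConfig):
    """Simulate an ASEReadCounter-style per-SNP allelic count table.

    Returns ``(snps, truth)``: a DataFrame with one row per
    (SNP, sample) holding ``ref_count``/``alt_count``, and a truth table
    mapping each gene to its simulated allelic proportion π.

    The ref/alt orientation of each SNP locus is randomized independently of
    the truly biased allele (constant across samples, as for a real variant),
    so downstream allocation — not column labels — must recover the bias.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    pi = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.true_prop, dtype=float)), (cfg.n_genes,)
    ).copy()
    genes = gene_models_frame(cfg)

    if isinstance(cfg.snps_per_gene, int):
        n_snps = np.full(cfg.n_genes, cfg.snps_per_gene, dtype=int)
    else:
        lo, hi = cfg.snps_per_gene
        n_snps = rng.integers(lo, hi + 1, size=cfg.n_genes)

    # one row per SNP locus
    snp_gene = np.repeat(np.arange(cfg.n_genes), n_snps)
    snp_pos = np.concatenate(
        [
            genes.loc[g, "start"]
            + np.sort(rng.choice(_GENE_SPAN, size=n_snps[g], replace=False))
            for g in range(cfg.n_genes)
        ]
    ).astype(int)
    snp_flip = rng.random(snp_gene.size) < 0.5  # ref carries the minor allele
    loci = pd.DataFrame(
        {
            "gene_idx": snp_gene,
            "gene_id": genes["gene_id"].to_numpy()[snp_gene],
            "chrom": genes["chrom"].to_numpy()[snp_gene],
            "pos": snp_pos,
            "flip": snp_flip,
        }
    )

    colonies = [f"colony{c + 1}" for c in range(cfg.n_colonies)]
    samples = pd.DataFrame(
        [
            (f"{col}_{st}_{r + 1}", col, st)
            for col in colonies
            for st in cfg.statuses
            for r in range(cfg.replicates_per_group)
        ],
        columns=["sample", "colony", "status"],
    )

    present = rng.random((cfg.n_genes, cfg.n_colonies)) >= cfg.missing_colony_rate

    rows = loci.merge(samples, how="cross")
    colony_idx = rows["colony"].map({c: i for i, c in enumerate(colonies)}).to_numpy()
    rows = rows[present[rows["gene_idx"].to_numpy(), colony_idx]].reset_index(drop=True)

    m = len(rows)
    if cfg.coverage_dist == "fixed":
        n = np.full(m, int(round(cfg.coverage_mean)))
    else:
        n = np.maximum(1, rng.poisson(cfg.coverage_mean, size=m))
    p_true = pi[rows["gene_idx"].to_numpy()]
    rho = cfg.overdispersion_rho
    if rho > 0.0:
        interior = (p_true > 0.0) & (p_true < 1.0)
        p = p_true.copy()
        if interior.any():
            a = p_true[interior] * (1.0 - rho) / rho
            b = (1.0 - p_true[interior]) * (1.0 - rho) / rho
            p[interior] = rng.beta(a, b)
    else:
        p = p_true
    allele1 = rng.binomial(n, p)  # reads from the truly favoured allele
    flip = rows["flip"].to_numpy()
    ref = np.where(flip, n - allele1, allele1)

    snps = pd.DataFrame(
        {
            "sample": rows["sample"],
            "colony": rows["colony"],
            "status": rows["status"],
            "chrom": rows["chrom"],
            "pos": rows["pos"],
            "gene_id": rows["gene_id"],
            "ref_count": ref.astype(int),
            "alt_count": (n - ref).astype(int),
        }
    )
    truth = pd.DataFrame({"gene_id": genes["gene_id"], "true_prop": pi})
    return snps, truth


@dataclass
class MethSimConfig:
    """Configuration for the epiread generator.

    Each region carries ``cpgs_per_region`` CpGs on its own chromosome-like
    contig.  AMR regions draw each read from ``profile_a`` with probability
    ``mixing`` and otherwise from ``profile_b``; non-AMR regions share
    ``profile_a`` for both alleles.  Every sampled state is flipped with
    probability ``conversion_error`` (bisulfite conversion failure /
    sequencing error floor, default 0.05).
    """

    n_regions: int = 40
    cpgs_per_region: int = 12
    cpg_spacing: int = 50
    reads_per_cpg: int = 15
    profile_a: Union[float, Sequence[float]] = 0.9
    profile_b: Union[float, Sequence[float]] = 0.1
    is_amr: Union[int, Sequence[bool]] = 8
    mixing: float = 0.5
    conversion_error: float = 0.05
    read_trim_max: int = 0  # >0 enables partial reads with uniform end trims
    seed: int = 0

    def _profiles(self):
        a = np.broadcast_to(
            np.atleast_1d(np.asarray(self.profile_a, dtype=float)),
            (self.cpgs_per_region,),
        )
        b = np.broadcast_to(
            np.atleast_1d(np.asarray(self.profile_b, dtype=float)),
            (self.cpgs_per_region,),
        )
        return a, b

    def validate(self) -> None:
        pa = np.atleast_1d(np.asarray(self.profile_a, dtype=float))
        pb = np.atleast_1d(np.asarray(self.profile_b, dtype=float))
        if pa.size != pb.size and 1 not in (pa.size, pb.size):
            raise ValueError("profile_a and profile_b must have equal length")
        for prof in (pa, pb):
            if prof.size not in (1, self.cpgs_per_region):
                raise ValueError("profiles must be scalar or length cpgs_per_region")
            if np.any(~np.isfinite(prof)) or np.any((prof < 0) | (prof > 1)):
                raise ValueError("profile probabilities must be within [0, 1]")
        if self.reads_per_cpg < 1:
            raise ValueError("reads_per_cpg must be >= 1")
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError("mixing must be in [0, 1]")
        if not (0.0 <= self.conversion_error <= 1.0):
            raise ValueError("conversion_error must be in [0, 1]")
        if self.n_regions < 1 or self.cpgs_per_region < 1 or self.cpg_spacing < 1:
            raise ValueError("n_regions, cpgs_per_region, cpg_spacing must be >= 1")
        if not isinstance(self.is_amr, int) and len(self.is_amr) != self.n_regions:
            raise ValueError("is_amr sequence must have length n_regions")
        if isinstance(self.is_amr, int) and not 0 <= self.is_amr <= self.n_regions:
            raise ValueError("is_amr count must be within [0, n_regions]")


def simulate_epireads(cfg: MethSimConfig):
    """Simulate epireads and the matching per-CpG cytosine report.

    Returns ``(epireads, cytosine, truth)``:

    * ``epireads`` — DataFrame (chrom, start, states) with ``start`` the
      0-based index of the read's first CpG in its chromosome's ordered CpG
      list and ``states`` a string over {C, T} (C = methylated);
    * ``cytosine`` — DataFrame (chrom, pos, strand, count_methylated,
      count_unmethylated), equal to the column sums of the epireads;
    * ``truth`` — region table with the ``is_amr`` flag and coordinates.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    prof_a, prof_b = cfg._profiles()
    w = cfg.cpgs_per_region

    if isinstance(cfg.is_amr, int):
        amr_flags = np.zeros(cfg.n_regions, dtype=bool)
        amr_flags[rng.choice(cfg.n_regions, size=cfg.is_amr, replace=False)] = True
    else:
        amr_flags = np.asarray(cfg.is_amr, dtype=bool)

    epi_rows, cyt_rows, truth_rows = [], [], []
    for r in range(cfg.n_regions):
        chrom = f"reg{r:03d}"
        positions = 1000 + cfg.cpg_spacing * np.arange(w)  # 1-based
        meth = np.zeros(w, dtype=int)
        total = np.zeros(w, dtype=int)
        for _ in range(cfg.reads_per_cpg):
            if amr_flags[r]:
                prof = prof_a if rng.random() < cfg.mixing else prof_b
            else:
                prof = prof_a
            states = (rng.random(w) < prof).astype(int)
            err = rng.random(w) < cfg.conversion_error
            states[err] = 1 - states[err]
            lo, hi = 0, w
            if cfg.read_trim_max > 0:
                lo = int(rng.integers(0, cfg.read_trim_max + 1))
                hi = w - int(rng.integers(0, cfg.read_trim_max + 1))
                if hi <= lo:  # keep at least one CpG
                    lo, hi = 0, 1
            meth[lo:hi] += states[lo:hi]
            total[lo:hi] += 1
            epi_rows.append(
                (chrom, lo, "".join("C" if s else "T" for s in states[lo:hi]))
            )
        for j in range(w):
            cyt_rows.append((chrom, int(positions[j]), "+", int(meth[j]),
                             int(total[j] - meth[j])))
        truth_rows.append(
            (f"region{r:03d}", chrom, int(positions[0]), int(positions[-1]),
             bool(amr_flags[r]))
        )

    epireads = pd.DataFrame(epi_rows, columns=["chrom", "start", "states"])
    cytosine = pd.DataFrame(
        cyt_rows,
        columns=["chrom", "pos", "strand", "count_methylated", "count_unmethylated"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["region_id", "chrom", "start_pos", "end_pos", "is_amr"]
    )
    return epireads, cytosine, truth


# ---------------------------------------------------------------------------
# plain-text writers (formats shared with the readers in beeallele.io)

def write_counts_tsv(snps: pd.DataFrame, path) -> None:
    out = snps.rename(
        columns={"chrom": "contig", "pos": "position",
                 "ref_count": "refCount", "alt_count": "altCount"}
    )[["contig", "position", "refCount", "altCount", "sample"]]
    out.to_csv(path, sep="\t", index=False)


def write_samples_tsv(snps: pd.DataFrame, path) -> None:
    sheet = snps[["sample", "colony", "status"]].drop_duplicates()
    sheet.to_csv(path, sep="\t", index=False)


def write_epireads(epireads: pd.DataFrame, path) -> None:
    epireads.to_csv(path, sep="\t", index=False, header=False)


def write_cytosine_report(cytosine: pd.DataFrame, path) -> None:
    cytosine.to_csv(path, sep="\t", index=False)


def write_gff(genes: pd.DataFrame, path, exons: Optional[pd.DataFrame] = None) -> None:
    """Write gene (and optional exon) models as GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tbeeallele\tgene\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )
            if exons is not None:
                sub = exons[exons["gene_id"] == row.gene_id]
                for k, ex in enumerate(sub.itertuples(index=False), start=1):
                    fh.write(
                        f"{ex.chrom}\tbeeallele\texon\t{ex.start}\t{ex.end}\t.\t+\t.\t"
                        f"ID={row.gene_id}.e{k};Parent={row.gene_id}\n"
                    )
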