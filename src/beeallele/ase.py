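"""Per-gene allele-specific expression calling from per-SNP allelic counts.

The pipeline follows the design used for diploid samples without parental
genomes: because the phase of each heterozygous SNP is unknown, the larger
count at every SNP is allocated to "allele 1" and the smaller to "allele 2",
counts are summed per gene into one representative sample per reproductive
status per colony, and a quasibinomial logistic regression (status + colony
as covariates) tests each gene's grand-mean allelic proportion against 0.5.
The allocation step inflates null proportions above 0.5 by construction,
which is why a gene is only called ASE when, in addition to q < 0.05, its
mean allelic proportion for a status exceeds 0.65.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as st

from .stats import bh_adjust

__all__ = [
    "AseConfig",
    "GlmFit",
    "annotate_snps",
    "filter_snps",
    "allocate_alleles",
    "aggregate_by_gene",
    "eligibility_filter",
    "fit_ase_glm",
    "classify_ase",
    "run_ase",
]


@dataclass
class AseConfig:
    """Thresholds of the ASE caller.

    min_coverage: minimum ref+alt reads per SNP (default 10).
    min_colonies_per_status: colonies a gene must appear in, for at least one
        status, to be tested (default 2 of 3).
    q_threshold / prop_threshold: a gene is ASE for a status when its BH
        q-value is below 0.05 and its mean allelic proportion across that
        status's colonies exceeds 0.65.
    """

    min_coverage: int = 10
    min_colonies_per_status: int = 2
    q_threshold: float = 0.05
    prop_threshold: float = 0.65
    statuses: tuple = ("reproductive", "sterile")

    def validate(self) -> None:
        if self.min_coverage < 1 or self.min_colonies_per_status < 1:
            raise ValueError("coverage and colony minima must be positive")
        for thr in (self.q_threshold, self.prop_threshold):
            if not (0.0 < thr < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")
        if len(self.statuses) != 2:
            raise ValueError("exactly two reproductive statuses are expected")


def _genes_frame(genes) -> pd.DataFrame:
    """Accept either a plain genes DataFrame or an io.GeneModels object."""
    if hasattr(genes, "genes"):
        genes = genes.genes
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene models lack columns: {sorted(missing)}")
    return genes


def annotate_snps(snps: pd.DataFrame, genes) -> pd.DataFrame:
    """Assign gene identifiers to SNPs by 1-based inclusive containment.

    A SNP inside several (e.g. overlapping or antisense) genes is duplicated,
    one row per gene; SNPs in no gene get ``gene_id = None``.  Chromosomes
    absent from the annotation are warned about once.
    """
    genes = _genes_frame(genes)
    known = set(genes["chrom"])
    orphans = set(snps["chrom"]) - known
    if orphans:
        warnings.warn(
            f"{len(orphans)} SNP chromosome(s) absent from annotation: "
            f"{sorted(orphans)[:5]}"
        )
    base = snps.drop(columns=["gene_id"], errors="ignore")
    hits = base.merge(genes, on="chrom", how="left")
    inside = (hits["pos"] >= hits["start"]) & (hits["pos"] <= hits["end"])
    annotated = hits[inside].drop(columns=["start", "end"])
    # SNPs with no containing gene: keep one row with gene_id None
    key = ["sample", "chrom", "pos"] if "sample" in base.columns else ["chrom", "pos"]
    matched = annotated[key].drop_duplicates()
    unmatched = base.merge(matched, on=key, how="left", indicator=True)
    unmatched = unmatched[unmatched["_merge"] == "left_only"].drop(columns="_merge")
    unmatched["gene_id"] = None
    out = pd.concat([annotated, unmatched], ignore_index=True)
    return out.sort_values(key + ["gene_id"], na_position="last").reset_index(drop=True)


def filter_snps(snps: pd.DataFrame, cfg: AseConfig) -> pd.DataFrame:
    """Keep SNPs with coverage >= min_coverage, both alleles observed
    (a zero count suggests a homozygote mis-called as heterozygous), and a
    gene assignment."""
    cov = snps["ref_count"] + snps["alt_count"]
    keep = (
        (cov >= cfg.min_coverage)
        & (snps["ref_count"] > 0)
        & (snps["alt_count"] > 0)
        & snps["gene_id"].notna()
    )
    return snps[keep].reset_index(drop=True)


def allocate_alleles(snps: pd.DataFrame) -> pd.DataFrame:
    """Per SNP row, allele1 = max(ref, alt), allele2 = min(ref, alt).

    Ties (ref == alt) put the reference count on allele 1; the split is
    symmetric so orientation invariance is preserved.
    """
    out = snps.copy()
    ref = out["ref_count"].to_numpy()
    alt = out["alt_count"].to_numpy()
    out["allele1_count"] = np.maximum(ref, alt)
    out["allele2_count"] = np.minimum(ref, alt)
    return out


def aggregate_by_gene(snps: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Sum allocated counts per (gene, colony, status).

    Replicate samples of a (colony, status) group collapse into one
    representative sample.  ``n_snps`` counts distinct SNP loci contributing
    to the group.  A sample missing from the sheet is a hard error.
    """
    unknown = set(snps["sample"]) - set(samples["sample"])
    if unknown:
        raise KeyError(f"samples absent from sample sheet: {sorted(unknown)[:5]}")
    merged = snps.drop(columns=["colony", "status"], errors="ignore").merge(
        samples[["sample", "colony", "status"]], on="sample", how="left"
    )
    grp = merged.groupby(["gene_id", "colony", "status"], sort=True)
    table = grp.agg(
        allele1_total=("allele1_count", "sum"),
        allele2_total=("allele2_count", "sum"),
        n_snps=("pos", "nunique"),
    ).reset_index()
    return table


def eligibility_filter(table: pd.DataFrame, cfg: AseConfig):
    """Genes testable for ASE: present in >= min_colonies_per_status colonies
    for at least one status.  Returns the sorted gene list."""
    counts = (
        table.groupby(["gene_id", "status"])["colony"].nunique().reset_index()
    )
    ok = counts[counts["colony"] >= cfg.min_colonies_per_status]
    return sorted(ok["gene_id"].unique())


@dataclass
class GlmFit:
    """Per-gene test result of the quasibinomial logistic regression."""

    p_value: float
    estimate: float  # grand-mean log-odds of allele 1
    dispersion: float
    df_resid: int
    method: str  # quasibinomial | intercept_only | exact_binomial
    converged: bool = True


def _effect_code(values: pd.Series) -> np.ndarray:
    """Sum-to-zero (effect) coding: k levels -> k-1 columns."""
    levels = sorted(pd.unique(values))
    cols = []
    arr = np.asarray(values)
    for lev in levels[1:]:
        col = np.where(arr == lev, 1.0, np.where(arr == levels[0], -1.0, 0.0))
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def _exact_binomial(a1: np.ndarray, a2: np.ndarray, method: str) -> GlmFit:
    k, n = int(a1.sum()), int((a1 + a2).sum())
    p = st.binomtest(k, n, 0.5).pvalue
    frac = min(max(k / n, 1e-12), 1 - 1e-12)
    return GlmFit(
        p_value=float(p),
        estimate=float(np.log(frac / (1 - frac))),
        dispersion=1.0,
        df_resid=0,
        method=method,
    )


def fit_ase_glm(rows: pd.DataFrame) -> GlmFit:
    """Quasibinomial logistic regression of allele-1 counts for one gene.

    The model regresses (allele1_total, allele2_total) on reproductive status
    and colony (sum-to-zero coding), so the intercept is the gene's
    grand-mean allelic log-odds; H0 is intercept = 0, i.e. proportion 0.5.
    Dispersion φ = Pearson χ² / residual df, floored at 1 (no
    under-dispersion credit); the p-value uses a t reference with residual df
    and standard errors scaled by √φ.  Degenerate designs fall back to an
    intercept-only refit (saturated model) or an exact two-sided binomial
    test of the pooled counts (single row, or all counts on one allele).
    """
    a1 = rows["allele1_total"].to_numpy(dtype=float)
    a2 = rows["allele2_total"].to_numpy(dtype=float)
    if np.any(a1 + a2 <= 0):
        raise ValueError("every group must have positive total counts")
    if len(rows) < 2 or np.all(a2 == 0) or np.all(a1 == 0):
        return _exact_binomial(a1, a2, "exact_binomial")

    endog = np.column_stack([a1, a2])
    design = np.column_stack(
        [np.ones(len(rows)), _effect_code(rows["status"]), _effect_code(rows["colony"])]
    )
    method = "quasibinomial"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(endog, design, family=sm.families.Binomial()).fit()
        except Exception:
            return _exact_binomial(a1, a2, "exact_binomial")
        if res.df_resid <= 0:
            design = np.ones((len(rows), 1))
            res = sm.GLM(endog, design, family=sm.families.Binomial()).fit()
            method = "intercept_only"
    df_resid = int(res.df_resid)
    if df_resid <= 0:
        return _exact_binomial(a1, a2, "exact_binomial")
    phi = max(1.0, float(res.pearson_chi2) / df_resid)
    se = float(res.bse[0]) * np.sqrt(phi)
    est = float(res.params[0])
    if not np.isfinite(se) or se == 0.0:
        return _exact_binomial(a1, a2, "exact_binomial")
    tval = est / se
    p = 2.0 * st.t.sf(abs(tval), df_resid)
    return GlmFit(
        p_value=float(p),
        estimate=est,
        dispersion=phi,
        df_resid=df_resid,
        method=method,
        converged=bool(getattr(res, "converged", True)),
    )


def _mean_props(table: pd.DataFrame, statuses) -> pd.DataFrame:
    tab = table.copy()
    tab["prop"] = tab["allele1_total"] / (tab["allele1_total"] + tab["allele2_total"])
    piv = tab.pivot_table(index="gene_id", columns="status", values="prop",
                          aggfunc="mean")
    for s in statuses:
        if s not in piv.columns:
            piv[s] = np.nan
    return piv[list(statuses)]


def classify_ase(table: pd.DataFrame, fits: pd.DataFrame, cfg: AseConfig) -> pd.DataFrame:
    """BH-correct the tested genes and apply the two-part ASE call.

    ``fits`` must carry one row per tested gene with a ``p_value`` column.
    A gene is ASE for a status when q < q_threshold and its mean allelic
    proportion across that status's colonies exceeds prop_threshold; the
    ``ase_class`` column reports shared / reproductive_only / sterile_only /
    none accordingly.
    """
    cfg.validate()
    res = fits.copy().reset_index(drop=True)
    res["q_value"] = bh_adjust(res["p_value"].to_numpy())
    props = _mean_props(table[table["gene_id"].isin(res["gene_id"])], cfg.statuses)
    s_a, s_b = cfg.statuses
    res["mean_prop_repro"] = res["gene_id"].map(props[s_a]).astype(float)
    res["mean_prop_sterile"] = res["gene_id"].map(props[s_b]).astype(float)
    sig = res["q_value"] < cfg.q_threshold
    res["ase_repro"] = sig & (res["mean_prop_repro"] > cfg.prop_threshold)
    res["ase_sterile"] = sig & (res["mean_prop_sterile"] > cfg.prop_threshold)
    res["ase_class"] = np.select(
        [
            res["ase_repro"] & res["ase_sterile"],
            res["ase_repro"],
            res["ase_sterile"],
        ],
        ["shared", "reproductive_only", "sterile_only"],
        default="none",
    )
    groups = table.groupby("gene_id").size()
    res["n_groups_tested"] = res["gene_id"].map(groups).fillna(0).astype(int)
    return res


def run_ase(snps: pd.DataFrame, samples: pd.DataFrame, genes, cfg: AseConfig = None,
            log=None):
    """Full ASE pipeline: annotate → filter → allocate → aggregate →
    eligibility → per-gene quasibinomial test → classification.

    ``genes`` may be None when ``snps`` already carries gene_id.  Returns the
    per-gene results DataFrame; filter-stage row counts are appended to
    ``log`` (a RunLog) when given.
    """
    cfg = cfg or AseConfig()
    cfg.validate()

    def _log(stage, **kw):
        if log is not None:
            log.record(stage, **kw)

    if genes is not None:
        snps = annotate_snps(snps, genes)
    elif "gene_id" not in snps.columns:
        raise ValueError("either gene models or a gene_id column is required")
    n_in = len(snps)
    filt = filter_snps(snps, cfg)
    _log("filter_snps", n_input=n_in, n_retained=len(filt), n_removed=n_in - len(filt))
    alloc = allocate_alleles(filt)
    table = aggregate_by_gene(alloc, samples)
    tested = eligibility_filter(table, cfg)
    _log("eligibility", n_genes_total=table["gene_id"].nunique(),
         n_genes_tested=len(tested))
    fit_rows = []
    for gene in tested:
        fit = fit_ase_glm(table[table["gene_id"] == gene])
        fit_rows.append(
            dict(gene_id=gene, p_value=fit.p_value, estimate=fit.estimate,
                 dispersion=fit.dispersion, df_resid=fit.df_resid,
                 method=fit.method)
        )
    if not fit_rows:
        return pd.DataFrame(
            columns=["gene_id", "p_value", "q_value", "mean_prop_repro",
                     "mean_prop_sterile", "ase_repro", "ase_sterile", "ase_class"]
        )
    fits = pd.DataFrame(fit_rows)
    results = classify_ase(table, fits, cfg)
    _log("classify", n_tested=len(results),
         n_ase=int((results["ase_class"] != "none").sum()))
    return results
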