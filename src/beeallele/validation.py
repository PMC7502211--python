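"""Recovery benchmarks run on synthetic data with known truth.

These routines regenerate data from the generators, run the full callers,
and score them against the simulation truth.  They are used both by the
test suite and by ``scripts/acceptance.py``; every random choice derives
from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import amr as amr_mod
from . import ase as ase_mod
from . import synthio
from .io import cpg_positions_from_report

__all__ = ["ase_recovery", "amr_recovery", "glm_type_i_error"]


def ase_recovery(
    seed: int,
    n_signal: int = 150,
    n_null: int = 300,
    signal_prop: float = 0.85,
    null_rho: float = 0.1,
    coverage: float = 30.0,
    snps_per_gene: int = 3,
) -> dict:
    """Sensitivity and null call rate of the ASE caller.

    One synthetic study (3 colonies × 2 statuses, 3 replicates per group)
    containing ``n_signal`` genes at allelic proportion ``signal_prop``
    (overdispersion-free) and ``n_null`` balanced genes with beta-binomial
    intra-class correlation ``null_rho``; the two gene classes are analysed
    together, so BH correction sees the realistic mixed p-value pool.  A
    gene counts as called when it is ASE for either status.
    """
    rng = np.random.default_rng(seed)
    s_sig, s_null = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))

    sig_cfg = synthio.AseSimConfig(
        n_genes=n_signal, snps_per_gene=snps_per_gene, coverage_mean=coverage,
        true_prop=signal_prop, overdispersion_rho=0.0, seed=s_sig,
    )
    null_cfg = synthio.AseSimConfig(
        n_genes=n_null, snps_per_gene=snps_per_gene, coverage_mean=coverage,
        true_prop=0.5, overdispersion_rho=null_rho, seed=s_null,
    )
    sig_snps, _ = synthio.simulate_ase_counts(sig_cfg)
    null_snps, _ = synthio.simulate_ase_counts(null_cfg)
    null_snps = null_snps.assign(gene_id="null_" + null_snps["gene_id"])
    snps = pd.concat([sig_snps, null_snps], ignore_index=True)
    samples = snps[["sample", "colony", "status"]].drop_duplicates()

    results = ase_mod.run_ase(snps, samples, genes=None, cfg=ase_mod.AseConfig())
    called = results.loc[results["ase_class"] != "none", "gene_id"]
    is_null = results["gene_id"].str.startswith("null_")
    n_sig_called = int((~called.str.startswith("null_")).sum())
    n_null_called = int(called.str.startswith("null_").sum())
    return {
        "sensitivity": n_sig_called / int((~is_null).sum()),
        "null_call_rate": n_null_called / int(is_null.sum()),
        "n_signal_tested": int((~is_null).sum()),
        "n_null_tested": int(is_null.sum()),
    }


def amr_recovery(
    seed: int,
    n_datasets: int = 10,
    n_regions: int = 40,
    n_amr: int = 8,
    reads_per_cpg: int = 15,
    profile_high: float = 0.9,
    profile_low: float = 0.1,
) -> dict:
    """Region-level recall/precision of the AMR caller, and window-level
    null type-I error.

    Each dataset holds ``n_regions`` regions with ``n_amr`` true AMRs
    (two-epiallele mixture of ``profile_high`` vs ``profile_low``); the
    remaining regions share one profile.  Recall and precision are pooled
    over ``n_datasets`` replicate datasets to reduce the Monte-Carlo error
    of the estimates; the null type-I error is the fraction of
    windows in truly single-epiallele regions with raw p < 0.05, with a
    cluster (per-region) standard error since windows within a region share
    reads.
    """
    rng = np.random.default_rng(seed)
    cfg = amr_mod.AmrConfig()
    tp = fn = fp = n_called = 0
    null_rates = []  # per-region window type-I rates
    for _ in range(n_datasets):
        s_sim, s_fit = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
        sim = synthio.MethSimConfig(
            n_regions=n_regions, is_amr=n_amr, reads_per_cpg=reads_per_cpg,
            profile_a=profile_high, profile_b=profile_low, seed=s_sim,
        )
        epireads, cytosine, truth = synthio.simulate_epireads(sim)
        cpg_pos = cpg_positions_from_report(cytosine)
        windows, _ = amr_mod.scan_windows(epireads, cpg_pos, cfg)
        fits = amr_mod.fit_windows(windows, cfg, seed=s_fit)
        regions = amr_mod.call_amrs(fits, cfg)

        true_chroms = set(truth.loc[truth["is_amr"], "chrom"])
        called_chroms = list(regions["chrom"])
        hit = {c for c in called_chroms if c in true_chroms}
        tp += len(true_chroms & hit)
        fn += len(true_chroms - hit)
        fp += sum(1 for c in called_chroms if c not in true_chroms)
        n_called += len(called_chroms)

        null_fits = fits[~fits["chrom"].isin(true_chroms)]
        for _, grp in null_fits.groupby("chrom"):
            null_rates.append(float((grp["p_value"] < 0.05).mean()))

    null_rates = np.asarray(null_rates)
    return {
        "recall": tp / (tp + fn),
        "precision": 1.0 - fp / n_called if n_called else float("nan"),
        "n_true_regions": tp + fn,
        "n_called_regions": n_called,
        "window_type_i": float(null_rates.mean()),
        "window_type_i_se": float(null_rates.std(ddof=1) / np.sqrt(len(null_rates))),
        "n_null_regions": int(len(null_rates)),
    }


def glm_type_i_error(
    seed: int,
    n_genes: int = 2000,
    rho: float = 0.1,
    coverage: int = 30,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the quasibinomial gene test itself.

    Counts are drawn directly at proportion 0.5 (no max/min allocation, so
    H0 is exactly true) for 6 groups (3 colonies × 2 statuses) per gene.
    """
    rng = np.random.default_rng(seed)
    colonies = [f"colony{i}" for i in (1, 2, 3)]
    statuses = ["reproductive", "sterile"]
    rej = 0
    a, b = 0.5 * (1 - rho) / rho, 0.5 * (1 - rho) / rho
    for _ in range(n_genes):
        p = rng.beta(a, b, size=6) if rho > 0 else np.full(6, 0.5)
        a1 = rng.binomial(coverage, p)
        rows = pd.DataFrame(
            {
                "colony": np.repeat(colonies, 2),
                "status": statuses * 3,
                "allele1_total": a1,
                "allele2_total": coverage - a1,
            }
        )
        fit = ase_mod.fit_ase_glm(rows)
        rej += fit.p_value < alpha
    return rej / n_genes
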