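"""Allelically methylated region (AMR) detection from bisulfite epireads.

A sliding window of ``w`` consecutive CpGs (default 3, minimum 10 reads per
CpG) is scanned along each allowed chromosome.  For each window two models
are fit to the epireads: a single per-CpG Bernoulli methylation profile
shared by both alleles, and a 50:50 mixture of two profiles (one per
allele), fit by EM.  Twice the log-likelihood gain is referred to a χ²
distribution with ``w`` degrees of freedom (the added parameters) to give a
per-window p-value; windows are BH-corrected, and significant windows that
overlap or abut in CpG-index space are merged into regions.

Also provides gene-level weighted methylation (total methylated reads over
total reads across a gene's CpGs), used to define the methylated-gene
background for enrichment analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as st

from .stats import bh_adjust

__all__ = [
    "AmrConfig",
    "EpireadWindow",
    "AmrModelFit",
    "scan_windows",
    "fit_single_profile",
    "fit_two_profile",
    "fit_windows",
    "call_amrs",
    "annotate_amrs",
    "weighted_methylation",
    "run_amr",
]

_EPS = 1e-6  # probability clamp shared by both models


@dataclass
class AmrConfig:
    window_size: int = 3
    min_cpg_coverage: int = 10
    q_threshold: float = 0.05
    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-8
    mixing: float = 0.5
    free_mixing: bool = False  # estimate the allele fraction instead of fixing 0.5

    def validate(self) -> None:
        if self.window_size < 1 or self.min_cpg_coverage < 1:
            raise ValueError("window_size and min_cpg_coverage must be >= 1")
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold must be in (0, 1)")
        if self.n_restarts < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid EM settings")
        if not (0.0 < self.mixing < 1.0):
            raise ValueError("mixing must be in (0, 1)")


@dataclass
class EpireadWindow:
    """Epireads overlapping one w-CpG window.

    ``reads`` is an (n_reads, w) float matrix with 1 = methylated (C),
    0 = unmethylated (T), NaN = CpG not covered by the read.
    """

    chrom: str
    cpg_indices: np.ndarray  # w consecutive indices into the chromosome CpG list
    cpg_positions: np.ndarray  # 1-based genomic positions of those CpGs
    reads: np.ndarray
    coverage_per_cpg: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.coverage_per_cpg is None:
            self.coverage_per_cpg = (~np.isnan(self.reads)).sum(axis=0)


@dataclass
class AmrModelFit:
    ll_single: float
    ll_two: float
    profiles: np.ndarray  # (2, w) per-CpG methylation probabilities
    single_profile: np.ndarray
    lr_stat: float
    p_value: float
    em_iterations: int
    converged: bool
    mixing: float = 0.5


def _parse_epireads(epireads: pd.DataFrame):
    """Group epireads by chromosome into (starts, state arrays)."""
    by_chrom: Dict[str, list] = {}
    for chrom, start, states in epireads[["chrom", "start", "states"]].itertuples(
        index=False
    ):
        vec = np.frombuffer(states.encode(), dtype=np.uint8)
        arr = np.where(vec == ord("C"), 1.0, 0.0)
        if not np.all((vec == ord("C")) | (vec == ord("T"))):
            raise ValueError(f"epiread state string must be over {{C,T}}: {states!r}")
        by_chrom.setdefault(chrom, []).append((int(start), arr))
    return by_chrom


def scan_windows(
    epireads: pd.DataFrame,
    cpg_positions: Dict[str, Sequence[int]],
    cfg: AmrConfig = None,
    chroms: Optional[Iterable[str]] = None,
):
    """Slide a w-CpG window (step 1 CpG) along each allowed chromosome.

    Windows where any CpG has fewer than ``min_cpg_coverage`` covering reads
    are skipped and counted.  Returns ``(windows, n_skipped)``.
    """
    cfg = cfg or AmrConfig()
    cfg.validate()
    w = cfg.window_size
    reads_by_chrom = _parse_epireads(epireads)
    allowed = set(chroms) if chroms is not None else None

    windows: List[EpireadWindow] = []
    n_skipped = 0
    for chrom in sorted(cpg_positions):
        if allowed is not None and chrom not in allowed:
            continue
        pos = np.asarray(cpg_positions[chrom], dtype=int)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"CpG positions must be strictly increasing on {chrom}")
        m = len(pos)
        if m < w:
            warnings.warn(f"chromosome {chrom} has fewer than {w} CpGs; no windows")
            continue
        reads = reads_by_chrom.get(chrom, [])
        coverage = np.zeros(m, dtype=int)
        for start, arr in reads:
            end = min(start + len(arr), m)
            coverage[start:end] += 1
        for i in range(m - w + 1):
            if coverage[i : i + w].min() < cfg.min_cpg_coverage:
                n_skipped += 1
                continue
            rows = []
            for start, arr in reads:
                end = start + len(arr)
                if start < i + w and end > i:
                    row = np.full(w, np.nan)
                    lo = max(start, i)
                    hi = min(end, i + w)
                    row[lo - i : hi - i] = arr[lo - start : hi - start]
                    rows.append(row)
            windows.append(
                EpireadWindow(
                    chrom=chrom,
                    cpg_indices=np.arange(i, i + w),
                    cpg_positions=pos[i : i + w],
                    reads=np.array(rows),
                )
            )
    return windows, n_skipped


def fit_single_profile(window: EpireadWindow):
    """One shared per-CpG methylation profile; returns (log-likelihood, profile).

    The ML profile is the per-CpG methylated fraction (clamped to
    [1e-6, 1-1e-6]); missing read states contribute nothing.
    """
    R = window.reads
    obs = ~np.isnan(R)
    X = np.nan_to_num(R)
    n = obs.sum(axis=0).astype(float)
    if np.any(n == 0):
        raise ValueError("zero coverage inside a tested window")
    m = (X * obs).sum(axis=0)
    prof = np.clip(m / n, _EPS, 1.0 - _EPS)
    ll = float(np.sum(m * np.log(prof) + (n - m) * np.log1p(-prof)))
    return ll, prof


def _read_loglik(X, obs, prof):
    """Per-read log-likelihood under one profile, missing states skipped."""
    lp = np.log(prof)
    lq = np.log1p(-prof)
    return np.where(obs, X * lp + (1.0 - X) * lq, 0.0).sum(axis=1)


def _em(X, obs, pa, pb, mix, free_mixing, max_iter, tol):
    ll_prev = -np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        la = _read_loglik(X, obs, pa) + np.log(mix)
        lb = _read_loglik(X, obs, pb) + np.log1p(-mix)
        tot = np.logaddexp(la, lb)
        ll = float(tot.sum())
        r = np.exp(la - tot)  # responsibility for profile a
        wa = (r[:, None] * obs).sum(axis=0)
        wb = ((1.0 - r)[:, None] * obs).sum(axis=0)
        na = (r[:, None] * X * obs).sum(axis=0)
        nb = ((1.0 - r)[:, None] * X * obs).sum(axis=0)
        pa = np.clip(np.divide(na, wa, out=np.full_like(na, 0.5), where=wa > 0),
                     _EPS, 1.0 - _EPS)
        pb = np.clip(np.divide(nb, wb, out=np.full_like(nb, 0.5), where=wb > 0),
                     _EPS, 1.0 - _EPS)
        if free_mixing:
            mix = float(np.clip(r.mean(), _EPS, 1.0 - _EPS))
        if ll - ll_prev < tol and it > 1:
            converged = True
            ll_prev = max(ll, ll_prev)
            break
        ll_prev = ll
    return ll_prev, pa, pb, mix, it, converged


def fit_two_profile(window: EpireadWindow, cfg: AmrConfig = None,
                    rng: np.random.Generator = None) -> AmrModelFit:
    """Two-epiallele mixture model for one window.

    A 50:50 (by default) mixture of two per-CpG Bernoulli profiles is fit by
    EM over the window's reads, with ``n_restarts`` initialisations keeping
    the best log-likelihood.  The first restart starts both profiles at the
    shared-profile optimum (the mixture family contains that point, so the
    nesting invariant ll_two >= ll_single holds by construction); the second
    splits the shared profile up/down; the rest are random.  The likelihood
    ratio statistic 2(ll_two - ll_single) is referred to χ² with w degrees
    of freedom (the w added profile parameters).
    """
    cfg = cfg or AmrConfig()
    cfg.validate()
    rng = rng or np.random.default_rng(0)
    R = window.reads
    obs = ~np.isnan(R)
    X = np.nan_to_num(R)
    w = R.shape[1]

    ll_single, prof = fit_single_profile(window)

    inits = [(prof.copy(), prof.copy()),
             (np.clip(prof + 0.3, _EPS, 1 - _EPS), np.clip(prof - 0.3, _EPS, 1 - _EPS))]
    while len(inits) < cfg.n_restarts:
        inits.append((rng.uniform(size=w), rng.uniform(size=w)))
    inits = inits[: cfg.n_restarts]

    best = None
    for pa0, pb0 in inits:
        ll, pa, pb, mix, it, conv = _em(
            X, obs, pa0, pb0, cfg.mixing, cfg.free_mixing, cfg.max_iter, cfg.tol
        )
        if best is None or ll > best[0]:
            best = (ll, pa, pb, mix, it, conv)
    ll_two, pa, pb, mix, it, conv = best
    ll_two = max(ll_two, ll_single)  # numerical guard; family is nested
    lr = 2.0 * (ll_two - ll_single)
    p = float(st.chi2.sf(max(lr, 0.0), df=w))
    return AmrModelFit(
        ll_single=ll_single,
        ll_two=ll_two,
        profiles=np.vstack([pa, pb]),
        single_profile=prof,
        lr_stat=lr,
        p_value=p,
        em_iterations=it,
        converged=conv,
        mixing=mix,
    )


def fit_windows(windows: Sequence[EpireadWindow], cfg: AmrConfig = None,
                seed: int = 0) -> pd.DataFrame:
    """Fit both models on every window; one row per window with the LR test."""
    cfg = cfg or AmrConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for win in windows:
        fit = fit_two_profile(win, cfg, rng)
        rows.append(
            dict(
                chrom=win.chrom,
                start_idx=int(win.cpg_indices[0]),
                end_idx=int(win.cpg_indices[-1]),
                start_pos=int(win.cpg_positions[0]),
                end_pos=int(win.cpg_positions[-1]),
                ll_single=fit.ll_single,
                ll_two=fit.ll_two,
                lr_stat=fit.lr_stat,
                p_value=fit.p_value,
                converged=fit.converged,
            )
        )
    cols = ["chrom", "start_idx", "end_idx", "start_pos", "end_pos",
            "ll_single", "ll_two", "lr_stat", "p_value", "converged"]
    return pd.DataFrame(rows, columns=cols)


def call_amrs(window_fits: pd.DataFrame, cfg: AmrConfig = None) -> pd.DataFrame:
    """BH-correct window p-values and merge significant windows into regions.

    Windows with q < q_threshold that overlap or abut in CpG-index space are
    merged; the region spans the first to last CpG position of its member
    windows (reported 0-based half-open, BED style).  The region carries the
    minimum member p and minimum member q — q is not recomputed at region
    level.
    """
    cfg = cfg or AmrConfig()
    fits = window_fits.copy().reset_index(drop=True)
    cols = ["region_id", "chrom", "start", "end", "p_value", "q_value", "n_windows"]
    if fits.empty:
        return pd.DataFrame(columns=cols)
    fits["q_value"] = bh_adjust(fits["p_value"].to_numpy())
    sig = fits[fits["q_value"] < cfg.q_threshold].sort_values(["chrom", "start_idx"])
    regions = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start_idx <= cur["end_idx"] + 1:
                cur["end_idx"] = max(cur["end_idx"], row.end_idx)
                cur["end_pos"] = max(cur["end_pos"], row.end_pos)
                cur["p_value"] = min(cur["p_value"], row.p_value)
                cur["q_value"] = min(cur["q_value"], row.q_value)
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = dict(chrom=chrom, start_idx=row.start_idx, end_idx=row.end_idx,
                           start_pos=row.start_pos, end_pos=row.end_pos,
                           p_value=row.p_value, q_value=row.q_value, n_windows=1)
        if cur is not None:
            regions.append(cur)
    out_rows = [
        dict(
            region_id=f"amr{k:04d}",
            chrom=r["chrom"],
            start=r["start_pos"] - 1,  # 1-based CpG -> 0-based half-open
            end=r["end_pos"],
            p_value=r["p_value"],
            q_value=r["q_value"],
            n_windows=r["n_windows"],
        )
        for k, r in enumerate(regions)
    ]
    return pd.DataFrame(out_rows, columns=cols)


def annotate_amrs(regions: pd.DataFrame, genes, exons: pd.DataFrame = None) -> pd.DataFrame:
    """Attach overlapping gene ids and an exon/intron/no-annotation feature.

    ``genes`` may be an ``io.GeneModels`` (then its exons are used) or a
    plain genes DataFrame with an optional separate ``exons`` frame.  A
    region overlapping any exon of an assigned gene is labelled ``exon``;
    one inside a gene body but outside all exons is ``intron``; otherwise
    ``no_annotation``.  Regions crossing several genes list them all,
    semicolon separated.
    """
    if hasattr(genes, "genes"):
        exons = genes.exons if exons is None else exons
        genes = genes.genes
    out = regions.copy()
    gene_lists, features = [], []
    for row in out.itertuples(index=False):
        g_start, g_end = row.start + 1, row.end  # genomic 1-based inclusive
        cand = genes[genes["chrom"] == row.chrom]
        hit = cand[(cand["start"] <= g_end) & (cand["end"] >= g_start)]
        ids = sorted(hit["gene_id"])
        gene_lists.append(";".join(ids))
        if not ids:
            features.append("no_annotation")
            continue
        feature = "no_annotation"
        if exons is not None and len(exons):
            ex = exons[exons["gene_id"].isin(ids) & (exons["chrom"] == row.chrom)]
            if len(ex) and bool(
                ((ex["start"] <= g_end) & (ex["end"] >= g_start)).any()
            ):
                feature = "exon"
        if feature != "exon":
            inside = hit[(hit["start"] <= g_start) & (hit["end"] >= g_end)]
            feature = "intron" if len(inside) else "no_annotation"
        features.append(feature)
    out["gene_ids"] = gene_lists
    out["feature"] = features
    return out


def weighted_methylation(cytosine: pd.DataFrame, genes, error_rate: float = 0.05) -> pd.DataFrame:
    """Gene-level weighted methylation: Σ methylated / Σ total reads over the
    gene's CpGs.  A gene is methylated when its level strictly exceeds
    ``error_rate`` (the bisulfite conversion error floor).  Genes with no
    covered CpG get NaN and is_methylated=False."""
    if hasattr(genes, "genes"):
        genes = genes.genes
    rows = []
    for chrom, grp in cytosine.groupby("chrom"):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(grp["count_methylated"].to_numpy())])
        ct = np.concatenate(
            [[0], np.cumsum((grp["count_methylated"] + grp["count_unmethylated"]).to_numpy())]
        )
        for g in genes[genes["chrom"] == chrom].itertuples(index=False):
            lo = np.searchsorted(pos, g.start, side="left")
            hi = np.searchsorted(pos, g.end, side="right")
            m = cm[hi] - cm[lo]
            t = ct[hi] - ct[lo]
            rows.append((g.gene_id, m, t))
    covered = {r[0] for r in rows}
    for g in genes.itertuples(index=False):
        if g.gene_id not in covered:
            rows.append((g.gene_id, 0, 0))
    out = pd.DataFrame(rows, columns=["gene_id", "meth_reads", "total_reads"])
    out = out.groupby("gene_id", as_index=False).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["weighted_level"] = np.where(
            out["total_reads"] > 0, out["meth_reads"] / out["total_reads"], np.nan
        )
    out["is_methylated"] = (out["total_reads"] > 0) & (out["weighted_level"] > error_rate)
    return out.sort_values("gene_id").reset_index(drop=True)


def run_amr(
    epireads: pd.DataFrame,
    cpg_positions: Dict[str, Sequence[int]],
    cfg: AmrConfig = None,
    chroms: Optional[Iterable[str]] = None,
    seed: int = 0,
    genes=None,
    log=None,
):
    """Scan, fit, BH-correct, merge, and (optionally) annotate AMRs.

    Returns ``(regions, window_fits)``.
    """
    cfg = cfg or AmrConfig()
    windows, n_skipped = scan_windows(epireads, cpg_positions, cfg, chroms)
    if log is not None:
        log.record("scan_windows", n_tested=len(windows), n_skipped=n_skipped)
    fits = fit_windows(windows, cfg, seed=seed)
    regions = call_amrs(fits, cfg)
    if genes is not None and len(regions):
        regions = annotate_amrs(regions, genes)
    if log is not None:
        log.record("call_amrs", n_regions=len(regions))
    return regions, fits
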