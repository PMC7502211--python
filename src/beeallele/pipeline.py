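"""Pipeline orchestration: configuration, run log, and the end-to-end driver.

``run_pipeline`` chains the synthetic generators (optional), the ASE caller,
the AMR caller per reproductive group, gene-level weighted methylation, and
the overlap statistics, writing every stage's outputs plus a reconciled run
log.  The whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import amr as amr_mod
from . import ase as ase_mod
from . import io as io_mod
from . import overlap as ov_mod
from . import synthio

__all__ = ["PipelineConfig", "RunLog", "run_pipeline"]


class RunLog:
    """Timestamped stage records with filter-count reconciliation."""

    def __init__(self):
        self.records = []

    def record(self, stage: str, **fields):
        if {"n_input", "n_retained", "n_removed"} <= set(fields):
            if fields["n_input"] != fields["n_retained"] + fields["n_removed"]:
                raise ValueError(f"filter counts do not reconcile at stage {stage}")
        entry = {
            "stage": stage,
            "time": datetime.datetime.now().isoformat(timespec="seconds"),
        }
        entry.update(fields)
        self.records.append(entry)
        print(f"[beeallele] {stage}: "
              + ", ".join(f"{k}={v}" for k, v in fields.items()), file=sys.stderr)

    def write(self, path):
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


@dataclass
class PipelineConfig:
    """Resolved configuration of a full synthetic-driven run."""

    seed: int = 0
    outdir: str = "beeallele_out"
    ase_sim: synthio.AseSimConfig = field(default_factory=synthio.AseSimConfig)
    meth_sim: synthio.MethSimConfig = field(default_factory=synthio.MethSimConfig)
    ase: ase_mod.AseConfig = field(default_factory=ase_mod.AseConfig)
    amr: amr_mod.AmrConfig = field(default_factory=amr_mod.AmrConfig)
    go_map: Optional[str] = None  # optional gene->GO-terms TSV
    conversion_error: float = 0.05

    def validate(self) -> None:
        self.ase_sim.validate()
        self.meth_sim.validate()
        self.ase.validate()
        self.amr.validate()
        if not (0.0 <= self.conversion_error < 1.0):
            raise ValueError("conversion_error must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("seed", "outdir", "go_map", "conversion_error"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for key, obj in (("ase_sim", cfg.ase_sim), ("meth_sim", cfg.meth_sim),
                         ("ase", cfg.ase), ("amr", cfg.amr)):
            for k, v in (raw.get(key) or {}).items():
                if not hasattr(obj, k):
                    raise ValueError(f"unknown option {key}.{k}")
                setattr(obj, k, tuple(v) if isinstance(v, list) else v)
        cfg.validate()
        return cfg

    def resolved_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate → ASE → AMR (per reproductive group) → methylation →
    overlap statistics → report.  Returns a bundle of result frames."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.record("start", config_hash=cfg.config_hash(), seed=cfg.seed)
    (out / "config.yaml").write_text(cfg.resolved_yaml())

    rng = np.random.default_rng(cfg.seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    # --- ASE ---------------------------------------------------------------
    ase_sim = synthio.AseSimConfig(**{**asdict(cfg.ase_sim), "seed": int(sub[0])})
    ase_sim.statuses = tuple(ase_sim.statuses)
    snps, ase_truth = synthio.simulate_ase_counts(ase_sim)
    log.record("simulate_ase", n_snp_rows=len(snps), n_genes=ase_sim.n_genes)
    samples = snps[["sample", "colony", "status"]].drop_duplicates()
    ase_results = ase_mod.run_ase(snps, samples, genes=None, cfg=cfg.ase, log=log)
    io_mod.write_results_tsv(ase_results, out / "ase_results.tsv")
    io_mod.write_results_tsv(ase_truth, out / "ase_truth.tsv")

    # --- AMR per reproductive group ----------------------------------------
    regions_by_group = {}
    meth_by_group = {}
    for k, status in enumerate(cfg.ase.statuses):
        msim = synthio.MethSimConfig(**{**asdict(cfg.meth_sim), "seed": int(sub[1]) + k})
        epireads, cytosine, meth_truth = synthio.simulate_epireads(msim)
        cpg_pos = io_mod.cpg_positions_from_report(cytosine)
        # map synthetic methylation regions onto the ASE gene space so the
        # joint gene-level statistics are meaningful
        gene_ids = ase_truth["gene_id"].to_numpy()
        genes = pd.DataFrame(
            {
                "gene_id": [gene_ids[i % len(gene_ids)] for i in range(len(meth_truth))],
                "chrom": meth_truth["chrom"],
                "start": meth_truth["start_pos"],
                "end": meth_truth["end_pos"],
            }
        )
        regions, fits = amr_mod.run_amr(
            epireads, cpg_pos, cfg.amr, seed=int(sub[2]) + k, genes=genes, log=log
        )
        meth = amr_mod.weighted_methylation(cytosine, genes, cfg.conversion_error)
        regions_by_group[status] = regions
        meth_by_group[status] = meth
        io_mod.write_results_tsv(fits, out / f"amr_windows_{status}.tsv")
        if len(regions):
            io_mod.write_bed(regions, out / f"amr_regions_{status}.bed")
        io_mod.write_results_tsv(meth, out / f"methylation_{status}.tsv")

    # --- overlap statistics -------------------------------------------------
    s_a, s_b = cfg.ase.statuses
    ase_genes = {
        s_a: set(ase_results.loc[ase_results["ase_repro"], "gene_id"]),
        s_b: set(ase_results.loc[ase_results["ase_sterile"], "gene_id"]),
    }
    amr_genes = {
        s: set(g for gl in regions_by_group[s].get("gene_ids", pd.Series(dtype=str))
               for g in str(gl).split(";") if g and g != "nan")
        for s in cfg.ase.statuses
    }
    tested = set(ase_results["gene_id"])
    summary = {
        "n_genes_tested_ase": len(tested),
        "n_ase_genes": int((ase_results["ase_class"] != "none").sum()),
        "n_amr_regions": {s: int(len(regions_by_group[s])) for s in cfg.ase.statuses},
    }
    counts = [len(regions_by_group[s]) for s in cfg.ase.statuses]
    if min(counts) > 0:
        stat, dfree, p = ov_mod.chi2_gof(counts)
        summary["amr_count_chi2"] = {"statistic": stat, "df": dfree, "p_value": p}
    part_ase = ov_mod.classify_shared(ase_genes[s_a], ase_genes[s_b])
    part_amr = ov_mod.classify_shared(amr_genes[s_a], amr_genes[s_b])
    summary["ase_shared"] = sorted(part_ase.shared)
    summary["amr_shared"] = sorted(part_amr.shared)
    ase_any = ase_genes[s_a] | ase_genes[s_b]
    amr_any = amr_genes[s_a] | amr_genes[s_b]
    universe = tested | amr_any
    if universe:
        summary["ase_amr_overlap_p"] = ov_mod.hypergeom_overlap(
            ase_any & universe, amr_any & universe, universe
        )
    if cfg.go_map:
        go = io_mod.read_go_map(cfg.go_map)
        background = set(go) | tested
        enr = ov_mod.go_enrichment(ase_any & background, go, background)
        io_mod.write_results_tsv(enr, out / "go_enrichment_ase.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    log.record("done", **{k: v for k, v in summary.items()
                          if isinstance(v, (int, float))})
    log.write(out / "run_log.jsonl")
    return {
        "ase_results": ase_results,
        "ase_truth": ase_truth,
        "regions": regions_by_group,
        "methylation": meth_by_group,
        "summary": summary,
        "log": log,
    }
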