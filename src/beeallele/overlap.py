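"""Association and enrichment statistics tying ASE and ASM together.

Set-overlap significance (hypergeometric upper tail over a declared
universe), GO-term enrichment against a caller-supplied background,
chi-square goodness of fit on category counts, Spearman rank correlation of
allelic proportions, Kruskal–Wallis with Dunn post hoc, and the
interaction-versus-main-effects ANOVA relating allelic expression proportion
to reproductive status and AMR category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as st

from .stats import bh_adjust

__all__ = [
    "hypergeom_overlap",
    "chi2_gof",
    "spearman_corr",
    "kruskal_dunn",
    "interaction_anova",
    "go_enrichment",
    "classify_shared",
    "SharedPartition",
]


def hypergeom_overlap(set_a: Set, set_b: Set, universe: Set) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= |A∩B|) when |A| draws are made without replacement from a
    universe of size |U| containing |B| successes.  Both sets must be
    subsets of the universe.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be contained in the universe")
    if not universe:
        raise ValueError("universe must be non-empty")
    k = len(set_a & set_b)
    return float(st.hypergeom.sf(k - 1, len(universe), len(set_b), len(set_a)))


def chi2_gof(observed: Sequence[float], expected_props: Sequence[float] = None):
    """Pearson chi-square goodness of fit.

    Returns ``(statistic, df, p_value)``; expectation is uniform across
    categories unless ``expected_props`` is given.
    """
    obs = np.asarray(observed, dtype=float)
    if expected_props is None:
        exp = np.full(obs.size, obs.sum() / obs.size)
    else:
        props = np.asarray(expected_props, dtype=float)
        exp = obs.sum() * props / props.sum()
    stat, p = st.chisquare(obs, exp)
    return float(stat), obs.size - 1, float(p)


def spearman_corr(x, y):
    """Spearman rank correlation (average ranks for ties), t-approximation p."""
    rho, p = st.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class KruskalDunnResult:
    kw_stat: float
    kw_df: int
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_value, q_value


def kruskal_dunn(groups: Sequence[Sequence[float]], labels: Sequence[str] = None) -> KruskalDunnResult:
    """Kruskal–Wallis H (tie corrected) with Dunn pairwise post hoc.

    Dunn Z uses the tie-corrected pooled rank variance
    ``[N(N+1)/12 − Σ(t³−t)/(12(N−1))]·(1/n_i + 1/n_j)``; pairwise p-values
    are two-sided normal and BH-corrected over the pairwise family.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    h, kw_p = st.kruskal(*groups)
    pooled = np.concatenate(groups)
    ranks = st.rankdata(pooled)
    n = len(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    off = 0
    for sz in sizes:
        mean_ranks.append(ranks[off : off + sz].mean())
        off += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_fac = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_fac * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            rows.append((labels[i], labels[j], float(z),
                         float(2.0 * st.norm.sf(abs(z)))))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_value"])
    pairwise["q_value"] = bh_adjust(pairwise["p_value"].to_numpy())
    return KruskalDunnResult(float(h), len(groups) - 1, float(kw_p), pairwise)


def interaction_anova(proportion, status, category):
    """F-test of the status × category interaction on allelic proportion.

    Least-squares fits of the main-effects and interaction models are
    compared: F = [(RSS_main − RSS_int)/Δdf] / [RSS_int/df_resid].
    Returns ``(F, (df_num, df_den), p_value)``.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(proportion, dtype=float),
            "status": np.asarray(status),
            "category": np.asarray(category),
        }
    )
    main = smf.ols("y ~ C(status) + C(category)", data=df).fit()
    inter = smf.ols("y ~ C(status) * C(category)", data=df).fit()
    tab = sm.stats.anova_lm(main, inter)
    f = float(tab["F"].iloc[1])
    p = float(tab["Pr(>F)"].iloc[1])
    df_num = int(tab["df_diff"].iloc[1])
    df_den = int(inter.df_resid)
    return f, (df_num, df_den), p


def go_enrichment(
    study: Set,
    annotation: Mapping[str, Set],
    background: Set,
    q_threshold: float = 0.05,
    only_significant: bool = False,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment of a study set vs a background.

    ``annotation`` maps gene_id → set of term ids; every annotated gene must
    be in the background and the study must be a subset of the background.
    Terms are used as annotated (no ancestor propagation).  One row per term
    present in the study set, with k (study hits), K (background hits),
    n (study size), N (background size), p and BH q over those terms.
    """
    study, background = set(study), set(background)
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    stray = set(annotation) - background
    if stray:
        raise ValueError(f"annotated genes outside background: {sorted(stray)[:5]}")
    cols = ["term", "k", "K", "n", "N", "p_value", "q_value", "enriched"]
    if not study:
        return pd.DataFrame(columns=cols)
    term_bg: Dict[str, int] = {}
    term_study: Dict[str, int] = {}
    for gene, terms in annotation.items():
        for t in terms:
            term_bg[t] = term_bg.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1
    n, N = len(study), len(background)
    rows = []
    for t, k in sorted(term_study.items()):
        K = term_bg[t]
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        rows.append((t, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=cols[:6])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = out["q_value"] < q_threshold
    if only_significant:
        out = out[out["enriched"]].reset_index(drop=True)
    return out


@dataclass(frozen=True)
class SharedPartition:
    shared: frozenset
    a_only: frozenset
    b_only: frozenset


def classify_shared(set_a: Iterable, set_b: Iterable) -> SharedPartition:
    """Partition two gene sets into shared / a-only / b-only."""
    a, b = set(set_a), set(set_b)
    return SharedPartition(frozenset(a & b), frozenset(a - b), frozenset(b - a))
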