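"""Gene-set enrichment with frequency-matched backgrounds; gene tiers.

Two complementary tests: (1) upper-tail hypergeometric overlap of each
gene set with the top-K associated genes, with Benjamini-Hochberg q
values across sets; (2) a one-sided Wilcoxon rank-sum test of whether
set genes have lower association P values than background genes matched
on variant count and cumulative allele frequency.  Fold enrichment is
the set's representation in the top decile of associations relative to
the matched background.  Genes are then tiered by their membership in
significantly enriched sets and their association strength.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file (set name, description, tab-separated genes)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def restrict_to_universe(
    gene_sets: dict[str, list[str]], universe: set[str]
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Drop set genes absent from the association universe (logged)."""
    out, dropped = {}, {}
    for name, genes in gene_sets.items():
        kept = [g for g in genes if g in universe]
        dropped[name] = len(genes) - len(kept)
        out[name] = kept
    return out, dropped


def hypergeom_overlap(top_genes: set, gene_set: set, universe: set) -> float:
    """Upper-tail hypergeometric P of the observed overlap or larger."""
    if not universe:
        raise ValueError("empty universe")
    if not set(top_genes) <= set(universe):
        raise ValueError("top genes must be drawn from the universe")
    gene_set = set(gene_set) & set(universe)
    overlap = len(set(top_genes) & gene_set)
    return float(
        hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(top_genes))
    )


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def match_background(
    target_genes: list[str],
    features: pd.DataFrame,
    fold: int = 50,
    feature_cols: tuple[str, str] = ("n_variants", "cumulative_af"),
) -> list[str]:
    """Select ``fold`` background genes per set gene, feature-matched.

    Matching is nearest-neighbour in (log variant count, log cumulative
    allele frequency) space, excluding the set itself, sampling without
    replacement.  If the pool cannot supply the full fold, a smaller
    background is returned with a warning.

    ``features`` is indexed by gene id with the two feature columns.
    """
    target = [g for g in target_genes if g in features.index]
    pool = features.index.difference(target)
    space = np.column_stack(
        [np.log(features[c].to_numpy(dtype=float) + 1e-9) for c in feature_cols]
    )
    # scale features so both axes matter comparably
    scale = space.std(axis=0)
    scale[scale == 0] = 1.0
    space = space / scale
    loc = {g: i for i, g in enumerate(features.index)}
    pool_idx = np.array([loc[g] for g in pool])
    taken = np.zeros(len(pool_idx), dtype=bool)
    matched: list[str] = []
    for g in target:
        d = np.linalg.norm(space[pool_idx] - space[loc[g]], axis=1)
        d[taken] = np.inf
        order = np.argsort(d, kind="stable")
        avail = order[~np.isinf(d[order])][:fold]
        if len(avail) < fold:
            warnings.warn(
                f"background pool exhausted for {g}: {len(avail)} < {fold}",
                stacklevel=2,
            )
        taken[avail] = True
        matched.extend(pool[avail])
    return matched


def ranksum_enrichment(set_ps, background_ps) -> float:
    """One-sided Wilcoxon rank-sum P that set genes have lower P values.

    Exact when the combined sample size is at most 20, otherwise the
    normal approximation with tie correction.
    """
    set_ps = np.asarray(set_ps, dtype=float)
    background_ps = np.asarray(background_ps, dtype=float)
    if set_ps.size == 0 or background_ps.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if set_ps.size + background_ps.size <= 20 else "asymptotic"
    return float(
        mannwhitneyu(set_ps, background_ps, alternative="less", method=method).pvalue
    )


def fold_enrichment(set_ps, background_ps) -> float:
    """Set representation in the background's top association decile.

    (fraction of set genes with P below the background's 10th
    percentile) / 0.10; a set drawn from the background gives ~1, a set
    entirely inside the top decile gives 10.
    """
    background_ps = np.asarray(background_ps, dtype=float)
    set_ps = np.asarray(set_ps, dtype=float)
    if background_ps.size < 10:
        raise ValueError("need at least 10 background genes for a decile cutoff")
    cutoff = np.quantile(background_ps, 0.10)
    return float(np.mean(set_ps <= cutoff) / 0.10)


def enrich_gene_sets(
    gene_ps: pd.Series,
    gene_sets: dict[str, list[str]],
    features: pd.DataFrame | None = None,
    top_k: int = 50,
    q_threshold: float = 0.01,
    background_fold: int = 50,
) -> pd.DataFrame:
    """Run both enrichment tests for every gene set.

    ``gene_ps`` maps gene id -> consolidated association P.  Returns a
    frame with overlap counts, hypergeometric P, BH q, rank-sum P and
    fold enrichment (the latter two only when ``features`` allows a
    matched background).
    """
    universe = set(gene_ps.index)
    sets_u, _ = restrict_to_universe(gene_sets, universe)
    top = set(gene_ps.nsmallest(top_k).index)
    rows = []
    for name, genes in sets_u.items():
        p_hyper = hypergeom_overlap(top, set(genes), universe)
        row = {
            "set": name,
            "n_genes": len(genes),
            "overlap": len(top & set(genes)),
            "hypergeom_p": p_hyper,
            "ranksum_p": np.nan,
            "fold_enrichment": np.nan,
        }
        if features is not None and genes:
            bg = match_background(genes, features, fold=background_fold)
            bg = [g for g in bg if g in gene_ps.index]
            if bg:
                row["ranksum_p"] = ranksum_enrichment(
                    gene_ps.loc[genes].to_numpy(), gene_ps.loc[bg].to_numpy()
                )
                if len(bg) >= 10:
                    row["fold_enrichment"] = fold_enrichment(
                        gene_ps.loc[genes].to_numpy(), gene_ps.loc[bg].to_numpy()
                    )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_qvalues(out["hypergeom_p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out


def assign_tiers(
    gene_ps: pd.Series,
    enriched_sets: dict[str, list[str]],
    top_k: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tier genes by association rank and enriched-set membership.

    Tier 3: among the top ``top_k`` associations and in >= 2 enriched
    sets.  Tier 4: in >= 1 enriched set and nominally associated
    (P < ``alpha``).  ``enriched_sets`` should contain only the sets
    already called significant (q below the enrichment threshold).
    """
    membership = {g: 0 for g in gene_ps.index}
    for genes in enriched_sets.values():
        for g in genes:
            if g in membership:
                membership[g] += 1
    top = set(gene_ps.nsmallest(top_k).index)
    rows = []
    for g, p in gene_ps.items():
        m = membership[g]
        tier = None
        if g in top and m >= 2:
            tier = 3
        elif m >= 1 and p < alpha:
            tier = 4
        rows.append(
            {
                "gene_id": g,
                "p": p,
                "n_enriched_sets": m,
                "in_top": g in top,
                "tier": tier,
            }
        )
    return pd.DataFrame(rows)
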