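"""Pathway-level enrichment of interaction-scan signals.

SNPs are mapped to genes within a flanking window (default 20 kb,
boundaries inclusive); each gene is scored by its best SNP,
score = max(-log10 p_int); pathways whose count of genes with mapped
SNPs falls outside [20, 200] are excluded; the remaining gene sets are
tested with a weighted Kolmogorov-Smirnov running sum over the ranked
gene list (weight exponent 1):

    hit  at rank j (member):     + score_j / (sum of member scores)
    miss at rank j (non-member): - 1 / (N - N_H)

ES is the running-sum value of maximal absolute deviation (signed).
Null distributions come from size-matched gene-label permutations on
the fixed ranked list; NES = ES / mean(|null ES| of the same sign);
nominal p = (1 + #{null >= observed, same sign}) / (k + 1); FDR q is
GSEA-style from the pooled null NES distribution, capped at 1.

Phenotype permutation (re-running the genome-wide scan per permutation)
is statistically stricter but computationally heavy; gene-label
permutation is the default and only built-in mode here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "map_snps_to_genes",
    "gene_statistic",
    "gene_scores_from_scan",
    "rank_genes",
    "filter_pathways",
    "enrichment_score",
    "permutation_test",
    "report_pathways",
]

DEFAULT_WINDOW = 20_000
DEFAULT_MIN_SIZE, DEFAULT_MAX_SIZE = 20, 200
DEFAULT_SIG_P = 1e-3  # "significant gene" reporting threshold on best-SNP p_int


@dataclass
class GeneSetCollection:
    """Gene intervals (1-based inclusive) plus pathway -> gene sets."""

    gene_intervals: pd.DataFrame  # columns gene_id, chrom, start, end
    sets: dict[str, list[str]]
    source_labels: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gi = self.gene_intervals
        if (gi["start"] > gi["end"]).any():
            raise ValueError("invalid gene interval (start > end)")
        for pid, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate gene ids within set {pid}")


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: GeneSetCollection | pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> tuple[dict[str, list[str]], int]:
    """Map each SNP to every gene within ``window`` bp (inclusive).

    ``snps`` needs columns snp_id, chrom, pos. SNP s maps to gene g iff
    they share a chromosome and pos in [start - window, end + window].
    Returns (gene_id -> snp_id list, count of SNPs mapping to no gene).
    """
    gi = genes.gene_intervals if isinstance(genes, GeneSetCollection) else genes
    mapping: dict[str, list[str]] = {}
    mapped = np.zeros(len(snps), dtype=bool)
    pos = snps["pos"].to_numpy(dtype=np.int64)
    chrom = snps["chrom"].astype(str).to_numpy()
    sid = snps["snp_id"].astype(str).to_numpy()
    for row in gi.itertuples(index=False):
        sel = (
            (chrom == str(row.chrom))
            & (pos >= row.start - window)
            & (pos <= row.end + window)
        )
        if sel.any():
            mapping[row.gene_id] = list(sid[sel])
            mapped |= sel
    return mapping, int((~mapped).sum())


def gene_statistic(p_values) -> float:
    """Gene score: max of -log10(p_int) over the gene's SNPs."""
    p = np.asarray(list(p_values), dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("gene has no SNP with a finite p-value")
    return float(np.max(-np.log10(np.clip(p, 1e-300, None))))


def gene_scores_from_scan(
    scan_results: pd.DataFrame,
    mapping: dict[str, list[str]],
) -> pd.Series:
    """Best-SNP score per gene from scan results (snp_id, p_int columns).

    Genes whose SNPs all lack a finite p are excluded.
    """
    p_by_snp = scan_results.set_index("snp_id")["p_int"]
    scores = {}
    for gene, snp_ids in mapping.items():
        p = p_by_snp.reindex(snp_ids).to_numpy(dtype=float)
        p = p[np.isfinite(p)]
        if len(p):
            scores[gene] = gene_statistic(p)
    return pd.Series(scores, name="score")


def rank_genes(gene_scores: pd.Series) -> pd.DataFrame:
    """Ranked gene list, descending score; stable tie order by gene id."""
    s = gene_scores.sort_index().sort_values(ascending=False, kind="stable")
    return pd.DataFrame({"gene_id": s.index, "score": s.to_numpy()})


def filter_pathways(
    collection: GeneSetCollection,
    mapped_genes,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> GeneSetCollection:
    """Keep pathways whose count of genes with mapped SNPs is in [min, max]."""
    mapped = set(mapped_genes)
    kept = {
        pid: genes
        for pid, genes in collection.sets.items()
        if min_size <= len(set(genes) & mapped) <= max_size
    }
    return GeneSetCollection(
        gene_intervals=collection.gene_intervals,
        sets=kept,
        source_labels={p: collection.source_labels.get(p, "other") for p in kept},
        descriptions={p: collection.descriptions.get(p, "") for p in kept},
    )


def enrichment_score(scores: np.ndarray, member: np.ndarray) -> float:
    """Weighted KS running-sum enrichment score on a ranked list.

    ``scores`` are the ranked (descending) gene scores, ``member`` a
    boolean membership mask of the same length. Signed value of the
    running sum at its maximal absolute deviation.
    """
    scores = np.asarray(scores, dtype=float)
    member = np.asarray(member, dtype=bool)
    n = len(scores)
    n_h = int(member.sum())
    if n_h == 0 or n_h == n:
        raise ValueError("need at least one member and one non-member")
    total = scores[member].sum()
    if total <= 0:
        raise ValueError("zero total member score; ES undefined")
    step = np.where(member, scores / total, -1.0 / (n - n_h))
    run = np.cumsum(step)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Vectorised ES for k permutations given member positions.

    ``pos``: (k, s) sorted 0-based ranks of members; ``weights``: (k, s)
    member scores at those ranks. Uses the fact that running-sum extremes
    occur at member positions (after a hit) or just before one (after the
    preceding miss run).
    """
    k, s = pos.shape
    totals = weights.sum(axis=1, keepdims=True)
    cumw = np.cumsum(weights, axis=1) / totals
    j = np.arange(1, s + 1)
    miss = 1.0 / (n - s)
    at_member = cumw - (pos + 1 - j) * miss          # peak after each hit
    before = np.concatenate(
        [np.zeros((k, 1)), cumw[:, :-1]], axis=1
    ) - (pos - (j - 1)) * miss                        # trough before each hit
    hi = at_member.max(axis=1)
    lo = before.min(axis=1)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


def permutation_test(
    collection: GeneSetCollection,
    ranked: pd.DataFrame,
    k_perm: int = 1000,
    seed: int = 0,
    sig_p: float = DEFAULT_SIG_P,
) -> pd.DataFrame:
    """Size-matched gene-label permutation test for every pathway.

    Returns one row per pathway: es, nes, p_nominal, fdr_q and the
    total / selected (>= 1 mapped SNP) / significant (best-SNP p below
    ``sig_p``) gene counts. Deterministic given ``seed``.
    """
    if k_perm < 100:
        raise ValueError("k_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    sig_score = -np.log10(sig_p)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for pid, members in collection.sets.items():
        mpos = np.array(sorted(index[g] for g in members if g in index))
        s = len(mpos)
        if s == 0 or s == n:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[mpos] = True
        es = enrichment_score(scores, mask)

        perm_pos = np.sort(
            rng.permuted(np.tile(np.arange(n), (k_perm, 1)), axis=1)[:, :s],
            axis=1,
        )
        null_es = _es_from_positions(perm_pos, scores[perm_pos], n)

        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
        degenerate = (not same_sign.any()) or np.ptp(null_es) == 0 or not np.isfinite(denom) or denom == 0
        nes = es / denom if not degenerate else np.nan
        null_nes = null_es[same_sign] / denom if not degenerate else np.array([])
        null_nes_pool.append(null_nes)

        if es >= 0:
            exceed = int((null_es[same_sign] >= es).sum())
        else:
            exceed = int((null_es[same_sign] <= es).sum())
        p_nom = (1 + exceed) / (k_perm + 1)

        total_members = len(set(members))
        rows.append({
            "pathway_id": pid,
            "description": collection.descriptions.get(pid, ""),
            "es": es, "nes": nes, "p_nominal": p_nom, "fdr_q": np.nan,
            "n_genes_total": total_members,
            "n_genes_selected": s,
            "n_genes_significant": int((scores[mpos] >= sig_score).sum()),
            "status": "degenerate_null" if degenerate else "ok",
        })

    out = pd.DataFrame(rows)
    if out.empty:
        return out

    pooled = np.concatenate([x for x in null_nes_pool if len(x)]) if null_nes_pool else np.array([])
    obs = out["nes"].to_numpy(dtype=float)
    q = np.ones(len(out))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes) or len(pooled) == 0:
            q[i] = 1.0
            continue
        if nes >= 0:
            frac_null = (pooled >= nes).mean()
            frac_obs = (obs[np.isfinite(obs)] >= nes).mean()
        else:
            frac_null = (pooled <= nes).mean()
            frac_obs = (obs[np.isfinite(obs)] <= nes).mean()
        q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
        q[i] = max(q[i], 1.0 / (len(pooled) + 1))  # keep q in (0, 1]
    out["fdr_q"] = q
    return out


def report_pathways(results: pd.DataFrame) -> pd.DataFrame:
    """Report table sorted by FDR q ascending (description, FDR, counts)."""
    if results.empty:
        return pd.DataFrame(
            columns=["pathway_id", "description", "fdr_q",
                     "n_genes_significant", "n_genes_selected", "n_genes_total"]
        )
    cols = ["pathway_id", "description", "fdr_q",
            "n_genes_significant", "n_genes_selected", "n_genes_total"]
    return results.sort_values("fdr_q", kind="stable")[cols].reset_index(drop=True)
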