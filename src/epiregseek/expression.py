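"""Differential expression of genes and TEs, per-gene ANOVA, and the
methylome-transcriptome epiregulation screen.

DEG calling follows a nonparametric divergence-probability scheme: for a
condition contrast each gene contributes a signal point (|log2 ratio|,
|difference|) computed on condition mean FPKM (pseudocount-stabilised), and
a noise cloud is assembled from all within-condition replicate-pair
contrasts across all genes.  The divergence probability of a gene is the
fraction of noise points strictly dominated by its signal point.  A gene is
a DEG when probability >= 0.8 and fold-change >= 2.  The scheme is this
package's own self-contained statistic; externally computed probabilities
can be supplied instead via ``call_degs(..., probabilities=...)``.

DETs are called on TE counts with a conditional binomial test (TE count in
condition B versus the pooled count, success probability set by the library
size ratio) with Benjamini-Hochberg adjustment; TEs overlapping any
protein-coding gene body are discarded before testing.

The epiregulation screen joins CG/CHG DMRs whose midpoint falls in a gene's
CDS or within 2 kb of its TSS/TES to that gene's DEG record for the same
ordered condition pair.  Associations where the methylation and expression
directions agree (hyper & up, or hypo & down) are *positive* and are
discarded; the genes of the remaining negative associations form the
putative epiregulated gene list.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import GeneModel, TEModel

CONDITIONS = ("LS", "LL", "HS", "HL")


def _condition_columns(samples: pd.DataFrame, condition: str) -> list[str]:
    cols = samples.loc[samples["condition"] == condition, "sample"].tolist()
    if not cols:
        raise ValueError(f"no samples for condition {condition!r}")
    return cols


def divergence_probability(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Signal statistics and divergence probability per gene (see module
    docstring).  Returns a frame indexed like ``fpkm`` with columns
    ``mean_a``, ``mean_b``, ``log2fc`` and ``prob``."""
    cols_a = _condition_columns(samples, cond_a)
    cols_b = _condition_columns(samples, cond_b)
    mean_a = fpkm[cols_a].mean(axis=1).to_numpy()
    mean_b = fpkm[cols_b].mean(axis=1).to_numpy()
    m_sig = np.abs(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
    d_sig = np.abs(mean_b - mean_a)
    noise_m, noise_d = [], []
    for cols in (cols_a, cols_b):
        for c1, c2 in combinations(cols, 2):
            x1 = fpkm[c1].to_numpy()
            x2 = fpkm[c2].to_numpy()
            noise_m.append(np.abs(np.log2((x1 + pseudocount) / (x2 + pseudocount))))
            noise_d.append(np.abs(x1 - x2))
    nm = np.concatenate(noise_m)
    nd = np.concatenate(noise_d)
    # P(noise strictly dominated) per gene, chunked to bound memory
    prob = np.empty(len(m_sig))
    chunk = max(1, int(5e7) // max(len(nm), 1))
    for s in range(0, len(m_sig), chunk):
        e = min(s + chunk, len(m_sig))
        dominated = (nm[None, :] < m_sig[s:e, None]) & (nd[None, :] < d_sig[s:e, None])
        prob[s:e] = dominated.mean(axis=1)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": np.log2((mean_b + pseudocount) / (mean_a + pseudocount)),
            "prob": prob,
        },
        index=fpkm.index,
    )


def call_degs(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    min_fc: float = 2.0,
    min_prob: float = 0.8,
    pseudocount: float = 1.0,
    probabilities: pd.Series | None = None,
) -> pd.DataFrame:
    """Differentially expressed genes between ``cond_a`` and ``cond_b``.

    Emits one row per DEG: gene, log2fc (B over A, pseudocount-stabilised),
    prob, direction (up/down).  Both the fold-change (>= ``min_fc``) and the
    divergence-probability (>= ``min_prob``) thresholds are enforced.
    """
    table = divergence_probability(fpkm, samples, cond_a, cond_b, pseudocount)
    if probabilities is not None:
        table["prob"] = probabilities.reindex(table.index)
    keep = (table["prob"] >= min_prob) & (np.abs(table["log2fc"]) >= np.log2(min_fc))
    out = table[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.insert(0, "gene_id", out.index)
    out["cond_a"] = cond_a
    out["cond_b"] = cond_b
    return out.reset_index(drop=True)


def deg_overlap(deg_sets: dict[str, set]) -> dict[tuple, int]:
    """Counts for every region of the Venn partition of 2+ DEG id sets,
    keyed by the sorted tuple of member set names."""
    names = sorted(deg_sets)
    out = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(set(deg_sets[m]) for m in members))
            rest = [set(deg_sets[m]) for m in names if m not in members]
            outside = set.union(*rest) if rest else set()
            out[members] = len(inside - outside)
    return out


def gene_anova(
    fpkm: pd.DataFrame, samples: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Per-gene two-way fixed-effects ANOVA of log2(FPKM+1).

    Factors are decoded from the condition labels: temperature (L*/H*) and
    photoperiod (*S/*L), a balanced 2x2 design with equal replication.
    Classical sums of squares (all SS types coincide on balanced data); every
    term is tested against the residual.  Returns (per-gene p-value frame,
    counts of genes significant per term at ``alpha``).
    """
    temp = samples["condition"].str[0].to_numpy()
    photo = samples["condition"].str[1].to_numpy()
    y = np.log2(fpkm[samples["sample"]].to_numpy() + 1.0)
    cells = {}
    for t in ("L", "H"):
        for p in ("S", "L"):
            mask = (temp == t) & (photo == p)
            if mask.sum() == 0:
                raise ValueError(f"missing design cell temperature={t} photoperiod={p}")
            cells[(t, p)] = mask
    r = {k: int(v.sum()) for k, v in cells.items()}
    if len(set(r.values())) != 1:
        raise ValueError("unbalanced 2x2 design: unequal replication per cell")
    reps = next(iter(r.values()))
    cell_means = {k: y[:, m].mean(axis=1) for k, m in cells.items()}
    grand = y.mean(axis=1)
    t_means = {t: (cell_means[(t, "S")] + cell_means[(t, "L")]) / 2 for t in ("L", "H")}
    p_means = {p: (cell_means[("L", p)] + cell_means[("H", p)]) / 2 for p in ("S", "L")}
    ss_t = 2 * reps * sum((t_means[t] - grand) ** 2 for t in ("L", "H"))
    ss_p = 2 * reps * sum((p_means[p] - grand) ** 2 for p in ("S", "L"))
    ss_tp = reps * sum(
        (cell_means[(t, p)] - t_means[t] - p_means[p] + grand) ** 2
        for t in ("L", "H")
        for p in ("S", "L")
    )
    ss_e = np.zeros_like(grand)
    for k, m in cells.items():
        ss_e += ((y[:, m] - cell_means[k][:, None]) ** 2).sum(axis=1)
    df_e = 4 * (reps - 1)
    if df_e <= 0:
        raise ValueError("need at least 2 replicates per cell")
    ms_e = ss_e / df_e
    with np.errstate(invalid="ignore", divide="ignore"):
        result = pd.DataFrame(
            {
                "p_temperature": stats.f.sf(ss_t / ms_e, 1, df_e),
                "p_photoperiod": stats.f.sf(ss_p / ms_e, 1, df_e),
                "p_interaction": stats.f.sf(ss_tp / ms_e, 1, df_e),
            },
            index=fpkm.index,
        )
    counts = {
        "temperature": int((result["p_temperature"] < alpha).sum()),
        "photoperiod": int((result["p_photoperiod"] < alpha).sum()),
        "interaction": int((result["p_interaction"] < alpha).sum()),
    }
    return result, counts


def te_expression(
    te_counts: pd.DataFrame, te_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """FPKM for TEs: count / (length/1e3) / (library size/1e6)."""
    lengths = te_lengths.reindex(te_counts.index)
    libs = library_sizes.reindex(te_counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all TE lengths must be positive")
    if (libs <= 0).any() or libs.isna().any():
        raise ValueError("all library sizes must be positive")
    return te_counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


def _overlaps_any_gene(te: TEModel, genes: list[GeneModel]) -> bool:
    return any(
        g.chrom == te.chrom and g.start < te.end and te.start < g.end for g in genes
    )


def call_dets(
    te_counts: pd.DataFrame,
    samples: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    genes: list[GeneModel],
    te_models: list[TEModel],
    alpha: float = 0.05,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Differentially expressed TEs between two conditions.

    TEs overlapping any protein-coding gene body are discarded before
    testing.  Counts are pooled across replicates per condition; each TE's
    condition-B count is tested against Binomial(total, Lb/(La+Lb)) where
    La/Lb are the condition library sizes, and BH-adjusted p < ``alpha``
    survivors are emitted with their direction (library-size-normalised).
    """
    cols_a = _condition_columns(samples, cond_a)
    cols_b = _condition_columns(samples, cond_b)
    if library_sizes is None:
        library_sizes = te_counts.sum(axis=0)
    la = float(library_sizes[cols_a].sum())
    lb = float(library_sizes[cols_b].sum())
    models = {t.id: t for t in te_models}
    keep_ids = [
        tid
        for tid in te_counts.index
        if tid in models and not _overlaps_any_gene(models[tid], genes)
    ]
    a = te_counts.loc[keep_ids, cols_a].sum(axis=1)
    b = te_counts.loc[keep_ids, cols_b].sum(axis=1)
    total = a + b
    p0 = lb / (la + lb)
    pvals = np.ones(len(keep_ids))
    for i, tid in enumerate(keep_ids):
        n = int(total[tid])
        if n > 0:
            pvals[i] = stats.binomtest(int(b[tid]), n, p0).pvalue
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    rate_a = a / la
    rate_b = b / lb
    out = pd.DataFrame(
        {
            "te_id": keep_ids,
            "count_a": a.to_numpy(),
            "count_b": b.to_numpy(),
            "pvalue": pvals,
            "padj": padj,
            "direction": np.where(rate_b.to_numpy() > rate_a.to_numpy(), "up", "down"),
        }
    )
    out = out[out["padj"] < alpha].reset_index(drop=True)
    out["cond_a"] = cond_a
    out["cond_b"] = cond_b
    return out


EPIREG_CONTEXTS = ("CG", "CHG")
EPIREG_FLANK = 2000


def _region_label(gene: GeneModel, midpoint: int, flank: int) -> str | None:
    for s, e in gene.cds:
        if s <= midpoint < e:
            return "CDS"
    if abs(midpoint - gene.tss) <= flank:
        return "within-2kb-of-TSS"
    if abs(midpoint - gene.tes) <= flank:
        return "within-2kb-of-TES"
    return None


def epireg_screen(
    dmrs: pd.DataFrame,
    degs: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = EPIREG_FLANK,
) -> tuple[pd.DataFrame, list[str], dict]:
    """Screen for putative epiregulation: CG/CHG DMRs near DEGs with
    discordant directions.

    ``dmrs`` needs columns dmr_id, chrom, start, end, context, direction;
    ``degs`` needs gene_id and direction (same ordered condition pair as the
    DMRs).  Returns (event table, putative epiregulated gene list, summary).
    An association is *positive* when methylation and expression move the
    same way (hyper & up / hypo & down); positives are discarded and the
    remaining genes, deduplicated, form the putative list.
    """
    deg_dir = dict(zip(degs["gene_id"], degs["direction"]))
    eligible = dmrs[dmrs["context"].isin(EPIREG_CONTEXTS)]
    events = []
    for _, d in eligible.iterrows():
        midpoint = (int(d["start"]) + int(d["end"])) // 2
        for g in genes:
            if g.chrom != d["chrom"] or g.id not in deg_dir:
                continue
            label = _region_label(g, midpoint, flank)
            if label is None:
                continue
            expr_dir = deg_dir[g.id]
            positive = (d["direction"] == "hyper") == (expr_dir == "up")
            events.append(
                {
                    "dmr_id": d["dmr_id"],
                    "gene_id": g.id,
                    "region": label,
                    "context": d["context"],
                    "meth_direction": d["direction"],
                    "expr_direction": expr_dir,
                    "sign": "positive" if positive else "negative",
                }
            )
    events = pd.DataFrame(
        events,
        columns=[
            "dmr_id",
            "gene_id",
            "region",
            "context",
            "meth_direction",
            "expr_direction",
            "sign",
        ],
    )
    negative = events[events["sign"] == "negative"]
    putative = sorted(negative["gene_id"].unique())
    summary = {
        "n_events": int(len(events)),
        "fraction_positive": float((events["sign"] == "positive").mean())
        if len(events)
        else float("nan"),
        "n_putative_genes": len(putative),
    }
    return events, putative, summary
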