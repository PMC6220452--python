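"""Seed-and-extend differentially methylated region (DMR) calling.

A candidate DMR starts from a *seed*: five adjacent same-context cytosines
of which at least four are DmCs sharing one direction, with a two-sided
Wilcoxon rank-sum test on the five per-site methylation levels (condition A
vs condition B) significant at p < 0.05.  The seed is then extended site by
site in increasing coordinate order: the next same-context cytosine is
incorporated while it shares the seed's response pattern and the rank-sum
test over the enlarged region stays significant; extension stops at the
first failure.  Candidates shorter than 50 bp or with a mean methylation
level difference below 0.1 are discarded (both thresholds inclusive, since
the discard rule is for regions strictly smaller than the cut-offs).

"Adjacent motifs" are taken as consecutive same-context cytosines in
coordinate order pooling both strands (a strand-separated mode is
available).  Overlapping candidates of the same direction are merged and
their delta recomputed over the union of member sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import CONTEXTS, call_dmcs_frame

SEED_SIZE = 5

#: Exact (permutation) rank-sum null is used when both groups are at most
#: this large; otherwise the normal approximation with tie correction.
EXACT_MAX_N = 8


@dataclass
class DMR:
    """A contiguous differentially methylated region.

    ``start``/``end`` are 0-based half-open, spanning the first to last
    member cytosine inclusive (a single base occupies 1 bp).  ``delta`` is
    the difference of mean per-site MLs, condition B minus condition A.
    """

    chrom: str
    start: int
    end: int
    context: str
    direction: str
    ml_a: float
    ml_b: float
    wilcoxon_p: float
    n_sites: int
    member_pos: list = field(default_factory=list)

    @property
    def delta(self) -> float:
        return self.ml_b - self.ml_a

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group relabelings of
    the pooled midranks (ties handled naturally)."""
    from itertools import combinations as _combos

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    sums = np.fromiter(
        (sum(c) for c in _combos(ranks, n1)), dtype=float
    )
    eps = 1e-9
    p_low = np.mean(sums <= obs + eps)
    p_high = np.mean(sums >= obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def rank_sum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation distribution when both groups have at most
    :data:`EXACT_MAX_N` observations; normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N:
        return _exact_rank_sum_p(a, b)
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def seed_test(
    mls_a,
    mls_b,
    dmc_dirs,
    alpha: float = 0.05,
    min_concordant: int = 4,
    veto_opposite: bool = True,
) -> tuple[bool, int, float]:
    """Test a 5-site window as a DMR seed.

    ``dmc_dirs`` holds +1/-1 for hyper/hypo DmCs and 0 for non-DmC sites.
    Returns ``(is_seed, direction, wilcoxon_p)`` with direction +1/-1 (0 when
    not a seed).  A window qualifies when at least ``min_concordant`` of the
    five sites are DmCs of one direction (an opposite-direction DmC vetoes
    the window unless ``veto_opposite`` is off) and the rank-sum test on the
    five per-site ML pairs is significant.
    """
    dmc_dirs = np.asarray(dmc_dirs)
    if not (len(mls_a) == len(mls_b) == len(dmc_dirs) == SEED_SIZE):
        raise ValueError(f"seed window must have exactly {SEED_SIZE} sites")
    n_hyper = int(np.sum(dmc_dirs == 1))
    n_hypo = int(np.sum(dmc_dirs == -1))
    if n_hyper >= min_concordant and (n_hypo == 0 or not veto_opposite):
        direction = 1
    elif n_hypo >= min_concordant and (n_hyper == 0 or not veto_opposite):
        direction = -1
    else:
        return False, 0, float("nan")
    p = rank_sum_p(mls_a, mls_b)
    return p < alpha, direction if p < alpha else 0, p


def extend_seed(
    mls_a,
    mls_b,
    dmc_dirs,
    seed_start: int,
    direction: int,
    alpha: float = 0.05,
    strict: bool = True,
) -> int:
    """Extend a seed 3' (increasing coordinates) one site at a time.

    Arrays cover a whole same-context site series; the seed occupies
    ``[seed_start, seed_start + 5)``.  Returns the exclusive end index of the
    maximal candidate.  In strict mode the next site must itself be a DmC of
    the seed's direction; the lenient mode also admits non-significant sites
    whose ML difference has the seed's sign.  In either mode the rank-sum
    test over the enlarged region must stay significant.
    """
    n = len(mls_a)
    end = seed_start + SEED_SIZE
    while end < n:
        d = dmc_dirs[end]
        if strict:
            concordant = d == direction
        else:
            concordant = d == direction or (
                d == 0 and np.sign(mls_b[end] - mls_a[end]) == direction
            )
        if not concordant:
            break
        p = rank_sum_p(mls_a[seed_start : end + 1], mls_b[seed_start : end + 1])
        if p >= alpha:
            break
        end += 1
    return end


def _merge_candidates(cands: list[tuple[int, int, int, float]]):
    """Merge overlapping same-direction (start_idx, end_idx) candidates;
    keeps the smallest seed p among the merged."""
    merged: list[list] = []
    for s, e, d, p in sorted(cands):
        if merged and s < merged[-1][1] and d == merged[-1][2]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][3] = min(merged[-1][3], p)
        else:
            merged.append([s, e, d, p])
    return merged


def call_dmrs(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    context: str,
    alpha: float = 0.05,
    min_len: int = 50,
    min_delta: float = 0.1,
    dmc_alpha: float = 0.05,
    dmc_min_delta: float = 0.2,
    min_coverage: int = 4,
    strict: bool = True,
    pool_strands: bool = True,
    veto_opposite: bool = True,
) -> list[DMR]:
    """Call DMRs of one context between two cytosine reports.

    Runs DmC calling, scans 5-site windows per chromosome, extends seeds,
    merges overlapping same-direction candidates and applies the length and
    delta filters.  Output is sorted by (chrom, start).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    sites = call_dmcs_frame(
        report_a,
        report_b,
        alpha=dmc_alpha,
        min_delta=dmc_min_delta,
        min_coverage=min_coverage,
    )
    sites = sites[sites["context"] == context]
    return call_dmrs_from_sites(
        sites,
        context,
        alpha=alpha,
        min_len=min_len,
        min_delta=min_delta,
        strict=strict,
        pool_strands=pool_strands,
        veto_opposite=veto_opposite,
    )


def call_dmrs_from_sites(
    sites: pd.DataFrame,
    context: str,
    alpha: float = 0.05,
    min_len: int = 50,
    min_delta: float = 0.1,
    strict: bool = True,
    pool_strands: bool = True,
    veto_opposite: bool = True,
) -> list[DMR]:
    """As :func:`call_dmrs` but starting from a pre-computed per-site frame
    (the output of :func:`epiregseek.methylome.call_dmcs_frame`)."""
    candidates: list[DMR] = []
    if pool_strands:
        group_keys = ["chrom"]
    else:
        group_keys = ["chrom", "strand"]
    for _, chrom_sites in sites.groupby(group_keys, sort=True):
        chrom_sites = chrom_sites.sort_values(["pos", "strand"])
        pos = chrom_sites["pos"].to_numpy()
        mls_a = chrom_sites["ml_a"].to_numpy()
        mls_b = chrom_sites["ml_b"].to_numpy()
        dirs = chrom_sites["dmc_dir"].to_numpy()
        chrom = chrom_sites["chrom"].iloc[0]
        n = len(pos)
        raw: list[tuple[int, int, int, float]] = []
        i = 0
        while i + SEED_SIZE <= n:
            window_dirs = dirs[i : i + SEED_SIZE]
            # cheap concordance pre-check before running the rank-sum test
            if max(np.sum(window_dirs == 1), np.sum(window_dirs == -1)) >= 4:
                is_seed, direction, p = seed_test(
                    mls_a[i : i + SEED_SIZE],
                    mls_b[i : i + SEED_SIZE],
                    window_dirs,
                    alpha=alpha,
                    veto_opposite=veto_opposite,
                )
                if is_seed:
                    end = extend_seed(
                        mls_a, mls_b, dirs, i, direction, alpha=alpha, strict=strict
                    )
                    raw.append((i, end, direction, p))
            i += 1
        for s, e, d, p in _merge_candidates(raw):
            # trim to the outermost concordant DmCs: edge sites without a
            # differential call carry no signal and would inflate the span
            member_dirs = dirs[s:e]
            concordant = np.nonzero(member_dirs == d)[0]
            if concordant.size == 0:
                continue
            s, e = s + int(concordant[0]), s + int(concordant[-1]) + 1
            candidates.append(
                DMR(
                    chrom=chrom,
                    start=int(pos[s]),
                    end=int(pos[e - 1]) + 1,
                    context=context,
                    direction="hyper" if d > 0 else "hypo",
                    ml_a=float(np.mean(mls_a[s:e])),
                    ml_b=float(np.mean(mls_b[s:e])),
                    wilcoxon_p=p,
                    n_sites=e - s,
                    member_pos=[int(x) for x in pos[s:e]],
                )
            )
    kept, _ = filter_dmrs(candidates, min_len=min_len, min_delta=min_delta)
    kept.sort(key=lambda d: (d.chrom, d.start))
    return kept


def filter_dmrs(
    candidates: list[DMR], min_len: int = 50, min_delta: float = 0.1
) -> tuple[list[DMR], dict]:
    """Apply the inclusive length and |delta| thresholds.

    Returns (survivors, discard counts per reason); a candidate failing both
    thresholds is counted under both reasons.
    """
    kept = []
    discarded = {"short": 0, "small_delta": 0}
    for d in candidates:
        too_short = d.length < min_len
        too_flat = abs(d.delta) < min_delta
        if too_short:
            discarded["short"] += 1
        if too_flat:
            discarded["small_delta"] += 1
        if not too_short and not too_flat:
            kept.append(d)
    return kept, discarded


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Tabulate DMRs (one row each, ``dmr_id`` assigned in sorted order)."""
    rows = [
        {
            "dmr_id": f"DMR{i:05d}",
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "context": d.context,
            "direction": d.direction,
            "ml_a": d.ml_a,
            "ml_b": d.ml_b,
            "delta": d.delta,
            "wilcoxon_p": d.wilcoxon_p,
            "n_sites": d.n_sites,
        }
        for i, d in enumerate(dmrs)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "dmr_id",
            "chrom",
            "start",
            "end",
            "context",
            "direction",
            "ml_a",
            "ml_b",
            "delta",
            "wilcoxon_p",
            "n_sites",
        ],
    )
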