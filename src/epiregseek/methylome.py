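"""Methylcytosine and differential-cytosine calling from per-cytosine count data.

Implements the site-level layer of a WGBS comparison between two conditions:

* sequence-context classification (CG / CHG / CHH, H = A, T or C, read 5'->3'
  on the cytosine's own strand);
* methylcytosine (mC) calling by a one-sided binomial test against the
  bisulfite non-conversion rate;
* methylation level (ML = methylated reads / total reads) and genome-wide
  context summaries;
* differentially methylated cytosine (DmC) calling with a two-sided Fisher
  exact test (p < alpha) combined with an absolute ML difference filter
  (|delta| >= 0.2 by default).

CG sites are kept strand-specific throughout: symmetric CpG pairs are two
distinct sites, so intersection keys between condition comparisons stay
unambiguous.  No multiple-testing correction is applied to DmC p-values;
the raw-p + delta-filter rule is deliberate and documented in the methods
note.  Sites below a configurable coverage floor (default 4 reads in either
sample) are excluded from DmC testing because Fisher's test is powerless on
tiny counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTEXTS = ("CG", "CHG", "CHH")

_H = frozenset("ATC")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Columns of a per-cytosine report frame (positions 0-based in memory).
REPORT_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine's counts in one sample.  ``pos`` is 0-based on the
    forward reference; for ``strand == '-'`` the cytosine appears as a G in
    the forward sequence."""

    chrom: str
    pos: int
    strand: str
    context: str | None
    meth_reads: int
    total_reads: int

    def __post_init__(self):
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"need 0 <= meth_reads <= total_reads, got "
                f"{self.meth_reads}/{self.total_reads}"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class MCall:
    """Binomial methylcytosine call for a single site."""

    site: CytosineSite
    is_mc: bool
    min_required_reads: int | None
    p_tail: float


@dataclass(frozen=True)
class DmC:
    """A differentially methylated cytosine (condition B relative to A)."""

    site_key: tuple
    context: str | None
    ml_a: float
    ml_b: float
    fisher_p: float

    @property
    def delta(self) -> float:
        return self.ml_b - self.ml_a

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


def classify_context(genome: dict, chrom: str, pos: int, strand: str) -> str | None:
    """Classify the sequence context of the cytosine at ``(chrom, pos, strand)``.

    ``genome`` maps chromosome name to an upper-case sequence string.  Returns
    ``None`` when the base is not a C on the requested strand, when fewer than
    two downstream bases exist, or when any base of the motif is ambiguous.
    """
    seq = genome[chrom]
    if pos < 0 or pos >= len(seq):
        raise IndexError(f"position {pos} outside {chrom} (length {len(seq)})")
    if strand == "+":
        if seq[pos] != "C":
            return None
        if pos + 2 >= len(seq):
            return None
        b1, b2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if seq[pos] != "G":  # a C on the reverse strand
            return None
        if pos - 2 < 0:
            return None
        b1 = _COMPLEMENT.get(seq[pos - 1], "N")
        b2 = _COMPLEMENT.get(seq[pos - 2], "N")
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if b1 not in "ACGT" or b2 not in "ACGT":
        return None
    if b1 == "G":
        return "CG"
    if b2 == "G":  # b1 is H here
        return "CHG"
    return "CHH"


def min_meth_reads(coverage: int, error_rate: float, alpha: float = 0.05) -> int | None:
    """Smallest methylated-read count that rejects the non-conversion null.

    Returns the smallest ``k`` with ``P(X >= k | n=coverage, p=error_rate)
    < alpha`` where ``error_rate = 1 - conversion_rate``, or ``None`` when no
    call is possible (zero coverage, or even ``k = coverage`` fails).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 <= error_rate < 1:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    if coverage == 0:
        return None
    ks = np.arange(1, coverage + 1)
    tails = stats.binom.sf(ks - 1, coverage, error_rate)
    passing = np.nonzero(tails < alpha)[0]
    if passing.size == 0:
        return None
    return int(ks[passing[0]])


def call_mc(site: CytosineSite, conversion_rate: float, alpha: float = 0.05) -> MCall:
    """Call a site methylated when its methylated-read count reaches the
    binomial threshold implied by the bisulfite conversion rate."""
    if not 0 < conversion_rate <= 1:
        raise ValueError(f"conversion_rate must be in (0, 1], got {conversion_rate}")
    error_rate = 1.0 - conversion_rate
    k = min_meth_reads(site.total_reads, error_rate, alpha)
    if site.total_reads > 0:
        p_tail = float(stats.binom.sf(site.meth_reads - 1, site.total_reads, error_rate))
    else:
        p_tail = float("nan")
    is_mc = k is not None and site.total_reads > 0 and site.meth_reads >= k
    return MCall(site=site, is_mc=is_mc, min_required_reads=k, p_tail=p_tail)


def site_ml(site: CytosineSite) -> float | None:
    """Methylation level (meth/total); ``None`` for uncovered sites, which are
    excluded from summaries rather than counted as 0."""
    if site.total_reads == 0:
        return None
    return site.meth_reads / site.total_reads


def call_mcs_frame(
    report: pd.DataFrame, conversion_rate: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Vectorised mC calling over a cytosine-report frame.

    Adds ``ml`` (NaN when uncovered) and boolean ``is_mc`` columns.
    """
    if not 0 < conversion_rate <= 1:
        raise ValueError(f"conversion_rate must be in (0, 1], got {conversion_rate}")
    error_rate = 1.0 - conversion_rate
    out = report.copy()
    total = out["total"].to_numpy()
    meth = out["meth"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ml"] = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    # threshold depends only on coverage: compute once per distinct coverage
    thresholds = {
        int(n): min_meth_reads(int(n), error_rate, alpha) for n in np.unique(total)
    }
    kmin = np.array(
        [np.inf if thresholds[int(n)] is None else thresholds[int(n)] for n in total]
    )
    out["is_mc"] = (total > 0) & (meth >= kmin)
    return out


def context_summary(called: pd.DataFrame) -> pd.DataFrame:
    """Per-context (and overall) mean ML, covered-C count, mC count and mC/C.

    ``called`` must carry ``context``, ``total``, ``ml`` and ``is_mc`` columns
    (see :func:`call_mcs_frame`).  Contexts with no covered sites are reported
    with NaN mean ML and zero counts.
    """
    covered = called[called["total"] > 0]
    rows = []
    groups = [("C", covered)] + [
        (ctx, covered[covered["context"] == ctx]) for ctx in CONTEXTS
    ]
    for label, sub in groups:
        n_c = len(sub)
        n_mc = int(sub["is_mc"].sum())
        rows.append(
            {
                "context": label,
                "mean_ml": float(sub["ml"].mean()) if n_c else float("nan"),
                "n_c": n_c,
                "n_mc": n_mc,
                "mc_per_c": n_mc / n_c if n_c else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("context")


def increment_rate(treatment: float, control: float) -> float:
    """Relative change (treatment - control) / control, e.g. a control mean
    ML of 0.2 rising to 0.275 is an increment rate of 0.375 (37.5%)."""
    if control == 0:
        raise ZeroDivisionError("increment rate undefined for a zero control value")
    return (treatment - control) / control


def call_dmc(
    site_a: CytosineSite,
    site_b: CytosineSite,
    alpha: float = 0.05,
    min_delta: float = 0.2,
) -> DmC | None:
    """Fisher-exact DmC call for one site measured in two conditions.

    Returns a :class:`DmC` iff the two-sided Fisher p on the 2x2 count table
    is below ``alpha`` and the absolute ML difference reaches ``min_delta``;
    ``None`` otherwise (including when either side is uncovered).
    """
    if site_a.key != site_b.key:
        raise ValueError(f"site keys differ: {site_a.key} vs {site_b.key}")
    if site_a.total_reads == 0 or site_b.total_reads == 0:
        return None
    ml_a = site_a.meth_reads / site_a.total_reads
    ml_b = site_b.meth_reads / site_b.total_reads
    table = [
        [site_a.meth_reads, site_a.total_reads - site_a.meth_reads],
        [site_b.meth_reads, site_b.total_reads - site_b.meth_reads],
    ]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if p < alpha and abs(ml_b - ml_a) >= min_delta:
        return DmC(site_a.key, site_a.context, ml_a, ml_b, p)
    return None


def merge_reports(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two cytosine reports on (chrom, pos, strand), yielding one
    row per site present in both with ``_a``/``_b`` suffixed count columns."""
    keys = ["chrom", "pos", "strand", "context"]
    merged = report_a.merge(report_b, on=keys, suffixes=("_a", "_b"))
    return merged.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def call_dmcs_frame(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    alpha: float = 0.05,
    min_delta: float = 0.2,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Vectorised DmC calling between two cytosine reports.

    Returns the merged per-site frame restricted to sites covered at
    ``min_coverage`` or more in both conditions, with columns ``ml_a``,
    ``ml_b``, ``delta``, ``fisher_p`` (NaN where not tested), ``is_dmc`` and
    ``dmc_dir`` (+1 hyper, -1 hypo, 0 otherwise).  Fisher tests are only run
    on sites passing the delta filter; the others cannot be DmCs.
    """
    merged = merge_reports(report_a, report_b)
    covered = (merged["total_a"] >= min_coverage) & (merged["total_b"] >= min_coverage)
    merged = merged[covered].reset_index(drop=True)
    merged["ml_a"] = merged["meth_a"] / merged["total_a"]
    merged["ml_b"] = merged["meth_b"] / merged["total_b"]
    merged["delta"] = merged["ml_b"] - merged["ml_a"]
    merged["fisher_p"] = np.nan
    candidate = merged.index[merged["delta"].abs() >= min_delta]
    ps = np.empty(len(candidate))
    ma = merged["meth_a"].to_numpy()
    ta = merged["total_a"].to_numpy()
    mb = merged["meth_b"].to_numpy()
    tb = merged["total_b"].to_numpy()
    for i, idx in enumerate(candidate):
        table = [[ma[idx], ta[idx] - ma[idx]], [mb[idx], tb[idx] - mb[idx]]]
        ps[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    merged.loc[candidate, "fisher_p"] = ps
    merged["is_dmc"] = merged["fisher_p"] < alpha
    merged["dmc_dir"] = np.where(
        merged["is_dmc"], np.sign(merged["delta"]).astype(int), 0
    )
    return merged
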