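"""Association of methylation features with genes and transposable elements.

Conventions (all coordinates 0-based half-open in memory; GFF3 is converted
on read):

* a *genic region* is the gene body plus 2 kb of flanking sequence on each
  side, clipped to the chromosome;
* a TE contributes only its body;
* a query point (a DmC, or a DMR/DET midpoint) may lie in several features
  at once; its category is one of ``gene-only`` / ``TE-only`` / ``TE&gene``
  / ``none``;
* a genic query is assigned to the single nearest gene, distance measured
  to the gene body (0 inside; ties broken toward the smaller gene id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

GENIC_FLANK = 2000

TE_CLASSES = ("LTR", "LINE", "SINE", "DNA", "unknown")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: body interval, strand, CDS intervals.

    TSS/TES are the mRNA boundaries: on '+' the TSS is ``start`` and the TES
    is ``end - 1`` (last transcribed base); reversed on '-'.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty gene body for {self.id}")
        for s, e in self.cds:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"CDS [{s},{e}) outside body of {self.id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TEModel:
    """A transposable element body with its class label."""

    id: str
    chrom: str
    start: int
    end: int
    te_class: str = "unknown"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty TE interval for {self.id}")


@dataclass(frozen=True)
class FeatureAssignment:
    chrom: str
    pos: int
    category: str  # gene-only | TE-only | TE&gene | none
    gene_id: str | None
    te_ids: tuple


def genic_region(
    gene: GeneModel, chrom_length: int | None = None, flank: int = GENIC_FLANK
) -> tuple[int, int]:
    """Gene body extended by ``flank`` bases each side, clipped to [0, L)."""
    start = max(0, gene.start - flank)
    end = gene.end + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def _body_distance(gene: GeneModel, pos: int) -> int:
    if pos < gene.start:
        return gene.start - pos
    if pos >= gene.end:
        return pos - (gene.end - 1)
    return 0


class FeatureIndex:
    """Interval index over genic regions and TE bodies for point assignment."""

    def __init__(
        self,
        genes: list[GeneModel],
        tes: list[TEModel],
        chrom_lengths: dict | None = None,
        flank: int = GENIC_FLANK,
        nearest_by: str = "body",
    ):
        if nearest_by not in ("body", "tss"):
            raise ValueError("nearest_by must be 'body' or 'tss'")
        self.nearest_by = nearest_by
        self._genes = {g.id: g for g in genes}
        self._tes = {t.id: t for t in tes}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._te_trees: dict[str, IntervalTree] = {}
        self.chroms = set()
        if chrom_lengths:
            self.chroms.update(chrom_lengths)
        for g in genes:
            L = chrom_lengths.get(g.chrom) if chrom_lengths else None
            s, e = genic_region(g, L, flank)
            self._gene_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.id)
            self.chroms.add(g.chrom)
        for t in tes:
            self._te_trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.id)
            self.chroms.add(t.chrom)

    def assign(self, chrom: str, pos: int) -> FeatureAssignment:
        """Assign one point to its feature category (see module docstring)."""
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        te_ids = tuple(
            sorted(iv.data for iv in self._te_trees.get(chrom, IntervalTree())[pos])
        )
        gene_hits = [
            self._genes[iv.data]
            for iv in self._gene_trees.get(chrom, IntervalTree())[pos]
        ]
        gene_id = None
        if gene_hits:
            if self.nearest_by == "body":
                gene_id = min(
                    gene_hits, key=lambda g: (_body_distance(g, pos), g.id)
                ).id
            else:
                gene_id = min(gene_hits, key=lambda g: (abs(pos - g.tss), g.id)).id
        if gene_id and te_ids:
            category = "TE&gene"
        elif gene_id:
            category = "gene-only"
        elif te_ids:
            category = "TE-only"
        else:
            category = "none"
        return FeatureAssignment(chrom, pos, category, gene_id, te_ids)

    def te_overlaps(self, chrom: str, start: int, end: int) -> tuple:
        """ids of TEs whose body overlaps [start, end) (for full-interval
        DMR-TE association)."""
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return tuple(
            sorted(iv.data for iv in self._te_trees.get(chrom, IntervalTree())[start:end])
        )


def assign_point(
    chrom: str,
    pos: int,
    genes: list[GeneModel],
    tes: list[TEModel],
    chrom_lengths: dict | None = None,
) -> FeatureAssignment:
    """One-shot convenience wrapper around :class:`FeatureIndex`."""
    return FeatureIndex(genes, tes, chrom_lengths).assign(chrom, pos)


def assign_frame(
    index: FeatureIndex, points: pd.DataFrame, pos_col: str = "pos"
) -> pd.DataFrame:
    """Assign every (chrom, pos) row of ``points``; returns the frame with
    ``category``, ``gene_id`` and ``te_ids`` columns appended."""
    cats, gids, tids = [], [], []
    for chrom, pos in zip(points["chrom"], points[pos_col]):
        a = index.assign(chrom, int(pos))
        cats.append(a.category)
        gids.append(a.gene_id)
        tids.append(",".join(a.te_ids))
    out = points.copy()
    out["category"] = cats
    out["gene_id"] = gids
    out["te_ids"] = tids
    return out


DMC_KEY = ["chrom", "pos", "strand", "context"]


def shared_dmcs(dmc_sets: dict[str, pd.DataFrame]) -> dict:
    """Intersect two or more keyed DmC sets.

    Each frame must carry the key columns (chrom, pos, strand, context) and a
    ``delta`` column.  Returns the all-way intersection with one delta column
    per comparison, the sign-concordance fraction across comparisons,
    per-context shared counts, and counts for every region of the Venn
    partition (keyed by the sorted tuple of member set names).
    """
    if len(dmc_sets) < 2:
        raise ValueError("need at least two DmC sets to intersect")
    names = sorted(dmc_sets)
    shared = None
    for name in names:
        df = dmc_sets[name][DMC_KEY + ["delta"]].rename(columns={"delta": f"delta_{name}"})
        shared = df if shared is None else shared.merge(df, on=DMC_KEY)
    delta_cols = [f"delta_{n}" for n in names]
    if len(shared):
        signs = np.sign(shared[delta_cols].to_numpy())
        concordant = np.all(signs == signs[:, [0]], axis=1)
        concordance = float(np.mean(concordant))
    else:
        concordance = float("nan")
    per_context = shared.groupby("context").size().to_dict()
    # Venn partition over exact membership patterns
    key_sets = {
        n: set(map(tuple, dmc_sets[n][DMC_KEY].itertuples(index=False)))
        for n in names
    }
    venn = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(key_sets[m] for m in members))
            outside = set.union(
                *(key_sets[m] for m in names if m not in members), set()
            )
            venn[members] = len(inside - outside)
    return {
        "shared": shared,
        "concordance": concordance,
        "per_context": per_context,
        "venn": venn,
    }


def window_counts(
    features: pd.DataFrame,
    window_size: int = 2_000_000,
    pos_col: str = "pos",
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Count features in half-open genomic windows [k*w, (k+1)*w) per
    chromosome; the last window is truncated at the chromosome end.  When
    ``chrom_lengths`` is given, empty windows are included with count 0."""
    rows = []
    grouped = features.groupby("chrom")
    seen = {}
    for chrom, sub in grouped:
        bins = (sub[pos_col] // window_size).astype(int)
        seen[chrom] = bins.value_counts().to_dict()
    chroms = sorted(set(seen) | set(chrom_lengths or {}))
    for chrom in chroms:
        counts = seen.get(chrom, {})
        if chrom_lengths and chrom in chrom_lengths:
            n_win = max(1, -(-chrom_lengths[chrom] // window_size))
            idxs = range(n_win)
        else:
            idxs = sorted(counts)
        for k in idxs:
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": k * window_size,
                    "count": int(counts.get(k, 0)),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "window_start", "count"])


def te_breakdown(
    assignments: list[FeatureAssignment] | pd.DataFrame, tes: list[TEModel]
) -> dict[str, int]:
    """Count, per TE class, the distinct TEs hit by any query (each TE counted
    once no matter how many queries fall in it)."""
    te_class = {t.id: t.te_class for t in tes}
    hit: set[str] = set()
    if isinstance(assignments, pd.DataFrame):
        for ids in assignments["te_ids"]:
            if ids:
                hit.update(ids.split(","))
    else:
        for a in assignments:
            hit.update(a.te_ids)
    counts: dict[str, int] = {}
    for tid in hit:
        cls = te_class[tid]
        counts[cls] = counts.get(cls, 0) + 1
    return counts
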