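"""Synthetic WGBS / RNA-seq / phenotype data with planted, recoverable truth.

The generator emulates the data a two-condition shoot-apex methylome study
produces, at desk scale:

* a random genome (configurable GC fraction) with gene and TE annotations;
* per-cytosine methylation reports for a control and one or more treatment
  conditions — every cytosine of every context on both strands receives a
  (methylated, unmethylated) count pair drawn binomially from its true
  methylation level, with negative-binomial coverage and imperfect
  bisulfite conversion (unmethylated cytosines still read methylated at
  rate 1 - conversion_rate);
* planted DMRs of known span, delta and direction (true MLs differ between
  conditions only inside planted regions);
* expression count + FPKM matrices over the four incubator conditions
  (LS/LL/HS/HL x replicates) with planted DEGs/DETs, including promoter
  methylation <-> expression couplings of known sign;
* a balanced multi-year / two-season PNPF phenotype table generated on the
  arcsine scale from known variance components.

All randomness flows from a single seed; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import GeneModel, TEModel, genic_region
from .methylome import CONTEXTS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = _BASES
_COMP = np.zeros(256, dtype=np.uint8)
_COMP[_A], _COMP[_C], _COMP[_G], _COMP[_T] = _T, _G, _C, _A

CONTROL_INDEX = 0


class ConfigurationError(ValueError):
    """Raised when a simulation request is internally inconsistent."""


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the defaults define the study conditions
    every recovery test runs under (see docs/methods.md)."""

    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 250_000
    gc_fraction: float = 0.37
    # annotation
    n_genes: int = 50
    n_tes: int = 80
    te_class_mix: dict = field(
        default_factory=lambda: {
            "LTR": 0.40,
            "unknown": 0.25,
            "LINE": 0.15,
            "DNA": 0.15,
            "SINE": 0.05,
        }
    )
    te_gene_overlap_fraction: float = 0.2
    gene_length: tuple = (1500, 4000)
    te_length: tuple = (300, 2000)
    # methylome
    baseline_ml: dict = field(
        default_factory=lambda: {"CG": 0.60, "CHG": 0.35, "CHH": 0.08}
    )
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0  # negative-binomial shape k
    conversion_rate: float = 0.99
    conditions: tuple = ("LS", "HL")  # first entry is the control
    # planted DMRs
    n_dmrs: dict = field(default_factory=lambda: {"CG": 5, "CHG": 5, "CHH": 8})
    dmr_delta: float = 0.8
    dmr_min_sites: int = 8
    dmr_min_span: int = 100
    dmr_max_span: int = 500
    dmr_hyper_fraction: float = 0.5
    dmr_margin: int = 500  # minimum gap between planted regions
    # epiregulation couplings
    n_epiregs: int = 8
    n_positive_couplings: int = 4
    epireg_log2fc: float = 2.0
    epireg_dmr_delta: float = 0.5
    # expression
    n_replicates: int = 3
    n_degs: int = 25
    deg_log2fc: float = 3.0
    #: negative-binomial shape for replicate noise (CV ~ 1/sqrt(k) ~ 11%):
    #: pooled-tissue triplicates under controlled conditions are tight
    expr_dispersion: float = 80.0
    expr_base_mean: float = 200.0
    #: planted DEG/coupling genes are given at least this baseline mean count:
    #: differential calls are only meaningful on solidly expressed genes
    deg_base_floor: float = 600.0
    n_dets: int = 5
    det_log2fc: float = 3.0
    te_base_mean: float = 50.0
    # phenotype (field design)
    n_years: int = 5
    n_seasons: int = 2
    n_varieties: int = 30
    n_pheno_reps: int = 3
    pheno_grand_mean: float = 0.70  # arcsine scale
    variance_components: dict = field(
        default_factory=lambda: {
            "year": 0.0006,
            "variety": 0.05,
            "season_year": 0.035,
            "year_variety": 0.009,
            "season_year_variety": 0.012,
            "residual": 0.0005,
        }
    )

    def validate(self):
        if self.chrom_length < 10_000:
            raise ConfigurationError("chromosome lengths must be at least 10 kb")
        if not 0 < self.conversion_rate <= 1:
            raise ConfigurationError("conversion rate must lie in (0, 1]")
        for ctx, ml in self.baseline_ml.items():
            if not 0 <= ml <= 1:
                raise ConfigurationError(f"baseline ML for {ctx} outside [0, 1]")
        if not 0 < self.dmr_delta <= 1 or not 0 < self.epireg_dmr_delta <= 1:
            raise ConfigurationError(
                "planted delta must lie in (0, 1] so MLs stay inside [0, 1]"
            )
        if not 0 <= self.gc_fraction <= 1:
            raise ConfigurationError("GC fraction must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 expression replicates")
        if min(self.n_years, self.n_seasons, self.n_varieties, self.n_pheno_reps) < 1:
            raise ConfigurationError("phenotype design sizes must be positive")
        if any(v < 0 for v in self.variance_components.values()):
            raise ConfigurationError("variance components must be non-negative")
        if len(self.conditions) < 2:
            raise ConfigurationError("need a control and at least one treatment")


@dataclass
class TruthTable:
    """Planted truth for parameter-recovery tests."""

    planted_dmrs: pd.DataFrame  # dmr_id chrom start end context ml_a ml_b direction role
    planted_degs: pd.DataFrame  # gene_id log2fc direction role
    planted_dets: pd.DataFrame  # te_id log2fc direction
    planted_epiregs: pd.DataFrame  # gene_id dmr_id sign
    variance_components: dict

    def validate(self):
        d = self.planted_dmrs.sort_values(["context", "chrom", "start"])
        for (_, _), sub in d.groupby(["context", "chrom"]):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("planted DMRs overlap within a context")
        dmr_ids = set(self.planted_dmrs["dmr_id"])
        gene_ids = set(self.planted_degs["gene_id"])
        for _, row in self.planted_epiregs.iterrows():
            if row["dmr_id"] not in dmr_ids:
                raise ValueError(f"epireg references unknown DMR {row['dmr_id']}")
            if row["gene_id"] not in gene_ids:
                raise ValueError(f"epireg references unknown gene {row['gene_id']}")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be non-negative")


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict
    genes: list
    tes: list
    cytosines: pd.DataFrame
    methylomes: dict  # condition -> cytosine report frame
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    te_counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series
    te_lengths: pd.Series
    phenotype: pd.DataFrame
    truth: TruthTable

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}


def _rngs(seed: int, names=("genome", "annotation", "truth", "methylome", "expression", "phenotype")):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------- genome


def gen_genome(config: SimulationConfig, rng=None) -> dict:
    """Random genome over {A,C,G,T} at the configured GC fraction."""
    config.validate()
    rng = rng or _rngs(config.seed)["genome"]
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {}
    for i in range(config.n_chrom):
        arr = rng.choice(_BASES, size=config.chrom_length, p=p)
        genome[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return genome


def enumerate_cytosines(genome: dict) -> pd.DataFrame:
    """All cytosines on both strands with their CG/CHG/CHH context
    (sites truncated by chromosome ends are dropped)."""
    frames = []
    for chrom in sorted(genome):
        seq = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        n = len(seq)
        # forward strand: C at i, context from i+1, i+2
        fwd = np.nonzero(seq[: n - 2] == _C)[0]
        b1, b2 = seq[fwd + 1], seq[fwd + 2]
        ctx_f = np.where(b1 == _G, "CG", np.where(b2 == _G, "CHG", "CHH"))
        # reverse strand: C appears as G at i; context from i-1, i-2 complemented
        rev = np.nonzero(seq[2:] == _G)[0] + 2
        c1, c2 = _COMP[seq[rev - 1]], _COMP[seq[rev - 2]]
        ctx_r = np.where(c1 == _G, "CG", np.where(c2 == _G, "CHG", "CHH"))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([fwd, rev]),
                    "strand": ["+"] * len(fwd) + ["-"] * len(rev),
                    "context": np.concatenate([ctx_f, ctx_r]),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


# ------------------------------------------------------------ annotation


def gen_annotation(genome: dict, config: SimulationConfig, rng=None):
    """Place non-overlapping gene models and TE intervals on the genome.

    A ``te_gene_overlap_fraction`` share of TEs is placed overlapping genic
    regions (body +- 2 kb); the rest is placed strictly outside them.
    """
    rng = rng or _rngs(config.seed)["annotation"]
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    total = sum(lengths.values())
    genes: list[GeneModel] = []
    # allocate genes per chromosome proportional to length
    alloc = {c: int(round(config.n_genes * lengths[c] / total)) for c in chroms}
    drift = config.n_genes - sum(alloc.values())
    alloc[chroms[0]] += drift
    gid = 0
    for chrom in chroms:
        pos = int(rng.integers(2500, 6000))
        placed = 0
        while placed < alloc[chrom]:
            body_len = int(rng.integers(*config.gene_length))
            if pos + body_len + 2500 > lengths[chrom]:
                raise ConfigurationError(
                    f"cannot fit {config.n_genes} genes on this genome"
                )
            start, end = pos, pos + body_len
            strand = "+" if rng.random() < 0.5 else "-"
            n_cds = int(rng.integers(1, 4))
            cuts = np.sort(rng.integers(start + 50, end - 50, size=2 * n_cds))
            cds = tuple(
                (int(cuts[2 * j]), int(cuts[2 * j + 1]))
                for j in range(n_cds)
                if cuts[2 * j] < cuts[2 * j + 1]
            )
            if not cds:
                cds = ((start, end),)
            gid += 1
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, start, end, cds))
            placed += 1
            pos = end + int(rng.integers(4200, 6500))
    # TE placement
    regions = {
        c: [genic_region(g, lengths[c]) for g in genes if g.chrom == c] for c in chroms
    }
    classes = sorted(config.te_class_mix)
    probs = np.array([config.te_class_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    n_overlap = int(round(config.te_gene_overlap_fraction * config.n_tes))
    tes: list[TEModel] = []
    genic_genes = [g for g in genes]
    for i in range(config.n_tes):
        te_len = int(rng.integers(*config.te_length))
        te_class = str(rng.choice(classes, p=probs))
        if i < n_overlap:
            if not genic_genes:
                raise ConfigurationError("cannot place overlapping TEs without genes")
            g = genic_genes[int(rng.integers(len(genic_genes)))]
            lo = max(0, g.start - 1500)
            hi = min(lengths[g.chrom] - te_len, g.end + 1500)
            if hi <= lo:
                hi = lo + 1
            start = int(rng.integers(lo, hi))
            chrom = g.chrom
        else:
            for _ in range(1000):
                chrom = str(
                    rng.choice(chroms, p=[lengths[c] / total for c in chroms])
                )
                start = int(rng.integers(0, lengths[chrom] - te_len))
                if not any(
                    s < start + te_len and start < e for s, e in regions[chrom]
                ):
                    break
            else:
                raise ConfigurationError(
                    f"cannot place {config.n_tes} TEs outside genic regions"
                )
        tes.append(
            TEModel(f"TE{i + 1:04d}", chrom, start, min(start + te_len, lengths[chrom]), te_class)
        )
    return genes, tes


# ----------------------------------------------------------------- truth


def _planted_mls(delta: float, direction: str) -> tuple[float, float]:
    lo, hi = (1 - delta) / 2, (1 + delta) / 2
    return (lo, hi) if direction == "hyper" else (hi, lo)


def _find_run(pos: np.ndarray, anchor: int, min_sites: int, min_span: int, max_span: int):
    """Grow a site run rightwards from ``anchor`` until it has >= min_sites
    sites and spans >= min_span bp; reject when it would exceed max_span."""
    m = min_sites
    while anchor + m <= len(pos):
        span = int(pos[anchor + m - 1] - pos[anchor]) + 1
        if span > max_span:
            return None
        if span >= min_span:
            return anchor, anchor + m, span
        m += 1
    return None


class _Planner:
    """Bookkeeping for disjoint planted intervals (with a safety margin)."""

    def __init__(self, margin: int):
        self.margin = margin
        self.placed: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        return any(
            s - self.margin < end and start < e + self.margin
            for s, e in self.placed.get(chrom, [])
        )

    def add(self, chrom: str, start: int, end: int):
        self.placed.setdefault(chrom, []).append((start, end))


def gen_truth(
    genome: dict,
    genes: list[GeneModel],
    cytosines: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
) -> TruthTable:
    """Plan all planted features: random DMRs away from genic regions,
    promoter DMRs coupled to planted DEGs (negative and positive sign),
    free-standing DEGs, and DETs."""
    rng = rng or _rngs(config.seed)["truth"]
    planner = _Planner(config.dmr_margin)
    ctx_sites = {
        (chrom, ctx): sub["pos"].to_numpy()
        for (chrom, ctx), sub in cytosines.groupby(["chrom", "context"])
    }
    gene_spans = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append((g.start - 2500, g.end + 2500))
    dmr_rows, epireg_rows, deg_rows = [], [], []
    dmr_n = 0

    def plant_random(context: str) -> bool:
        nonlocal dmr_n
        chroms = sorted(genome)
        for _ in range(300):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = ctx_sites.get((chrom, context))
            if pos is None or len(pos) < config.dmr_min_sites:
                continue
            anchor = int(rng.integers(0, len(pos) - config.dmr_min_sites + 1))
            run = _find_run(
                pos, anchor, config.dmr_min_sites, config.dmr_min_span, config.dmr_max_span
            )
            if run is None:
                continue
            s, e = int(pos[run[0]]), int(pos[run[1] - 1]) + 1
            if planner.conflicts(chrom, s, e):
                continue
            if any(gs < e and s < ge for gs, ge in gene_spans.get(chrom, [])):
                continue  # keep random DMRs clear of genic regions
            direction = "hyper" if rng.random() < config.dmr_hyper_fraction else "hypo"
            ml_a, ml_b = _planted_mls(config.dmr_delta, direction)
            dmr_n += 1
            dmr_rows.append(
                {
                    "dmr_id": f"planted{dmr_n:03d}",
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "context": context,
                    "ml_a": ml_a,
                    "ml_b": ml_b,
                    "direction": direction,
                    "role": "random",
                }
            )
            planner.add(chrom, s, e)
            return True
        return False

    for context, n in sorted(config.n_dmrs.items()):
        if context not in CONTEXTS:
            raise ConfigurationError(f"unknown DMR context {context!r}")
        for _ in range(n):
            if not plant_random(context):
                raise ConfigurationError(
                    f"could not place a planted {context} DMR; genome too crowded"
                )

    # promoter couplings: hypermethylated promoter DMR + DEG of known direction
    candidates = list(genes)
    rng.shuffle(candidates)
    wanted = [("negative", "down")] * config.n_epiregs + [
        ("positive", "up")
    ] * config.n_positive_couplings
    placed = 0
    for sign, expr_dir in wanted:
        ok = False
        while candidates and not ok:
            g = candidates.pop()
            context = "CG" if rng.random() < 0.5 else "CHG"
            pos = ctx_sites.get((g.chrom, context))
            if pos is None:
                continue
            window = pos[(pos >= g.tss - 1500) & (pos <= g.tss + 1500)]
            if len(window) < config.dmr_min_sites:
                continue
            run = _find_run(
                window, 0, config.dmr_min_sites, config.dmr_min_span, config.dmr_max_span
            )
            if run is None:
                continue
            s, e = int(window[run[0]]), int(window[run[1] - 1]) + 1
            mid = (s + e) // 2
            if abs(mid - g.tss) > 1900 or planner.conflicts(g.chrom, s, e):
                continue
            ml_a, ml_b = _planted_mls(config.epireg_dmr_delta, "hyper")
            dmr_n += 1
            dmr_id = f"planted{dmr_n:03d}"
            dmr_rows.append(
                {
                    "dmr_id": dmr_id,
                    "chrom": g.chrom,
                    "start": s,
                    "end": e,
                    "context": context,
                    "ml_a": ml_a,
                    "ml_b": ml_b,
                    "direction": "hyper",
                    "role": "coupling",
                }
            )
            planner.add(g.chrom, s, e)
            lfc = config.epireg_log2fc if expr_dir == "up" else -config.epireg_log2fc
            deg_rows.append(
                {
                    "gene_id": g.id,
                    "log2fc": lfc,
                    "direction": expr_dir,
                    "role": "coupling",
                }
            )
            epireg_rows.append({"gene_id": g.id, "dmr_id": dmr_id, "sign": sign})
            ok = True
            placed += 1
    if placed < len(wanted):
        raise ConfigurationError(
            "could not place all promoter couplings; increase genome size"
        )

    # free-standing DEGs among the remaining genes
    if len(candidates) < config.n_degs:
        raise ConfigurationError("not enough genes left for planted DEGs")
    for g in candidates[: config.n_degs]:
        direction = "up" if rng.random() < 0.5 else "down"
        lfc = config.deg_log2fc if direction == "up" else -config.deg_log2fc
        deg_rows.append(
            {"gene_id": g.id, "log2fc": lfc, "direction": direction, "role": "free"}
        )

    truth = TruthTable(
        planted_dmrs=pd.DataFrame(
            dmr_rows,
            columns=[
                "dmr_id",
                "chrom",
                "start",
                "end",
                "context",
                "ml_a",
                "ml_b",
                "direction",
                "role",
            ],
        ),
        planted_degs=pd.DataFrame(
            deg_rows, columns=["gene_id", "log2fc", "direction", "role"]
        ),
        planted_dets=pd.DataFrame(columns=["te_id", "log2fc", "direction"]),
        planted_epiregs=pd.DataFrame(
            epireg_rows, columns=["gene_id", "dmr_id", "sign"]
        ),
        variance_components=dict(config.variance_components),
    )
    return truth


# ------------------------------------------------------------- methylome


def gen_methylome(
    genome: dict,
    cytosines: pd.DataFrame,
    truth: TruthTable,
    config: SimulationConfig,
    rng=None,
) -> dict:
    """Per-condition cytosine reports (first configured condition is the
    control; every other condition carries the planted deltas)."""
    rng = rng or _rngs(config.seed)["methylome"]
    err = 1.0 - config.conversion_rate
    ml_control = (
        cytosines["context"].map(config.baseline_ml).to_numpy(dtype=float)
    )
    ml_treat = ml_control.copy()
    chrom_arr = cytosines["chrom"].to_numpy()
    pos_arr = cytosines["pos"].to_numpy()
    ctx_arr = cytosines["context"].to_numpy()
    for _, d in truth.planted_dmrs.iterrows():
        mask = (
            (chrom_arr == d["chrom"])
            & (ctx_arr == d["context"])
            & (pos_arr >= d["start"])
            & (pos_arr < d["end"])
        )
        ml_control[mask] = d["ml_a"]
        ml_treat[mask] = d["ml_b"]
    if np.any(ml_control < 0) or np.any(ml_control > 1) or np.any(ml_treat > 1):
        raise ConfigurationError("planted delta pushes a true ML outside [0, 1]")
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    reports = {}
    for i, cond in enumerate(config.conditions):
        ml = ml_control if i == CONTROL_INDEX else ml_treat
        coverage = rng.negative_binomial(k, p_nb, size=len(ml))
        p_obs = ml + (1 - ml) * err
        meth = rng.binomial(coverage, p_obs)
        reports[cond] = pd.DataFrame(
            {
                "chrom": chrom_arr,
                "pos": pos_arr,
                "strand": cytosines["strand"].to_numpy(),
                "context": ctx_arr,
                "meth": meth,
                "total": coverage,
            }
        )
    return reports


# ------------------------------------------------------------ expression


def gen_expression(
    genes: list[GeneModel],
    tes: list[TEModel],
    truth: TruthTable,
    config: SimulationConfig,
    rng=None,
):
    """Count and FPKM matrices over LS/LL/HS/HL with planted DEGs and DETs.

    Planted fold-changes apply in the treatment condition
    (``config.conditions[1]``); all other conditions share the control mean.
    Returns (counts, fpkm, te_counts, samples, gene_lengths, te_lengths)
    and fills ``truth.planted_dets`` in place.
    """
    rng = rng or _rngs(config.seed)["expression"]
    all_conditions = ("LS", "LL", "HS", "HL")
    treat = config.conditions[1]
    gene_ids = [g.id for g in genes]
    gene_lengths = pd.Series({g.id: g.end - g.start for g in genes}, name="length")
    base = rng.lognormal(np.log(config.expr_base_mean), 1.2, size=len(genes))
    lfc = truth.planted_degs.set_index("gene_id")["log2fc"]
    planted = np.array([g in lfc.index for g in gene_ids])
    base[planted] = np.maximum(base[planted], config.deg_base_floor)
    fold = np.array([2.0 ** lfc.get(g, 0.0) for g in gene_ids])
    k = config.expr_dispersion
    samples, cols = [], {}
    for cond in all_conditions:
        mu = base * fold if cond == treat else base
        for r in range(1, config.n_replicates + 1):
            name = f"{cond}_{r}"
            cols[name] = rng.negative_binomial(k, k / (k + mu))
            samples.append({"sample": name, "condition": cond, "replicate": r})
    counts = pd.DataFrame(cols, index=gene_ids)
    samples = pd.DataFrame(samples)
    # library size is the design depth (expected control total), identical
    # across samples: column-sum normalisation on a few dozen genes would be
    # dominated by the planted fold-changes themselves (compositional bias)
    depth = float(base.sum())
    if depth <= 0:
        raise ConfigurationError("zero library size in generated expression data")
    libs = pd.Series(depth, index=counts.columns)
    samples["library_size"] = libs.to_numpy()
    fpkm = counts.div(gene_lengths / 1e3, axis=0).div(libs / 1e6, axis=1)
    # TEs: plant DETs on TEs free of gene-body overlap so they survive the filter
    te_lengths = pd.Series({t.id: t.end - t.start for t in tes}, name="length")
    gene_iv = {}
    for g in genes:
        gene_iv.setdefault(g.chrom, []).append((g.start, g.end))
    free = [
        t.id
        for t in tes
        if not any(s < t.end and t.start < e for s, e in gene_iv.get(t.chrom, []))
    ]
    if len(free) < config.n_dets:
        raise ConfigurationError("not enough gene-free TEs for planted DETs")
    det_ids = list(rng.choice(free, size=config.n_dets, replace=False))
    det_rows = []
    te_base = rng.lognormal(np.log(config.te_base_mean), 1.0, size=len(tes))
    te_fold = np.ones(len(tes))
    for tid in det_ids:
        i = [t.id for t in tes].index(tid)
        direction = "up" if rng.random() < 0.7 else "down"
        lfc_t = config.det_log2fc if direction == "up" else -config.det_log2fc
        te_fold[i] = 2.0**lfc_t
        det_rows.append({"te_id": tid, "log2fc": lfc_t, "direction": direction})
    te_cols = {}
    for cond in all_conditions:
        mu = te_base * te_fold if cond == treat else te_base
        for r in range(1, config.n_replicates + 1):
            te_cols[f"{cond}_{r}"] = rng.negative_binomial(k, k / (k + mu))
    te_counts = pd.DataFrame(te_cols, index=[t.id for t in tes])
    truth.planted_dets = pd.DataFrame(
        det_rows, columns=["te_id", "log2fc", "direction"]
    )
    return counts, fpkm, te_counts, samples, gene_lengths, te_lengths


# ------------------------------------------------------------- phenotype


def gen_phenotype(config: SimulationConfig, truth: TruthTable | None = None, rng=None):
    """Balanced field phenotype table generated on the arcsine scale as a sum
    of variance-component draws, then back-transformed to PNPF in [0, 1]."""
    rng = rng or _rngs(config.seed)["phenotype"]
    vc = dict(config.variance_components)
    a, b, v, r = (
        config.n_years,
        config.n_seasons,
        config.n_varieties,
        config.n_pheno_reps,
    )
    if min(a, b, v, r) < 1:
        raise ConfigurationError("phenotype design sizes must be positive")
    sd = {k: float(np.sqrt(val)) for k, val in vc.items()}
    years = [2010 + i for i in range(a)]
    seasons = ["spring", "early_autumn"][:b] or ["spring"]
    varieties = [f"ST{i + 1:03d}" for i in range(v)]
    e_year = {y: rng.normal(0, sd.get("year", 0)) for y in years}
    e_var = {k: rng.normal(0, sd.get("variety", 0)) for k in varieties}
    e_sy = {(y, s): rng.normal(0, sd.get("season_year", 0)) for y in years for s in seasons}
    e_yv = {
        (y, k): rng.normal(0, sd.get("year_variety", 0)) for y in years for k in varieties
    }
    e_syv = {
        (y, s, k): rng.normal(0, sd.get("season_year_variety", 0))
        for y in years
        for s in seasons
        for k in varieties
    }
    rows = []
    for y in years:
        for s in seasons:
            for k in varieties:
                mu = (
                    config.pheno_grand_mean
                    + e_year[y]
                    + e_var[k]
                    + e_sy[(y, s)]
                    + e_yv[(y, k)]
                    + e_syv[(y, s, k)]
                )
                eps = rng.normal(0, sd.get("residual", 0), size=r)
                for rep, e in enumerate(eps, start=1):
                    t = float(np.clip(mu + e, 0.0, np.pi / 2))
                    rows.append(
                        {
                            "accession": k,
                            "year": y,
                            "season": s,
                            "rep": rep,
                            "pnpf": float(np.sin(t) ** 2),
                        }
                    )
    return pd.DataFrame(rows)


def gen_incubator_phenotype(
    config: SimulationConfig,
    rng=None,
    n_varieties: int = 4,
    n_reps: int = 3,
    effects: dict | None = None,
):
    """Balanced variety x temperature x photoperiod PNPF table for the
    factorial decomposition, with configurable effect standard deviations on
    the arcsine scale."""
    rng = rng or _rngs(config.seed, names=("incubator",))["incubator"]
    eff = {
        "variety": 0.25,
        "temperature": 0.06,
        "photoperiod": 0.06,
        "interaction": 0.03,
        "residual": 0.05,
    }
    eff.update(effects or {})
    varieties = [f"V{i + 1}" for i in range(n_varieties)]
    temps = ["low", "high"]
    photos = ["short", "long"]
    e_v = {v: rng.normal(0, eff["variety"]) for v in varieties}
    e_t = {"low": eff["temperature"], "high": -eff["temperature"]}
    e_p = {"short": eff["photoperiod"], "long": -eff["photoperiod"]}
    e_i = {
        (v, t, p): rng.normal(0, eff["interaction"])
        for v in varieties
        for t in temps
        for p in photos
    }
    rows = []
    for v in varieties:
        for t in temps:
            for p in photos:
                mu = 0.6 + e_v[v] + e_t[t] + e_p[p] + e_i[(v, t, p)]
                for rep in range(1, n_reps + 1):
                    y = float(
                        np.clip(mu + rng.normal(0, eff["residual"]), 0.0, np.pi / 2)
                    )
                    rows.append(
                        {
                            "accession": v,
                            "temperature": t,
                            "photoperiod": p,
                            "rep": rep,
                            "pnpf": float(np.sin(y) ** 2),
                        }
                    )
    return pd.DataFrame(rows)


# ----------------------------------------------------------- orchestrator


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run every generator off one seed and return the full bundle."""
    config.validate()
    rngs = _rngs(config.seed)
    genome = gen_genome(config, rngs["genome"])
    genes, tes = gen_annotation(genome, config, rngs["annotation"])
    cytosines = enumerate_cytosines(genome)
    truth = gen_truth(genome, genes, cytosines, config, rngs["truth"])
    methylomes = gen_methylome(genome, cytosines, truth, config, rngs["methylome"])
    counts, fpkm, te_counts, samples, glen, tlen = gen_expression(
        genes, tes, truth, config, rngs["expression"]
    )
    phenotype = gen_phenotype(config, truth, rngs["phenotype"])
    truth.validate()
    return SimulationResult(
        config=config,
        genome=genome,
        genes=genes,
        tes=tes,
        cytosines=cytosines,
        methylomes=methylomes,
        counts=counts,
        fpkm=fpkm,
        te_counts=te_counts,
        samples=samples,
        gene_lengths=glen,
        te_lengths=tlen,
        phenotype=phenotype,
        truth=truth,
    )


def config_with(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """Copy a config (default-constructed when omitted) with overrides."""
    base = config or SimulationConfig()
    return replace(base, **overrides)
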