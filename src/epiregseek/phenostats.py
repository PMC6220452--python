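"""PNPF phenotype statistics: sex-type classification, seasonal-change
tests, and balanced fixed-effects ANOVA variance decompositions.

PNPF (proportion of nodes with pistillate flowers) is the femaleness
measure: the fraction of the first 25 main-stem nodes bearing a female
flower.  PNPF values are arcsine-square-root transformed before parametric
tests (asin(sqrt(p)), mapping [0, 1] onto [0, pi/2]).

Two ANOVA layouts are provided:

* ``nested_anova`` — the multi-year field design with Season nested in
  Year: sources Year, Variety, Season(Year), Year x Variety,
  Season(Year) x Variety, Residual;
* ``factorial_anova`` — the incubator experiment: a full three-way
  Variety x Temperature x Photoperiod decomposition.

Both assume balanced data and use classical sums of squares computed
directly from group means (on balanced designs all SS types coincide);
every term is tested against the residual mean square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SEX_TYPES = ("subandroecy", "normal monoecy", "gynoecy/subgynoecy")


def pnpf(node_records, max_node: int = 25) -> float | None:
    """Proportion of pistillate nodes among the first ``max_node`` nodes.

    ``node_records`` is an iterable of (node index starting at 1,
    is_pistillate) pairs.  Returns ``None`` for an empty record set.
    """
    records = list(node_records)
    if not records:
        return None
    n_pist = sum(1 for idx, pist in records if pist and idx <= max_node)
    return n_pist / max_node


def classify_sex_type(pnpf_spring: float) -> str:
    """Sex-type group from spring PNPF: subandroecy (< 0.25), normal
    monoecy (0.25 <= PNPF < 0.75), gynoecy/subgynoecy (>= 0.75)."""
    if not 0 <= pnpf_spring <= 1:
        raise ValueError(f"PNPF must be in [0, 1], got {pnpf_spring}")
    if pnpf_spring < 0.25:
        return "subandroecy"
    if pnpf_spring < 0.75:
        return "normal monoecy"
    return "gynoecy/subgynoecy"


def arcsine_transform(p):
    """asin(sqrt(p)); accepts scalars or arrays, domain [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("PNPF values must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


def seasonal_change_summary(
    table: pd.DataFrame,
    alpha: float = 0.05,
    decrease_threshold: float = 0.4,
    welch: bool = True,
    spring: str = "spring",
    autumn: str = "early_autumn",
) -> tuple[pd.DataFrame, dict]:
    """Per-accession spring-vs-autumn comparison and germplasm-level counts.

    ``table`` carries accession, season and pnpf columns (one row per
    observation).  The t-test (Welch by default) runs on arcsine-transformed
    values; means and the relative decrease (spring - autumn)/spring are on
    the raw PNPF scale.  Accessions with fewer than two observations in
    either season are flagged not testable.  The summary also reports the
    linear fit (slope, intercept, r) of autumn means on spring means.
    """
    rows = []
    for acc, sub in table.groupby("accession"):
        sp = sub.loc[sub["season"] == spring, "pnpf"].to_numpy()
        au = sub.loc[sub["season"] == autumn, "pnpf"].to_numpy()
        mean_sp = float(sp.mean()) if len(sp) else float("nan")
        mean_au = float(au.mean()) if len(au) else float("nan")
        testable = len(sp) >= 2 and len(au) >= 2
        if testable:
            t, p = stats.ttest_ind(
                arcsine_transform(sp), arcsine_transform(au), equal_var=not welch
            )
            p = float(p)
        else:
            p = float("nan")
        rel_dec = (mean_sp - mean_au) / mean_sp if mean_sp > 0 else float("nan")
        rows.append(
            {
                "accession": acc,
                "mean_spring": mean_sp,
                "mean_autumn": mean_au,
                "relative_decrease": rel_dec,
                "t_p": p,
                "testable": testable,
                "significant_decrease": testable and p < alpha and mean_au < mean_sp,
            }
        )
    per_acc = pd.DataFrame(rows)
    if len(per_acc) >= 2:
        fit = stats.linregress(per_acc["mean_spring"], per_acc["mean_autumn"])
    else:
        from types import SimpleNamespace

        fit = SimpleNamespace(slope=float("nan"), intercept=float("nan"), rvalue=float("nan"))
    summary = {
        "n_accessions": len(per_acc),
        "n_testable": int(per_acc["testable"].sum()),
        "n_significant_decrease": int(per_acc["significant_decrease"].sum()),
        "n_large_decrease": int(
            (per_acc["relative_decrease"] > decrease_threshold).sum()
        ),
        "fraction_significant_decrease": float(per_acc["significant_decrease"].mean()),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
    }
    return per_acc, summary


def _check_balance(table: pd.DataFrame, factors: list[str]) -> int:
    counts = table.groupby(factors, observed=True).size()
    full = 1
    for f in factors:
        full *= table[f].nunique()
    if len(counts) != full or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every "
            + " x ".join(factors)
            + " cell must be filled with the same number of replicates"
        )
    return int(counts.iloc[0])


def _ss(values: np.ndarray) -> float:
    return float(np.sum(values))


def nested_anova(
    field_table: pd.DataFrame,
    response: str = "pnpf",
    arcsine: bool = True,
    ms_decimals: int | None = None,
    tss_decimals: int | None = None,
) -> pd.DataFrame:
    """Field-design ANOVA with Season nested in Year.

    ``field_table`` needs year, season, variety (or accession) and response
    columns, balanced over year x season x variety with equal replication.
    Sources and df: Year (a-1), Variety (v-1), Season(Year) a(b-1),
    Year x Variety (a-1)(v-1), Season(Year) x Variety a(b-1)(v-1),
    Residual by subtraction.
    """
    t = field_table.rename(columns={"accession": "variety"}).copy()
    r = _check_balance(t, ["year", "season", "variety"])
    # seasons must be crossed identically within each year for the nested df
    y = arcsine_transform(t[response].to_numpy()) if arcsine else t[response].to_numpy()
    t = t.assign(_y=y)
    a = t["year"].nunique()
    b = t["season"].nunique()
    v = t["variety"].nunique()
    grand = t["_y"].mean()
    m_i = t.groupby("year")["_y"].mean()
    m_k = t.groupby("variety")["_y"].mean()
    m_ij = t.groupby(["year", "season"])["_y"].mean()
    m_ik = t.groupby(["year", "variety"])["_y"].mean()
    m_ijk = t.groupby(["year", "season", "variety"])["_y"].mean()
    ss_year = b * v * r * _ss((m_i - grand) ** 2)
    ss_var = a * b * r * _ss((m_k - grand) ** 2)
    ss_season = v * r * _ss((m_ij - m_ij.index.get_level_values("year").map(m_i)) ** 2)
    dev_ik = (
        m_ik
        - m_ik.index.get_level_values("year").map(m_i)
        - m_ik.index.get_level_values("variety").map(m_k)
        + grand
    )
    ss_yv = b * r * _ss(dev_ik**2)
    idx = m_ijk.index
    dev_ijk = (
        m_ijk.to_numpy()
        - m_ij.reindex(
            pd.MultiIndex.from_arrays(
                [idx.get_level_values("year"), idx.get_level_values("season")]
            )
        ).to_numpy()
        - m_ik.reindex(
            pd.MultiIndex.from_arrays(
                [idx.get_level_values("year"), idx.get_level_values("variety")]
            )
        ).to_numpy()
        + idx.get_level_values("year").map(m_i).to_numpy()
    )
    ss_sv = r * _ss(dev_ijk**2)
    cell_mean = t.groupby(["year", "season", "variety"])["_y"].transform("mean")
    ss_resid = _ss((t["_y"] - cell_mean) ** 2)
    n = len(t)
    rows = [
        ("Year", a - 1, ss_year),
        ("Variety", v - 1, ss_var),
        ("Season (Year)", a * (b - 1), ss_season),
        ("Year x Variety", (a - 1) * (v - 1), ss_yv),
        ("Season (Year) x Variety", a * (b - 1) * (v - 1), ss_sv),
        ("Residual", a * b * v * (r - 1), ss_resid),
    ]
    assert sum(df for _, df, _ in rows) == n - 1
    return finalize_table(rows, ms_decimals=ms_decimals, tss_decimals=tss_decimals)


def factorial_anova(
    incubator_table: pd.DataFrame,
    response: str = "pnpf",
    arcsine: bool = True,
    ms_decimals: int | None = None,
    tss_decimals: int | None = None,
) -> pd.DataFrame:
    """Full three-way Variety x Temperature x Photoperiod decomposition of
    the balanced incubator experiment."""
    t = incubator_table.rename(columns={"accession": "variety"}).copy()
    factors = ["variety", "temperature", "photoperiod"]
    r = _check_balance(t, factors)
    if r < 2:
        raise ValueError("need replicate observations per cell")
    y = arcsine_transform(t[response].to_numpy()) if arcsine else t[response].to_numpy()
    t = t.assign(_y=y)
    levels = {f: sorted(t[f].unique()) for f in factors}
    sizes = {f: len(levels[f]) for f in factors}
    n = len(t)
    grand = t["_y"].mean()
    main = {f: t.groupby(f)["_y"].mean() for f in factors}
    pair = {
        (f1, f2): t.groupby([f1, f2])["_y"].mean()
        for i, f1 in enumerate(factors)
        for f2 in factors[i + 1 :]
    }
    triple = t.groupby(factors)["_y"].mean()

    def ss_main(f):
        return (n // sizes[f]) * _ss((main[f] - grand) ** 2)

    def ss_pair(f1, f2):
        m = pair[(f1, f2)]
        dev = (
            m
            - m.index.get_level_values(f1).map(main[f1])
            - m.index.get_level_values(f2).map(main[f2])
            + grand
        )
        return (n // (sizes[f1] * sizes[f2])) * _ss(dev**2)

    # m_abc - m_ab - m_ac - m_bc + m_a + m_b + m_c - g
    idx = triple.index
    dev3 = triple.to_numpy().astype(float)
    for (f1, f2), m in pair.items():
        dev3 -= m.reindex(
            pd.MultiIndex.from_arrays(
                [idx.get_level_values(f1), idx.get_level_values(f2)]
            )
        ).to_numpy()
    for f in factors:
        dev3 += idx.get_level_values(f).map(main[f]).to_numpy()
    dev3 -= grand
    ss_vtp = r * _ss(dev3**2)
    cell_mean = t.groupby(factors)["_y"].transform("mean")
    ss_resid = _ss((t["_y"] - cell_mean) ** 2)
    dfv, dft, dfp = (sizes[f] - 1 for f in factors)
    rows = [
        ("Variety", dfv, ss_main("variety")),
        ("Temperature", dft, ss_main("temperature")),
        ("Photoperiod", dfp, ss_main("photoperiod")),
        ("Variety x Temp", dfv * dft, ss_pair("variety", "temperature")),
        ("Variety x Photo", dfv * dfp, ss_pair("variety", "photoperiod")),
        ("Temp x Photo", dft * dfp, ss_pair("temperature", "photoperiod")),
        ("Variety x Temp x Photo", dfv * dft * dfp, ss_vtp),
        ("Residual", n - sizes["variety"] * sizes["temperature"] * sizes["photoperiod"], ss_resid),
    ]
    assert sum(df for _, df, _ in rows) == n - 1
    return finalize_table(rows, ms_decimals=ms_decimals, tss_decimals=tss_decimals)


def finalize_table(
    rows: list[tuple[str, int, float]],
    total_ss: float | None = None,
    ms_decimals: int | None = None,
    tss_decimals: int | None = None,
) -> pd.DataFrame:
    """Assemble an ANOVA table from (source, df, SS) rows.

    Fills MS = SS/df, F against the Residual row (when present), p, the
    significance mark (** for p < 0.01) and TSS% = 100*SS/total SS.  The
    total SS defaults to the sum of the rows but can be supplied explicitly
    (useful when reproducing a printed table whose total differs from the
    component sum).  ``ms_decimals``/``tss_decimals`` round the MS and TSS%
    columns to a printed precision; ``None`` leaves them exact.  A Total row
    is appended.
    """
    if any(df <= 0 for _, df, _ in rows):
        raise ValueError("all df must be positive")
    if any(ss < 0 for _, _, ss in rows):
        raise ValueError("all SS must be non-negative")
    if total_ss is None:
        total_ss = sum(ss for _, _, ss in rows)
    if total_ss <= 0:
        tss_pct = [float("nan")] * len(rows)
    else:
        tss_pct = [100.0 * ss / total_ss for _, _, ss in rows]
    ms = [ss / df for _, df, ss in rows]
    resid_ms = None
    resid_df = None
    for (name, df, ss), m in zip(rows, ms):
        if name == "Residual":
            resid_ms, resid_df = m, df
    fvals, pvals, sig = [], [], []
    for (name, df, ss), m in zip(rows, ms):
        if resid_ms and resid_ms > 0 and name != "Residual":
            f = m / resid_ms
            p = float(stats.f.sf(f, df, resid_df))
        else:
            f, p = float("nan"), float("nan")
        fvals.append(f)
        pvals.append(p)
        sig.append("**" if p < 0.01 else "")
    if ms_decimals is not None:
        ms = [round(m, ms_decimals) for m in ms]
    if tss_decimals is not None:
        tss_pct = [round(x, tss_decimals) for x in tss_pct]
    out = pd.DataFrame(
        {
            "source": [name for name, _, _ in rows],
            "df": [df for _, df, _ in rows],
            "SS": [ss for _, _, ss in rows],
            "MS": ms,
            "F": fvals,
            "p": pvals,
            "sig": sig,
            "TSS_pct": tss_pct,
        }
    )
    total_row = pd.DataFrame(
        {
            "source": ["Total"],
            "df": [sum(df for _, df, _ in rows)],
            "SS": [total_ss],
            "MS": [float("nan")],
            "F": [float("nan")],
            "p": [float("nan")],
            "sig": [""],
            "TSS_pct": [float("nan")],
        }
    )
    return pd.concat([out, total_row], ignore_index=True)
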