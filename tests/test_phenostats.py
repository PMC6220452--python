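"""PNPF statistics: transformation, classification, seasonal tests and the
balanced ANOVA decompositions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiregseek.phenostats import (
    arcsine_transform,
    classify_sex_type,
    factorial_anova,
    finalize_table,
    nested_anova,
    pnpf,
    seasonal_change_summary,
)
from epiregseek.simulate import SimulationConfig, gen_incubator_phenotype, gen_phenotype


def test_pnpf_proportions():
    assert pnpf([(i, False) for i in range(1, 26)]) == 0.0
    assert pnpf([(i, True) for i in range(1, 26)]) == 1.0
    assert pnpf([(i, i <= 10) for i in range(1, 26)]) == pytest.approx(0.4)
    assert pnpf([]) is None


def test_sex_type_thresholds_are_lower_inclusive():
    assert classify_sex_type(0.10) == "subandroecy"
    assert classify_sex_type(0.25) == "normal monoecy"
    assert classify_sex_type(0.74) == "normal monoecy"
    assert classify_sex_type(0.75) == "gynoecy/subgynoecy"
    with pytest.raises(ValueError):
        classify_sex_type(1.2)


def test_arcsine_transform_closed_forms():
    assert arcsine_transform(0.0) == 0.0
    assert arcsine_transform(1.0) == pytest.approx(np.pi / 2)
    assert arcsine_transform(0.5) == pytest.approx(np.pi / 4)
    with pytest.raises(ValueError):
        arcsine_transform(-0.01)


@settings(derandomize=True, max_examples=100)
@given(
    st.floats(0, 1, allow_nan=False),
    st.floats(0, 1, allow_nan=False),
)
def test_arcsine_transform_monotone_onto_range(p, q):
    tp, tq = arcsine_transform(p), arcsine_transform(q)
    assert 0 <= tp <= np.pi / 2
    if p < q:
        assert tp < tq


# ---------------------------------------------------------------- seasonal


def _season_table(rows):
    return pd.DataFrame(rows, columns=["accession", "season", "pnpf"])


def test_identical_seasons_show_no_change():
    rows = [("a1", s, p) for s in ("spring", "early_autumn") for p in (0.4, 0.5, 0.45)]
    per_acc, summary = seasonal_change_summary(_season_table(rows))
    row = per_acc.iloc[0]
    assert row["relative_decrease"] == pytest.approx(0.0)
    assert not row["significant_decrease"]
    assert summary["n_significant_decrease"] == 0


def test_constructed_decrease_is_significant():
    rng = np.random.default_rng(0)
    rows = [("a1", "spring", p) for p in 0.6 + rng.normal(0, 0.005, 15)]
    rows += [("a1", "early_autumn", p) for p in 0.2 + rng.normal(0, 0.005, 15)]
    per_acc, summary = seasonal_change_summary(_season_table(rows))
    row = per_acc.iloc[0]
    assert row["significant_decrease"]
    assert row["relative_decrease"] == pytest.approx(2 / 3, abs=0.02)
    assert summary["n_large_decrease"] == 1


def test_singleton_season_flagged_not_testable():
    rows = [("a1", "spring", 0.5), ("a1", "early_autumn", 0.3)]
    per_acc, summary = seasonal_change_summary(_season_table(rows))
    assert not per_acc.iloc[0]["testable"]
    assert summary["n_testable"] == 0


def test_germplasm_significant_fraction_recovers_planted_share():
    """With 70% of accessions carrying a large true decrease and ample
    replication, the significant-decrease fraction lands within 5 points of
    the planted share (power ~ 1 for decreasers, ~ 0 for stable lines)."""
    rng = np.random.default_rng(17)
    n_acc, n_rep = 200, 15
    rows = []
    for i in range(n_acc):
        drops = i < int(0.7 * n_acc)
        base = rng.uniform(0.45, 0.65)
        autumn = base - 0.3 if drops else base
        rows += [(f"a{i}", "spring", np.clip(base + rng.normal(0, 0.05), 0, 1)) for _ in range(n_rep)]
        rows += [(f"a{i}", "early_autumn", np.clip(autumn + rng.normal(0, 0.05), 0, 1)) for _ in range(n_rep)]
    _, summary = seasonal_change_summary(_season_table(rows))
    assert summary["fraction_significant_decrease"] == pytest.approx(0.7, abs=0.05)
    assert -0.1 < summary["slope"] < 1.1  # autumn-on-spring fit is reported


# ------------------------------------------------------------------ ANOVA


def test_nested_anova_df_matches_field_design():
    """5 years x 2 seasons x 359 varieties gives the printed df column
    (4, 358, 5, 1432, 1790)."""
    cfg = SimulationConfig(seed=0, n_years=5, n_seasons=2, n_varieties=359, n_pheno_reps=3)
    table = nested_anova(gen_phenotype(cfg))
    df = table.set_index("source")["df"]
    assert df["Year"] == 4
    assert df["Variety"] == 358
    assert df["Season (Year)"] == 5
    assert df["Year x Variety"] == 1432
    assert df["Season (Year) x Variety"] == 1790
    assert df["Total"] == 10_769


def test_nested_anova_constant_response_gives_zero_ss():
    cfg = SimulationConfig(
        seed=0, n_years=2, n_varieties=4, n_pheno_reps=2,
        variance_components={k: 0.0 for k in ("year", "variety", "season_year", "year_variety", "season_year_variety", "residual")},
    )
    table = nested_anova(gen_phenotype(cfg))
    assert (table["SS"].abs() < 1e-12).all()


def test_nested_anova_matches_statsmodels_and_group_mean_oracle():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    cfg = SimulationConfig(seed=5, n_years=3, n_varieties=6, n_pheno_reps=2)
    pheno = gen_phenotype(cfg)
    mine = nested_anova(pheno).set_index("source")
    d = pheno.rename(columns={"accession": "variety"}).copy()
    d["y"] = arcsine_transform(d["pnpf"].to_numpy())
    fit = smf.ols(
        "y ~ C(year) + C(variety) + C(year):C(season) + C(year):C(variety)"
        " + C(year):C(season):C(variety)",
        data=d,
    ).fit()
    oracle = anova_lm(fit, typ=1)
    pairs = [
        ("Year", "C(year)"),
        ("Variety", "C(variety)"),
        ("Season (Year)", "C(year):C(season)"),
        ("Year x Variety", "C(year):C(variety)"),
        ("Season (Year) x Variety", "C(year):C(season):C(variety)"),
        ("Residual", "Residual"),
    ]
    for name, key in pairs:
        assert mine.loc[name, "SS"] == pytest.approx(oracle.loc[key, "sum_sq"], rel=1e-8)
    # additivity on the balanced design
    comp = mine.drop(index="Total")
    assert comp["SS"].sum() == pytest.approx(mine.loc["Total", "SS"], rel=1e-10)


def test_nested_anova_rejects_unbalanced_table():
    cfg = SimulationConfig(seed=1, n_years=2, n_varieties=3, n_pheno_reps=2)
    pheno = gen_phenotype(cfg).iloc[:-1]  # drop one observation
    with pytest.raises(ValueError):
        nested_anova(pheno)


def test_variety_variance_dominates_ss_share():
    cfg = SimulationConfig(
        seed=3, n_years=3, n_varieties=20, n_pheno_reps=3,
        variance_components={
            "year": 0.0005, "variety": 0.2, "season_year": 0.002,
            "year_variety": 0.0005, "season_year_variety": 0.0005, "residual": 0.0005,
        },
    )
    table = nested_anova(gen_phenotype(cfg)).set_index("source")
    shares = table["TSS_pct"].drop(index=["Total"])
    assert shares.idxmax() == "Variety" and shares["Variety"] > 60


def test_factorial_anova_df_and_additivity():
    inc = gen_incubator_phenotype(SimulationConfig(seed=2))
    table = factorial_anova(inc).set_index("source")
    assert table["df"].drop(index="Total").tolist() == [3, 1, 1, 3, 3, 1, 3, 32]
    comp = table.drop(index="Total")
    assert comp["SS"].sum() == pytest.approx(table.loc["Total", "SS"], rel=1e-10)


def test_factorial_anova_matches_statsmodels_oracle():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    inc = gen_incubator_phenotype(SimulationConfig(seed=4))
    mine = factorial_anova(inc).set_index("source")
    d = inc.rename(columns={"accession": "variety"}).copy()
    d["y"] = arcsine_transform(d["pnpf"].to_numpy())
    oracle = anova_lm(
        smf.ols("y ~ C(variety) * C(temperature) * C(photoperiod)", data=d).fit(),
        typ=1,
    )
    pairs = [
        ("Variety", "C(variety)"),
        ("Temperature", "C(temperature)"),
        ("Photoperiod", "C(photoperiod)"),
        ("Variety x Temp", "C(variety):C(temperature)"),
        ("Variety x Photo", "C(variety):C(photoperiod)"),
        ("Temp x Photo", "C(temperature):C(photoperiod)"),
        ("Variety x Temp x Photo", "C(variety):C(temperature):C(photoperiod)"),
        ("Residual", "Residual"),
    ]
    for name, key in pairs:
        assert mine.loc[name, "SS"] == pytest.approx(oracle.loc[key, "sum_sq"], rel=1e-8)


def test_pure_temperature_effect_dominates_factorial_table():
    inc = gen_incubator_phenotype(
        SimulationConfig(seed=6),
        effects={"variety": 0.0, "temperature": 0.3, "photoperiod": 0.0,
                 "interaction": 0.0, "residual": 0.01},
    )
    table = factorial_anova(inc).set_index("source")
    ss = table["SS"]
    assert ss["Temperature"] > 10 * max(
        ss["Variety"], ss["Photoperiod"], ss["Temp x Photo"]
    )


# --------------------------------------------------------------- printing


def test_finalize_table_reproduces_printed_field_cells():
    """The printed field-survey ANOVA arithmetic: MS = SS/df and
    TSS% = 100*SS/total at the table's printed precision."""
    rows = [
        ("Year", 4, 3.20),
        ("Variety", 358, 295.00),
        ("Season (Year)", 5, 202.00),
        ("Year x Variety", 1432, 55.66),
        ("Season (Year) x Variety", 1790, 68.74),
        ("Residual", 7180, 1.02),
    ]
    table = finalize_table(rows, total_ss=625.60, ms_decimals=3, tss_decimals=2)
    t = table.set_index("source")
    assert t.loc["Year", "MS"] == 0.800
    assert t.loc["Variety", "MS"] == 0.824
    assert t.loc["Season (Year) x Variety", "MS"] == 0.038
    assert t.loc["Residual", "MS"] == 0.000
    assert t.loc["Year", "TSS_pct"] == 0.51
    assert t.loc["Variety", "TSS_pct"] == 47.15
    assert t.loc["Season (Year)", "TSS_pct"] == 32.29
    assert t.loc["Year x Variety", "TSS_pct"] == 8.90
    assert t.loc["Season (Year) x Variety", "TSS_pct"] == 10.99
    assert t.loc["Residual", "TSS_pct"] == 0.16
    assert t.loc["Total", "df"] == 10_769


def test_finalize_table_reproduces_printed_incubator_ms_cells():
    rows = [
        ("Variety", 3, 7.274),
        ("Temperature", 1, 0.239),
        ("Photoperiod", 1, 0.340),
        ("Variety x Temp", 3, 0.344),
        ("Variety x Photo", 3, 0.215),
        ("Temp x Photo", 1, 0.046),
        ("Variety x Temp x Photo", 3, 0.031),
        ("Residual", 32, 0.113),
    ]
    t = finalize_table(rows, total_ss=25.377, ms_decimals=3, tss_decimals=3)
    t = t.set_index("source")
    assert t.loc["Variety", "MS"] == 2.425
    assert t.loc["Temperature", "MS"] == 0.239
    assert t.loc["Photoperiod", "MS"] == 0.340
    assert t.loc["Variety x Temp", "MS"] == 0.115
    assert t.loc["Variety x Photo", "MS"] == 0.072
    assert t.loc["Temp x Photo", "MS"] == 0.046
    assert t.loc["Variety x Temp x Photo", "MS"] == 0.010
    assert t.loc["Residual", "MS"] == 0.004


def test_finalize_table_edge_cases():
    t = finalize_table([("A", 2, 0.0), ("Residual", 4, 1.0)])
    t = t.set_index("source")
    assert t.loc["A", "MS"] == 0.0 and t.loc["A", "TSS_pct"] == 0.0
    with pytest.raises(ValueError):
        finalize_table([("A", 0, 1.0)])
    with pytest.raises(ValueError):
        finalize_table([("A", 2, -1.0)])
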