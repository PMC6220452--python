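"""DEG/DET calling, per-gene two-way ANOVA and the epiregulation screen."""

import numpy as np
import pandas as pd
import pytest

from epiregseek.expression import (
    call_degs,
    call_dets,
    deg_overlap,
    divergence_probability,
    epireg_screen,
    gene_anova,
    te_expression,
)
from epiregseek.features import GeneModel, TEModel


def sheet(conditions=("LS", "LL", "HS", "HL"), reps=3):
    rows = [
        {"sample": f"{c}_{r}", "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(rows)


def matrix(gene_rows, samples):
    return pd.DataFrame(gene_rows, columns=samples["sample"]).astype(float)


# ----------------------------------------------------------------- DEGs


def test_clear_separation_is_called_deg_up():
    s = sheet(("LS", "HL"))
    rng = np.random.default_rng(0)
    rows = {f"g{i}": rng.normal(20, 1, 6) for i in range(30)}
    rows["hit"] = np.array([10, 10.5, 9.5, 40, 41, 39])
    fpkm = pd.DataFrame(rows, index=s["sample"]).T
    degs = call_degs(fpkm, s, "LS", "HL")
    assert "hit" in set(degs["gene_id"])
    hit = degs.set_index("gene_id").loc["hit"]
    assert hit["direction"] == "up" and hit["prob"] >= 0.8


def test_subthreshold_fold_change_never_deg():
    s = sheet(("LS", "HL"))
    fpkm = pd.DataFrame(
        {"g": [10, 10, 10, 15, 15, 15]}, index=s["sample"]
    ).T.astype(float)
    tab = divergence_probability(fpkm, s, "LS", "HL")
    assert abs(tab.loc["g", "log2fc"]) < 1  # FC 1.5 < 2
    assert len(call_degs(fpkm, s, "LS", "HL")) == 0


def test_null_and_planted_recall_at_scale():
    """2000-gene simulation: few false DEGs under the null; planted 8-fold
    shifts on expressed genes recovered at >= 95%."""
    rng = np.random.default_rng(21)
    n_genes, n_planted = 2000, 100
    s = sheet(("LS", "HL"))
    base = rng.lognormal(np.log(200), 1.2, size=n_genes)
    planted_idx = rng.choice(np.nonzero(base > np.median(base))[0], n_planted, replace=False)
    fold = np.ones(n_genes)
    fold[planted_idx] = np.where(rng.random(n_planted) < 0.5, 8.0, 1 / 8.0)
    k = 80.0
    cols = {}
    for c, f in (("LS", np.ones(n_genes)), ("HL", fold)):
        for r in (1, 2, 3):
            cols[f"{c}_{r}"] = rng.negative_binomial(k, k / (k + base * f))
    fpkm = pd.DataFrame(cols).astype(float)
    fpkm.index = [f"g{i}" for i in range(n_genes)]
    degs = set(call_degs(fpkm, s, "LS", "HL")["gene_id"])
    planted = {f"g{i}" for i in planted_idx}
    false_positives = degs - planted
    recall = len(degs & planted) / n_planted
    assert recall >= 0.95
    assert len(false_positives) / (n_genes - n_planted) < 0.05


def test_deg_overlap_venn_partition():
    sets = {"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c", "e"}}
    venn = deg_overlap(sets)
    assert venn[("A", "B", "C")] == 1  # {c}
    assert venn[("A", "B")] == 1  # {b}
    assert venn[("C",)] == 1  # {e}
    same = deg_overlap({"A": {"x"}, "B": {"x"}})
    assert same[("A", "B")] == 1 and same[("A",)] == 0


# ---------------------------------------------------------------- ANOVA


def test_pure_temperature_gene_flags_only_temperature():
    s = sheet()
    rng = np.random.default_rng(2)
    means = {"LS": 10, "LL": 10, "HS": 40, "HL": 40}
    row = np.concatenate(
        [means[c] + rng.normal(0, 0.01, 3) for c in ("LS", "LL", "HS", "HL")]
    )
    fpkm = pd.DataFrame([row], columns=s["sample"], index=["g"])
    pvals, counts = gene_anova(fpkm, s)
    assert pvals.loc["g", "p_temperature"] < 1e-6
    assert pvals.loc["g", "p_photoperiod"] > 0.05
    assert pvals.loc["g", "p_interaction"] > 0.05
    assert counts == {"temperature": 1, "photoperiod": 0, "interaction": 0}


def test_interaction_only_gene_flags_interaction():
    s = sheet()
    rng = np.random.default_rng(3)
    means = {"LS": 10, "LL": 40, "HS": 40, "HL": 10}  # pure interaction pattern
    row = np.concatenate(
        [means[c] + rng.normal(0, 0.01, 3) for c in ("LS", "LL", "HS", "HL")]
    )
    fpkm = pd.DataFrame([row], columns=s["sample"], index=["g"])
    pvals, _ = gene_anova(fpkm, s)
    assert pvals.loc["g", "p_interaction"] < 1e-6
    assert pvals.loc["g", "p_temperature"] > 0.05


def test_gene_anova_matches_statsmodels_oracle():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    s = sheet()
    rng = np.random.default_rng(4)
    fpkm = pd.DataFrame(
        rng.lognormal(3, 0.5, size=(5, 12)), columns=s["sample"],
        index=[f"g{i}" for i in range(5)],
    )
    pvals, _ = gene_anova(fpkm, s)
    for g in fpkm.index:
        d = pd.DataFrame(
            {
                "y": np.log2(fpkm.loc[g] + 1).to_numpy(),
                "t": s["condition"].str[0],
                "p": s["condition"].str[1],
            }
        )
        table = anova_lm(smf.ols("y ~ C(t) * C(p)", data=d).fit(), typ=1)
        assert pvals.loc[g, "p_temperature"] == pytest.approx(table.loc["C(t)", "PR(>F)"])
        assert pvals.loc[g, "p_photoperiod"] == pytest.approx(table.loc["C(p)", "PR(>F)"])
        assert pvals.loc[g, "p_interaction"] == pytest.approx(
            table.loc["C(t):C(p)", "PR(>F)"]
        )


def test_gene_anova_null_type_one_error_near_alpha():
    s = sheet()
    rng = np.random.default_rng(5)
    n = 2000
    fpkm = pd.DataFrame(
        rng.lognormal(3, 0.4, size=(n, 12)), columns=s["sample"],
        index=[f"g{i}" for i in range(n)],
    )
    _, counts = gene_anova(fpkm, s, alpha=0.05)
    for term, c in counts.items():
        # binomial(2000, 0.05): mean 100, sd ~9.7; allow ~4 sd
        assert 60 <= c <= 140, f"{term}: {c}"


# --------------------------------------------------------------- TE FPKM


def test_te_fpkm_unit_case_and_scaling():
    counts = pd.DataFrame({"s1": [100, 0]}, index=["t1", "t2"])
    lengths = pd.Series({"t1": 1000, "t2": 500})
    out = te_expression(counts, lengths, pd.Series({"s1": 1_000_000}))
    assert out.loc["t1", "s1"] == pytest.approx(100.0)
    assert out.loc["t2", "s1"] == 0.0
    doubled = te_expression(counts, lengths, pd.Series({"s1": 2_000_000}))
    assert doubled.loc["t1", "s1"] == pytest.approx(50.0)
    with pytest.raises(ValueError):
        te_expression(counts, pd.Series({"t1": 0, "t2": 500}), pd.Series({"s1": 1e6}))
    with pytest.raises(ValueError):
        te_expression(counts, lengths, pd.Series({"s1": 0}))


# ------------------------------------------------------------------ DETs


def test_gene_overlapping_te_is_discarded():
    s = sheet(("LS", "HL"))
    genes = [GeneModel("g1", "chr1", "+", 1000, 3000)]
    tes = [
        TEModel("in_gene", "chr1", 2000, 2500, "LTR"),
        TEModel("free", "chr1", 50_000, 50_500, "LTR"),
    ]
    counts = pd.DataFrame(
        {f"{c}_{r}": [1000, 1000] for c in ("LS", "HL") for r in (1, 2, 3)},
        index=["in_gene", "free"],
    )
    counts.loc["in_gene", ["HL_1", "HL_2", "HL_3"]] = 100_000  # huge shift
    dets = call_dets(counts, s, "LS", "HL", genes, tes)
    assert "in_gene" not in set(dets["te_id"])


def test_equal_counts_are_not_dets():
    s = sheet(("LS", "HL"))
    tes = [TEModel(f"t{i}", "chr1", 10_000 * i, 10_000 * i + 500, "LTR") for i in range(5)]
    counts = pd.DataFrame(
        {f"{c}_{r}": [200] * 5 for c in ("LS", "HL") for r in (1, 2, 3)},
        index=[t.id for t in tes],
    )
    assert len(call_dets(counts, s, "LS", "HL", [], tes)) == 0


def test_planted_te_shift_recovered_as_det(sim):
    dets = call_dets(
        sim.te_counts, sim.samples, "LS", "HL", sim.genes, sim.tes
    )
    planted = set(sim.truth.planted_dets["te_id"])
    assert planted <= set(dets["te_id"])


# ---------------------------------------------------------------- epireg


def _screen_fixture():
    genes = [
        GeneModel("gene1", "chr1", "+", 10_000, 14_000, ((10_500, 12_000),)),
        GeneModel("gene2", "chr1", "+", 30_000, 34_000, ((30_500, 32_000),)),
    ]
    dmrs = pd.DataFrame(
        [
            # hyper CHG DMR 500 bp upstream of gene1's TSS
            ("d1", "chr1", 9_400, 9_600, "CHG", "hyper"),
            # hyper CG DMR inside gene2's CDS
            ("d2", "chr1", 31_000, 31_200, "CG", "hyper"),
            # CHH DMRs are never eligible
            ("d3", "chr1", 9_400, 9_600, "CHH", "hyper"),
            # second (hypo) DMR near gene1, downstream of its TES
            ("d4", "chr1", 14_500, 14_700, "CG", "hypo"),
        ],
        columns=["dmr_id", "chrom", "start", "end", "context", "direction"],
    )
    degs = pd.DataFrame(
        {"gene_id": ["gene1", "gene2"], "direction": ["down", "up"]}
    )
    return dmrs, degs, genes


def test_epireg_sign_rule_and_context_filter():
    dmrs, degs, genes = _screen_fixture()
    events, putative, summary = epireg_screen(dmrs, degs, genes)
    by_dmr = events.set_index("dmr_id")
    assert by_dmr.loc["d1", "sign"] == "negative"  # hyper + down
    assert by_dmr.loc["d1", "region"] == "within-2kb-of-TSS"
    assert by_dmr.loc["d2", "sign"] == "positive"  # hyper + up -> discarded
    assert "d3" not in by_dmr.index  # CHH filtered, not an error
    assert "gene2" not in putative
    # d4 is hypo while gene1 is down: concordant, hence also positive
    assert by_dmr.loc["d4", "sign"] == "positive"
    assert summary["n_events"] == 3
    assert summary["fraction_positive"] == pytest.approx(2 / 3)


def test_gene_with_two_negative_dmrs_deduplicated_in_putative_list():
    dmrs, degs, genes = _screen_fixture()
    events, putative, _ = epireg_screen(dmrs, degs, genes)
    gene1_events = events[events["gene_id"] == "gene1"]
    # d4 is hypo and gene1 is down -> positive; flip gene1 to up instead
    degs2 = degs.copy()
    degs2.loc[degs2["gene_id"] == "gene1", "direction"] = "up"
    events2, putative2, _ = epireg_screen(
        dmrs[dmrs["dmr_id"].isin(["d1", "d4"])], degs2, genes
    )
    # d1 hyper+up = positive; d4 hypo+up = negative
    assert set(events2["sign"]) == {"positive", "negative"}
    assert putative2 == ["gene1"]
    assert len(gene1_events) == 2  # once per event, once in the gene list


def test_epireg_recovery_on_simulation(sim, sim_dmrs):
    """Planted promoter-hypermethylation/down-regulation couplings come back
    as negative associations; planted concordant couplings never enter the
    putative list."""
    from epiregseek.dmr import dmrs_to_frame

    degs = call_degs(sim.fpkm, sim.samples, "LS", "HL")
    frame = dmrs_to_frame(sim_dmrs["CG"] + sim_dmrs["CHG"])
    _, putative, _ = epireg_screen(frame, degs, sim.genes)
    truth = sim.truth.planted_epiregs
    neg = set(truth.loc[truth["sign"] == "negative", "gene_id"])
    pos = set(truth.loc[truth["sign"] == "positive", "gene_id"])
    assert len(neg & set(putative)) / len(neg) >= 0.9
    assert not (pos & set(putative))
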