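"""Splice-ratio statistic, IC filtering cascade, normalization, and the
paired group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from medlsm import annotation as ann
from medlsm import simulate as sim
from medlsm import splicing as spl


def _count_matrix(counts: dict, time_points, libs=None, mode="whole_gene"):
    df = pd.DataFrame(counts).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    samples = pd.DataFrame(
        {
            "time_point": time_points,
            "time_label": [f"{t}h" for t in time_points],
            "batch": ["B1"] * len(time_points),
            "library_size": libs or [float(df[c].sum()) for c in df.columns],
        },
        index=pd.Index(df.columns, name="sample"),
    )
    return spl.CountMatrix(mode=mode, counts=df, samples=samples)


# ------------------------------------------------------------- splice ratio


@pytest.mark.parametrize(
    "E,G,Le,Li,expected",
    [
        (100, 100, 800, 100, 1.0),       # no intron reads: fully spliced
        (80, 90, 800, 100, 0.0),         # equal densities: unspliced
        (80, 85, 800, 100, 0.5),         # I=5: 1 - (5/100)/(80/800)
        (10, 200, 100, 100, 0.0),        # clamped at 0
    ],
)
def test_splice_ratio_values(E, G, Le, Li, expected):
    assert spl.splice_ratio(E, G, Le, Li) == pytest.approx(expected)


def test_splice_ratio_undefined_when_no_exon_reads():
    assert np.isnan(spl.splice_ratio(0, 5, 800, 100))


def test_splice_ratio_rejects_nonpositive_lengths():
    with pytest.raises(ValueError):
        spl.splice_ratio(10, 12, 0, 100)


@given(st.integers(min_value=1, max_value=500),
       st.lists(st.integers(min_value=0, max_value=300), min_size=2,
                max_size=8))
@settings(deadline=None, max_examples=100)
def test_splice_ratio_monotone_non_increasing_in_intron_reads(E, intron_counts):
    intron_counts = sorted(intron_counts)
    ratios = [spl.splice_ratio(E, E + I, 800, 150) for I in intron_counts]
    assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))


# ------------------------------------------------------------ IC filtering


def _toy_annotation():
    genes = []
    spec = {
        # gid: (intron_length, )
        "ok1": 100, "ok2": 200, "ok3": 60, "ok4": 30,
        "short1": 20, "short2": 10,
        "low1": 100, "low2": 100, "low3": 100,
        "hcr1": 100,
    }
    x = 1000
    for gid, ilen in spec.items():
        exons = [(x, x + 200), (x + 200 + ilen, x + 800 + ilen)]
        genes.append(ann.Gene(id=gid, name=gid, chrom="chr1", strand="+",
                              cds_start=x, cds_end=exons[-1][1], exons=exons))
        x += 3000
    return ann.GenomeAnnotation(chromosomes={"chr1": 50_000}, genes=genes)


def test_filter_cascade_on_planted_violations():
    """10 genes: 2 short-intron, 3 low-count, 1 HCR -> 4 retained."""
    annot = _toy_annotation()
    counts = {g.id: [100, 120] for g in annot.genes}
    for gid in ("low1", "low2", "low3"):
        counts[gid] = [100, 50]  # below 75 in one sample
    cm = _count_matrix(counts, [0, 1])
    retained, audit = spl.filter_ic_genes(annot, cm, hcr_genes={"hcr1"})
    assert sorted(retained) == ["ok1", "ok2", "ok3", "ok4"]
    reasons = audit.loc[~audit["retained"], "reason"]
    assert (reasons.loc[["short1", "short2"]] == "intron_too_short").all()
    assert (reasons.loc[["low1", "low2", "low3"]] == "low_counts").all()
    assert reasons.loc["hcr1"] == "hcr_associated"


def test_zero_intron_reads_do_not_disqualify():
    """A well-covered gene with no intron reads anywhere is retained."""
    annot = _toy_annotation()
    counts = {g.id: [80, 80] for g in annot.genes}
    cm = _count_matrix(counts, [0, 1])
    retained, _ = spl.filter_ic_genes(annot, cm)
    assert "ok1" in retained  # G = E is allowed; only G >= 75 matters


def test_filter_audit_partitions_with_one_reason_each():
    annot = _toy_annotation()
    counts = {g.id: [100, 100] for g in annot.genes}
    cm = _count_matrix(counts, [0, 1])
    retained, audit = spl.filter_ic_genes(annot, cm, hcr_genes={"hcr1"})
    assert len(retained) + (~audit["retained"]).sum() == len(annot)
    assert audit.loc[~audit["retained"], "reason"].notna().all()
    assert audit.loc[audit["retained"], "reason"].isna().all()


# ---------------------------------------------------------- normalization


def test_equal_libraries_unchanged():
    cm = _count_matrix({"a": [10, 10]}, [0, 1], libs=[1e6, 1e6])
    out = spl.normalize_libraries(cm)
    assert out.counts.equals(cm.counts * 1.0)


def test_normalization_scale_factors():
    cm = _count_matrix({"a": [100, 100]}, [0, 1], libs=[1e6, 2e6])
    out = spl.normalize_libraries(cm)
    assert out.counts.iloc[0, 0] == pytest.approx(150.0)  # x1.5
    assert out.counts.iloc[0, 1] == pytest.approx(75.0)   # x0.75
    assert (out.samples["library_size"] == 1.5e6).all()


def test_zero_library_is_an_error():
    cm = _count_matrix({"a": [1, 1]}, [0, 1], libs=[0.0, 1e6])
    with pytest.raises(ValueError):
        spl.normalize_libraries(cm)


# ----------------------------------------------------- expression summary


def test_expression_summary_averages_replicates():
    cm = _count_matrix({"a": [10, 20, 7]}, [0, 0, 1])
    out = spl.expression_summary(cm)
    assert out.loc["a", 0] == 15.0
    assert out.loc["a", 1] == 7.0


def test_balanced_design_grand_mean_identity():
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 100, size=8).tolist()
    cm = _count_matrix({"a": vals}, [0, 0, 1, 1, 2, 2, 3, 3])
    out = spl.expression_summary(cm)
    assert out.loc["a"].mean() == pytest.approx(np.mean(vals))


# -------------------------------------------------------- group comparison


def _values(data):
    return pd.DataFrame(data, columns=[0, 3]).rename_axis("gene_id")


def test_identical_timepoints_give_t0_p1():
    vals = _values({0: [0.5, 0.6, 0.7, 0.8], 3: [0.5, 0.6, 0.7, 0.8]})
    vals.index = [f"g{i}" for i in range(4)]
    res = spl.compare_groups(vals, {g: "x" for g in vals.index}, 0, 3)
    assert res["x"].t_statistic == 0.0
    assert res["x"].p_value == 1.0


def test_constant_nonzero_shift_is_degenerate():
    vals = _values({0: [0.5] * 5, 3: [0.6] * 5})
    vals.index = [f"g{i}" for i in range(5)]
    res = spl.compare_groups(vals, {g: "x" for g in vals.index}, 0, 3)
    assert res["x"].degenerate
    assert np.isinf(res["x"].t_statistic)


def test_t_statistic_matches_textbook_formula():
    a = np.array([0.90, 0.85, 0.88, 0.92, 0.80, 0.86])
    b = np.array([0.80, 0.79, 0.81, 0.85, 0.70, 0.82])
    vals = pd.DataFrame({0: a, 3: b}, index=[f"g{i}" for i in range(6)])
    res = spl.compare_groups(vals, {g: "x" for g in vals.index}, 0, 3)
    d = b - a
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert res["x"].t_statistic == pytest.approx(t_hand, abs=1e-12)


def test_small_group_is_flagged_not_tested():
    vals = _values({0: [0.5, 0.6], 3: [0.4, 0.5]})
    vals.index = ["g0", "g1"]
    res = spl.compare_groups(vals, {g: "x" for g in vals.index}, 0, 3)
    assert res["x"].warning is not None
    assert np.isnan(res["x"].p_value)


def test_planted_drop_detected_only_in_co_occupied_group():
    annot, truth = sim.make_genome(
        n_genes=150, frac_ic=1.0, seed=1009,
        group_sizes={"co_occupied": 72, "neither": 45,
                     "lsm3_only": 17, "mediator_only": 7},
    )
    whole, exon = sim.simulate_rnaseq_counts(annot, truth, seed=2009)
    retained, _ = spl.filter_ic_genes(annot, whole)
    ratios = spl.splice_ratio_by_timepoint(
        spl.splice_table(annot, whole, exon, gene_ids=retained)
    )
    groups = {g: truth.table.loc[g, "group"] for g in retained}
    res = spl.compare_groups(ratios, groups, t0=0, t1=3)
    assert res["co_occupied"].p_value < 0.01
    assert res["neither"].p_value > 0.01


def test_paired_matrix_validation_clamps_deficits(caplog):
    whole = _count_matrix({"a": [5, 5]}, [0, 1], mode="whole_gene")
    exon = _count_matrix({"a": [7, 5]}, [0, 1], mode="exon_only")
    w2, _ = spl.validate_paired(whole, exon)
    assert w2.counts.loc["a", "s0"] == 7
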