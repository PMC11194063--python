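"""Metagene matrices, summit offsets, clustering, transition index."""

import numpy as np
import pandas as pd
import pytest

from medlsm import annotation as ann
from medlsm import profiles as prof
from medlsm import simulate as sim
from medlsm.chip import CoverageTrack


def _gene(gid, start, end, strand="+", exons=None, chrom="chr1"):
    return ann.Gene(id=gid, name=gid, chrom=chrom, strand=strand,
                    cds_start=start, cds_end=end,
                    exons=exons or [(start, end)])


def _track(values, bin_size=10, library=1e6):
    return CoverageTrack("s", bin_size,
                         {"chr1": np.asarray(values, float)}, library)


def test_uniform_coverage_gives_constant_matrix():
    t = _track(np.full(2000, 7.0))  # CPM identity at library 1e6
    genes = [_gene("a", 5000, 8000), _gene("b", 9000, 12_000, "-")]
    m = prof.metagene_matrix(t, genes, "cds_start", window=(-1000, 1000))
    assert np.allclose(m.values, 7.0)


def test_scaled_body_indicator_geometry():
    v = np.zeros(2000)
    v[500:800] = 1.0  # exactly the CDS [5000, 8000)
    t = _track(v)
    m = prof.metagene_matrix(t, [_gene("a", 5000, 8000)], "scaled_body",
                             flank=500, body_bins=100)
    fb = m.flank_bins
    row = m.values[0]
    assert np.allclose(row[:fb], 0.0)
    assert np.allclose(row[fb : fb + 100], 1.0)
    assert np.allclose(row[fb + 100 :], 0.0)


def test_minus_strand_bump_appears_downstream_on_oriented_axis():
    """A bump 250 bp genomically LEFT of a minus-strand gene's last-intron
    3' end shows up at +250 on the oriented axis."""
    g = _gene("a", 5000, 8000, "-", exons=[(5000, 6800), (7000, 8000)])
    anchor = 6800  # leftmost intron boundary = 3'-most splice site
    v = np.zeros(2000)
    v[(anchor - 250) // 10] = 100.0
    m = prof.metagene_matrix(_track(v), [g], "last_intron_3prime_end",
                             window=(-500, 1000))
    col = int(np.argmax(m.values[0]))
    assert m.offsets[col] == 250


def test_scaled_body_resampling_conserves_total_signal():
    rng = np.random.default_rng(0)
    v = rng.gamma(2.0, 1.0, 2000)
    g = _gene("a", 5130, 7890)
    m = prof.metagene_matrix(_track(v), [g], "scaled_body",
                             flank=0, body_bins=100)
    b0, b1 = 513, 789
    original = v[b0:b1].sum()
    resampled = m.values[0].sum() * (b1 - b0) / 100
    assert resampled == pytest.approx(original, rel=1e-9)


def test_summit_offset_zero_for_bump_at_anchor():
    g = _gene("a", 5000, 8000, exons=[(5000, 6000), (6500, 8000)])
    v = np.zeros(2000)
    v[650] = 50.0  # exactly at the last-intron 3' end (6500)
    m = prof.metagene_matrix(_track(v), [g], "last_intron_3prime_end",
                             window=(-500, 1000))
    assert prof.summit_offset(m, smooth_bins=1) == 0


def test_summit_offset_flat_profile_is_an_error():
    m = prof.metagene_matrix(_track(np.ones(2000)), [_gene("a", 5000, 8000)],
                             "cds_end", window=(-500, 500))
    with pytest.raises(ValueError, match="flat"):
        prof.summit_offset(m)


def test_summit_offset_is_strand_symmetric():
    """Mirroring the genome and flipping strands leaves the offset unchanged."""
    L = 20_000
    g = _gene("a", 5000, 8000, "+", exons=[(5000, 6000), (6500, 8000)])
    v = np.zeros(L // 10)
    v[(6500 + 250) // 10] = 50.0
    m = prof.metagene_matrix(_track(v), [g], "last_intron_3prime_end",
                             window=(-500, 1000))
    g_m = _gene("a", L - 8000, L - 5000, "-",
                exons=[(L - 8000, L - 6500), (L - 6000, L - 5000)])
    v_m = np.zeros(L // 10)
    v_m[(L - (6500 + 250)) // 10] = 50.0
    m_m = prof.metagene_matrix(_track(v_m), [g_m], "last_intron_3prime_end",
                               window=(-500, 1000))
    assert prof.summit_offset(m, smooth_bins=1) == \
        prof.summit_offset(m_m, smooth_bins=1)


def test_summit_offset_recovers_planted_cohort_truth():
    """50 genes, three replicates: estimate within 20 bp of the planted 250."""
    annot, truth = sim.make_genome(n_genes=50, frac_ic=1.0, seed=11,
                                   group_sizes={"co_occupied": 50})
    tracks, _ = sim.simulate_chip_coverage(annot, truth, time_point=3,
                                           n_replicates=3, seed=13)
    ic = [g for g in annot.genes if g.is_ic]
    pooled = prof.pool_rows([
        prof.metagene_matrix(tr, ic, "last_intron_3prime_end",
                             window=(-500, 1000))
        for tr in tracks
    ])
    assert abs(prof.summit_offset(pooled) - 250) <= 20


def test_summit_offset_converges_with_amplitude():
    """Error shrinks as the planted bump dominates the noise."""
    annot, truth = sim.make_genome(n_genes=30, frac_ic=1.0, seed=17,
                                   group_sizes={"co_occupied": 30})
    errors = []
    for scale in (0.25, 1.0, 8.0):
        t2 = sim.SimTruth(table=truth.table.copy(), seed=truth.seed)
        t2.table["lsm3_amp"] = truth.table["lsm3_amp"] * scale
        tracks, _ = sim.simulate_chip_coverage(annot, t2, time_point=0,
                                               n_replicates=1, seed=19,
                                               factor="lsm3")
        ic = [g for g in annot.genes if g.is_ic]
        m = prof.metagene_matrix(tracks[0], ic, "last_intron_3prime_end",
                                 window=(-500, 1000))
        errors.append(abs(prof.summit_offset(m) - 250))
    assert errors[-1] <= 20
    assert errors[-1] <= errors[0]


def test_intronless_genes_are_excluded_from_intron_anchor():
    t = _track(np.ones(2000))
    genes = [_gene("a", 5000, 8000, exons=[(5000, 6000), (6500, 8000)]),
             _gene("b", 10_000, 11_000)]
    m = prof.metagene_matrix(t, genes, "last_intron_3prime_end",
                             window=(-500, 500))
    assert m.gene_ids == ["a"]


# ------------------------------------------------------------------ k-means


def test_kmeans_k1_closed_form():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(40, 5)),
                     index=[f"g{i}" for i in range(40)])
    res = prof.kmeans_cluster(X, k=1, seed=0)
    assert np.allclose(res.centroids[0], X.mean(axis=0))
    assert res.inertia == pytest.approx(
        ((X - X.mean(axis=0)) ** 2).to_numpy().sum()
    )


def test_kmeans_separates_planted_blobs():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.1, size=(30, 4))
    b = rng.normal(10, 0.1, size=(30, 4))
    X = pd.DataFrame(np.vstack([a, b]),
                     index=[f"g{i}" for i in range(60)])
    res = prof.kmeans_cluster(X, k=2, seed=0)
    labels = res.assignments.to_numpy()
    assert len(set(labels[:30])) == 1
    assert len(set(labels[30:])) == 1
    assert labels[0] != labels[-1]


def test_kmeans_deterministic_given_seed():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(50, 6)))
    r1 = prof.kmeans_cluster(X, k=4, seed=9)
    r2 = prof.kmeans_cluster(X, k=4, seed=9)
    assert r1.assignments.equals(r2.assignments)


def test_kmeans_inertia_non_increasing_in_k():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(60, 6)))
    inertias = [prof.kmeans_cluster(X, k=k, seed=0).inertia
                for k in range(1, 7)]
    assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))


def test_kmeans_k_larger_than_n_is_an_error():
    X = pd.DataFrame(np.zeros((3, 2)))
    with pytest.raises(ValueError):
        prof.kmeans_cluster(X, k=5)


# ---------------------------------------------------------- transition index


def test_transition_index_zero_for_equal_windows():
    p = pd.DataFrame({0: [2.0, 3.0]}, index=["a", "b"])
    idx, med = prof.transition_index(p, p.copy())
    assert np.allclose(idx.to_numpy(), 0.0)
    assert med.iloc[0] == 0.0


def test_transition_index_log2_arithmetic():
    p = pd.DataFrame({0: [1000.0]}, index=["a"])
    q = pd.DataFrame({0: [4000.0]}, index=["a"])
    idx, _ = prof.transition_index(p, q, pseudocount=1e-9)
    assert idx.iloc[0, 0] == pytest.approx(2.0, abs=1e-6)


def test_transition_index_increases_across_schedule():
    """Promoter-decreasing / 3'-increasing schedule yields a strictly
    increasing cohort median index."""
    annot, truth = sim.make_genome(n_genes=60, frac_ic=1.0, seed=23,
                                   group_sizes={"co_occupied": 50})
    co = annot.subset(truth.genes_in_group("co_occupied"))
    prom, three = {}, {}
    for t in range(4):
        tracks, _ = sim.simulate_chip_coverage(annot, truth, time_point=t,
                                               n_replicates=1, seed=29 + t)
        prom[t] = prof.anchored_window_mean(tracks[0], co, "cds_start",
                                            prof.PROMOTER_WINDOW)
        three[t] = prof.anchored_window_mean(tracks[0], co, "cds_end",
                                             prof.THREEPRIME_WINDOW)
    _, med = prof.transition_index(pd.DataFrame(prom), pd.DataFrame(three))
    assert med.is_monotonic_increasing
    assert med.iloc[0] < med.iloc[-1]
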