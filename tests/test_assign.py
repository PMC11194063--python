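"""Peak-to-gene assignment geometry, two-gene resolution, and curation."""

import pytest

from medlsm import annotation as ann
from medlsm import assign as asg
from medlsm import chip
from medlsm.chip import Peak, PeakSet


def _annot(genes):
    return ann.GenomeAnnotation(chromosomes={"chr1": 100_000}, genes=genes)


def _gene(gid, start, end, strand="+", exons=None, **kw):
    return ann.Gene(id=gid, name=gid, chrom="chr1", strand=strand,
                    cds_start=start, cds_end=end,
                    exons=exons or [(start, end)], **kw)


def _peak(start, end, summit=None):
    return Peak(chrom="chr1", start=start, end=end,
                summit=summit if summit is not None else (start + end) // 2,
                fold_enrichment=4.0, q_value=0.01)


def test_peak_beyond_flank_has_no_candidates():
    annot = _annot([_gene("a", 5000, 6000)])
    peaks = PeakSet(peaks=[_peak(3900, 4400)])  # 600 bp from the gene
    out = asg.genes_near_peaks(peaks, annot, flank=500)
    assert out[0].candidate_ids == []


def test_peak_overlapping_one_gene_is_single():
    annot = _annot([_gene("a", 5000, 6000)])
    out = asg.genes_near_peaks(PeakSet(peaks=[_peak(5400, 5700)]), annot)
    assert out[0].overlap_type == "single"
    assert out[0].candidate_ids == ["a"]


def test_convergent_geometry_detected():
    # two genes transcribed toward each other, peak between them
    annot = _annot([_gene("a", 1000, 2000, "+"), _gene("b", 2200, 3200, "-")])
    out = asg.genes_near_peaks(PeakSet(peaks=[_peak(1950, 2250)]), annot)
    assert out[0].overlap_type == "convergent"
    assert out[0].candidate_ids == ["a", "b"]


def test_parallel_and_embedded_and_3prime_types():
    host = _gene("host", 1000, 3000, "+",
                 exons=[(1000, 1200), (2400, 3000)])
    inner = _gene("inner", 1400, 1900, "-")
    annot = _annot([host, inner])
    out = asg.genes_near_peaks(PeakSet(peaks=[_peak(2300, 2600)]), annot)
    assert out[0].overlap_type == "intron_embedded"

    a = _gene("a", 1000, 2000, "+")
    b = _gene("b", 1850, 2900, "-", is_dubious=True,
              feature_class="dubious_orf")
    annot2 = _annot([a, b])
    out2 = asg.genes_near_peaks(PeakSet(peaks=[_peak(1800, 2100)]), annot2)
    assert out2[0].overlap_type == "overlapping_3prime_exons"

    annot3 = _annot([_gene("a", 1000, 2000, "+"), _gene("b", 2200, 3200, "+")])
    out3 = asg.genes_near_peaks(PeakSet(peaks=[_peak(1950, 2250)]), annot3)
    assert out3[0].overlap_type == "parallel"


def test_summit_rule_resolves_to_containing_gene():
    annot = _annot([_gene("a", 1000, 2000, "+"), _gene("b", 2200, 3200, "+")])
    peaks = PeakSet(peaks=[_peak(1700, 2300, summit=1900)])  # summit in a
    out = asg.resolve_two_gene_regions(asg.genes_near_peaks(peaks, annot),
                                       annot)
    assert out[0].resolved_id == "a"
    assert not out[0].unresolved


def test_dubious_candidate_dropped_for_3prime_overlap():
    a = _gene("a", 1000, 2000, "+")
    b = _gene("b", 1850, 2900, "-", is_dubious=True,
              feature_class="dubious_orf")
    annot = _annot([a, b])
    peaks = PeakSet(peaks=[_peak(1800, 2100)])
    out = asg.resolve_two_gene_regions(asg.genes_near_peaks(peaks, annot),
                                       annot)
    assert out[0].resolved_id == "a"


def test_summit_in_neither_candidate_is_flagged_unresolved():
    annot = _annot([_gene("a", 1000, 2000, "+"), _gene("b", 2400, 3400, "+")])
    peaks = PeakSet(peaks=[_peak(2000, 2400, summit=2200)])  # between genes
    out = asg.resolve_two_gene_regions(asg.genes_near_peaks(peaks, annot),
                                       annot)
    assert out[0].resolved_id is None
    assert out[0].unresolved


def test_resolution_never_invents_genes(curation_fixture):
    annot, peaks, hcr, _ = curation_fixture
    kept, _ = chip.mask_hcr(peaks, hcr)
    assignments = asg.genes_near_peaks(kept, annot)
    resolved = asg.resolve_two_gene_regions(assignments, annot)
    for a in resolved:
        if a.resolved_id is not None:
            assert a.resolved_id in a.candidate_ids


@pytest.mark.parametrize(
    "peak,gene_kw,reason",
    [
        # plus-strand gene, peak entirely past the CDS end
        (_peak(2100, 2400), {}, "downstream_of_cds"),
        # ncRNA candidate
        (_peak(1400, 1700), {"feature_class": "ncRNA"}, "ncRNA"),
        # over-broad peak
        (Peak(chrom="chr1", start=500, end=4600, summit=1500,
              fold_enrichment=3.0, q_value=0.01), {}, "broad_diffuse"),
    ],
)
def test_curation_removal_rules(peak, gene_kw, reason):
    g = _gene("a", 1000, 2000, "+", **gene_kw)
    annot = _annot([g])
    asn = asg.PeakGeneAssignment(peak=peak, candidate_ids=["a"],
                                 overlap_type="single", resolved_id="a")
    curated, audited = asg.curate_gene_list([asn], annot,
                                            broad_width_threshold=2000)
    assert curated == []
    assert audited[0].removal_reasons["a"] == reason


def test_hcr_overlap_removal():
    g = _gene("a", 1000, 2000)
    asn = asg.PeakGeneAssignment(peak=_peak(1400, 1700),
                                 candidate_ids=["a"],
                                 overlap_type="single", resolved_id="a")
    curated, audited = asg.curate_gene_list([asn], _annot([g]),
                                            hcr=[("chr1", 1600, 1900)])
    assert curated == []
    assert audited[0].removal_reasons["a"] == "hcr_overlap"


def test_minus_strand_downstream_is_leftward():
    g = _gene("a", 1000, 2000, "-")
    asn = asg.PeakGeneAssignment(peak=_peak(600, 900), candidate_ids=["a"],
                                 overlap_type="single", resolved_id="a")
    curated, audited = asg.curate_gene_list([asn], _annot([g]))
    assert audited[0].removal_reasons["a"] == "downstream_of_cds"


def test_audit_partitions_candidates(curation_fixture):
    """Every resolved gene is either curated or carries exactly one reason."""
    annot, peaks, hcr, _ = curation_fixture
    kept, _ = chip.mask_hcr(peaks, hcr)
    resolved = asg.resolve_two_gene_regions(
        asg.genes_near_peaks(kept, annot), annot
    )
    curated, audited = asg.curate_gene_list(resolved, annot, hcr)
    curated_set = set(curated)
    for before, after in zip(resolved, audited):
        if before.resolved_id is None:
            continue
        gid = before.resolved_id
        in_list = gid in curated_set
        has_reason = gid in after.removal_reasons
        assert in_list != has_reason
        if has_reason:
            assert len(after.removal_reasons) == 1


def test_curation_bookkeeping_matches_planted_counts(curation_fixture):
    """127 regions -> 116 after HCR masking; 149 candidates over 33
    two-gene regions resolve and curate to 116 genes with the planted
    81/17/14/4 class partition."""
    annot, peaks, hcr, expected = curation_fixture
    assert len(peaks) == expected["peaks_called"]
    kept, removed = chip.mask_hcr(peaks, hcr)
    assert len(kept) == expected["peaks_after_hcr"]
    assignments = asg.genes_near_peaks(kept, annot)
    assert sum(len(a.candidate_ids) for a in assignments) == \
        expected["candidate_genes"]
    assert sum(1 for a in assignments if a.is_two_gene_region) == \
        expected["two_gene_regions"]
    resolved = asg.resolve_two_gene_regions(assignments, annot)
    curated, _ = asg.curate_gene_list(resolved, annot, hcr)
    assert len(curated) == expected["curated_genes"]
    assert sorted(curated) == sorted(expected["curated_ids"])
    assert ann.class_counts(annot.subset(curated)) == expected["class_counts"]
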