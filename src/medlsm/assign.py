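"""Peak-to-gene assignment and rule-based curation.

Each curated peak is linked to all genes whose span overlaps the peak
extended by a flank (default +/-500 bp).  Regions hitting two genes come in
four geometries — convergent, parallel, embedded in an intron, or with
overlapping 3'-exons — and are resolved by the corresponding rule: keep the
gene containing the peak summit for the first three, drop dubious-ORF
candidates for the fourth.  A final curation pass removes genes whose peaks
lie downstream of the CDS, overlap hyper-ChIPable regions, belong to
disallowed feature classes, or derive from over-broad (diffuse) peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import Gene, GenomeAnnotation
from .chip import Peak, PeakSet

__all__ = [
    "PeakGeneAssignment",
    "genes_near_peaks",
    "resolve_two_gene_regions",
    "curate_gene_list",
    "audit_frame",
]

OVERLAP_TYPES = (
    "single",
    "convergent",
    "parallel",
    "intron_embedded",
    "overlapping_3prime_exons",
)

REMOVAL_REASONS = (
    "downstream_of_cds",
    "hcr_overlap",
    "dubious_orf",
    "ncRNA",
    "ARS",
    "centromere",
    "transposon",
    "broad_diffuse",
)

_DISALLOWED_CLASSES = ("dubious_orf", "ncRNA", "ARS", "centromere", "transposon")


@dataclass
class PeakGeneAssignment:
    """One peak with its candidate genes and resolution state."""

    peak: Peak
    candidate_ids: list[str]
    overlap_type: str = "single"
    resolved_id: Optional[str] = None
    removal_reasons: dict[str, str] = field(default_factory=dict)
    unresolved: bool = False

    @property
    def is_two_gene_region(self) -> bool:
        return len(self.candidate_ids) >= 2


def _classify_pair(a: Gene, b: Gene) -> str:
    """Overlap geometry of a two-gene region."""
    for host, inner in ((a, b), (b, a)):
        for istart, iend in host.introns:
            if istart <= inner.cds_start and inner.cds_end <= iend:
                return "intron_embedded"
    if a.strand != b.strand:
        ea, eb = a.last_exon(), b.last_exon()
        if ea[0] < eb[1] and eb[0] < ea[1]:
            return "overlapping_3prime_exons"
        return "convergent"
    return "parallel"


def genes_near_peaks(
    peaks: PeakSet, annot: GenomeAnnotation, flank: int = 500
) -> list[PeakGeneAssignment]:
    """Link each peak to every gene overlapping [start - flank, end + flank)."""
    trees: dict[str, IntervalTree] = {}
    for g in annot.genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.cds_start, g.cds_end, g.id
        )
    genes = annot.genes_by_id
    out: list[PeakGeneAssignment] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = (
            sorted(iv.data for iv in tree.overlap(p.start - flank, p.end + flank))
            if tree
            else []
        )
        if len(hits) <= 1:
            otype = "single"
        elif len(hits) == 2:
            otype = _classify_pair(genes[hits[0]], genes[hits[1]])
        else:
            strands = {genes[h].strand for h in hits}
            otype = "parallel" if len(strands) == 1 else "convergent"
        out.append(
            PeakGeneAssignment(peak=p, candidate_ids=hits, overlap_type=otype)
        )
    return out


def resolve_two_gene_regions(
    assignments: Sequence[PeakGeneAssignment], annot: GenomeAnnotation
) -> list[PeakGeneAssignment]:
    """Resolve multi-candidate regions to a single gene.

    Convergent / parallel / intron-embedded regions keep the candidate whose
    span contains the peak summit; overlapping-3'-exon regions drop dubious
    candidates.  A region where no rule singles out one gene is flagged
    ``unresolved`` for manual review.
    """
    genes = annot.genes_by_id
    out: list[PeakGeneAssignment] = []
    for asn in assignments:
        asn = PeakGeneAssignment(
            peak=asn.peak,
            candidate_ids=list(asn.candidate_ids),
            overlap_type=asn.overlap_type,
        )
        cands = asn.candidate_ids
        if len(cands) == 0:
            out.append(asn)
            continue
        if len(cands) == 1:
            asn.resolved_id = cands[0]
            out.append(asn)
            continue
        if asn.overlap_type == "overlapping_3prime_exons":
            keep = [c for c in cands if not genes[c].is_dubious]
        else:
            keep = [c for c in cands if genes[c].contains(asn.peak.summit)]
        if len(keep) == 1:
            asn.resolved_id = keep[0]
        else:
            asn.unresolved = True
        out.append(asn)
    return out


def curate_gene_list(
    assignments: Sequence[PeakGeneAssignment],
    annot: GenomeAnnotation,
    hcr: Iterable[tuple[str, int, int]] = (),
    broad_width_threshold: int = 2000,
) -> tuple[list[str], list[PeakGeneAssignment]]:
    """Apply the removal rules to resolved assignments.

    A resolved gene is removed when (in reason-priority order): its feature
    class is disallowed (dubious ORF, ncRNA, ARS, centromere, transposon);
    its peak overlaps a hyper-ChIPable region; the peak lies entirely
    downstream of the CDS end in transcription orientation; or the peak is
    wider than ``broad_width_threshold`` (the reproducible proxy for "broad
    diffuse" peaks).  The rules are independent, so the curated *set* does
    not depend on rule order; the recorded reason is the first that fires.

    Returns ``(curated gene ids, audited assignments)``; every removal
    carries exactly one reason code per gene.
    """
    genes = annot.genes_by_id
    hcr_trees: dict[str, IntervalTree] = {}
    for chrom, start, end in hcr:
        hcr_trees.setdefault(chrom, IntervalTree()).addi(start, end)

    curated: list[str] = []
    audited: list[PeakGeneAssignment] = []
    for asn in assignments:
        asn = PeakGeneAssignment(
            peak=asn.peak,
            candidate_ids=list(asn.candidate_ids),
            overlap_type=asn.overlap_type,
            resolved_id=asn.resolved_id,
            unresolved=asn.unresolved,
        )
        audited.append(asn)
        if asn.resolved_id is None:
            continue
        g = genes[asn.resolved_id]
        p = asn.peak
        reason = None
        if g.feature_class in _DISALLOWED_CLASSES:
            reason = "dubious_orf" if g.is_dubious else g.feature_class
        elif p.chrom in hcr_trees and hcr_trees[p.chrom].overlap(p.start, p.end):
            reason = "hcr_overlap"
        elif _downstream_of_cds(p, g):
            reason = "downstream_of_cds"
        elif p.width > broad_width_threshold:
            reason = "broad_diffuse"
        if reason is None:
            curated.append(g.id)
        else:
            asn.removal_reasons[g.id] = reason
            asn.resolved_id = None
    return sorted(set(curated)), audited


def _downstream_of_cds(peak: Peak, gene: Gene) -> bool:
    """True when the peak lies entirely 3' of the CDS end (oriented)."""
    if gene.strand == "+":
        return peak.start >= gene.cds_end
    return peak.end <= gene.cds_start


def audit_frame(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    """Flat audit table: one row per (peak, candidate gene)."""
    rows = []
    for i, asn in enumerate(assignments):
        for gid in asn.candidate_ids or [None]:
            rows.append(
                {
                    "peak_index": i,
                    "chrom": asn.peak.chrom,
                    "start": asn.peak.start,
                    "end": asn.peak.end,
                    "overlap_type": asn.overlap_type,
                    "candidate": gid,
                    "resolved": asn.resolved_id,
                    "removal_reason": asn.removal_reasons.get(gid)
                    if gid
                    else None,
                    "unresolved": asn.unresolved,
                }
            )
    return pd.DataFrame(rows)
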