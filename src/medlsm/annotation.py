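"""Genome annotation model, gene-class flags, and coordinate landmarks.

The pipeline works with a single-transcript gene model: each gene is a CDS
span on one strand, covered by an ordered set of exons whose gaps are the
introns.  All internal coordinates are 0-based, half-open; conversion to the
1-based inclusive convention of GTF happens only at I/O.

Landmarks are reported in *transcription orientation*: for a minus-strand
gene the "CDS end" is the leftmost genomic coordinate, and the "last intron"
is the intron whose 3' splice site lies nearest the transcription 3' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils

logger = logging.getLogger(__name__)

#: recognised gene feature classes
FEATURE_CLASSES = (
    "protein_coding",
    "ncRNA",
    "ARS",
    "centromere",
    "transposon",
    "dubious_orf",
)

#: the four IC/RP occupancy classes
GENE_CLASSES = ("IC-RP", "IC-nonRP", "nonIC-RP", "nonIC-nonRP")


@dataclass
class Gene:
    """One gene with exon structure and class flags.

    ``exons`` are 0-based half-open intervals sorted by start; gaps between
    consecutive exons are the introns.
    """

    id: str
    name: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]
    is_rp: bool = False
    is_dubious: bool = False
    feature_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"gene {self.id}: empty exon ({a},{b})")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"gene {self.id}: overlapping exons")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (genomic order)."""
        return [
            (b0, a1)
            for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])
            if a1 > b0
        ]

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def is_ic(self) -> bool:
        return self.n_introns >= 1

    @property
    def min_intron_length(self) -> Optional[int]:
        introns = self.introns
        return min(b - a for a, b in introns) if introns else None

    @property
    def total_intron_length(self) -> int:
        return sum(b - a for a, b in self.introns)

    @property
    def total_exon_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_start, self.cds_end

    def contains(self, pos: int) -> bool:
        return self.cds_start <= pos < self.cds_end

    def last_exon(self) -> tuple[int, int]:
        """Transcription-last exon (rightmost for '+', leftmost for '-')."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]


@dataclass
class GeneLandmarks:
    """Orientation-aware anchor coordinates for one gene.

    ``cds_start`` / ``cds_end`` are the genomic coordinates of the
    transcription start / end of the CDS.  ``last_intron_3prime_end`` is the
    genomic coordinate of the 3' splice site of the 3'-most intron, or None
    for intronless genes.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    last_intron_3prime_end: Optional[int] = None

    @property
    def has_intron(self) -> bool:
        return self.last_intron_3prime_end is not None


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a list of genes with unique identifiers."""

    chromosomes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id}")
            seen.add(g.id)
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chrom}")
            if not (0 <= g.cds_start < g.cds_end <= self.chromosomes[g.chrom]):
                raise ValueError(
                    f"gene {g.id}: interval outside chromosome {g.chrom}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        return self.genes_by_id[gene_id]

    @property
    def genes_by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes}

    def subset(self, gene_ids: Iterable[str]) -> list[Gene]:
        wanted = set(gene_ids)
        return [g for g in self.genes if g.id in wanted]


def classify_gene(gene: Gene) -> str:
    """Four-way IC/RP class: IC iff the gene has >=1 intron, RP iff flagged."""
    ic = "IC" if gene.is_ic else "nonIC"
    rp = "RP" if gene.is_rp else "nonRP"
    return f"{ic}-{rp}"


def class_counts(genes: Iterable[Gene]) -> dict[str, int]:
    """Count genes in each of the four IC/RP classes (all keys present)."""
    counts = {c: 0 for c in GENE_CLASSES}
    for g in genes:
        counts[classify_gene(g)] += 1
    return counts


def gene_landmarks(gene: Gene) -> GeneLandmarks:
    """Landmarks for one gene, orientation-corrected."""
    introns = gene.introns
    if gene.strand == "+":
        start, end = gene.cds_start, gene.cds_end
        # 3'-most intron is the rightmost gap; its 3' splice site is its
        # right boundary (start of the following exon)
        last3 = introns[-1][1] if introns else None
    else:
        start, end = gene.cds_end, gene.cds_start
        # transcription runs right->left: 3'-most intron is the leftmost
        # gap and its 3' splice site is its left boundary
        last3 = introns[0][0] if introns else None
    return GeneLandmarks(
        gene_id=gene.id,
        chrom=gene.chrom,
        strand=gene.strand,
        cds_start=start,
        cds_end=end,
        last_intron_3prime_end=last3,
    )


def derive_landmarks(annot: GenomeAnnotation) -> list[GeneLandmarks]:
    """One landmark record per gene, in annotation order."""
    return [gene_landmarks(g) for g in annot.genes]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CHROM_SIZE_PREFIX = "#!chrom-size"


def write_annotation(annot: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as a GTF subset (gene + exon features).

    Chromosome sizes go into ``#!chrom-size`` header lines so that a
    write/read round trip reconstructs the annotation exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        for chrom, size in annot.chromosomes.items():
            fh.write(f"{_CHROM_SIZE_PREFIX} {chrom} {size}\n")
        for g in annot.genes:
            attrs = (
                f'gene_id "{g.id}"; gene_name "{g.name}"; '
                f'gene_biotype "{g.feature_class}"; '
                f'rp "{"1" if g.is_rp else "0"}";'
            )
            fh.write(
                f"{g.chrom}\tmedlsm\tgene\t{g.cds_start + 1}\t{g.cds_end}\t"
                f".\t{g.strand}\t.\t{attrs}\n"
            )
            for (a, b) in g.exons:
                fh.write(
                    f"{g.chrom}\tmedlsm\texon\t{a + 1}\t{b}\t.\t{g.strand}\t"
                    f'.\tgene_id "{g.id}";\n'
                )


def read_annotation(
    path: str | Path,
    rp_list: Optional[str | Path | Iterable[str]] = None,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> GenomeAnnotation:
    """Read a GTF subset into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    path
        GTF file with ``gene`` and ``exon`` features.  Gene class is taken
        from a ``gene_biotype`` attribute when present.
    rp_list
        Optional BED/TSV file (or iterable) of ribosomal-protein gene ids;
        membership sets ``is_rp``.  When absent, an ``rp`` attribute in the
        GTF is honoured.
    chrom_sizes
        Optional chromosome-length map; overrides any ``#!chrom-size``
        header lines.  When neither is available, lengths default to the
        rightmost annotated coordinate per chromosome.
    """
    path = Path(path)
    sizes: dict[str, int] = {}
    with path.open() as fh:
        for line in fh:
            if line.startswith(_CHROM_SIZE_PREFIX):
                _, chrom, size = line.split()
                sizes[chrom] = int(size)
    if chrom_sizes is not None:
        sizes = dict(chrom_sizes)

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    rp_ids: Optional[set[str]] = None
    if rp_list is not None:
        rp_ids = (
            read_gene_ids(rp_list)
            if isinstance(rp_list, (str, Path))
            else set(rp_list)
        )

    genes: list[Gene] = []
    declared: set[str] = set()
    for f in db.features_of_type("gene"):
        if f.end < f.start:
            logger.warning("rejecting malformed gene record %s", f.id)
            continue
        gene_id = f.attributes["gene_id"][0]
        declared.add(gene_id)
        exons: list[tuple[int, int]] = []
        for e in db.children(f, featuretype="exon"):
            if e.end < e.start:
                logger.warning("rejecting malformed exon in gene %s", gene_id)
                continue
            exons.append((e.start - 1, e.end))
        if not exons:
            exons = [(f.start - 1, f.end)]
        fclass = f.attributes.get("gene_biotype", ["protein_coding"])[0]
        if fclass not in FEATURE_CLASSES:
            fclass = "protein_coding"
        rp_attr = f.attributes.get("rp", ["0"])[0] == "1"
        is_rp = gene_id in rp_ids if rp_ids is not None else rp_attr
        genes.append(
            Gene(
                id=gene_id,
                name=f.attributes.get("gene_name", [gene_id])[0],
                chrom=f.seqid,
                strand=f.strand,
                cds_start=f.start - 1,
                cds_end=f.end,
                exons=exons,
                is_rp=is_rp,
                is_dubious=fclass == "dubious_orf",
                feature_class=fclass,
            )
        )

    for e in db.features_of_type("exon"):
        gid = e.attributes["gene_id"][0]
        if gid not in declared:
            raise ValueError(f"exon references undeclared gene {gid}")

    if not sizes:
        for g in genes:
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.cds_end)
    for g in genes:
        if g.chrom not in sizes:
            raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")

    return GenomeAnnotation(chromosomes=sizes, genes=genes)


def read_gene_ids(path: str | Path) -> set[str]:
    """Read gene ids from a BED6 file (name column) or a one-id-per-line TSV."""
    ids: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4 and _is_int(fields[1]) and _is_int(fields[2]):
                ids.add(fields[3])  # BED: name column
            else:
                ids.add(fields[0])
    return ids


def write_gene_ids(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False
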