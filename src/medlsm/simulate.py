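"""Synthetic genomes, ChIP coverage, and paired RNA-seq counts with ground truth.

Everything downstream of read alignment is exercised against data from this
module: a yeast-like annotation with intron-containing (IC) and ribosomal
protein (RP) gene classes, ChIP coverage tracks with promoter peaks and
3'-exon peaks whose relative amplitudes shift across a four-point growth
time course, and paired whole-gene / exon-only RNA-seq count matrices with
known per-gene splice ratios.

The generators are pure functions of their parameters and a seed.  Coverage
is Poisson around a smooth expected profile: a flat background plus Gaussian
bumps (the Gaussian emulates fragment-size smoothing at roughly 300 bp and
gives the expected profile a unique argmax).  RNA-seq counts are Poisson
with intron read density tied to ``1 - splice_ratio`` times the exon read
density, so the downstream splice-ratio estimator is consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, gene_landmarks
from .chip import CoverageTrack, Peak, PeakSet

__all__ = [
    "SimTruth",
    "make_genome",
    "simulate_chip_coverage",
    "expected_chip_profile",
    "simulate_rnaseq_counts",
    "hcr_intervals",
    "make_curation_fixture",
    "make_cooccupancy_lists",
]

#: occupancy groups used in the RNA-seq comparisons
GROUPS = ("co_occupied", "neither", "lsm3_only", "mediator_only", "background")

#: default group proportions among IC genes (72/45/17/7 of 141)
DEFAULT_GROUP_WEIGHTS = {
    "co_occupied": 72,
    "neither": 45,
    "lsm3_only": 17,
    "mediator_only": 7,
}

N_TIME_POINTS = 4
TIME_POINT_LABELS = ("0h", "2h", "4h", "6h")

# Mediator-like factor amplitude schedules (expected counts per bin at the
# bump centre), mirroring the promoter -> 3'-exon occupancy transition.
PROMOTER_SCHEDULE = np.array([10.0, 7.0, 3.5, 0.4])
THREEPRIME_SCHEDULE = np.array([0.8, 1.6, 3.5, 8.0])
MEDIATOR_ONLY_PROMOTER = np.array([8.0, 8.0, 7.0, 6.0])

#: expression schedules (expected exon reads per kb at unit library factor)
EXPRESSION_SCHEDULES = {
    "co_occupied": np.array([800.0, 800.0, 600.0, 400.0]),
    "neither": np.array([350.0, 350.0, 350.0, 350.0]),
    "lsm3_only": np.array([350.0, 350.0, 320.0, 300.0]),
    "mediator_only": np.array([350.0, 350.0, 320.0, 300.0]),
    "background": np.array([120.0, 120.0, 120.0, 120.0]),
}

#: splice-ratio drop per time point for the co-occupied group
CO_OCCUPIED_SPLICE_DROP = np.array([0.0, 0.0, 0.03, 0.10])

DEFAULT_SUMMIT_OFFSET = 250  # bp downstream of the last-intron 3' end
DEFAULT_FRAGMENT_SIGMA = 130.0  # bp; bump width from fragment smoothing
DEFAULT_BACKGROUND_RATE = 0.10  # reads per bp
PROMOTER_UPSTREAM = 200  # bump centre, bp upstream of the CDS start


@dataclass
class SimTruth:
    """Ground truth for one simulated study.

    ``table`` is indexed by gene id with per-gene columns: ``group``,
    ``pair_type``, ``in_hcr``, ``lsm3_amp``, ``summit_offset`` and, per time
    point ``t`` in 0..3, ``promoter_amp_t{t}``, ``threeprime_amp_t{t}``,
    ``expression_t{t}`` (exon reads per kb) and ``splice_t{t}``.
    """

    table: pd.DataFrame
    seed: int
    background_rate: float = DEFAULT_BACKGROUND_RATE
    fragment_sigma: float = DEFAULT_FRAGMENT_SIGMA
    time_points: tuple[str, ...] = TIME_POINT_LABELS

    def genes_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def splice_truth(self, time_point: int) -> pd.Series:
        return self.table[f"splice_t{time_point}"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------


def _gene_structure(
    rng: np.random.Generator,
    start: int,
    strand: str,
    ic: bool,
    intron_length_range: tuple[int, int],
) -> tuple[int, int, list[tuple[int, int]]]:
    """Return (cds_start, cds_end, exons) for a gene beginning at ``start``."""
    if ic:
        # short 5' exon, intron, then a final exon ending ~50-140 bp past the
        # planted 3' summit so the summit also sits just upstream of the CDS end
        e1 = int(rng.integers(60, 150))
        ilen = int(rng.integers(intron_length_range[0], intron_length_range[1] + 1))
        e2 = int(rng.integers(300, 390))
        if strand == "+":
            exons = [(start, start + e1), (start + e1 + ilen, start + e1 + ilen + e2)]
        else:
            # mirror so the short first exon sits at the transcription 5' end
            exons = [(start, start + e2), (start + e2 + ilen, start + e2 + ilen + e1)]
        return start, exons[-1][1], exons
    length = int(rng.integers(500, 1200))
    return start, start + length, [(start, start + length)]


def make_genome(
    n_genes: int = 200,
    frac_ic: float = 0.5,
    frac_rp: float = 0.25,
    intron_length_range: tuple[int, int] = (60, 400),
    seed: int = 0,
    n_chromosomes: int = 2,
    pair_counts: Optional[dict[str, int]] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
    group_sizes: Optional[dict[str, int]] = None,
    n_hcr_genes: int = 0,
) -> tuple[GenomeAnnotation, SimTruth]:
    """Build a synthetic annotation plus matched ground truth.

    Genes are packed without overlap onto ``n_chromosomes`` chromosomes with
    generous spacing so that +/-500 bp peak flanks never touch a neighbour
    except inside deliberately constructed two-gene regions.  ``pair_counts``
    maps overlap types (``convergent``, ``parallel``, ``intron_embedded``,
    ``overlapping_3prime_exons``) to the number of two-gene regions of that
    type; pair members are drawn from the ``n_genes`` budget.

    ``group_sizes`` fixes the number of IC genes per occupancy group; by
    default IC genes are split proportionally to the 72/45/17/7 study
    groups.  ``n_hcr_genes`` marks that many genes as lying in
    hyper-ChIPable regions (see :func:`hcr_intervals`).
    """
    if not (0 <= frac_ic <= 1 and 0 <= frac_rp <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    pair_counts = dict(pair_counts or {})
    n_paired = 2 * sum(pair_counts.values())
    if n_paired > n_genes:
        raise ValueError("pair_counts require more genes than n_genes")

    rng = np.random.default_rng(seed)
    n_ic = int(round(frac_ic * n_genes))
    n_rp = int(round(frac_rp * n_genes))

    # IC flags: pair construction may force IC (intron-embedded hosts);
    # assign forced flags first, then fill to the exact count.
    gene_plan: list[dict] = [{"ic": None, "pair_type": "none", "dubious": False}
                            for _ in range(n_genes)]
    idx = 0
    pair_specs: list[tuple[str, int, int]] = []  # (type, index_a, index_b)
    for ptype, count in pair_counts.items():
        if ptype not in ("convergent", "parallel", "intron_embedded",
                         "overlapping_3prime_exons"):
            raise ValueError(f"unknown pair type {ptype!r}")
        for _ in range(count):
            a, b = idx, idx + 1
            idx += 2
            pair_specs.append((ptype, a, b))
            if ptype == "intron_embedded":
                gene_plan[a]["ic"] = True   # host needs a long intron
                gene_plan[b]["ic"] = False  # embedded gene is intronless
            if ptype == "overlapping_3prime_exons":
                gene_plan[b]["dubious"] = True
            gene_plan[a]["pair_type"] = ptype
            gene_plan[b]["pair_type"] = ptype

    # exact IC count when unconstrained; pair geometry (embedded genes are
    # intronless, their hosts intron-containing) can clip the achievable count
    forced_ic = sum(1 for p in gene_plan if p["ic"] is True)
    free = [i for i, p in enumerate(gene_plan) if p["ic"] is None]
    n_more = min(max(0, n_ic - forced_ic), len(free))
    for i in rng.choice(free, size=n_more, replace=False):
        gene_plan[i]["ic"] = True
    for p in gene_plan:
        if p["ic"] is None:
            p["ic"] = False

    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    cursors = {c: 2000 for c in chrom_names}
    genes: list[Gene] = []
    placed_on: dict[int, str] = {}

    def place(i: int, chrom: str, start: int, strand: str,
              structure=None) -> Gene:
        plan = gene_plan[i]
        if structure is None:
            s, e, exons = _gene_structure(
                rng, start, strand, plan["ic"], intron_length_range
            )
        else:
            s, e, exons = structure
        g = Gene(
            id=f"g{i + 1:04d}",
            name=f"SYN{i + 1}",
            chrom=chrom,
            strand=strand,
            cds_start=s,
            cds_end=e,
            exons=exons,
            is_dubious=plan["dubious"],
            feature_class="dubious_orf" if plan["dubious"] else "protein_coding",
        )
        genes.append(g)
        placed_on[i] = chrom
        return g

    def spacing() -> int:
        return int(rng.integers(1400, 2200))

    # paired regions first, then singletons, round-robin over chromosomes
    chrom_cycle = 0
    for ptype, a, b in pair_specs:
        chrom = chrom_names[chrom_cycle % n_chromosomes]
        chrom_cycle += 1
        x = cursors[chrom]
        if ptype == "convergent":
            ga = place(a, chrom, x, "+")
            gap = int(rng.integers(80, 200))
            gb = place(b, chrom, ga.cds_end + gap, "-")
        elif ptype == "parallel":
            ga = place(a, chrom, x, "+")
            gap = int(rng.integers(80, 200))
            gb = place(b, chrom, ga.cds_end + gap, "+")
        elif ptype == "intron_embedded":
            inner_len = int(rng.integers(200, 350))
            e1 = int(rng.integers(60, 150))
            ilen = inner_len + 300
            e2 = int(rng.integers(450, 900))
            exons = [(x, x + e1), (x + e1 + ilen, x + e1 + ilen + e2)]
            ga = place(a, chrom, x, "+", structure=(x, exons[-1][1], exons))
            inner_start = x + e1 + 150
            gb = place(
                b, chrom, inner_start, "-",
                structure=(inner_start, inner_start + inner_len,
                           [(inner_start, inner_start + inner_len)]),
            )
        else:  # overlapping_3prime_exons
            ga = place(a, chrom, x, "+")
            ov = int(rng.integers(60, 150))
            bstart = ga.cds_end - ov
            blen = int(rng.integers(500, 900))
            gb = place(
                b, chrom, bstart, "-",
                structure=(bstart, bstart + blen, [(bstart, bstart + blen)]),
            )
        cursors[chrom] = max(ga.cds_end, gb.cds_end) + spacing()

    for i in range(n_genes):
        if i in placed_on:
            continue
        chrom = chrom_names[chrom_cycle % n_chromosomes]
        chrom_cycle += 1
        strand = "+" if rng.random() < 0.5 else "-"
        g = place(i, chrom, cursors[chrom], strand)
        cursors[chrom] = g.cds_end + spacing()

    if chrom_lengths is not None:
        for c in chrom_names:
            if cursors[c] + 2000 > chrom_lengths.get(c, 0):
                raise ValueError(
                    f"infeasible packing: {c} needs {cursors[c] + 2000} bp"
                )
        sizes = dict(chrom_lengths)
    else:
        sizes = {c: cursors[c] + 2000 for c in chrom_names}

    genes.sort(key=lambda g: (g.chrom, g.cds_start))
    annot = GenomeAnnotation(chromosomes=sizes, genes=genes)

    # RP flags: exact count, IC genes twice as likely (RP genes in yeast are
    # predominantly intron-containing)
    ids = [g.id for g in annot.genes]
    ic_flags = np.array([g.is_ic for g in annot.genes])
    weights = np.where(ic_flags, 2.0, 1.0)
    weights /= weights.sum()
    rp_idx = rng.choice(len(ids), size=min(n_rp, len(ids)), replace=False, p=weights)
    for j in rp_idx:
        annot.genes[j].is_rp = True

    truth = _build_truth(
        annot, rng, seed,
        group_sizes=group_sizes,
        n_hcr_genes=n_hcr_genes,
        pair_type={g.id: gene_plan[int(g.id[1:]) - 1]["pair_type"]
                   for g in annot.genes},
    )
    return annot, truth


def _build_truth(
    annot: GenomeAnnotation,
    rng: np.random.Generator,
    seed: int,
    group_sizes: Optional[dict[str, int]],
    n_hcr_genes: int,
    pair_type: dict[str, str],
) -> SimTruth:
    ids = [g.id for g in annot.genes]
    ic_ids = [g.id for g in annot.genes if g.is_ic]
    n_ic = len(ic_ids)

    if group_sizes is None:
        total = sum(DEFAULT_GROUP_WEIGHTS.values())
        group_sizes = {
            g: int(round(w * n_ic / total))
            for g, w in DEFAULT_GROUP_WEIGHTS.items()
        }
    if sum(group_sizes.values()) > n_ic:
        raise ValueError("group_sizes exceed the number of IC genes")

    perm = list(rng.permutation(ic_ids))
    group = {i: "background" for i in ids}
    pos = 0
    for name, size in group_sizes.items():
        for gid in perm[pos : pos + size]:
            group[gid] = name
        pos += size

    df = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    df["group"] = [group[i] for i in ids]
    df["pair_type"] = [pair_type.get(i, "none") for i in ids]
    df["is_ic"] = [annot.gene(i).is_ic for i in ids]
    df["is_rp"] = [annot.gene(i).is_rp for i in ids]
    df["summit_offset"] = DEFAULT_SUMMIT_OFFSET

    jitter = rng.uniform(0.8, 1.25, size=len(ids))
    lsm3 = np.zeros(len(ids))
    for j, gid in enumerate(ids):
        if group[gid] == "co_occupied":
            lsm3[j] = 9.0 * jitter[j]
        elif group[gid] == "lsm3_only":
            lsm3[j] = 6.0 * jitter[j]
    df["lsm3_amp"] = lsm3

    base_splice = np.zeros(len(ids))
    for j, gid in enumerate(ids):
        grp = group[gid]
        if not df["is_ic"].iloc[j]:
            base_splice[j] = np.nan
        elif grp == "co_occupied":
            base_splice[j] = rng.uniform(0.85, 0.97)
        elif grp == "neither":
            base_splice[j] = rng.uniform(0.55, 0.90)
        else:
            base_splice[j] = rng.uniform(0.70, 0.95)

    for t in range(N_TIME_POINTS):
        prom = np.zeros(len(ids))
        three = np.zeros(len(ids))
        expr = np.zeros(len(ids))
        spl = np.array(base_splice)
        for j, gid in enumerate(ids):
            grp = group[gid]
            if grp == "co_occupied":
                prom[j] = PROMOTER_SCHEDULE[t] * jitter[j]
                three[j] = THREEPRIME_SCHEDULE[t] * jitter[j]
                spl[j] = base_splice[j] - CO_OCCUPIED_SPLICE_DROP[t]
            elif grp == "mediator_only":
                prom[j] = MEDIATOR_ONLY_PROMOTER[t] * jitter[j]
            expr[j] = EXPRESSION_SCHEDULES[grp][t] * jitter[j]
        df[f"promoter_amp_t{t}"] = prom
        df[f"threeprime_amp_t{t}"] = three
        df[f"expression_t{t}"] = expr
        df[f"splice_t{t}"] = np.clip(spl, 0.0, 1.0)

    in_hcr = np.zeros(len(ids), dtype=bool)
    if n_hcr_genes:
        hcr_idx = rng.choice(len(ids), size=n_hcr_genes, replace=False)
        in_hcr[hcr_idx] = True
    df["in_hcr"] = in_hcr

    return SimTruth(table=df, seed=seed)


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------


def _bump_centers(gene: Gene, truth_row: pd.Series) -> dict[str, float]:
    """Genomic bump centres for one gene (promoter / 3'-exon / lsm3)."""
    lm = gene_landmarks(gene)
    sign = 1 if gene.strand == "+" else -1
    promoter = lm.cds_start - sign * PROMOTER_UPSTREAM
    if lm.has_intron:
        three = lm.last_intron_3prime_end + sign * truth_row["summit_offset"]
    else:
        three = lm.cds_end - sign * 70
    return {"promoter": promoter, "threeprime": three}


def expected_chip_profile(
    annot: GenomeAnnotation,
    truth: SimTruth,
    time_point: int,
    bin_size: int = 10,
    factor: str = "mediator",
) -> dict[str, np.ndarray]:
    """Noise-free expected counts per bin for one factor at one time point.

    ``factor`` is ``"mediator"`` (promoter + 3'-exon bumps following the
    time-course schedules) or ``"lsm3"`` (time-invariant 3'-exon bumps).
    The returned vectors include the flat background.
    """
    if factor not in ("mediator", "lsm3"):
        raise ValueError("factor must be 'mediator' or 'lsm3'")
    sigma = truth.fragment_sigma
    rate = {
        c: np.full(-(-size // bin_size), truth.background_rate * bin_size)
        for c, size in annot.chromosomes.items()
    }
    centers = {
        c: (np.arange(len(v)) + 0.5) * bin_size for c, v in rate.items()
    }
    for gene in annot.genes:
        row = truth.table.loc[gene.id]
        pos = _bump_centers(gene, row)
        if factor == "mediator":
            bumps = [
                (pos["promoter"], row[f"promoter_amp_t{time_point}"]),
                (pos["threeprime"], row[f"threeprime_amp_t{time_point}"]),
            ]
        else:
            bumps = [(pos["threeprime"], row["lsm3_amp"])]
        x = centers[gene.chrom]
        for center, amp in bumps:
            if amp <= 0:
                continue
            lo = np.searchsorted(x, center - 6 * sigma)
            hi = np.searchsorted(x, center + 6 * sigma)
            d = x[lo:hi] - center
            rate[gene.chrom][lo:hi] += amp * np.exp(-0.5 * (d / sigma) ** 2)
    return rate


def simulate_chip_coverage(
    annot: GenomeAnnotation,
    truth: SimTruth,
    time_point: int = 0,
    n_replicates: int = 3,
    bin_size: int = 10,
    seed: int = 0,
    factor: str = "mediator",
) -> tuple[list[CoverageTrack], CoverageTrack]:
    """Poisson-sample IP replicate tracks plus one background-only control.

    Replicates share the expected profile and differ only in the Poisson
    noise stream.  The control track is background-only, emulating the
    untagged-strain ChIP.
    """
    rate = expected_chip_profile(annot, truth, time_point, bin_size, factor)
    label = truth.time_points[time_point]
    streams = np.random.SeedSequence(seed).spawn(n_replicates + 1)
    tracks = []
    for r in range(n_replicates):
        rng = np.random.default_rng(streams[r])
        values = {c: rng.poisson(v).astype(float) for c, v in rate.items()}
        lib = sum(v.sum() for v in values.values())
        tracks.append(
            CoverageTrack(
                sample_id=f"{factor}_{label}_rep{r + 1}",
                bin_size=bin_size,
                values=values,
                library_size=float(lib),
                condition=label,
            )
        )
    rng = np.random.default_rng(streams[-1])
    ctl_values = {
        c: rng.poisson(np.full_like(v, truth.background_rate * bin_size)).astype(float)
        for c, v in rate.items()
    }
    control = CoverageTrack(
        sample_id=f"control_{label}",
        bin_size=bin_size,
        values=ctl_values,
        library_size=float(sum(v.sum() for v in ctl_values.values())),
        condition=label,
    )
    return tracks, control


def hcr_intervals(
    annot: GenomeAnnotation, truth: SimTruth, pad: int = 150
) -> list[tuple[str, int, int]]:
    """BED-style intervals covering the 3'-peak region of HCR-flagged genes."""
    out = []
    for gene in annot.genes:
        row = truth.table.loc[gene.id]
        if not row["in_hcr"]:
            continue
        center = _bump_centers(gene, row)["threeprime"]
        out.append((gene.chrom, max(0, int(center) - pad), int(center) + pad))
    return sorted(out)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def simulate_rnaseq_counts(
    annot: GenomeAnnotation,
    truth: SimTruth,
    n_replicates_per_timepoint: Sequence[int] | int = (24, 6, 6, 6),
    library_size_factors: Optional[Sequence[float]] = None,
    library_sd: float = 0.15,
    seed: int = 0,
):
    """Paired whole-gene and exon-only count matrices.

    For gene *g* with exon length Le, intron length Li, expression level
    ``e`` (exon reads per kb) and true splice ratio ``s``, sample ``j`` with
    library factor ``f_j`` draws::

        E ~ Poisson(e * f_j * Le / 1000)          (exon-only count)
        I ~ Poisson(e * f_j * (1 - s) * Li / 1000)  (intron reads)
        G = E + I                                  (whole-gene count)

    so intron read density is exactly ``(1 - s)`` times exon read density in
    expectation and whole-gene counts dominate exon-only counts by
    construction.  Library factors default to log-normal with spread
    ``library_sd``; passing explicit factors makes expected totals scale
    linearly in them.  Returns ``(whole_gene, exon_only)`` as
    :class:`medlsm.splicing.CountMatrix`.
    """
    from .splicing import CountMatrix  # local import to avoid a cycle

    if isinstance(n_replicates_per_timepoint, int):
        reps = [n_replicates_per_timepoint] * N_TIME_POINTS
    else:
        reps = list(n_replicates_per_timepoint)
    if len(reps) != N_TIME_POINTS:
        raise ValueError(f"expected {N_TIME_POINTS} replicate counts")

    rng = np.random.default_rng(seed)
    samples = []
    for t, n in enumerate(reps):
        for r in range(n):
            samples.append((t, r))
    n_samples = len(samples)
    if library_size_factors is None:
        factors = rng.lognormal(mean=0.0, sigma=library_sd, size=n_samples)
    else:
        factors = np.asarray(library_size_factors, dtype=float)
        if factors.shape != (n_samples,):
            raise ValueError("library_size_factors length != number of samples")

    ids = [g.id for g in annot.genes]
    le = np.array([g.total_exon_length for g in annot.genes], dtype=float)
    li = np.array([g.total_intron_length for g in annot.genes], dtype=float)

    exon = np.zeros((len(ids), n_samples), dtype=int)
    whole = np.zeros((len(ids), n_samples), dtype=int)
    for j, ((t, _), f) in enumerate(zip(samples, factors)):
        e_level = truth.table[f"expression_t{t}"].to_numpy() * f
        s = np.nan_to_num(truth.table[f"splice_t{t}"].to_numpy(), nan=1.0)
        lam_e = e_level * le / 1000.0
        lam_i = e_level * (1.0 - s) * li / 1000.0
        ecount = rng.poisson(lam_e)
        icount = rng.poisson(lam_i)
        exon[:, j] = ecount
        whole[:, j] = ecount + icount

    names = [
        f"t{t}_{truth.time_points[t]}_rep{r + 1}" for (t, r) in samples
    ]
    meta = pd.DataFrame(
        {
            "time_point": [t for t, _ in samples],
            "time_label": [truth.time_points[t] for t, _ in samples],
            "batch": ["B1"] * n_samples,
            "library_size": whole.sum(axis=0).astype(float),
        },
        index=pd.Index(names, name="sample"),
    )
    counts_whole = pd.DataFrame(whole, index=pd.Index(ids, name="gene_id"), columns=names)
    counts_exon = pd.DataFrame(exon, index=pd.Index(ids, name="gene_id"), columns=names)
    return (
        CountMatrix(mode="whole_gene", counts=counts_whole, samples=meta),
        CountMatrix(mode="exon_only", counts=counts_exon, samples=meta.copy()),
    )


def expected_gene_depth(
    annot: GenomeAnnotation, truth: SimTruth, time_point: int
) -> pd.Series:
    """Expected whole-gene count per gene at unit library factor."""
    le = np.array([g.total_exon_length for g in annot.genes], float)
    li = np.array([g.total_intron_length for g in annot.genes], float)
    e = truth.table[f"expression_t{time_point}"].to_numpy()
    s = np.nan_to_num(truth.table[f"splice_t{time_point}"].to_numpy(), nan=1.0)
    return pd.Series(e * (le + (1.0 - s) * li) / 1000.0,
                     index=truth.table.index)


# ---------------------------------------------------------------------------
# Bookkeeping fixtures
# ---------------------------------------------------------------------------


def make_curation_fixture(seed: int = 0):
    """Synthetic peak/annotation/HCR fixture for the curation bookkeeping.

    Constructs, by design: 127 called regions of which 11 overlap
    hyper-ChIPable regions (leaving 116), and 33 two-gene regions among the
    116 so that 149 candidate genes resolve to 116 curated genes.  The 116
    curated genes carry IC/RP flags partitioning as 81/17/14/4; the 11
    HCR-removed genes are all IC and 9 of them RP.

    Returns ``(annot, peaks, hcr, expected)`` where ``expected`` is a dict
    of the planted bookkeeping counts.
    """
    n_pairs = {"convergent": 9, "parallel": 9, "intron_embedded": 7,
               "overlapping_3prime_exons": 8}
    n_pair_genes = 2 * sum(n_pairs.values())  # 66
    n_singles = 116 - sum(n_pairs.values())   # 83
    n_hcr = 11
    n_genes = n_pair_genes + n_singles + n_hcr  # 160

    # IC flags are assigned after construction below via class planting, so
    # build everything intron-containing first and strip introns later where
    # the class plan requires a nonIC gene.
    annot, truth = make_genome(
        n_genes=n_genes,
        frac_ic=1.0,
        frac_rp=0.0,
        seed=seed,
        n_chromosomes=4,
        pair_counts=n_pairs,
        group_sizes={},
    )

    # kept gene per region: singles keep themselves; pairs keep the first
    # member (the non-dubious one for overlapping 3'-exon pairs); pair
    # construction places members under consecutive ids
    pair_ids = sorted(
        (f"g{i + 1:04d}", f"g{i + 2:04d}") for i in range(0, n_pair_genes, 2)
    )
    kept_pair_members = [a for a, _ in pair_ids]
    single_ids = [g.id for g in annot.genes
                  if truth.table.loc[g.id, "pair_type"] == "none"]
    single_ids.sort()
    hcr_gene_ids = single_ids[-n_hcr:]
    curated_singles = single_ids[:-n_hcr]
    curated = sorted(kept_pair_members + curated_singles)  # 116 ids
    assert len(curated) == 116

    # plant the 81/17/14/4 IC-RP class partition on the curated genes
    rng = np.random.default_rng(seed + 1)
    order = list(rng.permutation(curated))
    classes = (["IC-RP"] * 81 + ["IC-nonRP"] * 17 +
               ["nonIC-RP"] * 14 + ["nonIC-nonRP"] * 4)
    genes_by_id = annot.genes_by_id
    embedded_hosts = {
        a for (ptype, a) in
        ((truth.table.loc[g.id, "pair_type"], g.id) for g in annot.genes)
        if ptype == "intron_embedded" and genes_by_id[a].n_introns > 0
    }
    # hosts of embedded genes must stay IC: swap any host drawn as nonIC
    for i, gid in enumerate(order):
        if classes[i].startswith("nonIC") and gid in embedded_hosts:
            for j, other in enumerate(order):
                if classes[j].startswith("IC") and other not in embedded_hosts:
                    order[i], order[j] = order[j], order[i]
                    break
    for gid, cls in zip(order, classes):
        g = genes_by_id[gid]
        g.is_rp = cls.endswith("-RP")
        if cls.startswith("nonIC") and g.n_introns:
            g.exons = [(g.cds_start, g.cds_end)]
    for k, gid in enumerate(hcr_gene_ids):  # all IC already; 9 of 11 RP
        genes_by_id[gid].is_rp = k < 9

    # one peak per region; summit inside the kept gene and, for pairs, the
    # peak close enough to the partner that both fall within a 500 bp flank
    peaks: list[Peak] = []
    half = 150

    def add_peak(chrom: str, summit: int) -> None:
        peaks.append(
            Peak(
                chrom=chrom,
                start=summit - half,
                end=summit + half,
                summit=summit,
                fold_enrichment=4.0,
                q_value=1e-6,
                replicate_support=3,
            )
        )

    for gid in curated_singles + hcr_gene_ids:
        g = genes_by_id[gid]
        add_peak(g.chrom, (g.cds_start + g.cds_end) // 2)
    for a, b in pair_ids:
        ga, gb = genes_by_id[a], genes_by_id[b]
        ptype = truth.table.loc[a, "pair_type"]
        if ptype == "intron_embedded":
            # summit in the host exon just downstream of the embedded gene
            summit = ga.exons[-1][0] + 100
        elif ptype == "overlapping_3prime_exons":
            summit = (gb.cds_start + ga.cds_end) // 2  # inside the overlap
        else:  # convergent / parallel: just inside the kept gene's 3' end
            summit = ga.cds_end - 100
        add_peak(ga.chrom, summit)
    peak_set = PeakSet(peaks=peaks, sample_ids=["lsm3_fixture"])
    assert len(peak_set) == 127

    hcr = [
        (genes_by_id[gid].chrom,
         (genes_by_id[gid].cds_start + genes_by_id[gid].cds_end) // 2 - 50,
         (genes_by_id[gid].cds_start + genes_by_id[gid].cds_end) // 2 + 50)
        for gid in hcr_gene_ids
    ]

    expected = {
        "peaks_called": 127,
        "peaks_after_hcr": 116,
        "candidate_genes": 149,
        "two_gene_regions": 33,
        "curated_genes": 116,
        "curated_ids": curated,
        "class_counts": {"IC-RP": 81, "IC-nonRP": 17,
                         "nonIC-RP": 14, "nonIC-nonRP": 4},
    }
    return annot, peak_set, hcr, expected


def make_cooccupancy_lists(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the curated occupancy gene lists.

    Builds a gene table (one row per gene in a 6600-gene population) with
    IC/RP flags and Mediator/Lsm3 membership whose marginal counts follow
    the study bookkeeping: 725 Mediator genes, 116 Lsm3 genes, 86 common;
    within the common set 82 RP, 76 IC and 73 IC-RP; the Lsm3 set splits
    81/17/14/4 over the four classes; population totals 376 IC, 138 RP and
    90 IC-RP genes.  Columns: ``is_ic``, ``is_rp``, ``in_mediator``,
    ``in_lsm3``.
    """
    n_pop, n_ic, n_rp, n_icrp = 6600, 376, 138, 90

    rows: list[tuple[bool, bool, bool, bool]] = []

    def add(n: int, ic: bool, rp: bool, med: bool, lsm: bool) -> None:
        rows.extend([(ic, rp, med, lsm)] * n)

    # Lsm3 & Mediator common set: 86 genes = 73 IC-RP + 9 nonIC-RP +
    # 3 IC-nonRP + 1 nonIC-nonRP (so 82 RP and 76 IC)
    add(73, True, True, True, True)
    add(9, False, True, True, True)
    add(3, True, False, True, True)
    add(1, False, False, True, True)
    # Lsm3-unique 30 genes completing the 81/17/14/4 split of the 116
    add(8, True, True, False, True)    # IC-RP: 73 + 8 = 81
    add(14, True, False, False, True)  # IC-nonRP: 3 + 14 = 17
    add(5, False, True, False, True)   # nonIC-RP: 9 + 5 = 14
    add(3, False, False, False, True)  # nonIC-nonRP: 1 + 3 = 4
    # Mediator-unique 639 genes; modest RP/IC content
    add(5, True, True, True, False)
    add(10, False, True, True, False)
    add(30, True, False, True, False)
    add(594, False, False, True, False)
    # rest of the population, honouring the global class totals
    icrp_left = n_icrp - 73 - 8 - 5          # 4
    rp_left = n_rp - (73 + 9 + 8 + 5 + 5 + 10) - icrp_left  # nonIC-RP filler
    ic_left = n_ic - (73 + 3 + 8 + 14 + 5 + 30) - icrp_left  # IC-nonRP filler
    add(icrp_left, True, True, False, False)
    add(rp_left, False, True, False, False)
    add(ic_left, True, False, False, False)
    add(n_pop - len(rows), False, False, False, False)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(rows))
    ids = [f"y{i + 1:04d}" for i in range(len(rows))]
    shuffled = [rows[p] for p in perm]
    df = pd.DataFrame(
        shuffled, columns=["is_ic", "is_rp", "in_mediator", "in_lsm3"],
        index=pd.Index(ids, name="gene_id"),
    )
    return df
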