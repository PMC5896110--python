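"""Synthetic genomes, annotations and aligned reads with known truth.

The generator emulates the data this package consumes: multi-intron genes on
both strands, a minority intron class carrying the minor-spliceosome donor
and branch-point consensus motifs, per-intron per-condition retention
fractions, spliced fragments producing N-containing CIGARs across exactly
the intron intervals, and unspliced fragments reading through intron bodies.

Two levels are provided:

* :func:`make_genome` + :func:`simulate_reads` — a full FASTA/GTF/BAM
  pipeline: each fragment independently decides, per intron it would span,
  whether it is retained (probability ``r``, fragment follows genomic
  sequence) or spliced (fragment skips the intron, CIGAR N over exactly the
  intron).  Per-gene expression is gamma-mixed so fragment totals are
  negative-binomially overdispersed.  Retention is decided per fragment
  independently (no isoform-level phasing across introns), a documented
  simplification adequate for per-intron estimators.
* :func:`simulate_counts` — a count-level generator producing paired
  intron/junction NB count matrices directly, for calibration and power
  studies of the differential tests.

All randomness flows from one seed; per-sample child seeds are derived by
fixed offsets so adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .diffir import MergedIntExResult, median_of_ratios
from .u12annot import consensus, default_pwms, reverse_complement

__all__ = [
    "SimConfig",
    "SimulatedIntron",
    "SimulatedGenome",
    "CountSimulation",
    "make_genome",
    "simulate_reads",
    "simulate_counts",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a small two-condition bulk RNA-seq experiment with a
    minority of minor-spliceosome introns, baseline retention around 10%
    (Beta(2, 18)), and a four-fold retention increase planted at a subset of
    introns in the test condition.
    """

    seed: int = 0
    n_genes: int = 20
    introns_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (80, 200)
    intron_length: tuple[int, int] = (150, 400)
    intergenic_gap: int = 300
    u12_fraction: float = 0.15
    retention_beta: tuple[float, float] = (2.0, 18.0)
    # minor-spliceosome introns are spliced less efficiently; their baseline
    # retention odds are multiplied by this factor in every condition
    u12_retention_multiplier: float = 4.0
    # fixed per-intron retention fractions cycled in intron order instead of
    # Beta draws (for designed parameter-recovery experiments)
    retention_values: tuple[float, ...] | None = None
    differential_fraction: float = 0.0
    effect_fold: float = 4.0
    conditions: tuple[str, str] = ("ctrl", "test")
    samples_per_condition: int = 4
    fragments_per_sample: int = 20_000
    read_length: int = 75
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 20.0
    paired: bool = True
    nb_overdispersion: float = 0.1
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        if not 0 <= self.u12_fraction <= 1:
            raise ValueError("u12_fraction must lie in [0,1]")
        if self.exon_length[0] * (self.introns_per_gene[0] + 1) < self.fragment_length_mean:
            raise ValueError("exon structure too short for the fragment length")
        if self.intron_length[0] < 60:
            raise ValueError("introns must be >= 60 nt to carry the planted motifs")
        if self.read_length > self.fragment_length_mean - 3 * self.fragment_length_sd:
            warnings.warn("read length close to fragment length; mates will overlap heavily")


@dataclass
class SimulatedIntron:
    gene_id: str
    ordinal: int
    chrom: str
    start: int
    end: int
    strand: str
    intron_class: str                 # "U12" | "U2"
    retention: dict[str, float]       # condition -> r
    differential: bool

    @property
    def expected_delta_psi(self) -> float:
        conds = list(self.retention)
        return self.retention[conds[-1]] - self.retention[conds[0]]


@dataclass
class SimulatedGenome:
    config: SimConfig
    chrom_sequences: dict[str, str]
    gene_exons: dict[str, list[tuple[int, int]]]  # collapsed = single isoform
    gene_strand: dict[str, str]
    introns: list[SimulatedIntron]
    intron_lookup: dict[str, list[SimulatedIntron]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for intron in self.introns:
            self.intron_lookup.setdefault(intron.gene_id, []).append(intron)

    @property
    def sample_names(self) -> list[str]:
        c = self.config
        return [f"{cond}_{k + 1}" for cond in c.conditions
                for k in range(c.samples_per_condition)]

    def condition_of(self, sample: str) -> str:
        return sample.rsplit("_", 1)[0]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.chrom_sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gid in sorted(self.gene_exons):
                strand = self.gene_strand[gid]
                for s, e in self.gene_exons[gid]:
                    fh.write("\t".join([
                        self.config.chrom_name, "sim", "exon",
                        str(s + 1), str(e), ".", strand, ".",
                        f'gene_id "{gid}"; transcript_id "{gid}.t1";',
                    ]) + "\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        conds = self.config.conditions
        with open(path, "w") as fh:
            fh.write("\t".join(
                ["gene_id", "intron_ordinal", "chrom", "begin", "end", "strand",
                 "intron_class"] + [f"retention_{c}" for c in conds]
                + ["expected_delta_psi", "differential"]) + "\n")
            for it in self.introns:
                fh.write("\t".join(
                    [it.gene_id, str(it.ordinal), it.chrom, str(it.start + 1),
                     str(it.end), it.strand, it.intron_class]
                    + [f"{it.retention[c]:.6g}" for c in conds]
                    + [f"{it.expected_delta_psi:.6g}", str(it.differential)]) + "\n")

    def write_sample_sheet(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tcondition\n")
            for s in self.sample_names:
                fh.write(f"{s}\t{self.condition_of(s)}\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _intron_sequence(rng: np.random.Generator, length: int, u12: bool,
                     motifs: dict[str, str]) -> str:
    """Intron sequence in transcription orientation: planted donor at the 5'
    end, AG acceptor, and (for the minor class) the branch-point consensus
    with its window starting 20 nt upstream of the 3' end."""
    seq = list(_random_seq(rng, length))
    donor = motifs["u12_donor"] if u12 else motifs["u2_donor"]
    seq[:len(donor)] = donor
    seq[-2:] = "AG"
    if u12:
        bp = motifs["u12_bp"]
        start = length - 20  # window start at offset -20 from the 3' end
        seq[start:start + len(bp)] = bp
    else:
        # keep the major-class branch region free of the minor consensus
        pass
    return "".join(seq)


def make_genome(config: SimConfig) -> SimulatedGenome:
    """Build a deterministic random genome + single-isoform annotation with
    planted intron classes and per-condition retention fractions."""
    rng = np.random.default_rng(config.seed)
    pwms = default_pwms()
    motifs = {
        "u12_donor": consensus(pwms["u12_donor"]),
        "u12_bp": consensus(pwms["u12_branchpoint"]),
        "u2_donor": consensus(pwms["u2_donor"]),
    }
    chrom = config.chrom_name
    chunks: list[str] = []
    pos = 0
    gene_exons: dict[str, list[tuple[int, int]]] = {}
    gene_strand: dict[str, str] = {}
    introns: list[SimulatedIntron] = []
    a, b = config.retention_beta
    cond_ref, cond_test = config.conditions

    # choose differential introns over the whole genome up front
    n_introns_per_gene = rng.integers(config.introns_per_gene[0],
                                      config.introns_per_gene[1] + 1,
                                      size=config.n_genes)
    total_introns = int(n_introns_per_gene.sum())
    n_diff = int(round(config.differential_fraction * total_introns))
    diff_flat = set(rng.choice(total_introns, size=n_diff, replace=False).tolist())
    u12_flat = set(rng.choice(total_introns,
                              size=int(round(config.u12_fraction * total_introns)),
                              replace=False).tolist())

    flat = 0
    for g in range(config.n_genes):
        gid = f"g{g + 1:03d}"
        strand = "+" if g % 2 == 0 else "-"
        n_int = int(n_introns_per_gene[g])
        gap = _random_seq(rng, config.intergenic_gap)
        chunks.append(gap)
        pos += len(gap)
        exons: list[tuple[int, int]] = []
        for i in range(n_int + 1):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            chunks.append(_random_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_int:
                ilen = int(rng.integers(config.intron_length[0],
                                        config.intron_length[1] + 1))
                is_u12 = flat in u12_flat
                iseq = _intron_sequence(rng, ilen, is_u12, motifs)
                if strand == "-":
                    iseq = reverse_complement(iseq)
                chunks.append(iseq)
                if config.retention_values is not None:
                    # explicit planted values are taken verbatim
                    r_ref = float(config.retention_values[
                        flat % len(config.retention_values)])
                elif is_u12 and config.u12_retention_multiplier != 1.0:
                    r0 = float(rng.beta(a, b))
                    odds = r0 / (1 - r0) * config.u12_retention_multiplier
                    r_ref = odds / (1 + odds)
                else:
                    r_ref = float(rng.beta(a, b))
                is_diff = flat in diff_flat
                r_test = min(0.95, r_ref * config.effect_fold) if is_diff else r_ref
                introns.append(SimulatedIntron(
                    gene_id=gid, ordinal=i + 1, chrom=chrom,
                    start=pos, end=pos + ilen, strand=strand,
                    intron_class="U12" if is_u12 else "U2",
                    retention={cond_ref: r_ref, cond_test: r_test},
                    differential=is_diff,
                ))
                pos += ilen
                flat += 1
        gene_exons[gid] = exons
        gene_strand[gid] = strand
    chunks.append(_random_seq(rng, config.intergenic_gap))
    genome = "".join(chunks)

    # minus-strand genes list introns 5'->3' in transcription order: renumber
    # ordinals to follow genomic coordinates, matching the reference builder.
    return SimulatedGenome(
        config=config, chrom_sequences={chrom: genome},
        gene_exons=gene_exons, gene_strand=gene_strand, introns=introns,
    )


def _sample_seed(base_seed: int, sample_index: int) -> int:
    return (base_seed + 7919 * (sample_index + 1)) % (2 ** 31 - 1)


def simulate_reads(
    sim: SimulatedGenome,
    out_dir: str | Path,
    max_resample_warn: float = 0.01,
) -> dict[str, Path]:
    """Write one coordinate-sorted, indexed BAM per sample plus the FASTA,
    GTF, truth and sample-sheet files.  Returns sample -> BAM path."""
    cfg = sim.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.write_fasta(out / "genome.fa")
    sim.write_gtf(out / "annot.gtf")
    sim.write_truth_tsv(out / "truth.tsv")
    sim.write_sample_sheet(out / "sample_sheet.tsv")

    chrom = cfg.chrom_name
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(sim.chrom_sequences[chrom])}],
    }
    gene_ids = sorted(sim.gene_exons)
    bam_paths: dict[str, Path] = {}

    for k, sample in enumerate(sim.sample_names):
        rng = np.random.default_rng(_sample_seed(cfg.seed, k))
        cond = sim.condition_of(sample)
        # gamma-mixed per-gene expression -> NB-overdispersed fragment totals
        alpha = max(cfg.nb_overdispersion, 1e-9)
        weights = rng.gamma(shape=1.0 / alpha, scale=alpha, size=len(gene_ids))
        lam = cfg.fragments_per_sample / len(gene_ids) * weights
        n_frags = rng.poisson(lam)

        records = []
        resampled = 0
        total = 0
        for gid, n_g in zip(gene_ids, n_frags):
            exons = sim.gene_exons[gid]
            gene_introns = sim.intron_lookup.get(gid, [])
            span = exons[-1][1] - exons[0][0]  # all-retained molecule length
            for fi in range(int(n_g)):
                total += 1
                flen = int(round(rng.normal(cfg.fragment_length_mean,
                                            cfg.fragment_length_sd)))
                flen = max(cfg.read_length, flen)
                # Draw the source molecule (per-intron retention, probability
                # r), then accept it with probability proportional to the
                # number of fragment start positions it offers.  Molecules at
                # molar frequency r thus contribute fragments in proportion
                # to their length, as sequencing does, which keeps junction
                # and boundary read densities in the exact (1-r):r ratio.
                for _ in range(200):
                    retained = [rng.random() < it.retention[cond]
                                for it in gene_introns]
                    segments = _effective_segments(exons, gene_introns, retained)
                    eff_len = sum(e - s for s, e in segments)
                    n_pos = eff_len - flen + 1
                    if n_pos > 0 and rng.random() < n_pos / (span - flen + 1):
                        break
                else:
                    resampled += 1
                    flen = min(flen, eff_len)
                start = int(rng.integers(0, eff_len - flen + 1))
                frag_id = f"{sample}:{gid}:{fi}"
                records.extend(_fragment_records(
                    frag_id, chrom, segments, start, flen,
                    cfg.read_length, cfg.paired, rng))
        if total and resampled / max(total, 1) > max_resample_warn:
            warnings.warn(
                f"{sample}: {resampled}/{total} fragments truncated to their molecule")

        unsorted = out / f".{sample}.unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            for rec in records:
                bam.write(rec_to_segment(rec, bam.header))
        bam_path = out / f"{sample}.bam"
        pysam.sort("-o", str(bam_path), str(unsorted))
        pysam.index(str(bam_path))
        unsorted.unlink()
        bam_paths[sample] = bam_path
    return bam_paths


def _effective_segments(exons, gene_introns, retained) -> list[tuple[int, int]]:
    """Genomic segments of the fragment's source isoform in coordinate
    order: exons plus retained introns, merged where contiguous."""
    segs = list(exons)
    for it, keep in zip(gene_introns, retained):
        if keep:
            segs.append((it.start, it.end))
    segs.sort()
    merged: list[tuple[int, int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _map_span(segments, t_start: int, t_len: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate span onto genomic blocks."""
    blocks = []
    offset = 0
    remaining_start = t_start
    remaining = t_len
    for s, e in segments:
        seg_len = e - s
        if remaining_start >= seg_len:
            remaining_start -= seg_len
            continue
        take = min(seg_len - remaining_start, remaining)
        blocks.append((s + remaining_start, s + remaining_start + take))
        remaining -= take
        remaining_start = 0
        if remaining == 0:
            break
    return blocks


def _cigar_from_blocks(blocks) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            cig.append((3, s - blocks[i - 1][1]))  # N
        cig.append((0, e - s))                     # M
    return cig


def rec_to_segment(rec: dict, header) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec["qname"]
    seg.flag = rec["flag"]
    seg.reference_id = header.get_tid(rec["chrom"])
    seg.reference_start = rec["pos"]
    seg.mapping_quality = 60
    seg.cigartuples = rec["cigar"]
    read_len = sum(l for op, l in rec["cigar"] if op in (0, 1, 4))
    seg.query_sequence = "A" * read_len
    seg.query_qualities = pysam.qualitystring_to_array("I" * read_len)
    if rec.get("mate_pos") is not None:
        seg.next_reference_id = seg.reference_id
        seg.next_reference_start = rec["mate_pos"]
        seg.template_length = rec["tlen"]
    else:
        seg.next_reference_id = -1
        seg.next_reference_start = -1
    return seg


def _fragment_records(frag_id, chrom, segments, start, flen, read_len, paired, rng):
    if not paired:
        blocks = _map_span(segments, start, min(read_len, flen))
        return [{
            "qname": frag_id, "flag": 0, "chrom": chrom,
            "pos": blocks[0][0], "cigar": _cigar_from_blocks(blocks),
        }]
    b1 = _map_span(segments, start, read_len)
    b2 = _map_span(segments, start + flen - read_len, read_len)
    pos1, pos2 = b1[0][0], b2[0][0]
    end2 = b2[-1][1]
    tlen = end2 - pos1
    f1 = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
    f2 = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
    return [
        {"qname": frag_id, "flag": f1, "chrom": chrom, "pos": pos1,
         "cigar": _cigar_from_blocks(b1), "mate_pos": pos2, "tlen": tlen},
        {"qname": frag_id, "flag": f2, "chrom": chrom, "pos": pos2,
         "cigar": _cigar_from_blocks(b2), "mate_pos": pos1, "tlen": -tlen},
    ]


@dataclass
class UsageCountSimulation:
    """Gene-structured intron count simulation for the usage test."""

    result: object                 # InterestResult (IntRet, intron rows only)
    condition: dict[str, str]
    differential: np.ndarray       # bool per intron row
    true_fold: np.ndarray


def simulate_usage_counts(
    n_genes: int = 125,
    introns_per_gene: int = 4,
    n_per_group: int = 4,
    seed: int = 0,
    base_mean: float = 400.0,
    base_sigma: float = 0.3,
    dispersion: float = 0.1,
    usage_dispersion: float = 0.02,
    differential_fraction: float = 0.0,
    effect_fold: float = 4.0,
    libsize_range: tuple[float, float] = (0.7, 1.3),
    conditions: tuple[str, str] = ("ctrl", "test"),
) -> UsageCountSimulation:
    """Simulate per-gene intron count matrices for the gene-wise usage test.

    All introns of a gene share the gene's expression: the gene total is
    ``D_gs ~ NB(b_g * l_s, dispersion)`` and is split multinomially among
    the introns with weights that carry a log-normal replicate jitter of
    variance ``log(1 + usage_dispersion)``; differential introns get their
    weight multiplied by ``effect_fold`` in the test condition.  This is the
    correlation structure the usage test's paired design is built for.
    """
    from .refprep import GenomicInterval, ReferenceRow
    from .summarize import InterestResult

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    cond_labels = [conditions[0]] * n_per_group + [conditions[1]] * n_per_group
    samples = [f"{c}_{i % n_per_group + 1}" for i, c in enumerate(cond_labels)]
    is_test = np.array([c == conditions[1] for c in cond_labels])

    n_introns = n_genes * introns_per_gene
    n_diff = int(round(differential_fraction * n_introns))
    diff_idx = set(rng.choice(n_introns, size=n_diff, replace=False).tolist())

    b = rng.lognormal(np.log(base_mean), base_sigma, size=n_genes)
    lib = rng.uniform(*libsize_range, size=n_samples)
    w_base = rng.gamma(2.0, 1.0, size=n_introns) + 0.2
    sigma_u = np.sqrt(np.log1p(usage_dispersion))

    counts = np.zeros((n_introns, n_samples), dtype=np.int64)
    features = []
    differential = np.zeros(n_introns, dtype=bool)
    fold = np.ones(n_introns)
    pos = 0
    for g in range(n_genes):
        gid = f"ug{g + 1:04d}"
        idx = np.arange(g * introns_per_gene, (g + 1) * introns_per_gene)
        for o, i in enumerate(idx, start=1):
            features.append(ReferenceRow(
                interval=GenomicInterval("simU", pos + 1, pos + 101),
                feature_kind="intron", gene_id=gid,
                collapsed_transcript_ids=frozenset({f"{gid}.t1"}), ordinal=o,
            ))
            pos += 200
            if i in diff_idx:
                differential[i] = True
                fold[i] = effect_fold
        mu_g = b[g] * lib
        shape = 1.0 / max(dispersion, 1e-9)
        D = rng.poisson(rng.gamma(shape, mu_g / shape)) if dispersion > 0 \
            else rng.poisson(mu_g)
        for s in range(n_samples):
            w = w_base[idx] * rng.lognormal(0.0, sigma_u, size=len(idx))
            if is_test[s]:
                w = w * fold[idx]
            counts[idx, s] = rng.multinomial(D[s], w / w.sum())

    result = InterestResult(mode="IntRet", features=features,
                            samples=samples, raw_counts=counts)
    return UsageCountSimulation(
        result=result, condition=dict(zip(samples, cond_labels)),
        differential=differential, true_fold=fold,
    )


def intron_count_result(cs: "CountSimulation"):
    """Wrap a count-level simulation's intron counts as an IntRet result
    (synthetic coordinates), for the gene-wise usage test which consumes
    intron counts only."""
    from .refprep import GenomicInterval, ReferenceRow
    from .summarize import InterestResult

    features = []
    pos = 0
    for gene_id, ordinal in cs.merged.intron_keys:
        features.append(ReferenceRow(
            interval=GenomicInterval("simC", pos + 1, pos + 101),
            feature_kind="intron", gene_id=gene_id,
            collapsed_transcript_ids=frozenset({f"{gene_id}.t1"}),
            ordinal=ordinal,
        ))
        pos += 200
    return InterestResult(
        mode="IntRet", features=features,
        samples=list(cs.merged.samples),
        raw_counts=cs.merged.intron_counts,
    )


@dataclass
class CountSimulation:
    """Count-level differential-test simulation with its ground truth."""

    merged: MergedIntExResult
    condition: dict[str, str]
    differential: np.ndarray      # bool per intron
    true_fold: np.ndarray         # planted retention fold (test vs ref)


def simulate_counts(
    n_introns: int = 500,
    n_per_group: int = 4,
    seed: int = 0,
    base_mean: float = 150.0,
    base_sigma: float = 0.3,
    retention_beta: tuple[float, float] = (2.0, 6.0),
    differential_fraction: float = 0.0,
    effect_fold: float = 4.0,
    dispersion: float = 0.1,
    retention_dispersion: float = 0.02,
    libsize_range: tuple[float, float] = (0.7, 1.3),
    conditions: tuple[str, str] = ("ctrl", "test"),
    min_intron_mean: float = 0.0,
) -> CountSimulation:
    """Draw paired intron/junction count matrices (the count-level marginal
    of the read simulator).

    The fragments informative for intron ``i`` in sample ``s`` share the
    gene's expression level: their total is ``N_is ~ NB(b_i * l_s,
    dispersion)`` with log-normal base depth ``b_i`` and library factor
    ``l_s``; each fragment then independently shows retention with
    probability ``rho_is / (1 + rho_is)``, so ``Y_is ~ Binomial(N_is, .)``
    and ``J_is = N_is - Y_is``.  The retention odds ``rho_is`` carry a
    log-normal biological jitter of variance ``log(1 + retention_dispersion)``
    across replicates, and the planted condition effect multiplies the odds
    by ``effect_fold`` (equal to the retention-level fold when retention is
    low).  Intron and junction counts are thus positively correlated through
    expression noise, the structure the paired-design tests exploit.
    ``min_intron_mean`` floors the expected baseline intron coverage, for
    designed power experiments that prescribe a minimum fragment depth.
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    cond_labels = [conditions[0]] * n_per_group + [conditions[1]] * n_per_group
    samples = [f"{c}_{i % n_per_group + 1}" for i, c in enumerate(cond_labels)]

    b = rng.lognormal(mean=np.log(base_mean), sigma=base_sigma, size=n_introns)
    r = rng.beta(*retention_beta, size=n_introns)
    rho = r / (1 - r)
    lib = rng.uniform(*libsize_range, size=n_samples)

    n_diff = int(round(differential_fraction * n_introns))
    diff_idx = rng.choice(n_introns, size=n_diff, replace=False)
    fold = np.ones(n_introns)
    fold[diff_idx] = effect_fold
    is_test = np.array([c == conditions[1] for c in cond_labels])

    if min_intron_mean > 0:
        b = np.maximum(b, min_intron_mean / np.minimum(rho / (1 + rho), 1.0)
                       / min(libsize_range))
    mu_n = b[:, None] * lib[None, :]
    if dispersion > 0:
        shape = 1.0 / dispersion
        N = rng.poisson(rng.gamma(shape, mu_n / shape))
    else:
        N = rng.poisson(mu_n)

    sigma_rho = np.sqrt(np.log1p(retention_dispersion))
    jitter = rng.lognormal(mean=0.0, sigma=sigma_rho, size=(n_introns, n_samples)) \
        if retention_dispersion > 0 else np.ones((n_introns, n_samples))
    odds = rho[:, None] * jitter \
        * np.where(is_test[None, :], fold[:, None], 1.0)
    p_ret = odds / (1.0 + odds)
    Y = rng.binomial(N, p_ret)
    J = N - Y

    merged = MergedIntExResult(
        intron_keys=[(f"sim{i // 8 + 1:04d}", i % 8 + 1) for i in range(n_introns)],
        samples=samples,
        intron_counts=Y.astype(np.int64),
        junction_counts=J.astype(np.int64),
        size_factors={"intron": median_of_ratios(Y),
                      "junction": median_of_ratios(J)},
        excluded=[],
    )
    differential = np.zeros(n_introns, dtype=bool)
    differential[diff_idx] = True
    return CountSimulation(
        merged=merged,
        condition=dict(zip(samples, cond_labels)),
        differential=differential,
        true_fold=fold,
    )
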