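"""Build the intron/exon reference from a GTF/GFF3 annotation.

Exons of all isoforms of a gene are collapsed to a non-overlapping set; the
introns are exactly the gaps between consecutive collapsed exons.  A separate
junction reference enumerates the distinct exon-exon junctions implied by each
transcript's consecutive exon pairs (repeated junctions collapsed to a single
copy), each linked back to the collapsed intron it spans when one exists.

Coordinates are 0-based half-open internally; GTF/GFF3 input (1-based
inclusive) is converted at the boundary, and emitted TSVs are 1-based
inclusive to match annotation conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "GenomicInterval",
    "ReferenceRow",
    "JunctionRef",
    "GeneModel",
    "AnnotationError",
    "parse_annotation",
    "build_reference",
    "union_junction_ref",
    "apply_repeat_mask",
    "read_bed",
    "write_reference_tsv",
    "read_reference_tsv",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class ReferenceRow:
    interval: GenomicInterval
    feature_kind: str  # "intron" | "exon"
    gene_id: str
    collapsed_transcript_ids: frozenset[str]
    ordinal: int  # 1-based within (gene, kind), 5'->3' in genomic coordinates
    intron_class: str = "unannotated"  # "U12" | "U2" | "unannotated"
    repeat_overlap_fraction: float = 0.0
    masked_subintervals: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.gene_id, self.feature_kind, self.ordinal)

    @property
    def intron_key(self) -> tuple[str, int]:
        return (self.gene_id, self.ordinal)


@dataclass(frozen=True)
class JunctionRef:
    gene_id: str
    chrom: str
    donor_end: int       # 0-based end of the upstream exon == gap start
    acceptor_start: int  # 0-based start of the downstream exon == gap end
    flanked_intron_ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError("junction donor_end must precede acceptor_start")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.gene_id, self.chrom, self.donor_end, self.acceptor_start)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attrs(attr_field: str, gff3: bool) -> dict[str, str]:
    pat = _GFF3_ATTR if gff3 else _GTF_ATTR
    return {m.group(1).strip(): m.group(2) for m in pat.finditer(attr_field)}


def parse_annotation(annotation_path: str | Path) -> dict[str, GeneModel]:
    """Read a GTF/GFF3 file into per-gene, per-transcript ordered exon lists.

    The format is sniffed per line: ``key "value";`` attributes are treated as
    GTF, ``key=value`` as GFF3 (exons attach to transcripts via ``Parent``,
    transcripts to genes via their own ``Parent``).  Returns a mapping from
    gene id to :class:`GeneModel` with exon intervals converted to 0-based
    half-open and sorted 5'->3' in genomic coordinates.
    """
    path = Path(annotation_path)
    genes: dict[str, GeneModel] = {}
    # GFF3 transcript -> gene resolution may need a second pass
    tx_parent: dict[str, str] = {}
    pending_exons: list[tuple[str, str, int, int, str, int]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            gff3 = "=" in attrs and '"' not in attrs
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise AnnotationError(f"{path}:{lineno}: invalid coordinates {start_s}-{end_s}")
            attr = _parse_attrs(attrs, gff3)
            kind = ftype.lower()
            if gff3:
                if kind in {"mrna", "transcript"}:
                    tid = attr.get("ID")
                    gid = attr.get("Parent")
                    if tid and gid:
                        tx_parent[tid] = gid
                elif kind == "exon":
                    tid = attr.get("Parent")
                    if not tid:
                        raise AnnotationError(f"{path}:{lineno}: exon without Parent attribute")
                    pending_exons.append((tid, chrom, start, end, strand, lineno))
            else:
                if kind != "exon":
                    continue
                gid = attr.get("gene_id")
                tid = attr.get("transcript_id")
                if not gid or not tid:
                    raise AnnotationError(
                        f"{path}:{lineno}: exon lacks gene_id/transcript_id attributes"
                    )
                _add_exon(genes, gid, tid, chrom, start, end, strand, path, lineno)

    for tid, chrom, start, end, strand, lineno in pending_exons:
        # A transcript id doubles as gene id when no parent record exists.
        gid = tx_parent.get(tid, tid)
        _add_exon(genes, gid, tid, chrom, start, end, strand, path, lineno)

    for gene in genes.values():
        for tid, exons in gene.transcripts.items():
            exons.sort()
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise AnnotationError(
                        f"transcript {tid} of gene {gene.gene_id} has overlapping "
                        f"exons [{s1},{e1}) and [{s2},{e2})"
                    )
    return genes


def _add_exon(genes, gid, tid, chrom, start, end, strand, path, lineno):
    gene = genes.get(gid)
    if gene is None:
        gene = genes[gid] = GeneModel(gene_id=gid, chrom=chrom, strand=strand)
    elif gene.chrom != chrom:
        raise AnnotationError(
            f"{path}:{lineno}: gene {gid} spans chromosomes {gene.chrom} and {chrom}"
        )
    gene.transcripts.setdefault(tid, []).append((start, end))


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; bookended ([a,b),[b,c)) intervals are merged."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def build_reference(
    gene_models: dict[str, GeneModel],
    strand_aware_ordinals: bool = False,
) -> list[ReferenceRow]:
    """Collapse each gene's isoform exons and derive introns as the gaps.

    Rows are sorted by (chrom, start); exon and intron ordinals are each
    1-based and consecutive within the gene, following genomic coordinates
    by default.  With ``strand_aware_ordinals`` they follow transcription
    direction instead (ordinal 1 is the 5'-most feature of the gene).
    """
    rows: list[ReferenceRow] = []
    for gid in sorted(gene_models):
        gene = gene_models[gid]
        all_exons = [iv for exons in gene.transcripts.values() for iv in exons]
        if not all_exons:
            continue
        merged = merge_intervals(all_exons)
        tids = frozenset(gene.transcripts)
        flip = strand_aware_ordinals and gene.strand == "-"

        def ordinal(i: int, n: int) -> int:
            return n - i + 1 if flip else i

        n_ex = len(merged)
        for i, (s, e) in enumerate(merged, start=1):
            rows.append(ReferenceRow(
                interval=GenomicInterval(gene.chrom, s, e, gene.strand),
                feature_kind="exon", gene_id=gid,
                collapsed_transcript_ids=tids, ordinal=ordinal(i, n_ex),
            ))
        n_int = n_ex - 1
        for i, ((_, gap_s), (gap_e, _)) in enumerate(zip(merged, merged[1:]), start=1):
            rows.append(ReferenceRow(
                interval=GenomicInterval(gene.chrom, gap_s, gap_e, gene.strand),
                feature_kind="intron", gene_id=gid,
                collapsed_transcript_ids=tids, ordinal=ordinal(i, n_int),
            ))
    rows.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end,
                             r.gene_id, r.feature_kind, r.ordinal))
    return rows


def union_junction_ref(
    gene_models: dict[str, GeneModel],
    reference: list[ReferenceRow] | None = None,
) -> list[JunctionRef]:
    """Distinct exon-exon junctions from consecutive exon pairs of every
    transcript, one copy per (gene, chrom, donor_end, acceptor_start).

    When the collapsed reference is given, each junction is linked to the
    intron whose coordinates it exactly spans (if any).
    """
    intron_by_span: dict[tuple[str, str, int, int], int] = {}
    if reference is not None:
        for row in reference:
            if row.feature_kind == "intron":
                iv = row.interval
                intron_by_span[(row.gene_id, iv.chrom, iv.start, iv.end)] = row.ordinal

    seen: dict[tuple[str, str, int, int], JunctionRef] = {}
    for gid in sorted(gene_models):
        gene = gene_models[gid]
        for exons in gene.transcripts.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if e1 >= s2:  # bookended exons imply no junction gap
                    continue
                key = (gid, gene.chrom, e1, s2)
                if key not in seen:
                    seen[key] = JunctionRef(
                        gene_id=gid, chrom=gene.chrom, donor_end=e1,
                        acceptor_start=s2,
                        flanked_intron_ordinal=intron_by_span.get(key),
                    )
    return sorted(seen.values(), key=lambda j: j.key)


def read_bed(bed_path: str | Path) -> list[GenomicInterval]:
    """Read a 3+-column BED file (0-based half-open) of repeat regions."""
    out = []
    with open(bed_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{bed_path}:{lineno}: BED needs >= 3 columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def apply_repeat_mask(
    reference: list[ReferenceRow],
    repeats: list[GenomicInterval],
    known_chroms: set[str] | None = None,
) -> list[ReferenceRow]:
    """Record repeat overlap on every reference row.

    Rows are never removed: ``repeat_overlap_fraction`` is set to
    overlap/length and the masked sub-intervals are stored so that counting
    can exclude fragments that fall entirely inside repeats.
    """
    import warnings

    ref_chroms = {r.interval.chrom for r in reference}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rep in repeats:
        if rep.chrom not in ref_chroms and (known_chroms is None or rep.chrom not in known_chroms):
            warnings.warn(f"repeat region on unknown chromosome {rep.chrom!r} ignored")
            continue
        by_chrom.setdefault(rep.chrom, []).append((rep.start, rep.end))
    by_chrom = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}

    out = []
    for row in reference:
        iv = row.interval
        masked = [
            (max(iv.start, s), min(iv.end, e))
            for s, e in by_chrom.get(iv.chrom, [])
            if s < iv.end and e > iv.start
        ]
        frac = sum(e - s for s, e in masked) / iv.length
        out.append(replace(row, repeat_overlap_fraction=frac,
                           masked_subintervals=tuple(masked)))
    return out


_REF_COLUMNS = ["chrom", "begin", "end", "strand", "kind", "gene_id", "ordinal",
                "intron_class", "repeat_fraction", "collapsed_transcript_ids"]


def write_reference_tsv(reference: list[ReferenceRow], path: str | Path) -> None:
    """Emit the reference as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("\t".join(_REF_COLUMNS) + "\n")
        for row in reference:
            iv = row.interval
            fh.write("\t".join([
                iv.chrom, str(iv.start + 1), str(iv.end), iv.strand,
                row.feature_kind, row.gene_id, str(row.ordinal),
                row.intron_class, f"{row.repeat_overlap_fraction:.6g}",
                ",".join(sorted(row.collapsed_transcript_ids)),
            ]) + "\n")


def read_reference_tsv(path: str | Path) -> list[ReferenceRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _REF_COLUMNS:
            raise AnnotationError(f"{path}: unexpected reference header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(ReferenceRow(
                interval=GenomicInterval(f[0], int(f[1]) - 1, int(f[2]), f[3]),
                feature_kind=f[4], gene_id=f[5], ordinal=int(f[6]),
                intron_class=f[7], repeat_overlap_fraction=float(f[8]),
                collapsed_transcript_ids=frozenset(x for x in f[9].split(",") if x),
            ))
    return rows
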