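"""Stream alignments from BAM/SAM, reduce them to fragments, and count them
against the intron/exon reference (IntRet mode) or the exon-exon junction
reference (ExEx mode).

The atomic counting unit is the *fragment*: a single-end read, or a read pair
with the mates' aligned blocks unioned so overlapping mates are never counted
twice.  Reads are processed in batches of ``m`` fragments; batches may be
counted on parallel workers and the partial count vectors summed, which is
exact because counting is a per-fragment sum — results are bit-identical for
every (chunk size, worker count) combination.

Counting rules, IntRet mode: a fragment supports retention of an intron when
one of its blocks overlaps the intron and either crosses an intron-exon
boundary by at least ``junction_anchor`` bases on each side, or (by default)
lies entirely within the intron.  A fragment whose splice gap (CIGAR N)
coincides exactly with the intron is a spliced fragment and never counts as
retention of that intron.  ExEx mode: a fragment supports a junction when one
of its splice gaps matches the junction exactly with anchored flanking blocks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .refprep import JunctionRef, ReferenceRow, merge_intervals

__all__ = [
    "FragmentBlocks",
    "InterestResult",
    "CountingOptions",
    "FeatureIndex",
    "JunctionIndex",
    "iterate_fragments",
    "count_intron_retention",
    "count_exon_junctions",
    "merge_partials",
    "run_summarization",
    "summarize_samples",
]


@dataclass
class FragmentBlocks:
    """One sequenced fragment reduced to genomic alignment blocks.

    ``blocks`` come from CIGAR M/=/X/D operations (D is absorbed into the
    flanking block); N operations and mate gaps split blocks, but only N
    gaps are recorded as ``splice_gaps``.
    """

    fragment_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    splice_gaps: tuple[tuple[int, int], ...] = ()
    is_paired: bool = False
    strand: str = "."


@dataclass
class CountingOptions:
    paired: bool = False
    include_contained: bool = True
    junction_anchor: int = 1
    exclude_repeats: bool = False
    count_secondary: bool = False
    ignore_duplicates: bool = False
    stranded: str | None = None  # None | "forward" | "reverse"
    # Which intron-exon boundary crossings support retention: "either" counts
    # a block crossing either boundary (the default descriptive mode);
    # "donor" restricts to the transcriptional 5' boundary, giving retention
    # support the same geometric opportunity as an exon-exon junction read —
    # the matched configuration the PSI estimator relies on.
    retention_boundary: str = "either"


def _read_to_blocks(read: pysam.AlignedSegment) -> tuple[tuple[tuple[int, int], ...],
                                                         tuple[tuple[int, int], ...]]:
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    block_start: int | None = None
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a block
            if block_start is None:
                block_start = pos
            pos += length
        elif op == 3:  # N: splice gap splits blocks
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            gaps.append((pos, pos + length))
            pos += length
        # I, S, H, P do not consume reference
    if block_start is not None:
        blocks.append((block_start, pos))
    return tuple(blocks), tuple(gaps)


def _fragment_from_reads(reads: list[pysam.AlignedSegment]) -> FragmentBlocks:
    all_blocks: list[tuple[int, int]] = []
    all_gaps: set[tuple[int, int]] = set()
    for r in reads:
        b, g = _read_to_blocks(r)
        all_blocks.extend(b)
        all_gaps.update(g)
    blocks = tuple(merge_intervals(all_blocks))
    # A gap overlapped by a block of the other mate is not a consistent splice
    # gap of the fragment; drop it defensively.
    gaps = tuple(sorted(
        (gs, ge) for gs, ge in all_gaps
        if not any(bs < ge and be > gs for bs, be in blocks)
    ))
    first = reads[0]
    r1 = next((r for r in reads if not r.is_paired or r.is_read1), first)
    strand = "-" if r1.is_reverse else "+"
    return FragmentBlocks(
        fragment_id=first.query_name or "",
        chrom=first.reference_name or "",
        blocks=blocks,
        splice_gaps=gaps,
        is_paired=len(reads) > 1,
        strand=strand,
    )


def iterate_fragments(
    bam_path: str | Path,
    chunk_size: int = 1_000_000,
    paired: bool = False,
    options: CountingOptions | None = None,
) -> Iterator[list[FragmentBlocks]]:
    """Yield batches of at most ``chunk_size`` fragments from a BAM/SAM file.

    Default filters drop unmapped, secondary and supplementary alignments.
    With ``paired`` the two mates of a pair are joined into one fragment; a
    read whose mate never appears is emitted as a single-read fragment.
    Every passing alignment contributes to exactly one fragment in exactly
    one batch.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    opts = options or CountingOptions(paired=paired)
    path = str(bam_path)
    mode = "r" if path.endswith(".sam") else "rb"
    batch: list[FragmentBlocks] = []
    # pending mates keyed by (qname, chrom); coordinate distance is unbounded
    # within a chromosome, so pairs split across chromosomes fall back to
    # single-read fragments.
    pending: dict[tuple[str, str], pysam.AlignedSegment] = {}

    with pysam.AlignmentFile(path, mode) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_supplementary:
                continue
            if read.is_secondary and not opts.count_secondary:
                continue
            if read.is_duplicate and opts.ignore_duplicates:
                continue
            if paired and read.is_paired and read.is_proper_pair \
                    and read.reference_name == read.next_reference_name:
                key = (read.query_name or "", read.reference_name or "")
                mate = pending.pop(key, None)
                if mate is None:
                    pending[key] = read
                    continue
                batch.append(_fragment_from_reads([mate, read]))
            else:
                batch.append(_fragment_from_reads([read]))
            if len(batch) >= chunk_size:
                yield batch
                batch = []
        # unmatched mates become single-read fragments
        for read in pending.values():
            batch.append(_fragment_from_reads([read]))
            if len(batch) >= chunk_size:
                yield batch
                batch = []
    if batch:
        yield batch


class FeatureIndex:
    """Interval lookup over reference rows for IntRet counting."""

    def __init__(self, reference: Sequence[ReferenceRow]):
        self.rows = list(reference)
        self.trees: dict[str, IntervalTree] = {}
        for idx, row in enumerate(self.rows):
            iv = row.interval
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)

    def __len__(self) -> int:
        return len(self.rows)

    def candidates(self, chrom: str, start: int, end: int) -> set[int]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(start, end)}


class JunctionIndex:
    """Exact-gap lookup over junction references for ExEx counting."""

    def __init__(self, junctions: Sequence[JunctionRef]):
        self.junctions = list(junctions)
        self.by_gap: dict[tuple[str, int, int], list[int]] = {}
        for idx, j in enumerate(self.junctions):
            self.by_gap.setdefault((j.chrom, j.donor_end, j.acceptor_start), []).append(idx)

    def __len__(self) -> int:
        return len(self.junctions)


def _block_supports_feature(
    block: tuple[int, int], start: int, end: int,
    anchor: int, include_contained: bool,
    boundaries: str = "either", strand: str = ".",
) -> bool:
    bs, be = block
    if min(be, end) - max(bs, start) <= 0:
        return False
    crosses_left = bs <= start - anchor and be >= start + anchor
    crosses_right = bs <= end - anchor and be >= end + anchor
    if boundaries == "donor":
        crossed = crosses_right if strand == "-" else crosses_left
    else:
        crossed = crosses_left or crosses_right
    if crossed:
        return True
    return include_contained and bs >= start and be <= end


def _overlap_fully_masked(
    blocks: Sequence[tuple[int, int]], start: int, end: int,
    masked: Sequence[tuple[int, int]],
) -> bool:
    for bs, be in blocks:
        s, e = max(bs, start), min(be, end)
        if s >= e:
            continue
        # overlap segment [s,e) must be covered by the masked sub-intervals
        pos = s
        for ms, me in masked:
            if ms <= pos < me:
                pos = min(e, me)
                if pos >= e:
                    break
        if pos < e:
            return False
    return True


def _strand_ok(frag: FragmentBlocks, feat_strand: str, stranded: str | None) -> bool:
    if stranded is None or feat_strand == ".":
        return True
    frag_strand = frag.strand if stranded == "forward" else ("+" if frag.strand == "-" else "-")
    return frag_strand == feat_strand


def count_intron_retention(
    batch: Iterable[FragmentBlocks],
    reference: FeatureIndex | Sequence[ReferenceRow],
    include_contained: bool = True,
    junction_anchor: int = 1,
    exclude_repeats: bool = False,
    stranded: str | None = None,
    retention_boundary: str = "either",
) -> np.ndarray:
    """Count fragments supporting retention of each reference feature.

    Returns an integer vector aligned with the reference rows; each fragment
    increments a given feature at most once.
    """
    index = reference if isinstance(reference, FeatureIndex) else FeatureIndex(reference)
    counts = np.zeros(len(index), dtype=np.int64)
    for frag in batch:
        cand: set[int] = set()
        for bs, be in frag.blocks:
            cand |= index.candidates(frag.chrom, bs, be)
        for idx in cand:
            row = index.rows[idx]
            iv = row.interval
            if not _strand_ok(frag, iv.strand, stranded):
                continue
            if row.feature_kind == "intron" and (iv.start, iv.end) in frag.splice_gaps:
                continue  # spliced across this intron
            if exclude_repeats and row.masked_subintervals and _overlap_fully_masked(
                    frag.blocks, iv.start, iv.end, row.masked_subintervals):
                continue
            bnd = retention_boundary if row.feature_kind == "intron" else "either"
            if any(_block_supports_feature(b, iv.start, iv.end, junction_anchor,
                                           include_contained, bnd, iv.strand)
                   for b in frag.blocks):
                counts[idx] += 1
    return counts


def count_exon_junctions(
    batch: Iterable[FragmentBlocks],
    junction_ref: JunctionIndex | Sequence[JunctionRef],
    junction_anchor: int = 1,
    stranded: str | None = None,
) -> np.ndarray:
    """Count fragments whose splice gaps exactly match each reference junction."""
    index = junction_ref if isinstance(junction_ref, JunctionIndex) else JunctionIndex(junction_ref)
    counts = np.zeros(len(index), dtype=np.int64)
    for frag in batch:
        hit: set[int] = set()
        for gs, ge in frag.splice_gaps:
            idxs = index.by_gap.get((frag.chrom, gs, ge))
            if not idxs:
                continue
            left_ok = any(be == gs and be - bs >= junction_anchor for bs, be in frag.blocks)
            right_ok = any(bs == ge and be - bs >= junction_anchor for bs, be in frag.blocks)
            if left_ok and right_ok:
                hit.update(idxs)
        for idx in hit:
            counts[idx] += 1
    return counts


def merge_partials(partials: Sequence[np.ndarray], n_features: int | None = None) -> np.ndarray:
    """Element-wise sum of partial count vectors (associative and commutative,
    so the merged result does not depend on batch boundaries or scheduling)."""
    partials = list(partials)
    if not partials:
        if n_features is None:
            raise ValueError("empty partial list requires n_features")
        return np.zeros(n_features, dtype=np.int64)
    sizes = {len(p) for p in partials}
    if len(sizes) != 1:
        raise ValueError(f"mismatched feature spaces in partials: sizes {sorted(sizes)}")
    return np.sum(partials, axis=0).astype(np.int64)


@dataclass
class InterestResult:
    """Feature x sample count matrix with per-feature metadata."""

    mode: str  # "IntRet" | "ExEx"
    features: list  # ReferenceRow (IntRet) or JunctionRef (ExEx)
    samples: list[str]
    raw_counts: np.ndarray  # int, features x samples
    normalized: np.ndarray | None = None  # FPKM (IntRet mode)
    run_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts)
        if self.raw_counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("raw_counts shape does not match features x samples")
        if (self.raw_counts < 0).any():
            raise ValueError("raw counts must be non-negative")

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def to_dataframe(self, normalized: bool = False):
        import pandas as pd

        mat = self.normalized if normalized else self.raw_counts
        if mat is None:
            raise ValueError("no normalized matrix available")
        if self.mode == "IntRet":
            meta = {
                "chrom": [f.interval.chrom for f in self.features],
                "begin": [f.interval.start + 1 for f in self.features],
                "end": [f.interval.end for f in self.features],
                "strand": [f.interval.strand for f in self.features],
                "kind": [f.feature_kind for f in self.features],
                "gene_id": [f.gene_id for f in self.features],
                "ordinal": [f.ordinal for f in self.features],
                "intron_class": [f.intron_class for f in self.features],
            }
        else:
            meta = {
                "chrom": [j.chrom for j in self.features],
                "donor_end": [j.donor_end for j in self.features],
                "acceptor_start": [j.acceptor_start for j in self.features],
                "gene_id": [j.gene_id for j in self.features],
                "flanked_intron_ordinal": [
                    -1 if j.flanked_intron_ordinal is None else j.flanked_intron_ordinal
                    for j in self.features],
            }
        df = pd.DataFrame(meta)
        for k, s in enumerate(self.samples):
            df[s] = mat[:, k]
        return df

    def write_tsv(self, path: str | Path, normalized: bool = False) -> None:
        self.to_dataframe(normalized=normalized).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parallel worker machinery: each worker process builds its index once

_WORKER_STATE: dict = {}


def _init_worker(mode: str, features, opts: CountingOptions) -> None:
    if mode == "IntRet":
        _WORKER_STATE["index"] = FeatureIndex(features)
    else:
        _WORKER_STATE["index"] = JunctionIndex(features)
    _WORKER_STATE["mode"] = mode
    _WORKER_STATE["opts"] = opts


def _count_batch_worker(batch: list[FragmentBlocks]) -> np.ndarray:
    opts: CountingOptions = _WORKER_STATE["opts"]
    if _WORKER_STATE["mode"] == "IntRet":
        return count_intron_retention(
            batch, _WORKER_STATE["index"],
            include_contained=opts.include_contained,
            junction_anchor=opts.junction_anchor,
            exclude_repeats=opts.exclude_repeats,
            stranded=opts.stranded,
            retention_boundary=opts.retention_boundary,
        )
    return count_exon_junctions(
        batch, _WORKER_STATE["index"],
        junction_anchor=opts.junction_anchor, stranded=opts.stranded,
    )


def _count_sample(
    bam_path: str | Path, mode: str, features, chunk_size: int,
    n_workers: int, opts: CountingOptions,
) -> np.ndarray:
    batches = iterate_fragments(bam_path, chunk_size=chunk_size,
                                paired=opts.paired, options=opts)
    if n_workers <= 1:
        _init_worker(mode, features, opts)
        partials = [_count_batch_worker(b) for b in batches]
    else:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(
            max_workers=n_workers, initializer=_init_worker,
            initargs=(mode, features, opts),
        ) as pool:
            partials = list(pool.map(_count_batch_worker, batches, chunksize=1))
    return merge_partials(partials, n_features=len(features))


def run_summarization(
    bam_path: str | Path | dict[str, str | Path],
    reference: Sequence[ReferenceRow] | None = None,
    mode: str = "IntRet",
    chunk_size: int = 1_000_000,
    n_workers: int = 1,
    junction_ref: Sequence[JunctionRef] | None = None,
    options: CountingOptions | None = None,
) -> InterestResult:
    """Summarize one or more BAM files into an :class:`InterestResult`.

    ``bam_path`` may be a single path (sample named after the file stem) or a
    mapping of sample name to path.  ``mode`` selects intron-retention
    (``IntRet``, requires ``reference``) or exon-exon junction counting
    (``ExEx``, requires ``junction_ref``).  FPKM normalization is attached in
    IntRet mode.  Results are deterministic and independent of ``chunk_size``
    and ``n_workers``.
    """
    if mode not in ("IntRet", "ExEx"):
        raise ValueError(f"unknown mode {mode!r}")
    features = list(reference) if mode == "IntRet" else list(junction_ref or [])
    if not features and mode == "IntRet" and reference is None:
        raise ValueError("IntRet mode requires a reference")
    if mode == "ExEx" and junction_ref is None:
        raise ValueError("ExEx mode requires a junction reference")
    opts = options or CountingOptions()
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")

    if isinstance(bam_path, (str, Path)):
        samples = {Path(bam_path).stem: bam_path}
    else:
        samples = dict(bam_path)

    counts = np.zeros((len(features), len(samples)), dtype=np.int64)
    for k, (name, path) in enumerate(samples.items()):
        if not os.path.exists(str(path)):
            raise FileNotFoundError(f"alignment file not found: {path}")
        counts[:, k] = _count_sample(path, mode, features, chunk_size, n_workers, opts)

    result = InterestResult(
        mode=mode, features=features, samples=list(samples),
        raw_counts=counts,
        run_metadata={
            "chunk_size": chunk_size, "n_workers": n_workers,
            "include_contained": opts.include_contained,
            "junction_anchor": opts.junction_anchor,
            "exclude_repeats": opts.exclude_repeats,
            "stranded": opts.stranded, "paired": opts.paired,
            "retention_boundary": opts.retention_boundary,
        },
    )
    if mode == "IntRet":
        from .quantify import fpkm

        result.normalized = fpkm(result)
    return result


def summarize_samples(
    bam_paths: dict[str, str | Path], **kwargs
) -> InterestResult:
    """Alias of :func:`run_summarization` for explicit multi-sample calls."""
    return run_summarization(bam_paths, **kwargs)
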