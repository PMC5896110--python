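"""Shared fixtures: tiny hand-written annotations and a small simulated
dataset (genome + GTF + per-sample BAMs with ground truth) reused across
module tests, plus independent brute-force counting oracles."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pysam
import pytest

from intrest.refprep import build_reference, parse_annotation, union_junction_ref
from intrest.simdata import SimConfig, make_genome, simulate_reads


def write_gtf(path: Path, rows: list[tuple[str, int, int, str, str, str]]) -> Path:
    """rows: (chrom, start1, end1, strand, gene_id, transcript_id)."""
    with open(path, "w") as fh:
        for chrom, s, e, strand, gid, tid in rows:
            fh.write("\t".join([
                chrom, "test", "exon", str(s), str(e), ".", strand, ".",
                f'gene_id "{gid}"; transcript_id "{tid}";']) + "\n")
    return path


@pytest.fixture()
def two_isoform_gtf(tmp_path):
    # g1: t1 exons [100,200),[400,500); t2 exons [100,250),[400,500)
    return write_gtf(tmp_path / "two_isoform.gtf", [
        ("chr1", 101, 200, "+", "g1", "t1"),
        ("chr1", 401, 500, "+", "g1", "t1"),
        ("chr1", 101, 250, "+", "g1", "t2"),
        ("chr1", 401, 500, "+", "g1", "t2"),
    ])


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Small two-condition simulation shared by counting/quantify tests."""
    cfg = SimConfig(seed=42, n_genes=10, fragments_per_sample=4000,
                    samples_per_condition=2, differential_fraction=0.2,
                    u12_fraction=0.2)
    sim = make_genome(cfg)
    out = tmp_path_factory.mktemp("small_sim")
    bams = simulate_reads(sim, out)
    genes = parse_annotation(out / "annot.gtf")
    reference = build_reference(genes)
    junctions = union_junction_ref(genes, reference)
    return {"sim": sim, "dir": out, "bams": bams,
            "reference": reference, "junctions": junctions}


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive: re-derive everything from pysam
# records with plain loops, no shared code with the counting path)

def oracle_fragments(bam_path, paired: bool):
    """(blocks, gaps) per fragment, re-derived independently."""
    frags = {}
    order = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            blocks, gaps = [], []
            pos = read.reference_start
            start = None
            for op, ln in read.cigartuples:
                if op in (0, 7, 8, 2):
                    if start is None:
                        start = pos
                    pos += ln
                elif op == 3:
                    blocks.append((start, pos))
                    start = None
                    gaps.append((pos, pos + ln))
                    pos += ln
            if start is not None:
                blocks.append((start, pos))
            key = read.query_name if paired else (read.query_name, read.flag)
            if key not in frags:
                frags[key] = (read.reference_name, [], [])
                order.append(key)
            frags[key][1].extend(blocks)
            frags[key][2].extend(gaps)
    out = []
    for key in order:
        chrom, blocks, gaps = frags[key]
        merged = []
        for s, e in sorted(blocks):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        merged = [tuple(b) for b in merged]
        gaps = sorted({g for g in gaps
                       if not any(bs < g[1] and be > g[0] for bs, be in merged)})
        out.append((chrom, merged, gaps))
    return out


def oracle_intron_counts(fragments, rows, include_contained=True, anchor=1,
                         boundary="either"):
    counts = [0] * len(rows)
    for chrom, blocks, gaps in fragments:
        for i, row in enumerate(rows):
            iv = row.interval
            if iv.chrom != chrom:
                continue
            if row.feature_kind == "intron" and (iv.start, iv.end) in gaps:
                continue
            hit = False
            for bs, be in blocks:
                if min(be, iv.end) - max(bs, iv.start) <= 0:
                    continue
                left = bs <= iv.start - anchor and be >= iv.start + anchor
                right = bs <= iv.end - anchor and be >= iv.end + anchor
                if row.feature_kind == "intron" and boundary == "donor":
                    crossed = right if iv.strand == "-" else left
                else:
                    crossed = left or right
                if crossed or (include_contained and bs >= iv.start and be <= iv.end):
                    hit = True
            if hit:
                counts[i] += 1
    return np.array(counts)


def oracle_junction_counts(fragments, junctions, anchor=1):
    counts = [0] * len(junctions)
    for chrom, blocks, gaps in fragments:
        for j, jr in enumerate(junctions):
            if jr.chrom != chrom:
                continue
            if (jr.donor_end, jr.acceptor_start) not in gaps:
                continue
            left = any(be == jr.donor_end and be - bs >= anchor for bs, be in blocks)
            right = any(bs == jr.acceptor_start and be - bs >= anchor
                        for bs, be in blocks)
            if left and right:
                counts[j] += 1
    return np.array(counts)


def binom_3sd(r: float, n: int) -> float:
    return 3.0 * math.sqrt(max(r * (1.0 - r), 1e-12) / n)
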