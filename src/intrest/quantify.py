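"""Normalization and effect sizes for intron retention.

The descriptive quantities are:

* transcript-scaled FPKM: for intron *i* of gene *g* with introns
  ``k = 1..I``, ``FPKM_ig = X_ig / (L_ig * sum_k X_kg) * 1e9`` — fragments
  per kilobase scaled by the gene's total intron-mapped fragments, which
  makes retention comparable across genes regardless of expression level;
* PSI (percent spliced in): ``psi = R / (R + S)`` where R counts fragments
  supporting retention of the intron and S counts fragments spliced across
  it (exon-exon junction reads); left undefined below a support floor.
  For PSI to estimate the retention fraction without bias, R must be counted
  with the same geometric opportunity as a junction read: a junction read
  must span one splice point, so retention support must likewise be
  restricted to fragments crossing one splice point (the donor boundary)
  rather than any fragment touching the intron body, whose opportunity grows
  with intron length.  :func:`psi_counting_options` returns the matched
  counting configuration; conditional on the total support R+S, R is then
  Binomial(R+S, r) for true retention fraction r;
* delta-PSI: difference of group-mean PSI between two conditions, in [-1, 1];
* log2 fold change of library-size-scaled retention counts between groups.

Undefined values propagate as NaN and never silently become 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .refprep import JunctionRef, ReferenceRow
from .summarize import CountingOptions, InterestResult

__all__ = [
    "PsiTable",
    "fpkm",
    "psi",
    "psi_counting_options",
    "delta_psi",
    "lfc",
    "low_count_filter",
    "link_junctions_to_introns",
]


def psi_counting_options(paired: bool = False, junction_anchor: int = 1,
                         **kwargs) -> CountingOptions:
    """Counting options for PSI retention support, matched to junction-read
    geometry: only fragments whose block crosses the intron's donor boundary
    count, intron-body-contained fragments do not."""
    return CountingOptions(
        paired=paired, junction_anchor=junction_anchor,
        include_contained=False, retention_boundary="donor", **kwargs)


def fpkm(result: InterestResult) -> np.ndarray:
    """Transcript-scaled FPKM for every feature of an IntRet result.

    The denominator for an intron is the sum of raw counts over *all introns
    of its gene* (and, symmetrically, the gene's exon-count sum for exon
    rows).  Genes whose denominator is zero yield NaN, not 0.
    """
    if result.mode != "IntRet":
        raise ValueError("fpkm applies to IntRet results")
    counts = result.raw_counts.astype(float)
    out = np.full_like(counts, np.nan)
    lengths = np.array([f.interval.length for f in result.features], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero-length feature in reference")

    groups: dict[tuple[str, str], list[int]] = {}
    for i, f in enumerate(result.features):
        groups.setdefault((f.gene_id, f.feature_kind), []).append(i)
    for idxs in groups.values():
        idx = np.array(idxs)
        denom = counts[idx].sum(axis=0)  # per sample
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = counts[idx] / (lengths[idx, None] * denom[None, :]) * 1e9
        vals[:, denom == 0] = np.nan
        out[idx] = vals
    return out


def link_junctions_to_introns(
    intret_features: Sequence[ReferenceRow],
    junctions: Sequence[JunctionRef],
) -> dict[int, list[int]]:
    """Map intron feature index -> indices of junctions spanning it."""
    intron_pos: dict[tuple[str, int], int] = {}
    for i, f in enumerate(intret_features):
        if f.feature_kind == "intron":
            intron_pos[(f.gene_id, f.ordinal)] = i
    links: dict[int, list[int]] = {}
    for j, jr in enumerate(junctions):
        if jr.flanked_intron_ordinal is None:
            continue
        i = intron_pos.get((jr.gene_id, jr.flanked_intron_ordinal))
        if i is not None:
            links.setdefault(i, []).append(j)
    return links


@dataclass
class PsiTable:
    """Per-intron, per-sample percent-spliced-in with its supporting counts."""

    intron_keys: list[tuple[str, int]]      # (gene_id, ordinal)
    samples: list[str]
    psi: np.ndarray                          # introns x samples, NaN = undefined
    retention_support: np.ndarray            # R_is
    splice_support: np.ndarray               # S_is
    min_support: int
    undefined_reason: list[str | None]       # per intron: "no_junction" | None

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({
            "gene_id": [k[0] for k in self.intron_keys],
            "intron_ordinal": [k[1] for k in self.intron_keys],
            "undefined_reason": ["" if r is None else r for r in self.undefined_reason],
        })
        for k, s in enumerate(self.samples):
            df[f"psi_{s}"] = self.psi[:, k]
            df[f"R_{s}"] = self.retention_support[:, k]
            df[f"S_{s}"] = self.splice_support[:, k]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def psi(
    intret: InterestResult,
    exex: InterestResult,
    min_support: int = 10,
) -> PsiTable:
    """PSI per intron per sample: R/(R+S) where S sums the junction(s)
    spanning the intron; undefined (NaN) when R+S is below ``min_support``
    or the intron has no linked junction."""
    if intret.samples != exex.samples:
        raise ValueError("IntRet and ExEx results must share the same sample set")
    links = link_junctions_to_introns(intret.features, exex.features)
    intron_idx = [i for i, f in enumerate(intret.features) if f.feature_kind == "intron"]
    n, S = len(intron_idx), len(intret.samples)
    R_mat = np.zeros((n, S), dtype=np.int64)
    S_mat = np.zeros((n, S), dtype=np.int64)
    psis = np.full((n, S), np.nan)
    reasons: list[str | None] = []
    keys = []
    for r, i in enumerate(intron_idx):
        feat = intret.features[i]
        keys.append((feat.gene_id, feat.ordinal))
        R_mat[r] = intret.raw_counts[i]
        jidx = links.get(i)
        if not jidx:
            reasons.append("no_junction")
            continue
        reasons.append(None)
        S_mat[r] = exex.raw_counts[jidx].sum(axis=0)
        total = R_mat[r] + S_mat[r]
        ok = total >= min_support
        psis[r, ok] = R_mat[r, ok] / total[ok]
    return PsiTable(
        intron_keys=keys, samples=list(intret.samples), psi=psis,
        retention_support=R_mat, splice_support=S_mat,
        min_support=min_support, undefined_reason=reasons,
    )


def delta_psi(
    psi_table: PsiTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> np.ndarray:
    """Mean PSI of group A minus mean PSI of group B per intron (NaN when
    either group has no defined PSI).  Values lie in [-1, 1]."""
    ga = set(group_a)
    gb = set(group_b)
    if not ga or not gb:
        raise ValueError("groups must be non-empty")
    if ga & gb:
        raise ValueError("groups must be disjoint")
    ia = [psi_table.samples.index(s) for s in group_a]
    ib = [psi_table.samples.index(s) for s in group_b]
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        ma = np.nanmean(psi_table.psi[:, ia], axis=1)
        mb = np.nanmean(psi_table.psi[:, ib], axis=1)
    return ma - mb


def lfc(
    result: InterestResult,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 0.5,
    library_sizes: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-feature log2 fold change of retention between two conditions.

    Raw counts are scaled to counts-per-million of the sample's total mapped
    fragments (column totals unless ``library_sizes`` is given), the group
    means taken, and a fixed additive pseudocount applied before the ratio so
    zero-count groups stay finite.
    """
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    ia = [result.sample_index(s) for s in group_a]
    ib = [result.sample_index(s) for s in group_b]
    if library_sizes is None:
        libs = result.raw_counts.sum(axis=0).astype(float)
    else:
        libs = np.array([library_sizes[s] for s in result.samples], dtype=float)
    libs = np.where(libs == 0, 1.0, libs)
    cpm = result.raw_counts / libs[None, :] * 1e6
    mean_a = cpm[:, ia].mean(axis=1)
    mean_b = cpm[:, ib].mean(axis=1)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def low_count_filter(result: InterestResult, threshold: float = 1.0) -> InterestResult:
    """Drop all features of genes whose introns *all* have cross-sample mean
    raw count at or below ``threshold``; genes with at least one adequately
    covered intron are kept whole.  Genes without introns are kept."""
    if result.mode != "IntRet":
        raise ValueError("low_count_filter applies to IntRet results")
    means = result.raw_counts.mean(axis=1)
    gene_keep: dict[str, bool] = {}
    gene_has_intron: dict[str, bool] = {}
    for i, f in enumerate(result.features):
        if f.feature_kind == "intron":
            gene_has_intron[f.gene_id] = True
            if means[i] > threshold:
                gene_keep[f.gene_id] = True
    keep_idx = [
        i for i, f in enumerate(result.features)
        if gene_keep.get(f.gene_id, not gene_has_intron.get(f.gene_id, False))
    ]
    idx = np.array(keep_idx, dtype=int)
    return InterestResult(
        mode=result.mode,
        features=[result.features[i] for i in keep_idx],
        samples=list(result.samples),
        raw_counts=result.raw_counts[idx] if len(idx) else
            np.zeros((0, len(result.samples)), dtype=np.int64),
        normalized=None if result.normalized is None else
            (result.normalized[idx] if len(idx) else
             np.zeros((0, len(result.samples)))),
        run_metadata=dict(result.run_metadata, low_count_threshold=threshold),
    )
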