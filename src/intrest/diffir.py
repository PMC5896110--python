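"""Differential intron-retention statistics.

Three test styles are provided, all built on per-intron negative-binomial
GLMs (see :mod:`intrest.nbglm`):

* deseq-style — per intron, the intron-retention counts and the counts of
  the exon-exon junction(s) spanning it are stacked into one 2S-observation
  model ``~ covariates + measurement_type + condition +
  condition:measurement_type``; the Wald test on the interaction asks
  whether retention changed *relative to* the junction (expression) level.
  Observations with outlying Cook's distances invalidate the intron's test,
  mirroring the default outlier policy of count-based differential tools.
* edger-style — identical stacked model, but a likelihood-ratio test of the
  interaction and no Cook's filtering.
* dexseq-style — a gene-wise usage test on intron counts only: each intron is
  compared against the summed counts of the *other* introns of its gene, so
  the null is "this intron's retention moved like the rest of the gene".

P-values are Benjamini-Hochberg adjusted over the tested introns.  A
permutation Jonckheere-Terpstra trend test for ordered group alternatives is
included for class-level comparisons (e.g. retention of minor-spliceosome
introns across condition severity).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .nbglm import NBFit, fit_nb_glm, fit_single, lr_test, wald_test
from .quantify import link_junctions_to_introns
from .summarize import InterestResult

__all__ = [
    "MergedIntExResult",
    "DifferentialResult",
    "merge_int_ex",
    "median_of_ratios",
    "deseq_style_test",
    "edger_style_test",
    "dexseq_style_test",
    "bh_adjust",
    "jonckheere_statistic",
    "jonckheere_trend_test",
    "results_to_dataframe",
    "write_differential_tsv",
]

LN2 = float(np.log(2.0))


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Per-sample size factors by the median-of-ratios rule over features
    with all-nonzero rows; falls back to total-count ratios (normalized to
    geometric mean 1) when no such row exists."""
    counts = np.asarray(counts, dtype=float)
    ok = (counts > 0).all(axis=1)
    if ok.sum() >= 1:
        logs = np.log(counts[ok])
        ref = logs.mean(axis=1)  # log geometric mean per feature
        sf = np.exp(np.median(logs - ref[:, None], axis=0))
        if np.all(np.isfinite(sf)) and np.all(sf > 0):
            return sf
    totals = counts.sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


@dataclass
class MergedIntExResult:
    """Per-intron paired intron/junction counts across samples."""

    intron_keys: list[tuple[str, int]]   # (gene_id, ordinal)
    samples: list[str]
    intron_counts: np.ndarray            # Y_is, introns x samples
    junction_counts: np.ndarray          # J_is, introns x samples
    size_factors: dict[str, np.ndarray]  # {"intron": ..., "junction": ...}
    excluded: list[tuple[tuple[str, int], str]]
    sample_annotations: dict[str, dict] | None = None


def merge_int_ex(
    intret: InterestResult,
    exex: InterestResult,
    shared_size_factors: bool = False,
) -> MergedIntExResult:
    """Pair every intron's retention counts with the counts of the exon-exon
    junction(s) spanning it; introns without a linked junction are excluded
    with a reason.  Size factors are computed per measurement type by
    default so depth differences cannot masquerade as retention changes."""
    if set(intret.samples) != set(exex.samples):
        raise ValueError("IntRet and ExEx results must cover the same samples")
    order = [exex.samples.index(s) for s in intret.samples]
    links = link_junctions_to_introns(intret.features, exex.features)

    keys, Y, J = [], [], []
    excluded: list[tuple[tuple[str, int], str]] = []
    for i, f in enumerate(intret.features):
        if f.feature_kind != "intron":
            continue
        key = (f.gene_id, f.ordinal)
        jidx = links.get(i)
        if not jidx:
            excluded.append((key, "no_junction"))
            continue
        keys.append(key)
        Y.append(intret.raw_counts[i])
        J.append(exex.raw_counts[jidx][:, order].sum(axis=0))
    Y = np.array(Y, dtype=np.int64).reshape(len(keys), len(intret.samples))
    J = np.array(J, dtype=np.int64).reshape(len(keys), len(intret.samples))
    if shared_size_factors:
        sf = median_of_ratios(np.vstack([Y, J]))
        size_factors = {"intron": sf, "junction": sf.copy()}
    else:
        size_factors = {"intron": median_of_ratios(Y),
                        "junction": median_of_ratios(J)}
    return MergedIntExResult(
        intron_keys=keys, samples=list(intret.samples),
        intron_counts=Y, junction_counts=J,
        size_factors=size_factors, excluded=excluded,
    )


@dataclass
class DifferentialResult:
    intron_key: tuple[str, int]
    log2_fold_change: float
    statistic: float
    p_value: float
    p_adjusted: float
    direction: str               # "up" | "down" | "ns"
    test_name: str
    filtered_reason: str | None = None


def _condition_vector(
    samples: Sequence[str],
    condition: Mapping[str, str] | Sequence[str],
    test_level: str | None,
    ref_level: str | None,
) -> tuple[np.ndarray, str, str]:
    if isinstance(condition, Mapping):
        labels = [condition[s] for s in samples]
    else:
        labels = list(condition)
        if len(labels) != len(samples):
            raise ValueError("condition vector length must match samples")
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"exactly two condition levels required, got {levels}")
    if ref_level is None and test_level is None:
        ref_level, test_level = levels
    elif ref_level is None:
        ref_level = next(l for l in levels if l != test_level)
    elif test_level is None:
        test_level = next(l for l in levels if l != ref_level)
    for level in (ref_level, test_level):
        n = labels.count(level)
        if n < 2:
            raise ValueError(f"condition level {level!r} has {n} sample(s); need >= 2")
    return np.array([1.0 if l == test_level else 0.0 for l in labels]), test_level, ref_level


def _covariate_matrix(
    samples: Sequence[str], covariates: Mapping[str, Sequence[float]] | None
) -> np.ndarray:
    if not covariates:
        return np.zeros((len(samples), 0))
    cols = [np.asarray(v, dtype=float) for v in covariates.values()]
    return np.column_stack(cols)


def _stacked_design(
    cond: np.ndarray, covar: np.ndarray, paired: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design over 2S observations (first S = intron/focus rows, then S =
    junction/other rows); the tested coefficient is the condition x
    measurement-type interaction, i.e. the change of retention relative to
    the junction level.  Returns (full, reduced, interaction column index).

    With ``paired`` (default) each sample gets its own intercept —
    ``~ sample + type + [covar:type] + condition:type`` — so gene-expression
    fluctuations shared by the two measurements of one RNA sample are
    absorbed instead of being double-counted as independent noise; the
    sample-level condition main effect is then collinear and dropped, and
    sample-level covariates enter as covariate:type interactions.  Without
    pairing the design is ``~ 1 + covar + type + condition + type:cond``.
    """
    S = len(cond)
    ones = np.ones(2 * S)
    typ = np.concatenate([np.ones(S), np.zeros(S)])
    cond2 = np.concatenate([cond, cond])
    cov2 = np.vstack([covar, covar]) if covar.size else np.zeros((2 * S, 0))
    if paired:
        dummies = np.zeros((2 * S, S - 1))
        for s in range(1, S):
            dummies[s, s - 1] = 1.0
            dummies[S + s, s - 1] = 1.0
        X_red = np.column_stack([ones, dummies, typ, *(cov2 * typ[:, None]).T])
    else:
        X_red = np.column_stack([ones, *cov2.T, typ, cond2])
    X_full = np.column_stack([X_red, typ * cond2])
    return X_full, X_red, X_full.shape[1] - 1


def _directions(lfcs, padj, alpha):
    out = []
    for l, q in zip(lfcs, padj):
        if np.isfinite(q) and q < alpha:
            out.append("up" if l > 0 else "down")
        else:
            out.append("ns")
    return out


def _stacked_test(
    merged: MergedIntExResult,
    condition,
    covariates=None,
    test_level: str | None = None,
    ref_level: str | None = None,
    alpha: float = 0.01,
    min_total: int = 10,
    use_wald: bool = True,
    cooks_filter: bool = True,
    cooks_quantile: float = 0.99,
    paired_design: bool = True,
    test_name: str = "deseq-style",
) -> list[DifferentialResult]:
    cond, test_level, ref_level = _condition_vector(
        merged.samples, condition, test_level, ref_level)
    covar = _covariate_matrix(merged.samples, covariates)
    X_full, X_red, k_int = _stacked_design(cond, covar, paired=paired_design)
    counts = np.hstack([merged.intron_counts, merged.junction_counts])
    offsets = np.log(np.concatenate([
        merged.size_factors["intron"], merged.size_factors["junction"]]))

    n = counts.shape[0]
    totals = counts.sum(axis=1)
    testable = totals >= min_total
    reasons: list[str | None] = [None if t else "low_count" for t in testable]

    lfcs = np.full(n, np.nan)
    statv = np.full(n, np.nan)
    pvals = np.full(n, np.nan)

    idx = np.flatnonzero(testable)
    if idx.size:
        fits = fit_nb_glm(counts[idx], X_full, offsets)
        m_obs, p_coef = X_full.shape
        cooks_cut = stats.f.ppf(cooks_quantile, p_coef, m_obs - p_coef)
        # replicate cells (measurement-type x condition) for the robust
        # dispersion used in outlier screening
        typ = np.concatenate([np.ones(len(cond)), np.zeros(len(cond))])
        cells = (2 * typ + np.concatenate([cond, cond])).astype(int)
        for j, i in enumerate(idx):
            fit: NBFit = fits[j]
            if fit.flagged == "all_zero":
                reasons[i] = "low_count"
                continue
            lfcs[i] = fit.beta[k_int] / LN2
            if cooks_filter:
                from .nbglm import fit_single, robust_mom_dispersion

                a_rob = robust_mom_dispersion(counts[i], cells, offsets)
                cooks = fit_single(counts[i], X_full, offsets, a_rob).cooks
                if np.nanmax(cooks) > cooks_cut:
                    reasons[i] = "cooks_outlier"
                    continue
            if fit.flagged == "not_converged":
                reasons[i] = "not_converged"
                continue
            if use_wald:
                statv[i], pvals[i] = wald_test(fit, k_int)
            else:
                statv[i], pvals[i] = lr_test(
                    counts[i], X_full, X_red, offsets, fit.alpha)

    padj = bh_adjust(pvals)
    dirs = _directions(lfcs, padj, alpha)
    return [
        DifferentialResult(
            intron_key=merged.intron_keys[i], log2_fold_change=float(lfcs[i]),
            statistic=float(statv[i]), p_value=float(pvals[i]),
            p_adjusted=float(padj[i]), direction=dirs[i],
            test_name=test_name, filtered_reason=reasons[i],
        )
        for i in range(n)
    ]


def deseq_style_test(
    merged: MergedIntExResult, condition, covariates=None,
    test_level: str | None = None, ref_level: str | None = None,
    alpha: float = 0.01, min_total: int = 10,
    cooks_filter: bool = True, cooks_quantile: float = 0.99,
    paired_design: bool = True,
) -> list[DifferentialResult]:
    """Wald test on the condition x measurement-type interaction (change of
    retention relative to the flanking junction level), with Cook's-distance
    outlier filtering and BH adjustment."""
    return _stacked_test(
        merged, condition, covariates, test_level, ref_level, alpha,
        min_total, use_wald=True, cooks_filter=cooks_filter,
        cooks_quantile=cooks_quantile, paired_design=paired_design,
        test_name="deseq-style",
    )


def edger_style_test(
    merged: MergedIntExResult, condition, covariates=None,
    test_level: str | None = None, ref_level: str | None = None,
    alpha: float = 0.01, min_total: int = 10,
    paired_design: bool = True,
) -> list[DifferentialResult]:
    """Likelihood-ratio test on the same stacked model (no Cook's filter)."""
    return _stacked_test(
        merged, condition, covariates, test_level, ref_level, alpha,
        min_total, use_wald=False, cooks_filter=False,
        paired_design=paired_design, test_name="edger-style",
    )


def dexseq_style_test(
    intret: InterestResult, condition,
    test_level: str | None = None, ref_level: str | None = None,
    alpha: float = 0.01, min_total: int = 10,
    paired_design: bool = True,
) -> list[DifferentialResult]:
    """Gene-wise usage test: each intron's counts vs the summed counts of
    the other introns of its gene, LRT on the condition x this-intron
    interaction.  Uses intron counts only; single-intron genes are excluded."""
    samples = intret.samples
    cond, test_level, ref_level = _condition_vector(samples, condition,
                                                    test_level, ref_level)
    intron_idx = [i for i, f in enumerate(intret.features)
                  if f.feature_kind == "intron"]
    by_gene: dict[str, list[int]] = {}
    for i in intron_idx:
        by_gene.setdefault(intret.features[i].gene_id, []).append(i)

    Y_all = intret.raw_counts[intron_idx].astype(float)
    sf = median_of_ratios(Y_all)
    offsets = np.log(np.concatenate([sf, sf]))
    X_full, X_red, k_int = _stacked_design(
        cond, np.zeros((len(samples), 0)), paired=paired_design)

    keys, rows, others, reasons_pre = [], [], [], []
    for gene, idxs in sorted(by_gene.items()):
        gene_counts = intret.raw_counts[idxs].astype(float)
        for pos, i in enumerate(idxs):
            f = intret.features[i]
            key = (f.gene_id, f.ordinal)
            if len(idxs) < 2:
                keys.append(key); rows.append(None); others.append(None)
                reasons_pre.append("single_intron_gene")
                continue
            other = gene_counts.sum(axis=0) - gene_counts[pos]
            if not np.any(other > 0):
                keys.append(key); rows.append(None); others.append(None)
                reasons_pre.append("zero_others")
                continue
            keys.append(key); rows.append(gene_counts[pos]); others.append(other)
            reasons_pre.append(None)

    n = len(keys)
    lfcs = np.full(n, np.nan)
    statv = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    reasons: list[str | None] = list(reasons_pre)

    test_idx = [i for i in range(n) if reasons[i] is None]
    if test_idx:
        counts = np.array([np.concatenate([rows[i], others[i]]) for i in test_idx])
        totals = counts.sum(axis=1)
        keep = totals >= min_total
        for j, i in enumerate(test_idx):
            if not keep[j]:
                reasons[i] = "low_count"
        kept = [i for j, i in enumerate(test_idx) if keep[j]]
        if kept:
            counts_k = counts[keep]
            fits = fit_nb_glm(counts_k, X_full, offsets)
            for j, i in enumerate(kept):
                fit = fits[j]
                if fit.flagged == "all_zero":
                    reasons[i] = "low_count"
                    continue
                lfcs[i] = fit.beta[k_int] / LN2
                if fit.flagged == "not_converged":
                    reasons[i] = "not_converged"
                    continue
                statv[i], pvals[i] = lr_test(
                    counts_k[j], X_full, X_red, offsets, fit.alpha)

    padj = bh_adjust(pvals)
    dirs = _directions(lfcs, padj, alpha)
    return [
        DifferentialResult(
            intron_key=keys[i], log2_fold_change=float(lfcs[i]),
            statistic=float(statv[i]), p_value=float(pvals[i]),
            p_adjusted=float(padj[i]), direction=dirs[i],
            test_name="dexseq-style", filtered_reason=reasons[i],
        )
        for i in range(n)
    ]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through and are
    excluded from the hypothesis count."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    vals = p[ok]
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(q, 1.0)
    out[ok] = adj
    return out


def jonckheere_statistic(groups: Sequence[np.ndarray]) -> float:
    """Jonckheere-Terpstra statistic: over all ordered group pairs a < b,
    the number of (x in a, y in b) pairs with y > x, ties counted 1/2."""
    stat = 0.0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            x = np.asarray(groups[a])[:, None]
            y = np.asarray(groups[b])[None, :]
            stat += float(np.sum(y > x) + 0.5 * np.sum(y == x))
    return stat


def jonckheere_trend_test(
    values_by_ordered_groups: Sequence[Sequence[float]],
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "increasing",
) -> tuple[float, float]:
    """Permutation Jonckheere-Terpstra trend test.

    The p-value uses the +1 correction, ``(1 + #{permuted >= observed}) /
    (1 + n_permutations)`` for the increasing alternative (mirrored for
    decreasing), so it can never be exactly zero — its floor at 10000
    permutations is 1/10001.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_ordered_groups]
    if len(groups) < 2:
        raise ValueError("need at least two ordered groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = jonckheere_statistic(groups)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    cuts = np.cumsum(sizes)[:-1]
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = jonckheere_statistic(np.split(perm, cuts))
        if alternative == "increasing":
            extreme += stat >= observed
        else:
            extreme += stat <= observed
    p = (1 + extreme) / (1 + n_permutations)
    return observed, float(p)


def results_to_dataframe(results: Sequence[DifferentialResult]):
    import pandas as pd

    return pd.DataFrame({
        "gene_id": [r.intron_key[0] for r in results],
        "intron_ordinal": [r.intron_key[1] for r in results],
        "log2_fold_change": [r.log2_fold_change for r in results],
        "statistic": [r.statistic for r in results],
        "p_value": [r.p_value for r in results],
        "p_adjusted": [r.p_adjusted for r in results],
        "direction": [r.direction for r in results],
        "test_name": [r.test_name for r in results],
        "filtered_reason": ["" if r.filtered_reason is None else r.filtered_reason
                            for r in results],
    })


def write_differential_tsv(results: Sequence[DifferentialResult], path: str | Path) -> None:
    results_to_dataframe(results).to_csv(path, sep="\t", index=False, na_rep="NA")
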