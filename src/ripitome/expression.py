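"""Count-based expression and binding analysis.

Covers the RNA-seq/RIP-seq side of the pipeline: FPKM conversion, the
expressed-gene filters, differential expression/binding of two groups by a
conditional negative-binomial exact test with a common dispersion, splicing
scoring of inclusion/exclusion feature pairs, and assignment of genes to the
three activation classes (differentially expressed only, both, alternatively
spliced only).

The count model is NB with variance mu + phi*mu**2.  Library sizes are
equalized by linear rescaling to the geometric-mean depth, the common
dispersion is estimated by maximizing the conditional (on per-group gene
totals) log-likelihood summed over genes, and each gene is tested by
conditioning on the total count across both groups: under the null the split
of the total between groups follows a negative hypergeometric law, and the
two-sided p-value is the total probability of all splits no more likely than
the observed one.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .enrichment import bh_adjust

__all__ = [
    "compute_fpkm",
    "filter_expressed",
    "differential_expression",
    "nb_exact_test",
    "estimate_common_dispersion",
    "splicing_scores",
    "classify_genes",
]

GENE_CLASSES = ("DE_only", "DE_and_AS", "AS_only", "neither")


def _group_columns(groups: Mapping[str, str], samples: Iterable[str]) -> dict[str, list[str]]:
    cols: dict[str, list[str]] = {}
    for s in samples:
        if s not in groups:
            raise ValueError(f"sample {s!r} has no group label")
        cols.setdefault(groups[s], []).append(s)
    return cols


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of exon model per million mapped reads.

    ``FPKM[g, s] = count[g, s] / ((length[g]/1e3) * (colsum[s]/1e6))`` with
    the per-sample mapped total taken as the column sum.  Every gene must
    have an exon-model length; missing genes are reported in the error.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without exon-model length: {sorted(missing)[:10]}")
    lens = lengths.reindex(counts.index).astype(float)
    if (lens <= 0).any():
        raise ValueError("exon-model lengths must be positive")
    libsize = counts.sum(axis=0).astype(float)
    return counts.div(lens / 1e3, axis=0).div(libsize / 1e6, axis=1)


def filter_expressed(
    fpkm: pd.DataFrame,
    groups: Mapping[str, str],
    log2_threshold: float | None = None,
    rule: str = "rnaseq",
) -> list[str]:
    """Expressed-gene filter on the log2(FPKM) scale.

    A gene is retained iff ``log2(FPKM) > log2_threshold`` in strictly more
    than half the samples of at least one group.  The default threshold is
    -2 for whole-transcriptome RNA-seq and +2 for RIP-seq bound-transcript
    calling.  All-zero genes are never retained (log2 0 = -inf).
    """
    if rule not in ("rnaseq", "ripseq"):
        raise ValueError(f"rule must be rnaseq/ripseq, got {rule!r}")
    if log2_threshold is None:
        log2_threshold = -2.0 if rule == "rnaseq" else 2.0
    with np.errstate(divide="ignore"):
        passing = np.log2(fpkm.to_numpy(dtype=float)) > log2_threshold
    passing = pd.DataFrame(passing, index=fpkm.index, columns=fpkm.columns)
    keep = pd.Series(False, index=fpkm.index)
    for _, cols in _group_columns(groups, fpkm.columns).items():
        keep |= passing[cols].sum(axis=1) > len(cols) / 2
    return list(fpkm.index[keep])


def _conditional_log_pmf(total: int, r_a: float, r_b: float) -> np.ndarray:
    """Log pmf of the group-A sum given the overall total, under equal means.

    For NB counts with common success probability, the group sums S_A, S_B
    are NB(r_a), NB(r_b) and S_A | S_A+S_B = total follows the negative
    hypergeometric distribution; the probability parameter cancels.
    """
    s = np.arange(total + 1, dtype=float)
    logp = (
        gammaln(s + r_a) - gammaln(s + 1.0)
        + gammaln(total - s + r_b) - gammaln(total - s + 1.0)
    )
    return logp - logsumexp(logp)


def nb_exact_test(
    sum_a: int, sum_b: int, n_a: int, n_b: int, dispersion: float
) -> float:
    """Two-sided conditional NB exact test of equal group means.

    ``dispersion`` is phi in Var = mu + phi*mu**2; each group sum is NB with
    size ``n/phi``.  The p-value is the summed conditional probability of
    every split of the total whose probability does not exceed that of the
    observed split (the double-tail convention for discrete tests).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one sample")
    phi = max(float(dispersion), 1e-8)
    total = int(sum_a) + int(sum_b)
    if total == 0:
        return 1.0
    logp = _conditional_log_pmf(total, n_a / phi, n_b / phi)
    obs = logp[int(sum_a)]
    keep = logp <= obs + 1e-10  # tolerate float ties
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _equalize_libsizes(counts: pd.DataFrame) -> pd.DataFrame:
    """Pseudo-counts rescaled to the geometric-mean library size."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    target = float(np.exp(np.log(lib).mean()))
    pseudo = counts.mul(target / lib, axis=1)
    return pseudo.round().astype(np.int64)


def estimate_common_dispersion(
    pseudo: pd.DataFrame, groups: Mapping[str, str]
) -> float:
    """Common NB dispersion by maximum conditional likelihood.

    Sums, over genes and groups, the log-likelihood of the within-group
    counts conditional on their total (which removes the mean parameter) and
    maximizes it over phi on a log scale.
    """
    blocks = []
    for _, cols in _group_columns(groups, pseudo.columns).items():
        y = pseudo[cols].to_numpy(dtype=float)
        if y.shape[1] >= 2:
            blocks.append(y)
    if not blocks:
        raise ValueError("need at least one group with >= 2 samples")

    def neg_cll(log_phi: float) -> float:
        r = 1.0 / math.exp(log_phi)
        ll = 0.0
        for y in blocks:
            n = y.shape[1]
            tot = y.sum(axis=1)
            ll += float(
                (gammaln(y + r).sum(axis=1)
                 - n * gammaln(r)
                 + gammaln(n * r)
                 - gammaln(tot + n * r)).sum()
            )
        return -ll

    res = minimize_scalar(neg_cll, bounds=(math.log(1e-6), math.log(10.0)),
                          method="bounded", options={"xatol": 1e-4})
    return float(math.exp(res.x))


def differential_expression(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    dispersion: float | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-group differential expression/binding by the NB exact test.

    Returns a frame indexed by gene with ``log2fc`` (second group over first,
    by sorted group label, with a small prior count), ``pvalue``, ``padj``
    (Benjamini-Hochberg) and ``direction`` in {up, down, none}.  ``direction``
    is non-none only for genes with adjusted p < ``alpha``.
    """
    by_group = _group_columns(groups, counts.columns)
    if len(by_group) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(by_group)}")
    (label_a, cols_a), (label_b, cols_b) = sorted(by_group.items())
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least two samples")

    pseudo = _equalize_libsizes(counts)
    phi = estimate_common_dispersion(pseudo, groups) if dispersion is None else dispersion

    sums_a = pseudo[cols_a].sum(axis=1).to_numpy()
    sums_b = pseudo[cols_b].sum(axis=1).to_numpy()
    n_a, n_b = len(cols_a), len(cols_b)

    mean_a = sums_a / n_a
    mean_b = sums_b / n_b
    log2fc = np.log2((mean_b + prior_count) / (mean_a + prior_count))

    pvals = np.array(
        [nb_exact_test(sa, sb, n_a, n_b, phi) for sa, sb in zip(sums_a, sums_b)]
    )
    padj = bh_adjust(pvals)
    direction = np.where(
        padj < alpha, np.where(log2fc > 0, "up", "down"), "none"
    )
    # an exact zero fold change cannot be called in either direction
    direction = np.where((padj < alpha) & (log2fc == 0), "none", direction)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "direction": direction,
            "group_a": label_a,
            "group_b": label_b,
        },
        index=counts.index,
    )


def splicing_scores(
    intensities: pd.DataFrame,
    groups: Mapping[str, str],
    cond_a: str,
    cond_b: str,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Splicing-index scoring of inclusion/exclusion feature pairs.

    ``intensities`` is long-form with columns ``gene`` and ``role`` (one of
    inclusion/exclusion/gene) plus one column per sample; sample columns are
    averaged within each condition.  For each feature,

        SI = log2( (I_feature / I_gene)_condB / (I_feature / I_gene)_condA )

    so a probe brighter in the control condition A gets a negative SI.  The
    reciprocity score is ``(SI_inclusion - SI_exclusion) / 2`` and a gene is
    flagged alternatively spliced iff ``|reciprocity| > threshold`` (default
    0.2, the conventional reciprocal-isoform cutoff).
    """
    required = {"gene", "role"}
    if not required.issubset(intensities.columns):
        raise ValueError("intensities needs 'gene' and 'role' columns")
    samples = [c for c in intensities.columns if c not in required]
    cols_a = [s for s in samples if groups.get(s) == cond_a]
    cols_b = [s for s in samples if groups.get(s) == cond_b]
    if not cols_a or not cols_b:
        raise ValueError("both conditions need at least one sample column")
    values = intensities[samples].to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("intensities must be positive")

    mean_a = intensities[cols_a].mean(axis=1)
    mean_b = intensities[cols_b].mean(axis=1)
    wide_a = intensities.assign(v=mean_a).pivot_table(index="gene", columns="role", values="v")
    wide_b = intensities.assign(v=mean_b).pivot_table(index="gene", columns="role", values="v")
    for wide in (wide_a, wide_b):
        missing = {"inclusion", "exclusion", "gene"} - set(wide.columns)
        if missing:
            raise ValueError(f"missing roles in intensity table: {sorted(missing)}")

    si = np.log2((wide_b.div(wide_b["gene"], axis=0))
                 / (wide_a.div(wide_a["gene"], axis=0)))
    reciprocity = (si["inclusion"] - si["exclusion"]) / 2.0
    return pd.DataFrame(
        {
            "si_inclusion": si["inclusion"],
            "si_exclusion": si["exclusion"],
            "reciprocity": reciprocity,
            "spliced": reciprocity.abs() > threshold,
        }
    )


def classify_genes(
    de_genes: Iterable[str],
    spliced_genes: Iterable[str],
    universe: Iterable[str] | None = None,
) -> pd.Series:
    """Partition genes into DE-only / DE-and-AS / AS-only / neither.

    ``de_genes`` and ``spliced_genes`` are the significant-call sets; the
    universe defaults to their union (in which case no gene is 'neither').
    """
    de = set(de_genes)
    spliced = set(spliced_genes)
    genes = set(universe) if universe is not None else de | spliced
    if not (de | spliced) <= genes:
        raise ValueError("universe must contain all classified genes")

    def label(g: str) -> str:
        if g in de and g in spliced:
            return "DE_and_AS"
        if g in de:
            return "DE_only"
        if g in spliced:
            return "AS_only"
        return "neither"

    idx = sorted(genes)
    return pd.Series([label(g) for g in idx], index=idx, name="gene_class")
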