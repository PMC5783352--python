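"""Expressed-tRF filtering, TMM normalization and differential abundance.

The differential test is a two-sided Fisher exact test on counts pooled
within each group against library sizes scaled by trimmed-mean-of-M-values
(TMM) normalization factors, with Benjamini-Hochberg adjustment across
bins.  This is an exact test under count-sampling noise; it does not model
biological overdispersion between replicates (see the package methods
note for the implications).

Sex-bias classification follows a strict cross-strain consistency rule: a
tRF is female-biased only when its (normalized) count is higher in the
female than in the male library of *every* strain, and symmetrically for
male bias; everything else is "inconsistent".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .annotation import TRNAGene, make_bins
from .counting import CountMatrix, build_count_matrix
from .errors import DegenerateSampleError, ValidationError

log = logging.getLogger(__name__)

FEMALE_BIASED = "Female biased"
MALE_BIASED = "Male biased"
INCONSISTENT = "inconsistent"


def _counts_frame(matrix) -> pd.DataFrame:
    return matrix.counts if isinstance(matrix, CountMatrix) else matrix


def filter_expressed(matrix, min_count: int = 100, min_samples: int = 3):
    """Keep bins with strictly more than ``min_count`` reads in at least
    ``min_samples`` samples (the "expressed tRF" rule).  Idempotent; row
    order is preserved.  Accepts and returns either a
    :class:`~trfbin.counting.CountMatrix` or a plain DataFrame.
    """
    df = _counts_frame(matrix)
    keep = (df > min_count).sum(axis=1) >= min_samples
    if isinstance(matrix, CountMatrix):
        return matrix.subset_bins(df.index[keep])
    return df.loc[keep]


@dataclass(frozen=True)
class NormalizationFactors:
    """TMM scaling factors, rescaled to geometric mean 1."""

    sample_ids: tuple
    factors: np.ndarray
    reference_sample: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValidationError("normalization factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.factors))))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"factor geometric mean {gm} != 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, index=list(self.sample_ids), name="tmm_factor")


def _tmm_pair(obs, lib_obs, ref, lib_ref, trim_m, trim_a):
    """TMM factor of one sample against the reference.

    M is the log2 ratio of count fractions, A their mean; the most extreme
    ``trim_m`` of M and ``trim_a`` of A are discarded on each side (by
    rank, double-sided) and the factor is 2 to the precision-weighted mean
    of the remaining M, weights being inverse asymptotic binomial
    variances.
    """
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise DegenerateSampleError("sample shares no nonzero bins with the reference")
    o = obs[mask].astype(float)
    r = ref[mask].astype(float)
    po = o / lib_obs
    pr = r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * (np.log2(po) + np.log2(pr))
    # asymptotic binomial variance of M; precision weight is its inverse
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    w = 1.0 / v
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    return float(f) if np.isfinite(f) else 1.0


def tmm_factors(
    matrix,
    library_sizes: Optional[pd.Series] = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions across samples.  Factors are
    rescaled to geometric mean 1, so they are reported on the usual
    relative scale.
    """
    df = _counts_frame(matrix)
    if library_sizes is None:
        if not isinstance(matrix, CountMatrix):
            raise ValidationError("library_sizes required with a plain DataFrame")
        library_sizes = matrix.library_sizes
    libs = library_sizes.reindex(df.columns).astype(float)
    if df.shape[1] < 2:
        raise ValidationError("TMM requires at least two samples")
    if (libs <= 0).any():
        raise ValidationError("every sample must have positive library size")

    frac75 = df.divide(libs, axis=1).quantile(0.75, axis=0)
    ref_id = (frac75 - frac75.mean()).abs().idxmin()
    ref = df[ref_id].to_numpy()
    lib_ref = float(libs[ref_id])

    factors = np.array(
        [
            _tmm_pair(df[sid].to_numpy(), float(libs[sid]), ref, lib_ref, trim_m, trim_a)
            for sid in df.columns
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(tuple(df.columns), factors, ref_id)


def fisher_pair(count_a: int, lib_a: int, count_b: int, lib_b: int) -> float:
    """Two-sided Fisher exact p for [[count_a, lib_a-count_a],
    [count_b, lib_b-count_b]] (sum of hypergeometric probabilities not
    exceeding that of the observed table)."""
    if lib_a <= 0 or lib_b <= 0:
        raise ValidationError("library sizes must be positive")
    if count_a < 0 or count_b < 0 or count_a > lib_a or count_b > lib_b:
        raise ValidationError("counts must lie in [0, library size]")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DiffResult:
    """One per-bin two-group contrast on pooled counts."""

    bin_id: str
    group_a: str
    group_b: str
    count_a: int
    count_b: int
    lib_a: int
    lib_b: int
    log2fc: float
    p_value: float
    q_value: float
    direction: str


def pairwise_contrast(
    matrix,
    factors: Optional[NormalizationFactors],
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    group_a_label: str = "A",
    group_b_label: str = "B",
    use_tmm_libs: bool = True,
) -> list:
    """Fisher-exact differential abundance between two sample groups.

    Counts are pooled within each group; library sizes are pooled after
    scaling by the TMM factors (rounded to the nearest integer) unless
    ``use_tmm_libs`` is off.  The log2 fold change is computed from pooled
    count fractions with a +0.5 continuity offset, and the direction label
    is gated on ``p < alpha``.
    """
    df = _counts_frame(matrix)
    set_a, set_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    if set_a & set_b:
        raise ValidationError(f"groups overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - set(df.columns)
    if missing:
        raise ValidationError(f"unknown samples in contrast: {sorted(missing)}")
    if isinstance(matrix, CountMatrix):
        libs = matrix.library_sizes.astype(float)
    else:
        libs = df.sum(axis=0).astype(float)
    if factors is not None and use_tmm_libs:
        fac = factors.as_series().reindex(df.columns)
        libs = libs * fac
    lib_a = int(round(libs[list(group_a)].sum()))
    lib_b = int(round(libs[list(group_b)].sum()))

    pooled_a = df[list(group_a)].sum(axis=1)
    pooled_b = df[list(group_b)].sum(axis=1)
    pvals = np.array(
        [
            fisher_pair(int(ca), lib_a, int(cb), lib_b)
            for ca, cb in zip(pooled_a, pooled_b)
        ]
    )
    qvals = bh_adjust(pvals)
    results = []
    for bid, ca, cb, p, q in zip(df.index, pooled_a, pooled_b, pvals, qvals):
        lfc = math.log2((ca + 0.5) / lib_a) - math.log2((cb + 0.5) / lib_b)
        if p < alpha and lfc > 0:
            direction = "up_in_a"
        elif p < alpha and lfc < 0:
            direction = "up_in_b"
        else:
            direction = "unchanged"
        results.append(
            DiffResult(
                bin_id=bid,
                group_a=group_a_label,
                group_b=group_b_label,
                count_a=int(ca),
                count_b=int(cb),
                lib_a=lib_a,
                lib_b=lib_b,
                log2fc=lfc,
                p_value=float(p),
                q_value=float(q),
                direction=direction,
            )
        )
    return results


def diff_results_frame(results: Iterable[DiffResult]) -> pd.DataFrame:
    rows = [
        {
            "bin_id": r.bin_id,
            "region_label": r.bin_id.split(":")[-1],
            "group_a": r.group_a,
            "group_b": r.group_b,
            "count_a": r.count_a,
            "count_b": r.count_b,
            "lib_a": r.lib_a,
            "lib_b": r.lib_b,
            "log2fc": r.log2fc,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def classify_sex_bias(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    female: str = "female",
    male: str = "male",
) -> pd.DataFrame:
    """Strict cross-strain sex-bias classification.

    ``sample_meta`` must carry ``sex`` and ``strain`` columns and every
    strain must contribute exactly one female and one male sample.  A bin
    is "Female biased" iff its female count exceeds the male count in
    every strain (strict inequality), "Male biased" for the mirror
    pattern, and "inconsistent" otherwise.  Cross-strain mean counts per
    sex are reported alongside.
    """
    for col in ("sex", "strain"):
        if col not in sample_meta.columns:
            raise ValidationError(f"sample_meta lacks a '{col}' column")
    meta = sample_meta.loc[sample_meta.index.isin(counts.columns)]
    f_cols, m_cols, strains = [], [], []
    for strain, sub in meta.groupby("strain", sort=True):
        f = sub.index[sub["sex"] == female]
        m = sub.index[sub["sex"] == male]
        if len(f) != 1 or len(m) != 1:
            raise ValidationError(
                f"strain {strain!r} must have exactly one {female} and one {male} sample"
            )
        f_cols.append(f[0])
        m_cols.append(m[0])
        strains.append(strain)
    fmat = counts[f_cols].to_numpy(dtype=float)
    mmat = counts[m_cols].to_numpy(dtype=float)
    labels = np.where(
        (fmat > mmat).all(axis=1),
        FEMALE_BIASED,
        np.where((mmat > fmat).all(axis=1), MALE_BIASED, INCONSISTENT),
    )
    return pd.DataFrame(
        {
            "mean_female": fmat.mean(axis=1),
            "mean_male": mmat.mean(axis=1),
            "label": labels,
        },
        index=counts.index,
    )


def window_sweep(
    aln_sources: Mapping[str, Sequence],
    genes: Sequence[TRNAGene],
    structures: Mapping[str, object],
    group_a: Sequence[str],
    group_b: Sequence[str],
    available_flanks: Optional[Mapping[str, tuple]] = None,
    sizes: Sequence[int] = (15, 20, 25, 30, 35),
    flank: int = 30,
    min_overlap: int = 10,
    stranded: bool = True,
    min_count: int = 100,
    min_samples: int = 3,
    alpha: float = 0.05,
):
    """Re-bin, re-count, re-filter and re-test at each candidate bin width.

    Returns ``(table, best_window)`` where the table has one row per
    window size with the number of bins, expressed bins and significant
    contrasts, and ``best_window`` maximizes the significant count with
    ties broken toward the smallest window.  ``aln_sources`` must be
    re-iterable (e.g. lists of alignment records keyed by sample).
    """
    if not sizes:
        raise ValidationError("sizes must be non-empty")
    rows = []
    for w in sizes:
        bins = []
        for g in genes:
            af5, af3 = (
                available_flanks.get(g.gene_id, (flank, flank))
                if available_flanks is not None
                else (flank, flank)
            )
            bins.extend(
                make_bins(
                    g,
                    structures[g.gene_id],
                    window=w,
                    flank=flank,
                    available_flank_5=af5,
                    available_flank_3=af3,
                )
            )
        cm = build_count_matrix(
            list(aln_sources.items()), bins, min_overlap=min_overlap, stranded=stranded
        )
        expressed = filter_expressed(cm, min_count=min_count, min_samples=min_samples)
        n_expressed = expressed.counts.shape[0]
        n_sig = 0
        if n_expressed and cm.library_sizes.gt(0).all():
            try:
                factors = tmm_factors(expressed)
            except (ValidationError, DegenerateSampleError):
                factors = None
            res = pairwise_contrast(
                expressed, factors, list(group_a), list(group_b), alpha=alpha
            )
            n_sig = sum(r.p_value < alpha for r in res)
        rows.append(
            {"window": w, "n_bins": len(bins), "n_expressed": n_expressed, "n_significant": n_sig}
        )
    table = pd.DataFrame(rows)
    if table["n_significant"].eq(0).all():
        log.warning("window_sweep: no significant tRFs at any size; reporting smallest")
    best = int(
        table.sort_values(["n_significant", "window"], ascending=[False, True])["window"].iloc[0]
    )
    return table, best
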