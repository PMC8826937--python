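"""Three-stage count normalization and fraction-proportion computation.

The chain converts raw per-library read counts into quantities proportional to
the number of mRNA copies of each gene present in each gradient fraction:

1. median-of-ratios size factors (library-size normalization, the DESeq
   estimator re-implemented here) remove sequencing-depth differences;
2. multiplication by the ribodepleted RNA yield (ng) of the library, divided
   by the fixed aliquot used for library construction, undoes the fact that a
   constant mass of ribodepleted RNA went into sequencing;
3. multiplication by the total RNA (µg) extracted from the fraction, divided
   by the fixed aliquot used for ribodepletion, undoes the constant-mass
   ribodepletion input.

Per-gene percentages across fractions A..G then estimate the distribution of
that gene's mRNA copies over ribosome loads.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import FRACTIONS, FractionCountMatrix, ProportionProfile

logger = logging.getLogger(__name__)

#: ng of ribodepleted RNA used to construct each sequencing library.
LIBRARY_ALIQUOT_NG = 10.0
#: µg of total RNA used per fraction as ribodepletion input.
RIBODEPLETION_ALIQUOT_UG = 5.0
#: Genes whose summed count stays below this in every replicate are excluded.
LOW_COUNT_THRESHOLD = 10


def filter_low_counts(raw: FractionCountMatrix, threshold: float = LOW_COUNT_THRESHOLD,
                      scope: str = "per_replicate"):
    """Drop weakly detected genes before normalization.

    With ``scope="per_replicate"`` (default) a gene is excluded when its count
    summed over fractions is below ``threshold`` in *every* replicate — the
    least destructive reading of a total-count filter.  ``scope="total"``
    instead compares the grand sum over all libraries against ``threshold``.

    Returns ``(retained, report)`` where ``retained`` is a
    :class:`FractionCountMatrix` restricted to kept genes and ``report`` a
    DataFrame listing excluded genes with their per-replicate totals.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if scope not in ("per_replicate", "total"):
        raise ValueError(f"unknown filter scope {scope!r}")
    per_rep = raw.counts.T.groupby(level=1).sum().T  # genes x replicates
    if scope == "per_replicate":
        excluded_mask = (per_rep < threshold).all(axis=1)
    else:
        excluded_mask = per_rep.sum(axis=1) < threshold
    excluded = per_rep.loc[excluded_mask].copy()
    excluded.insert(0, "phase", raw.phase)
    retained = raw.select_genes(raw.genes[~excluded_mask])
    if len(excluded):
        logger.info("excluded %d low-count genes (threshold %s, scope %s)",
                    len(excluded), threshold, scope)
    return retained, excluded


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor for every library (column).

    For library ℓ the factor is the median, over genes with a strictly
    positive geometric mean across libraries, of count[g, ℓ] divided by that
    geometric mean.  Genes containing any zero are thereby ignored, the
    standard convention.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty count matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    log_geomeans = logs.mean(axis=1)
    usable = np.isfinite(log_geomeans)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every library; "
                         "size factors are undefined")
    ratios = arr[usable] / np.exp(log_geomeans[usable, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def ribodepletion_scale(n_deseq, ribodepleted_qty, aliquot_ng: float = LIBRARY_ALIQUOT_NG):
    """Rescale size-factor-normalized counts by the ribodepleted yield (ng).

    ``N_ribo = N_deseq * ribodepleted_qty / aliquot_ng`` — a constant
    ``aliquot_ng`` of ribodepleted RNA was sequenced regardless of the yield,
    so counts must be scaled back up by the yield to stay proportional to
    fraction content.
    """
    qty = np.asarray(ribodepleted_qty, dtype=float)
    if (qty <= 0).any():
        raise ValueError("ribodepleted quantity must be positive")
    return n_deseq * qty / aliquot_ng


def total_rna_scale(n_ribo, total_rna_qty, aliquot_ug: float = RIBODEPLETION_ALIQUOT_UG):
    """Rescale by the total RNA (µg) extracted from the fraction.

    ``N = N_ribo * total_rna_qty / aliquot_ug`` — a constant ``aliquot_ug`` of
    total RNA entered ribodepletion regardless of how much the fraction held.
    """
    qty = np.asarray(total_rna_qty, dtype=float)
    if (qty <= 0).any():
        raise ValueError("total RNA quantity must be positive")
    return n_ribo * qty / aliquot_ug


def normalize_counts(raw: FractionCountMatrix,
                     aliquot_ng: float = LIBRARY_ALIQUOT_NG,
                     aliquot_ug: float = RIBODEPLETION_ALIQUOT_UG,
                     size_factors: pd.Series | None = None) -> FractionCountMatrix:
    """Run the full three-stage chain, returning final normalized counts.

    Size factors are estimated jointly over all libraries of the matrix (one
    phase); pass ``size_factors`` to reuse precomputed factors.
    """
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(raw.counts)
    n_deseq = raw.counts / size_factors
    n_ribo = ribodepletion_scale(n_deseq, raw.ribodepleted_ng.reindex(n_deseq.columns),
                                 aliquot_ng)
    final = total_rna_scale(n_ribo, raw.total_rna_ug.reindex(n_ribo.columns), aliquot_ug)
    return raw.with_counts(final)


def compute_proportions(final: FractionCountMatrix) -> ProportionProfile:
    """Percent of each gene's mRNA copies in each fraction, per replicate.

    ``proportion[i, j, k] = N[i, j, k] / Σ_j N[i, j, k] × 100``.  Replicates in
    which a gene has zero total are dropped (NaN) with a logged warning; genes
    absent from every replicate are removed entirely and reported.
    """
    counts = final.counts
    totals = counts.T.groupby(level=1).sum().T  # genes x replicates
    rep_level = counts.columns.get_level_values(1)
    denom = totals.loc[:, rep_level]
    denom.columns = counts.columns
    with np.errstate(divide="ignore", invalid="ignore"):
        props = counts / denom * 100.0
    empty = totals == 0
    if empty.to_numpy().any():
        n_dropped = int(empty.to_numpy().sum())
        logger.warning("%d (gene, replicate) profiles had zero total and were dropped",
                       n_dropped)
        mask = empty.loc[:, rep_level]
        mask.columns = counts.columns
        props = props.mask(mask)
    all_empty = empty.all(axis=1)
    if all_empty.any():
        logger.warning("genes with no signal in any replicate excluded: %s",
                       list(counts.index[all_empty]))
        props = props.loc[~all_empty]
    order = [f for f in FRACTIONS if f in props.columns.get_level_values(0)]
    props = props.loc[:, order]
    return ProportionProfile(props, phase=final.phase)
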