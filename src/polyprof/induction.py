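"""Low- vs high-mRNA-concentration comparisons and qPCR quantification.

When transcription of a gene is induced, its mRNA copies redistribute across
the gradient: a drop in the free fraction A and gains in the heavy polysome
fractions indicate increased ribosome loading.  The comparison is summarized
by per-fraction log ratios of mean proportions (high / low) and the relative
RO increase.  mRNA abundances measured by qPCR are expressed relative to
constant ERCC spike-ins via the delta-Ct fold-change method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FRACTIONS, FractionCountMatrix, ProportionProfile

DEFAULT_LOG_BASE = 2.0
#: Pseudo-proportion (percentage points) guarding empty fractions in ratios.
DEFAULT_PSEUDO = 0.1


def fraction_log_ratios(mean_high, mean_low, base: float = DEFAULT_LOG_BASE,
                        pseudo: float = DEFAULT_PSEUDO) -> np.ndarray:
    """Per-fraction log ratio of mean proportions, high over low.

    ``ratio_j = log_base((high_j + pseudo) / (low_j + pseudo))``; negative in
    a fraction means the high-concentration condition holds a smaller share
    of the mRNA copies there.  ``pseudo = 0`` is allowed when every fraction
    is positive.
    """
    hi = np.asarray(mean_high, dtype=float)
    lo = np.asarray(mean_low, dtype=float)
    if (hi < 0).any() or (lo < 0).any():
        raise ValueError("proportions must be nonnegative")
    for name, v in (("mean_high", hi), ("mean_low", lo)):
        if not np.isclose(v.sum(), 100.0):
            raise ValueError(f"{name} must sum to 100")
    if pseudo < 0:
        raise ValueError("pseudo must be nonnegative")
    if pseudo == 0 and ((hi == 0).any() or (lo == 0).any()):
        raise ValueError("pseudo = 0 requires all fractions positive")
    return np.log((hi + pseudo) / (lo + pseudo)) / np.log(base)


def ro_change(ro_low: float, ro_high: float) -> float:
    """Relative RO increase in percent: (high − low) / low × 100."""
    if ro_low <= 0:
        raise ValueError("relative change undefined for ro_low <= 0")
    return (ro_high - ro_low) / ro_low * 100.0


@dataclass
class InductionComparison:
    """Per-gene summary of a low/high transcription comparison."""

    table: pd.DataFrame  # gene x [log ratios per fraction, ro_low, ro_high, ...]
    log_base: float
    pseudo: float

    def __getitem__(self, gene):
        return self.table.loc[gene]


def compare_conditions(low: FractionCountMatrix | ProportionProfile,
                       high: FractionCountMatrix | ProportionProfile,
                       base: float = DEFAULT_LOG_BASE,
                       pseudo: float = DEFAULT_PSEUDO,
                       genes=None) -> InductionComparison:
    """Full low/high comparison from raw counts or ready-made proportions.

    Count matrices are normalized per condition (the conditions are separate
    experiments, never normalized jointly); log ratios and the RO change are
    computed on the mean profiles of the genes common to both conditions
    (restricted to ``genes`` when given).
    """
    from .normalization import compute_proportions, normalize_counts

    def to_mean_props(obj):
        if isinstance(obj, FractionCountMatrix):
            obj = compute_proportions(normalize_counts(obj))
        return obj.mean_proportions

    mean_low = to_mean_props(low)
    mean_high = to_mean_props(high)
    common = mean_low.index.intersection(mean_high.index)
    if genes is not None:
        common = common.intersection(pd.Index(genes))
    rows = {}
    for gene in common:
        lo = mean_low.loc[gene, list(FRACTIONS)].to_numpy()
        hi = mean_high.loc[gene, list(FRACTIONS)].to_numpy()
        ratios = fraction_log_ratios(hi, lo, base=base, pseudo=pseudo)
        ro_low, ro_high = 100.0 - lo[0], 100.0 - hi[0]
        rows[gene] = [*ratios, ro_low, ro_high,
                      ro_change(ro_low, ro_high) if ro_low > 0 else np.nan]
    cols = [f"log_ratio_{f}" for f in FRACTIONS] + \
        ["ro_low", "ro_high", "ro_percent_increase"]
    return InductionComparison(
        pd.DataFrame.from_dict(rows, orient="index", columns=cols),
        log_base=base, pseudo=pseudo)


def delta_ct_abundance(measurements: pd.DataFrame,
                       efficiency: float = 2.0) -> pd.Series:
    """Relative abundance per gene from a Ct table, vs spike-in normalizers.

    Per primer pair ``abundance = efficiency^(ct_spike − ct_target)``; genes
    measured with several primer pairs get the geometric mean of the pair
    values (fold-change domain).  ``measurements`` needs columns gene,
    ct_target, ct_spike (and optionally primer_pair).
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    required = {"gene", "ct_target", "ct_spike"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if measurements["ct_spike"].isna().any():
        raise ValueError("missing spike-in Ct value")
    per_pair = efficiency ** (measurements["ct_spike"] - measurements["ct_target"])
    logs = np.log(per_pair)
    out = np.exp(logs.groupby(measurements["gene"].to_numpy()).mean())
    out.name = "rel_abundance"
    return out


def qpcr_fraction_normalize(rel_abundance, total_rna_qty,
                            aliquot_ug: float = 5.0):
    """Correct per-fraction qPCR abundances for the total RNA of the fraction.

    Only ``aliquot_ug`` of each fraction's total RNA entered the assay, so
    abundances are rescaled by ``total_rna_qty / aliquot_ug`` before
    computing proportions and RO downstream.
    """
    ab = np.asarray(rel_abundance, dtype=float)
    qty = np.asarray(total_rna_qty, dtype=float)
    if (qty <= 0).any():
        raise ValueError("total RNA quantities must be positive")
    out = ab * qty / aliquot_ug
    if isinstance(rel_abundance, pd.Series):
        return pd.Series(out, index=rel_abundance.index,
                         name=rel_abundance.name)
    return out
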