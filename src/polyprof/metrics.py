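"""Ribosome occupancy, bootstrap peak-fraction calling and ribosome density.

Ribosome occupancy (RO) of a gene is the percentage of its mRNA copies bound
by at least one ribosome — the summed proportions in fractions B..G, i.e.
100 minus the fraction-A proportion.  The peak fraction is the translated
fraction holding the largest mean proportion, validated by bootstrapping the
replicate residuals; ribosome density (RD) converts the peak fraction's
ribosome number into ribosomes per 100 nt of ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FRACTIONS, TRANSLATED_FRACTIONS, ProportionProfile
from .gradient import RibosomeMap, build_ribosome_map

DEFAULT_N_BOOT = 1000
DEFAULT_CONFINEMENT = 0.95
#: Approximate footprint of one ribosome on mRNA, in nucleotides.
RIBOSOME_FOOTPRINT_NT = 30


def ribosome_occupancy(profile: ProportionProfile) -> pd.DataFrame:
    """Per-gene RO replicates with mean and sample standard deviation.

    ``RO[i, k] = Σ_{j=B..G} proportion[i, j, k] = 100 − proportion[i, A, k]``.
    Columns: one ``RO_rep<k>`` per replicate, then ``RO_mean`` and ``RO_sd``
    (ddof=1; NaN with a single replicate).
    """
    props = profile.proportions
    a = props.xs("A", axis=1, level=0)
    ro = 100.0 - a
    out = ro.copy()
    out.columns = [f"RO_rep{k}" for k in ro.columns]
    out["RO_mean"] = ro.mean(axis=1)
    out["RO_sd"] = ro.std(axis=1, ddof=1)
    return out


@dataclass
class PeakCall:
    """Bootstrap peak determination for one gene."""

    peak_fraction: str | None
    peak_frequency: float
    confined: bool
    frequencies: pd.Series  # relative frequency per fraction B..G


def bootstrap_peak_fraction(profiles: pd.DataFrame | np.ndarray,
                            n_boot: int = DEFAULT_N_BOOT,
                            conf: float = DEFAULT_CONFINEMENT,
                            seed=None) -> PeakCall:
    """Call the peak translated fraction of one gene by residual bootstrap.

    ``profiles`` holds one replicate per column over the fractions A..G
    (rows).  Residuals ``r[j, k] = p[j, k] − mean_k p[j]`` are pooled over all
    fractions and replicates; each bootstrap profile adds one residual, drawn
    with replacement, to the mean proportion of every fraction, and its peak
    is the argmax over B..G (ties resolved toward the lighter fraction).  The
    modal peak's relative frequency over ``n_boot`` data sets is returned;
    the call is *confined* to a single fraction when that frequency reaches
    ``conf``.

    Bootstrap profiles are not renormalized to 100 and negatives are not
    clipped: only the argmax is consumed, renormalization cannot change it
    and clipping could.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != len(FRACTIONS):
        raise ValueError("profiles must be fractions (7) x replicates")
    if arr.shape[1] < 2:
        raise ValueError("residual bootstrap requires at least 2 replicates")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    mean = arr.mean(axis=1)
    residuals = (arr - mean[:, None]).ravel()
    translated = mean[1:]
    if np.allclose(residuals, 0.0) and np.allclose(translated, 0.0):
        freqs = pd.Series(np.nan, index=list(TRANSLATED_FRACTIONS))
        return PeakCall(None, np.nan, False, freqs)
    rng = np.random.default_rng(seed)
    draws = rng.choice(residuals, size=(n_boot, len(FRACTIONS)), replace=True)
    boot = mean[None, :] + draws
    peaks = np.argmax(boot[:, 1:], axis=1)  # over B..G; first (lighter) wins ties
    counts = np.bincount(peaks, minlength=len(TRANSLATED_FRACTIONS))
    freqs = pd.Series(counts / n_boot, index=list(TRANSLATED_FRACTIONS))
    modal = int(np.argmax(counts))
    peak_frequency = counts[modal] / n_boot
    return PeakCall(TRANSLATED_FRACTIONS[modal], float(peak_frequency),
                    peak_frequency >= conf, freqs)


def max_theoretical_density(footprint_nt: float = RIBOSOME_FOOTPRINT_NT) -> float:
    """Maximum packing density, ribosomes per 100 nt, for a given footprint."""
    if footprint_nt <= 0:
        raise ValueError("footprint must be positive")
    return 100.0 / footprint_nt


def ribosome_density(peak: str, ribosome_map: RibosomeMap, orf_length: float) -> float:
    """Ribosomes per 100 nt: peak fraction's ribosome number / ORF length × 100."""
    if peak == "A":
        raise ValueError("fraction A holds untranslated mRNA; no density is defined")
    if peak not in TRANSLATED_FRACTIONS:
        raise ValueError(f"unknown fraction {peak!r}")
    if orf_length <= 0:
        raise ValueError("ORF length must be positive")
    return ribosome_map[peak] / orf_length * 100.0


def filter_outlier_rd(metrics: pd.DataFrame, cutoff: float | None = None):
    """Exclude genes whose RD strictly exceeds the theoretical maximum.

    Returns ``(retained, excluded)`` views of the metrics table; genes with no
    RD (not confined) are retained untouched.
    """
    if cutoff is None:
        cutoff = max_theoretical_density()
    outlier = metrics["RD"] > cutoff
    return metrics.loc[~outlier.fillna(False)], metrics.loc[outlier.fillna(False)]


class PolysomeProfilingResults:
    """Fitted translation metrics for one phase.

    Attributes
    ----------
    metrics : pandas.DataFrame
        Per gene: RO replicates, mean, sd; peak fraction, bootstrap peak
        frequency, confined flag; RD (NaN unless confined) and outlier flag.
    proportions : ProportionProfile
        The normalized fraction proportions the metrics derive from.
    excluded_low_count, excluded_rd_outliers : pandas.DataFrame
        Exclusion reports.
    """

    def __init__(self, model, metrics, proportions, excluded_low_count,
                 excluded_rd_outliers, size_factors, n_boot, conf, seed):
        self.model = model
        self.metrics = metrics
        self.proportions = proportions
        self.excluded_low_count = excluded_low_count
        self.excluded_rd_outliers = excluded_rd_outliers
        self.size_factors = size_factors
        self.n_boot = n_boot
        self.confinement = conf
        self.seed = seed
        self.ribosome_map = model.ribosome_map

    @property
    def retained(self) -> pd.DataFrame:
        """Metrics after removal of RD outliers."""
        return self.metrics.loc[~self.metrics["RD_outlier"].fillna(False)]

    def summary(self) -> str:
        m = self.retained
        conf_n = int(m["confined"].sum())
        lines = [
            "Polysome profiling translation metrics",
            "=" * 48,
            f"phase:                 {self.proportions.phase}",
            f"genes analysed:        {len(m)}",
            f"genes low-count excl.: {len(self.excluded_low_count)}",
            f"RD outliers excluded:  {len(self.excluded_rd_outliers)}",
            f"bootstrap data sets:   {self.n_boot} (confinement >= {self.confinement:.2f})",
            f"ribosome map:          " + ", ".join(
                f"{f}={self.ribosome_map[f]}" for f in FRACTIONS),
            "-" * 48,
            f"mean RO:               {m['RO_mean'].mean():.1f}% "
            f"+/- {m['RO_mean'].std(ddof=1):.1f}%",
            f"genes with confined peak: {conf_n}",
        ]
        if conf_n:
            lines.append(f"mean RD (confined):    {m['RD'].mean():.2f} ribosomes/100 nt")
            lines.append(f"max theoretical RD:    {max_theoretical_density():.1f} "
                         "ribosomes/100 nt")
        return "\n".join(lines)

    def plot_profile(self, gene, ax=None):
        """Bar plot of a gene's mean fraction profile with replicate points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        prof = self.proportions.replicate_profiles(gene)
        ax.bar(prof.index, prof.mean(axis=1), color="#7f9fc4", label="mean")
        for rep in prof.columns:
            ax.plot(prof.index, prof[rep], "k.", ms=4)
        ax.set_xlabel("fraction")
        ax.set_ylabel("% of mRNA copies")
        ax.set_title(str(gene))
        return ax


class PolysomeProfilingModel:
    """End-to-end polysome-profiling analysis for one growth phase.

    Built from a raw :class:`FractionCountMatrix` and per-gene ORF lengths;
    :meth:`fit` runs low-count filtering, the three-stage normalization,
    proportion computation, RO, bootstrap peak calling and RD, and returns a
    :class:`PolysomeProfilingResults`.

    Parameters
    ----------
    counts : FractionCountMatrix
        Raw per-(fraction, replicate) read counts with RNA-quantity metadata.
    orf_lengths : pandas.Series
        ORF length (nt) per gene; genes lacking a length get no RD.
    ribosome_map : RibosomeMap, optional
        Ribosome numbers per fraction (defaults to A..E = 0..4, F = 6, G = 9).
    low_count_threshold : int
        Total-read filter applied per replicate before normalization.
    """

    def __init__(self, counts, orf_lengths=None, ribosome_map=None,
                 low_count_threshold=None, filter_scope="per_replicate"):
        from . import normalization as _norm

        self.counts = counts
        self.orf_lengths = orf_lengths
        self.ribosome_map = ribosome_map or build_ribosome_map()
        self.low_count_threshold = (_norm.LOW_COUNT_THRESHOLD
                                    if low_count_threshold is None
                                    else low_count_threshold)
        self.filter_scope = filter_scope

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, metadata: pd.DataFrame,
                       orf_lengths=None, **kwargs) -> "PolysomeProfilingModel":
        """Build from a genes x library_id frame plus a library metadata table.

        ``metadata`` columns: library_id, fraction, replicate, ribodepleted_ng,
        total_rna_ug and optionally phase.
        """
        from .io import counts_from_long_metadata

        fcm = counts_from_long_metadata(counts, metadata)
        return cls(fcm, orf_lengths=orf_lengths, **kwargs)

    def fit(self, n_boot: int = DEFAULT_N_BOOT, conf: float = DEFAULT_CONFINEMENT,
            seed=None, rd_cutoff: float | None = None) -> PolysomeProfilingResults:
        from . import normalization as _norm

        retained, excluded = _norm.filter_low_counts(
            self.counts, self.low_count_threshold, scope=self.filter_scope)
        size_factors = _norm.size_factors_median_of_ratios(retained.counts)
        final = _norm.normalize_counts(retained, size_factors=size_factors)
        proportions = _norm.compute_proportions(final)
        metrics = ribosome_occupancy(proportions)

        genes = proportions.genes
        child_seeds = np.random.SeedSequence(seed).spawn(len(genes))
        peak_rows = {}
        for gene, child in zip(genes, child_seeds):
            prof = proportions.replicate_profiles(gene)
            if prof.shape[1] < 2 or prof.shape[0] != len(FRACTIONS):
                peak_rows[gene] = (None, np.nan, False)
                continue
            call = bootstrap_peak_fraction(prof.to_numpy(), n_boot=n_boot,
                                           conf=conf, seed=child)
            peak_rows[gene] = (call.peak_fraction, call.peak_frequency, call.confined)
        peaks = pd.DataFrame.from_dict(
            peak_rows, orient="index",
            columns=["peak_fraction", "peak_frequency", "confined"]).reindex(genes)
        metrics = metrics.join(peaks)

        rd = np.full(len(genes), np.nan)
        if self.orf_lengths is not None:
            lengths = self.orf_lengths.reindex(genes)
            for pos, gene in enumerate(genes):
                if metrics.loc[gene, "confined"] and np.isfinite(lengths.iloc[pos]):
                    rd[pos] = ribosome_density(metrics.loc[gene, "peak_fraction"],
                                               self.ribosome_map, lengths.iloc[pos])
        metrics["RD"] = rd
        cutoff = max_theoretical_density() if rd_cutoff is None else rd_cutoff
        metrics["RD_outlier"] = metrics["RD"] > cutoff
        _, rd_excluded = filter_outlier_rd(metrics, cutoff)
        return PolysomeProfilingResults(self, metrics, proportions, excluded,
                                        rd_excluded, size_factors, n_boot, conf, seed)
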