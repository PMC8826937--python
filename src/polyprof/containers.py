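"""In-memory containers for gradient count data and fraction proportions.

Counts are held as a genes x libraries :class:`pandas.DataFrame` whose columns
are a two-level MultiIndex ``(fraction, replicate)``; per-library RNA-quantity
metadata live alongside in two Series sharing that index.  A "library" is one
sequencing library prepared from one pooled gradient fraction of one
biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Gradient fractions in order of increasing ribosome load.  Fraction A holds
#: free mRNA (plus free ribosomal subunits); B is the monosome; C..G carry
#: increasing numbers of ribosomes.
FRACTIONS = ("A", "B", "C", "D", "E", "F", "G")

#: Fractions whose mRNA is bound by at least one ribosome.
TRANSLATED_FRACTIONS = FRACTIONS[1:]


def _library_index(frame_or_series) -> pd.MultiIndex:
    idx = frame_or_series.columns if isinstance(frame_or_series, pd.DataFrame) else frame_or_series.index
    if not isinstance(idx, pd.MultiIndex) or idx.nlevels != 2:
        raise ValueError("library axis must be a (fraction, replicate) MultiIndex")
    return idx


@dataclass
class FractionCountMatrix:
    """Read counts per (gene, fraction, replicate) with library metadata.

    Parameters
    ----------
    counts
        genes x libraries frame; columns are ``(fraction, replicate)`` pairs.
        Values may be raw integer counts or normalized (float) counts.
    ribodepleted_ng
        RNA quantity (ng) recovered from ribodepletion of each library,
        indexed like the count columns.
    total_rna_ug
        Total RNA (µg) extracted from each pooled fraction, same index.
    phase
        Growth-phase label of the dataset ("exponential", "stationary" or
        any custom label); normalization never mixes phases.
    """

    counts: pd.DataFrame
    ribodepleted_ng: pd.Series
    total_rna_ug: pd.Series
    phase: str = "custom"

    def __post_init__(self) -> None:
        cols = _library_index(self.counts)
        if (np.asarray(self.counts, dtype=float) < 0).any():
            raise ValueError("counts must be nonnegative")
        for name, series in (("ribodepleted_ng", self.ribodepleted_ng),
                             ("total_rna_ug", self.total_rna_ug)):
            missing = cols.difference(_library_index(series))
            if len(missing):
                raise ValueError(f"{name} missing for libraries: {list(missing)}")
        self.ribodepleted_ng = self.ribodepleted_ng.reindex(cols)
        self.total_rna_ug = self.total_rna_ug.reindex(cols)

    @property
    def fractions(self) -> list[str]:
        return list(self.counts.columns.get_level_values(0).unique())

    @property
    def replicates(self) -> list:
        return list(self.counts.columns.get_level_values(1).unique())

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def select_genes(self, genes) -> "FractionCountMatrix":
        return FractionCountMatrix(self.counts.loc[genes], self.ribodepleted_ng,
                                   self.total_rna_ug, self.phase)

    def with_counts(self, counts: pd.DataFrame) -> "FractionCountMatrix":
        """Return a copy carrying ``counts`` but the same metadata."""
        return FractionCountMatrix(counts, self.ribodepleted_ng,
                                   self.total_rna_ug, self.phase)


@dataclass
class ProportionProfile:
    """Percent of each gene's mRNA copies found in each fraction, per replicate.

    ``proportions`` is genes x (fraction, replicate); every present
    (gene, replicate) column-slice sums to 100.  Replicates in which a gene had
    zero total signal are NaN throughout.
    """

    proportions: pd.DataFrame
    phase: str = "custom"

    _SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        _library_index(self.proportions)
        vals = np.asarray(self.proportions, dtype=float)
        if np.nanmin(vals, initial=0.0) < -self._SUM_TOL:
            raise ValueError("proportions must be nonnegative")
        sums = self.proportions.T.groupby(level=1).sum(min_count=1).T
        bad = ~(np.isnan(sums.to_numpy()) | np.isclose(sums.to_numpy(), 100.0, atol=1e-6))
        if bad.any():
            raise ValueError("each (gene, replicate) profile must sum to 100")

    @property
    def replicates(self) -> list:
        return list(self.proportions.columns.get_level_values(1).unique())

    @property
    def genes(self) -> pd.Index:
        return self.proportions.index

    @property
    def mean_proportions(self) -> pd.DataFrame:
        """genes x fractions mean profile over the replicates present."""
        return self.proportions.T.groupby(level=0).mean().T

    def replicate_profiles(self, gene) -> pd.DataFrame:
        """fractions x replicates profile matrix for one gene (NaN reps dropped)."""
        prof = self.proportions.loc[gene].unstack(level=1)
        return prof.dropna(axis=1, how="all").reindex(
            [f for f in FRACTIONS if f in prof.index])
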