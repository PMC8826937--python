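"""Pooling of sucrose-gradient subfractions into analysis fractions A..G.

A gradient run yields 24 subfractions, top of gradient first.  The leading
subfractions contain free RNA and free 30S/50S ribosomal subunits — their
23S/16S rRNA ratio deviates from the ~1.8 characteristic of whole 70S
ribosomes — and are pooled as fraction A.  The remaining subfractions are
partitioned at the local minima of total rRNA abundance separating successive
polysome peaks: the first peak is the monosome (fraction B), the 2nd–4th
peaks carry 2–4 ribosomes (C–E), and the heavier material is pooled into F
and G, whose ribosome numbers are extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FRACTIONS, FractionCountMatrix

#: 23S/16S mass-ratio window accepted as "whole ribosomes" (centred on ~1.8).
RATIO_WINDOW = (1.5, 2.1)

SUBFRACTION_COLUMNS = ("subfraction_id", "rrna16s_qty", "rrna23s_qty",
                       "total_rna_qty", "ribodepleted_qty")

N_SUBFRACTIONS = 24


class UnresolvableGradientError(ValueError):
    """Raised when too few polysome peaks can be resolved in the rRNA trace."""


def validate_subfraction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check and canonicalize a 24-row subfraction table (sorted by id)."""
    missing = set(SUBFRACTION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"subfraction table missing columns: {sorted(missing)}")
    if len(table) != N_SUBFRACTIONS:
        raise ValueError(f"expected {N_SUBFRACTIONS} subfractions, got {len(table)}")
    if table["subfraction_id"].duplicated().any():
        raise ValueError("subfraction ids must be unique")
    table = table.sort_values("subfraction_id").reset_index(drop=True)
    if not table["subfraction_id"].between(1, N_SUBFRACTIONS).all():
        raise ValueError("subfraction ids must lie in 1..24")
    for col in SUBFRACTION_COLUMNS[1:]:
        if (table[col] < 0).any():
            raise ValueError(f"{col} must be nonnegative")
    return table


def _smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving average with edge shrinking (window must be odd)."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def classify_subfractions(table: pd.DataFrame,
                          ratio_window: tuple[float, float] = RATIO_WINDOW,
                          smooth_window: int = 3) -> pd.Series:
    """Map each subfraction id to a fraction label A..G.

    The leading contiguous run of subfractions whose 23S/16S ratio falls
    outside ``ratio_window`` (free subunits / free RNA) becomes fraction A.
    The rest is cut at local minima of the smoothed total rRNA (16S+23S)
    abundance; peak blocks 1–4 become B–E and the remaining blocks are pooled
    into F and G.  At least six peak blocks' worth of material must be
    resolvable to fill B..G; otherwise the trace is reported unresolvable.
    """
    table = validate_subfraction_table(table)
    rrna_total = (table["rrna16s_qty"] + table["rrna23s_qty"]).to_numpy(dtype=float)
    if (rrna_total > 0).sum() < 7:
        raise UnresolvableGradientError("fewer than 7 subfractions contain rRNA")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(table["rrna16s_qty"] > 0,
                         table["rrna23s_qty"] / table["rrna16s_qty"], np.inf)

    lo, hi = ratio_window
    n_free = 0
    while n_free < len(ratio) and not (lo <= ratio[n_free] <= hi):
        n_free += 1
    if n_free == 0 or len(ratio) - n_free < 6:
        raise UnresolvableGradientError(
            "could not delimit a free-subunit block (fraction A) from the 23S/16S trace")

    body = rrna_total[n_free:]
    smoothed = _smooth(body, smooth_window)
    # block boundaries: local minima of the smoothed trace; a plateau (run of
    # equal values) counts as one minimum when strictly below both neighbour
    # runs, with the boundary at its first position
    runs = []  # (start_index, value)
    for i, val in enumerate(smoothed):
        if not runs or not np.isclose(val, runs[-1][1]):
            runs.append((i, val))
    minima = [runs[r][0] for r in range(1, len(runs) - 1)
              if runs[r][1] < runs[r - 1][1] and runs[r][1] < runs[r + 1][1]]
    # blocks are [start, end) index ranges within `body`; a minimum closes a
    # block and itself starts the next one (trough material rides with the
    # heavier peak, mirroring manual gating between peaks)
    bounds = [0, *minima, len(body)]
    blocks = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    if len(blocks) < 4:
        raise UnresolvableGradientError(
            f"only {len(blocks)} polysome peaks resolvable; at least 4 required")

    labels = ["A"] * n_free
    for bi, (start, end) in enumerate(blocks[:4]):
        labels += [FRACTIONS[1 + bi]] * (end - start)
    rest = blocks[4:]
    if not rest:
        raise UnresolvableGradientError(
            "no material beyond the 4th peak; cannot form fractions F and G")
    if len(rest) == 1:
        start, end = rest[0]
        if end - start < 2:
            raise UnresolvableGradientError(
                "single heavy-polysome subfraction cannot fill both F and G")
        mid = start + (end - start) // 2
        labels += ["F"] * (mid - start) + ["G"] * (end - mid)
    else:
        n_f_blocks = len(rest) // 2
        for idx, (start, end) in enumerate(rest):
            labels += [("F" if idx < n_f_blocks else "G")] * (end - start)
    return pd.Series(labels, index=table["subfraction_id"].to_numpy(), name="fraction")


def pool_counts(subfraction_counts: pd.DataFrame, labels: pd.Series,
                subfraction_meta: pd.DataFrame | None = None,
                replicate=1, phase: str = "custom") -> FractionCountMatrix:
    """Sum gene counts (and RNA quantities) of subfractions sharing a label.

    ``subfraction_counts`` is genes x subfraction_id.  Metadata, when given as
    a table with ``ribodepleted_qty``/``total_rna_qty`` columns indexed by
    ``subfraction_id``, is summed the same way; otherwise unit quantities are
    emitted (pool-only use).  Counts are conserved exactly.
    """
    unlabeled = [c for c in subfraction_counts.columns if c not in labels.index]
    if unlabeled:
        raise ValueError(f"no fraction label for subfractions: {unlabeled}")
    lab = labels.loc[subfraction_counts.columns]
    pooled = subfraction_counts.T.groupby(lab.to_numpy()).sum().T
    order = [f for f in FRACTIONS if f in pooled.columns]
    pooled = pooled[order]
    cols = pd.MultiIndex.from_product([order, [replicate]],
                                      names=["fraction", "replicate"])
    pooled.columns = cols
    if subfraction_meta is not None:
        meta = subfraction_meta.set_index("subfraction_id") \
            if "subfraction_id" in subfraction_meta.columns else subfraction_meta
        grouped = meta.loc[labels.index].groupby(labels.to_numpy()).sum()
        ribo = grouped["ribodepleted_qty"].reindex(order)
        total = grouped["total_rna_qty"].reindex(order)
    else:
        ribo = pd.Series(10.0, index=pd.Index(order))
        total = pd.Series(5.0, index=pd.Index(order))
    ribo.index = cols
    total.index = cols
    return FractionCountMatrix(pooled, ribo, total, phase=phase)


@dataclass(frozen=True)
class RibosomeMap:
    """Number of ribosomes attributed to each fraction A..G.

    A carries free mRNA (0 ribosomes); B is the monosome; C, D, E carry 2, 3
    and 4 ribosomes (the 2nd–4th peaks); F and G pool heavier polysomes whose
    ribosome numbers are extrapolated and therefore configurable.
    """

    counts: dict

    def __getitem__(self, fraction: str) -> int:
        if fraction not in self.counts:
            raise KeyError(f"no ribosome number for fraction {fraction!r}")
        return self.counts[fraction]

    def __iter__(self):
        return iter(self.counts)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name="ribosomes")


DEFAULT_F_RIBOSOMES = 6
DEFAULT_G_RIBOSOMES = 9


def build_ribosome_map(f_count: int = DEFAULT_F_RIBOSOMES,
                       g_count: int = DEFAULT_G_RIBOSOMES) -> RibosomeMap:
    """Ribosome numbers per fraction: fixed A..E, configurable F and G.

    ``f_count``/``g_count`` default to midpoints of plausible pooled polysome
    ranges (5–7 and 8–10); they must keep the map strictly increasing beyond
    fraction E.
    """
    if not (4 < f_count < g_count):
        raise ValueError("ribosome map must increase: require 4 < f_count < g_count")
    return RibosomeMap({"A": 0, "B": 1, "C": 2, "D": 3, "E": 4,
                        "F": int(f_count), "G": int(g_count)})
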