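"""Readers and writers for the plain-text tables the pipeline consumes.

Counts arrive either as HTSeq-count style two-column TSVs (one per library)
or as a single genes x libraries matrix TSV, in both cases accompanied by a
library metadata TSV with columns ``library_id, fraction, replicate,
ribodepleted_ng, total_rna_ug`` (and optionally ``phase``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import FractionCountMatrix

METADATA_COLUMNS = ("library_id", "fraction", "replicate",
                    "ribodepleted_ng", "total_rna_ug")

#: HTSeq-count appends special counter rows; they are never genes.
HTSEQ_SPECIAL_PREFIX = "__"


def read_htseq_counts(path) -> pd.Series:
    """One library's counts from a two-column (gene TAB count) TSV."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["gene", "count"],
                      dtype={0: str}, comment="#")
    tab = tab[~tab["gene"].str.startswith(HTSEQ_SPECIAL_PREFIX)]
    return tab.set_index("gene")["count"]


def read_library_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def counts_from_long_metadata(counts: pd.DataFrame,
                              metadata: pd.DataFrame) -> FractionCountMatrix:
    """Assemble a FractionCountMatrix from a genes x library_id frame."""
    meta = metadata.set_index("library_id")
    unknown = [c for c in counts.columns if c not in meta.index]
    if unknown:
        raise ValueError(f"libraries without metadata: {unknown}")
    meta = meta.loc[list(counts.columns)]
    cols = pd.MultiIndex.from_arrays([meta["fraction"], meta["replicate"]],
                                     names=["fraction", "replicate"])
    mat = counts.copy()
    mat.columns = cols
    ribo = pd.Series(meta["ribodepleted_ng"].to_numpy(), index=cols)
    total = pd.Series(meta["total_rna_ug"].to_numpy(), index=cols)
    phase = meta["phase"].iloc[0] if "phase" in meta.columns else "custom"
    return FractionCountMatrix(mat, ribo, total, phase=str(phase))


def read_count_dataset(counts_path, metadata_path) -> FractionCountMatrix:
    """Load counts (directory of HTSeq TSVs or one matrix TSV) + metadata."""
    metadata = read_library_metadata(metadata_path)
    counts_path = Path(counts_path)
    if counts_path.is_dir():
        series = {}
        for lib in metadata["library_id"]:
            f = counts_path / f"{lib}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"no count file for library {lib!r}: {f}")
            series[lib] = read_htseq_counts(f)
        counts = pd.DataFrame(series).fillna(0)
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    return counts_from_long_metadata(counts, metadata)


def write_count_dataset(fcm: FractionCountMatrix, out_dir,
                        matrix_name: str = "counts.tsv",
                        meta_name: str = "libraries.tsv") -> None:
    """Write a matrix TSV plus the library metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib_ids = [f"{f}_rep{k}" for f, k in fcm.counts.columns]
    mat = fcm.counts.copy()
    mat.columns = lib_ids
    mat.rename_axis("gene").to_csv(out / matrix_name, sep="\t")
    meta = pd.DataFrame({
        "library_id": lib_ids,
        "fraction": [f for f, _ in fcm.counts.columns],
        "replicate": [k for _, k in fcm.counts.columns],
        "ribodepleted_ng": fcm.ribodepleted_ng.to_numpy(),
        "total_rna_ug": fcm.total_rna_ug.to_numpy(),
        "phase": fcm.phase,
    })
    meta.to_csv(out / meta_name, sep="\t", index=False)


def read_subfraction_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_proportions(profile, path) -> None:
    """Long proportions TSV: gene, replicate, A..G."""
    props = profile.proportions
    long = props.stack(level=1, future_stack=True)
    long.index.names = ["gene", "replicate"]
    long.reset_index().to_csv(path, sep="\t", index=False)


def read_proportions(path):
    from .containers import ProportionProfile

    long = pd.read_csv(path, sep="\t")
    wide = long.set_index(["gene", "replicate"]).unstack("replicate")
    wide.columns.names = ["fraction", "replicate"]
    return ProportionProfile(wide.dropna(axis=1, how="all"))


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_orf_lengths(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return tab.iloc[:, 0]
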