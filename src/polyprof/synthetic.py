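"""Synthetic gradient data with known ground truth.

The generator emulates the statistical structure the analysis assumes: seven
pooled fractions A..G per replicate (A = free mRNA, B..G = 1..many ribosomes),
three biological replicates, multinomial read sampling of a
Dirichlet-perturbed true per-gene fraction profile, per-library scale
distortions that the normalization chain must undo, covariates linearly tied
to RO and log RD with known coefficients, and paired low/high-transcription
datasets.  It makes no attempt to model translation mechanistically
(initiation/elongation kinetics, ribosome traffic) or to simulate reads at the
sequence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FRACTIONS, TRANSLATED_FRACTIONS, FractionCountMatrix

DEFAULT_N_GENES = 300
DEFAULT_DEPTH = 50_000
DEFAULT_N_REPS = 3
#: Dirichlet concentration controlling replicate-to-replicate profile noise.
DEFAULT_NOISE_CONC = 200.0
#: Minimum of the simulated RO range (the analysed genes span roughly 15-100%).
RO_TRUTH_MIN = 15.0
RO_TRUTH_MAX = 100.0


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated dataset."""

    table: pd.DataFrame  # per gene: ro_true, peak_true, rd_true, orf_length, abundance
    profiles: pd.DataFrame | None = None  # genes x fractions, percent
    beta_true: dict | None = None  # predictor -> standardized coefficient
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = self.table
        if "ro_true" in t and not t["ro_true"].between(0, 100).all():
            raise ValueError("ro_true must lie in [0, 100]")
        if "peak_true" in t and (t["peak_true"] == "A").any():
            raise ValueError("peak_true may never be fraction A")
        if "rd_true" in t and (t["rd_true"].dropna() <= 0).any():
            raise ValueError("rd_true must be positive")
        if "orf_length" in t and (t["orf_length"] < 50).any():
            raise ValueError("orf_length must be >= 50 nt")


def simulate_fraction_profile(ro_true: float, peak: str, spread: float = 1.0,
                              n_fractions: int = 7) -> np.ndarray:
    """True percentage profile over A..G for one gene.

    Fraction A receives ``100 − ro_true``; the translated mass is spread over
    B..G by a tempered binomial kernel with its mode at ``peak``:
    ``w_k ∝ Binom(k; 5, p_peak)^(1/spread)`` with ``p_peak`` placing the
    binomial mode on the peak bin.  ``spread = 1`` gives the plain binomial,
    ``spread → 0`` a point mass at the peak, larger values a flatter profile.
    """
    if not 0 <= ro_true <= 100:
        raise ValueError("ro_true must lie in [0, 100]")
    if peak not in TRANSLATED_FRACTIONS:
        raise ValueError("peak must be a translated fraction B..G")
    if spread < 0:
        raise ValueError("spread must be nonnegative")
    if n_fractions != len(FRACTIONS):
        raise ValueError("only the 7-fraction A..G layout is supported")
    n_bins = len(TRANSLATED_FRACTIONS)
    mode = TRANSLATED_FRACTIONS.index(peak)
    if spread == 0:
        kernel = np.zeros(n_bins)
        kernel[mode] = 1.0
    else:
        base = stats.binom.pmf(np.arange(n_bins), n_bins - 1, mode / (n_bins - 1))
        # temper in log space relative to the mode so tiny spread degrades
        # gracefully to a point mass instead of underflowing
        with np.errstate(divide="ignore"):
            logw = np.where(base > 0, np.log(base) - np.log(base.max()), -np.inf)
        kernel = np.exp(logw / spread)
        kernel /= kernel.sum()
    profile = np.empty(len(FRACTIONS))
    profile[0] = 100.0 - ro_true
    profile[1:] = ro_true * kernel
    return profile


def _random_truth(n_genes: int, rng: np.random.Generator,
                  spread: float = 1.0,
                  abundance_sigma: float = 0.6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-gene ground truth: RO, peak, ORF length, mRNA abundance."""
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    ro = rng.uniform(RO_TRUTH_MIN, RO_TRUTH_MAX, n_genes)
    peaks = rng.choice(list(TRANSLATED_FRACTIONS), n_genes)
    orf_length = np.maximum(50, rng.lognormal(np.log(900), 0.5, n_genes)).round()
    abundance = rng.lognormal(0.0, abundance_sigma, n_genes)
    profiles = np.vstack([simulate_fraction_profile(r, p, spread)
                          for r, p in zip(ro, peaks)])
    table = pd.DataFrame({"ro_true": ro, "peak_true": peaks,
                          "orf_length": orf_length, "abundance": abundance},
                         index=pd.Index(genes, name="gene"))
    prof = pd.DataFrame(profiles, index=table.index, columns=list(FRACTIONS))
    return table, prof


def simulate_counts(true_profiles: pd.DataFrame | None = None,
                    depth: float = DEFAULT_DEPTH,
                    noise_conc: float | None = DEFAULT_NOISE_CONC,
                    lib_distortion=None,
                    n_reps: int = DEFAULT_N_REPS,
                    seed=None,
                    abundance: pd.Series | None = None,
                    n_genes: int = DEFAULT_N_GENES,
                    profile_spread: float = 1.0,
                    sampling: str = "multinomial",
                    phase: str = "synthetic"):
    """Simulate a raw :class:`FractionCountMatrix` plus its ground truth.

    For replicate ``k`` each gene's true profile is perturbed by a Dirichlet
    draw with concentration ``noise_conc × profile`` (``noise_conc=None``
    disables replicate noise).  Each gene's reads for that replicate —
    ``depth × 7 × abundance share`` on average per library — are distributed
    over the fractions A..G by a multinomial draw around the perturbed
    profile (``sampling="expected"`` emits the exact expected counts
    instead), after which every library's column is scaled by its
    ``lib_distortion`` factor, emulating uneven yields from ribodepletion to
    sequencing.

    Per-library metadata (ribodepleted ng, total-RNA µg) are emitted
    consistently with the realized library preparation: their product is
    proportional to the median-of-ratios size factor of the *undistorted*
    count matrix — the measured RNA-quantity record of what each fraction
    actually yielded — which is exactly the rescaling the three-stage
    normalization chain needs to undo the fraction-composition bias of
    library-size normalization and recover the per-replicate profiles.

    Returns ``(FractionCountMatrix, SyntheticTruth)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    if sampling not in ("multinomial", "expected"):
        raise ValueError(f"unknown sampling mode {sampling!r}")
    rng = np.random.default_rng(seed)
    if true_profiles is None:
        table, true_profiles = _random_truth(n_genes, rng, spread=profile_spread)
        if abundance is None:
            abundance = table["abundance"]
    else:
        true_profiles = pd.DataFrame(true_profiles).copy()
        if not np.allclose(true_profiles.sum(axis=1), 100.0):
            raise ValueError("true profiles must sum to 100")
        peaks = true_profiles[list(TRANSLATED_FRACTIONS)].idxmax(axis=1)
        table = pd.DataFrame({
            "ro_true": 100.0 - true_profiles["A"],
            "peak_true": peaks,
            "orf_length": 900.0,
            "abundance": 1.0 if abundance is None else abundance,
        }, index=true_profiles.index)
        if abundance is None:
            abundance = table["abundance"]

    genes = true_profiles.index
    n = len(genes)
    cols = pd.MultiIndex.from_product([list(FRACTIONS), range(1, n_reps + 1)],
                                      names=["fraction", "replicate"])
    if lib_distortion is None:
        distortion = pd.Series(1.0, index=cols)
    else:
        distortion = pd.Series(np.broadcast_to(np.asarray(lib_distortion, float),
                                               len(cols)).copy(), index=cols)
        if (distortion <= 0).any():
            raise ValueError("library distortion factors must be positive")

    p_true = true_profiles.to_numpy() / 100.0
    ab = np.asarray(abundance, dtype=float)
    # reads per gene and replicate: average library depth equals `depth`
    gene_reads = depth * len(FRACTIONS) * ab / ab.sum()

    counts = pd.DataFrame(0.0, index=genes, columns=cols)
    undistorted = np.empty((n, len(cols)))
    for k in range(1, n_reps + 1):
        if noise_conc is None or np.isinf(noise_conc):
            p = p_true
        else:
            alpha = noise_conc * p_true
            pos = p_true > 0
            gamma = np.where(pos, rng.gamma(np.where(pos, alpha, 1.0)), 0.0)
            p = gamma / gamma.sum(axis=1, keepdims=True)
        expected = gene_reads[:, None] * p  # genes x fractions
        if sampling == "expected":
            block = expected
        else:
            block = np.vstack([rng.multinomial(int(round(gene_reads[i])), p[i])
                               for i in range(n)]).astype(float)
        for j, frac in enumerate(FRACTIONS):
            lib = (frac, k)
            counts[lib] = block[:, j] * distortion[lib]
            undistorted[:, cols.get_loc(lib)] = block[:, j]

    # metadata product proportional to the undistorted size factor: the ng
    # yield of ribodepletion varies with the fraction's mRNA content while the
    # total-RNA quantity is dominated by rRNA and drawn independently
    from .normalization import size_factors_median_of_ratios

    v = size_factors_median_of_ratios(
        pd.DataFrame(undistorted, index=genes, columns=cols))
    total_ug = pd.Series(rng.uniform(10.0, 60.0, len(cols)), index=cols)
    ribo_ng = 150.0 * v * (30.0 / total_ug)
    ribo_ng.name = None

    fcm = FractionCountMatrix(counts, ribo_ng, total_ug, phase=phase)
    truth = SyntheticTruth(table=table, profiles=true_profiles)
    return fcm, truth


# --- covariate study -------------------------------------------------------

QUANTITATIVE_PREDICTORS = ("mrna_conc", "orf_length", "orf_gc", "cai",
                           "chrom_location", "hydrophobicity", "utr5_gc",
                           "utr5_length", "dg_tir")
QUALITATIVE_PREDICTORS = ("strand", "essentiality", "signal_peptide",
                          "inner_membrane", "cell_location", "cog",
                          "csra_target", "second_utr_nt")
ALL_PREDICTORS = QUANTITATIVE_PREDICTORS + QUALITATIVE_PREDICTORS

#: Predictors entering the models log-transformed.
DEFAULT_LOG_FLAGS = ("mrna_conc", "orf_length", "cai", "utr5_length")

CELL_LOCATIONS = ("cytoplasm", "inner_membrane", "periplasm", "outer_membrane")
COG_CLASSES = ("metabolism", "information", "cellular", "poorly_characterized")

#: Default true standardized effects for the recovery study; residual sd 0.822
#: puts the population R² at 0.25, inside the range typical of these models.
DEFAULT_BETA_TRUE = {
    "mrna_conc": 0.30, "orf_gc": -0.25, "cai": 0.20,
    "utr5_length": 0.15, "inner_membrane": -0.10,
}
DEFAULT_SIGMA = 0.822


def _draw_covariates(n_genes: int, rng: np.random.Generator) -> pd.DataFrame:
    genes = pd.Index([f"gene{i:04d}" for i in range(n_genes)], name="gene")
    return pd.DataFrame({
        "mrna_conc": rng.lognormal(0.0, 1.0, n_genes),
        "orf_length": np.maximum(50, rng.lognormal(np.log(900), 0.5, n_genes)).round(),
        "orf_gc": rng.uniform(40, 62, n_genes),
        "cai": rng.uniform(0.15, 0.85, n_genes),
        "chrom_location": rng.uniform(0, 2.3e6, n_genes),
        "hydrophobicity": rng.normal(-0.3, 0.4, n_genes),
        "utr5_gc": rng.uniform(25, 65, n_genes),
        "utr5_length": np.maximum(5, rng.lognormal(np.log(60), 0.7, n_genes)).round(),
        "dg_tir": rng.normal(-8.0, 3.0, n_genes),
        "strand": rng.choice(["+", "-"], n_genes),
        "essentiality": rng.random(n_genes) < 0.1,
        "signal_peptide": rng.random(n_genes) < 0.15,
        "inner_membrane": rng.random(n_genes) < 0.25,
        "cell_location": rng.choice(CELL_LOCATIONS, n_genes,
                                    p=[0.6, 0.25, 0.1, 0.05]),
        "cog": rng.choice(COG_CLASSES, n_genes, p=[0.4, 0.2, 0.2, 0.2]),
        "csra_target": rng.random(n_genes) < 0.1,
        "second_utr_nt": rng.choice(["purine", "pyrimidine"], n_genes),
    }, index=genes)


def standardized_effect_columns(cov: pd.DataFrame) -> pd.DataFrame:
    """One standardized column per predictor used to build the linear truth.

    Quantitative predictors are (log-transformed where flagged then) z-scored.
    Boolean predictors contribute an indicator with +1 on the True level, so
    a positive coefficient means the property raises the response; other
    qualitative predictors contribute their first sum-to-zero contrast
    column.  Every column is standardized to mean 0, sd 1, so the true
    coefficients attached to them are standardized effects.
    """
    from .regression import encode_qualitative

    cols = {}
    for name in QUANTITATIVE_PREDICTORS:
        x = cov[name].astype(float)
        if name in DEFAULT_LOG_FLAGS:
            x = np.log10(x)
        cols[name] = x
    for name in QUALITATIVE_PREDICTORS:
        if cov[name].dtype == bool:
            cols[name] = pd.Series(np.where(cov[name], 1.0, -1.0),
                                   index=cov.index)
        else:
            enc = encode_qualitative(cov[name])
            cols[name] = enc.iloc[:, 0]
    out = pd.DataFrame(cols, index=cov.index)
    return (out - out.mean()) / out.std(ddof=1)


def simulate_covariate_study(n_genes: int = 800,
                             beta_true: dict | None = None,
                             sigma: float = DEFAULT_SIGMA,
                             seed=None,
                             alpha_ro: float = 60.0,
                             beta_rd: dict | None = None,
                             alpha_rd: float = -0.3):
    """Covariate table plus RO / log10 RD responses with known coefficients.

    ``ro_true = clip(alpha_ro + Xβ + ε, 15, 100)`` and
    ``log10 rd_true = alpha_rd + Xβ' + ε'`` with ε, ε' ~ Normal(0, sigma) and
    X the standardized effect columns of the named predictors.  ``beta_rd``
    defaults to ``beta_true`` without any ``orf_length`` term (RD is defined
    per unit ORF length, so length is excluded from its model).

    Returns ``(covariates, SyntheticTruth)``; the truth table carries
    ``ro_true`` and ``rd_true``.
    """
    beta_true = dict(DEFAULT_BETA_TRUE if beta_true is None else beta_true)
    unknown = set(beta_true) - set(ALL_PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictors in beta_true: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(n_genes, rng)
    eff = standardized_effect_columns(cov)
    n_design_cols = eff.shape[1] + 1
    if n_genes < n_design_cols:
        raise ValueError(f"n_genes must be >= {n_design_cols} design columns")

    def linear(betas: dict) -> np.ndarray:
        out = np.zeros(n_genes)
        for name, b in betas.items():
            out += b * eff[name].to_numpy()
        return out

    ro = np.clip(alpha_ro + linear(beta_true) + rng.normal(0, sigma, n_genes),
                 RO_TRUTH_MIN, RO_TRUTH_MAX)
    if beta_rd is None:
        beta_rd = {k: v for k, v in beta_true.items() if k != "orf_length"}
    log_rd = alpha_rd + linear(beta_rd) + rng.normal(0, sigma, n_genes)
    table = pd.DataFrame({"ro_true": ro, "rd_true": 10.0 ** log_rd,
                          "orf_length": cov["orf_length"]}, index=cov.index)
    truth = SyntheticTruth(table=table, beta_true=beta_true, covariates=cov)
    return cov, truth


# --- induction pairs -------------------------------------------------------

def shift_from_a(amount: float, targets=("E", "F", "G")):
    """Shift rule moving ``amount`` (0..1] of fraction A equally into ``targets``."""
    if not 0 <= amount <= 1:
        raise ValueError("amount must lie in [0, 1]")
    t_idx = [FRACTIONS.index(t) for t in targets]

    def rule(profile: np.ndarray) -> np.ndarray:
        out = np.asarray(profile, dtype=float).copy()
        moved = out[0] * amount
        out[0] -= moved
        for i in t_idx:
            out[i] += moved / len(t_idx)
        return out

    return rule


def simulate_induction_pair(base_profile, mrna_fold: float = 20.0,
                            shift=None, seed=None,
                            depth: float = DEFAULT_DEPTH,
                            noise_conc: float | None = DEFAULT_NOISE_CONC,
                            n_reps: int = DEFAULT_N_REPS,
                            background_genes: int = 50):
    """Paired low/high-transcription count matrices for induced genes.

    ``base_profile`` maps gene id -> A..G percentage vector (a single vector
    is accepted for one gene).  Under induction each gene's profile is
    transformed by ``shift`` (callable profile -> profile; identity when
    None) and its mRNA abundance multiplied by ``mrna_fold``.  A background
    population of unperturbed genes is added so library-composition
    normalization has a stable reference.

    Returns ``(low, high, truth)`` where truth records both profiles and the
    expected RO under each condition.
    """
    if mrna_fold <= 1:
        raise ValueError("mrna_fold must exceed 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    if isinstance(base_profile, (list, tuple, np.ndarray, pd.Series)):
        base_profile = {"induced_gene": np.asarray(base_profile, dtype=float)}
    base = pd.DataFrame(base_profile).T
    base.columns = list(FRACTIONS)
    if not np.allclose(base.sum(axis=1), 100.0):
        raise ValueError("base profiles must sum to 100")
    shift = shift if shift is not None else (lambda p: p)
    shifted = np.vstack([shift(row) for row in base.to_numpy()])
    if (shifted < -1e-9).any():
        raise ValueError("shift rule produced negative proportions")
    if not np.allclose(shifted.sum(axis=1), 100.0):
        raise ValueError("shift rule must conserve total proportion")
    shifted = pd.DataFrame(np.clip(shifted, 0, None), index=base.index,
                           columns=base.columns)

    rng = np.random.default_rng(seed)
    bg_table, bg_profiles = _random_truth(background_genes, rng)
    bg_profiles.index = [f"bg{i:04d}" for i in range(background_genes)]
    bg_abundance = pd.Series(bg_table["abundance"].to_numpy(), index=bg_profiles.index)

    low_profiles = pd.concat([base, bg_profiles])
    high_profiles = pd.concat([shifted, bg_profiles])
    low_ab = pd.concat([pd.Series(1.0, index=base.index), bg_abundance])
    high_ab = pd.concat([pd.Series(float(mrna_fold), index=base.index), bg_abundance])

    seeds = np.random.SeedSequence(rng.integers(2**31)).spawn(2)
    low, _ = simulate_counts(low_profiles, depth=depth, noise_conc=noise_conc,
                             n_reps=n_reps, seed=seeds[0], abundance=low_ab,
                             phase="low")
    high, _ = simulate_counts(high_profiles, depth=depth, noise_conc=noise_conc,
                              n_reps=n_reps, seed=seeds[1], abundance=high_ab,
                              phase="high")
    truth = pd.DataFrame({
        "ro_low": 100.0 - base["A"],
        "ro_high": 100.0 - shifted["A"],
    }, index=base.index)
    return low, high, truth


# --- qPCR ------------------------------------------------------------------

def simulate_qpcr(rel_abundances: dict | pd.Series, spike_ct: float = 20.0,
                  efficiency: float = 2.0, noise_sd: float = 0.0,
                  seed=None, n_primer_pairs: int = 1) -> pd.DataFrame:
    """Ct table for target genes against a constant spike-in normalizer.

    ``Ct_target = spike_ct − log_efficiency(rel_abundance) + Normal(0, noise_sd)``
    per primer pair.  Columns: gene, primer_pair, ct_target, ct_spike.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    rel = pd.Series(rel_abundances, dtype=float)
    if (rel <= 0).any():
        raise ValueError("relative abundances must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, ab in rel.items():
        for pp in range(1, n_primer_pairs + 1):
            ct = spike_ct - np.log(ab) / np.log(efficiency)
            ct += rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((gene, pp, ct, spike_ct))
    return pd.DataFrame(rows, columns=["gene", "primer_pair", "ct_target", "ct_spike"])
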