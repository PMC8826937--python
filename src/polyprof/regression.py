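"""Multiple linear regression of translation metrics on gene covariates.

RO (percent) and log RD are modelled as linear functions of ~17 gene-level
predictors: mRNA concentration, ORF length and GC%, CAI, distance from OriC,
GRAVY hydrophobicity, 5'UTR length and GC%, TIR folding energy, strand,
essentiality, signal peptide, inner-membrane flag, cellular location, COG
class, CsrA-target status and the purine/pyrimidine class of the second 5'UTR
nucleotide.  Positive skewed predictors are log-transformed, all quantitative
columns are centred and reduced, qualitative predictors enter with
sum-to-zero (deviation) coding, coefficients are estimated by least squares
and the model is optionally pruned by stepwise AIC selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import (ALL_PREDICTORS, DEFAULT_LOG_FLAGS,
                        QUALITATIVE_PREDICTORS, QUANTITATIVE_PREDICTORS)


def transform_covariates(table: pd.DataFrame, log_flags=DEFAULT_LOG_FLAGS,
                         response=None, response_kind: str = "RO"):
    """Standardized quantitative design columns plus transformed response.

    Log-flagged columns are log10-transformed (strictly positive values
    required), then every quantitative column is z-scored (sample sd).  For
    the RD model the response is log10-transformed and ``orf_length`` is
    dropped from the design — RD is already normalized per unit ORF length.

    Returns ``(design, response)``; ``response`` is None when not supplied.
    """
    quant = [c for c in QUANTITATIVE_PREDICTORS if c in table.columns]
    if response_kind not in ("RO", "RD", "logRD"):
        raise ValueError("response_kind must be 'RO' or 'RD'")
    if response_kind in ("RD", "logRD") and "orf_length" in quant:
        quant.remove("orf_length")
    out = {}
    for col in quant:
        x = table[col].astype(float)
        if col in log_flags:
            if (x <= 0).any():
                raise ValueError(f"column {col!r} must be strictly positive "
                                 "to be log-transformed")
            x = np.log10(x)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    design = pd.DataFrame(out, index=table.index)
    y = None
    if response is not None:
        y = pd.Series(response, index=table.index, dtype=float)
        if response_kind in ("RD", "logRD"):
            if (y <= 0).any():
                raise ValueError("RD must be strictly positive for the log model")
            y = np.log10(y)
    return design, y


def encode_qualitative(levels: pd.Series) -> pd.DataFrame:
    """Sum-to-zero (deviation) coding: k−1 columns for k observed levels.

    Column ``<name>[<level>]`` is 1 on that level, −1 on the last (reference)
    level and 0 elsewhere, so each level's coefficient is its deviation from
    the mean of all levels.
    """
    levels = pd.Series(levels)
    cats = sorted(pd.unique(levels.astype(str)))
    if len(cats) < 2:
        raise ValueError(f"column {levels.name!r} has a single level; "
                         "deviation coding needs at least 2")
    ref = cats[-1]
    name = levels.name or "factor"
    out = {}
    s = levels.astype(str)
    for lev in cats[:-1]:
        col = np.where(s == lev, 1.0, np.where(s == ref, -1.0, 0.0))
        out[f"{name}[{lev}]"] = col
    return pd.DataFrame(out, index=levels.index)


def expand_deviation_coefficients(levels: pd.Series, coefs: pd.Series) -> pd.Series:
    """Per-level coefficients (summing to 0) from the k−1 contrast estimates."""
    cats = sorted(pd.unique(pd.Series(levels).astype(str)))
    name = pd.Series(levels).name or "factor"
    vals = {lev: coefs[f"{name}[{lev}]"] for lev in cats[:-1]}
    vals[cats[-1]] = -sum(vals.values())
    return pd.Series(vals)


def build_design(table: pd.DataFrame, log_flags=DEFAULT_LOG_FLAGS,
                 response=None, response_kind: str = "RO",
                 predictors=None):
    """Full design: standardized quantitative + deviation-coded qualitative.

    Returns ``(design, response, blocks)`` where ``blocks`` maps each
    predictor name to its design-column names (qualitative predictors own
    several columns that move together in model selection).  Genes with any
    missing value are dropped listwise.
    """
    predictors = list(ALL_PREDICTORS if predictors is None else predictors)
    cols = [c for c in predictors if c in table.columns]
    sub = table[cols].copy()
    keep = sub.notna().all(axis=1)
    if response is not None:
        resp = pd.Series(response, index=table.index)
        keep &= resp.notna()
    sub = sub.loc[keep]
    design_q, y = transform_covariates(
        sub, log_flags,
        None if response is None else pd.Series(response, index=table.index).loc[keep],
        response_kind)
    parts = [design_q]
    blocks = {c: [c] for c in design_q.columns}
    for col in QUALITATIVE_PREDICTORS:
        if col not in sub.columns:
            continue
        enc = encode_qualitative(sub[col].rename(col))
        blocks[col] = list(enc.columns)
        parts.append(enc)
    design = pd.concat(parts, axis=1)
    n_dropped = int((~keep).sum())
    return design, y, blocks, n_dropped


@dataclass
class TranslationRegressionResults:
    """Fitted regression of a translation metric on gene covariates."""

    response: str
    params: pd.Series
    pvalues: pd.Series
    r_squared: float
    aic: float
    n_genes: int
    included_predictors: list
    blocks: dict
    level_coefficients: dict = field(default_factory=dict)
    n_dropped: int = 0
    sm_results: object = None

    @property
    def intercept(self) -> float:
        return self.params["const"]

    def coefficient_table(self) -> pd.DataFrame:
        """Long table: predictor, level, coefficient, p-value (expanded
        per-level coefficients for qualitative predictors sum to zero)."""
        rows = []
        for pred in self.included_predictors:
            if pred in self.level_coefficients:
                pvals = {c: self.pvalues[c] for c in self.blocks[pred]}
                expanded = self.level_coefficients[pred]
                for lev, coef in expanded.items():
                    key = f"{pred}[{lev}]"
                    rows.append((pred, lev, coef, pvals.get(key, np.nan)))
            else:
                rows.append((pred, "", self.params[pred], self.pvalues[pred]))
        return pd.DataFrame(rows, columns=["predictor", "level",
                                           "coefficient", "p_value"])

    def summary(self) -> str:
        tab = self.coefficient_table()
        lines = [
            f"Translation regression: response = {self.response}",
            "=" * 56,
            f"n genes: {self.n_genes}   (dropped for missing values: {self.n_dropped})",
            f"R^2: {self.r_squared:.3f}   AIC: {self.aic:.1f}",
            f"intercept: {self.intercept:.4f}",
            f"predictors included: {len(self.included_predictors)}",
            "-" * 56,
            tab.to_string(index=False,
                          float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


def _result_from_fit(fit, response, blocks, included, table, n_dropped):
    level_coefs = {}
    for pred in included:
        if pred in QUALITATIVE_PREDICTORS and pred in table.columns:
            level_coefs[pred] = expand_deviation_coefficients(
                table[pred].rename(pred), fit.params)
    return TranslationRegressionResults(
        response=response, params=fit.params, pvalues=fit.pvalues,
        r_squared=float(fit.rsquared), aic=float(fit.aic),
        n_genes=int(fit.nobs), included_predictors=list(included),
        blocks=blocks, level_coefficients=level_coefs,
        n_dropped=n_dropped, sm_results=fit)


def fit_ols(design: pd.DataFrame, response: pd.Series,
            add_constant: bool = True):
    """Ordinary least squares with per-coefficient two-sided t-test p-values.

    Raises on rank deficiency, naming the collinear columns.
    """
    X = sm.add_constant(design, has_constant="add") if add_constant else design
    if len(response) <= X.shape[1]:
        raise ValueError("need more genes than design columns")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-10 * max(abs(np.diag(r)))]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return sm.OLS(np.asarray(response, float), X).fit()


def stepwise_aic(design: pd.DataFrame, response: pd.Series, blocks: dict,
                 direction: str = "both"):
    """Stepwise predictor-block selection minimizing AIC.

    Whole predictors (all design columns of a qualitative block) are added or
    removed while AIC strictly decreases; deterministic given the block
    order.  Starts from the full model for ``backward``/``both`` and from the
    intercept-only model for ``forward``.

    Returns ``(fit, included_predictors)``.
    """
    if direction not in ("both", "backward", "forward"):
        raise ValueError("direction must be 'both', 'backward' or 'forward'")
    all_preds = list(blocks)
    included = [] if direction == "forward" else list(all_preds)

    def fit_subset(preds):
        cols = [c for p in preds for c in blocks[p]]
        X = sm.add_constant(design[cols], has_constant="add")
        return sm.OLS(np.asarray(response, float), X).fit()

    current = fit_subset(included)
    current_aic = current.aic
    while True:
        best = None
        if direction in ("both", "backward"):
            for p in included:
                cand = [q for q in included if q != p]
                f = fit_subset(cand)
                if f.aic < current_aic and (best is None or f.aic < best[0]):
                    best = (f.aic, f, cand)
        if direction in ("both", "forward"):
            for p in all_preds:
                if p in included:
                    continue
                cand = included + [p]
                f = fit_subset(cand)
                if f.aic < current_aic and (best is None or f.aic < best[0]):
                    best = (f.aic, f, cand)
        if best is None:
            return current, included
        current_aic, current, included = best


def spearman_bh(metric: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of a metric against each covariate, BH-adjusted.

    Rank correlation handles ties by average ranks; p-values are adjusted
    across the covariate family with the Benjamini-Hochberg step-up
    procedure.  Constant covariates yield NaN and are excluded from the
    adjustment family.
    """
    covariates = pd.DataFrame(covariates)
    rows = {}
    for col in covariates.columns:
        pair = pd.concat([pd.Series(metric), covariates[col]], axis=1).dropna()
        if len(pair) < 3:
            raise ValueError(f"need >= 3 paired observations for {col!r}")
        if pair[col].nunique() < 2 or pair.iloc[:, 0].nunique() < 2:
            rows[col] = (np.nan, np.nan, len(pair))
            continue
        rho, p = stats.spearmanr(pair.iloc[:, 0], pair[col])
        rows[col] = (rho, p, len(pair))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["rho", "p_value", "n"])
    valid = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = multipletests(out.loc[valid, "p_value"],
                                              method="fdr_bh")[1]
    out["p_adjusted"] = adj
    return out


class TranslationRegressionModel:
    """statsmodels-style front end for the RO / log RD covariate regression.

    Parameters
    ----------
    covariates : pandas.DataFrame
        Gene covariate table (any subset of the 17 canonical predictors).
    response : pandas.Series
        Per-gene metric: RO (percent) or RD (ribosomes/100 nt, logged
        internally when ``response_kind`` is "RD").
    response_kind : {"RO", "RD"}
    log_flags, predictors
        Override which quantitative predictors are log-transformed and which
        predictors enter the full model.
    """

    def __init__(self, covariates: pd.DataFrame, response: pd.Series,
                 response_kind: str = "RO", log_flags=DEFAULT_LOG_FLAGS,
                 predictors=None):
        self.covariates = covariates
        self.response = pd.Series(response).reindex(covariates.index)
        self.response_kind = response_kind
        self.log_flags = log_flags
        self.predictors = predictors
        self.design, self.y, self.blocks, self.n_dropped = build_design(
            covariates, log_flags, self.response, response_kind, predictors)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response_col: str,
                       response_kind: str = "RO", **kwargs):
        cov = frame.drop(columns=[response_col])
        return cls(cov, frame[response_col], response_kind, **kwargs)

    def fit(self, select: str = "none", direction: str = "both"):
        """Fit by OLS; ``select="aic"`` runs stepwise AIC block selection."""
        table = self.covariates.loc[self.design.index]
        if select == "none":
            f = fit_ols(self.design, self.y)
            included = list(self.blocks)
        elif select == "aic":
            f, included = stepwise_aic(self.design, self.y, self.blocks,
                                       direction)
        else:
            raise ValueError("select must be 'none' or 'aic'")
        name = "RO" if self.response_kind == "RO" else "logRD"
        return _result_from_fit(f, name, self.blocks, included, table,
                                self.n_dropped)
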