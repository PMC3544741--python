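"""Cell-type deconvolution of bulk expression by composition-interaction
multiple linear regression.

For each gene the observed log2 expression of sample i is modeled as

    y_i = beta0 + sum_j beta_j * P_ij + sum_j gamma_j * P_ij * RS_i + eps_i,
    eps_i ~ N(0, sigma^2),

where P_ij is the pathologist-estimated fraction of cell type j in sample i
and RS_i the binary relapse indicator.  beta_j is then the cell-type-specific
expression in non-relapse samples and gamma_j = beta_j(relapse) -
beta_j(non-relapse) the relapse differential for that cell type.  Inference
on each coefficient is an ordinary two-sided t-test on the residual degrees
of freedom; gamma_tumor and its p-value are the quantities of interest for
outcome-linked, tumor-cell-specific expression.

The design matrix is shared across all genes of a matrix, so the whole array
is fit with a single rank-revealing factorization — this is what makes
genome-scale fits (tens of thousands of probe sets) take seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

INTERCEPT = "intercept"


class CollinearityError(ValueError):
    """Design matrix numerically rank-deficient."""


class UnderdeterminedError(ValueError):
    """Not enough residual degrees of freedom to fit."""


class DataError(ValueError):
    """Non-finite or misaligned input data."""


def _as_fractions(compositions: pd.DataFrame) -> pd.DataFrame:
    """Rescale percentage-scale tables (0-100) to fractions with a warning."""
    if compositions.to_numpy().max() > 1.5:
        log.warning("composition table looks percentage-scaled; dividing by 100")
        return compositions / 100.0
    return compositions


def interaction_name(cell_type: str) -> str:
    return f"{cell_type}:relapse"


def build_design(
    compositions: pd.DataFrame,
    relapse: pd.Series,
    modeled_types: list[str] | tuple[str, ...] = ("tumor", "stroma", "BPH"),
    cond_max: float = 1e10,
) -> pd.DataFrame:
    """Samples x coefficients design: intercept, one fraction column per
    modeled cell type, then one fraction x relapse interaction per type.

    Raises :class:`CollinearityError` when the design (ignoring identically
    zero columns, which the fit drops) is numerically rank-deficient — e.g.
    when all simplex fractions are modeled together with the intercept.
    """
    missing = [t for t in modeled_types if t not in compositions.columns]
    if missing:
        raise DataError(f"modeled cell types absent from composition table: {missing}")
    comp = _as_fractions(compositions[list(modeled_types)])
    rs = relapse.reindex(comp.index)
    if rs.isna().any():
        raise DataError("relapse labels missing for some samples")
    rs = rs.astype(float)

    design = pd.DataFrame(index=comp.index)
    design[INTERCEPT] = 1.0
    for t in modeled_types:
        design[t] = comp[t]
    for t in modeled_types:
        design[interaction_name(t)] = comp[t] * rs

    live = design.loc[:, (design != 0).any(axis=0)]
    cond = np.linalg.cond(live.to_numpy())
    if cond > cond_max:
        # name the columns involved in the near-dependence via pivoted QR
        arr = live.to_numpy()
        arr = arr / np.linalg.norm(arr, axis=0)
        _, rmat = np.linalg.qr(arr)
        small = np.abs(np.diag(rmat)) < 1e-8 * np.abs(np.diag(rmat)).max()
        offending = list(live.columns[np.flatnonzero(small)]) or list(live.columns)
        raise CollinearityError(
            f"design condition number {cond:.3g} exceeds {cond_max:.3g}; "
            f"columns involved: {offending}"
        )
    return design


@dataclass
class MLRFit:
    """Per-gene fit: coefficient estimates with SE, t and two-sided p.

    Coefficients for columns dropped from the design (identically zero, e.g.
    interactions when no sample relapsed) are reported as NaN.
    """

    gene_id: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    resid_sd: float

    def beta(self, cell_type: str) -> float:
        return float(self.params[cell_type])

    def gamma(self, cell_type: str) -> float:
        return float(self.params[interaction_name(cell_type)])


class CellTypeInteractionRegression(BaseEstimator):
    """Per-gene OLS of expression on cell-type fractions and fraction x
    relapse interactions, sklearn-style.

    Parameters
    ----------
    modeled_types : cell types entered as fraction + interaction columns.
        Leave at least one composition column out (the remainder type) or the
        fractions are collinear with the intercept.
    relapse_col : name of the relapse indicator column of ``X``.
    center_samples : subtract each sample's mean expression over all genes
        before fitting (paper-replication normalization; expresses beta
        relative to the array mean).  Off by default.
    cond_max : condition-number bound above which the design is rejected.

    After ``fit(X, y)`` with ``X`` a samples x (fractions + relapse)
    DataFrame and ``y`` of shape (n_samples,) or (n_samples, n_genes):

    ``coef_``, ``bse_``, ``tvalues_``, ``pvalues_`` : (n_genes, n_columns)
    DataFrames over the full design columns (dropped columns NaN);
    ``df_resid_``, ``resid_sd_``, ``design_``, ``dropped_columns_``.
    """

    def __init__(
        self,
        modeled_types: tuple[str, ...] = ("tumor", "stroma", "BPH"),
        relapse_col: str = "relapse",
        center_samples: bool = False,
        cond_max: float = 1e10,
    ):
        self.modeled_types = modeled_types
        self.relapse_col = relapse_col
        self.center_samples = center_samples
        self.cond_max = cond_max

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "CellTypeInteractionRegression":
        if self.relapse_col not in X.columns:
            raise DataError(f"X lacks relapse column {self.relapse_col!r}")
        relapse = X[self.relapse_col]
        comp = X.drop(columns=[self.relapse_col])
        design = build_design(comp, relapse, self.modeled_types, self.cond_max)

        Y = np.asarray(y, float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        if Y.shape[0] != len(design):
            raise DataError(f"y has {Y.shape[0]} samples, design has {len(design)}")
        if not np.isfinite(Y).all():
            raise DataError("y contains non-finite values")
        if self.center_samples:
            Y = Y - Y.mean(axis=1, keepdims=True)

        cols = list(design.columns)
        keep = [(design[c] != 0).any() for c in cols]
        dropped = [c for c, k in zip(cols, keep) if not k]
        if dropped:
            log.info("dropping identically-zero design columns: %s", dropped)
        Xd = design.loc[:, [c for c, k in zip(cols, keep) if k]]
        A = Xd.to_numpy()
        n, p = A.shape
        df = n - p
        if df < 1:
            raise UnderdeterminedError(f"{n} samples, {p} coefficients: df < 1")

        # one shared factorization for every gene of the matrix
        q, r = np.linalg.qr(A)
        coefs = np.linalg.solve(r, q.T @ Y)  # (p, g)
        resid = Y - A @ coefs
        rss = (resid**2).sum(axis=0)
        sigma2 = rss / df
        rinv = np.linalg.inv(r)
        xtx_inv_diag = (rinv**2).sum(axis=1)  # diag of (X'X)^-1
        se = np.sqrt(np.outer(xtx_inv_diag, sigma2))  # (p, g)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, coefs / se, 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

        genes = (
            list(y.columns) if isinstance(y, pd.DataFrame)
            else [f"g{i}" for i in range(Y.shape[1])]
        )

        def _table(block: np.ndarray) -> pd.DataFrame:
            out = pd.DataFrame(np.nan, index=genes, columns=cols)
            out.loc[:, list(Xd.columns)] = block.T
            return out

        self.design_ = design
        self.dropped_columns_ = dropped
        self.coef_ = _table(coefs)
        self.bse_ = _table(se)
        self.tvalues_ = _table(tvals)
        self.pvalues_ = _table(pvals)
        self.df_resid_ = df
        self.resid_sd_ = pd.Series(np.sqrt(sigma2), index=genes, name="resid_sd")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self._squeeze = squeeze
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        relapse = X[self.relapse_col]
        comp = X.drop(columns=[self.relapse_col])
        design = build_design(comp, relapse, self.modeled_types, self.cond_max)
        coefs = self.coef_.fillna(0.0).to_numpy().T
        out = design.to_numpy() @ coefs
        return out[:, 0] if self._squeeze else out

    # -- reporting --------------------------------------------------------

    def results_(self) -> pd.DataFrame:
        """Tidy fit table: one row per gene, beta/gamma/se/t/p per column."""
        rows = {"gene_id": self.coef_.index}
        table = pd.DataFrame(rows).set_index("gene_id")
        table["beta0"] = self.coef_[INTERCEPT]
        for t in self.modeled_types:
            table[f"beta_{t}"] = self.coef_[t]
            table[f"gamma_{t}"] = self.coef_[interaction_name(t)]
        for stat, src in (("se", self.bse_), ("t", self.tvalues_), ("p", self.pvalues_)):
            for c in self.coef_.columns:
                table[f"{stat}_{c}"] = src[c]
        table["df_resid"] = self.df_resid_
        table["resid_sd"] = self.resid_sd_
        return table


# ---------------------------------------------------------------------------
# functional wrappers


def fit_gene(y, design: pd.DataFrame) -> MLRFit:
    """Fit one gene against a prebuilt design matrix (OLS via QR).

    ``y`` may be a Series (its name becomes the gene id) or an array.
    """
    Y = np.asarray(y, float)
    if Y.ndim != 1 or Y.size != len(design):
        raise DataError("y must be one value per design row")
    if not np.isfinite(Y).all():
        raise DataError("y contains non-finite values")

    cols = list(design.columns)
    keep = [(design[c] != 0).any() for c in cols]
    Xd = design.loc[:, [c for c, k in zip(cols, keep) if k]]
    n, p = Xd.shape
    df = n - p
    if df < 1:
        raise UnderdeterminedError(f"{n} samples, {p} coefficients: df < 1")
    A = Xd.to_numpy()
    q, r = np.linalg.qr(A)
    coef = np.linalg.solve(r, q.T @ Y)
    resid = Y - A @ coef
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    se = np.sqrt((rinv**2).sum(axis=1) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    def _full(vals: np.ndarray) -> pd.Series:
        s = pd.Series(np.nan, index=cols)
        s[list(Xd.columns)] = vals
        return s

    gene_id = getattr(y, "name", None) or "gene"
    return MLRFit(
        gene_id=str(gene_id),
        params=_full(coef),
        bse=_full(se),
        tvalues=_full(tvals),
        pvalues=_full(pvals),
        df_resid=df,
        resid_sd=float(np.sqrt(sigma2)),
    )


def fit_all(
    expr: pd.DataFrame,
    compositions: pd.DataFrame,
    relapse: pd.Series,
    modeled_types: tuple[str, ...] = ("tumor", "stroma", "BPH"),
    center_samples: bool = False,
) -> pd.DataFrame:
    """Fit every probe row of a probes x samples matrix; returns the tidy
    fit table indexed by gene id, in the input probe order."""
    shared = expr.columns.intersection(compositions.index)
    if len(shared) < len(expr.columns):
        raise DataError("expression samples missing from the composition table")
    X = compositions.loc[expr.columns].copy()
    X["relapse"] = relapse.reindex(expr.columns)
    est = CellTypeInteractionRegression(
        modeled_types=modeled_types, center_samples=center_samples
    )
    est.fit(X, expr.T)
    log.info("fit %d genes x %d samples (df=%d)", expr.shape[0], expr.shape[1],
             est.df_resid_)
    return est.results_()


def rank_by_gamma(fits: pd.DataFrame, cell_type: str) -> pd.DataFrame:
    """Order genes by ascending relapse differential for one cell type.

    Most negative gamma first; ties broken lexicographically by gene id;
    adds a 1-based ``rank`` column.
    """
    col = f"gamma_{cell_type}"
    if col not in fits.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    out = fits.copy()
    out["_gid"] = out.index.astype(str)
    out = out.sort_values([col, "_gid"], kind="mergesort").drop(columns="_gid")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def significant_negative_gamma(
    fits: pd.DataFrame, cell_type: str = "tumor", alpha: float = 0.05
) -> pd.Series:
    """Boolean mask: gamma < 0 with two-sided p <= alpha — the definition of
    a 'significant negative' relapse differential used for enrichment."""
    return (fits[f"gamma_{cell_type}"] < 0) & (
        fits[f"p_{interaction_name(cell_type)}"] <= alpha
    )
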