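"""Seed-gene co-expression screening.

Given a probes x samples log2 expression matrix and one seed probe (Egr3 in
the original application), compute for every probe the Pearson correlation R
with the seed across samples, the two-sided p-value from the exact t
transform t = R * sqrt((n-2)/(1-R^2)), and the OLS slope of the candidate on
the seed.  Candidates are the positively correlated probes passing the fixed
cutoffs R >= 0.45 and p <= 0.001 (inclusive), and lists from different array
platforms are intersected at the unique-gene-symbol level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)


def pearson_screen(expr: pd.DataFrame, seed_probe: str) -> pd.DataFrame:
    """Correlate every probe with the seed probe across samples.

    Missing entries are dropped pairwise; each record carries its own n.
    Returns a DataFrame indexed by probe_id with columns pearson_r,
    p_two_sided, slope, n_samples, degenerate.  Zero-variance probes get
    NaN statistics and ``degenerate=True`` (excluded from filtering); the
    seed itself is included with R = 1.
    """
    if seed_probe not in expr.index:
        raise KeyError(f"seed probe {seed_probe!r} not in matrix")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")

    X = expr.to_numpy(float)
    s = expr.loc[seed_probe].to_numpy(float)
    seed_ok = np.isfinite(s)
    ok = np.isfinite(X) & seed_ok[None, :]
    n = ok.sum(axis=1).astype(float)

    Xm = np.where(ok, X, 0.0)
    Sm = np.where(ok, s[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xm.sum(axis=1) / n
        ms = Sm.sum(axis=1) / n
        dx = np.where(ok, X - mx[:, None], 0.0)
        ds = np.where(ok, s[None, :] - ms[:, None], 0.0)
        sxy = (dx * ds).sum(axis=1)
        sxx = (dx * dx).sum(axis=1)
        sss = (ds * ds).sum(axis=1)
        r = sxy / np.sqrt(sxx * sss)
        slope = sxy / sss
        # exact self-correlation for numerically identical profiles
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isinf(t), 0.0, p)

    degenerate = (sxx <= 0) | (sss <= 0) | (n < 3)
    out = pd.DataFrame(
        {
            "pearson_r": np.where(degenerate, np.nan, r),
            "p_two_sided": np.where(degenerate, np.nan, p),
            "slope": np.where(degenerate, np.nan, slope),
            "n_samples": n.astype(int),
            "degenerate": degenerate,
        },
        index=expr.index.rename("probe_id"),
    )
    n_deg = int(degenerate.sum())
    if n_deg:
        log.warning("%d zero-variance probe(s) flagged and excluded from filtering", n_deg)
    return out


def filter_candidates(
    records: pd.DataFrame,
    min_r: float = 0.45,
    max_p: float = 0.001,
    seed_probe: str | None = None,
) -> pd.DataFrame:
    """Positively correlated records with R >= min_r and p <= max_p
    (inclusive bounds); degenerate records and the seed itself are excluded."""
    ok = (
        ~records["degenerate"]
        & (records["pearson_r"] >= min_r)
        & (records["p_two_sided"] <= max_p)
    )
    out = records[ok]
    if seed_probe is not None and seed_probe in out.index:
        out = out.drop(index=seed_probe)
    return out


def top_k_by_p(records: pd.DataFrame, k: int = 150) -> pd.DataFrame:
    """k smallest p-values among positively correlated records; ties broken
    by larger R, then probe id."""
    pos = records[~records["degenerate"] & (records["pearson_r"] > 0)].copy()
    if k > len(pos):
        log.info("requested top %d but only %d positive records", k, len(pos))
        k = len(pos)
    pos["_gid"] = pos.index.astype(str)
    pos = pos.sort_values(
        ["p_two_sided", "pearson_r", "_gid"], ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_gid")
    return pos.head(k)


def annotate(records: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach gene symbols from a two-column probe_id -> gene_symbol table."""
    ann = annotation.set_index("probe_id")["gene_symbol"] if "probe_id" in annotation.columns else annotation.iloc[:, 0]
    out = records.copy()
    out["gene_symbol"] = ann.reindex(out.index)
    return out


def _symbols(probes, annotation: pd.DataFrame) -> set[str]:
    ann = annotation.set_index("probe_id")["gene_symbol"]
    syms = ann.reindex(probes)
    missing = syms.isna()
    if missing.any():
        log.warning("%d probe(s) without annotation excluded from gene-level overlap",
                    int(missing.sum()))
    return {str(s).upper() for s in syms.dropna()}


@dataclass(frozen=True)
class OverlapReport:
    """Probe- and unique-gene-level intersection of two candidate lists.

    A gene counts once regardless of probe multiplicity; symbol matching is
    case-insensitive."""

    n_probes_a: int
    n_probes_b: int
    probe_overlap: tuple[str, ...]
    n_genes_a: int
    n_genes_b: int
    gene_overlap: tuple[str, ...]

    @property
    def n_gene_overlap(self) -> int:
        return len(self.gene_overlap)


def cross_platform_overlap(
    list_a, list_b, annotation_a: pd.DataFrame, annotation_b: pd.DataFrame
) -> OverlapReport:
    """Intersect candidate lists from two platforms.

    ``list_a`` / ``list_b`` are iterables of probe ids (or DataFrames indexed
    by probe id).  Probe-level intersection is reported where probe ids are
    shared; the headline count is the unique-gene-symbol intersection.
    """
    probes_a = list(list_a.index) if isinstance(list_a, pd.DataFrame) else list(list_a)
    probes_b = list(list_b.index) if isinstance(list_b, pd.DataFrame) else list(list_b)
    genes_a = _symbols(probes_a, annotation_a)
    genes_b = _symbols(probes_b, annotation_b)
    return OverlapReport(
        n_probes_a=len(set(probes_a)),
        n_probes_b=len(set(probes_b)),
        probe_overlap=tuple(sorted(set(probes_a) & set(probes_b))),
        n_genes_a=len(genes_a),
        n_genes_b=len(genes_b),
        gene_overlap=tuple(sorted(genes_a & genes_b)),
    )


def candidate_table(records: pd.DataFrame, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Supplementary-table-style output: probe_id, gene_symbol, R, p, slope,
    sorted by slope descending."""
    out = annotate(records, annotation) if annotation is not None else records.copy()
    cols = [c for c in ("gene_symbol", "pearson_r", "p_two_sided", "slope", "n_samples") if c in out.columns]
    return out[cols].sort_values("slope", ascending=False, kind="mergesort")


class SeedCorrelationScreen(BaseEstimator):
    """sklearn-style wrapper around the seed-gene screen.

    ``fit(X)`` with X a probes x samples DataFrame computes ``records_``
    (all probes) and ``candidates_`` (cutoffs applied, seed excluded).
    """

    def __init__(self, seed_probe: str, min_r: float = 0.45, max_p: float = 0.001):
        self.seed_probe = seed_probe
        self.min_r = min_r
        self.max_p = max_p

    def fit(self, X: pd.DataFrame, y=None) -> "SeedCorrelationScreen":
        self.records_ = pearson_screen(X, self.seed_probe)
        self.candidates_ = filter_candidates(
            self.records_, self.min_r, self.max_p, seed_probe=self.seed_probe
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Rows of ``X`` that passed the screen."""
        return X.loc[X.index.intersection(self.candidates_.index)]
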