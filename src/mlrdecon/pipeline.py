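"""End-to-end replication pipeline and small auxiliary statistics.

``run_replication`` composes the full analysis on a synthetic cohort whose
ground truth is known: simulate compositions, outcomes and expression
(EGR-family presets + null genes + a seed-correlated module), fit the
composition-interaction regression genome-wide, rank the tumor relapse
differentials, screen for seed-correlated genes, run the three Monte-Carlo
enrichment tests, scan generated promoters for ERE sites, and quantify a
synthetic IHC image.  Every stage is deterministic given the config seed and
all outputs embed the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import correlation, deconvolution, enrichment, ihc, motif, presets, simulate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the replication run; defaults are the study-scale conditions."""

    seed: int = 0
    n_samples: int = presets.DEFAULT_N_SAMPLES
    relapse_fraction: float = presets.DEFAULT_RELAPSE_FRACTION
    dirichlet_alpha: tuple[float, ...] = presets.DEFAULT_DIRICHLET_ALPHA
    n_null_genes: int = 2000
    n_module_genes: int = 98
    module_target_r: float = 0.7
    noise_sd: float = presets.CALIBRATED_NOISE_SD
    screen_min_r: float = 0.45
    screen_max_p: float = 0.001
    motif_threshold: float = 0.80
    promoter_length: int = 500
    promoter_site_fraction: float = 0.627
    image_size: int = 512
    alpha: float = 0.05
    outdir: str | None = None

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(report: dict, name: str, t0: float) -> float:
    dt = time.perf_counter() - t0
    report.setdefault("timings_s", {})[name] = round(dt, 3)
    log.info("stage %s: %.2fs", name, dt)
    return time.perf_counter()


def run_replication(config: PipelineConfig) -> dict:
    """Run every stage on one synthetic cohort; returns the report dict and,
    when ``config.outdir`` is set, writes all stage outputs there."""
    report: dict = {"seed": config.seed, "config_hash": config.hash(),
                    "config": dataclasses.asdict(config)}
    t0 = time.perf_counter()

    # --- cohort + expression -------------------------------------------
    spec = simulate.CohortSpec(
        n_samples=config.n_samples,
        dirichlet_alpha=config.dirichlet_alpha,
        relapse_fraction=config.relapse_fraction,
        seed=config.seed,
    )
    comps = simulate.generate_compositions(spec)
    relapse = simulate.generate_relapse_labels(spec)
    models = list(presets.table2_models(noise_sd=config.noise_sd).values())
    rng = np.random.default_rng(config.seed + 10)
    for k in range(config.n_null_genes):
        models.append(
            simulate.GeneModel(
                gene_id=f"null{k:05d}_at",
                beta0=float(rng.normal(presets.DEFAULT_BETA0, 1.0)),
                noise_sd=config.noise_sd,
            )
        )
    expr = simulate.simulate_expression(comps, relapse, models, seed=config.seed + 20)
    module = simulate.simulate_correlated_module(
        expr.loc["Egr3"],
        simulate.CorrelatedModuleSpec(
            n_genes=config.n_module_genes,
            target_R=config.module_target_r,
            seed=config.seed + 30,
        ),
    )
    expr = pd.concat([expr, module])
    t0 = _stage(report, "simulate", t0)

    # --- deconvolution --------------------------------------------------
    fits = deconvolution.fit_all(expr, comps, relapse, presets.MODELED_TYPES)
    ranked = deconvolution.rank_by_gamma(fits, "tumor")
    sig = deconvolution.significant_negative_gamma(fits, "tumor", config.alpha)
    background_rate = float(sig.mean())
    report["deconvolution"] = {
        "n_genes": int(len(fits)),
        "egr3_gamma_tumor": float(fits.loc["Egr3", "gamma_tumor"]),
        "egr3_gamma_tumor_p": float(fits.loc["Egr3", "p_tumor:relapse"]),
        "egr3_gamma_tumor_significant_negative": bool(sig.loc["Egr3"]),
        "egr3_rank_gamma_tumor": int(ranked.index.get_loc("Egr3") + 1),
        "significant_negative_gamma_fraction": background_rate,
    }
    t0 = _stage(report, "deconvolve", t0)

    # --- correlation screen --------------------------------------------
    screen = correlation.SeedCorrelationScreen(
        "Egr3", min_r=config.screen_min_r, max_p=config.screen_max_p
    ).fit(expr)
    candidates = screen.candidates_
    module_recovered = candidates.index.intersection(module.index)
    report["correlation_screen"] = {
        "n_candidates": int(len(candidates)),
        "n_module_genes_recovered": int(len(module_recovered)),
        "module_recall": float(len(module_recovered) / config.n_module_genes),
    }
    t0 = _stage(report, "correlate", t0)

    # --- enrichment simulations ----------------------------------------
    sig_frac = enrichment.significant_fraction_test(seed=config.seed + 40)
    motif_freq = enrichment.motif_frequency_test(seed=config.seed + 41)
    overlap = enrichment.overlap_test(seed=config.seed + 42)
    report["enrichment"] = {
        r.test: {"empirical_p": r.empirical_p, "p_label": r.p_label,
                 "oracle_p": r.oracle_p, "n_as_extreme": r.n_as_extreme}
        for r in (sig_frac, motif_freq, overlap)
    }
    t0 = _stage(report, "enrich", t0)

    # --- motif scan -----------------------------------------------------
    matrix = motif.build_ere_matrix()
    promoters = simulate.generate_promoters(
        n=config.n_module_genes,
        length=config.promoter_length,
        matrix=matrix,
        site_fraction=config.promoter_site_fraction,
        seed=config.seed + 50,
        threshold=config.motif_threshold,
    )
    frac, site_table = motif.fraction_with_site(promoters, matrix, config.motif_threshold)
    report["motif_scan"] = {
        "fraction_with_site": frac,
        "n_promoters": len(promoters),
        "threshold": config.motif_threshold,
    }
    t0 = _stage(report, "scan_motifs", t0)

    # --- IHC quantification --------------------------------------------
    half = config.image_size // 2
    glands = [
        simulate.GlandSpec(center=(half // 2, half // 2), radius=half // 3,
                           intensity=90, lumen=True),
        simulate.GlandSpec(center=(half // 2, half + half // 2), radius=half // 3,
                           intensity=150),
        simulate.GlandSpec(center=(half + half // 2, half // 2), radius=half // 3,
                           intensity=190),
    ]
    image, masks = simulate.generate_ihc_image(
        config.image_size, config.image_size, glands, stroma_intensity=230,
        seed=config.seed + 60,
    )
    region_masks = {
        f"gland_{i}": _region_mask(masks["gland"], g, config.image_size)
        for i, g in enumerate(glands)
    }
    region_masks["stroma_0"] = masks["stroma"]
    scores = ihc.region_scores(image, region_masks)
    gland_scores = scores.loc[[r for r in scores.index if r.startswith("gland")], "weighted_score"]
    stroma_scores = scores.loc[[r for r in scores.index if r.startswith("stroma")], "weighted_score"]
    report["ihc"] = {
        "gland_weighted_score_mean": float(gland_scores.mean()),
        "stroma_weighted_score_mean": float(stroma_scores.mean()),
        "gland_nsr_mean": float(scores.loc[gland_scores.index, "nsr"].mean()),
    }
    t0 = _stage(report, "quantify_ihc", t0)

    if config.outdir:
        _write_outputs(Path(config.outdir), config, report, comps, relapse, expr,
                       fits, ranked, candidates, site_table, image, scores,
                       (sig_frac, motif_freq, overlap), matrix, promoters)
    return report


def _region_mask(gland_mask: np.ndarray, g: simulate.GlandSpec, size: int) -> np.ndarray:
    from skimage.draw import disk

    m = np.zeros((size, size), bool)
    rr, cc = disk(g.center, g.radius, shape=m.shape)
    m[rr, cc] = True
    return m & gland_mask


def _write_outputs(outdir, config, report, comps, relapse, expr, fits, ranked,
                   candidates, site_table, image, scores, enrich_results,
                   matrix, promoters) -> None:
    from Bio import SeqIO
    from PIL import Image

    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.hash()}
    comps.to_csv(outdir / "compositions.tsv", sep="\t")
    relapse.to_frame().to_csv(outdir / "relapse.tsv", sep="\t")
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    fits.to_csv(outdir / "fits.tsv", sep="\t")
    ranked.to_csv(outdir / "fits_ranked_gamma_tumor.tsv", sep="\t")
    candidates.to_csv(outdir / "candidates.tsv", sep="\t")
    site_table.to_csv(outdir / "motif_sites.tsv", sep="\t")
    scores.to_csv(outdir / "ihc_scores.csv")
    Image.fromarray(image).save(outdir / "ihc_image.png")
    Image.fromarray(ihc.pseudocolor(image)).save(outdir / "ihc_pseudocolor.png")
    (outdir / "ere_matrix.json").write_text(matrix.to_json())
    SeqIO.write(promoters, outdir / "promoters.fasta", "fasta")
    for r in enrich_results:
        (outdir / f"enrichment_{r.test}.json").write_text(r.to_json())
    (outdir / "report.json").write_text(json.dumps({**stamp, **report}, indent=2))


# ---------------------------------------------------------------------------
# study-level experiments


def gamma_recovery(
    gene: str = "Egr3",
    n_cohorts: int = 100,
    n_samples: int = presets.DEFAULT_N_SAMPLES,
    noise_sd: float = presets.CALIBRATED_NOISE_SD,
    seed: int = 0,
) -> dict:
    """Parameter-recovery experiment for one EGR preset.

    Generates ``n_cohorts`` independent cohorts with the preset's published
    coefficients as ground truth, fits the interaction regression to each,
    and summarizes the estimated tumor relapse differential: its mean and SD
    across cohorts, and the empirical coverage of the 95% t-intervals pooled
    over all fitted coefficients.
    """
    models = presets.table2_models(noise_sd=noise_sd)
    if gene not in models:
        raise ValueError(f"unknown preset {gene!r}; have {sorted(models)}")
    model = models[gene]
    truth = {deconvolution.INTERCEPT: model.beta0}
    for t in presets.MODELED_TYPES:
        truth[t] = model.beta.get(t, 0.0)
        truth[deconvolution.interaction_name(t)] = model.gamma.get(t, 0.0)

    rng = np.random.default_rng(seed)
    gammas, covered, n_intervals = [], 0, 0
    for _ in range(n_cohorts):
        s = int(rng.integers(0, 2**31 - 1))
        spec = simulate.CohortSpec(
            n_samples=n_samples,
            dirichlet_alpha=presets.DEFAULT_DIRICHLET_ALPHA,
            relapse_fraction=presets.DEFAULT_RELAPSE_FRACTION,
            seed=s,
        )
        comps = simulate.generate_compositions(spec)
        relapse = simulate.generate_relapse_labels(spec)
        expr = simulate.simulate_expression(comps, relapse, [model], seed=s + 1)
        X = comps.copy()
        X["relapse"] = relapse
        est = deconvolution.CellTypeInteractionRegression(presets.MODELED_TYPES)
        est.fit(X, expr.T)
        gammas.append(float(est.coef_.iloc[0][deconvolution.interaction_name("tumor")]))
        tcrit = stats.t.ppf(0.975, est.df_resid_)
        for col, true_val in truth.items():
            b = float(est.coef_.iloc[0][col])
            se = float(est.bse_.iloc[0][col])
            covered += abs(b - true_val) <= tcrit * se
            n_intervals += 1
    gammas = np.asarray(gammas)
    return {
        "gene": gene,
        "n_cohorts": n_cohorts,
        "gamma_tumor_truth": model.gamma.get("tumor", 0.0),
        "gamma_tumor_mean": float(gammas.mean()),
        "gamma_tumor_sd": float(gammas.std(ddof=1)),
        "coverage_95": float(covered / n_intervals),
    }


def null_calibration(
    n_genes: int = 10_000,
    n_samples: int = presets.DEFAULT_N_SAMPLES,
    noise_sd: float = presets.CALIBRATED_NOISE_SD,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of null genes (all gamma = 0) called significant-negative.

    Under the two-sided t-test at level ``alpha`` the expected fraction with
    a significant *negative* tumor differential is ``alpha / 2``.
    """
    spec = simulate.CohortSpec(
        n_samples=n_samples,
        dirichlet_alpha=presets.DEFAULT_DIRICHLET_ALPHA,
        relapse_fraction=presets.DEFAULT_RELAPSE_FRACTION,
        seed=seed,
    )
    comps = simulate.generate_compositions(spec)
    relapse = simulate.generate_relapse_labels(spec)
    models = [
        simulate.GeneModel(gene_id=f"null{k:05d}_at", beta0=presets.DEFAULT_BETA0,
                           noise_sd=noise_sd)
        for k in range(n_genes)
    ]
    expr = simulate.simulate_expression(comps, relapse, models, seed=seed + 1)
    fits = deconvolution.fit_all(expr, comps, relapse, presets.MODELED_TYPES)
    frac = float(deconvolution.significant_negative_gamma(fits, "tumor", alpha).mean())
    return {"n_genes": n_genes, "alpha": alpha,
            "significant_negative_fraction": frac, "expected": alpha / 2}


# ---------------------------------------------------------------------------
# auxiliary statistics


def fold_change(group_a, group_b) -> tuple[float, float]:
    """Ratio of linear-scale means, mean(a)/mean(b), with a Welch t-test on
    the log2 values (two-sided p)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("linear-scale values must be positive")
    fold = a.mean() / b.mean()
    _, p = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False)
    return float(fold), float(p)


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
    sd_target: float = 0.0,
    sd_ref: float = 0.0,
) -> tuple[float, tuple[float, float]]:
    """Relative qPCR quantification by the 2^-ddCT method.

    ddCT = (Ct_target - Ct_ref) treated - (Ct_target - Ct_ref) control;
    fold = 2^-ddCT.  The error interval propagates the target and reference
    SDs in quadrature: 2^-(ddCT +/- sqrt(sd_target^2 + sd_ref^2)).
    """
    if sd_target < 0 or sd_ref < 0:
        raise ValueError("standard deviations must be nonnegative")
    ddct_value = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    fold = 2.0 ** (-ddct_value)
    spread = float(np.hypot(sd_target, sd_ref))
    lo = 2.0 ** (-(ddct_value + spread))
    hi = 2.0 ** (-(ddct_value - spread))
    return float(fold), (float(lo), float(hi))
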