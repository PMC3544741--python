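"""Synthetic cohorts, expression matrices, correlated modules, promoters and
IHC-like images.

Everything here emulates the statistical structure the downstream analyses
assume: Dirichlet cell-type fractions on the simplex, per-gene expression from
the composition-interaction linear model

    y_i = beta0 + sum_j beta_j * P_ij + sum_j gamma_j * P_ij * RS_i + eps_i,

gene modules with a prescribed Pearson correlation to a seed profile,
promoter sequences with planted ERE consensus sites at a controlled
background frequency, and grayscale images with gland/stroma/lumen regions of
controlled staining intensity.  All generators are reproducible bit-for-bit
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk


class ParameterError(ValueError):
    """Invalid generator parameters."""


class AlignmentError(ValueError):
    """Sample identifiers or counts do not line up."""


class DegenerateInputError(ValueError):
    """Input with no usable variance."""


class LayoutError(ValueError):
    """Overlapping or out-of-bounds image regions."""


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level parameters: sample count, cell types with Dirichlet
    concentrations for the pathologist-style composition, and the fraction of
    samples carrying the relapse outcome."""

    n_samples: int
    cell_types: tuple[str, ...] = ("tumor", "stroma", "BPH", "other")
    dirichlet_alpha: tuple[float, ...] = (3.0, 6.0, 2.4, 0.6)
    relapse_fraction: float = 38 / 101
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be positive")
        if len(self.dirichlet_alpha) != len(self.cell_types):
            raise ParameterError("one dirichlet_alpha per cell type required")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ParameterError("dirichlet_alpha entries must be positive")
        if not 0.0 <= self.relapse_fraction <= 1.0:
            raise ParameterError("relapse_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GeneModel:
    """Ground-truth coefficients of one gene under the interaction model.

    ``beta`` holds the non-relapse cell-type coefficients, ``gamma`` the
    relapse-minus-non-relapse differentials; cell types absent from either
    dict contribute zero.
    """

    gene_id: str
    beta0: float
    beta: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class CorrelatedModuleSpec:
    """A block of genes tracking a seed profile at a target Pearson R."""

    n_genes: int
    slope_range: tuple[float, float] = (0.2, 1.2)
    target_R: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_R <= 1.0:
            raise ParameterError("target_R must lie in (0, 1]")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")


def generate_compositions(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-sample cell-type fractions from the Dirichlet of the spec.

    Returns a samples x cell-types DataFrame whose rows are nonnegative and
    sum to one.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = rng.dirichlet(spec.dirichlet_alpha, size=spec.n_samples)
    index = [f"S{i:04d}" for i in range(spec.n_samples)]
    return pd.DataFrame(fractions, index=index, columns=list(spec.cell_types))


def generate_relapse_labels(spec: CohortSpec) -> pd.Series:
    """Binary relapse indicator, one per sample, expectation relapse_fraction.

    Drawn from an independent stream (seed + 1) so composition draws do not
    shift when the outcome fraction changes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    labels = (rng.random(spec.n_samples) < spec.relapse_fraction).astype(int)
    index = [f"S{i:04d}" for i in range(spec.n_samples)]
    return pd.Series(labels, index=index, name="relapse")


def simulate_expression(
    compositions: pd.DataFrame,
    relapse: pd.Series,
    models: list[GeneModel],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a probes x samples log2 expression matrix under the
    composition-interaction model.

    With ``noise_sd = 0`` the output equals the linear predictor exactly.
    """
    if len(compositions) != len(relapse):
        raise AlignmentError(
            f"{len(compositions)} composition rows vs {len(relapse)} relapse labels"
        )
    if not compositions.index.equals(relapse.index):
        relapse = relapse.reindex(compositions.index)
        if relapse.isna().any():
            raise AlignmentError("relapse labels missing for some samples")

    rng = np.random.default_rng(seed)
    P = compositions.to_numpy(float)
    rs = relapse.to_numpy(float)
    types = list(compositions.columns)

    rows = np.empty((len(models), len(compositions)))
    for k, m in enumerate(models):
        unknown = (set(m.beta) | set(m.gamma)) - set(types)
        if unknown:
            raise AlignmentError(f"gene {m.gene_id}: unknown cell types {sorted(unknown)}")
        b = np.array([m.beta.get(t, 0.0) for t in types])
        g = np.array([m.gamma.get(t, 0.0) for t in types])
        mu = m.beta0 + P @ b + (P @ g) * rs
        if m.noise_sd > 0:
            mu = mu + rng.normal(0.0, m.noise_sd, size=mu.shape)
        rows[k] = mu
    return pd.DataFrame(rows, index=[m.gene_id for m in models], columns=compositions.index)


def simulate_correlated_module(
    seed_profile: pd.Series, spec: CorrelatedModuleSpec
) -> pd.DataFrame:
    """Genes that track ``seed_profile`` linearly with expected Pearson R
    equal to ``spec.target_R``.

    Each gene is ``slope * seed + noise`` with noise SD
    ``|slope| * sd(seed) * sqrt(1/R^2 - 1)``, which makes the population
    correlation exactly the target.
    """
    x = np.asarray(seed_profile, float)
    if x.size < 3:
        raise DegenerateInputError("seed profile needs at least 3 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("seed profile has zero variance")

    rng = np.random.default_rng(spec.seed)
    slopes = rng.uniform(*spec.slope_range, size=spec.n_genes)
    noise_scale = np.abs(slopes) * sd * np.sqrt(1.0 / spec.target_R**2 - 1.0)
    noise = rng.standard_normal((spec.n_genes, x.size)) * noise_scale[:, None]
    values = slopes[:, None] * x[None, :] + noise
    index = [f"mod{g:04d}_at" for g in range(spec.n_genes)]
    out = pd.DataFrame(values, index=index, columns=seed_profile.index)
    out.attrs["slopes"] = pd.Series(slopes, index=index)
    return out


# ---------------------------------------------------------------------------
# promoters


def generate_promoters(
    n: int,
    length: int,
    matrix,
    site_fraction: float,
    seed: int = 0,
    threshold: float = 0.80,
    max_tries: int = 2000,
) -> list:
    """Random promoter sequences with planted consensus ERE sites.

    Each record independently carries a site with probability
    ``site_fraction`` (a random consensus realization overwritten at a random
    offset).  Records designated negative are rejection-sampled against the
    scanner itself until no window on either strand scores at or above
    ``threshold``, so the planted background frequency is exact by
    construction.  Returns Biopython ``SeqRecord`` objects with ids usable as
    gene ids.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .motif import scan_sequence

    if length < matrix.width:
        raise ParameterError("promoter length shorter than motif width")
    if not 0.0 <= site_fraction <= 1.0:
        raise ParameterError("site_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    has_site = rng.random(n) < site_fraction
    records = []
    for i in range(n):
        if has_site[i]:
            seq = rng.choice(bases, size=length)
            site = matrix.sample_consensus(rng)
            off = int(rng.integers(0, length - matrix.width + 1))
            seq[off : off + matrix.width] = list(site)
            s = "".join(seq)
        else:
            for _ in range(max_tries):
                s = "".join(rng.choice(bases, size=length))
                if not scan_sequence(s, matrix, threshold=threshold):
                    break
            else:  # pragma: no cover - astronomically unlikely at sane lengths
                raise ParameterError("could not rejection-sample a negative promoter")
        records.append(SeqRecord(Seq(s), id=f"gene{i:04d}", description=""))
    return records


# ---------------------------------------------------------------------------
# IHC images


@dataclass(frozen=True)
class GlandSpec:
    """A circular gland region: center (row, col), radius in pixels, staining
    intensity of its epithelium, and optionally an unstained central lumen."""

    center: tuple[int, int]
    radius: int
    intensity: int
    lumen: bool = False
    lumen_radius: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.intensity <= 255:
            raise ParameterError("intensity must lie in [0, 255]")


def generate_ihc_image(
    width: int,
    height: int,
    glands: list[GlandSpec],
    stroma_intensity: int = 230,
    lumen_intensity: int = 250,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Synthetic 8-bit IHC-like image plus labeled region masks.

    Pixel intensities are drawn tightly around the specified values (Gaussian
    jitter clipped to +/- 8 so band classification at the standard thresholds
    is never perturbed).  Lumen pixels sit above the weak threshold, i.e.
    unstained.  Returns ``(image, {"gland": ..., "stroma": ..., "lumen": ...})``
    boolean masks; the stroma mask is everything outside the glands.
    """
    if not 0 <= stroma_intensity <= 255:
        raise ParameterError("stroma_intensity must lie in [0, 255]")
    rng = np.random.default_rng(seed)

    def _jitter(value: float, n: int) -> np.ndarray:
        raw = rng.normal(value, noise_sd, size=n)
        return np.clip(raw, max(0.0, value - 8), min(255.0, value + 8))

    shape = (height, width)
    img = np.empty(shape, float)
    img[...] = _jitter(stroma_intensity, height * width).reshape(shape)

    gland_mask = np.zeros(shape, bool)
    lumen_mask = np.zeros(shape, bool)
    for g in glands:
        rr, cc = disk(g.center, g.radius, shape=shape)
        if gland_mask[rr, cc].any():
            raise LayoutError(f"gland at {g.center} overlaps a previous gland")
        gland_mask[rr, cc] = True
        img[rr, cc] = _jitter(g.intensity, rr.size)
        if g.lumen:
            lr = g.lumen_radius if g.lumen_radius is not None else max(1, g.radius // 3)
            lrr, lcc = disk(g.center, lr, shape=shape)
            lumen_mask[lrr, lcc] = True
            img[lrr, lcc] = _jitter(lumen_intensity, lrr.size)

    masks = {
        "gland": gland_mask,
        "stroma": ~gland_mask,
        "lumen": lumen_mask,
    }
    return img.round().astype(np.uint8), masks
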