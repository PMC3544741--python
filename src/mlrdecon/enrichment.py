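"""Monte-Carlo enrichment tests with closed-form oracles.

Three 10,000-draw resampling tests ask whether an observed candidate-list
property could arise by chance:

* motif frequency — could 81 random genes from a pool in which 62.7% carry a
  V$EGRF site show sites at >= 99% frequency?
* list overlap — could random 80- and 121-gene sets from a 9148-gene universe
  share >= 43 unique genes?
* significant-gamma fraction — could a 98-probe list drawn from a background
  with a 6.1% rate of significant negative tumor differentials contain >= 14
  significant probes?

The empirical p-value follows the resampling convention
``count as-extreme / n_sims`` with ties counting as extreme; a zero count is
reported as the bound ``< 1/n_sims``.  Each test also carries the exact tail
probability (binomial or hypergeometric) as an independent oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one resampling test plus its closed-form oracle."""

    test: str
    observed_statistic: float
    n_sims: int
    n_as_extreme: int
    empirical_p: float
    oracle_p: float
    seed: int
    params: dict

    @property
    def empirical_p_bound(self) -> float:
        """count/n_sims, floored at 1/n_sims when no draw was as extreme."""
        return max(self.empirical_p, 1.0 / self.n_sims)

    @property
    def p_label(self) -> str:
        if self.n_as_extreme == 0:
            return f"<{1.0 / self.n_sims:g}"
        return f"{self.empirical_p:g}"

    def to_json(self) -> str:
        d = asdict(self)
        d["p_label"] = self.p_label
        return json.dumps(d, indent=2)


def _finish(test, observed, n_sims, count, oracle_p, seed, params, plus_one):
    if plus_one:
        empirical = (count + 1) / (n_sims + 1)
    else:
        empirical = count / n_sims
    return EnrichmentResult(
        test=test,
        observed_statistic=observed,
        n_sims=n_sims,
        n_as_extreme=int(count),
        empirical_p=float(empirical),
        oracle_p=float(oracle_p),
        seed=seed,
        params=params,
    )


def motif_frequency_test(
    n_genes: int = 81,
    background_freq: float = 0.627,
    observed_fraction: float = 0.99,
    n_sims: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> EnrichmentResult:
    """Can a random gene set reach the observed motif-positive fraction?

    Each simulation draws ``n_genes`` independent Bernoulli(background_freq)
    site indicators; a draw is as extreme when its positive fraction is
    >= ``observed_fraction``.  Oracle: upper binomial tail at
    ``ceil(observed_fraction * n_genes)`` successes.
    """
    if not 0.0 < background_freq < 1.0:
        raise ValueError("background_freq must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    k_needed = math.ceil(observed_fraction * n_genes)
    draws = rng.binomial(n_genes, background_freq, size=n_sims)
    count = int((draws >= k_needed).sum())
    oracle = stats.binom.sf(k_needed - 1, n_genes, background_freq)
    return _finish(
        "motif_frequency", observed_fraction, n_sims, count, oracle, seed,
        {"n_genes": n_genes, "background_freq": background_freq,
         "k_needed": k_needed},
        plus_one,
    )


def overlap_test(
    universe: int = 9148,
    size_a: int = 80,
    size_b: int = 121,
    observed_overlap: int = 43,
    n_sims: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> EnrichmentResult:
    """Can two random gene sets overlap as much as the observed lists?

    Each simulation draws two sets without replacement from the universe and
    records their intersection size (distributionally the hypergeometric with
    ``size_b`` successes and ``size_a`` draws).  Oracle: upper hypergeometric
    tail at the observed overlap.
    """
    if size_a > universe or size_b > universe:
        raise ValueError("set sizes cannot exceed the universe")
    if observed_overlap > min(size_a, size_b):
        raise ValueError("observed overlap larger than the smaller set")
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(size_b, universe - size_b, size_a, size=n_sims)
    count = int((draws >= observed_overlap).sum())
    oracle = stats.hypergeom.sf(observed_overlap - 1, universe, size_b, size_a)
    return _finish(
        "overlap", observed_overlap, n_sims, count, oracle, seed,
        {"universe": universe, "size_a": size_a, "size_b": size_b},
        plus_one,
    )


def significant_fraction_test(
    list_size: int = 98,
    background_rate: float = 0.061,
    observed_count: int = 14,
    n_sims: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
    background_indicators: np.ndarray | None = None,
) -> EnrichmentResult:
    """Can a random list contain as many significant genes as observed?

    Each simulation draws ``list_size`` Bernoulli(background_rate)
    significance indicators and a draw is as extreme when it holds
    >= ``observed_count`` successes.  Oracle: upper binomial tail.

    When ``background_indicators`` (a 0/1 array over the real background,
    e.g. the per-probe significant-negative-gamma mask of a genome-wide fit)
    is supplied, sampling is finite-population without replacement from those
    indicators instead of the Bernoulli approximation, and the oracle is the
    corresponding hypergeometric tail.
    """
    rng = np.random.default_rng(seed)
    if background_indicators is not None:
        pool = np.asarray(background_indicators).astype(bool)
        n_succ = int(pool.sum())
        draws = rng.hypergeometric(n_succ, pool.size - n_succ, list_size, size=n_sims)
        oracle = stats.hypergeom.sf(observed_count - 1, pool.size, n_succ, list_size)
        params = {"list_size": list_size, "population": pool.size,
                  "population_successes": n_succ}
    else:
        if not 0.0 < background_rate < 1.0:
            raise ValueError("background_rate must lie in (0, 1)")
        draws = rng.binomial(list_size, background_rate, size=n_sims)
        oracle = stats.binom.sf(observed_count - 1, list_size, background_rate)
        params = {"list_size": list_size, "background_rate": background_rate}
    count = int((draws >= observed_count).sum())
    return _finish(
        "significant_fraction", observed_count, n_sims, count, oracle, seed,
        params, plus_one,
    )
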