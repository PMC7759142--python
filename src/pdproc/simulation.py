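"""Generators for the two simulation studies.

Study 1 draws completely random, independent Bernoulli responses — no
participant-level signal at all — to show which correlations among PDP
scores arise from the scoring arithmetic alone.  A variant holds every
participant's congruent-item mean constant, which flips the U-D correlation
strongly negative.

Study 2 generates highly *consistent* responding: two independent blocks of
equicorrelated standard gaussians (one per dilemma set) are dichotomized at
item-specific cutoffs, with each incongruent cutoff forced below its
congruent partner so that congruent harms are always the more unacceptable
in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ResponseMatrix

__all__ = [
    "SimulationConfig",
    "simulate_random",
    "simulate_random_constant_c",
    "simulate_correlated",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for both simulation studies.

    Defaults reproduce the study conditions: 10,000 responders, ten dilemma
    pairs, fair-coin responding for the random design, latent inter-item
    correlation 0.50 with congruent cutoffs uniform on [-1, 2] and each
    incongruent cutoff uniform on [-2, paired congruent cutoff] for the
    correlated design.
    """

    n_participants: int = 10_000
    k_pairs: int = 10
    p_unacc: float = 0.5
    latent_r: float = 0.50
    c_cut_range: tuple[float, float] = (-1.0, 2.0)
    ic_cut_lower: float = -2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.k_pairs < 2:
            raise ValueError("k_pairs must be >= 2")
        if not 0.0 <= self.p_unacc <= 1.0:
            raise ValueError("p_unacc must be in [0, 1]")
        if not 0.0 <= self.latent_r < 1.0:
            raise ValueError("latent_r must be in [0, 1)")
        lo, hi = self.c_cut_range
        if not lo < hi:
            raise ValueError("c_cut_range must satisfy min < max")
        if not self.ic_cut_lower < lo:
            raise ValueError("ic_cut_lower must lie below the C cutoff range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _pair_labels(k: int) -> tuple[str, ...]:
    return tuple(f"d{i + 1}" for i in range(k))


def simulate_random(config: SimulationConfig) -> ResponseMatrix:
    """Independent Bernoulli(p_unacc) responses for all 2k items."""
    rng = config.rng()
    n, k = config.n_participants, config.k_pairs
    resp = (rng.random((n, 2 * k)) < config.p_unacc).astype(np.int8)
    return ResponseMatrix(
        c_items=resp[:, :k],
        ic_items=resp[:, k:],
        pair_labels=_pair_labels(k),
    )


def simulate_random_constant_c(
    config: SimulationConfig, c_constant: float
) -> ResponseMatrix:
    """Random IC responses with a constant congruent-item mean per responder.

    ``c_constant`` must be attainable as a k-item mean, i.e. a multiple of
    1/k.  Every responder gets exactly ``c_constant * k`` unacceptable C
    responses (positions shuffled independently per responder); IC items are
    Bernoulli(p_unacc) as in the fully random design.
    """
    n, k = config.n_participants, config.k_pairs
    n_ones = c_constant * k
    if not np.isclose(n_ones, round(n_ones)) or not 0 <= c_constant <= 1:
        raise ValueError(
            f"c_constant={c_constant} is not attainable as a mean of {k} binary items"
        )
    n_ones = int(round(n_ones))
    rng = config.rng()
    c = np.zeros((n, k), dtype=np.int8)
    c[:, :n_ones] = 1
    # independent position shuffle per row; row means stay exactly c_constant
    c = rng.permuted(c, axis=1)
    ic = (rng.random((n, k)) < config.p_unacc).astype(np.int8)
    return ResponseMatrix(c_items=c, ic_items=ic, pair_labels=_pair_labels(k))


def _equicorrelated_block(
    rng: np.random.Generator, n: int, k: int, r: float
) -> np.ndarray:
    # one shared factor + independent noise gives exact equicorrelation r
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, k))
    return np.sqrt(r) * shared + np.sqrt(1.0 - r) * noise


def simulate_correlated(
    config: SimulationConfig,
) -> tuple[ResponseMatrix, pd.DataFrame]:
    """Dichotomized equicorrelated-gaussian responses with ordered cutoffs.

    Two independent n x k blocks of standard gaussians with equicorrelation
    ``latent_r`` represent the C and IC dilemma sets.  One cutoff is drawn
    per item: C cutoffs i.i.d. uniform on ``c_cut_range``; the IC cutoff of
    pair j uniform on [``ic_cut_lower``, C cutoff j], so it always lies
    below its partner.  A response is unacceptable (1) when the latent falls
    below the item's cutoff, hence C items are always the more unacceptable
    in expectation.

    Returns the response matrix and a per-pair DataFrame of realized
    cutoffs.
    """
    rng = config.rng()
    n, k, r = config.n_participants, config.k_pairs, config.latent_r
    latent_c = _equicorrelated_block(rng, n, k, r)
    latent_ic = _equicorrelated_block(rng, n, k, r)
    c_cuts = rng.uniform(*config.c_cut_range, size=k)
    ic_cuts = rng.uniform(config.ic_cut_lower, c_cuts)
    matrix = ResponseMatrix(
        c_items=(latent_c < c_cuts).astype(np.int8),
        ic_items=(latent_ic < ic_cuts).astype(np.int8),
        pair_labels=_pair_labels(k),
    )
    cutoffs = pd.DataFrame(
        {"c_cutoff": c_cuts, "ic_cutoff": ic_cuts},
        index=pd.Index(matrix.pair_labels, name="pair"),
    )
    return matrix, cutoffs
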