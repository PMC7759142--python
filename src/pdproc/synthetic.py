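"""Empirical-like synthetic data.

These generators stand in for a real dilemma-battery sample: responses are
drawn per dilemma pair from a four-category joint distribution over the
(C, IC) response patterns, so marginal acceptance rates and pattern
proportions mirror those of a real study while the joint structure *across*
pairs is independent by default (real inter-dilemma correlations are
near zero, median absolute ~0.06, and published tables give no cross-pair
joint distribution to emulate).  An optional linked Likert battery emulates
a high-conflict moral dilemma (HCMD) scale whose latent trait correlates
with the responder's IC-unacceptance tendency.

``DEFAULT_PATTERNS`` carries representative proportions for the nine classic
dilemma pairs (abortion AB, animal research AR, border crossing BC, car
accident CA, hard times HT, relationship REL, time machine TM, torture TOR,
vaccine policy VP) observed in a large online sample (N = 1,010), and is the
package's default generating distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LikertMatrix, ResponseMatrix
from .scoring import PATTERN_ROWS

__all__ = [
    "PatternSpec",
    "pattern_table_summary",
    "DEFAULT_PATTERNS",
    "default_pattern_spec",
    "generate_empirical_mimic",
    "generate_hcmd",
]

# rows: both_unacc, both_acc, ic_acc_c_unacc, ic_unacc_c_acc
DEFAULT_PATTERNS = pd.DataFrame(
    {
        "AB": [0.048, 0.736, 0.200, 0.017],
        "AR": [0.260, 0.280, 0.444, 0.015],
        "BC": [0.569, 0.099, 0.321, 0.010],
        "CA": [0.233, 0.085, 0.668, 0.013],
        "HT": [0.928, 0.013, 0.048, 0.013],
        "REL": [0.814, 0.017, 0.161, 0.008],
        "TM": [0.363, 0.220, 0.380, 0.037],
        "TOR": [0.436, 0.268, 0.286, 0.010],
        "VP": [0.097, 0.305, 0.585, 0.013],
    },
    index=list(PATTERN_ROWS[:4]),
)


@dataclass(frozen=True)
class PatternSpec:
    """Generating distribution for an empirical-like sample.

    ``patterns`` holds one column per dilemma pair with the four joint
    pattern probabilities (rows ``both_unacc``, ``both_acc``,
    ``ic_acc_c_unacc``, ``ic_unacc_c_acc``).  Columns whose probabilities
    sum more than 0.01 away from 1 are rejected; smaller discrepancies
    (printed-rounding noise) are renormalized exactly.

    ``hcmd_link`` is the correlation between the shared latent driving the
    HCMD battery and the responder's (standardized) IC-unacceptance
    tendency; negative values give the empirically observed polarity (more
    deontological PDP responding, lower HCMD acceptability ratings).
    """

    patterns: pd.DataFrame = field(default_factory=lambda: DEFAULT_PATTERNS.copy())
    n_participants: int = 1010
    seed: int = 0
    hcmd_link: float = 0.0
    n_hcmd_items: int = 12
    hcmd_item_loading: float = 0.7

    def __post_init__(self):
        pats = self.patterns.copy()
        if list(pats.index) != list(PATTERN_ROWS[:4]):
            raise ValueError(f"pattern rows must be {PATTERN_ROWS[:4]}")
        if (pats.to_numpy() < 0).any():
            raise ValueError("pattern probabilities must be non-negative")
        sums = pats.sum(axis=0)
        off = (sums - 1.0).abs()
        if (off > 0.01).any():
            bad = off.idxmax()
            raise ValueError(
                f"pattern probabilities for pair {bad!r} sum to {sums[bad]:.3f}, "
                "more than 0.01 away from 1"
            )
        pats = pats / sums  # renormalize exactly
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not -1.0 <= self.hcmd_link <= 1.0:
            raise ValueError("hcmd_link must be in [-1, 1]")
        if not 0.0 <= self.hcmd_item_loading <= 1.0:
            raise ValueError("hcmd_item_loading must be in [0, 1]")
        if self.n_hcmd_items < 1:
            raise ValueError("n_hcmd_items must be >= 1")
        object.__setattr__(self, "patterns", pats)


def default_pattern_spec(**overrides) -> PatternSpec:
    """The nine-dilemma default sample specification (N = 1,010)."""
    return PatternSpec(**overrides)


def generate_empirical_mimic(spec: PatternSpec) -> ResponseMatrix:
    """Draw each participant x pair outcome from the pair's four-category
    distribution; pairs are independent of one another.

    Each pair draws from a substream keyed by (seed, pair label), so
    permuting the spec's columns permutes the output columns identically.
    """
    n = spec.n_participants
    pairs = list(spec.patterns.columns)
    k = len(pairs)
    # category codes 0..3 follow PATTERN_ROWS order
    c_of_cat = np.array([1, 0, 1, 0], dtype=np.int8)
    ic_of_cat = np.array([1, 0, 0, 1], dtype=np.int8)
    c = np.empty((n, k), dtype=np.int8)
    ic = np.empty((n, k), dtype=np.int8)
    for j, pair in enumerate(pairs):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, zlib.crc32(str(pair).encode())])
        )
        probs = spec.patterns[pair].to_numpy()
        cats = rng.choice(4, size=n, p=probs)
        c[:, j] = c_of_cat[cats]
        ic[:, j] = ic_of_cat[cats]
    return ResponseMatrix(c_items=c, ic_items=ic, pair_labels=tuple(pairs))


def pattern_table_summary(patterns: pd.DataFrame) -> dict:
    """Arithmetic summary of a pattern-proportion table (no sampling).

    Returns the per-pair difference statistic (sensible-direction switches
    minus perverse switches) and the unweighted mean acceptance rates per
    dilemma set implied by the table: IC acceptance = both_acc +
    ic_acc_c_unacc, C acceptance = both_acc + ic_unacc_c_acc.
    """
    if list(patterns.index) != list(PATTERN_ROWS[:4]):
        raise ValueError(f"pattern rows must be {PATTERN_ROWS[:4]}")
    difference = patterns.loc["ic_acc_c_unacc"] - patterns.loc["ic_unacc_c_acc"]
    acc_ic = patterns.loc["both_acc"] + patterns.loc["ic_acc_c_unacc"]
    acc_c = patterns.loc["both_acc"] + patterns.loc["ic_unacc_c_acc"]
    return {
        "difference": difference,
        "pct_acc_ic": 100 * float(acc_ic.mean()),
        "pct_acc_c": 100 * float(acc_c.mean()),
    }


def generate_hcmd(spec: PatternSpec, responses: ResponseMatrix) -> LikertMatrix:
    """Likert (1..7) HCMD battery linked to the PDP responses.

    Each participant gets a latent trait correlated ``hcmd_link`` with their
    standardized IC-unacceptance tendency (the PDP traditional score); item
    latents mix the trait with independent noise at ``hcmd_item_loading``
    and are discretized into seven equal-probability bins (thresholds at
    standard-normal septile quantiles), giving a symmetric Likert marginal.
    With ``hcmd_link = 0`` the two batteries are independent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x4C6B]))
    n = responses.n_participants
    ts = responses.ic_items.mean(axis=1)
    sd = ts.std()
    z_ts = (ts - ts.mean()) / sd if sd > 0 else np.zeros(n)
    link = spec.hcmd_link
    trait = link * z_ts + np.sqrt(max(0.0, 1.0 - link**2)) * rng.standard_normal(n)
    lam = spec.hcmd_item_loading
    item_latent = lam * trait[:, None] + np.sqrt(1.0 - lam**2) * rng.standard_normal(
        (n, spec.n_hcmd_items)
    )
    from scipy.stats import norm

    thresholds = norm.ppf(np.arange(1, 7) / 7.0)
    values = 1 + np.searchsorted(thresholds, item_latent).reshape(
        n, spec.n_hcmd_items
    )
    return LikertMatrix(
        values=values,
        participant_ids=responses.participant_ids,
    )
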