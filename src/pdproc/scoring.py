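"""PDP scoring and response-pattern classification.

The process-dissociation procedure decomposes dilemma responses into a
utilitarian parameter ``U`` and a deontological parameter ``D``::

    U  = P(unacceptable | congruent) - P(unacceptable | incongruent)
    D  = P(unacceptable | incongruent) / (1 - U)
    TS = P(unacceptable | incongruent)        (traditional bipolar score)

where the conditional probabilities are within-participant means over the
respective item sets.  ``D`` is undefined exactly when ``U = 1`` (every C
item unacceptable, every IC item acceptable) and is reported as missing.

``U`` admits an equivalent sum-score formulation — the C items together with
reverse-coded IC items, up to an affine constant — which makes standard
internal-consistency machinery (alpha, omega, factor analysis) applicable to
it; ``build_alt_u_items`` constructs that item matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import LikertMatrix, ResponseMatrix

__all__ = [
    "score_pdp",
    "build_alt_u_items",
    "classify_patterns",
    "filter_realistic",
    "score_hcmd",
    "PATTERN_ROWS",
]

#: row order of the pattern-proportion table
PATTERN_ROWS = (
    "both_unacc",
    "both_acc",
    "ic_acc_c_unacc",
    "ic_unacc_c_acc",
    "difference",
)


def score_pdp(responses: ResponseMatrix) -> pd.DataFrame:
    """Per-participant PDP scores.

    Returns a DataFrame indexed by participant id with columns
    ``p_unacc_c``, ``p_unacc_ic``, ``U``, ``D``, ``TS``; ``D`` is NaN for
    participants with ``U = 1``.
    """
    p_c = responses.c_items.mean(axis=1)
    p_ic = responses.ic_items.mean(axis=1)
    u = p_c - p_ic
    ts = p_ic
    # (1 - p_c) + p_ic equals 1 - U algebraically but stays exact when
    # p_c = 1, where naive 1 - U would leave roundoff in the ratio
    denom = (1.0 - p_c) + p_ic
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(u < 1.0, ts / denom, np.nan)
    # numerator <= denominator algebraically; clip float roundoff at the edge
    d = np.clip(d, 0.0, 1.0)
    return pd.DataFrame(
        {"p_unacc_c": p_c, "p_unacc_ic": p_ic, "U": u, "D": d, "TS": ts},
        index=pd.Index(responses.participant_ids, name="id"),
    )


def build_alt_u_items(responses: ResponseMatrix) -> pd.DataFrame:
    """Item matrix of the sum-score formulation of ``U``.

    Columns 1..k are the C items unchanged; columns k+1..2k are the
    reverse-coded IC items (1 - response).  For every participant,
    ``2 * mean(row) - 1`` equals their ``U`` exactly, so the matrix can be
    fed to any internal-consistency estimator in place of ``U`` itself.
    """
    cols = [f"C_{p}" for p in responses.pair_labels] + [
        f"ICrev_{p}" for p in responses.pair_labels
    ]
    items = np.hstack([responses.c_items, 1 - responses.ic_items])
    return pd.DataFrame(
        items,
        index=pd.Index(responses.participant_ids, name="id"),
        columns=cols,
    )


def classify_patterns(responses: ResponseMatrix) -> pd.DataFrame:
    """Per-pair proportions of the four C/IC joint response patterns.

    Rows: both unacceptable (C=1, IC=1); both acceptable (C=0, IC=0);
    IC acceptable & C unacceptable (C=1, IC=0); IC unacceptable & C
    acceptable (C=0, IC=1); and the difference of the last two, which
    summarizes how often the congruency manipulation moved a participant in
    the theoretically sensible direction net of the opposite (perverse)
    move.  Columns are the pair labels; proportions are over participants
    and partition to 1 per pair.
    """
    c = responses.c_items
    ic = responses.ic_items
    table = pd.DataFrame(
        [
            ((c == 1) & (ic == 1)).mean(axis=0),
            ((c == 0) & (ic == 0)).mean(axis=0),
            ((c == 1) & (ic == 0)).mean(axis=0),
            ((c == 0) & (ic == 1)).mean(axis=0),
        ],
        index=list(PATTERN_ROWS[:4]),
        columns=list(responses.pair_labels),
    )
    table.loc["difference"] = (
        table.loc["ic_acc_c_unacc"] - table.loc["ic_unacc_c_acc"]
    )
    return table


def filter_realistic(
    scores: pd.DataFrame, strict: bool = False
) -> tuple[pd.DataFrame, float]:
    """Restrict to "realistic" responders and report the retained fraction.

    A realistic responder accepts harm in IC dilemmas at least as readily as
    in C dilemmas (``U >= 0``); with ``strict=True`` only responders with
    ``U > 0`` are kept.  The inclusive default matches how the subset
    statistics behave in large samples; participants at exactly ``U = 0``
    are a sizeable mass for short binary batteries, and excluding them
    visibly shifts the subset correlations.
    """
    mask = scores["U"] > 0 if strict else scores["U"] >= 0
    subset = scores.loc[mask]
    return subset, float(mask.mean())


def score_hcmd(likert: LikertMatrix) -> pd.Series:
    """Bipolar score of the high-conflict moral dilemma battery.

    The row mean of the 1..7 acceptability ratings; higher = more
    utilitarian.  Note the polarity is opposite to the PDP traditional
    score, for which higher values mean more deontological responding.
    """
    return pd.Series(
        likert.values.mean(axis=1),
        index=pd.Index(likert.participant_ids, name="id"),
        name="HCMD",
    )
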