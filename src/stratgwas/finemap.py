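"""Single-causal Bayes-factor fine-mapping and credible sets.

Under the assumption of exactly one causal variant per locus, each variant's
evidence is summarized by a Wakefield-style approximate Bayes factor
computed from its association z-score and standard error,

    ln BF = 0.5 * ln( se^2 / (se^2 + W) ) + 0.5 * z^2 * W / (se^2 + W),

where ``W`` is the prior variance of the causal log-odds effect (prior sd
0.2 by default). With a flat prior over which variant is causal, the
posterior probability of variant i is ``BF_i / sum_j BF_j``; the 99%
credible set is the smallest set of variants, taken in descending posterior
order, whose cumulative posterior reaches 0.99.

The single-signal assumption is load-bearing: regions flagged as carrying
multiple independent signals by the conditional analysis must not be passed
here, and ``credible_set`` refuses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CredibleSet", "log_bayes_factor", "credible_set"]

DEFAULT_PRIOR_SD = 0.2


@dataclass
class CredibleSet:
    """Posterior summary of a single-causal locus.

    ``table`` holds one row per variant sorted by descending posterior with
    columns ``variant_id, pos, z, log_bf, posterior, cumulative,
    in_credible_set``; ``members`` lists the credible variants in that
    order; ``width`` is the base-pair span of the credible members.
    """

    locus: str
    table: pd.DataFrame
    level: float
    prior_sd: float
    members: list[str] = field(init=False)
    width: int = field(init=False)

    def __post_init__(self) -> None:
        inset = self.table[self.table["in_credible_set"]]
        self.members = inset["variant_id"].tolist()
        pos = inset["pos"].to_numpy()
        self.width = int(pos.max() - pos.min()) if len(pos) else 0


def log_bayes_factor(z, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Approximate log Bayes factor for association from (z, se).

    ``prior_sd`` is the prior standard deviation of the causal effect on the
    log-odds scale; ``W = prior_sd**2``. As ``W -> 0`` the log BF tends to 0
    for any z (the prior collapses onto the null); at z = 0 it is negative
    (evidence against association).
    """
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    w = float(prior_sd) ** 2
    v = se**2
    lbf = 0.5 * np.log(v / (v + w)) + 0.5 * z**2 * w / (v + w)
    if lbf.ndim == 0:
        return float(lbf)
    return lbf


def credible_set(
    locus_stats: pd.DataFrame,
    level: float = 0.99,
    prior_sd: float = DEFAULT_PRIOR_SD,
    locus: str | None = None,
    multi_signal: bool = False,
) -> CredibleSet:
    """Build the credible set for one locus from per-variant (z, se).

    Parameters
    ----------
    locus_stats : frame with columns ``variant_id, pos, z, se``.
    level : cumulative posterior mass the set must reach (default 0.99).
    multi_signal : set by the caller when conditional analysis found more
        than one independent signal; such regions violate the single-causal
        assumption and are refused.
    """
    if multi_signal:
        raise ValueError(
            "region carries multiple independent signals; the single-causal "
            "Bayes-factor model cannot be applied — fine-map each "
            "conditioned signal separately"
        )
    if locus_stats.empty:
        raise ValueError("locus has no variants")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    df = locus_stats[["variant_id", "pos", "z"]].copy()
    lbf = log_bayes_factor(
        locus_stats["z"].to_numpy(), locus_stats["se"].to_numpy(), prior_sd
    )
    lbf = np.atleast_1d(lbf)
    df["log_bf"] = lbf
    # softmax over log BFs, stabilized
    m = lbf.max()
    post = np.exp(lbf - m)
    post /= post.sum()
    df["posterior"] = post
    df = df.sort_values(
        ["posterior", "variant_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["cumulative"] = df["posterior"].cumsum()
    # smallest prefix whose mass reaches the level
    n_in = int(np.searchsorted(df["cumulative"].to_numpy(), level - 1e-12) + 1)
    n_in = min(n_in, len(df))
    df["in_credible_set"] = np.arange(len(df)) < n_in
    name = locus if locus is not None else str(df.loc[0, "variant_id"])
    return CredibleSet(locus=name, table=df, level=level, prior_sd=prior_sd)
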