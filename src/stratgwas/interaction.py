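"""Cross-stratum difference and 2df joint tests on stratified effects.

Given per-stratum log-odds-ratio estimates (beta_A, se_A) and (beta_B, se_B)
for the same variant, two complementary questions are asked:

* Do the effects differ between strata?  A Z-test on the contrast,

      Z_diff = (beta_A - beta_B) / sqrt(se_A^2 + se_B^2 - 2 r se_A se_B),

  where ``r`` is a single genome-wide correlation between the two strata's
  effect estimates (Spearman rank correlation across variants; near zero for
  disjoint strata, but estimated from the data rather than assumed).

* Is there any effect in either stratum, allowing them to differ?  The
  2-degree-of-freedom joint chi-square,

      C_joint = (beta_A/se_A)^2 + (beta_B/se_B)^2,  P = exp(-C/2),

  which beats the usual 1df main-effect test when the effect is
  concentrated in, or differs between, strata.

Both tests consume the genomic-control-corrected (beta, se) pairs and are
agnostic to whether the strata are age groups or sexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "DiffResult",
    "JointResult",
    "estimate_cross_stratum_correlation",
    "diff_test",
    "joint_2df",
    "screen_genomewide",
    "candidate_lookup",
]

GENOME_WIDE_ALPHA = 5e-8


@dataclass(frozen=True)
class DiffResult:
    """Difference Z-test result for one variant."""

    variant_id: str
    z_diff: float
    p_diff: float
    r_used: float


@dataclass(frozen=True)
class JointResult:
    """2df joint chi-square result for one variant."""

    variant_id: str
    c_joint: float
    p_joint: float


def estimate_cross_stratum_correlation(
    scan_a: pd.DataFrame, scan_b: pd.DataFrame, min_overlap: int = 100
) -> float:
    """Spearman rank correlation of effect sizes across the two strata.

    Computed over the variants present in both scans; used as the shared
    ``r`` in the difference-test denominator.
    """
    merged = scan_a[["variant_id", "beta"]].merge(
        scan_b[["variant_id", "beta"]], on="variant_id", suffixes=("_a", "_b")
    )
    if len(merged) < min_overlap:
        raise ValueError(
            f"only {len(merged)} variants overlap between strata "
            f"(need >= {min_overlap}) to estimate the effect correlation"
        )
    rho = stats.spearmanr(merged["beta_a"], merged["beta_b"]).statistic
    return float(rho)


def diff_test(beta_a, se_a, beta_b, se_b, r: float = 0.0):
    """Z-test for a difference between two stratum-specific effects.

    Vectorized over variants. Returns ``(z_diff, p_diff)`` arrays (scalars in,
    scalars out). ``r`` is the cross-stratum effect correlation entering the
    denominator ``sqrt(se_a^2 + se_b^2 - 2 r se_a se_b)``.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    se_a = np.asarray(se_a, dtype=float)
    se_b = np.asarray(se_b, dtype=float)
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise ValueError("standard errors must be positive")
    var = se_a**2 + se_b**2 - 2.0 * r * se_a * se_b
    if np.any(var <= 0):
        raise ValueError(
            "non-positive variance of the effect difference; "
            f"r={r} is too extreme for these standard errors"
        )
    z = (beta_a - beta_b) / np.sqrt(var)
    p = 2.0 * ndtr(-np.abs(z))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def joint_2df(beta_a, se_a, beta_b, se_b):
    """2df joint chi-square test of the stratified effects.

    Returns ``(c_joint, p_joint)``; ``p_joint`` is the chi-square(2df)
    survival probability, i.e. ``exp(-c/2)``.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    se_a = np.asarray(se_a, dtype=float)
    se_b = np.asarray(se_b, dtype=float)
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise ValueError("standard errors must be positive")
    c = (beta_a / se_a) ** 2 + (beta_b / se_b) ** 2
    p = stats.chi2.sf(c, df=2)
    if c.ndim == 0:
        return float(c), float(p)
    return c, p


def _merge_strata(scan_a: pd.DataFrame, scan_b: pd.DataFrame) -> pd.DataFrame:
    keys = ["variant_id", "chr", "pos"]
    cols = keys + ["beta", "se", "p"]
    merged = scan_a[cols].merge(
        scan_b[["variant_id", "beta", "se", "p"]],
        on="variant_id",
        suffixes=("_a", "_b"),
    )
    if merged.empty:
        only_a = set(scan_a["variant_id"]) - set(scan_b["variant_id"])
        only_b = set(scan_b["variant_id"]) - set(scan_a["variant_id"])
        raise ValueError(
            "strata share no variants; "
            f"{len(only_a)} only in A (e.g. {sorted(only_a)[:3]}), "
            f"{len(only_b)} only in B (e.g. {sorted(only_b)[:3]})"
        )
    dropped = (len(scan_a) - len(merged), len(scan_b) - len(merged))
    if any(dropped):
        logger.info(
            "difference/joint testing: %d variants only in stratum A and %d "
            "only in stratum B were excluded (both strata required)",
            *dropped,
        )
    return merged


def screen_genomewide(
    scan_a: pd.DataFrame,
    scan_b: pd.DataFrame,
    mode: str = "both",
    alpha: float = GENOME_WIDE_ALPHA,
    r: float = 0.0,
) -> pd.DataFrame:
    """Apply difference and/or joint tests to every variant in both scans.

    Variants filtered out of one stratum (e.g. by the MAC threshold) are
    excluded, since both (beta, se) pairs are required. ``mode`` selects
    "diff", "joint" or "both"; the significance flags ``sig_diff`` /
    ``sig_joint`` mark P below ``alpha``.
    """
    if mode not in ("diff", "joint", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    out = _merge_strata(scan_a, scan_b)
    ba, sa = out["beta_a"].to_numpy(), out["se_a"].to_numpy()
    bb, sb = out["beta_b"].to_numpy(), out["se_b"].to_numpy()
    if mode in ("diff", "both"):
        z, p = diff_test(ba, sa, bb, sb, r=r)
        out["z_diff"], out["p_diff"], out["r_used"] = z, p, r
        out["sig_diff"] = p < alpha
    if mode in ("joint", "both"):
        c, p = joint_2df(ba, sa, bb, sb)
        out["c_joint"], out["p_joint"] = c, p
        out["sig_joint"] = p < alpha
    return out


def candidate_lookup(
    scan_a: pd.DataFrame,
    scan_b: pd.DataFrame,
    variant_ids: list[str],
    alpha: float | None = None,
    r: float = 0.0,
    stratum_alpha: float = 0.05,
) -> pd.DataFrame:
    """Focused difference test on a list of candidate (known) variants.

    The significance threshold defaults to the Bonferroni correction
    ``0.05 / len(variant_ids)``. Each row also carries the qualitative
    interaction annotations: ``one_stratum_only`` (nominal effect in exactly
    one stratum) and ``opposite_direction`` (nominally significant effects of
    opposite sign).
    """
    if len(variant_ids) == 0:
        cols = ["variant_id", "chr", "pos", "beta_a", "se_a", "p_a", "beta_b",
                "se_b", "p_b", "z_diff", "p_diff", "sig_bonferroni",
                "one_stratum_only", "opposite_direction"]
        return pd.DataFrame(columns=cols)
    if alpha is None:
        alpha = 0.05 / len(variant_ids)
    merged = _merge_strata(scan_a, scan_b)
    found = merged[merged["variant_id"].isin(variant_ids)].reset_index(drop=True)
    missing = sorted(set(variant_ids) - set(found["variant_id"]))
    if missing:
        logger.warning("candidate variants missing from scans: %s", missing)
    z, p = diff_test(
        found["beta_a"].to_numpy(), found["se_a"].to_numpy(),
        found["beta_b"].to_numpy(), found["se_b"].to_numpy(), r=r,
    )
    found["z_diff"], found["p_diff"] = z, p
    found["sig_bonferroni"] = found["p_diff"] < alpha
    nominal_a = found["p_a"] < stratum_alpha
    nominal_b = found["p_b"] < stratum_alpha
    found["one_stratum_only"] = nominal_a ^ nominal_b
    found["opposite_direction"] = (
        nominal_a & nominal_b & (np.sign(found["beta_a"]) != np.sign(found["beta_b"]))
    )
    return found
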