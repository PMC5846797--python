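"""Region clumping, LD, conditional analysis and locus definition.

Genome-wide significant variants are clumped into regions with a liberal
+/-10 Mb physical window around the smallest-P lead. Within a region,
statistically independent secondary signals are sought by re-running the
stratified scans with the lead variant's dosage added as a covariate and
re-testing the conditioned effects; the loop repeats, accumulating leads,
until no conditioned P-value clears the threshold. Locus boundaries for
biological follow-up span all variants correlated with the lead (r^2 > 0.5)
padded by 500 kb on each side.

All genomic coordinates are 1-based inclusive; BED conversion happens only
at the I/O layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stratgwas import firth as firth_mod
from stratgwas import interaction

logger = logging.getLogger(__name__)

__all__ = [
    "RegionCluster",
    "LocusDefinition",
    "clump",
    "compute_r2",
    "conditional_scan",
    "define_locus",
]


@dataclass
class RegionCluster:
    """A clumped region: the lead variant and the members it absorbed."""

    lead: str
    members: list[str]
    chr: str
    window: tuple[int, int]


@dataclass
class LocusDefinition:
    """LD-based locus around a lead variant.

    ``correlated`` are the variants with r^2 > the threshold with the lead
    (the lead itself included, r^2 = 1); boundaries stretch from the first
    to the last correlated position padded by ``pad`` bp and floored at 1.
    """

    lead: str
    correlated: list[str]
    chr: str
    boundaries: tuple[int, int]
    genes: list[str] = field(default_factory=list)


def clump(
    significant: pd.DataFrame, window: int = 10_000_000
) -> list[RegionCluster]:
    """Greedy distance-based clumping of significant variants.

    Repeatedly takes the unassigned variant with the smallest P-value as a
    lead (ties broken by smaller chromosome then position) and absorbs all
    unassigned variants within +/-``window`` bp on the same chromosome.

    ``significant`` needs columns ``variant_id, chr, pos, p``.
    """
    if significant.empty:
        return []
    df = significant.copy()
    df["_chr"] = df["chr"].astype(str)
    # stable tie-break: P, then chromosome, then position
    df = df.sort_values(["p", "_chr", "pos"], kind="mergesort").reset_index(drop=True)
    unassigned = np.ones(len(df), dtype=bool)
    pos = df["pos"].to_numpy(dtype=np.int64)
    chrom = df["_chr"].to_numpy()
    vid = df["variant_id"].to_numpy()
    clusters: list[RegionCluster] = []
    for i in range(len(df)):
        if not unassigned[i]:
            continue
        near = unassigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        members = vid[near].tolist()
        unassigned[near] = False
        clusters.append(
            RegionCluster(
                lead=vid[i],
                members=members,
                chr=chrom[i],
                window=(max(1, int(pos[i]) - window), int(pos[i]) + window),
            )
        )
    return clusters


def compute_r2(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Monomorphic input makes r^2 undefined; it is reported as 0.0 with a
    warning so LD screens simply treat the pair as uncorrelated.
    """
    dos_i = np.asarray(dos_i, dtype=float)
    dos_j = np.asarray(dos_j, dtype=float)
    if dos_i.shape != dos_j.shape:
        raise ValueError("dosage vectors must cover the same samples")
    if np.ptp(dos_i) == 0.0 or np.ptp(dos_j) == 0.0:
        warnings.warn(
            "r^2 undefined for a monomorphic variant; reporting 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    r = np.corrcoef(dos_i, dos_j)[0, 1]
    return float(r * r)


def conditional_scan(
    region_variants: pd.DataFrame,
    dosages: np.ndarray,
    samples: pd.DataFrame,
    stratum_masks: dict[str, np.ndarray],
    lead: str,
    mode: str = "joint",
    alpha: float = interaction.GENOME_WIDE_ALPHA,
    r: float = 0.0,
    covariates: tuple[str, ...] = ("pc1", "pc2", "wga"),
    mac_min: int = 20,
    max_signals: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Iterative conditional analysis within one region.

    Starting from the given lead, the stratified scans are repeated for all
    region variants with the dosages of every accumulated lead added as
    covariates, and the conditioned (beta, se) pairs are re-tested with the
    difference or joint statistic. While the smallest conditioned P-value is
    below ``alpha`` the corresponding variant joins the lead list and the
    loop continues. Variants collinear with a current lead (r^2 > 0.95) are
    skipped with a logged reason.

    Parameters
    ----------
    region_variants : frame with ``variant_id, chr, pos, ea, oa`` rows
        aligned to ``dosages`` (variants x all samples).
    stratum_masks : mapping of the two stratum names to boolean sample masks.
    mode : "diff" or "joint" — which conditioned statistic drives selection.

    Returns
    -------
    (leads, last_results): the independent signal leads in discovery order
    and the conditioned test results from the final iteration (the one in
    which nothing further reached ``alpha``).
    """
    if mode not in ("diff", "joint"):
        raise ValueError(f"unknown mode {mode!r}")
    names = list(stratum_masks)
    if len(names) != 2:
        raise ValueError("exactly two strata required")
    vids = region_variants["variant_id"].to_numpy()
    if lead not in vids:
        raise ValueError(f"lead {lead!r} not among region variants")
    idx_of = {v: i for i, v in enumerate(vids)}
    leads = [lead]
    max_signals = max_signals if max_signals is not None else len(vids)

    while True:
        lead_dos = dosages[[idx_of[v] for v in leads], :]
        # drop variants collinear with any current lead (incl. the leads)
        testable = []
        for i, v in enumerate(vids):
            r2max = max(compute_r2(dosages[i], ld) for ld in lead_dos)
            if r2max > 0.95:
                logger.info(
                    "variant %s skipped in conditional scan (r^2=%.3f with a lead)",
                    v, r2max,
                )
            else:
                testable.append(i)
        if not testable:
            return leads, pd.DataFrame()
        scans = {}
        for name in names:
            mask = stratum_masks[name]
            sam = samples.loc[mask].reset_index(drop=True).copy()
            for j, lv in enumerate(leads):
                sam[f"_cond_{lv}"] = lead_dos[j, mask]
            cond_covs = tuple(covariates) + tuple(f"_cond_{lv}" for lv in leads)
            scans[name] = firth_mod.scan_stratum(
                dosages[np.ix_(testable, mask.nonzero()[0])],
                region_variants.iloc[testable].reset_index(drop=True),
                sam,
                stratum=name,
                covariates=cond_covs,
                mac_min=mac_min,
            )
        if scans[names[0]].empty or scans[names[1]].empty:
            return leads, pd.DataFrame()
        try:
            res = interaction.screen_genomewide(
                scans[names[0]], scans[names[1]], mode=mode, alpha=alpha, r=r
            )
        except ValueError:
            return leads, pd.DataFrame()
        pcol = "p_diff" if mode == "diff" else "p_joint"
        if res.empty or res[pcol].min() >= alpha or len(leads) >= max_signals:
            return leads, res
        best = res.loc[res[pcol].idxmin(), "variant_id"]
        logger.info("conditional scan: independent signal at %s (%s=%.3g)",
                    best, pcol, res[pcol].min())
        leads.append(best)


def define_locus(
    lead: str,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    genes: pd.DataFrame | None = None,
    r2_threshold: float = 0.5,
    pad: int = 500_000,
) -> LocusDefinition:
    """Define locus boundaries from LD with the lead variant.

    All variants with r^2 > ``r2_threshold`` with the lead (on the same
    chromosome) span the core; boundaries extend ``pad`` bp beyond the first
    and last correlated position, floored at 1. Genes whose span intersects
    the boundaries (``genes`` columns: gene, chr, start, end; 1-based
    inclusive) are attached.
    """
    vids = variants["variant_id"].to_numpy()
    idx_of = {v: i for i, v in enumerate(vids)}
    if lead not in idx_of:
        raise ValueError(f"lead {lead!r} not among variants")
    li = idx_of[lead]
    lead_chr = str(variants["chr"].iloc[li])
    chrom = variants["chr"].astype(str).to_numpy()
    lead_dos = dosages[li]
    correlated: list[str] = []
    positions: list[int] = []
    for i, v in enumerate(vids):
        if chrom[i] != lead_chr:
            continue
        r2 = 1.0 if i == li else compute_r2(dosages[i], lead_dos)
        if r2 > r2_threshold or i == li:
            correlated.append(v)
            positions.append(int(variants["pos"].iloc[i]))
    start = max(1, min(positions) - pad)
    end = max(positions) + pad
    overlapped: list[str] = []
    if genes is not None and not genes.empty:
        g = genes[genes["chr"].astype(str) == lead_chr]
        hit = (g["start"].astype(int) <= end) & (g["end"].astype(int) >= start)
        overlapped = g.loc[hit, "gene"].tolist()
    return LocusDefinition(
        lead=lead,
        correlated=correlated,
        chr=lead_chr,
        boundaries=(start, end),
        genes=overlapped,
    )
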