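"""Stratum definition, scan orchestration and genomic-control correction.

The primary design splits a case-control sample into "younger" and "older"
strata using separate age cutoffs for cases and controls (the median age
within each status group), so that both strata retain a usable case-control
balance. A sex split uses the recorded category directly. Either way the
downstream machinery is identical: one Firth scan per stratum, genomic
control per stratum, then cross-stratum tests.

Genomic control estimates the inflation factor lambda as the median Wald
chi-square over null-ish variants divided by the chi-square(1 df) median
0.4549364. Variants within +/-10 Mb of known disease loci are excluded from
the estimate so that true signals do not masquerade as inflation. The
correction inflates standard errors by sqrt(max(1, lambda)), leaving effect
sizes untouched, so that the corrected (beta, se) pairs feed directly into
the difference and joint tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stratgwas import firth

__all__ = [
    "CHI2_1_MEDIAN",
    "StratumSpec",
    "GCResult",
    "median_split",
    "sex_split",
    "sensitivity_split",
    "scan_strata",
    "exclusion_windows",
    "gc_lambda",
    "apply_gc",
]

# median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = 0.4549364


@dataclass(frozen=True)
class StratumSpec:
    """A named rule assigning samples to one stratum.

    For the age axis the rule is a pair of cutoffs (cases, controls) plus a
    side: the "younger" stratum takes cases with age <= case cutoff and
    controls with age <= control cutoff; "older" is the complement. For the
    sex axis the rule is a category value matched against the ``sex`` column.
    """

    name: str
    axis: str  # "age" | "sex"
    case_cutoff: float | None = None
    control_cutoff: float | None = None
    side: str | None = None  # "le" (younger) or "gt" (older)
    sex_value: str | None = None
    case_age_range: tuple[float | None, float | None] | None = None

    def mask(self, samples: pd.DataFrame) -> np.ndarray:
        status = samples["status"].to_numpy() == 1
        if self.axis == "sex":
            return (samples["sex"].astype(str) == str(self.sex_value)).to_numpy()
        age = samples["age"].to_numpy(dtype=float)
        if self.case_age_range is not None:
            lo, hi = self.case_age_range
            keep = np.ones(len(samples), dtype=bool)
            if lo is not None:
                keep &= age >= lo
            if hi is not None:
                keep &= age <= hi
            ctrl_keep = (
                age <= self.control_cutoff if self.side == "le" else age > self.control_cutoff
            )
            return np.where(status, keep, ctrl_keep)
        if self.side == "le":
            return np.where(status, age <= self.case_cutoff, age <= self.control_cutoff)
        return np.where(status, age > self.case_cutoff, age > self.control_cutoff)


def median_split(samples: pd.DataFrame) -> tuple[StratumSpec, StratumSpec, pd.Series]:
    """Split samples into younger/older strata by within-status median age.

    The case cutoff is the median age among cases and the control cutoff the
    median age among controls; ``<=`` is assigned to the younger stratum.

    Returns the two stratum specs and a per-sample label series.
    """
    if samples["age"].isna().any():
        missing = samples.index[samples["age"].isna()].tolist()
        raise ValueError(f"samples with missing age cannot be stratified: {missing}")
    status = samples["status"] == 1
    case_cut = float(samples.loc[status, "age"].median())
    ctrl_cut = float(samples.loc[~status, "age"].median())
    younger = StratumSpec(
        "younger", "age", case_cutoff=case_cut, control_cutoff=ctrl_cut, side="le"
    )
    older = StratumSpec(
        "older", "age", case_cutoff=case_cut, control_cutoff=ctrl_cut, side="gt"
    )
    labels = pd.Series(
        np.where(younger.mask(samples), "younger", "older"),
        index=samples.index,
        name="stratum",
    )
    return younger, older, labels


def sex_split(
    samples: pd.DataFrame, female: str = "F", male: str = "M"
) -> tuple[StratumSpec, StratumSpec, pd.Series]:
    """Split samples by the recorded sex category."""
    seen = set(samples["sex"].astype(str).unique())
    if not seen <= {female, male}:
        raise ValueError(f"unexpected sex categories {seen - {female, male}}")
    fspec = StratumSpec("female", "sex", sex_value=female)
    mspec = StratumSpec("male", "sex", sex_value=male)
    labels = pd.Series(
        np.where(fspec.mask(samples), "female", "male"),
        index=samples.index,
        name="stratum",
    )
    return fspec, mspec, labels


def sensitivity_split(
    samples: pd.DataFrame, young_max: float = 65.0, old_min: float = 85.0
) -> tuple[StratumSpec, StratumSpec, pd.Series]:
    """Contrast truly-young cases (<= young_max) with truly-old (>= old_min).

    Cases of intermediate age are excluded (label NA); controls are split by
    their median age as in the primary design.
    """
    status = samples["status"] == 1
    ctrl_cut = float(samples.loc[~status, "age"].median())
    young = StratumSpec(
        "truly_young", "age", control_cutoff=ctrl_cut, side="le",
        case_age_range=(None, young_max),
    )
    old = StratumSpec(
        "truly_old", "age", control_cutoff=ctrl_cut, side="gt",
        case_age_range=(old_min, None),
    )
    age = samples["age"].to_numpy(dtype=float)
    lab = np.where(young.mask(samples), "truly_young", "")
    lab = np.where(old.mask(samples), "truly_old", lab)
    excluded = status.to_numpy() & (age > young_max) & (age < old_min)
    lab = np.where(excluded, "", lab)
    labels = pd.Series(lab, index=samples.index, name="stratum").replace("", pd.NA)
    return young, old, labels


def scan_strata(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    specs: tuple[StratumSpec, StratumSpec],
    covariates: tuple[str, ...] = ("pc1", "pc2", "wga"),
    mac_min: int = 20,
) -> dict[str, pd.DataFrame]:
    """Run the Firth association scan in each stratum.

    Returns a mapping from stratum name to its scan frame (uncorrected; see
    :func:`gc_lambda` and :func:`apply_gc`).
    """
    out: dict[str, pd.DataFrame] = {}
    for spec in specs:
        mask = spec.mask(samples)
        if not mask.any():
            raise ValueError(f"stratum {spec.name!r} is empty")
        out[spec.name] = firth.scan_stratum(
            dosages[:, mask],
            variants,
            samples.loc[mask].reset_index(drop=True),
            stratum=spec.name,
            covariates=covariates,
            mac_min=mac_min,
        )
    return out


@dataclass
class GCResult:
    """Genomic-control inflation estimate for one stratum scan."""

    stratum: str
    lambda_gc: float
    n_variants_used: int
    exclusion_windows: list[tuple] = field(default_factory=list)

    @property
    def applied_lambda(self) -> float:
        """Inflation actually applied: never deflate below 1."""
        return max(1.0, self.lambda_gc)


def exclusion_windows(
    known_loci: pd.DataFrame, window: int = 10_000_000
) -> list[tuple]:
    """+/-``window`` bp closed intervals around known lead variants.

    ``known_loci`` needs columns ``chr`` and ``pos`` (1-based). Window starts
    are floored at 1.
    """
    return [
        (row.chr, max(1, int(row.pos) - window), int(row.pos) + window)
        for row in known_loci.itertuples()
    ]


def _outside_windows(scan: pd.DataFrame, windows: list[tuple]) -> np.ndarray:
    keep = np.ones(len(scan), dtype=bool)
    chrom = scan["chr"].astype(str).to_numpy()
    pos = scan["pos"].to_numpy(dtype=np.int64)
    for wchr, start, end in windows:
        keep &= ~((chrom == str(wchr)) & (pos >= start) & (pos <= end))
    return keep


def gc_lambda(
    scan: pd.DataFrame,
    known_loci: pd.DataFrame | None = None,
    window: int = 10_000_000,
    min_retained: int = 1000,
    stratum: str | None = None,
) -> GCResult:
    """Estimate the genomic-control inflation factor for one stratum scan.

    lambda = median(z^2) / 0.4549364 over variants outside all exclusion
    windows (known loci +/- ``window`` bp).
    """
    windows = exclusion_windows(known_loci, window) if known_loci is not None else []
    keep = _outside_windows(scan, windows)
    n_used = int(keep.sum())
    if n_used < min_retained:
        raise ValueError(
            f"only {n_used} variants remain outside exclusion windows "
            f"(need >= {min_retained}); consider smaller windows"
        )
    z = scan.loc[keep, "z"].to_numpy(dtype=float)
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    if stratum is not None:
        name = stratum
    elif "stratum" in scan.columns and len(scan):
        name = str(scan["stratum"].iloc[0])
    else:
        name = "all"
    return GCResult(
        stratum=name, lambda_gc=lam, n_variants_used=n_used, exclusion_windows=windows
    )


def apply_gc(scan: pd.DataFrame, gc: GCResult | float) -> pd.DataFrame:
    """Apply genomic control by inflating standard errors.

    se <- se * sqrt(max(1, lambda)); z and p are recomputed while beta is
    left unchanged, so the correction propagates into the difference and
    joint tests through the standard errors. Returns a new frame.
    """
    lam = gc.applied_lambda if isinstance(gc, GCResult) else max(1.0, float(gc))
    out = scan.copy()
    if lam > 1.0:
        out["se"] = out["se"] * np.sqrt(lam)
        out["z"] = out["beta"] / out["se"]
        out["p"] = firth.wald_p(out["z"].to_numpy())
    return out
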