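"""Gene priority score (GPS): equal-weight sums of binary evidence flags.

Candidate genes at a locus are scored by summing eleven binary evidence
columns — expression in retina and RPE/choroid, mouse eye phenotypes,
overlap with the credible set, protein-altering / UTR / other exonic or
splice-site / promoter variants, local eQTL status, gene essentiality, and
known Mendelian retinopathy involvement. Flags arrive from upstream
curation as '+' (supporting), '-' (absent), '0' (scored zero) or 'NA'
(unknown); only '+' scores. Unknown is kept distinct from absent on output
but contributes nothing to the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EVIDENCE_COLUMNS",
    "GPSRecord",
    "parse_flag",
    "expression_flag",
    "score_genes",
]

EVIDENCE_COLUMNS = [
    "expressed_retina",
    "expressed_rpe_choroid",
    "mgi_eye_phenotype",
    "has_credible_variant",
    "protein_altering",
    "utr_5_or_3",
    "other_exonic_splice",
    "promoter_1kb",
    "local_eqtl",
    "essential_exac",
    "mendelian_retinopathy",
]

_TRUE = {"+", "1", "true", "yes"}
_FALSE = {"-", "0", "false", "no"}
_UNKNOWN = {"na", "nan", "", "?", "unknown"}


@dataclass(frozen=True)
class GPSRecord:
    """One gene's priority score (0-11 with the standard columns)."""

    gene: str
    gps: int


def parse_flag(value) -> bool | None:
    """Map a raw evidence entry to True / False / None (unknown)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    if s in _UNKNOWN:
        return None
    raise ValueError(f"unrecognized evidence flag {value!r}")


def expression_flag(fpkm) -> bool | None:
    """Expression call from an FPKM value: expressed iff FPKM > 1.

    Missing values return None (unknown; scores 0). Negative FPKM is a
    data error.
    """
    if fpkm is None or pd.isna(fpkm):
        return None
    fpkm = float(fpkm)
    if fpkm < 0:
        raise ValueError(f"FPKM cannot be negative: {fpkm}")
    return fpkm > 1.0


def score_genes(
    flags: pd.DataFrame,
    columns: list[str] | None = None,
    weights: list[float] | None = None,
) -> pd.DataFrame:
    """Score a gene-by-evidence flag table and rank genes.

    Parameters
    ----------
    flags : frame with a ``gene`` column plus one column per evidence class;
        entries parsed by :func:`parse_flag`. Duplicate genes are rejected.
    columns : evidence columns to score (defaults to every non-``gene``
        column, in table order).
    weights : optional per-column weights; defaults to all ones, giving the
        equal-weight GPS.

    Returns
    -------
    Frame with ``gene``, the parsed flags ('+', '-', 'NA' preserved) and
    ``gps``, sorted by descending score with alphabetical tie-break.
    """
    if "gene" not in flags.columns:
        raise ValueError("flag table needs a 'gene' column")
    dup = flags["gene"][flags["gene"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate genes in flag table: {sorted(set(dup))}")
    if columns is None:
        # standard layout when available; otherwise every non-gene column
        if set(EVIDENCE_COLUMNS) <= set(flags.columns):
            columns = list(EVIDENCE_COLUMNS)
        else:
            columns = [c for c in flags.columns if c != "gene"]
    if weights is None:
        weights = [1.0] * len(columns)
    if len(weights) != len(columns):
        raise ValueError("weights must match the evidence columns")

    out = pd.DataFrame({"gene": flags["gene"].astype(str)})
    scores = pd.Series(0.0, index=flags.index)
    for col, w in zip(columns, weights):
        parsed = []
        for idx, raw in flags[col].items():
            try:
                tri = parse_flag(raw)
            except ValueError as exc:
                raise ValueError(
                    f"gene {flags.loc[idx, 'gene']!r}, column {col!r}: {exc}"
                ) from exc
            parsed.append(tri)
        scores += [w if tri is True else 0.0 for tri in parsed]
        out[col] = ["+" if t is True else ("-" if t is False else "NA") for t in parsed]
    out["gps"] = scores.astype(int) if all(float(w).is_integer() for w in weights) else scores
    out = out.sort_values(
        ["gps", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
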