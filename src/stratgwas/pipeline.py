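"""End-to-end pipeline: stratify -> scan -> GC -> tests -> regions -> follow-up.

:func:`run_pipeline` sequences the full analysis on in-memory inputs (or a
freshly simulated dataset) and writes every stage's artifacts under an
output directory together with a JSON run report capturing the package
version, seed, thresholds, inflation factors and the estimated cross-stratum
effect correlation — enough to reproduce the run byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import stratgwas
from stratgwas import finemap as finemap_mod
from stratgwas import genes as genes_mod
from stratgwas import interaction, io, regions, stratify

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Paths, stratification rule and thresholds for one pipeline run.

    Threshold defaults follow standard GWAS practice: genome-wide alpha
    5e-8, stratum MAC minimum 20, clump window 10 Mb, locus definition at
    r^2 > 0.5 with 500 kb padding, 99% credible sets, and a Bonferroni
    denominator of 34 for the known-variant follow-up.
    """

    genotypes: str | None = None
    samples: str | None = None
    known_loci: str | None = None
    gene_table: str | None = None
    evidence_flags: str | None = None
    axis: str = "age"
    alpha_gw: float = 5e-8
    mac_min: int = 20
    clump_window: int = 10_000_000
    gc_window: int = 10_000_000
    gc_min_retained: int = 1000
    locus_r2: float = 0.5
    locus_pad: int = 500_000
    credible_level: float = 0.99
    finemap_prior_sd: float = 0.2
    bonferroni_m: int = 34
    default_r: float = 0.03
    covariates: tuple[str, ...] = ("pc1", "pc2", "wga")
    seed: int = 0
    out_dir: str = "stratgwas_out"

    def __post_init__(self) -> None:
        for name in ("alpha_gw", "mac_min", "clump_window", "locus_r2",
                     "locus_pad", "credible_level", "bonferroni_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.axis not in ("age", "sex"):
            raise ValueError("axis must be 'age' or 'sex'")

    def validate_paths(self) -> None:
        for name in ("genotypes", "samples", "known_loci", "gene_table",
                     "evidence_flags"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML (keys = PipelineConfig fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "covariates" in raw:
        raw["covariates"] = tuple(raw["covariates"])
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's outputs."""

    scans: dict[str, pd.DataFrame]
    gc: dict[str, stratify.GCResult]
    r_estimate: float
    tests: pd.DataFrame
    candidates: pd.DataFrame | None
    clusters: list[regions.RegionCluster]
    conditional_leads: dict[str, list[str]]
    loci: list[regions.LocusDefinition]
    credible_sets: list[finemap_mod.CredibleSet]
    gps: pd.DataFrame | None
    report: dict = field(default_factory=dict)


def _overall_z(tests: pd.DataFrame) -> pd.DataFrame:
    """Pooled (inverse-variance) association z per variant for fine-mapping."""
    w_a = 1.0 / tests["se_a"] ** 2
    w_b = 1.0 / tests["se_b"] ** 2
    beta = (tests["beta_a"] * w_a + tests["beta_b"] * w_b) / (w_a + w_b)
    se = np.sqrt(1.0 / (w_a + w_b))
    return pd.DataFrame({
        "variant_id": tests["variant_id"],
        "pos": tests["pos"],
        "z": beta / se,
        "se": se,
    })


def run_pipeline(
    config: PipelineConfig,
    dosages: np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    known_loci: pd.DataFrame | None = None,
    gene_table: pd.DataFrame | None = None,
    evidence_flags: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the full stratified interaction analysis.

    Inputs may be passed in memory; anything not passed is loaded from the
    paths in ``config`` (genotype files may be ``.vcf`` or dosage ``.tsv``).
    Stages: stratify -> per-stratum Firth scans -> genomic control ->
    difference + joint screens (-> known-variant lookup) -> clumping ->
    conditional analysis -> locus definition -> credible sets (-> gene
    priority scores). Artifacts are written under ``config.out_dir`` unless
    ``write=False``.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    if dosages is None or variants is None:
        if config.genotypes is None:
            raise ValueError("no genotypes provided (in memory or by path)")
        if str(config.genotypes).endswith(".vcf"):
            variants, dosages, geno_ids = io.read_dosage_vcf(config.genotypes)
        else:
            variants, dosages, geno_ids = io.read_dosage_tsv(config.genotypes)
        if samples is None:
            if config.samples is None:
                raise ValueError("no sample table provided")
            samples = io.read_sample_table(config.samples)
        dosages, samples = io.align_samples(dosages, geno_ids, samples)
    elif samples is None:
        raise ValueError("no sample table provided")
    if known_loci is None and config.known_loci is not None:
        known_loci = io.read_known_loci(config.known_loci)
    if gene_table is None and config.gene_table is not None:
        gene_table = io.read_gene_table(config.gene_table)
    if evidence_flags is None and config.evidence_flags is not None:
        evidence_flags = pd.read_csv(config.evidence_flags, sep="\t")

    # 1. stratify
    if config.axis == "age":
        spec_a, spec_b, labels = stratify.median_split(samples)
    else:
        spec_a, spec_b, labels = stratify.sex_split(samples)
    name_a, name_b = spec_a.name, spec_b.name
    logger.info("strata: %s=%d, %s=%d", name_a, (labels == name_a).sum(),
                name_b, (labels == name_b).sum())

    # 2. per-stratum scans
    scans = stratify.scan_strata(
        dosages, variants, samples, (spec_a, spec_b),
        covariates=config.covariates, mac_min=config.mac_min,
    )

    # 3. genomic control
    gc: dict[str, stratify.GCResult] = {}
    for name, scan in scans.items():
        try:
            gc[name] = stratify.gc_lambda(
                scan, known_loci, window=config.gc_window,
                min_retained=config.gc_min_retained, stratum=name,
            )
            scans[name] = stratify.apply_gc(scan, gc[name])
        except ValueError as exc:
            logger.warning("genomic control skipped for %s: %s", name, exc)

    # 4. cross-stratum correlation, difference + joint screens
    try:
        r_est = interaction.estimate_cross_stratum_correlation(
            scans[name_a], scans[name_b]
        )
    except ValueError:
        logger.warning("too few shared variants to estimate r; using default %.2f",
                       config.default_r)
        r_est = config.default_r
    tests = interaction.screen_genomewide(
        scans[name_a], scans[name_b], mode="both", alpha=config.alpha_gw, r=r_est
    )

    # 5. known-variant follow-up
    candidates = None
    if known_loci is not None and len(known_loci):
        candidates = interaction.candidate_lookup(
            scans[name_a], scans[name_b], known_loci["rsid"].tolist(),
            alpha=0.05 / config.bonferroni_m, r=r_est,
        )

    # 6. clump the joint-significant set; conditional analysis per region
    sig = tests[tests["sig_joint"]] if len(tests) else tests
    clusters = regions.clump(
        sig.rename(columns={"p_joint": "p"})[["variant_id", "chr", "pos", "p"]]
        if len(sig) else pd.DataFrame(columns=["variant_id", "chr", "pos", "p"]),
        window=config.clump_window,
    )
    masks = {
        name_a: (labels == name_a).to_numpy(),
        name_b: (labels == name_b).to_numpy(),
    }
    conditional_leads: dict[str, list[str]] = {}
    loci: list[regions.LocusDefinition] = []
    credible_sets: list[finemap_mod.CredibleSet] = []
    vid_index = {v: i for i, v in enumerate(variants["variant_id"])}
    for cluster in clusters:
        member_idx = [vid_index[v] for v in cluster.members]
        region_vars = variants.iloc[member_idx].reset_index(drop=True)
        region_dos = dosages[member_idx]
        leads, _ = regions.conditional_scan(
            region_vars, region_dos, samples, masks, cluster.lead,
            mode="joint", alpha=config.alpha_gw, r=r_est,
            covariates=config.covariates, mac_min=config.mac_min,
        )
        conditional_leads[cluster.lead] = leads
        locus = regions.define_locus(
            cluster.lead, variants, dosages, gene_table,
            r2_threshold=config.locus_r2, pad=config.locus_pad,
        )
        loci.append(locus)
        # 7. fine-map single-signal loci on the pooled association z
        locus_tests = tests[tests["variant_id"].isin(locus.correlated)]
        if len(locus_tests):
            cs = finemap_mod.credible_set(
                _overall_z(locus_tests),
                level=config.credible_level,
                prior_sd=config.finemap_prior_sd,
                locus=cluster.lead,
                multi_signal=len(leads) > 1,
            ) if len(leads) == 1 else None
            if cs is not None:
                credible_sets.append(cs)
            else:
                logger.warning("locus %s has %d independent signals; "
                               "skipping single-causal fine-mapping",
                               cluster.lead, len(leads))

    # 8. gene priority scores
    gps = genes_mod.score_genes(evidence_flags) if evidence_flags is not None else None

    report = {
        "package_version": stratgwas.__version__,
        "seed": config.seed,
        "axis": config.axis,
        "strata": {name_a: int((labels == name_a).sum()),
                   name_b: int((labels == name_b).sum())},
        "thresholds": {
            "alpha_gw": config.alpha_gw, "mac_min": config.mac_min,
            "clump_window": config.clump_window, "locus_r2": config.locus_r2,
            "locus_pad": config.locus_pad,
            "credible_level": config.credible_level,
            "bonferroni_m": config.bonferroni_m,
        },
        "lambda_gc": {k: v.lambda_gc for k, v in gc.items()},
        "r_estimate": r_est,
        "n_variants_tested": int(len(tests)),
        "n_significant_joint": int(tests["sig_joint"].sum()) if len(tests) else 0,
        "n_significant_diff": int(tests["sig_diff"].sum()) if len(tests) else 0,
        "n_regions": len(clusters),
    }

    result = PipelineResult(
        scans=scans, gc=gc, r_estimate=r_est, tests=tests,
        candidates=candidates, clusters=clusters,
        conditional_leads=conditional_leads, loci=loci,
        credible_sets=credible_sets, gps=gps, report=report,
    )
    if write:
        _write_artifacts(out, config, result)
    return result


def _write_artifacts(out: Path, config: PipelineConfig, res: PipelineResult) -> None:
    for name, scan in res.scans.items():
        scan.to_csv(out / f"scan_{name}.tsv", sep="\t", index=False)
    with open(out / "lambda_report.json", "w") as fh:
        json.dump(
            {k: {"lambda_gc": v.lambda_gc, "n_variants_used": v.n_variants_used}
             for k, v in res.gc.items()},
            fh, indent=2,
        )
    res.tests.to_csv(out / "interaction_tests.tsv", sep="\t", index=False)
    if res.candidates is not None:
        res.candidates.to_csv(out / "candidate_lookup.tsv", sep="\t", index=False)
    if res.loci:
        io.write_bed(out / "loci.bed", pd.DataFrame({
            "chr": [l.chr for l in res.loci],
            "start": [l.boundaries[0] for l in res.loci],
            "end": [l.boundaries[1] for l in res.loci],
            "name": [l.lead for l in res.loci],
        }))
        with open(out / "loci.json", "w") as fh:
            json.dump([{
                "lead": l.lead, "chr": l.chr, "boundaries": list(l.boundaries),
                "n_correlated": len(l.correlated), "genes": l.genes,
                "independent_signals": res.conditional_leads.get(l.lead, [l.lead]),
            } for l in res.loci], fh, indent=2)
    for cs in res.credible_sets:
        cs.table.to_csv(out / f"credible_set_{cs.locus}.tsv", sep="\t", index=False)
    if res.gps is not None:
        res.gps.to_csv(out / "gps.tsv", sep="\t", index=False)
    with open(out / "run_report.json", "w") as fh:
        json.dump(res.report, fh, indent=2)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(config).items()}, fh)
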