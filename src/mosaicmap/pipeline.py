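"""End-to-end orchestration: screen -> route -> validate -> cohort stats.

Candidate mosaic sites from the screening stage are routed by hotspot
status: variants on a pre-designed genotyping-assay hotspot go to droplet
digital PCR, everything else to amplicon validation (optionally both).
A candidate is *confirmed* when at least one validation estimate clears
the 0.5% interval floor (and, for amplicon calls, sits outside the
heterozygous band).  Confirmed mosaics are aggregated by sex into a 2x2
table handed to the exact cohort statistics, and all outputs (per-subject
TSV, VCF of confirmed calls, JSON cohort report, manifest, JSONL run log)
are deterministic functions of config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .cohort import CohortAssociation, ContingencyTable
from .ddpcr import DropletMafModel, MafEstimate
from .pasm import AmpliconMafModel, ErrorModel, PasmThresholds, fit_error_model
from .screen import GenotypeCall, PileupSite, ScreenModel, ScreenThresholds
from .simulate import (
    AMPLICON_INPUT_COPIES,
    CohortSimConfig,
    DropletSimConfig,
    SEMEN_FRACTIONS,
    SimConfig,
    TISSUES,
    simulate_amplicon,
    simulate_cohort,
    simulate_droplets,
    simulate_pileup,
    simulate_tissue_panel,
)

__all__ = [
    "HotspotList",
    "DEFAULT_HOTSPOTS",
    "route_candidate",
    "PipelineConfig",
    "run_pipeline",
    "generate_fixtures",
    "analyze_tissue_panel",
]

logger = logging.getLogger(__name__)

# Representative recurrent MECP2 hotspot coding changes with pre-designed
# genotyping assays (user-overridable; the classical C>T hotspot set).
DEFAULT_HOTSPOTS = frozenset(
    {
        ("MECP2", "c.316C>T"),   # p.Arg106Trp
        ("MECP2", "c.317G>A"),   # p.Arg106Gln
        ("MECP2", "c.397C>T"),   # p.Arg133Cys
        ("MECP2", "c.473C>T"),   # p.Thr158Met
        ("MECP2", "c.502C>T"),   # p.Arg168Ter
        ("MECP2", "c.763C>T"),   # p.Arg255Ter
        ("MECP2", "c.808C>T"),   # p.Arg270Ter
        ("MECP2", "c.880C>T"),   # p.Arg294Ter
        ("MECP2", "c.916C>T"),   # p.Arg306Cys
        ("MECP2", "c.806delG"),  # p.Gly269AlafsTer20
    }
)


class HotspotList:
    """Set of (gene, coding-change) identifiers with direct ddPCR assays."""

    def __init__(self, entries=DEFAULT_HOTSPOTS):
        self._entries = frozenset(tuple(e) for e in entries)

    def __contains__(self, item) -> bool:
        return tuple(item) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(sorted(self._entries))


def route_candidate(
    call: GenotypeCall,
    hotspots: HotspotList,
    variant_id: tuple[str, str] | None = None,
    both: bool = False,
) -> list[str]:
    """Validation plan for one mosaic candidate.

    Hotspot variants go to ddPCR (a genotyping assay already exists);
    non-hotspot variants to amplicon validation.  ``both=True`` requests
    both routes; an unidentifiable variant falls back to amplicon
    validation with a warning.
    """
    if call.label != "mosaic_candidate":
        raise ValueError("routing applies to mosaic candidates only")
    if both:
        return ["ddpcr", "pasm"]
    if variant_id is None:
        logger.warning("site %s has no variant identifier; routed to pasm",
                       call.site_id)
        return ["pasm"]
    return ["ddpcr"] if variant_id in hotspots else ["pasm"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of a synthetic end-to-end run."""

    seed: int = 0
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    exact_counts: bool = False  # force mosaic counts to round(rate * n)
    depth: int = 1000
    input_copies: int = 3000
    error_rate: float = 1e-3
    amplicon_depth: int = 12_000
    amplicon_input_copies: int = AMPLICON_INPUT_COPIES
    ddpcr_total_copies: int = 50_000
    ddpcr_n_droplets: int = 5_000_000
    n_control_sites: int = 10
    hotspot_fraction: float = 0.5  # fraction of mosaic variants on hotspots
    screen_thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    pasm_thresholds: PasmThresholds = field(default_factory=PasmThresholds)
    ddpcr_min_ci_low: float = 0.0  # confirm ddPCR when ci_low >= max(this, floor)
    require_both: bool = False


_VARIANT_CATALOG = [
    # (gene, coding change, pos, ref, alt) – hotspot status comes from the list
    ("MECP2", "c.316C>T", 153_296_777, "G", "A"),
    ("MECP2", "c.317G>A", 153_296_776, "C", "T"),
    ("MECP2", "c.502C>T", 153_296_591, "G", "A"),
    ("MECP2", "c.880C>T", 153_296_213, "G", "A"),
    ("MECP2", "c.353G>A", 153_296_740, "C", "T"),
    ("MECP2", "c.455C>G", 153_296_638, "G", "C"),
    ("MECP2", "c.674C>G", 153_296_419, "G", "C"),
    ("MECP2", "c.1157del", 153_295_936, "TC", "T"),
]


def _assign_exact_counts(cohort: pd.DataFrame, cfg: PipelineConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Force the mosaic counts to round(rate * n) per sex (fixture truth)."""
    from .simulate import _draw_mafs

    cohort = cohort.copy()
    cohort["is_mosaic"] = False
    cohort["true_maf"] = np.nan
    for sex, n, rate in (("M", cfg.cohort.n_male, cfg.cohort.rate_male),
                         ("F", cfg.cohort.n_female, cfg.cohort.rate_female)):
        k = int(round(rate * n))
        idx = cohort.index[cohort["sex"] == sex]
        chosen = rng.choice(idx, size=k, replace=False) if k else []
        cohort.loc[chosen, "is_mosaic"] = True
        if k:
            cohort.loc[chosen, "true_maf"] = _draw_mafs(
                cfg.cohort.maf_distribution, k, rng)
    return cohort


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic analysis and return the cohort report.

    Steps: simulate the cohort; simulate one screened pileup site per
    subject; screen; route candidates (hotspot -> ddPCR, else amplicon);
    validate; aggregate confirmed mosaics by sex; exact Fisher / odds
    ratio.  If ``outdir`` is given, writes calls.tsv, confirmed.vcf,
    cohort_report.json, manifest.json and run.jsonl there.
    """
    rng = np.random.default_rng(config.seed)
    cohort_cfg = CohortSimConfig(
        n_male=config.cohort.n_male, n_female=config.cohort.n_female,
        rate_male=config.cohort.rate_male, rate_female=config.cohort.rate_female,
        maf_distribution=config.cohort.maf_distribution,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cohort = simulate_cohort(cohort_cfg)
    if config.exact_counts:
        cohort = _assign_exact_counts(cohort, config, rng)

    hotspots = HotspotList()
    error_model = _control_error_model(config, rng)

    log_events: list[dict] = []
    rows: list[dict] = []
    vcf_records: list[dict] = []

    for _, subj in cohort.iterrows():
        true_maf = 0.0 if not subj.is_mosaic else float(subj.true_maf)
        variant = _VARIANT_CATALOG[int(rng.integers(0, len(_VARIANT_CATALOG)))] \
            if subj.is_mosaic else _VARIANT_CATALOG[0]
        gene, cchange, pos, ref, alt = variant
        site = simulate_pileup(
            SimConfig(true_maf=true_maf, depth=config.depth,
                      input_copies=config.input_copies,
                      error_rate=config.error_rate,
                      seed=int(rng.integers(0, 2**31 - 1)), n_sites=1)
        )[0]
        site = PileupSite(
            site_id=f"{subj.subject_id}:{gene}:{cchange}",
            ref_count=site.ref_count, alt_count=site.alt_count,
            error_rate=site.error_rate, chrom="chrX", pos=pos,
            ref=ref, alt=alt, true_maf=true_maf,
        )
        call = ScreenModel([site], config.screen_thresholds).fit().calls[0]
        row = {
            "subject_id": subj.subject_id, "sex": subj.sex,
            "gene": gene, "coding_change": cchange,
            "true_mosaic": bool(subj.is_mosaic),
            "true_maf": true_maf if subj.is_mosaic else np.nan,
            "screen_call": call.label, "screen_maf": call.map_maf,
            "screen_ci_lo": call.ci_low, "screen_ci_hi": call.ci_high,
            "route": "", "validation_method": "", "validated_maf": np.nan,
            "validated_ci_lo": np.nan, "validated_ci_hi": np.nan,
            "confirmed": False,
        }
        if call.label == "mosaic_candidate":
            plan = route_candidate(call, hotspots, (gene, cchange),
                                   both=config.require_both)
            row["route"] = "+".join(plan)
            confirmations = []
            for method in plan:
                est = _validate(method, true_maf, config, error_model, rng)
                ok = _confirms(method, est, config)
                confirmations.append(ok)
                if ok or np.isnan(row["validated_maf"]):
                    row["validation_method"] = method
                    row["validated_maf"] = est.map_maf
                    row["validated_ci_lo"] = est.ci_low
                    row["validated_ci_hi"] = est.ci_high
            row["confirmed"] = (all(confirmations) if config.require_both
                                else any(confirmations))
            log_events.append({"subject": subj.subject_id, "event": "validated",
                               "plan": plan, "confirmed": row["confirmed"]})
        if row["confirmed"]:
            vcf_records.append({
                "chrom": "chrX", "pos": pos, "id": f"{gene}:{cchange}",
                "ref": ref, "alt": alt, "maf": row["validated_maf"],
                "ci_low": row["validated_ci_lo"], "ci_high": row["validated_ci_hi"],
                "call": "mosaic_confirmed", "method": row["validation_method"],
                "subject": subj.subject_id,
            })
        rows.append(row)

    calls = pd.DataFrame(rows)
    a = int((calls.confirmed & (calls.sex == "M")).sum())
    b = int((~calls.confirmed & (calls.sex == "M")).sum())
    c = int((calls.confirmed & (calls.sex == "F")).sum())
    d = int((~calls.confirmed & (calls.sex == "F")).sum())
    table = ContingencyTable(a, b, c, d)

    report: dict = {
        "n_subjects": len(calls),
        "table": {"a": a, "b": b, "c": c, "d": d},
        "truth_table": {
            "a": int((calls.true_mosaic & (calls.sex == "M")).sum()),
            "b": int((~calls.true_mosaic & (calls.sex == "M")).sum()),
            "c": int((calls.true_mosaic & (calls.sex == "F")).sum()),
            "d": int((~calls.true_mosaic & (calls.sex == "F")).sum()),
        },
        "n_candidates": int((calls.screen_call == "mosaic_candidate").sum()),
        "n_confirmed": int(calls.confirmed.sum()),
    }
    if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
        report["stats"] = None
        report["note"] = "degenerate 2x2 margin; Fisher test uninformative (p=1)"
    else:
        report["stats"] = CohortAssociation(table).fit().to_dict()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        mio.write_vcf(vcf_records, outdir / "confirmed.vcf")
        (outdir / "cohort_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        mio.write_manifest(
            {"config": config, "package": "mosaicmap"}, outdir / "manifest.json")
        with open(outdir / "run.jsonl", "w") as fh:
            for ev in log_events:
                fh.write(json.dumps(ev, sort_keys=True) + "\n")
    report["calls"] = calls
    return report


def _control_error_model(config: PipelineConfig,
                         rng: np.random.Generator) -> ErrorModel:
    controls = simulate_pileup(
        SimConfig(true_maf=0.0, depth=config.amplicon_depth,
                  input_copies=config.amplicon_input_copies,
                  error_rate=config.error_rate,
                  seed=int(rng.integers(0, 2**31 - 1)),
                  n_sites=config.n_control_sites)
    )
    return fit_error_model(controls)


def _validate(method: str, true_maf: float, config: PipelineConfig,
              error_model: ErrorModel, rng: np.random.Generator) -> MafEstimate:
    if method == "pasm":
        site = simulate_amplicon(
            SimConfig(true_maf=true_maf, depth=config.amplicon_depth,
                      input_copies=config.amplicon_input_copies,
                      error_rate=config.error_rate,
                      seed=int(rng.integers(0, 2**31 - 1)))
        )
        return AmpliconMafModel.from_site(site, error_model).fit()
    if method == "ddpcr":
        d = simulate_droplets(
            DropletSimConfig(true_maf=true_maf,
                             total_copies=config.ddpcr_total_copies,
                             n_droplets=config.ddpcr_n_droplets,
                             seed=int(rng.integers(0, 2**31 - 1)))
        )
        return DropletMafModel(d).fit()
    raise ValueError(f"unknown validation method {method!r}")


def _confirms(method: str, est: MafEstimate, config: PipelineConfig) -> bool:
    if not est.quantifiable:
        return False
    if method == "pasm":
        from .pasm import validate_candidate

        return validate_candidate(est, config.pasm_thresholds).decision \
            == "mosaic_confirmed"
    floor = max(config.ddpcr_min_ci_low, config.pasm_thresholds.homref_lower_bound)
    return est.ci_low >= floor


def analyze_tissue_panel(panel: dict, min_mu: int = 3) -> pd.DataFrame:
    """Quantify every tissue of a droplet panel and flag detections.

    A tissue is *detected* when it has at least ``min_mu`` MU droplets
    (the default limit-of-detection rule).  Returns a tidy per-tissue
    DataFrame of estimates.
    """
    rows = []
    for tissue, d in panel.items():
        est = DropletMafModel(d).fit()
        rows.append({
            "tissue": tissue,
            "mu": d.mu, "wt": d.wt, "na": d.na,
            "maf": est.map_maf, "ci_lo": est.ci_low, "ci_hi": est.ci_high,
            "detected": bool(d.mu >= min_mu),
            "is_semen_fraction": tissue in SEMEN_FRACTIONS,
        })
    return pd.DataFrame(rows)


def generate_fixtures(scenario: str, seed: int, outdir: str | Path) -> dict:
    """Write a self-contained synthetic input bundle for tests and docs.

    Scenarios
    ---------
    ``reference_cohort`` : sex-stratified cohort whose truth table is exactly
        (3, 15; 2, 451) — 18 males with 3 mosaic, 453 females with 2.
    ``negative`` : same cohort sizes, zero mosaics.
    ``germline_only`` / ``early_embryonic`` : single-subject tissue
        panels as droplet CSVs.

    Writes site/droplet/cohort tables plus a manifest JSON; identical
    scenario + seed produce identical bundles.  Returns the file map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    files: dict[str, str] = {}

    if scenario in ("reference_cohort", "negative"):
        cfg = PipelineConfig(
            seed=seed,
            cohort=CohortSimConfig(
                rate_male=0.0 if scenario == "negative" else 3 / 18,
                rate_female=0.0 if scenario == "negative" else 2 / 453,
                seed=seed,
            ),
            exact_counts=True,
        )
        cohort = _assign_exact_counts(
            simulate_cohort(cfg.cohort), cfg, rng)
        mio.write_cohort_table(cohort, outdir / "cohort.tsv")
        files["cohort"] = "cohort.tsv"
        sites = []
        for _, subj in cohort.iterrows():
            true_maf = float(subj.true_maf) if subj.is_mosaic else 0.0
            s = simulate_pileup(SimConfig(
                true_maf=true_maf, depth=cfg.depth,
                input_copies=cfg.input_copies, error_rate=cfg.error_rate,
                seed=int(rng.integers(0, 2**31 - 1)), n_sites=1))[0]
            sites.append(PileupSite(
                site_id=str(subj.subject_id), ref_count=s.ref_count,
                alt_count=s.alt_count, error_rate=s.error_rate,
                chrom="chrX", pos=153_296_777, ref="G", alt="A",
                true_maf=true_maf))
        mio.write_site_table(sites, outdir / "sites.tsv")
        files["sites"] = "sites.tsv"
    elif scenario in ("germline_only", "germline_only_sp_ot",
                      "early_embryonic", "negative_control"):
        panel = simulate_tissue_panel(scenario, seed=seed)
        mio.write_droplet_table(
            [("subject0", t, d) for t, d in panel.items()],
            outdir / "droplets.csv")
        files["droplets"] = "droplets.csv"
    else:
        raise ValueError(f"unknown fixture scenario {scenario!r}")

    mio.write_manifest({"scenario": scenario, "seed": seed, "files": files},
                       outdir / "manifest.json")
    files["manifest"] = "manifest.json"
    return files
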