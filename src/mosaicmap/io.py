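"""Readers and writers for the pipeline's plain-text interchange formats.

Site tables are TSV (site_id, chrom, pos [1-based], ref, alt, ref_count,
alt_count, error_rate, optional true_maf); droplet tables are CSV
(sample_id, tissue, mu, wt, na); cohort tables are TSV.  Confirmed calls
can additionally be written as VCFv4.2 with the MAF and its 95% interval
in INFO (keys MAF, MAF_CI95_LO, MAF_CI95_HI, CALL).  A manifest JSON
records the generating config and seed for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd

from .ddpcr import DropletData
from .screen import PileupSite

__all__ = [
    "write_site_table", "read_site_table",
    "write_droplet_table", "read_droplet_table",
    "write_cohort_table", "read_cohort_table",
    "write_vcf", "write_manifest",
]

SITE_COLUMNS = ["site_id", "chrom", "pos", "ref", "alt",
                "ref_count", "alt_count", "error_rate", "true_maf"]


def write_site_table(sites: list[PileupSite], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "ref_count": [s.ref_count for s in sites],
            "alt_count": [s.alt_count for s in sites],
            "error_rate": [s.error_rate for s in sites],
            "true_maf": [s.true_maf for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[PileupSite]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for _, r in df.iterrows():
        true_maf = r.get("true_maf")
        sites.append(
            PileupSite(
                site_id=str(r["site_id"]),
                ref_count=int(r["ref_count"]),
                alt_count=int(r["alt_count"]),
                error_rate=float(r["error_rate"]),
                chrom=str(r.get("chrom", ".")),
                pos=int(r.get("pos", 0)),
                ref=str(r.get("ref", "N")),
                alt=str(r.get("alt", "N")),
                true_maf=None if pd.isna(true_maf) else float(true_maf),
            )
        )
    return sites


def write_droplet_table(
    rows: list[tuple[str, str, DropletData]], path: str | Path
) -> None:
    """Write (sample_id, tissue, DropletData) rows as CSV."""
    df = pd.DataFrame(
        {
            "sample_id": [r[0] for r in rows],
            "tissue": [r[1] for r in rows],
            "mu": [r[2].mu for r in rows],
            "wt": [r[2].wt for r in rows],
            "na": [r[2].na for r in rows],
        }
    )
    df.to_csv(path, index=False)


def read_droplet_table(path: str | Path) -> list[tuple[str, str, DropletData]]:
    df = pd.read_csv(path)
    return [
        (str(r["sample_id"]), str(r["tissue"]),
         DropletData(mu=int(r["mu"]), wt=int(r["wt"]), na=int(r["na"])))
        for _, r in df.iterrows()
    ]


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mosaicmap
##INFO=<ID=MAF,Number=1,Type=Float,Description="MAP mutant allelic fraction">
##INFO=<ID=MAF_CI95_LO,Number=1,Type=Float,Description="95% interval lower bound">
##INFO=<ID=MAF_CI95_HI,Number=1,Type=Float,Description="95% interval upper bound">
##INFO=<ID=CALL,Number=1,Type=String,Description="Genotype/validation call">
##INFO=<ID=METHOD,Number=1,Type=String,Description="Quantification method (screen/pasm/ddpcr)">
##INFO=<ID=SUBJECT,Number=1,Type=String,Description="Subject identifier">
##contig=<ID=chrX>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(records: list[dict], path: str | Path) -> None:
    """Write call records as a minimal VCFv4.2 file (1-based coordinates).

    Each record is a dict with chrom, pos, id, ref, alt, maf, ci_low,
    ci_high, call, method and optionally subject.
    """
    lines = [_VCF_HEADER]
    for r in sorted(records, key=lambda r: (str(r["chrom"]), int(r["pos"]))):
        info = (
            f"MAF={r['maf']:.6f};MAF_CI95_LO={r['ci_low']:.6f};"
            f"MAF_CI95_HI={r['ci_high']:.6f};CALL={r['call']};METHOD={r['method']}"
        )
        if r.get("subject"):
            info += f";SUBJECT={r['subject']}"
        lines.append(
            f"{r['chrom']}\t{int(r['pos'])}\t{r.get('id', '.')}\t"
            f"{r['ref']}\t{r['alt']}\t.\tPASS\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_manifest(config: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config, indent=2, default=_jsonable,
                                     sort_keys=True) + "\n")
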