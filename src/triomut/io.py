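"""Plain-text I/O at the pipeline stage boundaries.

Intermediate contracts are TSV with headers so every stage is
independently re-runnable; reference sequences travel as FASTA, interval
tracks as BED (0-based half-open), and site tables / calls additionally
as minimal multi-sample VCF at the pipeline boundaries.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calling import CallableMask, CallResult, DnmCall, FamilyLayout
from .exceptions import MalformedInputError
from .strata import STRATA


def write_site_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    table["alt"] = table["alt"].fillna("")
    return table


def write_truth(truth, path) -> None:
    truth.records.to_csv(path, sep="\t", index=False)


def write_calls(calls: CallResult | Iterable[DnmCall] | pd.DataFrame, path) -> None:
    if isinstance(calls, CallResult):
        frame = calls.calls_frame
    elif isinstance(calls, pd.DataFrame):
        frame = calls
    else:
        frame = pd.DataFrame([c.__dict__ for c in calls])
    frame.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_rejections(rejections: pd.DataFrame, path) -> None:
    rejections.to_csv(path, sep="\t", index=False)


def write_callable_masks(masks: Mapping[str, CallableMask], path) -> None:
    rows = []
    for child, mask in masks.items():
        row = {"offspring_id": child, "total": mask.total}
        row.update(mask.by_stratum)
        rows.append(row)
    pd.DataFrame(rows, columns=["offspring_id", "total", *STRATA]).to_csv(
        path, sep="\t", index=False
    )


def read_callable_masks(path) -> dict[str, CallableMask]:
    frame = pd.read_csv(path, sep="\t")
    masks = {}
    for _, row in frame.iterrows():
        by_stratum = {label: int(row[label]) for label in STRATA}
        mask = CallableMask(offspring_id=row["offspring_id"], by_stratum=by_stratum)
        if mask.total != int(row["total"]):
            raise MalformedInputError(
                f"stratum counts do not sum to total for {row['offspring_id']}"
            )
        masks[row["offspring_id"]] = mask
    return masks


# ---------------------------------------------------------------------------
# VCF


def write_calls_vcf(calls, reference_lengths: Mapping[str, int], path) -> None:
    """Write DNM calls as a minimal VCF with the carrier in INFO."""
    frame = calls.calls_frame if isinstance(calls, CallResult) else calls
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triomut\n")
        for chrom, length in reference_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=OFFSPRING,Number=1,Type=String,Description="Carrier offspring">\n')
        fh.write('##INFO=<ID=MUTTYPE,Number=1,Type=String,Description="Strand-collapsed class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in frame.iterrows():
            info = f"OFFSPRING={row['offspring_id']}"
            if isinstance(row.get("mutation_type"), str):
                info += f";MUTTYPE={row['mutation_type'].replace('->', '_')}"
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{info}\n"
            )


def write_site_table_vcf(
    table: pd.DataFrame, layout: FamilyLayout, reference_lengths: Mapping[str, int], path
) -> None:
    """Emit a site table as a minimal multi-sample VCF (GT:DP:AD)."""
    samples = layout.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triomut\n")
        for chrom, length in reference_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Site mapping quality">\n')
        fh.write('##INFO=<ID=MNR,Number=1,Type=Integer,Description="Max non-reference sites per read">\n')
        fh.write('##FILTER=<ID=LowQual,Description="Caller low-quality flag">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for _, row in table.iterrows():
            alt = row["alt"] if row["alt"] else "."
            filt = "LowQual" if row.get("low_quality", False) else "PASS"
            info = f"MQ={row['mq']};MNR={int(row.get('max_nonref_per_read', 0))}"
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".", row["ref"], alt,
                ".", filt, info, "GT:DP:AD",
            ]
            for s in samples:
                fields.append(f"{row[f'GT_{s}']}:{int(row[f'DP_{s}'])}:{int(row[f'AD_{s}'])}")
            fh.write("\t".join(fields) + "\n")


def read_site_table_vcf(path, layout: FamilyLayout) -> pd.DataFrame:
    """Build a site table from a multi-sample VCF (real-data entry point).

    Expects biallelic SNV records carrying per-sample GT/DP/AD and a
    site-level MQ (INFO field); the LowQual filter flag maps onto the
    caller-low-quality column.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        for s in layout.samples:
            if s not in vcf_samples:
                raise MalformedInputError(f"sample {s!r} missing from VCF")
        for rec in vcf:
            if rec.alts is not None and len(rec.alts) > 1:
                raise MalformedInputError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; split first"
                )
            alt = rec.alts[0] if rec.alts else ""
            if alt and (len(rec.ref) != 1 or len(alt) != 1):
                continue  # indels are out of scope
            mq = rec.info.get("MQ", 60.0)
            low_quality = "LowQual" in (rec.filter.keys() or [])
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alt or "",
                "mq": float(mq),
                "low_quality": low_quality,
                "max_nonref_per_read": int(rec.info.get("MNR", 0)),
            }
            for s in layout.samples:
                sample = rec.samples[s]
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    gt_str = "./."
                else:
                    gt_str = "/".join(str(a) for a in gt)
                dp = sample.get("DP") or 0
                ad = sample.get("AD")
                if isinstance(ad, (tuple, list)):
                    alt_reads = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                else:
                    alt_reads = int(ad or 0)
                row[f"GT_{s}"] = gt_str
                row[f"DP_{s}"] = int(dp)
                row[f"AD_{s}"] = alt_reads
            rows.append(row)
    return pd.DataFrame(rows)
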