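"""File-format plumbing: TSV tables, minimal VCF read/write, fixtures.

All tables are tab-separated with a header row; coordinates are 1-based.
The VCF writer emits uncompressed VCF 4.2 with GT (and optionally DS)
fields; the reader accepts hard calls or dosages and returns a samples x
variants dosage frame plus hard genotype classes.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_trait_table",
    "read_vcf_genotypes",
    "write_vcf",
    "example_hits",
    "write_json",
]

_GT_TO_DOSE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1, "1/1": 2, "1|1": 2}


def read_counts_tsv(path) -> pd.DataFrame:
    """Allelic count table: sample_id, tsnp_id, chrom, pos, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample_id", "tsnp_id", "chrom", "pos", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_trait_table(path) -> pd.DataFrame:
    """Samples x traits table; first column is the sample id (index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf_genotypes(path) -> pd.DataFrame:
    """Parse a (plain-text) VCF into a samples x variants dosage frame.

    Uses GT when present, falling back to DS rounded to the nearest hard
    call for the genotype-class view; missing calls become NaN.
    """
    try:
        from cyvcf2 import VCF  # binary-format capable path

        variants, ids, samples = [], [], None
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            g = np.asarray(var.gt_types, dtype=float)  # 0,1,2,3(=unknown)
            g[g == 2] = np.nan  # cyvcf2: 2 is UNKNOWN
            g[g == 3] = 2.0
            variants.append(g)
        return pd.DataFrame(np.column_stack(variants), index=samples, columns=ids)
    except ImportError:
        pass
    rows, samples, ids = [], None, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid = fields[0], fields[1], fields[2]
            ids.append(vid if vid not in (".", "") else f"{chrom}:{pos}")
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT") if "GT" in fmt else None
            ds_i = fmt.index("DS") if "DS" in fmt else None
            doses = []
            for cell in fields[9:]:
                parts = cell.split(":")
                d = np.nan
                if gt_i is not None:
                    d = _GT_TO_DOSE.get(parts[gt_i], np.nan)
                if np.isnan(d) and ds_i is not None:
                    try:
                        d = float(parts[ds_i])
                    except ValueError:
                        d = np.nan
                doses.append(d)
            rows.append(doses)
    return pd.DataFrame(np.array(rows, dtype=float).T, index=samples, columns=ids)


def write_vcf(path, sample_ids, variants) -> None:
    """Write a minimal VCF 4.2.

    ``variants`` is an iterable of dicts with keys ``chrom``, ``pos``,
    ``id``, ``ref``, ``alt`` and ``genotypes`` — an (n_samples, 2) phased
    haplotype array.
    """
    variants = list(variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v["chrom"] for v in variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for v in variants:
            gts = "\t".join(f"{int(h1)}|{int(h2)}" for h1, h2 in v["genotypes"])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def example_hits() -> pd.DataFrame:
    """Packaged fixture of published headline GxE results (12 rows)."""
    with resources.as_file(resources.files("reqtl.data") / "example_hits.tsv") as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
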