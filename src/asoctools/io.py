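"""Readers/writers for the standard formats at the package boundary.

TSV is the canonical interchange format; VCF, BED, JASPAR PFM, FASTA and
MatrixMarket readers are adapters onto the in-memory tables.  Coordinate
conventions are enforced here and only here: VCF and SNP positions are
1-based, BED intervals 0-based half-open.

Every table writer prepends a ``#``-prefixed provenance header echoing the
package version and the full parameter set of the producing command, so the
thresholds of a run are auditable from its output alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO, motifs

from . import __version__

__all__ = [
    "read_allelic_tsv", "write_allelic_tsv",
    "read_allelic_vcf", "write_allelic_vcf",
    "read_bed", "write_bed",
    "read_pfm", "read_fasta_windows",
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "read_two_column_map", "write_two_column_map",
    "write_table", "read_table", "write_json", "read_json",
]

logger = logging.getLogger(__name__)


def _provenance(params: dict | None) -> list[str]:
    lines = [f"# asoctools {__version__}"]
    for k, v in (params or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def write_table(df: pd.DataFrame, path, params: dict | None = None,
                index: bool = False) -> None:
    """Write a TSV with a ``#`` provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a provenance-headered TSV."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# allelic count records


def write_allelic_tsv(records: pd.DataFrame, path, params: dict | None = None):
    write_table(records, path, params=params)


def read_allelic_tsv(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"snp_id", "chrom", "pos", "ref_allele", "alt_allele",
                "sample_id", "gt", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allelic count table missing columns: {sorted(missing)}")
    return df


def read_allelic_vcf(path) -> pd.DataFrame:
    """Read per-sample allelic counts from a VCF with FORMAT GT and AD.

    One record per sample x biallelic SNP site (genotypes of any zygosity are
    emitted; heterozygosity is filtered downstream).  Multiallelic and
    non-SNP sites are skipped with a counted warning.  Positions stay
    1-based.
    """
    vf = pysam.VariantFile(str(path))
    fmts = set(vf.header.formats.keys())
    for needed in ("GT", "AD"):
        if needed not in fmts:
            raise ValueError(f"VCF FORMAT lacks required field {needed}")
    rows = []
    skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
        for sample, call in rec.samples.items():
            gt = call.get("GT")
            ad = call.get("AD")
            if gt is None or gt[0] is None or ad is None or ad[0] is None:
                continue
            sep = "|" if call.phased else "/"
            rows.append(
                (
                    snp_id, rec.chrom, rec.pos, rec.ref, alts[0], sample,
                    sep.join(str(a) for a in gt),
                    int(ad[0]), int(ad[1]),
                )
            )
    if skipped:
        logger.warning("skipped %d multiallelic/non-SNP VCF sites", skipped)
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "ref_allele", "alt_allele",
                 "sample_id", "gt", "ref_count", "alt_count"],
    )
    df.attrs["n_skipped_sites"] = skipped
    return df


def write_allelic_vcf(records: pd.DataFrame, path) -> None:
    """Write an allelic count table as a minimal VCF (FORMAT GT:AD:DP)."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(records["chrom"]):
        header.contigs.add(str(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    samples = sorted(pd.unique(records["sample_id"]))
    for s in samples:
        header.add_sample(str(s))
    vf = pysam.VariantFile(str(path), "w", header=header)
    keys = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele"]
    for (snp_id, chrom, pos, ref, alt), sub in records.groupby(keys, sort=True):
        rec = vf.new_record(
            contig=str(chrom), start=int(pos) - 1, stop=int(pos),
            alleles=(ref, alt), id=str(snp_id),
        )
        per_sample = sub.set_index("sample_id")
        for s in samples:
            if s in per_sample.index:
                row = per_sample.loc[s]
                gt = tuple(int(a) for a in str(row["gt"]).replace("|", "/").split("/"))
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = "|" in str(row["gt"])
                rec.samples[s]["AD"] = (int(row["ref_count"]), int(row["alt_count"]))
                rec.samples[s]["DP"] = int(row["ref_count"]) + int(row["alt_count"])
        vf.write(rec)
    vf.close()


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path) -> pd.DataFrame:
    """Read >= 3-column BED into sorted 0-based half-open intervals."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"BED interval with end <= start at line {bad[0] + 1}")
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JASPAR PFM and FASTA windows


def read_pfm(path) -> tuple[np.ndarray, str]:
    """Read a JASPAR flat-file PFM; returns (L x 4 counts in A,C,G,T order, name)."""
    with open(path) as fh:
        try:
            m = motifs.read(fh, "jaspar")
        except Exception as exc:
            raise ValueError(f"cannot parse JASPAR PFM {path}: {exc}") from exc
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
    name = m.name or getattr(m, "matrix_id", "") or "PFM"
    return counts, str(name)


def read_fasta_windows(path) -> list[dict]:
    """Read SNP windows from FASTA; ``snp_index=K`` may ride in the description."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        snp_index = None
        for token in rec.description.split():
            if token.startswith("snp_index="):
                snp_index = int(token.split("=", 1)[1])
        out.append({"id": rec.id, "seq": str(rec.seq).upper(),
                    "snp_index": snp_index})
    return out


# ---------------------------------------------------------------------------
# count matrices and sidecar maps


def write_counts_tsv(counts: pd.DataFrame, path, params: dict | None = None):
    """Counts TSV: first column ``transcript_id``, one column per sample."""
    out = counts.copy()
    out.insert(0, "transcript_id", counts.index)
    write_table(out, path, params=params)


def read_counts_tsv(path) -> pd.DataFrame:
    df = read_table(path)
    return df.set_index("transcript_id")


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """MatrixMarket triple: ``<prefix>.mtx``, ``<prefix>.rows``, ``<prefix>.cols``."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix

    prefix = str(prefix)
    spio.mmwrite(prefix + ".mtx", csr_matrix(counts.to_numpy()))
    Path(prefix + ".rows").write_text("\n".join(map(str, counts.index)) + "\n")
    Path(prefix + ".cols").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    from scipy import io as spio

    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray()
    rows = Path(prefix + ".rows").read_text().splitlines()
    cols = Path(prefix + ".cols").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)


def write_two_column_map(mapping: pd.Series, path, names=("key", "value")) -> None:
    df = mapping.rename_axis(names[0]).rename(names[1]).reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_two_column_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return df.set_index(df.columns[0])[df.columns[1]]
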