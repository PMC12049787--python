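"""Ground-truthed synthetic data generators.

Every downstream stage of the package (allelic-imbalance calling, motif
disruption scoring, dual-species differential expression) is exercisable on
the output of this module without any external download.  Each generator
records the ground truth it planted so that tests can measure error rates
against a known answer.

All randomness flows from a single explicit seed through
:func:`numpy.random.default_rng`; identical configuration + seed yields
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ASoCSimConfig",
    "CocultureSimConfig",
    "simulate_allelic_counts",
    "simulate_coculture_counts",
    "simulate_motif_site",
    "simulate_peaks",
]

_BASES = np.array(["A", "C", "G", "T"])

#: canonical column order of an allelic count record table
RECORD_COLUMNS = [
    "snp_id", "chrom", "pos", "ref_allele", "alt_allele",
    "sample_id", "gt", "ref_count", "alt_count",
]


@dataclass
class ASoCSimConfig:
    """Configuration of the heterozygous-SNP allelic count simulator.

    The generator emulates the per-donor sampling implicit in pooling allelic
    ATAC-seq reads across heterozygous samples: each donor is heterozygous at
    a SNP with probability ``het_prob``; heterozygous donors contribute a
    read depth drawn from a negative binomial (Gamma–Poisson) with mean
    ``depth_mean`` and size ``depth_dispersion`` (``inf`` recovers Poisson),
    and alt-allele reads are binomial at an effective fraction that combines
    the true allelic fraction with a multiplicative reference-mapping bias
    ``ref_bias`` (1.0 = unbiased):

        p_eff = a / (a + ref_bias * (1 - a))

    where ``a`` is ``alt_fraction`` at truly imbalanced SNPs and 0.5
    otherwise.
    """

    n_snps: int = 10_000
    n_donors: int = 10
    het_prob: float = 0.5
    depth_mean: float = 60.0
    depth_dispersion: float = 10.0
    frac_imbalanced: float = 0.1
    alt_fraction: float = 0.65
    ref_bias: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.het_prob <= 1.0):
            raise ValueError(f"het_prob must be in [0, 1], got {self.het_prob}")
        if not (0.0 <= self.frac_imbalanced <= 1.0):
            raise ValueError(
                f"frac_imbalanced must be in [0, 1], got {self.frac_imbalanced}")
        if not (0.0 < self.alt_fraction < 1.0):
            raise ValueError(
                f"alt_fraction must be in (0, 1), got {self.alt_fraction}")
        if not (self.depth_mean > 0 and math.isfinite(self.depth_mean)):
            raise ValueError(f"depth_mean must be positive, got {self.depth_mean}")
        if not (self.ref_bias > 0 and math.isfinite(self.ref_bias)):
            raise ValueError(f"ref_bias must be positive, got {self.ref_bias}")
        if not self.depth_dispersion > 0:
            raise ValueError(
                f"depth_dispersion must be positive, got {self.depth_dispersion}")
        if self.n_snps < 1 or self.n_donors < 1:
            raise ValueError("n_snps and n_donors must be >= 1")


@dataclass
class CocultureSimConfig:
    """Configuration of the mixed human/mouse co-culture count simulator.

    Emulates a two-genotype-group experiment in which human neurons are
    co-cultured with mouse astrocytes and sequenced as one library, so each
    sample's reads split between the two species according to its cellular
    composition.  Per sample a human:mouse ratio ``r`` is drawn log-normally
    (``ratio_sd`` is the standard deviation of ``log r``; 0 makes the ratio
    exactly ``ratio_mean``), a library size likewise, and the human
    transcriptome receives an expected ``L*r/(1+r)`` share of reads, the
    mouse one ``L/(1+r)``.  Counts are negative binomial around per-transcript
    log-normal base abundances; a planted two-group effect of ``2**log2fc``
    (random sign per transcript) is applied to a fraction of transcripts in
    the first group; independent Bernoulli dropout zeroes entries.
    """

    n_transcripts_h: int = 4000
    n_transcripts_m: int = 3200
    n_samples_per_group: int = 9
    groups: tuple[str, str] = ("TT", "CC")
    ratio_mean: float = 1.0
    ratio_sd: float = 0.3
    frac_de_h: float = 0.1
    frac_de_m: float = 0.1
    log2fc: float = 1.0
    nb_dispersion: float = 0.1
    libsize_mean: float = 2e6
    libsize_sd: float = 0.2
    dropout_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_transcripts_h", "n_transcripts_m", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_de_h", "frac_de_m", "dropout_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.ratio_mean <= 0 or self.libsize_mean <= 0:
            raise ValueError("ratio_mean and libsize_mean must be positive")
        if self.ratio_sd < 0 or self.libsize_sd < 0:
            raise ValueError("ratio_sd and libsize_sd must be >= 0")
        if len(set(self.groups)) != 2:
            raise ValueError("groups must be two distinct labels")


def _nb_counts(rng: np.random.Generator, mean, size_param) -> np.ndarray:
    """Gamma–Poisson (negative binomial) draws with NB size ``size_param``.

    ``size_param = inf`` degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if np.isinf(size_param):
        return rng.poisson(mean)
    lam = rng.gamma(shape=size_param, scale=np.maximum(mean, 1e-300) / size_param)
    return rng.poisson(lam)


def simulate_allelic_counts(
    config: ASoCSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-donor allelic read counts at heterozygous SNPs.

    Returns
    -------
    records : DataFrame
        One row per (SNP, heterozygous donor) with columns
        ``snp_id, chrom, pos, ref_allele, alt_allele, sample_id, gt,
        ref_count, alt_count``.  Non-heterozygous donors emit no record.
    truth : DataFrame
        One row per SNP: ``snp_id, is_imbalanced, alt_fraction, p_eff``
        (the binomial success probability after mapping bias).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_snps, n_donors = config.n_snps, config.n_donors

    snp_ids = np.array([f"snp{i:06d}" for i in range(n_snps)])
    pos = np.arange(1, n_snps + 1, dtype=np.int64) * 1000
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4

    n_imb = int(round(config.frac_imbalanced * n_snps))
    imbalanced = np.zeros(n_snps, dtype=bool)
    imbalanced[rng.choice(n_snps, size=n_imb, replace=False)] = True
    a = np.where(imbalanced, config.alt_fraction, 0.5)
    p_eff = a / (a + config.ref_bias * (1.0 - a))

    het = rng.random((n_snps, n_donors)) < config.het_prob
    snp_i, donor_i = np.nonzero(het)
    depth = _nb_counts(
        rng, np.full(snp_i.size, config.depth_mean), config.depth_dispersion
    )
    alt_count = rng.binomial(depth, p_eff[snp_i])
    ref_count = depth - alt_count

    records = pd.DataFrame(
        {
            "snp_id": snp_ids[snp_i],
            "chrom": "chr1",
            "pos": pos[snp_i],
            "ref_allele": _BASES[ref_idx[snp_i]],
            "alt_allele": _BASES[alt_idx[snp_i]],
            "sample_id": np.array([f"donor{j:03d}" for j in range(n_donors)])[donor_i],
            "gt": "0/1",
            "ref_count": ref_count.astype(np.int64),
            "alt_count": alt_count.astype(np.int64),
        },
        columns=RECORD_COLUMNS,
    )
    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "chr1",
            "pos": pos,
            "is_imbalanced": imbalanced,
            "alt_fraction": a,
            "p_eff": p_eff,
        }
    )
    return records, truth


def simulate_coculture_counts(config: CocultureSimConfig):
    """Simulate a transcript x sample count matrix from a two-species co-culture.

    Returns
    -------
    matrix : :class:`asoctools.coculture.SpeciesCountMatrix`
        Counts with per-transcript species labels and per-sample group labels.
    truth : dict
        ``transcripts`` — DataFrame (transcript_id, species, is_de, log2fc);
        ``samples`` — DataFrame (sample_id, group, ratio, libsize).
    """
    from .coculture import SpeciesCountMatrix  # deferred: avoid import cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    n_h, n_m = config.n_transcripts_h, config.n_transcripts_m
    n_per = config.n_samples_per_group
    n_samples = 2 * n_per
    ga, gb = config.groups

    t_ids = np.array(
        [f"ENST{i:08d}" for i in range(n_h)]
        + [f"ENSMUST{i:08d}" for i in range(n_m)]
    )
    species = np.array(["human"] * n_h + ["mouse"] * n_m)
    sample_ids = np.array([f"s{j:02d}" for j in range(n_samples)])
    group = np.array([ga] * n_per + [gb] * n_per)

    # per-sample composition and library size (log-normal)
    log_r = rng.normal(np.log(config.ratio_mean), config.ratio_sd, size=n_samples)
    ratio = np.exp(log_r)
    libsize = np.exp(
        rng.normal(np.log(config.libsize_mean), config.libsize_sd, size=n_samples)
    )
    pool_h = libsize * ratio / (1.0 + ratio)
    pool_m = libsize / (1.0 + ratio)

    # per-transcript relative abundance, normalised within species
    base = np.exp(rng.normal(0.0, 1.0, size=n_h + n_m))
    w = base.copy()
    w[:n_h] /= w[:n_h].sum()
    w[n_h:] /= w[n_h:].sum()

    # planted DE: effect 2**(+-log2fc) applied in the first group
    is_de = np.zeros(n_h + n_m, dtype=bool)
    for lo, n_t, frac in ((0, n_h, config.frac_de_h), (n_h, n_m, config.frac_de_m)):
        k = int(round(frac * n_t))
        is_de[lo + rng.choice(n_t, size=k, replace=False)] = True
    sign = np.where(rng.random(n_h + n_m) < 0.5, 1.0, -1.0)
    lfc = np.where(is_de, sign * config.log2fc, 0.0)

    mu = np.empty((n_h + n_m, n_samples))
    mu[:n_h] = np.outer(w[:n_h], pool_h)
    mu[n_h:] = np.outer(w[n_h:], pool_m)
    in_a = group == ga
    mu[:, in_a] *= np.power(2.0, lfc)[:, None]

    size_param = np.inf if config.nb_dispersion == 0 else 1.0 / config.nb_dispersion
    counts = _nb_counts(rng, mu, size_param)
    if config.dropout_prob > 0:
        counts = np.where(
            rng.random(counts.shape) < config.dropout_prob, 0, counts
        )

    matrix = SpeciesCountMatrix(
        counts=pd.DataFrame(counts, index=t_ids, columns=sample_ids),
        species=pd.Series(species, index=t_ids, name="species"),
        groups=pd.Series(group, index=sample_ids, name="group"),
    )
    truth = {
        "transcripts": pd.DataFrame(
            {
                "transcript_id": t_ids,
                "species": species,
                "is_de": is_de,
                "log2fc": lfc,
            }
        ),
        "samples": pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": group,
                "ratio": ratio,
                "libsize": libsize,
            }
        ),
    }
    return matrix, truth


def simulate_motif_site(
    pwm,
    planted_allele: str | None = None,
    disrupt: bool = True,
    flank: int = 10,
    seed: int = 0,
) -> tuple[str, str, int]:
    """Embed a PWM consensus around a central SNP and optionally disrupt it.

    The returned windows have length ``2*flank + 1`` with the SNP at index
    ``flank``.  The motif consensus is planted at a random offset chosen so
    the motif covers the SNP.  The reference window carries the consensus
    base (or ``planted_allele`` if given) at the SNP; if ``disrupt`` the
    alternative window carries the PWM's lowest-probability base at that
    motif column, otherwise it equals the reference window.

    Returns ``(window_ref, window_alt, truth_offset)`` where ``truth_offset``
    is the 0-based offset of the planted motif within the window.
    """
    L = pwm.probs.shape[0]
    if flank < L:
        raise ValueError(f"flank ({flank}) must be >= motif length ({L})")
    rng = np.random.default_rng(seed)
    width = 2 * flank + 1
    snp_index = flank

    lo = max(0, snp_index - L + 1)
    hi = min(snp_index, width - L)
    offset = int(rng.integers(lo, hi + 1))

    window = _BASES[rng.integers(0, 4, size=width)]
    consensus = np.argmax(pwm.probs, axis=1)
    window[offset:offset + L] = _BASES[consensus]

    col = snp_index - offset
    if planted_allele is not None:
        window[snp_index] = planted_allele.upper()
    ref = window.copy()
    alt = window.copy()
    if disrupt:
        worst = int(np.argmin(pwm.probs[col]))
        alt[snp_index] = _BASES[worst]
    return "".join(ref), "".join(alt), offset


def simulate_peaks(
    snp_positions,
    covered_fraction: float,
    peak_halfwidth: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit non-overlapping BED intervals covering an exact fraction of SNPs.

    Parameters
    ----------
    snp_positions : DataFrame with ``chrom`` and 1-based ``pos`` columns
        (or a 1-D array of positions, assumed on one chromosome ``chr1``).
    covered_fraction : exact fraction of SNPs to place strictly inside a peak.
    peak_halfwidth : nominal half-width; peaks are shrunk at midpoints between
        neighbouring SNPs so that uncovered SNPs fall in no interval and the
        emitted intervals are pairwise disjoint.

    Returns a BED-convention DataFrame (``chrom, start, end``; 0-based
    half-open), sorted by chromosome and start.
    """
    if not (0.0 <= covered_fraction <= 1.0):
        raise ValueError(f"covered_fraction must be in [0, 1], got {covered_fraction}")
    if isinstance(snp_positions, pd.DataFrame):
        df = snp_positions[["chrom", "pos"]].copy()
    else:
        df = pd.DataFrame({"chrom": "chr1", "pos": np.asarray(snp_positions)})
    if df["pos"].duplicated().any() and df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate SNP positions")

    rng = np.random.default_rng(seed)
    n = len(df)
    k = int(round(covered_fraction * n))
    covered = np.zeros(n, dtype=bool)
    covered[rng.choice(n, size=k, replace=False)] = True
    df = df.assign(_covered=covered)

    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        p = sub["pos"].to_numpy() - 1  # 0-based SNP coordinates
        cov = sub["_covered"].to_numpy()
        for i in np.nonzero(cov)[0]:
            left = p[i] - peak_halfwidth
            right = p[i] + peak_halfwidth + 1
            if i > 0:
                left = max(left, (p[i - 1] + p[i]) // 2 + 1)
            if i < len(p) - 1:
                right = min(right, (p[i] + p[i + 1]) // 2 + 1)
            left = max(left, 0)
            rows.append((chrom, int(left), int(right)))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return peaks.sort_values(["chrom", "start"], ignore_index=True)
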