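"""Dual-species co-culture RNA-seq differential expression.

Human neurons co-cultured with mouse astrocytes are sequenced as one library
and the reads assigned to species by alignment to a concatenated
human + mouse reference.  Because the neuron:astrocyte composition varies
between wells, per-sample *species-specific* read totals act as the
correction factor: each species' transcripts are normalised against that
species' own total in each sample, which makes the two-group DE test
invariant to composition shifts.

The pipeline: species partitioning and correction factors → expression
filter (a transcript must be expressed, i.e. have a nonzero count, in at
least 75% of samples) → CPM / PCA diagnostics → per-species two-group
negative-binomial DE with BH FDR → per-gene representative transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .asoc import bh_adjust
from .nbglm import fit_nb_two_group

__all__ = [
    "SpeciesCountMatrix",
    "CorrectionFactors",
    "CocultureDE",
    "split_by_species",
    "expression_filter",
    "cpm",
    "pca_embed",
    "fit_nb_de",
    "represent_genes",
]

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse")


@dataclass
class SpeciesCountMatrix:
    """Transcript x sample counts with species and group labels.

    ``counts`` rows are transcripts, columns samples; ``species`` maps each
    transcript to ``human`` or ``mouse``; ``groups`` (optional) maps each
    sample to one of exactly two condition labels.
    """

    counts: pd.DataFrame
    species: pd.Series
    groups: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.index.equals(self.species.index):
            self.species = self.species.reindex(self.counts.index)
        if self.species.isna().any():
            missing = self.species.index[self.species.isna()][:5].tolist()
            raise ValueError(f"species label missing for transcripts: {missing}")
        bad = set(self.species.unique()) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.counts.columns)
            if self.groups.isna().any():
                raise ValueError("group label missing for some samples")
            if self.groups.nunique() != 2:
                raise ValueError("exactly two distinct group labels are required")

    @property
    def species_totals(self) -> pd.DataFrame:
        """Per-sample total counts per species (samples x species)."""
        return pd.DataFrame(
            {sp: self.counts.loc[self.species == sp].sum(axis=0) for sp in SPECIES}
        )


@dataclass
class CorrectionFactors:
    """Per-sample composition correction: human/mouse ratio and library sizes.

    ``effective_sizes`` holds, per sample, the species-specific effective
    library size (that species' read total in that sample); ``whole`` is the
    plain per-sample grand total (used by the single-offset mode the
    correction factor is meant to replace).
    """

    ratio: pd.Series
    effective_sizes: pd.DataFrame  # samples x {human, mouse}
    whole: pd.Series

    def offsets(self, species: str, mode: str = "species") -> pd.Series:
        """Log effective library size per sample for one species' transcripts."""
        if mode == "species":
            return np.log(self.effective_sizes[species])
        if mode == "whole":
            return np.log(self.whole)
        raise ValueError(f"unknown offset mode {mode!r}")


def split_by_species(matrix: SpeciesCountMatrix):
    """Partition a mixed matrix by species and compute correction factors.

    Returns ``(human_counts, mouse_counts, CorrectionFactors)``.  A sample
    with zero total in either species has an undefined composition ratio and
    raises ``ValueError`` naming the sample.
    """
    totals = matrix.species_totals
    for sp in SPECIES:
        zero = totals.index[totals[sp] == 0]
        if len(zero):
            raise ValueError(
                f"sample {zero[0]!r} has zero {sp} counts; composition ratio undefined"
            )
    human = matrix.counts.loc[matrix.species == "human"]
    mouse = matrix.counts.loc[matrix.species == "mouse"]
    cf = CorrectionFactors(
        ratio=(totals["human"] / totals["mouse"]).rename("ratio"),
        effective_sizes=totals,
        whole=totals.sum(axis=1).rename("whole"),
    )
    return human, mouse, cf


def expression_filter(counts: pd.DataFrame, min_fraction: float = 0.75) -> pd.DataFrame:
    """Retain transcripts expressed (nonzero) in >= ``min_fraction`` of samples.

    The comparison is ``expressed_samples >= min_fraction * n_samples`` on the
    exact rational (7 of 9 samples passes 0.75; 6 of 9 does not).
    """
    n = counts.shape[1]
    expressed = (counts.to_numpy() > 0).sum(axis=1)
    return counts.loc[expressed * 1.0 >= min_fraction * n]


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million against per-sample (effective) library sizes.

    With ``library_sizes=None`` each column's own total is used; supplying
    species-specific effective sizes realises the composition correction.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    return counts * (1e6 / library_sizes)


def pca_embed(
    cpm_matrix: pd.DataFrame,
    n_components: int = 2,
    log_transform: bool = True,
):
    """Sample-space PCA of (log2) CPM values.

    Transcripts are features (centred by PCA); samples are observations.
    Returns ``(coords, explained_variance_ratio)`` where ``coords`` is a
    samples x components DataFrame with columns ``PC1, PC2, ...``.
    """
    n_samples = cpm_matrix.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_samples < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds the {n_samples} samples"
        )
    x = cpm_matrix.to_numpy(dtype=float).T
    if log_transform:
        x = np.log2(x + 1.0)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x)
    # identical samples: zero total variance, ratio is 0/0 -> report 0
    evr = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return (
        pd.DataFrame(
            coords,
            index=cpm_matrix.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        evr,
    )


def fit_nb_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    offsets: pd.Series | None = None,
    dispersion=None,
    prior_df: float = 10.0,
    fdr: float = 0.05,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial DE over a count matrix.

    ``offsets`` are per-sample log effective library sizes (default: log of
    each column total).  ``log2fc`` is the first group versus the second; the
    first group is ``group_order[0]`` when given, else the label of the first
    sample.  All-zero transcripts are excluded with a warning.  Returns a
    per-transcript table ``transcript_id, log2fc, p_value, fdr, significant,
    mean_count``.
    """
    groups = pd.Series(groups).reindex(counts.columns)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    if group_order is not None:
        if set(group_order) != set(levels):
            raise ValueError("group_order does not match the labels present")
        levels = np.asarray(group_order)
    counts_a = (groups == levels[0]).sum()
    counts_b = (groups == levels[1]).sum()
    if counts_a < 2 or counts_b < 2:
        raise ValueError("each group needs >= 2 samples")

    y = counts.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    if not nonzero.all():
        logger.warning("excluding %d all-zero transcripts", int((~nonzero).sum()))
    y = y[nonzero]
    ids = counts.index[nonzero]

    if offsets is None:
        off = np.log(counts.sum(axis=0).to_numpy(dtype=float))
    else:
        off = pd.Series(offsets).reindex(counts.columns).to_numpy(dtype=float)
    if not np.all(np.isfinite(off)):
        raise ValueError("offsets must be finite (positive library sizes)")
    fit = fit_nb_two_group(
        y, (groups == levels[0]).to_numpy(), off,
        dispersion=dispersion, prior_df=prior_df,
    )
    q = bh_adjust(np.clip(fit["p_value"], np.nextafter(0, 1), 1.0))
    return pd.DataFrame(
        {
            "transcript_id": ids,
            "log2fc": fit["log2fc"],
            "p_value": fit["p_value"],
            "fdr": q,
            "significant": q < fdr,
            "mean_count": fit["mean_count"],
            "dispersion": fit["alpha"],
        }
    ).reset_index(drop=True)


def represent_genes(
    de_table: pd.DataFrame, transcript_to_gene: pd.Series | dict
) -> pd.DataFrame:
    """Flag, per gene, the top-ranked (smallest-p) transcript as representative.

    Ties at identical p prefer the higher mean expression, then the
    lexicographically smaller transcript id.  Transcripts absent from the map
    represent themselves (gene_id = transcript_id).
    """
    t2g = pd.Series(transcript_to_gene)
    out = de_table.copy()
    out["gene_id"] = out["transcript_id"].map(t2g).fillna(out["transcript_id"])
    ranked = out.sort_values(
        ["gene_id", "p_value", "mean_count", "transcript_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    rep_ids = ranked.groupby("gene_id", sort=False)["transcript_id"].first()
    out["gene_representative"] = out["transcript_id"].isin(set(rep_ids))
    return out


class CocultureDE(BaseEstimator):
    """Composition-corrected two-group DE for dual-species co-culture RNA-seq.

    Parameters
    ----------
    min_expressed_fraction : expression filter — a transcript must have a
        nonzero count in at least this fraction of samples (default 0.75).
    offset_mode : ``"species"`` (default) normalises each species' transcripts
        by that species' per-sample read total (the composition correction);
        ``"whole"`` uses a single per-sample grand total.
    fdr : BH significance threshold (``significant`` ⇔ ``fdr < threshold``).
    prior_df : dispersion-moderation weight of the trend prior.
    group_order : optional (A, B) pair fixing the log2fc orientation.

    Attributes (after :meth:`fit`)
    ------------------------------
    correction_factors_ : :class:`CorrectionFactors`
    results_ : concatenated per-transcript DE table with ``species`` (and,
        when a transcript→gene map is given, ``gene_id`` and
        ``gene_representative``).
    filtered_ids_ : index of transcripts surviving the expression filter.
    pca_ / pca_variance_ratio_ : sample coordinates and explained variance of
        the log2-CPM PCA over all filtered transcripts.
    """

    def __init__(
        self,
        min_expressed_fraction: float = 0.75,
        offset_mode: str = "species",
        fdr: float = 0.05,
        prior_df: float = 10.0,
        group_order: tuple[str, str] | None = None,
    ):
        self.min_expressed_fraction = min_expressed_fraction
        self.offset_mode = offset_mode
        self.fdr = fdr
        self.prior_df = prior_df
        self.group_order = group_order

    def fit(self, matrix: SpeciesCountMatrix, transcript_to_gene=None):
        if matrix.groups is None:
            raise ValueError("the matrix must carry two-level group labels")
        human, mouse, cf = split_by_species(matrix)
        self.correction_factors_ = cf

        tables = []
        cpm_blocks = []
        filtered_index = []
        for sp, block in (("human", human), ("mouse", mouse)):
            kept = expression_filter(block, self.min_expressed_fraction)
            filtered_index.append(kept.index)
            eff = cf.offsets(sp, mode=self.offset_mode)
            cpm_blocks.append(cpm(kept, library_sizes=np.exp(eff)))
            tab = fit_nb_de(
                kept,
                matrix.groups,
                offsets=eff,
                prior_df=self.prior_df,
                fdr=self.fdr,
                group_order=self.group_order,
            )
            tab.insert(1, "species", sp)
            tables.append(tab)
        self.filtered_ids_ = filtered_index[0].append(filtered_index[1])
        results = pd.concat(tables, ignore_index=True)
        if transcript_to_gene is not None:
            results = represent_genes(results, transcript_to_gene)
        self.results_ = results

        all_cpm = pd.concat(cpm_blocks, axis=0)
        n_comp = min(2, matrix.counts.shape[1])
        self.pca_, self.pca_variance_ratio_ = pca_embed(all_cpm, n_components=n_comp)
        return self
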