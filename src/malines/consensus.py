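"""Consensus de novo mutation calling for MA lines.

A candidate is a site that is heterozygous in exactly one jointly genotyped
line of a regime and homozygous-reference in every other line, restricted to
the regime's callable mask.  Hard filters stand in for manual read-level
curation; each rejected candidate carries exactly one primary reason tag.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import spectrum as spectrum_mod
from .errors import ConfigError
from .io_formats import HET, HOM_ALT, HOM_REF, NO_CALL, CallableMask, GenotypeMatrix
from .seqcodes import BASES

CANDIDATE_COLUMNS = [
    "regime_id", "line_id", "position", "ref_base", "alt_base", "caller",
    "status", "rejection_reason", "depth", "alt_count", "alt_fraction",
    "other_alt_count", "min_other_depth", "posterior",
]


@dataclass(frozen=True)
class FilterConfig:
    """Automated curation thresholds (stand-ins for manual inspection)."""

    min_depth: int = 10
    max_depth_fold: float = 3.0
    allele_balance_range: tuple[float, float] = (0.3, 0.7)
    cluster_window: int = 100
    min_other_line_depth: int = 5
    hom_max_alt_fraction: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.allele_balance_range
        if not (0.0 < lo < 0.5 < hi < 1.0):
            raise ConfigError("allele_balance_range must satisfy 0 < lo < 0.5 < hi < 1")
        if self.cluster_window <= 0:
            raise ConfigError("cluster_window must be positive")
        if self.min_depth < 1 or self.min_other_line_depth < 0:
            raise ConfigError("depth thresholds must be positive")
        if not (0.0 <= self.hom_max_alt_fraction < lo):
            raise ConfigError("hom_max_alt_fraction must lie in [0, allele-balance lo)")


def genotype_from_evidence(
    allele_depths: Sequence[int], ref_code: int, config: FilterConfig
) -> int:
    """Threshold genotyper for one line/site cell.

    het iff the non-reference fraction lies within the allele-balance range
    and depth >= min_depth; hom-ref (hom-alt) iff the non-reference fraction
    is below ``hom_max_alt_fraction`` (above its complement); else no-call.
    """
    ad = np.asarray(allele_depths, dtype=np.int64)
    depth = int(ad.sum())
    if depth < config.min_depth:
        return NO_CALL
    alt_fraction = (depth - int(ad[ref_code])) / depth
    lo, hi = config.allele_balance_range
    if alt_fraction <= config.hom_max_alt_fraction:
        return HOM_REF
    if lo <= alt_fraction <= hi:
        return HET
    if alt_fraction >= 1.0 - config.hom_max_alt_fraction:
        return HOM_ALT
    return NO_CALL


def genotype_array_from_evidence(
    ad: np.ndarray, ref_codes: np.ndarray, config: FilterConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized genotyper over an ``(n_lines, n_sites, 4)`` depth array.

    Returns ``(gt, alt_codes, alt_counts)`` where ``alt_codes`` is each
    cell's top non-reference allele.
    """
    n_lines, n_sites, _ = ad.shape
    rows = np.arange(n_lines)[:, None]
    cols = np.arange(n_sites)[None, :]
    ref = np.asarray(ref_codes)[None, :]
    depth = ad.sum(axis=2)
    ref_count = ad[rows, cols, ref]
    nonref = depth - ref_count
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, nonref / np.maximum(depth, 1), 0.0)
    masked = ad.copy()
    masked[rows, cols, ref] = -1
    alt_codes = masked.argmax(axis=2).astype(np.int8)
    alt_counts = np.take_along_axis(ad, alt_codes[:, :, None].astype(np.intp), axis=2)[:, :, 0]

    gt = np.full((n_lines, n_sites), NO_CALL, dtype=np.int8)
    deep = depth >= config.min_depth
    lo, hi = config.allele_balance_range
    gt[deep & (frac <= config.hom_max_alt_fraction)] = HOM_REF
    gt[deep & (frac >= lo) & (frac <= hi)] = HET
    gt[deep & (frac >= 1.0 - config.hom_max_alt_fraction)] = HOM_ALT
    return gt, alt_codes, alt_counts


def callable_sites(gt: np.ndarray, mask: np.ndarray | None = None) -> int:
    """Sites genotyped (non-missing) in every line, optionally within a mask."""
    if gt.ndim != 2 or gt.shape[0] < 1:
        raise ValueError("need a (n_lines, n_sites) genotype array with >= 1 line")
    ok = (gt != NO_CALL).all(axis=0)
    if mask is not None:
        ok &= mask
    return int(ok.sum())


def consensus_candidates(
    matrix: GenotypeMatrix,
    regime_samples: Sequence[str],
    mask: CallableMask,
    regime_id: str = "R1",
) -> pd.DataFrame:
    """Consensus candidates from a (VCF-derived) genotype matrix.

    A site yields a candidate for line *i* iff line *i* is het and every
    other regime line is hom-ref, the site is callable, and every line is
    genotyped.  Sites where any other line is het or hom-alt are excluded
    entirely (inherited founder variation).
    """
    idx = matrix.sample_index(regime_samples)
    gt = matrix.gt[idx]
    n_lines = len(idx)
    callable_mask = np.zeros(matrix.n_sites, dtype=bool)
    for chrom in np.unique(matrix.chrom.astype(str)):
        sel = matrix.chrom.astype(str) == chrom
        callable_mask[sel] = mask.contains(chrom, matrix.positions[sel])
    het_count = (gt == HET).sum(axis=0)
    homref_count = (gt == HOM_REF).sum(axis=0)
    site_ok = callable_mask & (het_count == 1) & (homref_count == n_lines - 1)
    sites = np.flatnonzero(site_ok)
    focal = (gt[:, sites] == HET).argmax(axis=0)

    rows = []
    for s, f in zip(sites, focal):
        depth = alt_count = frac = other_alt = min_other = np.nan
        if matrix.ad is not None:
            ref_d, alt_d = matrix.ad[idx[f], s]
            depth = int(ref_d + alt_d)
            alt_count = int(alt_d)
            frac = alt_count / depth if depth else 0.0
            other_alt = 0
            others = np.delete(idx, f)
            min_other = int(matrix.ad[others, s].sum(axis=1).min())
        rows.append(
            (
                regime_id, regime_samples[f], int(matrix.positions[s]),
                str(matrix.ref[s]), str(matrix.alt[s]), "consensus",
                "candidate", None, depth, alt_count, frac, other_alt,
                min_other, np.nan,
            )
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def consensus_from_evidence(
    ad: np.ndarray,
    ref_codes: np.ndarray,
    line_names: Sequence[str],
    mask_dense: np.ndarray,
    config: FilterConfig,
    regime_id: str = "R1",
) -> pd.DataFrame:
    """Consensus candidates straight from dense simulated read evidence."""
    gt, alt_codes, alt_counts = genotype_array_from_evidence(ad, ref_codes, config)
    n_lines, n_sites = gt.shape
    het_count = (gt == HET).sum(axis=0)
    homref_count = (gt == HOM_REF).sum(axis=0)
    site_ok = mask_dense & (het_count == 1) & (homref_count == n_lines - 1)
    sites = np.flatnonzero(site_ok)
    focal = (gt[:, sites] == HET).argmax(axis=0)
    depth = ad.sum(axis=2)

    rows = []
    for s, f in zip(sites, focal):
        d = int(depth[f, s])
        ac = int(alt_counts[f, s])
        ref_c = int(ref_codes[s])
        nonref = d - int(ad[f, s, ref_c])
        others = np.delete(np.arange(n_lines), f)
        rows.append(
            (
                regime_id, line_names[f], int(s) + 1, BASES[ref_c],
                BASES[int(alt_codes[f, s])], "consensus", "candidate", None,
                d, ac, ac / d if d else 0.0, nonref - ac,
                int(depth[others, s].min()), np.nan,
            )
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


_FILTER_ORDER = (
    "low_depth", "high_depth", "allele_balance", "multiallelic", "low_other_depth"
)


def apply_filters(
    candidates: pd.DataFrame,
    config: FilterConfig,
    mean_depth_by_line: Mapping[str, float],
) -> pd.DataFrame:
    """Label each candidate accepted/rejected with one primary reason.

    Per-candidate filters run in a fixed precedence order; the cluster
    filter then rejects *all* same-line candidates within
    ``cluster_window`` bp of each other among the survivors.
    """
    df = candidates.copy().reset_index(drop=True)
    if df.empty:
        df["status"] = pd.Series(dtype=object)
        df["rejection_reason"] = pd.Series(dtype=object)
        return df
    reasons: list[str | None] = []
    for row in df.itertuples():
        reason = None
        mean_depth = mean_depth_by_line.get(row.line_id, np.nan)
        if not np.isnan(row.depth):
            lo, hi = config.allele_balance_range
            if row.depth < config.min_depth:
                reason = "low_depth"
            elif (
                np.isfinite(mean_depth)
                and row.depth > config.max_depth_fold * mean_depth
            ):
                reason = "high_depth"
            elif not (lo <= row.alt_fraction <= hi):
                reason = "allele_balance"
            elif row.other_alt_count >= 2:
                reason = "multiallelic"
            elif row.min_other_depth < config.min_other_line_depth:
                reason = "low_other_depth"
        reasons.append(reason)
    df["rejection_reason"] = reasons
    df["status"] = np.where(df["rejection_reason"].isna(), "accepted", "rejected")

    # cluster filter: pairs of surviving candidates too close in one line
    for line_id, group in df[df.status == "accepted"].groupby("line_id"):
        pos = group["position"].sort_values()
        close = pos.diff() <= config.cluster_window
        bad = set(pos.index[close]) | set(pos.index[close.shift(-1, fill_value=False)])
        for i in bad:
            df.loc[i, "status"] = "rejected"
            df.loc[i, "rejection_reason"] = "cluster"
    return df


def acceptance_rate_table(candidates: pd.DataFrame) -> pd.DataFrame:
    """Accepted/rejected tallies per regime with a chi-squared homogeneity p.

    The chi-squared column is repeated on every row for convenience; it
    tests whether the acceptance rate differs between regimes.
    """
    tab = (
        candidates.groupby("regime_id")["status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["accepted", "rejected"], fill_value=0)
    )
    tab["n_candidates"] = tab.sum(axis=1)
    tab["acceptance_rate"] = tab["accepted"] / tab["n_candidates"].replace(0, np.nan)
    counts = tab[["accepted", "rejected"]].to_numpy()
    if counts.shape[0] >= 2 and (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
        res = spectrum_mod.chisq_contingency(counts, B=2000, seed=0)
        tab["chisq"] = res.statistic
        tab["p_simulated"] = res.p_simulated
    else:
        tab["chisq"] = np.nan
        tab["p_simulated"] = np.nan
    return tab.reset_index()
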