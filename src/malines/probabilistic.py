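"""Probabilistic de novo mutation calling (simplified accuMUlate-style model).

Per site, the model weighs L+1 hypotheses: "line i carries a de novo
heterozygote while all other lines are homozygous reference" (prior theta
per line) against "no line mutated" (prior 1 - L*theta).  Read counts are
reduced to biallelic totals: under a heterozygote, non-reference reads
arise with probability 0.5; under homozygous reference, with the sequencing
error rate epsilon.  All arithmetic is in log space (no underflow for
depths up to 1e4).

This is a deliberate reduction of the published Dirichlet-multinomial
pedigree model to a binomial two-hypothesis form; it is sufficient for the
downstream statistics but does not reproduce that software's numerics.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .consensus import CANDIDATE_COLUMNS
from .errors import ConfigError
from .seqcodes import BASES

HOM_REF_P = "hom_ref"
HET_P = "het"
HOM_ALT_P = "hom_alt"


@dataclass(frozen=True)
class ProbModelParams:
    theta: float = 1e-7
    seq_error: float = 1e-3
    posterior_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 0.1):
            raise ConfigError("theta must satisfy 0 < theta << 1")
        if not (0.0 <= self.seq_error < 0.5):
            raise ConfigError("seq_error must lie in [0, 0.5)")
        if not (0.0 < self.posterior_cutoff < 1.0):
            raise ConfigError("posterior_cutoff must lie in (0, 1)")


def _alt_probability(genotype: str, epsilon: float) -> float:
    if genotype == HOM_REF_P:
        return epsilon
    if genotype == HET_P:
        return 0.5
    if genotype == HOM_ALT_P:
        return 1.0 - epsilon
    raise ValueError(f"unknown genotype {genotype!r}")


def genotype_log_likelihood(
    alt_count: int | np.ndarray, depth: int | np.ndarray, genotype: str, epsilon: float
) -> np.ndarray:
    """log P(alt_count | depth, genotype); exactly 0 at depth 0 (no data)."""
    p = _alt_probability(genotype, epsilon)
    return stats.binom.logpmf(alt_count, depth, p)


def genotype_likelihood(
    alt_count: int, depth: int, genotype: str, epsilon: float
) -> float:
    """Binomial likelihood of the observed alt count under one genotype."""
    return float(np.exp(genotype_log_likelihood(alt_count, depth, genotype, epsilon)))


def site_mutation_posteriors(
    alt_counts: np.ndarray, depths: np.ndarray, params: ProbModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-line posteriors of the one-mutant-line hypothesis at each site.

    Parameters
    ----------
    alt_counts, depths
        ``(n_lines,)`` or ``(n_lines, n_sites)`` integer arrays.

    Returns
    -------
    posteriors
        Same shape as the input; ``posteriors[i]`` is the posterior that
        line *i* is the (single) mutated line.
    null_weight
        Posterior of "no line mutated", one value per site.  Together the
        L+1 weights sum to 1 at every site.
    """
    alt = np.asarray(alt_counts)
    dep = np.asarray(depths)
    squeeze = alt.ndim == 1
    if squeeze:
        alt = alt[:, None]
        dep = dep[:, None]
    n_lines = alt.shape[0]
    if n_lines < 2:
        raise ValueError("need >= 2 lines")

    ll_homref = genotype_log_likelihood(alt, dep, HOM_REF_P, params.seq_error)
    ll_het = genotype_log_likelihood(alt, dep, HET_P, params.seq_error)
    total_homref = ll_homref.sum(axis=0)  # (n_sites,)

    log_theta = np.log(params.theta)
    log_null_prior = np.log1p(-n_lines * params.theta)
    scores = log_theta + total_homref[None, :] + ll_het - ll_homref
    null_score = log_null_prior + total_homref
    stacked = np.vstack([scores, null_score[None, :]])
    if not np.isfinite(stacked).any(axis=0).all():
        raise ValueError("unscorable site: all hypotheses have zero likelihood")
    log_norm = logsumexp(stacked, axis=0)
    posteriors = np.exp(scores - log_norm[None, :])
    null_weight = np.exp(null_score - log_norm)
    if squeeze:
        return posteriors[:, 0], null_weight[0]
    return posteriors, null_weight


def call_probabilistic(
    ad: np.ndarray,
    ref_codes: np.ndarray,
    line_names: Sequence[str],
    mask_dense: np.ndarray,
    params: ProbModelParams,
    regime_id: str = "R1",
) -> pd.DataFrame:
    """Probabilistic candidates from dense read evidence.

    Candidates are (line, site) pairs whose single-mutant posterior reaches
    ``posterior_cutoff`` at callable sites; they then go through the same
    hard filters as the consensus arm.
    """
    n_lines, n_sites, _ = ad.shape
    rows_idx = np.arange(n_lines)[:, None]
    cols_idx = np.arange(n_sites)[None, :]
    ref = np.asarray(ref_codes)[None, :]
    depth = ad.sum(axis=2)
    nonref = depth - ad[rows_idx, cols_idx, ref]

    # only sites with some non-reference evidence can clear any sane cutoff
    interesting = np.flatnonzero(mask_dense & (nonref.sum(axis=0) > 0))
    if len(interesting) == 0:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    post, _ = site_mutation_posteriors(
        nonref[:, interesting], depth[:, interesting], params
    )
    hit_line, hit_site = np.nonzero(post >= params.posterior_cutoff)

    masked = ad.copy()
    masked[rows_idx, cols_idx, ref] = -1
    alt_codes = masked.argmax(axis=2)

    rows = []
    for f, k in zip(hit_line, hit_site):
        s = int(interesting[k])
        d = int(depth[f, s])
        ac = int(ad[f, s, alt_codes[f, s]])
        others = np.delete(np.arange(n_lines), f)
        rows.append(
            (
                regime_id, line_names[f], s + 1, BASES[int(ref_codes[s])],
                BASES[int(alt_codes[f, s])], "probabilistic", "candidate",
                None, d, ac, ac / d if d else 0.0,
                int(nonref[f, s]) - ac, int(depth[others, s].min()),
                float(post[f, k]),
            )
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def merge_cohorts(
    consensus_set: pd.DataFrame, probabilistic_set: pd.DataFrame, mode: str = "shared"
) -> pd.DataFrame:
    """Combine the two callers' accepted candidates.

    ``shared`` keeps the intersection on (line, position, alt);
    ``union`` keeps everything, marking overlaps ``caller="both"``.
    """
    if mode not in ("shared", "union"):
        raise ValueError(f"mode must be 'shared' or 'union', got {mode!r}")
    key = ["line_id", "position", "alt_base"]
    cons = consensus_set.copy()
    prob = probabilistic_set.copy()
    cons_keys = set(map(tuple, cons[key].itertuples(index=False))) if len(cons) else set()
    prob_keys = set(map(tuple, prob[key].itertuples(index=False))) if len(prob) else set()
    shared_keys = cons_keys & prob_keys

    def _is_shared(df: pd.DataFrame) -> pd.Series:
        if df.empty:
            return pd.Series(dtype=bool)
        return df[key].apply(tuple, axis=1).isin(shared_keys)

    if mode == "shared":
        out = cons[_is_shared(cons)].copy()
        out["caller"] = "both"
        return out.reset_index(drop=True)
    only_prob = prob[~_is_shared(prob)] if len(prob) else prob
    frames = [df for df in (cons, only_prob) if len(df)]
    out = pd.concat(frames, ignore_index=True) if frames else cons
    if len(out):
        out.loc[_is_shared(out).to_numpy(), "caller"] = "both"
    return out.sort_values(["line_id", "position"]).reset_index(drop=True)
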