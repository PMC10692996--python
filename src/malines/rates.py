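"""Per-site per-generation mutation rates and regime-comparison GLMs.

The point estimator is mu = m / (L * n * T): m mutations over L lines,
n callable sites and T generations, evaluated in exact rational arithmetic
before conversion to float.  Regime contrasts are likelihood-ratio tests
from binomial and Poisson generalized linear models.

Note on the Poisson model: callable sites enter as a log(n*T) offset, the
standard rate parameterization.  Using them as prior weights instead (as
some analyses do) inflates the statistic by orders of magnitude and is
deliberately not reproduced here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats


def _fit_glm(endog, exog, family, offset=None):
    # a regime-saturated model (one observation per regime) triggers
    # harmless perfect-separation / zero-df warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(endog, exog, family=family, offset=offset).fit()


@dataclass
class MutationRateEstimate:
    """mu = m/(L*n*T) with its inputs; ``se_mu`` only at regime level."""

    m: int
    L: int
    n: int
    T: int
    mu: float
    se_mu: float | None = None

    def scaled(self, scale: float = 1e8) -> float:
        """mu on a printing scale (default 1e-8 units)."""
        return self.mu * scale


@dataclass
class RegimeComparison:
    statistic: float
    df: int
    p: float
    model: str


def mutation_rate(m: int, L: int, n: int, T: int) -> MutationRateEstimate:
    """Exact-rational mutation rate estimate; line-level when ``L == 1``."""
    if min(L, n, T) < 1:
        raise ZeroDivisionError("L, n and T must all be >= 1")
    if m < 0:
        raise ValueError("m must be >= 0")
    mu = float(Fraction(m, L * n * T))
    return MutationRateEstimate(m=m, L=L, n=n, T=T, mu=mu)


def regime_mean_rate(
    per_line_counts: Sequence[int], n: int, T: int
) -> MutationRateEstimate:
    """Mean of per-line rates with SE = sample SD of per-line mu / sqrt(L)."""
    counts = np.asarray(per_line_counts, dtype=np.int64)
    L = len(counts)
    if L < 2:
        raise ValueError("need >= 2 lines for a regime-level estimate")
    per_line_mu = np.array([mutation_rate(int(m), 1, n, T).mu for m in counts])
    mean_mu = float(per_line_mu.mean())
    if counts.min() == counts.max():  # avoid float fuzz: identical lines => SE 0
        se = 0.0
    else:
        se = float(per_line_mu.std(ddof=1) / np.sqrt(L))
    return MutationRateEstimate(
        m=int(counts.sum()), L=L, n=n, T=T, mu=mean_mu, se_mu=se
    )


def _flatten(
    counts_per_regime: Mapping[str, Sequence[int]],
    n_per_regime: Mapping[str, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    regimes = list(counts_per_regime)
    if len(regimes) < 2:
        raise ValueError("need >= 2 regimes to compare")
    m, n, labels = [], [], []
    for r in regimes:
        for c in counts_per_regime[r]:
            m.append(int(c))
            n.append(int(n_per_regime[r]))
            labels.append(r)
    return np.array(m, float), np.array(n, float), np.array(labels), regimes


def _design(labels: np.ndarray, regimes: list[str]) -> np.ndarray:
    cols = [np.ones(len(labels))]
    for r in regimes[1:]:
        cols.append((labels == r).astype(float))
    return np.column_stack(cols)


def compare_regimes_binomial(
    counts_per_regime: Mapping[str, Sequence[int]],
    n_per_regime: Mapping[str, int],
) -> RegimeComparison:
    """LR test of a regime-factor binomial GLM against intercept-only.

    Each line contributes a (mutated sites, non-mutated sites) response with
    its regime's callable-site total as the number of trials.
    """
    m, n, labels, regimes = _flatten(counts_per_regime, n_per_regime)
    df = len(regimes) - 1
    if m.sum() == 0:
        return RegimeComparison(statistic=0.0, df=df, p=1.0, model="binomial")
    endog = np.column_stack([m, n - m])
    full = _fit_glm(endog, _design(labels, regimes), sm.families.Binomial())
    null = _fit_glm(endog, np.ones((len(m), 1)), sm.families.Binomial())
    lr = float(2.0 * (full.llf - null.llf))
    lr = max(lr, 0.0)
    return RegimeComparison(
        statistic=lr, df=df, p=float(stats.chi2.sf(lr, df)), model="binomial"
    )


def compare_regimes_poisson(
    counts_per_regime: Mapping[str, Sequence[int]],
    n_per_regime: Mapping[str, int],
    T: int = 1,
) -> RegimeComparison:
    """LR test of a regime-factor Poisson GLM with a log(n*T) exposure offset."""
    m, n, labels, regimes = _flatten(counts_per_regime, n_per_regime)
    df = len(regimes) - 1
    if m.sum() == 0:
        return RegimeComparison(statistic=0.0, df=df, p=1.0, model="poisson")
    offset = np.log(n * T)
    full = _fit_glm(m, _design(labels, regimes), sm.families.Poisson(), offset=offset)
    null = _fit_glm(m, np.ones((len(m), 1)), sm.families.Poisson(), offset=offset)
    lr = float(2.0 * (full.llf - null.llf))
    lr = max(lr, 0.0)
    return RegimeComparison(
        statistic=lr, df=df, p=float(stats.chi2.sf(lr, df)), model="poisson"
    )


def bootstrap_p_binomial(
    counts_per_regime: Mapping[str, Sequence[int]],
    n_per_regime: Mapping[str, int],
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Seeded parametric-bootstrap p-value for the binomial regime contrast.

    Useful when per-regime counts are too small to trust the asymptotic
    chi-square reference.
    """
    observed = compare_regimes_binomial(counts_per_regime, n_per_regime).statistic
    m, n, labels, regimes = _flatten(counts_per_regime, n_per_regime)
    p_null = m.sum() / n.sum()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        sim = rng.binomial(n.astype(np.int64), p_null)
        sim_counts = {r: sim[labels == r].tolist() for r in regimes}
        stat = compare_regimes_binomial(sim_counts, n_per_regime).statistic
        if stat >= observed - 1e-9:
            hits += 1
    return hits / B
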