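"""Strand-collapsed substitution spectrum and chi-squared tests.

The twelve ordered single-base substitutions collapse into six classes by
identifying each change with its reverse complement.  Transitions are the
first two classes; the remaining four are transversions.  Chi-squared
p-values can be simulated by seeded Monte-Carlo multinomial draws.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import MalinesError

#: the six strand-collapsed substitution classes, transitions first
TYPES = ("A:T>G:C", "G:C>A:T", "A:T>C:G", "G:C>T:A", "A:T>T:A", "G:C>C:G")
TRANSITION_TYPES = TYPES[:2]

_CLASS = {
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
}


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Map a substitution to its strand-collapsed class.

    Returns ``(class, is_transition)``.  Raises ``ValueError`` for
    non-ACGT input or ``ref == alt``.
    """
    key = (ref, alt)
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if key not in _CLASS:
        raise ValueError(f"non-ACGT substitution {ref}>{alt}")
    cls = _CLASS[key]
    return cls, cls in TRANSITION_TYPES


@dataclass
class SpectrumCounts:
    """Tallies of the six substitution classes with transition/transversion pools."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for t in TYPES:
            self.counts.setdefault(t, 0)

    @property
    def ts(self) -> int:
        return sum(self.counts[t] for t in TRANSITION_TYPES)

    @property
    def tv(self) -> int:
        return sum(self.counts[t] for t in TYPES[2:])

    @property
    def total(self) -> int:
        return self.ts + self.tv

    @property
    def ts_tv_ratio(self) -> float | None:
        """Ts:Tv ratio, or ``None`` when there are no transversions."""
        if self.tv == 0:
            return None
        return self.ts / self.tv

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[t] for t in TYPES], dtype=np.int64)


def tally(pairs: Iterable[tuple[str, str]]) -> SpectrumCounts:
    """Tally (ref, alt) pairs into :class:`SpectrumCounts`."""
    counts = {t: 0 for t in TYPES}
    for ref, alt in pairs:
        cls, _ = classify_substitution(ref, alt)
        counts[cls] += 1
    return SpectrumCounts(counts)


@dataclass
class ChisqResult:
    statistic: float
    p_simulated: float
    B: int
    seed: int


def chisq_gof(
    observed: Sequence[int],
    expected_proportions: Sequence[float] | None = None,
    B: int = 10_000,
    seed: int = 0,
    add_one: bool = False,
) -> ChisqResult:
    """Pearson goodness-of-fit with a Monte-Carlo simulated p-value.

    Parameters
    ----------
    observed
        Non-negative category counts, not all zero.
    expected_proportions
        Expected proportions (summing to 1); equal proportions if ``None``.
    B
        Number of seeded multinomial replicates for the p-value.
    add_one
        Use the (1 + #{sim >= obs}) / (B + 1) convention instead of the
        plain Monte-Carlo fraction.
    """
    obs = np.asarray(observed, dtype=np.int64)
    if (obs < 0).any():
        raise ValueError("negative counts")
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all counts are zero")
    if B < 1:
        raise ValueError("B must be >= 1")
    if expected_proportions is None:
        props = np.full(len(obs), 1.0 / len(obs))
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("expected proportions must sum to 1")
    expected = n * props
    if (expected == 0).any():
        raise ValueError("zero expected cell")
    statistic = float(((obs - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, props, size=B)
    sim = ((draws - expected) ** 2 / expected).sum(axis=1)
    hits = int((sim >= statistic - 1e-9).sum())
    p = (hits + 1) / (B + 1) if add_one else hits / B
    return ChisqResult(statistic=statistic, p_simulated=float(p), B=B, seed=seed)


def chisq_contingency(
    table: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
    add_one: bool = False,
) -> ChisqResult:
    """Pearson independence test on a 2-D table, p-value by Monte-Carlo.

    Replicate tables are multinomial draws with the independence cell
    probabilities implied by the observed margins; each replicate's X^2 is
    computed against its own margins (parametric bootstrap).
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D non-negative array")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    if (rows == 0).any() or (cols == 0).any() or n == 0:
        raise MalinesError("degenerate margins in contingency table")
    statistic, _, _, _ = stats.chi2_contingency(obs, correction=False)
    statistic = float(statistic)

    probs = np.outer(rows, cols).astype(float) / (n * n)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs.ravel(), size=B).reshape(B, *obs.shape)
    r = draws.sum(axis=2, keepdims=True)
    c = draws.sum(axis=1, keepdims=True)
    expected = r * c / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (draws - expected) ** 2 / expected, 0.0)
    sim = contrib.sum(axis=(1, 2))
    hits = int((sim >= statistic - 1e-9).sum())
    p = (hits + 1) / (B + 1) if add_one else hits / B
    return ChisqResult(statistic=statistic, p_simulated=float(p), B=B, seed=seed)
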