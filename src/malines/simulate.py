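"""Forward simulation of a mutation-accumulation (MA) experiment.

Produces a diploid founder genome, regime/line/generation structure with
single-pair transmission, per-line read evidence as per-site allele depths,
per-regime callable masks, a toy gene annotation and a line-survival table —
all with known ground truth, so every downstream stage can be validated
without external data.

Model notes
-----------
* Per-line observable mutation counts are Poisson with mean
  ``mu * genome_length * generations``.  Mendelian transmission through the
  single-pair bottlenecks is applied at draw time: raw per-generation influx
  is thinned by ``0.5**(T - g)``, with the influx scaled so the surviving
  total keeps the stated mean; the generation of origin of surviving
  mutations is therefore distributed proportionally to ``0.5**(T - g)``.
* Depth is negative-binomial (mean per regime, shared dispersion).
* Heterozygous allele balance is symmetric binomial at 0.5 before error;
  each read is misread with probability ``seq_error`` (uniform over the
  other three bases).
* Only single-nucleotide mutations are simulated; each mutation is
  heterozygous in exactly one line.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats, spectrum
from .effects import Annotation, Transcript
from .errors import ConfigError
from .io_formats import CallableMask
from .seqcodes import BASES, decode

_MASK_BLOCK = 200  # bp; granularity of the simulated callable mask


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated MA experiment.  ``seed`` is mandatory."""

    seed: int
    genome_length: int = 1_000_000
    gc_content: float = 0.38
    n_regimes: int = 3
    lines_per_regime: int = 6
    generations: int = 3
    mu_per_regime: tuple[float, ...] = (0.74e-8, 0.30e-8, 1.20e-8)
    ts_fraction: float = 0.9
    mean_depth_per_regime: tuple[float, ...] = (68.5, 76.6, 52.9)
    depth_dispersion: float = 5.0
    seq_error: float = 1e-3
    callable_fraction_target: float = 0.74
    extinction_prob_per_regime: tuple[float, ...] = (0.02, 0.05, 0.3)
    founded_lines_per_regime: int = 60
    restrict_to_callable: bool = True

    def __post_init__(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not (math.isfinite(value) and 0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be a probability in [0,1], got {value}")

        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        if self.genome_length < 10_000:
            raise ConfigError("genome_length must be >= 10^4")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if self.n_regimes < 1 or self.lines_per_regime < 1:
            raise ConfigError("n_regimes and lines_per_regime must be >= 1")
        if self.founded_lines_per_regime < self.lines_per_regime:
            raise ConfigError("founded_lines_per_regime < lines_per_regime")
        _prob("gc_content", self.gc_content)
        _prob("ts_fraction", self.ts_fraction)
        _prob("seq_error", self.seq_error)
        _prob("callable_fraction_target", self.callable_fraction_target)
        for name, per_regime in (
            ("mu_per_regime", self.mu_per_regime),
            ("mean_depth_per_regime", self.mean_depth_per_regime),
            ("extinction_prob_per_regime", self.extinction_prob_per_regime),
        ):
            if len(per_regime) != self.n_regimes:
                raise ConfigError(f"{name} must have n_regimes={self.n_regimes} entries")
        for mu in self.mu_per_regime:
            if not (math.isfinite(mu) and mu >= 0):
                raise ConfigError(f"mutation rates must be finite and >= 0, got {mu}")
        for d in self.mean_depth_per_regime:
            if not (math.isfinite(d) and d >= 0):
                raise ConfigError(f"mean depths must be finite and >= 0, got {d}")
        for p in self.extinction_prob_per_regime:
            _prob("extinction_prob_per_regime", p)
        if not (math.isfinite(self.depth_dispersion) and self.depth_dispersion > 0):
            raise ConfigError("depth_dispersion must be finite and > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError("config file must set a seed")
        for key in ("mu_per_regime", "mean_depth_per_regime", "extinction_prob_per_regime"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Experiment:
    """Everything one simulated MA experiment produced."""

    config: SimulationConfig
    reference_codes: np.ndarray
    regimes: list[str]
    lines: dict[str, list[str]]
    truth: pd.DataFrame
    masks: dict[str, CallableMask]
    evidence: dict[str, np.ndarray] | None
    annotation: Annotation
    survival: pd.DataFrame
    chrom: str = "chr1"

    @property
    def reference(self) -> str:
        return decode(self.reference_codes)

    def write(self, out_dir: str | Path) -> None:
        """Write reference FASTA, masks (BED), truth/survival TSV, GFF3."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta({self.chrom: self.reference}, out / "reference.fa")
        for regime, mask in self.masks.items():
            io_formats.write_bed(mask, out / f"callable_{regime}.bed")
        io_formats.write_tsv(self.truth, out / "truth.tsv")
        io_formats.write_tsv(self.survival, out / "survival.tsv")
        self.annotation.to_gff3(out / "annotation.gff3")


def _transition(codes: np.ndarray) -> np.ndarray:
    return codes ^ 2  # A<->G, C<->T under the ACGT coding


def _draw_alt_codes(rng: np.random.Generator, ref_codes: np.ndarray, ts_fraction: float) -> np.ndarray:
    """Alt base codes: transition w.p. ts_fraction, else one of 2 transversions."""
    n = len(ref_codes)
    is_ts = rng.random(n) < ts_fraction
    alts = _transition(ref_codes)
    # the two transversion partners of base b are the complementary pair {b^1, b^3}
    pick = rng.integers(0, 2, size=n)
    tv = np.where(pick == 0, ref_codes ^ 1, ref_codes ^ 3)
    alts[~is_ts] = tv[~is_ts]
    return alts.astype(np.int8)


def _draw_mask(
    rng: np.random.Generator, genome_length: int, target: float, chrom: str
) -> CallableMask:
    if target >= 1.0:
        dense = np.ones(genome_length, dtype=bool)
    else:
        n_blocks = (genome_length + _MASK_BLOCK - 1) // _MASK_BLOCK
        block_ok = rng.random(n_blocks) < target
        dense = np.repeat(block_ok, _MASK_BLOCK)[:genome_length]
    return CallableMask.from_boolean(dense, chrom)


def _sample_positions(
    rng: np.random.Generator, k: int, genome_length: int, mask_dense: np.ndarray | None
) -> np.ndarray:
    """k distinct 1-based positions, restricted to the mask when given."""
    chosen: set[int] = set()
    guard = 0
    while len(chosen) < k:
        draw = rng.integers(1, genome_length + 1, size=max(4 * k, 16))
        for pos in draw:
            pos = int(pos)
            if mask_dense is not None and not mask_dense[pos - 1]:
                continue
            chosen.add(pos)
            if len(chosen) == k:
                break
        guard += 1
        if guard > 1000:  # pragma: no cover - pathological mask
            raise ConfigError("cannot place mutations: callable mask too sparse")
    return np.array(sorted(chosen), dtype=np.int64)[:k]


def _noisy_allele_depths(
    rng: np.random.Generator,
    depth: np.ndarray,
    ref_codes: np.ndarray,
    seq_error: float,
) -> np.ndarray:
    """Homozygous-reference read evidence with uniform sequencing error."""
    n_lines, n_sites = depth.shape
    err = rng.binomial(depth, seq_error)
    e1 = rng.binomial(err, 1.0 / 3.0)
    e2 = rng.binomial(err - e1, 0.5)
    e3 = err - e1 - e2
    ad = np.zeros((n_lines, n_sites, 4), dtype=np.int32)
    rows = np.arange(n_lines)[:, None]
    cols = np.arange(n_sites)[None, :]
    ref = ref_codes[None, :]
    ad[rows, cols, ref] = depth - err
    ad[rows, cols, (ref + 1) % 4] = e1
    ad[rows, cols, (ref + 2) % 4] = e2
    ad[rows, cols, (ref + 3) % 4] = e3
    return ad


def _het_cell(
    rng: np.random.Generator, depth: int, ref_code: int, alt_code: int, seq_error: float
) -> np.ndarray:
    """Allele depths for one heterozygous line/site cell."""
    cell = np.zeros(4, dtype=np.int64)
    alt_true = rng.binomial(depth, 0.5)
    ref_true = depth - alt_true
    for true_code, n_true in ((ref_code, ref_true), (alt_code, alt_true)):
        n_err = rng.binomial(n_true, seq_error)
        cell[true_code] += n_true - n_err
        others = [c for c in range(4) if c != true_code]
        cell[others] += rng.multinomial(n_err, [1.0 / 3.0] * 3)
    return cell


def _toy_annotation(genome_length: int, n_genes: int = 2, window: int = 500) -> Annotation:
    """Deterministic toy gene models: 3 exons each, CDS == exons, 600 coding bp."""
    exon_lens = (150, 300, 150)
    intron_len = 90
    span = sum(exon_lens) + 2 * intron_len
    transcripts = []
    for i in range(n_genes):
        anchor = (i + 1) * genome_length // (n_genes + 1)
        start = anchor - span // 2
        if start < window + 1 or start + span - 1 > genome_length - window:
            continue
        exons = []
        pos = start
        for length in exon_lens:
            exons.append((pos, pos + length - 1))
            pos += length + intron_len
        end = exons[-1][1]
        strand = "+" if i % 2 == 0 else "-"
        transcripts.append(
            Transcript(
                transcript_id=f"gene{i + 1}.t1",
                gene_id=f"gene{i + 1}",
                seqid="chr1",
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                cds=list(exons),
            )
        )
    return Annotation(transcripts=transcripts, window=window)


def _survival_table(
    rng: np.random.Generator, config: SimulationConfig, regimes: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for r, regime in enumerate(regimes):
        p_ext = config.extinction_prob_per_regime[r]
        alive = config.founded_lines_per_regime
        rows.append((regime, 0, alive, 1.0))
        for g in range(1, config.generations + 1):
            alive = int(rng.binomial(alive, 1.0 - p_ext))
            rows.append((regime, g, alive, alive / config.founded_lines_per_regime))
    return pd.DataFrame(rows, columns=["regime_id", "generation", "n_alive", "fraction_alive"])


def simulate_experiment(config: SimulationConfig, evidence: str = "dense") -> Experiment:
    """Run one seeded MA-experiment simulation.

    Parameters
    ----------
    config
        Validated :class:`SimulationConfig`.
    evidence
        ``"dense"`` draws per-site allele depths for every line
        (``(lines, genome, 4)`` int32 per regime); ``"none"`` skips read
        evidence entirely (truth, masks, survival and annotation only),
        which is what large parameter-recovery sweeps use.
    """
    if evidence not in ("dense", "none"):
        raise ConfigError(f"evidence must be 'dense' or 'none', got {evidence!r}")
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    T = config.generations

    gc = config.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cuts = np.cumsum(base_probs)[:3]
    u = rng.random(G)
    ref_codes = ((u >= cuts[0]).astype(np.int8)
                 + (u >= cuts[1]).astype(np.int8)
                 + (u >= cuts[2]).astype(np.int8))
    del u

    regimes = [f"R{r + 1}" for r in range(config.n_regimes)]
    lines = {r: [f"{r}_L{i + 1}" for i in range(config.lines_per_regime)] for r in regimes}

    masks = {
        r: _draw_mask(rng, G, config.callable_fraction_target, "chr1") for r in regimes
    }

    # transmission weights: a generation-g mutation reaches the sequenced
    # M(T) individual with probability 0.5**(T - g)
    weights = np.array([0.5 ** (T - g) for g in range(1, T + 1)])
    truth_rows = []
    for r_idx, regime in enumerate(regimes):
        mu = config.mu_per_regime[r_idx]
        mask_dense = (
            masks[regime].to_boolean("chr1", G) if config.restrict_to_callable else None
        )
        lam_raw = mu * G * T / weights.sum()  # per-generation raw influx
        for line in lines[regime]:
            for g in range(1, T + 1):
                raw = rng.poisson(lam_raw)
                surviving = rng.binomial(raw, weights[g - 1]) if raw else 0
                if surviving == 0:
                    continue
                positions = _sample_positions(rng, surviving, G, mask_dense)
                refs = ref_codes[positions - 1]
                alts = _draw_alt_codes(rng, refs, config.ts_fraction)
                for pos, rc, ac in zip(positions, refs, alts):
                    truth_rows.append(
                        (regime, line, int(pos), BASES[rc], BASES[ac], g)
                    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["regime_id", "line_id", "position", "ref_base", "alt_base",
                 "generation_of_origin"],
    )
    if len(truth):
        # a site mutated in two lines of a regime would not be de novo-unique;
        # resample collisions away (they are vanishingly rare at real rates)
        dup = truth.duplicated(subset=["regime_id", "position"], keep="first")
        truth = truth[~dup].reset_index(drop=True)
    truth = truth.sort_values(["regime_id", "line_id", "position"]).reset_index(drop=True)

    evidence_arrays: dict[str, np.ndarray] | None = None
    if evidence == "dense":
        evidence_arrays = {}
        for r_idx, regime in enumerate(regimes):
            mean_depth = config.mean_depth_per_regime[r_idx]
            r = config.depth_dispersion
            p = r / (r + mean_depth) if mean_depth > 0 else 1.0
            shape = (config.lines_per_regime, G)
            depth = rng.negative_binomial(r, p, size=shape) if mean_depth > 0 else np.zeros(shape, np.int64)
            ad = _noisy_allele_depths(rng, depth, ref_codes, config.seq_error)
            line_index = {name: i for i, name in enumerate(lines[regime])}
            for row in truth[truth.regime_id == regime].itertuples():
                i = line_index[row.line_id]
                s = row.position - 1
                ad[i, s, :] = _het_cell(
                    rng,
                    int(depth[i, s]),
                    int(ref_codes[s]),
                    int(np.flatnonzero(BASES == row.alt_base)[0]),
                    config.seq_error,
                )
            evidence_arrays[regime] = ad

    annotation = _toy_annotation(G)
    survival = _survival_table(rng, config, regimes)

    return Experiment(
        config=config,
        reference_codes=ref_codes,
        regimes=regimes,
        lines=lines,
        truth=truth,
        masks=masks,
        evidence=evidence_arrays,
        annotation=annotation,
        survival=survival,
    )


def spectrum_of_truth(truth: pd.DataFrame) -> spectrum.SpectrumCounts:
    """Six-class spectrum of the simulated truth (simulator self-check)."""
    return spectrum.tally(zip(truth["ref_base"], truth["alt_base"]))
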