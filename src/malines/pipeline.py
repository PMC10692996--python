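"""End-to-end orchestration: simulate -> call -> merge -> rates -> spectrum
-> effects -> report, plus a "reference-counts" mode that re-runs the whole
statistics layer on published count tables without sequence data."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus, effects, io_formats, probabilistic, rates, spectrum
from .consensus import FilterConfig
from .errors import MalinesError
from .probabilistic import ProbModelParams
from .simulate import Experiment, SimulationConfig, simulate_experiment


@dataclass
class RunConfig:
    """One reproducible pipeline run. Every stochastic stage is seeded."""

    sim: SimulationConfig
    out_dir: Path
    caller: str = "both"  # consensus | probabilistic | both
    merge: str = "shared"  # shared | union
    filters: FilterConfig = field(default_factory=FilterConfig)
    prob: ProbModelParams = field(default_factory=ProbModelParams)
    B: int = 10_000
    stats_seed: int = 0
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.caller not in ("consensus", "probabilistic", "both"):
            raise MalinesError(f"unknown caller mode {self.caller!r}")
        if self.merge not in ("shared", "union"):
            raise MalinesError(f"unknown merge mode {self.merge!r}")


def call_regime(
    experiment: Experiment,
    regime: str,
    caller: str,
    filters: FilterConfig,
    prob: ProbModelParams,
    merge: str,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Call, filter and merge one regime.

    Returns ``(accepted, audit, n_callable)`` where ``audit`` is every
    candidate from both arms with its filter outcome.
    """
    if experiment.evidence is None:
        raise MalinesError("experiment was simulated without read evidence")
    ad = experiment.evidence[regime]
    ref_codes = experiment.reference_codes
    mask_dense = experiment.masks[regime].to_boolean(experiment.chrom, len(ref_codes))
    line_names = experiment.lines[regime]
    mean_depth = {
        name: float(ad[i].sum(axis=1).mean()) for i, name in enumerate(line_names)
    }

    gt, _, _ = consensus.genotype_array_from_evidence(ad, ref_codes, filters)
    n_callable = consensus.callable_sites(gt, mask_dense)

    audits = []
    cons_acc = prob_acc = None
    if caller in ("consensus", "both"):
        cand = consensus.consensus_from_evidence(
            ad, ref_codes, line_names, mask_dense, filters, regime
        )
        cand = consensus.apply_filters(cand, filters, mean_depth)
        audits.append(cand)
        cons_acc = cand[cand.status == "accepted"]
    if caller in ("probabilistic", "both"):
        cand = probabilistic.call_probabilistic(
            ad, ref_codes, line_names, mask_dense, prob, regime
        )
        cand = consensus.apply_filters(cand, filters, mean_depth)
        audits.append(cand)
        prob_acc = cand[cand.status == "accepted"]

    if caller == "consensus":
        accepted = cons_acc
    elif caller == "probabilistic":
        accepted = prob_acc
    else:
        accepted = probabilistic.merge_cohorts(cons_acc, prob_acc, mode=merge)
    non_empty_audits = [a for a in audits if len(a)]
    if non_empty_audits:
        audit = pd.concat(non_empty_audits, ignore_index=True)
    elif audits:
        audit = audits[0]
    else:
        audit = pd.DataFrame()
    return accepted.reset_index(drop=True), audit, n_callable


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline and write all stage outputs.

    Returns the machine-readable summary (also written as
    ``summary.json``).  Any stage failure is re-raised with the stage name.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise MalinesError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise MalinesError(f"stage {name!r} failed: {exc}") from exc

    experiment = _stage("simulate", simulate_experiment, config.sim)
    _stage("simulate-write", experiment.write, out)

    summary: dict = {
        "config": {
            "sim": asdict(config.sim),
            "caller": config.caller,
            "merge": config.merge,
            "filters": asdict(config.filters),
            "prob": asdict(config.prob),
            "B": config.B,
            "stats_seed": config.stats_seed,
        },
        "regimes": {},
    }
    accepted_frames = []
    counts_per_regime: dict[str, list[int]] = {}
    n_per_regime: dict[str, int] = {}
    effects_by_regime: dict[str, list[str]] = {}
    for regime in experiment.regimes:
        accepted, audit, n_callable = _stage(
            "call", call_regime, experiment, regime, config.caller,
            config.filters, config.prob, config.merge,
        )
        accepted_frames.append(accepted)
        io_formats.write_tsv(audit, out / f"candidates_{regime}.tsv")

        per_line = [
            int((accepted.line_id == line).sum()) for line in experiment.lines[regime]
        ]
        counts_per_regime[regime] = per_line
        n_per_regime[regime] = n_callable
        est = _stage(
            "rates", rates.regime_mean_rate, per_line, max(n_callable, 1),
            config.sim.generations,
        )
        spec = _stage(
            "spectrum", spectrum.tally,
            zip(accepted.ref_base, accepted.alt_base),
        )
        terms = [
            _stage(
                "effects", effects.predict_effect, int(row.position), row.ref_base,
                row.alt_base, experiment.annotation, experiment.reference,
            )
            for row in accepted.itertuples()
        ]
        effects_by_regime[regime] = terms
        summary["regimes"][regime] = {
            "m": int(sum(per_line)),
            "per_line_m": per_line,
            "n_callable": n_callable,
            "T": config.sim.generations,
            "mu": est.mu,
            "se_mu": est.se_mu,
            "spectrum": spec.counts,
            "ts": spec.ts,
            "tv": spec.tv,
            "ts_tv_ratio": spec.ts_tv_ratio,
        }

    non_empty = [f for f in accepted_frames if len(f)]
    all_accepted = (
        pd.concat(non_empty, ignore_index=True) if non_empty else accepted_frames[0]
    )
    io_formats.write_tsv(all_accepted, out / "accepted.tsv")

    table = _stage("effects", effects.effect_table, effects_by_regime, experiment.regimes)
    io_formats.write_tsv(table.reset_index(names="category"), out / "effect_table.tsv")
    summary["effect_table"] = {c: table[c].to_dict() for c in table.columns}

    if len(experiment.regimes) >= 2:
        binom = _stage("stats", rates.compare_regimes_binomial, counts_per_regime,
                       n_per_regime)
        poiss = _stage("stats", rates.compare_regimes_poisson, counts_per_regime,
                       n_per_regime, config.sim.generations)
        summary["comparisons"] = {
            "binomial": asdict(binom),
            "poisson": asdict(poiss),
        }

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# statistics layer re-run on published count tables (no sequence data)
# ---------------------------------------------------------------------------

def load_reference_counts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bundled per-regime mutation counts and effect-category counts from
    the original MA study (main-text tables)."""
    base = resources.files("malines") / "data"
    regime_counts = pd.read_csv(str(base / "regime_counts.tsv"), sep="\t")
    effect_counts = pd.read_csv(str(base / "effect_counts.tsv"), sep="\t")
    return regime_counts, effect_counts


def reference_check(
    regime_counts: pd.DataFrame,
    effect_counts: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
) -> dict:
    """Recompute the statistics layer from count tables alone.

    ``regime_counts`` needs columns regime/m/lines/callable_sites/
    generations/transitions/transversions; ``effect_counts`` is a
    consequence x regime table with a ``consequence`` column.
    """
    out: dict = {"regimes": {}, "seed": seed, "B": B}
    counts_per_regime = {}
    n_per_regime = {}
    for row in regime_counts.itertuples():
        est = rates.mutation_rate(
            int(row.m), int(row.lines), int(row.callable_sites), int(row.generations)
        )
        gof = spectrum.chisq_gof(
            [int(row.transitions), int(row.transversions)], B=B, seed=seed
        )
        out["regimes"][row.regime] = {
            "m": int(row.m),
            "mu_1e8": round(est.scaled(1e8), 2),
            "ts": int(row.transitions),
            "tv": int(row.transversions),
            "tstv_chisq": round(gof.statistic, 2),
            "tstv_p_simulated": gof.p_simulated,
        }
        # regime totals: trials are lines x callable sites (per-line counts
        # live in the study's supplement and are not recoverable here)
        counts_per_regime[row.regime] = [int(row.m)]
        n_per_regime[row.regime] = int(row.lines) * int(row.callable_sites)

    ts_total = int(regime_counts.transitions.sum())
    tv_total = int(regime_counts.transversions.sum())
    out["pooled"] = {
        "ts": ts_total,
        "tv": tv_total,
        "ts_tv_ratio": None if tv_total == 0 else ts_total / tv_total,
    }

    eff = effect_counts.set_index("consequence")
    impacts = effects.impacts_from_consequences(eff)
    out["effect_gof"] = {}
    for name, row_counts in pd.concat([eff, impacts]).iterrows():
        counts = row_counts.to_numpy(dtype=np.int64)
        if counts.sum() < 1:
            continue
        gof = spectrum.chisq_gof(counts, B=B, seed=seed)
        out["effect_gof"][name] = {
            "counts": counts.tolist(),
            "N": int(counts.sum()),
            "chisq": round(gof.statistic, 2),
            "p_simulated": gof.p_simulated,
        }

    T = int(regime_counts.generations.iloc[0])
    out["comparisons"] = {
        "binomial": asdict(rates.compare_regimes_binomial(counts_per_regime, n_per_regime)),
        "poisson": asdict(rates.compare_regimes_poisson(counts_per_regime, n_per_regime, T)),
    }
    return out
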