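import numpy as np
import pandas as pd
import pytest

from malines.consensus import (
    FilterConfig,
    acceptance_rate_table,
    apply_filters,
    callable_sites,
    consensus_candidates,
    consensus_from_evidence,
    genotype_array_from_evidence,
    genotype_from_evidence,
)
from malines.errors import ConfigError
from malines.io_formats import HET, HOM_ALT, HOM_REF, NO_CALL, CallableMask, GenotypeMatrix


def _ad_cell(ref_code, alt_code, ref_n, alt_n, extra=None):
    cell = [0, 0, 0, 0]
    cell[ref_code] += ref_n
    cell[alt_code] += alt_n
    if extra:
        for code, n in extra.items():
            cell[code] += n
    return cell


class TestGenotypeFromEvidence:
    def test_balanced_het(self, filters):
        assert genotype_from_evidence(_ad_cell(0, 2, 15, 15), 0, filters) == HET

    def test_low_depth_no_call(self, filters):
        assert genotype_from_evidence(_ad_cell(0, 2, 2, 1), 0, filters) == NO_CALL

    def test_clean_hom_ref(self, filters):
        assert genotype_from_evidence(_ad_cell(0, 2, 30, 0), 0, filters) == HOM_REF

    def test_hom_alt(self, filters):
        assert genotype_from_evidence(_ad_cell(0, 2, 0, 30), 0, filters) == HOM_ALT

    def test_exhaustive_sweep_matches_threshold_oracle(self, filters):
        depth = 20
        lo, hi = filters.allele_balance_range
        for alt in range(depth + 1):
            got = genotype_from_evidence(_ad_cell(1, 3, depth - alt, alt), 1, filters)
            frac = alt / depth
            if frac <= filters.hom_max_alt_fraction:
                want = HOM_REF
            elif lo <= frac <= hi:
                want = HET
            elif frac >= 1 - filters.hom_max_alt_fraction:
                want = HOM_ALT
            else:
                want = NO_CALL
            assert got == want, f"alt={alt}"

    def test_vectorized_agrees_with_scalar(self, filters, rng):
        n_lines, n_sites = 4, 300
        ad = rng.integers(0, 25, size=(n_lines, n_sites, 4)).astype(np.int32)
        ref_codes = rng.integers(0, 4, size=n_sites).astype(np.int8)
        gt, _, _ = genotype_array_from_evidence(ad, ref_codes, filters)
        for i in range(n_lines):
            for j in range(0, n_sites, 7):
                assert gt[i, j] == genotype_from_evidence(
                    ad[i, j], int(ref_codes[j]), filters
                )


class TestCallableSites:
    def test_fully_genotyped(self):
        gt = np.full((6, 10_000), HOM_REF, dtype=np.int8)
        assert callable_sites(gt) == 10_000

    def test_one_missing_cell(self):
        gt = np.full((6, 10_000), HOM_REF, dtype=np.int8)
        gt[3, 42] = NO_CALL
        assert callable_sites(gt) == 9_999

    def test_random_missingness_matches_brute_force(self, rng):
        gt = rng.choice([NO_CALL, HOM_REF, HET], size=(6, 5_000),
                        p=[0.1, 0.8, 0.1]).astype(np.int8)
        mask = rng.random(5_000) < 0.7
        brute = sum(
            1 for j in range(5_000)
            if mask[j] and all(gt[i, j] != NO_CALL for i in range(6))
        )
        assert callable_sites(gt, mask) == brute

    def test_empty_regime_rejected(self):
        with pytest.raises(ValueError):
            callable_sites(np.empty((0, 10), dtype=np.int8))


def _toy_matrix(gt_rows, positions=None):
    gt = np.array(gt_rows, dtype=np.int8)
    n_samples, n_sites = gt.shape
    positions = positions if positions is not None else np.arange(1, n_sites + 1)
    return GenotypeMatrix(
        samples=[f"L{i}" for i in range(n_samples)],
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype="U1"),
        alt=np.array(["G"] * n_sites, dtype="U1"),
        gt=gt,
    )


def _full_mask(length=10_000):
    return CallableMask({"chr1": np.array([[1, length]], dtype=np.int64)})


class TestConsensusCandidates:
    def test_single_het_is_candidate(self):
        m = _toy_matrix([[HET], [HOM_REF], [HOM_REF], [HOM_REF], [HOM_REF], [HOM_REF]])
        cand = consensus_candidates(m, m.samples, _full_mask())
        assert len(cand) == 1
        assert cand.line_id.iloc[0] == "L0"
        assert cand.position.iloc[0] == 1

    def test_shared_het_not_candidate(self):
        m = _toy_matrix([[HET], [HET], [HOM_REF], [HOM_REF], [HOM_REF], [HOM_REF]])
        assert len(consensus_candidates(m, m.samples, _full_mask())) == 0

    def test_hom_alt_other_line_excluded(self):
        m = _toy_matrix([[HET], [HOM_ALT], [HOM_REF], [HOM_REF], [HOM_REF], [HOM_REF]])
        assert len(consensus_candidates(m, m.samples, _full_mask())) == 0

    def test_no_call_other_line_excluded(self):
        m = _toy_matrix([[HET], [NO_CALL], [HOM_REF], [HOM_REF], [HOM_REF], [HOM_REF]])
        assert len(consensus_candidates(m, m.samples, _full_mask())) == 0

    def test_uncallable_site_excluded(self):
        m = _toy_matrix(
            [[HET], [HOM_REF], [HOM_REF], [HOM_REF], [HOM_REF], [HOM_REF]],
            positions=[500],
        )
        mask = CallableMask({"chr1": np.array([[1, 100]], dtype=np.int64)})
        assert len(consensus_candidates(m, m.samples, mask)) == 0

    def test_random_matrices_match_brute_force(self, rng):
        n_lines, n_sites = 6, 10_000
        gt = rng.choice(
            [NO_CALL, HOM_REF, HET, HOM_ALT], size=(n_lines, n_sites),
            p=[0.02, 0.9, 0.06, 0.02],
        ).astype(np.int8)
        m = _toy_matrix(gt)
        dense = rng.random(n_sites) < 0.8
        mask = CallableMask.from_boolean(dense, "chr1")
        cand = consensus_candidates(m, m.samples, mask)
        got = set(zip(cand.line_id, cand.position))
        want = set()
        for j in range(n_sites):
            if not dense[j]:
                continue
            col = gt[:, j]
            hets = [i for i in range(n_lines) if col[i] == HET]
            homrefs = [i for i in range(n_lines) if col[i] == HOM_REF]
            if len(hets) == 1 and len(homrefs) == n_lines - 1:
                want.add((f"L{hets[0]}", j + 1))
        assert got == want


def _candidate_row(**kw):
    base = dict(
        regime_id="R1", line_id="L0", position=100, ref_base="A", alt_base="G",
        caller="consensus", status="candidate", rejection_reason=None,
        depth=30, alt_count=15, alt_fraction=0.5, other_alt_count=0,
        min_other_depth=20, posterior=np.nan,
    )
    base.update(kw)
    return base


MEAN_DEPTH = {"L0": 30.0, "L1": 30.0}


class TestApplyFilters:
    def test_extreme_allele_balance_rejected(self, filters):
        df = pd.DataFrame([_candidate_row(alt_fraction=0.05, alt_count=2, depth=40)])
        out = apply_filters(df, filters, MEAN_DEPTH)
        assert out.status.iloc[0] == "rejected"
        assert out.rejection_reason.iloc[0] == "allele_balance"

    def test_cluster_rejects_both(self, filters):
        cfg = FilterConfig(cluster_window=10)
        df = pd.DataFrame([
            _candidate_row(position=100),
            _candidate_row(position=103),
        ])
        out = apply_filters(df, cfg, MEAN_DEPTH)
        assert (out.status == "rejected").all()
        assert (out.rejection_reason == "cluster").all()

    def test_cluster_only_within_line(self, filters):
        cfg = FilterConfig(cluster_window=10)
        df = pd.DataFrame([
            _candidate_row(position=100, line_id="L0"),
            _candidate_row(position=103, line_id="L1"),
        ])
        out = apply_filters(df, cfg, MEAN_DEPTH)
        assert (out.status == "accepted").all()

    def test_low_depth_primary_reason(self, filters):
        df = pd.DataFrame([_candidate_row(depth=5, alt_count=1, alt_fraction=0.2)])
        out = apply_filters(df, filters, MEAN_DEPTH)
        assert out.rejection_reason.iloc[0] == "low_depth"

    def test_high_depth_rejected(self, filters):
        df = pd.DataFrame([_candidate_row(depth=200, alt_count=100)])
        out = apply_filters(df, filters, MEAN_DEPTH)
        assert out.rejection_reason.iloc[0] == "high_depth"

    def test_multiallelic_rejected(self, filters):
        df = pd.DataFrame([_candidate_row(other_alt_count=3)])
        out = apply_filters(df, filters, MEAN_DEPTH)
        assert out.rejection_reason.iloc[0] == "multiallelic"

    def test_low_other_depth_rejected(self, filters):
        df = pd.DataFrame([_candidate_row(min_other_depth=2)])
        out = apply_filters(df, filters, MEAN_DEPTH)
        assert out.rejection_reason.iloc[0] == "low_other_depth"

    def test_exactly_one_primary_reason(self, filters):
        df = pd.DataFrame([_candidate_row(depth=5, alt_fraction=0.05, min_other_depth=0)])
        out = apply_filters(df, filters, MEAN_DEPTH)
        assert out.rejection_reason.iloc[0] == "low_depth"

    def test_empty_input(self, filters):
        out = apply_filters(pd.DataFrame(columns=["line_id", "position"]), filters, {})
        assert len(out) == 0


def test_truth_recovered_on_clean_deep_data():
    # seq_error=0 and deep coverage: all truth accepted, zero false accepts
    from malines.simulate import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(
        seed=3, genome_length=40_000, n_regimes=1, lines_per_regime=6,
        mu_per_regime=(5e-6,), mean_depth_per_regime=(80.0,),
        depth_dispersion=100.0,
        extinction_prob_per_regime=(0.0,), seq_error=0.0,
        callable_fraction_target=1.0,
    )
    exp = simulate_experiment(cfg)
    filters = FilterConfig()
    ad = exp.evidence["R1"]
    mask = exp.masks["R1"].to_boolean("chr1", cfg.genome_length)
    cand = consensus_from_evidence(
        ad, exp.reference_codes, exp.lines["R1"], mask, filters, "R1"
    )
    mean_depth = {n: float(ad[i].sum(axis=1).mean()) for i, n in enumerate(exp.lines["R1"])}
    out = apply_filters(cand, filters, mean_depth)
    accepted = out[out.status == "accepted"]
    got = set(zip(accepted.line_id, accepted.position, accepted.alt_base))
    want = set(zip(exp.truth.line_id, exp.truth.position, exp.truth.alt_base))
    assert len(want) > 0
    assert got == want


def test_acceptance_rate_table():
    rows = []
    for regime, n_acc, n_rej in (("R1", 8, 2), ("R2", 7, 3)):
        for k in range(n_acc):
            rows.append(_candidate_row(regime_id=regime, position=1000 * (k + 1),
                                       status="accepted"))
        for k in range(n_rej):
            rows.append(_candidate_row(regime_id=regime, position=50_000 + 1000 * k,
                                       status="rejected", rejection_reason="low_depth"))
    tab = acceptance_rate_table(pd.DataFrame(rows))
    assert set(tab.regime_id) == {"R1", "R2"}
    assert tab.set_index("regime_id").loc["R1", "acceptance_rate"] == 0.8
    assert np.isfinite(tab.chisq).all()


def test_filter_config_validation():
    with pytest.raises(ConfigError):
        FilterConfig(allele_balance_range=(0.6, 0.7))
    with pytest.raises(ConfigError):
        FilterConfig(cluster_window=0)
    with pytest.raises(ConfigError):
        FilterConfig(hom_max_alt_fraction=0.4)
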