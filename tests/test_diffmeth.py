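import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats
from sklearn.base import clone

from episig import (EBayesPrior, EpiSignatureSelector, MatchConfig,
                    SelectConfig, bh_adjust, derive_signature, estimate_prior,
                    moderated_t, prune_correlated, select_matched_controls,
                    select_probes)
from episig.diffmeth import compute_probe_stats
from episig.io import write_signature


def matched_case_control_ids(sheet, seed=0):
    cases = sheet[sheet.group == "case"]
    pool = sheet[sheet.group == "control"]
    ctrl_ids, _ = select_matched_controls(cases, pool,
                                          MatchConfig(ratio=3, seed=seed))
    return cases["sample_id"].tolist(), ctrl_ids


def bh_brute(p):
    """Definition-based BH step-up: raw adjusted p*n/rank, then cumulative
    minimum from the largest rank down, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = min(running, 1.0)
    return adj


class TestEstimatePrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(50, 3.5), df_residual=8)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(3.5, rel=1e-12)

    def test_parameter_recovery_from_simulation(self):
        rng = np.random.default_rng(7)
        d0, s0_sq, df = 4.0, 2.0, 10
        true_var = s0_sq * d0 / rng.chisquare(d0, 50_000)
        s2 = true_var * rng.chisquare(df, 50_000) / df
        prior = estimate_prior(s2, df)
        assert prior.d0 == pytest.approx(4.0, abs=0.5)
        assert prior.s0_sq == pytest.approx(2.0, abs=0.1)

    def test_matches_independent_root_finder(self):
        """Moment equations solved independently with brentq on the
        trigamma equation must agree with the package fit to 1e-6."""
        variances = np.arange(1.0, 11.0)
        df = 6
        prior = estimate_prior(variances, df)

        half = df / 2.0
        e = np.log(variances) - special.digamma(half) + math.log(half)
        target = np.var(e, ddof=1) - special.polygamma(1, half)
        assert target > 0  # this fixture has excess dispersion
        x = optimize.brentq(
            lambda v: special.polygamma(1, v) - target, 1e-6, 1e8, xtol=1e-14)
        d0_oracle = 2.0 * x
        s0_oracle = math.exp(
            np.mean(e) + special.digamma(d0_oracle / 2) - math.log(d0_oracle / 2))
        assert prior.d0 == pytest.approx(d0_oracle, abs=1e-6)
        assert prior.s0_sq == pytest.approx(s0_oracle, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior(np.zeros(20), 5)
        with pytest.raises(ValueError):
            estimate_prior(np.ones(5), 5)  # too few probes


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self):
        """With no shrinkage the moderated t is the textbook pooled
        two-sample t (scipy oracle, 100 random instances, tol 1e-10)."""
        rng = np.random.default_rng(0)
        prior = EBayesPrior(d0=0.0, s0_sq=1.0)
        for _ in range(100):
            n1, n2 = rng.integers(3, 8, 2)
            a = rng.normal(rng.uniform(-1, 1), 1.0, n1)
            b = rng.normal(0, 1.0, n2)
            out = moderated_t(a, b, prior)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert out["t_moderated"][0] == pytest.approx(ref.statistic, abs=1e-10)
            assert out["p_value"][0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_equal_means_zero_t_unit_p(self):
        out = moderated_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                          EBayesPrior(d0=4, s0_sq=1.0))
        assert out["t_moderated"][0] == 0.0
        assert out["p_value"][0] == 1.0
        assert out["delta"][0] == 0.0

    def test_infinite_d0_uses_normal_reference(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 5), rng.normal(0, 1, 5)
        prior = EBayesPrior(d0=math.inf, s0_sq=1.0)
        out = moderated_t(a, b, prior)
        t_expected = (a.mean() - b.mean()) / math.sqrt(1.0 * (1 / 5 + 1 / 5))
        assert out["t_moderated"][0] == pytest.approx(t_expected, abs=1e-12)
        assert out["p_value"][0] == pytest.approx(
            2 * stats.norm.sf(abs(t_expected)), abs=1e-12)

    def test_shrinkage_pulls_toward_prior_variance(self):
        # tiny sample variance + large prior variance -> smaller |t| than raw
        a = np.array([1.0, 1.01, 0.99])
        b = np.array([0.0, 0.01, -0.01])
        raw = moderated_t(a, b, EBayesPrior(d0=0.0, s0_sq=1.0))
        shrunk = moderated_t(a, b, EBayesPrior(d0=50.0, s0_sq=1.0))
        assert abs(shrunk["t_moderated"][0]) < abs(raw["t_moderated"][0])


class TestLimmaCrossCheck:
    def test_matches_limma_on_small_matrix(self, tmp_path):
        """Independent oracle: limma's lmFit/eBayes on the same M-values
        must reproduce the prior (d0, s0_sq) and moderated t."""
        rng = np.random.default_rng(42)
        n_probes, n1, n2 = 120, 5, 6
        m = rng.normal(0, 1, (n_probes, n1 + n2))
        m[:10, :n1] += 2.0  # a handful of true effects
        frame = pd.DataFrame(
            m, index=[f"cg{i}" for i in range(n_probes)],
            columns=[f"s{i}" for i in range(n1 + n2)])
        frame.to_csv(tmp_path / "m.csv")
        script = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.csv("{tmp_path / 'm.csv'}", row.names=1))
        group <- factor(c(rep("case", {n1}), rep("control", {n2})), levels=c("control","case"))
        design <- model.matrix(~ group)
        fit <- eBayes(lmFit(m, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
        out$d0 <- fit$df.prior; out$s02 <- fit$s2.prior
        write.csv(out, "{tmp_path / 'limma.csv'}")
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)

        case = m[:, :n1]
        control = m[:, n1:]
        dg = n1 + n2 - 2
        pooled = ((n1 - 1) * case.var(axis=1, ddof=1)
                  + (n2 - 1) * control.var(axis=1, ddof=1)) / dg
        prior = estimate_prior(pooled, dg)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        ours = moderated_t(case, control, prior)
        np.testing.assert_allclose(
            ours["t_moderated"].to_numpy(), ref["t"].to_numpy(), rtol=1e-4)
        np.testing.assert_allclose(
            ours["p_value"].to_numpy(), ref["p"].to_numpy(), rtol=1e-4)


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5], [0.5]),
        ([0.05, 0.05, 0.05], [0.05, 0.05, 0.05]),
    ])
    def test_hand_computed_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_brute_force_on_all_orderings(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, 6)
        import itertools
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            np.testing.assert_allclose(bh_adjust(p), bh_brute(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_adjusted_bounded_between_raw_and_one(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


def _stats_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "delta_beta", "t_moderated",
                                       "p_value", "p_adjusted"])


class TestSelectProbes:
    def test_nothing_passes_gives_empty(self):
        frame = _stats_frame([("cg1", 0.05, 3.0, 0.2, 0.5)])
        assert select_probes(frame).empty

    def test_ties_broken_by_probe_id(self):
        frame = _stats_frame([("cgB", 0.2, 5.0, 1e-6, 1e-5),
                              ("cgA", 0.2, 5.0, 1e-6, 1e-5)])
        out = select_probes(frame)
        assert out["probe_id"].tolist() == ["cgA", "cgB"]
        assert out["rank"].tolist() == [1, 2]

    def test_output_subset_of_input_and_capped(self):
        rng = np.random.default_rng(4)
        frame = _stats_frame([
            (f"cg{i}", rng.uniform(-0.4, 0.4), rng.normal(0, 8),
             rng.uniform(0, 0.05), rng.uniform(0, 0.05)) for i in range(50)])
        out = select_probes(frame, SelectConfig(max_probes=10))
        assert len(out) <= 10
        assert set(out["probe_id"]) <= set(frame["probe_id"])

    def test_ranking_by_combined_score(self):
        frame = _stats_frame([("cg1", 0.15, 4.0, 1e-6, 1e-5),   # score 0.60
                              ("cg2", 0.30, 3.0, 1e-6, 1e-5),   # score 0.90
                              ("cg3", 0.11, 9.0, 1e-6, 1e-5)])  # score 0.99
        out = select_probes(frame)
        assert out["probe_id"].tolist() == ["cg3", "cg2", "cg1"]


class TestPruneCorrelated:
    def _training(self, values, probes):
        return pd.DataFrame(values, index=probes,
                            columns=[f"s{i}" for i in range(values.shape[1])])

    def test_duplicate_probe_keeps_higher_rank(self):
        rng = np.random.default_rng(5)
        row = rng.uniform(0.2, 0.8, 10)
        training = self._training(np.vstack([row, row]), ["cgTop", "cgDup"])
        selected = _stats_frame([("cgTop", 0.2, 9.0, 1e-9, 1e-8),
                                 ("cgDup", 0.2, 8.0, 1e-9, 1e-8)])
        selected["rank"] = [1, 2]
        out = prune_correlated(selected, training, prune_r=0.9)
        assert out["probe_id"].tolist() == ["cgTop"]

    def test_uncorrelated_probes_unchanged(self):
        rng = np.random.default_rng(6)
        training = self._training(rng.uniform(0, 1, (4, 200)),
                                  [f"cg{i}" for i in range(4)])
        selected = _stats_frame([(f"cg{i}", 0.2, 5.0 - i, 1e-9, 1e-8)
                                 for i in range(4)])
        selected["rank"] = range(1, 5)
        out = prune_correlated(selected, training, prune_r=0.9)
        assert out["probe_id"].tolist() == [f"cg{i}" for i in range(4)]

    def test_matches_brute_force_greedy_on_latent_factor_fixture(self):
        """Five probes sharing a latent factor: the kept set must equal an
        independent greedy walk over the full correlation matrix."""
        rng = np.random.default_rng(7)
        latent = rng.normal(0, 1, 60)
        loadings = [1.0, 0.98, 0.2, 0.95, 0.1]
        values = np.vstack([
            l * latent + math.sqrt(max(1 - l * l, 1e-12)) * rng.normal(0, 1, 60)
            for l in loadings])
        probes = [f"cg{i}" for i in range(5)]
        training = self._training((values - values.min()) /
                                  (values.max() - values.min()), probes)
        selected = _stats_frame([(p, 0.2, 9.0 - i, 1e-9, 1e-8)
                                 for i, p in enumerate(probes)])
        selected["rank"] = range(1, 6)

        corr = np.corrcoef(training.to_numpy())
        kept_oracle = []
        for i in range(5):
            if all(abs(corr[i, j]) < 0.9 for j in kept_oracle):
                kept_oracle.append(i)
        out = prune_correlated(selected, training, prune_r=0.9)
        assert out["probe_id"].tolist() == [probes[i] for i in kept_oracle]

    def test_never_longer_than_input(self, small_cohort):
        beta, sheet, _ = small_cohort
        cases, ctrls = matched_case_control_ids(sheet)
        frame, _ = compute_probe_stats(beta.loc[:, cases + ctrls], cases, ctrls)
        selected = select_probes(frame)
        pruned = prune_correlated(selected, beta.loc[:, cases + ctrls])
        assert len(pruned) <= len(selected)
        assert pruned["rank"].tolist() == list(range(1, len(pruned) + 1))


class TestDeriveSignature:
    def test_recovers_planted_probes(self, small_cohort):
        beta, sheet, truth = small_cohort
        cases, ctrls = matched_case_control_ids(sheet)
        sig = derive_signature(beta, sheet, cases, ctrls)
        planted = set(truth.signature_probe_ids)
        got = set(sig.probe_ids)
        assert len(got & planted) / len(planted) >= 0.9   # sensitivity
        assert len(got & planted) / len(got) >= 0.9       # precision

    def test_null_cohort_gives_empty_signature(self):
        from episig import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(n_probes=2000, n_signature_probes=60,
                               delta_beta=0.0, n_cases=8, n_controls=60,
                               n_reference=0, n_age_probes=100,
                               n_sex_probes=50, n_batch_probes=50, seed=21)
        beta, sheet, _ = simulate_cohort(cfg)
        cases, ctrls = matched_case_control_ids(sheet)
        sig = derive_signature(beta, sheet, cases, ctrls)
        assert len(sig) == 0

    def test_repeated_runs_byte_identical(self, small_cohort, tmp_path):
        beta, sheet, _ = small_cohort
        cases, ctrls = matched_case_control_ids(sheet)
        paths = []
        for run in (1, 2):
            sig = derive_signature(beta, sheet, cases, ctrls)
            path = tmp_path / f"sig{run}.tsv"
            write_signature(sig.probes, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_overlapping_groups_rejected(self, small_cohort):
        beta, sheet, _ = small_cohort
        cases = sheet.loc[sheet.group == "case", "sample_id"].tolist()
        with pytest.raises(ValueError, match="overlap"):
            derive_signature(beta, sheet, cases, cases)

    def test_provenance_counts_are_monotone(self, small_cohort):
        beta, sheet, _ = small_cohort
        cases, ctrls = matched_case_control_ids(sheet)
        counts = derive_signature(beta, sheet, cases, ctrls).provenance["counts"]
        assert (counts["probes_in"] >= counts["probes_after_qc"]
                >= counts["probes_significant"] >= counts["probes_selected"]
                >= counts["probes_pruned"])


class TestEpiSignatureSelectorEstimator:
    def test_sklearn_contract_and_transform(self, small_cohort):
        beta, sheet, truth = small_cohort
        ids = sheet.loc[sheet.group.isin(["case", "control"]), "sample_id"]
        X = beta.loc[:, ids].T
        y = (sheet.set_index("sample_id").loc[ids, "group"] == "case").to_numpy()
        sel = EpiSignatureSelector(alpha=0.01)
        assert clone(sel).get_params()["alpha"] == 0.01
        sel.fit(X, y)
        reduced = sel.transform(X)
        assert list(reduced.columns) == sel.probe_ids_
        assert reduced.shape == (len(ids), len(sel.probe_ids_))
        assert len(set(sel.probe_ids_) & set(truth.signature_probe_ids)) > 0

    def test_requires_both_classes(self, tiny_beta):
        sel = EpiSignatureSelector()
        with pytest.raises(ValueError):
            sel.fit(tiny_beta.T, np.ones(tiny_beta.shape[1]))
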