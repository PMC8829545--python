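"""Mixed-model enrichment, BH correction, and t-test contracts."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytopheno.clustering import ClusterLabels
from cytopheno.glmm import fit_binomial_glmm
from cytopheno.stats import (
    bh_adjust,
    default_contrasts,
    differential_scan,
    enrichment_scan,
    fit_cluster_glmm,
    marker_quantile_lm,
    paired_t,
    unpaired_t,
)
from cytopheno.synthetic import CohortSpec, PopulationArchetype, generate_cohort


def membership_cohort(seed, delta=0.0, subject_sd=0.3, subjects=5,
                      cells=2000, groups=("controller", "acute")):
    """Two-population cohort; binarizing population B gives the exact GLMM."""
    pops = [
        PopulationArchetype("A", np.zeros(2), np.full(2, 0.3)),
        PopulationArchetype("B", np.ones(2), np.full(2, 0.3)),
    ]
    spec = CohortSpec(
        populations=pops, markers=["m1", "m2"], groups=groups,
        subjects_per_group=subjects, cells_per_subject=cells,
        subject_sd=subject_sd, enrichment={(groups[-1], "B"): delta},
        enrichable=["B"], seed=seed,
    )
    t = generate_cohort(spec)
    labels = ClusterLabels(
        labels=(t.truth_population == "B").astype(int), resolution=0.1, seed=0
    )
    subject_groups = {s: t.group[t.subject_id == s][0] for s in t.subjects}
    return t, labels, subject_groups


class TestBinomialGLMM:
    def test_matches_lme4_glmer_laplace_fit(self):
        rng = np.random.default_rng(7)
        m = 12
        x = np.repeat([0, 1], m // 2)
        u = rng.normal(0, 0.4, m)
        n = rng.integers(500, 1500, m)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x + u)))
        y = rng.binomial(n, p)
        fit = fit_binomial_glmm(y, n, np.column_stack([np.ones(m), x]))
        rows = "\n".join(f"{a} {b} {c}" for a, b, c in zip(y, n, x))
        rscript = (
            'suppressMessages(library(lme4));'
            f'd <- read.table(text="{rows}", col.names=c("y","n","x"));'
            'd$subject <- factor(1:nrow(d));'
            'f <- glmer(cbind(y, n-y) ~ x + (1|subject), data=d, family=binomial);'
            'cat(fixef(f), sqrt(diag(vcov(f))), sqrt(unlist(VarCorr(f))[1]), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        b0, b1, se0, se1, sigma = map(float, out.stdout.split())
        assert fit.beta[0] == pytest.approx(b0, abs=1e-3)
        assert fit.beta[1] == pytest.approx(b1, abs=1e-3)
        assert fit.se[1] == pytest.approx(se1, rel=1e-2)
        assert fit.sigma == pytest.approx(sigma, abs=1e-3)

    def test_null_estimates_unbiased_and_nonsignificant(self):
        # planted log-OR 0, subject SD 0.3: the sampling SD of the group
        # coefficient is ~ sqrt(2 sigma^2 / 5) ~ 0.19, so individual
        # estimates scatter accordingly; the mean must sit near 0 and the
        # Wald test must keep its nominal size
        hits, ests = 0, []
        for seed in range(20):
            table, labels, sg = membership_cohort(seed, delta=0.0)
            row = fit_cluster_glmm(labels, 1, table.subject_id, sg, "controller")
            ests.append(row["log_odds_ratio"][0])
            if row["p_value"][0] < 0.05:
                hits += 1
        assert abs(np.mean(ests)) < 0.1
        assert hits <= 3

    def test_planted_effect_recovered(self):
        ests = []
        for seed in range(20):
            table, labels, sg = membership_cohort(seed + 50, delta=1.0)
            row = fit_cluster_glmm(labels, 1, table.subject_id, sg, "controller")
            ests.append(row["log_odds_ratio"][0])
        assert np.mean(ests) == pytest.approx(1.0, abs=0.15)

    def test_sigma_near_zero_for_exchangeable_subjects(self):
        table, labels, sg = membership_cohort(3, delta=0.0, subject_sd=0.0)
        row = fit_cluster_glmm(labels, 1, table.subject_id, sg, "controller")
        assert row["subject_sd"][0] < 0.05

    def test_complete_separation_flagged_not_silent(self):
        y = np.array([0, 0, 0, 500, 500, 500])
        n = np.full(6, 500)
        x = np.repeat([0, 1], 3)
        fit = fit_binomial_glmm(y, n, np.column_stack([np.ones(6), x]))
        assert fit.flag == "separation"


class TestEnrichmentScan:
    def test_single_enriched_population_dominates_discoveries(self):
        # a rare population planted as acute-enriched: its cluster is
        # discovered in every replicate, and false-positive rows among
        # the 21 null (cluster, contrast) pairs stay at FDR-like rarity
        found_true, false_rows, null_rows = 0, 0, 0
        for seed in range(10):
            pops = [
                PopulationArchetype(f"p{j}", np.full(2, float(j)), np.full(2, 0.2),
                                    -2.5 if j == 0 else 0.0)
                for j in range(8)
            ]
            spec = CohortSpec(
                populations=pops, markers=["m1", "m2"],
                groups=("controller", "acute", "chronic"), subjects_per_group=5,
                cells_per_subject=2000, subject_sd=0.3,
                subject_effect="per_population",
                enrichment={("acute", "p0"): 1.2}, seed=seed,
            )
            t = generate_cohort(spec)
            codes = {f"p{j}": j for j in range(8)}
            labels = ClusterLabels(
                labels=np.array([codes[x] for x in t.truth_population]),
                resolution=0.1, seed=0,
            )
            sg = {s: t.group[t.subject_id == s][0] for s in t.subjects}
            res = enrichment_scan(labels, t.subject_id, sg)
            sig = res[res["significant"]]
            found_true += 0 in set(sig["cluster"])
            false_rows += (sig["cluster"] != 0).sum()
            null_rows += (res["cluster"] != 0).sum()
        assert found_true == 10
        assert false_rows / null_rows <= 0.06

    def test_zero_planted_effects_keep_fdr_controlled(self):
        rates = []
        for seed in range(10):
            pops = [
                PopulationArchetype(f"p{j}", np.full(2, float(j)), np.full(2, 0.2))
                for j in range(4)
            ]
            spec = CohortSpec(
                populations=pops, markers=["m1", "m2"],
                groups=("controller", "acute", "chronic"), subjects_per_group=5,
                cells_per_subject=2000, subject_sd=0.3,
                subject_effect="per_population", seed=seed + 300,
            )
            t = generate_cohort(spec)
            codes = {f"p{j}": j for j in range(4)}
            labels = ClusterLabels(
                labels=np.array([codes[x] for x in t.truth_population]),
                resolution=0.1, seed=0,
            )
            sg = {s: t.group[t.subject_id == s][0] for s in t.subjects}
            res = enrichment_scan(labels, t.subject_id, sg)
            rates.append(res["significant"].mean())
        assert np.mean(rates) <= 0.08

    def test_one_cluster_one_contrast_adjusted_equals_raw(self):
        table, labels, sg = membership_cohort(2, delta=0.3)
        # drop cluster 0 cells to leave one tested cluster
        lab = labels.labels.copy()
        lab[lab == 0] = -1
        one = ClusterLabels(labels=lab, resolution=0.1, seed=0)
        res = enrichment_scan(one, table.subject_id, sg,
                              contrasts=[("acute", "controller")])
        assert len(res) == 1
        assert res["adjusted_p"][0] == pytest.approx(res["p_value"][0])

    def test_default_contrasts_for_three_group_design(self):
        got = default_contrasts(["controller", "acute", "chronic"])
        assert got == [("controller", "acute"), ("chronic", "acute"),
                       ("controller", "chronic")]


class TestBH:
    def test_worked_vector_all_collapse_to_largest(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, 0.05)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 12)
            p = rng.random(m)
            q = bh_adjust(p)
            order = np.argsort(p)
            ranks = np.empty(m, dtype=int)
            ranks[order] = np.arange(1, m + 1)
            brute = np.array([
                min(min(p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]), 1.0)
                for i in range(m)
            ])
            np.testing.assert_allclose(q, brute, atol=0)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_agrees_with_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-12).all()


class TestTTests:
    def test_paired_closed_form(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = paired_t(x, np.zeros(3))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_paired_antisymmetry(self):
        x, y = np.array([1.0, 3.0, 2.5]), np.array([0.5, 1.0, 4.0])
        t1, p1 = paired_t(x, y)
        t2, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_paired_symmetric_differences_give_zero_t(self):
        t, p = paired_t(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_paired_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_unpaired_identical_arms(self):
        t, p = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_unpaired_antisymmetry(self):
        x, y = [1.0, 2.0, 4.0], [0.0, 3.0, 3.5, 5.0]
        t1, _ = unpaired_t(x, y)
        t2, _ = unpaired_t(y, x)
        assert t1 == pytest.approx(-t2)

    def test_unpaired_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            unpaired_t([1.0, 1.0], [2.0, 2.0])

    def test_both_match_textbook_formulas_on_random_samples(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(0.3, 1.0, rng.integers(3, 9))
            y = rng.normal(0.0, 1.0, len(x))
            # paired: t = mean(d) / (sd(d)/sqrt(n)), df = n-1
            d = x - y
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p_ref = 2 * sps.t.sf(abs(t_ref), len(d) - 1)
            t, p = paired_t(x, y)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)
            # unpaired, pooled variance, df = n1+n2-2
            z = rng.normal(0.0, 1.0, rng.integers(3, 9))
            n1, n2 = len(x), len(z)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * z.var(ddof=1)) / (n1 + n2 - 2)
            t_ref = (x.mean() - z.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p_ref = 2 * sps.t.sf(abs(t_ref), n1 + n2 - 2)
            t, p = unpaired_t(x, z)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)


class TestDifferentialScan:
    def test_paired_compartment_scan_detects_planted_shift(self):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(10):
            base = rng.normal(20, 2)
            rows.append({"subject_id": f"s{s}", "compartment": "blood",
                         "percentage": base})
            rows.append({"subject_id": f"s{s}", "compartment": "LN",
                         "percentage": base + 5 + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        res = differential_scan({"subset": df}, "percentage", mode="paired",
                                arms=("blood", "LN"))
        assert res["significant"].iloc[0]
        assert res["t"].iloc[0] < 0  # LN arm larger

    def test_undefined_rows_kept_as_missing(self):
        df = pd.DataFrame({
            "subject_id": ["s1", "s2"], "compartment": ["blood", "blood"],
            "percentage": [1.0, 2.0],
        })  # no LN arm at all
        res = differential_scan({"broken": df}, "percentage", mode="paired",
                                arms=("blood", "LN"))
        assert np.isnan(res["p_value"].iloc[0])
        assert not res["significant"].iloc[0]


class TestMarkerQuantileLM:
    @pytest.fixture()
    def gated(self):
        from cytopheno.events import EventTable
        from cytopheno.gating import GateNode, GateTree, evaluate_gate_tree, parse_atom

        rng = np.random.default_rng(1)
        n_per = 30
        frames = []
        for g, shift in (("controller", 0.0), ("acute", 2.0)):
            for s in range(3):
                vals = np.column_stack([
                    np.full(n_per, 5.0),  # gate channel: everyone passes
                    np.full(n_per, shift) + np.linspace(-1, 1, n_per),
                ])
                frames.append(pd.DataFrame({
                    "CD3": vals[:, 0], "PD1": vals[:, 1],
                    "subject_id": f"{g}{s}", "group": g, "compartment": "blood",
                }))
        df = pd.concat(frames, ignore_index=True)
        table = EventTable.from_dataframe(df, markers=["CD3", "PD1"])
        tree = GateTree(nodes=[GateNode("T", "root", [parse_atom("CD3+")])])
        return table, evaluate_gate_tree(table, tree)

    def test_exact_group_difference_recovered(self, gated):
        table, assign = gated
        res = marker_quantile_lm(table, assign, "T", ["PD1"], quantile=0.5,
                                 reference="controller")
        assert res["coefficient"].iloc[0] == pytest.approx(2.0, abs=1e-10)

    def test_quantile_out_of_range_rejected(self, gated):
        table, assign = gated
        with pytest.raises(ValueError, match="quantile"):
            marker_quantile_lm(table, assign, "T", ["PD1"], quantile=1.5)
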