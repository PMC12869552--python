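"""Design construction, BH correction, reporting, and mixed-model fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reprobiome.association import (RichnessMixedModel, bh_adjust,
                                    build_design, report_fraction)


def _samples(n=60, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "state": rng.choice(["CYCLING", "PREGNANT", "PPA"], n),
        "female_id": rng.choice([f"F{i}" for i in range(8)], n),
        "social_group": rng.choice(["G1", "G2", "G3"], n),
        "plate": rng.choice(["P1", "P2", "P3", "P4"], n),
        "age": rng.uniform(5, 20, n),
        "rainfall": rng.gamma(2, 30, n),
        "depth": rng.integers(5000, 60000, n).astype(float),
        "collection_index": np.arange(n, dtype=float),
        "diet_shannon": rng.normal(2.2, 0.3, n),
        "fE_resid": rng.normal(0, 1, n),
        "fP_resid": rng.normal(0, 1, n),
        "fGC_resid": rng.normal(0, 1, n),
    })


class TestBuildDesign:
    def test_reference_coding_gives_two_state_columns(self):
        d = build_design(_samples())
        state_cols = [c for c in d.X.columns if c.startswith("state_")]
        assert sorted(state_cols) == ["state_PPA", "state_PREGNANT"]

    def test_interaction_columns_hormones_by_states(self):
        d = build_design(_samples(), interactions=True)
        inter = [c for c in d.X.columns if ":" in c]
        assert len(inter) == 6  # 3 hormones x 2 non-reference states

    def test_continuous_columns_standardized(self):
        d = build_design(_samples())
        cont = [c for c in d.X.columns if not c.startswith("state_")
                and ":" not in c]
        for c in cont:
            assert abs(d.X[c].mean()) < 1e-9
            assert d.X[c].std(ddof=1) == pytest.approx(1.0)

    def test_missing_covariate_drops_sample_with_warning(self):
        s = _samples()
        s.loc[3, "rainfall"] = np.nan
        with pytest.warns(UserWarning, match="dropped 1"):
            d = build_design(s)
        assert len(d.X) == len(s) - 1
        assert d.dropped["sample_id"].tolist() == ["s3"]


def _bh_oracle(p):
    """Step-up definition: q_(i) = min over j >= i of p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q[order[rank - 1]] = running
    return q


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals),
                                   atol=1e-12)

    def test_monotone_in_sorted_p_order(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestReportFraction:
    @pytest.mark.parametrize("k,n,pct", [
        (92, 401, 22.9), (0, 401, 0.0), (401, 401, 100.0), (1, 3, 33.3),
        (1, 8, 12.5),
    ])
    def test_half_up_percent(self, k, n, pct):
        assert report_fraction(k, n) == pct

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            report_fraction(1, 0)

    def test_k_beyond_n_rejected(self):
        with pytest.raises(ValueError):
            report_fraction(5, 4)


class TestTaxonModels:
    @staticmethod
    def _clr_and_design(seed, n_effect):
        import warnings

        from reprobiome.compositional import clr_transform, filter_prevalence
        from reprobiome.pipeline import label_cohort
        from reprobiome.synthetic import CohortParams, generate_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = generate_cohort(CohortParams(
                n_females=50, seed=seed, n_effect_taxa=n_effect,
                n_recruited_taxa=0))
            labels, _ = label_cohort(cohort)
            df = cohort.samples.merge(
                labels[["sample_id", "state", "excluded"]], on="sample_id")
            df["depth"] = cohort.counts.counts.sum(
                axis=1).loc[df["sample_id"]].values
            kept = df[~df["excluded"]].reset_index(drop=True)
            table = filter_prevalence(cohort.counts, 0.2)
            clr = clr_transform(table.counts).loc[kept["sample_id"]]
            design = build_design(kept, hormones=False)
        return cohort, clr, design

    def test_injected_taxa_flagged_with_high_sensitivity(self):
        """Three taxa with a 0.6 log-fold pregnancy effect among ten
        fitted taxa are flagged (q < 0.05, |beta| > 0.4) in at least 90%
        of taxon-replicates over 20 simulated cohorts; unaffected taxa
        stay unflagged."""
        import warnings

        from reprobiome.association import TaxonMixedModels
        hits = trials = false_pos = null_trials = 0
        for rep in range(20):
            cohort, clr, design = self._clr_and_design(800 + rep, 3)
            effect = [t for t in cohort.truth.effect_taxa
                      if t in clr.columns]
            others = [c for c in clr.columns if c not in effect][:7]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = TaxonMixedModels().fit(design, clr[effect + others])
            flagged = set(model.flagged("state_PREGNANT"))
            hits += len(flagged & set(effect))
            trials += len(effect)
            false_pos += len(flagged - set(effect))
            null_trials += len(others)
        assert hits / trials >= 0.9
        assert false_pos / null_trials <= 0.05

    def test_permuted_labels_flag_almost_nothing(self):
        """Shuffling state labels within females destroys the signal:
        the flagged fraction collapses to roughly the FDR level."""
        import warnings

        import numpy.random as npr

        from reprobiome.association import TaxonMixedModels
        cohort, clr, design = self._clr_and_design(850, 3)
        rng = npr.default_rng(0)
        X = design.X.copy()
        state_cols = ["state_PPA", "state_PREGNANT"]
        for fid, idx in design.groups.groupby("female_id").groups.items():
            perm = rng.permutation(len(idx))
            X.loc[idx, state_cols] = X.loc[idx, state_cols].to_numpy()[perm]
        design.X = X
        taxa = list(clr.columns[:20])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = TaxonMixedModels().fit(design, clr[taxa])
        assert len(model.flagged("state_PREGNANT")) / len(taxa) <= 0.1


class TestRichnessModel:
    def test_adding_constant_shifts_only_the_intercept(self):
        rng = np.random.default_rng(14)
        s = _samples(120, rng)
        y = rng.normal(240, 20, len(s))
        d = build_design(s, hormones=False)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = RichnessMixedModel().fit(d, y).results_.set_index("term")
            r2 = RichnessMixedModel().fit(d, y + 50).results_.set_index("term")
        assert r2.loc["Intercept", "beta"] - r1.loc["Intercept", "beta"] \
            == pytest.approx(50, abs=1e-4)
        other = r1.index.drop("Intercept")
        np.testing.assert_allclose(r1.loc[other, "beta"],
                                   r2.loc[other, "beta"], atol=1e-5)
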