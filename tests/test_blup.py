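import numpy as np
import pandas as pd
import pytest

from herdtrend import tables
from herdtrend.blup import (
    ModelSpec,
    build_mme,
    combine_parities,
    dense_gls_blup,
    realized_trends,
    rebase,
    reliability,
    solve_mme,
)
from herdtrend.pedigree import Pedigree, tabular_A

from conftest import random_pedigree


def single_animal_ped():
    return Pedigree.from_frame(
        pd.DataFrame({"id": ["a"], "sire": [None], "dam": [None], "sex": ["F"]})
    )


def random_instance(rng, n_anim=40, n_rec_frac=0.6, t=2, missing=0.3):
    ped = random_pedigree(rng, n_anim)
    W = rng.normal(size=(t, t))
    G = W @ W.T + t * np.eye(t)
    W = rng.normal(size=(t, t))
    E = W @ W.T + t * np.eye(t)
    traits = tuple(f"tr{i}" for i in range(t))
    model = ModelSpec(traits=traits, G=G, E=E, fixed_effects=("hys",))
    rows = []
    rec_animals = [a for a in ped.ids if rng.random() < n_rec_frac]
    for a in rec_animals:
        row = {"animal": a, "hys": f"h{rng.integers(3)}"}
        y = rng.normal(size=t)
        obs = rng.random(t) >= missing
        if not obs.any():
            obs[rng.integers(t)] = True
        for i, tr in enumerate(traits):
            row[tr] = y[i] if obs[i] else np.nan
        rows.append(row)
    return ped, model, pd.DataFrame(rows)


class TestBuildAndSolve:
    def test_scalar_shrinkage_closed_form(self):
        g, e, y = 4.0, 2.0, 3.0
        model = ModelSpec(traits=("y",), G=[[g]], E=[[e]], fixed_effects=())
        system = build_mme(pd.DataFrame({"animal": ["a"], "y": [y]}), model,
                          single_animal_ped())
        sol = solve_mme(system)
        assert sol[0] == pytest.approx(y * g / (g + e))

    def test_no_records_zero_ebvs(self):
        model = ModelSpec(traits=("y",), G=[[1.0]], E=[[1.0]], fixed_effects=())
        recs = pd.DataFrame({"animal": pd.Series(dtype=object), "y": pd.Series(dtype=float)})
        ped = random_pedigree(np.random.default_rng(0), 10)
        system = build_mme(recs, model, ped)
        np.testing.assert_allclose(solve_mme(system), 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_gls(self, seed):
        """Sparse MME solutions equal dense GLS/BLUP with missing traits."""
        rng = np.random.default_rng(seed)
        ped, model, recs = random_instance(rng)
        system = build_mme(recs, model, ped)
        res_sparse = system.split(solve_mme(system))
        res_dense = dense_gls_blup(recs, model, ped, tabular_A(ped))
        np.testing.assert_allclose(
            res_sparse.ebv.to_numpy(), res_dense.ebv.to_numpy(), atol=1e-8
        )
        for key, val in res_sparse.fixed.items():
            assert val == pytest.approx(res_dense.fixed[key], abs=1e-8)

    def test_direct_and_cg_agree(self):
        rng = np.random.default_rng(7)
        ped, model, recs = random_instance(rng, n_anim=120)
        system = build_mme(recs, model, ped)
        direct = solve_mme(system, method="direct")
        cg = solve_mme(system, method="cg", tol=1e-12)
        assert np.abs(direct - cg).max() < 1e-6

    def test_record_order_invariance(self):
        rng = np.random.default_rng(9)
        ped, model, recs = random_instance(rng)
        system1 = build_mme(recs, model, ped)
        shuffled = recs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        system2 = build_mme(shuffled, model, ped)
        np.testing.assert_allclose(
            solve_mme(system1), solve_mme(system2), atol=1e-8
        )

    def test_unknown_animal_rejected(self):
        model = ModelSpec(traits=("y",), G=[[1.0]], E=[[1.0]], fixed_effects=())
        recs = pd.DataFrame({"animal": ["ghost"], "y": [1.0]})
        from herdtrend.pedigree import PedigreeError

        with pytest.raises(PedigreeError, match="unknown animal"):
            build_mme(recs, model, single_animal_ped())


class TestReliability:
    def test_unrelated_animal_without_records_zero(self):
        rng = np.random.default_rng(1)
        ped, model, recs = random_instance(rng, n_anim=20, n_rec_frac=0.5)
        system = build_mme(recs, model, ped)
        rel = reliability(system)
        founders = set(ped.ids[ped.is_founder])
        recorded = set(recs["animal"])
        # an unrelated founder with no records and no recorded descendants
        A = tabular_A(ped)
        for i, a in enumerate(ped.ids):
            if a in founders and a not in recorded:
                related = [j for j, b in enumerate(ped.ids)
                           if b in recorded and A[i, j] != 0]
                if not related:
                    assert rel.loc[a].max() == pytest.approx(0.0, abs=1e-9)

    def test_near_perfect_record_high_reliability(self):
        model = ModelSpec(traits=("y",), G=[[4.0]], E=[[1e-8]], fixed_effects=())
        system = build_mme(pd.DataFrame({"animal": ["a"], "y": [1.0]}), model,
                          single_animal_ped())
        rel = reliability(system)
        assert rel.iloc[0, 0] > 1 - 1e-6

    def test_matches_dense_pev(self):
        """r^2 from the sparse system equals 1 - PEV/G with PEV from the
        dense inverse coefficient matrix."""
        rng = np.random.default_rng(4)
        ped, model, recs = random_instance(rng, n_anim=50, missing=0.0)
        system = build_mme(recs, model, ped)
        rel = reliability(system)
        Cinv = np.linalg.pinv(system.C.toarray())
        t = len(model.traits)
        for pos, a in enumerate(ped.ids):
            for i in range(t):
                k = system.genetic_offset(pos, i)
                expect = 1.0 - Cinv[k, k] / model.G[i, i]
                assert rel.loc[a].iloc[i] == pytest.approx(max(expect, 0.0), abs=1e-9)

    def test_size_limit(self):
        rng = np.random.default_rng(5)
        ped, model, recs = random_instance(rng, n_anim=30)
        system = build_mme(recs, model, ped)
        with pytest.raises(ValueError, match="dense inversion limit"):
            reliability(system, dense_limit=10)


class TestRebase:
    def _ebv(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            rng.normal(size=(20, 2)), columns=["a", "b"],
            index=[f"x{i}" for i in range(20)]
        )

    def test_whole_population_base_sums_to_zero(self):
        ebv = self._ebv()
        out = rebase(ebv, np.ones(20, dtype=bool))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self):
        ebv = self._ebv()
        mask = np.zeros(20, dtype=bool)
        mask[:5] = True
        once = rebase(ebv, mask)
        twice = rebase(once, mask)
        pd.testing.assert_frame_equal(once, twice)

    def test_shift_invariance(self):
        ebv = self._ebv()
        mask = np.zeros(20, dtype=bool)
        mask[3:9] = True
        base = rebase(ebv, mask)
        shifted = rebase(ebv + 17.5, mask)
        pd.testing.assert_frame_equal(base, shifted)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty base cohort"):
            rebase(self._ebv(), np.zeros(20, dtype=bool))


class TestCombineParities:
    def test_first_parity_only(self):
        p1 = pd.DataFrame({"y": [10.0]}, index=["a"])
        p2 = pd.DataFrame({"y": [20.0]}, index=["a"])
        p3 = pd.DataFrame({"y": [30.0]}, index=["a"])
        out = combine_parities([p1, p2, p3], [1, 0, 0])
        assert out.loc["a", "y"] == 10.0

    def test_weighted_average(self):
        frames = [pd.DataFrame({"y": [v]}, index=["a"]) for v in (10.0, 20.0, 30.0)]
        out = combine_parities(frames, [0.5, 0.3, 0.2])
        assert out.loc["a", "y"] == pytest.approx(17.0)

    def test_weights_normalized(self):
        frames = [pd.DataFrame({"y": [v]}, index=["a"]) for v in (10.0, 20.0)]
        out = combine_parities(frames, [2.0, 2.0])
        assert out.loc["a", "y"] == pytest.approx(15.0)

    def test_negative_weights_rejected(self):
        frames = [pd.DataFrame({"y": [1.0]}, index=["a"])] * 2
        with pytest.raises(ValueError, match="non-negative"):
            combine_parities(frames, [1.0, -0.5])


class TestRealizedTrends:
    def _dates(self, years):
        return pd.Series(pd.to_datetime([f"{y}-06-01" for y in years]),
                         index=[f"c{i}" for i in range(len(years))])

    def test_constant_ebv_zero_slope(self):
        years = [2000, 2001, 2002, 2003]
        ebv = pd.DataFrame({"y": np.ones(4)}, index=[f"c{i}" for i in range(4)])
        out = realized_trends(ebv, self._dates(years))
        assert out.loc["y", "slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        years = np.array([2000, 2001, 2002, 2003, 2004])
        dates = self._dates(years)
        days = (dates - dates.min()).dt.days.to_numpy()
        ebv = pd.DataFrame({"y": 2.5 * days / 365.25},
                           index=[f"c{i}" for i in range(5)])
        out = realized_trends(ebv, dates)
        assert out.loc["y", "slope"] == pytest.approx(2.5, rel=1e-9)
        assert out.loc["y", "se"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_within_sampling_bounds(self):
        rng = np.random.default_rng(0)
        n = 10_000
        years = rng.integers(2000, 2010, n)
        dates = pd.Series(
            pd.to_datetime([f"{y}-06-01" for y in years]),
            index=[f"c{i}" for i in range(n)],
        )
        days = (dates - dates.min()).dt.days.to_numpy()
        ebv = pd.DataFrame({"y": 2.5 * days / 365.25 + rng.normal(0, 1, n)},
                           index=dates.index)
        out = realized_trends(ebv, dates)
        assert abs(out.loc["y", "slope"] - 2.5) < 3 * out.loc["y", "se"] + 1e-9

    def test_too_few_dates_rejected(self):
        ebv = pd.DataFrame({"y": [1.0, 2.0]}, index=["a", "b"])
        dates = pd.Series(pd.to_datetime(["2000-01-01", "2000-01-01"]),
                          index=["a", "b"])
        with pytest.raises(ValueError, match="3 distinct birth dates"):
            realized_trends(ebv, dates)


class TestEbvQuality:
    def test_blup_unbiased_and_correlated_with_truth(self):
        """On a correctly specified simulation, regression of true BV on EBV
        has slope ~1 and EBV-truth correlation increases with reliability."""
        from herdtrend.simdata import SimConfig, simulate_all

        cfg = SimConfig(seed=31, n_founders=330, n_generations=2, dams_per_sire=10,
                        progeny_per_dam=2, n_herds=4, n_snps=10, n_causal=0,
                        traits=tables.TRAITS)
        ped, truth, phen, _, _ = simulate_all(cfg)
        traits = ["protein"]
        sub = phen[(phen.parity == 1) & (phen.trait == "protein")]
        recs = sub.rename(columns={"value": "protein"})[["animal", "hys", "protein"]]
        model = ModelSpec(traits=("protein",),
                          G=tables.submatrix(cfg.G, traits),
                          E=tables.submatrix(cfg.E, traits),
                          fixed_effects=("hys",))
        system = build_mme(recs, model, ped)
        res = system.split(solve_mme(system))
        ebv = res.ebv["protein"]
        tbv = truth.breeding_values["protein"]
        recorded = recs["animal"].unique()
        x, y = ebv.loc[recorded].to_numpy(), tbv.loc[recorded].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)
        assert np.corrcoef(x, y)[0, 1] > 0.5
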