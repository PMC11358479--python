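"""Quadratic-logistic niche model: labelling, fitting, validation scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from paleodisp import (
    LandMask,
    NicheLogistic,
    NicheModel,
    ScalarField,
    SiteCatalog,
    auc,
    brier_score,
    brier_skill_score,
    build_grid,
    build_presence_absence,
    fit_niche,
    standardize,
    train_ensemble,
)
from paleodisp.niche import PresenceAbsenceSet, _design
from paleodisp.exceptions import (
    DegeneratePredictorError,
    UndefinedScoreError,
    UnfittableDataError,
)


def _truth_model():
    A = np.array(
        [
            [-1.2, 0.3, 0.0, 0.0],
            [0.3, -0.6, 0.0, 0.0],
            [0.0, 0.0, 0.6, -0.2],
            [0.0, 0.0, -0.2, -0.4],
        ]
    )
    B = np.array([2.5, 1.5, -2.0, 1.0])
    return NicheModel(A, B, 0.3)


def _simulated_pa(n, seed, model=None):
    rng = np.random.default_rng(seed)
    P = rng.standard_normal((n, 4))
    model = model or _truth_model()
    phi = model.predict(P)
    y = (rng.random(n) < phi).astype(int)
    cells = np.column_stack([np.arange(n) // 1000, np.arange(n) % 1000])
    return (
        PresenceAbsenceSet(
            cells=cells,
            x_raw=P,
            labels=y,
            provenance=np.array(["presence" if v else "pseudo-absence" for v in y]),
            n_presence=int(y.sum()),
            n_pseudo=int((1 - y).sum()),
        ),
        P,
        phi,
    )


class TestStandardize:
    def test_unit_moments(self):
        z, m, s = standardize(np.array([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            standardize(np.full(5, 2.0))

    def test_new_value_at_mean_maps_to_zero(self):
        _, m, s = standardize(np.array([2.0, 4.0, 6.0]))
        assert (4.0 - m) / s == 0.0


class TestPresenceAbsence:
    @pytest.fixture
    def setup(self):
        grid = build_grid((0.0, 5.0), (40.0, 45.0), 0.5)
        land = np.ones(grid.shape, dtype=bool)
        mask = LandMask(grid, land)
        rng = np.random.default_rng(3)
        fields = {
            "T_m": ScalarField(grid, rng.uniform(0, 12, grid.shape), units="degC"),
            "T_delta": ScalarField(grid, rng.uniform(4, 8, grid.shape), units="degC"),
            "R_m": ScalarField(grid, rng.uniform(60, 160, grid.shape), units="mm"),
            "R_delta": ScalarField(grid, rng.uniform(30, 50, grid.shape), units="%"),
        }
        return grid, mask, fields

    def _sites(self, rows):
        return SiteCatalog(
            pd.DataFrame(rows, columns=["id", "lon", "lat", "phase"])
        )

    def test_stacked_sites_collapse_to_one_presence(self, setup):
        grid, mask, fields = setup
        sites = self._sites(
            [("a", 1.1, 40.6, "P1"), ("b", 1.2, 40.7, "P1"), ("c", 3.3, 43.3, "P1")]
        )
        pa = build_presence_absence(sites, fields, grid, mask, seed=0)
        assert pa.n_presence == 2

    def test_duplicated_catalogue_is_idempotent(self, setup):
        grid, mask, fields = setup
        rows = [("a", 1.1, 40.6, "P1"), ("c", 3.3, 43.3, "P1")]
        dup = rows + [(f"{i}x", lon, lat, ph) for i, (_, lon, lat, ph) in enumerate(rows)]
        pa1 = build_presence_absence(self._sites(rows), fields, grid, mask, seed=9)
        pa2 = build_presence_absence(self._sites(dup), fields, grid, mask, seed=9)
        assert pa1.n_presence == pa2.n_presence
        assert np.array_equal(pa1.labels, pa2.labels)
        assert np.allclose(pa1.x_raw, pa2.x_raw)

    def test_cold_cell_is_apriori_absence(self, setup):
        grid, mask, fields = setup
        cold = fields["T_m"].values.copy()
        i, j = grid.locate(4.6, 44.6)
        cold[i, j] = -5.0
        fields = dict(fields, T_m=ScalarField(grid, cold, units="degC"))
        sites = self._sites([("a", 1.1, 40.6, "P1")])
        pa = build_presence_absence(sites, fields, grid, mask, seed=0)
        k = next(
            idx for idx, c in enumerate(pa.cells) if tuple(c) == (i, j)
        )
        assert pa.provenance[k] == "a-priori-absence"
        assert pa.labels[k] == 0

    def test_option1_exclusion_arithmetic(self, setup):
        grid, mask, fields = setup
        # force a-priori absences: chill 20 site-free cells
        cold = fields["T_m"].values.copy()
        cold[:2, :] = -10.0
        fields = dict(fields, T_m=ScalarField(grid, cold, units="degC"))
        sites = self._sites([("a", 1.1, 43.6, "P1")])
        pa = build_presence_absence(
            sites, fields, grid, mask, pseudo_absence_option=1, seed=0
        )
        n_cells = grid.nlat * grid.nlon
        assert len(pa) == 1 + 20  # presences + a-priori absences only
        assert pa.n_pseudo == n_cells - len(pa)

    def test_option3_label_rate_matches_presence_fraction(self, setup):
        grid, mask, fields = setup
        sites = self._sites(
            [(f"s{k}", 0.3 + 0.5 * k, 40.2, "P1") for k in range(8)]
        )
        ones = []
        for seed in range(30):
            pa = build_presence_absence(
                sites, fields, grid, mask, pseudo_absence_option=3, seed=seed
            )
            pseudo = pa.provenance == "pseudo-absence"
            ones.append(pa.labels[pseudo].mean())
        p = pa.n_presence / (pa.n_presence + pa.n_pseudo)
        se = np.sqrt(p * (1 - p) / (pa.n_pseudo * 30))
        assert np.mean(ones) == pytest.approx(p, abs=3 * se)

    def test_block_aggregation_reduces_records(self, setup):
        grid, mask, fields = setup
        sites = self._sites([("a", 1.1, 40.6, "P1"), ("b", 1.6, 40.6, "P1")])
        pa_cell = build_presence_absence(sites, fields, grid, mask, seed=0)
        pa_block = build_presence_absence(
            sites, fields, grid, mask, block_size=1.0, seed=0
        )
        assert pa_block.n_presence == 1  # both sites fall in one 1-degree block
        assert pa_cell.n_presence == 2
        assert len(pa_block) < len(pa_cell)

    def test_no_presence_raises(self, setup):
        grid, mask, fields = setup
        with pytest.raises(UnfittableDataError):
            build_presence_absence(self._sites([]), fields, grid, mask, seed=0)


class TestQuadraticLogistic:
    def test_predict_closed_forms(self):
        m = NicheModel(np.zeros((4, 4)), np.zeros(4), 0.0)
        assert m.predict(np.zeros((1, 4)))[0] == 0.5
        m = NicheModel(np.zeros((4, 4)), np.zeros(4), np.log(3.0))
        assert m.predict(np.ones((3, 4)))[0] == pytest.approx(0.75)

    def test_phi_strictly_inside_unit_interval_and_monotone_in_q(self):
        m = _truth_model()
        P = np.random.default_rng(0).standard_normal((500, 4))
        q = m.q(P)
        phi = m.predict(P)
        assert np.all((phi > 0) & (phi < 1))
        order = np.argsort(q)
        assert np.all(np.diff(phi[order]) >= 0)

    def test_parameter_recovery_within_three_standard_errors(self):
        pa, P, _ = _simulated_pa(5000, seed=11)
        # fit in the same (already standard normal) basis the truth uses
        res = NicheLogistic(pa.labels, P).fit()
        truth = _truth_model().to_vector()
        z = np.abs(res.params_vector() - truth) / res.bse
        assert np.all(z < 3.0)

    def test_single_class_rejected(self):
        with pytest.raises(UnfittableDataError):
            NicheLogistic(np.zeros(50), np.random.default_rng(0).standard_normal((50, 4)))

    def test_null_data_shrinks_coefficients(self):
        rng = np.random.default_rng(21)
        P = rng.standard_normal((4000, 4))
        y = rng.random(4000) < 0.4  # labels independent of predictors
        res = NicheLogistic(y.astype(int), P).fit()
        vec = res.params_vector()
        assert np.max(np.abs(vec[1:])) < 0.15
        ens = train_ensemble(
            PresenceAbsenceSet(
                cells=np.column_stack([np.arange(4000) // 1000, np.arange(4000) % 1000]),
                x_raw=P,
                labels=y.astype(int),
                provenance=np.array(["presence"] * 4000),
                n_presence=int(y.sum()),
                n_pseudo=0,
            ),
            n_members=20,
            seed=5,
        )
        assert abs(ens.bss) < 0.05

    def test_matches_statsmodels_glm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        pa, _, _ = _simulated_pa(1500, seed=31)
        res = NicheLogistic.from_presence_absence(pa).fit(ridge=0.0)
        X = _design(pa.x)
        glm = sm.GLM(pa.labels, X, family=sm.families.Binomial()).fit()
        assert np.allclose(res.params_vector(), glm.params, atol=1e-6)
        assert np.allclose(res.bse, glm.bse, rtol=1e-4)

    def test_summary_mentions_terms(self):
        pa, _, _ = _simulated_pa(800, seed=41)
        res = NicheLogistic.from_presence_absence(pa).fit()
        text = res.summary()
        assert "B[T_m]" in text and "log-lik" in text

    def test_fit_niche_wrapper_returns_symmetric_A(self):
        pa, _, _ = _simulated_pa(800, seed=42)
        model = fit_niche(pa)
        assert np.array_equal(model.A, model.A.T)


class TestScores:
    def test_perfect_predictions_give_unit_skill(self):
        labels = np.array([1.0, 0.0, 1.0, 1.0])
        ref = np.full(4, 0.5)
        assert brier_score(labels, labels) == 0.0
        assert brier_skill_score([labels], [labels], [ref]) == 1.0

    def test_reference_member_contributes_zero(self):
        labels = np.array([1.0, 0.0])
        ref = np.full(2, 0.5)
        assert brier_skill_score([ref], [labels], [ref]) == 0.0

    def test_half_probability_brier_value(self):
        assert brier_score(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == 0.25

    def test_zero_reference_score_rejected(self):
        labels = np.array([1.0, 0.0])
        with pytest.raises(UndefinedScoreError):
            brier_skill_score([labels], [labels], [labels])

    def test_auc_extremes(self):
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0
        assert auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0])) == 0.5

    def test_auc_single_class_rejected(self):
        with pytest.raises(UndefinedScoreError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_auc_null_distribution(self):
        rng = np.random.default_rng(17)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_auc_matches_mann_whitney(self):
        rng = np.random.default_rng(19)
        scores = np.round(rng.random(400), 2)  # ties on purpose
        labels = rng.integers(0, 2, 400)
        n1, n0 = labels.sum(), (1 - labels).sum()
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc(scores, labels) == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestEnsembleTraining:
    def test_single_member_has_zero_spread(self):
        pa, P, _ = _simulated_pa(600, seed=51)
        ens = train_ensemble(pa, n_members=1, seed=2)
        assert np.all(ens.std_phi(P) == 0.0)

    def test_same_seed_is_bit_identical(self):
        pa, P, _ = _simulated_pa(600, seed=52)
        a = train_ensemble(pa, n_members=5, seed=3)
        b = train_ensemble(pa, n_members=5, seed=3)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.A, mb.A)
            assert np.array_equal(ma.B, mb.B)
            assert ma.C == mb.C
        assert np.array_equal(a.member_bs, b.member_bs)

    def test_mean_field_stays_in_unit_interval(self):
        pa, P, _ = _simulated_pa(600, seed=53)
        ens = train_ensemble(pa, n_members=8, seed=4)
        mean = ens.mean_phi(P)
        assert np.all((mean >= 0) & (mean <= 1))
        assert np.all(ens.std_phi(P) >= 0)

    def test_roundtrip_serialization(self):
        pa, P, _ = _simulated_pa(400, seed=54)
        ens = train_ensemble(pa, n_members=3, seed=6)
        from paleodisp.niche import NicheEnsemble

        clone = NicheEnsemble.from_dict(ens.to_dict())
        assert np.allclose(clone.mean_phi(P), ens.mean_phi(P))
        assert clone.bss == pytest.approx(ens.bss)
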