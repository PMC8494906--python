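"""Closed-population likelihood against a brute-force oracle, AICc and
model-averaging rules."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

import opencamscr as oc
from opencamscr.capture_data import ClosedSessionHistory
from opencamscr.scr_closed import ClosedModelSpec, aicc, closed_loglik, model_average
from opencamscr.statespace import StateSpaceMask


# ---------------------------------------------------------------------- #
# independent brute-force likelihood (nested loops, no shared code paths)
# ---------------------------------------------------------------------- #

def brute_force_loglik(hist, mask, spec, params):
    D = params["D"]
    ncls = 1 if spec.model_id == "M0" else 2
    g0s = list(params["g0"]) * (ncls if len(params["g0"]) == 1 else 1)
    sigs = list(params["sigma"]) * (ncls if len(params["sigma"]) == 1 else 1)
    pmix = params.get("pmix")
    a = mask.cell_area
    n, J, K = hist.y.shape

    def pday(c, d):
        return g0s[c] * math.exp(-d * d / (2 * sigs[c] ** 2))

    def w(i, c):
        if ncls == 1:
            return 1.0
        base = pmix if c == 0 else 1.0 - pmix
        if hist.sexes[i] == 0:
            return base if c == 0 else 0.0
        if hist.sexes[i] == 1:
            return base if c == 1 else 0.0
        return base

    Lambda = 0.0
    for cell in mask.cell_centres:
        for c in range(ncls):
            prod = 1.0
            for j in range(J):
                d = math.hypot(cell[0] - hist.site_coords[j, 0],
                               cell[1] - hist.site_coords[j, 1])
                for k in range(K):
                    p = 1.0 - (1.0 - pday(c, d)) ** hist.usage[j, k]
                    prod *= 1.0 - p
            wc = 1.0 if ncls == 1 else (pmix if c == 0 else 1.0 - pmix)
            Lambda += D * a * wc * (1.0 - prod)

    ll = -Lambda - float(gammaln(n + 1))
    for i in range(n):
        total = 0.0
        for cell in mask.cell_centres:
            for c in range(ncls):
                prod = 1.0
                for j in range(J):
                    d = math.hypot(cell[0] - hist.site_coords[j, 0],
                                   cell[1] - hist.site_coords[j, 1])
                    for k in range(K):
                        p = 1.0 - (1.0 - pday(c, d)) ** hist.usage[j, k]
                        prod *= p if hist.y[i, j, k] else 1.0 - p
                total += D * a * w(i, c) * prod
        ll += math.log(total)
    return ll


def _tiny_instance(seed=0, n=2, J=3, K=3, sexes=(0, -1)):
    rng = np.random.default_rng(seed)
    coords = np.array([[0.0, 0.0], [2_000.0, 0.0], [0.0, 2_000.0]])[:J]
    y = (rng.random((n, J, K)) < 0.3).astype(np.uint8)
    y[y.sum(axis=(1, 2)) == 0, 0, 0] = 1  # every individual detected
    usage = rng.integers(1, 6, (J, K))
    hist = ClosedSessionHistory(
        y=y, usage=usage, site_coords=coords,
        sexes=np.array(sexes[:n], dtype=np.int8), days_per_occasion=5,
    )
    gx, gy = np.meshgrid(np.linspace(-2_000, 4_000, 4), np.linspace(-2_000, 4_000, 4))
    mask = StateSpaceMask(
        cell_centres=np.column_stack([gx.ravel(), gy.ravel()]),
        spacing=2_000.0, buffer_width=2_000.0, bounds=(-3_000, 5_000, -3_000, 5_000),
    )
    return hist, mask


class TestHalfNormal:
    def test_value_at_centre(self):
        assert oc.halfnormal_p(0.0, 0.3, 4_000.0) == pytest.approx(0.3)

    def test_half_maximum_distance(self):
        sigma = 4_000.0
        d = sigma * math.sqrt(2 * math.log(2))
        assert oc.halfnormal_p(d, 0.2, sigma) == pytest.approx(0.1)

    def test_monotone_decay_to_zero(self):
        d = np.linspace(0, 60_000, 100)
        p = oc.halfnormal_p(d, 0.01, 4_000.0)
        assert np.all(np.diff(p) <= 0)
        assert p[-1] < 1e-10

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            oc.halfnormal_p(10.0, 0.1, 0.0)


class TestClosedLoglik:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("model_id", ["M0", "sex_on_sigma", "sex_on_g0_sigma"])
    def test_matches_brute_force(self, seed, model_id):
        hist, mask = _tiny_instance(seed, n=3, sexes=(0, 1, -1))
        spec = ClosedModelSpec(model_id)
        params = {"D": 0.005, "g0": (0.05, 0.08)[: spec.n_classes],
                  "sigma": (1_500.0, 2_500.0)[: spec.n_classes], "pmix": 0.6}
        assert closed_loglik(hist, mask, spec, params) == pytest.approx(
            brute_force_loglik(hist, mask, spec, params), abs=1e-8
        )

    def test_single_site_single_occasion_hand_case(self):
        hist, mask = _tiny_instance(3, n=1, J=1, K=1, sexes=(0,))
        params = {"D": 0.01, "g0": (0.1,), "sigma": (2_000.0,)}
        spec = ClosedModelSpec("M0")
        assert closed_loglik(hist, mask, spec, params) == pytest.approx(
            brute_force_loglik(hist, mask, spec, params), abs=1e-10
        )

    def test_lambda_invariant_to_cell_bookkeeping(self):
        """Same geometry expressed with double cell area and half the cells
        leaves the expected count Lambda (hence the -Lambda term) unchanged."""
        hist, mask = _tiny_instance(4)
        spec = ClosedModelSpec("M0")
        params = {"D": 0.004, "g0": (0.05,), "sigma": (2_000.0,)}
        half = StateSpaceMask(
            cell_centres=mask.cell_centres[::2], spacing=mask.spacing * np.sqrt(2),
            buffer_width=mask.buffer_width, bounds=mask.bounds,
        )
        # cross-check through the brute-force oracle on both representations
        full = brute_force_loglik(hist, mask, spec, params)
        assert closed_loglik(hist, mask, spec, params) == pytest.approx(full, abs=1e-8)
        half_ll = brute_force_loglik(hist, half, spec, params)
        assert closed_loglik(hist, half, spec, params) == pytest.approx(half_ll, abs=1e-8)

    def test_unknown_sex_pmix_one_is_female_likelihood(self):
        hist, mask = _tiny_instance(5, n=2, sexes=(-1, -1))
        mix = closed_loglik(
            hist, mask, ClosedModelSpec("sex_on_sigma"),
            {"D": 0.004, "g0": (0.05, 0.05), "sigma": (1_800.0, 3_000.0), "pmix": 1.0},
        )
        female_only = closed_loglik(
            hist, mask, ClosedModelSpec("M0"),
            {"D": 0.004, "g0": (0.05,), "sigma": (1_800.0,)},
        )
        assert mix == pytest.approx(female_only, abs=1e-10)

    def test_relabeling_invariance(self):
        hist, mask = _tiny_instance(6, n=3, sexes=(0, 1, -1))
        spec = ClosedModelSpec("M0")
        params = {"D": 0.004, "g0": (0.06,), "sigma": (2_200.0,)}
        base = closed_loglik(hist, mask, spec, params)
        perm = [2, 0, 1]
        hist2 = ClosedSessionHistory(
            y=hist.y[perm], usage=hist.usage, site_coords=hist.site_coords,
            sexes=hist.sexes[perm], days_per_occasion=5,
        )
        assert closed_loglik(hist2, mask, spec, params) == pytest.approx(base, abs=1e-10)

    def test_all_zero_history_rejected(self):
        hist, mask = _tiny_instance(7)
        hist.y[:] = 0
        with pytest.raises(ValueError):
            closed_loglik(hist, mask, ClosedModelSpec("M0"),
                          {"D": 0.004, "g0": (0.05,), "sigma": (2_000.0,)})


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-100.0, 3, 20) == pytest.approx(207.5)

    def test_no_parameters(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)

    def test_converges_to_aic(self):
        assert aicc(-100.0, 3, 10 ** 9) == pytest.approx(206.0, abs=1e-6)

    def test_undefined_small_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 3, 4)


class TestModelAverage:
    def _fit(self, model_id, D, se, aicc_value):
        from opencamscr.scr_closed import ClosedFitResult

        return ClosedFitResult(
            model_id=model_id, estimates={"D": D}, se={"D": se},
            ci={"D": (D - 2 * se, D + 2 * se)}, loglik=-100.0, K=3, n=20,
            aicc_value=aicc_value, converged=True, spatial_recaptures=5,
        )

    def test_single_model_passthrough(self):
        avg = model_average([self._fit("M0", 0.012, 0.002, 100.0)])
        assert avg.density_per_100km2 == pytest.approx(1.2)

    def test_equal_weights_midpoint(self):
        avg = model_average(
            [self._fit("M0", 0.010, 0.002, 100.0),
             self._fit("sex_on_sigma", 0.020, 0.002, 100.0)]
        )
        assert avg.density_per_100km2 == pytest.approx(1.5)

    def test_delta_two_excluded(self):
        avg = model_average(
            [self._fit("M0", 0.010, 0.002, 100.0),
             self._fit("sex_on_sigma", 0.020, 0.002, 102.0)]
        )
        assert avg.retained == ["M0"]
        assert avg.density_per_100km2 == pytest.approx(1.0)

    def test_no_converged_fits(self):
        f = self._fit("M0", 0.01, 0.002, 100.0)
        f.converged = False
        with pytest.raises(ValueError):
            model_average([f])


class TestFitClosed:
    def test_no_spatial_recaptures_flagged(self):
        hist, mask = _tiny_instance(8, n=2, sexes=(0, 1))
        hist.y[:] = 0
        hist.y[0, 0, 0] = 1
        hist.y[1, 1, 0] = 1
        fit = oc.fit_closed(hist, mask, ClosedModelSpec("M0"))
        assert fit.spatial_recaptures == 0
        assert not fit.converged
        assert any("spatial" in w for w in fit.warnings)

    def test_m0_preferred_on_sexless_data(self, study_array, study_mask):
        """With no real sex effect, dAICc should favour the null model in
        the majority of replicates."""
        from opencamscr.capture_data import collapse_occasions

        wins = 0
        for s in range(5):
            p = oc.SimulationParams(
                n_primary=1, n_secondary=100, N_initial=50, seed=40 + s,
                g0=(0.012, 0.012), sigma=(4_000.0, 4_000.0), psi=0.5,
            )
            traj = oc.simulate_population(p, study_mask)
            h = oc.simulate_detections(traj, study_array, p)
            ch = collapse_occasions(h, 5)
            f0 = oc.fit_closed(ch, study_mask, ClosedModelSpec("M0"))
            f1 = oc.fit_closed(ch, study_mask, ClosedModelSpec("sex_on_sigma"))
            if f0.aicc_value < f1.aicc_value:
                wins += 1
        assert wins >= 3
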