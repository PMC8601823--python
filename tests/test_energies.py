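"""Localized statistics and speeds against naive pure-Python oracles."""

import numpy as np
import pytest

from alrls.config import RunConfig
from alrls.energies import (
    ball_mask,
    evolution_fields,
    energy_value,
    local_stats,
    ms_speed,
    um_speed,
)
from alrls.level_set import dirac, heaviside, init_phi_circle
from alrls.preprocess import normalize


# ---------------------------------------------------------------------------
# oracles: deliberately naive loops, independent of the implementation


def oracle_ball_cells(center, radius, shape):
    cells = []
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                cells.append((r, c))
    return cells


def oracle_local_stats(image, phi, center, radius, eps):
    su = sv = au = av = 0.0
    for r, c in oracle_ball_cells(center, radius, image.shape):
        h = float(heaviside(phi[r, c], eps))
        au += h
        av += 1.0 - h
        su += h * image[r, c]
        sv += (1.0 - h) * image[r, c]
    u = su / au if au >= 1e-8 else 0.0
    v = sv / av if av >= 1e-8 else 0.0
    return u, v, au, av


def oracle_speed(image, phi, x, cfg, model):
    ix = image[x[0], x[1]]
    total = 0.0
    for r, c in oracle_ball_cells(x, cfg.ball_radius, image.shape):
        dl = float(dirac(phi[r, c], cfg.epsilon_heaviside))
        if dl == 0.0:
            continue
        u, v, au, av = oracle_local_stats(image, phi, (r, c), cfg.ball_radius, cfg.epsilon_heaviside)
        if au < 1e-8 or av < 1e-8:
            continue
        if model == "UM":
            total += dl * (cfg.lambda1 * (ix - u) ** 2 - cfg.lambda2 * (ix - v) ** 2)
        else:
            total += dl * (cfg.lambda2 * (ix - u) ** 2 / au - cfg.lambda1 * (ix - v) ** 2 / av)
    return total


def random_instance(seed, shape=(16, 16)):
    rng = np.random.default_rng(seed)
    image = rng.random(shape)
    center = (rng.integers(4, shape[0] - 4), rng.integers(4, shape[1] - 4))
    phi = init_phi_circle(shape, center, rng.integers(2, 5))
    return image, phi


# ---------------------------------------------------------------------------


class TestBallMask:
    def test_radius_one_is_plus_shape(self):
        ball = ball_mask((8, 8), 1, (16, 16))
        assert int(ball.mask.sum()) == 5

    def test_corner_clipping(self):
        ball = ball_mask((0, 0), 6, (16, 16))
        cells = oracle_ball_cells((0, 0), 6, (16, 16))
        assert int(ball.mask.sum()) == len(cells)

    def test_cell_count_matches_brute_force(self):
        ball = ball_mask((20, 20), 5, (64, 64))
        assert int(ball.mask.sum()) == len(oracle_ball_cells((20, 20), 5, (64, 64)))

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            ball_mask((8, 8), 0, (16, 16))


class TestLocalStats:
    def test_constant_image_means(self, small_cfg):
        image = np.full((16, 16), 0.6)
        phi = init_phi_circle((16, 16), (8, 8), 4)
        st = local_stats(image, phi, ball_mask((8, 8), 4, (16, 16)), small_cfg.epsilon_heaviside)
        assert st.u_x == pytest.approx(0.6)
        assert st.v_x == pytest.approx(0.6)

    def test_all_interior_ball_degenerate(self, small_cfg):
        image = np.random.default_rng(0).random((32, 32))
        phi = init_phi_circle((32, 32), (16, 16), 12)
        st = local_stats(image, phi, ball_mask((16, 16), 3, (32, 32)), small_cfg.epsilon_heaviside)
        assert st.A_v < 1e-8
        assert st.degenerate

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_loop(self, seed, small_cfg):
        image, phi = random_instance(seed)
        ball = ball_mask((8, 8), small_cfg.ball_radius, (16, 16))
        st = local_stats(image, phi, ball, small_cfg.epsilon_heaviside)
        u, v, au, av = oracle_local_stats(image, phi, (8, 8), small_cfg.ball_radius, small_cfg.epsilon_heaviside)
        assert st.u_x == pytest.approx(u, abs=1e-10)
        assert st.v_x == pytest.approx(v, abs=1e-10)
        assert st.A_u == pytest.approx(au, abs=1e-10)
        assert st.A_v == pytest.approx(av, abs=1e-10)


class TestSpeeds:
    def test_null_weights_give_zero_um(self):
        # lambda1 = lambda2 paired with a constant image: both residual
        # families coincide, so the UM speed vanishes identically
        image = np.full((16, 16), 0.5)
        phi = init_phi_circle((16, 16), (8, 8), 4)
        cfg = RunConfig(ball_radius=4)
        assert um_speed(image, phi, (8, 4), cfg) == pytest.approx(0.0, abs=1e-12)
        assert ms_speed(image, phi, (8, 4), cfg) == pytest.approx(0.0, abs=1e-12)

    def test_dark_cavity_expansion_sign(self):
        # contour inside a dark disk with a bright surround within the ball:
        # the speed at dark contour pixels must be negative (grow interior)
        image = np.full((32, 32), 0.9)
        rr, cc = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        image[(rr - 16) ** 2 + (cc - 16) ** 2 <= 100] = 0.1
        phi = init_phi_circle((32, 32), (16, 16), 5)
        cfg = RunConfig(ball_radius=12, energy_model="UM")
        assert um_speed(image, phi, (16, 11), cfg) < 0
        cfg_ms = RunConfig(ball_radius=12, energy_model="MS")
        assert ms_speed(image, phi, (16, 11), cfg_ms) < 0

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("model", ["UM", "MS"])
    def test_matches_naive_loop(self, seed, model):
        image, phi = random_instance(seed)
        cfg = RunConfig(ball_radius=4, energy_model=model, lambda1=1.3, lambda2=0.8)
        x = (8, 5)
        ours = um_speed(image, phi, x, cfg) if model == "UM" else ms_speed(image, phi, x, cfg)
        assert ours == pytest.approx(oracle_speed(image, phi, x, cfg, model), abs=1e-10)

    @pytest.mark.parametrize("model", ["UM", "MS"])
    def test_field_matches_per_point(self, model, rng):
        image = rng.random((24, 24))
        phi = init_phi_circle((24, 24), (12, 12), 6)
        cfg = RunConfig(ball_radius=5, energy_model=model)
        fields = evolution_fields(image, phi, cfg)
        for x in [(6, 12), (12, 6), (15, 15), (12, 18)]:
            per_point = um_speed(image, phi, x, cfg) if model == "UM" else ms_speed(image, phi, x, cfg)
            assert fields.speed[x] == pytest.approx(per_point, abs=1e-8)

    def test_global_limit_is_chan_vese_force(self, rng):
        # ball >= image diagonal: the UM speed field is proportional to the
        # global Chan-Vese force (I-u)^2 - (I-v)^2 over the band
        image = rng.random((24, 24))
        phi = init_phi_circle((24, 24), (12, 12), 6)
        cfg = RunConfig(ball_radius=40, energy_model="UM")
        fields = evolution_fields(image, phi, cfg)
        H = np.asarray(heaviside(phi, cfg.epsilon_heaviside))
        u = (H * image).sum() / H.sum()
        v = ((1 - H) * image).sum() / (1 - H).sum()
        cv = (image - u) ** 2 - (image - v) ** 2
        band = np.abs(phi) <= 6
        a, b = fields.speed[band], cv[band]
        cosine = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cosine > 0.999

    def test_interior_exterior_symmetry(self, rng):
        # relabeling interior/exterior (phi -> -phi) with lambda1 <-> lambda2
        # swapped flips the sign of both speeds
        image = rng.random((16, 16))
        phi = init_phi_circle((16, 16), (8, 8), 4)
        for model, fn in (("UM", um_speed), ("MS", ms_speed)):
            cfg = RunConfig(ball_radius=4, energy_model=model, lambda1=1.3, lambda2=0.8)
            swapped = RunConfig(ball_radius=4, energy_model=model, lambda1=0.8, lambda2=1.3)
            x = (8, 4)
            assert fn(image, phi, x, cfg) == pytest.approx(-fn(image, -phi, x, swapped), abs=1e-10)


class TestEnergy:
    def test_ms_energy_zero_on_constant_image(self):
        image = np.full((16, 16), 0.5)
        phi = init_phi_circle((16, 16), (8, 8), 4)
        cfg = RunConfig(ball_radius=4, mu=0.0, energy_model="MS")
        assert energy_value(image, phi, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_regularization_part_linear_in_mu(self, rng):
        image = rng.random((16, 16))
        phi = init_phi_circle((16, 16), (8, 8), 4)
        e0 = energy_value(image, phi, RunConfig(ball_radius=4, mu=0.0))
        e1 = energy_value(image, phi, RunConfig(ball_radius=4, mu=0.1))
        e2 = energy_value(image, phi, RunConfig(ball_radius=4, mu=0.2))
        assert e2 - e0 == pytest.approx(2 * (e1 - e0), rel=1e-9)

    def test_energy_descends_after_transient_on_clean_phantom(self, clean_phantom):
        # the UM trace shows the textbook shape: a small initial increase,
        # then descent to a converged value well below the transient peak
        from alrls.model import SinusLevelSet

        res = SinusLevelSet(
            clean_phantom.image, clean_phantom.cavity_centroid, 7,
            config=RunConfig(energy_model="UM"),
        ).fit()
        e = res.energy_trace
        assert len(e) > 20
        assert np.mean(e[-10:]) < np.mean(e[10:20])
        assert e[-1] < e[0]
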