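"""Color schemes, tamoxifen-decay math and the staining operator."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy.integrate import quad

from gcbrainbow.staining import (
    BLACK,
    ColorScheme,
    StainingProtocol,
    apply_staining,
    builtin_schemes,
    draw_founder_colors,
    get_scheme,
    initial_staining_probability,
    load_scheme_csv,
    staining_probability_at,
)


def toy_state(colors):
    """Minimal stand-in exposing a mutable color array."""
    return SimpleNamespace(color=np.asarray(colors, dtype=np.int16))


class TestColorSchemes:
    def test_builtin_names(self):
        names = {s.name for s in builtin_schemes()}
        assert names == {"4-color", "tamoxifen", "founder", "10-equal"}

    @pytest.mark.parametrize("name", ["4-color", "tamoxifen", "founder", "10-equal"])
    def test_probabilities_sum_to_one(self, name):
        scheme = get_scheme(name)
        assert scheme.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert scheme.colors[0] == BLACK

    def test_four_color_values(self):
        scheme = get_scheme("4-color")
        expected = dict(zip(scheme.colors, scheme.probabilities))
        assert expected[BLACK] == pytest.approx(0.40)
        for c in ("YFP", "RFP", "CFP"):
            assert expected[c] == pytest.approx(0.18)
        assert expected["GFP"] == pytest.approx(0.06)

    def test_printed_black_fractions_preserved(self):
        """Black (= unstained) fractions are the printed measurements."""
        assert get_scheme("tamoxifen").probabilities[0] == pytest.approx(0.52)
        assert get_scheme("founder").probabilities[0] == pytest.approx(0.11)
        assert get_scheme("tamoxifen").stained_fraction == pytest.approx(0.48)
        assert get_scheme("founder").stained_fraction == pytest.approx(0.89)

    def test_tamoxifen_color_values_at_printed_precision(self):
        scheme = get_scheme("tamoxifen")
        probs = dict(zip(scheme.colors, scheme.probabilities))
        assert probs["YFP"] == pytest.approx(0.13, abs=5e-3)
        assert probs["G/Y"] == pytest.approx(0.001, abs=5e-4)

    def test_ten_equal_is_equiprobable(self):
        scheme = get_scheme("10-equal")
        assert scheme.n_colors == 10
        assert np.allclose(scheme.probabilities[1:], 0.048)

    def test_validation(self):
        with pytest.raises(ValueError, match="black"):
            ColorScheme("x", ("YFP", "RFP"), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="sum"):
            ColorScheme("x", (BLACK, "YFP"), np.array([0.5, 0.4]))

    def test_scheme_csv_round_trip(self, tmp_path):
        scheme = get_scheme("4-color")
        path = tmp_path / "palette.csv"
        path.write_text(
            "color,probability\n"
            + "\n".join(
                f"{c},{float(p)!r}"
                for c, p in zip(scheme.colors, scheme.probabilities)
            )
        )
        loaded = load_scheme_csv(path)
        assert loaded.colors == scheme.colors
        np.testing.assert_allclose(loaded.probabilities, scheme.probabilities)


class TestDecayCalibration:
    def test_closed_form(self):
        """p0*dt = f / (tau * (1 - exp(-stop/tau)))."""
        p0 = initial_staining_probability(0.48, 24.0, 48.0, 1.0)
        assert p0 == pytest.approx(0.48 / (24 * (1 - np.exp(-2.0))))

    def test_infinite_stop_limit(self):
        """Without a cut-off the calibration reduces to f/tau per dt."""
        p0 = initial_staining_probability(0.3, 24.0, tau_stainstop=1e9)
        assert p0 == pytest.approx(0.3 / 24.0, rel=1e-9)

    def test_linear_in_target_fraction(self):
        a = initial_staining_probability(0.2)
        b = initial_staining_probability(0.4)
        assert b == pytest.approx(2 * a)

    def test_closed_form_matches_numerical_integration(self):
        """The accumulated decay integral recovers f to 1e-6 (both rules)."""
        f, tau, stop = 0.48, 24.0, 48.0
        p0 = initial_staining_probability(f, tau, stop, dt_stain=1.0)
        integral, _ = quad(lambda t: p0 * np.exp(-t / tau), 0, stop)
        assert integral == pytest.approx(f, abs=1e-9)
        t = np.linspace(0, stop, 20001)
        assert np.trapezoid(p0 * np.exp(-t / tau), t) == pytest.approx(f, rel=1e-6)

    def test_exact_calibration_realizes_target(self):
        """The default calibration inverts the no-restain product form."""
        proto = StainingProtocol(mode="decay", scheme=get_scheme("tamoxifen"))
        q = proto.p_stain_0 * proto.dt_stain
        k = np.arange(48)
        realized = 1 - np.prod(1 - q * np.exp(-k / 24.0))
        assert realized == pytest.approx(proto.f_stained, abs=1e-10)
        linear = initial_staining_probability(proto.f_stained)
        assert q > linear  # exact compensates the union bound

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            initial_staining_probability(0.48, tau_tamoxifen=-1)
        with pytest.raises(ValueError):
            initial_staining_probability(1.2)


class TestDecaySchedule:
    @pytest.fixture
    def proto(self):
        return StainingProtocol(
            mode="decay", scheme=get_scheme("tamoxifen"), t_start=48.0
        )

    def test_initial_value(self, proto):
        assert staining_probability_at(proto, 48.0) == pytest.approx(
            proto.p_stain_0 * proto.dt_stain
        )

    def test_decay_constant(self, proto):
        """One tamoxifen half-time after injection the probability is 1/e."""
        assert staining_probability_at(proto, 48.0 + 24.0) == pytest.approx(
            proto.p_stain_0 * proto.dt_stain * np.exp(-1)
        )

    def test_window(self, proto):
        assert staining_probability_at(proto, 47.9) == 0.0
        assert staining_probability_at(proto, 48.0 + 48.0) == 0.0

    def test_call_schedule(self, proto):
        times = proto.staining_times()
        assert times[0] == 48.0 and times[-1] == 95.0 and len(times) == 48


class TestApplyStaining:
    def test_one_shot_fraction_and_color_frequencies(self):
        scheme = get_scheme("tamoxifen")
        proto = StainingProtocol(mode="one_shot", scheme=scheme, t_start=48.0)
        state = toy_state(np.zeros(200_000))
        rng = np.random.default_rng(7)
        n = apply_staining(state, proto, rng)
        frac = (state.color > 0).mean()
        assert n == (state.color > 0).sum()
        assert frac == pytest.approx(0.48, abs=0.005)
        # conditional color frequencies -> renormalized non-black column
        stained = state.color[state.color > 0]
        freq = np.bincount(stained, minlength=11)[1:] / stained.size
        np.testing.assert_allclose(
            freq, scheme.non_black_probabilities(), atol=0.006
        )

    def test_restain_disabled_preserves_colors(self):
        proto = StainingProtocol(
            mode="decay", scheme=get_scheme("tamoxifen"), t_start=0.0
        )
        state = toy_state(np.full(5000, 3))
        rng = np.random.default_rng(0)
        n = apply_staining(state, proto, rng, t=0.0)
        assert n == 0
        assert np.all(state.color == 3)

    def test_restain_enabled_redraws_but_never_unstains(self):
        proto = StainingProtocol(
            mode="decay", scheme=get_scheme("tamoxifen"), t_start=0.0,
            allow_restain=True, f_stained=0.9,
        )
        state = toy_state(np.full(20_000, 3))
        rng = np.random.default_rng(0)
        n = apply_staining(state, proto, rng, t=0.0)
        assert n > 0
        assert np.all(state.color > 0)  # a recombined cell cannot revert
        assert (state.color != 3).any()

    def test_outside_window_is_noop(self):
        proto = StainingProtocol(
            mode="decay", scheme=get_scheme("tamoxifen"), t_start=48.0
        )
        state = toy_state(np.zeros(1000))
        assert apply_staining(state, proto, np.random.default_rng(0), t=10.0) == 0
        assert (state.color == 0).all()

    def test_founder_draw_includes_black(self):
        rng = np.random.default_rng(11)
        colors = draw_founder_colors(get_scheme("founder"), 100_000, rng)
        assert (colors == 0).mean() == pytest.approx(0.11, abs=0.005)
        assert colors.max() <= 10
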