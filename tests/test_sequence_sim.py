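"""Steady-state simulator: phase schedules, dual-route agreement, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcgre import (
    SequenceParams,
    TissueParams,
    ernst_signal,
    phase_vs_t2_curve,
    quadratic_phase_schedule,
    simulate_steady_state_epg,
    simulate_steady_state_isochromat,
    weighting_intervals,
)

# --------------------------------------------------------------------------
# quadratic phase schedule
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "theta,n,phi0,expected",
    [
        (117.0, 4, 0.0, [0.0, 117.0, 351.0, 342.0]),
        (0.0, 3, 0.0, [0.0, 0.0, 0.0]),
        (1.5, 3, 0.0, [0.0, 1.5, 4.5]),
    ],
)
def test_schedule_examples(theta, n, phi0, expected):
    sched = quadratic_phase_schedule(theta, n, phi0)
    np.testing.assert_allclose(sched.phases, expected, atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    theta=st.floats(-180, 179.99),
    n=st.integers(2, 200),
    phi0=st.floats(0, 359.0),
)
def test_schedule_recurrence_matches_closed_form(theta, n, phi0):
    phases = quadratic_phase_schedule(theta, n, phi0).phases
    running = phi0
    for i in range(1, n):
        running = running + i * theta
        diff = (phases[i] - running) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6


def test_schedule_rejects_bad_input():
    with pytest.raises(ValueError):
        quadratic_phase_schedule(np.nan, 4)
    with pytest.raises(ValueError):
        quadratic_phase_schedule(1.5, 0)


def test_sequence_params_validation():
    with pytest.raises(ValueError):
        SequenceParams(theta=200.0)
    with pytest.raises(ValueError):
        SequenceParams(te=(2.38, 0.08))
    with pytest.raises(ValueError):
        SequenceParams(flip=0.0)
    assert SequenceParams(theta=1.5).negated().theta == -1.5


# --------------------------------------------------------------------------
# dual simulation routes
# --------------------------------------------------------------------------

GRID = [
    (theta, t1, t2)
    for theta in (0.0, 1.5, 4.0, 117.0)
    for t1 in (1000.0, 4000.0)
    for t2 in (0.11, 1.0, 10.0, 80.0, 2000.0)
    if t2 <= t1
]


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_epg_matches_isochromat_over_grid():
    """Configuration-state and spin-ensemble routes agree to 1e-3 relative."""
    worst = 0.0
    for theta, t1, t2 in GRID:
        seq = SequenceParams(theta=theta)
        tissue = TissueParams(t1=t1, t2=t2)
        a = simulate_steady_state_isochromat(seq, tissue)
        b = simulate_steady_state_epg(seq, tissue)
        rel = abs(a.s_ute - b.s_ute) / max(abs(a.s_ute), 1e-30)
        worst = max(worst, rel)
    assert worst < 1e-3


def test_ideal_spoiling_near_ernst():
    """At theta=117 the magnitude approaches the Ernst value; quadratic RF
    spoiling without diffusion retains a known residual deviation (<10%),
    far smaller than the coherent theta=0 excess."""
    seq117 = SequenceParams(theta=117.0)
    seq0 = SequenceParams(theta=0.0)
    tissue = TissueParams(t1=1000.0, t2=80.0)
    ernst = ernst_signal(seq117, tissue)
    mag117 = abs(simulate_steady_state_epg(seq117, tissue).s_ute) * np.exp(
        seq117.te[0] / tissue.t2
    )
    mag0 = abs(simulate_steady_state_epg(seq0, tissue).s_ute) * np.exp(seq0.te[0] / tissue.t2)
    assert abs(mag117 - ernst) / ernst < 0.10
    assert abs(mag0 - ernst) / ernst > 1.0  # coherent SSFP is nowhere near


def test_short_t2_magnitude_independent_of_theta():
    """For T2 << TR no coherence survives the TR, so the increment is moot."""
    mags = []
    for theta in (0.0, 1.5, 4.0, 117.0):
        s = simulate_steady_state_epg(SequenceParams(theta=theta), TissueParams(1000.0, 0.11))
        mags.append(abs(s.s_ute))
    assert (max(mags) - min(mags)) / max(mags) < 0.01


def test_conjugate_symmetry_of_negated_pass():
    tissue = TissueParams(t1=1000.0, t2=80.0)
    a = simulate_steady_state_epg(SequenceParams(theta=1.5), tissue)
    b = simulate_steady_state_epg(SequenceParams(theta=-1.5), tissue)
    assert abs(a.s_ute - np.conj(b.s_ute)) / abs(a.s_ute) < 1e-6
    ai = simulate_steady_state_isochromat(SequenceParams(theta=1.5), tissue)
    bi = simulate_steady_state_isochromat(SequenceParams(theta=-1.5), tissue)
    assert abs(ai.s_ute - np.conj(bi.s_ute)) / abs(ai.s_ute) < 1e-6


def test_signal_linear_in_proton_density():
    seq = SequenceParams()
    s1 = simulate_steady_state_epg(seq, TissueParams(1000.0, 80.0, pd=1.0))
    s2 = simulate_steady_state_epg(seq, TissueParams(1000.0, 80.0, pd=0.37))
    assert s2.s_ute == pytest.approx(0.37 * s1.s_ute, rel=1e-12)
    s0 = simulate_steady_state_epg(seq, TissueParams(1000.0, 80.0, pd=0.0))
    assert s0.s_ute == 0


def test_intra_tr_echo_decay_exact():
    seq = SequenceParams()
    for theta in (0.0, 1.5, 117.0):
        s = simulate_steady_state_epg(SequenceParams(theta=theta), TissueParams(900.0, 45.0))
        expected = np.exp(-(seq.te[1] - seq.te[0]) / 45.0)
        assert abs(s.s_cte / s.s_ute - expected) < 1e-12


# --------------------------------------------------------------------------
# phase-vs-T2 curves and weighting intervals
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def t2_grid():
    return np.geomspace(10.0, 2000.0, 25)


def test_phase_monotone_for_small_positive_increment(t2_grid):
    ph = phase_vs_t2_curve(SequenceParams(theta=1.5), t2_grid, 4000.0)
    assert np.all(np.diff(ph) > 0)


def test_phase_curve_negation_for_flipped_increment(t2_grid):
    ph_pos = phase_vs_t2_curve(SequenceParams(theta=1.5), t2_grid, 4000.0)
    ph_neg = phase_vs_t2_curve(SequenceParams(theta=-1.5), t2_grid, 4000.0)
    np.testing.assert_allclose(ph_neg, -ph_pos, atol=1e-9)


def test_phase_curve_flat_at_ideal_spoiling(t2_grid):
    # declared flatness tolerance: 0.5 rad at the default 24-degree flip
    ph = phase_vs_t2_curve(SequenceParams(theta=117.0), t2_grid, 4000.0)
    assert np.ptp(ph) < 0.5


def test_phase_curve_rejects_t2_above_t1(t2_grid):
    with pytest.raises(ValueError):
        phase_vs_t2_curve(SequenceParams(), t2_grid, t1_fixed=100.0)


def test_weighting_intervals_disjoint(default_seq, brain_tissues):
    t1w, t2w = weighting_intervals(default_seq, brain_tissues)
    assert t1w is not None and t2w is not None
    lo1, hi1 = t1w
    lo2, hi2 = t2w
    assert hi2 < lo1 or hi1 < lo2  # disjoint
    for lo, hi in (t1w, t2w):
        assert 0 <= lo <= hi < 180


def test_weighting_intervals_requires_three_distinct_tissues(default_seq, brain_tissues):
    with pytest.raises(ValueError):
        weighting_intervals(default_seq, brain_tissues[:1])
    dup = [brain_tissues[0], brain_tissues[0], brain_tissues[2]]
    with pytest.raises(ValueError):
        weighting_intervals(default_seq, dup)
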