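"""Stochastic airway deposition: physics forms, sampling, Monte Carlo."""

import numpy as np
import pytest

from aerodpi.lung_deposition import (
    AirwayGeometry,
    AirwaySegment,
    BreathingPattern,
    DepositionResult,
    GenerationStats,
    LungDepositionModel,
    Particle,
    cunningham_slip,
    deposition_probability_segment,
    diffusion_coefficient,
    extrathoracic_deposition,
    sample_airway_path,
    settling_velocity,
    simulate_deposition,
)

N_SMALL = 20_000


def single_tube_geometry(diameter=0.1, length=2.0, gravity=(0.0, 0.0)):
    return AirwayGeometry(
        (
            GenerationStats(
                1, "bronchial", diameter_cm=diameter, length_cm=length,
                sigma_g=1.0, branch_angle_deg=(0.0, 0.0),
                gravity_angle_deg=gravity,
            ),
        )
    )


def test_physics_magnitudes():
    """Settling velocity and diffusivity at textbook orders of magnitude."""
    assert settling_velocity(2.0) == pytest.approx(0.013, rel=0.15)
    assert cunningham_slip(0.1) > cunningham_slip(10.0) > 1.0
    assert diffusion_coefficient(0.01) > diffusion_coefficient(1.0)


def test_segment_probability_limits():
    seg = AirwaySegment(1, "bronchial", 0.3, 1.0, 0.0, 0.0)
    # vanishing size and residence (flow kept consistent, L/t = velocity):
    # no mechanism is active and the probability vanishes
    area = np.pi * (seg.diameter_cm / 2) ** 2
    residence = 1e-9
    p_small = deposition_probability_segment(
        Particle(1e-3), seg, area * seg.length_cm / residence, residence
    )
    assert p_small == pytest.approx(0.0, abs=1e-3)
    seg = AirwaySegment(1, "bronchial", 0.3, 1.0, 30.0, 0.0)
    # residence -> infinity: sedimentation certainty in a horizontal tube
    p_long = deposition_probability_segment(Particle(2.0), seg, 100.0, 1e9)
    assert p_long == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= deposition_probability_segment(Particle(2.0), seg, 50.0, 0.05) <= 1.0


def test_extrathoracic_curve():
    assert extrathoracic_deposition(0.0, 30.0) == 0.0
    grid = np.linspace(0.1, 15.0, 50)
    vals = extrathoracic_deposition(grid, 30.0)
    assert np.all(np.diff(vals) >= 0)
    assert extrathoracic_deposition(10.0, 30.0) > 10 * extrathoracic_deposition(1.0, 30.0)
    with pytest.raises(KeyError):
        extrathoracic_deposition(2.0, 30.0, mode="tracheostomy")


def test_path_sampling_seeded_and_degenerate():
    geom = AirwayGeometry.default()
    p1 = sample_airway_path(geom, 42)
    p2 = sample_airway_path(geom, 42)
    assert p1 == p2
    zero_sd = AirwayGeometry(
        tuple(
            GenerationStats(g.generation, g.region, g.diameter_cm, g.length_cm,
                            1.0, (30.0, 30.0), (45.0, 45.0))
            for g in geom.generations
        )
    )
    path = sample_airway_path(zero_sd, 0)
    for seg, g in zip(path, geom.generations):
        assert seg.diameter_cm == pytest.approx(g.diameter_cm)
        assert seg.length_cm == pytest.approx(g.length_cm)


def test_path_sampling_distribution_oracle():
    """Mean sampled diameter per generation matches the lognormal mean."""
    geom = AirwayGeometry.default()
    n = 4000
    diams = np.array(
        [[s.diameter_cm for s in sample_airway_path(geom, seed)] for seed in range(n)]
    )
    for j, g in enumerate(geom.generations[:4]):
        expected = g.diameter_cm * np.exp(0.5 * np.log(g.sigma_g) ** 2)
        sd = expected * np.sqrt(np.exp(np.log(g.sigma_g) ** 2) - 1.0)
        assert abs(diams[:, j].mean() - expected) < 3 * sd / np.sqrt(n)


def test_default_geometry_scaled_to_frc():
    geom = AirwayGeometry.default(frc_cm3=3300.0)
    assert geom.total_volume_cm3() == pytest.approx(3300.0, rel=1e-6)
    assert sum(g.region == "bronchial" for g in geom.generations) == 16
    assert sum(g.region == "acinar" for g in geom.generations) == 8


def test_simulation_conservation_and_identity():
    res = simulate_deposition((2.0, 2.0), BreathingPattern(), n_particles=N_SMALL,
                              seed=11)
    total = res.extrathoracic + res.bronchial + res.acinar + res.exhaled
    assert total == pytest.approx(100.0, abs=1e-9)
    assert res.lung == res.bronchial + res.acinar  # tally identity
    assert res.n_particles == N_SMALL


def test_simulation_seeded_determinism():
    a = simulate_deposition((2.0, 2.0), BreathingPattern(), n_particles=5000, seed=9)
    b = simulate_deposition((2.0, 2.0), BreathingPattern(), n_particles=5000, seed=9)
    assert a == b
    c = simulate_deposition((2.0, 2.0), BreathingPattern(), n_particles=5000, seed=10)
    assert a != c


def test_lung_deposition_monotone_in_breath_hold():
    holds = [0.0, 5.0, 10.0]
    lungs = [
        simulate_deposition(
            (2.0, 2.0), BreathingPattern(breath_hold=h), n_particles=N_SMALL, seed=2
        ).lung
        for h in holds
    ]
    assert lungs[0] <= lungs[1] <= lungs[2]


def test_acinar_exceeds_bronchial_for_fine_aerosol():
    """~2 µm MMAD aerosol with a slow deep breath deposits mostly acinar."""
    res = simulate_deposition(
        (2.0, 2.0),
        BreathingPattern(inhaled_volume=1.7, inhalation_time=3.2, breath_hold=10.0),
        n_particles=N_SMALL,
        seed=4,
    )
    assert res.acinar > res.bronchial


def test_extrathoracic_monotone_in_mmad():
    ets = [
        simulate_deposition((m, 2.0), BreathingPattern(), n_particles=N_SMALL,
                            seed=8).extrathoracic
        for m in (1.0, 2.5, 6.0)
    ]
    assert ets[0] < ets[1] < ets[2]


def test_se_scales_as_inverse_sqrt_n():
    r_small = simulate_deposition((2.0, 2.0), BreathingPattern(),
                                  n_particles=1_000, seed=1)
    r_large = simulate_deposition((2.0, 2.0), BreathingPattern(),
                                  n_particles=100_000, seed=1)
    ratio = r_small.se["acinar"] / r_large.se["acinar"]
    assert ratio == pytest.approx(10.0, rel=0.25)


def test_single_tube_monte_carlo_matches_analytic():
    """MC deposition in a fixed horizontal tube equals the closed form.

    With a degenerate one-segment geometry, no extrathoracic filter and no
    breath-hold, each particle deposits on inhalation or exhalation with
    probability 1-(1-P)^2 where P is the analytic single-tube probability.
    """
    geom = single_tube_geometry()
    breathing = BreathingPattern(
        inhaled_volume=0.0005, inhalation_time=1.0, breath_hold=0.0
    )
    d_ae = 5.0
    n = 100_000
    res = simulate_deposition(
        (d_ae, 1.0), breathing, geometry=geom, n_particles=n, seed=123,
        include_extrathoracic=False,
    )
    flow = breathing.flow_cm3_s
    seg = AirwaySegment(1, "bronchial", 0.1, 2.0, 0.0, 0.0)
    velocity = flow / (np.pi * (0.1 / 2) ** 2)
    p_single = deposition_probability_segment(Particle(d_ae), seg, flow, 2.0 / velocity)
    p_round_trip = 1.0 - (1.0 - p_single) ** 2
    se = np.sqrt(p_round_trip * (1 - p_round_trip) / n)
    assert abs(res.bronchial / 100.0 - p_round_trip) < 3 * se
    assert res.acinar == 0.0


def test_model_object_and_summary():
    model = LungDepositionModel((2.0, 2.0), BreathingPattern(breath_hold=10.0))
    res = model.simulate(n_particles=2000, seed=0)
    assert isinstance(res, DepositionResult)
    text = res.summary()
    assert "acinar" in text and "extrathoracic" in text
    assert model.fit(n_particles=2000, seed=0) == res
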