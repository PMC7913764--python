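"""Cascade-impactor reduction: ED/EF, probit MMAD/GSD fit, FPD/FPF."""

import numpy as np
import pytest
from scipy.stats import norm

from aerodpi.impactor import (
    ACI_CUTOFFS_28LPM,
    CascadeImpactorModel,
    ImpactorRun,
    cumulative_undersize,
    emitted_dose,
    emitted_fraction,
    fine_particle_dose,
    fine_particle_fraction,
    fit_mmad_gsd,
    inhaled_volume,
    scale_cutoffs,
)
from aerodpi.synthetic_data import FixtureSpec, generate


def make_run(stage_masses, throat=0.0, device=0.0, capsules=0.0, loaded=1.0):
    return ImpactorRun(
        mass_device=device,
        mass_capsules=capsules,
        mass_induction_port=throat,
        mass_per_stage=tuple(stage_masses),
        loaded_api=loaded,
    )


def lognormal_stage_masses(mmad, gsd, sized=1000.0):
    cutoffs = np.array(ACI_CUTOFFS_28LPM[:-1])
    cdf = norm.cdf(np.log(cutoffs / mmad) / np.log(gsd))
    below = np.append(cdf, 0.0)
    upper = np.insert(cdf, 0, 1.0)
    return sized * (upper - below)


def test_emitted_dose_is_everything_past_the_capsule():
    run = make_run([10] * 9, throat=15, device=50, capsules=5, loaded=200)
    assert emitted_dose(run) == pytest.approx(105.0)
    # mass balance: ED + device + capsules == total recovered, exactly
    assert emitted_dose(run) + run.mass_device + run.mass_capsules == pytest.approx(
        run.total_recovered, abs=0.0
    )


def test_all_mass_in_device_gives_zero_ed():
    run = make_run([0] * 9, device=100, capsules=20, loaded=200)
    assert emitted_dose(run) == 0.0


@pytest.mark.parametrize(
    "ed,loaded,expected", [(5.98, 8.26, 72.4), (4.24, 5.07, 83.6), (0.0, 5.0, 0.0)]
)
def test_emitted_fraction_examples(ed, loaded, expected):
    assert emitted_fraction(ed, loaded) == pytest.approx(expected, abs=0.05)


def test_cumulative_undersize_hand_count():
    """Equal mass on stages 2 and 4 only: half below 3.3 µm, all below 5.8 µm."""
    masses = [0, 0, 50, 0, 50, 0, 0, 0, 0]
    cum = dict(cumulative_undersize(make_run(masses)))
    assert cum[3.3] == pytest.approx(0.5)
    assert cum[5.8] == pytest.approx(1.0)
    assert cum[9.0] == pytest.approx(1.0)
    assert cum[2.1] == pytest.approx(0.0)


def test_cumulative_undersize_all_on_filter():
    masses = [0] * 8 + [100]
    cum = cumulative_undersize(make_run(masses))
    assert all(f == pytest.approx(1.0) for _, f in cum)


def test_cumulative_undersize_monotone_and_bounded():
    rng = np.random.default_rng(7)
    masses = rng.random(9) * 100
    cum = cumulative_undersize(make_run(masses))
    fracs = [f for _, f in cum][::-1]  # ascending cut-off order
    assert all(0.0 <= f <= 1.0 for f in fracs)
    assert all(b >= a for a, b in zip(fracs, fracs[1:]))


@pytest.mark.parametrize("mmad", [0.8, 1.55, 2.33, 4.0, 8.0])
@pytest.mark.parametrize("gsd", [1.3, 2.0, 3.0])
def test_fit_recovers_generating_lognormal(mmad, gsd):
    """Noise-free lognormal depositions recover (MMAD, GSD) within 2%."""
    run = make_run(lognormal_stage_masses(mmad, gsd))
    fit_mmad, fit_gsd, diag = fit_mmad_gsd(cumulative_undersize(run))
    assert fit_mmad == pytest.approx(mmad, rel=0.02)
    assert fit_gsd == pytest.approx(gsd, rel=0.02)
    assert diag["r_squared"] > 0.999


def test_degenerate_distribution_rejected():
    # everything below the lowest cut-off -> no points strictly inside (0,1)
    run = make_run([0] * 8 + [100.0])
    with pytest.raises(ValueError):
        fit_mmad_gsd(cumulative_undersize(run))


def test_fpd_closed_form_and_limits():
    run = make_run(lognormal_stage_masses(2.0, 2.0, sized=1000.0))
    fpd = fine_particle_dose(run, 2.0, 2.0)
    assert fpd / run.sized_mass == pytest.approx(
        norm.cdf(np.log(5.0 / 2.0) / np.log(2.0)), rel=1e-9
    )
    # MMAD at exactly 5 µm -> half of the sized mass is "fine"
    assert fine_particle_dose(run, 5.0, 2.0) == pytest.approx(
        0.5 * run.sized_mass, rel=1e-9
    )
    # narrow distribution far below 5 µm -> everything is fine
    assert fine_particle_dose(run, 1.0, 1.0) == pytest.approx(run.sized_mass)


@pytest.mark.parametrize(
    "fpd,ed,expected", [(4.52, 5.98, 75.6), (2.51, 3.40, 73.8), (0.0, 5.0, 0.0)]
)
def test_fine_particle_fraction_examples(fpd, ed, expected):
    assert fine_particle_fraction(fpd, ed) == pytest.approx(expected, abs=0.05)


def test_fpf_invariant_under_mass_scaling():
    masses = lognormal_stage_masses(2.0, 1.8)
    res1 = CascadeImpactorModel(make_run(masses, throat=100, loaded=1500)).fit()
    res2 = CascadeImpactorModel(
        make_run(masses * 7.5, throat=750, loaded=11250)
    ).fit()
    assert res1.fpf == pytest.approx(res2.fpf, rel=1e-9)
    assert res1.ef == pytest.approx(res2.ef, rel=1e-9)


@pytest.mark.parametrize(
    "flow,t,expected", [(28.3, 4.0, 1.887), (60.0, 60.0, 60.0), (28.3, 0.0, 0.0)]
)
def test_inhaled_volume(flow, t, expected):
    assert inhaled_volume(flow, t) == pytest.approx(expected, abs=5e-3)


def test_cutoff_flow_scaling():
    same = scale_cutoffs(28.3)
    assert same == pytest.approx(ACI_CUTOFFS_28LPM)
    faster = scale_cutoffs(60.0)
    assert all(a < b for a, b in zip(faster[:-1], ACI_CUTOFFS_28LPM[:-1]))


def test_model_results_and_summary_from_synthetic_run():
    df, truth = generate(
        FixtureSpec("impactor_run", {"mmad_um": 1.74, "gsd": 1.9}, 0.0, 5)
    )
    res = CascadeImpactorModel.from_dataframe(df, loaded_api=truth["loaded_ug"]).fit()
    assert res.mmad == pytest.approx(1.74, rel=0.02)
    assert res.gsd == pytest.approx(1.9, rel=0.02)
    assert 0 <= res.fpf <= 100 and res.fpd <= res.ed
    text = res.summary()
    assert "MMAD" in text and "fine particle frac" in text
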