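import numpy as np
import pytest

from srclock import (
    BioluminescenceSeries,
    PlateProtocol,
    StimulusVector,
    WellStimulus,
    forward_amplitude,
    generate_plate,
    invert_amplitude,
    measure_plate_sr,
)


def plate_series(data, stim_time_h):
    """Split a long-format plate frame into per-well series."""
    return [
        BioluminescenceSeries(
            time_h=g.time_h.to_numpy(),
            values=g.luminescence.to_numpy(),
            stim_time_h=stim_time_h,
            well=well,
        )
        for well, g in data.groupby("well")
    ]


def recover_strengths(F_targets, seed, n_oscillators=2000):
    """Full chain on one simulated plate (control + saturating reference
    + target wells): generate, measure with same-plate corrections,
    invert the forward amplitude map back to stimulus strengths."""
    protocol = PlateProtocol(
        stimuli=[WellStimulus(F=0.0), WellStimulus(F=50.0, phi_rad=1.0)]
        + [WellStimulus(F=F, phi_rad=1.0) for F in F_targets],
        n_oscillators=n_oscillators,
        alpha=10.0,
        seed=seed,
    )
    data, _ = generate_plate(protocol)
    srs = measure_plate_sr(
        plate_series(data, protocol.stim_time_h),
        control_well="W00",
        reference_well="W01",
        reference_true_R=forward_amplitude(50.0),
    )
    return [
        invert_amplitude(min(srs[f"W{i + 2:02d}"].R, 0.999))
        for i in range(len(F_targets))
    ]


@pytest.fixture(scope="session")
def dense_quadrature_oracle():
    """Independent dense-quadrature evaluation of the SR integral.

    Deliberately written from scratch (midpoint rule on the complex
    integrand, no srclock internals) so it can stand as an oracle for the
    package's forward map and SR estimators.
    """

    def oracle(F: float, phi: float = 0.0, n: int = 1_000_000) -> complex:
        theta = 2 * np.pi * (np.arange(n) + 0.5) / n  # midpoint: avoids F=1 singular node
        z = np.exp(1j * theta) + F * np.exp(1j * phi)
        return np.exp(1j * np.angle(z)).mean()

    return oracle


@pytest.fixture(scope="session")
def small_plate():
    """A compact synthetic plate (3 wells: control, moderate, strong)
    shared by estimation tests."""
    protocol = PlateProtocol(
        stimuli=[
            WellStimulus(F=0.0),
            WellStimulus(F=0.6, phi_rad=np.pi / 2),
            WellStimulus(F=8.0, phi_rad=np.pi / 2),
        ],
        n_oscillators=200,
        duration_h=168.0,
        seed=11,
    )
    data, truth = generate_plate(protocol)
    return protocol, data, truth


@pytest.fixture
def stim_half():
    return StimulusVector(F=0.5, phi=np.pi / 2)
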