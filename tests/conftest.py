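import pandas as pd
import pytest

import allerquant as aq
from allerquant import synthetic_data as synth


@pytest.fixture(scope="session")
def panel():
    return aq.load_default_panel()


@pytest.fixture(scope="session")
def milk_entry(panel):
    return panel.entry("Milk caseinate")


@pytest.fixture(scope="session")
def truth(panel):
    """Generating calibration lines (slope, intercept) for every marker."""
    return {code: (b, 0.0) for code, b in synth.default_slopes(panel).items()}


@pytest.fixture(scope="session")
def noiseless_calibration_ratios(panel):
    design = synth.CalibrationDesign(noise_rel=0, noise_abs=0, heavy_area_jitter=0)
    table = synth.simulate_calibration(design, panel, seed=11)
    return aq.compute_lh_ratios(table)


@pytest.fixture(scope="session")
def mcffv_noiseless_fit(noiseless_calibration_ratios):
    from allerquant.calibration import fit_from_table

    return fit_from_table(noiseless_calibration_ratios, "mc-FFV")


@pytest.fixture
def tiny_peak_table():
    """Two transitions, light/heavy pairs, one with a zero heavy area."""
    rows = []
    for tr, (light, heavy) in enumerate([(500.0, 1000.0), (300.0, 0.0)]):
        for channel, area in (("light", light), ("heavy", heavy)):
            rows.append(
                dict(
                    sample_id="s1",
                    condition="calibrant",
                    nominal_level=1.0,
                    peptide_code="mc-FFV",
                    transition_index=tr,
                    channel=channel,
                    area=area,
                    biological_rep="b0",
                    technical_rep="t0",
                    day="d0",
                    analyst="a1",
                )
            )
    return pd.DataFrame(rows)
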