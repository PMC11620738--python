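import pytest

from polascore import CalibrationModel, Cell, CellPairMeasurement, Reporter, t_critical

PAPER_SLOPE = -0.034
PAPER_INTERCEPT = 0.0148
PAPER_SE = 0.0613
PAPER_N = 97


@pytest.fixture(scope="session")
def reference_model() -> CalibrationModel:
    """Calibration built from the published constants (n=97 control pairs)."""
    t = t_critical(PAPER_N - 2, 0.05)
    return CalibrationModel(
        slope=PAPER_SLOPE,
        intercept=PAPER_INTERCEPT,
        residual_se=PAPER_SE,
        n=PAPER_N,
        df=PAPER_N - 2,
        t_crit=t,
        v_upper=t * PAPER_SE,
        v_lower=-t * PAPER_SE,
    )


def make_measurement(
    proximal: float = 100.0,
    distal: float = 100.0,
    z: float = 0.0,
    reporter: Reporter = Reporter.pop1,
    genotype: str = "wt",
    cell: Cell = Cell.Z1,
    temperature_c: float = 22.5,
    animal_id: str = "a1",
) -> CellPairMeasurement:
    return CellPairMeasurement(
        animal_id=animal_id,
        genotype=genotype,
        temperature_c=temperature_c,
        cell=cell,
        reporter=reporter,
        intensity_proximal=proximal,
        intensity_distal=distal,
        z_distance_um=z,
    )
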