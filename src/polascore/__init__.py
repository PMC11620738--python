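"""polascore: depth-calibrated scoring of two-cell fluorescence-ratio polarity.

Pipeline stages:

1. :mod:`polascore.measurements_io` — data model and delimited-text I/O.
2. :mod:`polascore.calibration` — depth-attenuation OLS fit and confidence band.
3. :mod:`polascore.polarity_classification` — residuals, signed/absolute calls,
   group summaries, violin plots.
4. :mod:`polascore.penetrance_stats` — count reconstruction from rounded
   percentages, Pearson chi-square and Student t tests.
5. :mod:`polascore.synthetic_data` — seeded generators with known ground truth.
"""

from importlib import resources

from .calibration import (
    CalibrationModel,
    fit_depth_regression,
    load_model,
    predict_log_ratio,
    save_model,
    t_critical,
)
from .measurements_io import (
    LOG_BASE,
    Cell,
    CellPairMeasurement,
    PhenotypeRecord,
    Region,
    Reporter,
    log_ratio,
    read_measurements,
    read_phenotypes,
    write_measurements,
    write_phenotypes,
)
from .penetrance_stats import (
    ContingencyTable2x2,
    TestResult,
    enhancement_test,
    pearson_chi2,
    reconstruct_count,
    student_t,
)
from .polarity_classification import (
    AbsoluteClass,
    GenotypeSummary,
    PolarityCall,
    SignedClass,
    plot_violin,
    score_measurement,
    score_measurements,
    summarize,
)
from .synthetic_data import (
    GenotypeProfile,
    ZDistribution,
    simulate_control,
    simulate_phenotype_table,
    simulate_reporter,
)

__version__ = "0.1.0"


def load_example_penetrance() -> list[PhenotypeRecord]:
    """Bundled missing-DTC penetrance table (genotype x region percent/n)."""
    with resources.as_file(
        resources.files("polascore").joinpath("data/dtc_penetrance.csv")
    ) as path:
        return read_phenotypes(path)
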