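import matplotlib
import pytest

matplotlib.use("Agg")

from vialmix.data_model import TreatmentCell
from vialmix.simulate import ScheduleSpec, SurvivalSimParams, simulate_survival_experiment


@pytest.fixture(scope="session")
def small_survival_dataset():
    """A small but realistic simulated starvation assay (36 vials)."""
    params = SurvivalSimParams(
        beta={"Intercept": 90.0, "SexM": -15.0, "SelC": -10.0},
        sigma_resid=15.0,
        sigma_line=2.0,
        sigma_vial=4.0,
        vials_per_cell=1,
        flies_per_vial=(8, 12),
        schedule={
            "F": ScheduleSpec(6.0, 12.0, 120.0),
            "M": ScheduleSpec(6.0, 12.0, 96.0),
        },
        seed=42,
    )
    records, truth = simulate_survival_experiment(params)
    return records, truth, params


@pytest.fixture()
def toy_vial_factory():
    """Build a single hand-specified vial record."""
    from vialmix.data_model import VialIntervalRecord

    def make(
        boundaries=(90.0, 100.0, 110.0),
        deaths=(0, 1, 1),
        n_censored=1,
        vial_id="v1",
        line_id=1,
        sex="F",
    ):
        return VialIntervalRecord(
            vial_id=vial_id,
            line_id=line_id,
            cell=TreatmentCell(regime="R", sex=sex, cue="none"),
            start_age_h=75.0,
            n_start=int(sum(deaths)) + n_censored,
            boundaries=tuple(boundaries),
            deaths=tuple(deaths),
            n_censored=n_censored,
        )

    return make
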