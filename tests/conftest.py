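import numpy as np
import pytest

from petmrbids import PhantomSpec, make_structural_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid=(32, 32, 16), semi_axes_vox=(11.0, 9.0, 5.5), seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_structural_phantom(small_spec)


@pytest.fixture(scope="session")
def mini_cohort(tmp_path_factory):
    """A 3-subject cohort with one retest subject, one planted missing
    PET scan and a tag-dropout on T1w, shared across test modules."""
    from petmrbids import make_cohort

    out = tmp_path_factory.mktemp("mini_cohort")
    manifest = make_cohort(
        out,
        n_subjects=3,
        retest_subjects=(2,),
        missingness_plan=[("03", "01", "pet_h2o")],
        dropout_plan={"t1_mprage": ["EchoTime"]},
        sequences=["t1_mprage", "t2_spc", "t2star_gre", "ep2d_diff", "pet_h2o"],
        seed=1234,
    )
    return out, manifest


@pytest.fixture(scope="session")
def mini_bids(mini_cohort):
    """The mini cohort converted to BIDS."""
    import pandas as pd

    from petmrbids import convert_series, index_dicom_tree, load_configs, write_dataset
    from petmrbids.synthetic_fixtures import TRACER_SCHEDULES

    out, manifest = mini_cohort
    overview, tagmap, doses = load_configs(
        out / "sequence_overview.csv", out / "tag_map.csv", out / "pet_doses.csv"
    )
    records = index_dicom_tree(out / "raw")
    items = convert_series(
        records, overview, tagmap, doses, orientation="RPI", frame_schedules=TRACER_SCHEDULES
    )
    bids_root = out / "bids"
    write_dataset(items, bids_root, participants=pd.read_csv(out / "participants.csv"))
    return bids_root, items, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(20170115)
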