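import numpy as np
import pytest

import qmapsynth as q


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom spec shared by fast unit tests."""
    return q.PhantomSpec(matrix_size=(4, 48, 48), n_subjects=3, seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return q.generate_phantom(small_spec, "S001")


@pytest.fixture(scope="session")
def acq():
    return q.AcquisitionSpec()


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full desk-scale pipeline run (30 subjects, tiny U-Net) with an
    out-of-distribution stressed stratum, shared by the end-to-end tests."""
    cfg = q.RunConfig(
        domain_shift=q.DomainShiftSpec(bias_field_amplitude=0.10, snr_scale=2.0,
                                       global_offset_ms=3.0, seed=77),
        seed=1,
    )
    run_dir = tmp_path_factory.mktemp("pipeline") / "run"
    result = q.run_pipeline(cfg, run_dir)
    return cfg, run_dir, result


@pytest.fixture()
def flat_truth():
    """A phantom whose relaxation times are overwritten with constants,
    so analytic decay values can be asserted exactly."""
    spec = q.PhantomSpec(matrix_size=(2, 32, 32), n_subjects=1, seed=7,
                         noise_sigma=0.0, lesion_rate=0.0)
    ph = q.generate_phantom(spec, "FLAT")
    inside = ph.labels.label_volume != q.LABEL_TABLE["background"]
    t1r = np.where(inside, 40.0, 0.0)
    t2 = np.where(inside, 30.0, 0.0)
    s0 = np.where(inside, 100.0, 0.0)
    return q.PhantomTruth(
        t1rho_truth=q.QuantMap(t1r, "T1rho"),
        t2_truth=q.QuantMap(t2, "T2"),
        s0=s0,
        labels=ph.labels,
        subject_id="FLAT",
        spec_used=spec,
    )
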