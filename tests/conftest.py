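import numpy as np
import pytest
from hypothesis import settings

import barsense as bs
from barsense.diff import Contrast, estimate_dispersion, size_factors, wald_test
from barsense.quantify import collapse_to_sensors
from barsense.simulate import Effect, EffectSpec, simulate_counts

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel():
    return bs.build_default_panel(1)


@pytest.fixture(scope="session")
def small_design():
    """One genotype, vehicle + AMPA at 10 uM, 4 replicates: 8 wells."""
    return bs.build_design(
        genotypes=("control",),
        treatments=("AMPA",),
        doses=(10.0,),
        timepoints=(4,),
        n_replicates=4,
        seed=2,
    )


@pytest.fixture(scope="session")
def recovery_design():
    """Vehicle + three treatments at one dose, 4 replicates each: 16 wells.

    The extra strata give the pooled dispersion estimator ~12 residual df,
    mirroring how dispersions are estimated from a whole assay run rather
    than from the two contrasted groups alone.
    """
    return bs.build_design(
        genotypes=("control",),
        treatments=("AMPA", "BIC", "forskolin"),
        doses=(10.0,),
        timepoints=(4,),
        n_replicates=4,
        seed=8,
    )


@pytest.fixture(scope="session")
def lfc_recovery_run(default_panel, recovery_design):
    """500-seed log2FC recovery at baseline 500 / dispersion 0.05 / n = 4+4.

    Every pathway sensor responds with true LFC exactly 2 at the tested dose
    (Lmax 4, EC50 10, Hill 1 evaluated at dose 10).  Returns per-fit absolute
    errors and 95% CI coverage indicators, pooled over sensors and seeds.
    """
    panel = default_panel
    effects = EffectSpec(
        [
            Effect(s.sensor_id, tr, lmax=4.0, ec50=10.0)
            for s in panel.pathway_sensors
            for tr in ("AMPA", "BIC", "forskolin")
        ]
    )
    contrast = Contrast("AMPA10_vs_veh", {"treatment": "AMPA"}, {"treatment": "vehicle"})
    sensors = [s.sensor_id for s in panel.pathway_sensors]
    errors, covered = [], []
    for i in range(500):
        cm, truth = simulate_counts(
            panel, recovery_design, effects, seed=20_000 + i, baselines=500.0, dispersion=0.05
        )
        scm, ctrl = collapse_to_sensors(cm, panel)
        s = size_factors(ctrl)
        disp = estimate_dispersion(scm, s, recovery_design)
        res = wald_test(scm, s, disp, contrast, recovery_design).set_index("sensor_id")
        true_lfc = 2.0
        for sid in sensors:
            err = res.loc[sid, "log2fc"] - true_lfc
            errors.append(abs(err))
            covered.append(abs(err) <= 1.96 * res.loc[sid, "se"])
    return {"errors": np.array(errors), "covered": np.array(covered)}
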