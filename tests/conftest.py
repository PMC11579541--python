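import math

import numpy as np
import pytest

from dmpk import ConcentrationTimeProfile


def make_profile(times, concs, route="oral", dose=20.0, species="rat",
                 subject="s1", matrix="plasma", loq=0.0, tau=None):
    return ConcentrationTimeProfile(
        subject_id=subject, species=species, matrix=matrix, route=route,
        dose=dose, times=np.asarray(times, float),
        concentrations=np.asarray(concs, float), loq=loq, tau=tau)


@pytest.fixture
def oral_closed_form():
    """Noise-free one-compartment oral concentration (μg/L) and its integrals."""

    def model(t, dose=20.0, ka=2.0, ke=0.18, v=8.0, f=0.42):
        t = np.asarray(t, float)
        return 1000.0 * f * dose * ka / (v * (ka - ke)) * (
            np.exp(-ke * t) - np.exp(-ka * t))

    def auc_to(t_end, dose=20.0, ka=2.0, ke=0.18, v=8.0, f=0.42):
        return 1000.0 * f * dose * ka / (v * (ka - ke)) * (
            (1 - math.exp(-ke * t_end)) / ke - (1 - math.exp(-ka * t_end)) / ka)

    model.auc_to = auc_to
    return model
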