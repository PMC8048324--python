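"""Shared fixtures: small synthetic cohorts and their processed artefacts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nmrstrat.oplsda import fit_oplsda
from nmrstrat.preprocess import (BucketGrid, ParetoScaler, bucket_spectra,
                                 exclude_water, reference_to_alanine)
from nmrstrat.spectra import CHANNEL_CPMG
from nmrstrat.synth import CohortSpec, EffectProfile, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-patient default-profile cohort with rendered spectra."""
    spec = CohortSpec(n_patients=16, seed=101)
    spectra, clinical, truth = generate_cohort(spec, EffectProfile())
    return spectra, clinical, truth


@pytest.fixture(scope="session")
def fitted_small_cohort(small_cohort):
    """Preprocessed matrix and fitted OPLS-DA model for the small cohort."""
    spectra, clinical, truth = small_cohort
    cpmg = [reference_to_alanine(s) for s in spectra
            if s.channel == CHANNEL_CPMG]
    table = exclude_water(bucket_spectra(cpmg, BucketGrid()))
    X = ParetoScaler().fit_transform(table.values)
    y = np.array([s.timepoint for s in cpmg])
    model = fit_oplsda(X, y, n_orth=2)
    meta = pd.DataFrame({
        "patient_id": [s.patient_id for s in cpmg],
        "timepoint": [s.timepoint for s in cpmg],
    })
    return table, X, y, model, meta, clinical, truth
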