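"""Shared fixtures.

The expensive fixture is ``texture_bundle``: a 200-patient phantom cohort
whose classes have equal marrow mean SUV and equal field SD but different
spatial correlation lengths, pushed through segmentation, feature
extraction, harmonization and the PCA signature once per session.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from marrowpet.harmonization import combat_apply, combat_fit
from marrowpet.phantom import CohortSpec, PhantomSpec, generate_cohort_table
from marrowpet.pipeline import extract_cohort_features
from marrowpet.radiomics import ALL_FEATURES, SUV_FEATURES
from marrowpet.signature import apply_signature, fit_signature

TEXTURE_COHORT_SEED = 1
TEXTURE_COHORT_N = 200


@dataclass
class TextureBundle:
    cohort: pd.DataFrame
    features_raw: pd.DataFrame     # patient_id, scanner_id + 19 features (+ mtv_ml)
    features: pd.DataFrame         # harmonized 19-feature table
    suv: pd.DataFrame              # harmonized SUV columns
    scores: pd.DataFrame           # PCA component scores
    n_components: int


@pytest.fixture(scope="session")
def texture_bundle() -> TextureBundle:
    cspec = CohortSpec(n_patients=TEXTURE_COHORT_N, seed=TEXTURE_COHORT_SEED)
    cohort = generate_cohort_table(cspec)
    pspec = PhantomSpec.texture_only()
    raw = extract_cohort_features(cohort, pspec, master_seed=TEXTURE_COHORT_SEED)
    fmat = raw[ALL_FEATURES]
    model = combat_fit(fmat, raw["scanner_id"])
    harmonized = combat_apply(fmat, raw["scanner_id"], model)
    sig = fit_signature(harmonized)
    scores = apply_signature(harmonized, sig)
    return TextureBundle(
        cohort=cohort,
        features_raw=raw,
        features=harmonized,
        suv=harmonized[SUV_FEATURES],
        scores=scores,
        n_components=sig.n_retained,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231104)
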