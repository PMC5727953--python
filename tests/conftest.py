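"""Shared fixtures: small synthetic landscapes and fitted models.

Expensive artifacts (landscape, fitted boosted models) are session-scoped;
boosting uses a raised learning rate and small tree cap sized for the
suite's ~600-row problems, not the production defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

import nichecast as nc
from nichecast import synthetic as syn

# boosting settings for ~600-row synthetic problems
FAST_BRT = dict(learning_rate=0.05, max_trees=1500, n_step=25)


@pytest.fixture(scope="session")
def landscape():
    return syn.generate_landscape(
        60, 60,
        syn.default_layer_specs(),
        syn.default_correlation_targets(),
        seed=101,
    )


@pytest.fixture(scope="session")
def montane_niche():
    return syn.preset_niche("montane")


@pytest.fixture(scope="session")
def lowland_niche():
    return syn.preset_niche("lowland")


def build_training_set(stack, niche, n=300, seed=0):
    """Occurrences -> envelope profile -> pseudo-absences -> labelled samples."""
    occ = syn.generate_occurrences(stack, niche, n, seed=seed)
    sm = nc.extract_values(stack, occ.x, occ.y)
    envm = nc.BioclimEnvelope().fit(sm.frame)
    classified = nc.jenks_classify(envm.score_stack(stack), 5)
    pa = nc.sample_pseudoabsences(classified, n, seed=seed + 1)
    x = np.concatenate([occ.x, pa.x])
    y = np.concatenate([occ.y, pa.y])
    samples = nc.extract_values(stack, x, y).with_response([1] * n + [0] * n)
    return occ, pa, samples


@pytest.fixture(scope="session")
def montane_model(landscape, montane_niche):
    occ, pa, samples = build_training_set(landscape, montane_niche, seed=11)
    model = nc.BoostedSuitability(random_state=42, **FAST_BRT).fit(
        samples.frame, samples.response
    )
    return {"occ": occ, "pa": pa, "samples": samples, "model": model}


@pytest.fixture(scope="session")
def lowland_model(landscape, lowland_niche):
    occ, pa, samples = build_training_set(landscape, lowland_niche, seed=12)
    model = nc.BoostedSuitability(random_state=43, **FAST_BRT).fit(
        samples.frame, samples.response
    )
    return {"occ": occ, "pa": pa, "samples": samples, "model": model}
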