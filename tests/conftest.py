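"""Shared fixtures: phantoms are rendered once per session and reused."""

import dataclasses

import numpy as np
import pytest

from pbvckit import phantom as ph


def truth_labels(truth):
    """Ground-truth label map collapsed onto the CSF/GM/WM codes used by
    the histogram classifier (ventricles count as CSF, lesions as WM)."""
    tl = truth.label_map.data
    lab = np.zeros_like(tl)
    lab[(tl == ph.CSF) | (tl == ph.VENT)] = 1
    lab[tl == ph.GM] = 2
    lab[(tl == ph.WM) | (tl == ph.LES)] = 3
    return truth.label_map.with_data(lab)


@pytest.fixture(scope="session")
def ms_spec():
    """MS-like phantom at analysis scale: lesions, noise and bias on."""
    return ph.preset_spec("T15", scale=3.0, rng_seed=3,
                          noise_sigma=0.05, bias_amplitude=0.1)


@pytest.fixture(scope="session")
def ms_session(ms_spec):
    t1, flair, truth = ph.render_session(ms_spec)
    return {"t1": t1, "flair": flair, "truth": truth, "spec": ms_spec}


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and bias-free MS-like phantom."""
    return ph.preset_spec("T15", scale=3.0, rng_seed=3)


@pytest.fixture(scope="session")
def clean_session(clean_spec):
    t1, flair, truth = ph.render_session(clean_spec)
    return {"t1": t1, "flair": flair, "truth": truth, "spec": clean_spec}


@pytest.fixture(scope="session")
def subject_priors(ms_spec):
    """Atlas-style priors: blurred truth of the lesion-free subject."""
    from pbvckit.preproc import priors_from_truth

    spec_nl = dataclasses.replace(ms_spec, lesion_seeds=(), noise_sigma=0.0,
                                  bias_amplitude=0.0)
    return priors_from_truth(ph.build_label_map(spec_nl))
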