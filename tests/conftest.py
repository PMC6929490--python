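"""Shared fixtures: scaled-down synthetic datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from memtype import synthetic
from memtype.pssm import pad_truncate_pssm
from memtype.seq_encoding import encode_dataset

#: scaled-down study conditions used by the training tests
N_CLASSES = 4
PER_CLASS = 100
FIXED_LEN = 200
SEPARABILITY = 0.9
LENGTHS = synthetic.LengthParams(mu=np.log(150), sigma=0.25,
                                 min_len=50, max_len=FIXED_LEN)


def make_seq_arrays(separability: float, seed: int,
                    per_class: int = PER_CLASS, k: int = N_CLASSES,
                    table=None):
    """Encoded sequence tensor + labels at the given separability."""
    profiles = synthetic.make_class_profiles(k, separability, seed,
                                             lengths=LENGTHS)
    ds = synthetic.sample_dataset(profiles, [per_class] * k, seed=seed + 1)
    x = encode_dataset(ds.sequences, T=FIXED_LEN, table=table)
    return x, ds.labels, ds


def make_pssm_arrays(separability: float, seed: int,
                     per_class: int = PER_CLASS, k: int = N_CLASSES):
    """Padded PSSM tensor + labels at the given separability."""
    profiles = synthetic.make_class_profiles(k, separability, seed,
                                             lengths=LENGTHS)
    ds = synthetic.sample_dataset(profiles, [per_class] * k, seed=seed + 1,
                                  with_pssm=True)
    x = np.stack([pad_truncate_pssm(p, FIXED_LEN)[0] for p in ds.pssms])
    return x, ds.labels, ds


@pytest.fixture(scope="session")
def seq_data():
    """One separable sequence dataset shared by the non-acceptance tests."""
    return make_seq_arrays(SEPARABILITY, seed=11)


@pytest.fixture(scope="session")
def pssm_data():
    """One separable PSSM dataset shared by the non-acceptance tests."""
    return make_pssm_arrays(SEPARABILITY, seed=13)
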