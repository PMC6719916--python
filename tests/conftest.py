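"""Shared fixtures: small synthetic corpora and feature sets.

Everything is generated programmatically and seeded; session scope keeps
the expensive corpora to one build per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from meowdag.benchmark import corpus_features
from meowdag.features import Normalizer
from meowdag.synthetic import (ClassProfile, CorpusSpec, default_profiles,
                               generate_corpus, make_separable_profiles)


@pytest.fixture(scope="session")
def default_corpus():
    """The full default 448-clip corpus, in memory (clips + manifest)."""
    return generate_corpus(CorpusSpec(seed=7))


@pytest.fixture(scope="session")
def small_separable():
    """Tiny, widely separated 3-class corpus: (sequences, labels).

    12 clips per class, >= octave f0 spacing, normalized MFCC features —
    enough for quick classifier mechanics tests.
    """
    counts = {(ctx, "MC", "NF"): 12 for ctx in ("food", "isolation",
                                                "brushing")}
    spec = CorpusSpec(cell_counts=counts,
                      profiles=make_separable_profiles(), seed=11)
    seqs, labels = corpus_features(seed=11, spec=spec)
    norm = Normalizer().fit(list(seqs.values()))
    return {c: norm.transform(x) for c, x in seqs.items()}, labels


@pytest.fixture()
def flat_profile():
    return ClassProfile("food", f0_base=300.0, f0_contour="flat",
                        n_harmonics=4, am_rate=4.0, am_depth=0.4,
                        noise_snr=np.inf, duration_mean=0.8,
                        duration_var=1e-4, f0_jitter=0.0,
                        rolloff_jitter=0.0, level_db_range=0.0)
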