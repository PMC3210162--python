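import numpy as np
import pandas as pd
import pytest

from cnvmap import simulate_cohort, study_mirror_config


def make_calls(rows):
    """Build a call table from (sample, pop, chrom, start, end, state, source,
    lod, confidence, n_probes) tuples; trailing fields optional."""
    defaults = (np.nan, np.nan, np.nan)
    records = []
    for r in rows:
        r = tuple(r) + defaults[len(r) - 7 :] if len(r) < 10 else tuple(r)
        records.append(
            dict(
                zip(
                    [
                        "sample_id",
                        "population",
                        "chrom",
                        "start",
                        "end",
                        "copy_state",
                        "source",
                        "lod",
                        "confidence",
                        "n_probes",
                    ],
                    r,
                )
            )
        )
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-population, 40-locus cohort with every noise feature switched on."""
    config = study_mirror_config(
        n_loci=40,
        seed=11,
        populations={"A": 14, "B": 12, "C": 8},
        singleton_rate=0.5,
        complex_rate=0.05,
        missing_rate=0.02,
        qc_noise=0.05,
    )
    calls, samples, truth = simulate_cohort(config)
    return calls, samples, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """A noise-free cohort: built CNVRs coincide exactly with the truth loci."""
    config = study_mirror_config(
        n_loci=30,
        seed=7,
        populations={"A": 20, "B": 15},
        boundary_jitter_sd=0.0,
        singleton_rate=0.0,
        complex_rate=0.0,
        missing_rate=0.0,
        qc_noise=0.0,
    )
    calls, samples, truth = simulate_cohort(config)
    return calls, samples, truth
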