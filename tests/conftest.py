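"""Shared fixtures: one default locus and one aligned P1 library per session."""

import numpy as np
import pytest

from pseudolink import pipeline as pl
from pseudolink.locus import LocusSpec, build_locus, default_transcript


@pytest.fixture(scope="session")
def locus_default():
    """Default synthetic locus: (spec, reference, annotation, transcript)."""
    spec = LocusSpec()
    ref, ann = build_locus(spec)
    return spec, ref, ann, default_transcript(spec)


@pytest.fixture(scope="session")
def p1_run():
    """One neutral (no variant) P1 library, locus-aligned, with fragments."""
    cfg = pl.make_config("P1", "none", seed=11)
    bundle = pl.build_locus_bundle(cfg)
    sim = pl.simulate_bundle(bundle, cfg)
    aln = pl.align_stage(sim, bundle, cfg)
    return cfg, bundle, sim, aln


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
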