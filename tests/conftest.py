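import warnings

import numpy as np
import pytest

from spliceatlas import GeneLocus, generate_locus, make_transcript, preset_auts2a_like


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # the diff engine warns on deliberately malformed fixtures
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def preset_locus_truth():
    return generate_locus(preset_auts2a_like(seed=0))


def build_locus(
    exons,
    sequence=None,
    cds=None,
    alternatives=(),
    evidence=(),
    seed=0,
    contig="chr",
):
    """Hand-build a plus-strand locus; random background unless given."""
    ref = make_transcript("ref", contig, exons, cds=cds)
    n = max(e[1] for t in [exons, *[a[1] for a in alternatives]] for e in t) + 50
    if sequence is None:
        rng = np.random.default_rng(seed)
        sequence = "".join(rng.choice(list("ACGT"), size=n))
    alts = [make_transcript(tid, contig, ex, cds=c) for tid, ex, c in (
        (a[0], a[1], a[2] if len(a) > 2 else None) for a in alternatives
    )]
    return GeneLocus(contig, sequence, ref, alts, list(evidence))


@pytest.fixture
def locus_builder():
    return build_locus
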