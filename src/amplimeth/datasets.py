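"""Packaged fixtures.

The only packaged dataset is a SYNTHETIC stand-in for the human CRP promoter
amplicon: a 551-bp sequence (the −550 ~ +1 bp window) generated by
:func:`amplimeth.simulate.simulate_amplicon` to carry five CpGs — one of
them a C/A SNP-CpG at −286 — and the exceptionally low observed/expected
CpG ratio (~0.23) characteristic of acute-phase-reactant promoters.  It is
not genomic sequence; its generating call and seed are recorded in the JSON
descriptor's ``provenance`` field.
"""

from __future__ import annotations

import json
from importlib import resources

from .bisulfite import ReferenceAmplicon
from .io import load_amplicon

_PKG = "amplimeth.data"
FIXTURE_BASENAME = "crp_promoter_synthetic"


def load_crp_like_amplicon() -> ReferenceAmplicon:
    """Load the synthetic CRP-like promoter amplicon (−550 ~ +1 bp window)."""
    data = resources.files(_PKG)
    return load_amplicon(
        data / f"{FIXTURE_BASENAME}.fa", data / f"{FIXTURE_BASENAME}.json"
    )


def crp_fixture_provenance() -> dict:
    """Return the fixture's recorded generation provenance."""
    data = resources.files(_PKG)
    meta = json.loads((data / f"{FIXTURE_BASENAME}.json").read_text())
    return meta["provenance"]
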