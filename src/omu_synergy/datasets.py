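"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_top30_screen() -> pd.DataFrame:
    """Published MCF7 two-drug validation screen (top-30 candidate list).

    Thirty drug pairs prioritized from single-drug data on the MCF7 breast
    cancer line, with each pair's single-drug GRmax values, its differential
    growth impact score (DGIS) and the ZIP synergy score measured in a 6x6
    dose-response experiment.  Applying the standard ZIP > 5 call to the
    ``zip`` column identifies the truly synergistic combinations.
    """
    with resources.files("omu_synergy.data").joinpath("mcf7_top30_screen.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
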