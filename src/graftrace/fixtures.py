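"""Packaged reference tables of published mobile-mRNA identifiers.

Two small tables of pumpkin (Cucurbita moschata, ``CmoCh``-prefixed) gene
identifiers reported as graft-mobile in cucumber scions: the drought
stress-responsive set specific to drought-stressed heterografts, and the
photosynthesis-related set with its condition labels (P-WS = heterograft
under drought, P-WW = heterograft well-watered).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("graftrace").joinpath("data", name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_stress_responsive_mobile() -> pd.DataFrame:
    """Drought stress-responsive mobile mRNAs found in heterografts (P-WS)."""
    return _load("stress_responsive_mobile.tsv")


def load_photosynthesis_mobile() -> pd.DataFrame:
    """Photosynthesis-related mobile mRNAs with their condition labels."""
    return _load("photosynthesis_mobile.tsv")


def load_published_mobile_tables() -> dict[str, pd.DataFrame]:
    return {
        "stress_responsive": load_stress_responsive_mobile(),
        "photosynthesis": load_photosynthesis_mobile(),
    }
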