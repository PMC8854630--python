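"""Relative quantification by the 2^-delta-delta-Ct method and the
mobility-verification decision rule.

Each sample's target Ct is normalized against a reference gene
(delta Ct = Ct_target - Ct_reference); delta-delta Ct subtracts the mean
delta Ct of the calibrator group, and the relative expression ratio is
2^(-delta-delta Ct), assuming perfect doubling per cycle.  A putative mobile
transcript is confirmed when, assayed with rootstock-specific primers, its
mean ratio in heterograft scions exceeds the homograft mean by a fold
threshold — high signal in heterografts, none or nearly none in homografts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample", "group", "ct_target", "ct_reference")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks column(s) {missing}")
    return table


def ddct_ratio(table: pd.DataFrame,
               calibrator_group: str = "calibrator") -> pd.Series:
    """2^-ddCt relative expression per sample, indexed by sample id.

    Rows with a missing reference Ct are skipped with a warning; the
    calibrator group must be present.
    """
    table = validate_ct_table(table)
    ok = table["ct_reference"].notna() & table["ct_target"].notna()
    skipped = table.loc[~ok, "sample"].tolist()
    if skipped:
        log.warning("skipping sample(s) without complete Ct values: %s",
                    skipped)
    t = table.loc[ok]
    if not ((t["ct_target"] > 0) & (t["ct_reference"] > 0)).all():
        raise ValueError("Ct values must be finite and positive")
    dct = t["ct_target"] - t["ct_reference"]
    cal = dct[t["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"no rows in calibrator group {calibrator_group!r}")
    ddct = dct - cal.mean()
    ratios = np.power(2.0, -ddct)
    ratios.index = t["sample"]
    return ratios


def verify_mobility(hetero_ratios: dict[str, "pd.Series | list | np.ndarray"],
                    homo_ratios: dict[str, "pd.Series | list | np.ndarray"],
                    fold_threshold: float = 10.0,
                    homo_floor: float = 1e-3) -> pd.DataFrame:
    """Per-gene mobility decision from heterograft vs homograft ratios.

    confirmed <=> mean(hetero) >= fold_threshold * max(mean(homo), floor).
    The floor keeps the rule defined when homografts show no signal at all;
    a zero floor with an all-zero homograft mean is rejected.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    genes = sorted(set(hetero_ratios) & set(homo_ratios))
    rows = []
    for g in genes:
        h = float(np.mean(np.asarray(hetero_ratios[g], dtype=float)))
        c = float(np.mean(np.asarray(homo_ratios[g], dtype=float)))
        if c <= 0 and homo_floor <= 0:
            raise ValueError(
                f"gene {g}: homograft mean is zero and no floor is set")
        floored = max(c, homo_floor)
        rows.append({"gene": g, "hetero_mean": h, "homo_mean": c,
                     "confirmed": h >= fold_threshold * floored})
    return pd.DataFrame(rows, columns=["gene", "hetero_mean", "homo_mean",
                                       "confirmed"])


def simulate_assay(rng: np.random.Generator, true_fold: float,
                   n_replicates: int = 3, cv: float = 0.2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Lognormal-noise qPCR ratios for a (hetero, homo) gene assay.

    The homograft baseline is 1; the heterograft ratio is ``true_fold``;
    both carry multiplicative lognormal noise of the given CV.
    """
    sigma = np.sqrt(np.log1p(cv ** 2))
    hetero = true_fold * rng.lognormal(-sigma ** 2 / 2, sigma, n_replicates)
    homo = rng.lognormal(-sigma ** 2 / 2, sigma, n_replicates)
    return hetero, homo
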