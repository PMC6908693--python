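"""Global LOX-transcript normalization and log-log regression.

Per station and size class, lipoxygenase (LOX) transcript abundance is
normalized by the total diatom transcript abundance of the same sample,
then regressed on diatom metagenome abundance (a proxy for diatom
standing stock) in log10-log10 space, per size class and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .regress import RegressionResult, fit_simple

TARA_COLUMNS = [
    "station",
    "size_class",
    "lox_transcripts",
    "total_diatom_transcripts",
    "diatom_metagenome",
]


def validate_tara(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TARA_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"tara table missing columns: {missing}")
    if (table["lox_transcripts"] < 0).any():
        raise DataError("negative LOX transcript abundance")
    if (table["total_diatom_transcripts"] <= 0).any():
        raise DataError("total diatom transcript abundance must be > 0")
    if (table["diatom_metagenome"] <= 0).any():
        raise DataError("diatom metagenome abundance must be > 0")
    return table


def normalize_lox(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``lox_normalized`` = LOX / total diatom transcripts.

    Zero-LOX rows keep a zero normalized value; they are excluded from the
    log regression downstream (their count is reported there).
    """
    table = validate_tara(table)
    out = table.copy()
    out["lox_normalized"] = out["lox_transcripts"] / out["total_diatom_transcripts"]
    return out


@dataclass
class TaraFit:
    pooled: RegressionResult
    per_class: dict[str, RegressionResult]
    failed_classes: dict[str, str]
    n_zero_excluded: int
    rows_are_station_by_size_class: bool = True


def fit_global(table: pd.DataFrame) -> TaraFit:
    """ln(normalized LOX) ~ ln(diatom metagenome), pooled and per class.

    The fit is on the natural-log scale (slope, R², F and df are base
    invariant; the intercept is then comparable with the planted value).
    Surface-sample convention: each row (station x size class) is one
    observation, so a station sampled in several size fractions appears
    once per fraction.  A size class whose metagenome abundance is constant
    cannot be fitted; it is recorded as failed while the pooled fit proceeds.
    """
    if "lox_normalized" not in table.columns:
        table = normalize_lox(table)
    usable = table[table["lox_normalized"] > 0]
    n_zero = len(table) - len(usable)
    if len(usable) < 3:
        raise DataError("fewer than 3 usable rows for the global fit")
    x = np.log(usable["diatom_metagenome"])
    y = np.log(usable["lox_normalized"])
    x.name = "ln_metagenome"
    pooled = fit_simple(x, y)
    per_class: dict[str, RegressionResult] = {}
    failed: dict[str, str] = {}
    for size, sub in usable.groupby("size_class"):
        try:
            xs = np.log(sub["diatom_metagenome"])
            xs.name = "ln_metagenome"
            per_class[str(size)] = fit_simple(xs, np.log(sub["lox_normalized"]))
        except DataError as exc:
            failed[str(size)] = str(exc)
    return TaraFit(pooled, per_class, failed, n_zero)
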