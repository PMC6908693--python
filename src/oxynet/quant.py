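"""Targeted oxylipin (LOFA) quantification and normalization.

Raw chromatogram peak areas are converted to absolute nanogram amounts
against a single internal standard (1 µg of 16-hydroxyhexadecanoic acid
spiked per sample), then normalized per litre of filtered seawater, per
diatom cell, and per nanogram of diatom carbon.  The default analyte panel
is the six-compound LOFA panel: one hydroxy acid and one epoxy-alcohol for
each of the three fatty-acid precursors HTrA (C16:3), EPA (C20:5) and
DHA (C22:6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

# Precursor classes
HTRA = "HTrA"
EPA = "EPA"
DHA = "DHA"
PRECURSORS = (HTRA, EPA, DHA)

# Oxidation classes
HYDROXY = "hydroxy-acid"
EPOXY = "epoxy-alcohol"
OXIDATION_CLASSES = (HYDROXY, EPOXY)

#: per-cell production groups: [0, 100) fg/cell is "low", [100, 300) is
#: "medium", >= 300 is "high" (boundaries assigned upward).
PRODUCTION_BOUNDS = (100.0, 300.0)

NG_TO_FG = 1e6  # 1 ng = 10^6 fg


@dataclass(frozen=True)
class Analyte:
    code: str
    precursor: str
    oxidation: str
    display_name: str


@dataclass(frozen=True)
class AnalytePanel:
    """Mapping from analyte code to precursor / oxidation class."""

    analytes: tuple[Analyte, ...] = field(default_factory=tuple)

    def __post_init__(self):
        codes = [a.code for a in self.analytes]
        if len(set(codes)) != len(codes):
            raise DataError("duplicate analyte codes in panel")
        for a in self.analytes:
            if a.precursor not in PRECURSORS:
                raise DataError(f"unknown precursor '{a.precursor}' for {a.code}")
            if a.oxidation not in OXIDATION_CLASSES:
                raise DataError(f"unknown oxidation class '{a.oxidation}' for {a.code}")

    @property
    def codes(self) -> list[str]:
        return [a.code for a in self.analytes]

    def __len__(self) -> int:
        return len(self.analytes)

    def __getitem__(self, code: str) -> Analyte:
        for a in self.analytes:
            if a.code == code:
                return a
        raise KeyError(code)

    def by_precursor(self, precursor: str) -> list[str]:
        return [a.code for a in self.analytes if a.precursor == precursor]

    def by_oxidation(self, oxidation: str) -> list[str]:
        return [a.code for a in self.analytes if a.oxidation == oxidation]


def default_panel() -> AnalytePanel:
    """The six targeted LOFAs."""
    return AnalytePanel(
        (
            Analyte("HHTrE", HTRA, HYDROXY, "hydroxy-hexadecatrienoic acid"),
            Analyte("EHHDE", HTRA, EPOXY, "epoxy-hydroxy-hexadecadienoic acid"),
            Analyte("HEPE", EPA, HYDROXY, "hydroxy-eicosapentaenoic acid"),
            Analyte("EHETE", EPA, EPOXY, "epoxy-hydroxy-eicosatetraenoic acid"),
            Analyte("HDoHE", DHA, HYDROXY, "hydroxy-docosahexaenoic acid"),
            Analyte("EHDPE", DHA, EPOXY, "epoxy-hydroxy-docosapentaenoic acid"),
        )
    )


PEAK_COLUMNS = ["sample", "analyte", "peak_area", "standard_area", "volume_l"]


def validate_peaks(peaks: pd.DataFrame, panel: AnalytePanel) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise DataError(f"peak table missing columns: {missing}")
    unknown = sorted(set(peaks["analyte"]) - set(panel.codes))
    if unknown:
        raise DataError(f"unknown analyte codes: {unknown}")
    if (peaks["peak_area"] < 0).any():
        raise DataError("negative peak area")
    if (peaks["standard_area"] <= 0).any():
        raise DataError("standard area must be > 0")
    if (peaks["volume_l"] <= 0).any():
        raise DataError("filtered volume must be > 0")
    per_sample = peaks.groupby("sample")["standard_area"].nunique()
    if (per_sample > 1).any():
        bad = per_sample[per_sample > 1].index.tolist()
        raise DataError(f"multiple standard areas within sample(s): {bad}")
    return peaks


def quantify(peaks: pd.DataFrame, panel: AnalytePanel | None = None) -> pd.DataFrame:
    """Absolute amount per analyte: ng_x = a_x * 1000 / a_S.

    The factor 1000 carries the 1 µg internal standard into nanograms.
    Returns a samples x analytes DataFrame of ng; a `volume_l` column is
    appended for downstream per-litre normalization.
    """
    panel = panel if panel is not None else default_panel()
    peaks = validate_peaks(peaks, panel)
    out = peaks.copy()
    out["ng"] = out["peak_area"] * 1000.0 / out["standard_area"]
    wide = out.pivot_table(index="sample", columns="analyte", values="ng", sort=False)
    wide = wide.reindex(columns=panel.codes)
    vol = out.groupby("sample", sort=False)["volume_l"].first()
    wide["volume_l"] = vol
    wide.columns.name = None
    return wide


def normalize_per_litre(ng: pd.DataFrame, volume: pd.Series | None = None) -> pd.DataFrame:
    """ng/L per analyte: absolute ng divided by filtered volume (L)."""
    if volume is None:
        if "volume_l" not in ng.columns:
            raise DataError("no volume_l column and no volume series given")
        volume = ng["volume_l"]
        ng = ng.drop(columns="volume_l")
    elif "volume_l" in ng.columns:
        ng = ng.drop(columns="volume_l")
    volume = volume.reindex(ng.index)
    if (volume <= 0).any() or volume.isna().any():
        raise DataError("filtered volume must be > 0 for every sample")
    return ng.div(volume, axis=0)


def normalize_per_cell(ng_per_litre: pd.DataFrame, diatom_density: pd.Series) -> pd.DataFrame:
    """fg per diatom cell: (ng/L * 10^6) / (cells/L).

    Weeks with zero or missing diatom density yield missing values (the
    division is undefined and such weeks are dropped from later statistics).
    """
    density = diatom_density.reindex(ng_per_litre.index)
    if (density.dropna() < 0).any():
        raise DataError("negative diatom density")
    density = density.where(density > 0)  # 0 -> NaN
    return ng_per_litre.mul(NG_TO_FG).div(density, axis=0)


def biomass_carbon(
    biovolume_um3: float | pd.Series,
    density: pd.Series,
    c1: float = 0.288,
    c2: float = 0.811,
) -> pd.Series:
    """Diatom carbon (ng-C/L) from mean cell biovolume and density.

    Per-cell carbon follows the diatom power law pg C = c1 * V^c2 with V in
    µm³; coefficients are configurable.
    """
    bv = np.asarray(biovolume_um3, dtype=float)
    if (bv <= 0).any() if bv.ndim else bv <= 0:
        raise DataError("biovolume must be > 0")
    if (pd.Series(density).dropna() < 0).any():
        raise DataError("negative density")
    pg_per_cell = c1 * bv ** c2
    return pg_per_cell * density / 1000.0  # pg/L -> ng/L


def aggregate_classes(values: pd.DataFrame, panel: AnalytePanel | None = None) -> pd.DataFrame:
    """Sum per precursor class, per oxidation class, and in total.

    Works on any per-analyte table (ng/L or fg/cell); NaN propagates so a
    week with missing per-cell values stays missing in the aggregates.
    """
    panel = panel if panel is not None else default_panel()
    cols = [c for c in panel.codes if c in values.columns]
    if len(cols) < len(panel.codes):
        raise DataError(f"profile missing analytes: {sorted(set(panel.codes) - set(cols))}")
    agg = pd.DataFrame(index=values.index)
    for prec in PRECURSORS:
        agg[f"{prec}-derived"] = values[panel.by_precursor(prec)].sum(axis=1, min_count=len(panel.by_precursor(prec)))
    agg["hydroxy-acids"] = values[panel.by_oxidation(HYDROXY)].sum(axis=1, min_count=len(panel.by_oxidation(HYDROXY)))
    agg["epoxy-alcohols"] = values[panel.by_oxidation(EPOXY)].sum(axis=1, min_count=len(panel.by_oxidation(EPOXY)))
    agg["total"] = values[cols].sum(axis=1, min_count=len(cols))
    return agg


def classify_production(fg_per_cell: float | pd.Series) -> pd.Series | str | None:
    """Label per-cell production as low / medium / high.

    [0, 100) fg/cell -> "low", [100, 300) -> "medium", >= 300 -> "high";
    missing values stay unlabelled (None).
    """
    scalar = np.isscalar(fg_per_cell)
    s = pd.Series([fg_per_cell]) if scalar else pd.Series(fg_per_cell)
    if (s.dropna() < 0).any():
        raise DataError("negative fg/cell value")
    lo, hi = PRODUCTION_BOUNDS
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    out[s < lo] = "low"
    out[(s >= lo) & (s < hi)] = "medium"
    out[s >= hi] = "high"
    out[s.isna()] = None
    if scalar:
        return out.iloc[0]
    out.index = s.index
    return out


@dataclass
class LofaProfile:
    """Per-sample oxylipin profile on every normalization scale."""

    ng: pd.DataFrame
    ng_per_litre: pd.DataFrame
    fg_per_cell: pd.DataFrame
    class_ng_per_litre: pd.DataFrame
    class_fg_per_cell: pd.DataFrame
    production_group: pd.Series
    fg_per_ng_carbon: pd.DataFrame | None = None

    @property
    def samples(self) -> pd.Index:
        return self.ng_per_litre.index


def build_profile(
    peaks: pd.DataFrame,
    diatom_density: pd.Series,
    panel: AnalytePanel | None = None,
    biovolume_um3: float | None = None,
) -> LofaProfile:
    """Run the full quantification chain peak areas -> LofaProfile."""
    panel = panel if panel is not None else default_panel()
    ng = quantify(peaks, panel)
    ng_l = normalize_per_litre(ng)
    fg_cell = normalize_per_cell(ng_l, diatom_density)
    class_ng_l = aggregate_classes(ng_l, panel)
    class_fg = aggregate_classes(fg_cell, panel)
    groups = classify_production(class_fg["total"])
    fg_per_c = None
    if biovolume_um3 is not None:
        carbon = biomass_carbon(biovolume_um3, diatom_density.reindex(ng_l.index))
        carbon = carbon.where(carbon > 0)
        fg_per_c = ng_l.mul(NG_TO_FG).div(carbon, axis=0)
    return LofaProfile(
        ng=ng.drop(columns="volume_l"),
        ng_per_litre=ng_l,
        fg_per_cell=fg_cell,
        class_ng_per_litre=class_ng_l,
        class_fg_per_cell=class_fg,
        production_group=groups,
        fg_per_ng_carbon=fg_per_c,
    )
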