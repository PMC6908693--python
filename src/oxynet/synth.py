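"""Synthetic weekly plankton datasets with planted density-dependence.

The generator emulates the statistical structure of a one-year coastal
time series: guild-structured seasonal diatom blooms spanning more than
two orders of magnitude in total density, a targeted-oxylipin peak table
whose planted per-cell values follow an inverse log-log density law,
a salinity series with near-constant water-mass windows, and a global
station table in which normalized lipoxygenase (LOX) transcript abundance
declines log-linearly with diatom metagenome abundance.

Both planted relations live on the natural-log scale:
``ln(fg/cell) = a + b * ln(cells/L)`` with defaults a = 10.75, b = -0.46
(81 fg/cell at 10^6 cells/L, ~1400 fg/cell at sparse winter densities),
and ``ln(normalized LOX) = 21.33 - 0.7 * ln(metagenome abundance)``.
Log-log slopes are invariant under the choice of log base.

Every planted parameter is recorded in ``SynthDataset.truth`` so recovery
tests can compare estimates against ground truth.  The peak-area model is
the exact algebraic inverse of the quantification chain, so noise-free
peaks quantify back to the planted values to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from . import quant
from .quant import NG_TO_FG, PRECURSORS

# Fractions of the planted per-cell total carried by each precursor class,
# following the observed ordering EPA > DHA > HTrA.
DEFAULT_CLASS_FRACTIONS = {"EPA": 0.7668, "DHA": 0.2196, "HTrA": 0.0136}
# Hydroxy acid vs epoxy-alcohol split within a precursor class.
DEFAULT_OXIDATION_SPLIT = {"hydroxy-acid": 0.7, "epoxy-alcohol": 0.3}

# Water-mass windows: (start week, length, salinity level PSU, jitter PSU).
# One long late-winter window plus three short ones, echoing the observed
# 38±0.06 (7 wk), 37.5±0.12, 37.7±0.05 and 38.2±0.01 PSU periods.
DEFAULT_SALINITY_WINDOWS = (
    (5, 7, 38.0, 0.06),
    (14, 3, 37.5, 0.12),
    (18, 3, 37.7, 0.05),
    (40, 3, 38.2, 0.01),
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters governing every stochastic draw of the generator."""

    seed: int = 0
    n_weeks: int = 52
    n_taxa: int = 53
    n_modules: int = 3
    density_slope_b: float = -0.46
    density_intercept_a: float = 10.75  # ln fg/cell at ln density 0
    noise_sd: float = 0.38  # ln-scale residual SD; R^2 ~ 0.855 at default densities
    detection_limit: float = 250.0  # cells/L below which a count is recorded as 0
    tara_slope: float = -0.7
    tara_intercept: float = 21.33  # ln normalized LOX at ln metagenome 0
    tara_noise_sd: float = 1.97  # ln-scale; R^2 ~ 0.4 with sd(ln G) = 2.3
    tara_n_stations: int = 146
    salinity_windows: tuple = DEFAULT_SALINITY_WINDOWS
    standard_area: float = 5.0e5
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    oxidation_split: dict = field(default_factory=lambda: dict(DEFAULT_OXIDATION_SPLIT))

    def __post_init__(self):
        if self.n_modules < 1:
            raise ConfigurationError("n_modules must be >= 1")
        if self.n_taxa < self.n_modules:
            raise ConfigurationError("n_taxa must be >= n_modules")
        if self.n_weeks < 4:
            raise ConfigurationError("n_weeks must be >= 4")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.tara_noise_sd < 0:
            raise ConfigurationError("tara_noise_sd must be >= 0")
        if self.standard_area <= 0:
            raise ConfigurationError("standard_area must be > 0")
        if self.detection_limit < 0:
            raise ConfigurationError("detection_limit must be >= 0")
        if self.tara_n_stations < 3:
            raise ConfigurationError("tara_n_stations must be >= 3")
        spans = []
        for w in self.salinity_windows:
            start, length, level, jitter = w
            if length < 1 or start < 0 or start + length > self.n_weeks:
                raise ConfigurationError(f"salinity_windows: window {w} outside n_weeks")
            if jitter < 0:
                raise ConfigurationError("salinity_windows: jitter must be >= 0")
            spans.append((start, start + length))
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ConfigurationError("salinity_windows: overlapping windows")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent, reproducible substream per operation
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def week_labels(n_weeks: int) -> list[str]:
    return [f"W{w + 1:02d}" for w in range(n_weeks)]


def guild_assignment(config: SynthConfig) -> np.ndarray:
    """Taxon -> guild labels, round-robin so guilds are near-equal in size."""
    return np.arange(config.n_taxa) % config.n_modules


def generate_community(config: SynthConfig) -> pd.DataFrame:
    """Taxa x weeks abundance matrix (cells/L) with guild-structured blooms.

    Taxa within a guild share a Gaussian-in-time bloom envelope multiplied
    by per-taxon lognormal noise (ln-scale SD = ``noise_sd``), so within-guild
    rank co-variation is strongly positive while between-guild co-variation
    is weak.  Counts below ``detection_limit`` are recorded as absent, as a
    settling-chamber count would be, so presence/absence varies seasonally.
    Total weekly density spans >= 2 orders of magnitude.
    """
    rng = _rng(config, 1)
    t = np.arange(config.n_weeks, dtype=float)
    guilds = guild_assignment(config)
    centers = config.n_weeks * (np.arange(config.n_modules) + 0.5) / config.n_modules
    width = max(config.n_weeks / (7.0 * config.n_modules), 1.2)

    envelopes = np.empty((config.n_modules, config.n_weeks))
    for g in range(config.n_modules):
        # small floor keeps abundances positive between blooms
        envelopes[g] = 0.0015 + np.exp(-0.5 * ((t - centers[g]) / width) ** 2)

    scales = 10 ** rng.normal(5.0, 0.4, size=config.n_taxa)  # peak cells/L per taxon
    noise = np.exp(rng.normal(0.0, config.noise_sd, size=(config.n_taxa, config.n_weeks)))
    values = scales[:, None] * envelopes[guilds] * noise
    values[values < config.detection_limit] = 0.0

    taxa = [f"taxon_{i + 1:02d}" for i in range(config.n_taxa)]
    return pd.DataFrame(values, index=taxa, columns=week_labels(config.n_weeks))


def planted_per_cell(config: SynthConfig, total_density: np.ndarray,
                     noise: np.ndarray) -> dict[str, np.ndarray]:
    """Planted per-class fg/cell values for given weekly total densities.

    ln(class fg/cell) = [a + ln(f_class)] + b * ln(density) + eps, so the
    class values sum to exp(a + b * ln D) when noise is zero.
    """
    logd = np.log(total_density)
    out = {}
    for k, prec in enumerate(PRECURSORS):
        frac = config.class_fractions[prec]
        out[prec] = np.exp(
            config.density_intercept_a + np.log(frac)
            + config.density_slope_b * logd + noise[k]
        )
    return out


def generate_lofa_peaks(abundance: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Peak table whose quantification recovers the planted per-cell law.

    The chain runs backwards through the quantification formulas:
    fg/cell -> ng/L (times density / 10^6) -> ng (times volume) ->
    peak area (ng * a_S / 1000).  Weeks with zero total density get zero
    areas (their per-cell values are undefined).
    """
    if abundance.shape[1] < 4:
        raise ConfigurationError("abundance must cover >= 4 weeks")
    rng = _rng(config, 2)
    weeks = abundance.columns
    total = abundance.sum(axis=0).to_numpy(dtype=float)
    volumes = rng.choice([0.5, 1.0, 2.0], size=len(weeks))
    noise = rng.normal(0.0, config.noise_sd, size=(len(PRECURSORS), len(weeks)))

    panel = quant.default_panel()
    rows = []
    positive = total > 0
    safe_total = np.where(positive, total, 1.0)
    per_class = planted_per_cell(config, safe_total, noise)
    for j, wk in enumerate(weeks):
        for prec in PRECURSORS:
            for code in panel.by_precursor(prec):
                split = config.oxidation_split[panel[code].oxidation]
                if positive[j]:
                    fg_cell = per_class[prec][j] * split
                    ng_l = fg_cell * total[j] / NG_TO_FG
                    ng = ng_l * volumes[j]
                    area = ng * config.standard_area / 1000.0
                else:
                    area = 0.0
                rows.append((wk, code, area, config.standard_area, volumes[j]))
    return pd.DataFrame(rows, columns=quant.PEAK_COLUMNS)


def generate_environment(config: SynthConfig) -> pd.DataFrame:
    """Weekly environmental series with declared salinity plateaus.

    Inside a declared window the salinity equals the window level plus
    uniform jitter; elsewhere it follows a reflecting random walk between
    35.8 and 37.2 PSU whose steps are at least 0.35 PSU, so consecutive
    non-window weeks never mimic a plateau and declared windows (levels
    >= 37.5 PSU) are recoverable exactly at the default 0.15 PSU tolerance.
    """
    rng = _rng(config, 3)
    n = config.n_weeks
    t = np.arange(n, dtype=float)

    salinity = np.empty(n)
    in_window = np.zeros(n, dtype=bool)
    for start, length, level, jitter in config.salinity_windows:
        idx = slice(start, start + length)
        salinity[idx] = level + rng.uniform(-jitter, jitter, size=length)
        in_window[idx] = True

    s, direction = 36.5, 1.0
    lo, hi = 35.8, 37.2
    for j in range(n):
        if in_window[j]:
            continue
        step = rng.uniform(0.35, 0.6)
        if not (lo <= s + direction * step <= hi):
            direction = -direction
        s = float(np.clip(s + direction * step, lo, hi))
        salinity[j] = s

    temperature = 19.5 + 6.5 * np.sin(2 * np.pi * (t - 18.0) / n) + rng.normal(0, 0.4, n)
    chl_a = 10 ** (0.3 + 0.5 * np.sin(2 * np.pi * (t - 10.0) / n) + rng.normal(0, 0.15, n))
    return pd.DataFrame(
        {"salinity": salinity, "temperature": temperature, "chl_a": chl_a},
        index=week_labels(n),
    )


TARA_SIZE_CLASSES = ("0.8-5", "5-20", "20-180", "180-2000")


def generate_tara(config: SynthConfig) -> pd.DataFrame:
    """Station table with a planted log-log transcript/metagenome relation.

    Diatom metagenome abundance G is lognormal across rows; normalized LOX
    expression is exp(intercept + slope * ln G + eps).  Raw LOX and total
    diatom transcript columns are emitted so that their ratio equals the
    normalized value exactly.
    """
    rng = _rng(config, 4)
    n = config.tara_n_stations
    g = np.exp(rng.normal(46.0, 2.3, size=n))  # ~10^20 median, one-decade SD
    eps = rng.normal(0.0, config.tara_noise_sd, size=n)
    normalized = np.exp(config.tara_intercept + config.tara_slope * np.log(g) + eps)
    total_transcripts = np.exp(rng.normal(20.7, 1.15, size=n))
    lox = normalized * total_transcripts
    return pd.DataFrame(
        {
            "station": [f"TARA_{i // len(TARA_SIZE_CLASSES) + 1:03d}" for i in range(n)],
            "size_class": [TARA_SIZE_CLASSES[i % len(TARA_SIZE_CLASSES)] for i in range(n)],
            "lox_transcripts": lox,
            "total_diatom_transcripts": total_transcripts,
            "diatom_metagenome": g,
        }
    )


@dataclass
class SynthDataset:
    """Bundle of generated tables plus the ground truth that made them."""

    abundance: pd.DataFrame
    peaks: pd.DataFrame
    environment: pd.DataFrame
    tara: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.abundance.to_csv(outdir / "abundance.csv", index_label="taxon")
        self.peaks.to_csv(outdir / "peaks.csv", index=False)
        self.environment.to_csv(outdir / "environment.csv", index_label="week")
        self.tara.to_csv(outdir / "tara.csv", index=False)
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=True)


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """All four tables from one config; deterministic per seed."""
    abundance = generate_community(config)
    peaks = generate_lofa_peaks(abundance, config)
    environment = generate_environment(config)
    tara = generate_tara(config)
    truth = asdict(config)
    truth["salinity_windows"] = [list(w) for w in config.salinity_windows]
    truth["guilds"] = {
        taxon: int(g)
        for taxon, g in zip(abundance.index, guild_assignment(config))
    }
    return SynthDataset(abundance, peaks, environment, tara, truth)
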