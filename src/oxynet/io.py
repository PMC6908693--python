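"""Table readers/writers with schema validation, and the pipeline driver.

The pipeline chains every stage end-to-end: quantification ->
class aggregation -> density regressions -> production-group community
tests -> global transcript fit -> annotated co-variation network with
null tests.  Each stochastic step derives its seed from the single
pipeline seed and logs it; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, StageError
from . import multivar, network as netmod, quant, regress, tara as taramod

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    numeric: tuple[str, ...]
    index: str | None = None


ABUNDANCE_SCHEMA = TableSchema("abundance", ("taxon",), (), index="taxon")
PEAKS_SCHEMA = TableSchema(
    "peaks", tuple(quant.PEAK_COLUMNS), ("peak_area", "standard_area", "volume_l")
)
ENV_SCHEMA = TableSchema(
    "environment", ("week", "salinity", "temperature", "chl_a"),
    ("salinity", "temperature", "chl_a"), index="week",
)
TARA_SCHEMA = TableSchema(
    "tara", tuple(taramod.TARA_COLUMNS),
    ("lox_transcripts", "total_diatom_transcripts", "diatom_metagenome"),
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Schema-checked CSV reader (UTF-8, header row, '.' decimal)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{schema.name}: file not found: {path}")
    if path.stat().st_size == 0:
        raise DataError(f"{schema.name}: empty file: {path}")
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in schema.columns if c not in frame.columns]
    if missing:
        raise DataError(f"{schema.name}: missing columns {missing}")
    numeric = set(schema.numeric)
    if schema.name == "abundance":
        numeric |= set(frame.columns) - {"taxon"}
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise DataError(
                f"{schema.name}: non-numeric value in column '{col}' at row {bad[0] + 2}"
            )
        frame[col] = coerced
    if schema.index:
        frame = frame.set_index(schema.index)
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=index_label is not None, index_label=index_label)


@dataclass
class PipelineConfig:
    abundance_path: str
    peaks_path: str
    environment_path: str
    tara_path: str
    outdir: str
    seed: int = 0
    rho_min: float = 0.7
    alpha: float = 0.05
    vif_limit: float = 10.0
    salinity_tolerance: float = 0.15
    permutations: int = 9999
    reshuffles: int = 1000
    nmds_restarts: int = 20

    def __post_init__(self):
        for name in ("rho_min", "alpha", "vif_limit", "salinity_tolerance"):
            if getattr(self, name) <= 0:
                raise DataError(f"threshold {name} must be positive")


def run_pipeline_frames(
    abundance: pd.DataFrame,
    peaks: pd.DataFrame,
    environment: pd.DataFrame,
    tara_table: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Execute every analysis stage on in-memory tables.

    Returns a bundle with the per-stage objects plus a YAML-serializable
    summary.  Stage failures raise :class:`StageError` with the stage name.
    """
    bundle: dict = {}
    summary: dict = {"seed": config.seed}

    try:
        density = abundance.sum(axis=0)
        profile = quant.build_profile(peaks, density)
        bundle["profile"] = profile
        summary["quantify"] = {
            "n_samples": int(len(profile.samples)),
            "panel_size": len(quant.default_panel()),
            "total_ng_per_litre_mean": float(profile.class_ng_per_litre["total"].mean()),
        }
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc

    try:
        log_density = regress.ln_series(density, "diatom density")
        y_cell = regress.ln_series(profile.class_fg_per_cell["total"], "fg/cell")
        retained, dropped = regress.exclude_outliers(log_density, y_cell)
        fit_cell = regress.fit_simple(
            log_density.loc[retained].rename("ln_density"),
            y_cell.loc[retained], excluded=list(dropped.index),
        )
        y_litre = regress.ln_series(profile.class_ng_per_litre["total"], "ng/L")
        fit_litre = regress.fit_simple(log_density.rename("ln_density"), y_litre)
        bundle["fit_per_cell"], bundle["fit_per_litre"] = fit_cell, fit_litre
        summary["regress"] = {
            "per_cell_slope": fit_cell.slope,
            "per_cell_intercept": fit_cell.intercept,
            "per_cell_adj_r2": fit_cell.adj_r2,
            "per_cell_df": fit_cell.df_resid,
            "per_cell_n": fit_cell.n,
            "per_litre_slope": fit_litre.slope,
            "per_litre_adj_r2": fit_litre.adj_r2,
            "excluded": [str(i) for i in dropped.index],
        }
    except Exception as exc:
        raise StageError("regress", str(exc)) from exc

    try:
        groups = profile.production_group.dropna()
        usable = [w for w in abundance.columns if w in groups.index]
        groups = groups.loc[usable]
        counts = groups.value_counts()
        multivar_summary: dict = {"group_sizes": {str(k): int(v) for k, v in counts.items()}}
        if len(counts) >= 2 and (counts >= 2).all():
            mat = abundance[usable]
            balanced, bal_groups, padded = multivar.balance_groups(mat, groups)
            dist = multivar.bray_curtis(balanced)
            res = multivar.anosim(dist, bal_groups, config.permutations,
                                  config.seed, pairwise=True)
            binary = (mat > 0).astype(float)
            bal_bin, bal_bin_groups, _ = multivar.balance_groups(binary, groups)
            res_j = multivar.anosim(multivar.jaccard(bal_bin), bal_bin_groups,
                                    config.permutations, config.seed)
            ord_res = multivar.nmds(multivar.bray_curtis(mat), seed=config.seed,
                                    restarts=config.nmds_restarts)
            bundle["anosim_bc"], bundle["anosim_jac"], bundle["nmds"] = res, res_j, ord_res
            simper_pairs = multivar.simper_all(mat, groups)
            bundle["simper"] = simper_pairs
            multivar_summary.update(
                anosim_braycurtis_r=res.r, anosim_braycurtis_p=res.p,
                anosim_jaccard_r=res_j.r, anosim_jaccard_p=res_j.p,
                nmds_stress=ord_res.stress, n_padded=len(padded),
            )
        else:
            multivar_summary["skipped"] = "fewer than 2 usable production groups"
        summary["multivar"] = multivar_summary
    except Exception as exc:
        raise StageError("multivar", str(exc)) from exc

    try:
        fit = taramod.fit_global(tara_table)
        bundle["tara_fit"] = fit
        summary["tara"] = {
            "slope": fit.pooled.slope,
            "intercept": fit.pooled.intercept,
            "adj_r2": fit.pooled.adj_r2,
            "df": fit.pooled.df_resid,
            "n": fit.pooled.n,
            "n_zero_excluded": fit.n_zero_excluded,
            "n_size_classes": len(fit.per_class),
        }
    except Exception as exc:
        raise StageError("tara", str(exc)) from exc

    try:
        windows = netmod.detect_water_masses(
            environment["salinity"], config.salinity_tolerance
        )
        edges = []
        for w in windows:
            edges.extend(
                netmod.spearman_edges(abundance, w, config.rho_min, config.alpha)
            )
        net = netmod.build_network(edges, list(abundance.index))
        net = netmod.find_modules(net, seed=config.seed)
        netmod.annotate_edges(net.edges, profile.class_fg_per_cell, windows)
        null_tests = {}
        for cls in netmod.CLASS_COLUMNS:
            try:
                null_tests[cls] = netmod.null_module_test(
                    net, cls, config.reshuffles, config.seed
                )
            except DataError as exc:
                log.info("null test skipped for %s: %s", cls, exc)
        bundle["windows"], bundle["network"], bundle["null_tests"] = windows, net, null_tests
        deg = netmod.degree_summary(net)
        summary["network"] = {
            "windows": [
                {"label": w.label, "weeks": list(w.weeks),
                 "salinity_mean": round(w.salinity_mean, 3)}
                for w in windows
            ],
            "n_edges": int(net.graph.number_of_edges()),
            "modularity_q": net.modularity_q,
            "n_modules": len({m for m in net.modules.values() if m is not None}),
            **deg,
            "null_tests": {
                cls: [
                    {"module": r.module, "t": round(r.t_stat, 3), "df": r.df,
                     "p": r.p, "equal_variance": r.equal_variance}
                    for r in results
                ]
                for cls, results in null_tests.items()
            },
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("network", str(exc)) from exc

    bundle["summary"] = summary
    return bundle


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; writes per-stage CSVs and a YAML report."""
    abundance = read_table(config.abundance_path, ABUNDANCE_SCHEMA)
    peaks = read_table(config.peaks_path, PEAKS_SCHEMA)
    environment = read_table(config.environment_path, ENV_SCHEMA)
    tara_table = read_table(config.tara_path, TARA_SCHEMA)

    bundle = run_pipeline_frames(abundance, peaks, environment, tara_table, config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = bundle["profile"]
    write_table(profile.ng_per_litre, outdir / "profile_ng_per_litre.csv", "sample")
    write_table(profile.fg_per_cell, outdir / "profile_fg_per_cell.csv", "sample")
    write_table(profile.class_fg_per_cell, outdir / "profile_classes_fg_per_cell.csv", "sample")
    if "network" in bundle:
        net = bundle["network"]
        write_table(netmod.edge_list_frame(net), outdir / "network_edges.csv")
        write_table(net.degree_table(), outdir / "network_nodes.csv", "taxon")
        netmod.write_graphml(net, outdir / "network.graphml")
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(_round_floats(bundle["summary"]), fh, sort_keys=True)
    return bundle


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
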