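"""File formats, run manifests, and the end-to-end pipeline.

All tables are tab-delimited UTF-8 with required headers; fit reports and
manifests are JSON.  Clone tables are long format (clone_id, replicate,
condition, day, n_cells); barcode tables come in long (barcode, sample,
reads) or wide (barcode x samples) layout with an optional spike-in
annotation file (barcode, true_cells).  Every pipeline run writes a
manifest recording the command, the config snapshot, the seeds and the
input digests, so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CloneSizeSample, TwoStateParams
from .heritability import BarcodeCountTable, null_distribution
from .metrics import HIGH, classify_proliferative, log2_divisions, summarize_by_group
from .modality import bimodality_coefficient, fit_gmm
from .ode import fit_growth_model
from .sweep import parameter_sweep
from .synthetic import SyntheticConfig, gen_barcode_experiment, gen_clone_size_table

logger = logging.getLogger("clonedyn")

CLONE_TABLE_COLUMNS = ["clone_id", "replicate", "condition", "day", "n_cells"]

__all__ = [
    "read_clone_table",
    "write_clone_table",
    "read_barcode_table",
    "write_barcode_table",
    "RunManifest",
    "run_pipeline",
]


class TableValidationError(ValueError):
    """A delimited input table failed validation."""


def read_clone_table(
    path, drop_singletons: bool = True
) -> pd.DataFrame:
    """Read and validate a clone-size table.

    Rows with missing, non-integer, or sub-1 cell counts are rejected with
    their (1-based, header included) line numbers.  Single-cell clones are
    filtered by default, the imaging-analysis convention; the number
    removed is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    missing = [c for c in CLONE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing column(s) {missing}")
    counts = pd.to_numeric(df["n_cells"], errors="coerce")
    bad = counts.isna() | (counts < 1) | (counts != counts.round())
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise TableValidationError(
            f"{path}: invalid n_cells on line(s) {lines[:20]}"
            + (" ..." if len(lines) > 20 else "")
        )
    df["n_cells"] = counts.astype(np.int64)
    df["day"] = pd.to_numeric(df["day"], errors="raise")
    if drop_singletons:
        n1 = int((df["n_cells"] == 1).sum())
        if n1:
            logger.info("filtered %d single-cell clone(s) from %s", n1, path)
        df = df[df["n_cells"] > 1].reset_index(drop=True)
    return df


def write_clone_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_barcode_table(
    path, layout: str = "long", spikein_path=None
) -> BarcodeCountTable:
    """Read a barcode count table in long or wide layout.

    Long layout needs columns (barcode, sample, reads); duplicate
    (barcode, sample) rows are an error and barcodes absent from a sample
    are treated as 0 reads with a warning.  Wide layout is barcode plus one
    column per sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    if "barcode" not in df.columns:
        raise TableValidationError(f"{path}: missing 'barcode' column")
    if layout == "long":
        for col in ("sample", "reads"):
            if col not in df.columns:
                raise TableValidationError(f"{path}: missing '{col}' column")
        dup = df.duplicated(["barcode", "sample"])
        if dup.any():
            raise TableValidationError(
                f"{path}: duplicate (barcode, sample) rows at lines "
                f"{(df.index[dup] + 2).tolist()[:10]}"
            )
        wide = df.pivot(index="barcode", columns="sample", values="reads")
        n_missing = int(wide.isna().sum().sum())
        if n_missing:
            logger.warning(
                "%s: %d barcode/sample combinations absent; treated as 0 reads",
                path,
                n_missing,
            )
        wide = wide.fillna(0)
    elif layout == "wide":
        wide = df.set_index("barcode")
    else:
        raise ValueError("layout must be 'long' or 'wide'")
    wide.columns.name = None
    spike = None
    if spikein_path is not None:
        sp = pd.read_csv(spikein_path, sep="\t", dtype={"barcode": str})
        for col in ("barcode", "true_cells"):
            if col not in sp.columns:
                raise TableValidationError(
                    f"{spikein_path}: missing '{col}' column"
                )
        spike = sp.set_index("barcode")["true_cells"].astype(float)
    return BarcodeCountTable(counts=wide, spikein_true_cells=spike)


def write_barcode_table(table: BarcodeCountTable, path, layout: str = "long") -> None:
    if layout == "long":
        long = (
            table.counts.rename_axis("barcode")
            .reset_index()
            .melt(id_vars="barcode", var_name="sample", value_name="reads")
        )
        long.to_csv(path, sep="\t", index=False)
    else:
        table.counts.rename_axis("barcode").reset_index().to_csv(
            path, sep="\t", index=False
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline/CLI run."""

    command: str
    config: dict
    seed: int
    input_digests: dict = field(default_factory=dict)
    package_version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, TwoStateParams):
        return vars(obj)
    return str(obj)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the two end-to-end analyses on synthetic or supplied data.

    Stages: clone-table generation (or loading), grouped metrics, per-day
    modality analysis, day-8 KS parameter sweep per clone class, growth-
    curve ODE fits of the per-class mean curves, and the barcode
    heritability analysis with a non-heritable null.  Stage outputs land in
    ``out_dir`` together with a manifest; any stage failure aborts with the
    stage name while earlier outputs are preserved.

    ``config`` keys (all optional except ``seed``): ``clone_table`` (path;
    otherwise synthetic), ``n_clones``, ``days``, ``sweep_grid_step``,
    ``sweep_n_sim``, ``n_null_replicates``, ``heritable``, ``n_barcodes``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(
        command="run_pipeline",
        config=dict(config),
        seed=seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    results: dict = {}
    stage = "setup"
    try:
        stage = "clone_table"
        if "clone_table" in config:
            manifest.input_digests[str(config["clone_table"])] = _sha256(
                config["clone_table"]
            )
            table = read_clone_table(config["clone_table"])
            syn_cfg = SyntheticConfig(seed=seed)
        else:
            syn_cfg = SyntheticConfig(
                seed=seed,
                n_clones=int(config.get("n_clones", 500)),
                days=tuple(config.get("days", (2.0, 5.0, 8.0, 11.0))),
                heritable=bool(config.get("heritable", True)),
                n_barcodes=int(config.get("n_barcodes", 1000)),
            )
            table = gen_clone_size_table(syn_cfg)
            write_clone_table(table, out_dir / "clone_table.tsv")
        if table.empty:
            raise TableValidationError("clone table is empty after filtering")

        stage = "metrics"
        summary = summarize_by_group(table, ["day"])
        summary.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        results["metrics"] = summary

        stage = "modality"
        modality_rows = []
        for day, grp in table.groupby("day"):
            div = log2_divisions(grp["n_cells"].to_numpy(), drop_singletons=True)
            if div.size < 10 or np.ptp(div) == 0:
                continue
            call = bimodality_coefficient(div)
            gmm = fit_gmm(div, candidate_components=(1, 2, 3), seed=seed)
            modality_rows.append(
                {
                    "day": day,
                    "coefficient": call.coefficient,
                    "call": call.call,
                    "gmm_components": gmm.n_components,
                    "gmm_means": json.dumps(gmm.means.tolist()),
                    "gmm_weights": json.dumps(gmm.weights.tolist()),
                }
            )
        modality_df = pd.DataFrame(modality_rows)
        modality_df.to_csv(out_dir / "modality.tsv", sep="\t", index=False)
        results["modality"] = modality_df

        stage = "sweep"
        day8 = table[np.isclose(table["day"], 8.0)]
        sweep_results = {}
        if len(day8) >= 50:
            sizes = day8["n_cells"].to_numpy()
            labels = classify_proliferative(sizes)
            step = float(config.get("sweep_grid_step", 0.05))
            grid = np.round(np.arange(0.0, 1.0001, step), 10)
            n_sim = int(config.get("sweep_n_sim", 500))
            for name, mask in (
                ("highly_proliferative", labels == HIGH),
                ("less_proliferative", labels != HIGH),
            ):
                if mask.sum() < 10:
                    continue
                res = parameter_sweep(
                    CloneSizeSample(sizes[mask], day=8.0, label=name),
                    g_grid=grid, k_grid=grid, n_sim_clones=n_sim,
                    t_obs=8.0, seed=seed,
                )
                res.to_long_frame().to_csv(
                    out_dir / f"sweep_{name}.tsv", sep="\t", index=False
                )
                sweep_results[name] = {
                    "g_x": res.best.g_x, "k_y": res.best.k_y,
                }
        results["sweep"] = sweep_results

        stage = "ode_fit"
        ode_results = {}
        sizes_by_day = table.groupby("day")["n_cells"]
        day8_labels = (
            classify_proliferative(day8["n_cells"].to_numpy())
            if len(day8) >= 10
            else None
        )
        if day8_labels is not None and table["day"].nunique() >= 3:
            hp_ids = set(day8.loc[day8_labels == HIGH, "clone_id"])
            for name, model in (
                ("highly_proliferative", "exponential"),
                ("less_proliferative", "logistic_rate"),
            ):
                sel = table["clone_id"].isin(hp_ids)
                sub = table[sel if name == "highly_proliferative" else ~sel]
                curve = sub.groupby("day")["n_cells"].mean()
                if len(curve) < (2 if model == "exponential" else 3):
                    continue
                fit = fit_growth_model(
                    model, curve.index.to_numpy(), curve.to_numpy(),
                    random_state=seed,
                )
                ode_results[name] = {
                    "model": model,
                    "g_x": fit.params.g_x,
                    "k_y": fit.params.k_y,
                    "capacity": fit.params.capacity,
                    "cost": fit.cost,
                    "converged": fit.converged,
                    "doubling_time": fit.doubling_time,
                }
        results["ode_fit"] = ode_results
        (out_dir / "ode_fits.json").write_text(
            json.dumps(ode_results, indent=2, default=_json_default)
        )

        stage = "heritability"
        reads, truth = gen_barcode_experiment(syn_cfg)
        write_barcode_table(reads, out_dir / "barcode_reads.tsv")
        clones = reads.without_spikeins()
        ref_div = log2_divisions(
            day8.loc[day8["n_cells"] > 1, "n_cells"].to_numpy()
        )
        herit = null_distribution(
            ref_div,
            growth_dist_kind=syn_cfg.growth_dist,
            n_replicates=int(config.get("n_null_replicates", 1000)),
            seed=seed,
            n_barcodes=syn_cfg.n_barcodes,
            pre_doublings=syn_cfg.pre_doublings,
            observed=(clones.sample("A"), clones.sample("B")),
        )
        herit_report = {
            "observed_overlap": herit.overlap_fraction,
            "observed_pearson_r": herit.pearson_r,
            "observed_pearson_p": herit.pearson_p,
            "empirical_p": herit.empirical_p,
            "empirical_p_overlap": herit.empirical_p_overlap,
            "growth_dist_kind": herit.growth_dist_kind,
            **herit.summary,
        }
        (out_dir / "heritability.json").write_text(
            json.dumps(herit_report, indent=2, default=_json_default)
        )
        results["heritability"] = herit_report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    results["manifest"] = manifest
    return results
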