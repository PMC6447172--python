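"""End-to-end study orchestration: 2D and 3D branches from one config.

The 2D branch loads an activity table plus a descriptor matrix, splits (or
takes fixed test ids), fits the MLR model and reports the validation suite
and descriptor contributions.  The 3D branch loads aligned molecules (or
generates the synthetic benchmark), computes and preprocesses both fields,
optionally runs SRD/FFD selection, fits PLS and reports calibration, LOO and
repeated-LMO statistics, field contributions and contour maps.  Everything
is deterministic given the seeds in the config, and the report carries the
provenance needed to re-run it bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import compound_data, mif_engine, molio, pls3d, qsar2d, synthdata

__all__ = ["RunConfig", "run_study", "load_config", "format_stats_table"]


@dataclass
class RunConfig:
    branch: str = "both"  # "2d" | "3d" | "both"
    system: str = "S2"
    activities: str | None = None  # None -> packaged triazine table
    descriptors: str | None = None  # CSV path; None with synthetic_2d -> generated
    model_descriptors: list[str] | None = None
    published_model: str | None = None  # e.g. "model_5"
    test_ids: list[int] | None = None
    split_fraction: float = 0.8
    molecules: str | None = None  # mol2/sdf/xyz path; None -> synthetic benchmark
    grid_extents: tuple[float, float, float] = (26.0, 18.0, 22.0)
    grid_spacing: float = 2.0
    n_components: int | None = None  # None -> choose by LOO q2 over 1..5
    lmo_fraction: float = 0.75
    lmo_repetitions: int = 50
    run_srd_ffd: bool = False
    synthetic_noise_sd: float = 0.1
    seed: int = 0
    output_dir: str = "triazqsar_run"

    def validate(self) -> None:
        if self.branch not in ("2d", "3d", "both"):
            raise ValueError(f"branch must be 2d/3d/both, got {self.branch!r}")
        for path in (self.activities, self.descriptors, self.molecules):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid_extents" in raw:
        raw["grid_extents"] = tuple(raw["grid_extents"])
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_2d(config: RunConfig, table: compound_data.ActivityTable) -> dict[str, Any]:
    import pandas as pd

    synthetic = config.descriptors is None
    if not synthetic:
        X = qsar2d.read_descriptor_matrix(config.descriptors)
        y = table.pic50(config.system)
    else:
        # no descriptor table supplied: run the branch on a fully synthetic
        # study with a planted linear model (activities included)
        synth_cfg = synthdata.Synthetic2DConfig(
            n_compounds=len(table.records),
            noise_sd=config.synthetic_noise_sd,
            seed=config.seed,
        )
        X, y_synth, _ = synthdata.gen_descriptor_data(synth_cfg)
        X = qsar2d.DescriptorMatrix(table.ids, X.descriptor_names, X.values)
        y = pd.Series(y_synth, index=table.ids, name="pIC50_synthetic")

    if config.test_ids:
        test_ids = list(config.test_ids)
        train_ids = [i for i in table.ids if i not in test_ids]
        if not compound_data.check_split_constraints(y, train_ids, test_ids):
            raise compound_data.SplitError("fixed test ids violate the range constraints")
    else:
        rng = np.random.default_rng(config.seed)
        ids = np.asarray(table.ids)
        n_train = max(2, int(round(config.split_fraction * len(ids))))
        for _ in range(1000):
            perm = rng.permutation(len(ids))
            cand_train = [int(i) for i in ids[perm[:n_train]]]
            cand_test = [int(i) for i in ids[perm[n_train:]]]
            if compound_data.check_split_constraints(y, cand_train, cand_test):
                train_ids, test_ids = sorted(cand_train), sorted(cand_test)
                break
        else:
            raise compound_data.SplitError("no constraint-satisfying split found")

    names = (
        list(qsar2d.load_published_models()[config.published_model].coefficients)
        if config.published_model
        else config.model_descriptors or X.descriptor_names[:3]
    )
    Xtr, Xte = X.subset_rows(train_ids), X.subset_rows(test_ids)
    model, stats = qsar2d.validation_stats(
        names, Xtr, y.loc[train_ids], Xte, y.loc[test_ids]
    )
    contrib = qsar2d.descriptor_contribution(names, Xtr, y.loc[train_ids].to_numpy())
    predictions = qsar2d.evaluate_linear_model(model, X)
    return {
        "system": config.system,
        "synthetic": synthetic,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "descriptors": names,
        "model": {"intercept": model.intercept, "coefficients": model.coefficients},
        "stats": stats.as_dict(),
        "contributions_percent": contrib.alpha,
        "observed_vs_predicted": {
            int(i): {"observed": float(y.loc[i]), "predicted": float(predictions.loc[i])}
            for i in table.ids
        },
    }


def _run_3d(config: RunConfig, table: compound_data.ActivityTable, out: Path) -> dict[str, Any]:
    spec = mif_engine.GridSpec(extents=config.grid_extents, spacing=config.grid_spacing)
    if config.molecules is not None:
        molecules = molio.read_molecules(config.molecules)
        grid = mif_engine.make_grid(spec, molecules)
        blocks = mif_engine.compute_fields(molecules, grid)
        mif = mif_engine.preprocess_fields(blocks, grid=grid)
        y = table.pic50(config.system).loc[molecules.ids].to_numpy()
        truth = None
    else:
        molecules, grid, mif, y, truth = synthdata.triazine_like_benchmark(
            seed=config.seed,
            noise_sd=config.synthetic_noise_sd,
            spacing=config.grid_spacing,
        )

    n_comp = config.n_components or pls3d.choose_components(mif.X, y)
    report: dict[str, Any] = {
        "system": config.system,
        "grid": {
            "extents": list(config.grid_extents),
            "spacing": config.grid_spacing,
            "counts": list(grid.counts),
            "n_points": grid.n_points,
        },
        "preprocessing": {
            "kept_columns": int(mif.kept.sum()),
            "dropped": mif.drop_counts(),
        },
        "n_components": n_comp,
        "synthetic": truth is not None,
    }

    X_work: np.ndarray | mif_engine.MifMatrix = mif
    if config.run_srd_ffd:
        pre = pls3d.fit_pls(mif, y, n_comp)
        groups = pls3d.srd_group(mif, pre.coefficients)
        ffd = pls3d.ffd_select(mif, y, groups, n_comp, seed=config.seed)
        report["srd_ffd"] = {
            "n_groups": groups.n_groups,
            "kept_groups": len(ffd.kept_groups),
            "dropped_groups": len(ffd.dropped_groups),
            "kept_columns": int(len(ffd.kept_columns)),
        }
        X_work = mif.X[:, ffd.kept_columns]

    model = pls3d.fit_pls(X_work, y, n_comp)
    summary = pls3d.model_summary(model, X_work, y)
    loo = pls3d.loo_cv(X_work, y, n_comp)
    lmo = pls3d.lmo_cv(
        X_work, y, n_comp,
        fraction=config.lmo_fraction,
        repetitions=config.lmo_repetitions,
        seed=config.seed,
    )
    report["stats"] = {
        "r2": summary["r2"],
        "sdec": summary["sdec"],
        "f_test": summary["f_test"],
        "q2_loo": loo.q2,
        "sdep_loo": loo.sdep,
        "q2_lmo": lmo.q2,
        "sdep_lmo": lmo.sdep,
    }
    if not config.run_srd_ffd:
        contrib = pls3d.field_contributions(model, mif)
        report["field_contributions_percent"] = contrib.shares
        pls3d.export_contour(model, mif, out / "contours")
        report["contours"] = str(out / "contours")
    preds = model.predict(X_work)
    report["observed_vs_predicted"] = {
        int(i): {"observed": float(o), "predicted": float(p)}
        for i, o, p in zip(molecules.ids, y, preds)
    }
    return report


def run_study(config: RunConfig) -> dict[str, Any]:
    """Run the configured branches and write report.json + report.txt."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = (
        compound_data.read_compound_table(config.activities)
        if config.activities
        else compound_data.load_triazine_table()
    )
    report: dict[str, Any] = {
        "provenance": {
            "config": dataclasses.asdict(config),
            "config_hash": _config_hash(config),
            "seed": config.seed,
        }
    }
    if config.branch in ("2d", "both"):
        try:
            report["qsar_2d"] = _run_2d(config, table)
        except Exception as exc:
            raise RuntimeError(f"2D branch failed ({type(exc).__name__}): {exc}") from exc
    if config.branch in ("3d", "both"):
        try:
            report["qsar_3d"] = _run_3d(config, table, out)
        except Exception as exc:
            raise RuntimeError(f"3D branch failed ({type(exc).__name__}): {exc}") from exc
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "report.txt").write_text(format_stats_table(report))
    return report


def format_stats_table(report: dict[str, Any]) -> str:
    """Human-readable statistics tables mirroring the usual QSAR layout."""
    lines = []
    if "qsar_2d" in report:
        s = report["qsar_2d"]["stats"]
        lines += [
            f"2D QSAR ({report['qsar_2d']['system']}) — "
            f"{report['qsar_2d']['descriptors']}",
            f"{'R2':>10}{'R2_adj':>10}{'q2':>10}{'pred_R2':>10}"
            f"{'MaxErr':>10}{'RMSE':>10}{'LOF':>10}",
            f"{s['r2']:>10.3f}{s['r2_adj']:>10.3f}{s['q2_loo']:>10.3f}"
            f"{s['pred_r2']:>10.3f}{s['max_error']:>10.3f}{s['rmse']:>10.3f}"
            f"{s['lof']:>10.3f}",
            "",
        ]
    if "qsar_3d" in report:
        s = report["qsar_3d"]["stats"]
        lines += [
            f"3D QSAR ({report['qsar_3d']['system']}) — "
            f"{report['qsar_3d']['n_components']} components, "
            f"{report['qsar_3d']['preprocessing']['kept_columns']} grid variables",
            f"{'R2':>8}{'SDEC':>8}{'F':>8}{'q2_LOO':>9}{'SDEP':>8}"
            f"{'q2_LMO':>9}{'SDEP':>8}",
            f"{s['r2']:>8.3f}{s['sdec']:>8.3f}{s['f_test']:>8.1f}"
            f"{s['q2_loo']:>9.3f}{s['sdep_loo']:>8.3f}"
            f"{s['q2_lmo']:>9.3f}{s['sdep_lmo']:>8.3f}",
            "",
        ]
    return "\n".join(lines)
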