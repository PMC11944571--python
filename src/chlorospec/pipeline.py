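"""End-to-end study replica: data -> preprocessing -> Kennard-Stone split
-> MSD subset-size sweep -> PLSR + Cubist-lite calibration on the
nominated subset -> validation metrics, tables and figures.

Every random consumer derives its stream from the root seed via named
substreams, so inserting a stage never perturbs the draws of another.
All outputs land in one run directory together with the serialized
configuration and a log of every default actually used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cubist import (
    DEFAULT_COMMITTEES,
    DEFAULT_NEIGHBORS,
    TreeConfig,
    fit_cubist,
    grid_search_cubist,
)
from .evaluation import evaluate_with_groups
from .plsr import fit_plsr, important_bands, predict_plsr
from .preprocess import SGConfig, preprocess
from .representativeness import MSDConfig, fit_pca, msd_sweep
from .spectra_io import (
    SpectraSet,
    join_metadata,
    read_metadata,
    read_spectra,
    write_spectra,
)
from .subset_select import SubsetPlan, kennard_stone, ks_split
from .synthetic import GeneratorConfig, simulate_dataset, substream, tiny_config

log = logging.getLogger("chlorospec")


@dataclass
class RunConfig:
    """Pipeline settings; mirrors the CLI flags one-to-one."""

    seed: int = 1
    out_dir: str = "runs/replica"
    # data: either simulate ("study" | "tiny") or read from files
    simulate: str | None = "study"
    spectra_path: str | None = None
    meta_path: str | None = None
    # preprocessing
    sg_window: int = 15
    sg_order: int = 1
    trim: tuple[float, float] | None = None
    # split + sweep
    calibration_fraction: float = 0.8        # 280 of 350 in the study design
    subset_sizes: tuple[int, ...] | None = None   # None: auto from pool size
    msd_k: int = 6
    msd_grid: int = 512
    nomination_rel_tol: float = 0.10
    # models
    max_lv: int = 20
    committees: tuple[int, ...] = DEFAULT_COMMITTEES
    neighbors: tuple[int, ...] = DEFAULT_NEIGHBORS
    cv_folds: int = 10
    skip: tuple[str, ...] = ()               # any of: "plsr", "cubist", "plots"
    make_plots: bool = True

    def to_yaml(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("trim", "subset_sizes", "committees", "neighbors", "skip"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg


def _auto_sizes(n_cal: int) -> tuple[int, ...]:
    """Serial subset sizes: the study ladder when the pool allows it,
    otherwise a short ladder scaled to the pool."""
    if n_cal >= 260:
        return (60, 100, 140, 180, 220, 260)
    lo = max(2, n_cal // 4)
    sizes = sorted({int(s) for s in np.linspace(lo, n_cal, 4)})
    return tuple(s for s in sizes if 2 <= s <= n_cal)


def _load_data(cfg: RunConfig) -> tuple[SpectraSet, pd.DataFrame]:
    if cfg.simulate is not None:
        gen = (
            tiny_config(cfg.seed)
            if cfg.simulate == "tiny"
            else GeneratorConfig(seed=cfg.seed)
        )
        log.info("simulating %s design (seed %d)", cfg.simulate, cfg.seed)
        return simulate_dataset(gen)
    if cfg.spectra_path is None or cfg.meta_path is None:
        raise ValueError("either enable simulation or provide input paths")
    spectra = read_spectra(cfg.spectra_path)
    meta = read_metadata(cfg.meta_path)
    spectra, meta, dropped = join_metadata(spectra, meta, strict=False)
    if dropped:
        log.warning("dropped %d spectra without metadata", dropped)
    return spectra, meta


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every enabled stage; returns the run directory.

    Deterministic given the config (including the seed): rerunning
    produces byte-identical reports.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> Path:
    cfg.to_yaml(out / "config.yaml")
    log.info("chlorospec %s, root seed %d", __version__, cfg.seed)

    stage = "data"
    try:
        spectra, meta = _load_data(cfg)

        stage = "preprocess"
        sg = SGConfig(window=cfg.sg_window, polyorder=cfg.sg_order)
        absorb = preprocess(spectra, sg, trim=cfg.trim)
        write_spectra(absorb, out / "preprocessed.csv")
        log.info(
            "preprocessed %d spectra: absorbance + SG(window=%d, order=%d)",
            absorb.n_samples, sg.window, sg.polyorder,
        )

        stage = "select"
        n_cal = int(round(cfg.calibration_fraction * absorb.n_samples))
        ks_space = fit_pca(absorb.values, var_threshold=0.99).scores
        cal_idx, val_idx = ks_split(ks_space, n_cal)
        (out / "calibration.ids").write_text(
            "\n".join(absorb.sample_ids[i] for i in cal_idx) + "\n"
        )
        (out / "validation.ids").write_text(
            "\n".join(absorb.sample_ids[i] for i in val_idx) + "\n"
        )
        log.info("KS split: %d calibration / %d validation (PC space, 99%% var)",
                 len(cal_idx), len(val_idx))

        stage = "msd-sweep"
        sizes = cfg.subset_sizes or _auto_sizes(len(cal_idx))
        plan = SubsetPlan(sizes=sizes)
        msd_cfg = MSDConfig(k=cfg.msd_k, grid_points=cfg.msd_grid)
        cal_X, val_X = absorb.values[cal_idx], absorb.values[val_idx]
        results, nominated = msd_sweep(
            cal_X, val_X, plan, msd_cfg, cfg.nomination_rel_tol
        )
        k_used = results[0].k
        sweep = pd.DataFrame(
            {
                "size": [r.subset_size for r in results],
                **{
                    f"d2_pc{j + 1}": [r.d2[j] for r in results]
                    for j in range(k_used)
                },
                "msd": [r.msd for r in results],
            }
        )
        sweep["nominated"] = sweep["size"] == nominated
        sweep.to_csv(out / "msd_sweep.tsv", sep="\t", index=False)
        log.info(
            "MSD sweep over sizes %s: k=%d PCs, Silverman bandwidth on the "
            "validation scores, grid %d points; nominated size %d "
            "(within %.0f%% of the sweep minimum)",
            list(sizes), k_used, msd_cfg.grid_points, nominated,
            100 * cfg.nomination_rel_tol,
        )

        # nominated KS subset of the calibration pool, in the plan's space
        sub_space = fit_pca(cal_X, var_threshold=plan.pc_variance).scores
        sub_idx = cal_idx[kennard_stone(sub_space, nominated)]
        (out / f"subset_{nominated}.ids").write_text(
            "\n".join(absorb.sample_ids[i] for i in sub_idx) + "\n"
        )
        X_fit = absorb.values[sub_idx]
        y_fit = meta["chlorophyll"].to_numpy(float)[sub_idx]
        y_val = meta["chlorophyll"].to_numpy(float)[val_idx]
        meta_val = meta.iloc[val_idx]

        reports = {}
        predictions: dict[str, np.ndarray] = {}

        if "plsr" not in cfg.skip:
            stage = "plsr"
            max_lv = min(cfg.max_lv, len(sub_idx) - 1, absorb.n_wavelengths)
            model = fit_plsr(X_fit, y_fit, max_lv=max_lv,
                             wavelengths=absorb.wavelengths)
            log.info("PLSR: %d LVs chosen by LOO CV (max_lv %d)",
                     model.n_lv, max_lv)
            pred = predict_plsr(model, val_X)
            predictions["plsr"] = pred
            rep = evaluate_with_groups(y_val, pred, meta_val, "validation")
            reports["plsr"] = rep
            bands = important_bands(model.vip, absorb.wavelengths, 1.0,
                                    merge_gap_nm=10.0)
            artifact = model.to_dict()
            artifact["vip_bands_nm"] = bands
            (out / "plsr_model.json").write_text(json.dumps(artifact, indent=1))
            log.info("PLSR validation: R2=%.3f RMSEP=%.3f bias=%.3f; "
                     "VIP>1 bands: %s", rep.r2, rep.rmse, rep.bias, bands)

        if "cubist" not in cfg.skip:
            stage = "cubist"
            fold_seed = int(substream(cfg.seed, "cubist-folds").integers(2**31))
            if len(sub_idx) >= max(20, cfg.cv_folds):
                cub = grid_search_cubist(
                    X_fit, y_fit, cfg.committees, cfg.neighbors,
                    folds=cfg.cv_folds, seed=fold_seed,
                )
                log.info(
                    "Cubist grid search (%d-fold CV, fold seed %d, fold hash "
                    "%s): best committees=%d neighbors=%d",
                    cfg.cv_folds, fold_seed, cub.cv_fold_hash,
                    cub.committees, cub.neighbors,
                )
            else:  # pool too small for the study grid: single modest cell
                c = min(cfg.committees)
                k = min(min(cfg.neighbors), len(sub_idx))
                cub = fit_cubist(X_fit, y_fit, c, k,
                                 TreeConfig(min_leaf=max(2, len(sub_idx) // 4)))
                log.info("pool too small for grid search; fitted c=%d k=%d", c, k)
            pred = cub.predict(val_X)
            predictions["cubist"] = pred
            rep = evaluate_with_groups(y_val, pred, meta_val, "validation")
            reports["cubist"] = rep
            (out / "cubist_model.json").write_text(
                json.dumps(cub.to_dict(), indent=1)
            )
            log.info("Cubist validation: R2=%.3f RMSEP=%.3f bias=%.3f",
                     rep.r2, rep.rmse, rep.bias)

        stage = "evaluate"
        summary = {name: rep.to_dict() for name, rep in reports.items()}
        (out / "evaluation.json").write_text(json.dumps(summary, indent=1))
        rows = [
            {"model": name, **rep.to_dict()} for name, rep in reports.items()
        ]
        pd.DataFrame(rows).to_csv(out / "evaluation.tsv", sep="\t", index=False)
        for name, rep in reports.items():
            rep.per_month.to_csv(out / f"monthly_{name}.tsv", sep="\t", index=False)
            rep.per_species.to_csv(out / f"species_{name}.tsv", sep="\t", index=False)

        if cfg.make_plots and "plots" not in cfg.skip:
            stage = "plots"
            _make_plots(out, results, sweep, reports, predictions, y_val,
                        absorb, meta_val)
        return out
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, out)
        raise


def _make_plots(out, results, sweep, reports, predictions, y_val, absorb, meta_val):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # PC score densities (subset vs population) + MSD curve
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    last = results[-1]
    for pair in last.pairs[: min(3, last.k)]:
        axes[0].plot(pair.grid, pair.p_pop, label=f"PC{pair.pc_index + 1} pop")
        axes[0].plot(pair.grid, pair.p_subset, "--",
                     label=f"PC{pair.pc_index + 1} subset")
    axes[0].set_xlabel("PC score")
    axes[0].set_ylabel("density")
    axes[0].legend(fontsize=6)
    axes[1].plot(sweep["size"], sweep["msd"], "o-")
    axes[1].set_xlabel("subset size")
    axes[1].set_ylabel("MSD")
    fig.tight_layout()
    fig.savefig(out / "fig_densities_msd.png", dpi=120)
    plt.close(fig)

    if predictions:
        fig, axes = plt.subplots(1, len(predictions), figsize=(5 * len(predictions), 4),
                                 squeeze=False)
        for ax, (name, pred) in zip(axes[0], predictions.items()):
            ax.scatter(y_val, pred, s=12)
            lims = [min(y_val.min(), pred.min()), max(y_val.max(), pred.max())]
            ax.plot(lims, lims, "k--", lw=1)
            ax.set_title(name)
            ax.set_xlabel("measured chlorophyll (mg/g)")
            ax.set_ylabel("predicted (mg/g)")
        fig.tight_layout()
        fig.savefig(out / "fig_pred_vs_obs.png", dpi=120)
        plt.close(fig)

    plsr_json = out / "plsr_model.json"
    if plsr_json.exists():
        artifact = json.loads(plsr_json.read_text())
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(artifact["wavelengths"], artifact["vip"])
        ax.axhline(1.0, ls="--", color="k", lw=1)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("VIP")
        fig.tight_layout()
        fig.savefig(out / "fig_vip.png", dpi=120)
        plt.close(fig)

    if reports:
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, rep in reports.items():
            pm = rep.per_month
            ax.errorbar(pm["month"], pm["pred_mean"], yerr=pm["pred_se"],
                        marker="o", capsize=3, label=f"{name} predicted")
        pm = next(iter(reports.values())).per_month
        ax.plot(pm["month"], pm["obs_mean"], "k.", ms=10, label="measured mean")
        ax.set_xlabel("month")
        ax.set_ylabel("chlorophyll (mg/g)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "fig_monthly.png", dpi=120)
        plt.close(fig)
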