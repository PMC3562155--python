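"""End-to-end pipeline: fit -> predict -> FBA/FVA -> power law -> branch fluxes.

A single seeded run regenerates (or reads) the measurement table,
estimates the equilibrium constants and PEP/pyruvate ratios, predicts
the held-out glucose cells, runs FBA/FVA on the toy network, fits the
power-law node kinetics from the flux summary, and decomposes the
steady-state phosphoryl flux between the two PTS branches.  All outputs
are plain TSV/JSON in the configured output directory.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, branch, fba, fit as fit_mod, io as io_mod, mca, synth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str = "ptsflux_out"
    measurements_path: str | None = None   # None: generate synthetically
    network_path: str | None = None        # None: bundled toy network
    flux_table_path: str | None = None     # None: reference node fluxes
    stages: tuple[str, ...] = ("fit", "predict", "fba", "powerlaw", "fluxes")
    seed: int = 0
    noise_sd: float = 0.05
    noise_model: str = "band"
    n_starts: int = 8
    solver_tol: float = 1e-10
    growth_rate: float = 0.2
    uptake_measured: float | None = None
    target_ntr_share: float = 0.78

    KNOWN_STAGES = ("fit", "predict", "fba", "powerlaw", "fluxes")

    def validate(self) -> None:
        for s in self.stages:
            if s not in self.KNOWN_STAGES:
                raise io_mod.ValidationError(
                    f"unknown stage {s!r}; allowed: {self.KNOWN_STAGES}")
        if self.solver_tol <= 0 or self.noise_sd < 0:
            raise io_mod.ValidationError("tolerances must be positive")
        for name in ("measurements_path", "network_path", "flux_table_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise io_mod.ValidationError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise io_mod.ValidationError(
                f"{path}: unknown configuration keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the result bundle.

    Deterministic for a fixed seed; a stage failure raises a
    :class:`StageError` naming the stage, with earlier outputs retained
    on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"version": __version__, "seed": config.seed,
           "stages": list(config.stages)}
    bundle: dict = {"log": log}

    params = branch.calibrated_parameters(
        target_ntr_share=config.target_ntr_share)

    if config.measurements_path:
        data = io_mod.read_measurements(config.measurements_path)
    else:
        design = synth.SyntheticDesign(noise_sd=config.noise_sd,
                                       noise_model=config.noise_model,
                                       seed=config.seed, params=params)
        data = synth.generate_phospho_dataset(design)
        io_mod.write_measurements(data, out / "measurements.tsv")

    if "fit" in config.stages:
        try:
            res = fit_mod.fit_equilibrium_constants(
                data, n_starts=config.n_starts, seed=config.seed)
        except Exception as exc:
            raise StageError("fit", exc) from exc
        bundle["fit"] = res
        (out / "fit_parameters.json").write_text(res.to_json())
        res.residual_table().to_csv(out / "fit_residuals.tsv", sep="\t",
                                    index=False)
        log["fit_cost"] = res.cost

    if "predict" in config.stages:
        try:
            res = bundle.get("fit") or fit_mod.fit_equilibrium_constants(data)
            rows = []
            for strain in synth.DEFAULT_STRAINS:
                for cond in ("CAA", "CAA_fructose", "CAA_glucose"):
                    rows.append({"strain": strain, "condition": cond,
                                 "predicted_ptsN_fraction":
                                     res.predict(strain, cond)})
            pred = pd.DataFrame(rows)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("predict", exc) from exc
        bundle["predictions"] = pred
        pred.to_csv(out / "predictions.tsv", sep="\t", index=False)

    if "fba" in config.stages:
        try:
            net = (fba.read_network_tsv(config.network_path)
                   if config.network_path else synth.make_toy_network())
            fba.write_network_tsv(net, out / "network.tsv")
            uptake = config.uptake_measured
            ngam = 0.0
            if uptake is not None:
                ngam = fba.calibrate_ngam(net, config.growth_rate, uptake,
                                          "EX_fru")
                net = net.set_ngam(ngam)
            nominal = fba.minimize_substrate_uptake(net, config.growth_rate,
                                                    "EX_fru")
            if not nominal.ok:
                raise fba.LPError(f"uptake minimisation: {nominal.status}")
            fixed = net.with_bounds(net.biomass_id, config.growth_rate,
                                    config.growth_rate)
            var = fba.fva(fixed, "EX_fru", sense="min")
            report = var.relative_ranges()
        except StageError:
            raise
        except Exception as exc:
            raise StageError("fba", exc) from exc
        bundle["fba"] = {"ngam": ngam, "fluxes": nominal.fluxes,
                         "fva": report}
        report.to_csv(out / "fva_report.tsv", sep="\t", index=False)
        log["ngam"] = ngam

    if "powerlaw" in config.stages:
        try:
            table = (io_mod.read_flux_table(config.flux_table_path)
                     if config.flux_table_path else synth.reference_flux_table())
            k = mca.slope_k_from_conditions(table)
            pts = _calibration_points(table)
            pl = mca.fit_powerlaw_two_points(*pts)
            ra_grid = np.linspace(0.5, 12.0, 47)
            curve = mca.characteristic_curve(pl, k, (0.0, min(0.6, 2 * k)),
                                             ra_grid)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("powerlaw", exc) from exc
        bundle["powerlaw"] = {"fit": pl, "k": k, "curve": curve}
        curve.to_csv(out / "characteristic_curve.tsv", sep="\t", index=False)
        (out / "powerlaw_fit.json").write_text(json.dumps(
            {"kc": pl.kc, "nc": pl.nc, "kd": pl.kd, "nd": pl.nd,
             "alpha": pl.alpha, "n_prime": pl.n_prime, "k": k}, indent=2))

    if "fluxes" in config.stages:
        try:
            result = branch.steady_branch_fluxes(params)
        except Exception as exc:
            raise StageError("fluxes", exc) from exc
        bundle["branch_fluxes"] = result
        rows = [{"reaction": r, "net_rate": getattr(result, r)}
                for r in ("r1", "r2", "r3", "r4", "r5", "r_fru")]
        df = pd.DataFrame(rows)
        df["share_of_uptake"] = [result.ntr_share, result.ntr_share,
                                 result.ntr_share, result.c_share,
                                 -result.ntr_share, 1.0]
        df.to_csv(out / "branch_fluxes.tsv", sep="\t", index=False)
        log["ntr_share"] = result.ntr_share

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle


def _calibration_points(table: pd.DataFrame) -> list[tuple[float, float]]:
    """(rc, pp) calibration points from the flux table's two conditions."""
    pts = []
    for cond, pp in (("CAA", branch.DEFAULT_PP["CAA"]),
                     ("CAA_fructose", branch.DEFAULT_PP["CAA_fructose"])):
        sel = table[(table["condition"] == cond)
                    & (table["reaction"] == "pyr_to_pep")]
        if len(sel) != 1:
            raise io_mod.ValidationError(
                f"flux table needs a unique pyr_to_pep row for {cond!r}")
        pts.append((float(sel["nominal"].iloc[0]), pp))
    return pts
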