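"""Tables, configuration, and end-to-end pipeline orchestration.

All artifacts are plain CSV (UTF-8, header row, '.' decimal) and JSON — the
pipeline's data objects are small tables, and transparency beats
compactness. Every randomized stage takes an explicit seed derived from the
run configuration, and the run manifest records file hashes, seeds and
stage order so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import design as dz
from . import dose_response as dr
from . import ranking as rk
from . import response_surface as rs
from . import synergy as sy
from . import synthetic as syn

__all__ = [
    "TableError",
    "read_table",
    "write_table",
    "DrugConfig",
    "RunConfig",
    "run_pipeline",
]


class TableError(ValueError):
    pass


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV with the documented dialect (UTF-8, header, '.' decimal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required_columns=None, numeric_columns=None) -> pd.DataFrame:
    """Read a pipeline CSV, validating header and numeric parsing.

    Raises ``TableError`` naming the offending column (and flagging
    locale-style ',' decimals) rather than silently yielding object
    columns; an empty file is an explicit empty-input error.
    """
    path = Path(path)
    try:
        # round_trip parsing guarantees write -> read identity on floats
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TableError(f"{path}: empty input file") from None
    if df.empty and len(df.columns) == 0:
        raise TableError(f"{path}: empty input file")
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise TableError(f"{path}: missing required columns {missing}")
    for col in numeric_columns or []:
        if df[col].dtype == object:
            sample = df[col].astype(str)
            if sample.str.contains(",").any():
                line = int(sample.str.contains(",").idxmax()) + 2
                raise TableError(
                    f"{path}: column '{col}' line {line}: ',' decimals are not "
                    f"supported; use '.' as the decimal separator"
                )
            try:
                df[col] = df[col].astype(float)
            except ValueError as exc:
                raise TableError(f"{path}: column '{col}' is not numeric: {exc}") from None
    return df


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class DrugConfig(BaseModel):
    name: str
    cmax: float = Field(gt=0, description="maximum clinical serum concentration, uM")
    vehicle: str = "water"


class RunConfig(BaseModel):
    """Validated configuration for an end-to-end synthetic screen."""

    drugs: list[DrugConfig]
    sexes: list[str] = ["male", "female"]
    seed: int = Field(ge=0, lt=2**31)
    well_sd: float = Field(default=10.0, ge=0)
    replicates: int = Field(default=3, ge=1)
    p_enter: float = Field(default=rs.P_ENTER, gt=0, lt=1)
    p_remove: float = Field(default=rs.P_REMOVE, gt=0, lt=1)
    lambda_grid: list[float] = list(rs.DEFAULT_LAMBDA_GRID)
    top_n_per_stratum: int = Field(default=3, ge=1)
    n_controls: int = Field(default=2, ge=1)
    planted_bliss_excess: float = 20.0
    output_dir: str = "vicombo_output"

    @field_validator("drugs")
    @classmethod
    def _eight_drugs(cls, v):
        if len(v) != 8:
            raise ValueError("the screening design requires exactly 8 drugs")
        return v

    @field_validator("sexes")
    @classmethod
    def _known_sexes(cls, v):
        bad = set(v) - {"male", "female"}
        if bad:
            raise ValueError(f"unknown sexes: {sorted(bad)}")
        return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(base: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the config seed."""
    digest = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic screen: dose-response -> levels -> OACD ->
    surface fit -> ranking -> sex bias -> validation -> synergy.

    Returns the run manifest (also written to ``manifest.json``): stage
    order, per-stage seeds, and a content hash for every output file.
    Rerunning with an identical config reproduces identical bytes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    drugs = tuple(d.name for d in config.drugs)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "stage_seeds": {},
        "files": {},
    }
    files: list[Path] = []

    def stage(name: str) -> int:
        s = _stage_seed(config.seed, name)
        manifest["stages"].append(name)
        manifest["stage_seeds"][name] = s
        return s

    # ground truth per sex
    surfaces = dict(zip(("male", "female"), syn.make_sex_pair(stage("truth"), drugs)))

    oacd = dz.build_oacd(8, drugs)
    mono = dz.monotherapy_runs(8, drugs)
    fit_design = oacd.concat(mono)
    design_df = pd.DataFrame(fit_design.runs, columns=list(drugs))
    design_df.insert(0, "run_id", np.arange(len(design_df)))
    design_df["block_label"] = fit_design.block_labels
    files.append(write_table(design_df, out / "design.csv"))

    space = dz.full_factorial(8, 3, drugs)
    models: dict[str, rs.QuadraticModel] = {}
    rankings: dict[str, pd.DataFrame] = {}

    for sex in config.sexes:
        surface = surfaces[sex]
        seed_dr = stage(f"dose_response_{sex}")
        curves = syn.make_drug_curves(seed_dr, drugs, sex)

        # monotherapy dose-response: simulate, fit, select levels
        curve_rows, level_rows, dr_tables = [], [], []
        for i, drug in enumerate(drugs):
            eff_true, tox_true = curves[drug]
            doses = np.geomspace(eff_true.ec50 / 100, eff_true.ec50 * 100, 8)
            noise = syn.NoiseModel(config.well_sd, config.replicates, seed_dr + i)
            tab = syn.simulate_monotherapy(eff_true, doses, noise)
            dr_tables.append(tab)
            fit = dr.fit_4pl(
                tab["dose_uM"].to_numpy(), tab["response_pct"].to_numpy(),
                drug=drug, sex=sex,
            )
            ec = {f: dr.absolute_ec(fit, f) for f in (1, 2, 20) if f < fit.top}
            # cytotoxicity bounds from the noiseless ground-truth curve
            cc1 = dr.absolute_ec(tox_true, 1)
            cc2 = dr.absolute_ec(tox_true, 2)
            info = dr.DrugInfo(drug, cmax=config.drugs[i].cmax, vehicle=config.drugs[i].vehicle)
            levels = dr.select_levels(ec[1], cc1, ec[2], cc2, info, sex=sex)
            curve_rows.append(
                (drug, sex, "asma_reduction", fit.top, fit.ec50, fit.hill,
                 ec[1], ec[2], ec.get(20, np.nan), cc1, cc2)
            )
            level_rows.append((drug, sex, levels.l1, levels.l2, levels.l1_bound, levels.l2_bound))
        files.append(write_table(pd.concat(dr_tables), out / f"dose_response_{sex}.csv"))
        files.append(
            write_table(
                pd.DataFrame(
                    curve_rows,
                    columns=["drug", "sex", "readout", "top", "ec50", "hill",
                             "ec1", "ec2", "ec20", "cc1", "cc2"],
                ),
                out / f"curves_{sex}.csv",
            )
        )
        levels_df = pd.DataFrame(
            level_rows, columns=["drug", "sex", "l1_uM", "l2_uM", "l1_bound", "l2_bound"]
        )
        files.append(write_table(levels_df, out / f"levels_{sex}.csv"))

        # screen: simulate design responses, fit the quadratic surface
        seed_screen = stage(f"screen_{sex}")
        noise = syn.NoiseModel(config.well_sd, config.replicates, seed_screen)
        resp = syn.simulate_design_responses(surface, fit_design, noise)
        files.append(write_table(resp, out / f"responses_{sex}.csv"))
        model = rs.fit_response_surface(
            resp[list(drugs)].to_numpy(), resp["response_pct"].to_numpy(), drugs,
            p_enter=config.p_enter, p_remove=config.p_remove,
            candidate_lambdas=tuple(config.lambda_grid),
        )
        models[sex] = model
        coef_df = pd.DataFrame(
            {
                "term": [t.label(drugs) for t in model.terms],
                "kind": [t.kind for t in model.terms],
                "coefficient": model.coefficients,
                "p_value": model.p_values,
            }
        )
        files.append(write_table(coef_df, out / f"coefficients_{sex}.csv"))

        X, _ = rs.expand_terms(resp[list(drugs)].to_numpy())
        scan = rs.outlier_scan(
            X, rs.power_transform(
                resp["response_pct"].to_numpy() + model.shift, model.transform_lambda
            ),
        )
        diag = {
            "sex": sex,
            "lambda": model.transform_lambda,
            "shift": model.shift,
            "adj_r2": model.adj_r2,
            "n": model.n_obs,
            "p": len(model.terms),
            "outliers": list(scan.flagged),
        }
        diag_path = out / f"diagnostics_{sex}.json"
        diag_path.write_text(json.dumps(diag, indent=1, sort_keys=True))
        files.append(diag_path)

        # rank the full space
        stage(f"rank_{sex}")
        ranked = rk.predict_all(model, space)
        rankings[sex] = ranked
        files.append(write_table(ranked, out / f"ranked_{sex}.csv"))

        # candidate selection + validation against fresh simulated measurements
        seed_val = stage(f"validate_{sex}")
        cands = pd.concat(
            [rk.top_k_by_drug_count(ranked, k, config.top_n_per_stratum) for k in (2, 3, 4)]
            + [rk.bottom_controls(ranked, config.n_controls)]
        ).reset_index(drop=True)
        val_design = dz.DesignMatrix(
            drugs, cands[list(drugs)].to_numpy(), ("custom",) * len(cands)
        )
        val_noise = syn.NoiseModel(config.well_sd, config.replicates, seed_val)
        val_resp = syn.simulate_design_responses(surface, val_design, val_noise)
        measured = val_resp.groupby("run_id")["response_pct"].mean().to_numpy()
        report = rk.validate_predictions(cands["predicted_pct"].to_numpy(), measured)
        cands["measured_pct"] = measured
        files.append(write_table(cands, out / f"validation_{sex}.csv"))
        vr_path = out / f"validation_report_{sex}.json"
        vr_path.write_text(
            json.dumps(
                {"r": report.r, "p_value": report.p_value, "slope": report.slope,
                 "intercept": report.intercept, "n": report.n},
                indent=1, sort_keys=True,
            )
        )
        files.append(vr_path)

        # checkerboard synergy on the sex's planted pair
        seed_cb = stage(f"synergy_{sex}")
        pair = syn._MALE_PAIR if sex == "male" else syn._FEMALE_PAIR
        da, db = drugs[pair[0]], drugs[pair[1]]
        l2a = float(levels_df.loc[levels_df["drug"] == da, "l2_uM"].iloc[0])
        l2b = float(levels_df.loc[levels_df["drug"] == db, "l2_uM"].iloc[0])
        lad_a = dz.checkerboard_ladder(l2a, da)
        lad_b = dz.checkerboard_ladder(l2b, db)
        cb_noise = syn.NoiseModel(config.well_sd, config.replicates, seed_cb)
        cb = syn.simulate_checkerboard(
            curves[da][0], curves[db][0], config.planted_bliss_excess,
            lad_a, lad_b, cb_noise,
        )
        files.append(write_table(cb, out / f"checkerboard_{sex}.csv"))
        smap = sy.score_checkerboard(cb, da, db)
        files.append(write_table(smap.cells, out / f"synergy_{sex}.csv"))

    # sex-bias differencing over the aligned space
    if set(config.sexes) == {"male", "female"}:
        stage("sex_bias")
        bias = rk.sex_bias_table(rankings["male"], rankings["female"], drugs)
        files.append(write_table(bias, out / "sex_bias.csv"))

    for f in files:
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
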