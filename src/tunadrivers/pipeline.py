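"""End-to-end orchestration: raw input tables to fitted model and reports.

Stages run in a fixed order — harmonize effort, spatial diversity,
price deflation, feature assembly, ridge fit with cross-validation,
elasticities, HDI-versus-status — each writing its CSV artifact.  A
single master seed fans out deterministically to per-stage seeds, so a
config plus seed fully determines every output file (hash-stable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, effort, elasticity, features, hdi, prices, ridge
from .errors import ConfigurationError

INPUT_CLASSES = ("effort", "prices", "fuel", "climate", "hdi", "status")
STAGES = ("harmonize", "diversity", "deflate", "build", "fit", "elasticity", "hdi")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the master."""
    idx = STAGES.index(stage) if stage in STAGES else 100 + hash(stage) % 100
    ss = np.random.SeedSequence((int(master_seed), idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def stage_deflate(
    price_table: pd.DataFrame,
    fuel_table: pd.DataFrame,
    base_year: int = prices.DEFAULT_BASE_YEAR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deflate species prices and fuel to real base-year USD.

    ``price_table`` is long-format (species, form, year, nominal_price,
    currency, fx_to_usd, deflator); ``fuel_table`` has (year,
    nominal_usd_per_barrel, deflator).  Returns (real species prices
    with labels ``{species}_{form}``, real fuel series).
    """
    frames = []
    for (species, form), grp in price_table.groupby(["species", "form"]):
        grp = grp.sort_values("year")
        series = prices.NominalPriceSeries(
            label=f"{species}_{form}",
            years=grp["year"].astype(int).tolist(),
            nominal_values=grp["nominal_price"].astype(float).tolist(),
            currency=str(grp["currency"].iloc[0]),
            fx_to_usd=dict(zip(grp["year"].astype(int), grp["fx_to_usd"].astype(float))),
            deflator_index=dict(zip(grp["year"].astype(int), grp["deflator"].astype(float))),
        )
        frames.append(prices.to_real(series, base_year).to_frame())
    real_fish = pd.concat(frames, ignore_index=True)

    fuel_sorted = fuel_table.sort_values("year")
    fuel_series = prices.NominalPriceSeries(
        label="fuel",
        years=fuel_sorted["year"].astype(int).tolist(),
        nominal_values=fuel_sorted["nominal_usd_per_barrel"].astype(float).tolist(),
        currency="USD",
        deflator_index=dict(
            zip(fuel_sorted["year"].astype(int), fuel_sorted["deflator"].astype(float))
        ),
    )
    real_fuel = prices.to_real(fuel_series, base_year).to_frame()
    return real_fish, real_fuel


def stage_build(
    status: pd.DataFrame,
    sw_indices: pd.DataFrame,
    real_fish: pd.DataFrame,
    real_fuel: pd.DataFrame,
    climate: pd.DataFrame,
    hdi_table: pd.DataFrame,
    stock_registry=None,
) -> pd.DataFrame:
    """Assemble the analysis matrix; ``hdi_table`` carries a region column."""
    region_map = hdi_table[["country", "region"]].drop_duplicates()
    return features.build_feature_table(
        status=status,
        sw_indices=sw_indices,
        real_prices=real_fish,
        fuel=real_fuel,
        climate=climate,
        hdi=hdi_table[["country", "year", "hdi"]],
        region_map=region_map,
        stock_registry=stock_registry,
    )


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run.

    Exactly one of ``synthetic`` (a SyntheticConfig) or ``inputs`` (a
    mapping of the six input classes to CSV paths) must be given.
    """

    out_dir: str
    synthetic: object | None = None
    inputs: dict[str, str] | None = None
    conversion_rules: str | None = None
    base_year: int = prices.DEFAULT_BASE_YEAR
    folds: int = 10
    train_fraction: float = 2.0 / 3.0
    n_lambda: int = 100
    lambda_ratio: float = 1e-4
    lambda_scale: str = "sum"
    perturbation: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError("exactly one of 'synthetic' or 'inputs' must be set")
        if self.inputs is not None:
            missing = [c for c in INPUT_CLASSES if c not in self.inputs]
            if missing:
                raise ConfigurationError(f"inputs missing classes: {missing}")
            absent = [p for p in self.inputs.values() if not Path(p).exists()]
            if absent:
                raise ConfigurationError(f"input files not found: {absent}")
        if self.conversion_rules is not None and not Path(self.conversion_rules).exists():
            raise ConfigurationError(f"conversion-rule file not found: {self.conversion_rules}")
        if self.lambda_scale not in ("sum", "mean"):
            raise ConfigurationError(f"lambda_scale must be 'sum' or 'mean', got {self.lambda_scale!r}")

    @classmethod
    def from_file(cls, path: str, out_dir: str | None = None) -> "PipelineConfig":
        """Load from YAML or JSON; a ``synthetic`` mapping becomes a SyntheticConfig."""
        from .synthetic import SyntheticConfig

        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("synthetic") is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if out_dir is not None:
            raw["out_dir"] = out_dir
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the artifact manifest.

    The manifest maps each stage to its output files with row counts
    and SHA-256 hashes; a run log records seeds and dropped-row
    accounting.  Configuration is validated before any stage runs.
    """
    from .synthetic import generate_bundle, write_bundle

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = effort.load_rules(config.conversion_rules)
    log: dict = {"seed": config.seed, "stages": {}}
    manifest: dict = {}

    def record(stage: str, name: str, df: pd.DataFrame, **extra) -> None:
        path = out / name
        _write_csv(df, path)
        manifest.setdefault(stage, []).append(
            {"file": name, "rows": int(len(df)), "sha256": _sha256(path)}
        )
        if extra:
            log["stages"].setdefault(stage, {}).update(extra)

    # --- inputs -----------------------------------------------------------
    base_year = config.base_year
    if config.synthetic is not None:
        bundle = generate_bundle(config.synthetic)
        write_bundle(bundle, out / "inputs")
        base_year = config.synthetic.base_year
        tables = {
            "effort": bundle.effort_records,
            "prices": bundle.price_series,
            "fuel": bundle.fuel_series,
            "climate": bundle.climate_series,
            "hdi": bundle.hdi_table,
            "status": bundle.status_series,
        }
    else:
        tables = {c: pd.read_csv(config.inputs[c]) for c in INPUT_CLASSES}

    # --- stages -----------------------------------------------------------
    harmonized = effort.harmonize_table(tables["effort"], rules)
    record("harmonize", "effort_harmonized.csv", harmonized, n_skipped=harmonized.attrs.get("n_skipped", 0))

    sw = diversity.compute_indices(harmonized)
    record("diversity", "spatial_diversity.csv", sw, n_undefined=sw.attrs.get("n_undefined", 0))

    real_fish, real_fuel = stage_deflate(tables["prices"], tables["fuel"], base_year)
    record("deflate", "real_prices.csv", pd.concat([real_fish, real_fuel], ignore_index=True))

    table = stage_build(tables["status"], sw, real_fish, real_fuel, tables["climate"], tables["hdi"])
    record("build", "feature_table.csv", table, n_dropped=table.attrs.get("n_dropped", 0))
    schema = [{"column": c, "role": ("key" if c in features.KEY_COLUMNS else "response" if c == features.RESPONSE_COLUMN else "dummy" if table[c].isin((0, 1)).all() and c not in features.CONTINUOUS_COLUMNS else "continuous")} for c in table.columns]
    (out / "feature_schema.json").write_text(json.dumps(schema, indent=1))

    report = ridge.fit_and_test(
        table,
        train_fraction=config.train_fraction,
        k=config.folds,
        seed=stage_seed(config.seed, "fit"),
        lambda_scale=config.lambda_scale,
    )
    coef_rows = [{"variable": "(Intercept)", "coefficient": report.full_fit.intercept}] + [
        {"variable": k, "coefficient": v} for k, v in report.full_fit.coefficients.items()
    ]
    record("fit", "coefficients.csv", pd.DataFrame(coef_rows))
    record("fit", "cv_curve.csv", report.cv.to_frame())
    x_cols = [c for c in features.feature_columns() if c in table.columns]
    path_res = ridge.lambda_path(
        table[x_cols], table[features.RESPONSE_COLUMN], report.cv.lambda_grid,
        lambda_scale=config.lambda_scale,
    )
    record("fit", "lambda_path.csv", path_res.to_frame())
    log["stages"]["fit"] = {
        "lambda_min": report.cv.lambda_min,
        "lambda_1se": report.cv.lambda_1se,
        "test_mse": report.test_mse,
        "test_r2": report.test_r2,
        "deviance_explained": report.deviance_explained,
        "n_train": report.n_train,
        "n_test": report.n_test,
    }

    elas = elasticity.elasticity_matrix(report.full_fit, table, factor=config.perturbation)
    record("elasticity", "elasticities.csv", elas)

    region_map = tables["hdi"][["country", "region"]].drop_duplicates()
    points = hdi.period_aggregate(
        tables["hdi"][["country", "year", "hdi"]], tables["status"], region_map
    )
    record("hdi", "hdi_points.csv", points)
    record("hdi", "hdi_trend.csv", hdi.linear_trend(points))
    record("hdi", "hdi_reference_counts.csv", hdi.reference_line_report(points))

    log["config"] = {
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
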