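"""End-to-end orchestration: records -> imputation -> fit -> predict -> attribute.

The pipeline mirrors the analysis protocol: screen admission records by
keyword, reconstruct admission dates from discharge minus length of
stay, multiply impute missing lengths of stay (predictive mean
matching, m datasets), aggregate each completed dataset to a daily
series, fit the ZINB distributed-lag model per dataset, pool the
coefficient vectors and covariances by Rubin's rules, and compute
centered relative-rate predictions and backward attributable fractions
(with climate-shift scenarios and Monte-Carlo intervals) from the
pooled fit.  Every stage's randomness is governed by an explicit seed
in the config, and a run manifest records the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import af_with_ci
from .imputation import pmm_impute, pool_rubin_vector
from .model import (
    ExposureTerm,
    FittedZINB,
    ModelSpec,
    build_design,
    coefficient_table,
    fit_from_bundle,
    pearson_residuals,
    residual_acf,
)
from .prediction import crosspred_table, predict_rr
from .records import (
    aggregate_daily,
    filter_pneumonia,
    read_records,
    reconstruct_admission_dates,
    write_daily_series,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

#: Default exposure-shift scenarios (positive and negative displacement
#: of each exposure distribution) and AF subrange bounds, matching the
#: reporting conventions of the study: +/-2 degC for temperature and
#: DTR, +/-5 % for relative humidity; "low" = temp < 14 degC or
#: RH < 40 %, "high" = temp > 26 degC, RH > 80 % or DTR > 20 degC.
DEFAULT_SHIFTS = {"mean_temp": 2.0, "rh": 5.0, "dtr": 2.0}
DEFAULT_SUBRANGES: dict[str, dict[str, tuple[float, float]]] = {
    "mean_temp": {"low": (-np.inf, 14.0), "high": (26.0, np.inf)},
    "rh": {"low": (-np.inf, 40.0), "high": (80.0, np.inf)},
    "dtr": {"high": (20.0, np.inf)},  # no "low": the reference is the minimum
}


@dataclass
class PipelineConfig:
    """Single configuration block for a full pipeline run."""

    records_path: str | None = None
    meteorology_path: str | None = None
    output_dir: str = "pneumolag_out"
    start_date: str = "2007-10-10"
    end_date: str = "2015-12-31"
    # imputation
    m: int = 20
    k_donors: int = 5
    imputation_seed: int = 1
    skip_pooling_if_single: bool = True
    # model
    max_lag: int = 21
    n_exposure_knots: int = 3
    n_lag_knots: int = 2
    n_fourier_pairs: int = 1
    fourier_in_zero: bool = True
    trend_df: int = 5
    zero_prev_days: int = 3
    centers: dict = field(
        default_factory=lambda: {"mean_temp": 21.0, "rh": 67.0, "dtr": 1.3}
    )
    # prediction / attribution
    n_grid: int = 50
    shifts: dict = field(default_factory=lambda: dict(DEFAULT_SHIFTS))
    subranges: dict = field(default_factory=dict)  # empty -> defaults
    n_mc: int = 1000
    attribution_seed: int = 2
    # simulate subcommand
    simulate_days: int = 3000
    simulate_seed: int = 10

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            exposures=[
                ExposureTerm(
                    "mean_temp", self.centers["mean_temp"], self.max_lag,
                    self.n_exposure_knots, self.n_lag_knots,
                ),
                ExposureTerm(
                    "rh", self.centers["rh"], self.max_lag,
                    self.n_exposure_knots, self.n_lag_knots,
                ),
                ExposureTerm("dtr", self.centers["dtr"], 0, self.n_exposure_knots),
            ],
            n_fourier_pairs=self.n_fourier_pairs,
            fourier_in_zero=self.fourier_in_zero,
            trend_df=self.trend_df,
            zero_prev_days=self.zero_prev_days,
        )

    def resolved_subranges(self, name: str) -> dict[str, tuple[float, float]]:
        raw = self.subranges.get(name) if self.subranges else None
        if raw is None:
            return {
                k: tuple(v) for k, v in DEFAULT_SUBRANGES.get(name, {}).items()
            }
        return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pooled_fit(fits: list[FittedZINB], m: int) -> FittedZINB:
    """Rubin-pool per-imputation fits at the coefficient level."""
    if m == 1:
        return fits[0]
    coef = np.array(
        [
            np.concatenate([f.count_params, f.zero_params, [np.log(f.alpha)]])
            for f in fits
        ]
    )
    point, cov = pool_rubin_vector(coef, [f.covariance for f in fits])
    tmpl = fits[0]
    p, q = tmpl.n_count, len(tmpl.zero_params)
    return FittedZINB(
        count_params=point[:p],
        count_names=tmpl.count_names,
        zero_params=point[p : p + q],
        zero_names=tmpl.zero_names,
        alpha=float(np.exp(point[-1])),
        covariance=cov,
        loglik=float(np.mean([f.loglik for f in fits])),
        converged=all(f.converged for f in fits),
        n_used=tmpl.n_used,
        grad_norm=max(f.grad_norm for f in fits),
        term_slices=tmpl.term_slices,
    )


def run_pipeline(
    config: PipelineConfig,
    records=None,
    meteorology: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns the artifact bundle and writes tables.

    ``records``/``meteorology`` may be passed directly (e.g. from the
    synthetic generator); otherwise they are read from the configured
    paths.  Output tables: coefficients, lag-specific and cumulative RR
    curves, the attributable-fraction table (per exposure x scenario,
    as percentages), residual diagnostics and a run manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if records is None:
        if config.records_path is None:
            raise ValueError("stage records: no records provided or configured")
        records = read_records(config.records_path)
    if meteorology is None:
        if config.meteorology_path is None:
            raise ValueError("stage records: no meteorology provided or configured")
        meteorology = pd.read_csv(
            config.meteorology_path, parse_dates=["date"]
        ).set_index("date")

    start = pd.Timestamp(config.start_date).date()
    end = pd.Timestamp(config.end_date).date()

    kept = filter_pneumonia(records)
    logger.info("stage records: %d of %d records screened in", len(kept), len(records))
    recon = reconstruct_admission_dates(kept)

    if recon.needs_imputation:
        if config.m < 2:
            raise ValueError(
                "stage imputation: records need imputation but m < 2 "
                "(Rubin pooling undefined)"
            )
        pool = recon.resolved + recon.needs_imputation
        imp = pmm_impute(
            pool, m=config.m, k_donors=config.k_donors, seed=config.imputation_seed
        )
        completed_sets = [
            reconstruct_admission_dates(ds).resolved for ds in imp.completed_datasets
        ]
        m_eff = config.m
    else:
        m_eff = 1 if config.skip_pooling_if_single else config.m
        completed_sets = [recon.resolved] * m_eff

    spec = config.model_spec()
    fits: list[FittedZINB] = []
    bundle = None
    daily0 = None
    for i, recs in enumerate(completed_sets):
        daily = aggregate_daily(recs, start, end, meteorology)
        b = build_design(daily, spec)
        if i == 0:
            bundle, daily0 = b, daily
            write_daily_series(daily, out / "daily_series.csv")
        fits.append(fit_from_bundle(b))
        logger.info("stage model: fitted imputation %d/%d", i + 1, m_eff)
        if m_eff > 1 and i == 0 and not recon.needs_imputation:
            # identical datasets -> identical fits; avoid refitting
            fits = fits * m_eff
            break

    fit = _pooled_fit(fits, m_eff)
    coefficient_table(fit).to_csv(out / "coefficients.csv", index=False)

    rr_tables = []
    af_rows = []
    counts = bundle.y
    for term in spec.exposures:
        cb = bundle.crossbases[term.name]
        center = term.center
        cp = predict_rr(fit, cb, center=center)
        rr_tables.append(crosspred_table(cp))
        exposure_full = daily0[term.name].to_numpy(dtype=float)[
            bundle.first_valid - cb.max_lag :
        ]
        subr = config.resolved_subranges(term.name)
        shift = config.shifts.get(term.name, 0.0)
        for scen_shift, scen_label in [
            (0.0, "none"),
            (shift, f"+{shift:g}"),
            (-shift, f"-{shift:g}"),
        ]:
            if scen_label != "none" and shift == 0:
                continue
            res = af_with_ci(
                fit, cb, exposure_full, counts, center,
                subranges=subr, shifts=(scen_shift,),
                n_mc=config.n_mc, seed=config.attribution_seed,
            )[0]
            row = {
                "exposure": term.name,
                "scenario": scen_label,
                "total_af_pct": 100 * res.total_af,
                "total_lo_pct": 100 * res.ci_low,
                "total_hi_pct": 100 * res.ci_high,
            }
            for label in ("low", "high"):
                if label in res.subrange_af:
                    lo, hi = res.subrange_ci[label]
                    row[f"{label}_af_pct"] = 100 * res.subrange_af[label]
                    row[f"{label}_lo_pct"] = 100 * lo
                    row[f"{label}_hi_pct"] = 100 * hi
                else:
                    row[f"{label}_af_pct"] = np.nan
                    row[f"{label}_lo_pct"] = np.nan
                    row[f"{label}_hi_pct"] = np.nan
            af_rows.append(row)

    rr_table = pd.concat(rr_tables, ignore_index=True)
    rr_table.to_csv(out / "rr_table.csv", index=False, float_format="%.10g")
    af_table = pd.DataFrame(af_rows)
    af_table.to_csv(out / "af_table.csv", index=False, float_format="%.10g")

    resid = pearson_residuals(fit, bundle)
    acf = residual_acf(resid)
    pd.DataFrame(
        {"date": bundle.index, "pearson_residual": resid}
    ).to_csv(out / "residuals.csv", index=False, float_format="%.10g")
    pd.DataFrame({"lag": np.arange(len(acf)), "acf": acf}).to_csv(
        out / "residual_acf.csv", index=False, float_format="%.10g"
    )

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "n_records_in": len(records),
        "n_screened_in": len(kept),
        "n_excluded_no_dates": len(recon.excluded),
        "n_needing_imputation": len(recon.needs_imputation),
        "m_effective": m_eff,
        "n_days_used": int(fit.n_used),
        "converged": bool(fit.converged),
        "loglik": fit.loglik,
        "alpha": fit.alpha,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "fit": fit,
        "bundle": bundle,
        "daily": daily0,
        "rr_table": rr_table,
        "af_table": af_table,
        "manifest": manifest,
    }
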