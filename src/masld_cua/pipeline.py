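"""End-to-end analysis pipeline with a reproducible report.

Orchestrates: cohort generation (or CSV ingestion) -> utility mapping ->
QALY estimation -> base-case economics -> one-way and probabilistic
sensitivity analysis -> clinical paired statistics -> pharmacy
expenditure analysis.  The run writes a machine-readable ``results.json``
plus human-readable CSV tables; identical configuration and seeds yield
byte-identical JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from masld_cua import economics as econ
from masld_cua import clinical, pharma, sensitivity
from masld_cua.cohort import CohortSpec, SyntheticCohort, generate_cohort
from masld_cua.mapping import (
    MappingCoefficients,
    build_utility_series,
    frame_to_visits,
    read_sf36_csv,
    series_to_frame,
)
from masld_cua.qaly import estimate_gain_lmm, estimate_gain_locf

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``synthetic_spec`` or ``input_dir`` supplies the data
    tables.  ``input_dir`` must contain the CSVs written by
    :func:`masld_cua.cohort.write_cohort_csvs` (or equivalently shaped
    real extracts).
    """

    output_dir: str | Path
    synthetic_spec: CohortSpec | None = None
    input_dir: str | Path | None = None
    coefficients_file: str | Path | None = None
    cost_model: econ.CostModel = field(default_factory=econ.CostModel)
    thresholds: econ.ThresholdSet = field(default_factory=econ.ThresholdSet)
    psa: sensitivity.PSAConfig = field(default_factory=sensitivity.PSAConfig)
    qaly_method: str = "lmm"
    horizon_months: float | None = None
    owsa_qaly_range: tuple[float, float] = (0.01, 0.161)
    owsa_cost_fraction: float = 0.20

    def __post_init__(self) -> None:
        if (self.synthetic_spec is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of synthetic_spec or input_dir must be set"
            )
        if self.qaly_method not in ("lmm", "locf"):
            raise ValueError(f"qaly_method must be 'lmm' or 'locf', got {self.qaly_method!r}")


def _load_tables(config: RunConfig):
    if config.synthetic_spec is not None:
        cohort = generate_cohort(config.synthetic_spec)
        return cohort
    indir = Path(config.input_dir)
    frames = {}
    for name in (
        "sf36_visits",
        "clinical_prepost",
        "steatosis_prepost",
        "activity_flags",
        "expenditures",
    ):
        path = indir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        frames[name] = pd.read_csv(path)
    return SyntheticCohort(
        sf36_visits=frames["sf36_visits"],
        clinical_prepost=frames["clinical_prepost"],
        steatosis_prepost=frames["steatosis_prepost"],
        activity_flags=frames["activity_flags"],
        expenditures=frames["expenditures"],
        spec=CohortSpec(),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle to ``output_dir``.

    Returns the report dictionary (what ``results.json`` holds).  Any
    stage failure raises :class:`PipelineError` naming the stage, and no
    partial outputs are left behind (files are written only after every
    stage has succeeded).
    """
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "stages": {}}
    tables: dict[str, pd.DataFrame] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrap

    cohort = stage("ingest")(lambda: _load_tables(config))
    report["stages"]["ingest"] = {
        "source": "synthetic" if config.synthetic_spec is not None else str(config.input_dir),
        "n_patients": int(cohort.sf36_visits["patient_id"].nunique()),
        "n_visits": int(len(cohort.sf36_visits)),
    }
    if config.synthetic_spec is not None:
        report["stages"]["ingest"]["seed"] = config.synthetic_spec.seed

    def _map():
        coeffs = (
            MappingCoefficients.from_file(config.coefficients_file)
            if config.coefficients_file
            else MappingCoefficients.default()
        )
        visits = frame_to_visits(cohort.sf36_visits)
        return coeffs, build_utility_series(visits, coeffs)

    coeffs, series = stage("map_utilities")(_map)
    tables["utilities"] = series_to_frame(series)
    report["stages"]["map_utilities"] = {
        "algorithm": coeffs.name,
        "n_series": len(series),
    }

    def _qaly():
        locf = estimate_gain_locf(series)
        lmm = estimate_gain_lmm(series, horizon_months=config.horizon_months)
        return locf, lmm

    locf, lmm = stage("estimate_qaly")(_qaly)
    primary = lmm if config.qaly_method == "lmm" else locf
    report["stages"]["estimate_qaly"] = {
        "locf": locf.__dict__,
        "lmm": lmm.__dict__,
        "primary": config.qaly_method,
    }

    def _econ():
        cost = econ.total_program_cost(config.cost_model)
        inputs = econ.EconomicInputs(c1=cost, e1=primary.gain)
        icer = econ.compute_icer(inputs)
        nmb = econ.nmb_table(inputs, config.thresholds)
        return cost, inputs, icer, nmb

    cost, inputs, icer, nmb = stage("economics")(_econ)
    report["stages"]["economics"] = {
        "annual_cost": cost,
        "qaly_gain": primary.gain,
        "icer": icer.value,
        "icer_label": icer.label,
        "nmb": {str(int(w)): v for w, v in nmb.items()},
        "cost_components": [list(c) for c in config.cost_model.components],
    }

    def _owsa():
        lo, hi = config.owsa_qaly_range
        ranges = [
            sensitivity.OwsaRange("qaly_gain", lo, hi),
            sensitivity.OwsaRange(
                "cost",
                cost * (1 - config.owsa_cost_fraction),
                cost * (1 + config.owsa_cost_fraction),
            ),
        ]
        return sensitivity.run_owsa(inputs, ranges, config.thresholds)

    tornado = stage("owsa")(_owsa)
    tables["tornado"] = pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "icer_swing": e.icer_swing,
                **{f"delta_nmb_low_{int(w)}": v for w, v in e.delta_nmb_low.items()},
                **{f"delta_nmb_high_{int(w)}": v for w, v in e.delta_nmb_high.items()},
            }
            for e in tornado
        ]
    )
    report["stages"]["owsa"] = {
        "entries": tables["tornado"].to_dict(orient="records")
    }

    def _psa():
        draws = sensitivity.sample_psa(config.psa)
        summary = sensitivity.summarize_psa(draws, config.thresholds)
        plane = sensitivity.ce_plane_points(draws, config.thresholds)
        return draws, summary, plane

    draws, psa_summary, plane = stage("psa")(_psa)
    tables["psa_draws"] = pd.DataFrame({"qaly": draws.qaly, "cost": draws.cost})
    tables["ceac"] = pd.DataFrame(psa_summary.ceac, columns=["wtp", "prob_cost_effective"])
    report["stages"]["psa"] = {
        "seed": config.psa.seed,
        "n_sims": config.psa.n_sims,
        "n_excluded": psa_summary.n_excluded,
        "icer": psa_summary.icer,
        "nmb": {str(int(w)): s for w, s in psa_summary.nmb.items()},
        "ceac": [list(p) for p in psa_summary.ceac],
        "ce_plane": {
            "quadrants": plane.quadrants,
            "below_or_on_ray": {str(int(w)): c for w, c in plane.below_or_on_ray.items()},
        },
    }

    def _clinical():
        markers = clinical.summarize_markers(cohort.clinical_prepost)
        ordinal = clinical.ordinal_wilcoxon(
            cohort.steatosis_prepost["pre"], cohort.steatosis_prepost["post"]
        )
        k = int(cohort.activity_flags["maintained"].sum())
        n = int(len(cohort.activity_flags))
        activity = clinical.wilson_interval(k, n)
        deltas = (
            cohort.steatosis_prepost["post"] - cohort.steatosis_prepost["pre"]
        ).to_numpy(dtype=float)
        if deltas.any():
            power = clinical.posthoc_power_wilcoxon(
                deltas, n_sims=1_000, seed=config.psa.seed
            )
        else:
            power = None
        return markers, ordinal, activity, power

    markers, ordinal, activity, power = stage("clinical_stats")(_clinical)
    tables["clinical_markers"] = markers
    report["stages"]["clinical_stats"] = {
        "markers": markers.to_dict(orient="records"),
        "steatosis": {
            "p_value": ordinal.p_value,
            "pre_median": ordinal.pre_median,
            "pre_iqr": list(ordinal.pre_iqr),
            "post_median": ordinal.post_median,
            "post_iqr": list(ordinal.post_iqr),
            "n": ordinal.n,
        },
        "activity": activity.__dict__,
        "posthoc_power": None if power is None else {
            "power": power.power,
            "alpha": power.alpha,
            "n_sims": power.n_sims,
        },
    }

    def _pharma():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = pharma.filter_consecutive_years(cohort.expenditures)
            roster = cohort.expenditures[["patient_id", "year"]].drop_duplicates()
            years = pharma.summarize_years(records, roster)
            top5 = pharma.top_k_classes(records, k=5)
            totals = pharma.patient_year_totals(records, roster)
            trend = pharma.trend_mixed_model(totals)
            try:
                anova = pharma.trend_rm_anova(totals)
            except Exception:
                anova = None
        return years, top5, trend, anova

    years, top5, trend, anova = stage("pharma")(_pharma)
    tables["year_summary"] = pharma.year_summary_frame(years)
    report["stages"]["pharma"] = {
        "year_summary": tables["year_summary"].to_dict(orient="records"),
        "top_classes": top5,
        "trend": trend.__dict__,
        "rm_anova": None if anova is None else anova.__dict__,
    }

    # all stages succeeded: write the bundle
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "results.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
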