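"""End-to-end orchestration: generate, measure, cost, model, PSA, report.

One call to :func:`run_pipeline` executes the whole analysis under a
single seed and writes a reproducible report bundle of TSV/CSV/JSON
files. The stages are usable independently; this module only wires
them together and owns the file formats.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import costing, effectiveness as eff, markov, psa as psa_mod
from .config import RunConfig, validate_config
from .states import HealthState, STATE_INDEX, STATE_ORDER
from .synthetic_data import PatientRegistry, generate_paired_cohort

logger = logging.getLogger("pucea")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage substream: one global seed, stage-name-hashed offset."""
    offset = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, offset]))


@dataclass
class ModelResult:
    """Deterministic base-case model outputs."""

    control_trace: markov.CohortTrace
    intervention_traces: dict[str, markov.CohortTrace]
    control_qalys: float
    control_cost: float
    intervention_values: dict[str, tuple[float, float]]  # (qalys, cost)
    deltas: dict[str, tuple[float, float]]  # (delta_cost, delta_qaly)
    icers: dict[str, float | str]
    matrices: dict[str, markov.TransitionMatrix]


def initial_occupancy(config: RunConfig) -> np.ndarray:
    counts = config.cohort.baseline_state_counts
    occ = np.zeros(len(STATE_ORDER))
    for state, count in counts.items():
        occ[STATE_INDEX[state]] = count
    return occ / occ.sum()


def _registries(
    config: RunConfig, seed: int
) -> tuple[PatientRegistry, PatientRegistry]:
    if config.registry_baseline_path or config.registry_final_path:
        for name in ("registry_baseline_path", "registry_final_path"):
            path = getattr(config, name)
            if path is None or not Path(path).exists():
                raise PipelineError(
                    f"stage synthetic_data: registry file not found: {path}"
                )
        return (
            PatientRegistry.from_csv(config.registry_baseline_path),
            PatientRegistry.from_csv(config.registry_final_path),
        )
    rng = stage_rng(seed, "synthetic_data")
    return generate_paired_cohort(config.cohort, config.intervention_effect, rng)


def build_model(
    config: RunConfig,
    baseline: PatientRegistry,
    final: PatientRegistry,
    costs_standard: costing.CostProfile,
    costs_qic: costing.CostProfile,
    utilities: markov.UtilityProfile | None = None,
) -> ModelResult:
    """Estimate matrices, run both arms per scenario, value the traces."""
    utilities = utilities or config.utilities
    year_cycles = 12
    n_years = config.years

    control_monthly = markov.estimate_monthly_matrix_control(
        baseline,
        config.cohort.healing_prob_90d_by_grade,
        config.cohort.grade_mix,
        denominator=config.cohort.n_patients,
    )
    annual = markov.estimate_annual_matrix_intervention(baseline, final)
    intervention_monthly = markov.annual_to_monthly(annual)

    mort = config.annual_mortality
    control_mort = markov.add_mortality(control_monthly, mort)
    init = initial_occupancy(config)

    # Year 1 runs the observed dynamics without the death overlay (both
    # arms identically); mortality enters with the extrapolation year.
    control_schedule = [(control_monthly, year_cycles), (control_mort, (n_years - 1) * year_cycles)]
    control_trace = markov.run_cohort(init, control_schedule)

    matrices: dict[str, markov.TransitionMatrix] = {
        "control_monthly": control_monthly,
        "intervention_annual": annual,
        "intervention_monthly": intervention_monthly,
    }
    intervention_traces: dict[str, markov.CohortTrace] = {}
    for name in config.scenarios:
        spec = markov.ScenarioSpec(name)
        year2 = markov.scenario_matrix(spec, intervention_monthly, annual, init)
        year2_mort = markov.add_mortality(year2, mort)
        matrices[f"scenario_{name}_monthly"] = year2_mort
        schedule = [
            (intervention_monthly, year_cycles),
            (year2_mort, (n_years - 1) * year_cycles),
        ]
        intervention_traces[name] = markov.run_cohort(init, schedule)

    control_qalys, control_cost = markov.accumulate(
        control_trace, utilities, costs_standard, config.discount
    )
    intervention_values = {}
    deltas = {}
    icers = {}
    for name, trace in intervention_traces.items():
        q, c = markov.accumulate(
            trace,
            utilities,
            costs_qic,
            config.discount,
            overhead_years=1.0,
            overhead_timing=config.overhead_timing,
        )
        intervention_values[name] = (q, c)
        dc, dq = c - control_cost, q - control_qalys
        deltas[name] = (dc, dq)
        icers[name] = markov.icer(dc, dq)

    return ModelResult(
        control_trace=control_trace,
        intervention_traces=intervention_traces,
        control_qalys=control_qalys,
        control_cost=control_cost,
        intervention_values=intervention_values,
        deltas=deltas,
        icers=icers,
        matrices=matrices,
    )


def psa_model_runner(config: RunConfig, result: ModelResult):
    """Closure revaluing the fixed traces under perturbed inputs.

    Transition matrices (hence traces) are held fixed unless
    ``config.psa.perturb_transitions`` is set, in which case the
    year-1 matrices are Dirichlet-perturbed and the traces re-run.
    """
    control_trace = result.control_trace
    traces = result.intervention_traces
    mort = config.annual_mortality

    def runner(costs_std, costs_qic, utilities, rng):
        if config.psa.perturb_transitions:
            kappa = config.psa.transition_concentration
            ctrl = markov.TransitionMatrix(
                psa_mod.perturb_transition_rows(
                    result.matrices["control_monthly"].probs, kappa, rng
                )
            )
            interv = markov.TransitionMatrix(
                psa_mod.perturb_transition_rows(
                    result.matrices["intervention_monthly"].probs, kappa, rng
                )
            )
            ctrl_mort = markov.add_mortality(ctrl, mort)
            init = initial_occupancy(config)
            c_trace = markov.run_cohort(
                init, [(ctrl, 12), (ctrl_mort, 12 * (config.years - 1))]
            )
            i_traces = {}
            for name in config.scenarios:
                year2 = markov.scenario_matrix(
                    markov.ScenarioSpec(name),
                    interv,
                    result.matrices["intervention_annual"],
                    init,
                )
                i_traces[name] = markov.run_cohort(
                    init,
                    [
                        (interv, 12),
                        (markov.add_mortality(year2, mort), 12 * (config.years - 1)),
                    ],
                )
        else:
            c_trace, i_traces = control_trace, traces

        q0, c0 = markov.accumulate(
            c_trace, utilities, costs_std, config.discount
        )
        out = {}
        for name, trace in i_traces.items():
            q, c = markov.accumulate(
                trace,
                utilities,
                costs_qic,
                config.discount,
                overhead_years=1.0,
                overhead_timing=config.overhead_timing,
            )
            out[name] = (c - c0, q - q0)
        return out

    return runner


def cea_table(result: ModelResult, scenarios: tuple[str, ...]) -> pd.DataFrame:
    """Incremental cost / QALY / ICER table, one column per scenario."""
    rows = {
        "delta_cost_per_person": {
            s: result.deltas[s][0] for s in scenarios
        },
        "delta_qaly_per_person": {
            s: result.deltas[s][1] for s in scenarios
        },
        "icer": {s: result.icers[s] for s in scenarios},
    }
    df = pd.DataFrame(rows).T
    df.index.name = "measure"
    return df[list(scenarios)]


def reference_cea_table(
    reference_increments: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """ICERs recomputed from externally supplied incremental values."""
    rows = []
    for scenario, (dc, dq) in reference_increments.items():
        rows.append(
            {
                "scenario": scenario,
                "delta_cost_per_person": dc,
                "delta_qaly_per_person": dq,
                "icer": markov.icer(dc, dq),
            }
        )
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


@dataclass
class ReportBundle:
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    model: ModelResult | None = None
    psa_result: psa_mod.PSAResult | None = None
    effects: pd.DataFrame | None = None


def run_pipeline(
    config: RunConfig, out_dir: str | Path, seed: int | None = None
) -> ReportBundle:
    """Run every stage and write the report bundle to ``out_dir``.

    Outputs: registries (CSV), an effectiveness table, the per-state
    cost table, transition matrices and cohort traces, the incremental
    cost-effectiveness table (model-based, plus one from the configured
    reference increments), PSA samples/summary/acceptability curve, and
    a run manifest with the config hash and seed. Deterministic: the
    same config and seed produce byte-identical files.
    """
    seed = config.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)

    violations = validate_config(config)
    if violations:
        raise PipelineError(f"stage validate: invalid config: {violations}")

    def record(name: str, path: Path) -> None:
        bundle.files[name] = path

    try:
        baseline, final = _registries(config, seed)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage synthetic_data: {exc}") from exc
    baseline.to_csv(out / "registry_baseline.csv")
    final.to_csv(out / "registry_final.csv")
    record("registry_baseline", out / "registry_baseline.csv")
    record("registry_final", out / "registry_final.csv")

    try:
        before = eff.effect_measures(baseline, config.cohort.n_patients)
        after = eff.effect_measures(final, config.cohort.n_patients)
        effects = eff.effects_table(before, after)
        test = eff.compare_pre_post(
            eff.patient_pu_indicators(baseline),
            eff.patient_pu_indicators(final),
        )
    except Exception as exc:
        raise PipelineError(f"stage effectiveness: {exc}") from exc
    _write_tsv(effects, out / "effects_table.tsv")
    record("effects_table", out / "effects_table.tsv")
    bundle.effects = effects

    try:
        costs_standard, costs_qic = costing.build_cost_profiles(
            {
                k: v
                for k, v in (config.cost_config or {}).items()
                if k != "wages"
            }
        )
        cost_table = costing.cost_profile_table(costs_standard, costs_qic)
    except Exception as exc:
        raise PipelineError(f"stage costing: {exc}") from exc
    _write_tsv(cost_table, out / "cost_profiles.tsv")
    record("cost_profiles", out / "cost_profiles.tsv")

    try:
        model = build_model(config, baseline, final, costs_standard, costs_qic)
    except Exception as exc:
        raise PipelineError(f"stage markov: {exc}") from exc
    bundle.model = model
    for name, matrix in model.matrices.items():
        _write_tsv(matrix.to_frame(), out / f"matrix_{name}.tsv", index=True)
        record(f"matrix_{name}", out / f"matrix_{name}.tsv")
    _write_tsv(model.control_trace.to_frame(), out / "trace_control.tsv")
    record("trace_control", out / "trace_control.tsv")
    for name, trace in model.intervention_traces.items():
        _write_tsv(trace.to_frame(), out / f"trace_intervention_{name}.tsv")
        record(f"trace_intervention_{name}", out / f"trace_intervention_{name}.tsv")
    _write_tsv(
        cea_table(model, config.scenarios), out / "cea_summary.tsv", index=True
    )
    record("cea_summary", out / "cea_summary.tsv")
    if config.reference_increments:
        _write_tsv(
            reference_cea_table(config.reference_increments),
            out / "cea_reference.tsv",
        )
        record("cea_reference", out / "cea_reference.tsv")

    try:
        psa_config = psa_mod.PSAConfig(
            **{**config.psa.__dict__, "seed": seed}
        )
        runner = psa_model_runner(config, model)
        psa_result = psa_mod.run_psa(
            runner,
            costs_standard,
            costs_qic,
            config.utilities,
            psa_config,
        )
    except Exception as exc:
        raise PipelineError(f"stage psa: {exc}") from exc
    bundle.psa_result = psa_result
    _write_tsv(psa_result.samples, out / "psa_samples.tsv")
    record("psa_samples", out / "psa_samples.tsv")
    _write_tsv(psa_result.summary(), out / "psa_summary.tsv")
    record("psa_summary", out / "psa_summary.tsv")
    curves = []
    for scenario in psa_result.scenarios:
        summary = psa_mod.ce_plane_summary(psa_result, scenario=scenario)
        curve = summary["curve"].assign(scenario=scenario)
        curves.append(curve)
    _write_tsv(pd.concat(curves, ignore_index=True), out / "acceptability_curve.tsv")
    record("acceptability_curve", out / "acceptability_curve.tsv")

    try:
        pkg_version = _pkg_version("pucea")
    except Exception:  # not installed (e.g. source checkout)
        pkg_version = "unknown"
    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "package_version": pkg_version,
        "pre_post_test": {
            "statistic": test.statistic,
            "pvalue": test.pvalue,
            "paired": test.paired,
            "degenerate": test.degenerate,
        },
        "files": {k: p.name for k, p in bundle.files.items()},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str),
        encoding="utf-8",
    )
    record("manifest", out / "manifest.json")
    logger.info("pipeline complete: %d files in %s", len(bundle.files), out)
    return bundle
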