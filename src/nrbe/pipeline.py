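"""End-to-end orchestration: counts table in, RBE report out.

For every cell line the pipeline computes, per arm, the plating efficiency
and survival points; fits the LQ model; extracts D10 with a bootstrap SD;
decomposes the mixed beam; and evaluates the pure-neutron RBE with both
estimators. Cell lines are then rolled up into a cohort summary, and a
spectrum-weighted RBE is added when spectrum inputs are present.

A separate "paper-values" mode accepts pre-computed D10 endpoints and
redoes only the decomposition arithmetic, for datasets where raw colony
counts are not available.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .assay import (
    ColonyCountRecord,
    plating_efficiency,
    replicate_survival_fractions,
    survival_fractions,
)
from .lq import DEFAULT_BOOTSTRAP_SEED, d10_uncertainty, dose_at_survival, fit_lq
from .rbe import (
    BeamComposition,
    CohortSummary,
    RBEEstimate,
    contamination_fraction,
    percent_difference,
    rbe_dose_partition,
    rbe_sf_division,
    summarize_cohort,
)
from .spectrum import spectrum_weighted_rbe

__all__ = ["RunConfig", "run_pipeline", "paper_values_report", "write_report"]

logger = logging.getLogger("nrbe")


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``endpoint_survival`` generalizes the D10 endpoint (0.1 = 10% survival
    by default). ``beam`` carries either dose rates or an explicit
    contamination-gamma fraction.
    """

    counts_path: str
    output_dir: str | None = None
    beam: BeamComposition = field(default_factory=BeamComposition)
    endpoint_survival: float = 0.1
    weighting: str = "none"
    clip_sf: bool = False
    drop_unestimable: bool = False
    n_boot: int = 1000
    bootstrap_seed: int = DEFAULT_BOOTSTRAP_SEED
    spectrum_path: str | None = None
    rbe_curve_path: str | None = None
    energy_unit: str = "eV"
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.endpoint_survival < 1:
            raise ValueError("endpoint_survival must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        inputs = raw.get("inputs", {})
        beam_raw = raw.get("beam", {})
        analysis = raw.get("analysis", {})
        boot = raw.get("bootstrap", {})
        return cls(
            counts_path=inputs["counts"],
            spectrum_path=inputs.get("spectrum"),
            rbe_curve_path=inputs.get("rbe_curve"),
            energy_unit=inputs.get("energy_unit", "eV"),
            beam=BeamComposition(
                neutron_dose_rate=beam_raw.get("neutron_dose_rate_gy_h"),
                gamma_dose_rate=beam_raw.get("gamma_dose_rate_gy_h"),
                gamma_fraction_override=beam_raw.get("gamma_fraction_override"),
            ),
            endpoint_survival=analysis.get("endpoint_survival", 0.1),
            weighting=analysis.get("weighting", "none"),
            clip_sf=analysis.get("clip_sf", False),
            drop_unestimable=analysis.get("drop_unestimable", False),
            n_boot=boot.get("n_boot", 1000),
            bootstrap_seed=boot.get("seed", DEFAULT_BOOTSTRAP_SEED),
            output_dir=raw.get("output_dir"),
            seed=raw.get("seed", 0),
            make_plots=raw.get("make_plots", False),
        )

    def digest(self) -> str:
        # fingerprint of everything that affects the numbers; where the
        # outputs land (and whether plots are drawn) is excluded
        payload = {
            k: repr(v)
            for k, v in sorted(vars(self).items())
            if k not in ("output_dir", "make_plots")
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _estimate_dict(est: RBEEstimate) -> dict:
    return {
        "method": est.method,
        "gamma_d10_gy": est.gamma_d10,
        "beam_d10_gy": est.beam_d10,
        "contamination_gamma_dose_gy": est.contamination_gamma_dose,
        "pure_neutron_dose_gy": est.pure_neutron_dose,
        "rbe_beam": est.rbe_beam,
        "rbe_pure_neutron": est.rbe_pure_neutron,
    }


def _analyze_cell_line(
    line: str,
    records: Sequence[ColonyCountRecord],
    f: float,
    config: RunConfig,
) -> tuple[dict, RBEEstimate, RBEEstimate, dict]:
    result: dict = {}
    points_by_arm: dict = {}
    arm_fit = {}
    arm_d10 = {}
    for arm in ("gamma", "neutron_beam"):
        arm_records = [r for r in records if r.arm == arm]
        controls = [r for r in arm_records if r.dose == 0]
        irradiated = [r for r in arm_records if r.dose > 0]
        if not controls or not irradiated:
            raise ValueError(f"arm {arm!r} needs both control and irradiated records")
        pe = plating_efficiency(controls)
        points = survival_fractions(
            irradiated, pe, clip=config.clip_sf, drop_unestimable=config.drop_unestimable
        )
        rep_sfs = replicate_survival_fractions(
            irradiated, pe, drop_unestimable=config.drop_unestimable
        )
        params = fit_lq(points, weighting=config.weighting)
        boot = d10_uncertainty(
            rep_sfs,
            weighting=config.weighting,
            n_boot=config.n_boot,
            seed=config.bootstrap_seed,
            control_pe_ratios=[c.colonies / c.cells_seeded for c in controls],
        )
        endpoint_dose = dose_at_survival(params, config.endpoint_survival)
        points_by_arm[(line, arm)] = points
        arm_fit[arm] = params
        arm_d10[arm] = endpoint_dose
        result[arm] = {
            "plating_efficiency": pe,
            "alpha_gy1": params.alpha,
            "beta_gy2": params.beta,
            "d10_gy": endpoint_dose,
            "d10_sd_gy": boot.sd,
            "points": [
                {"dose_gy": p.dose, "sf": p.sf, "sd": p.sd, "n": p.n} for p in points
            ],
        }

    est1 = rbe_dose_partition(arm_d10["gamma"], arm_d10["neutron_beam"], f, cell_line=line)
    est2 = rbe_sf_division(
        points_by_arm[(line, "neutron_beam")],
        arm_fit["gamma"],
        arm_d10["gamma"],
        f,
        weighting=config.weighting,
        cell_line=line,
        endpoint_survival=config.endpoint_survival,
    )
    result["rbe"] = {
        "dose_partition": _estimate_dict(est1),
        "sf_division": _estimate_dict(est2),
        "percent_difference": percent_difference(
            est1.rbe_pure_neutron, est2.rbe_pure_neutron
        ),
    }
    return result, est1, est2, points_by_arm


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``; returns the report.

    Per-line failures are recorded and skipped; the run only fails (raises)
    when no cell line could be analyzed. When ``config.output_dir`` is set
    the report, the Table-2-shaped CSV and the tidy survival table are
    written there.
    """
    records = nio.read_counts_table(config.counts_path)
    f = contamination_fraction(config.beam)
    by_line: dict[str, list[ColonyCountRecord]] = {}
    for rec in records:
        by_line.setdefault(rec.cell_line, []).append(rec)

    report: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "gamma_fraction": f,
        "endpoint_survival": config.endpoint_survival,
        "cell_lines": {},
        "failures": {},
    }
    estimates: list[RBEEstimate] = []
    all_points: dict = {}
    for line in sorted(by_line):
        try:
            result, est1, est2, points_by_arm = _analyze_cell_line(
                line, by_line[line], f, config
            )
        except (ValueError, RuntimeError) as exc:
            logger.error("cell line %s failed: %s", line, exc)
            report["failures"][line] = str(exc)
            continue
        report["cell_lines"][line] = result
        estimates.extend([est1, est2])
        all_points.update(points_by_arm)

    if not report["cell_lines"]:
        raise RuntimeError(f"all cell lines failed: {report['failures']}")

    cohort = summarize_cohort(estimates)
    report["cohort"] = {
        "mean_rbe_by_method": cohort.mean_rbe_by_method,
        "percent_difference_range": list(cohort.percent_difference_range),
        "scatter": cohort.scatter,
    }

    if config.spectrum_path and config.rbe_curve_path:
        spec = nio.read_spectrum(config.spectrum_path, config.energy_unit)
        curve = nio.read_rbe_curve(config.rbe_curve_path, config.energy_unit)
        report["spectrum_weighted_rbe"] = spectrum_weighted_rbe(spec, curve)

    if config.output_dir:
        write_report(report, config.output_dir, points_by_arm=all_points)
        if config.make_plots:
            _write_plots(report, all_points, config.output_dir)
    return report


def paper_values_report(d10_table: pd.DataFrame, gamma_fraction: float) -> dict:
    """Redo the RBE arithmetic from pre-computed D10 endpoints.

    ``d10_table`` needs columns ``cell_line, gamma_d10_gy, beam_d10_gy``
    and optionally ``rbe_sf_division`` (the reported second-method values;
    they cannot be recomputed without survival points). Displayed values
    and the inter-method comparison use 2-decimal rounding, matching the
    precision at which such endpoints are conventionally reported.
    """
    required = {"cell_line", "gamma_d10_gy", "beam_d10_gy"}
    missing = required - set(d10_table.columns)
    if missing:
        raise nio.SchemaError(f"missing columns: {sorted(missing)}")
    has_m2 = "rbe_sf_division" in d10_table.columns

    rows = []
    for _, row in d10_table.iterrows():
        est = rbe_dose_partition(
            float(row["gamma_d10_gy"]),
            float(row["beam_d10_gy"]),
            gamma_fraction,
            cell_line=str(row["cell_line"]),
        )
        entry = {
            "cell_line": est.cell_line,
            "gamma_d10_gy": est.gamma_d10,
            "beam_d10_gy": est.beam_d10,
            "contamination_gamma_dose_gy": round(est.contamination_gamma_dose, 2),
            "pure_neutron_dose_gy": round(est.pure_neutron_dose, 2),
            "rbe_dose_partition": round(est.rbe_pure_neutron, 2),
        }
        if has_m2:
            m2 = round(float(row["rbe_sf_division"]), 2)
            entry["rbe_sf_division"] = m2
            entry["percent_difference"] = percent_difference(
                entry["rbe_dose_partition"], m2
            )
        rows.append(entry)

    report: dict = {"gamma_fraction": gamma_fraction, "cell_lines": rows}
    report["mean_rbe_dose_partition"] = round(
        float(np.mean([r["rbe_dose_partition"] for r in rows])), 2
    )
    if has_m2:
        report["mean_rbe_sf_division"] = round(
            float(np.mean([r["rbe_sf_division"] for r in rows])), 2
        )
        diffs = [r["percent_difference"] for r in rows]
        report["percent_difference_range"] = [min(diffs), max(diffs)]
    return report


def _table_rows(report: dict) -> pd.DataFrame:
    rows = []
    for line, res in sorted(report["cell_lines"].items()):
        e1 = res["rbe"]["dose_partition"]
        e2 = res["rbe"]["sf_division"]
        rows.append(
            {
                "cell_line": line,
                "gamma_d10_gy": round(res["gamma"]["d10_gy"], 2),
                "gamma_d10_sd_gy": round(res["gamma"]["d10_sd_gy"], 2),
                "beam_d10_gy": round(res["neutron_beam"]["d10_gy"], 2),
                "beam_d10_sd_gy": round(res["neutron_beam"]["d10_sd_gy"], 2),
                "contamination_gamma_dose_gy": round(e1["contamination_gamma_dose_gy"], 2),
                "pure_neutron_dose_gy": round(e1["pure_neutron_dose_gy"], 2),
                "rbe_dose_partition": round(e1["rbe_pure_neutron"], 2),
                "rbe_sf_division": round(e2["rbe_pure_neutron"], 2),
                "percent_difference": round(res["rbe"]["percent_difference"], 2),
            }
        )
    return pd.DataFrame(rows)


def write_report(report: dict, output_dir, points_by_arm: dict | None = None) -> None:
    """Write report.json (full precision), report.csv (2-dp display) and
    the tidy survival table; deterministic ordering and formatting so
    reruns are byte-identical."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if report.get("cell_lines") and isinstance(report["cell_lines"], dict):
        _table_rows(report).to_csv(out / "report.csv", index=False, float_format="%.2f")
    if points_by_arm:
        nio.write_survival_table(points_by_arm, out / "survival.csv")


def _write_plots(report: dict, points_by_arm: dict, output_dir) -> None:
    # survival curves per line plus the radiosensitivity-vs-RBE scatter
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    for line, res in report["cell_lines"].items():
        fig, ax = plt.subplots()
        doses = np.linspace(0, 10, 200)
        for arm, color in (("gamma", "tab:blue"), ("neutron_beam", "tab:red")):
            a, b = res[arm]["alpha_gy1"], res[arm]["beta_gy2"]
            ax.plot(doses, np.exp(-a * doses - b * doses**2), color=color, label=arm)
            pts = points_by_arm.get((line, arm), [])
            ax.errorbar(
                [p.dose for p in pts],
                [p.sf for p in pts],
                yerr=[p.sd for p in pts],
                fmt="o",
                color=color,
            )
        ax.set_yscale("log")
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("surviving fraction")
        ax.set_title(line)
        ax.legend()
        fig.savefig(out / f"survival_{line}.png", dpi=150)
        plt.close(fig)

    fig, ax = plt.subplots()
    for method, marker in (("dose_partition", "o"), ("sf_division", "s")):
        pts = report["cohort"]["scatter"][method]
        ax.scatter([g for g, _ in pts], [r for _, r in pts], marker=marker, label=method)
    ax.set_xlabel("gamma D10 (Gy)")
    ax.set_ylabel("pure-neutron RBE")
    ax.legend()
    fig.savefig(out / "rbe_vs_gamma_d10.png", dpi=150)
    plt.close(fig)
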